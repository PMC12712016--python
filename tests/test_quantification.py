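import math

import pytest
from hypothesis import given, settings, strategies as st

from cpnquant import (
    AggregateCounts,
    CountTable,
    areal_distribution,
    homotopic_fraction,
    laterality_index,
    percent_cpn,
    profile,
    round_half_up,
)
from cpnquant.quantification import ZeroTotalError, contra_only_areas


def _counts(ipsi, contra, homotopic=0):
    return AggregateCounts(
        case_id="X", total=ipsi + contra, ipsi=ipsi, contra=contra, homotopic=homotopic
    )


class TestPercentCpn:
    @pytest.mark.parametrize(
        "ipsi,contra,printed",
        [(11804, 4115, 25.8), (33566, 246, 0.7), (2030, 49, 2.4), (10582, 2018, 16.0)],
    )
    def test_reference_cases(self, ipsi, contra, printed):
        assert round_half_up(percent_cpn(_counts(ipsi, contra)), 1) == printed

    def test_no_callosal_labeling_is_zero(self):
        assert percent_cpn(_counts(100, 0)) == 0.0

    def test_zero_total_raises(self):
        with pytest.raises(ZeroTotalError):
            percent_cpn(_counts(0, 0))

    @given(st.integers(0, 10**6), st.integers(0, 10**6))
    def test_complement_sums_to_100_exactly(self, ipsi, contra):
        if ipsi + contra == 0:
            return
        c = _counts(ipsi, contra)
        assert percent_cpn(c) + 100.0 * ipsi / (ipsi + contra) == pytest.approx(100.0, abs=1e-12)


class TestHomotopicFraction:
    @pytest.mark.parametrize(
        "contra,homotopic,printed",
        [(4115, 2374, 57.7), (2079, 1767, 85.0), (49, 3, 6.1)],
    )
    def test_reference_cases(self, contra, homotopic, printed):
        assert round_half_up(homotopic_fraction(_counts(100, contra, homotopic)), 1) == printed

    def test_all_homotopic_is_100(self):
        assert homotopic_fraction(_counts(10, 7, 7)) == 100.0

    def test_zero_contra_is_undefined_not_zero(self):
        assert math.isnan(homotopic_fraction(_counts(100, 0, 0)))


class TestArealDistribution:
    def test_ipsi_already_normalized(self, toy_table):
        assert areal_distribution(toy_table, "ipsi") == {"F2": 30.0, "F6": 50.0, "24": 20.0}

    def test_contra_excludes_homotopic_area(self, toy_table):
        # contra {F7: 40, F6: 30, F2: 30}; dropping homotopic F7 leaves 50/50
        assert areal_distribution(toy_table, "contra") == {"F6": 50.0, "F2": 50.0}

    def test_single_area_is_100(self):
        table = CountTable("X", "F7", {"F2": 13}, {})
        assert areal_distribution(table, "ipsi") == {"F2": 100.0}

    def test_empty_hemisphere_returns_empty(self):
        table = CountTable("X", "F7", {}, {"F7": 5})
        assert areal_distribution(table, "ipsi") == {}
        assert areal_distribution(table, "contra") == {}

    @given(
        st.dictionaries(
            st.sampled_from(["F2", "F6", "24", "F5", "46d"]),
            st.integers(0, 1000),
            min_size=1,
        )
    )
    def test_distribution_sums_to_100(self, counts):
        table = CountTable("X", "F7", counts, dict(counts))
        for hemi in ("ipsi", "contra"):
            dist = areal_distribution(table, hemi)
            if dist:
                assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)


class TestLateralityIndex:
    def test_direct_division(self):
        table = CountTable("X", "F7", {"F2": 200, "F6": 800}, {"F2": 100})
        assert laterality_index(table)["F2"] == pytest.approx(0.5)

    def test_symmetric_labeling_is_one(self):
        table = CountTable("X", "F7", {"F2": 50, "F6": 950}, {"F2": 50})
        assert laterality_index(table)["F2"] == pytest.approx(1.0)

    def test_index_may_exceed_one(self):
        table = CountTable("X", "F7", {"F2": 50, "F6": 950}, {"F2": 240})
        assert laterality_index(table)["F2"] == pytest.approx(4.8)

    def test_exactly_at_filter_is_excluded(self):
        # F2 is exactly 1.0% of ipsilateral labeling: strict filter drops it
        table = CountTable("X", "F7", {"F2": 1, "F6": 99}, {"F2": 1})
        assert "F2" not in laterality_index(table)

    def test_contra_only_areas_reported_separately(self):
        table = CountTable("X", "F7", {"F6": 100}, {"F2": 30, "F7": 4})
        assert laterality_index(table) == {"F6": 0.0}
        assert contra_only_areas(table) == {"F2": 30}

    @settings(max_examples=50)
    @given(
        st.dictionaries(st.sampled_from(["F2", "F6", "24", "F5"]), st.integers(0, 500), min_size=1),
        st.dictionaries(st.sampled_from(["F2", "F6", "24", "F5"]), st.integers(0, 500)),
    )
    def test_matches_brute_force_oracle(self, ipsi, contra):
        table = CountTable("X", "F7", ipsi, contra)
        got = laterality_index(table, min_ipsi_pct=1.0)
        total = sum(ipsi.values())
        expected = {}
        for area, n in ipsi.items():
            if total and n / total * 100 > 1.0:
                expected[area] = contra.get(area, 0) / n
        assert got == pytest.approx(expected)


class TestProfile:
    def test_fixture_entry_30FB(self, fixture_entries):
        entry = next(e for e in fixture_entries if e.case_id == "30FB")
        prof = profile(entry)
        assert round_half_up(prof.pct_cpn, 1) == 6.4
        assert round_half_up(prof.pct_homotopic, 1) == 48.7
        assert prof.laterality == {}  # no per-area detail on fixture entries

    def test_fixture_entry_13TB(self, fixture_entries):
        entry = next(e for e in fixture_entries if e.case_id == "13TB")
        assert round_half_up(profile(entry).pct_cpn, 1) == 2.4

    def test_toy_dataset_full_profile(self, toy_dataset):
        prof = profile(toy_dataset, "TOY")
        assert prof.pct_cpn == pytest.approx(100 * 6 / 16)
        assert prof.pct_homotopic == pytest.approx(100 * 4 / 6)
        assert prof.ipsi_distribution == {"F2": 100.0}
        assert prof.contra_distribution == {"F6": 100.0}
        assert prof.laterality == {"F2": 0.0}


@pytest.mark.parametrize(
    "value,expected",
    [(25.849, 25.8), (25.85, 25.9), (0.05, 0.1), (-0.25, -0.3), (6.1200001, 6.1)],
)
def test_round_half_up_ties_away_from_zero(value, expected):
    assert round_half_up(value, 1) == expected


def test_count_table_rejects_injected_area_in_ipsi():
    with pytest.raises(ValueError, match="excluded"):
        CountTable("X", "F7", {"F7": 3}, {})
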