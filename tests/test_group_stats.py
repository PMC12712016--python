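import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpnquant import bh_adjust, nb_rate_regression, pearson, region_summary
from cpnquant.group_stats import regression_groups


def brute_force_bh(p):
    """Step-up adjustment computed literally from its definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def brute_force_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestPearson:
    def test_identity_vector_is_perfectly_correlated(self):
        res = pearson([1.0, 2.0, 5.0, 7.0], [1.0, 2.0, 5.0, 7.0])
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [3.0, 4.0])

    @settings(max_examples=50)
    @given(
        st.lists(
            st.integers(-10000, 10000).map(lambda v: v / 100), min_size=4, max_size=30
        ).filter(lambda v: len(set(v)) > 1),
        st.randoms(use_true_random=False),
    )
    def test_matches_covariance_formula(self, x, rng):
        y = [v + rng.uniform(-10, 10) for v in x]
        if len(set(y)) < 2:
            return
        res = pearson(x, y)
        assert res.r == pytest.approx(brute_force_pearson(x, y), abs=1e-12)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_hand_computed_step_up(self):
        # ranks 1..3: 0.01*3/1, 0.02*3/2, 0.03*3/3 -> step-up min gives 0.03 each
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_preserves_ordering(self):
        p = [0.04, 0.001, 0.3, 0.01]
        adj = bh_adjust(p)
        assert list(np.argsort(adj)) == list(np.argsort(p))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=5))
    def test_matches_brute_force_on_all_permutations(self, p):
        for perm in itertools.permutations(p):
            assert bh_adjust(list(perm)) == pytest.approx(brute_force_bh(perm), abs=1e-12)


class TestNBRegression:
    def _simulated(self, seed=0, rr=0.5, n=12, alpha=0.3, mean_rate=0.15):
        rng = np.random.default_rng(seed)
        totals = rng.integers(3000, 40000, size=2 * n)
        group = np.array(["A"] * n + ["B"] * n, dtype=object)
        rate = np.where(group == "A", mean_rate, mean_rate * rr)
        mu = totals * rate
        if alpha > 0:
            lam = rng.gamma(1 / alpha, alpha * mu)
        else:
            lam = mu
        counts = rng.poisson(lam)
        return counts, totals, group

    def test_identical_groups_give_unit_ratio(self):
        counts = np.array([10, 20, 30, 10, 20, 30])
        totals = np.array([100, 200, 300, 100, 200, 300])
        group = np.array(["A", "A", "A", "B", "B", "B"], dtype=object)
        res = nb_rate_regression(counts, totals, group)
        assert res.rate_ratios["B_vs_A"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_dispersion_equals_poisson_glm(self):
        import statsmodels.api as sm

        counts, totals, group = self._simulated(seed=3)
        res = nb_rate_regression(counts, totals, group, dispersion=0)
        design = np.column_stack([np.ones_like(totals), (group == "B").astype(float)])
        pois = sm.Poisson(counts, design, offset=np.log(totals)).fit(disp=0)
        assert res.rate_ratios["B_vs_A"] == pytest.approx(math.exp(pois.params[1]), abs=1e-6)
        near_zero = nb_rate_regression(counts, totals, group, dispersion=1e-10)
        assert near_zero.rate_ratios["B_vs_A"] == pytest.approx(
            res.rate_ratios["B_vs_A"], abs=1e-6
        )

    def test_label_exchange_inverts_ratios(self):
        counts, totals, group = self._simulated(seed=5)
        fwd = nb_rate_regression(counts, totals, group)
        # within one fit, RR(B vs A) and RR(A vs B) are exact reciprocals
        delta = fwd.coefficients["B"] - fwd.coefficients["A"]
        assert fwd.rate_ratios["B_vs_A"] * math.exp(-delta) == pytest.approx(1.0, abs=1e-9)
        # refitting with the reference group exchanged inverts the ratio
        order = np.argsort(group != "B", kind="stable")
        rev = nb_rate_regression(counts[order], totals[order], group[order])
        assert fwd.rate_ratios["B_vs_A"] * rev.rate_ratios["A_vs_B"] == pytest.approx(
            1.0, abs=1e-6
        )

    def test_parameter_recovery_over_replicates(self):
        """Median estimated ratio over 200 overdispersed replicates near truth 0.5."""
        estimates = []
        for seed in range(200):
            counts, totals, group = self._simulated(seed=seed, rr=0.5, n=12, alpha=0.3)
            res = nb_rate_regression(counts, totals, group, dispersion=0.3)
            estimates.append(res.rate_ratios["B_vs_A"])
        assert 0.45 <= float(np.median(estimates)) <= 0.55

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            nb_rate_regression([1, 2, 3], [10, 20, 30], ["A", "A", "B"])

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            nb_rate_regression([1, 2, 3, 4], [10, 0, 30, 40], ["A", "A", "B", "B"])


class TestRegionGrouping:
    def test_membership_counts(self, fixture_entries):
        grp = regression_groups(fixture_entries)
        sizes = grp.region.value_counts().to_dict()
        assert sizes == {"parietal": 12, "premotor": 10, "prefrontal": 9}

    def test_f1_and_opercular_excluded(self, fixture_entries):
        grp = regression_groups(fixture_entries)
        assert len(grp) == 31
        excluded = {e.case_id for e in fixture_entries} - set(grp.case_id)
        assert excluded == {"13TB", "62FR", "56FB", "56DY", "42FB"}

    def test_pf_cases_count_as_parietal(self, fixture_entries):
        grp = regression_groups(fixture_entries).set_index("case_id")
        assert grp.loc["29DY", "region"] == "parietal"
        assert grp.loc["27FB", "region"] == "parietal"


class TestRegionSummary:
    def test_single_case_region_collapses(self, fixture_entries):
        one = [e for e in fixture_entries if e.case_id == "30FB"]
        res = region_summary(one, "prefrontal")
        assert res.mean_pct_cpn == res.min_pct_cpn == res.max_pct_cpn
        assert res.n_cases == 1

    def test_empty_region_rejected(self, fixture_entries):
        with pytest.raises(ValueError, match="no cases"):
            region_summary(fixture_entries, "cingulate")

    def test_exclusion_by_area(self, fixture_entries):
        full = region_summary(fixture_entries, "parietal")
        trimmed = region_summary(fixture_entries, "parietal", exclude_areas=("PF",))
        assert full.n_cases == 12 and trimmed.n_cases == 10
        assert trimmed.mean_pct_cpn > full.mean_pct_cpn  # PF cases are the weakest
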