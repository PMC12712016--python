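"""Case-level connectivity statistics.

Four statistics summarize one tracer injection:

* ``percent_cpn`` — callosally projecting neurons (CPNs) as a percentage of
  all labeled neurons, 100·contra/(ipsi+contra), with the injected area
  already excluded from the ipsilateral count.
* ``homotopic_fraction`` — CPNs in the area homotopic to the injected one as
  a percentage of all CPNs, 100·homotopic/contra.
* ``areal_distribution`` — per-area percentage distribution within one
  hemisphere, excluding the injected area ipsilaterally and the homotopic
  area contralaterally.
* ``laterality_index`` — per-area contra/ipsi count ratio, computed only for
  areas whose ipsilateral share (after the injected-area exclusion) exceeds
  1%.  0 means purely ipsilateral labeling, 1 bilateral symmetry, and values
  above 1 mean more contralateral than ipsilateral neurons.

All statistics are kept at full precision internally; report columns round
half-up to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .dataset_io import AggregateCounts, LabelingDataset, aggregate

__all__ = [
    "CountTable",
    "ConnectivityProfile",
    "ZeroTotalError",
    "round_half_up",
    "percent_cpn",
    "homotopic_fraction",
    "areal_distribution",
    "laterality_index",
    "contra_only_areas",
    "profile",
]


class ZeroTotalError(ZeroDivisionError):
    """A percentage was requested for a case with no countable labeling."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed report columns do."""
    if math.isnan(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class CountTable:
    """Per-(hemisphere, area) labeled-neuron counts for one case.

    ``per_area_ipsi`` never contains the injected area (that exclusion is
    applied upstream); ``homotopic_area`` is the area-level label counted as
    homotopic contralaterally.
    """

    case_id: str
    injected_area: str
    per_area_ipsi: dict[str, int]
    per_area_contra: dict[str, int]
    homotopic_area: str = ""

    def __post_init__(self) -> None:
        if not self.homotopic_area:
            self.homotopic_area = self.injected_area
        if self.injected_area in self.per_area_ipsi or self.homotopic_area in self.per_area_ipsi:
            raise ValueError("injected area must be excluded from ipsilateral counts")
        for side in (self.per_area_ipsi, self.per_area_contra):
            if any(v < 0 for v in side.values()):
                raise ValueError("counts must be non-negative")

    @classmethod
    def from_dataset(cls, dataset: LabelingDataset, case_id: str) -> "CountTable":
        case = dataset.case(case_id)
        target = dataset.parcellation.homotopy_target(case.injected_area)
        ipsi: dict[str, int] = {}
        contra: dict[str, int] = {}
        for r in dataset.records_for(case_id):
            if r.hemisphere == "ipsi":
                if r.area in (case.injected_area, target):
                    continue
                ipsi[r.area] = ipsi.get(r.area, 0) + r.count
            else:
                contra[r.area] = contra.get(r.area, 0) + r.count
        return cls(
            case_id=case_id,
            injected_area=case.injected_area,
            per_area_ipsi=ipsi,
            per_area_contra=contra,
            homotopic_area=target,
        )

    def aggregate(self) -> AggregateCounts:
        ipsi = sum(self.per_area_ipsi.values())
        contra = sum(self.per_area_contra.values())
        return AggregateCounts(
            case_id=self.case_id,
            total=ipsi + contra,
            ipsi=ipsi,
            contra=contra,
            homotopic=self.per_area_contra.get(self.homotopic_area, 0),
            injected_area=self.injected_area,
        )


@dataclass
class ConnectivityProfile:
    """Derived statistics of one case.

    ``pct_homotopic`` is NaN when the case has no CPNs: absence of callosal
    labeling is not a 0% homotopic share, it leaves the fraction undefined.
    """

    case_id: str
    pct_cpn: float
    pct_homotopic: float
    ipsi_distribution: dict[str, float] = field(default_factory=dict)
    contra_distribution: dict[str, float] = field(default_factory=dict)
    laterality: dict[str, float] = field(default_factory=dict)


def percent_cpn(counts: AggregateCounts) -> float:
    """CPNs as a percentage of all labeled neurons (full precision)."""
    if counts.total <= 0:
        raise ZeroTotalError(f"case {counts.case_id}: no labeled neurons counted")
    return 100.0 * counts.contra / counts.total


def homotopic_fraction(counts: AggregateCounts) -> float:
    """Homotopic CPNs as a percentage of all CPNs; NaN when contra == 0."""
    if counts.contra == 0:
        return math.nan
    return 100.0 * counts.homotopic / counts.contra


def areal_distribution(table: CountTable, hemisphere: str) -> dict[str, float]:
    """Per-area percentage distribution within one hemisphere.

    Ipsilaterally the injected area is excluded (already absent from the
    table); contralaterally the homotopic area is excluded before
    normalizing, so percentages describe the heterotopic distribution.
    Returns an empty mapping when nothing remains to normalize.
    """
    if hemisphere not in ("ipsi", "contra"):
        raise ValueError("hemisphere must be 'ipsi' or 'contra'")
    if hemisphere == "ipsi":
        counts = dict(table.per_area_ipsi)
    else:
        counts = {a: c for a, c in table.per_area_contra.items() if a != table.homotopic_area}
    total = sum(counts.values())
    if total == 0:
        return {}
    return {a: 100.0 * c / total for a, c in counts.items() if c > 0}


def laterality_index(table: CountTable, min_ipsi_pct: float = 1.0) -> dict[str, float]:
    """Contra/ipsi count ratio per area, for areas above the ipsi-share filter.

    The filter is strict: an area enters the map only when its share of the
    ipsilateral distribution (injected area excluded) is > ``min_ipsi_pct``.
    Areas labeled only contralaterally can never pass; see
    :func:`contra_only_areas` for the side report.
    """
    ipsi_total = sum(table.per_area_ipsi.values())
    if ipsi_total == 0:
        return {}
    out: dict[str, float] = {}
    for area, n_ipsi in table.per_area_ipsi.items():
        if 100.0 * n_ipsi / ipsi_total > min_ipsi_pct:
            out[area] = table.per_area_contra.get(area, 0) / n_ipsi
    return out


def contra_only_areas(table: CountTable) -> dict[str, int]:
    """Heterotopic areas labeled contralaterally but not ipsilaterally.

    These can never enter the laterality map (the ipsi filter fails with a
    zero numerator); they are reported here so no labeling is silently lost.
    """
    return {
        a: c
        for a, c in table.per_area_contra.items()
        if c > 0 and a != table.homotopic_area and table.per_area_ipsi.get(a, 0) == 0
    }


def profile(
    source: LabelingDataset | AggregateCounts | CountTable,
    case_id: str | None = None,
    min_ipsi_pct: float = 1.0,
) -> ConnectivityProfile:
    """Assemble the full per-case profile.

    Accepts a dataset (with ``case_id``), a per-area :class:`CountTable`, or
    a bare :class:`AggregateCounts` fixture entry — in the last case only
    ``pct_cpn`` and ``pct_homotopic`` can be populated.
    """
    if isinstance(source, LabelingDataset):
        if case_id is None:
            raise ValueError("case_id required when profiling a dataset")
        table: CountTable | None = CountTable.from_dataset(source, case_id)
        counts = aggregate(source, case_id)
    elif isinstance(source, CountTable):
        table = source
        counts = source.aggregate()
    else:
        table = None
        counts = source
    prof = ConnectivityProfile(
        case_id=counts.case_id,
        pct_cpn=percent_cpn(counts),
        pct_homotopic=homotopic_fraction(counts),
    )
    if table is not None:
        prof.ipsi_distribution = areal_distribution(table, "ipsi")
        prof.contra_distribution = areal_distribution(table, "contra")
        prof.laterality = laterality_index(table, min_ipsi_pct=min_ipsi_pct)
    return prof
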