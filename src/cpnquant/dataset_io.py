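"""Readers, writers, and validation for tracer-labeling datasets.

Two CSV files describe an experiment: a *cases* file (one row per tracer
deposit — the unit of analysis) and a *records* file (one row per labeled
neuron, or per aggregated group of neurons sharing case, section, hemisphere,
area, and layer).  A bundled fixture carries the per-case aggregate counts
of the reference dataset (36 injections).

Hemisphere is recorded relative to the injection (``ipsi``/``contra``);
layer compartments are ``superficial`` (II–III), ``deep`` (V–VI), or
``unknown``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .parcellation import Parcellation, UnknownAreaError, default_parcellation

__all__ = [
    "InjectionCase",
    "NeuronRecord",
    "AggregateCounts",
    "LabelingDataset",
    "SchemaError",
    "ReferentialError",
    "read_dataset",
    "write_dataset",
    "load_table2_fixture",
    "aggregate",
]

logger = logging.getLogger(__name__)

HEMISPHERES = ("ipsi", "contra")
LAYERS = ("superficial", "deep", "unknown")
TRACERS = ("FB", "DY", "TB", "FR", "CTBg", "other")

CASES_COLUMNS = [
    "case_id",
    "species",
    "sex",
    "age_years",
    "injected_hemisphere",
    "injected_area",
    "tracer",
    "amount_ul",
]
RECORDS_COLUMNS = ["case_id", "section_um", "hemisphere", "area", "layer", "count"]


class SchemaError(ValueError):
    """A file is missing required columns or a value fails its type check."""


class ReferentialError(ValueError):
    """A record references a case or area not present in the dataset."""


@dataclass(frozen=True)
class InjectionCase:
    """One tracer deposit in one area of one hemisphere."""

    case_id: str
    species: str = ""
    sex: str = ""
    age_years: float = math.nan
    injected_hemisphere: str = ""
    injected_area: str = ""
    tracer: str = "other"
    amount_ul: float = math.nan

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        if self.age_years == self.age_years and self.age_years < 0:
            raise ValueError("age_years must be non-negative")


@dataclass(frozen=True)
class NeuronRecord:
    """One retrogradely labeled neuron (or an aggregated group, count > 1)."""

    case_id: str
    section_um: int
    hemisphere: str
    area: str
    layer: str = "unknown"
    count: int = 1

    def __post_init__(self) -> None:
        if self.section_um < 0:
            raise ValueError("section_um must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")


@dataclass(frozen=True)
class AggregateCounts:
    """Per-case labeled-neuron totals.

    ``ipsi`` counts neurons in the injected hemisphere *outside the injected
    area*; ``contra`` counts all neurons in the opposite hemisphere;
    ``homotopic`` counts the contralateral neurons in the area homotopic to
    the injected one.  ``n_excluded_injected`` reports how many ipsilateral
    records fell inside the injected area itself (excluded, never dropped
    silently).
    """

    case_id: str
    total: int
    ipsi: int
    contra: int
    homotopic: int
    injected_area: str = ""
    n_excluded_injected: int = 0

    def __post_init__(self) -> None:
        if self.total != self.ipsi + self.contra:
            raise ValueError(
                f"{self.case_id}: total ({self.total}) != ipsi + contra "
                f"({self.ipsi} + {self.contra})"
            )
        if not 0 <= self.homotopic <= self.contra:
            raise ValueError(f"{self.case_id}: homotopic must lie in [0, contra]")


@dataclass
class LabelingDataset:
    """Validated collection of cases and their per-neuron records."""

    cases: list[InjectionCase]
    records: list[NeuronRecord]
    parcellation: Parcellation = field(default_factory=default_parcellation)

    def __post_init__(self) -> None:
        ids = [c.case_id for c in self.cases]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate case_id in dataset")
        self._case_index = {c.case_id: c for c in self.cases}

    def case(self, case_id: str) -> InjectionCase:
        if case_id not in self._case_index:
            raise KeyError(f"unknown case {case_id!r}")
        return self._case_index[case_id]

    def records_for(self, case_id: str) -> list[NeuronRecord]:
        self.case(case_id)
        return [r for r in self.records if r.case_id == case_id]

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.case_id, r.section_um, r.hemisphere, r.area, r.layer, r.count)
                for r in self.records
            ],
            columns=RECORDS_COLUMNS,
        )


def _require_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} file is missing columns: {', '.join(missing)}")


def read_dataset(
    cases_path: str | Path,
    records_path: str | Path,
    parcellation: Parcellation | None = None,
) -> LabelingDataset:
    """Read and validate a cases/records CSV pair.

    Raises :class:`SchemaError` for missing columns or malformed values,
    :class:`ReferentialError` for records naming unknown cases or areas.
    Error messages carry the 1-based data row numbers of every rejected row.
    """
    parc = parcellation if parcellation is not None else default_parcellation()
    cases_df = pd.read_csv(cases_path, dtype=str, keep_default_na=False)
    _require_columns(cases_df, CASES_COLUMNS, "cases")
    records_df = pd.read_csv(records_path, dtype=str, keep_default_na=False)
    _require_columns(records_df, ["case_id", "section_um", "hemisphere", "area"], "records")

    cases: list[InjectionCase] = []
    problems: list[str] = []
    for i, row in enumerate(cases_df.itertuples(index=False), start=1):
        try:
            parc.resolve(row.injected_area)
            cases.append(
                InjectionCase(
                    case_id=row.case_id,
                    species=row.species,
                    sex=row.sex,
                    age_years=float(row.age_years) if row.age_years else math.nan,
                    injected_hemisphere=row.injected_hemisphere,
                    injected_area=row.injected_area.strip(),
                    tracer=row.tracer if row.tracer in TRACERS else "other",
                    amount_ul=float(row.amount_ul) if row.amount_ul else math.nan,
                )
            )
        except UnknownAreaError as exc:
            problems.append(f"cases row {i}: {exc}")
        except (TypeError, ValueError) as exc:
            problems.append(f"cases row {i}: {exc}")
    if problems:
        raise SchemaError("; ".join(problems))

    known_ids = {c.case_id for c in cases}
    records: list[NeuronRecord] = []
    value_problems: list[str] = []
    ref_problems: list[str] = []
    for i, row in enumerate(records_df.itertuples(index=False), start=1):
        raw = row._asdict()
        if raw["case_id"] not in known_ids:
            ref_problems.append(f"records row {i}: unknown case {raw['case_id']!r}")
            continue
        try:
            parc.resolve(raw["area"])
        except UnknownAreaError as exc:
            ref_problems.append(f"records row {i}: {exc}")
            continue
        try:
            records.append(
                NeuronRecord(
                    case_id=raw["case_id"],
                    section_um=int(raw["section_um"]),
                    hemisphere=raw["hemisphere"],
                    area=raw["area"].strip(),
                    layer=raw.get("layer") or "unknown",
                    count=int(raw.get("count") or 1),
                )
            )
        except (TypeError, ValueError) as exc:
            value_problems.append(f"records row {i}: {exc}")
    if ref_problems:
        raise ReferentialError("; ".join(ref_problems))
    if value_problems:
        raise SchemaError("; ".join(value_problems))
    if not records:
        logger.warning("records file %s contained no data rows", records_path)
    return LabelingDataset(cases=cases, records=records, parcellation=parc)


def write_dataset(dataset: LabelingDataset, cases_path: str | Path, records_path: str | Path) -> None:
    """Write a dataset back to the cases/records CSV dialect (UTF-8, '.')."""
    with open(cases_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CASES_COLUMNS)
        for c in dataset.cases:
            writer.writerow(
                [
                    c.case_id,
                    c.species,
                    c.sex,
                    "" if c.age_years != c.age_years else c.age_years,
                    c.injected_hemisphere,
                    c.injected_area,
                    c.tracer,
                    "" if c.amount_ul != c.amount_ul else c.amount_ul,
                ]
            )
    with open(records_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORDS_COLUMNS)
        for r in dataset.records:
            writer.writerow([r.case_id, r.section_um, r.hemisphere, r.area, r.layer, r.count])


def load_table2_fixture() -> list[AggregateCounts]:
    """The bundled per-case aggregate counts of the reference dataset.

    Returns 36 entries, one per tracer injection, each carrying the injected
    area so region grouping and homotopy resolve against the default
    parcellation.
    """
    ref = resources.files("cpnquant.data").joinpath("table2_counts.csv")
    entries: list[AggregateCounts] = []
    with ref.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                AggregateCounts(
                    case_id=row["case_id"],
                    total=int(row["total"]),
                    ipsi=int(row["ipsi"]),
                    contra=int(row["contra"]),
                    homotopic=int(row["homotopic"]),
                    injected_area=row["injected_area"],
                )
            )
    return entries


def load_table2_printed() -> pd.DataFrame:
    """Fixture counts together with the printed percentage columns.

    The ``pct_contra`` / ``pct_homotopic`` columns are the 1-decimal
    percentages as printed in the reference table; they are presentation
    values, kept for cross-checks, never used in computation.
    """
    ref = resources.files("cpnquant.data").joinpath("table2_counts.csv")
    with ref.open(encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    return frame


def aggregate(dataset: LabelingDataset, case_id: str) -> AggregateCounts:
    """Aggregate a case's records into ipsi/contra/homotopic totals.

    Ipsilateral neurons inside the injected area are excluded from ``ipsi``
    (and from ``total``) and reported via ``n_excluded_injected``; the
    exclusion applies only ipsilaterally — contralaterally the same-named
    area is the homotopic area and is counted.
    """
    case = dataset.case(case_id)
    target = dataset.parcellation.homotopy_target(case.injected_area)
    injected_labels = {case.injected_area, target}
    ipsi = contra = homotopic = excluded = 0
    for r in dataset.records_for(case_id):
        if r.hemisphere == "ipsi":
            if r.area in injected_labels:
                excluded += r.count
            else:
                ipsi += r.count
        else:
            contra += r.count
            if r.area == target:
                homotopic += r.count
    if ipsi + contra == 0:
        logger.warning("case %s has no countable labeling outside the injected area", case_id)
    return AggregateCounts(
        case_id=case_id,
        total=ipsi + contra,
        ipsi=ipsi,
        contra=contra,
        homotopic=homotopic,
        injected_area=case.injected_area,
        n_excluded_injected=excluded,
    )
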