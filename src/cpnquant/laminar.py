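"""Laminar origin of projections: s/d fractions and hierarchical classes.

Retrogradely labeled neurons are assigned to the superficial compartment
(layers II–III) or the deep compartment (layers V–VI).  The superficial
fraction s/(s+d) summarizes the laminar origin of one projection and maps
onto the hierarchical classes of the Felleman–Van Essen model: projections
arising mainly from superficial layers are *feedforward*, mainly from deep
layers *feedback*, and roughly bilaminar ones *lateral*.

The literature defines these classes only qualitatively ("mainly", "more
equally distributed"); the numeric boundaries used here (feedforward at
s-fraction >= 0.70, feedback at <= 0.30, both closed) are a conventional
symmetric criterion and are configurable.  Projections with fewer than
``min_neurons`` layer-assigned neurons are *indeterminate* rather than
classified from noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .dataset_io import LabelingDataset, NeuronRecord

__all__ = [
    "LaminarProfile",
    "superficial_fraction",
    "classify_laminar",
    "laminar_summary",
    "FF_THRESHOLD",
    "FB_THRESHOLD",
    "MIN_NEURONS",
]

FF_THRESHOLD = 0.70
FB_THRESHOLD = 0.30
MIN_NEURONS = 20


@dataclass
class LaminarProfile:
    """Laminar composition of one (source area -> injected area) projection."""

    case_id: str
    source_area: str
    hemisphere: str
    n_superficial: int
    n_deep: int
    n_unknown: int = 0
    klass: str | None = None

    @property
    def n_assigned(self) -> int:
        return self.n_superficial + self.n_deep

    @property
    def s_fraction(self) -> float:
        """Superficial share among layer-assigned neurons; NaN if none."""
        if self.n_assigned == 0:
            return math.nan
        return self.n_superficial / self.n_assigned


def superficial_fraction(
    records: Iterable[NeuronRecord],
    sampling_um: int = 300,
    phase_um: int = 0,
) -> LaminarProfile:
    """Count layers over sections on a regular grid and form the profile.

    Only records whose ``section_um`` is congruent to ``phase_um`` modulo
    ``sampling_um`` are counted — one section in each repeating series, as
    when alternate series are reserved for different stains.  Neurons with
    unknown layer are tallied in ``n_unknown`` and excluded from the
    fraction.  The records must all belong to one (case, hemisphere, area).
    """
    if sampling_um <= 0:
        raise ValueError("sampling_um must be positive")
    records = list(records)
    n_sup = n_deep = n_unk = 0
    case_id = source = hemi = ""
    for r in records:
        if case_id and (r.case_id, r.hemisphere, r.area) != (case_id, hemi, source):
            raise ValueError("records must share one (case, hemisphere, area)")
        case_id, hemi, source = r.case_id, r.hemisphere, r.area
        if r.section_um % sampling_um != phase_um % sampling_um:
            continue
        if r.layer == "superficial":
            n_sup += r.count
        elif r.layer == "deep":
            n_deep += r.count
        else:
            n_unk += r.count
    return LaminarProfile(
        case_id=case_id,
        source_area=source,
        hemisphere=hemi,
        n_superficial=n_sup,
        n_deep=n_deep,
        n_unknown=n_unk,
    )


def classify_laminar(
    profile: LaminarProfile,
    ff_threshold: float = FF_THRESHOLD,
    fb_threshold: float = FB_THRESHOLD,
    min_neurons: int = MIN_NEURONS,
) -> str:
    """Assign the hierarchical class of a projection from its s-fraction.

    Closed thresholds: an s-fraction exactly at ``ff_threshold`` is
    feedforward and exactly at ``fb_threshold`` is feedback.
    """
    if ff_threshold <= fb_threshold:
        raise ValueError("ff_threshold must exceed fb_threshold")
    if profile.n_assigned < min_neurons:
        return "indeterminate"
    s = profile.s_fraction
    if s >= ff_threshold:
        return "feedforward"
    if s <= fb_threshold:
        return "feedback"
    return "lateral"


def laminar_summary(
    dataset: LabelingDataset,
    sampling_um: int = 300,
    phase_um: int = 0,
    ff_threshold: float = FF_THRESHOLD,
    fb_threshold: float = FB_THRESHOLD,
    min_neurons: int = MIN_NEURONS,
) -> pd.DataFrame:
    """Per-connection laminar classes for every case in a dataset.

    One row per (injected area, source area, hemisphere) with at least
    ``min_neurons`` layer-assigned neurons on the sampled sections.
    ``homotopic`` marks the contralateral same-named source;
    ``differs_from_ipsi`` marks contralateral sources whose class differs
    from the determinate class of the same source ipsilaterally.
    """
    rows = []
    for case in dataset.cases:
        target_label = dataset.parcellation.homotopy_target(case.injected_area)
        by_key: dict[tuple[str, str], list[NeuronRecord]] = {}
        for r in dataset.records_for(case.case_id):
            if r.hemisphere == "ipsi" and r.area in (case.injected_area, target_label):
                continue
            by_key.setdefault((r.hemisphere, r.area), []).append(r)
        for (hemi, area), recs in sorted(by_key.items()):
            prof = superficial_fraction(recs, sampling_um=sampling_um, phase_um=phase_um)
            klass = classify_laminar(
                prof, ff_threshold=ff_threshold, fb_threshold=fb_threshold, min_neurons=min_neurons
            )
            rows.append(
                {
                    "case_id": case.case_id,
                    "target_area": case.injected_area,
                    "source_area": area,
                    "hemisphere": hemi,
                    "n_superficial": prof.n_superficial,
                    "n_deep": prof.n_deep,
                    "n_unknown": prof.n_unknown,
                    "s_fraction": prof.s_fraction,
                    "klass": klass,
                    "homotopic": hemi == "contra" and area == target_label,
                    "ff_threshold": ff_threshold,
                    "fb_threshold": fb_threshold,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "case_id",
            "target_area",
            "source_area",
            "hemisphere",
            "n_superficial",
            "n_deep",
            "n_unknown",
            "s_fraction",
            "klass",
            "homotopic",
            "ff_threshold",
            "fb_threshold",
        ],
    )
    frame = frame[frame.n_superficial + frame.n_deep >= min_neurons].reset_index(drop=True)
    ipsi_class = {
        (r.case_id, r.source_area): r.klass
        for r in frame[frame.hemisphere == "ipsi"].itertuples()
        if r.klass != "indeterminate"
    }
    frame["differs_from_ipsi"] = [
        r.hemisphere == "contra"
        and r.klass != "indeterminate"
        and ipsi_class.get((r.case_id, r.source_area), r.klass) != r.klass
        for r in frame.itertuples()
    ]
    return frame
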