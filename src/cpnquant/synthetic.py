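"""Synthetic bilateral labeling datasets with known ground truth.

Raw per-neuron charts for tract-tracing experiments are rarely published,
so every pipeline stage here is exercised against simulated data whose
generative parameters are known exactly.  One simulated case mimics the
structure of a charted retrograde-tracer experiment:

* the case total is negative-binomially distributed across replicates
  (gamma-Poisson mixture, NB2 dispersion ``alpha``), matching the strong
  cross-case overdispersion of real labeling totals;
* the total splits binomially into contralateral (CPNs) vs ipsilateral
  neurons by the true %CPN, and CPNs split binomially into homotopic vs
  heterotopic by the true homotopic share;
* heterotopic and ipsilateral neurons scatter multinomially over areas
  according to configurable weights;
* each neuron falls on one section of a regular grid (uniformly) and is
  superficial with probability given by the per-(hemisphere, area) true
  s-fraction, with a configurable unknown-layer rate.

Records are emitted aggregated per (area, section, layer) via the ``count``
column, which keeps large simulations cheap without changing any analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset_io import AggregateCounts, InjectionCase, LabelingDataset, NeuronRecord
from .parcellation import Parcellation, default_parcellation
from . import dataset_io

__all__ = ["SimulationConfig", "GroundTruth", "simulate_case", "paper_like_suite"]


@dataclass
class SimulationConfig:
    """Generative parameters of one simulated injection case."""

    injected_area: str
    mean_total: float = 20000.0
    pct_cpn_true: float = 12.0
    pct_homotopic_true: float = 45.0
    heterotopic_weights: dict[str, float] = field(default_factory=dict)
    ipsi_weights: dict[str, float] = field(default_factory=dict)
    s_fraction_true: dict[tuple[str, str], float] = field(default_factory=dict)
    default_s_fraction: float = 0.65
    unknown_layer_rate: float = 0.05
    dispersion: float = 0.2
    section_spacing_um: int = 300
    n_sections: int = 100
    seed: int = 0
    case_id: str = "SIM"
    parcellation: Parcellation | None = None

    def validate(self) -> None:
        if not 0 <= self.pct_cpn_true <= 100 or not 0 <= self.pct_homotopic_true <= 100:
            raise ValueError("pct_cpn_true and pct_homotopic_true must lie in [0, 100]")
        if self.mean_total <= 0 or self.dispersion < 0:
            raise ValueError("mean_total must be > 0 and dispersion >= 0")
        if not 0 <= self.unknown_layer_rate < 1:
            raise ValueError("unknown_layer_rate must lie in [0, 1)")
        if self.n_sections < 1 or self.section_spacing_um < 1:
            raise ValueError("need a positive section grid")
        for side, weights in (("ipsi", self.ipsi_weights), ("heterotopic", self.heterotopic_weights)):
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{side} weights must be non-negative")
        if sum(self.ipsi_weights.values()) <= 0:
            raise ValueError("ipsi weights must sum to a positive value")
        if self.pct_cpn_true > 0 and self.pct_homotopic_true < 100:
            if sum(self.heterotopic_weights.values()) <= 0:
                raise ValueError("heterotopic weights required when heterotopic CPNs expected")


@dataclass
class GroundTruth:
    """Config echo plus the expected and realized per-area composition."""

    config: SimulationConfig
    realized_total: int
    realized_contra: int
    realized_homotopic: int
    expected_contra_by_area: dict[str, float]
    expected_ipsi_by_area: dict[str, float]


def _draw_total(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if alpha == 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return int(rng.poisson(lam))


def _scatter(
    rng: np.random.Generator, n: int, weights: dict[str, float]
) -> dict[str, int]:
    areas = sorted(weights)
    w = np.array([weights[a] for a in areas], dtype=float)
    if n == 0 or w.sum() == 0:
        return {}
    counts = rng.multinomial(n, w / w.sum())
    return {a: int(c) for a, c in zip(areas, counts) if c}


def _emit_records(
    rng: np.random.Generator,
    config: SimulationConfig,
    hemisphere: str,
    area_counts: dict[str, int],
) -> list[NeuronRecord]:
    grid = np.arange(config.n_sections) * config.section_spacing_um
    records: list[NeuronRecord] = []
    for area in sorted(area_counts):
        n = area_counts[area]
        s_true = config.s_fraction_true.get((hemisphere, area), config.default_s_fraction)
        per_section = rng.multinomial(n, np.full(config.n_sections, 1.0 / config.n_sections))
        for section, c in zip(grid, per_section):
            if c == 0:
                continue
            n_unknown = rng.binomial(c, config.unknown_layer_rate)
            n_sup = rng.binomial(c - n_unknown, s_true)
            n_deep = c - n_unknown - n_sup
            for layer, k in (("superficial", n_sup), ("deep", n_deep), ("unknown", n_unknown)):
                if k:
                    records.append(
                        NeuronRecord(
                            case_id=config.case_id,
                            section_um=int(section),
                            hemisphere=hemisphere,
                            area=area,
                            layer=layer,
                            count=int(k),
                        )
                    )
    return records


def simulate_case(config: SimulationConfig) -> tuple[LabelingDataset, GroundTruth]:
    """Draw one labeling dataset from the generative model.

    Fully reproducible from ``config.seed``; the returned ground truth
    carries both the expected per-area composition and the realized splits.
    """
    config.validate()
    parc = config.parcellation if config.parcellation is not None else default_parcellation()
    target = parc.homotopy_target(config.injected_area)
    if target in config.heterotopic_weights or config.injected_area in config.ipsi_weights:
        raise ValueError("weights must not include the injected/homotopic area")
    rng = np.random.default_rng(config.seed)

    total = _draw_total(rng, config.mean_total, config.dispersion)
    n_contra = rng.binomial(total, config.pct_cpn_true / 100.0)
    n_ipsi = total - n_contra
    n_homotopic = rng.binomial(n_contra, config.pct_homotopic_true / 100.0)
    contra_counts = _scatter(rng, n_contra - n_homotopic, config.heterotopic_weights)
    if n_homotopic:
        contra_counts[target] = contra_counts.get(target, 0) + n_homotopic
    ipsi_counts = _scatter(rng, n_ipsi, config.ipsi_weights)

    records = _emit_records(rng, config, "contra", contra_counts)
    records += _emit_records(rng, config, "ipsi", ipsi_counts)
    case = InjectionCase(
        case_id=config.case_id,
        species="synthetic",
        injected_hemisphere="R",
        injected_area=config.injected_area,
    )
    dataset = LabelingDataset(cases=[case], records=records, parcellation=parc)

    wsum_c = sum(config.heterotopic_weights.values()) or 1.0
    wsum_i = sum(config.ipsi_weights.values()) or 1.0
    mean_contra = config.mean_total * config.pct_cpn_true / 100.0
    mean_hetero = mean_contra * (1 - config.pct_homotopic_true / 100.0)
    expected_contra = {
        a: mean_hetero * w / wsum_c for a, w in config.heterotopic_weights.items()
    }
    expected_contra[target] = (
        expected_contra.get(target, 0.0) + mean_contra * config.pct_homotopic_true / 100.0
    )
    mean_ipsi = config.mean_total * (1 - config.pct_cpn_true / 100.0)
    expected_ipsi = {a: mean_ipsi * w / wsum_i for a, w in config.ipsi_weights.items()}
    truth = GroundTruth(
        config=config,
        realized_total=int(total),
        realized_contra=int(n_contra),
        realized_homotopic=int(n_homotopic),
        expected_contra_by_area=expected_contra,
        expected_ipsi_by_area=expected_ipsi,
    )
    return dataset, truth


# s-fractions mirroring the qualitative pattern of callosal laminar origins:
# homotopic and within-region projections are predominantly superficial
# (feedforward) except for frontal motor areas, where they are bilaminar
# (lateral); cingulate sources project mainly from deep layers (feedback).
_REGION_S = {
    "prefrontal": 0.80,
    "premotor": 0.50,
    "frontal_opercular": 0.78,
    "parietal": 0.80,
    "F1": 0.50,
    "cingulate": 0.20,
    "other": 0.50,
}


def _suite_config(
    entry: AggregateCounts, parc: Parcellation, seed: int, index: int
) -> SimulationConfig:
    target = parc.homotopy_target(entry.injected_area)
    region = parc.region_of(target)
    same_region = [
        a.name
        for a in parc
        if a.region == region and a.parent is None and a.name not in (target, entry.injected_area)
    ]
    # harmonically decaying weights over same-region areas, plus a rostral
    # cingulate contribution, echo the adjacency-dominated spread of labeling
    ipsi_w = {a: 1.0 / (i + 1) for i, a in enumerate(same_region)}
    ipsi_w["24"] = 0.3
    het_w = dict(ipsi_w)
    s_true: dict[tuple[str, str], float] = {}
    for hemi in ("ipsi", "contra"):
        for a in list(het_w) + [target]:
            s_true[(hemi, a)] = _REGION_S[parc.region_of(a)]
    s_true[("contra", target)] = max(_REGION_S[region], 0.75)  # homotopic: feedforward-leaning
    child_seed = int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))
    pct_cpn = 100.0 * entry.contra / entry.total
    pct_hom = 100.0 * entry.homotopic / entry.contra if entry.contra else 0.0
    return SimulationConfig(
        injected_area=entry.injected_area,
        mean_total=float(entry.total),
        pct_cpn_true=pct_cpn,
        pct_homotopic_true=pct_hom,
        heterotopic_weights=het_w,
        ipsi_weights=ipsi_w,
        s_fraction_true=s_true,
        dispersion=0.2,
        seed=child_seed,
        case_id=entry.case_id,
        parcellation=parc,
    )


def paper_like_suite(seed: int = 0) -> list[tuple[LabelingDataset, GroundTruth]]:
    """Simulate one case per bundled fixture row (36 cases).

    Each simulated case targets the fixture row's printed total, %CPN, and
    homotopic share, so the full pipeline can be exercised end to end at
    realistic scale.  Per-case generators derive from ``(seed, index)`` so
    individual cases are independently reproducible.
    """
    parc = default_parcellation()
    out = []
    for i, entry in enumerate(dataset_io.load_table2_fixture()):
        config = _suite_config(entry, parc, seed, i)
        out.append(simulate_case(config))
    return out
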