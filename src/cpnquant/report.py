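"""Report assembly: per-case tables, percentage series, laterality matrix.

A :class:`ReportBundle` collects the derived products of one analysis run:
a per-case aggregate table with derived percentages (the reference table's
layout), the %CPN / homotopic-share series (bar-chart ready), the case-by-
area laterality matrix with its homotopic mask (heatmap ready), region
summaries, and the group statistics.  Writers emit CSV/JSON with a sidecar
recording every exclusion rule and threshold used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset_io import AggregateCounts, LabelingDataset, aggregate, load_table2_fixture
from .group_stats import table2_statistics
from .quantification import (
    CountTable,
    homotopic_fraction,
    percent_cpn,
    profile,
    round_half_up,
)

__all__ = ["ReportBundle", "build_report", "write_bundle", "render_heatmap"]


@dataclass
class ReportBundle:
    table2_like: pd.DataFrame
    fig2_like: pd.DataFrame
    distributions: pd.DataFrame = field(default_factory=pd.DataFrame)
    laterality: pd.DataFrame = field(default_factory=pd.DataFrame)
    fig7_like: pd.DataFrame = field(default_factory=pd.DataFrame)
    fig7_mask: pd.DataFrame = field(default_factory=pd.DataFrame)
    region_summaries: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def build_report(
    entries: list[AggregateCounts] | None = None,
    dataset: LabelingDataset | None = None,
    min_ipsi_pct: float = 1.0,
    with_stats: bool = True,
) -> ReportBundle:
    """Assemble the report from fixture entries and/or a per-neuron dataset.

    Fixture entries carry no per-area detail, so the laterality matrix is
    only populated when a dataset is given.
    """
    if entries is None and dataset is None:
        entries = load_table2_fixture()
    profiles = {}
    if dataset is not None:
        if entries is None:
            entries = [aggregate(dataset, c.case_id) for c in dataset.cases]
        for c in dataset.cases:
            profiles[c.case_id] = profile(dataset, c.case_id, min_ipsi_pct=min_ipsi_pct)

    rows = []
    for e in entries:
        pct = percent_cpn(e)
        hom = homotopic_fraction(e)
        rows.append(
            {
                "case_id": e.case_id,
                "injected_area": e.injected_area,
                "total": e.total,
                "ipsi": e.ipsi,
                "contra": e.contra,
                "homotopic": e.homotopic,
                "pct_cpn": pct,
                "pct_homotopic": hom,
                "pct_cpn_1dp": round_half_up(pct, 1),
                "pct_homotopic_1dp": round_half_up(hom, 1),
            }
        )
    table2_like = pd.DataFrame(rows)
    fig2_like = table2_like[["case_id", "pct_cpn", "pct_homotopic"]].copy()

    dist_rows = []
    lat_rows = []
    for cid, p in profiles.items():
        for hemi, dist in (("ipsi", p.ipsi_distribution), ("contra", p.contra_distribution)):
            for area, pct in sorted(dist.items()):
                dist_rows.append(
                    {"case_id": cid, "hemisphere": hemi, "area": area,
                     "percent": pct, "percent_1dp": round_half_up(pct, 1)}
                )
        for area, idx in sorted(p.laterality.items()):
            lat_rows.append({"case_id": cid, "area": area, "index": idx})
    distributions = pd.DataFrame(
        dist_rows, columns=["case_id", "hemisphere", "area", "percent", "percent_1dp"]
    )
    laterality = pd.DataFrame(lat_rows, columns=["case_id", "area", "index"])

    fig7_like = pd.DataFrame()
    fig7_mask = pd.DataFrame()
    if profiles:
        areas = sorted({a for p in profiles.values() for a in p.laterality})
        targets = {
            c.case_id: dataset.parcellation.homotopy_target(c.injected_area)
            for c in dataset.cases
        }
        fig7_like = pd.DataFrame(
            [[p.laterality.get(a, np.nan) for a in areas] for p in profiles.values()],
            index=list(profiles),
            columns=areas,
            dtype=float,
        )
        fig7_mask = pd.DataFrame(
            [[targets[cid] == a for a in areas] for cid in profiles],
            index=list(profiles),
            columns=areas,
        )
        fig7_like = fig7_like.mask(fig7_mask)

    stats: dict = {}
    summaries: dict = {}
    if with_stats and len(entries) >= 6:
        raw = table2_statistics(
            entries, dataset.parcellation if dataset is not None else None
        )
        summaries = {k: dataclasses.asdict(v) for k, v in raw["region_summaries"].items()}
        stats = {
            "correlations": [dataclasses.asdict(c) for c in raw["correlations"]],
            "regression": dataclasses.asdict(raw["regression"]),
        }
    params = {
        "package_version": __version__,
        "min_ipsi_pct": min_ipsi_pct,
        "exclusions": {
            "ipsilateral": "injected area excluded from counts and distributions",
            "contralateral": "homotopic area excluded from the heterotopic distribution",
            "laterality_filter": f"areas with ipsilateral share > {min_ipsi_pct}% only",
        },
    }
    return ReportBundle(
        table2_like=table2_like,
        fig2_like=fig2_like,
        distributions=distributions,
        laterality=laterality,
        fig7_like=fig7_like,
        fig7_mask=fig7_mask,
        region_summaries=summaries,
        stats=stats,
        params=params,
    )


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write every report product to ``outdir``; returns the paths written.

    Missing values are empty CSV cells / JSON nulls, never sentinels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(frame: pd.DataFrame, name: str, **kw) -> None:
        path = outdir / name
        frame.to_csv(path, index=kw.pop("index", False), **kw)
        written.append(path)

    _csv(bundle.table2_like, "table2_like.csv")
    _csv(bundle.fig2_like, "fig2_like.csv")
    if not bundle.distributions.empty:
        _csv(bundle.distributions, "distribution.csv")
    if not bundle.laterality.empty:
        _csv(bundle.laterality, "laterality.csv")
    if not bundle.fig7_like.empty:
        _csv(bundle.fig7_like, "fig7_laterality.csv", index=True)
        _csv(bundle.fig7_mask, "fig7_homotopic_mask.csv", index=True)
    payload = {
        "region_summaries": bundle.region_summaries,
        "stats": _jsonable(bundle.stats),
    }
    stats_path = outdir / "stats.json"
    stats_path.write_text(json.dumps(payload, indent=1, allow_nan=False), encoding="utf-8")
    written.append(stats_path)
    params_path = outdir / "params.json"
    params_path.write_text(json.dumps(bundle.params, indent=1), encoding="utf-8")
    written.append(params_path)
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def render_heatmap(
    fig7_like: pd.DataFrame,
    fig7_mask: pd.DataFrame | None = None,
    path: str | Path | None = None,
):
    """Render the case-by-area laterality matrix as a heatmap.

    Homotopic cells (masked) are crossed out; missing cells (areas below the
    ipsilateral filter) are left blank.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.ma.masked_invalid(fig7_like.to_numpy(dtype=float))
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * fig7_like.shape[1]), max(3, 0.3 * fig7_like.shape[0]))
    )
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(fig7_like.shape[1]), fig7_like.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(fig7_like.shape[0]), fig7_like.index, fontsize=6)
    if fig7_mask is not None and not fig7_mask.empty:
        ys, xs = np.nonzero(fig7_mask.to_numpy(dtype=bool))
        ax.scatter(xs, ys, marker="x", color="white", s=30)
    fig.colorbar(im, ax=ax, label="laterality index (contra / ipsi)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
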