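"""Cross-case statistics.

Covers the group-level analyses applied to the per-case aggregates:
Pearson correlations between case statistics, region-wise summaries of the
%CPN, and a negative-binomial (NB2) rate-ratio regression of callosal
counts on region group with the per-case total as exposure, with
Benjamini–Hochberg adjustment over the pairwise contrasts.

The regression models contra_i ~ NB(mu_i, alpha) with
log mu_i = log(total_i) + beta_{group(i)} and NB2 variance mu + alpha*mu^2,
the dispersion alpha estimated by maximum likelihood (counts of this kind
are strongly overdispersed across cases).  Exponentiated group contrasts
are rate ratios: the relative rate of callosal labeling per labeled neuron
between two regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dataset_io import AggregateCounts
from .parcellation import Parcellation, default_parcellation
from .quantification import percent_cpn

__all__ = [
    "CorrelationResult",
    "NBRegressionResult",
    "RegionSummary",
    "pearson",
    "bh_adjust",
    "nb_rate_regression",
    "region_summary",
    "regression_groups",
    "table2_statistics",
]

#: Region classes entering the rate-ratio regression.  Injections in F1 and
#: in frontal opercular areas are excluded; the two PF cases count as
#: parietal.  Overridable per call.
DEFAULT_REGRESSION_REGIONS = ("prefrontal", "premotor", "parietal")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    x_name: str = "x"
    y_name: str = "y"


@dataclass
class NBRegressionResult:
    """Pairwise rate ratios from one NB2 fit.

    ``contrasts`` are ordered ``"A_vs_B"`` labels meaning rate(A)/rate(B);
    ``p_adjusted`` is Benjamini–Hochberg over exactly these contrasts.
    """

    groups: list[str]
    coefficients: dict[str, float]
    rate_ratios: dict[str, float]
    dispersion: float
    p_values: dict[str, float]
    p_adjusted: dict[str, float]
    n: int = 0
    converged: bool = True
    group_sizes: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class RegionSummary:
    region: str
    mean_pct_cpn: float
    min_pct_cpn: float
    max_pct_cpn: float
    n_cases: int


def pearson(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: a vector has zero variance")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size,
                             x_name=x_name, y_name=y_name)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_rate_regression(
    contra_counts,
    totals,
    group,
    dispersion: float | None = None,
) -> NBRegressionResult:
    """Fit counts ~ group with a log(total) exposure offset and NB2 variance.

    ``dispersion=None`` (default) estimates alpha by maximum likelihood;
    ``dispersion=0`` is the Poisson limit; a positive value fixes alpha.
    Returns all pairwise rate ratios with Wald p-values and their BH
    adjustment.
    """
    y = np.asarray(contra_counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    group = np.asarray(group, dtype=object)
    if not (y.shape == totals.shape == group.shape):
        raise ValueError("counts, totals, and group must have equal length")
    if np.any(totals <= 0):
        raise ValueError("totals must be positive (they form the exposure offset)")
    labels = list(dict.fromkeys(group))  # first-appearance order
    sizes = {g: int(np.sum(group == g)) for g in labels}
    if len(labels) < 2 or min(sizes.values()) < 2:
        raise ValueError("need at least two groups with at least two members each")
    offset = np.log(totals)
    design = pd.DataFrame({g: (group == g).astype(float) for g in labels[1:]})
    design.insert(0, "const", 1.0)

    if dispersion is None:
        import warnings

        model = sm.NegativeBinomial(y, design, offset=offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(disp=0, method="newton", maxiter=100, tol=1e-8)
        alpha = float(fit.params["alpha"])
        converged = bool(fit.mle_retvals.get("converged", True))
        # the optimizer can stall on the alpha -> 0 boundary when the data
        # are equidispersed; a near-zero gradient there is a valid optimum
        score_ok = float(np.max(np.abs(fit.mle_retvals.get("score", [np.inf])))) < 1e-4
        if not converged and score_ok and alpha < 1e-4:
            return nb_rate_regression(contra_counts, totals, group, dispersion=0.0)
        converged = converged or score_ok
        params = fit.params.drop("alpha")
        cov = fit.cov_params().drop("alpha", axis=0).drop("alpha", axis=1)
    else:
        if dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        family = (
            sm.families.Poisson()
            if dispersion == 0
            else sm.families.NegativeBinomial(alpha=dispersion)
        )
        fit = sm.GLM(y, design, family=family, offset=offset).fit()
        alpha = float(dispersion)
        params = fit.params
        cov = fit.cov_params()
        converged = True
    if not converged:
        raise RuntimeError(
            "NB regression did not converge; " + str(getattr(fit, "mle_retvals", ""))
        )

    beta = {labels[0]: 0.0}
    beta.update({g: float(params[g]) for g in labels[1:]})

    def contrast_var(a: str, b: str) -> float:
        v = 0.0
        if a != labels[0]:
            v += cov.loc[a, a]
        if b != labels[0]:
            v += cov.loc[b, b]
        if a != labels[0] and b != labels[0]:
            v -= 2 * cov.loc[a, b]
        return v

    rate_ratios: dict[str, float] = {}
    p_values: dict[str, float] = {}
    for a, b in combinations(labels, 2):
        # report the later-listed group relative to the earlier one
        name = f"{b}_vs_{a}"
        delta = beta[b] - beta[a]
        rate_ratios[name] = math.exp(delta)
        se = math.sqrt(contrast_var(b, a))
        z = delta / se if se > 0 else math.inf
        p_values[name] = 2 * sps.norm.sf(abs(z))
    adj = bh_adjust(list(p_values.values()))
    p_adjusted = dict(zip(p_values, adj))
    return NBRegressionResult(
        groups=labels,
        coefficients=beta,
        rate_ratios=rate_ratios,
        dispersion=alpha,
        p_values=p_values,
        p_adjusted=p_adjusted,
        n=int(y.size),
        converged=converged,
        group_sizes=sizes,
    )


def regression_groups(
    entries: list[AggregateCounts],
    parcellation: Parcellation | None = None,
    regions: tuple[str, ...] = DEFAULT_REGRESSION_REGIONS,
) -> pd.DataFrame:
    """Map fixture entries to regression groups by the region of the injected area.

    Returns the subset of cases whose region is in ``regions`` with columns
    case_id, region, contra, total.  With the defaults this excludes F1 and
    frontal opercular injections and keeps PF with the parietal group.
    """
    parc = parcellation if parcellation is not None else default_parcellation()
    rows = []
    for e in entries:
        region = parc.region_of(parc.resolve(e.injected_area))
        if region in regions:
            rows.append((e.case_id, region, e.contra, e.total))
    return pd.DataFrame(rows, columns=["case_id", "region", "contra", "total"])


def region_summary(
    entries: list[AggregateCounts],
    region: str,
    parcellation: Parcellation | None = None,
    exclude_areas: tuple[str, ...] = (),
) -> RegionSummary:
    """Mean/min/max %CPN over the cases injected in one region.

    ``exclude_areas`` drops cases by area-level injected label (e.g. PF when
    summarizing the parietal region without its weakly callosal cases).
    """
    parc = parcellation if parcellation is not None else default_parcellation()
    vals = []
    for e in entries:
        area = parc.resolve(e.injected_area)
        if parc.region_of(area) != region:
            continue
        if parc.homotopy_target(e.injected_area) in exclude_areas:
            continue
        vals.append(percent_cpn(e))
    if not vals:
        raise ValueError(f"no cases injected in region {region!r}")
    return RegionSummary(
        region=region,
        mean_pct_cpn=float(np.mean(vals)),
        min_pct_cpn=float(np.min(vals)),
        max_pct_cpn=float(np.max(vals)),
        n_cases=len(vals),
    )


def table2_statistics(
    entries: list[AggregateCounts],
    parcellation: Parcellation | None = None,
) -> dict:
    """The full group-level analysis of a per-case aggregate table.

    Computes (a) the correlation between total labeling and %CPN, (b) the
    correlation between %CPN and the homotopic fraction over cases with
    CPNs, (c) the NB2 rate-ratio regression over the default region groups,
    and (d) per-region %CPN summaries.  %CPN values are recomputed at full
    precision from the counts, never taken from rounded report columns.
    """
    totals = [e.total for e in entries]
    pct = [percent_cpn(e) for e in entries]
    hom = [100.0 * e.homotopic / e.contra for e in entries if e.contra > 0]
    pct_with_contra = [percent_cpn(e) for e in entries if e.contra > 0]
    corr_total = pearson(totals, pct, "total_labeled", "pct_cpn")
    corr_hom = pearson(pct_with_contra, hom, "pct_cpn", "pct_homotopic")
    grp = regression_groups(entries, parcellation)
    reg = nb_rate_regression(grp.contra, grp.total, grp.region)
    summaries = {
        "premotor": region_summary(entries, "premotor", parcellation),
        "parietal_excl_PF": region_summary(entries, "parietal", parcellation, exclude_areas=("PF",)),
        "prefrontal": region_summary(entries, "prefrontal", parcellation),
    }
    return {
        "correlations": [corr_total, corr_hom],
        "regression": reg,
        "region_summaries": summaries,
    }
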