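"""Sensitivity analyses for two-sample MR estimates.

Heterogeneity among per-SNP causal estimates is the summary-level
footprint of pleiotropy or invalid instruments, so every diagnostic here
interrogates it from a different angle: Cochran's Q (global dispersion of
the Wald ratios around the pooled estimate), leave-one-out re-estimation
(influence of single instruments), MR-PRESSO (simulation-calibrated
residual-sum-of-squares test with per-SNP outlier detection and a
distortion check), and funnel-plot coordinates (asymmetry of ratio versus
precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import MREstimate, ivw, wald_ratio
from .harmonize import HarmonizedSet

__all__ = [
    "HeterogeneityResult",
    "LeaveOneOutRow",
    "LeaveOneOutTable",
    "PressoResult",
    "FunnelData",
    "cochran_q",
    "leave_one_out",
    "mr_presso",
    "funnel_data",
]

FULL_SET_LABEL = "(all SNPs)"


@dataclass
class HeterogeneityResult:
    """Cochran's Q with its chi-square df and upper-tail p."""

    q_stat: float
    df: int
    pval: float


@dataclass
class LeaveOneOutRow:
    omitted: str  # FULL_SET_LABEL marks the all-SNP reference row
    estimate: MREstimate
    influential: bool = False


@dataclass
class LeaveOneOutTable:
    rows: list[LeaveOneOutRow]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def any_influential(self) -> bool:
        return any(r.influential for r in self.rows if r.omitted != FULL_SET_LABEL)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "omitted": [r.omitted for r in self.rows],
                "beta": [r.estimate.beta for r in self.rows],
                "se": [r.estimate.se for r in self.rows],
                "or": [r.estimate.or_ for r in self.rows],
                "ci_low": [r.estimate.ci_low for r in self.rows],
                "ci_high": [r.estimate.ci_high for r in self.rows],
                "pval": [r.estimate.pval for r in self.rows],
                "influential": [r.influential for r in self.rows],
            }
        )


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and (when triggered) distortion results."""

    global_rss_observed: float
    global_pval: float
    per_snp_pvals: dict[str, float]
    outliers: list[str]
    n_sim: int
    seed: int | None
    outlier_significance: float
    distortion_pct: float | None = None
    distortion_pval: float | None = None


@dataclass
class FunnelData:
    """Per-SNP (ratio, precision) coordinates with the pooled reference line."""

    snp_ids: list[str]
    ratios: np.ndarray
    precisions: np.ndarray
    reference: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "ratio": self.ratios,
                "precision": self.precisions,
                "reference": self.reference,
            }
        )


def _first_order_weights(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    beta_x, _, beta_y, se_y = hset.arrays()
    return beta_y / beta_x, (beta_x / se_y) ** 2


def _second_order_weights(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    beta_x, se_x, beta_y, se_y = hset.arrays()
    var = se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4
    return beta_y / beta_x, 1.0 / var


def cochran_q(hset: HarmonizedSet, weights: str = "first_order") -> HeterogeneityResult:
    """Cochran's Q heterogeneity test on the per-SNP Wald ratios.

    Q = sum_j w_j (ratio_j − beta_IVW)² with inverse-variance weights and
    the fixed-effect IVW pooled estimate under the same weights; the p-value
    is the upper tail of chi-square on k−1 df.  ``weights="first_order"``
    (default) matches the IVW weights 1/se_ratio²; ``"second_order"``
    additionally propagates exposure-side sampling error into the ratio
    variance.
    """
    k = len(hset)
    if k < 2:
        raise ValueError(f"Cochran's Q needs at least 2 instruments (k = {k})")
    if weights == "first_order":
        ratios, w = _first_order_weights(hset)
    elif weights == "second_order":
        ratios, w = _second_order_weights(hset)
    else:
        raise ValueError(f"unknown weights variant {weights!r}")
    beta = np.sum(w * ratios) / np.sum(w)
    q_stat = float(np.sum(w * (ratios - beta) ** 2))
    return HeterogeneityResult(
        q_stat=q_stat, df=k - 1, pval=float(sps.chi2.sf(q_stat, k - 1))
    )


def leave_one_out(
    hset: HarmonizedSet, model: str = "multiplicative_random"
) -> LeaveOneOutTable:
    """Re-estimate IVW omitting each instrument in turn.

    The table holds one row per omitted SNP plus the full-set estimate
    (labelled ``(all SNPs)``) appended last.  A row is flagged
    ``influential`` when omitting that SNP moves the point estimate across
    the null (its sign changes) or outside the full-set confidence
    interval.  With k = 2 the omission rows degrade to single-SNP Wald
    ratios (fixed-effect IVW).
    """
    k = len(hset)
    if k < 2:
        raise ValueError(f"leave-one-out needs at least 2 instruments (k = {k})")
    full = ivw(hset, model=model)
    rows: list[LeaveOneOutRow] = []
    for s in hset:
        reduced = hset.without(s.snp_id)
        reduced_model = model if len(reduced) >= 2 else "fixed"
        est = ivw(reduced, model=reduced_model)
        crossed_null = est.beta * full.beta < 0
        influential = crossed_null or not (
            full.ci_low <= est.or_ <= full.ci_high
        )
        rows.append(LeaveOneOutRow(omitted=s.snp_id, estimate=est, influential=influential))
    rows.append(LeaveOneOutRow(omitted=FULL_SET_LABEL, estimate=full, influential=False))
    return LeaveOneOutTable(rows=rows)


def _loo_ivw_betas(beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray) -> np.ndarray:
    """Fixed-effect IVW slope excluding each SNP in turn (vectorized)."""
    w = (beta_x / se_y) ** 2
    num = np.sum(w * beta_y / beta_x)
    den = np.sum(w)
    return (num - w * beta_y / beta_x) / (den - w)


def _presso_rss(
    beta_x: np.ndarray, beta_y: np.ndarray, se_y: np.ndarray
) -> tuple[float, np.ndarray]:
    beta_loo = _loo_ivw_betas(beta_x, beta_y, se_y)
    residuals = (beta_y - beta_loo * beta_x) ** 2 / se_y**2
    return float(np.sum(residuals)), residuals


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 10_000,
    seed: int | None = None,
    outlier_significance: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global pleiotropy test with per-SNP outlier detection.

    The observed statistic is the leave-one-out weighted residual sum of
    squares RSS = sum_j (beta_y_j − b_(−j)·beta_x_j)² / se_y_j², where
    b_(−j) is the fixed-effect IVW slope computed without SNP j.  The null
    distribution comes from ``n_sim`` parametric draws
    beta_x*_j ~ N(beta_x_j, se_x_j), beta_y*_j ~ N(b_(−j)·beta_x_j, se_y_j)
    with the RSS recomputed on each draw; the global p-value is the
    add-one tail proportion (1 + #{RSS* >= RSS_obs}) / (n_sim + 1).

    Per-SNP outlier p-values compare each observed weighted residual to its
    own simulated distribution and are tested against
    ``outlier_significance`` / k (Bonferroni).  When outliers are found, the
    distortion test reports the percent change of the IVW estimate after
    outlier removal, calibrated against removals of random same-size
    subsets.

    Requires k >= 4 so the leave-one-out slopes remain stable.
    """
    k = len(hset)
    if k < 4:
        raise ValueError(f"too few SNPs for MR-PRESSO (k = {k} < 4)")
    beta_x, se_x, beta_y, se_y = hset.arrays()
    rss_obs, resid_obs = _presso_rss(beta_x, beta_y, se_y)
    beta_loo = _loo_ivw_betas(beta_x, beta_y, se_y)

    rng = np.random.default_rng(seed)
    exceed_global = 0
    exceed_snp = np.zeros(k)
    for _ in range(n_sim):
        bx_star = rng.normal(beta_x, se_x)
        by_star = rng.normal(beta_loo * beta_x, se_y)
        bx_star[bx_star == 0.0] = np.finfo(float).tiny
        rss_star, resid_star = _presso_rss(bx_star, by_star, se_y)
        exceed_global += rss_star >= rss_obs
        exceed_snp += resid_star >= resid_obs
    global_pval = (1.0 + exceed_global) / (n_sim + 1.0)
    per_snp = (1.0 + exceed_snp) / (n_sim + 1.0)
    per_snp_pvals = dict(zip(hset.ids, per_snp))
    threshold = outlier_significance / k
    outliers = [snp for snp, p in per_snp_pvals.items() if p < threshold]

    distortion_pct: float | None = None
    distortion_pval: float | None = None
    if outliers and len(outliers) < k - 1:
        full_beta = ivw(hset, model="fixed").beta
        reduced_beta = ivw(hset.without(outliers), model="fixed").beta
        distortion_pct = 100.0 * (reduced_beta - full_beta) / abs(reduced_beta)
        # calibration: distortion from removing random subsets of equal size
        n_out = len(outliers)
        ids = np.array(hset.ids)
        null_distortion = np.empty(min(n_sim, 5000))
        for i in range(len(null_distortion)):
            drop = rng.choice(ids, size=n_out, replace=False)
            b = ivw(hset.without(drop.tolist()), model="fixed").beta
            null_distortion[i] = 100.0 * (b - full_beta) / abs(b) if b != 0 else 0.0
        tail = np.sum(np.abs(null_distortion) >= abs(distortion_pct))
        distortion_pval = float((1.0 + tail) / (len(null_distortion) + 1.0))

    return PressoResult(
        global_rss_observed=rss_obs,
        global_pval=float(global_pval),
        per_snp_pvals={s: float(p) for s, p in per_snp_pvals.items()},
        outliers=outliers,
        n_sim=n_sim,
        seed=seed,
        outlier_significance=outlier_significance,
        distortion_pct=distortion_pct,
        distortion_pval=distortion_pval,
    )


def funnel_data(
    hset: HarmonizedSet, model: str = "multiplicative_random"
) -> FunnelData:
    """Funnel-plot coordinates: per-SNP ratio against precision (1/SE).

    The vertical reference line sits at the pooled IVW estimate (that
    SNP's own ratio when k = 1).  Symmetry of the points about the
    reference is the visual check for directional pleiotropy.
    """
    estimates = [wald_ratio(s) for s in hset]
    ratios = np.array([e.ratio for e in estimates])
    precisions = np.array([1.0 / e.se_ratio for e in estimates])
    if len(hset) == 1:
        reference = float(ratios[0])
    else:
        reference = ivw(hset, model=model).beta
    return FunnelData(
        snp_ids=hset.ids, ratios=ratios, precisions=precisions, reference=reference
    )
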