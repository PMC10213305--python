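"""Causal-effect estimators for two-sample MR on summary statistics.

Each instrument j supplies a Wald ratio beta_y_j / beta_x_j with
first-order standard error se_y_j / |beta_x_j| (sampling error in the
exposure effect is ignored, the standard approximation for strong
instruments).  The estimators pool these ratios:

* **IVW** — inverse-variance-weighted mean of the ratios, algebraically a
  zero-intercept weighted regression of beta_y on beta_x with weights
  1/se_y².  The multiplicative random-effects variant scales the SE by the
  residual dispersion sigma-hat = sqrt(Q/(k−1)), left unconstrained (it may
  shrink the SE when the ratios underdisperse).
* **MR-Egger** — the same weighted regression with a free intercept.  The
  slope is a pleiotropy-robust causal estimate under the InSIDE assumption;
  a non-zero intercept indicates directional pleiotropy.  Requires
  instruments oriented to positive exposure effects, since the intercept is
  not invariant to allele orientation.
* **Weighted median** — the 50% point of the inverse-variance-weighted
  empirical distribution of ratios, consistent when at least half the
  weight comes from valid instruments.  Its SE comes from a parametric
  bootstrap.

Binary outcomes put beta_y on the log-odds scale, so exp(beta) is an odds
ratio per unit of exposure; results carry both scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .harmonize import HarmonizedSet, HarmonizedSnp

__all__ = [
    "RatioEstimate",
    "EggerIntercept",
    "MREstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "Z_95",
]

#: Normal quantile for two-sided 95% intervals.
Z_95 = float(sps.norm.ppf(0.975))


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio with first-order SE and inverse-variance weight."""

    snp_id: str
    ratio: float
    se_ratio: float
    weight: float


@dataclass
class EggerIntercept:
    """MR-Egger intercept block: average directional pleiotropy per SNP."""

    intercept: float
    se_intercept: float
    pval_intercept: float


@dataclass
class MREstimate:
    """A pooled causal estimate with normal-theory CI on the OR scale."""

    method: str
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float
    n_snp: int
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        beta: float,
        se: float,
        n_snp: int,
        df: int | None = None,
        extra: dict | None = None,
    ) -> "MREstimate":
        """Build an estimate, deriving p (normal, or t with ``df``) and the CI."""
        if se <= 0:
            raise ValueError(f"{method}: standard error must be positive, got {se!r}")
        z = beta / se
        if df is None:
            pval = 2.0 * sps.norm.sf(abs(z))
        else:
            pval = 2.0 * sps.t.sf(abs(z), df)
        pval = min(max(pval, np.finfo(float).tiny), 1.0)
        return cls(
            method=method,
            beta=float(beta),
            se=float(se),
            pval=float(pval),
            or_=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z_95 * se)),
            ci_high=float(np.exp(beta + Z_95 * se)),
            n_snp=n_snp,
            extra=extra or {},
        )


def wald_ratio(snp: HarmonizedSnp) -> RatioEstimate:
    """Single-instrument causal estimate beta_y/beta_x with first-order SE."""
    if snp.beta_x == 0:
        raise ValueError(f"null instrument {snp.snp_id}: beta_x = 0")
    ratio = snp.beta_y / snp.beta_x
    se_ratio = snp.se_y / abs(snp.beta_x)
    return RatioEstimate(
        snp_id=snp.snp_id,
        ratio=ratio,
        se_ratio=se_ratio,
        weight=1.0 / se_ratio**2,
    )


def _ratio_arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    estimates = [wald_ratio(s) for s in hset]
    ratios = np.array([e.ratio for e in estimates])
    weights = np.array([e.weight for e in estimates])
    return ratios, weights


def ivw(hset: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted pooled causal estimate.

    ``model="fixed"`` uses the analytic SE (sum of weights)^(-1/2);
    ``model="multiplicative_random"`` (default) multiplies it by the
    residual dispersion sigma-hat = sqrt(Q/(k−1)), unconstrained, and needs
    at least two instruments.  With a single instrument the fixed-effect
    estimate reduces to that SNP's Wald ratio.  The p-value is two-sided
    normal in both models.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = len(hset)
    ratios, weights = _ratio_arrays(hset)
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    se_fixed = float(np.sum(weights) ** -0.5)
    q_stat = float(np.sum(weights * (ratios - beta) ** 2))
    if model == "fixed":
        se = se_fixed
        sigma2 = None
    else:
        if k < 2:
            raise ValueError(
                "multiplicative random-effects IVW needs at least 2 instruments"
            )
        sigma2 = q_stat / (k - 1)
        se = se_fixed * float(np.sqrt(sigma2))
    extra = {"model": model, "q_stat": q_stat, "se_fixed": se_fixed}
    if sigma2 is not None:
        extra["sigma2"] = sigma2
    return MREstimate.from_beta_se("IVW", beta, se, n_snp=k, extra=extra)


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger: weighted regression of beta_y on beta_x with free intercept.

    Weights are 1/se_y².  The residual dispersion sigma-hat² (on k−2
    degrees of freedom, unconstrained) scales both standard errors
    multiplicatively; slope and intercept p-values are two-sided t with
    k−2 df.  The returned estimate's ``extra["intercept"]`` holds the
    :class:`EggerIntercept` block.

    Requires k >= 3 and exposure effects oriented positive (see
    :func:`tsmr.harmonize.orient_positive_exposure`): the intercept changes
    under allele reorientation, so the fit is only well defined for a fixed
    orientation convention.
    """
    k = len(hset)
    if k < 3:
        raise ValueError(f"insufficient instruments for Egger regression (k = {k} < 3)")
    beta_x, _, beta_y, se_y = hset.arrays()
    if np.any(beta_x < 0):
        raise ValueError(
            "egger requires exposure effects oriented positive; "
            "apply orient_positive_exposure first"
        )
    w = 1.0 / se_y**2
    design = np.column_stack([np.ones(k), beta_x])
    xtw = design.T * w
    normal = xtw @ design
    coef = np.linalg.solve(normal, xtw @ beta_y)
    resid = beta_y - design @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = np.linalg.inv(normal) * sigma2
    se_coef = np.sqrt(np.diag(cov))
    intercept_t = coef[0] / se_coef[0]
    intercept = EggerIntercept(
        intercept=float(coef[0]),
        se_intercept=float(se_coef[0]),
        pval_intercept=float(2.0 * sps.t.sf(abs(intercept_t), k - 2)),
    )
    return MREstimate.from_beta_se(
        "MR-Egger",
        float(coef[1]),
        float(se_coef[1]),
        n_snp=k,
        df=k - 2,
        extra={"intercept": intercept, "sigma2": sigma2},
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated 50% point of the weighted empirical ratio distribution.

    Sort ratios ascending; with normalized weights w', the j-th sorted
    ratio sits at cumulative probability s_j = sum_{i<=j} w'_i − w'_j/2;
    the estimate interpolates linearly between the bracketing s_j at 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def weighted_median(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted median estimator with parametric-bootstrap SE.

    The point estimate is deterministic.  Its SE is the standard deviation
    of the estimator over ``n_boot`` resamples drawing each
    (beta_x_j, beta_y_j) from independent normals centred on the observed
    effects with SDs (se_x_j, se_y_j); the p-value is two-sided normal.
    Reproducible bit-for-bit for a fixed ``seed``.
    """
    k = len(hset)
    if k < 3:
        raise ValueError(
            f"insufficient instruments for the weighted median (k = {k} < 3)"
        )
    if n_boot < 100:
        warnings.warn(
            f"n_boot = {n_boot} is small; the bootstrap SE will be noisy",
            stacklevel=2,
        )
    ratios, weights = _ratio_arrays(hset)
    point = _weighted_median_point(ratios, weights)

    beta_x, se_x, beta_y, se_y = hset.arrays()
    rng = np.random.default_rng(seed)
    bx_star = rng.normal(beta_x, se_x, size=(n_boot, k))
    by_star = rng.normal(beta_y, se_y, size=(n_boot, k))
    # guard against pathological resamples crossing zero exposure effect
    bx_star = np.where(bx_star == 0.0, np.finfo(float).tiny, bx_star)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        r_star = by_star[b] / bx_star[b]
        w_star = (bx_star[b] / se_y) ** 2
        boot[b] = _weighted_median_point(r_star, w_star)
    se = float(np.std(boot, ddof=1))
    return MREstimate.from_beta_se(
        "WME",
        point,
        se,
        n_snp=k,
        extra={"n_boot": n_boot, "seed": seed},
    )
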