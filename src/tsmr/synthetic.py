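"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator implements the standard summary-level MR data model: each
instrument j has a true exposure effect gamma_j and a direct (pleiotropic)
outcome effect alpha_j, and the observed associations are

    beta_x_j ~ Normal(gamma_j, se_x_j²)
    beta_y_j ~ Normal(theta·gamma_j + alpha_j, se_y_j²)

for a true causal effect theta.  Pleiotropy can be absent, balanced
(alpha centred at zero) or directional (non-zero mean), optionally
correlated with instrument strength to violate the InSIDE assumption.
Instruments are generated mutually independent (as after LD clumping);
no LD structure or individual-level genotypes are simulated.

Default magnitudes mirror the packaged instrument tables: exposure effects
of a few hundredths of a standard deviation with exposure SEs near 0.006
(a GWAS of ~7e4 individuals) and outcome SEs of 0.03-0.10 (case-control
GWAS of a few thousand cases).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .summary_data import SnpRecord, SummaryStats

__all__ = ["SimConfig", "TruthRecord", "generate", "generate_with_outliers", "se_from_sample_size"]

_PLEIOTROPY_MODES = ("none", "balanced", "directional")

# non-palindromic allele pairs only, so default harmonization keeps all SNPs
_ALLELE_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)


@dataclass
class SimConfig:
    """Parameters of the synthetic two-sample summary-statistic model.

    ``gamma_mean``/``gamma_sd`` describe the magnitude distribution of the
    true SNP-exposure effects (drawn positive by convention);
    ``inside_violation`` is the correlation between gamma_j and alpha_j (0
    preserves InSIDE).  SE ranges are sampled uniformly; ``n_x``/``n_y``
    are nominal GWAS sample sizes recorded in the output tables.
    """

    k: int = 100
    theta: float = 0.0
    gamma_mean: float = 0.06
    gamma_sd: float = 0.03
    pleiotropy: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    inside_violation: float = 0.0
    se_x_range: tuple[float, float] = (0.004, 0.008)
    se_y_range: tuple[float, float] = (0.03, 0.10)
    eaf_range: tuple[float, float] = (0.05, 0.95)
    n_x: float = 72_655.0
    n_y: float = 8_036.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.pleiotropy not in _PLEIOTROPY_MODES:
            raise ValueError(
                f"pleiotropy must be one of {_PLEIOTROPY_MODES}, got {self.pleiotropy!r}"
            )
        for name in ("gamma_sd", "alpha_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.inside_violation <= 1.0:
            raise ValueError(
                f"inside_violation must lie in [-1, 1], got {self.inside_violation}"
            )
        for name in ("se_x_range", "se_y_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got ({lo}, {hi})")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"eaf_range must lie within (0, 1), got ({lo}, {hi})")
        if self.n_x <= 0 or self.n_y <= 0:
            raise ValueError("sample sizes must be positive")


@dataclass
class TruthRecord:
    """Ground truth behind one generated dataset."""

    theta: float
    gamma: np.ndarray
    alpha: np.ndarray
    snp_ids: list[str]
    outlier_ids: tuple[str, ...] = ()
    config: SimConfig | None = None


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def generate(config: SimConfig) -> tuple[SummaryStats, SummaryStats, TruthRecord]:
    """Draw one two-sample dataset; bit-identical for a fixed config + seed."""
    rng = np.random.default_rng(config.seed)
    k = config.k

    gamma = np.abs(rng.normal(config.gamma_mean, config.gamma_sd, size=k))
    gamma = np.maximum(gamma, 1e-6)  # keep instruments non-null

    if config.pleiotropy == "none":
        alpha = np.zeros(k)
    else:
        mean = 0.0 if config.pleiotropy == "balanced" else config.alpha_mean
        rho = config.inside_violation
        eps = rng.normal(size=k)
        if config.gamma_sd > 0 and rho != 0.0:
            z_gamma = (gamma - np.mean(gamma)) / (np.std(gamma) or 1.0)
            shock = rho * z_gamma + np.sqrt(1.0 - rho**2) * eps
        else:
            shock = eps
        alpha = mean + config.alpha_sd * shock

    se_x = rng.uniform(*config.se_x_range, size=k)
    se_y = rng.uniform(*config.se_y_range, size=k)
    eaf = rng.uniform(*config.eaf_range, size=k)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)

    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(config.theta * gamma + alpha, se_y)
    p_x = _two_sided_p(beta_x, se_x)
    p_y = _two_sided_p(beta_y, se_y)

    snp_ids = [f"rs{1_000_001 + j}" for j in range(k)]
    exposure_records = []
    outcome_records = []
    for j, snp in enumerate(snp_ids):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        exposure_records.append(
            SnpRecord(
                snp, ea, oa,
                beta=float(beta_x[j]), se=float(se_x[j]), pval=float(p_x[j]),
                eaf=float(eaf[j]), n=config.n_x,
            )
        )
        outcome_records.append(
            SnpRecord(
                snp, ea, oa,
                beta=float(beta_y[j]), se=float(se_y[j]), pval=float(p_y[j]),
                eaf=float(eaf[j]), n=config.n_y,
            )
        )
    exposure = SummaryStats(
        exposure_records, trait_label="simulated exposure", trait_type="quantitative"
    )
    outcome = SummaryStats(
        outcome_records, trait_label="simulated outcome", trait_type="binary"
    )
    truth = TruthRecord(
        theta=config.theta, gamma=gamma, alpha=alpha, snp_ids=snp_ids, config=config
    )
    return exposure, outcome, truth


def generate_with_outliers(
    config: SimConfig,
    n_outliers: int,
    outlier_shift: float,
) -> tuple[SummaryStats, SummaryStats, TruthRecord]:
    """Like :func:`generate`, with ``n_outliers`` SNPs given an extra direct effect.

    The designated SNPs (chosen by an independent stream derived from the
    seed, so the base draw matches :func:`generate` exactly) have
    ``outlier_shift`` added to their pleiotropic effect alpha and to their
    observed outcome beta; the truth record marks them.  ``n_outliers = 0``
    is identical to :func:`generate`.
    """
    if n_outliers >= config.k:
        raise ValueError(
            f"n_outliers = {n_outliers} must be below k = {config.k}"
        )
    exposure, outcome, truth = generate(config)
    if n_outliers == 0:
        return exposure, outcome, truth

    picker = np.random.default_rng(
        None if config.seed is None else (int(config.seed) + 2**20)
    )
    idx = np.sort(picker.choice(config.k, size=n_outliers, replace=False))
    outlier_ids = tuple(truth.snp_ids[i] for i in idx)

    alpha = truth.alpha.copy()
    alpha[idx] += outlier_shift
    new_outcome_records = []
    for rec in outcome:
        if rec.snp_id in outlier_ids:
            beta = rec.beta + outlier_shift
            pval = float(_two_sided_p(np.array([beta]), np.array([rec.se]))[0])
            rec = replace(rec, beta=beta, pval=pval)
        new_outcome_records.append(rec)
    outcome = SummaryStats(
        new_outcome_records, trait_label=outcome.trait_label, trait_type="binary"
    )
    truth = replace(truth, alpha=alpha, outlier_ids=outlier_ids)
    return exposure, outcome, truth


def se_from_sample_size(n: float, eaf: float, phenotype_sd: float = 1.0) -> float:
    """Approximate GWAS SE of a per-allele effect from n and allele frequency.

    Uses se ≈ SD / sqrt(2·n·EAF·(1−EAF)), the large-sample variance of an
    OLS slope on allele dosage for a quantitative trait.
    """
    if not (0 < eaf < 1):
        raise ValueError(f"eaf must lie in (0, 1), got {eaf}")
    if n <= 0:
        raise ValueError("n must be positive")
    return phenotype_sd / np.sqrt(2.0 * n * eaf * (1.0 - eaf))
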