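"""Instrument selection for two-sample MR and instrument-strength statistics.

The selection pipeline mirrors standard practice for summary-level MR:

1. keep variants associated with the exposure at genome-wide significance
   (p < 5e-8, strict);
2. greedy LD clumping to approximate independence (r² threshold 0.001
   within a 10,000 kb window);
3. drop variants directly associated with the outcome in prior GWAS
   (p < 5e-8), a coarse pleiotropy screen;
4. drop variants associated with user-supplied confounder GWAS tables;
5. for instruments absent from the outcome table, substitute an LD proxy
   with r² above 0.8 when one exists.

Instrument strength is summarized by the variance in the exposure
explained per variant, R² = 2·EAF·(1−EAF)·(beta/SD)², and the F-statistic
F = ((N−k−1)/k) · R²/(1−R²); F > 10 is the conventional guard against
weak-instrument bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .harmonize import Exclusion, HarmonizedSet
from .summary_data import LDReference, SummaryStats

__all__ = [
    "SelectionConfig",
    "InstrumentStrength",
    "filter_significant",
    "clump",
    "screen_outcome_association",
    "screen_confounders",
    "substitute_proxies",
    "instrument_strength",
]


@dataclass
class SelectionConfig:
    """Thresholds governing instrument selection.

    ``missing_ld_policy`` controls unknown r² for pairs inside the clumping
    window: ``"conservative"`` treats them as above the threshold (the pair
    is pruned), ``"permissive"`` as independent.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_r2_floor: float = 0.8
    outcome_gwas_p_threshold: float = 5e-8
    missing_ld_policy: str = "conservative"

    def __post_init__(self) -> None:
        for name in ("p_threshold", "outcome_gwas_p_threshold"):
            value = getattr(self, name)
            if not (0 < value <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {value!r}")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError(f"clump_r2 must lie in [0, 1], got {self.clump_r2!r}")
        if not (0 < self.proxy_r2_floor <= 1):
            raise ValueError(
                f"proxy_r2_floor must lie in (0, 1], got {self.proxy_r2_floor!r}"
            )
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if self.clump_r2 >= self.proxy_r2_floor:
            raise ValueError(
                "clump_r2 must be below proxy_r2_floor "
                f"({self.clump_r2} >= {self.proxy_r2_floor})"
            )
        if self.missing_ld_policy not in ("conservative", "permissive"):
            raise ValueError(
                f"missing_ld_policy must be 'conservative' or 'permissive', "
                f"got {self.missing_ld_policy!r}"
            )


@dataclass
class InstrumentStrength:
    """Variance explained and F-statistic for a set of k instruments."""

    r2_total: float
    f_stat: float
    n: float
    k: int
    per_snp_r2: dict[str, float] = field(default_factory=dict)


def filter_significant(stats: SummaryStats, p_threshold: float = 5e-8) -> SummaryStats:
    """Keep variants with exposure p strictly below ``p_threshold``, in order."""
    return stats.subset(r.snp_id for r in stats if r.pval < p_threshold)


def _within_window(stats, a: str, b: str, window_kb: float, enforce: bool) -> bool:
    if not enforce:
        return True
    ra, rb = stats[a], stats[b]
    if ra.chrom != rb.chrom:
        return False
    return abs(ra.pos - rb.pos) <= window_kb * 1000.0


def clump(
    stats: SummaryStats,
    ld: LDReference,
    config: SelectionConfig | None = None,
    enforce_window: bool | None = None,
) -> SummaryStats:
    """Greedy LD clumping: retain approximately independent index variants.

    Repeatedly takes the remaining variant with the smallest p-value (ties
    broken by genomic position, then id) as an index SNP and prunes every
    other remaining variant within the window whose r² with it exceeds
    ``config.clump_r2``.  Pairs outside the window count as independent;
    unknown r² inside the window follows ``config.missing_ld_policy``.

    ``enforce_window=None`` (default) applies the distance window exactly
    when all records carry coordinates; passing ``True`` without positions
    raises ``ValueError``.  The result is independent of input row order.
    """
    config = config or SelectionConfig()
    have_pos = all(r.pos is not None and r.chrom is not None for r in stats)
    if enforce_window is None:
        enforce_window = have_pos
    elif enforce_window and not have_pos:
        raise ValueError(
            "clump: window enforcement requested but some records lack chrom/pos"
        )

    def order_key(snp_id: str):
        r = stats[snp_id]
        return (r.pval, r.pos if r.pos is not None else float("inf"), r.snp_id)

    remaining = sorted(stats.ids, key=order_key)
    index_snps: list[str] = []
    while remaining:
        head = remaining.pop(0)
        index_snps.append(head)
        survivors = []
        for other in remaining:
            if not _within_window(stats, head, other, config.clump_window_kb, enforce_window):
                survivors.append(other)
                continue
            r2 = ld.r2(head, other)
            if r2 is None:
                prune = config.missing_ld_policy == "conservative"
            else:
                prune = r2 > config.clump_r2
            if not prune:
                survivors.append(other)
        remaining = survivors
    # index SNPs in selection order (not input order)
    return SummaryStats(
        [stats[snp] for snp in index_snps],
        trait_label=stats.trait_label,
        trait_type=stats.trait_type,
    )


def screen_outcome_association(
    stats: SummaryStats,
    outcome: SummaryStats,
    p_threshold: float = 5e-8,
) -> tuple[SummaryStats, list[Exclusion]]:
    """Drop instruments directly associated with the outcome at ``p_threshold``.

    A variant whose prior outcome-GWAS p is strictly below the threshold
    likely acts on the outcome through pathways other than the exposure.
    Variants absent from the outcome table are retained (proxy search runs
    later).
    """
    keep: list[str] = []
    exclusions: list[Exclusion] = []
    for r in stats:
        out_rec = outcome.get(r.snp_id)
        if out_rec is not None and out_rec.pval < p_threshold:
            exclusions.append(
                Exclusion(
                    r.snp_id,
                    "outcome_associated",
                    f"outcome p = {out_rec.pval:.3g} < {p_threshold:g}",
                )
            )
        else:
            keep.append(r.snp_id)
    return stats.subset(keep), exclusions


def screen_confounders(
    stats: SummaryStats,
    confounder_tables: Sequence[SummaryStats],
    p_threshold: float = 5e-8,
) -> tuple[SummaryStats, list[Exclusion]]:
    """Drop instruments associated with any supplied confounder GWAS table.

    Each table's ``trait_label`` names the confounder in the exclusion log.
    An empty table list is the identity.
    """
    keep: list[str] = []
    exclusions: list[Exclusion] = []
    for r in stats:
        hit = None
        for table in confounder_tables:
            rec = table.get(r.snp_id)
            if rec is not None and rec.pval < p_threshold:
                hit = (table.trait_label or "confounder", rec.pval)
                break
        if hit is None:
            keep.append(r.snp_id)
        else:
            exclusions.append(
                Exclusion(
                    r.snp_id,
                    "confounder_associated",
                    f"{hit[0]}: p = {hit[1]:.3g} < {p_threshold:g}",
                )
            )
    return stats.subset(keep), exclusions


def substitute_proxies(
    missing: Iterable[str],
    outcome: SummaryStats,
    ld: LDReference,
    proxy_r2_floor: float = 0.8,
) -> tuple[dict[str, tuple[str, float]], list[str]]:
    """Find LD proxies in the outcome table for absent instruments.

    For each missing variant the outcome-present partner with the highest
    r² at or above ``proxy_r2_floor`` is chosen; ties are broken by smaller
    outcome p-value, then lexicographic id.  Variants with no qualifying
    proxy are returned in the unresolved list (they should be excluded from
    the analysis).
    """
    mapping: dict[str, tuple[str, float]] = {}
    unresolved: list[str] = []
    for snp_id in missing:
        candidates = [
            (partner, r2)
            for partner, r2 in ld.partners(snp_id).items()
            if partner in outcome and r2 >= proxy_r2_floor
        ]
        if not candidates:
            unresolved.append(snp_id)
            continue
        best = min(
            candidates,
            key=lambda item: (-item[1], outcome[item[0]].pval, item[0]),
        )
        mapping[snp_id] = best
    return mapping, unresolved


def instrument_strength(
    hset: HarmonizedSet,
    n: float,
    sd: float = 1.0,
) -> InstrumentStrength:
    """Variance explained and F-statistic for the instrument set.

    Per variant, R² = 2·EAF·(1−EAF)·(beta_x/SD)²; the total is the sum over
    the k instruments (valid because clumped instruments are approximately
    independent).  F = ((N−k−1)/k) · R²/(1−R²) with N the exposure-GWAS
    sample size.  ``sd`` is the phenotypic standard deviation of the
    exposure; the default of 1 assumes standardized betas.
    """
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd!r}")
    k = len(hset)
    if n <= k + 1:
        raise ValueError(f"sample size n = {n} must exceed k + 1 = {k + 1}")
    per_snp: dict[str, float] = {}
    for s in hset:
        if s.eaf is None:
            raise ValueError(f"instrument {s.snp_id} lacks EAF; cannot compute R²")
        per_snp[s.snp_id] = 2.0 * s.eaf * (1.0 - s.eaf) * (s.beta_x / sd) ** 2
    r2_total = sum(per_snp.values())
    if r2_total >= 1:
        raise ValueError(f"total R² = {r2_total:.3f} is not below 1; check sd")
    f_stat = ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))
    return InstrumentStrength(
        r2_total=r2_total, f_stat=f_stat, n=n, k=k, per_snp_r2=per_snp
    )
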