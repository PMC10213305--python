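"""Align exposure and outcome associations onto a shared effect allele.

Two-sample MR estimators consume paired per-SNP effects (beta_x, beta_y)
that refer to the *same* allele.  Harmonization matches each instrument
across the two GWAS tables, sign-flipping the outcome effect when its
alleles are swapped, complementing strands when the allele pair only
matches after A<->T / C<->G substitution, and resolving or discarding
palindromic (A/T, C/G) variants whose strand cannot be inferred from the
alleles alone.  Every exclusion and flip is logged with a reason code so
the selection pipeline remains auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

from .summary_data import SummaryStats, SummaryDataError

__all__ = [
    "HarmonizedSnp",
    "HarmonizedSet",
    "Exclusion",
    "harmonize",
    "orient_positive_exposure",
    "write_exclusion_log",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: EAF band within which a palindromic SNP's strand cannot be inferred.
DEFAULT_AMBIGUITY_BAND = (0.42, 0.58)


@dataclass
class HarmonizedSnp:
    """Paired exposure/outcome effects for one instrument on a common allele."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float | None = None
    flipped: bool = False
    proxy_for: str | None = None

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError(
                f"{self.snp_id}: standard errors must be positive "
                f"(se_x={self.se_x}, se_y={self.se_y})"
            )


@dataclass
class Exclusion:
    """One SNP dropped during harmonization/selection, with a reason code."""

    snp_id: str
    reason: str
    detail: str = ""


class HarmonizedSet:
    """Ordered collection of harmonized instruments for one exposure/outcome pair."""

    def __init__(
        self,
        snps: Iterable[HarmonizedSnp],
        exposure_label: str = "",
        outcome_label: str = "",
    ) -> None:
        self.snps: list[HarmonizedSnp] = list(snps)
        if not self.snps:
            raise ValueError("a HarmonizedSet needs at least one SNP")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp ids in HarmonizedSet")
        self.exposure_label = exposure_label
        self.outcome_label = outcome_label

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[HarmonizedSnp]:
        return iter(self.snps)

    def __getitem__(self, snp_id: str) -> HarmonizedSnp:
        for s in self.snps:
            if s.snp_id == snp_id:
                return s
        raise KeyError(snp_id)

    def __repr__(self) -> str:
        return (
            f"HarmonizedSet({self.exposure_label!r} -> {self.outcome_label!r}, "
            f"{len(self)} SNPs)"
        )

    @property
    def ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_x, se_x, beta_y, se_y) as float arrays in set order."""
        return (
            np.array([s.beta_x for s in self.snps], dtype=float),
            np.array([s.se_x for s in self.snps], dtype=float),
            np.array([s.beta_y for s in self.snps], dtype=float),
            np.array([s.se_y for s in self.snps], dtype=float),
        )

    def without(self, snp_ids: str | Iterable[str]) -> "HarmonizedSet":
        drop = {snp_ids} if isinstance(snp_ids, str) else set(snp_ids)
        return HarmonizedSet(
            (s for s in self.snps if s.snp_id not in drop),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )

    def replaced(self, snps: Iterable[HarmonizedSnp]) -> "HarmonizedSet":
        return HarmonizedSet(
            snps, exposure_label=self.exposure_label, outcome_label=self.outcome_label
        )


def _complemented(allele_pair: tuple[str, str]) -> tuple[str, str]:
    return _COMPLEMENT[allele_pair[0]], _COMPLEMENT[allele_pair[1]]


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "infer_by_eaf",
    ambiguity_band: tuple[float, float] = DEFAULT_AMBIGUITY_BAND,
    proxy_map: Mapping[str, str] | None = None,
) -> tuple[HarmonizedSet, list[Exclusion]]:
    """Pair each instrument's exposure and outcome effects on one allele.

    Only SNPs present in both tables are retained, in exposure order.
    When the outcome lists the alleles swapped, its beta is sign-flipped
    (and EAF complemented) and the record is marked ``flipped``.  When the
    alleles match only after strand complementation, the outcome record is
    complemented first.  Palindromic variants (A/T or C/G) are handled per
    ``palindrome_policy``:

    ``"drop"``
        always excluded (reason ``palindromic``);
    ``"infer_by_eaf"`` (default)
        aligned by comparing allele frequencies across the two tables,
        but excluded (reason ``palindromic_ambiguous``) when either EAF
        falls inside ``ambiguity_band``;
    ``"keep"``
        aligned by allele letters, trusting both GWAS to share a strand.

    ``proxy_map`` (outcome-table id -> original instrument id) stamps the
    ``proxy_for`` audit field for instruments that were substituted by an
    LD proxy upstream.

    Returns the harmonized set and the exclusion log.  Raises
    :class:`SummaryDataError` if the table intersection is empty.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    proxy_map = dict(proxy_map or {})

    shared = [r.snp_id for r in exposure if r.snp_id in outcome]
    if not shared:
        raise SummaryDataError(
            "no shared SNPs between exposure and outcome tables; nothing to harmonize"
        )

    snps: list[HarmonizedSnp] = []
    exclusions: list[Exclusion] = []
    for snp_id in shared:
        x = exposure[snp_id]
        y = outcome[snp_id]
        x_pair = (x.effect_allele, x.other_allele)
        y_pair = (y.effect_allele, y.other_allele)
        y_eaf = y.eaf

        if x.is_palindromic:
            if palindrome_policy == "drop":
                exclusions.append(
                    Exclusion(snp_id, "palindromic", f"alleles {x_pair[0]}/{x_pair[1]}")
                )
                continue
            if set(y_pair) != set(x_pair):
                exclusions.append(
                    Exclusion(
                        snp_id,
                        "allele_mismatch",
                        f"exposure {x_pair}, outcome {y_pair}",
                    )
                )
                continue
            flipped = y_pair != x_pair
            if palindrome_policy == "infer_by_eaf":
                if x.eaf is None or y_eaf is None:
                    exclusions.append(
                        Exclusion(snp_id, "palindromic_no_eaf", "EAF required to infer strand")
                    )
                    continue
                lo, hi = ambiguity_band
                y_eaf_aligned = 1.0 - y_eaf if flipped else y_eaf
                if lo <= x.eaf <= hi or lo <= y_eaf_aligned <= hi:
                    exclusions.append(
                        Exclusion(
                            snp_id,
                            "palindromic_ambiguous",
                            f"EAF {x.eaf:.3f}/{y_eaf_aligned:.3f} in [{lo}, {hi}]",
                        )
                    )
                    continue
                # frequencies on opposite sides of 0.5 imply the outcome is
                # reported on the other strand: flip once more
                if (x.eaf < 0.5) != (y_eaf_aligned < 0.5):
                    flipped = not flipped
        else:
            if y_pair == x_pair:
                flipped = False
            elif y_pair == (x_pair[1], x_pair[0]):
                flipped = True
            else:
                y_comp = _complemented(y_pair)
                if y_comp == x_pair:
                    flipped = False
                elif y_comp == (x_pair[1], x_pair[0]):
                    flipped = True
                else:
                    exclusions.append(
                        Exclusion(
                            snp_id,
                            "allele_mismatch",
                            f"exposure {x_pair}, outcome {y_pair}",
                        )
                    )
                    continue

        beta_y = -y.beta if flipped else y.beta
        snps.append(
            HarmonizedSnp(
                snp_id=snp_id,
                beta_x=x.beta,
                se_x=x.se,
                beta_y=beta_y,
                se_y=y.se,
                eaf=x.eaf,
                flipped=flipped,
                proxy_for=proxy_map.get(snp_id),
            )
        )
        if flipped:
            logger.debug("harmonize: flipped outcome effect for %s", snp_id)

    if not snps:
        raise SummaryDataError(
            "harmonization excluded every shared SNP; see exclusion log"
        )
    hset = HarmonizedSet(
        snps,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
    )
    return hset, exclusions


def orient_positive_exposure(hset: HarmonizedSet) -> HarmonizedSet:
    """Flip instruments so every exposure effect is positive.

    MR-Egger's intercept depends on the orientation of the instruments, so
    the conventional choice is to code each effect allele as the
    exposure-increasing allele.  Both betas of a SNP are sign-flipped
    together (and its EAF complemented), leaving every Wald ratio
    unchanged.  Idempotent.  Instruments with an exactly zero exposure
    effect carry no orientation (and no causal information) and are
    dropped with a warning.
    """
    out: list[HarmonizedSnp] = []
    for s in hset:
        if s.beta_x > 0:
            out.append(s)
        elif s.beta_x < 0:
            out.append(
                replace(
                    s,
                    beta_x=-s.beta_x,
                    beta_y=-s.beta_y,
                    eaf=None if s.eaf is None else 1.0 - s.eaf,
                    flipped=not s.flipped,
                )
            )
        else:
            logger.warning(
                "orient_positive_exposure: dropping null instrument %s (beta_x = 0)",
                s.snp_id,
            )
    if not out:
        raise ValueError("orientation removed every instrument (all beta_x = 0)")
    return hset.replaced(out)


def write_exclusion_log(exclusions: Iterable[Exclusion], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("snp_id\treason\tdetail\n")
        for e in exclusions:
            fh.write(f"{e.snp_id}\t{e.reason}\t{e.detail}\n")
    return path
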