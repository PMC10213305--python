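"""Data model and I/O for GWAS summary statistics and LD reference tables.

The central container is :class:`SummaryStats`, an ordered collection of
per-SNP association records for one trait (alleles, effect-allele frequency,
beta, SE, p-value).  Pairwise linkage disequilibrium is held by
:class:`LDReference`, a symmetric r-squared lookup used for clumping and
proxy substitution.

Two built-in instrument tables are shipped with the package (see
:func:`builtin_fixture`): the cigarettes-per-day instruments paired with
Alzheimer's disease outcome associations for a Chinese case-control cohort
(5 SNPs) and a Japanese cohort (4 SNPs, two of them LD proxies).  They let
every estimator and diagnostic in the package be exercised end to end
without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "SummaryDataError",
    "SnpRecord",
    "SummaryStats",
    "LDReference",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_table",
    "write_ld_table",
    "builtin_fixture",
    "DEFAULT_COLUMNS",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default header names for summary-statistic files, per field.
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "NEA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
    "chrom": "CHR",
    "pos": "POS",
}

_REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


class SummaryDataError(ValueError):
    """Raised for malformed or invalid summary-statistic / LD input."""


@dataclass
class SnpRecord:
    """A single SNP association: alleles, frequency and effect estimate.

    ``beta`` is the per-effect-allele association: a log odds ratio for
    binary traits, trait units for quantitative traits.  ``eaf`` (effect
    allele frequency) is optional; it is needed only for variance-explained
    calculations and palindrome resolution, and operations that require it
    fail explicitly rather than imputing.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def validation_errors(self) -> list[str]:
        """Return human-readable descriptions of every violated invariant."""
        problems: list[str] = []
        if not self.snp_id:
            problems.append("empty snp_id")
        for label, allele in (
            ("effect_allele", self.effect_allele),
            ("other_allele", self.other_allele),
        ):
            if allele not in VALID_ALLELES:
                problems.append(f"{label} {allele!r} is not one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            problems.append(f"effect and other allele are both {self.effect_allele!r}")
        if not math.isfinite(self.beta):
            problems.append(f"beta {self.beta!r} is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            problems.append(f"se {self.se!r} must be a finite positive number")
        if not (math.isfinite(self.pval) and 0 < self.pval <= 1):
            problems.append(f"pval {self.pval!r} must lie in (0, 1]")
        if self.eaf is not None and not (math.isfinite(self.eaf) and 0 < self.eaf < 1):
            problems.append(f"eaf {self.eaf!r} must lie in (0, 1)")
        return problems

    def validate(self) -> "SnpRecord":
        problems = self.validation_errors()
        if problems:
            raise SummaryDataError(
                f"invalid record for {self.snp_id!r}: " + "; ".join(problems)
            )
        return self

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


class SummaryStats:
    """Ordered, uniquely-keyed collection of :class:`SnpRecord` for one trait.

    ``trait_type`` distinguishes quantitative exposures (betas in trait
    units) from binary outcomes (betas on the log-odds scale); estimators
    use it only for labelling, never to rescale.
    """

    def __init__(
        self,
        records: Iterable[SnpRecord],
        trait_label: str = "",
        trait_type: str = "quantitative",
    ) -> None:
        if trait_type not in ("quantitative", "binary"):
            raise SummaryDataError(
                f"trait_type must be 'quantitative' or 'binary', got {trait_type!r}"
            )
        self.trait_label = trait_label
        self.trait_type = trait_type
        self._records: dict[str, SnpRecord] = {}
        duplicates: list[str] = []
        for rec in records:
            if rec.snp_id in self._records:
                duplicates.append(rec.snp_id)
            else:
                self._records[rec.snp_id] = rec
        if duplicates:
            raise SummaryDataError(
                f"duplicate snp_id in {trait_label or 'summary table'}: "
                + ", ".join(sorted(set(duplicates)))
            )

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self._records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._records

    def __getitem__(self, snp_id: str) -> SnpRecord:
        return self._records[snp_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryStats):
            return NotImplemented
        return (
            self.trait_label == other.trait_label
            and self.trait_type == other.trait_type
            and list(self) == list(other)
        )

    def __repr__(self) -> str:
        return (
            f"SummaryStats({self.trait_label!r}, {self.trait_type}, "
            f"{len(self)} SNPs)"
        )

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def get(self, snp_id: str) -> SnpRecord | None:
        return self._records.get(snp_id)

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStats":
        """New table restricted to ``snp_ids``, preserving this table's order."""
        wanted = set(snp_ids)
        return SummaryStats(
            (r for r in self if r.snp_id in wanted),
            trait_label=self.trait_label,
            trait_type=self.trait_type,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = DEFAULT_COLUMNS
        rows = []
        for r in self:
            rows.append(
                {
                    cols["snp_id"]: r.snp_id,
                    cols["effect_allele"]: r.effect_allele,
                    cols["other_allele"]: r.other_allele,
                    cols["eaf"]: r.eaf,
                    cols["beta"]: r.beta,
                    cols["se"]: r.se,
                    cols["pval"]: r.pval,
                    cols["n"]: r.n,
                    cols["chrom"]: r.chrom,
                    cols["pos"]: r.pos,
                }
            )
        frame = pd.DataFrame(rows, columns=list(cols.values()))
        # drop all-missing optional columns so written files stay tidy
        optional = [cols[f] for f in ("eaf", "n", "chrom", "pos")]
        keep = [c for c in frame.columns if c not in optional or frame[c].notna().any()]
        return frame[keep] if len(frame) else frame[[cols[f] for f in _REQUIRED_FIELDS]]


def _sniff_delimiter(header_line: str) -> str:
    """Choose between tab and comma by inspecting the header row."""
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    return r"\s+"


def _parse_float(text: str, what: str, row: int) -> float:
    try:
        return float(text)
    except (TypeError, ValueError):
        raise SummaryDataError(f"row {row}: cannot parse {what} value {text!r}")


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    trait_label: str | None = None,
) -> SummaryStats:
    """Read a delimited summary-statistic file into a validated table.

    Parameters
    ----------
    path:
        TSV or CSV file with a header row (delimiter auto-detected).
    column_map:
        Optional overrides of :data:`DEFAULT_COLUMNS`, keyed by field name
        (``snp_id``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
        ``se``, ``pval``, ``n``, ``chrom``, ``pos``).
    trait_type:
        ``"quantitative"`` or ``"binary"``.
    trait_label:
        Defaults to the file stem.

    Raises
    ------
    SummaryDataError
        If a mapped required column is missing, if any row violates a record
        invariant (the message cites the 1-based file row), or if snp ids
        are duplicated.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise SummaryDataError(
                f"unknown column_map fields: {', '.join(sorted(unknown))}"
            )
        cols.update(column_map)

    with open(path) as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise SummaryDataError(f"{path}: empty file (no header row)")
    sep = _sniff_delimiter(header_line.rstrip("\n"))
    frame = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    frame.columns = [c.strip() for c in frame.columns]

    missing = [cols[f] for f in _REQUIRED_FIELDS if cols[f] not in frame.columns]
    if missing:
        raise SummaryDataError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    records: list[SnpRecord] = []
    problems: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        file_row = i + 2  # 1-based, after the header
        row_map = dict(zip(frame.columns, row))

        def cell(fieldname: str) -> str | None:
            col = cols[fieldname]
            if col not in row_map:
                return None
            value = row_map[col]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            value = str(value).strip()
            return value or None

        try:
            rec = SnpRecord(
                snp_id=str(cell("snp_id") or ""),
                effect_allele=str(cell("effect_allele") or "").upper(),
                other_allele=str(cell("other_allele") or "").upper(),
                beta=_parse_float(cell("beta"), "beta", file_row),
                se=_parse_float(cell("se"), "se", file_row),
                pval=_parse_float(cell("pval"), "p", file_row),
                eaf=(
                    _parse_float(cell("eaf"), "eaf", file_row)
                    if cell("eaf") is not None
                    else None
                ),
                n=(
                    _parse_float(cell("n"), "n", file_row)
                    if cell("n") is not None
                    else None
                ),
                chrom=cell("chrom"),
                pos=int(_parse_float(cell("pos"), "pos", file_row))
                if cell("pos") is not None
                else None,
            )
        except SummaryDataError as exc:
            problems.append(str(exc))
            continue
        row_problems = rec.validation_errors()
        if row_problems:
            problems.append(f"row {file_row} ({rec.snp_id}): " + "; ".join(row_problems))
        else:
            records.append(rec)
    if problems:
        raise SummaryDataError(
            f"{path}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return SummaryStats(
        records,
        trait_label=trait_label if trait_label is not None else path.stem,
        trait_type=trait_type,
    )


def write_summary_stats(stats: SummaryStats, path: str | Path) -> Path:
    """Write a table as TSV in the dialect :func:`read_summary_stats` reads.

    Numeric fields are written with :func:`repr` precision, so a write/read
    round trip reproduces every value bit-for-bit.
    """
    path = Path(path)
    frame = stats.to_frame()
    with open(path, "w") as fh:
        fh.write("\t".join(frame.columns) + "\n")
        for _, row in frame.iterrows():
            cells = []
            for col, value in row.items():
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    cells.append("")
                elif isinstance(value, float):
                    cells.append(repr(value))
                else:
                    cells.append(str(value))
            fh.write("\t".join(cells) + "\n")
    return path


class LDReference:
    """Symmetric pairwise r-squared lookup.

    Absent pairs are *unknown* (``None``), which is deliberately distinct
    from an r-squared of 0: clumping policy decides how to treat unknowns.
    A variant is always in perfect LD with itself.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), value in pairs.items():
                self.add(a, b, value)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise SummaryDataError(f"r2 for ({a}, {b}) must lie in [0, 1], got {r2!r}")
        self._r2[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float | None:
        """r² between two variants; ``None`` when the pair is unlisted."""
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b))

    def partners(self, snp_id: str) -> dict[str, float]:
        """All variants with a listed r² to ``snp_id``."""
        out: dict[str, float] = {}
        for (a, b), value in self._r2.items():
            if a == snp_id:
                out[b] = value
            elif b == snp_id:
                out[a] = value
        return out

    def __len__(self) -> int:
        return len(self._r2)

    def items(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), value in sorted(self._r2.items()):
            yield a, b, value


def read_ld_table(path: str | Path) -> LDReference:
    """Read a 3-column (snp_a, snp_b, r2) delimited text file.

    A header row is detected by the third field failing to parse as a
    number, so both headered (``SNP_A SNP_B R2``) and bare files work.
    """
    path = Path(path)
    ld = LDReference()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) < 3:
                raise SummaryDataError(
                    f"{path} line {lineno}: expected 3 columns, got {len(parts)}"
                )
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                r2 = float(raw)
            except ValueError:
                if lineno == 1:
                    continue  # header row
                raise SummaryDataError(
                    f"{path} line {lineno}: cannot parse r2 value {raw!r}"
                )
            try:
                ld.add(a, b, r2)
            except SummaryDataError as exc:
                raise SummaryDataError(f"{path} line {lineno}: {exc}")
    return ld


def write_ld_table(ld: LDReference, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("SNP_A\tSNP_B\tR2\n")
        for a, b, value in ld.items():
            fh.write(f"{a}\t{b}\t{repr(value)}\n")
    return path


# ---------------------------------------------------------------------------
# Built-in instrument fixtures
# ---------------------------------------------------------------------------
# Cigarettes-per-day (CPD) instruments from a BioBank Japan GWAS of up to
# 72,655 individuals, paired with Alzheimer's disease (AD) associations from
# a Chinese WGS case-control cohort (1,000 cases / 500 controls) and a
# Japanese cohort (3,962 cases / 4,074 controls).  One EAF is listed per SNP
# (the exposure effect-allele frequency); exposure and outcome rows share
# the printed effect allele.  In the Japanese table rs3825845 and rs12151139
# are LD proxies (r² = 0.91 and 0.95) for rs13329271 and rs56129017.

_CPD_N = 72655.0

# snp_id, EA, NEA, EAF, beta_cpd, se_cpd, p_cpd, beta_ad, se_ad, p_ad
_CHINESE_TABLE = (
    ("rs78277894", "A", "G", 0.336, 0.040, 0.006, 5.63e-13, 0.080, 0.101, 0.428),
    ("rs2435355", "C", "T", 0.195, -0.036, 0.007, 3.62e-08, 0.093, 0.096, 0.334),
    ("rs79105258", "A", "C", 0.257, 0.055, 0.007, 4.76e-17, -0.104, 0.093, 0.262),
    ("rs13329271", "C", "A", 0.516, -0.044, 0.005, 2.71e-16, -0.108, 0.084, 0.200),
    ("rs56129017", "T", "C", 0.260, 0.131, 0.006, 2.18e-96, -0.122, 0.088, 0.164),
)

_JAPANESE_TABLE = (
    ("rs78277894", "A", "G", 0.336, 0.040, 0.006, 5.63e-13, -0.007, 0.035, 0.845),
    ("rs2435355", "C", "T", 0.195, -0.036, 0.007, 3.62e-08, -0.055, 0.042, 0.190),
    ("rs3825845", "T", "C", 0.503, -0.041, 0.005, 6.95e-15, 0.007, 0.033, 0.842),
    ("rs12151139", "T", "C", 0.256, 0.122, 0.006, 4.83e-92, 0.018, 0.038, 0.636),
)

_FIXTURES = {"chinese": _CHINESE_TABLE, "japanese": _JAPANESE_TABLE}

#: Proxy relationships used by the Japanese cohort (proxy -> original, r²).
JAPANESE_PROXIES: dict[str, tuple[str, float]] = {
    "rs3825845": ("rs13329271", 0.91),
    "rs12151139": ("rs56129017", 0.95),
}


def builtin_fixture(name: str) -> tuple[SummaryStats, SummaryStats]:
    """Return the packaged (exposure, outcome) instrument tables.

    ``name`` selects the AD outcome cohort: ``"chinese"`` (5 SNPs) or
    ``"japanese"`` (4 SNPs).  The exposure table is the CPD GWAS in both
    cases; exposure records carry the GWAS sample size (n = 72,655).
    """
    key = name.lower()
    if key not in _FIXTURES:
        raise SummaryDataError(
            f"unknown fixture {name!r}; valid fixtures: "
            + ", ".join(sorted(_FIXTURES))
        )
    exposure_records = []
    outcome_records = []
    for snp, ea, nea, eaf, bx, sx, px, by, sy, py in _FIXTURES[key]:
        exposure_records.append(
            SnpRecord(snp, ea, nea, beta=bx, se=sx, pval=px, eaf=eaf, n=_CPD_N).validate()
        )
        outcome_records.append(
            SnpRecord(snp, ea, nea, beta=by, se=sy, pval=py, eaf=eaf).validate()
        )
    exposure = SummaryStats(exposure_records, trait_label="CPD", trait_type="quantitative")
    outcome = SummaryStats(
        outcome_records, trait_label=f"AD ({key})", trait_type="binary"
    )
    return exposure, outcome
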