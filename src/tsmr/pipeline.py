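"""Configuration-driven end-to-end two-sample MR run.

``run`` wires the modules together in the order of the study design:
instrument selection (significance filter, optional LD clumping, outcome
and confounder screens, proxy substitution), harmonization, orientation,
the three estimators (IVW, MR-Egger, weighted median), and the sensitivity
suite (Cochran's Q, leave-one-out, MR-PRESSO, funnel/forest coordinates).
Outputs are deterministic for a fixed seed: a results table (full
precision JSON plus a 3-decimal human rendering), a sensitivity JSON, an
exclusion log and a manifest sufficient to replay the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .diagnostics import (
    FunnelData,
    HeterogeneityResult,
    LeaveOneOutTable,
    PressoResult,
    cochran_q,
    funnel_data,
    leave_one_out,
    mr_presso,
)
from .estimators import MREstimate, Z_95, egger, ivw, wald_ratio, weighted_median
from .harmonize import (
    Exclusion,
    HarmonizedSet,
    harmonize,
    orient_positive_exposure,
    write_exclusion_log,
)
from .instruments import (
    SelectionConfig,
    filter_significant,
    clump,
    instrument_strength,
    screen_confounders,
    screen_outcome_association,
    substitute_proxies,
)
from .summary_data import (
    LDReference,
    SummaryDataError,
    SummaryStats,
    read_ld_table,
    read_summary_stats,
)

__all__ = ["RunConfig", "RunReport", "run", "run_from_tables"]

logger = logging.getLogger(__name__)

_RUNCONFIG_KEYS = {
    "exposure_path",
    "outcome_path",
    "ld_path",
    "confounder_paths",
    "selection",
    "ivw_model",
    "palindrome_policy",
    "n_boot",
    "n_sim",
    "seed",
    "exposure_sd",
    "out_dir",
}


@dataclass
class RunConfig:
    """Fully specifies one pipeline run; loadable from a YAML file."""

    exposure_path: str
    outcome_path: str
    seed: int
    ld_path: str | None = None
    confounder_paths: Sequence[str] = ()
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    ivw_model: str = "multiplicative_random"
    palindrome_policy: str = "infer_by_eaf"
    n_boot: int = 1000
    n_sim: int = 10_000
    exposure_sd: float = 1.0
    out_dir: str = "tsmr_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration; unknown keys are errors (fail closed)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(
                f"{path}: unknown config key(s): {', '.join(sorted(unknown))}"
            )
        selection_raw = raw.pop("selection", {}) or {}
        known_sel = {f.name for f in dataclasses.fields(SelectionConfig)}
        unknown_sel = set(selection_raw) - known_sel
        if unknown_sel:
            raise ValueError(
                f"{path}: unknown selection key(s): {', '.join(sorted(unknown_sel))}"
            )
        if "seed" not in raw:
            raise ValueError(f"{path}: a seed is required (stochastic steps enabled)")
        return cls(selection=SelectionConfig(**selection_raw), **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["confounder_paths"] = list(d["confounder_paths"])
        return d


@dataclass
class RunReport:
    """In-memory bundle of everything one pipeline run computed."""

    hset: HarmonizedSet
    estimates: dict[str, MREstimate]
    heterogeneity: HeterogeneityResult | None
    loo: LeaveOneOutTable | None
    presso: PressoResult | None
    funnel: FunnelData | None
    exclusions: list[Exclusion]
    strength: Any | None
    warnings: list[str]
    out_dir: Path | None = None


def _estimate_dict(est: MREstimate) -> dict[str, Any]:
    d = {
        "method": est.method,
        "beta": est.beta,
        "se": est.se,
        "pval": est.pval,
        "or": est.or_,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_snp": est.n_snp,
    }
    extra = {}
    for key, value in est.extra.items():
        if dataclasses.is_dataclass(value):
            extra[key] = dataclasses.asdict(value)
        elif isinstance(value, (int, float, str, bool, type(None))):
            extra[key] = value
    if extra:
        d["extra"] = extra
    return d


def _results_tsv(estimates: Mapping[str, MREstimate]) -> str:
    """Human rendering mirroring the published result-table layout."""
    lines = ["Method\tOR (95% CI)\tp\tn SNP"]
    names = {
        "ivw": "Inverse variance-weighted (IVW)",
        "egger": "MR-Egger",
        "wme": "Weighted median estimator (WME)",
    }
    for key, label in names.items():
        est = estimates.get(key)
        if est is None:
            continue
        lines.append(
            f"{label}\t{est.or_:.3f} ({est.ci_low:.3f}–{est.ci_high:.3f})"
            f"\t{est.pval:.3f}\t{est.n_snp}"
        )
    return "\n".join(lines) + "\n"


def run_from_tables(
    exposure: SummaryStats,
    outcome: SummaryStats,
    config: RunConfig,
    ld: LDReference | None = None,
    confounders: Sequence[SummaryStats] = (),
) -> RunReport:
    """Execute selection -> harmonization -> estimation -> diagnostics.

    With fewer than 3 instruments after selection the run degrades to IVW
    and Cochran's Q only (with a warning); with zero instruments it raises.
    MR-PRESSO additionally needs at least 4 instruments.
    """
    notes: list[str] = []
    exclusions: list[Exclusion] = []

    selected = filter_significant(exposure, config.selection.p_threshold)
    if len(selected) < len(exposure):
        dropped = set(exposure.ids) - set(selected.ids)
        exclusions.extend(
            Exclusion(s, "not_genome_wide_significant",
                      f"exposure p >= {config.selection.p_threshold:g}")
            for s in sorted(dropped)
        )
    if ld is not None and len(selected) > 1:
        clumped = clump(selected, ld, config.selection)
        dropped = set(selected.ids) - set(clumped.ids)
        exclusions.extend(
            Exclusion(s, "clumped", "in LD with a stronger index SNP")
            for s in sorted(dropped)
        )
        selected = clumped
    selected, screen_log = screen_outcome_association(
        selected, outcome, config.selection.outcome_gwas_p_threshold
    )
    exclusions.extend(screen_log)
    if confounders:
        selected, conf_log = screen_confounders(
            selected, confounders, config.selection.outcome_gwas_p_threshold
        )
        exclusions.extend(conf_log)

    # proxy substitution for instruments missing from the outcome table
    missing = [s for s in selected.ids if s not in outcome]
    proxy_map: dict[str, str] = {}
    if missing:
        if ld is None:
            for snp in missing:
                exclusions.append(
                    Exclusion(snp, "absent_from_outcome", "no LD table for proxy search")
                )
            selected = selected.subset(s for s in selected.ids if s not in missing)
        else:
            mapping, unresolved = substitute_proxies(
                missing, outcome, ld, config.selection.proxy_r2_floor
            )
            keep = []
            for snp in selected.ids:
                if snp in mapping:
                    proxy, r2 = mapping[snp]
                    if proxy in exposure:
                        proxy_map[proxy] = snp
                        keep.append(proxy)
                        exclusions.append(
                            Exclusion(snp, "proxied", f"replaced by {proxy} (r2 = {r2:g})")
                        )
                    else:
                        exclusions.append(
                            Exclusion(snp, "proxy_not_in_exposure", f"candidate {proxy}")
                        )
                elif snp in unresolved:
                    exclusions.append(
                        Exclusion(snp, "no_proxy",
                                  f"no outcome SNP with r2 >= {config.selection.proxy_r2_floor:g}")
                    )
                else:
                    keep.append(snp)
            selected = exposure.subset(keep)

    if len(selected) == 0:
        raise SummaryDataError(
            "no instruments left after selection; see exclusion log"
        )

    hset, harm_log = harmonize(
        selected, outcome, palindrome_policy=config.palindrome_policy,
        proxy_map=proxy_map,
    )
    exclusions.extend(harm_log)
    hset = orient_positive_exposure(hset)
    k = len(hset)

    estimates: dict[str, MREstimate] = {}
    estimates["ivw"] = ivw(hset, model=config.ivw_model if k >= 2 else "fixed")
    if k >= 3:
        estimates["egger"] = egger(hset)
        estimates["wme"] = weighted_median(hset, n_boot=config.n_boot, seed=config.seed)
    else:
        notes.append(
            f"only {k} instrument(s) after selection: MR-Egger and the "
            "weighted median were skipped (need k >= 3)"
        )
        warnings.warn(notes[-1], stacklevel=2)

    heterogeneity = cochran_q(hset) if k >= 2 else None
    loo = leave_one_out(hset, model=config.ivw_model) if k >= 2 else None
    presso = None
    if k >= 4:
        presso = mr_presso(hset, n_sim=config.n_sim, seed=config.seed)
    else:
        notes.append(f"MR-PRESSO skipped: needs k >= 4, have {k}")
    funnel = funnel_data(hset, model=config.ivw_model if k >= 2 else "fixed")

    strength = None
    try:
        n_exposure = max(
            (s.n for s in (exposure.get(i) for i in hset.ids) if s is not None and s.n),
            default=None,
        )
        if n_exposure:
            strength = instrument_strength(hset, n=n_exposure, sd=config.exposure_sd)
    except ValueError as exc:
        notes.append(f"instrument strength not computed: {exc}")

    return RunReport(
        hset=hset,
        estimates=estimates,
        heterogeneity=heterogeneity,
        loo=loo,
        presso=presso,
        funnel=funnel,
        exclusions=exclusions,
        strength=strength,
        warnings=notes,
    )


def _forest_frame(report: RunReport):
    import pandas as pd

    rows = []
    for s in report.hset:
        est = wald_ratio(s)
        rows.append(
            {
                "snp_id": s.snp_id,
                "ratio": est.ratio,
                "se_ratio": est.se_ratio,
                "ci_low": est.ratio - Z_95 * est.se_ratio,
                "ci_high": est.ratio + Z_95 * est.se_ratio,
                "proxy_for": s.proxy_for or "",
            }
        )
    ivw_est = report.estimates["ivw"]
    rows.append(
        {
            "snp_id": "(IVW)",
            "ratio": ivw_est.beta,
            "se_ratio": ivw_est.se,
            "ci_low": ivw_est.beta - Z_95 * ivw_est.se,
            "ci_high": ivw_est.beta + Z_95 * ivw_est.se,
            "proxy_for": "",
        }
    )
    return pd.DataFrame(rows)


def write_report(report: RunReport, config: RunConfig, out_dir: str | Path) -> Path:
    """Serialize a run to ``out_dir``; byte-identical across identical runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "results.tsv").write_text(_results_tsv(report.estimates))
    results_json = {key: _estimate_dict(est) for key, est in report.estimates.items()}
    (out / "results.json").write_text(json.dumps(results_json, indent=2) + "\n")

    sensitivity: dict[str, Any] = {"warnings": report.warnings}
    if report.heterogeneity:
        sensitivity["cochran_q"] = dataclasses.asdict(report.heterogeneity)
    if report.presso:
        p = report.presso
        sensitivity["mr_presso"] = {
            "global_rss_observed": p.global_rss_observed,
            "global_pval": p.global_pval,
            "per_snp_pvals": p.per_snp_pvals,
            "outliers": p.outliers,
            "distortion_pct": p.distortion_pct,
            "distortion_pval": p.distortion_pval,
            "n_sim": p.n_sim,
            "seed": p.seed,
        }
    if report.strength:
        sensitivity["instrument_strength"] = {
            "r2_total": report.strength.r2_total,
            "f_stat": report.strength.f_stat,
            "n": report.strength.n,
            "k": report.strength.k,
            "per_snp_r2": report.strength.per_snp_r2,
        }
    (out / "sensitivity.json").write_text(json.dumps(sensitivity, indent=2) + "\n")

    if report.loo:
        report.loo.to_frame().to_csv(out / "leave_one_out.tsv", sep="\t", index=False)
    if report.funnel:
        report.funnel.to_frame().to_csv(out / "funnel.tsv", sep="\t", index=False)
    _forest_frame(report).to_csv(out / "forest.tsv", sep="\t", index=False)
    write_exclusion_log(report.exclusions, out / "exclusions.tsv")

    manifest = {
        "tsmr_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "n_instruments": len(report.hset),
        "instruments": report.hset.ids,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    report.out_dir = out
    return out


def run(config: RunConfig) -> RunReport:
    """Load inputs per ``config``, execute the pipeline, write the report."""
    exposure = read_summary_stats(config.exposure_path, trait_type="quantitative")
    outcome = read_summary_stats(config.outcome_path, trait_type="binary")
    ld = read_ld_table(config.ld_path) if config.ld_path else None
    confounders = [
        read_summary_stats(p, trait_type="binary") for p in config.confounder_paths
    ]
    report = run_from_tables(exposure, outcome, config, ld=ld, confounders=confounders)
    write_report(report, config, config.out_dir)
    return report
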