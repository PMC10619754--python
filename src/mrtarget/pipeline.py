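"""End-to-end analysis orchestration from a single YAML config.

For every (target, exposure, outcome) triple the pipeline selects cis
instruments, harmonizes the two studies, estimates the causal effect
(correlated IVW, reducing to a Wald ratio for a single instrument), runs
the sensitivity battery, re-expresses the estimate in the configured
reporting direction, optionally rescales it, and — when an outcome
declares itself adjusted for a mediator — produces a mediation contrast
against the matching unadjusted outcome. Everything is deterministic
given identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import estimators, harmonization, instrument_selection, mediation, summary_io
from .instrument_selection import SelectionConfig

logger = logging.getLogger(__name__)


@dataclass
class TargetSpec:
    name: str
    regions_path: str
    regions_dialect: str = "bed"
    snp_allowlist: Optional[list[str]] = None


@dataclass
class TraitSpec:
    name: str
    gwas_path: str
    units: str = ""
    kind: str = "quantitative"
    column_map: Optional[dict[str, str]] = None
    adjusted_for: Optional[dict[str, str]] = None  # {"base": ..., "mediator": ...}


@dataclass
class AnalysisConfig:
    targets: list[TargetSpec]
    exposures: list[TraitSpec]
    outcomes: list[TraitSpec]
    ld_matrix_path: str
    ld_ids_path: str
    out_dir: str
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    maf_exclusion: float = 0.42
    direction: str = estimators.PER_UNIT_DECREASE
    rescale_units: Optional[float] = None
    alpha: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for group, what in (
            (self.targets, "target"),
            (self.exposures, "exposure"),
            (self.outcomes, "outcome"),
        ):
            names = [t.name for t in group]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate {what} names: {names}")
        for path in [t.regions_path for t in self.targets] + [
            t.gwas_path for t in self.exposures + self.outcomes
        ] + [self.ld_matrix_path, self.ld_ids_path]:
            if not Path(path).exists():
                raise FileNotFoundError(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "AnalysisConfig":
        sel = SelectionConfig(**doc.get("selection", {}))
        return cls(
            targets=[TargetSpec(**t) for t in doc["targets"]],
            exposures=[TraitSpec(**t) for t in doc["exposures"]],
            outcomes=[TraitSpec(**t) for t in doc["outcomes"]],
            ld_matrix_path=doc["ld_matrix_path"],
            ld_ids_path=doc["ld_ids_path"],
            out_dir=doc["out_dir"],
            selection=sel,
            maf_exclusion=doc.get("maf_exclusion", 0.42),
            direction=doc.get("direction", estimators.PER_UNIT_DECREASE),
            rescale_units=doc.get("rescale_units"),
            alpha=doc.get("alpha", 0.05),
            seed=doc.get("seed"),
        )


def _estimate_to_dict(est: estimators.MREstimate | None) -> dict | None:
    return None if est is None else dataclasses.asdict(est)


def _sensitivity_to_dict(rep: estimators.SensitivityReport) -> dict:
    return {
        "q_stat": rep.q_stat,
        "q_df": rep.q_df,
        "q_pvalue": rep.q_pvalue,
        "egger_intercept": rep.egger_intercept,
        "egger_intercept_se": rep.egger_intercept_se,
        "egger_intercept_pvalue": rep.egger_intercept_pvalue,
        "egger_slope": _estimate_to_dict(rep.egger_slope),
        "pleiotropy_detected": rep.pleiotropy_detected,
        "loo": [
            {"dropped": vid, "estimate": _estimate_to_dict(est)}
            for vid, est in rep.loo
        ],
    }


def run_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Execute the full analysis and write the results bundle to out_dir.

    Returns a dict with ``results`` (rows for the results TSV),
    ``sensitivity``, ``mediation``, ``selection`` and ``log``. Per-triple
    failures are logged and skipped; only a run in which every triple
    fails raises.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ld = summary_io.read_ld_matrix(config.ld_matrix_path, config.ld_ids_path)

    exposures = {
        e.name: summary_io.read_summary_stats(
            e.gwas_path,
            column_map=e.column_map,
            trait_meta={"trait_name": e.name, "trait_kind": "quantitative",
                        "trait_units": e.units},
        )
        for e in config.exposures
    }
    outcomes = {
        o.name: summary_io.read_summary_stats(
            o.gwas_path,
            column_map=o.column_map,
            trait_meta={"trait_name": o.name, "trait_kind": o.kind,
                        "trait_units": o.units},
        )
        for o in config.outcomes
    }
    regions = {
        t.name: summary_io.read_regions(
            t.regions_path, dialect=t.regions_dialect, gene_symbol=t.name
        )
        for t in config.targets
    }

    rows: list[dict] = []
    estimates: dict[tuple[str, str, str], estimators.MREstimate] = {}
    sensitivity: dict[str, dict] = {}
    selection_log: dict[str, dict] = {}
    run_log: list[dict] = []
    n_failed = n_total = 0

    for target in config.targets:
        for exp in config.exposures:
            sel = instrument_selection.select_instruments(
                exposures[exp.name],
                regions[target.name],
                ld,
                config.selection,
                snp_allowlist=target.snp_allowlist,
            )
            selection_log[f"{target.name}|{exp.name}"] = {
                "retained": sel.retained,
                "candidate_count": sel.candidate_count,
                "fallback_used": sel.fallback_used,
                "p_threshold": sel.config_effective.p_threshold,
                "r2_clump": sel.config_effective.r2_clump,
            }
            for outc in config.outcomes:
                n_total += 1
                key = (target.name, exp.name, outc.name)
                try:
                    if not sel.retained:
                        raise ValueError("no instruments selected")
                    instr, report = harmonization.harmonize(
                        exposures[exp.name],
                        outcomes[outc.name],
                        ld,
                        sel.retained,
                        maf_exclusion=config.maf_exclusion,
                    )
                    est = estimators.ivw_correlated(instr, alpha=config.alpha)
                    sens = estimators.sensitivity_analysis(
                        instr, est, alpha=config.alpha
                    )
                    est = estimators.report_direction(est, config.direction)
                    if config.rescale_units:
                        est = estimators.rescale_effect(est, config.rescale_units)
                    estimates[key] = est
                    rows.append(
                        {
                            "target": target.name,
                            "exposure_trait": exp.name,
                            "outcome_trait": outc.name,
                            "estimate": est,
                        }
                    )
                    sensitivity["|".join(key)] = _sensitivity_to_dict(sens)
                    run_log.append(
                        {
                            "triple": list(key),
                            "status": "ok",
                            "n_snps": est.n_snps,
                            "fallback_used": sel.fallback_used,
                            "harmonization": dataclasses.asdict(report),
                        }
                    )
                except Exception as exc:
                    n_failed += 1
                    logger.warning("triple %s failed: %s", key, exc)
                    run_log.append(
                        {"triple": list(key), "status": "failed", "error": str(exc)}
                    )

    if n_total and n_failed == n_total:
        raise RuntimeError("every (target, exposure, outcome) triple failed")

    mediation_reports: dict[str, dict] = {}
    for outc in config.outcomes:
        if not outc.adjusted_for:
            continue
        base = outc.adjusted_for["base"]
        mediator = outc.adjusted_for.get("mediator")
        for target in config.targets:
            for exp in config.exposures:
                k_adj = (target.name, exp.name, outc.name)
                k_base = (target.name, exp.name, base)
                if k_adj not in estimates or k_base not in estimates:
                    continue
                med_est = estimates.get((target.name, exp.name, mediator))
                rep = mediation.mediation_contrast(
                    estimates[k_base], med_est, estimates[k_adj], alpha=config.alpha
                )
                mediation_reports["|".join(k_adj)] = {
                    "delta_theta": rep.delta_theta,
                    "delta_se": rep.delta_se,
                    "delta_z": rep.delta_z,
                    "delta_pvalue": rep.delta_pvalue,
                    "verdict": rep.verdict,
                    "se_assumption": rep.se_assumption,
                    "estimate_primary": _estimate_to_dict(rep.estimate_primary),
                    "estimate_mediator": _estimate_to_dict(rep.estimate_mediator),
                    "estimate_primary_adjusted": _estimate_to_dict(
                        rep.estimate_primary_adjusted
                    ),
                }

    bundle = {
        "results": rows,
        "sensitivity": sensitivity,
        "mediation": mediation_reports,
        "selection": selection_log,
        "log": run_log,
    }
    summary_io.write_results(rows, out_dir / "results.tsv")
    (out_dir / "sensitivity.json").write_text(json.dumps(sensitivity, indent=2) + "\n")
    if mediation_reports:
        (out_dir / "mediation.json").write_text(
            json.dumps(mediation_reports, indent=2) + "\n"
        )
    (out_dir / "run_log.json").write_text(
        json.dumps({"selection": selection_log, "triples": run_log}, indent=2) + "\n"
    )
    forest_table(bundle).to_csv(out_dir / "forest.tsv", sep="\t", index=False)
    return bundle


def forest_table(bundle: dict[str, Any]) -> pd.DataFrame:
    """Plot-ready table: one row per estimate, ordered by target.

    Binary outcomes carry OR columns; quantitative outcomes carry the
    effect size (beta) in outcome units and empty OR columns.
    """
    records = []
    for row in bundle["results"]:
        est = row["estimate"]
        or_vals = est.or_scale if est.or_scale is not None else (None, None, None)
        records.append(
            {
                "target": row["target"],
                "exposure_trait": row["exposure_trait"],
                "outcome_trait": row["outcome_trait"],
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.theta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "or": or_vals[0],
                "or_ci_low": or_vals[1],
                "or_ci_high": or_vals[2],
                "pvalue": est.pvalue,
                "direction": est.direction,
            }
        )
    df = pd.DataFrame(
        records,
        columns=[
            "target", "exposure_trait", "outcome_trait", "method", "n_snps",
            "beta", "se", "ci_low", "ci_high", "or", "or_ci_low", "or_ci_high",
            "pvalue", "direction",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            ["target", "exposure_trait", "outcome_trait"], kind="mergesort"
        ).reset_index(drop=True)
    return df
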