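"""End-to-end pipeline: simulate/load -> assemble -> impute -> weight ->
estimate -> report, with a manifest recording config hash, seed and
artifact checksums so that reruns are verifiably identical."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import effects as eff
from .assemble import assemble
from .impute import impute_metastases
from .model import COVARIATES, AnalysisSet, read_lot_table, write_lot_table
from .simulate import SimConfig, simulate_cohort
from .weighting import COVARIATE_LEVELS, att_weights, balance_table, fit_propensity

log = logging.getLogger("extcontrol")

STAGES = ("simulate", "assemble", "impute", "weight", "estimate", "report")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    input_csv: Optional[str] = None  # when set, replaces the simulate stage
    covariates: Sequence[str] = COVARIATES
    continuity: bool = False
    cr1: bool = False
    sim: dict = field(default_factory=dict)  # SimConfig field overrides

    def validate(self) -> None:
        unknown = [c for c in self.covariates if c not in COVARIATE_LEVELS]
        if unknown:
            raise ValueError(f"unknown covariate(s) in config: {unknown}")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(self.input_csv)
        known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(self.sim) - known
        if bad:
            raise ValueError(f"unknown sim option(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    A stage failure is recorded in the manifest (downstream stages are
    skipped) and re-raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }
    artifacts: list[Path] = []

    def finish(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        for p in artifacts:
            manifest["artifacts"][p.name] = _sha256(p)
        _write_json(out / "manifest.json", manifest)

    stage = "simulate"
    try:
        raw_csv = out / "cohort_raw.csv"
        if config.input_csv is not None:
            records = read_lot_table(config.input_csv)
            write_lot_table(records, raw_csv)
        else:
            sim = SimConfig(seed=config.seed, **config.sim)
            records = simulate_cohort(sim).records
            write_lot_table(records, raw_csv)
        artifacts.append(raw_csv)
        log.info("simulate: %d LOT records", len(records))

        stage = "assemble"
        analysis_set, report = assemble(records)
        write_lot_table(analysis_set.records, out / "analysis.csv")
        _write_json(
            out / "eligibility.json",
            {
                "input_lots": report.input_lots,
                "excluded_by_rule": report.excluded_by_rule,
                "retained": report.retained,
            },
        )
        artifacts += [out / "analysis.csv", out / "eligibility.json"]
        log.info(
            "assemble: %d trial records, %d control LOTs from %d patients",
            analysis_set.n_trial,
            analysis_set.n_control_lots,
            analysis_set.n_control_patients,
        )

        stage = "impute"
        imputed, audit = impute_metastases(analysis_set)
        write_lot_table(imputed.records, out / "imputed.csv")
        _write_json(
            out / "imputation_audit.json",
            {
                "n_missing_before": audit.n_missing_before,
                "n_rule_both": audit.n_rule_both,
                "n_rule_prior_only": audit.n_rule_prior_only,
                "n_rule_subsequent_only": audit.n_rule_subsequent_only,
                "n_unimputable": audit.n_unimputable,
                "n_missing_after": audit.n_missing_after,
            },
        )
        artifacts += [out / "imputed.csv", out / "imputation_audit.json"]
        log.info(
            "impute: %d missing blocks -> %d after neighbour rules",
            audit.n_missing_before,
            audit.n_missing_after,
        )

        stage = "weight"
        frame = imputed.to_frame()
        fit = att_weights(fit_propensity(frame, config.covariates))
        wdf = frame[["patient_id", "cohort", "lot_seq"]].copy()
        wdf["ps"] = fit.ps
        wdf["raw_weight"] = fit.raw_weight
        wdf["weight"] = fit.weight
        wdf.to_csv(out / "weights.csv", index=False)
        balance = balance_table(frame, fit, config.covariates)
        balance.to_frame().to_csv(out / "balance.csv", index=False)
        _write_json(
            out / "ps_overlap.json",
            {k: list(v) for k, v in fit.overlap_summary().items()},
        )
        artifacts += [out / "weights.csv", out / "balance.csv", out / "ps_overlap.json"]
        log.info(
            "weight: sum of control weights %.6f (renorm factor %.4f), max |SMD| %.3f -> %.3f",
            fit.weight[fit.treat == 0].sum(),
            fit.renorm_factor,
            balance.max_abs_smd(weighted=False),
            balance.max_abs_smd(weighted=True),
        )

        stage = "estimate"
        bundle = eff.run_all_endpoints(
            frame, fit, config.covariates, continuity=config.continuity, cr1=config.cr1
        )
        _write_json(out / "results.json", bundle.to_dict())
        artifacts.append(out / "results.json")
        for e in bundle.effects:
            log.info(
                "estimate: %s %s (%s) = %.2f (%.2f, %.2f), p=%.4f",
                e.endpoint, e.measure, e.method, e.estimate, e.ci_low, e.ci_high, e.p_value,
            )

        stage = "report"
        artifacts += render_reports(bundle, out, balance=balance)
    except Exception:
        finish(stage, "failed")
        raise
    finish(stage, "ok")
    for s in STAGES:
        manifest["stages"].setdefault(s, "ok")
    _write_json(out / "manifest.json", manifest)
    return out


def render_reports(bundle: eff.ResultsBundle, out_dir: str | Path, balance=None) -> list[Path]:
    """Emit publication-style data files.

    One KM data file per available time-to-event endpoint (both arms,
    unadjusted and ATT-adjusted), an effects table, a medians table
    (``NR`` when a curve never reaches 0.5), one forest file per fitted
    multivariable model, and the balance table when provided.  Missing
    pieces are logged and skipped, never fatal.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for endpoint in eff.ENDPOINTS:
        parts = []
        for arm in ("trial", "control"):
            for adj in ("unadjusted", "att"):
                curve = bundle.km.get(f"{endpoint}:{arm}:{adj}")
                if curve is None:
                    continue
                df = curve.to_frame()
                df.insert(0, "arm", arm)
                df.insert(1, "adjustment", adj)
                parts.append(df)
        if not parts:
            log.info("report: no KM curves for %s; skipped", endpoint)
            continue
        p = out / f"km_{endpoint}.csv"
        pd.concat(parts).to_csv(p, index=False)
        written.append(p)

    if bundle.effects:
        p = out / "effects.csv"
        pd.DataFrame([vars(e) for e in bundle.effects]).to_csv(p, index=False)
        written.append(p)

        rows = []
        for key, curve in bundle.km.items():
            endpoint, arm, adj = key.split(":")
            rows.append(
                {
                    "endpoint": endpoint,
                    "arm": arm,
                    "adjustment": adj,
                    "median_months": (
                        f"{curve.median_months():.2f}" if curve.median_defined else "NR"
                    ),
                    "ci_low_months": (
                        f"{curve.median_ci[0] / 30.4375:.2f}"
                        if np.isfinite(curve.median_ci[0])
                        else "NR"
                    ),
                    "ci_high_months": (
                        f"{curve.median_ci[1] / 30.4375:.2f}"
                        if np.isfinite(curve.median_ci[1])
                        else "NR"
                    ),
                }
            )
        p = out / "medians.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

    for name, forest in bundle.forests.items():
        p = out / f"forest_{name}.csv"
        forest.to_frame().to_csv(p, index=False)
        written.append(p)

    if balance is not None:
        p = out / "balance.csv"
        balance.to_frame().to_csv(p, index=False)
        written.append(p)
    return written
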