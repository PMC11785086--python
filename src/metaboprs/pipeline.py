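"""Declarative end-to-end pipeline: simulate, predict, discover, interact.

A :class:`RunConfig` wires the stages together with explicit seeds; every
stage writes plain TSV/JSON artifacts under the output directory together
with a run manifest, so identical configurations reproduce identical
artifacts byte for byte (the manifest's timestamp aside).
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable, SimulationConfig, generate_cohort, read_cohort, write_cohort
from .panel import RESILIENCE_TRIO, default_panel
from .prediction import compare_models, fit_prediction_model, stratified_auc
from .preprocess import impute, probit_matrix
from .reports import prevalence, summarize_characteristics
from .resilience import discover_resilience, residualize, stratify_by_prs
from .scores import (
    build_interaction_table,
    fit_mrs,
    resilience_sum,
    score_mrs,
    three_way_age_interaction,
)

ALL_STAGES = ("simulate", "report", "predict", "resilience", "interact")


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 2)."""


@dataclass
class RunConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    cohort_path: str | None = None
    simulate: SimulationConfig | None = None
    tiers: tuple[int, ...] = (3, 4)
    metabolite_sets: tuple[str, ...] = ("none", "full168")
    resilience_members: tuple[str, ...] = RESILIENCE_TRIO
    reference_mode: str = "within_prs_quartile"
    mrs_mode: str = "out_of_fold"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
        if "simulate" in self.stages and self.simulate is None:
            self.simulate = SimulationConfig(seed=self.seed)
        if "simulate" not in self.stages and self.cohort_path is None:
            raise ConfigError("config needs either a simulate stage or a cohort_path")
        if any(t not in (1, 2, 3, 4) for t in self.tiers):
            raise ConfigError("tiers must be within 1..4")
        if any(m not in ("none", "certified27", "full168") for m in self.metabolite_sets):
            raise ConfigError("metabolite_sets must be none/certified27/full168")
        if self.reference_mode not in ("within_prs_quartile", "global_q1q1"):
            raise ConfigError("reference_mode must be within_prs_quartile or global_q1q1")
        if self.mrs_mode not in ("out_of_fold", "full_fit"):
            raise ConfigError("mrs_mode must be out_of_fold or full_fit")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        sim = payload.pop("simulate", None)
        try:
            cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in payload.items()})
        except TypeError as err:
            raise ConfigError(str(err)) from err
        if sim is not None:
            if isinstance(sim, dict):
                sim = dict(sim)
                if "resilience_set" in sim:
                    sim["resilience_set"] = tuple(sim["resilience_set"])
                try:
                    cfg.simulate = SimulationConfig(**sim)
                except (TypeError, ValueError) as err:
                    raise ConfigError(f"bad simulate block: {err}") from err
            else:
                cfg.simulate = sim
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigError("configuration file must hold a mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def _resilience_tsv(result, path: Path) -> None:
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the artifact paths by name.

    On a stage failure the exception propagates after a ``FAILED`` marker
    file is written, so partial artifacts remain inspectable.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    started = time.time()
    try:
        cohort = _stage_cohort(config, out, artifacts)
        imputed = impute(cohort)
        probit = probit_matrix(imputed)
        if "report" in config.stages:
            _stage_report(cohort, out, artifacts)
        if "predict" in config.stages:
            _stage_predict(config, imputed, out, artifacts)
        if "resilience" in config.stages:
            _stage_resilience(config, imputed, probit, out, artifacts)
        if "interact" in config.stages:
            _stage_interact(config, imputed, probit, out, artifacts)
    except Exception:
        (out / "FAILED").write_text("pipeline stage failed; see traceback\n")
        raise
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "simulate": (dataclasses.asdict(config.simulate)
                     if config.simulate is not None else None),
        "artifacts": {k: str(v) for k, v in artifacts.items()},
        "elapsed_seconds": round(time.time() - started, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest["simulate"] = _jsonable(manifest["simulate"])
    path = out / "manifest.json"
    _write_json(path, manifest)
    artifacts["manifest"] = path
    return artifacts


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _stage_cohort(config: RunConfig, out: Path, artifacts: dict) -> CohortTable:
    if "simulate" in config.stages:
        cohort = generate_cohort(config.simulate)
        path = out / "cohort.csv"
        write_cohort(cohort, path)
        config.simulate.to_json(out / "cohort.config.json")
        artifacts["cohort"] = path
        artifacts["cohort_config"] = out / "cohort.config.json"
        return cohort
    panel = default_panel()
    return read_cohort(config.cohort_path, panel)


def _stage_report(cohort: CohortTable, out: Path, artifacts: dict) -> None:
    summary = summarize_characteristics(cohort)
    path = out / "characteristics.tsv"
    summary.to_csv(path, sep="\t", index=False)
    artifacts["characteristics"] = path
    status = cohort.status
    _write_json(out / "prevalence.json", {
        "n_cases": int(status.sum()),
        "n_noncases": int(len(status) - status.sum()),
        "prevalence_pct": prevalence(int(status.sum()), int(len(status) - status.sum())),
    })
    artifacts["prevalence"] = out / "prevalence.json"


def _stage_predict(config: RunConfig, imputed: CohortTable, out: Path,
                   artifacts: dict) -> None:
    probit = probit_matrix(imputed)
    fitted = {}
    for tier in config.tiers:
        for mset in config.metabolite_sets:
            if tier == 1 and mset == "none":
                continue
            model = fit_prediction_model(imputed, tier, mset, seed=config.seed,
                                         probit=probit)
            fitted[(tier, mset)] = model
            path = out / f"prediction_tier{tier}_{mset}.json"
            _write_json(path, model.to_dict())
            artifacts[f"prediction_tier{tier}_{mset}"] = path
    comparisons = []
    for tier in config.tiers:
        if (tier, "none") not in fitted:
            continue
        for mset in config.metabolite_sets:
            if mset == "none" or (tier, mset) not in fitted:
                continue
            cmp = compare_models(fitted[(tier, mset)], fitted[(tier, "none")])
            comparisons.append({
                "tier": tier, "with": mset, "without": "none",
                "auc_with": cmp.auc_a, "auc_without": cmp.auc_b,
                "delong_z": cmp.delong_z, "delong_p": cmp.delong_p,
            })
            strat = stratified_auc(imputed, fitted[(tier, mset)], fitted[(tier, "none")])
            spath = out / f"stratified_auc_tier{tier}_{mset}.tsv"
            strat.to_csv(spath, sep="\t", index=False, float_format="%.6g")
            artifacts[f"stratified_auc_tier{tier}_{mset}"] = spath
    if comparisons:
        path = out / "model_comparisons.json"
        _write_json(path, {"comparisons": comparisons})
        artifacts["model_comparisons"] = path


def _stage_resilience(config: RunConfig, imputed: CohortTable, probit,
                      out: Path, artifacts: dict) -> None:
    residuals = residualize(probit, imputed)
    top10, bottom50 = stratify_by_prs(imputed)
    for name, rows in (("top10", top10), ("bottom50", bottom50)):
        result = discover_resilience(residuals, imputed.status, rows, stratum=name)
        path = out / f"resilience_{name}.tsv"
        _resilience_tsv(result, path)
        artifacts[f"resilience_{name}"] = path
        _write_json(out / f"resilience_{name}_nef.json", {
            "n_effective": result.nef.n_effective,
            "variance_captured": result.nef.variance_captured,
            "n_cases": result.n_cases,
            "n_noncases": result.n_noncases,
        })
        artifacts[f"resilience_{name}_nef"] = out / f"resilience_{name}_nef.json"


def _stage_interact(config: RunConfig, imputed: CohortTable, probit,
                    out: Path, artifacts: dict) -> None:
    scores = {"resilience_sum": resilience_sum(probit, config.resilience_members)}
    mrs_model = fit_mrs(probit, imputed.status, seed=config.seed)
    scores["mrs"] = score_mrs(mrs_model, probit, mode=config.mrs_mode)
    pd.Series(mrs_model.betas, name="beta").rename_axis("metabolite") \
        .to_csv(out / "mrs_betas.tsv", sep="\t", float_format="%.6g")
    artifacts["mrs_betas"] = out / "mrs_betas.tsv"

    top10, _ = stratify_by_prs(imputed)
    for kind, score in scores.items():
        tab = build_interaction_table(imputed, score,
                                      reference_mode=config.reference_mode)
        path = out / f"interaction_{kind}.tsv"
        tab.grid.to_csv(path, sep="\t", index=False, float_format="%.6g")
        artifacts[f"interaction_{kind}"] = path
        payload = {
            "interaction_p": tab.interaction_p,
            "interaction_coef": tab.interaction_coef,
            "reference_mode": tab.reference_mode,
            "prs_cutpoints": list(tab.prs_quartiles.cutpoints),
            "score_cutpoints": list(tab.score_quartiles.cutpoints),
        }
        if kind == "resilience_sum":
            p3, c3 = three_way_age_interaction(imputed, score, top10)
            payload["three_way_age_p"] = p3
            payload["three_way_age_coef"] = c3
        _write_json(out / f"interaction_{kind}.json", payload)
        artifacts[f"interaction_{kind}_stats"] = out / f"interaction_{kind}.json"
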