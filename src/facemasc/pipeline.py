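"""End-to-end pipeline: simulate -> extract -> fit -> score -> compare.

Stages communicate through files in a run directory, so every number in
the final report is traceable to a stage output; the report itself only
collects stage results.  One seed governs the generator, CV folds and
resampling through derived substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import gender, stats, synthetic
from .distances import REPORTED_SELECTED_FEATURES
from .landmarks import read_landmarks, read_metadata, write_landmarks
from .synthetic import CohortConfig, FeatureTableConfig, records_to_frame

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage precondition failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    ``stages`` lists the enabled stages in execution order (subset of
    simulate, fit, score, compare).  The distance-level generator is used
    by default; ``simulate_landmarks`` switches the simulate stage to the
    landmark-level generator plus feature extraction for a (smaller)
    cohort.
    """

    out_dir: str | Path = "facemasc_run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "fit", "score", "compare")
    simulate_landmarks: bool = False
    features_file: str | None = None   # use an existing feature table
    meta_file: str | None = None
    k_folds: int = 10
    alpha_familywise: float = 0.05
    family_size: int = 10
    covariates: tuple[str, ...] = ("facial_area", "age")
    feature_subset: tuple[str, ...] | None = tuple(REPORTED_SELECTED_FEATURES)
    max_features: int = 10
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        for key in ("stages", "covariates", "feature_subset"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else str(v) if
                       isinstance(v, Path) else v)
                   for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _seed_for(config: RunConfig, stage: str) -> int:
    """Derived per-stage substream seed (kept below 2**31)."""
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run report dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    table: pd.DataFrame | None = None

    try:
        if "simulate" in config.stages:
            table = _stage_simulate(config, out, report)
        elif config.features_file:
            if not Path(config.features_file).exists():
                raise PipelineError(
                    f"extract: features file not found: {config.features_file}"
                )
            table = pd.read_csv(config.features_file)
            if config.meta_file:
                meta = read_metadata(config.meta_file)
                table = table.merge(meta, on="subject_id")
        else:
            raise PipelineError(
                "extract: no input (enable simulate or give features_file)"
            )

        model = None
        if "fit" in config.stages:
            model = _stage_fit(config, table, out, report)
        if "score" in config.stages:
            if model is None:
                raise PipelineError("score: no fitted model (enable fit)")
            table = _stage_score(config, table, model, out, report)
        if "compare" in config.stages:
            _stage_compare(config, table, out, report)
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _stage_simulate(config: RunConfig, out: Path, report: dict) -> pd.DataFrame:
    seed = _seed_for(config, "simulate")
    if config.simulate_landmarks:
        cohort_cfg = CohortConfig(seed=seed)
        records, lsets = synthetic.generate_cohort(cohort_cfg)
        write_landmarks(lsets, out / "landmarks.csv")
        vectors = [feat.extract_features(ls) for ls in lsets]
        table = feat.features_to_table(vectors).reset_index()
        table = table.merge(records_to_frame(records), on="subject_id")
    else:
        table, _records = synthetic.generate_feature_table(
            FeatureTableConfig(), seed=seed
        )
    records_path = out / "meta.csv"
    table[["subject_id", "sex", "family_group", "age"]].to_csv(
        records_path, index=False
    )
    table.to_csv(out / "features.csv", index=False)
    report["stages"]["simulate"] = {
        "seed": seed,
        "n_subjects": int(len(table)),
        "features_file": str(out / "features.csv"),
    }
    return table


def _feature_columns(config: RunConfig, table: pd.DataFrame) -> list[str]:
    if config.feature_subset:
        cols = [c for c in config.feature_subset if c in table.columns]
        if not cols:
            raise PipelineError("fit: none of the configured features present")
        return cols
    skip = {"subject_id", "sex", "family_group", "age", "facial_area",
            "masculinity_score"}
    return [c for c in table.columns if c not in skip
            and pd.api.types.is_numeric_dtype(table[c])]


def _stage_fit(config: RunConfig, table: pd.DataFrame, out: Path,
               report: dict):
    seed = _seed_for(config, "fit")
    cols = _feature_columns(config, table)
    model = gender.GenderMasculinityModel(
        feature_subset=cols if config.feature_subset else None,
        max_features=config.max_features, k=config.k_folds, seed=seed,
    ).fit(table[cols], table["sex"].to_numpy())
    model.to_json(out / "model.json")
    report["stages"]["fit"] = {
        "seed": seed,
        "selected_features": model.selected_features_,
        "cv_accuracy": model.cv_accuracy_,
        "model_file": str(out / "model.json"),
    }
    return model


def _stage_score(config: RunConfig, table: pd.DataFrame, model, out: Path,
                 report: dict) -> pd.DataFrame:
    scores = model.masculinity_score(table)
    scored = table.assign(masculinity_score=scores)
    scored[["subject_id", "masculinity_score"]].to_csv(
        out / "scores.csv", index=False
    )
    report["stages"]["score"] = {
        "n_scored": int(len(scored)),
        "score_min": float(scores.min()),
        "score_max": float(scores.max()),
        "scores_file": str(out / "scores.csv"),
    }
    return scored


def _stage_compare(config: RunConfig, table: pd.DataFrame, out: Path,
                   report: dict) -> None:
    seed = _seed_for(config, "compare")
    if "masculinity_score" not in table.columns:
        raise PipelineError("compare: no masculinity_score column "
                            "(enable score)")
    variables = ["masculinity_score"] + [
        c for c in _feature_columns(config, table)
        if c != "masculinity_score"
    ]
    analysis, transform_meta = feat.transform_features(table)

    screen = stats.screen_covariates(analysis, variables,
                                     covariates=("age", "facial_area"))
    active = tuple(
        c for c in config.covariates
        if any(r.include and r.covariate == c for r in screen)
    )
    alpha = stats.bonferroni_alpha(config.family_size,
                                   config.alpha_familywise)
    results = [
        stats.ancova_test(analysis, v, covariates=active, alpha=alpha)
        for v in variables
    ]
    table_out = stats.comparison_table(results, analysis)
    table_out.to_csv(out / "group_comparison.csv", index=False)

    significant = [r.variable for r in results if r.significant]
    diag_vars = significant or variables
    diag_acc = stats.classify_diagnosis(
        analysis, diag_vars, k=config.k_folds, seed=seed, balance=True
    )
    dens = stats.density_report(table)
    stats.density_table(dens).to_csv(out / "score_densities.csv", index=False)

    report["stages"]["compare"] = {
        "seed": seed,
        "alpha": alpha,
        "transforms": transform_meta,
        "covariates_used": list(active),
        "n_significant": len(significant),
        "significant": significant,
        "diagnosis_variables": diag_vars,
        "diagnosis_cv_accuracy": diag_acc,
        "comparison_file": str(out / "group_comparison.csv"),
        "densities_file": str(out / "score_densities.csv"),
        "group_results": {
            r.variable: {"F": r.F_group, "df": list(r.df_group),
                         "p": r.p_group, "d": r.d_adjusted,
                         "d_ci95": list(r.d_ci95),
                         "significant": r.significant}
            for r in results
        },
    }
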