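"""End-to-end pipeline: synthesis -> screening -> imputation -> BLUPs -> ML tiers.

``run_pipeline`` chains every stage on one ``RunConfig`` and writes each
stage's outputs under a run directory, together with a manifest (config echo,
master seed, config hash, per-stage shapes and warnings).  Any stage after
imputation can be toggled off; the manifest is emitted on success or failure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import impute as impute_mod
from . import io as io_mod
from . import linmod, prescriptive, synth, yield_model
from ._rng import child_int

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


_SCHEMA: dict = {
    "seed": 0,
    "out_dir": "runs/out",
    "input": None,  # path to an existing trial CSV; None -> synthesize
    "synth": {
        "n_genotypes": 32,
        "missing_rate": 0.05,
        "outlier_rate": 0.01,
        "gxm_fraction": 5 / 32,
        "gxm_shift_sd": 1.0,
    },
    "stages": {
        "outliers": True,
        "impute": True,
        "yield_model": True,
        "rfe": True,
        "fit_classes": True,
        "compare_sources": True,
    },
    "outliers": {"threshold": 3.0},
    "impute": {"max_iter": 10, "n_trees": 100},
    "model": {"n_trees": 300, "repeats": 10, "folds": 10, "split": 0.8, "tune": False, "per_treatment": True},
    "rfe": {"subset_sizes": None, "tolerance_pct": 5.0, "repeats": 10, "n_trees": 200},
    "selection": {"intensity": 0.2},
    "fit": {"k_sd": 1.0, "repeats": 10, "n_trees": 200},
}


def _merge(schema: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, default in schema.items():
        if isinstance(default, dict) and key != "synth_overrides":
            out[key] = _merge(default, user.get(key, {}) or {}, f"{path}{key}.")
        else:
            out[key] = user.get(key, default)
    unknown = set(user) - set(schema)
    if unknown:
        raise ValueError(f"unknown configuration key(s) {sorted(unknown)} under {path or 'top level'}")
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    options: dict

    @classmethod
    def from_dict(cls, user: dict) -> "RunConfig":
        return cls(_merge(_SCHEMA, user or {}))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io_mod.load_yaml_config(path))

    def __getitem__(self, key):
        return self.options[key]

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.options, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    config: dict
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    status: str = "running"

    def record(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=str)


def _save(df: pd.DataFrame, out_dir: Path, name: str) -> None:
    df.to_csv(out_dir / name, index=False, float_format="%.10g")


def _model_scopes(blups: pd.DataFrame, per_treatment: bool):
    yield "combined", blups
    if per_treatment:
        for (sid, trt), grp in blups.groupby(["study", "treatment"], observed=True, sort=True):
            yield f"{sid}:{trt}", grp


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute every enabled stage; outputs and a manifest under ``out_dir``."""
    opts = config.options
    seed = int(opts["seed"])
    out_dir = Path(opts["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config_hash=config.hash(), config=opts)
    try:
        _run_stages(config, manifest, out_dir)
        manifest.status = "success"
    except Exception as exc:  # manifest records the failure point, then re-raise
        manifest.record("FAILED", error=f"{type(exc).__name__}: {exc}")
        manifest.status = "failed"
        raise
    finally:
        (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest


def _run_stages(config: RunConfig, manifest: RunManifest, out_dir: Path) -> None:
    opts = config.options
    seed = int(opts["seed"])

    # --- synthesize or read ------------------------------------------------ #
    if opts["input"]:
        dataset = io_mod.read_trial(opts["input"])
        manifest.record("read", rows=len(dataset.records), source=str(opts["input"]))
    else:
        s = opts["synth"]
        trial_cfg = synth.default_config(
            n_genotypes=int(s["n_genotypes"]),
            gxm_fraction=float(s["gxm_fraction"]),
            gxm_shift_sd=float(s["gxm_shift_sd"]),
            missing_rate=float(s["missing_rate"]),
            outlier_rate=float(s["outlier_rate"]),
            seed=child_int(seed, "synth"),
        )
        dataset = synth.generate_trial(trial_cfg)
        dataset = synth.inject_outliers(dataset, trial_cfg.outlier_rate, 8.0, seed=child_int(seed, "outliers"))
        dataset = synth.inject_missingness(dataset, trial_cfg.missing_rate, seed=child_int(seed, "missing"))
        manifest.record("synth", rows=len(dataset.records), traits=len(dataset.trait_columns))
    io_mod.write_trial(dataset, out_dir / "trial.csv", out_dir / "trial.truth.json")

    # --- outlier screen ---------------------------------------------------- #
    if opts["stages"]["outliers"]:
        dataset, report = linmod.screen_outliers(dataset, threshold=float(opts["outliers"]["threshold"]))
        _save(report, out_dir, "outlier_report.csv")
        manifest.record("outliers", flagged=len(report))

    # rows with missing yield are dropped, never imputed
    keep = dataset.records["seed_yield"].notna()
    if (~keep).any():
        manifest.warnings.append(f"{int((~keep).sum())} rows dropped for missing seed yield")
        dataset.records = dataset.records[keep].reset_index(drop=True)

    # --- imputation -------------------------------------------------------- #
    if opts["stages"]["impute"] and dataset.records[dataset.trait_columns].isna().any().any():
        result = impute_mod.iterative_rf_impute(
            dataset.records[dataset.trait_columns],
            max_iter=int(opts["impute"]["max_iter"]),
            n_trees=int(opts["impute"]["n_trees"]),
            seed=child_int(seed, "impute"),
        )
        dataset.records[dataset.trait_columns] = result.completed
        manifest.record("impute", iterations=result.n_iterations, converged=result.converged)

    # --- BLUPs ------------------------------------------------------------- #
    blups = linmod.compute_blups(dataset)
    _save(blups, out_dir, "blups.csv")
    manifest.record("blups", rows=len(blups))

    trait_cols = dataset.trait_columns
    if not trait_cols or not opts["stages"]["yield_model"]:
        return

    # --- yield models + importance ---------------------------------------- #
    # models are trained on genotype-effect BLUP deviations (centered within
    # each management x location trial); see yield_model.ml_matrix
    mo = opts["model"]
    X_all, y_all = yield_model.ml_matrix(blups, trait_cols)
    reports, importances, results = {}, {}, {}
    for scope, grp in _model_scopes(blups, bool(mo["per_treatment"])):
        pos = grp.index.to_numpy()
        X = X_all.iloc[pos].reset_index(drop=True)
        y = y_all.iloc[pos].reset_index(drop=True)
        res = yield_model.train_yield_model(
            X,
            y,
            split=float(mo["split"]),
            folds=int(mo["folds"]),
            repeats=int(mo["repeats"]),
            n_trees=int(mo["n_trees"]),
            tune=bool(mo["tune"]),
            seed=child_int(seed, "model", scope),
        )
        imp, _ = yield_model.mean_importance(res, X, y, seed=child_int(seed, "importance", scope))
        reports[scope] = res.report
        importances[scope] = imp
        results[scope] = (res, X, y)
    perf = pd.concat(
        [r.per_repeat.assign(scope=s) for s, r in reports.items()], ignore_index=True
    )
    _save(perf, out_dir, "model_performance.csv")
    imp_df = pd.concat(
        [t.table.assign(scope=s).rename_axis("predictor").reset_index() for s, t in importances.items()],
        ignore_index=True,
    )
    _save(imp_df, out_dir, "importance.csv")
    manifest.record("yield_model", scopes=list(reports))

    # --- selection-decision metrics ---------------------------------------- #
    intensity = float(opts["selection"]["intensity"])
    sel_rows = []
    for scope, (res, X, y) in results.items():
        for rep, (forest, te) in enumerate(zip(res.forests, res.test_idx)):
            counts = prescriptive.selection_confusion(forest.predict(X.iloc[te]), y.iloc[te].to_numpy(), intensity)
            m = prescriptive.classification_metrics(counts)
            sel_rows.append({"scope": scope, "repeat": rep, **m.__dict__})
    sel = pd.DataFrame(sel_rows)
    _save(sel, out_dir, "selection_metrics.csv")
    manifest.record("selection", scopes=sel["scope"].nunique(), intensity=intensity)

    # --- RFE --------------------------------------------------------------- #
    subset = trait_cols
    if opts["stages"]["rfe"]:
        ro = opts["rfe"]
        rfe = yield_model.run_rfe(
            X_all,
            y_all,
            subset_sizes=ro["subset_sizes"],
            tolerance_pct=float(ro["tolerance_pct"]),
            repeats=int(ro["repeats"]),
            n_trees=int(ro["n_trees"]),
            seed=child_int(seed, "rfe"),
        )
        rfe.rmse_profile.reset_index().to_csv(out_dir / "rfe_profile.csv", index=False, float_format="%.10g")
        pd.DataFrame(
            {
                "predictor": rfe.ranking,
                "in_consensus": [c in rfe.consensus_subset for c in rfe.ranking],
                "in_tolerance_subset": [c in rfe.tolerance_subset for c in rfe.ranking],
            }
        ).to_csv(out_dir / "rfe_selection.csv", index=False)
        manifest.record(
            "rfe",
            optimal_size=rfe.optimal_size,
            tolerance_size=rfe.tolerance_size,
            consensus_size=len(rfe.consensus_subset),
        )
        subset = rfe.tolerance_subset

    # --- fit classes and classifiers --------------------------------------- #
    if not opts["stages"]["fit_classes"]:
        return
    fo = opts["fit"]
    trial_cfg_studies = synth.default_config().studies if not opts["input"] else None
    studies = []
    for sid in blups["study"].unique():
        match = None
        if trial_cfg_studies:
            match = next((st for st in trial_cfg_studies if st.study_id == sid), None)
        if match is None:
            levels = tuple(blups.loc[blups["study"] == sid, "treatment"].unique())
            match = synth.StudyDesign(sid, levels, 1, 2)
        studies.append(match)

    for study in studies:
        fit = prescriptive.compute_fit_deviations(blups, study)
        fit = prescriptive.assign_fit_classes(fit, k_sd=float(fo["k_sd"]))
        _save(fit.table, out_dir, f"fit_classes_{study.study_id}.csv")
        manifest.record(
            f"fit_classes:{study.study_id}",
            mu_g=fit.mu_g,
            sd_g=fit.sd_g,
            counts=fit.table["fit_class"].value_counts().to_dict(),
        )
        class_of = dict(zip(fit.table["genotype"], fit.table["fit_class"]))
        sub_mask = (
            (blups["study"] == study.study_id)
            & (blups["treatment"].isin(study.contrast_pair))
            & (blups["genotype"].isin(class_of))
        )
        pos = np.flatnonzero(sub_mask.to_numpy())
        rows = blups.iloc[pos].reset_index(drop=True)
        Xc = X_all.iloc[pos][list(subset)].reset_index(drop=True)
        yc = rows["genotype"].map(class_of)
        if yc.nunique() < 2:
            manifest.warnings.append(f"study {study.study_id}: single fit class; classifier skipped")
            continue
        metrics = prescriptive.train_fit_classifier(
            Xc,
            yc,
            groups=rows["genotype"],
            repeats=int(fo["repeats"]),
            n_trees=int(fo["n_trees"]),
            seed=child_int(seed, "fit_clf", study.study_id),
        )
        _save(metrics.reset_index(), out_dir, f"fit_classifier_{study.study_id}.csv")
        manifest.record(f"fit_classifier:{study.study_id}", classes=len(metrics))
        if opts["stages"]["compare_sources"]:
            comparison = prescriptive.compare_training_sources(
                Xc,
                yc,
                treatments=rows["treatment"],
                groups=rows["genotype"],
                repeats=int(fo["repeats"]),
                n_trees=int(fo["n_trees"]),
                seed=child_int(seed, "sources", study.study_id),
            )
            _save(comparison, out_dir, f"source_comparison_{study.study_id}.csv")
            manifest.record(f"compare_sources:{study.study_id}", sources=comparison["source"].nunique())
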