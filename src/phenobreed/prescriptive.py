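"""Genotype agro-management fit classification and breeding selection metrics.

A genotype's management-fit deviation D_g is the difference of its seed-yield
BLUP (averaged over locations) between the two contrast treatment levels of a
study.  Against the genotype-population mean mu_g and SD of D_g, genotypes
with D_g above mu_g + 1 SD are adapted to the first level, below mu_g - 1 SD
to the second, and universal in between (boundary values are universal).

Selection decisions at a breeder's selection intensity (top 20% by default)
are scored with a confusion matrix — selected = top-k by predicted yield,
positive = top-k by observed yield — from which sensitivity, specificity,
precision, balanced accuracy and overall selection accuracy follow.

Fit classes are predicted from the RFE-selected trait subset with a
random-forest classifier: genotype-level stratified 80/20 splits (all of a
genotype's rows stay on one side), minority classes upsampled inside the
training split only, per-class one-vs-rest metrics averaged over repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils import resample

from ._rng import child_int, substream
from .synth import StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "FitClassTable",
    "selection_confusion",
    "classification_metrics",
    "compute_fit_deviations",
    "assign_fit_classes",
    "upsample_classes",
    "train_fit_classifier",
    "compare_training_sources",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ClassMetrics:
    """Breeding-relevant classification metrics; undefined ratios are NaN."""

    BACC: float
    PRE: float
    SEN: float
    SPE: float
    selection_accuracy: float


def selection_confusion(predicted, observed, intensity: float = 0.2) -> ConfusionCounts:
    """Confusion matrix of advancing the top-``intensity`` fraction.

    ``positive`` = membership of the top-k by observed yield; ``selected`` =
    top-k by predicted yield, k = round(intensity * n).  Ties spanning the
    k-th rank are broken by stable input order (logged).
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be aligned 1-D vectors")
    n = len(pred)
    if n < 2:
        raise ValueError("need at least 2 candidates")
    if not (0 < intensity < 1):
        raise ValueError("intensity must be in (0, 1)")
    k = int(round(intensity * n))
    k = min(max(k, 1), n - 1)
    sel = np.argsort(-pred, kind="stable")[:k]
    pos = np.argsort(-obs, kind="stable")[:k]
    for name, vals, top in (("predicted", pred, sel), ("observed", obs, pos)):
        boundary = vals[top[-1]]
        if np.sum(vals == boundary) > 1:
            logger.info("ties at the selection boundary of %s broken by input order", name)
    tp = len(set(sel.tolist()) & set(pos.tolist()))
    return ConfusionCounts(TP=tp, FP=k - tp, FN=k - tp, TN=n - 2 * k + tp)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); returning missing", name)
        return float("nan")
    return num / den


def classification_metrics(counts: ConfusionCounts) -> ClassMetrics:
    """SEN, SPE, PRE, BACC and selection accuracy from a confusion matrix."""
    if counts.total == 0:
        raise ValueError("no decisions to score")
    sen = _ratio(counts.TP, counts.TP + counts.FN, "sensitivity")
    spe = _ratio(counts.TN, counts.TN + counts.FP, "specificity")
    pre = _ratio(counts.TP, counts.TP + counts.FP, "precision")
    bacc = (sen + spe) / 2.0
    acc = (counts.TP + counts.TN) / counts.total
    return ClassMetrics(BACC=bacc, PRE=pre, SEN=sen, SPE=spe, selection_accuracy=acc)


@dataclass
class FitClassTable:
    """Per-genotype fit deviation D_g and (after assignment) its class."""

    table: pd.DataFrame  # columns: genotype, D_g [, fit_class]
    mu_g: float
    sd_g: float
    contrast: tuple[str, str]
    labels: tuple[str, str, str]


def compute_fit_deviations(
    blups: pd.DataFrame, study: StudyDesign, contrast: tuple[str, str] | None = None
) -> FitClassTable:
    """D_g = seed-yield BLUP(level 1) - BLUP(level 2), averaged over locations.

    Genotypes missing either contrast level are excluded with a warning.
    mu_g and sd_g (sample SD, n-1) are computed over the retained genotypes.
    """
    contrast = contrast or study.contrast_pair
    t1, t2 = contrast
    sub = blups[blups["study"] == study.study_id]
    if sub.empty:
        raise ValueError(f"no BLUP rows for study {study.study_id!r}")
    means = sub.groupby(["genotype", "treatment"], observed=True)["seed_yield"].mean().unstack("treatment")
    for lev in (t1, t2):
        if lev not in means.columns:
            raise ValueError(f"contrast level {lev!r} absent from BLUP table")
    dropped = means.index[means[[t1, t2]].isna().any(axis=1)]
    if len(dropped):
        logger.warning("genotypes missing a contrast level excluded: %s", list(dropped))
        means = means.drop(index=dropped)
    d = means[t1] - means[t2]
    table = pd.DataFrame({"genotype": d.index, "D_g": d.to_numpy()}).reset_index(drop=True)
    labels = study.labels if contrast == study.contrast_pair else (f"{t1}-adapted", "U", f"{t2}-adapted")
    return FitClassTable(table=table, mu_g=float(d.mean()), sd_g=float(d.std(ddof=1)), contrast=(t1, t2), labels=labels)


def assign_fit_classes(fit: FitClassTable, k_sd: float = 1.0) -> FitClassTable:
    """Classify each genotype against mu_g +- k_sd x sd_g.

    Above the band: adapted to the first contrast level; below: adapted to the
    second; inside (boundary inclusive): universal.  Zero dispersion puts
    every genotype in the universal class.
    """
    hi = fit.mu_g + k_sd * fit.sd_g
    lo = fit.mu_g - k_sd * fit.sd_g
    lab_hi, lab_mid, lab_lo = fit.labels
    d = fit.table["D_g"].to_numpy()
    cls = np.where(d > hi, lab_hi, np.where(d < lo, lab_lo, lab_mid))
    if fit.sd_g == 0:
        cls = np.full(len(d), lab_mid, dtype=object)
    out = fit.table.copy()
    out["fit_class"] = cls
    return FitClassTable(out, fit.mu_g, fit.sd_g, fit.contrast, fit.labels)


def upsample_classes(X: pd.DataFrame, classes: pd.Series, seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Resample minority classes with replacement up to the majority count.

    Every synthetic row duplicates an existing row of its class.  A single
    class comes back unchanged with a warning.
    """
    counts = classes.value_counts()
    if len(counts) < 2:
        logger.warning("only one class present; nothing to upsample")
        return X.copy(), classes.copy()
    target = int(counts.max())
    parts_X, parts_y = [], []
    for i, (label, cnt) in enumerate(sorted(counts.items())):
        mask = classes == label
        parts_X.append(X[mask])
        parts_y.append(classes[mask])
        if cnt < target:
            Xr, yr = resample(
                X[mask], classes[mask], replace=True, n_samples=target - cnt, random_state=child_int(seed, "upsample", label)
            )
            parts_X.append(Xr)
            parts_y.append(yr)
    return pd.concat(parts_X), pd.concat(parts_y)


def _one_vs_rest_counts(y_true: np.ndarray, y_pred: np.ndarray, label) -> ConfusionCounts:
    t = y_true == label
    p = y_pred == label
    return ConfusionCounts(
        TP=int(np.sum(t & p)), TN=int(np.sum(~t & ~p)), FP=int(np.sum(~t & p)), FN=int(np.sum(t & ~p))
    )


def train_fit_classifier(
    X: pd.DataFrame,
    classes: pd.Series,
    groups: pd.Series | None = None,
    repeats: int = 10,
    n_trees: int = 200,
    split: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-forest fit-class prediction, per-class metrics averaged over repeats.

    ``groups`` (typically the genotype label per row) keeps all rows of one
    genotype on the same side of the stratified 80/20 split, so metrics
    reflect prediction on unseen genotypes.  Upsampling balances the training
    split only.  Returns a frame indexed by class with mean and SD of each
    metric plus the number of repeats where the class appeared in the test
    split.
    """
    if classes.nunique() < 2:
        raise ValueError("need >= 2 classes to train a classifier")
    groups = groups if groups is not None else pd.Series(np.arange(len(X)), index=X.index)
    per_class: dict = {c: [] for c in sorted(classes.unique())}
    unit = pd.DataFrame({"group": groups, "cls": classes}).drop_duplicates("group")
    for rep in range(repeats):
        strat = unit["cls"] if unit["cls"].value_counts().min() >= 2 else None
        if strat is None:
            logger.warning("a class has a single genotype; split not stratified this run")
        tr_g, te_g = train_test_split(
            unit["group"], test_size=1 - split, stratify=strat, random_state=child_int(seed, "clf_split", rep)
        )
        tr_mask = groups.isin(tr_g).to_numpy()
        Xtr, ytr = upsample_classes(X[tr_mask], classes[tr_mask], seed=child_int(seed, "clf_up", rep))
        clf = RandomForestClassifier(
            n_estimators=n_trees, min_samples_leaf=1, random_state=child_int(seed, "clf_fit", rep), n_jobs=1
        )
        clf.fit(Xtr.to_numpy(dtype=float), ytr.to_numpy())
        y_true = classes[~tr_mask].to_numpy()
        y_pred = clf.predict(X[~tr_mask].to_numpy(dtype=float))
        for label in per_class:
            if label not in set(y_true):
                continue  # class absent from this test split; averaged over available repeats
            m = classification_metrics(_one_vs_rest_counts(y_true, y_pred, label))
            per_class[label].append(m)
    rows = []
    for label, ms in per_class.items():
        if not ms:
            logger.warning("class %r never appeared in a test split", label)
            continue
        arr = pd.DataFrame([m.__dict__ for m in ms])
        row = {"fit_class": label, "n_repeats": len(ms)}
        for col in arr.columns:
            row[col] = arr[col].mean()
            row[f"{col}_sd"] = arr[col].std(ddof=1) if len(ms) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("fit_class")


def compare_training_sources(
    X: pd.DataFrame,
    classes: pd.Series,
    treatments: pd.Series,
    groups: pd.Series | None = None,
    sources: list[str] | None = None,
    repeats: int = 10,
    n_trees: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit-class prediction metrics per training-data source.

    Sources are each single treatment level plus the pooled ``all`` rows; the
    fit classes are fixed once (per genotype) and only the predictor rows
    change.  Sources with no rows are skipped with a warning.  Returns the
    per-source, per-class metric table used to judge whether one breeding
    pipeline can serve several management systems.
    """
    sources = sources if sources is not None else [*list(dict.fromkeys(treatments)), "all"]
    frames = []
    for src in sources:
        mask = np.ones(len(X), dtype=bool) if src == "all" else (treatments == src).to_numpy()
        if not mask.any():
            logger.warning("training source %r has no rows; skipped", src)
            continue
        res = train_fit_classifier(
            X[mask],
            classes[mask],
            groups=None if groups is None else groups[mask],
            repeats=repeats,
            n_trees=n_trees,
            seed=child_int(seed, "source", src),
        )
        res = res.reset_index()
        res.insert(0, "source", src)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
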