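"""Random-forest seed-yield regression with OOB permutation importance and RFE.

The forest is a bagging ensemble of regression trees with per-node feature
subsampling; in-bag indices are tracked per tree, so out-of-bag (OOB)
predictions, OOB error and tree-wise permutation importance are available
without touching the held-out test split.

Importance semantics: for every tree and predictor, permute that predictor
among the tree's OOB rows and record the increase in OOB mean squared error;
the raw importance is the mean increase across trees, and the scaled
importance maps the raw values onto [0, 100] with the top predictor at 100.

Recursive feature elimination (RFE) is backward selection on the importance
ranking: per training repeat, rank the predictors, retrain on the top-k for a
grid of subset sizes, and score each by OOB RMSE.  The optimal size minimizes
OOB RMSE; the tolerance size is the smallest subset within a given percentage
of the optimum.  A consensus subset collects predictors selected in at least
half of the repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from ._rng import child_int, substream

logger = logging.getLogger(__name__)

__all__ = [
    "OOBForest",
    "ModelReport",
    "TrainResult",
    "ImportanceTable",
    "RFEResult",
    "zscore_normalize",
    "ml_matrix",
    "train_yield_model",
    "permutation_importance",
    "mean_importance",
    "importance_contrast",
    "run_rfe",
    "default_subset_sizes",
]


def zscore_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Center and scale every predictor column: z = (x - mean) / sd.

    Sample standard deviation (n-1).  Returns the normalized matrix and a
    params frame (columns ``mean``, ``sd``) for reuse on held-out data.
    Constant columns make z undefined and raise, naming them.
    """
    mean = matrix.mean()
    sd = matrix.std(ddof=1)
    constant = list(matrix.columns[(sd == 0) | sd.isna()])
    if constant:
        raise ValueError(f"constant columns cannot be z-scored: {constant}")
    z = (matrix - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return z, params


def ml_matrix(blups: pd.DataFrame, trait_cols: list[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Genotype-effect design matrix and response from a BLUP table.

    Predictors and the seed-yield response are centered within each
    management-treatment x location trial, leaving the predicted genotype
    effects: environment main effects are not predictable from genotype
    phenotypes, and keeping them in the response lets any trait column act as
    a location fingerprint rather than a physiological predictor.  Predictors
    are then scaled to unit sample SD (z-scores of the centered values); a
    column with zero dispersion — a trait fully shrunk to the trial mean in
    every group — stays at exactly zero with a warning.
    """
    grouped = blups.groupby(["study", "treatment", "location"], observed=True)
    Xc = (blups[trait_cols] - grouped[trait_cols].transform("mean")).reset_index(drop=True)
    yc = (blups["seed_yield"] - grouped["seed_yield"].transform("mean")).reset_index(drop=True)
    sd = Xc.std(ddof=1)
    degenerate = list(Xc.columns[(sd == 0) | sd.isna()])
    if degenerate:
        logger.warning("predictor(s) with zero dispersion after centering kept as zeros: %s", degenerate)
        sd = sd.replace(0, 1.0).fillna(1.0)
    return Xc / sd, yc


def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


class OOBForest:
    """Regression forest with public per-tree in-bag bookkeeping.

    Bagging over depth-unlimited regression trees, ``mtry`` split candidates
    per node, minimum leaf size 5.  ``oob_predict`` aggregates each row's
    prediction over the trees that did not sample it.
    """

    def __init__(self, n_trees: int = 300, mtry: int | None = None, min_samples_leaf: int = 5, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed
        self.model: BaggingRegressor | None = None
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OOBForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        mtry = self.mtry or max(1, X.shape[1] // 3)
        self.model = BaggingRegressor(
            estimator=DecisionTreeRegressor(max_features=min(mtry, X.shape[1]), min_samples_leaf=self.min_samples_leaf),
            n_estimators=self.n_trees,
            bootstrap=True,
            n_jobs=1,
            random_state=self.seed,
        )
        self.model.fit(X, y)
        self._X, self._y = X, y
        return self

    def predict(self, X) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))

    def oob_masks(self) -> list[np.ndarray]:
        """Boolean OOB mask per tree over the training rows."""
        n = len(self._y)
        masks = []
        for sampled in self.model.estimators_samples_:
            inbag = np.zeros(n, dtype=bool)
            inbag[sampled] = True
            masks.append(~inbag)
        return masks

    def oob_predict(self) -> np.ndarray:
        """Per-row mean prediction over trees where the row was out-of-bag.

        Rows in-bag for every tree (vanishingly rare beyond a few trees) come
        back NaN and are excluded from OOB metrics.
        """
        n = len(self._y)
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.model.estimators_, self.oob_masks()):
            if not oob.any():
                continue
            total[oob] += tree.predict(self._X[oob])
            count[oob] += 1
        out = np.full(n, np.nan)
        seen = count > 0
        out[seen] = total[seen] / count[seen]
        return out

    def oob_metrics(self) -> tuple[float, float]:
        pred = self.oob_predict()
        ok = ~np.isnan(pred)
        return _rmse(self._y[ok], pred[ok]), _r2(self._y[ok], pred[ok])


@dataclass
class ModelReport:
    """Averaged and per-repeat performance of the yield model."""

    per_repeat: pd.DataFrame  # columns: repeat, mtry, oob_rmse, oob_r2, test_rmse, test_r2
    split_fraction: float
    n_folds: int

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    @property
    def means(self) -> pd.Series:
        return self.per_repeat[["oob_rmse", "oob_r2", "test_rmse", "test_r2"]].mean()


@dataclass
class TrainResult:
    """Fitted ensembles (one per repeat) with their splits, plus the report."""

    forests: list[OOBForest]
    train_idx: list[np.ndarray]
    test_idx: list[np.ndarray]
    report: ModelReport
    feature_names: list[str]


def _mtry_grid(p: int) -> list[int]:
    grid = sorted({max(1, p // 3), max(1, int(np.sqrt(p))), max(1, (2 * p) // 3)})
    return grid


def train_yield_model(
    X: pd.DataFrame,
    y: pd.Series,
    split: float = 0.8,
    folds: int = 10,
    repeats: int = 10,
    n_trees: int = 300,
    tune: bool = True,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> TrainResult:
    """Train the forest with repeated fresh 80/20 splits.

    Per repeat: random split; if ``tune``, the split-candidate count (mtry) is
    chosen by k-fold cross-validated RMSE on the training portion over the
    grid {p/3, sqrt(p), 2p/3}; the final forest is fit on the full training
    portion, and OOB (training) plus held-out test RMSE/R² recorded.  Rows
    with missing yield must be removed beforehand.  Fully deterministic for a
    fixed seed.
    """
    if len(X) != len(y):
        raise ValueError("X and y must be aligned")
    if y.isna().any():
        raise ValueError("remove rows with missing yield before training")
    if len(X) < folds:
        raise ValueError(f"fewer rows ({len(X)}) than folds ({folds})")
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n, p = Xv.shape
    n_train = int(round(split * n))
    rows = []
    forests, train_ids, test_ids = [], [], []
    for rep in range(repeats):
        perm = substream(seed, "split", rep).permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        mtry = max(1, p // 3)
        if tune:
            grid = _mtry_grid(p)
            if len(grid) > 1:
                cv_scores = []
                kf = KFold(n_splits=folds, shuffle=True, random_state=child_int(seed, "cv", rep))
                fold_splits = list(kf.split(tr))
                for m in grid:
                    errs = []
                    for f, (ia, ib) in enumerate(fold_splits):
                        fa, fb = tr[ia], tr[ib]
                        forest = OOBForest(n_trees, m, min_samples_leaf, child_int(seed, "cvfit", rep, m, f))
                        forest.fit(Xv[fa], yv[fa])
                        errs.append(_rmse(yv[fb], forest.predict(Xv[fb])))
                    cv_scores.append(np.mean(errs))
                mtry = grid[int(np.argmin(cv_scores))]
        forest = OOBForest(n_trees, mtry, min_samples_leaf, child_int(seed, "fit", rep))
        forest.fit(Xv[tr], yv[tr])
        oob_rmse, oob_r2 = forest.oob_metrics()
        pred = forest.predict(Xv[te])
        rows.append(
            {
                "repeat": rep,
                "mtry": mtry,
                "oob_rmse": oob_rmse,
                "oob_r2": oob_r2,
                "test_rmse": _rmse(yv[te], pred),
                "test_r2": _r2(yv[te], pred),
            }
        )
        forests.append(forest)
        train_ids.append(tr)
        test_ids.append(te)
    report = ModelReport(pd.DataFrame(rows), split, folds)
    return TrainResult(forests, train_ids, test_ids, report, list(X.columns))


@dataclass
class ImportanceTable:
    """Per-predictor permutation importance: raw, 0-100 scaled, and rank."""

    table: pd.DataFrame  # index: predictor; columns: raw_importance, scaled_importance, rank

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def _scale_importance(raw: pd.Series) -> pd.DataFrame:
    clipped = raw.clip(lower=0.0)
    top = clipped.max()
    scaled = 100.0 * clipped / top if top > 0 else clipped * 0.0
    # rank 1 = most important; ties broken by column order for reproducibility
    order = np.lexsort((np.arange(len(raw)), -raw.to_numpy()))
    rank = np.empty(len(raw), dtype=int)
    rank[order] = np.arange(1, len(raw) + 1)
    return pd.DataFrame({"raw_importance": raw, "scaled_importance": scaled, "rank": rank})


def permutation_importance(forest: OOBForest, X: pd.DataFrame, y: pd.Series, seed: int = 0) -> ImportanceTable:
    """Tree-wise OOB permutation importance of every predictor.

    For each tree: baseline OOB MSE, then for each predictor the OOB MSE with
    that predictor's values permuted among the tree's OOB rows; the raw
    importance is the mean MSE increase across trees.  Trees with no OOB rows
    are skipped with a warning.
    """
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    p = Xv.shape[1]
    acc = np.zeros(p)
    used = 0
    rng = substream(seed, "perm_importance")
    for tree, oob in zip(forest.model.estimators_, forest.oob_masks()):
        if not oob.any():
            logger.warning("tree with no OOB rows skipped in permutation importance")
            continue
        Xo = Xv[oob]
        yo = yv[oob]
        m = len(yo)
        base_mse = float(np.mean((yo - tree.predict(Xo)) ** 2))
        # one big prediction per tree: p stacked copies, each with one column permuted
        big = np.tile(Xo, (p, 1, 1))
        for j in range(p):
            big[j, :, j] = Xo[rng.permutation(m), j]
        preds = tree.predict(big.reshape(p * m, p)).reshape(p, m)
        acc += np.mean((yo[None, :] - preds) ** 2, axis=1) - base_mse
        used += 1
    if used == 0:
        raise ValueError("no tree had OOB rows; cannot compute importance")
    raw = pd.Series(acc / used, index=X.columns, name="raw_importance")
    return ImportanceTable(_scale_importance(raw))


def mean_importance(result: TrainResult, X: pd.DataFrame, y: pd.Series, seed: int = 0) -> tuple[ImportanceTable, list[ImportanceTable]]:
    """Importance per training repeat (on that repeat's training rows), plus the mean table."""
    per_repeat = []
    for rep, (forest, tr) in enumerate(zip(result.forests, result.train_idx)):
        per_repeat.append(permutation_importance(forest, X.iloc[tr], y.iloc[tr], seed=child_int(seed, "imp", rep)))
    raw = pd.concat([t.table["raw_importance"] for t in per_repeat], axis=1).mean(axis=1)
    return ImportanceTable(_scale_importance(raw)), per_repeat


def importance_contrast(a: ImportanceTable, b: ImportanceTable, threshold: float = 25.0) -> pd.DataFrame:
    """Scaled-importance differences between two treatments.

    Returns per-predictor scaled importances, |difference| on the 0-100
    scale, and whether it exceeds ``threshold`` — the screen used to call a
    predictor's importance conditional on the management system.
    """
    sa = a.table["scaled_importance"]
    sb = b.table["scaled_importance"].reindex(sa.index)
    diff = (sa - sb).abs()
    return pd.DataFrame(
        {"scaled_a": sa, "scaled_b": sb, "abs_difference": diff, "conditional": diff > threshold}
    ).sort_values("abs_difference", ascending=False)


def default_subset_sizes(p: int) -> list[int]:
    sizes = [*range(1, 11), 12, 15, 20, 25, 30, 40, 50]
    return sorted({s for s in sizes if s < p} | {p})


@dataclass
class RFEResult:
    """Backward-elimination outcome across training repeats."""

    rmse_profile: pd.DataFrame  # index: subset size; columns: one per repeat + 'mean'
    per_repeat_optimal: list[list[str]]
    per_repeat_tolerance: list[list[str]]
    consensus_subset: list[str]
    tolerance_subset: list[str]
    optimal_size: int
    tolerance_size: int
    tolerance_pct: float
    performance_full: ModelReport | None = None
    performance_subset: ModelReport | None = None
    ranking: list[str] = field(default_factory=list)


def _tolerance_size(sizes: list[int], rmse: np.ndarray, tolerance_pct: float) -> tuple[int, int]:
    best = int(np.argmin(rmse))
    bound = (1 + tolerance_pct / 100.0) * rmse[best]
    for i, s in enumerate(sizes):
        if rmse[i] <= bound:
            return sizes[best], s
    return sizes[best], sizes[best]


def run_rfe(
    X: pd.DataFrame,
    y: pd.Series,
    subset_sizes: list[int] | None = None,
    tolerance_pct: float = 5.0,
    repeats: int = 10,
    n_trees: int = 300,
    split: float = 0.8,
    min_samples_leaf: int = 5,
    seed: int = 0,
    evaluate: bool = True,
) -> RFEResult:
    """Recursive feature elimination with consensus and tolerance selection.

    Per repeat: fresh 80/20 split; permutation-importance ranking on the
    training portion; retrain on the top-k predictors for every subset size
    and score by OOB RMSE on the training portion.  The consensus subset
    collects predictors in the optimal subset of >= ceil(repeats/2) repeats.
    The final tolerance subset takes the smallest size within
    ``tolerance_pct`` of the minimum of the mean RMSE profile, filled with the
    top predictors by mean rank; with ``evaluate`` the full and reduced models
    are retrained and reported side by side.
    """
    if subset_sizes is not None and len(subset_sizes) == 0:
        raise ValueError("subset_sizes must not be empty")
    p = X.shape[1]
    sizes = sorted(set(subset_sizes)) if subset_sizes is not None else default_subset_sizes(p)
    if any(s < 1 or s > p for s in sizes):
        raise ValueError(f"subset sizes must lie in 1..{p}")
    if tolerance_pct < 0:
        raise ValueError("tolerance_pct must be >= 0")
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    n_train = int(round(split * n))
    profile = np.zeros((len(sizes), repeats))
    rank_acc = np.zeros(p)
    per_repeat_optimal, per_repeat_tolerance = [], []
    for rep in range(repeats):
        perm = substream(seed, "rfe_split", rep).permutation(n)
        tr = perm[:n_train]
        ranker = OOBForest(n_trees, max(1, p // 3), min_samples_leaf, child_int(seed, "rfe_rank", rep))
        ranker.fit(Xv[tr], yv[tr])
        imp = permutation_importance(ranker, X.iloc[tr], y.iloc[tr], seed=child_int(seed, "rfe_imp", rep))
        ranking = imp.ranking
        rank_acc += imp.table["rank"].reindex(X.columns).to_numpy()
        col_pos = [X.columns.get_loc(c) for c in ranking]
        for i, k in enumerate(sizes):
            keep = col_pos[:k]
            sub = OOBForest(n_trees, max(1, round(k / 3)), min_samples_leaf, child_int(seed, "rfe_sub", rep, k))
            sub.fit(Xv[np.ix_(tr, keep)], yv[tr])
            profile[i, rep] = sub.oob_metrics()[0]
        opt_size, tol_size = _tolerance_size(sizes, profile[:, rep], tolerance_pct)
        per_repeat_optimal.append(ranking[:opt_size])
        per_repeat_tolerance.append(ranking[:tol_size])

    mean_rmse = profile.mean(axis=1)
    optimal_size, tolerance_size = _tolerance_size(sizes, mean_rmse, tolerance_pct)
    need = int(np.ceil(repeats / 2))
    counts = pd.Series(0, index=X.columns, dtype=int)
    for sel in per_repeat_optimal:
        counts[sel] += 1
    consensus = [c for c in X.columns if counts[c] >= need]
    # final ranking: mean per-repeat rank, ties broken by column order
    mean_rank = rank_acc / repeats
    order = np.lexsort((np.arange(p), mean_rank))
    final_ranking = [X.columns[i] for i in order]
    tolerance_subset = final_ranking[:tolerance_size]

    prof_df = pd.DataFrame(profile, index=pd.Index(sizes, name="subset_size"), columns=[f"repeat_{r}" for r in range(repeats)])
    prof_df["mean"] = mean_rmse
    perf_full = perf_sub = None
    if evaluate:
        perf_full = train_yield_model(
            X, y, split=split, repeats=repeats, n_trees=n_trees, tune=False, min_samples_leaf=min_samples_leaf, seed=child_int(seed, "rfe_eval_full")
        ).report
        perf_sub = train_yield_model(
            X[tolerance_subset], y, split=split, repeats=repeats, n_trees=n_trees, tune=False, min_samples_leaf=min_samples_leaf, seed=child_int(seed, "rfe_eval_sub")
        ).report
    return RFEResult(
        rmse_profile=prof_df,
        per_repeat_optimal=per_repeat_optimal,
        per_repeat_tolerance=per_repeat_tolerance,
        consensus_subset=consensus,
        tolerance_subset=tolerance_subset,
        optimal_size=optimal_size,
        tolerance_size=tolerance_size,
        tolerance_pct=tolerance_pct,
        performance_full=perf_full,
        performance_subset=perf_sub,
        ranking=final_ranking,
    )
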