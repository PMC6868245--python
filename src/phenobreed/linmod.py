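"""RCB mixed models: effect estimation, outlier screening, variance components, BLUPs.

Three model layers mirror the analysis pipeline of a multi-environment
randomized-complete-block (RCB) trial:

1. A fixed-effects screen, ``y = mu + l + g + gl + t + gt + r(l) + eps``,
   fitted by least squares under sum-to-zero effect coding.  Its internally
   studentized residuals drive the +-3 outlier rule.
2. A random-effects decomposition per management system (genotype x location,
   replications within location) by the expected-mean-squares method of
   moments, feeding entry-mean heritability
   ``H² = s_g² / (s_g² + s_gl²/r + s_e²/(r l))``.  The divisor of the G x E
   term is ``r`` in the default ("as-printed") convention; the ``standard``
   convention divides by the number of environments ``l`` instead.
3. A per management-treatment x location shrinkage BLUP model
   ``y = mu + r + g + eps`` producing the genotype x treatment x location
   trait table consumed by the machine-learning stages.

All estimators use balanced-design closed forms (identical to REML on
balanced data); the fixed-effects layer tolerates near-balance from per-trait
missing or screened cells by solving the actual design matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import TrialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RCBFit",
    "VarianceComponents",
    "fit_rcb",
    "flag_outliers",
    "screen_outliers",
    "estimate_variance_components",
    "heritability",
    "compute_blups",
]


# --------------------------------------------------------------------------- #
# design-matrix helpers (sum-to-zero coding)
# --------------------------------------------------------------------------- #


def _codes(values) -> tuple[list, np.ndarray]:
    levels = list(dict.fromkeys(values))
    lookup = {v: i for i, v in enumerate(levels)}
    return levels, np.fromiter((lookup[v] for v in values), dtype=int, count=len(values))


def _stz(codes: np.ndarray, k: int) -> np.ndarray:
    """n x (k-1) sum-to-zero contrast columns for a k-level factor."""
    X = np.zeros((len(codes), k - 1))
    for j in range(k - 1):
        X[codes == j, j] = 1.0
    X[codes == k - 1, :] = -1.0
    return X


def _interact(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    n, ka = Xa.shape
    kb = Xb.shape[1]
    return (Xa[:, :, None] * Xb[:, None, :]).reshape(n, ka * kb)


def _expand_main(coef: np.ndarray) -> np.ndarray:
    return np.append(coef, -coef.sum())


def _expand_inter(coef: np.ndarray, ka: int, kb: int) -> np.ndarray:
    M = coef.reshape(ka - 1, kb - 1)
    full = np.zeros((ka, kb))
    full[: ka - 1, : kb - 1] = M
    full[ka - 1, : kb - 1] = -M.sum(axis=0)
    full[: ka - 1, kb - 1] = -M.sum(axis=1)
    full[ka - 1, kb - 1] = M.sum()
    return full


# --------------------------------------------------------------------------- #
# fixed-effects RCB fit
# --------------------------------------------------------------------------- #


@dataclass
class RCBFit:
    """Least-squares fit of the full RCB screen model for one trait."""

    trait: str
    study: str
    mu: float
    env_effects: dict[str, float]
    genotype_effects: dict[str, float]
    gxe_effects: dict[tuple[str, str], float]
    treatment_effects: dict[str, float]
    gxt_effects: dict[tuple[str, str], float]
    rep_effects: dict[tuple[str, str], float]
    residuals: pd.Series
    leverage: pd.Series
    residual_sd: float
    sigma_r2: float
    n_obs: int
    rank: int


def _single_study(dataset: TrialDataset, study: str | None) -> tuple[pd.DataFrame, str]:
    ids = dataset.study_ids()
    if study is None:
        if len(ids) != 1:
            raise ValueError(f"dataset holds studies {ids}; pass study=... to select one")
        study = ids[0]
    elif study not in ids:
        raise ValueError(f"study {study!r} not in dataset (has {ids})")
    return dataset.for_study(study), study


def fit_rcb(dataset: TrialDataset, trait: str, study: str | None = None) -> RCBFit:
    """Fit ``y = mu + l + g + gl + t + gt + r(l) + eps`` for one trait.

    Sum-to-zero constraints on every factor; replication-within-location
    estimated unshrunk so residuals sum to zero within each env x rep cell,
    with its variance component reported by method of moments.  Rows missing
    the trait are dropped; a genotype entirely absent from an environment or
    treatment makes the design rank-deficient and raises with the empty cells
    named.
    """
    df, study = _single_study(dataset, study)
    if trait not in df.columns:
        raise KeyError(f"trait {trait!r} not in dataset")
    sub = df[df[trait].notna()]
    n = len(sub)
    envs, ei = _codes(sub["environment"])
    genos, gi = _codes(sub["genotype"])
    trts, ti = _codes(sub["treatment"])
    reps, ri = _codes(sub["replication"])
    L, G, T, R = len(envs), len(genos), len(trts), len(reps)
    if G < 2 or L < 2 or R < 2:
        raise ValueError("fit_rcb needs >= 2 genotypes, environments and replications")

    Xe, Xg = _stz(ei, L), _stz(gi, G)
    blocks = [np.ones((n, 1)), Xe, Xg, _interact(Xg, Xe)]
    names = ["mu", "env", "geno", "gxe"]
    if T > 1:
        Xt = _stz(ti, T)
        blocks += [Xt, _interact(Xg, Xt)]
        names += ["trt", "gxt"]
    # replication nested within environment: (R-1) contrasts per environment
    Xr_in = np.zeros((n, L * (R - 1)))
    Xr = _stz(ri, R)
    for e in range(L):
        m = ei == e
        Xr_in[np.ix_(m, range(e * (R - 1), (e + 1) * (R - 1)))] = Xr[m]
    blocks.append(Xr_in)
    names.append("rep")

    X = np.hstack(blocks)
    y = sub[trait].to_numpy(dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        ge = pd.crosstab(sub["genotype"], sub["environment"])
        gt = pd.crosstab(sub["genotype"], sub["treatment"])
        empty = [f"genotype x environment {idx}" for idx in zip(*np.where(ge.to_numpy() == 0))]
        empty += [f"genotype x treatment {idx}" for idx in zip(*np.where(gt.to_numpy() == 0))]
        raise ValueError(f"rank-deficient RCB design for trait {trait!r}: empty cells {empty or 'unknown'}")

    Q, _ = np.linalg.qr(X)
    leverage = (Q**2).sum(axis=1)
    fitted = X @ beta
    resid = y - fitted
    dof = max(n - rank, 1)
    sse = float(resid @ resid)
    residual_sd = float(np.sqrt(sse / dof))

    # unpack coefficients
    pos = 0
    out: dict[str, np.ndarray] = {}
    widths = {"mu": 1, "env": L - 1, "geno": G - 1, "gxe": (G - 1) * (L - 1), "trt": T - 1, "gxt": (G - 1) * (T - 1), "rep": L * (R - 1)}
    for nm in names:
        out[nm] = beta[pos : pos + widths[nm]]
        pos += widths[nm]

    env_eff = dict(zip(envs, _expand_main(out["env"])))
    gen_eff = dict(zip(genos, _expand_main(out["geno"])))
    gxe_full = _expand_inter(out["gxe"], G, L)
    gxe_eff = {(g, e): gxe_full[a, b] for a, g in enumerate(genos) for b, e in enumerate(envs)}
    if T > 1:
        trt_eff = dict(zip(trts, _expand_main(out["trt"])))
        gxt_full = _expand_inter(out["gxt"], G, T)
        gxt_eff = {(g, t): gxt_full[a, b] for a, g in enumerate(genos) for b, t in enumerate(trts)}
    else:
        trt_eff = {trts[0]: 0.0}
        gxt_eff = {(g, trts[0]): 0.0 for g in genos}
    rep_eff = {}
    for e, env in enumerate(envs):
        vals = _expand_main(out["rep"][e * (R - 1) : (e + 1) * (R - 1)])
        for r, rep in enumerate(reps):
            rep_eff[(env, rep)] = vals[r]

    # method-of-moments variance of replication-within-location
    cell = n / (L * R)  # observations per env x rep cell (balanced: G*T)
    ss_rep = cell * sum(v**2 for v in rep_eff.values())
    df_rep = L * (R - 1)
    ms_rep = ss_rep / df_rep if df_rep else 0.0
    sigma_r2 = max((ms_rep - residual_sd**2) / cell, 0.0)

    return RCBFit(
        trait=trait,
        study=study,
        mu=float(out["mu"][0]),
        env_effects=env_eff,
        genotype_effects=gen_eff,
        gxe_effects=gxe_eff,
        treatment_effects=trt_eff,
        gxt_effects=gxt_eff,
        rep_effects=rep_eff,
        residuals=pd.Series(resid, index=sub.index),
        leverage=pd.Series(leverage, index=sub.index),
        residual_sd=residual_sd,
        sigma_r2=float(sigma_r2),
        n_obs=n,
        rank=int(rank),
    )


def studentized_residuals(fit: RCBFit) -> pd.Series:
    """Internally studentized residuals: e / (s * sqrt(1 - h))."""
    if fit.residual_sd == 0:
        return pd.Series(0.0, index=fit.residuals.index)
    h = np.clip(fit.leverage.to_numpy(), 0.0, 1.0 - 1e-12)
    return fit.residuals / (fit.residual_sd * np.sqrt(1.0 - h))


def flag_outliers(fit: RCBFit, threshold: float = 3.0) -> set:
    """Observation ids whose |studentized residual| exceeds ``threshold``.

    One pass only — removing the flagged cells and refitting is the caller's
    choice.  A degenerate perfect fit (zero residual SD) flags nothing.
    """
    if fit.residual_sd == 0:
        return set()
    t = studentized_residuals(fit)
    return set(t.index[np.abs(t.to_numpy()) > threshold])


def screen_outliers(
    dataset: TrialDataset, threshold: float = 3.0, traits: list[str] | None = None
) -> tuple[TrialDataset, pd.DataFrame]:
    """Per-trait outlier screen over every study; flagged cells set missing.

    Covers seed yield and every trait column by default.  Returns the cleaned
    dataset and a report of flagged cells (study, trait, row id, value,
    studentized residual).
    """
    out = dataset.copy()
    rows = []
    for sid in out.study_ids():
        cols = traits if traits is not None else ["seed_yield", *out.trait_columns]
        for col in cols:
            fit = fit_rcb(out, col, study=sid)
            flagged = flag_outliers(fit, threshold)
            if not flagged:
                continue
            t = studentized_residuals(fit)
            for idx in sorted(flagged):
                rows.append(
                    {"study": sid, "trait": col, "row": idx, "value": out.records.at[idx, col], "studentized": t.at[idx]}
                )
                out.records.at[idx, col] = np.nan
    report = pd.DataFrame(rows, columns=["study", "trait", "row", "value", "studentized"])
    return out, report


# --------------------------------------------------------------------------- #
# variance components and heritability
# --------------------------------------------------------------------------- #


@dataclass
class VarianceComponents:
    """EMS method-of-moments components for one trait and management system."""

    sigma_g2: float
    sigma_gl2: float
    sigma_r2: float
    sigma_e2: float
    truncated: tuple[str, ...] = field(default_factory=tuple)
    n_genotypes: int = 0
    n_locations: int = 0
    n_replications: int = 0


def estimate_variance_components(
    dataset: TrialDataset, trait: str, management_system: str, study: str | None = None
) -> VarianceComponents:
    """Random-model variance decomposition within one management system.

    The records for one treatment level form a balanced genotype x location
    layout with replications nested in locations.  Components come from the
    expected mean squares::

        E[MS_g]    = s_e² + r s_gl² + r l s_g²
        E[MS_gl]   = s_e² + r s_gl²
        E[MS_r(l)] = s_e² + G s_r²
        E[MS_e]    = s_e²

    Negative solutions are truncated to zero and flagged.  Unbalanced data
    (missing cells for the trait) are rejected: the closed forms above are
    exact only on the full factorial, and this package deliberately does not
    approximate REML on unbalanced layouts.
    """
    df, study = _single_study(dataset, study)
    sub = df[df["treatment"] == management_system]
    if sub.empty:
        raise ValueError(f"management system {management_system!r} not present in study {study!r}")
    if sub[trait].isna().any():
        raise ValueError(
            f"trait {trait!r} has missing cells in {management_system!r}; variance components require the complete "
            "balanced layout (impute or drop the trait first — see the documented balanced-design limitation)"
        )
    genos, gi = _codes(sub["genotype"])
    locs, li = _codes(sub["environment"])
    reps, ri = _codes(sub["replication"])
    G, L, R = len(genos), len(locs), len(reps)
    counts = np.zeros((G, L, R))
    np.add.at(counts, (gi, li, ri), 1)
    if not np.all(counts == 1):
        raise ValueError("unbalanced genotype x location x replication layout; balanced design required")

    y = sub[trait].to_numpy(dtype=float)
    cube = np.zeros((G, L, R))
    cube[gi, li, ri] = y
    mu = cube.mean()
    g_mean = cube.mean(axis=(1, 2))
    l_mean = cube.mean(axis=(0, 2))
    cell = cube.mean(axis=2)  # (G, L)
    reploc = cube.mean(axis=0)  # (L, R)

    ms_g = L * R * np.sum((g_mean - mu) ** 2) / (G - 1)
    ms_gl = R * np.sum((cell - g_mean[:, None] - l_mean[None, :] + mu) ** 2) / ((G - 1) * (L - 1))
    ms_r = G * np.sum((reploc - l_mean[:, None]) ** 2) / (L * (R - 1))
    resid = cube - cell[:, :, None] - reploc[None, :, :] + l_mean[None, :, None]
    ms_e = np.sum(resid**2) / (L * (G - 1) * (R - 1))

    raw = {
        "sigma_e2": ms_e,
        "sigma_gl2": (ms_gl - ms_e) / R,
        "sigma_g2": (ms_g - ms_gl) / (R * L),
        "sigma_r2": (ms_r - ms_e) / G,
    }
    truncated = tuple(k for k, v in raw.items() if v < 0)
    return VarianceComponents(
        sigma_g2=max(raw["sigma_g2"], 0.0),
        sigma_gl2=max(raw["sigma_gl2"], 0.0),
        sigma_r2=max(raw["sigma_r2"], 0.0),
        sigma_e2=max(raw["sigma_e2"], 0.0),
        truncated=truncated,
        n_genotypes=G,
        n_locations=L,
        n_replications=R,
    )


def heritability(vc: VarianceComponents, r: int, l: int, convention: str = "as-printed") -> float:
    """Entry-mean broad-sense heritability.

    ``as-printed`` (default): H² = s_g² / (s_g² + s_gl²/r + s_e²/(r l)) — the
    G x E term is divided by the number of replications.  ``standard``: the
    G x E term is divided by the number of environments ``l`` instead, the
    usual entry-mean formula.  The two coincide when r == l.
    """
    if r < 1 or l < 1:
        raise ValueError("r and l must be >= 1")
    if convention not in ("as-printed", "standard"):
        raise ValueError("convention must be 'as-printed' or 'standard'")
    denom_gl = r if convention == "as-printed" else l
    denom = vc.sigma_g2 + vc.sigma_gl2 / denom_gl + vc.sigma_e2 / (r * l)
    if denom == 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return float(vc.sigma_g2 / denom)


# --------------------------------------------------------------------------- #
# shrinkage BLUPs
# --------------------------------------------------------------------------- #


def compute_blups(dataset: TrialDataset, traits: list[str] | None = None) -> pd.DataFrame:
    """Genotype BLUPs per management-treatment x location, all traits at once.

    Within each (study, treatment, location) group the model is
    ``y = mu + r_i + g_j + eps`` with genotype random; on the balanced layout
    the BLUP is the shrunken genotype-mean deviation

        BLUP_j = mu + lambda (ybar_j - mu),  lambda = s_g² / (s_g² + s_e²/r)

    with components by method of moments within the group.  Missing cells are
    tolerated via nan-aware means (the shrinkage factor then uses the average
    replicate count); groups where s_g² truncates to zero shrink fully to the
    group mean.  Returns a tidy frame keyed by study, treatment, location,
    genotype with one column per trait (seed yield included).
    """
    cols = traits if traits is not None else ["seed_yield", *dataset.trait_columns]
    frames = []
    for (sid, trt, env), grp in dataset.records.groupby(["study", "treatment", "environment"], observed=True, sort=True):
        genos, gi = _codes(grp["genotype"])
        reps, ri = _codes(grp["replication"])
        G, R = len(genos), len(reps)
        if G < 2:
            raise ValueError(f"group ({sid}, {trt}, {env}) has fewer than 2 genotypes")
        A = np.full((G, R, len(cols)), np.nan)
        A[gi, ri, :] = grp[cols].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            ybar_g = np.nanmean(A, axis=1)  # (G, C)
            ybar_r = np.nanmean(A, axis=0)  # (R, C)
            mu = np.nanmean(A, axis=(0, 1))  # (C,)
        n_obs = np.sum(~np.isnan(A), axis=(0, 1))
        resid = A - ybar_g[:, None, :] - ybar_r[None, :, :] + mu
        sse = np.nansum(resid**2, axis=(0, 1))
        df_e = np.maximum(n_obs - G - R + 1, 1)
        ms_e = sse / df_e
        r_eff = np.maximum(n_obs / G, 1.0)
        ms_g = r_eff * np.nansum((ybar_g - mu) ** 2, axis=0) / (G - 1)
        sigma_g2 = np.clip((ms_g - ms_e) / r_eff, 0.0, None)
        denom = sigma_g2 + ms_e / r_eff
        lam = np.divide(sigma_g2, denom, out=np.zeros_like(denom), where=denom > 0)
        blup = mu[None, :] + lam[None, :] * (ybar_g - mu[None, :])
        frame = pd.DataFrame(blup, columns=cols)
        frame.insert(0, "genotype", genos)
        frame.insert(0, "location", env)
        frame.insert(0, "treatment", trt)
        frame.insert(0, "study", sid)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
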