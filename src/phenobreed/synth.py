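"""Synthetic multi-environment soybean trial generator.

The generator emulates a two-study phenotyping experiment: 32 genotypes grown
in randomized complete blocks (3 replications) under contrasting
agro-management treatments — row spacing (38/76 cm, five environments) and
seeding density (low/medium/high, four environments).  Seed yield follows the
additive mixed model

    y = mu + l_i + g_j + gl_ij + t_k + gt_jk + r_l(i) + driver terms + eps

with every random effect drawn i.i.d. normal at its configured variance.

Stage-wise phenotypic traits (SPAD, canopy temperature, LAI, iPAR, vegetation
indices, ...) are not drawn independently: each plot carries three latent
physiological drivers per growth stage — chlorophyll status, water status and
canopy size — that feed both the traits (through per-trait loadings) and seed
yield (through stage- and treatment-conditional weights).  This is the minimal
structure under which trait importance for yield prediction is real, ranked,
and differs between management treatments, so downstream feature-selection
machinery has a planted ground truth to recover.

A configurable subset of genotypes receives a systematic genotype-by-management
shift, mediated through the canopy driver under the first level of the study's
contrast pair.  Those genotypes define true management-fit classes (narrow-row
adapted, density adapted, ...) that the prescriptive tier tries to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "STAGES",
    "DRIVERS",
    "ConfigError",
    "StudyDesign",
    "TraitSpec",
    "TrialConfig",
    "GroundTruth",
    "TrialDataset",
    "default_trait_registry",
    "default_config",
    "variance_only_config",
    "generate_trial",
    "inject_missingness",
    "inject_outliers",
    "null_dg_sd",
    "planted_dg_shift",
    "make_sparse_regression",
]

STAGES = ("S1", "S2", "S3")
DRIVERS = ("chlorophyll", "water", "canopy")

DESIGN_COLUMNS = ("study", "environment", "replication", "genotype", "treatment", "seed_yield")


class ConfigError(ValueError):
    """Invalid trial configuration; the message names the offending field."""


# --------------------------------------------------------------------------- #
# configuration types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class StudyDesign:
    """One treatment study: ordered treatment levels x environments x blocks.

    ``contrast`` is the ordered pair of treatment levels used for the
    management-fit deviation D_g (first minus second); ``class_labels`` are the
    study-specific names for (first-level adapted, universal, second-level
    adapted) cohorts.
    """

    study_id: str
    treatment_levels: tuple[str, ...]
    n_environments: int
    n_replications: int
    contrast: tuple[str, str] | None = None
    class_labels: tuple[str, str, str] | None = None

    def __post_init__(self):
        if len(self.treatment_levels) < 2:
            raise ConfigError(f"StudyDesign.treatment_levels: study {self.study_id!r} needs >= 2 levels")
        if len(set(self.treatment_levels)) != len(self.treatment_levels):
            raise ConfigError(f"StudyDesign.treatment_levels: duplicate labels in study {self.study_id!r}")
        if self.n_environments < 1:
            raise ConfigError(f"StudyDesign.n_environments: study {self.study_id!r} needs >= 1")
        if self.n_replications < 2:
            raise ConfigError(f"StudyDesign.n_replications: study {self.study_id!r} needs >= 2")
        if self.contrast is not None:
            for lev in self.contrast:
                if lev not in self.treatment_levels:
                    raise ConfigError(f"StudyDesign.contrast: {lev!r} not a treatment level of {self.study_id!r}")

    @property
    def environments(self) -> list[str]:
        return [f"{self.study_id}-L{i + 1}" for i in range(self.n_environments)]

    @property
    def replications(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_replications)]

    @property
    def contrast_pair(self) -> tuple[str, str]:
        return self.contrast if self.contrast is not None else (self.treatment_levels[0], self.treatment_levels[1])

    @property
    def labels(self) -> tuple[str, str, str]:
        if self.class_labels is not None:
            return self.class_labels
        c1, c2 = self.contrast_pair
        return (f"{c1}-adapted", "U", f"{c2}-adapted")


@dataclass(frozen=True)
class TraitSpec:
    """A measured trait: baseline value plus linear loadings on the drivers.

    ``loadings`` maps driver name -> weight in trait units per driver SD; a
    trait with all-zero loadings is pure measurement noise.
    """

    name: str
    baseline: float
    loadings: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self):
        if not self.stages:
            raise ConfigError(f"TraitSpec.stages: trait {self.name!r} needs at least one stage")
        if self.noise_sd < 0:
            raise ConfigError(f"TraitSpec.noise_sd: trait {self.name!r} must be >= 0")
        for d, w in self.loadings.items():
            if d not in DRIVERS:
                raise ConfigError(f"TraitSpec.loadings: unknown driver {d!r} for trait {self.name!r}")
            if not np.isfinite(w):
                raise ConfigError(f"TraitSpec.loadings: non-finite loading for trait {self.name!r}")

    def column(self, stage: str) -> str:
        """Column name following the TRAIT_STAGE / VI_STAGE_INDEX convention."""
        if self.name.startswith("VI_"):
            return f"VI_{stage}_{self.name[3:]}"
        return f"{self.name}_{stage}"

    def is_noise(self) -> bool:
        return all(w == 0 for w in self.loadings.values()) or not self.loadings


_VARIANCE_KEYS = ("sigma_g2", "sigma_l2", "sigma_gl2", "sigma_t2", "sigma_gt2", "sigma_r2", "sigma_e2")

# driver -> stage -> yield weight, kg/ha per driver SD.  Chlorophyll status at
# seed fill (S3) is the strongest single driver of yield; canopy size matters
# most early (S1); water stress is negative throughout.
DEFAULT_DRIVER_WEIGHTS: dict[str, dict[str, float]] = {
    "chlorophyll": {"S1": 60.0, "S2": 150.0, "S3": 260.0},
    "water": {"S1": -40.0, "S2": -110.0, "S3": -150.0},
    "canopy": {"S1": 110.0, "S2": 70.0, "S3": 40.0},
}

# (study_id, treatment, driver) -> multiplier on the yield weight.  Canopy size
# pays off more where the canopy is slow to close (wide rows, low density), so
# trait importance is conditional on the management system.
DEFAULT_TREATMENT_SCALE: dict[tuple[str, str, str], float] = {
    ("IA-RS", "38cm", "canopy"): 0.7,
    ("IA-RS", "76cm", "canopy"): 1.4,
    ("IA-SD", "low", "canopy"): 1.5,
    ("IA-SD", "medium", "canopy"): 1.0,
    ("IA-SD", "high", "canopy"): 0.6,
    ("IA-SD", "low", "water"): 0.8,
    ("IA-SD", "high", "water"): 1.2,
}


def default_trait_registry() -> list[TraitSpec]:
    """The 22-trait registry measured at each of the three growth stages.

    SPAD is the cleanest proxy of the chlorophyll driver (highest
    loading-to-noise ratio), so SPAD_S3 is the planted strongest predictor of
    seed yield under the default driver weights.  MTA, VI_WBI and VI_CRI carry
    no driver loading at all: they are planted pure-noise predictors.
    """
    c, w, k = "chlorophyll", "water", "canopy"
    return [
        TraitSpec("SPAD", 40.0, {c: 4.0}, 1.0),
        TraitSpec("CT", 28.0, {w: -1.2}, 0.6),
        TraitSpec("LAI", 3.5, {k: 0.8}, 0.5),
        TraitSpec("MTA", 45.0, {}, 6.0),
        TraitSpec("iPAR", 0.75, {k: 0.08}, 0.05),
        TraitSpec("VI_NDVI", 0.75, {c: 0.02, k: 0.04}, 0.035),
        TraitSpec("VI_VREI2", 0.28, {c: -0.05}, 0.04),
        TraitSpec("VI_RARSa", 0.45, {c: 0.05}, 0.045),
        TraitSpec("VI_RARSb", 0.90, {c: 0.06}, 0.05),
        TraitSpec("VI_PRI", 0.02, {w: 0.012}, 0.010),
        TraitSpec("VI_RDVI", 0.55, {k: 0.05}, 0.04),
        TraitSpec("VI_NMDI", 0.65, {w: 0.05}, 0.04),
        TraitSpec("VI_GNDVI", 0.70, {c: 0.03, k: 0.02}, 0.03),
        TraitSpec("VI_SAVI", 0.60, {k: 0.045}, 0.04),
        TraitSpec("VI_OSAVI", 0.62, {c: 0.015, k: 0.04}, 0.04),
        TraitSpec("VI_MSR", 1.80, {c: 0.10, k: 0.12}, 0.12),
        TraitSpec("VI_SR", 8.00, {c: 0.60, k: 0.70}, 0.70),
        TraitSpec("VI_NDWI", 0.35, {w: 0.04}, 0.035),
        TraitSpec("VI_TCARI", 0.12, {c: -0.020, k: 0.010}, 0.020),
        TraitSpec("VI_MCARI", 0.15, {c: -0.025, k: 0.012}, 0.022),
        TraitSpec("VI_WBI", 0.95, {}, 0.03),
        TraitSpec("VI_CRI", 4.00, {}, 0.50),
    ]


@dataclass(frozen=True)
class TrialConfig:
    """Full description of the synthetic experiment.

    Variances are in kg²/ha² for yield; the latent drivers are unit-variance
    per plot and stage, split into a genotype component (``driver_geno_share``)
    and plot noise (``driver_plot_share``).  ``gxm_fraction`` of genotypes get
    a planted management-fit shift of ``gxm_shift_sd`` x SD(D_g), where
    SD(D_g) is the anticipated post-shift dispersion of the fit deviation (see
    :func:`planted_dg_shift`).
    """

    n_genotypes: int = 32
    studies: tuple[StudyDesign, ...] = (
        StudyDesign("IA-RS", ("38cm", "76cm"), 5, 3, contrast=("38cm", "76cm"), class_labels=("N", "U", "W")),
        StudyDesign("IA-SD", ("low", "medium", "high"), 4, 3, contrast=("medium", "low"), class_labels=("M", "U", "L")),
    )
    variance_components: dict[str, float] = field(
        default_factory=lambda: {
            "sigma_g2": 40_000.0,
            "sigma_l2": 90_000.0,
            "sigma_gl2": 10_000.0,
            "sigma_t2": 2_500.0,
            "sigma_gt2": 900.0,
            "sigma_r2": 2_500.0,
            "sigma_e2": 90_000.0,
        }
    )
    grand_mean_yield: float = 3500.0
    trait_registry: tuple[TraitSpec, ...] = field(default_factory=lambda: tuple(default_trait_registry()))
    driver_weights: dict[str, dict[str, float]] = field(default_factory=lambda: {d: dict(s) for d, s in DEFAULT_DRIVER_WEIGHTS.items()})
    treatment_scale: dict[tuple[str, str, str], float] = field(default_factory=lambda: dict(DEFAULT_TREATMENT_SCALE))
    driver_geno_share: float = 0.6
    driver_plot_share: float = 0.8
    gxm_fraction: float = 5 / 32
    gxm_shift_sd: float = 1.0
    missing_rate: float = 0.05
    outlier_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_genotypes < 2:
            raise ConfigError("n_genotypes: must be >= 2")
        if not self.studies:
            raise ConfigError("studies: at least one StudyDesign required")
        for key in _VARIANCE_KEYS:
            if key not in self.variance_components:
                raise ConfigError(f"variance_components: missing {key}")
            if self.variance_components[key] < 0:
                raise ConfigError(f"variance_components: {key} must be >= 0")
        for name, val in (("gxm_fraction", self.gxm_fraction), ("missing_rate", self.missing_rate), ("outlier_rate", self.outlier_rate)):
            if not (0 <= val < 1):
                raise ConfigError(f"{name}: must be in [0, 1)")
        if self.gxm_shift_sd < 0:
            raise ConfigError("gxm_shift_sd: must be >= 0")
        n_shift = round(self.gxm_fraction * self.n_genotypes)
        f = n_shift / self.n_genotypes
        if n_shift and self.gxm_shift_sd**2 * f * (1 - f) >= 1:
            raise ConfigError("gxm_shift_sd: too large for gxm_fraction; k^2 f (1-f) must be < 1 for the planted shift to be solvable")
        names = [t.name for t in self.trait_registry]
        if len(set(names)) != len(names):
            raise ConfigError("trait_registry: duplicate trait names")

    @property
    def genotypes(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genotypes)]

    def weight(self, study_id: str, treatment: str, driver: str, stage: str) -> float:
        base = self.driver_weights.get(driver, {}).get(stage, 0.0)
        return base * self.treatment_scale.get((study_id, treatment, driver), 1.0)

    def trait_columns(self) -> list[str]:
        return [spec.column(s) for spec in self.trait_registry for s in spec.stages]

    def noise_trait_columns(self) -> list[str]:
        """Planted pure-noise predictor columns (all driver loadings zero)."""
        return [spec.column(s) for spec in self.trait_registry if spec.is_noise() for s in spec.stages]


def default_config(**overrides) -> TrialConfig:
    """The default study conditions; keyword overrides replace fields."""
    return replace(TrialConfig(), **overrides) if overrides else TrialConfig()


def variance_only_config(
    sigma_g2: float,
    sigma_gl2: float,
    sigma_e2: float,
    *,
    n_genotypes: int = 32,
    n_environments: int = 4,
    n_replications: int = 3,
    grand_mean_yield: float = 1000.0,
    seed: int = 0,
) -> TrialConfig:
    """A single-study, yield-only configuration with pure variance components.

    Used for calibration studies of the variance-component and heritability
    estimators: driver weights, planted shifts, treatment and location
    variances are all zero, so genotype means follow the textbook two-way
    random model exactly.  The grand mean defaults far above zero so the
    non-negative yield floor never truncates the Gaussian draws.
    """
    study = StudyDesign("CAL", ("A", "B"), n_environments, n_replications)
    return TrialConfig(
        n_genotypes=n_genotypes,
        studies=(study,),
        variance_components={
            "sigma_g2": sigma_g2,
            "sigma_l2": 0.0,
            "sigma_gl2": sigma_gl2,
            "sigma_t2": 0.0,
            "sigma_gt2": 0.0,
            "sigma_r2": 0.0,
            "sigma_e2": sigma_e2,
        },
        grand_mean_yield=grand_mean_yield,
        trait_registry=(),
        driver_weights={d: {s: 0.0 for s in STAGES} for d in DRIVERS},
        treatment_scale={},
        gxm_fraction=0.0,
        missing_rate=0.0,
        outlier_rate=0.0,
        seed=seed,
    )


# --------------------------------------------------------------------------- #
# dataset container
# --------------------------------------------------------------------------- #


@dataclass
class GroundTruth:
    """Planted truth carried alongside a synthetic dataset, for testing only."""

    genotype_effects: dict[str, float] = field(default_factory=dict)
    shifted_genotypes: dict[str, list[str]] = field(default_factory=dict)
    true_fit_classes: dict[str, dict[str, str]] = field(default_factory=dict)
    dg_shift: dict[str, float] = field(default_factory=dict)
    missing_mask: list[tuple[int, str]] = field(default_factory=list)
    outlier_mask: list[tuple[int, str, float]] = field(default_factory=list)


@dataclass
class TrialDataset:
    """Plot-level trial records plus (optionally) the generating truth.

    ``records`` has one row per study x environment x replication x genotype x
    treatment, with ``seed_yield`` in kg/ha and one column per trait x stage.
    """

    records: pd.DataFrame
    truth: GroundTruth | None = None

    @property
    def trait_columns(self) -> list[str]:
        return [c for c in self.records.columns if c not in DESIGN_COLUMNS]

    @property
    def n_trait_cells(self) -> int:
        return len(self.records) * len(self.trait_columns)

    def study_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["study"]))

    def for_study(self, study_id: str) -> pd.DataFrame:
        return self.records[self.records["study"] == study_id]

    def copy(self) -> "TrialDataset":
        import copy as _copy

        return TrialDataset(self.records.copy(), _copy.deepcopy(self.truth))

    def is_complete_factorial(self) -> bool:
        """True when every genotype x treatment x environment x replication cell is present once."""
        for sid in self.study_ids():
            sub = self.for_study(sid)
            counts = sub.groupby(["environment", "replication", "genotype", "treatment"], observed=True).size()
            n_env = sub["environment"].nunique()
            n_rep = sub["replication"].nunique()
            n_g = sub["genotype"].nunique()
            n_t = sub["treatment"].nunique()
            if len(counts) != n_env * n_rep * n_g * n_t or (counts != 1).any():
                return False
        return True


# --------------------------------------------------------------------------- #
# planted-shift arithmetic
# --------------------------------------------------------------------------- #


def null_dg_sd(config: TrialConfig, study: StudyDesign) -> float:
    """Analytic SD of the fit deviation D_g with no planted shift.

    D_g is the difference of a genotype's mean yield between the two contrast
    levels (averaged over l environments x r replications).  Under the
    generative model its null variance collects: the two independent
    genotype-by-treatment draws, the residual and plot-driver noise of the two
    level means, and the genotype-level driver components whenever the yield
    weights differ between the levels (real, trait-linked G x M).
    """
    vc = config.variance_components
    t1, t2 = study.contrast_pair
    r, l = study.n_replications, study.n_environments
    alpha, beta = config.driver_geno_share, config.driver_plot_share
    v_plot = 0.0
    for t in (t1, t2):
        v_plot += sum(config.weight(study.study_id, t, d, s) ** 2 for d in DRIVERS for s in STAGES) * beta**2
    v_plot /= 2.0
    v_geno_gxm = 0.0
    for d in DRIVERS:
        w1 = sum(config.weight(study.study_id, t1, d, s) for s in STAGES)
        w2 = sum(config.weight(study.study_id, t2, d, s) for s in STAGES)
        v_geno_gxm += alpha**2 * (w1 - w2) ** 2
    v0 = 2 * vc["sigma_gt2"] + 2 * (vc["sigma_e2"] + v_plot) / (r * l) + v_geno_gxm
    return float(np.sqrt(v0))


def planted_dg_shift(config: TrialConfig, study: StudyDesign) -> float:
    """Size of the planted D_g shift, in kg/ha.

    The shift is sized as ``k = gxm_shift_sd`` times the SD of the *resulting*
    D_g distribution, solved self-consistently: with fraction f of genotypes
    shifted by delta in one direction, the post-shift variance is
    v0 + f(1-f) delta², so delta² = k² v0 / (1 - k² f (1-f)).  Sizing against
    the post-shift SD keeps "a k-SD outlier" meaningful to the +-1 SD class
    boundary even though the shifted genotypes inflate that boundary.
    """
    n_shift = round(config.gxm_fraction * config.n_genotypes)
    if n_shift == 0 or config.gxm_shift_sd == 0:
        return 0.0
    f = n_shift / config.n_genotypes
    k = config.gxm_shift_sd
    v0 = null_dg_sd(config, study) ** 2
    denom = 1 - k**2 * f * (1 - f)
    return float(k * np.sqrt(v0 / denom))


# --------------------------------------------------------------------------- #
# generation
# --------------------------------------------------------------------------- #


def generate_trial(config: TrialConfig) -> TrialDataset:
    """Draw a complete synthetic trial from the configured design.

    Deterministic for a fixed ``config.seed``: every random term lives on a
    named substream, so datasets are byte-identical across calls.
    """
    config.validate()
    vc = config.variance_components
    seed = config.seed
    G = config.n_genotypes
    genotypes = np.array(config.genotypes)

    g_eff = substream(seed, "genotype").normal(0.0, np.sqrt(vc["sigma_g2"]), G)
    u_geno = substream(seed, "driver_genotype").normal(0.0, 1.0, (G, len(DRIVERS)))

    truth = GroundTruth(genotype_effects=dict(zip(genotypes.tolist(), g_eff.tolist())))
    frames = []

    for study in config.studies:
        sid = study.study_id
        L, R, T = study.n_environments, study.n_replications, len(study.treatment_levels)
        envs = study.environments
        reps = study.replications
        trts = list(study.treatment_levels)

        l_eff = substream(seed, sid, "location").normal(0.0, np.sqrt(vc["sigma_l2"]), L)
        gl_eff = substream(seed, sid, "gxl").normal(0.0, np.sqrt(vc["sigma_gl2"]), (G, L))
        t_eff = substream(seed, sid, "treatment").normal(0.0, np.sqrt(vc["sigma_t2"]), T)
        gt_eff = substream(seed, sid, "gxt").normal(0.0, np.sqrt(vc["sigma_gt2"]), (G, T))
        r_eff = substream(seed, sid, "rep_in_loc").normal(0.0, np.sqrt(vc["sigma_r2"]), (L, R))

        # full factorial grid: environment-major, then replication, genotype, treatment
        ei, ri, gi, ti = (
            ix.ravel() for ix in np.meshgrid(np.arange(L), np.arange(R), np.arange(G), np.arange(T), indexing="ij")
        )
        n = len(ei)

        # latent drivers: genotype component + plot noise, (plot, driver, stage)
        e_plot = substream(seed, sid, "driver_plot").normal(0.0, 1.0, (n, len(DRIVERS), len(STAGES)))
        drivers = config.driver_geno_share * u_geno[gi][:, :, None] + config.driver_plot_share * e_plot

        # planted management-fit shift through the canopy driver at contrast level 1
        n_shift = round(config.gxm_fraction * G)
        shifted_idx = np.array([], dtype=int)
        delta = 0.0
        if n_shift and config.gxm_shift_sd > 0:
            shifted_idx = np.sort(substream(seed, sid, "gxm_select").choice(G, size=n_shift, replace=False))
            delta = planted_dg_shift(config, study)
            t1 = study.contrast_pair[0]
            canopy = DRIVERS.index("canopy")
            w_canopy_t1 = sum(config.weight(sid, t1, "canopy", s) for s in STAGES)
            mask = np.isin(gi, shifted_idx) & (np.array(trts)[ti] == t1)
            if abs(w_canopy_t1) > 1e-9:
                drivers[mask, canopy, :] += delta / w_canopy_t1
            else:  # no canopy pathway configured: apply the shift to yield directly
                t_eff = t_eff.copy()  # no-op, keeps branch explicit
                gt_eff = gt_eff.copy()
                gt_eff[shifted_idx, trts.index(t1)] += delta
        truth.shifted_genotypes[sid] = genotypes[shifted_idx].tolist()
        truth.dg_shift[sid] = delta
        adapted = study.labels[0]
        truth.true_fit_classes[sid] = {
            g: (adapted if i in shifted_idx else "U") for i, g in enumerate(genotypes)
        }

        # treatment x driver x stage yield-weight tensor
        W = np.zeros((T, len(DRIVERS), len(STAGES)))
        for a, t in enumerate(trts):
            for b, d in enumerate(DRIVERS):
                for c, s in enumerate(STAGES):
                    W[a, b, c] = config.weight(sid, t, d, s)
        y_driver = np.einsum("nds,nds->n", drivers, W[ti])

        eps = substream(seed, sid, "residual").normal(0.0, np.sqrt(vc["sigma_e2"]), n)
        y = (
            config.grand_mean_yield
            + l_eff[ei]
            + g_eff[gi]
            + gl_eff[gi, ei]
            + t_eff[ti]
            + gt_eff[gi, ti]
            + r_eff[ei, ri]
            + y_driver
            + eps
        )
        y = np.clip(y, 0.0, None)

        data = {
            "study": sid,
            "environment": np.array(envs)[ei],
            "replication": np.array(reps)[ri],
            "genotype": genotypes[gi],
            "treatment": np.array(trts)[ti],
            "seed_yield": y,
        }
        for spec in config.trait_registry:
            for c, s in enumerate(STAGES):
                if s not in spec.stages:
                    continue
                col = spec.column(s)
                val = np.full(n, spec.baseline)
                for b, d in enumerate(DRIVERS):
                    w = spec.loadings.get(d, 0.0)
                    if w:
                        val = val + w * drivers[:, b, c]
                if spec.noise_sd:
                    val = val + substream(seed, sid, "trait_noise", col).normal(0.0, spec.noise_sd, n)
                data[col] = val
        frames.append(pd.DataFrame(data))

    records = pd.concat(frames, ignore_index=True)
    return TrialDataset(records, truth)


def inject_missingness(dataset: TrialDataset, rate: float, seed: int) -> TrialDataset:
    """Mask exactly ``round(rate * n_trait_cells)`` trait cells at random.

    Yield is never masked (rows with missing yield are dropped, not imputed).
    The mask positions are recorded in ``truth.missing_mask``.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    out = dataset.copy()
    cols = out.trait_columns
    n_cells = len(out.records) * len(cols)
    k = round(rate * n_cells)
    if k == 0 or n_cells == 0:
        return out
    flat = substream(seed, "inject_missing").choice(n_cells, size=k, replace=False)
    rows, col_idx = np.divmod(flat, len(cols))
    if out.truth is None:
        out.truth = GroundTruth()
    col_arr = np.array(cols)
    for r, c in zip(rows.tolist(), col_idx.tolist()):
        out.records.iat[r, out.records.columns.get_loc(col_arr[c])] = np.nan
        out.truth.missing_mask.append((r, str(col_arr[c])))
    return out


def _within_cell_residual_sd(df: pd.DataFrame, col: str) -> float:
    """Pooled replicate-level residual SD of a trait within design cells."""
    grp = df.groupby(["study", "environment", "genotype", "treatment"], observed=True)[col]
    resid = df[col] - grp.transform("mean")
    n_obs = resid.notna().sum()
    n_cells = grp.mean().notna().sum()
    dof = max(int(n_obs - n_cells), 1)
    return float(np.sqrt(np.nansum(resid**2) / dof))


def inject_outliers(dataset: TrialDataset, rate: float, shift_sd: float, seed: int) -> TrialDataset:
    """Shift ``round(rate * n_trait_cells)`` trait cells by +-shift_sd residual SDs.

    ``shift_sd`` well above 3 makes the injected points detectable by the
    studentized-residual screen; positions and applied shifts are recorded in
    ``truth.outlier_mask``.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    out = dataset.copy()
    cols = out.trait_columns
    n_cells = len(out.records) * len(cols)
    k = round(rate * n_cells)
    if k == 0 or n_cells == 0:
        return out
    rng = substream(seed, "inject_outliers")
    flat = rng.choice(n_cells, size=k, replace=False)
    signs = rng.choice([-1.0, 1.0], size=k)
    rows, col_idx = np.divmod(flat, len(cols))
    resid_sd = {c: _within_cell_residual_sd(out.records, c) for c in set(np.array(cols)[col_idx])}
    if out.truth is None:
        out.truth = GroundTruth()
    for r, ci, sgn in zip(rows.tolist(), col_idx.tolist(), signs.tolist()):
        col = cols[ci]
        loc = out.records.columns.get_loc(col)
        cur = out.records.iat[r, loc]
        if pd.isna(cur):
            continue  # never stack an outlier on a masked cell
        shift = sgn * shift_sd * resid_sd[col]
        out.records.iat[r, loc] = cur + shift
        out.truth.outlier_mask.append((r, str(col), float(shift)))
    return out


# --------------------------------------------------------------------------- #
# auxiliary regression fixture
# --------------------------------------------------------------------------- #


def make_sparse_regression(
    n: int = 120,
    n_informative: int = 6,
    n_noise: int = 60,
    beta: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """A sparse linear signal among many pure-noise predictors.

    Returns (X, y, informative_names).  Informative columns are named
    ``S01..``, noise columns ``N01..``; all predictors are i.i.d. standard
    normal and y = beta * sum(informative) + eps.
    """
    rng = substream(seed, "sparse_regression")
    p = n_informative + n_noise
    X = rng.normal(size=(n, p))
    names = [f"S{i + 1:02d}" for i in range(n_informative)] + [f"N{i + 1:02d}" for i in range(n_noise)]
    y = beta * X[:, :n_informative].sum(axis=1) + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(X, columns=names), pd.Series(y, name="y"), names[:n_informative]
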