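"""Mixed-model layer: oracle equivalence, outlier rule, components, H², BLUPs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenobreed import linmod, synth
from phenobreed.linmod import VarianceComponents

from conftest import balanced_records


def means_oracle(df: pd.DataFrame, trait: str = "seed_yield") -> dict:
    """Closed-form effect decomposition on a balanced factorial (independent oracle).

    On a complete balanced layout the sum-to-zero least-squares estimates are
    the classical means contrasts; computed here entirely with groupby means.
    """
    y = df[trait]
    mu = y.mean()
    env = df.groupby("environment")[trait].mean() - mu
    gen = df.groupby("genotype")[trait].mean() - mu
    ge = df.groupby(["genotype", "environment"])[trait].mean()
    gxe = {
        (g, e): ge[(g, e)] - gen[g] - env[e] - mu
        for g, e in ge.index
    }
    trt = df.groupby("treatment")[trait].mean() - mu
    gt = df.groupby(["genotype", "treatment"])[trait].mean()
    gxt = {(g, t): gt[(g, t)] - gen[g] - trt[t] - mu for g, t in gt.index}
    er = df.groupby(["environment", "replication"])[trait].mean()
    rep = {(e, r): er[(e, r)] - (env[e] + mu) for e, r in er.index}
    fitted = (
        mu
        + df["environment"].map(env).to_numpy()
        + df["genotype"].map(gen).to_numpy()
        + np.array([gxe[(g, e)] for g, e in zip(df["genotype"], df["environment"])])
        + df["treatment"].map(trt).to_numpy()
        + np.array([gxt[(g, t)] for g, t in zip(df["genotype"], df["treatment"])])
        + np.array([rep[(e, r)] for e, r in zip(df["environment"], df["replication"])])
    )
    return {
        "mu": mu,
        "env": env.to_dict(),
        "gen": gen.to_dict(),
        "gxe": gxe,
        "trt": trt.to_dict(),
        "gxt": gxt,
        "rep": rep,
        "residuals": y.to_numpy() - fitted,
    }


class TestFitRCB:
    def test_constant_data_recovers_the_mean_with_zero_residuals(self):
        ds = synth.TrialDataset(balanced_records(mu=100.0, noise_sd=0.0, seed=0))
        fit = linmod.fit_rcb(ds, "seed_yield")
        assert fit.mu == pytest.approx(100.0)
        assert np.allclose(fit.residuals, 0.0, atol=1e-9)
        assert all(abs(v) < 1e-9 for v in fit.genotype_effects.values())

    def test_planted_sum_to_zero_genotype_effects_recovered_exactly(self):
        df = balanced_records(n_geno=4, mu=100.0, noise_sd=0.0, seed=0)
        planted = {"G01": 10.0, "G02": -10.0, "G03": 0.0, "G04": 0.0}
        df["seed_yield"] += df["genotype"].map(planted)
        fit = linmod.fit_rcb(synth.TrialDataset(df), "seed_yield")
        for g, val in planted.items():
            assert fit.genotype_effects[g] == pytest.approx(val, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_coefficients_match_the_balanced_means_oracle(self, seed):
        df = balanced_records(n_geno=5, n_env=3, n_rep=3, n_trt=2, noise_sd=5.0, seed=seed)
        ds = synth.TrialDataset(df)
        fit = linmod.fit_rcb(ds, "seed_yield")
        oracle = means_oracle(df)
        assert fit.mu == pytest.approx(oracle["mu"], rel=1e-8)
        for e, v in oracle["env"].items():
            assert fit.env_effects[e] == pytest.approx(v, rel=1e-8, abs=1e-8)
        for g, v in oracle["gen"].items():
            assert fit.genotype_effects[g] == pytest.approx(v, rel=1e-8, abs=1e-8)
        for k, v in oracle["gxt"].items():
            assert fit.gxt_effects[k] == pytest.approx(v, rel=1e-8, abs=1e-8)
        for k, v in oracle["rep"].items():
            assert fit.rep_effects[k] == pytest.approx(v, rel=1e-8, abs=1e-8)
        assert np.allclose(fit.residuals.to_numpy(), oracle["residuals"], atol=1e-8)

    def test_residuals_sum_to_zero_within_each_env_rep_cell(self, default_dataset):
        fit = linmod.fit_rcb(default_dataset, "seed_yield", study="IA-RS")
        df = default_dataset.for_study("IA-RS").assign(res=fit.residuals)
        sums = df.groupby(["environment", "replication"])["res"].sum()
        assert np.allclose(sums.to_numpy(), 0.0, atol=1e-6)

    def test_rank_deficiency_raises_naming_missing_cells(self):
        df = balanced_records(seed=1)
        df = df[~((df["genotype"] == "G01") & (df["environment"] == "E1"))]
        with pytest.raises(ValueError, match="empty cells"):
            linmod.fit_rcb(synth.TrialDataset(df), "seed_yield")


class TestOutliers:
    def test_single_gross_outlier_is_flagged(self):
        df = balanced_records(n_geno=5, n_env=3, n_rep=3, noise_sd=1.0, seed=4)
        ds = synth.TrialDataset(df)
        fit0 = linmod.fit_rcb(ds, "seed_yield")
        victim = df.index[10]
        df.loc[victim, "seed_yield"] += 10 * fit0.residual_sd
        fit = linmod.fit_rcb(synth.TrialDataset(df), "seed_yield")
        flagged = linmod.flag_outliers(fit, 3.0)
        assert victim in flagged
        assert linmod.flag_outliers(fit, np.inf) == set()

    def test_perfect_fit_flags_nothing(self):
        ds = synth.TrialDataset(balanced_records(noise_sd=0.0, seed=0))
        fit = linmod.fit_rcb(ds, "seed_yield")
        assert linmod.flag_outliers(fit, 3.0) == set()

    def test_screen_removes_flagged_cells_and_reports_them(self):
        cfg = synth.default_config(seed=31, studies=(synth.default_config().studies[0],))
        ds = synth.generate_trial(cfg)
        out = synth.inject_outliers(ds, 0.01, shift_sd=10.0, seed=2)
        cleaned, report = linmod.screen_outliers(out, traits=["seed_yield", "SPAD_S1", "CT_S2"])
        assert set(report.columns) == {"study", "trait", "row", "value", "studentized"}
        for _, row in report.iterrows():
            assert pd.isna(cleaned.records.at[row["row"], row["trait"]])
            assert abs(row["studentized"]) > 3


class TestVarianceComponents:
    def test_constant_data_has_all_zero_components(self):
        cfg = synth.variance_only_config(0.0, 0.0, 0.0, grand_mean_yield=500.0, seed=1)
        ds = synth.generate_trial(cfg)
        vc = linmod.estimate_variance_components(ds, "seed_yield", "A")
        assert (vc.sigma_g2, vc.sigma_gl2, vc.sigma_r2, vc.sigma_e2) == (0, 0, 0, 0)

    def test_zero_genotype_signal_estimates_near_zero(self):
        # mean sigma_g2-hat over 200 sims stays within 5% of the total variance
        ests = []
        for s in range(200):
            cfg = synth.variance_only_config(0.0, 0.0, 2.0, n_environments=3, seed=30_000 + s)
            ds = synth.generate_trial(cfg)
            ests.append(linmod.estimate_variance_components(ds, "seed_yield", "A").sigma_g2)
        assert np.mean(ests) < 0.05 * 2.0

    def test_unbalanced_or_incomplete_data_is_rejected(self, default_dataset):
        ds = default_dataset.copy()
        ds.records.loc[ds.records.index[0], "SPAD_S1"] = np.nan
        with pytest.raises(ValueError, match="balanced"):
            linmod.estimate_variance_components(ds, "SPAD_S1", "38cm", study="IA-RS")
        ds2 = default_dataset.copy()
        victim = ds2.records.index[ds2.records["treatment"] == "38cm"][0]
        ds2.records = ds2.records.drop(index=victim).reset_index(drop=True)
        with pytest.raises(ValueError, match="balanced"):
            linmod.estimate_variance_components(ds2, "seed_yield", "38cm", study="IA-RS")


class TestHeritability:
    def test_hand_values_both_conventions(self):
        vc = VarianceComponents(1.0, 0.5, 0.0, 2.0)
        assert linmod.heritability(vc, 3, 4, "as-printed") == pytest.approx(1 / (1 + 0.5 / 3 + 2 / 12))
        assert linmod.heritability(vc, 3, 4, "standard") == pytest.approx(1 / (1 + 0.5 / 4 + 2 / 12))

    def test_no_nongenetic_variance_gives_unity(self):
        assert linmod.heritability(VarianceComponents(9.0, 0.0, 0.0, 0.0), 3, 4) == 1.0

    def test_all_zero_components_is_undefined(self):
        with pytest.raises(ValueError):
            linmod.heritability(VarianceComponents(0.0, 0.0, 0.0, 0.0), 3, 4)

    @given(
        sg=st.floats(0.01, 100),
        sgl=st.floats(0.0, 100),
        se=st.floats(0.01, 100),
        r=st.integers(1, 6),
        l=st.integers(1, 8),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotonicity_in_design_size_and_noise(self, sg, sgl, se, r, l):
        vc = VarianceComponents(sg, sgl, 0.0, se)
        h = linmod.heritability(vc, r, l)
        assert 0 <= h <= 1
        assert linmod.heritability(vc, r + 1, l) >= h - 1e-12
        assert linmod.heritability(vc, r, l + 1) >= h - 1e-12
        noisier = VarianceComponents(sg, sgl, 0.0, se * 2)
        assert linmod.heritability(noisier, r, l) <= h + 1e-12


class TestBLUPs:
    def test_full_shrinkage_when_genotypes_are_identical(self):
        df = balanced_records(n_geno=4, n_env=2, n_rep=3, n_trt=2, mu=50.0, noise_sd=0.0, seed=0)
        rng = np.random.default_rng(1)
        # replicate noise only: genotype means identical within each group
        df["seed_yield"] += df["replication"].map({"R1": -1.0, "R2": 0.0, "R3": 1.0})
        table = linmod.compute_blups(synth.TrialDataset(df), traits=["seed_yield"])
        for _, grp in table.groupby(["study", "treatment", "location"]):
            assert np.allclose(grp["seed_yield"], grp["seed_yield"].mean(), atol=1e-9)

    def test_no_shrinkage_limit_equals_raw_genotype_means(self):
        # genotype signal with zero replicate noise: lambda -> 1
        df = balanced_records(n_geno=4, n_env=2, n_rep=3, n_trt=1, mu=0.0, noise_sd=0.0, seed=0)
        df["seed_yield"] += df["genotype"].map({"G01": 10.0, "G02": 20.0, "G03": 30.0, "G04": 40.0})
        table = linmod.compute_blups(synth.TrialDataset(df), traits=["seed_yield"])
        for _, grp in table.groupby(["study", "treatment", "location"]):
            got = dict(zip(grp["genotype"], grp["seed_yield"]))
            assert got == pytest.approx({"G01": 10.0, "G02": 20.0, "G03": 30.0, "G04": 40.0})

    def test_shrinkage_factor_matches_first_principles_arithmetic(self):
        df = balanced_records(n_geno=6, n_env=1, n_rep=3, n_trt=1, mu=100.0, noise_sd=4.0, seed=9)
        table = linmod.compute_blups(synth.TrialDataset(df), traits=["seed_yield"])
        # independent arithmetic: EMS from explicit sums of squares
        G, R = 6, 3
        mat = df.pivot_table(index="genotype", columns="replication", values="seed_yield").to_numpy()
        mu = mat.mean()
        gbar = mat.mean(axis=1)
        rbar = mat.mean(axis=0)
        sse = ((mat - gbar[:, None] - rbar[None, :] + mu) ** 2).sum()
        ms_e = sse / ((G - 1) * (R - 1))
        ms_g = R * ((gbar - mu) ** 2).sum() / (G - 1)
        sg2 = max((ms_g - ms_e) / R, 0.0)
        lam = sg2 / (sg2 + ms_e / R)
        expected = mu + lam * (gbar - mu)
        got = table.sort_values("genotype")["seed_yield"].to_numpy()
        assert np.allclose(got, expected, atol=1e-9)

    def test_blup_deviations_shrink_and_sum_to_zero(self, default_dataset, default_blups):
        raw = default_dataset.records.groupby(["study", "treatment", "environment", "genotype"], observed=True)[
            "seed_yield"
        ].mean()
        for key, grp in default_blups.groupby(["study", "treatment", "location"], observed=True):
            mu = grp["seed_yield"].mean()
            dev = grp["seed_yield"] - mu
            assert abs(dev.sum()) < 1e-6 * max(abs(mu), 1.0)
            raw_grp = raw.loc[key]
            raw_dev = raw_grp - raw_grp.mean()
            for g, d in zip(grp["genotype"], dev):
                assert abs(d) <= abs(raw_dev[g]) + 1e-9
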