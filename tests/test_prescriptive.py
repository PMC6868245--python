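"""Fit classes, selection confusion metrics and the fit classifier."""

import numpy as np
import pandas as pd
import pytest

from phenobreed import prescriptive, synth
from phenobreed.prescriptive import ClassMetrics, ConfusionCounts
from phenobreed._rng import substream


def brute_force_confusion(pred, obs, intensity):
    """Independent oracle: enumerate the per-candidate selection decisions."""
    n = len(pred)
    k = min(max(int(round(intensity * n)), 1), n - 1)
    sel = set(np.argsort(-np.asarray(pred), kind="stable")[:k].tolist())
    pos = set(np.argsort(-np.asarray(obs), kind="stable")[:k].tolist())
    tp = tn = fp = fn = 0
    for i in range(n):
        if i in sel and i in pos:
            tp += 1
        elif i in sel:
            fp += 1
        elif i in pos:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


class TestSelectionConfusion:
    def test_perfect_prediction(self):
        c = prescriptive.selection_confusion(np.arange(10.0), np.arange(10.0), 0.2)
        assert (c.TP, c.FP, c.FN, c.TN) == (2, 0, 0, 8)

    def test_partial_overlap_hand_values(self):
        obs = np.array([10, 9, 1, 2, 3, 4, 5, 6, 7, 8.0])  # top-2 observed: idx 0, 1
        pred = np.array([10, 1, 9, 2, 3, 4, 5, 6, 7, 8.0])  # top-2 predicted: idx 0, 2
        c = prescriptive.selection_confusion(pred, obs, 0.2)
        assert (c.TP, c.FP, c.FN, c.TN) == (1, 1, 1, 7)
        m = prescriptive.classification_metrics(c)
        assert m.selection_accuracy == pytest.approx(0.8)
        assert m.SEN == pytest.approx(0.5)
        assert m.SPE == pytest.approx(0.875)
        assert m.BACC == pytest.approx(0.6875)

    def test_reversed_prediction(self):
        obs = np.arange(10.0)
        c = prescriptive.selection_confusion(obs[::-1].copy(), obs, 0.2)
        assert (c.TP, c.FP, c.FN, c.TN) == (0, 2, 2, 6)

    def test_agrees_with_brute_force_enumeration(self):
        rng = substream(77, "confusion")
        for _ in range(100):
            n = int(rng.integers(5, 40))
            pred = rng.normal(size=n)
            obs = rng.normal(size=n)
            intensity = float(rng.uniform(0.1, 0.5))
            c = prescriptive.selection_confusion(pred, obs, intensity)
            assert (c.TP, c.TN, c.FP, c.FN) == tuple(brute_force_confusion(pred, obs, intensity))


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        m = prescriptive.classification_metrics(ConfusionCounts(3, 7, 0, 0))
        assert (m.BACC, m.PRE, m.SEN, m.SPE, m.selection_accuracy) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_degenerate_denominators_are_missing(self):
        m = prescriptive.classification_metrics(ConfusionCounts(0, 5, 0, 2))
        assert np.isnan(m.PRE)
        assert m.SEN == 0.0

    def test_bacc_identity_holds(self):
        rng = substream(5, "bacc")
        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(1, 20, 4))
            m = prescriptive.classification_metrics(ConfusionCounts(tp, tn, fp, fn))
            assert m.BACC == pytest.approx((m.SEN + m.SPE) / 2)


def tiny_blups(a, b, study_id="IA-RS", levels=("38cm", "76cm")):
    rows = []
    for g in sorted(a):
        rows.append({"study": study_id, "treatment": levels[0], "location": "L1", "genotype": g, "seed_yield": a[g]})
        rows.append({"study": study_id, "treatment": levels[1], "location": "L1", "genotype": g, "seed_yield": b[g]})
    return pd.DataFrame(rows)


RS = synth.default_config().studies[0]


class TestFitDeviations:
    def test_hand_arithmetic(self):
        blups = tiny_blups({"g1": 3100.0, "g2": 3000.0}, {"g1": 3000.0, "g2": 3050.0})
        fit = prescriptive.compute_fit_deviations(blups, RS)
        d = dict(zip(fit.table["genotype"], fit.table["D_g"]))
        assert d == pytest.approx({"g1": 100.0, "g2": -50.0})
        assert fit.mu_g == pytest.approx(25.0)
        assert fit.sd_g == pytest.approx(106.0660172, rel=1e-6)

    def test_identical_levels_give_zero_deviations(self):
        blups = tiny_blups({"g1": 3000.0, "g2": 3100.0}, {"g1": 3000.0, "g2": 3100.0})
        fit = prescriptive.compute_fit_deviations(blups, RS)
        assert np.allclose(fit.table["D_g"], 0.0)
        assert fit.mu_g == 0.0

    def test_swapping_the_contrast_negates_deviations(self):
        blups = tiny_blups({"g1": 3100.0, "g2": 3000.0}, {"g1": 3000.0, "g2": 3050.0})
        fwd = prescriptive.compute_fit_deviations(blups, RS, contrast=("38cm", "76cm"))
        rev = prescriptive.compute_fit_deviations(blups, RS, contrast=("76cm", "38cm"))
        assert np.allclose(fwd.table["D_g"].to_numpy(), -rev.table["D_g"].to_numpy())


class TestAssignClasses:
    def test_all_equal_deviations_are_universal(self):
        blups = tiny_blups({"g1": 3.0, "g2": 3.0}, {"g1": 1.0, "g2": 1.0})
        fit = prescriptive.assign_fit_classes(prescriptive.compute_fit_deviations(blups, RS))
        assert set(fit.table["fit_class"]) == {"U"}

    def test_standard_normal_deviations_calibrate_to_the_one_sd_band(self):
        rng = substream(31, "calib")
        d = rng.normal(size=1000)
        table = prescriptive.FitClassTable(
            pd.DataFrame({"genotype": [f"G{i}" for i in range(1000)], "D_g": d}),
            mu_g=float(d.mean()),
            sd_g=float(d.std(ddof=1)),
            contrast=("38cm", "76cm"),
            labels=("N", "U", "W"),
        )
        out = prescriptive.assign_fit_classes(table, k_sd=1.0)
        frac_u = (out.table["fit_class"] == "U").mean()
        assert abs(frac_u - 0.683) < 0.03

    def test_invariant_to_adding_a_constant_to_all_blups(self):
        base = tiny_blups({"g1": 3100.0, "g2": 3000.0, "g3": 2500.0}, {"g1": 3000.0, "g2": 3050.0, "g3": 2500.0})
        shifted = base.copy()
        shifted["seed_yield"] += 500.0
        a = prescriptive.assign_fit_classes(prescriptive.compute_fit_deviations(base, RS))
        b = prescriptive.assign_fit_classes(prescriptive.compute_fit_deviations(shifted, RS))
        assert list(a.table["fit_class"]) == list(b.table["fit_class"])

    def test_treatment_relabeling_flips_adapted_classes(self):
        base = tiny_blups({"g1": 3300.0, "g2": 3000.0, "g3": 2950.0}, {"g1": 3000.0, "g2": 3050.0, "g3": 3300.0})
        fwd = prescriptive.assign_fit_classes(prescriptive.compute_fit_deviations(base, RS, contrast=("38cm", "76cm")))
        rev = prescriptive.assign_fit_classes(prescriptive.compute_fit_deviations(base, RS, contrast=("76cm", "38cm")))
        # forward uses the study labels (N/U/W); reversed contrasts use generic
        # level-named labels, so compare by meaning: adapted-to-38cm stays so
        meaning = {"N": "38cm-adapted", "W": "76cm-adapted", "U": "U"}
        fwd_classes = dict(zip(fwd.table["genotype"], fwd.table["fit_class"]))
        rev_classes = dict(zip(rev.table["genotype"], rev.table["fit_class"]))
        for g in fwd_classes:
            assert rev_classes[g] == meaning[fwd_classes[g]]
        assert np.allclose(fwd.table["D_g"].to_numpy(), -rev.table["D_g"].to_numpy())


class TestUpsample:
    def test_counts_are_equalized(self):
        rng = substream(3, "up")
        X = pd.DataFrame({"x": rng.normal(size=16)})
        y = pd.Series(["A"] * 8 + ["B"] * 3 + ["C"] * 5)
        Xu, yu = prescriptive.upsample_classes(X, y, seed=1)
        assert yu.value_counts().to_dict() == {"A": 8, "B": 8, "C": 8}
        assert len(Xu) == 24
        # every synthetic row duplicates an existing row of its class
        for label in "ABC":
            pool = set(X[y == label]["x"])
            assert set(Xu[yu == label]["x"]) <= pool

    def test_balanced_input_unchanged_and_single_class_warned(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        y = pd.Series(["A", "A", "B", "B"])
        Xu, yu = prescriptive.upsample_classes(X, y, seed=1)
        assert len(Xu) == 4
        Xs, ys = prescriptive.upsample_classes(X, pd.Series(["A"] * 4), seed=1)
        assert len(Xs) == 4


class TestFitClassifier:
    def test_separable_classes_are_learned(self):
        rng = substream(9, "sep")
        n_geno = 30
        classes = pd.Series(["hi"] * 15 + ["lo"] * 15, index=range(n_geno))
        rows = []
        for g in range(n_geno):
            for _ in range(6):  # several rows per genotype, as in per-location BLUPs
                rows.append({"geno": g, "x1": (1.0 if classes[g] == "hi" else -1.0) + rng.normal(0, 0.1), "x2": rng.normal()})
        df = pd.DataFrame(rows)
        res = prescriptive.train_fit_classifier(
            df[["x1", "x2"]], df["geno"].map(classes), groups=df["geno"], repeats=5, n_trees=50, seed=2
        )
        assert (res["BACC"] >= 0.95).all()

    def test_source_comparison_shapes_and_null_equality(self):
        rng = substream(13, "src")
        n_geno = 24
        classes = pd.Series(["a"] * 8 + ["b"] * 8 + ["c"] * 8, index=range(n_geno))
        rows = []
        for g in range(n_geno):
            for trt in ("T1", "T2"):
                for _ in range(3):
                    rows.append({"geno": g, "trt": trt, "x1": rng.normal(), "x2": rng.normal()})
        df = pd.DataFrame(rows)
        out = prescriptive.compare_training_sources(
            df[["x1", "x2"]],
            df["geno"].map(classes),
            treatments=df["trt"],
            groups=df["geno"],
            repeats=3,
            n_trees=30,
            seed=4,
        )
        assert set(out["source"]) == {"T1", "T2", "all"}
        assert len(out) == 9  # sources x classes
        # predictors carry no class signal: every source hovers near chance
        assert out["BACC"].mean() == pytest.approx(0.5, abs=0.12)
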