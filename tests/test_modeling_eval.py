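"""Feature assembly, LASSO + MLP modeling, metrics, and statistics."""

import io

import numpy as np
import pandas as pd
import pytest

from tmegraph.dlps import DLPSFeatures
from tmegraph.modeling_eval import (
    ClinicalRecord, EvalReport, FeatureScaler, ModelConfig, PCRModel,
    ablation_run, assemble_features, bh_adjust, cross_val_auc, delong_test,
    evaluate, group_percentages, lasso_select, patient_feature_names,
    rank_auc, sensitivity_grid, spearman_with_ris,
    train_compartment_classifier, univariate_tests,
)
from tmegraph.sna_features import SNAFeatureVector


def make_clinical(**kw):
    base = dict(er_status=1, er_percent=80.0, pr_status=0, pr_percent=2.0,
                cep17=2.1, her2_cep17_ratio=4.4, pcr=0, ris_cm=1.3)
    base.update(kw)
    return ClinicalRecord(**base)


def separable_data(n=60, p=6, seed=0, effect=3.0):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(int)
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y
    X[:, 1] -= effect * y
    return X, y


class TestAssemble:
    def test_length_99_and_order(self):
        sna = SNAFeatureVector(np.arange(91, dtype=float))
        d = DLPSFeatures({"STROMA": (0.6, 0.1)})
        vec = assemble_features(sna, d, make_clinical(), "STROMA", "p1")
        assert vec.values.shape == (99,)
        assert vec.values[:91].tolist() == list(range(91))
        assert vec.values[91:93].tolist() == [0.6, 0.1]
        assert vec.values[93:].tolist() == [1, 80.0, 0, 2.0, 2.1, 4.4]
        assert len(patient_feature_names()) == 99

    def test_empty_graph_sna_zeros_still_valid(self):
        sna = SNAFeatureVector(np.zeros(91), valid=False)
        vec = assemble_features(sna, (0.0, 0.0), make_clinical(), "ITIL")
        assert not vec.values[:91].any()

    def test_csv_round_trip_preserves_columns(self, tmp_path):
        sna = SNAFeatureVector(np.random.default_rng(0).normal(size=91))
        vec = assemble_features(sna, (0.5, 0.2), make_clinical(), "TUMOR", "p9")
        df = pd.DataFrame([vec.values], columns=patient_feature_names(),
                          index=["p9"])
        buf = io.StringIO()
        df.to_csv(buf)
        back = pd.read_csv(io.StringIO(buf.getvalue()), index_col=0)
        assert back.columns.tolist() == patient_feature_names()
        assert back.loc["p9"].to_numpy() == pytest.approx(vec.values)

    def test_missing_clinical_field_named(self):
        with pytest.raises(ValueError, match="her2_cep17_ratio"):
            ClinicalRecord.from_dict({
                "er_status": 1, "er_percent": 50, "pr_status": 1,
                "pr_percent": 50, "cep17": 2.0, "pcr": 0, "ris_cm": 1.0,
            })

    def test_pcr_implies_zero_ris(self):
        with pytest.raises(ValueError, match="ris_cm = 0"):
            make_clinical(pcr=1, ris_cm=2.0)


class TestLasso:
    def test_huge_lambda_shrinks_everything(self):
        X, y = separable_data()
        X = FeatureScaler().fit_transform(X)
        res = lasso_select(X, y, lambda_=1e6)
        assert res.selected.size == 0
        assert not res.coef.any()

    def test_orthonormal_soft_threshold_closed_form(self):
        """On a design with X'X = nI the LASSO solution is the
        soft-thresholded univariate estimate sign(b)(|b| - lambda)+."""
        rng = np.random.default_rng(1)
        n, p = 64, 4
        M = rng.normal(size=(n, p))
        M -= M.mean(axis=0)                     # zero-mean columns
        Q, _ = np.linalg.qr(M)
        X = Q * np.sqrt(n)                      # centered, X'X = n I
        y = (rng.random(n) < 0.5).astype(float)
        lam = 0.05
        res = lasso_select(X, y, lambda_=lam)
        b = X.T @ (y - y.mean()) / n            # univariate estimates
        expect = np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)
        assert res.coef == pytest.approx(expect, abs=1e-6)

    def test_constant_column_warns_and_zeroed(self):
        X, y = separable_data()
        X[:, 3] = 7.0
        with pytest.warns(UserWarning, match="constant feature"):
            res = lasso_select(X, y, lambda_=0.01)
        assert res.coef[3] == 0.0

    def test_duplicate_column_mass_stable(self):
        X, y = separable_data(p=4)
        Xd = np.column_stack([X, X[:, 0]])
        r1 = lasso_select(FeatureScaler().fit_transform(Xd), y, lambda_=0.02)
        perm = [4, 1, 2, 3, 0]
        r2 = lasso_select(FeatureScaler().fit_transform(Xd[:, perm]), y,
                          lambda_=0.02)
        assert np.abs(r1.coef).sum() == pytest.approx(
            np.abs(r2.coef).sum(), abs=1e-6
        )

    def test_cv_choice_is_deterministic(self):
        X, y = separable_data(seed=5)
        X = FeatureScaler().fit_transform(X)
        cfg = ModelConfig(seed=9)
        assert lasso_select(X, y, cfg).lambda_ == lasso_select(X, y, cfg).lambda_


class TestClassifier:
    def test_separable_toy_cv_auc(self):
        X, y = separable_data(n=60, p=2)
        _, params, auc = train_compartment_classifier(X, y, ModelConfig(seed=0))
        assert auc >= 0.95

    def test_label_shuffle_null_band(self):
        X, y = separable_data(n=80, p=2)
        y = np.random.default_rng(0).permutation(y)
        _, _, auc = train_compartment_classifier(X, y, ModelConfig(seed=0))
        assert 0.35 <= auc <= 0.65

    def test_same_seed_same_hyperparameters(self):
        X, y = separable_data(n=40)
        _, p1, _ = train_compartment_classifier(X, y, ModelConfig(seed=4))
        _, p2, _ = train_compartment_classifier(X, y, ModelConfig(seed=4))
        assert p1 == p2

    def test_degenerate_fold_refused(self):
        X, y = separable_data(n=12)
        y[:] = 0
        y[:3] = 1  # only 3 positives < 5 folds
        with pytest.raises(ValueError, match="fewer folds"):
            train_compartment_classifier(X, y, ModelConfig(seed=0))

    def test_pipeline_attribution_prefers_signal_block(self):
        """When only the first block of columns carries signal, LASSO puts
        >= 90% of absolute coefficient mass there."""
        rng = np.random.default_rng(7)
        n = 120
        y = (np.arange(n) % 2).astype(int)
        signal = rng.normal(size=(n, 5)) + 2.0 * y[:, None]
        noise = rng.normal(size=(n, 20))
        X = FeatureScaler().fit_transform(np.column_stack([signal, noise]))
        res = lasso_select(X, y, ModelConfig(seed=0))
        mass = np.abs(res.coef)
        assert mass[:5].sum() >= 0.9 * mass.sum()


class TestEvaluate:
    def test_perfect_separation(self):
        rep = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert rep.auc == 1.0 and rep.f1 == 1.0 and rep.ppv == 1.0
        assert rep.recall == 1.0 and rep.npv == 1.0

    def test_all_ties_auc_half(self):
        rep = evaluate(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0]))
        assert rep.auc == 0.5

    def test_concordant_pair_example(self):
        auc = rank_auc(np.array([0.9, 0.4, 0.6, 0.2]), np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(3 / 4)

    def test_auc_equals_mannwhitney_u(self, rng):
        from scipy.stats import mannwhitneyu

        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, 40):
            labels[0] = 1 - labels[0]
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        n1, n0 = labels.sum(), (1 - labels).sum()
        assert rank_auc(scores, labels) == pytest.approx(u / (n1 * n0))

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single class"):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_empty_denominator_warns(self):
        with pytest.warns(UserWarning, match="PPV undefined"):
            rep = evaluate(np.array([0.1, 0.2, 0.3, 0.4]),
                           np.array([1, 0, 1, 0]), threshold=0.9)
        assert rep.ppv == 0.0


class TestDeLong:
    def test_identical_scores_z0_p1(self):
        s = np.array([0.8, 0.3, 0.6, 0.2, 0.9, 0.1])
        y = np.array([1, 0, 1, 0, 1, 0])
        with pytest.warns(UserWarning, match="zero variance"):
            z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_swap_symmetry(self, rng):
        y = rng.integers(0, 2, 40)
        y[:5], y[5:10] = 1, 0
        a, b = rng.uniform(size=40), rng.uniform(size=40)
        z1, p1 = delong_test(a, b, y)
        z2, p2 = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_detects_real_auc_difference(self, rng):
        y = np.repeat([1, 0], 50)
        good = y + rng.normal(0, 0.5, 100)
        noise = rng.uniform(size=100)
        good = (good - good.min()) / np.ptp(good)
        _, p = delong_test(good, noise, y)
        assert p < 0.01


class TestUnivariate:
    def test_bh_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_bh_monotone_and_not_below_raw(self, rng):
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_fully_separated_groups_minimal_p(self):
        x = np.concatenate([np.arange(10), np.arange(100, 110)])
        y = np.repeat([0, 1], 10)
        out = univariate_tests(pd.DataFrame({"f": x}), y)
        from scipy.stats import mannwhitneyu

        pmin = mannwhitneyu(x[y == 1], x[y == 0],
                            alternative="two-sided").pvalue
        assert out.loc[0, "p_raw"] == pytest.approx(pmin)
        assert pmin < 1e-3

    def test_categorical_uses_chi_square_and_constant_p1(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        df = pd.DataFrame({
            "cat": np.where(y == 1, rng.integers(0, 2, 60) | 1, 0),
            "const": 5.0,
            "cont": rng.normal(size=60) + y,
        })
        out = univariate_tests(df, y, categorical=["cat"]).set_index("feature")
        assert out.loc["cat", "test"] == "chi-square"
        assert out.loc["const", "p_raw"] == 1.0
        assert out.loc["cont", "test"] == "mann-whitney"


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_with_ris(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman_with_ris(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        """Pearson correlation of average ranks equals the reported rho."""
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 7.0])
        r = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0, 7.0])
        from scipy.stats import rankdata

        rx, rr = rankdata(x), rankdata(r)
        expect = np.corrcoef(rx, rr)[0, 1]
        assert spearman_with_ris(x, r)[0] == pytest.approx(expect)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant input"):
            rho, p = spearman_with_ris([1.0] * 5, [1, 2, 3, 4, 5])
        assert np.isnan(rho)


class TestPCRModel:
    def test_fit_predict_and_manifest(self):
        X, y = separable_data(n=60, p=10)
        model = PCRModel(ModelConfig(seed=0)).fit(X, y)
        proba = model.predict_proba(X)
        assert rank_auc(proba, y) > 0.9
        man = model.manifest()
        assert man["version"] == 1 and len(man["selected_indices"]) >= 1

    def test_cross_val_auc_no_leakage_null(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 30))
        y = (np.arange(80) % 2).astype(int)
        auc = cross_val_auc(X, y, ModelConfig(seed=0))
        assert 0.3 <= auc <= 0.7


class TestHarnesses:
    def test_sensitivity_grid_shape_and_determinism(self, tiny_cohort):
        cfg = ModelConfig(seed=0, lasso_lambda_grid=(0.01, 0.1),
                          mlp_hidden=((8,),), mlp_alphas=(1e-3,))
        grid = sensitivity_grid(
            tiny_cohort, K_values=(4, 5), P_values=(-50.0, -20.0),
            compartments=("STROMA",), config=cfg,
        )
        assert len(grid) == 4
        assert set(grid["K"]) == {4, 5} and set(grid["P"]) == {-50.0, -20.0}
        grid2 = sensitivity_grid(
            tiny_cohort, K_values=(4,), P_values=(-50.0,),
            compartments=("STROMA",), config=cfg,
        )
        cell = grid[(grid.K == 4) & (grid.P == -50.0)]["auc"].iloc[0]
        assert grid2["auc"].iloc[0] == pytest.approx(cell)

    def test_ablation_reports_and_identity_fraction(self):
        X, y = separable_data(n=80, p=5)
        Xt, yt = separable_data(n=40, p=5, seed=9)
        cfg = ModelConfig(seed=1, lasso_lambda_grid=(0.01, 0.1),
                          mlp_hidden=((8,),), mlp_alphas=(1e-3,))
        reports = ablation_run(X, y, Xt, yt, fractions=(0.5, 1.0), config=cfg)
        assert set(reports) == {0.5, 1.0}
        full = PCRModel(cfg).fit(X, y)
        direct = evaluate(full.predict_proba(Xt), yt)
        assert reports[1.0].auc == pytest.approx(direct.auc)

    def test_ablation_skips_too_small_fraction(self):
        X, y = separable_data(n=30, p=3)
        Xt, yt = separable_data(n=20, p=3, seed=2)
        cfg = ModelConfig(seed=0, lasso_lambda_grid=(0.1,),
                          mlp_hidden=((8,),), mlp_alphas=(1e-3,))
        with pytest.warns(UserWarning, match="skipped"):
            reports = ablation_run(X, y, Xt, yt, fractions=(0.1,), config=cfg)
        assert reports == {}


def test_group_percentages_printed_precision():
    out = group_percentages({"pcr": 36, "residual": 49}, total=85)
    assert out == {"pcr": 42.35, "residual": 57.65}


def test_eval_report_fields_in_unit_interval():
    rep = EvalReport(auc=0.9, f1=0.8, ppv=0.7, recall=0.95, npv=0.6)
    assert all(0 <= v <= 1 for v in rep.as_dict().values())
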