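"""Signature features and the cross-cohort histology random forest."""

import numpy as np
import pandas as pd
import pytest

from colitraj import predict, stats
from colitraj.io import Signature


def _we(E):
    return stats.WeightedExpression(E, np.ones_like(E.to_numpy()))


def _expr(rng, n_genes=30, n_samples=12, prefix="g"):
    E = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"{prefix}{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)])
    return _we(E)


class TestSignaturePCs:
    def test_single_direction_dominates_pc1(self, rng):
        load = rng.normal(size=10)
        scores = rng.normal(size=20)
        E = pd.DataFrame(
            np.outer(load, scores) + rng.normal(0, 0.01, size=(10, 20)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(20)])
        proj, pcs = predict.signature_pcs(_we(E), Signature("x", list(E.index)))
        assert proj.explained_variance_ratio[0] > 0.98
        r = abs(np.corrcoef(pcs["PC1"], scores)[0, 1])
        assert r > 0.99

    def test_projection_of_training_data_equals_fit_scores(self, rng):
        we = _expr(rng)
        sig = Signature("x", list(we.E.index)[:10])
        proj, pcs = predict.signature_pcs(we, sig)
        reproj = predict.project_pcs(proj, we)
        np.testing.assert_allclose(pcs.to_numpy(), reproj.to_numpy(), atol=1e-10)

    def test_small_signature_reduces_components(self, rng):
        we = _expr(rng)
        with pytest.warns(UserWarning, match="reducing"):
            proj, pcs = predict.signature_pcs(we, Signature("x", ["g0", "g1"]), n=3)
        assert pcs.shape[1] == 2

    def test_orthogonal_planted_factors_recovered(self, rng):
        v1 = np.concatenate([np.ones(10), np.zeros(10)])
        v2 = np.concatenate([np.zeros(10), np.ones(10)])
        s1 = rng.normal(0, 3, 40)
        s2 = rng.normal(0, 1, 40)
        E = pd.DataFrame(
            np.outer(v1, s1) + np.outer(v2, s2) + rng.normal(0, 0.05, (20, 40)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(40)])
        proj, _ = predict.signature_pcs(_we(E), Signature("x", list(E.index)))
        r1 = abs(np.corrcoef(proj.loadings[:, 0], v1)[0, 1])
        r2 = abs(np.corrcoef(proj.loadings[:, 1], v2)[0, 1])
        assert r1 > 0.95 and r2 > 0.95


class TestMedianScore:
    def test_hand_value(self):
        E = pd.DataFrame([[1.0], [2.0], [9.0]], index=list("abc"), columns=["s1"])
        s = predict.median_score(_we(E), Signature("x", list("abc")))
        assert s["s1"] == 2.0

    def test_constant_shift_equivariance(self, rng):
        we = _expr(rng)
        sig = Signature("x", list(we.E.index)[:7])
        base = predict.median_score(we, sig)
        shifted = predict.median_score(_we(we.E + 3.5), sig)
        np.testing.assert_allclose(shifted, base + 3.5)

    def test_empty_intersection_errors(self, rng):
        with pytest.raises(ValueError):
            predict.median_score(_expr(rng), Signature("x", ["absent"]))


class TestKappa:
    def test_hand_confusion_matrix(self):
        # [[2,1],[1,2]]: po=2/3, pe=1/2 -> kappa = 1/3
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 0, 1, 1]
        assert predict.cohen_kappa(a, b) == pytest.approx(1 / 3)

    def test_exhaustive_2x2_matches_sklearn(self):
        from itertools import product

        from sklearn.metrics import cohen_kappa_score

        for tp, fn, fp, tn in product(range(5), repeat=4):
            n = tp + fn + fp + tn
            if n == 0:
                continue
            a = [1] * (tp + fn) + [0] * (fp + tn)
            b = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            ours = predict.cohen_kappa(a, b)
            ref = cohen_kappa_score(a, b)
            if np.isnan(ref):  # single-label degenerate cases
                assert ours in (0.0, 1.0)
            else:
                assert ours == pytest.approx(ref, abs=1e-12)


class TestBuildFeatures:
    def _setup(self, rng):
        we_g = _expr(rng, 40, 15, "g")
        we_e = _expr(rng, 60, 15, "e")
        gene_sig = Signature("gene-sig", [f"g{i}" for i in range(12)])
        exon_sig = Signature("exon-sig", [f"e{i}" for i in range(12)])
        prof = pd.DataFrame({
            "vdj_read_cpm": rng.uniform(0, 100, 15),
            "clone_count": 5,
            "clonality": rng.uniform(0, 1, 15),
        }, index=we_g.E.columns)
        return we_g, we_e, gene_sig, exon_sig, prof

    def test_columns_match_model_formula(self, rng):
        we_g, we_e, gs, es, prof = self._setup(rng)
        builder = predict.fit_feature_builder(we_g, we_e, gs, es)
        feats = predict.build_features(builder, we_g, we_e, prof)
        assert list(feats.columns) == predict.FEATURE_COLUMNS
        assert not feats.isna().any().any()

    def test_missing_vdj_sample_errors(self, rng):
        we_g, we_e, gs, es, prof = self._setup(rng)
        builder = predict.fit_feature_builder(we_g, we_e, gs, es)
        with pytest.raises(ValueError, match="vdj"):
            predict.build_features(builder, we_g, we_e, prof.iloc[:-1])

    def test_empty_exon_signature_zero_filled(self, rng):
        we_g, we_e, gs, _, prof = self._setup(rng)
        with pytest.warns(UserWarning, match="zero-filled"):
            builder = predict.fit_feature_builder(
                we_g, we_e, gs, Signature("none", ["absent"]))
        feats = predict.build_features(builder, we_g, we_e, prof)
        assert (feats[predict.EXON_PC_COLUMNS] == 0).all().all()
        assert "exon_signature_empty" in builder.flags


class TestRandomForest:
    def _features(self, rng, n=40):
        X = pd.DataFrame(
            rng.normal(size=(n, len(predict.FEATURE_COLUMNS))),
            columns=predict.FEATURE_COLUMNS,
            index=[f"s{i}" for i in range(n)])
        return X

    def test_linear_outcome_retains_driver_and_fits(self, rng):
        X = self._features(rng)
        y = pd.Series(3.0 * X["PC1_gene"].to_numpy() + 10.0, index=X.index)
        model = predict.train_rf(X, y, n_trees=200, seed=1)
        assert "PC1_gene" in model.retained
        pred = model.forest.predict(X[model.retained].to_numpy())
        rho, _ = stats.spearman(pred, y.to_numpy())
        assert rho > 0.95

    def test_deterministic_given_seed(self, rng):
        X = self._features(rng)
        y = pd.Series(X["PC1_gene"].to_numpy() + rng.normal(0, 0.1, len(X)),
                      index=X.index)
        m1 = predict.train_rf(X, y, n_trees=100, seed=7)
        m2 = predict.train_rf(X, y, n_trees=100, seed=7)
        assert m1.retained == m2.retained
        np.testing.assert_array_equal(
            m1.forest.predict(X[m1.retained].to_numpy()),
            m2.forest.predict(X[m2.retained].to_numpy()))

    def test_constant_outcome_rejected(self, rng):
        X = self._features(rng)
        with pytest.raises(ValueError, match="constant"):
            predict.train_rf(X, pd.Series(1.0, index=X.index), seed=0)

    def test_validation_report_perfect_predictions(self, rng):
        X = self._features(rng)
        y = pd.Series(2.0 * X["PC1_gene"].to_numpy() ** 2 + 5, index=X.index)
        model = predict.train_rf(X, y, n_trees=200, seed=2)
        Xv = X.iloc[:10]
        # feed the model's own predictions back as the observed outcome
        yv = pd.Series(model.forest.predict(Xv[model.retained].to_numpy()),
                       index=Xv.index)
        rep = predict.validate(model, Xv, yv)
        assert rep["rho"] == pytest.approx(1.0)
        assert rep["kappa"] == 1.0
        assert len(rep["top_predictors"]) <= 3

    def test_validation_does_not_leak_into_training(self, rng):
        X = self._features(rng, n=30)
        y = pd.Series(X["PC1_gene"].to_numpy() + rng.normal(0, 0.2, 30),
                      index=X.index)
        model = predict.train_rf(X, y, n_trees=100, seed=3)
        Xv = self._features(np.random.default_rng(99), n=12)
        Xv.index = [f"v{i}" for i in range(12)]
        yv = pd.Series(Xv["PC1_gene"].to_numpy(), index=Xv.index)
        r1 = predict.validate(model, Xv, yv)
        # shuffling validation rows leaves the fitted model untouched
        order = np.random.default_rng(5).permutation(12)
        r2 = predict.validate(model, Xv.iloc[order], yv)
        assert r1["rho"] == pytest.approx(r2["rho"])
        assert model.retained == predict.train_rf(X, y, n_trees=100, seed=3).retained
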