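"""Interaction LRT, trajectory standardization and soft clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from colitraj import dynamic, simulate as sim, stats
from colitraj.io import CountMatrix


def _copied_groups_study(seed=0, n_genes=150, npg=4):
    """Disease samples are literal copies of day-matched control samples."""
    rng = np.random.default_rng(seed)
    days = (5, 12, 17, 36)
    blocks, cols, rows = [], [], []
    for d in days:
        base = rng.poisson(150, size=(n_genes, npg))
        blocks += [base, base]
        for grp in ("control", "disease"):
            for i in range(npg):
                cols.append(f"{grp[:3]}_d{d}_{i}")
                rows.append((f"{grp[:3]}_d{d}_{i}", grp, d, "TOY", "colon"))
    cm = CountMatrix(pd.DataFrame(
        np.hstack(blocks), index=[f"g{i}" for i in range(n_genes)], columns=cols))
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "day", "cohort", "tissue"])
    return cm, meta


class TestInteractionLRT:
    def test_copied_groups_give_null_statistics(self):
        cm, meta = _copied_groups_study()
        res = dynamic.interaction_lrt(cm, meta)
        assert res["df"].unique().tolist() == [3]
        assert res["stat"].min() >= -1e-6
        # identical groups: interaction adds nothing
        assert res["p"].median() > 0.5
        assert (res["q"] < 0.05).sum() == 0

    def test_four_days_give_three_df(self, small_study):
        res = dynamic.interaction_lrt(small_study["gene"], small_study["meta"])
        assert (res["df"] == 3).all()

    def test_planted_trajectories_detected(self, small_study):
        res = dynamic.interaction_lrt(small_study["gene"], small_study["meta"])
        truth = small_study["truth"]
        planted = [g for c in "ABCDE" for g in truth.genes_with_label(f"cluster-{c}")]
        hits = set(res.loc[res["q"] < 0.05, "gene_id"])
        assert len(hits & set(planted)) / len(planted) > 0.8

    def test_requires_both_groups_every_day(self, small_study):
        meta = small_study["meta"]
        broken = meta[~((meta["day"] == 36) & (meta["group"] == "control"))]
        with pytest.raises(ValueError, match="both groups"):
            dynamic.interaction_lrt(small_study["gene"], broken)


class TestTrajectories:
    def test_single_disease_sample_trajectory_is_that_sample(self, rng):
        E = pd.DataFrame(rng.normal(size=(5, 8)),
                         index=[f"g{i}" for i in range(5)],
                         columns=[f"s{j}" for j in range(8)])
        we = stats.WeightedExpression(E, np.ones_like(E.to_numpy()))
        meta = pd.DataFrame({
            "sample_id": list(E.columns),
            "group": ["disease", "control"] * 4,
            "day": [5, 5, 12, 12, 17, 17, 36, 36],
            "cohort": "TOY", "tissue": "colon"})
        T = dynamic.median_disease_trajectories(we, meta, list(E.index))
        np.testing.assert_allclose(T[5], E["s0"])
        np.testing.assert_allclose(T[17], E["s4"])

    def test_median_robust_to_outlier(self, rng):
        E = pd.DataFrame(np.zeros((1, 6)), index=["g0"],
                         columns=[f"s{j}" for j in range(6)])
        E.iloc[0, 2] = 1000.0
        we = stats.WeightedExpression(E, np.ones_like(E.to_numpy()))
        meta = pd.DataFrame({
            "sample_id": list(E.columns), "group": "disease",
            "day": [5, 5, 5, 12, 12, 12], "cohort": "TOY", "tissue": "colon"})
        T = dynamic.median_disease_trajectories(we, meta, ["g0"])
        assert T.loc["g0", 5] == 0.0


class TestStandardize:
    def test_hand_example(self):
        T = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=[5, 12, 17, 36])
        z = dynamic.standardize_trajectories(T)
        np.testing.assert_allclose(
            z.loc["g"], [-1.1619, -0.3873, 0.3873, 1.1619], atol=1e-4)

    def test_idempotent(self, rng):
        T = pd.DataFrame(rng.normal(size=(10, 4)))
        z1 = dynamic.standardize_trajectories(T)
        z2 = dynamic.standardize_trajectories(z1)
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_negation_symmetry(self, rng):
        row = rng.normal(size=(1, 4))
        a = dynamic.standardize_trajectories(pd.DataFrame(row))
        b = dynamic.standardize_trajectories(pd.DataFrame(-row))
        np.testing.assert_allclose(a.to_numpy(), -b.to_numpy(), atol=1e-12)

    def test_constant_rows_dropped_and_all_constant_errors(self):
        T = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="constant"):
            z = dynamic.standardize_trajectories(T)
        assert len(z) == 1
        with pytest.raises(ValueError):
            dynamic.standardize_trajectories(pd.DataFrame([[2.0, 2.0, 2.0]]))


class TestFuzzyCMeans:
    def test_memberships_sum_to_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)))
        cl = dynamic.fuzzy_cmeans(X, k=3, m=1.6, seed=1)
        np.testing.assert_allclose(cl.membership.sum(axis=1), 1.0, atol=1e-8)
        assert ((cl.membership >= 0) & (cl.membership <= 1)).all().all()

    def test_two_separated_groups_perfectly_recovered(self, rng):
        a = rng.normal(0, 0.05, size=(30, 4)) + np.array([1, 1, -1, -1])
        b = rng.normal(0, 0.05, size=(30, 4)) + np.array([-1, -1, 1, 1])
        X = pd.DataFrame(np.vstack([a, b]))
        cl = dynamic.fuzzy_cmeans(X, k=2, m=1.5, seed=0)
        truth = [0] * 30 + [1] * 30
        codes = pd.factorize(cl.hard_labels)[0]
        assert adjusted_rand_score(truth, codes) == 1.0

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 4)))
        a = dynamic.fuzzy_cmeans(X, k=3, m=1.8, seed=9)
        b = dynamic.fuzzy_cmeans(X, k=3, m=1.8, seed=9)
        pd.testing.assert_frame_equal(a.membership, b.membership)

    def test_low_fuzzifier_approaches_hard_assignment(self, rng):
        a = rng.normal(0, 0.05, size=(20, 4)) + np.array([1, 1, -1, -1])
        b = rng.normal(0, 0.05, size=(20, 4)) + np.array([-1, -1, 1, 1])
        X = pd.DataFrame(np.vstack([a, b]))
        cl = dynamic.fuzzy_cmeans(X, k=2, m=1.05, seed=0)
        assert cl.membership.to_numpy().max(axis=1).min() > 0.99

    def test_point_on_center_gets_full_membership(self):
        X = pd.DataFrame(np.array(
            [[1.0, 0, 0, 0]] * 10 + [[0, 0, 0, 1.0]] * 10))
        cl = dynamic.fuzzy_cmeans(X, k=2, m=2.0, seed=0)
        assert cl.membership.to_numpy().max(axis=1).min() > 1 - 1e-9

    def test_planted_canonical_shapes_recovered(self, small_study):
        gene, meta, truth = (small_study["gene"], small_study["meta"],
                             small_study["truth"])
        res = dynamic.interaction_lrt(gene, meta)
        hits = res.loc[res["q"] < 0.05, "gene_id"].tolist()
        we = stats.logcpm_transform(gene)
        Tz = dynamic.standardize_trajectories(
            dynamic.median_disease_trajectories(we, meta, hits))
        cl = dynamic.fuzzy_cmeans(Tz, k=5, seed=11)
        labels = truth.gene_labels
        pairs = [(labels[g].replace("cluster-", ""), c)
                 for g, c in cl.hard_labels.items()
                 if labels[g].startswith("cluster")]
        ari = adjusted_rand_score([a for a, _ in pairs], [b for _, b in pairs])
        assert ari > 0.8
        for lab in cl.centers.index:
            shape = np.asarray(dynamic.CANONICAL_SHAPES[lab], dtype=float)
            c = cl.centers.loc[lab].to_numpy()
            r = np.corrcoef(shape - shape.mean(), c - c.mean())[0, 1]
            assert r > 0.9


class TestSplicingTrajectory:
    def test_planted_dynamic_switch_detected(self):
        cfg = sim.SimulationConfig(
            n_genes=600, n_fixed_per_day=0, trajectory_members={},
            n_splice=0, n_splice_dynamic=20, seed=21)
        _, exon, ann, meta, truth = sim.simulate_counts(cfg)
        res = dynamic.splicing_trajectory_lrt(exon, ann, meta)
        planted = set(truth.genes_with_label("splice-dynamic"))
        hits = set(res.loc[res["q"] < 0.05, "gene_id"])
        assert len(hits & planted) / len(planted) >= 0.5
        null_genes = set(truth.genes_with_label("null"))
        assert len(hits & null_genes) <= 0.02 * len(null_genes)

    def test_simes_hand_combination(self):
        assert stats.simes_combine([0.001, 0.5, 0.9]) == pytest.approx(0.003)


def test_estimate_fuzzifier_reasonable_range():
    m = dynamic.estimate_fuzzifier(725, 4)
    assert 1.5 < m < 4.0
    assert dynamic.estimate_fuzzifier(1, 0) == 1.25
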