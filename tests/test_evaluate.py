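"""Panel evaluation: KNN, cross-validation, trajectories, stratification,
clustering order."""

import numpy as np
import pytest

from diagnet.datasets import ExpressionDataset
from diagnet.evaluate import (
    KNNClassifier,
    cluster_order,
    cross_validate,
    knn_predict,
    panel_trajectory,
    stratify_t,
)
from diagnet.synthetic import SimConfig, generate_expression, generate_network

from oracles import knn_oracle

import pandas as pd


@pytest.fixture(scope="module")
def panel_instance():
    cfg = SimConfig(rng_seed=8, n_cohorts=1, n_tumor=120, n_normal=30)
    net, truth = generate_network(cfg)
    ds = generate_expression(net, truth, cfg)[0]
    return cfg, net, truth, ds


class TestKNNPredict:
    def test_single_training_point(self):
        assert knn_predict([[0.0, 0.0]], ["a"], [5.0, 5.0], k=1) == "a"

    def test_matches_reference_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(5, 30))
            d = int(rng.integers(1, 5))
            k = int(rng.integers(1, n + 1))
            X = rng.normal(size=(n, d))
            y = rng.choice(["a", "b", "c"], size=n)
            test = rng.normal(size=d)
            assert knn_predict(X, y, test, k) == knn_oracle(
                X.tolist(), list(y), list(test), k
            )

    def test_vote_tie_broken_by_nearest(self):
        # k=2, one neighbor of each class: the closer one wins
        X = [[0.0], [3.0]]
        y = ["near", "far"]
        assert knn_predict(X, y, [1.0], k=2) == "near"

    def test_distance_tie_broken_by_sample_order(self):
        X = [[1.0], [-1.0]]
        y = ["first", "second"]
        assert knn_predict(X, y, [0.0], k=1) == "first"

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            knn_predict([[0.0]], ["a"], [0.0], k=0)
        with pytest.raises(ValueError):
            knn_predict([[0.0]], ["a"], [0.0], k=2)

    def test_well_separated_clusters_loocv(self):
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            a = r.normal(0.0, 1.0, size=(25, 2))
            b = r.normal(6.0, 1.0, size=(25, 2))
            X = np.vstack([a, b])
            y = np.array(["a"] * 25 + ["b"] * 25)
            correct = 0
            for i in range(len(y)):
                mask = np.arange(len(y)) != i
                correct += knn_predict(X[mask], y[mask], X[i], k=10) == y[i]
            accs.append(correct / len(y))
        assert np.mean(accs) >= 0.99


class TestCrossValidate:
    def test_loo_deterministic_collapses(self, panel_instance):
        _, _, truth, ds = panel_instance
        panel = sorted(truth.pivotal_genes)
        report = cross_validate(ds, panel, scheme="loo", repeats=100, seed=0)
        assert report.collapsed
        assert len(report.accuracies) == 1
        assert report.min == report.median == report.max

    def test_kfold_planted_panel_accuracy(self, panel_instance):
        _, _, truth, ds = panel_instance
        panel = sorted(truth.pivotal_genes)
        report = cross_validate(ds, panel, scheme="kfold10", repeats=20, seed=0)
        assert report.mean >= 0.85
        assert report.min <= report.median <= report.max

    def test_label_permutation_chance_level(self, panel_instance):
        _, _, truth, ds = panel_instance
        rng = np.random.default_rng(1)
        tumors = ds.tumor_samples
        annot = ds.annotations.copy()
        perm = rng.permutation(len(tumors))
        annot.loc[tumors, ["ER", "PR", "HER2"]] = (
            annot.loc[tumors, ["ER", "PR", "HER2"]].to_numpy()[perm]
        )
        shuffled = ExpressionDataset(name="perm", values=ds.values, annotations=annot)
        freqs = shuffled.subtypes().value_counts(normalize=True)
        report = cross_validate(
            shuffled, sorted(truth.pivotal_genes), repeats=20, seed=2
        )
        # chance level for a k-NN vote lies between the match rate of random
        # assignment (sum of squared class frequencies) and the majority rate
        assert (freqs**2).sum() - 0.08 <= report.mean <= freqs.max() + 0.05

    def test_missing_panel_gene_errors(self, panel_instance):
        _, _, _, ds = panel_instance
        with pytest.raises(KeyError):
            cross_validate(ds, ["NOT_A_GENE"], repeats=2, seed=0)

    def test_stratified_folds_error_on_singleton_class(self, panel_instance):
        _, _, truth, ds = panel_instance
        # keep one sample of one class
        tumors = ds.tumor_samples
        sub = ds.subtypes()
        tng = [s for s in tumors if sub[s] == "TNG"]
        keep = [s for s in ds.samples if s not in tng[1:]]
        crippled = ExpressionDataset(
            name="few",
            values=ds.values[keep],
            annotations=ds.annotations.loc[keep],
        )
        with pytest.raises(ValueError, match="class"):
            cross_validate(crippled, sorted(truth.pivotal_genes), repeats=2, seed=0)


class TestTrajectory:
    def test_rises_through_panel_then_plateaus(self, panel_instance):
        _, net, truth, ds = panel_instance
        noise = [g for g in sorted(net.nodes()) if g not in truth.diff_genes][:3]
        ranked = sorted(truth.pivotal_genes) + noise
        traj = panel_trajectory(ds, ranked, repeats=10, seed=0)
        assert len(traj) == len(ranked)
        size4 = traj.loc[4, "mean_accuracy"]
        assert size4 >= traj.loc[1, "mean_accuracy"]
        # plateau: adding noise genes does not appreciably help
        assert traj.loc[len(ranked), "mean_accuracy"] <= size4 + 0.05

    def test_single_prefix_matches_cross_validate(self, panel_instance):
        _, _, truth, ds = panel_instance
        gene = sorted(truth.pivotal_genes)[0]
        traj = panel_trajectory(ds, [gene], repeats=5, seed=3)
        report = cross_validate(ds, [gene], repeats=5, seed=3)
        assert traj.loc[1, "mean_accuracy"] == pytest.approx(report.mean)

    def test_empty_list_rejected(self, panel_instance):
        _, _, _, ds = panel_instance
        with pytest.raises(ValueError):
            panel_trajectory(ds, [])


class TestStratifyT:
    def test_er_splitting_gene_significant(self):
        pvals = []
        for seed in range(20):
            cfg = SimConfig(
                rng_seed=200 + seed, n_cohorts=1, n_tumor=80, n_normal=10,
                subtype_shift=2.0,
            )
            net, truth = generate_network(cfg)
            ds = generate_expression(net, truth, cfg)[0]
            er_gene = next(
                g
                for g in sorted(truth.pivotal_genes)
                if truth.effect_table[g]["subtype_shift"].get("HR+HER2-", 0) > 0
                and truth.effect_table[g]["subtype_shift"].get("HR+HER2+", 0) > 0
            )
            _, p = stratify_t(ds, er_gene, grouping="ER")
            pvals.append(p)
        assert np.mean(np.array(pvals) < 1e-6) >= 0.95

    def test_sign_flips_with_groups(self, panel_instance):
        _, _, truth, ds = panel_instance
        gene = sorted(truth.pivotal_genes)[0]
        t_er, _ = stratify_t(ds, gene, grouping="ER")
        # flip by inverting the receptor labels
        annot = ds.annotations.copy()
        er = annot["ER"].map({"+": "-", "-": "+", "NA": "NA"})
        annot["ER"] = er
        flipped = ExpressionDataset(name="flip", values=ds.values, annotations=annot)
        t_flip, _ = stratify_t(flipped, gene, grouping="ER")
        assert t_flip == pytest.approx(-t_er, rel=1e-9)

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(size=(1, 40)),
            index=["G1"],
            columns=[f"S{i}" for i in range(40)],
        )
        rows = []
        for i in range(40):
            er = "+" if i % 2 == 0 else "-"
            rows.append((f"S{i}", "tumor", er, er, "-"))
        annot = pd.DataFrame(
            rows, columns=["sample", "group", "ER", "PR", "HER2"]
        ).set_index("sample")
        # same distribution in both strata: t near 0 on average
        ds = ExpressionDataset(name="null", values=values, annotations=annot)
        t, p = stratify_t(ds, "G1", grouping="ER")
        assert abs(t) < 3 and p > 1e-3


class TestClusterOrder:
    def test_two_separated_classes_contiguous(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.3, size=(3, 10))
        b = rng.normal(5, 0.3, size=(3, 10))
        values = pd.DataFrame(
            np.hstack([a, b]),
            index=["G1", "G2", "G3"],
            columns=[f"A{i}" for i in range(10)] + [f"B{i}" for i in range(10)],
        )
        annot = pd.DataFrame(
            [(c, "tumor", "+", "+", "-") for c in values.columns],
            columns=["sample", "group", "ER", "PR", "HER2"],
        ).set_index("sample")
        ds = ExpressionDataset(name="sep", values=values, annotations=annot)
        order, tree = cluster_order(ds, ["G1", "G2", "G3"])
        labels = ["A" if s.startswith("A") else "B" for s in order]
        switches = sum(a != b for a, b in zip(labels, labels[1:]))
        assert switches == 1  # the two classes form contiguous blocks

    def test_two_samples_only_order(self):
        values = pd.DataFrame(
            [[1.0, 2.0]], index=["G1"], columns=["S1", "S2"]
        )
        annot = pd.DataFrame(
            [("S1", "tumor", "+", "+", "-"), ("S2", "tumor", "+", "+", "-")],
            columns=["sample", "group", "ER", "PR", "HER2"],
        ).set_index("sample")
        ds = ExpressionDataset(name="two", values=values, annotations=annot)
        order, _ = cluster_order(ds, ["G1"])
        assert sorted(order) == ["S1", "S2"]

    def test_deterministic_and_validates_options(self, panel_instance):
        _, _, truth, ds = panel_instance
        panel = sorted(truth.pivotal_genes)
        o1, _ = cluster_order(ds, panel, distance="correlation", linkage="complete")
        o2, _ = cluster_order(ds, panel, distance="correlation", linkage="complete")
        assert o1 == o2
        with pytest.raises(ValueError):
            cluster_order(ds, panel, distance="manhattan")
        with pytest.raises(ValueError):
            cluster_order(ds, panel, linkage="ward", distance="correlation")
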