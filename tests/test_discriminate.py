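import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from sporemorph.discriminate import (
    CVResult,
    FDAModel,
    FeatureSetSpec,
    compare_feature_sets,
    cv_success_rate,
    fit_fda,
    predict_fda,
    standard_feature_sets,
    stratified_partition,
)


def gaussian_classes(rng, K, p, n_per_class, spread=2.0):
    means = rng.normal(0, spread, (K, p))
    y = np.repeat(np.arange(K), n_per_class)
    X = means[y] + rng.normal(0, 1, (len(y), p))
    return X, y, means


class TestStratifiedPartition:
    def _table(self, counts):
        return pd.DataFrame(
            {"species_id": np.concatenate([[f"s{i}"] * n for i, n in enumerate(counts)])}
        )

    def test_seventy_thirty_split(self):
        tr, te = stratified_partition(self._table([10]), 0.7, np.random.default_rng(0))
        assert len(tr) == 7 and len(te) == 3

    def test_nonemptiness_guard(self):
        tr, te = stratified_partition(self._table([2]), 0.7, np.random.default_rng(0))
        assert len(tr) == 1 and len(te) == 1

    def test_disjoint_exhaustive_and_counts_stable_across_seeds(self):
        table = self._table([10, 7, 23])
        tr1, te1 = stratified_partition(table, 0.7, np.random.default_rng(1))
        tr2, te2 = stratified_partition(table, 0.7, np.random.default_rng(2))
        assert set(tr1) | set(te1) == set(range(len(table)))
        assert set(tr1) & set(te1) == set()
        assert not np.array_equal(tr1, tr2)
        for sp in table["species_id"].unique():
            mask = table["species_id"] == sp
            assert mask[tr1].sum() == mask[tr2].sum()

    def test_singleton_species_named_in_error(self):
        with pytest.raises(ValueError, match="s1"):
            stratified_partition(self._table([5, 1]), 0.7, np.random.default_rng(0))


class TestFitPredictFDA:
    def test_separable_classes_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 100)
        X = np.array([[0.0, 0.0], [10.0, 10.0]])[y] + rng.normal(0, 1, (200, 2))
        model = fit_fda(X, y)
        assert np.mean(predict_fda(model, X) == y) == 1.0

    def test_label_permutation_gives_chance_level(self):
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(100):
            X, y, _ = gaussian_classes(rng, 4, 3, 25)
            y_perm = rng.permutation(y)
            model = fit_fda(X[:60], y_perm[:60])
            accs.append(np.mean(predict_fda(model, X[60:]) == y_perm[60:]))
        assert abs(np.mean(accs) - 0.25) < 0.05

    def test_linear_basis_matches_independent_lda(self):
        # optimal scoring with a linear basis must reproduce classical
        # LDA predictions exactly
        rng = np.random.default_rng(0)
        for _ in range(20):
            K = int(rng.integers(2, 6))
            p = int(rng.integers(1, 6))
            X, y, means = gaussian_classes(rng, K, p, int(rng.integers(10, 40)), spread=1.2)
            Xte = means[rng.integers(0, K, 200)] + rng.normal(0, 1, (200, p))
            ours = predict_fda(fit_fda(X, y), Xte)
            ref = LinearDiscriminantAnalysis().fit(X, y).predict(Xte)
            np.testing.assert_array_equal(ours, ref)

    def test_training_predictions_deterministic(self):
        rng = np.random.default_rng(5)
        X, y, _ = gaussian_classes(rng, 3, 2, 20)
        m = fit_fda(X, y)
        np.testing.assert_array_equal(predict_fda(m, X), predict_fda(m, X))

    def test_point_at_centroid_assigned_to_its_class(self):
        rng = np.random.default_rng(6)
        X, y, means = gaussian_classes(rng, 3, 2, 30, spread=4.0)
        m = fit_fda(X, y)
        for k in range(3):
            x_cent = X[y == k].mean(axis=0, keepdims=True)
            assert predict_fda(m, x_cent)[0] == k

    def test_tie_resolves_to_first_label(self):
        # exactly symmetric centroids and equal priors: argmin takes the
        # first class in sorted label order
        model = FDAModel(
            classes=np.array(["a", "b"]),
            basis="linear",
            coef=np.array([[0.0], [1.0]]),  # z = x
            centroids=np.array([[-1.0], [1.0]]),
            dim_weights=np.array([1.0]),
            priors=np.array([0.5, 0.5]),
            eigenvalues=np.array([0.5]),
            n_features=1,
        )
        assert predict_fda(model, np.array([[0.0]]))[0] == "a"

    def test_singular_design_advises_ridge(self):
        X = np.ones((6, 1))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="ridge"):
            fit_fda(X, y)
        fit_fda(X + np.random.default_rng(0).normal(0, 1e-9, X.shape), y, basis=("ridge", 1.0))

    def test_poly_basis_solves_nonlinear_problem(self):
        # concentric classes: linear fails, quadratic basis succeeds
        rng = np.random.default_rng(2)
        r = np.concatenate([rng.uniform(0, 1, 100), rng.uniform(2, 3, 100)])
        ang = rng.uniform(0, 2 * np.pi, 200)
        X = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        y = np.repeat([0, 1], 100)
        acc_lin = np.mean(predict_fda(fit_fda(X, y), X) == y)
        acc_poly = np.mean(predict_fda(fit_fda(X, y, basis=("poly", 2)), X) == y)
        assert acc_poly > 0.95 > acc_lin

    def test_feature_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        X, y, _ = gaussian_classes(rng, 2, 3, 10)
        m = fit_fda(X, y)
        with pytest.raises(ValueError):
            predict_fda(m, X[:, :2])


def species_table(rng, n_species=5, rows_per_species=20, informative=True):
    rows = []
    for k in range(n_species):
        for _ in range(rows_per_species):
            base = k if informative else 0.0
            rows.append(
                {
                    "species_id": f"s{k}",
                    "f1": base + rng.normal(0, 0.8),
                    "f2": -base + rng.normal(0, 0.8),
                }
            )
    return pd.DataFrame(rows)


class TestCrossValidation:
    def test_separable_panel_near_perfect(self):
        rng = np.random.default_rng(0)
        rows = [
            {"species_id": f"s{k}", "f1": 10.0 * k + rng.normal(0, 0.8), "f2": rng.normal()}
            for k in range(3)
            for _ in range(20)
        ]
        table = pd.DataFrame(rows)
        res = cv_success_rate(table, FeatureSetSpec("X", ("f1", "f2")), n_reps=30, seed=1)
        assert res.mean_accuracy >= 0.99

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(1)
        table = species_table(rng)
        a = cv_success_rate(table, FeatureSetSpec("X", ("f1",)), n_reps=15, seed=9)
        b = cv_success_rate(table, FeatureSetSpec("X", ("f1",)), n_reps=15, seed=9)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        assert isinstance(a, CVResult) and a.n_replicates == 15

    def test_paired_partitions_shared_across_feature_sets(self):
        rng = np.random.default_rng(2)
        table = species_table(rng)
        both = compare_feature_sets(
            table,
            [FeatureSetSpec("A", ("f1",)), FeatureSetSpec("B", ("f2",))],
            n_reps=12,
            seed=4,
        )
        single = compare_feature_sets(table, [FeatureSetSpec("A", ("f1",))], n_reps=12, seed=4)
        assert both.partition_hashes == single.partition_hashes
        np.testing.assert_array_equal(
            both.replicates["A"].to_numpy(), single.replicates["A"].to_numpy()
        )

    def test_single_spec_gives_one_row(self):
        rng = np.random.default_rng(3)
        table = species_table(rng)
        comp = compare_feature_sets(table, [FeatureSetSpec("A", ("f1",))], n_reps=5, seed=0)
        assert len(comp.table) == 1

    def test_q_uninformative_when_species_share_aspect_ratio(self):
        # species differ in absolute size but share length/width: the
        # ratio carries no signal while length+width separates them
        rng = np.random.default_rng(4)
        rows = []
        for k in range(4):
            scale = 6.0 + 3.0 * k
            for _ in range(20):
                length = scale * np.exp(rng.normal(0, 0.05))
                width = length / 2.5 * np.exp(rng.normal(0, 0.03))
                rows.append(
                    {
                        "species_id": f"s{k}",
                        "length_um": length,
                        "width_um": width,
                        "q_ratio": length / width,
                    }
                )
        table = pd.DataFrame(rows)
        comp = compare_feature_sets(
            table,
            [FeatureSetSpec("LW", ("length_um", "width_um")), FeatureSetSpec("Q", ("q_ratio",))],
            n_reps=50,
            seed=1,
        )
        means = comp.table.set_index("model")["mean_accuracy"]
        assert means["LW"] > means["Q"]

    def test_unknown_column_rejected(self):
        rng = np.random.default_rng(5)
        table = species_table(rng)
        with pytest.raises(ValueError, match="nope"):
            compare_feature_sets(table, [FeatureSetSpec("bad", ("nope",))], n_reps=2, seed=0)


class TestStandardFeatureSets:
    def test_labels_and_unions(self):
        specs = {s.label: list(s.columns) for s in standard_feature_sets()}
        assert specs["S"] == ["sym_pc1"]
        assert specs["A"] == ["asym_pc1", "asym_pc2", "asym_pc3"]
        assert specs["G"] == ["glob_pc1", "glob_pc2"]
        assert specs["LW"] == ["length_um", "width_um"]
        assert specs["Q"] == ["q_ratio"]
        assert specs["SALW"] == specs["S"] + specs["A"] + specs["LW"]
        assert specs["GLW"] == specs["G"] + specs["LW"]
        assert specs["QLW"] == specs["Q"] + specs["LW"]
        assert specs["SIZEINT"] == ["size_int"]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            standard_feature_sets(["S", "XYZ"])
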