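import numpy as np
import pytest
from scipy import special

from unipeak.downstream import (
    CorrelationSplit,
    DistanceMatrix,
    interaction_correlation_split,
    loo_cv_r2,
    motif_occupancy_test,
    motif_summaries,
    motif_test_table,
    neighbor_joining,
    pearson_distance,
    pls_fit,
    pool_replicates,
    upgma,
    welch_signed_log10_p,
)
from unipeak.simulate import simulate_regulation

from conftest import random_additive_tree, svd_pls_predict


class TestPearsonDistance:
    def test_identical_and_anticorrelated(self):
        x = np.arange(10.0)
        values = np.column_stack([x, x, -x])
        d = pearson_distance(values, ["a", "b", "c"])
        assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.matrix[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(100, 6))
        d = pearson_distance(values, [f"s{i}" for i in range(6)])
        for i in range(6):
            for j in range(6):
                a, b = values[:, i], values[:, j]
                za = (a - a.mean()) / a.std()
                zb = (b - b.mean()) / b.std()
                assert d.matrix[i, j] == pytest.approx(1 - (za * zb).mean(), abs=1e-12)

    def test_zero_variance_sample_named(self):
        values = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="flatline"):
            pearson_distance(values, ["ok", "flatline"])


class TestUPGMA:
    def test_two_leaves_split_the_distance(self):
        tree = upgma(DistanceMatrix(["a", "b"], np.array([[0, 0.8], [0.8, 0]])))
        depths = tree.root_to_leaf_depths()
        assert depths["a"] == pytest.approx(0.4)
        assert depths["b"] == pytest.approx(0.4)

    def test_recovers_ultrametric_distances(self):
        # caterpillar ultrametric: heights 1, 2, 3
        names = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            dtype=float,
        )
        tree = upgma(DistanceMatrix(names, D))
        dm = tree.tip_distances()
        idx = {n: i for i, n in enumerate(dm.ids)}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert dm.matrix[idx[a], idx[b]] == pytest.approx(D[i, j], abs=1e-9)

    def test_ultrametricity_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            values = rng.normal(size=(40, n))
            d = pearson_distance(values, [f"s{i}" for i in range(n)])
            depths = list(upgma(d).root_to_leaf_depths().values())
            assert max(depths) - min(depths) < 1e-9

    def test_tie_merges_lexicographically_smallest_pair(self):
        names = ["c", "a", "b"]
        D = np.array([[0, 1.0, 1.0], [1.0, 0, 1.0], [1.0, 1.0, 0]])
        tree = upgma(DistanceMatrix(names, D))
        # first merge must be (a, b); the newick nests them together
        assert "(a:0.5,b:0.5)" in tree.newick

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestNeighborJoining:
    def test_recovers_known_additive_tree(self):
        # tree ((A:1,B:2):3,(C:4,D:5)) -> additive distances
        names = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(names, D))
        dm = tree.tip_distances()
        idx = {n: i for i, n in enumerate(dm.ids)}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert dm.matrix[idx[a], idx[b]] == pytest.approx(D[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        names = ["x", "y", "z"]
        D = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(names, D))
        dm = tree.tip_distances()
        idx = {n: i for i, n in enumerate(dm.ids)}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert dm.matrix[idx[a], idx[b]] == pytest.approx(D[i, j], abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        names, D = random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(names, D))
        dm = tree.tip_distances()
        idx = {name: i for i, name in enumerate(dm.ids)}
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                assert dm.matrix[idx[a], idx[b]] == pytest.approx(D[i, j], abs=1e-9)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]])))


def welch_oracle(a, b):
    """Textbook Welch formula via the regularized incomplete beta route."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * special.stdtr(df, -abs(t))
    sign = np.sign(np.mean(a) - np.mean(b))
    return t, p, (0.0 if p >= 1 else -np.log10(p)) * sign


class TestWelch:
    def test_identical_groups_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p, slp = welch_signed_log10_p(a, a.copy())
        assert t == 0.0 and p == 1.0 and slp == 0.0

    def test_constructed_groups_match_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 0.5, 10)
        b = rng.normal(2.0, 0.5, 10)
        t, p, slp = welch_signed_log10_p(a, b)
        ot, op, oslp = welch_oracle(a, b)
        assert t == pytest.approx(ot, abs=1e-10)
        assert slp == pytest.approx(oslp, abs=1e-10)

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 2, 12)
        _, _, s1 = welch_signed_log10_p(a, b)
        _, _, s2 = welch_signed_log10_p(b, a)
        assert s1 == pytest.approx(-s2, abs=1e-12)

    def test_small_group_returns_none(self):
        res = motif_occupancy_test(np.arange(5.0), np.array([1, 0, 0, 0, 0], bool))
        assert res is None


class TestMotifTables:
    def test_replicate_pooling_is_columnwise_mean(self):
        values = np.array([[1.0, 3.0, 10.0], [2.0, 4.0, 20.0]])
        pooled, names = pool_replicates(values, ["r1", "r2", "x"], ["A", "A", "B"])
        assert names == ["A", "B"]
        np.testing.assert_allclose(pooled[:, 0], [2.0, 3.0])
        np.testing.assert_allclose(pooled[:, 1], [10.0, 20.0])

    def test_summaries_are_row_and_column_sums(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.random((30, 5)) < 0.4)
        per_region, per_set = motif_summaries(table)
        arr = table.to_numpy()
        np.testing.assert_array_equal(per_region, arr.sum(axis=1))
        np.testing.assert_array_equal(per_set, arr.sum(axis=0))
        zeros = pd.DataFrame(np.zeros((4, 3), dtype=bool))
        r, c = motif_summaries(zeros)
        assert r.sum() == 0 and c.sum() == 0

    def test_motif_test_table_signs(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        hits = rng.random(60) < 0.5
        base = rng.normal(0, 0.3, 60)
        enriched = base + hits * 2.0
        depleted = base - hits * 2.0
        values = np.column_stack([enriched, depleted])
        table = pd.DataFrame({"setZ": hits})
        out = motif_test_table(values, ["s1", "s2"], ["UP", "DOWN"], table)
        assert out.loc["UP", "setZ"] > 0
        assert out.loc["DOWN", "setZ"] < 0


class TestInteractionSplit:
    def test_partition_sizes_and_exclusions(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(50, 5))
        targets = ["A", "A", "B", "C", "D"]
        pairs = {frozenset(("A", "B"))}
        split = interaction_correlation_split(
            values, [f"s{i}" for i in range(5)], targets, pairs
        )
        # C(5,2)=10 pairs, minus 1 same-target (A,A) = 9; A-B pairs: 2
        assert split.binding.size == 2
        assert split.non_binding.size == 7

    def test_replicates_only_is_an_error(self):
        values = np.random.default_rng(7).normal(size=(20, 2))
        with pytest.raises(ValueError):
            interaction_correlation_split(
                values, ["a", "b"], ["A", "A"], {frozenset(("A", "B"))}
            )

    def test_shared_latent_signal_raises_binding_correlation(self):
        rng = np.random.default_rng(8)
        latent = rng.normal(size=100)
        cols, targets = [], []
        for tf in "ABCD":
            shared = latent if tf in "AB" else rng.normal(size=100)
            cols.append(shared + rng.normal(0, 0.5, 100))
            targets.append(tf)
        split = interaction_correlation_split(
            np.column_stack(cols),
            [f"s{t}" for t in targets],
            targets,
            {frozenset(("A", "B"))},
        )
        assert split.mean_difference > 0.3


class TestPLS:
    def test_noiseless_low_rank_system_is_recovered(self):
        X, Y, truth = simulate_regulation(n_regions=200, noise_sd=0.0, seed=1)
        model = pls_fit(X, Y)
        assert min(model.cv_r2.values()) >= 0.99
        assert model.n_components >= truth["rank"] - 1

    def test_independent_response_has_no_skill(self):
        X, _, _ = simulate_regulation(n_regions=200, noise_sd=0.1, seed=2)
        Y = np.random.default_rng(3).normal(size=(200, 4))
        model = pls_fit(X, Y)
        assert max(model.cv_r2.values()) <= 0.1

    def test_single_predictor_equals_least_squares(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 2.0 * x + 1.0 + rng.normal(0, 0.1, 50)
        model = pls_fit(x, y, max_components=1)
        pred = model.predict(x[:, None], 1).ravel()
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(pred, slope * x + intercept, atol=1e-8)

    def test_full_components_match_ols_predictions(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        Y = X @ rng.normal(size=(4, 2)) + rng.normal(0, 0.2, (40, 2))
        model = pls_fit(X, Y, max_components=4)
        pred = model.predict(X, 4)
        Xa = np.column_stack([np.ones(40), X])
        beta, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
        np.testing.assert_allclose(pred, Xa @ beta, atol=1e-8)

    def test_loo_matches_literal_refit_oracle(self):
        """LOO CV R^2 equals a literal n-refit loop built on an independent
        SVD-based PLS implementation."""
        X, Y, _ = simulate_regulation(n_regions=30, n_tfs=8, noise_sd=0.3, seed=6)
        ncomp = 3
        got = loo_cv_r2(X, Y, ncomp)
        press = np.zeros(Y.shape[1])
        for i in range(30):
            mask = np.ones(30, dtype=bool)
            mask[i] = False
            pred = svd_pls_predict(X[mask], Y[mask], X[i : i + 1], ncomp)
            press += (pred.ravel() - Y[i]) ** 2
        tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        oracle = 1.0 - press / tss
        np.testing.assert_allclose(list(got.values()), oracle, atol=1e-8)

    def test_sklearn_cross_check(self):
        from sklearn.cross_decomposition import PLSRegression

        X, Y, _ = simulate_regulation(n_regions=60, noise_sd=0.3, seed=7)
        model = pls_fit(X, Y, max_components=3)
        mine = model.predict(X, 3)
        sk = PLSRegression(n_components=3, scale=True, tol=1e-10, max_iter=5000).fit(X, Y)
        np.testing.assert_allclose(mine, sk.predict(X), atol=1e-5)

    def test_constant_response_r2_is_zero(self):
        X, _, _ = simulate_regulation(n_regions=30, noise_sd=0.1, seed=8)
        Y = np.column_stack([np.full(30, 7.0)])
        got = loo_cv_r2(X, Y, 1)
        assert list(got.values()) == [0.0]

    def test_full_model_beats_input_only_on_signal(self):
        wins = 0
        for seed in range(10):
            X, Y, truth = simulate_regulation(
                n_regions=120, n_tfs=10, n_controls=3, noise_sd=0.2, seed=100 + seed
            )
            full = pls_fit(X, Y, variant="full")
            null = pls_fit(X[:, truth["n_tfs"] :], Y, variant="null")
            if np.mean(list(full.cv_r2.values())) >= np.mean(list(null.cv_r2.values())):
                wins += 1
        assert wins == 10

    def test_zero_variance_predictor_dropped(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([rng.normal(size=30), np.full(30, 3.0)])
        y = X[:, 0] * 2
        model = pls_fit(X, y, x_names=["good", "flat"], max_components=1)
        assert model.x_names == ["good"]
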