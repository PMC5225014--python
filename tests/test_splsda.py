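"""Sparse PLS-DA fitting, prediction, stability selection, sPLS and networks."""

import numpy as np
import pandas as pd
import pytest

from weanling import splsda as sp
from weanling.splsda import _center_scale, _indicator, _soft_threshold_keep


def two_group_labels(n=20):
    return np.array(["H"] * (n // 2) + ["D"] * (n - n // 2))


def separable_data(n=20, p=30, shift=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X[: n // 2, 0] = rng.uniform(shift, shift + 1, size=n // 2)
    X[n // 2:, 0] = rng.uniform(-shift - 1, -shift, size=n - n // 2)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])


class TestSoftThreshold:
    def test_exact_keep_count(self, rng):
        w = rng.normal(size=40)
        for keep in (1, 5, 39, 40):
            out = _soft_threshold_keep(w, keep)
            assert np.count_nonzero(out) == keep

    def test_tie_broken_by_feature_order(self):
        w = np.array([0.5, -0.5, 0.3])
        out = _soft_threshold_keep(w, 1)
        assert out[0] != 0 and out[1] == 0


class TestFit:
    def test_keep_all_matches_svd_direction(self, rng):
        X = rng.normal(size=(20, 15))
        y = two_group_labels()
        m = sp.splsda_fit(X, y, ncomp=1)
        Xc, _, _ = _center_scale(np.asarray(X, dtype=float))
        Yc, _, _ = _center_scale(_indicator(y, sorted(set(y))))
        u = np.linalg.svd(Xc.T @ Yc, full_matrices=False)[0][:, 0]
        assert min(np.abs(u - m.weights[:, 0]).max(),
                   np.abs(u + m.weights[:, 0]).max()) < 1e-8

    def test_scores_orthogonal_loadings_unit(self, rng):
        X = rng.normal(size=(24, 40))
        y = two_group_labels(24)
        m = sp.splsda_fit(X, y, ncomp=3, keepX=8)
        T = m.scores
        for i in range(3):
            for j in range(i + 1, 3):
                cos = T[:, i] @ T[:, j] / (np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j]))
                assert abs(cos) < 1e-6
        assert np.allclose(np.linalg.norm(m.weights, axis=0), 1.0)
        assert list((m.weights != 0).sum(axis=0)) == [8, 8, 8]

    def test_separating_feature_selected(self):
        X = separable_data()
        y = two_group_labels()
        m = sp.splsda_fit(X, y, ncomp=1, keepX=1)
        assert m.selected(0) == ["f0"]
        pred, _ = sp.splsda_predict(m, X)
        assert (pred == y).all()

    def test_duplicating_samples_keeps_loadings(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 10)))
        y = two_group_labels(12)
        m1 = sp.splsda_fit(X, y, ncomp=2, keepX=4)
        X2 = pd.concat([X, X], ignore_index=True)
        m2 = sp.splsda_fit(X2, np.concatenate([y, y]), ncomp=2, keepX=4)
        assert np.allclose(np.abs(m1.weights), np.abs(m2.weights), atol=1e-6)

    def test_one_class_rejected(self, rng):
        with pytest.raises(ValueError, match="class"):
            sp.splsda_fit(rng.normal(size=(10, 5)), ["H"] * 10)

    def test_bad_keepx_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        y = two_group_labels(10)
        with pytest.raises(ValueError):
            sp.splsda_fit(X, y, keepX=0)
        with pytest.raises(ValueError):
            sp.splsda_fit(X, y, keepX=6)


class TestPredict:
    def test_midpoint_ties_to_first_class(self):
        X = separable_data()
        y = two_group_labels()
        m = sp.splsda_fit(X, y, ncomp=1, keepX=1)
        # a sample projecting exactly onto the centroid midpoint
        mid = m.centroids.mean(axis=0)
        x_mid = pd.DataFrame(np.zeros((1, X.shape[1])), columns=X.columns)
        # solve for feature 0 value giving the midpoint score
        j = m.x_names.index("f0")
        x_mid.iloc[0, j] = m.x_mean[j] + m.x_std[j] * mid[0] / m.rotation[j, 0]
        pred, scores = sp.splsda_predict(m, x_mid)
        assert scores[0, 0] == pytest.approx(mid[0], abs=1e-9)
        assert pred[0] == sorted(set(y))[0]

    def test_feature_order_irrelevant(self, rng):
        X = separable_data()
        y = two_group_labels()
        m = sp.splsda_fit(X, y, ncomp=2, keepX=5)
        shuffled = X[list(X.columns[::-1])]
        p1, s1 = sp.splsda_predict(m, X)
        p2, s2 = sp.splsda_predict(m, shuffled)
        assert (p1 == p2).all()
        assert np.allclose(s1, s2)

    def test_missing_feature_named(self):
        X = separable_data()
        y = two_group_labels()
        m = sp.splsda_fit(X, y, ncomp=1)
        with pytest.raises(ValueError, match="f0"):
            sp.splsda_predict(m, X.drop(columns=["f0"]))


class TestStability:
    def test_stable_rule_requires_frequency_one(self):
        freq = pd.DataFrame({"comp1": [1.0, 0.9]}, index=["a", "b"])
        assert sp.stable_from_frequency(freq) == ["a"]

    def test_fallback_when_no_perfect_stability(self, caplog):
        freq = pd.DataFrame({"comp1": [0.95, 0.2]}, index=["a", "b"])
        assert sp.stable_from_frequency(freq, fallback_frequency=0.9) == ["a"]

    def test_signal_simulation_stage2_not_worse(self):
        failures = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 60))
            y = two_group_labels()
            X[:10, :5] += 3.0
            rep, model = sp.tune_and_stability(
                pd.DataFrame(X), y, ncomp_grid=(1, 2), keepx_grid=(10,),
                n_repeats=3, seed=seed)
            # nearly all planted features survive stability selection
            planted = set(str(i) for i in range(5))
            assert len(planted & set(rep.stable_set)) >= 4
            if rep.second_stage_error > rep.first_stage_error:
                failures += 1
        assert failures == 0

    def test_noise_frequencies_near_keep_ratio(self):
        # pure noise: each feature selected ~ keepX/p of the time
        means = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(size=(20, 50))
            y = two_group_labels()
            rep, _ = sp.tune_and_stability(
                pd.DataFrame(X), y, ncomp_grid=(1,), keepx_grid=(10,),
                n_repeats=2, seed=seed, fallback_frequency=0.0)
            means.append(rep.selection_frequency.values.mean())
        assert abs(np.mean(means) - 10 / 50) < 0.05


class TestSpls:
    def test_self_regression_perfect_correlation(self, rng):
        x = rng.normal(size=(20, 1))
        m = sp.spls_fit(x, x, ncomp=1, mode="regression")
        r = np.corrcoef(m.scores_x[:, 0], m.scores_y[:, 0])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_null_score_correlation_below_signal(self):
        # the first score pair maximizes covariance, so even pure noise
        # shows positive score correlation; real shared structure must
        # clearly exceed that optimism baseline
        null_rs, signal_rs = [], []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 5))
            Y = rng.normal(size=(20, 4))
            m = sp.spls_fit(X, Y, ncomp=1)
            null_rs.append(np.corrcoef(m.scores_x[:, 0], m.scores_y[:, 0])[0, 1])
            Y2 = np.asarray(X) @ rng.normal(size=(5, 4)) + 0.1 * rng.normal(size=(20, 4))
            m2 = sp.spls_fit(X, Y2, ncomp=1)
            signal_rs.append(np.corrcoef(m2.scores_x[:, 0], m2.scores_y[:, 0])[0, 1])
        assert np.mean(null_rs) < np.mean(signal_rs) - 0.2
        assert np.mean(signal_rs) > 0.95

    def test_planted_driver_selected(self, rng):
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"x{j}" for j in range(10)])
        Y = pd.DataFrame({"y": 3 * X["x4"] + 0.05 * rng.normal(size=n)})
        m = sp.spls_fit(X, Y, ncomp=1, keepX=1)
        assert np.flatnonzero(m.weights_x[:, 0]).tolist() == [4]

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            sp.spls_fit(rng.normal(size=(10, 3)), rng.normal(size=(9, 2)))


class TestNetwork:
    def test_linear_pair_positive_edge(self, rng):
        n = 40
        x = rng.normal(size=n)
        X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
        Y = pd.DataFrame({"y": 2 * x + 0.01 * rng.normal(size=n)})
        net = sp.relevance_network(sp.spls_fit(X, Y, ncomp=1), threshold=0.5)
        edge = net.edges[(net.edges.source == "x") & (net.edges.target == "y")]
        assert len(edge) == 1
        assert edge.iloc[0]["similarity"] > 0.95
        assert edge.iloc[0]["sign"] == "positive"

    def test_negated_pair_negative_edge(self, rng):
        n = 40
        x = rng.normal(size=n)
        X = pd.DataFrame({"x": x})
        Y = pd.DataFrame({"y": -x})
        net = sp.relevance_network(sp.spls_fit(X, Y, ncomp=1), threshold=0.5)
        assert net.edges.iloc[0]["sign"] == "negative"

    def test_threshold_filters_all(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)))
        Y = pd.DataFrame(rng.normal(size=(30, 2)))
        m = sp.spls_fit(X, Y, ncomp=1)
        net = sp.relevance_network(m, threshold=0.999)
        assert net.edges.empty

    def test_invalid_threshold(self, rng):
        m = sp.spls_fit(rng.normal(size=(10, 2)), rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            sp.relevance_network(m, threshold=1.5)

    def test_keep_all_full_rank_matches_pearson(self, rng):
        n, p, q = 50, 4, 3
        X = pd.DataFrame(rng.normal(size=(n, p)))
        L = rng.normal(size=(p, q))
        Y = pd.DataFrame(np.asarray(X) @ L + 0.5 * rng.normal(size=(n, q)))
        # keep-all regression-mode scores span X's column space at ncomp = p,
        # so the bilinear similarity reconstructs Pearson exactly
        m = sp.spls_fit(X, Y, ncomp=p, mode="regression")
        sim = sp.similarity_matrix(m).values
        pearson = np.corrcoef(np.asarray(X).T, np.asarray(Y).T)[:p, p:]
        assert np.abs(sim - pearson).max() < 1e-8


class TestAssociationMatrix:
    def test_duplicated_column_high_similarity(self, rng):
        n = 30
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"o{j}" for j in range(5)])
        Y = pd.DataFrame({"p_dup": X["o2"], "p_noise": rng.normal(size=n)})
        sim = sp.association_matrix(X, Y, ncomp=2)
        assert sim.loc["o2", "p_dup"] > 0.9

    def test_shape_contract(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 7)))
        Y = pd.DataFrame(rng.normal(size=(20, 4)))
        sim = sp.association_matrix(X, Y)
        assert sim.shape == (7, 4)

    def test_independent_blocks_concentrate_near_zero(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(20, 8)))
            Y = pd.DataFrame(rng.normal(size=(20, 6)))
            sim = sp.association_matrix(X, Y, ncomp=2).values
            fracs.append(np.mean(np.abs(sim) < 0.5))
        assert np.mean(fracs) > 0.9

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="3 samples"):
            sp.association_matrix(rng.normal(size=(2, 3)), rng.normal(size=(2, 2)))
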