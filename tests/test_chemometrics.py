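"""PLS-DA / VIP / PCA / split against independent oracles."""

import numpy as np
import pytest

from fcbtrace import (GeneratorConfig, generate_spectra_set, pca_scores,
                      plsda_fit, plsda_predict, split_dataset, vip_scores)
from fcbtrace.synthetic_data import (_BASE_DEPTHS, _CLASS_DELTAS, _DELTA_SCALE)


def textbook_nipals_pls2(X, Y, n_lv, tol=1e-14, max_iter=5000):
    """Literal textbook NIPALS PLS2 (Geladi & Kowalski style), no shortcuts."""
    X = X.copy()
    Y = Y.copy()
    n, p = X.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((Y.shape[1], n_lv))
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        u = Y[:, np.argmax((Y * Y).sum(axis=0))].copy()
        t_prev = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u
            w = w / np.sqrt(w @ w)
            t = X @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            if np.sqrt(((t - t_prev) ** 2).sum()) <= tol * np.sqrt((t * t).sum()):
                break
            t_prev = t
        pv = X.T @ t / (t @ t)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, q, t
        X = X - np.outer(t, pv)
        Y = Y - np.outer(t, q)
    return W, P, Q, T


def _toy_two_class(rng, n=6, p=4):
    X = rng.standard_normal((n, p))
    labels = np.array(["a", "b", "a", "b", "a", "b"])
    return X, labels


class TestPlsda:
    def test_single_informative_variable_dominates_lv1(self):
        X = np.zeros((8, 5))
        X[:, 0] = [1, -1, 1, -1, 1, -1, 1, -1]
        labels = np.array(list("abababab"))
        m = plsda_fit(X, labels, n_lv=1, scale=False)
        assert abs(m.weights[0, 0]) > 0.99

    def test_matches_textbook_nipals_oracle(self, rng):
        X, labels = _toy_two_class(rng)
        m = plsda_fit(X, labels, n_lv=2, scale=False)
        classes = np.unique(labels)
        Y = (labels[:, None] == classes[None, :]).astype(float)
        W, P, Q, T = textbook_nipals_pls2(X - X.mean(0), Y - Y.mean(0), 2)
        assert np.abs(m.weights - W).max() < 1e-8
        assert np.abs(m.x_loadings - P).max() < 1e-8
        assert np.abs(m.y_loadings - Q).max() < 1e-8
        assert np.abs(m.x_scores - T).max() < 1e-8

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, labels = _toy_two_class(rng, n=6, p=4)
        classes = np.unique(labels)
        Y = (labels[:, None] == classes[None, :]).astype(float)
        m = plsda_fit(X, labels, n_lv=2, scale=False)
        sk = PLSRegression(n_components=2, scale=False).fit(X, Y)
        # identical up to per-LV sign conventions
        for a in range(2):
            s = np.sign(m.weights[:, a] @ sk.x_weights_[:, a])
            assert np.abs(m.weights[:, a] - s * sk.x_weights_[:, a]).max() < 1e-6
            assert np.abs(m.x_scores[:, a] - s * sk.x_scores_[:, a]).max() < 1e-6

    def test_duplicated_samples_classified_perfectly(self):
        X = np.repeat(np.array([[0.0, 1.0], [3.0, -1.0]]), 4, axis=0)
        labels = np.repeat(["a", "b"], 4)
        m = plsda_fit(X, labels, n_lv=1)
        pred, _ = plsda_predict(m, X)
        assert np.array_equal(pred, labels)

    def test_orthogonal_scores(self, default_spectra):
        m = plsda_fit(default_spectra.reflectance, default_spectra.labels, n_lv=4)
        G = m.x_scores.T @ m.x_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_training_accuracy_nondecreasing_in_n_lv(self, default_spectra):
        X, y = default_spectra.reflectance, default_spectra.labels
        accs = []
        for a in (1, 2, 4, 8):
            m = plsda_fit(X, y, n_lv=a)
            pred, _ = plsda_predict(m, X)
            accs.append(np.mean(pred == np.asarray(y)))
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))

    def test_overlapping_pair_has_closest_centroids(self):
        """With SK-FC/YM-AC generated nearly identically, their 2-LV score
        centroids are the closest class pair."""
        from itertools import combinations

        depths = _BASE_DEPTHS[None, :] + _DELTA_SCALE * _CLASS_DELTAS.copy()
        depths[4] = depths[3] + 0.002
        hits = 0
        for seed in range(5):
            s = generate_spectra_set(GeneratorConfig(seed=seed, band_depths=depths))
            m = plsda_fit(s.reflectance, s.labels, n_lv=2)
            y = np.asarray(s.labels)
            cents = {c: m.x_scores[y == c].mean(axis=0) for c in np.unique(y)}
            d = {
                pair: np.linalg.norm(cents[pair[0]] - cents[pair[1]])
                for pair in combinations(sorted(cents), 2)
            }
            hits += min(d, key=d.get) == ("SK-FC", "YM-AC")
        assert hits >= 4

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            plsda_fit(rng.standard_normal((5, 3)), ["a"] * 5, n_lv=1)

    def test_variable_mismatch_rejected(self, rng):
        X, labels = _toy_two_class(rng)
        m = plsda_fit(X, labels, n_lv=1)
        with pytest.raises(ValueError, match="variable count"):
            plsda_predict(m, rng.standard_normal((2, 7)))


class TestVip:
    def test_single_informative_variable_gets_sqrt_p(self):
        X = np.zeros((8, 5))
        X[:, 0] = [1, -1, 1, -1, 1, -1, 1, -1]
        labels = np.array(list("abababab"))
        v = vip_scores(plsda_fit(X, labels, n_lv=1, scale=False))
        assert v[0] == pytest.approx(np.sqrt(5), abs=1e-8)
        assert np.abs(v[1:]).max() < 1e-8

    def test_sum_of_squares_equals_p(self, rng):
        X, labels = _toy_two_class(rng)
        for a in (1, 2):
            v = vip_scores(plsda_fit(X, labels, n_lv=a))
            assert (v**2).sum() == pytest.approx(4, abs=1e-8)

    def test_matches_direct_formula_evaluation(self, rng):
        X, labels = _toy_two_class(rng)
        m = plsda_fit(X, labels, n_lv=2, scale=False)
        p = X.shape[1]
        expect = np.array(
            [
                np.sqrt(p * sum(m.ssy[a] * m.weights[j, a] ** 2 for a in range(2))
                        / m.ssy.sum())
                for j in range(p)
            ]
        )
        assert np.allclose(vip_scores(m), expect, atol=1e-12)

    def test_threshold_one_marks_above_average_single_lv(self, rng):
        # closed form: with 1 LV, VIP_j > 1  <=>  w_j^2 > 1/p
        X = rng.standard_normal((10, 6))
        labels = np.array(list("ababababab"))
        m = plsda_fit(X, labels, n_lv=1)
        v = vip_scores(m)
        assert np.array_equal(v > 1, m.weights[:, 0] ** 2 > 1 / 6)


class TestPca:
    def test_collinear_points_explained_by_pc1(self):
        t = np.linspace(0, 1, 7)
        X = np.outer(t, [1.0, -2.0, 0.5])
        _, _, evr = pca_scores(X, k=1)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_reconstruction(self, rng):
        X = rng.standard_normal((8, 5))
        k = 5
        scores, loadings, _ = pca_scores(X, k=k)
        Xc = X - X.mean(axis=0)
        assert np.abs(scores @ loadings.T - Xc).max() < 1e-9

    def test_duplicated_rows_identical_scores(self, rng):
        X = rng.standard_normal((6, 4))
        X2 = np.vstack([X, X])
        scores, _, _ = pca_scores(X2, k=2)
        assert np.allclose(scores[:6], scores[6:], atol=1e-10)

    def test_sign_convention(self, rng):
        _, loadings, _ = pca_scores(rng.standard_normal((9, 5)), k=3)
        for a in range(3):
            assert loadings[np.argmax(np.abs(loadings[:, a])), a] > 0


class TestSplit:
    def test_study_split_sizes(self):
        s = split_dataset(90, (50, 25, 15), seed=0)
        assert (len(s.train), len(s.test), len(s.external)) == (50, 25, 15)
        assert len(set(s.train) | set(s.test) | set(s.external)) == 90

    def test_same_seed_identical(self):
        a, b = split_dataset(90, seed=4), split_dataset(90, seed=4)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.external, b.external)

    def test_membership_frequency_uniform(self):
        """Each sample's train-membership frequency ~ 50/90 across seeds."""
        n_seeds = 400
        counts = np.zeros(90)
        for seed in range(n_seeds):
            counts[split_dataset(90, seed=seed).train] += 1
        freq = counts / n_seeds
        assert np.abs(freq - 50 / 90).max() < 0.08

    def test_stratified_split_balances_classes(self):
        labels = np.repeat(list("abcde"), 18)
        s = split_dataset(90, (50, 25, 15), seed=1, labels=labels)
        for part, size in ((s.train, 10), (s.test, 5), (s.external, 3)):
            _, counts = np.unique(labels[part], return_counts=True)
            assert np.abs(counts - size).max() <= 1

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            split_dataset(90, (50, 25, 16))
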