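"""PLS-DA baseline, VIP scores, PCA and the train/test/external split.

Partial least squares discriminant analysis (PLS-DA) regresses a
one-hot class-membership matrix Y on the predictor matrix X through a
small number of latent variables (LVs) extracted by the NIPALS
algorithm (PLS2 with deflation).  Predicted class = argmax of the
predicted class responses, ties broken toward the lowest class index.

Variable importance in projection (VIP) follows Wold's definition:
per-variable contributions weighted by each LV's explained
Y-variance, normalised so the mean squared VIP equals 1 (hence the
conventional VIP > 1 selection threshold marks above-average
contributors).

By default predictors are autoscaled (mean-centred, unit variance)
before PLS-DA and PCA — the standard chemometrics convention; both
accept ``scale=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PLSModel",
    "SplitSpec",
    "plsda_fit",
    "plsda_predict",
    "vip_scores",
    "pca_scores",
    "split_dataset",
]


@dataclass
class PLSModel:
    """Fitted NIPALS PLS2 model on one-hot class responses."""

    classes: np.ndarray
    n_lv: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray       # p x A, unit-norm X-weights per LV
    x_loadings: np.ndarray    # p x A
    y_loadings: np.ndarray    # K x A
    x_scores: np.ndarray      # n x A
    ssy: np.ndarray           # explained Y sum of squares per LV
    scaled: bool = True


def _autoscale(X, scale):
    mean = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)  # constant columns: unit-variance guard
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def plsda_fit(X: np.ndarray, labels, n_lv: int = 2, scale: bool = True, tol: float = 1e-12,
              max_iter: int = 2000) -> PLSModel:
    """Fit a PLS2 discriminant model by NIPALS with deflation.

    ``labels`` may be any hashable class codes; Y is their one-hot
    encoding, column-centred.  Deterministic for a fixed input order.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least two classes")
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}]")
    Y = (labels[:, None] == classes[None, :]).astype(float)
    Xc, x_mean, x_scale = _autoscale(X, scale)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    Q = np.zeros((classes.size, n_lv))
    T = np.zeros((n, n_lv))
    ssy = np.zeros(n_lv)
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(n_lv):
        u = Yd[:, np.argmax((Yd**2).sum(axis=0))].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xd.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("degenerate deflated X; reduce n_lv")
            w /= nw
            t = Xd @ w
            q = Yd.T @ t / (t @ t)
            u = Yd @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        pv = Xd.T @ t / (t @ t)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pv, q, t
        ssy[a] = (t @ t) * (q @ q)
        Xd = Xd - np.outer(t, pv)
        Yd = Yd - np.outer(t, q)
    return PLSModel(classes, n_lv, x_mean, x_scale, y_mean, W, P, Q, T, ssy, scaled=scale)


def _coef(model: PLSModel) -> np.ndarray:
    # B = W (P^T W)^-1 Q^T maps scaled X to centred Y
    return model.weights @ np.linalg.solve(
        model.x_loadings.T @ model.weights, model.y_loadings.T
    )


def plsda_predict(model: PLSModel, X: np.ndarray):
    """Predicted labels and per-class response scores.

    Returns ``(labels, scores)`` where ``scores[i, k]`` is the
    predicted (continuous) one-hot response for class k.  argmax with
    ties broken toward the lowest class index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"variable count {X.shape[-1]} does not match the fitted model ({model.x_mean.size})"
        )
    Xs = (X - model.x_mean) / model.x_scale
    scores = Xs @ _coef(model) + model.y_mean
    return model.classes[np.argmax(scores, axis=1)], scores


def vip_scores(model: PLSModel) -> np.ndarray:
    """Wold's VIP: sqrt(p * sum_a ssy_a w_ja^2 / sum_a ssy_a)."""
    total = model.ssy.sum()
    if total <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    p = model.weights.shape[0]
    contrib = (model.weights**2) @ model.ssy
    return np.sqrt(p * contrib / total)


def pca_scores(X: np.ndarray, k: int, scale: bool = False):
    """Centred-SVD principal components.

    Returns ``(scores, loadings, explained_variance_ratio)``.  Sign
    convention: each loading vector's largest-magnitude entry is made
    positive, so duplicated datasets get identical score signs.
    """
    X = np.asarray(X, dtype=float)
    Xc, _, _ = _autoscale(X, scale)
    r = np.linalg.matrix_rank(Xc)
    if not 1 <= k <= r:
        raise ValueError(f"k must be in [1, rank={r}]")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    evr = s**2 / (s**2).sum()
    return (U * s)[:, :k], Vt[:k].T, evr[:k]


@dataclass
class SplitSpec:
    """Disjoint train / test / external-validation sample indices."""

    train: np.ndarray
    test: np.ndarray
    external: np.ndarray
    seed: int = 0

    def __post_init__(self):
        parts = [np.asarray(p, dtype=int) for p in (self.train, self.test, self.external)]
        self.train, self.test, self.external = parts
        allidx = np.concatenate(parts)
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("split parts overlap")


def split_dataset(n: int, sizes: tuple = (50, 25, 15), seed: int = 0,
                  labels=None) -> SplitSpec:
    """Uniform random partition of ``range(n)`` into train/test/external.

    ``sizes`` must sum to n.  If ``labels`` is given, the split is
    stratified: each class contributes proportionally (largest
    remainder rounding) to every part.
    """
    n_train, n_test, n_ext = sizes
    if n_train + n_test + n_ext != n:
        raise ValueError(f"split sizes {sizes} do not sum to n={n}")
    rng = np.random.default_rng(seed)
    if labels is None:
        perm = rng.permutation(n)
        return SplitSpec(perm[:n_train], perm[n_train : n_train + n_test],
                         perm[n_train + n_test :], seed)
    labels = np.asarray(labels)
    parts = [[], [], []]
    leftover = []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        quota = [len(idx) * s / n for s in sizes]
        take = [int(q) for q in quota]
        pos = 0
        for part, t in zip(parts, take):
            part.extend(idx[pos : pos + t])
            pos += t
        leftover.extend(idx[pos:])
    leftover = rng.permutation(np.array(leftover, dtype=int))
    pos = 0
    for i, (part, s) in enumerate(zip(parts, sizes)):
        need = s - len(part)
        part.extend(leftover[pos : pos + need])
        pos += need
    return SplitSpec(*(np.array(p, dtype=int) for p in parts), seed=seed)
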