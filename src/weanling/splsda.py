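"""Sparse partial least squares: discriminant analysis, regression mode,
stability selection and relevance networks.

sPLS-DA regresses a centered/scaled feature matrix on the group indicator
matrix; per component the dominant singular pair of X'Y is sparsified by
soft-thresholding the X weights so exactly ``keepX`` survive (the standard
lasso surrogate in sparse PLS), X is deflated by regression on the score,
and classification is by nearest class centroid in score space.

The two-stage procedure mirrors stability selection: stage 1 tunes
(ncomp, keepX) by stratified repeated cross-validation and records how often
each feature is selected across every fold x repeat; stage 2 refits on the
features selected in *all* folds (frequency = 1) and re-estimates the
cross-validated error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SplsModel",
    "SplsdaModel",
    "StabilityReport",
    "RelevanceNetwork",
    "splsda_fit",
    "splsda_predict",
    "tune_and_stability",
    "stable_from_frequency",
    "spls_fit",
    "relevance_network",
    "association_matrix",
]

log = logging.getLogger(__name__)


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Keep the ``keep`` largest |w|, soft-shrink them, zero the rest.

    Survivors shrink by the largest excluded magnitude; ties at the
    boundary resolve by feature order (earlier index wins), and a survivor
    tied exactly with the threshold keeps an infinitesimal weight so the
    nonzero count is exactly ``keep``.
    """
    p = w.size
    if keep >= p:
        return w.copy()
    if keep <= 0:
        raise ValueError("keepX must be positive")
    order = np.argsort(-np.abs(w), kind="stable")
    survivors = order[:keep]
    thr = np.abs(w[order[keep]])
    out = np.zeros_like(w)
    shrunk = np.abs(w[survivors]) - thr
    shrunk[shrunk <= 0] = 1e-12  # boundary tie: retain at negligible weight
    out[survivors] = np.sign(w[survivors]) * shrunk
    return out


def _center_scale(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    std = M.std(axis=0, ddof=1)
    std = np.where(std <= 0, 1.0, std)
    return (M - mean) / std, mean, std


def _dominant_pair(M: np.ndarray, keep_x: int, keep_y: int, tol: float = 1e-9,
                   max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Sparse dominant singular pair of M by alternating power iterations."""
    # dense initialization from the leading right singular vector
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    v = vt[0]
    u = np.zeros(M.shape[0])
    for _ in range(max_iter):
        u_new = _soft_threshold_keep(M @ v, keep_x)
        nu = np.linalg.norm(u_new)
        if nu == 0:
            break
        u_new /= nu
        v_new = _soft_threshold_keep(M.T @ u_new, keep_y)
        nv = np.linalg.norm(v_new)
        if nv == 0:
            break
        v_new /= nv
        if np.linalg.norm(u_new - u) < tol and np.linalg.norm(v_new - v) < tol:
            u, v = u_new, v_new
            break
        u, v = u_new, v_new
    # deterministic sign: largest-|.| weight positive
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0:
        u, v = -u, -v
    return u, v


@dataclass
class SplsModel:
    """Fitted sparse PLS between two numeric blocks."""

    mode: str
    ncomp: int
    x_names: list[str]
    y_names: list[str]
    weights_x: np.ndarray        # p x H
    weights_y: np.ndarray        # q x H
    loadings_x: np.ndarray       # p x H (regression loadings for deflation)
    scores_x: np.ndarray         # n x H
    scores_y: np.ndarray         # n x H
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    Xc: np.ndarray = field(repr=False, default=None)
    Yc: np.ndarray = field(repr=False, default=None)


@dataclass
class SplsdaModel:
    """Fitted sPLS-DA: sparse loadings, scores and class centroids."""

    ncomp: int
    keep_per_component: list[int]
    classes_: list[str]
    x_names: list[str]
    weights: np.ndarray          # p x H sparse X weights
    loadings: np.ndarray         # p x H regression loadings
    rotation: np.ndarray         # p x H, scores = Xc @ rotation
    scores: np.ndarray           # n x H training scores
    centroids: np.ndarray        # class x H
    x_mean: np.ndarray
    x_std: np.ndarray

    def selected(self, comp: int) -> list[str]:
        idx = np.flatnonzero(self.weights[:, comp])
        return [self.x_names[i] for i in idx]


@dataclass
class StabilityReport:
    selection_frequency: pd.DataFrame   # feature x component, in [0, 1]
    stable_set: list[str]
    first_stage_error: float
    second_stage_error: float
    best_ncomp: int
    best_keepx: int
    second_stage_keepx: int


@dataclass
class RelevanceNetwork:
    edges: pd.DataFrame                 # source, target, similarity, sign
    threshold: float


def _indicator(labels: np.ndarray, classes: list[str]) -> np.ndarray:
    return np.column_stack([(labels == c).astype(float) for c in classes])


def splsda_fit(X, labels, ncomp: int = 2, keepX=None) -> SplsdaModel:
    """Fit sPLS-DA of a samples x features block on two-group labels.

    ``keepX`` is the per-component count of nonzero feature weights (scalar
    or sequence; defaults to all features). Features are centered and
    unit-variance scaled internally; successive components are computed on
    the regression-deflated X, which makes score columns orthogonal.
    """
    X = pd.DataFrame(X)
    y = np.asarray(list(labels))
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("one class absent: need both groups to fit")
    if len(classes) > 2:
        raise ValueError("only two-class discrimination is supported")
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 samples")
    ncomp = min(ncomp, n - 1)
    if keepX is None:
        keepX = [p] * ncomp
    elif np.isscalar(keepX):
        keepX = [int(keepX)] * ncomp
    else:
        keepX = [int(k) for k in keepX][:ncomp]
        keepX += [keepX[-1]] * (ncomp - len(keepX))
    if any(k <= 0 for k in keepX):
        raise ValueError("keepX must be positive")
    if any(k > p for k in keepX):
        raise ValueError("keepX cannot exceed the number of features")

    Xc, x_mean, x_std = _center_scale(X.values.astype(float))
    Yc, _, _ = _center_scale(_indicator(y, classes))
    Xh, Yh = Xc.copy(), Yc.copy()
    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    for h in range(ncomp):
        u, _ = _dominant_pair(Xh.T @ Yh, keepX[h], Yh.shape[1])
        t = Xh @ u
        tt = float(t @ t)
        if tt <= 1e-300:
            log.warning("component %d collapsed; truncating at %d components", h + 1, h)
            ncomp = max(h, 1)
            W, P, T = W[:, :ncomp], P[:, :ncomp], T[:, :ncomp]
            keepX = keepX[:ncomp]
            break
        c = Xh.T @ t / tt
        d = Yh.T @ t / tt
        Xh = Xh - np.outer(t, c)
        Yh = Yh - np.outer(t, d)
        W[:, h], P[:, h], T[:, h] = u, c, t
    rotation = W @ np.linalg.pinv(P.T @ W)
    centroids = np.vstack([T[y == c].mean(axis=0) for c in classes])
    return SplsdaModel(
        ncomp=ncomp,
        keep_per_component=list(keepX),
        classes_=classes,
        x_names=[str(c) for c in X.columns],
        weights=W,
        loadings=P,
        rotation=rotation,
        scores=T,
        centroids=centroids,
        x_mean=x_mean,
        x_std=x_std,
    )


def splsda_predict(model: SplsdaModel, X_new, ncomp: int | None = None):
    """Project new samples and classify by nearest class centroid.

    Ties at the exact midpoint go deterministically to the first class in
    sorted label order. Returns (labels, scores).
    """
    X_new = pd.DataFrame(X_new)
    X_new.columns = [str(c) for c in X_new.columns]
    missing = [f for f in model.x_names if f not in set(X_new.columns)]
    if missing:
        raise ValueError(f"missing features: {missing[:10]}")
    X_new = X_new[model.x_names]
    h = model.ncomp if ncomp is None else min(ncomp, model.ncomp)
    Xc = (X_new.values.astype(float) - model.x_mean) / model.x_std
    scores = Xc @ model.rotation[:, :h]
    d2 = ((scores[:, None, :] - model.centroids[None, :, :h]) ** 2).sum(axis=2)
    # argmin takes the first minimum -> first class wins exact ties
    labels = np.array([model.classes_[i] for i in np.argmin(d2, axis=1)])
    return labels, scores


def _cv_errors(
    X: pd.DataFrame,
    y: np.ndarray,
    keepx: int,
    ncomp_max: int,
    splits: list[tuple[np.ndarray, np.ndarray]],
    collect_selection: bool = False,
):
    """Per-ncomp mean CV error for one keepX; optionally per-fold selections."""
    errors = np.zeros((len(splits), ncomp_max))
    selections = []
    for i, (tr, te) in enumerate(splits):
        model = splsda_fit(X.iloc[tr], y[tr], ncomp=ncomp_max, keepX=keepx)
        for h in range(1, ncomp_max + 1):
            if h > model.ncomp:
                errors[i, h - 1] = errors[i, model.ncomp - 1]
                continue
            pred, _ = splsda_predict(model, X.iloc[te], ncomp=h)
            errors[i, h - 1] = float(np.mean(pred != y[te]))
        if collect_selection:
            sel = pd.DataFrame(
                model.weights != 0, index=model.x_names,
                columns=range(1, model.weights.shape[1] + 1),
            )
            selections.append(sel)
    return errors.mean(axis=0), selections


def _make_splits(y: np.ndarray, n_folds: int, n_repeats: int, seed: int):
    _, counts = np.unique(y, return_counts=True)
    eff = min(n_folds, int(counts.min()))
    if eff < n_folds:
        log.warning("reducing folds from %d to %d (smallest class)", n_folds, eff)
    if eff < 2:
        raise ValueError("smallest class too small for cross-validation")
    splits = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=(seed + rep) % 2**31)
        splits.extend((tr, te) for tr, te in skf.split(np.zeros(len(y)), y))
    return splits


def tune_and_stability(
    X,
    labels,
    ncomp_grid=(1, 2, 3),
    keepx_grid=(5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    fallback_frequency: float = 0.9,
) -> tuple[StabilityReport, SplsdaModel]:
    """Two-stage sPLS-DA: tune, record selection stability, refit on the
    always-selected features.

    Stage 1 grid-searches (ncomp, keepX) by stratified ``n_folds``-fold CV
    repeated ``n_repeats`` times, minimizing mean classification error
    (ties prefer fewer components, then fewer features), and records each
    feature's selection frequency across all folds x repeats of the winning
    configuration. Stage 2 keeps the features with frequency exactly 1 on
    some component (falling back to frequency >= ``fallback_frequency``,
    logged, if that set is empty), re-tunes keepX on the restricted block
    and reports the second-stage CV error alongside the final model fitted
    on all samples.
    """
    X = pd.DataFrame(X)
    X.columns = [str(c) for c in X.columns]
    y = np.asarray(list(labels))
    p = X.shape[1]
    keepx_grid = sorted({min(int(k), p) for k in keepx_grid if k > 0})
    ncomp_max = int(max(ncomp_grid))
    splits = _make_splits(y, n_folds, n_repeats, seed)

    mean_err = {}
    for keepx in keepx_grid:
        per_ncomp, _ = _cv_errors(X, y, keepx, ncomp_max, splits)
        for ncomp in ncomp_grid:
            mean_err[(ncomp, keepx)] = per_ncomp[ncomp - 1]
    best_ncomp, best_keepx = min(mean_err, key=lambda k: (mean_err[k], k[0], k[1]))
    first_stage_error = float(mean_err[(best_ncomp, best_keepx)])

    _, selections = _cv_errors(X, y, best_keepx, best_ncomp, splits, collect_selection=True)
    freq = sum(sel.iloc[:, :best_ncomp].astype(float) for sel in selections) / len(selections)
    freq.columns = [f"comp{h}" for h in range(1, best_ncomp + 1)]
    stable = stable_from_frequency(freq, fallback_frequency)
    stable = [f for f in X.columns.astype(str) if f in set(stable)]

    Xs = X.loc[:, stable]
    grid2 = sorted({min(k, len(stable)) for k in keepx_grid} | {len(stable)})
    err2 = {}
    for keepx in grid2:
        per_ncomp, _ = _cv_errors(Xs, y, keepx, min(best_ncomp, len(stable)), splits)
        for ncomp in range(1, min(best_ncomp, len(stable)) + 1):
            err2[(ncomp, keepx)] = per_ncomp[ncomp - 1]
    ncomp2, keepx2 = min(err2, key=lambda k: (err2[k], k[0], k[1]))
    second_stage_error = float(err2[(ncomp2, keepx2)])
    final = splsda_fit(Xs, y, ncomp=ncomp2, keepX=keepx2)
    report = StabilityReport(
        selection_frequency=freq,
        stable_set=stable,
        first_stage_error=first_stage_error,
        second_stage_error=second_stage_error,
        best_ncomp=best_ncomp,
        best_keepx=best_keepx,
        second_stage_keepx=keepx2,
    )
    return report, final


def stable_from_frequency(freq: pd.DataFrame, fallback_frequency: float = 0.9) -> list[str]:
    """Features selected in every fold x repeat (frequency exactly 1) on at
    least one component; falls back to frequency >= ``fallback_frequency``
    (logged) when no feature is perfectly stable."""
    stable_mask = (freq == 1.0).any(axis=1)
    if not stable_mask.any():
        log.warning(
            "no feature reached selection frequency 1; falling back to >= %.2f",
            fallback_frequency,
        )
        stable_mask = (freq >= fallback_frequency).any(axis=1)
    if not stable_mask.any():
        raise ValueError("stability selection retained no features")
    return [str(f) for f in freq.index[stable_mask]]


def spls_fit(
    X, Y, ncomp: int = 2, keepX=None, keepY=None, mode: str = "regression"
) -> SplsModel:
    """Sparse PLS between two numeric blocks.

    In ``regression`` mode Y is deflated by the X scores (Y predicted from
    X); in ``canonical`` mode each block is deflated by its own scores
    (symmetric association). keepX / keepY bound the nonzero weights per
    component on each block (default: all).
    """
    X = pd.DataFrame(X)
    Y = pd.DataFrame(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same samples")
    if mode not in ("regression", "canonical"):
        raise ValueError(f"unknown mode: {mode}")
    n, p = X.shape
    q = Y.shape[1]
    # regression mode keeps deflating X even once Y's rank is exhausted
    ncomp = min(ncomp, n - 1, p) if mode == "regression" else min(ncomp, n - 1, p, q)

    def expand(k, dim):
        if k is None:
            return [dim] * ncomp
        if np.isscalar(k):
            return [int(k)] * ncomp
        ks = [int(v) for v in k][:ncomp]
        return ks + [ks[-1]] * (ncomp - len(ks))

    kx, ky = expand(keepX, p), expand(keepY, q)
    Xc, x_mean, x_std = _center_scale(X.values.astype(float))
    Yc, y_mean, y_std = _center_scale(Y.values.astype(float))
    Xh, Yh = Xc.copy(), Yc.copy()
    Wx = np.zeros((p, ncomp))
    Wy = np.zeros((q, ncomp))
    Px = np.zeros((p, ncomp))
    Tx = np.zeros((n, ncomp))
    Ty = np.zeros((n, ncomp))
    for h in range(ncomp):
        u, v = _dominant_pair(Xh.T @ Yh, kx[h], ky[h])
        t = Xh @ u
        w = Yh @ v
        tt = float(t @ t)
        if tt <= 1e-300:
            ncomp = h
            Wx, Wy, Px, Tx, Ty = (a[:, :h] for a in (Wx, Wy, Px, Tx, Ty))
            break
        c = Xh.T @ t / tt
        Xh = Xh - np.outer(t, c)
        if mode == "regression":
            d = Yh.T @ t / tt
            Yh = Yh - np.outer(t, d)
        else:
            ww = float(w @ w)
            e = Yh.T @ w / max(ww, 1e-300)
            Yh = Yh - np.outer(w, e)
        Wx[:, h], Wy[:, h], Px[:, h], Tx[:, h], Ty[:, h] = u, v, c, t, w
    return SplsModel(
        mode=mode,
        ncomp=ncomp,
        x_names=[str(c) for c in X.columns],
        y_names=[str(c) for c in Y.columns],
        weights_x=Wx,
        weights_y=Wy,
        loadings_x=Px,
        scores_x=Tx,
        scores_y=Ty,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        Xc=Xc,
        Yc=Yc,
    )


def _safe_corr(columns: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column with each score, zero if degenerate."""
    out = np.zeros((columns.shape[1], scores.shape[1]))
    cs = columns - columns.mean(axis=0)
    ss = scores - scores.mean(axis=0)
    cn = np.linalg.norm(cs, axis=0)
    sn = np.linalg.norm(ss, axis=0)
    valid_c = cn > 0
    valid_s = sn > 0
    num = cs.T @ ss
    denom = np.outer(np.where(valid_c, cn, 1.0), np.where(valid_s, sn, 1.0))
    out = num / denom
    out[~valid_c, :] = 0.0
    out[:, ~valid_s] = 0.0
    return out


def similarity_matrix(model: SplsModel) -> pd.DataFrame:
    """Bilinear cross-block similarity approximating the X-Y correlation
    matrix: sum_h cor(x_j, s_h) cor(y_k, s'_h) over components.

    In regression mode both blocks project on the X scores (s = s' = xi),
    which makes the similarity equal the plain Pearson cross-correlation
    exactly when every feature is kept and ncomp reaches the rank of X; in
    canonical mode Y projects on its own scores (s' = omega), the symmetric
    convention.
    """
    cx = _safe_corr(model.Xc, model.scores_x)
    y_scores = model.scores_x if model.mode == "regression" else model.scores_y
    cy = _safe_corr(model.Yc, y_scores)
    sim = cx @ cy.T
    return pd.DataFrame(sim, index=model.x_names, columns=model.y_names)


def relevance_network(model: SplsModel, threshold: float = 0.5) -> RelevanceNetwork:
    """Edges between X and Y features whose bilinear similarity exceeds
    ``threshold`` in magnitude, with the similarity's sign."""
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must lie in [0, 1)")
    sim = similarity_matrix(model)
    rows = []
    for xf in sim.index:
        for yf in sim.columns:
            s = float(sim.loc[xf, yf])
            if abs(s) > threshold:
                rows.append({"source": xf, "target": yf, "similarity": s,
                             "sign": "positive" if s > 0 else "negative"})
    edges = pd.DataFrame(rows, columns=["source", "target", "similarity", "sign"])
    return RelevanceNetwork(edges=edges, threshold=threshold)


def association_matrix(
    X_otus, Y_pathways, ncomp: int = 2, keepX=None, keepY=None,
    method: str = "spls",
) -> pd.DataFrame:
    """Feature x pathway association matrix for heatmap rendering.

    ``spls`` computes the bilinear similarity of a canonical-mode sparse
    PLS between the blocks; ``pearson`` falls back to the plain pairwise
    correlation matrix. Rows and columns are ordered by average-linkage
    hierarchical clustering of the similarity profiles.
    """
    X_otus = pd.DataFrame(X_otus)
    Y_pathways = pd.DataFrame(Y_pathways)
    if X_otus.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if method == "spls":
        model = spls_fit(X_otus, Y_pathways, ncomp=ncomp, keepX=keepX,
                         keepY=keepY, mode="canonical")
        sim = similarity_matrix(model)
    elif method == "pearson":
        # unit-variance scaling makes X'Y/(n-1) the Pearson matrix
        xc = _center_scale(X_otus.values.astype(float))[0]
        yc = _center_scale(Y_pathways.values.astype(float))[0]
        sim = pd.DataFrame(
            (xc.T @ yc) / (X_otus.shape[0] - 1),
            index=X_otus.columns.astype(str), columns=Y_pathways.columns.astype(str),
        )
    else:
        raise ValueError(f"unknown method: {method}")

    def order(frame: pd.DataFrame, axis: int) -> list:
        data = frame.values if axis == 0 else frame.values.T
        if data.shape[0] < 3:
            return list(range(data.shape[0]))
        link = hierarchy.linkage(pdist(data), method="average")
        return list(hierarchy.leaves_list(link))

    return sim.iloc[order(sim, 0), order(sim, 1)]
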