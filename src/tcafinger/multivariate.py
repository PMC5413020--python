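"""Latent-variable models: NIPALS PCA and OPLS-DA with cross-validated Q2.

PCA components are extracted iteratively (NIPALS) from the scaled matrix;
R2X(cum, a) = 1 - ||X - X_hat_a||^2 / ||X||^2.  OPLS-DA separates the
two-class response into one predictive component plus K components of
y-orthogonal variation that are removed from X before the predictive fit
(single-y O-PLS).  Q2 = 1 - PRESS/SS is estimated by stratified k-fold
cross-validation (default 7 folds, venetian-blind assignment after a
seeded shuffle); for PCA the held-out rows are predicted variable-group-
wise from the loadings so that pure noise yields Q2 <= 0.

Component loading signs are fixed so each loading vector's
largest-magnitude element is positive, making outputs reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ScalingRecord",
    "LatentModel",
    "scale_matrix",
    "inverse_scale",
    "fit_pca",
    "fit_oplsda",
    "q2_crossval",
    "rank_features",
    "crossval_folds",
]

log = logging.getLogger("tcafinger")

_CONV_TOL = 1e-12
_MAX_ITER = 2000


@dataclass(frozen=True)
class ScalingRecord:
    """Column centering/scaling applied before a latent-model fit."""

    center: np.ndarray
    scale: np.ndarray
    mode: str  # "uv" | "none"


@dataclass
class LatentModel:
    """A fitted PCA or OPLS-DA model.

    ``scores``/``loadings`` hold the predictive component first (OPLS-DA)
    followed by any orthogonal components.  ``weights`` is the predictive
    weight vector w and ``y_loading`` the scalar regression of y on the
    predictive score (OPLS-DA only).
    """

    kind: str  # "pca" | "oplsda"
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    r2x: np.ndarray  # per component
    r2x_cum: float
    scaling: Optional[ScalingRecord] = None
    # OPLS-DA extras
    weights: Optional[np.ndarray] = None
    ortho_weights: Optional[np.ndarray] = None
    ortho_loadings: Optional[np.ndarray] = None
    y_loading: float = 0.0
    y_mean: float = 0.0
    r2y_cum: float = np.nan
    q2_cum: float = np.nan
    n_orthogonal: int = 0

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def scale_matrix(
    X: np.ndarray, mode: str = "uv", center: bool = True
) -> Tuple[np.ndarray, ScalingRecord]:
    """Center columns and, for unit-variance mode, divide by column sd.

    Zero-variance features are rejected by index in unit-variance mode; the
    returned record allows exact back-transformation.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("scale_matrix: matrix contains missing values")
    c = X.mean(axis=0) if center else np.zeros(X.shape[1])
    if mode == "uv":
        s = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(s == 0)
        if zero.size:
            raise ValueError(
                f"scale_matrix: zero-variance feature column(s) {zero.tolist()[:10]}"
            )
    elif mode == "none":
        s = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return (X - c) / s, ScalingRecord(center=c, scale=s, mode=mode)


def inverse_scale(Xs: np.ndarray, record: ScalingRecord) -> np.ndarray:
    """Undo ``scale_matrix`` exactly."""
    return np.asarray(Xs, dtype=float) * record.scale + record.center


def _fix_sign(p: np.ndarray, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Make the largest-magnitude loading element positive."""
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        return -p, -t
    return p, t


def _nipals_component(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """One NIPALS PCA component (score t, unit loading p) of X."""
    # start from the column with the largest sum of squares
    j = int(np.argmax((X**2).sum(axis=0)))
    t = X[:, j].copy()
    if not np.any(t):
        t = X[:, 0] + 1e-12
    for it in range(_MAX_ITER):
        p = X.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = X @ p
        if np.linalg.norm(t_new - t) <= _CONV_TOL * max(1.0, np.linalg.norm(t_new)):
            t = t_new
            break
        t = t_new
    else:
        raise RuntimeError(
            f"NIPALS failed to converge in {_MAX_ITER} iterations "
            f"(last change {np.linalg.norm(t_new - t):.3g})"
        )
    return t, p


def fit_pca(X_scaled: np.ndarray, n_components: int) -> LatentModel:
    """NIPALS PCA on a pre-scaled matrix."""
    X = np.asarray(X_scaled, dtype=float)
    n, m = X.shape
    if not 1 <= n_components <= min(n - 1, m):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, m)}], got {n_components}"
        )
    ss_total = float((X**2).sum())
    if ss_total == 0:
        raise ValueError("fit_pca: zero matrix")
    Xr = X.copy()
    T = np.empty((n, n_components))
    P = np.empty((m, n_components))
    r2x = np.empty(n_components)
    for a in range(n_components):
        t, p = _nipals_component(Xr)
        p, t = _fix_sign(p, t)
        Xr = Xr - np.outer(t, p)
        T[:, a], P[:, a] = t, p
        r2x[a] = float(t @ t) / ss_total
    r2x_cum = 1.0 - float((Xr**2).sum()) / ss_total
    return LatentModel(kind="pca", scores=T, loadings=P, r2x=r2x, r2x_cum=r2x_cum)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _encode_classes(y: Sequence) -> Tuple[np.ndarray, float]:
    """Two-class indicator centered to zero mean; returns (y_centered, mean)."""
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"OPLS-DA needs exactly two classes, got {classes.tolist()}")
    ind = (y == classes[-1]).astype(float)
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than two samples")
    mu = float(ind.mean())
    return ind - mu, mu


def fit_oplsda(
    X_scaled: np.ndarray, y: Sequence, n_orthogonal: int = 1
) -> LatentModel:
    """Single-response O-PLS discriminant model.

    One predictive component captures the y-correlated variation; each of
    the ``n_orthogonal`` components removes y-orthogonal systematic
    variation from X before the predictive fit.  Reports R2X per component
    (predictive first), cumulative R2X and R2Y.
    """
    X0 = np.asarray(X_scaled, dtype=float)
    yc, y_mean = _encode_classes(y)
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    ss_x = float((X0**2).sum())
    ss_y = float(yc @ yc)
    X = X0.copy()

    w = X.T @ yc / (yc @ yc)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response is orthogonal to every feature")
    w /= nw

    W_o: List[np.ndarray] = []
    P_o: List[np.ndarray] = []
    T_o: List[np.ndarray] = []
    for k in range(n_orthogonal):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-10 * max(1.0, np.linalg.norm(p)):
            raise ValueError(
                f"n_orthogonal={n_orthogonal} exceeds the y-orthogonal rank "
                f"(failed at component {k + 1})"
            )
        w_o /= n_wo
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        p_o, t_o = _fix_sign(p_o, t_o)
        # keep w_o consistent with the (possibly flipped) t_o
        if not np.allclose(X @ w_o, t_o):
            w_o = -w_o
        X = X - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    t = X @ w
    p = X.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    p, t = _fix_sign(p, t)
    if not np.allclose(X @ w, t):
        w = -w
        c = -c

    y_hat = t * c
    r2y = 1.0 - float(((yc - y_hat) ** 2).sum()) / ss_y

    comps = [(t, p)] + list(zip(T_o, P_o))
    r2x = np.array([float((np.outer(tt, pp) ** 2).sum()) / ss_x for tt, pp in comps])
    scores = np.column_stack([tt for tt, _ in comps])
    loadings = np.column_stack([pp for _, pp in comps])

    return LatentModel(
        kind="oplsda",
        scores=scores,
        loadings=loadings,
        r2x=r2x,
        r2x_cum=float(r2x.sum()),
        weights=w,
        ortho_weights=np.column_stack(W_o) if W_o else np.empty((X0.shape[1], 0)),
        ortho_loadings=np.column_stack(P_o) if P_o else np.empty((X0.shape[1], 0)),
        y_loading=c,
        y_mean=y_mean,
        r2y_cum=r2y,
        n_orthogonal=n_orthogonal,
    )


def predict_oplsda(model: LatentModel, X_scaled: np.ndarray) -> np.ndarray:
    """Predict the centered class response for new (already scaled) rows."""
    if model.kind != "oplsda":
        raise ValueError("predict_oplsda needs an OPLS-DA model")
    X = np.asarray(X_scaled, dtype=float).copy()
    for k in range(model.n_orthogonal):
        w_o = model.ortho_weights[:, k]
        p_o = model.ortho_loadings[:, k]
        t_o = X @ w_o
        X = X - np.outer(t_o, p_o)
    return (X @ model.weights) * model.y_loading


def crossval_folds(
    n: int, folds: int, seed: int, y: Optional[Sequence] = None
) -> List[np.ndarray]:
    """Deterministic venetian-blind fold assignment after a seeded shuffle.

    With ``y`` given the assignment is stratified: each class is shuffled
    and dealt round-robin so every fold keeps both classes where possible.
    """
    if folds < 2:
        raise ValueError("need at least two folds")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds sample count {n}")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if y is None:
        order = rng.permutation(n)
        assign[order] = np.arange(n) % folds
    else:
        y = np.asarray(y)
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            idx = rng.permutation(idx)
            assign[idx] = np.arange(idx.size) % folds
    return [np.flatnonzero(assign == f) for f in range(folds)]


def _press_pca_rows(
    model: LatentModel, X_test: np.ndarray, n_groups: int = 7
) -> float:
    """PRESS for held-out rows predicted variable-group-wise from loadings.

    Each variable group is reconstructed from scores computed on the
    *other* variables only, so the held-out value never predicts itself
    (pure noise then yields Q2 <= 0).
    """
    P = model.loadings
    m = P.shape[0]
    groups = [np.arange(m) % n_groups == g for g in range(min(n_groups, m))]
    press = 0.0
    for g in groups:
        if g.all():
            continue
        P_in = P[~g]  # variables used to form scores
        P_out = P[g]
        gram = P_in.T @ P_in
        try:
            coef = np.linalg.solve(gram, P_in.T)
        except np.linalg.LinAlgError:
            coef = np.linalg.pinv(P_in)
        t = X_test[:, ~g] @ coef.T
        press += float(((X_test[:, g] - t @ P_out.T) ** 2).sum())
    return press


def q2_crossval(
    X_scaled: np.ndarray,
    kind: str = "pca",
    y: Optional[Sequence] = None,
    n_components: int = 2,
    n_orthogonal: int = 1,
    folds: int = 7,
    seed: int = 0,
) -> float:
    """Cumulative Q2 = 1 - PRESS/SS by k-fold cross-validation.

    For PCA, SS is the total sum of squares of X and held-out rows are
    predicted variable-group-wise; for OPLS-DA, SS is the sum of squares of
    the centered class response and PRESS accumulates the response
    prediction error on held-out samples.
    """
    X = np.asarray(X_scaled, dtype=float)
    n = X.shape[0]
    if kind == "pca":
        fold_idx = crossval_folds(n, folds, seed)
        press = 0.0
        for test in fold_idx:
            train = np.setdiff1d(np.arange(n), test)
            sub = fit_pca(X[train], min(n_components, len(train) - 1, X.shape[1]))
            press += _press_pca_rows(sub, X[test])
        return 1.0 - press / float((X**2).sum())
    if kind == "oplsda":
        if y is None:
            raise ValueError("OPLS-DA cross-validation needs class labels")
        y = np.asarray(y)
        fold_idx = crossval_folds(n, folds, seed, y=y)
        for f, test in enumerate(fold_idx):
            train = np.setdiff1d(np.arange(n), test)
            if np.unique(y[train]).size < 2:
                raise ValueError(f"fold {f}: training split has a single class")
        yc, _ = _encode_classes(y)
        press = 0.0
        for test in fold_idx:
            train = np.setdiff1d(np.arange(n), test)
            sub = fit_oplsda(X[train], y[train], n_orthogonal=n_orthogonal)
            y_all = (np.asarray(y) == np.unique(y)[-1]).astype(float)
            y_train_mean = float(y_all[train].mean())
            pred = predict_oplsda(sub, X[test]) + y_train_mean
            press += float(((y_all[test] - pred) ** 2).sum())
        return 1.0 - press / float((yc**2).sum())
    raise ValueError(f"unknown model kind {kind!r}")


def choose_orthogonal_components(
    X_scaled: np.ndarray,
    y: Sequence,
    max_orthogonal: int = 5,
    folds: int = 7,
    seed: int = 0,
    min_improvement: float = 0.01,
) -> int:
    """Pick K orthogonal components by the Q2-improvement >= 0.01 rule."""
    best_k, best_q2 = 0, q2_crossval(
        X_scaled, kind="oplsda", y=y, n_orthogonal=0, folds=folds, seed=seed
    )
    for k in range(1, max_orthogonal + 1):
        try:
            q2 = q2_crossval(
                X_scaled, kind="oplsda", y=y, n_orthogonal=k, folds=folds, seed=seed
            )
        except ValueError:
            break
        if q2 - best_q2 >= min_improvement:
            best_k, best_q2 = k, q2
        else:
            break
    return best_k


def rank_features(
    model: LatentModel, feature_ids: Sequence[str]
) -> pd.DataFrame:
    """Rank features by |predictive-component covariance loading|.

    Discriminant-based: only defined for OPLS-DA models.  Ties break by
    feature id for determinism.
    """
    if model.kind != "oplsda":
        raise ValueError("rank_features requires an OPLS-DA model (got PCA)")
    ids = list(feature_ids)
    if len(ids) != model.loadings.shape[0]:
        raise ValueError("feature id count does not match loading rows")
    p_pred = model.loadings[:, 0]
    df = pd.DataFrame(
        {"feature_id": ids, "loading": p_pred, "abs_loading": np.abs(p_pred)}
    )
    df = df.sort_values(
        ["abs_loading", "feature_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.index.name = "rank"
    return df
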