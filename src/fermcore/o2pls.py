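"""Bidirectional orthogonal PLS (O2PLS) with predictive-component VIP.

O2PLS decomposes two blocks measured on the same samples — here the
genus abundance block X and the flavor block Y — into a shared (joint)
part, block-specific structured (orthogonal) parts, and residuals:

    X = T W' + T_o P_o' + E        Y = U C' + U_o P_yo' + F

with K joint components, nx X-orthogonal and ny Y-orthogonal components,
and an inner regression U ~ T B linking the joint scores.  The joint
weights come from the SVD of X'Y; orthogonal structure is removed by
iterative deflation against the joint scores before the final joint
decomposition is recomputed.

VIP restricted to the predictive components ("VIP_pred") weights each
variable's squared normalised joint loading by the Y sum of squares that
the corresponding joint component explains through the inner relation;
sum_j VIP_j^2 = p always, so values above 1 flag variables of
above-average importance.  Orthogonal components never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "O2PLSModel",
    "fit_o2pls",
    "vip_pred",
    "predict_y",
    "predict_x",
    "cross_validate",
]


@dataclass
class O2PLSModel:
    K: int
    nx: int
    ny: int
    W: np.ndarray  # p x K joint X weights, orthonormal columns
    C: np.ndarray  # q x K joint Y weights, orthonormal columns
    T: np.ndarray  # n x K joint X scores
    U: np.ndarray  # n x K joint Y scores
    T_orth: np.ndarray  # n x nx
    P_orth: np.ndarray  # p x nx
    W_orth: np.ndarray  # p x nx (projection weights for new samples)
    U_orth: np.ndarray  # n x ny
    P_yorth: np.ndarray  # q x ny
    C_orth: np.ndarray  # q x ny
    B_T: np.ndarray  # K x K inner regression T -> U
    B_U: np.ndarray  # K x K inner regression U -> T
    r2x: float
    r2y: float
    r2y_pred: float
    r2_inner: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray
    scaling: str
    taxon_ids: list = field(default_factory=list)
    flavor_ids: list = field(default_factory=list)
    q2: float | None = None


def _scale(m: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = m.mean(axis=0)
    if scaling == "unit_variance":
        sd = m.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
    elif scaling == "center_only":
        sd = np.ones(m.shape[1])
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return (m - mean) / sd, mean, sd


def _joint_weights(x: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    u, _, vt = np.linalg.svd(x.T @ y, full_matrices=False)
    return u[:, :k], vt[:k].T


def _fix_signs(w: np.ndarray) -> np.ndarray:
    """Flip columns so each one's largest-magnitude element is positive."""
    signs = np.ones(w.shape[1])
    for a in range(w.shape[1]):
        i = np.argmax(np.abs(w[:, a]))
        if w[i, a] < 0:
            signs[a] = -1.0
    return signs


def fit_o2pls(
    x,
    y,
    K: int = 2,
    nx: int = 1,
    ny: int = 1,
    scaling: str = "unit_variance",
) -> O2PLSModel:
    """Fit the O2PLS model on aligned samples-by-features blocks.

    ``x`` and ``y`` may be DataFrames (indices must agree) or arrays.
    Raises on rank violations (K + nx exceeding what the data support) and
    mismatched samples.
    """
    x_ids = list(x.index) if isinstance(x, pd.DataFrame) else None
    y_ids = list(y.index) if isinstance(y, pd.DataFrame) else None
    if x_ids is not None and y_ids is not None and x_ids != y_ids:
        raise ValueError("x and y sample ids do not match")
    taxa = list(x.columns) if isinstance(x, pd.DataFrame) else []
    flavors = list(y.columns) if isinstance(y, pd.DataFrame) else []
    xm = np.asarray(x, dtype=float)
    ym = np.asarray(y, dtype=float)
    if xm.shape[0] != ym.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    n = xm.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    rank_lim = min(n - 1, xm.shape[1])
    if K + nx > rank_lim:
        raise ValueError(f"K + nx = {K + nx} exceeds X rank limit {rank_lim}")
    if K + ny > min(n - 1, ym.shape[1]):
        raise ValueError(f"K + ny = {K + ny} exceeds Y rank limit")

    x0, x_mean, x_scale = _scale(xm, scaling)
    y0, y_mean, y_scale = _scale(ym, scaling)
    xd, yd = x0.copy(), y0.copy()

    t_orth = np.zeros((n, nx))
    p_orth = np.zeros((xm.shape[1], nx))
    w_orth_all = np.zeros((xm.shape[1], nx))
    for i in range(nx):
        w, c = _joint_weights(xd, yd, K)
        t = xd @ w
        e = xd - t @ w.T
        uo, _, _ = np.linalg.svd(e.T @ t, full_matrices=False)
        wo = uo[:, 0]
        to = xd @ wo
        po = xd.T @ to / (to @ to)
        xd = xd - np.outer(to, po)
        t_orth[:, i] = to
        p_orth[:, i] = po
        w_orth_all[:, i] = wo

    u_orth = np.zeros((n, ny))
    p_yorth = np.zeros((ym.shape[1], ny))
    c_orth_all = np.zeros((ym.shape[1], ny))
    for i in range(ny):
        w, c = _joint_weights(xd, yd, K)
        u = yd @ c
        f = yd - u @ c.T
        vo, _, _ = np.linalg.svd(f.T @ u, full_matrices=False)
        co = vo[:, 0]
        uo = yd @ co
        pyo = yd.T @ uo / (uo @ uo)
        yd = yd - np.outer(uo, pyo)
        u_orth[:, i] = uo
        p_yorth[:, i] = pyo
        c_orth_all[:, i] = co

    w, c = _joint_weights(xd, yd, K)
    sw, sc = _fix_signs(w), _fix_signs(c)
    w, c = w * sw, c * sc
    t = xd @ w
    u = yd @ c
    b_t = np.linalg.lstsq(t, u, rcond=None)[0]
    b_u = np.linalg.lstsq(u, t, rcond=None)[0]

    # R2Y covers the full Y-side model: joint part predicted from X through
    # the inner relation, plus the Y-orthogonal reconstruction.  R2X is the
    # analogous X reconstruction (joint + X-orthogonal).
    y_hat = t @ b_t @ c.T + u_orth @ p_yorth.T
    ss_y = (y0**2).sum()
    r2y = 1.0 - ((y0 - y_hat) ** 2).sum() / ss_y
    r2y_pred = 1.0 - ((y0 - t @ b_t @ c.T) ** 2).sum() / ss_y
    x_hat = t @ w.T + t_orth @ p_orth.T
    r2x = 1.0 - ((x0 - x_hat) ** 2).sum() / (x0**2).sum()
    u_hat = t @ b_t
    r2_inner = 1.0 - ((u - u_hat) ** 2).sum() / (u**2).sum() if (u**2).sum() > 0 else 0.0

    return O2PLSModel(
        K=K, nx=nx, ny=ny,
        W=w, C=c, T=t, U=u,
        T_orth=t_orth, P_orth=p_orth, W_orth=w_orth_all,
        U_orth=u_orth, P_yorth=p_yorth, C_orth=c_orth_all,
        B_T=b_t, B_U=b_u, r2x=float(r2x), r2y=float(r2y), r2y_pred=float(r2y_pred),
        r2_inner=float(r2_inner),
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        scaling=scaling, taxon_ids=taxa, flavor_ids=flavors,
    )


def vip_pred(m: O2PLSModel) -> pd.Series:
    """Per-taxon VIP over the predictive (joint) components only.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ) with
    SSY_a the Y sum of squares explained by joint component a through the
    inner relation; sum_j VIP_j^2 = p.
    """
    if m.W is None:
        raise ValueError("model is not fitted")
    p = m.W.shape[0]
    ssy = np.zeros(m.K)
    for a in range(m.K):
        # C has orthonormal columns, so ||t_a b_a C'||^2 = ||t_a||^2 ||b_a||^2
        ssy[a] = (m.T[:, a] ** 2).sum() * (m.B_T[a] ** 2).sum()
    total = ssy.sum()
    if total == 0:
        raise ValueError("inner relation explains no Y variance; VIP undefined")
    wn = m.W / np.linalg.norm(m.W, axis=0, keepdims=True)
    vip = np.sqrt(p * (wn**2 @ ssy) / total)
    index = m.taxon_ids if m.taxon_ids else list(range(p))
    return pd.Series(vip, index=index, name="VIP_pred")


def predict_y(m: O2PLSModel, x_new) -> pd.DataFrame:
    """Predict the flavor block for new samples from their abundance rows.

    Applies the training centering/scaling, strips the X-orthogonal
    variation, projects to the joint scores, and maps through the inner
    regression and Y loadings back to the original Y units.
    """
    if isinstance(x_new, pd.DataFrame):
        if m.taxon_ids:
            unknown = [t for t in x_new.columns if t not in set(m.taxon_ids)]
            missing = [t for t in m.taxon_ids if t not in set(x_new.columns)]
            if unknown or missing:
                raise ValueError(
                    f"taxon set mismatch; unknown={unknown[:5]}, missing={missing[:5]}"
                )
            x_new = x_new[m.taxon_ids]
        index = x_new.index
        xm = x_new.to_numpy(dtype=float)
    else:
        xm = np.asarray(x_new, dtype=float)
        index = pd.RangeIndex(len(xm))
    xs = (xm - m.x_mean) / m.x_scale
    for i in range(m.nx):
        to = xs @ m.W_orth[:, i]
        xs = xs - np.outer(to, m.P_orth[:, i])
    t_new = xs @ m.W
    y_scaled = t_new @ m.B_T @ m.C.T
    y = y_scaled * m.y_scale + m.y_mean
    cols = m.flavor_ids if m.flavor_ids else pd.RangeIndex(y.shape[1])
    return pd.DataFrame(y, index=index, columns=cols)


def predict_x(m: O2PLSModel, y_new) -> pd.DataFrame:
    """Predict the abundance block from new flavor rows (the reverse direction)."""
    if isinstance(y_new, pd.DataFrame):
        if m.flavor_ids:
            y_new = y_new[m.flavor_ids]
        index = y_new.index
        ym = y_new.to_numpy(dtype=float)
    else:
        ym = np.asarray(y_new, dtype=float)
        index = pd.RangeIndex(len(ym))
    ys = (ym - m.y_mean) / m.y_scale
    for i in range(m.ny):
        uo = ys @ m.C_orth[:, i]
        ys = ys - np.outer(uo, m.P_yorth[:, i])
    u_new = ys @ m.C
    x_scaled = u_new @ m.B_U @ m.W.T
    x = x_scaled * m.x_scale + m.x_mean
    cols = m.taxon_ids if m.taxon_ids else pd.RangeIndex(x.shape[1])
    return pd.DataFrame(x, index=index, columns=cols)


def cross_validate(
    x,
    y,
    K_range=(1, 2, 3),
    nx_range=(0, 1),
    ny_range=(0, 1),
    n_folds: int | None = None,
    seed: int | None = None,
    scaling: str = "unit_variance",
):
    """Row-wise K-fold cross-validation over a grid of (K, nx, ny).

    Held-out rows are centered/scaled by the training fold.  Because the
    model is bidirectional, PRESS is accumulated in both directions
    (Y predicted from X and X predicted from Y); ``Q2`` combines them,
    which is what makes the Y-orthogonal rank ny identifiable (a Y-only
    PRESS is blind to it).  Per-direction ``Q2_Y`` and ``Q2_X`` are also
    reported.  Leave-one-out is used when n <= 10, else 7-fold (both
    overridable).  Infeasible cells (ranks too large for a training fold)
    are NaN.  Returns (table, best) where best maximises Q2 with the
    smallest K + nx + ny as tie-break.
    """
    xm = np.asarray(x, dtype=float)
    ym = np.asarray(y, dtype=float)
    n = xm.shape[0]
    if n_folds is None:
        n_folds = n if n <= 10 else 7
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds must be in [2, {n}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)

    rows = []
    for k in K_range:
        for nx in nx_range:
            for ny in ny_range:
                press_y = press_x = tss_y = tss_x = 0.0
                ok = True
                for test_idx in folds:
                    train_idx = np.setdiff1d(order, test_idx)
                    try:
                        m = fit_o2pls(
                            xm[train_idx], ym[train_idx],
                            K=k, nx=nx, ny=ny, scaling=scaling,
                        )
                    except ValueError:
                        ok = False
                        break
                    # residuals on the training-scaled metric, both directions
                    y_pred = predict_y(m, xm[test_idx]).to_numpy()
                    press_y += (((ym[test_idx] - y_pred) / m.y_scale) ** 2).sum()
                    tss_y += (((ym[test_idx] - m.y_mean) / m.y_scale) ** 2).sum()
                    x_pred = predict_x(m, ym[test_idx]).to_numpy()
                    press_x += (((xm[test_idx] - x_pred) / m.x_scale) ** 2).sum()
                    tss_x += (((xm[test_idx] - m.x_mean) / m.x_scale) ** 2).sum()
                if ok and tss_y > 0 and tss_x > 0:
                    q2y = 1.0 - press_y / tss_y
                    q2x = 1.0 - press_x / tss_x
                    q2 = 1.0 - (press_y + press_x) / (tss_y + tss_x)
                else:
                    q2y = q2x = q2 = np.nan
                rows.append(
                    {"K": k, "nx": nx, "ny": ny, "Q2": q2, "Q2_Y": q2y, "Q2_X": q2x}
                )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["Q2"])
    if len(valid) == 0:
        raise ValueError("no feasible (K, nx, ny) cell")
    best_q2 = valid["Q2"].max()
    contenders = valid[valid["Q2"] >= best_q2 - 1e-12].copy()
    contenders["size"] = contenders["K"] + contenders["nx"] + contenders["ny"]
    best = contenders.sort_values(["size", "K", "nx", "ny"]).iloc[0]
    selected = (int(best["K"]), int(best["nx"]), int(best["ny"]))
    return table, selected
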