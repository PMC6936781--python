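"""Flavor-block multivariate statistics.

PCA of the mixed volatile/amino-acid flavor matrix with row-wise
cross-validated Q2 per component (chemometrics-style component
significance), category counting against the packaged annotation, and
per-sample taste-class sums (umami = Glu + Asp, sweet = Ala + Gly + Ser +
Thr, bitter = the eight bitter amino acids; Lys and Phe stay
unclassified).

Unit-variance scaling is the default because the flavor block mixes
chromatogram peak areas with amino-acid concentrations; center-only is
available for single-platform data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import VF_CATEGORIES, FlavorTable

__all__ = [
    "PCAResult",
    "TasteClassSummary",
    "pca_fit",
    "pca_q2",
    "flavor_category_counts",
    "taste_class_sums",
    "correlation_distance",
]

Q2_LIMIT_DEFAULT = 0.05


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components
    r2x: np.ndarray  # per component
    cum_r2x: np.ndarray
    scaling: str
    mean_: np.ndarray
    scale_: np.ndarray


@dataclass
class TasteClassSummary:
    sums: pd.DataFrame  # samples x {umami, sweet, bitter, unclassified}
    members: dict


def _scale_matrix(y: np.ndarray, scaling: str, columns) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if scaling not in ("unit_variance", "center_only"):
        raise ValueError(f"unknown scaling {scaling!r}")
    mean = y.mean(axis=0)
    if scaling == "unit_variance":
        sd = y.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if len(zero):
            names = [columns[i] for i in zero]
            raise ValueError(
                f"constant column(s) cannot be unit-variance scaled: {names}"
            )
    else:
        sd = np.ones_like(mean)
    return (y - mean) / sd, mean, sd


def pca_fit(
    y: FlavorTable | pd.DataFrame,
    scaling: str = "unit_variance",
    n_comp: int | None = None,
) -> PCAResult:
    """PCA of the scaled flavor matrix via SVD.

    R2X per component is the eigenvalue fraction lambda_a / sum(lambda);
    components are ordered by decreasing R2X, and each loading column's
    largest-magnitude element is made positive for determinism.
    """
    data = y.data if isinstance(y, FlavorTable) else y
    n, p = data.shape
    max_comp = min(n - 1, p)
    if n_comp is None:
        n_comp = max_comp
    if not 1 <= n_comp <= max_comp:
        raise ValueError(f"n_comp must be in [1, {max_comp}]")
    ys, mean, sd = _scale_matrix(data.to_numpy(dtype=float), scaling, list(data.columns))
    u, s, vt = np.linalg.svd(ys, full_matrices=False)
    lam = s**2
    total = lam.sum()
    r2x = lam[:n_comp] / total
    loadings = vt[:n_comp].T.copy()
    scores = u[:, :n_comp] * s[:n_comp]
    for a in range(n_comp):
        i = np.argmax(np.abs(loadings[:, a]))
        if loadings[i, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    cols = [f"PC{a + 1}" for a in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=data.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=data.columns, columns=cols),
        r2x=r2x,
        cum_r2x=np.cumsum(r2x),
        scaling=scaling,
        mean_=mean,
        scale_=sd,
    )


def pca_q2(
    y: FlavorTable | pd.DataFrame,
    n_comp: int = 3,
    n_folds: int = 7,
    seed: int | None = None,
    scaling: str = "unit_variance",
    limit: float = Q2_LIMIT_DEFAULT,
) -> pd.DataFrame:
    """Cross-validated Q2 per PCA component with a significance limit.

    Row-wise K-fold CV: for each fold the loadings are re-estimated on the
    training rows and held-out rows are reconstructed component by
    component; Q2_a = 1 - PRESS_a / SS_{a-1}, where SS_{a-1} is the
    residual sum of squares of the full data after a-1 components.  A
    component is flagged significant when Q2_a exceeds ``limit``.
    """
    data = y.data if isinstance(y, FlavorTable) else y
    n, p = data.shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n_folds = min(n_folds, n)
    max_comp = min(n - max(2, int(np.ceil(n / n_folds))) , p, n_comp)
    if max_comp < 1:
        raise ValueError("too few samples for cross-validated PCA")
    ys, _, _ = _scale_matrix(data.to_numpy(dtype=float), scaling, list(data.columns))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)

    press = np.zeros(max_comp)
    for test_idx in folds:
        train_idx = np.setdiff1d(order, test_idx)
        ytr = ys[train_idx]
        yte = ys[test_idx]
        _, _, vt = np.linalg.svd(ytr - ytr.mean(axis=0), full_matrices=False)
        resid = yte - ytr.mean(axis=0)
        for a in range(max_comp):
            v = vt[a]
            resid = resid - np.outer(resid @ v, v)
            press[a] += (resid**2).sum()

    # residual SS of the full data after a components
    ss = np.zeros(max_comp + 1)
    ss[0] = (ys**2).sum()
    _, s, _ = np.linalg.svd(ys, full_matrices=False)
    lam = s**2
    for a in range(1, max_comp + 1):
        ss[a] = ss[0] - lam[:a].sum()
    q2 = 1.0 - press / ss[:-1]
    return pd.DataFrame(
        {
            "Q2": q2,
            "limit": limit,
            "significant": q2 > limit,
        },
        index=[f"PC{a + 1}" for a in range(max_comp)],
    )


def flavor_category_counts(annotation: pd.DataFrame) -> pd.Series:
    """Counts per VF category plus VF/AA/grand totals from an annotation frame."""
    vf = annotation[annotation["kind"] == "VF"]
    aa = annotation[annotation["kind"] == "AA"]
    unknown = vf[~vf["category"].isin(VF_CATEGORIES)]
    if len(unknown):
        raise ValueError(f"unknown VF category for: {list(unknown.index)}")
    counts = {cat: int((vf["category"] == cat).sum()) for cat in VF_CATEGORIES}
    counts["VF_total"] = len(vf)
    counts["AA_total"] = len(aa)
    counts["grand_total"] = len(vf) + len(aa)
    return pd.Series(counts, name="count")


def taste_class_sums(y: FlavorTable, strict: bool = False) -> TasteClassSummary:
    """Per-sample sums of umami / sweet / bitter amino-acid intensities.

    Unclassified amino acids are summed separately; with ``strict`` an AA
    lacking a taste class raises instead.
    """
    ann = y.annotation.loc[list(y.data.columns)]
    aa = ann[ann["kind"] == "AA"]
    members: dict[str, list[str]] = {}
    sums = {}
    for cls in ("umami", "sweet", "bitter", "unclassified"):
        ids = list(aa.index[aa["taste_class"] == cls])
        members[cls] = ids
        sums[cls] = y.data[ids].sum(axis=1) if ids else pd.Series(0.0, index=y.data.index)
    if strict and members["unclassified"]:
        raise ValueError(f"AAs without a taste class: {members['unclassified']}")
    return TasteClassSummary(sums=pd.DataFrame(sums), members=members)


def correlation_distance(data: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """1 - Pearson correlation between columns, as an HCA-ready distance.

    Used for clustering flavor components by their temporal profiles.
    """
    corr = np.corrcoef(data.to_numpy(dtype=float).T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return list(data.columns), d
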