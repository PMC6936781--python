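"""Sample ordination and grouping: distances, PCoA, HCA, PERMANOVA.

The Hellinger distance is the Euclidean distance between square-rooted
relative-abundance rows (range [0, sqrt(2)]; no extra sqrt(2)
normalisation).  PCoA uses Gower double-centering; negative eigenvalues
are reported and excluded from the variance-fraction denominator, with no
Lingoes/Cailliez correction by default.  PERMANOVA uses the add-one
permutation p-value and switches to exhaustive enumeration automatically
when the number of distinct relabelings is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, to_relative_abundance

__all__ = [
    "DistanceMatrix",
    "PCoAResult",
    "PermanovaResult",
    "HCAResult",
    "hellinger_transform",
    "hellinger_distance",
    "bray_curtis",
    "euclidean_distance",
    "pcoa",
    "hca",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if d.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match matrix size")
        if np.abs(d - d.T).max() > 1e-12:
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise ValueError("distance matrix must have zero diagonal")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = (d + d.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_fraction: np.ndarray  # per reported axis, relative to positive sum
    n_negative_eigenvalues: int


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None = None


@dataclass
class HCAResult:
    newick: str
    merge_table: np.ndarray  # scipy linkage matrix
    sample_ids: list[str]
    linkage: str

    def cut(self, k: int) -> pd.Series:
        labels = sch.fcluster(self.merge_table, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")


def hellinger_transform(t: AbundanceTable) -> pd.DataFrame:
    """Entrywise square root of relative abundances (samples x taxa)."""
    rel = t if t.proportions else to_relative_abundance(t)
    if (rel.values < 0).any():
        raise ValueError("negative abundances")
    return np.sqrt(rel.data)


def hellinger_distance(t: AbundanceTable) -> DistanceMatrix:
    h = hellinger_transform(t)
    d = squareform(pdist(h.to_numpy(), metric="euclidean"))
    return DistanceMatrix(list(h.index), d, metric="hellinger")


def bray_curtis(t: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on non-negative rows."""
    x = t.values
    if (x.sum(axis=1) == 0).any():
        bad = [s for s, r in zip(t.sample_ids, x) if r.sum() == 0]
        raise ValueError(f"all-zero sample(s) have undefined Bray-Curtis distance: {bad}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(t.sample_ids, d, metric="bray_curtis")


def euclidean_distance(data: pd.DataFrame, metric_name: str = "euclidean") -> DistanceMatrix:
    d = squareform(pdist(data.to_numpy(), metric="euclidean"))
    return DistanceMatrix(list(data.index), d, metric=metric_name)


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Principal coordinates analysis via Gower double-centering.

    B = -1/2 J D^2 J with J the centering projector; coordinates are
    eigenvectors scaled by sqrt(eigenvalue).  Variance fractions are taken
    relative to the sum of positive eigenvalues only; negative eigenvalues
    (non-Euclidean distances) are counted and reported.
    """
    n = d.n
    if not 1 <= n_axes < n:
        raise ValueError(f"n_axes must be in [1, {n - 1}]")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    pos_sum = evals[pos].sum()
    n_neg = int((evals < -1e-10 * max(abs(evals[0]), 1.0)).sum())
    coords = np.zeros((n, n_axes))
    frac = np.zeros(n_axes)
    for a in range(n_axes):
        if pos[a]:
            v = evecs[:, a] * np.sqrt(evals[a])
            # deterministic sign: largest-|element| positive
            i = np.argmax(np.abs(v))
            coords[:, a] = v * np.sign(v[i]) if v[i] != 0 else v
            frac[a] = evals[a] / pos_sum
    cols = [f"PCo{a + 1}" for a in range(n_axes)]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=d.sample_ids, columns=cols),
        eigenvalues=evals,
        variance_fraction=frac,
        n_negative_eigenvalues=n_neg,
    )


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.left, labels)
    right = _to_newick(node.right, labels)
    bl_left = node.dist - node.left.dist
    bl_right = node.dist - node.right.dist
    return f"({left}:{bl_left:.10g},{right}:{bl_right:.10g})"


def hca(d: DistanceMatrix, linkage: str = "average") -> HCAResult:
    """Agglomerative clustering of a distance matrix; returns newick + merges.

    Tie-breaking is scipy's deterministic lowest-index-pair rule, so the
    dendrogram is reproducible for a fixed input ordering; the topology is
    invariant to relabeling of samples.
    """
    if linkage not in ("average", "ward", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if d.n < 2:
        raise ValueError("need at least 2 samples to cluster")
    z = sch.linkage(squareform(d.values, checks=False), method=linkage)
    tree = sch.to_tree(z)
    newick = _to_newick(tree, d.sample_ids) + ";"
    return HCAResult(newick=newick, merge_table=z, sample_ids=d.sample_ids, linkage=linkage)


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R2 from squared distances and integer group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    n_groups = len(np.unique(labels))
    if ss_within == 0:  # perfectly separated groups -> infinite pseudo-F
        return np.inf, 1.0
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    r2 = ss_between / ss_total
    return f, r2


def _multiset_permutations(items: list):
    """Yield the distinct permutations of a sorted multiset (lexicographic)."""
    items = list(items)
    n = len(items)
    yield tuple(items)
    while True:
        # next lexicographic permutation (Narayana's algorithm)
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1 :] = reversed(items[i + 1 :])
        yield tuple(items)


def _count_distinct_relabelings(labels: np.ndarray) -> float:
    from math import factorial

    n = len(labels)
    denom = 1
    for g in np.unique(labels):
        denom *= factorial(int((labels == g).sum()))
    return factorial(n) / denom


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (Adonis) on a distance matrix.

    SS_total = (1/n) sum_{i<j} d_ij^2; SS_within sums the analogous
    per-group terms; pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)).
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  When the number of
    distinct relabelings is <= n_perm, all of them are enumerated and the
    p-value is exact (observed labeling included once).
    """
    labels = pd.Series(list(groups))
    if len(labels) != d.n:
        raise ValueError("groups length must match distance matrix")
    codes = pd.factorize(labels)[0]
    n_groups = len(np.unique(codes))
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if n_groups == d.n:
        raise ValueError("each group has a single sample; within-group SS undefined")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d2 = d.values**2
    f_obs, r2 = _permanova_stats(d2, codes)

    n_distinct = _count_distinct_relabelings(codes)
    if n_distinct <= n_perm:
        # exhaustive: enumerate distinct orderings of the label multiset
        count_ge = 0
        total = 0
        for perm in _multiset_permutations(sorted(codes)):
            f_p, _ = _permanova_stats(d2, np.array(perm))
            total += 1
            if f_p >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / total
        return PermanovaResult(f_obs, r2, p, total, True, seed)

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        f_p, _ = _permanova_stats(d2, rng.permutation(codes))
        if f_p >= f_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, False, seed)
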