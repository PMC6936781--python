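"""Per-sample alpha-diversity estimators and rarefaction.

Conventions follow the MOTHUR lineage common in amplicon studies:
Shannon in natural-log units (base-2 behind a flag), Simpson as the
finite-sample dominance estimator ``sum n_i(n_i-1) / (N(N-1))`` (the
plug-in ``sum p_i^2`` behind a flag), bias-corrected Chao1, ACE with a
rare-taxon cutoff of 10, and Good's coverage ``1 - singletons/N``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "sobs",
    "shannon",
    "simpson",
    "chao1",
    "ace",
    "goods_coverage",
    "alpha_diversity_table",
    "rarefaction_curve",
    "rarefaction_expected",
]


def _as_counts(counts, allow_total_one: bool = True) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() < 1:
        raise ValueError("counts vector has no observations")
    return c


def sobs(counts) -> int:
    """Observed richness: number of taxa with at least one read."""
    return int((_as_counts(counts) > 0).sum())


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i ln p_i over observed taxa (nats by default)."""
    c = _as_counts(counts)
    p = c[c > 0] / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(counts, finite_sample: bool = True) -> float:
    """Simpson dominance estimator, in [0, 1].

    With ``finite_sample`` (default) this is ``sum n_i(n_i-1) / (N(N-1))``,
    which requires N >= 2; otherwise the plug-in ``sum p_i^2``.
    """
    c = _as_counts(counts)
    n = c.sum()
    if not finite_sample:
        p = c / n
        return float((p**2).sum())
    if n < 2:
        raise ValueError("finite-sample Simpson needs at least 2 reads")
    return float((c * (c - 1)).sum() / (n * (n - 1)))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: Sobs + n1(n1-1) / (2(n2+1))."""
    c = _as_counts(counts)
    s_obs = (c > 0).sum()
    n1 = (c == 1).sum()
    n2 = (c == 2).sum()
    return float(s_obs + n1 * (n1 - 1) / (2.0 * (n2 + 1)))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Taxa with more than ``rare_cutoff`` reads form the abundant class; the
    rare class drives the coverage correction.  The squared coefficient of
    variation term is floored at 0.  When the rare-class sample coverage is
    0 (all rare taxa are singletons) the estimator is undefined and the
    function falls back to Chao1.
    """
    c = _as_counts(counts)
    c = c[c > 0]
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    n1 = int((rare == 1).sum())
    c_ace = 1.0 - n1 / n_rare
    if c_ace == 0:
        return chao1(counts)
    ks = np.arange(1, rare_cutoff + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma2 = (s_rare / c_ace) * (ks * (ks - 1) * fk).sum() / (n_rare * (n_rare - 1)) - 1.0
    gamma2 = max(gamma2, 0.0)
    return float(s_abund + s_rare / c_ace + (n1 / c_ace) * gamma2)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - n1/N: estimated fraction of the community sampled."""
    c = _as_counts(counts)
    return float(1.0 - (c == 1).sum() / c.sum())


def alpha_diversity_table(counts_df: pd.DataFrame, rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-sample diversity summary (rows = samples) with a Mean/SD footer.

    Columns mirror the usual amplicon report: Sobs, Shannon, Simpson, Ace,
    Chao1, Coverage.
    """
    rows = {}
    for sid, row in counts_df.iterrows():
        c = row.to_numpy(dtype=float)
        rows[sid] = {
            "Sobs": sobs(c),
            "Shannon": shannon(c),
            "Simpson": simpson(c),
            "Ace": ace(c, rare_cutoff=rare_cutoff),
            "Chao1": chao1(c),
            "Coverage": goods_coverage(c),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.loc["Mean"] = out.mean(axis=0)
    out.loc["SD"] = out.drop(index=["Mean"]).std(axis=0, ddof=1)
    return out


def rarefaction_expected(counts, depth: int) -> float:
    """Closed-form expected richness in a without-replacement subsample.

    E[S(d)] = sum_i [1 - C(N - n_i, d) / C(N, d)] from the hypergeometric
    probability that taxon i is missed entirely at depth d.
    """
    c = _as_counts(counts)
    c = c[c > 0]
    n = int(c.sum())
    if not 1 <= depth <= n:
        raise ValueError(f"depth must be in [1, {n}]")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    miss = np.zeros(len(c))
    feasible = (n - c) >= depth
    a = n - c[feasible]
    miss[feasible] = np.exp(log_comb(a, depth) - log_comb(n, depth))
    return float((1.0 - miss).sum())


def rarefaction_curve(
    counts,
    depths,
    reps: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean observed richness at each subsampling depth (without replacement).

    Returns a frame indexed by depth with columns ``mean_sobs``, ``sd_sobs``
    and the analytic ``expected`` from :func:`rarefaction_expected`.
    """
    c = _as_counts(counts).astype(int)
    n = int(c.sum())
    depths = [int(d) for d in depths]
    if any(d < 1 or d > n for d in depths):
        raise ValueError(f"depths must lie in [1, {n}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(c)), c)
    rows = []
    for d in depths:
        obs = np.empty(reps)
        for r in range(reps):
            draw = rng.choice(pool, size=d, replace=False)
            obs[r] = len(np.unique(draw))
        rows.append(
            {
                "depth": d,
                "mean_sobs": obs.mean(),
                "sd_sobs": obs.std(ddof=1) if reps > 1 else 0.0,
                "expected": rarefaction_expected(c, d),
            }
        )
    return pd.DataFrame(rows).set_index("depth")
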