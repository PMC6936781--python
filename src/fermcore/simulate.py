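"""Paired abundance/flavor data with known joint structure and planted core taxa.

The generator is a pushforward of the exact O2PLS model.  Latent blocks

    X_lat = T W' + T_o P_o' + E       Y = T C' + U_o P_yo' + F

share K joint score columns T; all score columns (joint, X-orthogonal,
Y-orthogonal) are made mutually orthogonal so that at ``noise_sd=0`` the
decomposition is exactly recoverable.  ``X_lat`` is mapped to positive
compositions by componentwise exponential followed by row normalisation
(softmax-like), so the latent linear structure survives approximately in
log-relative space; the flavor block is shifted to be non-negative (an
affine change that no downstream correlation or centered model sees).

A planted subset of "core" taxa carries joint-component loadings at
least ``core_margin`` (default 3) times the non-core loading scale, and
the flavor loadings are block-structured so each joint component touches
at least 16 flavor components spanning both the amino-acid and the
volatile class — the configuration the downstream screen is meant to
recover.  Defaults mirror the study design: 8 fermentation-day samples,
a 58-component flavor panel (42 volatiles + 16 amino acids).  Recovery
suites use larger n (stated per test); n = 8 keeps correlation estimates
noisy and is sanity-level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, FlavorTable, load_flavor_annotation

__all__ = [
    "SyntheticTruth",
    "generate_dataset",
    "sample_counts",
    "two_group_null_dataset",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for recovery tests."""

    n_samples: int
    n_taxa: int
    n_vf: int
    n_aa: int
    K: int
    nx: int
    ny: int
    noise_sd: float
    seed: int
    T_true: np.ndarray
    W_true: np.ndarray  # taxa x K, orthonormal columns
    C_true: np.ndarray  # flavors x K, orthonormal columns
    planted_core: list = field(default_factory=list)
    X_latent: np.ndarray | None = None  # pre-softmax X block
    Y_latent: np.ndarray | None = None  # pre-shift Y block
    taxon_ids: list = field(default_factory=list)
    component_ids: list = field(default_factory=list)


def _orthonormal_scores(rng, n, k_total):
    """n x k_total matrix with orthonormal, centered columns scaled to sd 1."""
    g = rng.standard_normal((n, k_total))
    g -= g.mean(axis=0)
    q, _ = np.linalg.qr(g)
    return q[:, :k_total] * np.sqrt(n - 1)


def generate_dataset(
    n_samples: int = 8,
    n_taxa: int = 50,
    n_vf: int = 42,
    n_aa: int = 16,
    K: int = 2,
    nx: int = 1,
    ny: int = 1,
    n_core: int = 6,
    noise_sd: float = 0.25,
    core_margin: float = 3.0,
    signal_sd: float = 3.0,
    orth_sd: float = 1.0,
    orth_loading_sd: float = 0.3,
    latent_scale: float = 0.2,
    seed: int = 0,
) -> tuple[AbundanceTable, FlavorTable, SyntheticTruth]:
    """Generate a paired abundance/flavor dataset with planted core taxa.

    Core taxa are split evenly over the joint components; each joint
    component's flavor loadings cover half the amino acids and half the
    volatiles, so every core taxon is wired to >= 16 flavor components of
    both classes (with the default panel sizes).

    Returns the proportions-valued :class:`AbundanceTable` (sample ids
    F1..Fn, day metadata), the :class:`FlavorTable` (components named by
    the packaged annotation), and the :class:`SyntheticTruth`, which also
    carries the latent (pre-composition) blocks for exact-model checks.
    """
    q = n_vf + n_aa
    if K + nx + ny > n_samples - 1:
        raise ValueError(
            "K + nx + ny exceeds the score rank limit (n_samples - 1); "
            "mutually orthogonal centered scores are infeasible"
        )
    if K + nx > min(n_samples - 1, n_taxa):
        raise ValueError("K + nx exceeds the X rank limit for this n_samples")
    if K + ny > min(n_samples - 1, q):
        raise ValueError("K + ny exceeds the Y rank limit for this n_samples")
    if n_core > n_taxa:
        raise ValueError("n_core cannot exceed n_taxa")
    if n_core < K:
        raise ValueError("need at least one core taxon per joint component")
    rng = np.random.default_rng(seed)

    scores = _orthonormal_scores(rng, n_samples, K + nx + ny)
    t = scores[:, :K] * signal_sd
    t_orth = scores[:, K : K + nx] * orth_sd if nx else np.zeros((n_samples, 0))
    u_orth = scores[:, K + nx :] * orth_sd if ny else np.zeros((n_samples, 0))

    # X loadings: core taxa get large entries on their assigned component,
    # non-core taxa small entries everywhere; columns orthonormalised by QR
    # (which preserves the core/non-core magnitude ratio to first order).
    core_idx = np.arange(n_core)
    w = rng.standard_normal((n_taxa, K)) * 0.1
    for j, taxon in enumerate(core_idx):
        a = j % K
        w[taxon, :] *= 0.0
        w[taxon, a] = core_margin * (1.0 if rng.random() < 0.5 else -1.0)
    w, _ = np.linalg.qr(w)
    w = w[:, :K]

    # Y loadings: block structure, each joint component supported on half
    # the AAs and half the VFs (disjoint blocks -> orthonormal columns).
    c = np.zeros((q, K))
    aa_blocks = np.array_split(np.arange(n_vf, q), K)
    vf_blocks = np.array_split(np.arange(n_vf), K)
    for a in range(K):
        sup = np.concatenate([vf_blocks[a], aa_blocks[a]])
        vals = 0.5 + 0.5 * rng.random(len(sup))
        c[sup, a] = vals * np.sign(rng.standard_normal(len(sup)))
    c /= np.linalg.norm(c, axis=0, keepdims=True)

    # orthogonal (block-specific) structure: systematic but secondary to the
    # joint signal, so it perturbs rather than buries the planted wiring
    p_orth = rng.standard_normal((n_taxa, nx)) * orth_loading_sd if nx else np.zeros((n_taxa, 0))
    p_yorth = rng.standard_normal((q, ny)) * orth_loading_sd if ny else np.zeros((q, 0))

    e = rng.standard_normal((n_samples, n_taxa)) * noise_sd
    f = rng.standard_normal((n_samples, q)) * noise_sd
    x_lat = t @ w.T + t_orth @ p_orth.T + e
    y_lat = t @ c.T * 1.0 + u_orth @ p_yorth.T + f

    taxon_ids = [f"core_{i + 1}" for i in range(n_core)] + [
        f"genus_{i + 1}" for i in range(n_taxa - n_core)
    ]
    sample_ids = [f"F{i + 1}" for i in range(n_samples)]

    ann = load_flavor_annotation()
    vf_names = list(ann.index[ann["kind"] == "VF"])
    aa_names = list(ann.index[ann["kind"] == "AA"])
    if n_vf <= len(vf_names) and n_aa <= len(aa_names):
        component_ids = vf_names[:n_vf] + aa_names[:n_aa]
        annotation = ann
    else:  # synthetic panel larger than the packaged one
        component_ids = [f"VF_{i + 1}" for i in range(n_vf)] + [
            f"AA_{i + 1}" for i in range(n_aa)
        ]
        annotation = pd.DataFrame(
            {
                "name": component_ids,
                "kind": ["VF"] * n_vf + ["AA"] * n_aa,
                "category": ["other"] * n_vf + [""] * n_aa,
                "taste_class": ["unclassified"] * (n_vf + n_aa),
            },
            index=pd.Index(component_ids, name="component_id"),
        )

    comp = np.exp(latent_scale * x_lat)
    comp /= comp.sum(axis=1, keepdims=True)
    metadata = pd.DataFrame({"day": np.arange(1, n_samples + 1)}, index=sample_ids)
    abundance = AbundanceTable(
        pd.DataFrame(comp, index=sample_ids, columns=taxon_ids),
        metadata=metadata,
        proportions=True,
    )
    y_shift = y_lat - min(y_lat.min(), 0.0)
    flavor = FlavorTable(
        pd.DataFrame(y_shift, index=sample_ids, columns=component_ids),
        annotation=annotation,
    )
    truth = SyntheticTruth(
        n_samples=n_samples, n_taxa=n_taxa, n_vf=n_vf, n_aa=n_aa,
        K=K, nx=nx, ny=ny, noise_sd=noise_sd, seed=seed,
        T_true=t, W_true=w, C_true=c,
        planted_core=taxon_ids[:n_core],
        X_latent=x_lat, Y_latent=y_lat,
        taxon_ids=taxon_ids, component_ids=component_ids,
    )
    return abundance, flavor, truth


def sample_counts(proportions: AbundanceTable, depth: int, seed: int | None = None) -> AbundanceTable:
    """Multinomial read sampling: each sample gets exactly ``depth`` reads."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not proportions.proportions:
        raise ValueError("input must be a proportions table")
    rng = np.random.default_rng(seed)
    counts = np.vstack(
        [rng.multinomial(depth, row / row.sum()) for row in proportions.values]
    )
    return AbundanceTable(
        pd.DataFrame(counts, index=proportions.sample_ids, columns=proportions.taxon_ids),
        metadata=proportions.metadata,
    )


def two_group_null_dataset(
    n_per_group: int = 5,
    n_taxa: int = 20,
    seed: int | None = None,
    shift: float = 0.0,
) -> AbundanceTable:
    """Exchangeable two-group compositions for type-I-error studies.

    All samples are i.i.d. (no group effect) unless ``shift`` adds a mean
    offset to the second group's latent block (power sanity checks).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    lat = rng.standard_normal((n, n_taxa))
    lat[n_per_group:, : n_taxa // 2] += shift
    comp = np.exp(lat)
    comp /= comp.sum(axis=1, keepdims=True)
    sample_ids = [f"S{i + 1}" for i in range(n)]
    groups = ["g1"] * n_per_group + ["g2"] * n_per_group
    metadata = pd.DataFrame(
        {"day": np.arange(1, n + 1), "group": groups}, index=sample_ids
    )
    return AbundanceTable(
        pd.DataFrame(comp, index=sample_ids, columns=[f"genus_{j + 1}" for j in range(n_taxa)]),
        metadata=metadata,
        proportions=True,
    )
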