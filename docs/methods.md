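# Methods

## Problem setting

Two blocks are measured on the same fermentation-day samples: a genus-level
abundance table **X** (n samples × p genera; counts or relative abundances)
and a flavor table **Y** (n × q) mixing volatile-compound peak areas and
free-amino-acid concentrations. The goal is to find the *functional core*
genera — those statistically wired to flavor formation across both chemical
classes — and to support that call with the surrounding descriptive
statistics (diversity, ordination, grouping tests, flavor PCA).

## Alpha diversity

All estimators take one non-negative count vector and ignore appended
zeros. Conventions follow the MOTHUR lineage common in amplicon work:

- Shannon `H = −Σ (nᵢ/N) ln(nᵢ/N)` in nats (base-2 behind a flag).
- Simpson is the finite-sample dominance `Σ nᵢ(nᵢ−1) / (N(N−1))`
  (requires N ≥ 2); the plug-in `Σ pᵢ²` is available behind a flag.
- Chao1 is bias-corrected: `Sobs + n₁(n₁−1)/(2(n₂+1))`.
- ACE uses rare cutoff 10 (configurable); the squared coefficient of
  variation is floored at 0, and when every rare taxon is a singleton
  (rare-class coverage 0) the estimator is undefined and falls back to
  Chao1.
- Good's coverage `1 − n₁/N`.
- Rarefaction subsamples without replacement; the analytic expectation
  `E[S(d)] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)]` is computed alongside and is the
  oracle the subsampler is tested against (3 SE at 200 replicates).

## Distances, ordination, grouping

The Hellinger transform is the entrywise square root of relative
abundances; the Hellinger distance is the Euclidean distance between
transformed rows, range [0, √2], with no extra √2 normalisation (the
dominant convention in community ecology). Bray–Curtis is available as an
alternative PCoA metric.

PCoA uses Gower double-centering `B = −½ J D² J`. Coordinates are
eigenvectors scaled by √eigenvalue with a deterministic sign convention.
Negative eigenvalues (non-Euclidean distances) are counted and reported;
variance fractions are taken relative to the sum of *positive* eigenvalues
only, and no Lingoes/Cailliez correction is applied by default.

Hierarchical clustering is scipy agglomeration (UPGMA default; ward and
complete available) on the condensed distance matrix, exported as a newick
string plus the merge table; cutting at k = 2 yields the group labels used
when no labels are supplied. scipy's lowest-index tie-breaking makes the
dendrogram deterministic for a fixed row order, and the topology is
invariant to sample relabeling.

PERMANOVA uses the squared-distance decomposition
`SS_total = (1/n) Σ_{i<j} d²ᵢⱼ`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²ᵢⱼ`,
pseudo-F `= (SS_between/(g−1)) / (SS_within/(n−g))`, and the add-one
permutation p-value `(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`. When the
number of distinct relabelings of the label multiset is ≤ n_perm, all of
them are enumerated (lexicographic successor algorithm) and the p-value is
the exact fraction. Perfectly separated groups give F = ∞, R² = 1. Note
that with two equal groups the complement labeling always ties the observed
statistic, so the smallest attainable exact p is 2/(number of relabelings).

## Flavor-block PCA and Q²

PCA is an SVD of the column-scaled matrix; unit-variance scaling is the
default because the block mixes chromatogram areas with amino-acid
concentrations. Per-component explained variance is `R²X_a = λ_a/Σλ`.

Component significance uses row-wise K-fold cross-validation: loadings are
re-estimated on each training fold and held-out rows are deflated component
by component; `Q²_a = 1 − PRESS_a / SS_{a−1}` with `SS_{a−1}` the full-data
residual sum of squares after a−1 components. A component is significant
when Q² exceeds the limit (default 0.05, configurable — the exact
per-component limit rule of commercial chemometrics software is not
public). Row-wise reconstruction carries a small optimism of order 1/q;
with the 58-component flavor panel this sits well below the default limit,
which the null-data test (100 noise runs) confirms.

## O2PLS

The decomposition
`X = T Wᵀ + T_o P_oᵀ + E`, `Y = U Cᵀ + U_o P_yoᵀ + F`, inner relation
`U ≈ T B_T`, is fitted by SVD plus deflation:

1. center and (by default) unit-variance scale both blocks;
2. repeat nx times: take W, C as the top-K singular vectors of XᵀY,
   T = XW, E = X − TWᵀ; the X-orthogonal weight is the dominant left
   singular vector of EᵀT; score `t_o = X w_o`, loading
   `p_o = Xᵀt_o/(t_oᵀt_o)`; deflate X. Symmetrically ny times for Y;
3. recompute the final W, C, T, U from the deflated blocks;
4. `B_T = (TᵀT)⁻¹TᵀU` (full K×K; with SVD-paired components it is
   near-diagonal, asserted as a diagnostic) and `B_U` for the reverse
   direction;
5. sign convention: each weight column's largest-magnitude element is
   positive.

R²Y measures the full Y-side model — the joint part predicted from X
through the inner relation plus the Y-orthogonal reconstruction —
so that data generated exactly from the model at zero noise give
R²Y = 1 (the Y-orthogonal part is real structure, not error). The
prediction-only variant `r2y_pred` (and `predict_y`, which strips
X-orthogonal variation from new samples before projecting) is what
cross-validation exercises. R²X is the analogous X reconstruction.

Cross-block score orthogonality (`T_oᵀU = 0`) is exact at the step where
each orthogonal component is extracted and at zero noise; after step 3
re-estimates the joint weights from the deflated blocks it holds to
O(noise²). Within-block orthogonality (`T_oᵀT = 0`, `U_oᵀU = 0`) is exact
by construction.

**Cross-validated rank selection.** Row-wise K-fold (leave-one-out when
n ≤ 10, else 7-fold), training-fold centering/scaling applied to held-out
rows. Because the model is bidirectional, PRESS is accumulated in *both*
directions (Y from X and X from Y) and combined into one Q²; a Y-only
PRESS cannot identify ny, since Y-orthogonal variation is unpredictable
from X no matter how it is modelled, whereas it does contaminate the
U scores used to predict X. Selection maximises Q² with the smallest
K + nx + ny as tie-break; infeasible cells are NaN, not errors.

**VIP_pred.** Public literature does not fix a unique VIP for O2PLS; this
package uses the standard PLS VIP restricted to the K predictive
components:
`VIPⱼ = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a )`, with
`SSY_a = ‖t_a‖²‖(B_T)_{a·}‖²` the Y sum of squares attributed to joint
component a through the inner relation (C has orthonormal columns).
Orthogonal components never contribute. `Σ VIPⱼ² = p` holds identically,
so 1.0 is the "average importance" reference line.

## Synthetic data

The generator is a pushforward of the exact model above. All score columns
(joint, X-orthogonal, Y-orthogonal) are drawn Gaussian, centered, and made
mutually orthonormal (QR), scaled to sd `signal_sd = 3` (joint) and
`orth_sd = 1` (orthogonal); this is what makes zero-noise recovery exact
rather than approximate. Defaults mirror the study design: n = 8
fermentation days, p = 50 genera, the packaged 58-component flavor panel
(42 VFs + 16 AAs), K = 2 joint and one orthogonal component per block,
i.i.d. Gaussian noise sd 0.25.

Six core taxa (three per joint component) carry pre-orthonormalisation
loadings 3× ... 30× the non-core scale (`core_margin = 3` against a
non-core scale of 0.1), and the flavor loadings are block-structured —
each joint component is supported on half the AAs and half the VFs
(disjoint blocks, hence orthonormal columns) — so each core taxon is wired
to ≥ 16 flavor components spanning both classes, the configuration the
screen is meant to detect. Orthogonal loadings have sd 0.3: systematic but
secondary, so block-specific structure perturbs rather than buries the
joint wiring.

The abundance block is mapped to compositions by `softmax(0.2 · X_lat)` per
row; the gain 0.2 keeps the map near-linear so that latent correlation
structure survives on the simplex. The latent (pre-softmax, pre-shift)
blocks are kept on the truth object because exact-model assertions only
make sense there — the compositional map is monotone but not linear. The
flavor block is shifted to be non-negative (an affine change invisible to
any centered statistic).

What the generator does **not** emulate: ecological succession dynamics,
sparsity/zero-inflation of real OTU tables, taxon-specific sequencing
noise, and compositional closure effects at realistic dominance levels
(near-uniform compositions keep closure distortion mild). Passing recovery
tests therefore show the chain is *correct*, not that n = 8 real samples
carry enough information — which is why recovery-grade tests run at n = 60
while the n = 8 default is exercised at sanity level only (the screen runs
and returns a subset; exact recovery is not asserted).

`sample_counts` adds multinomial read sampling at a fixed depth;
`two_group_null_dataset` provides exchangeable samples for the PERMANOVA
type-I study (and a `shift` knob for power sanity checks).

## Correlation networks and the core screen

Correlations (Pearson default, Spearman optional) are computed between
genus relative abundances and raw flavor intensities; an optional
`log10(v + pc)` transform uses pc = half the smallest positive value per
block. Constant columns yield NaN, which thresholding excludes — never a
silent zero. Edge inclusion is strict (`|r| > cutoff`, so a coefficient
exactly at 0.7 is out) while the screening cuts are inclusive
(VIP ≥ 1.00, partners ≥ 16), and both boundaries are pinned by tests.
The 0.8 network is a separate reporting layer; the screen always counts
partners at 0.7. No multiple-testing control enters the screen — it is a
pure effect-size filter; an informational BH column can be attached to
exports. Compositionality-aware correlation (SparCC-style) is a known
omission: proportions are closed, so some correlation is structural.

## Pipeline

`run_pipeline` chains the stages from a single config (YAML or
constructor), writing one artifact per stage plus a manifest (config hash,
seed, version). The config seed fans out to per-stage seeds by SHA-256
hashing of the stage name, so adding a stage never perturbs earlier
stages' randomness; reruns are bit-identical apart from timestamps. When
the input is a proportions table, the diversity stage first draws
multinomial counts at depth 10,000 (diversity estimators need integer
counts).

## Problem sizes used in checks

Recovery-grade assertions use n = 60 samples (50 seeds for the end-to-end
screen, 20 for VIP separation and rank selection); the PERMANOVA null
study uses 500 datasets of 2 × 5 samples with exact 252-relabeling
enumeration; rarefaction agreement uses 200 replicates. These sizes give
the simulations stable pass/fail behaviour at comfortable margins.

## Known limitations

- The O2PLS VIP definition is an interpretation (see above), not a
  standard; ranks are stable across reasonable alternatives but absolute
  values near 1.0 should not be over-read.
- At n = 8 the correlation estimates behind criteria i and iii are noisy;
  the screen at study scale is descriptive, not inferential.
- Real OTU tables are sparse and compositional; the generator's softmax
  map is a mild idealisation of both.
- The rarefaction subsampler materialises the read pool in memory; depths
  beyond ~10⁷ reads per sample would need a weighted sampler.
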