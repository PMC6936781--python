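"""Sample ordination and permutation grouping test.

Computes Hellinger distances between fermentation-day communities, a
PCoA, an average-linkage dendrogram cut into two groups, and a
PERMANOVA (Adonis) of that grouping.
"""

from fermcore import generate_dataset, hca, hellinger_distance, pcoa, permanova

abundance, _, _ = generate_dataset(n_samples=12, seed=2)
dist = hellinger_distance(abundance)

ordination = pcoa(dist, n_axes=2)
print("PCoA variance fractions:",
      [round(float(v), 4) for v in ordination.variance_fraction])

tree = hca(dist)
groups = tree.cut(2)
print("dendrogram 2-group cut:", groups.to_dict())

res = permanova(dist, groups, n_perm=999, seed=2)
print(f"PERMANOVA: pseudo-F={res.pseudo_f:.3f}  R2={res.r2:.3f}  p={res.p_value:.4f}")
print(
    "\nA small p says the between-group community differences exceed what "
    "label shuffling produces; R2 is the fraction of distance variance the "
    "grouping explains."
)
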