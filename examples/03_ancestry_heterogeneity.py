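"""Axes of genetic variation and ancestry-correlated heterogeneity.

Builds a distance matrix of mean allele-frequency differences between 19
studies drawn from four ancestry groups, extracts two MDS axes that separate
the groups, and runs the per-variant meta-regression that partitions
between-study heterogeneity into an ancestry-correlated part (tested on the
axes) and a residual part.
"""

import numpy as np

from transgwas import ancestry, simulate

cfg = simulate.SimConfig(seed=21, studies_per_ancestry=5)
rng = np.random.default_rng(21)
_, eaf = simulate.simulate_frequencies(cfg, rng, 2000)
eaf = eaf.iloc[:, :19]

d = ancestry.freq_distance_matrix(eaf)
axes = ancestry.mds_axes(d, list(eaf.columns), n_axes=2)

print("study coordinates on the two axes of genetic variation:")
for sid, (x, y) in zip(axes.study_ids, axes.coords):
    print(f"  {sid:>6}: {x:+.4f} {y:+.4f}")

# a variant with homogeneous allelic effects across all studies
k = 19
beta_hom = np.full(k, -0.02)
res = ancestry.meta_regression(beta_hom, np.full(k, 0.01), axes.coords)
print(f"\nhomogeneous variant: p_het_ancestry = {res.p_het_ancestry:.3f} "
      f"(no ancestry-correlated heterogeneity)")

# a variant whose effect tracks the first axis (ancestry-correlated)
beta_het = -0.02 + 0.02 * axes.coords[:, 0] / np.abs(axes.coords[:, 0]).max()
res = ancestry.meta_regression(beta_het, np.full(k, 0.002), axes.coords)
print(f"axis-correlated variant: p_het_ancestry = {res.p_het_ancestry:.2e}")

flags, threshold = ancestry.heterogeneity_screen(
    np.array([res.p_het_ancestry]), n_signals=127
)
print(f"\nBonferroni threshold for 127 signals: {threshold:.2g}; "
      f"flagged: {bool(flags[0])}")
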