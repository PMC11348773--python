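"""Discover a minimal diagnostic SNP set for one target population.

A 500-locus pool contains 10 planted, truly diagnostic loci (strong
drift) over a weakly structured background.  Iterative selection ranks
loci by their discriminant contributions (LD values) and grows the panel
batch-by-batch until the target population separates cleanly.
"""

from snpcascade import iterative_select, planted_panel

gm, labels, planted = planted_panel(
    n_background=490, n_diagnostic=10,
    f_background=0.01, f_diagnostic=0.5, seed=7,
)
print(f"pool: {gm.n_loci} loci, {gm.n_samples} samples, "
      f"{len(planted)} planted diagnostic loci")

selected, state = iterative_select(
    gm, labels, target="pop1", batch_size=25, tau=0.95, n_pca=20,
)
hits = sorted(set(selected) & set(planted))
print(f"selected {len(selected)} loci in {len(state.rounds)} round(s); "
      f"separation metric {state.metric:.3f} (min posterior of any "
      f"target sample for its own group)")
print(f"recovered {len(hits)} / {len(planted)} planted loci: {hits}")
# a high recovery means the LD-value ranking put the truly informative
# loci at the top of a 50x larger pool of noise loci
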