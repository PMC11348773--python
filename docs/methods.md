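# Methods

`snpcascade` implements a two-part methodology for SNP-based population
identification, modeled on panel-based honey-bee ancestry tools: (1)
discovery of small diagnostic SNP panels from dense genotype matrices by
iterative discriminant analysis, and (2) a hierarchical cascade of
per-node classifiers — a Knowledge Base Network (KBN) — that routes an
unknown sample from broad lineages down to a terminal population label
from its 0/1/2 genotypes, tolerating substantial missingness.

## Genotype model and encoding

Genotypes are allele dosages at biallelic SNPs: 0 (homozygous reference),
1 (heterozygous), 2 (homozygous alternate); missing calls are an internal
sentinel serialized as `NA`. VCF GT fields map `0/0 -> 0`, `0/1|1/0 -> 1`,
`1/1 -> 2`, `./. -> NA`; haploid callsets (e.g. drone sequencing) can be
*diplotized* by doubling the single allele (`1 -> 2`). Multiallelic
records are rejected or skipped, never coerced.

### Quality control

The pipeline order is fixed: loci first, then samples.

- **Variant hard filters.** A record is rejected iff any rule fires:
  `QUAL < 30`, `QD < 2.0`, `MQ < 4.0`, `MQRankSum < -12.4`,
  `ReadPosRankSum < -8.0`, `FS > 60.0`, `SOR > 3.0`. All comparisons are
  strict, so boundary values pass. Every threshold is configurable; note
  that the customary GATK values for `MQ` and `MQRankSum` are 40 and
  -12.5 — users following GATK convention should override the defaults.
  A missing annotation does not fire its rule (lenient mode); strict mode
  raises instead.
- **Monomorphic loci** (all non-missing genotypes identical) carry no
  discriminant information and are dropped.
- **Sample missingness.** Samples are dropped when their missing-locus
  count exceeds `max_missing_count` (default 96, the working cutoff for a
  272-SNP panel, i.e. ~35%) or their missing fraction exceeds
  `max_missing_frac` (default 0.5). Both cutoffs are inclusive-keep: a
  sample exactly at the cutoff is retained.
- **Flanking-window filter** for assay design keeps a locus only if no
  other variant lies within `window_bases` (default 32) on either side;
  the window is closed, so a neighbor at exactly 32 bases excludes.

## SVD imputation and PCA

Missing genotypes are completed by iterative low-rank matrix completion:
initialize missing cells at the observed locus mean (the allele-frequency
expectation), then alternate a rank-`r` truncated-SVD reconstruction of
the missing cells until the largest change falls below `tol`. Observed
cells are never altered; non-convergence is reported, not fatal. Defaults
(`rank=10`, `tol=1e-6`, `max_iter=100`) are this package's own choices —
the upstream workflows did the imputation in closed-source software
without publishing the scheme. Imputed values stay real-valued for PCA;
`round_to_genotype` exists for export. PCA is exact (SVD of the centered,
optionally unit-scaled matrix) with a deterministic sign convention: the
largest-magnitude loading of each component is positive. Zero-variance
columns under scaling are left at unit scale with a warning rather than
dropped, so loading rows stay aligned with locus ids; a centered constant
column contributes nothing either way.

## DAPC

Discriminant Analysis of Principal Components: project the
centered/scaled matrix onto `n_pca` principal components, then solve
Fisher's generalized eigenproblem `S_b w = λ S_w w` on the PC scores.
Axes are scaled to unit pooled within-group variance and at most
`min(n_groups - 1, n_pca)` are retained.

- **Posteriors.** Group membership uses Gaussian class-conditional
  densities with shared spherical covariance in discriminant space
  (log-posterior `log π_g − ||z − μ_g||²/2` up to normalization). This is
  a deliberate, recorded choice — the reference R implementation's
  posterior model is not fully documented — and it is what the tests pin
  down. Priors default to uniform (an assignment tool should not inherit
  the reference panel's sampling imbalance); proportional or explicit
  priors are available. Ties break to the lexicographically smallest
  label.
- **Regularization.** The within-group scatter gets a ridge of
  `1e-8 x mean diagonal` to survive degenerate small groups.
- **LD values.** The contribution of locus *j* to axis *a* is the squared
  composed loading (PCA loadings x discriminant coefficients), normalized
  to sum to 1 per axis; the per-locus sum over retained axes is the
  ranking statistic for panel selection.
- **Retained-PC choice.** Repeated stratified cross-validation (default
  90/10 split) scores each candidate `n_pca` by held-out assignment
  success; highest mean success wins, ties to the smallest candidate
  (`reps=30` by default; RMSE of `1 − posterior(truth)` is reported
  secondarily). Success is the selector because it is the operational
  quantity for an identification tool.
- Models serialize to a single versioned JSON; reloaded models reproduce
  predictions bit-exactly (arrays are stored C-contiguous for this
  reason).

## Iterative diagnostic-SNP selection

For a target group: fit DAPC on the full pool, rank loci by LD value,
seed the panel with the top `batch_size` (default 25). While the
separation criterion fails, append the next ranked batch; keep it if the
separation metric improves by at least `epsilon` (default 0.01),
otherwise discard it permanently. The separation criterion is
posterior-based: every target sample must have posterior >= `tau`
(default 0.95) for its own group and no non-target sample may be assigned
to the target; the metric is the minimum target-posterior. `tau` and
`epsilon` operationalize the visual "clearly discriminated, without
overlap" standard of the original workflow, which published no numeric
rule; they are module decisions. Running the procedure per group (broad
clusters first) and taking the union yields the panel.

## Ward clustering and the KBN

Ward minimum-variance agglomeration is implemented with Lance-Williams
updates on sum-of-squares-increase merge costs (singleton cost = half the
squared Euclidean distance on the mean-imputed dosage matrix). Heights
are the SSE increases themselves (scipy's ward heights are
`sqrt(2 x cost)`; the cross-check test states the exact relation). Ties
break deterministically to the lexicographically smallest pair of cluster
ids in creation order. An O(n³) from-scratch recomputation of every
candidate merge cost serves as the test oracle.

The KBN topology is explicit configuration, not auto-derived: the
original network's nodes were labeled manually, so the package proposes a
topology (`topology_from_dendrogram`, typically on a Ward tree of group
centroids) and the user confirms or edits it. A shipped default topology
(`default_reference_topology`) reconstructs the honey-bee skeleton —
Africa line vs. Europe/Asia line at the root, and the three
double-assignation terminals (scutellata/capensis, Madagascar/Seychelles,
Malta/Tunisia) — but intermediate branchings below the named nodes are a
faithful skeleton, not an exact replica, because the full published
branching is not enumerable from public descriptions.

Building the network fits one DAPC per internal node (classes = its
children; training set = reference samples under the node; `n_pca` by
per-node cross-validation at `training_fraction=0.9` unless fixed), plus
a Tier II resolver DAPC over the two confounded groups of each
double-assignation terminal. Prediction routes each sample by argmax
posterior at every node, with no reject option by default (an optional
abstention threshold exists for screening use). Missing panel loci are
filled node-locally with the current node's training means — they
contribute exactly zero after centering, which is why accuracy degrades
gracefully with missingness; whether the original tool re-imputes per
node or once globally is unstated, so this policy is recorded and tested.
Samples with more than `max_missing` (default 96) missing panel loci are
rejected up front.

## Frequency-based reference assignment

The classical comparator: per-population alt-allele frequencies
`(alt + c) / (2 n_obs + 2c)` with pseudocount `c = 0.5` (keeps fixed loci
off 0/1 so log-likelihoods stay finite), then either the Hardy-Weinberg
genotype log-likelihood or the Euclidean distance between dosage/2 and
the frequency vector, summed/computed over non-missing loci. Winner =
best score, lexicographic tie-break, ties flagged ambiguous. Monte Carlo
resampling p-values of the classical software are out of scope; only
rank-based assignment is implemented. GenePop two-digit-allele I/O is
provided for interoperability.

## Synthetic data generator

The Balding-Nichols F-model: ancestral frequency `p ~ U(0.05, 0.95)`,
population frequency `~ Beta(p(1−F)/F, (1−p)(1−F)/F)` (so `F` is the
expected fixation index; `F=0` collapses to the ancestral frequency),
genotypes `~ Binomial(2, freq)`. Admixed samples draw from a per-sample
mixture of population frequencies; a hybrid-cline helper sweeps the
ancestry proportion `q` between two parents. Missingness is completely at
random. Linkage is *not* simulated — target panels space SNPs hundreds of
kilobases apart, so independent loci are a reasonable fixture — and
neither are selection, spatial clines within populations, or
genotyping-platform artifacts (allele dropout, batch effects). Passing
tests on this generator therefore demonstrate correctness of the
algorithms under the stated population-genetic model, not performance on
any particular real panel.

`planted_panel`, the selection-recovery fixture, draws its 10 diagnostic
loci under strong drift (`F=0.5`) *conditioned* on a realized population
frequency spread of at least 0.5 (rejection sampling). Unconditioned
strong-drift draws frequently leave both populations at the same boundary
frequency, in which case a "planted" locus carries no signal and no
method — not even a per-locus FST oracle — could recover it; conditioning
makes the ground truth actually diagnostic, which is what a recovery
experiment requires.

## Benchmark experiments and problem sizes

`snpcascade.benchmarks` packages the headline experiments end-to-end so
they can be recomputed from one seed (see `scripts/acceptance.py`):

- Ward merge sequences vs. the O(n³) oracle on 50 random 6-10-sample
  fixtures; full-rank DAPC vs. plain LDA (scikit-learn) on a 60x20
  3-group matrix; rank-1 completion error on a masked 4x4 cell; the
  7-record single-violation hard-filter toy.
- Cascade parameter recovery: 6 populations x 60 samples, 300 loci,
  `F=0.15`, stratified 80/20 split, topology from a Ward tree of training
  centroids, per-node cross-validated `n_pca` over {10, 20, 40} with 3
  replicates — sizes chosen so the whole experiment is a few seconds
  while leaving ~12 held-out samples per group; the same held-out set is
  re-scored with 25% of genotypes masked.
- Planted-locus recovery (10 among 500, weak `F=0.01` background) and
  the reference-set sensitivity flip for a 50/50 admixed sample.

## Known limitations

- The DAPC posterior model (spherical Gaussian, uniform priors) is a
  documented choice, not a byte-level replica of any R implementation.
- The shipped honey-bee topology is a skeleton; real deployments should
  supply their confirmed topology JSON.
- The generator's i.i.d.-locus assumption means linkage-driven
  redundancy among panel candidates is not exercised.
- Frequency-based assignment assumes HWE within references; strong
  inbreeding or recent admixture in the reference panel violates it.
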