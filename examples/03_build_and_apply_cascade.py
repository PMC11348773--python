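"""Build a hierarchical cascade classifier (KBN) and assign unknowns.

Six populations are simulated and split 80/20.  The cascade topology is
proposed from a Ward tree of training-group centroids; every internal
node gets its own cross-validated DAPC classifier.  Held-out samples are
then routed root-to-terminal, including a variant with 25% of their
genotypes masked to show graceful degradation under missing data.
"""

import numpy as np

from snpcascade import GenotypeMatrix, MISSING, build_kbn, predict_kbn
from snpcascade import SimSpec, simulate_populations, topology_from_dendrogram, ward_cluster

spec = SimSpec(n_populations=6, samples_per_population=60, n_loci=300,
               fst=0.15, seed=5)
gm, labels, _ = simulate_populations(spec)
lab = np.array(labels)

rng = np.random.default_rng(5)
train, test = [], []
for g in sorted(set(labels)):
    idx = np.where(lab == g)[0]
    rng.shuffle(idx)
    cut = int(0.8 * len(idx))
    train += list(idx[:cut]); test += list(idx[cut:])
train, test = sorted(train), sorted(test)

gm_tr = gm.subset(samples=[gm.sample_ids[i] for i in train])
gm_te = gm.subset(samples=[gm.sample_ids[i] for i in test])
y_tr, y_te = lab[train], lab[test]

groups = sorted(set(labels))
X = gm_tr.as_float(fill="mean")
cents = np.vstack([X[y_tr == g].mean(axis=0) for g in groups])
dend = ward_cluster(cents)
dend.sample_ids = groups
topo = topology_from_dendrogram(dend)
print("proposed cascade topology (Ward tree of group centroids):")
print(" ", dend.to_newick())

net = build_kbn(gm_tr, list(y_tr), topo,
                xval_params={"grid": [10, 20, 40], "reps": 3}, seed=5)
results, _ = predict_kbn(net, gm_te, max_missing=None)
acc = np.mean([r.final_label == t for r, t in zip(results, y_te)])
print(f"\nheld-out accuracy: {acc:.1%} on {len(y_te)} samples")
print(f"example route: {results[0].sample_id} -> {' > '.join(results[0].path)}"
      f" (per-node max posterior {['%.3f' % p for p in results[0].max_posteriors]})")

vals = np.where(rng.random(gm_te.values.shape) < 0.25, np.int8(MISSING), gm_te.values)
masked = GenotypeMatrix(gm_te.sample_ids, gm_te.locus_ids, vals)
res_m, _ = predict_kbn(net, masked, max_missing=None)
acc_m = np.mean([r.final_label == t for r, t in zip(res_m, y_te)])
print(f"with 25% of genotypes masked: {acc_m:.1%} "
      "(node-local mean fill keeps routing stable)")
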