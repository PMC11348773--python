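"""Reproducible synthetic benchmark experiments.

Each function builds its own inputs with the simulator, runs the package's
method, and measures the result, so headline behavior — oracle
equivalence of the numerics, held-out cascade accuracy, robustness to
missing panel loci, planted-locus recovery, and reference-set sensitivity
— can be recomputed from a single seed.  The cross-checks deliberately go
through independent routes (an O(n^3) from-scratch Ward recomputation,
scikit-learn's LDA, closed-form rank-1 completion) rather than the
package's own code paths.
"""

from __future__ import annotations

import numpy as np

from .dapc import fit_dapc, predict_dapc
from .genotype_io import MISSING, GenotypeMatrix, VariantRecord, hard_filter_variants
from .kbn import build_kbn, predict_kbn, topology_from_dendrogram, ward_cluster
from .matrix_core import svd_impute
from .popassign import assign_sample, estimate_frequencies
from .snp_select import iterative_select
from .synth_data import SimSpec, planted_panel, simulate_populations


def brute_force_ward_merges(X: np.ndarray):
    """O(n^3) Ward oracle: recompute every candidate merge cost from raw
    member coordinates at every step (no Lance-Williams recurrences)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    members = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i in sorted(members):
            for j in sorted(members):
                if j <= i:
                    continue
                a, b = members[i], members[j]
                ca, cb = X[a].mean(axis=0), X[b].mean(axis=0)
                cost = len(a) * len(b) / (len(a) + len(b)) * ((ca - cb) ** 2).sum()
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, i, j)
        cost, i, j = best
        members[next_id] = members.pop(i) + members.pop(j)
        merges.append((i, j, cost, len(members[next_id])))
        next_id += 1
    return merges


def ward_oracle_agreement(seed: int = 0, n_fixtures: int = 50) -> float:
    """Fraction of random 6-10-sample fixtures whose full merge sequence
    (pairs, sizes, and heights) matches the brute-force oracle."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_fixtures):
        n = int(rng.integers(6, 11))
        X = rng.normal(size=(n, 4))
        ours = ward_cluster(X).merges
        oracle = brute_force_ward_merges(X)
        ok = all(
            (i1, j1, s1) == (i2, j2, s2) and abs(h1 - h2) <= 1e-9 * max(1, h2)
            for (i1, j1, h1, s1), (i2, j2, h2, s2) in zip(ours, oracle)
        )
        hits += ok
    return hits / n_fixtures


def dapc_lda_agreement(seed: int = 0, n: int = 60, p: int = 20) -> float:
    """Agreement of full-rank DAPC assignments with plain LDA
    (scikit-learn, uniform priors) on a 3-group toy matrix."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.repeat(["A", "B", "C"], n // 3)
    shift = {"A": 0.0, "B": 0.8, "C": 1.6}
    X[:, 0] += np.array([shift[c] for c in y])
    model = fit_dapc(X, y, n_pca=p)
    _, pred = predict_dapc(model, X)
    oracle = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(X, y)
    return float(np.mean(pred == oracle.predict(X)))


def impute_rank1_error(seed: int = 0) -> float:
    """Max abs error recovering one masked cell of a rank-1 4x4 matrix
    (closed form: the completion is u_i * v_j)."""
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.5, 2.0, size=4)
    v = rng.uniform(0.5, 2.0, size=4)
    X = np.outer(u, v)
    Xm = X.copy()
    Xm[1, 2] = np.nan
    imp = svd_impute(Xm, rank=1, tol=1e-13, max_iter=1000)
    return float(abs(imp.matrix[1, 2] - u[1] * v[2]))


def hard_filter_toy_check() -> dict:
    """Seven records each violating exactly one printed threshold, plus
    one all-boundary record: the filter must reject exactly the seven,
    each for its own distinct reason, and keep the boundary record."""
    base = {
        "QD": 10.0, "MQ": 50.0, "MQRankSum": 0.0,
        "ReadPosRankSum": 0.0, "FS": 1.0, "SOR": 1.0,
    }
    violations = [
        ("QUAL", {"QUAL": 29.0}),
        ("QD", {"QD": 1.9}),
        ("MQ", {"MQ": 3.9}),
        ("MQRankSum", {"MQRankSum": -12.5}),
        ("ReadPosRankSum", {"ReadPosRankSum": -8.1}),
        ("FS", {"FS": 60.1}),
        ("SOR", {"SOR": 3.1}),
    ]
    records = []
    for k, (_, ov) in enumerate(violations):
        ann = dict(base)
        qual = ov.get("QUAL", 100.0)
        ann.update({a: b for a, b in ov.items() if a != "QUAL"})
        records.append(VariantRecord("chr1", 100 + k, "A", "T", qual, ann))
    boundary = VariantRecord(
        "chr1", 999, "A", "T", 30.0,
        {"QD": 2.0, "MQ": 4.0, "MQRankSum": -12.4,
         "ReadPosRankSum": -8.0, "FS": 60.0, "SOR": 3.0},
    )
    kept, rejected = hard_filter_variants(records + [boundary])
    reasons = sorted(tuple(r[1]) for r in rejected)
    return {
        "n_input": len(records) + 1,
        "n_kept": len(kept),
        "n_rejected": len(rejected),
        "distinct_single_reasons": len(set(reasons)),
        "reasons_match": reasons == sorted((v[0],) for v in violations),
        "boundary_kept": boundary in kept,
    }


def kbn_holdout_experiment(
    seed: int = 0,
    n_populations: int = 6,
    samples_per_population: int = 60,
    n_loci: int = 300,
    fst: float = 0.15,
    train_fraction: float = 0.8,
    mask_fraction: float = 0.25,
) -> dict:
    """Held-out accuracy of a KBN on simulated structured populations.

    Simulates the stated populations, splits 80/20 stratified, derives the
    cascade topology from a Ward tree of training group centroids, builds
    the KBN on the training part, and scores the held-out samples — once
    as-is, and once with ``mask_fraction`` of panel genotypes masked at
    predict time to probe graceful degradation.
    """
    spec = SimSpec(
        n_populations=n_populations,
        samples_per_population=samples_per_population,
        n_loci=n_loci,
        fst=fst,
        seed=seed,
    )
    gm, labels, _ = simulate_populations(spec)
    lab = np.array(labels)
    rng = np.random.default_rng(seed + 1)

    train_idx, test_idx = [], []
    for g in sorted(set(labels)):
        idx = np.where(lab == g)[0]
        rng.shuffle(idx)
        n_tr = int(round(train_fraction * len(idx)))
        train_idx.extend(idx[:n_tr])
        test_idx.extend(idx[n_tr:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)

    gm_train = gm.subset(samples=[gm.sample_ids[i] for i in train_idx])
    gm_test = gm.subset(samples=[gm.sample_ids[i] for i in test_idx])
    y_train, y_test = lab[train_idx], lab[test_idx]

    groups = sorted(set(labels))
    Xtr = gm_train.as_float(fill="mean")
    cents = np.vstack([Xtr[y_train == g].mean(axis=0) for g in groups])
    dend = ward_cluster(cents)
    dend.sample_ids = groups
    topo = topology_from_dendrogram(dend)

    net = build_kbn(
        gm_train, list(y_train), topo,
        xval_params={"grid": [10, 20, 40], "reps": 3}, seed=seed,
    )
    results, _ = predict_kbn(net, gm_test, max_missing=None)
    acc = float(np.mean([r.final_label == t for r, t in zip(results, y_test)]))

    vals = gm_test.values.copy()
    mask = rng.random(vals.shape) < mask_fraction
    vals = np.where(mask, np.int8(MISSING), vals)
    masked = GenotypeMatrix(gm_test.sample_ids, gm_test.locus_ids, vals)
    results_m, _ = predict_kbn(net, masked, max_missing=None)
    acc_m = float(np.mean([r.final_label == t for r, t in zip(results_m, y_test)]))

    return {
        "holdout_accuracy": acc,
        "masked_accuracy": acc_m,
        "masked_drop": acc - acc_m,
        "n_test": len(test_idx),
        "n_train": len(train_idx),
    }


def selection_recovery_experiment(seed: int = 0) -> dict:
    """Recovery of 10 planted diagnostic loci among 500 by iterative
    selection (strongly drifted planted truth over a weak background)."""
    gm, labels, planted = planted_panel(
        n_background=490, n_diagnostic=10,
        f_background=0.01, f_diagnostic=0.5, seed=seed,
    )
    selected, state = iterative_select(gm, labels, "pop1", n_pca=20)
    return {
        "n_selected": len(selected),
        "n_recovered": len(set(selected) & set(planted)),
        "n_planted": len(planted),
        "separated": state.converged,
    }


def refset_sensitivity_experiment(seed: int = 0) -> dict:
    """Does an admixed sample's winning label change when a genetically
    closer reference population is added to the reference set?"""
    spec = SimSpec(
        n_populations=3, samples_per_population=40, n_loci=250,
        fst=0.25, seed=seed,
    )
    gm, labels, pf = simulate_populations(spec)
    rng = np.random.default_rng(seed + 1)
    mixed_freq = 0.5 * pf[0] + 0.5 * pf[1]
    sample = rng.binomial(2, mixed_freq).astype(np.int8)

    freqs_without = estimate_frequencies(gm, labels)
    winner_without = assign_sample(freqs_without, sample).winner

    extra = np.vstack([rng.binomial(2, mixed_freq) for _ in range(40)]).astype(np.int8)
    gm_ext = GenotypeMatrix(
        gm.sample_ids + [f"mix{i}" for i in range(40)],
        gm.locus_ids,
        np.vstack([gm.values, extra]),
    )
    freqs_with = estimate_frequencies(gm_ext, labels + ["closer_pop"] * 40)
    winner_with = assign_sample(freqs_with, sample).winner
    return {
        "winner_without_closer_ref": winner_without,
        "winner_with_closer_ref": winner_with,
        "winner_changed": winner_without != winner_with,
    }
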