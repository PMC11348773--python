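import json

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch

from snpcascade import (
    GenotypeMatrix,
    KBN,
    SimSpec,
    TopologyNode,
    build_kbn,
    cut_dendrogram,
    default_reference_topology,
    node_genotype_profile,
    predict_kbn,
    simulate_populations,
    topology_from_dendrogram,
    ward_cluster,
)


def brute_force_ward(X):
    """O(n^3) oracle: recompute the within-cluster SSE increase of every
    candidate merge from the raw member coordinates at every step."""
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


class TestWardCluster:
    @pytest.mark.parametrize("seed", range(10))
    def test_merge_sequence_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        X = rng.normal(size=(n, 4))
        dend = ward_cluster(X)
        oracle = brute_force_ward(X)
        for (i1, j1, h1, s1), (i2, j2, h2, s2) in zip(dend.merges, oracle):
            assert (i1, j1, s1) == (i2, j2, s2)
            assert h1 == pytest.approx(h2, rel=1e-9)

    def test_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(99)
        X = rng.normal(size=(20, 5))
        dend = ward_cluster(X)
        Z = sch.linkage(X, method="ward")
        # scipy ward heights are sqrt(2 * SSE increase)
        ours = np.array([m[2] for m in dend.merges])
        assert np.allclose(np.sqrt(2 * ours), Z[:, 2], rtol=1e-8)
        assert np.array_equal(dend.to_linkage()[:, 3], Z[:, 3])

    def test_identical_samples_merge_first_at_height_zero(self):
        X = np.array([[1.0, 1], [5, 5], [1, 1], [9, 9]])
        dend = ward_cluster(X)
        i, j, h, _ = dend.merges[0]
        assert {i, j} == {0, 2} and h == 0.0

    def test_heights_nondecreasing(self, four_pop):
        gm, _, _ = four_pop
        dend = ward_cluster(gm)
        hs = [m[2] for m in dend.merges]
        assert all(b >= a - 1e-9 for a, b in zip(hs, hs[1:]))

    def test_8_point_planar_toy(self):
        # two tight squares far apart: last merge joins the squares
        X = np.array(
            [[0, 0], [0, 1], [1, 0], [1, 1], [10, 10], [10, 11], [11, 10], [11, 11]],
            dtype=float,
        )
        dend = ward_cluster(X)
        assert dend.merges == brute_force_ward(X)
        labels = cut_dendrogram(dend, k=2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ward_cluster(np.array([[1.0, np.inf], [0, 0]]))

    def test_newick_export_parses(self, two_pop_separable):
        gm, _, _ = two_pop_separable
        dend = ward_cluster(gm.subset(samples=gm.sample_ids[:8]))
        nwk = dend.to_newick()
        from io import StringIO

        from Bio import Phylo

        tree = Phylo.read(StringIO(nwk), "newick")
        assert tree.count_terminals() == 8


class TestCutDendrogram:
    def test_k_extremes(self, four_pop):
        gm, _, _ = four_pop
        dend = ward_cluster(gm)
        assert len(set(cut_dendrogram(dend, k=gm.n_samples))) == gm.n_samples
        assert len(set(cut_dendrogram(dend, k=1))) == 1

    def test_k2_recovers_two_separated_populations(self, two_pop_separable):
        gm, labels, _ = two_pop_separable
        dend = ward_cluster(gm)
        cl = cut_dendrogram(dend, k=2)
        lab = np.array(labels)
        # each cut cluster maps to exactly one true population
        for c in set(cl):
            assert len(set(lab[cl == c])) == 1

    def test_invalid_args(self, two_pop_separable):
        gm, _, _ = two_pop_separable
        dend = ward_cluster(gm)
        with pytest.raises(ValueError):
            cut_dendrogram(dend, k=0)
        with pytest.raises(ValueError):
            cut_dendrogram(dend, height=-1.0)


class TestNodeProfile:
    def test_single_sample_indicator(self, toy_gm):
        prof = node_genotype_profile(toy_gm, ["a"])
        assert prof[0].tolist() == [1.0, 0.0, 0.0]
        assert prof[2].tolist() == [0.0, 0.0, 1.0]

    def test_mixed_node_fractions(self):
        vals = np.array([[0], [1], [1], [2]], dtype=np.int8)
        gm = GenotypeMatrix(["a", "b", "c", "d"], ["L1"], vals)
        prof = node_genotype_profile(gm, ["a", "b", "c", "d"])
        assert prof[0].tolist() == [0.25, 0.5, 0.25]

    def test_all_missing_locus_is_nan(self):
        vals = np.array([[-1], [-1]], dtype=np.int8)
        gm = GenotypeMatrix(["a", "b"], ["L1"], vals)
        prof = node_genotype_profile(gm, ["a", "b"])
        assert np.isnan(prof[0]).all()

    def test_parent_profile_is_member_weighted_child_mean(self):
        rng = np.random.default_rng(4)
        vals = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        gm = GenotypeMatrix(
            [f"s{i}" for i in range(10)], [f"L{j}" for j in range(6)], vals
        )
        left, right = gm.sample_ids[:4], gm.sample_ids[4:]
        pl = node_genotype_profile(gm, left)
        pr = node_genotype_profile(gm, right)
        pp = node_genotype_profile(gm, gm.sample_ids)
        assert np.allclose(pp, (4 * pl + 6 * pr) / 10)


class TestTopology:
    def test_default_reference_topology_valid(self):
        topo = default_reference_topology()
        topo.validate()
        doubles = [t for t in topo.walk() if t.is_double]
        assert {t.node_id for t in doubles} == {"B_1_1", "C_1_2_1", "D_1_2_2_2"}
        assert "Puerto Rico" in topo.labels()

    def test_round_trip_json(self):
        topo = default_reference_topology()
        back = TopologyNode.from_dict(json.loads(json.dumps(topo.to_dict())))
        assert back.to_dict() == topo.to_dict()

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError, match="single leaf"):
            TopologyNode("root", terminal_labels=["only"]).validate()

    def test_duplicate_label_rejected(self):
        topo = TopologyNode(
            "root",
            children=[
                TopologyNode("x", terminal_labels=["A"]),
                TopologyNode("y", terminal_labels=["A"]),
            ],
        )
        with pytest.raises(ValueError, match="twice"):
            topo.validate()

    def test_topology_from_dendrogram_covers_groups(self, four_pop):
        gm, labels, _ = four_pop
        lab = np.array(labels)
        groups = sorted(set(labels))
        X = gm.as_float(fill="mean")
        cents = np.vstack([X[lab == g].mean(axis=0) for g in groups])
        dend = ward_cluster(cents)
        dend.sample_ids = groups
        topo = topology_from_dendrogram(dend)
        topo.validate()
        assert sorted(topo.labels()) == groups


def _build_four_pop_kbn(four_pop, seed=0):
    gm, labels, _ = four_pop
    lab = np.array(labels)
    groups = sorted(set(labels))
    X = gm.as_float(fill="mean")
    cents = np.vstack([X[lab == g].mean(axis=0) for g in groups])
    dend = ward_cluster(cents)
    dend.sample_ids = groups
    topo = topology_from_dendrogram(dend)
    return gm, labels, build_kbn(
        gm, labels, topo, xval_params={"n_pca": 10}, seed=seed
    )


class TestBuildPredictKBN:
    def test_reference_samples_reassigned(self, four_pop):
        gm, labels, kbn = _build_four_pop_kbn(four_pop)
        results, rejected = predict_kbn(kbn, gm, max_missing=None)
        assert not rejected
        acc = np.mean([r.final_label == l for r, l in zip(results, labels)])
        assert acc >= 0.98
        assert all(r.path[0] == "root" for r in results)

    def test_training_reassignment_at_every_node(self, four_pop):
        gm, labels, kbn = _build_four_pop_kbn(four_pop)
        from snpcascade import predict_dapc

        lab = np.array(labels)
        for t in kbn.topology.walk():
            if t.is_leaf:
                continue
            node = kbn.nodes[t.node_id]
            sel = np.isin(lab, t.labels())
            sub = gm.subset(samples=[s for s, m in zip(gm.sample_ids, sel) if m])
            _, pred = predict_dapc(node.model, sub)
            child_of = {v: c.node_id for c in t.children for v in c.labels()}
            truth = [child_of[l] for l in lab[sel]]
            acc = np.mean([a == b for a, b in zip(pred, truth)])
            assert acc >= 0.98

    def test_double_assignation_resolved_by_tier2(self):
        spec = SimSpec(
            n_populations=3, samples_per_population=20, n_loci=120, fst=0.3, seed=5
        )
        gm, labels, _ = simulate_populations(spec)
        topo = TopologyNode(
            "root",
            children=[
                TopologyNode("A_1", terminal_labels=["pop1", "pop2"]),
                TopologyNode("A_2", terminal_labels=["pop3"]),
            ],
        )
        kbn = build_kbn(gm, labels, topo, xval_params={"n_pca": 8})
        assert "A_1_tierII" in kbn.nodes
        assert kbn.nodes["A_1_tierII"].tier == "II"
        results, _ = predict_kbn(kbn, gm, max_missing=None)
        acc = np.mean([r.final_label == l for r, l in zip(results, labels)])
        assert acc >= 0.95
        routed = [r for r in results if r.path[-1] == "A_1_tierII"]
        assert routed and all(
            r.final_label in ("pop1", "pop2") for r in routed
        )

    def test_rebuild_same_seed_identical_models(self, four_pop, tmp_path):
        _, _, k1 = _build_four_pop_kbn(four_pop, seed=3)
        _, _, k2 = _build_four_pop_kbn(four_pop, seed=3)
        d1, d2 = tmp_path / "k1", tmp_path / "k2"
        k1.save(d1)
        k2.save(d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_save_load_round_trip_predictions(self, four_pop, tmp_path):
        gm, labels, kbn = _build_four_pop_kbn(four_pop)
        kbn.save(tmp_path / "net")
        back = KBN.load(tmp_path / "net")
        r1, _ = predict_kbn(kbn, gm, max_missing=None)
        r2, _ = predict_kbn(back, gm, max_missing=None)
        assert [r.final_label for r in r1] == [r.final_label for r in r2]
        assert [r.path for r in r1] == [r.path for r in r2]

    def test_all_missing_sample_rejected(self, four_pop):
        gm, labels, kbn = _build_four_pop_kbn(four_pop)
        blank = GenotypeMatrix(
            ["ghost"], gm.locus_ids, np.full((1, gm.n_loci), -1, dtype=np.int8)
        )
        results, rejected = predict_kbn(kbn, blank, max_missing=96)
        assert not results
        assert rejected == [("ghost", gm.n_loci)]

    def test_min_group_size_enforced(self, four_pop):
        gm, labels, _ = four_pop
        topo = TopologyNode(
            "root",
            children=[
                TopologyNode("x", terminal_labels=["pop1"]),
                TopologyNode("y", terminal_labels=["missing_pop"]),
            ],
        )
        with pytest.raises(ValueError, match="labels not in topology"):
            build_kbn(gm.subset(samples=gm.sample_ids[:50]), labels[:50], topo)

    def test_min_posterior_abstention(self, four_pop):
        from snpcascade.kbn import UNASSIGNED

        gm, labels, kbn = _build_four_pop_kbn(four_pop)
        # an impossible threshold forces abstention at the root
        results, _ = predict_kbn(kbn, gm, max_missing=None, min_posterior=1.1)
        assert all(r.final_label == UNASSIGNED for r in results)
        assert all(len(r.path) == 1 for r in results)
        # default (off) never abstains
        results2, _ = predict_kbn(kbn, gm, max_missing=None)
        assert all(r.final_label != UNASSIGNED for r in results2)

    def test_masking_quarter_of_loci_degrades_gracefully(self, four_pop):
        gm, labels, kbn = _build_four_pop_kbn(four_pop)
        rng = np.random.default_rng(17)
        vals = gm.values.copy()
        mask = rng.random(vals.shape) < 0.25
        vals = np.where(mask, np.int8(-1), vals)
        masked = GenotypeMatrix(gm.sample_ids, gm.locus_ids, vals)
        base, _ = predict_kbn(kbn, gm, max_missing=None)
        degraded, _ = predict_kbn(kbn, masked, max_missing=None)
        acc0 = np.mean([r.final_label == l for r, l in zip(base, labels)])
        acc1 = np.mean([r.final_label == l for r, l in zip(degraded, labels)])
        assert acc0 - acc1 <= 0.05
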