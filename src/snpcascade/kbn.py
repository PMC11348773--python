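"""Ward clustering and the hierarchical Knowledge Base Network (KBN).

The KBN is a rooted tree of per-node DAPC classifiers.  Reference samples
are Ward-clustered from their 0/1/2 genotypes; the resulting dendrogram
(or an explicit, manually confirmed topology) defines how terminal
population labels are partitioned at each internal node.  An unknown
sample is routed from the root to a terminal by taking, at every node, the
child with the highest DAPC posterior.  Terminals may carry two candidate
labels (e.g. closely related sister populations); such "double
assignation" terminals hold a secondary (Tier II) DAPC trained on only the
two confounded groups, which produces the single final label.

Missing panel loci are handled node-locally: at each node the sample's
absent or missing loci are filled with that node's own reference means
(they contribute zero after centering), so routing degrades gracefully as
missingness grows.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy as sch

from .dapc import DAPCModel, fit_dapc, predict_dapc, xval_select_npca
from .genotype_io import GenotypeMatrix

# ---------------------------------------------------------------------------
# Ward hierarchical agglomerative clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Binary merge tree from Ward agglomeration.

    ``merges[t] = (i, j, height, size)`` merges clusters ``i`` and ``j``
    (ids: 0..n-1 are leaves, n+t is the cluster created at step t) at
    ``height`` = the increase in within-cluster sum of squares.  Heights
    are non-decreasing (Ward monotonicity).
    """

    sample_ids: list[str]
    merges: list[tuple[int, int, float, int]]
    #: optional manual text labels for nodes (leaf or internal ids)
    node_labels: dict[int, str] = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def members(self) -> dict[int, list[int]]:
        """Leaf index sets for every node id (leaves and internal)."""
        out = {i: [i] for i in range(self.n_leaves)}
        for t, (i, j, _, _) in enumerate(self.merges):
            out[self.n_leaves + t] = sorted(out[i] + out[j])
        return out

    def to_linkage(self) -> np.ndarray:
        """Scipy-style linkage matrix (heights kept on the SSE-increase scale)."""
        return np.array(
            [[i, j, h, s] for i, j, h, s in self.merges], dtype=float
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        label = {i: self.sample_ids[i] for i in range(self.n_leaves)}
        for t, (i, j, h, _) in enumerate(self.merges):
            nid = self.n_leaves + t
            height[nid] = h
            bi = max(h - height[i], 0.0)
            bj = max(h - height[j], 0.0)
            label[nid] = f"({label[i]}:{bi:.6g},{label[j]}:{bj:.6g})"
        return label[self.n_leaves + len(self.merges) - 1] + ";"


def ward_cluster(gm) -> Dendrogram:
    """Ward minimum-variance agglomeration via Lance-Williams updates.

    Input is a GenotypeMatrix (missing cells mean-filled) or a float
    array.  Pairwise merge cost is the increase in within-cluster sum of
    squares; for singletons this is half the squared Euclidean distance.
    Ties on the minimum cost break deterministically to the pair with the
    lexicographically smallest cluster ids (ids ordered by creation).
    """
    if isinstance(gm, GenotypeMatrix):
        X = gm.as_float(fill="mean")
        sample_ids = gm.sample_ids
    else:
        X = np.asarray(gm, dtype=float)
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")

    # cost matrix over active clusters, keyed by creation-ordered ids
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    INF = np.inf
    size = np.ones(2 * n - 1)
    D = np.full((2 * n - 1, 2 * n - 1), INF)
    D[:n, :n] = sq / 2.0
    np.fill_diagonal(D, INF)
    active = np.zeros(2 * n - 1, dtype=bool)
    active[:n] = True

    merges: list[tuple[int, int, float, int]] = []
    for t in range(n - 1):
        ids = np.where(active)[0]
        sub = D[np.ix_(ids, ids)]
        iu = np.triu_indices(len(ids), k=1)
        flat = sub[iu]
        best = int(np.argmin(flat))  # first occurrence = lexicographic (i, j)
        i, j = int(ids[iu[0][best]]), int(ids[iu[1][best]])
        h = float(D[i, j])
        new = n + t
        si, sj = size[i], size[j]
        size[new] = si + sj
        # Lance-Williams update for Ward on SSE-increase costs
        for k in ids:
            if k in (i, j):
                continue
            sk = size[k]
            D[new, k] = D[k, new] = (
                (si + sk) * D[i, k] + (sj + sk) * D[j, k] - sk * h
            ) / (si + sj + sk)
        active[i] = active[j] = False
        active[new] = True
        merges.append((i, j, h, int(size[new])))
    return Dendrogram(list(sample_ids), merges)


def cut_dendrogram(dend: Dendrogram, k: int | None = None, height: float | None = None) -> np.ndarray:
    """Flat cluster labels (1..k) by cluster count or merge height."""
    Z = dend.to_linkage()
    if k is not None:
        if not 1 <= k <= dend.n_leaves:
            raise ValueError(f"k must be in [1, {dend.n_leaves}]")
        return sch.fcluster(Z, t=k, criterion="maxclust")
    if height is None:
        raise ValueError("supply k or height")
    if height < 0:
        raise ValueError("height must be >= 0")
    return sch.fcluster(Z, t=height, criterion="distance")


def node_genotype_profile(gm: GenotypeMatrix, members: Sequence[str]) -> np.ndarray:
    """Per-locus fractions of genotype states {0,1,2} within a node.

    Returns an ``(n_loci, 3)`` array; each row sums to 1 over the
    non-missing members.  A locus entirely missing within the node yields
    a NaN row (undefined profile).
    """
    if len(members) == 0:
        raise ValueError("member set is empty")
    sub = gm.subset(samples=list(members))
    out = np.full((sub.n_loci, 3), np.nan)
    for j in range(sub.n_loci):
        col = sub.values[:, j]
        obs = col[col != -1]
        if obs.size:
            out[j] = [(obs == s).mean() for s in (0, 1, 2)]
    return out


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


@dataclass
class TopologyNode:
    """A node of the KBN blueprint.

    Internal nodes have >= 2 children; leaves carry one terminal label, or
    two for double-assignation terminals (resolved by a Tier II model).
    """

    node_id: str
    children: list["TopologyNode"] = field(default_factory=list)
    terminal_labels: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_double(self) -> bool:
        return self.is_leaf and len(self.terminal_labels) == 2

    def labels(self) -> list[str]:
        """All terminal labels under this node."""
        if self.is_leaf:
            return list(self.terminal_labels)
        out: list[str] = []
        for c in self.children:
            out.extend(c.labels())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.walk():
            if node.is_leaf:
                if not 1 <= len(node.terminal_labels) <= 2:
                    raise ValueError(
                        f"leaf {node.node_id!r} must carry 1 or 2 labels"
                    )
                dup = seen & set(node.terminal_labels)
                if dup:
                    raise ValueError(f"label(s) {sorted(dup)} appear twice")
                seen |= set(node.terminal_labels)
            elif len(node.children) < 2:
                raise ValueError(
                    f"internal node {node.node_id!r} has < 2 children"
                )
        if self.is_leaf:
            raise ValueError("topology root cannot be a single leaf")

    def to_dict(self) -> dict:
        d: dict = {"id": self.node_id}
        if self.is_leaf:
            d["labels"] = list(self.terminal_labels)
        else:
            d["children"] = [c.to_dict() for c in self.children]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TopologyNode":
        return cls(
            node_id=str(d["id"]),
            children=[cls.from_dict(c) for c in d.get("children", [])],
            terminal_labels=[str(l) for l in d.get("labels", [])],
        )


def default_reference_topology() -> TopologyNode:
    """The shipped honey-bee cascade skeleton (a reconstruction).

    Root splits into an Africa line (A_1) and a Europe/Asia line (A_2).
    Double-assignation terminals — scutellata/capensis,
    Madagascar/Seychelles, Malta/Tunisia — get Tier II resolvers.  The
    full published branching below the named nodes is not enumerable from
    public descriptions, so intermediate levels are a faithful skeleton.
    """

    def leaf(nid, *labels):
        return TopologyNode(nid, terminal_labels=list(labels))

    africa = TopologyNode(
        "A_1",
        children=[
            leaf("B_1_1", "A. m. scutellata", "A. m. capensis"),
            TopologyNode(
                "B_1_2",
                children=[
                    leaf("C_1_2_1", "Madagascar", "Seychelles"),
                    TopologyNode(
                        "C_1_2_2",
                        children=[
                            TopologyNode(
                                "D_1_2_2_1",
                                children=[
                                    leaf("E_1_2_2_1_1", "Puerto Rico"),
                                    leaf("E_1_2_2_1_2", "America-Africanized"),
                                ],
                            ),
                            leaf("D_1_2_2_2", "Malta", "Tunisia"),
                        ],
                    ),
                ],
            ),
        ],
    )
    europe_asia = TopologyNode(
        "A_2",
        children=[
            TopologyNode(
                "B_2_1",
                children=[
                    leaf("C_2_1_1", "EU_lig_like"),
                    leaf("C_2_1_2", "A. m. iberiensis"),
                ],
            ),
            TopologyNode(
                "B_2_2",
                children=[
                    leaf("C_2_2_1", "Georgia_Turkey"),
                    leaf("C_2_2_2", "Turkey"),
                ],
            ),
        ],
    )
    return TopologyNode("root", children=[africa, europe_asia])


def topology_from_dendrogram(dend: Dendrogram) -> TopologyNode:
    """Propose a KBN topology from a dendrogram over *group* centroids.

    Leaves of the dendrogram must be group labels.  Node ids encode depth
    as cascade levels (A, B, C, ...) with the child path appended; the
    result is a proposal the user is expected to confirm or edit.
    """
    n = dend.n_leaves
    if n < 2:
        raise ValueError("need >= 2 groups")
    children: dict[int, tuple[int, int]] = {}
    for t, (i, j, _, _) in enumerate(dend.merges):
        children[n + t] = (i, j)
    root_id = n + len(dend.merges) - 1

    def build(nid: int, depth: int, path: str) -> TopologyNode:
        name = f"{chr(ord('A') + min(depth, 25))}{path}"
        if nid < n:
            return TopologyNode(name, terminal_labels=[dend.sample_ids[nid]])
        i, j = children[nid]
        return TopologyNode(
            name if depth else "root",
            children=[build(i, depth + 1, path + "_1"), build(j, depth + 1, path + "_2")],
        )

    return build(root_id, 0, "")


# ---------------------------------------------------------------------------
# KBN build / predict
# ---------------------------------------------------------------------------


@dataclass
class KBNNode:
    node_id: str
    tier: str  # "I" or "II"
    model: DAPCModel | None  # None for simple terminals
    child_ids: dict[str, str]  # predicted class -> child node id
    terminal_labels: list[str]
    tier2_id: str | None = None  # resolver node for double terminals


@dataclass
class KBN:
    """A built Knowledge Base Network: topology plus per-node classifiers."""

    topology: TopologyNode
    nodes: dict[str, KBNNode]
    panel_loci: list[str]
    label_vocabulary: list[str]

    # -- serialization ---------------------------------------------------

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        meta = {
            "topology": self.topology.to_dict(),
            "panel_loci": self.panel_loci,
            "label_vocabulary": self.label_vocabulary,
            "nodes": {
                nid: {
                    "tier": nd.tier,
                    "child_ids": nd.child_ids,
                    "terminal_labels": nd.terminal_labels,
                    "tier2_id": nd.tier2_id,
                    "has_model": nd.model is not None,
                }
                for nid, nd in self.nodes.items()
            },
        }
        with open(os.path.join(directory, "topology.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        for nid, nd in self.nodes.items():
            if nd.model is not None:
                nd.model.save(os.path.join(directory, f"node_{nid}.json"))

    @classmethod
    def load(cls, directory) -> "KBN":
        with open(os.path.join(directory, "topology.json")) as fh:
            meta = json.load(fh)
        nodes = {}
        for nid, nd in meta["nodes"].items():
            model = None
            if nd["has_model"]:
                model = DAPCModel.load(os.path.join(directory, f"node_{nid}.json"))
            nodes[nid] = KBNNode(
                node_id=nid,
                tier=nd["tier"],
                model=model,
                child_ids=dict(nd["child_ids"]),
                terminal_labels=list(nd["terminal_labels"]),
                tier2_id=nd["tier2_id"],
            )
        return cls(
            topology=TopologyNode.from_dict(meta["topology"]),
            nodes=nodes,
            panel_loci=list(meta["panel_loci"]),
            label_vocabulary=list(meta["label_vocabulary"]),
        )


@dataclass
class AssignmentResult:
    """Routing record for one unknown sample."""

    sample_id: str
    path: list[str]  # visited node ids, root first
    posteriors: list[np.ndarray]  # per visited decision, over its classes
    max_posteriors: list[float]
    final_label: str
    n_missing: int


def build_kbn(
    gm: GenotypeMatrix,
    labels: Sequence[str],
    topology: TopologyNode,
    xval_params: dict | None = None,
    min_group_size: int = 3,
    seed: int = 0,
) -> KBN:
    """Train a DAPC classifier at every internal (and Tier II) node.

    At each internal node the classes are its children; the training set
    is the reference samples whose terminal label falls under the node.
    ``n_pca`` is chosen per node by stratified cross-validation
    (``training_fraction`` 0.9 by default) unless ``xval_params`` contains
    a fixed ``{"n_pca": value}``.  Double-assignation terminals get a
    Tier II resolver DAPC over their two confounded groups.
    """
    topology.validate()
    labels = [str(l) for l in labels]
    vocab = topology.labels()
    unknown = set(labels) - set(vocab)
    if unknown:
        raise ValueError(f"labels not in topology: {sorted(unknown)}")
    counts = {v: labels.count(v) for v in vocab}
    short = [v for v in vocab if counts.get(v, 0) < min_group_size]
    if short:
        raise ValueError(
            f"terminal group(s) below min_group_size={min_group_size}: {short}"
        )
    xp = dict(xval_params or {})
    fixed_npca = xp.pop("n_pca", None)
    xp.setdefault("training_fraction", 0.9)
    xp.setdefault("reps", 10)

    lab_arr = np.asarray(labels)
    nodes: dict[str, KBNNode] = {}

    def node_samples(t: TopologyNode) -> np.ndarray:
        return np.isin(lab_arr, t.labels())

    def fit_node(nid: str, sel: np.ndarray, y: np.ndarray) -> DAPCModel:
        sub = gm.subset(samples=[s for s, m in zip(gm.sample_ids, sel) if m])
        if fixed_npca is not None:
            n_pca = fixed_npca
        else:
            rep = xval_select_npca(sub, y, seed=seed, **xp)
            n_pca = rep.chosen_n_pca
        return fit_dapc(sub, y, n_pca=n_pca)

    for t in topology.walk():
        if t.is_leaf:
            model = None
            tier2_id = None
            if t.is_double:
                tier2_id = f"{t.node_id}_tierII"
                sel = node_samples(t)
                y = lab_arr[sel]
                model2 = fit_node(tier2_id, sel, y)
                nodes[tier2_id] = KBNNode(
                    node_id=tier2_id, tier="II", model=model2,
                    child_ids={}, terminal_labels=list(t.terminal_labels),
                )
            nodes[t.node_id] = KBNNode(
                node_id=t.node_id, tier="I", model=None, child_ids={},
                terminal_labels=list(t.terminal_labels), tier2_id=tier2_id,
            )
        else:
            sel = node_samples(t)
            child_of = {}
            for c in t.children:
                for v in c.labels():
                    child_of[v] = c.node_id
            y = np.array([child_of[l] for l in lab_arr[sel]])
            model = fit_node(t.node_id, sel, y)
            nodes[t.node_id] = KBNNode(
                node_id=t.node_id, tier="I", model=model,
                child_ids={cls: cls for cls in model.classes},
                terminal_labels=[],
            )
    return KBN(
        topology=topology,
        nodes=nodes,
        panel_loci=list(gm.locus_ids),
        label_vocabulary=vocab,
    )


#: final label given to samples abstained on under ``min_posterior``
UNASSIGNED = "unassigned"


def predict_kbn(
    kbn: KBN,
    gm_unknown: GenotypeMatrix,
    max_missing: int | None = 96,
    min_posterior: float | None = None,
) -> tuple[list[AssignmentResult], list[tuple[str, int]]]:
    """Route unknown samples through the cascade to a final label.

    Samples with more than ``max_missing`` missing panel loci (absent loci
    plus missing cells) are rejected and reported separately.  At every
    node the sample goes to the argmax-posterior child; double terminals
    are resolved by their Tier II model.  Prediction is deterministic.
    With ``min_posterior`` set (off by default), routing abstains — final
    label :data:`UNASSIGNED` — the first time a node's best posterior
    falls below the threshold; useful for screening.
    """
    panel = kbn.panel_loci
    have = set(gm_unknown.locus_ids)
    shared = [l for l in panel if l in have]
    absent = len(panel) - len(shared)
    sub = gm_unknown.subset(loci=shared)

    results: list[AssignmentResult] = []
    rejected: list[tuple[str, int]] = []
    by_id = {t.node_id: t for t in kbn.topology.walk()}

    for i, sid in enumerate(sub.sample_ids):
        row = sub.values[i : i + 1]
        n_missing = absent + int((row == -1).sum())
        if max_missing is not None and n_missing > max_missing:
            rejected.append((sid, n_missing))
            continue
        one = GenotypeMatrix([sid], sub.locus_ids, row)
        node = kbn.topology
        path = [node.node_id]
        posts: list[np.ndarray] = []
        maxp: list[float] = []
        abstained = False
        while not node.is_leaf:
            knode = kbn.nodes[node.node_id]
            post, pred = predict_dapc(knode.model, one)
            posts.append(post[0])
            maxp.append(float(post[0].max()))
            if min_posterior is not None and maxp[-1] < min_posterior:
                abstained = True
                break
            node = by_id[knode.child_ids[pred[0]]]
            path.append(node.node_id)
        if abstained:
            final = UNASSIGNED
        else:
            knode = kbn.nodes[node.node_id]
            if knode.tier2_id is not None:
                resolver = kbn.nodes[knode.tier2_id]
                post, pred = predict_dapc(resolver.model, one)
                posts.append(post[0])
                maxp.append(float(post[0].max()))
                path.append(resolver.node_id)
                final = pred[0]
            else:
                final = knode.terminal_labels[0]
        results.append(
            AssignmentResult(
                sample_id=sid, path=path, posteriors=posts,
                max_posteriors=maxp, final_label=final, n_missing=n_missing,
            )
        )
    return results, rejected
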