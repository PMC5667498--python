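"""Distance-based phylogenetics: p-distance and Kimura-2-parameter distances
with pairwise deletion, Neighbor-Joining reconstruction, column-bootstrap
bipartition support, and Newick input/output (via dendropy).

The K2P distance distinguishes transition (P) and transversion (Q)
proportions: d = -1/2 ln((1-2P-Q) sqrt(1-2Q)); it is exact on additive
matrices in the sense that NJ then reconstructs the generating tree.  NJ ties
are broken by lexicographic label order so trees are reproducible across
platforms; negative NJ branch lengths are kept raw in a diagnostics list and
clamped to zero on Newick output.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import InputError, SaturationError
from .seqio import MultipleAlignment

# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _encode(s: str) -> np.ndarray:
    lut = np.full(128, 5, dtype=np.int8)
    for i, c in enumerate("ACGTN-"):
        lut[ord(c)] = i
    return lut[np.frombuffer(s.upper().encode(), dtype=np.uint8)]


def _pq(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    use = (a < 4) & (b < 4)
    n = int(use.sum())
    if n == 0:
        raise InputError("no usable sites after pairwise deletion")
    aa, bb = a[use], b[use]
    diff = aa != bb
    # A(0)/G(2) are even codes, C(1)/T(3) odd: transitions keep parity
    transitions = diff & ((aa % 2) == (bb % 2))
    P = float(transitions.sum()) / n
    Q = float(diff.sum() - transitions.sum()) / n
    return P, Q, n


def k2p_distance(gapped_a, gapped_b) -> float:
    """Kimura-2-parameter distance with pairwise deletion."""
    a = _encode(gapped_a.residues if hasattr(gapped_a, "residues") else str(gapped_a))
    b = _encode(gapped_b.residues if hasattr(gapped_b, "residues") else str(gapped_b))
    if a.size != b.size:
        raise InputError("rows must have equal (aligned) length")
    P, Q, _ = _pq(a, b)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated pair (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance_fraction(gapped_a, gapped_b) -> float:
    """Proportion of divergent sites (0..1 scale) with pairwise deletion."""
    a = _encode(gapped_a.residues if hasattr(gapped_a, "residues") else str(gapped_a))
    b = _encode(gapped_b.residues if hasattr(gapped_b, "residues") else str(gapped_b))
    if a.size != b.size:
        raise InputError("rows must have equal (aligned) length")
    use = (a < 4) & (b < 4)
    n = int(use.sum())
    if n == 0:
        raise InputError("no usable sites after pairwise deletion")
    return float(np.count_nonzero(a[use] != b[use])) / n


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with ordered taxa and zero diagonal."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise InputError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise InputError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise InputError("diagonal must be zero")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise InputError("distances must be finite and non-negative")
        self.values = v

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def distance_matrix(msa: MultipleAlignment, model: str = "p") -> DistanceMatrix:
    """All-pairs distances from an alignment (``model`` in {"p", "k2p"})."""
    mat = msa.to_matrix()
    n = len(msa.members)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            if model == "p":
                use = (a < 4) & (b < 4)
                s = int(use.sum())
                if s == 0:
                    raise InputError(f"no usable sites for pair {msa.ids[i]},{msa.ids[j]}")
                d = float(np.count_nonzero(a[use] != b[use])) / s
            elif model == "k2p":
                P, Q, _ = _pq(a, b)
                w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
                if w1 <= 0 or w2 <= 0:
                    raise SaturationError(
                        f"saturated pair {msa.ids[i]},{msa.ids[j]}"
                    )
                d = -0.5 * math.log(w1 * math.sqrt(w2))
            else:
                raise InputError(f"unknown model {model!r}")
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(msa.ids), out)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional bipartition supports."""

    tree: dendropy.Tree
    negative_branches: list[tuple[str, float]] = field(default_factory=list)
    n_boot: int = 0
    skipped_replicates: int = 0

    @property
    def taxa(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def path_length(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        tns = self.tree.taxon_namespace
        return pdm.distance(tns.get_taxon(a), tns.get_taxon(b))

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each named by the smaller side's leaves
        (ties by the side not containing the alphabetically first taxon)."""
        all_taxa = frozenset(self.taxa)
        first = min(all_taxa)
        out = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            other = all_taxa - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(side if first not in side else other)
        return out

    def support_for(self, side: frozenset[str]) -> int | None:
        all_taxa = frozenset(self.taxa)
        first = min(all_taxa)
        want = side if first not in side else all_taxa - side
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            s = frozenset(l.taxon.label for l in node.leaf_iter())
            s = s if first not in s else all_taxa - s
            if s == want:
                return None if node.label is None else int(node.label)
        return None

    def as_newick(self) -> str:
        """Newick string with supports as internal labels; negative branch
        lengths clamped to zero (raw values stay in ``negative_branches``)."""
        clone = self.tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                edge.length = 0.0
        return clone.as_string(schema="newick", suppress_rooting=True).strip()


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei Neighbor-Joining.

    At each step the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined, with ties broken by the lexicographically smallest pair of node
    labels (internal nodes carry the smallest leaf label beneath them).
    """
    n = len(dm.taxa)
    if n < 3:
        raise InputError("neighbor joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace(dm.taxa)
    nodes = []
    labels = []
    for t in dm.taxa:
        node = dendropy.Node(taxon=tns.get_taxon(t))
        nodes.append(node)
        labels.append(t)
    D = dm.values.copy()
    active = list(range(n))
    negative = []

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair_key < best[1]
                ):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        ni, nj = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = li
        nj.edge.length = lj
        for lbl, length in ((labels[i], li), (labels[j], lj)):
            if length < 0:
                negative.append((lbl, float(length)))
        # distances to the new node
        new_index = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_index, k] = D[k, new_index] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [new_index]

    # join the final three nodes at a central node
    i, j, k = active
    central = dendropy.Node()
    a = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    b = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    c = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, length in ((i, a), (j, b), (k, c)):
        central.add_child(nodes[idx])
        nodes[idx].edge.length = length
        if length < 0:
            negative.append((labels[idx], float(length)))
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=central)
    tree.is_rooted = False
    return PhyloTree(tree, negative_branches=negative)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    msa: MultipleAlignment,
    distance_kind: str = "p",
    n: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree with bipartition supports from ``n`` column bootstraps.

    Columns are resampled with replacement, the tree is rebuilt per replicate,
    and each internal edge of the original tree is annotated with the
    percentage of successful replicates containing the same bipartition.
    Replicates with a saturated pair are skipped (and counted)."""
    if len(msa.members) < 4:
        raise InputError("bootstrap support needs >= 4 members")
    base = neighbor_joining(distance_matrix(msa, distance_kind))
    mat = msa.to_matrix()
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in base.bipartitions()}
    ok = 0
    skipped = 0
    L = msa.length
    for _ in range(n):
        idx = rng.integers(0, L, size=L)
        sub = mat[:, idx]
        try:
            dmat = _distance_from_matrix(sub, msa.ids, distance_kind)
            rep = neighbor_joining(dmat)
        except (SaturationError, InputError):
            skipped += 1
            continue
        ok += 1
        rep_bps = rep.bipartitions()
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicate(s) skipped (saturation)")
    if ok == 0:
        raise SaturationError("every bootstrap replicate was degenerate")

    all_taxa = frozenset(base.taxa)
    first = min(all_taxa)
    for node in base.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = side if first not in side else all_taxa - side
        if key in counts:
            node.label = str(int(round(100.0 * counts[key] / ok)))
    base.n_boot = ok
    base.skipped_replicates = skipped
    return base


def _distance_from_matrix(mat: np.ndarray, ids: list[str], model: str) -> DistanceMatrix:
    n = mat.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            use = (a < 4) & (b < 4)
            s = int(use.sum())
            if s == 0:
                raise InputError("degenerate pair in replicate")
            if model == "p":
                d = float(np.count_nonzero(a[use] != b[use])) / s
            else:
                aa, bb = a[use], b[use]
                diff = aa != bb
                trans = diff & ((aa % 2) == (bb % 2))
                P = float(trans.sum()) / s
                Q = float(diff.sum() - trans.sum()) / s
                w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
                if w1 <= 0 or w2 <= 0:
                    raise SaturationError("saturated replicate pair")
                d = -0.5 * math.log(w1 * math.sqrt(w2))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(ids), out)


# ---------------------------------------------------------------------------
# Newick round-trip and cluster membership
# ---------------------------------------------------------------------------


def write_newick(tree: PhyloTree, path) -> str:
    text = tree.as_newick()
    with open(path, "w") as fh:
        fh.write(text + "\n")
    return text


def read_newick(path_or_text) -> PhyloTree:
    text = str(path_or_text)
    if "(" not in text:
        with open(text) as fh:
            text = fh.read()
    tree = dendropy.Tree.get(data=text, schema="newick")
    tree.is_rooted = False
    return PhyloTree(tree)


def cluster_membership(
    tree: PhyloTree,
    reference_labels: dict[str, set[str]],
    support_threshold: int = 70,
) -> dict[str, str]:
    """Assign query leaves to exemplar clusters via supported clades.

    Each query taxon is assigned to the exemplar set with which it forms a
    monophyletic group of support >= threshold (smallest such clade wins,
    and the clade's exemplars must all belong to one set); queries in no
    supported single-type clade stay ``"unassigned"``.
    """
    exemplars = {lbl: typ for typ, lbls in reference_labels.items() for lbl in lbls}
    if not set(exemplars) <= set(tree.taxa):
        raise InputError("exemplar leaves missing from the tree")
    queries = [t for t in tree.taxa if t not in exemplars]
    all_taxa = frozenset(tree.taxa)
    clades = []
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        support = 100 if node.label is None else int(node.label)
        if support < support_threshold:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        # an unrooted edge supports both sides of its bipartition
        clades.append(leaves)
        clades.append(all_taxa - leaves)
    out = {}
    for q in queries:
        assigned = "unassigned"
        best_size = None
        for leaves in clades:
            if q not in leaves:
                continue
            types = {exemplars[l] for l in leaves if l in exemplars}
            if len(types) != 1:
                continue
            if best_size is None or len(leaves) < best_size:
                best_size = len(leaves)
                assigned = next(iter(types))
        out[q] = assigned
    return out
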