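import math

import numpy as np
import pytest

from ervclock import phylo
from ervclock.errors import InputError, SaturationError
from ervclock.phylo import (
    DistanceMatrix,
    bootstrap_support,
    cluster_membership,
    distance_matrix,
    k2p_distance,
    neighbor_joining,
    read_newick,
    write_newick,
)
from ervclock.seqio import GappedSequence, MultipleAlignment
from ervclock.simulate import simulate_msa_from_consensus


def msa(**rows):
    return MultipleAlignment([GappedSequence(k, v) for k, v in rows.items()])


# --- K2P ----------------------------------------------------------------------


def seq_pair_with(P: float, Q: float, n: int = 200):
    """Build a pair realising exact transition/transversion proportions."""
    n_p, n_q = round(P * n), round(Q * n)
    a = "A" * n
    b = "G" * n_p + "C" * n_q + "A" * (n - n_p - n_q)
    return a, b


def test_k2p_identity_is_zero():
    assert k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0


@pytest.mark.parametrize("P,Q", [(0.1, 0.05), (0.0, 0.25), (0.2, 0.1)])
def test_k2p_matches_closed_form(P, Q):
    a, b = seq_pair_with(P, Q)
    expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
    assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-9)


def test_k2p_saturation_raises():
    a, b = seq_pair_with(0.45, 0.2)
    with pytest.raises(SaturationError):
        k2p_distance(a, b)


def test_k2p_dominates_p_distance(rng):
    """Jensen-type inequality: the K2P correction never falls below the raw
    mismatch proportion."""
    for _ in range(50):
        n = int(rng.integers(50, 300))
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = "".join(
            c if rng.random() > 0.15 else rng.choice(list("ACGT")) for c in a
        )
        try:
            d = k2p_distance(a, b)
        except SaturationError:
            continue
        assert d >= phylo.p_distance_fraction(a, b) - 1e-12


# --- Neighbor Joining -----------------------------------------------------------


def test_three_taxon_pendant_lengths():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], float))
    tree = neighbor_joining(dm)
    assert tree.path_length("A", "B") == pytest.approx(2.0)
    assert tree.path_length("A", "C") == pytest.approx(4.0)
    assert tree.path_length("B", "C") == pytest.approx(6.0)


def tree_distances(edges: dict, taxa: list) -> np.ndarray:
    """Path lengths on an explicitly listed tree (test-side oracle)."""
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in edges.items():
        g.add_edge(u, v, weight=w)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = nx.shortest_path_length(
                g, taxa[i], taxa[j], weight="weight"
            )
    return out


FOUR_TAXON = {
    ("A", "u"): 1.0,
    ("B", "u"): 2.0,
    ("u", "v"): 3.0,
    ("C", "v"): 4.0,
    ("D", "v"): 5.0,
}

SIX_TAXON = {
    ("A", "u"): 1.0,
    ("B", "u"): 1.0,
    ("u", "v"): 2.0,
    ("C", "v"): 3.0,
    ("v", "w"): 1.5,
    ("D", "w"): 2.5,
    ("w", "x"): 1.0,
    ("E", "x"): 0.5,
    ("F", "x"): 4.0,
}


@pytest.mark.parametrize(
    "edges,taxa,split",
    [
        (FOUR_TAXON, list("ABCD"), frozenset({"C", "D"})),
        (SIX_TAXON, list("ABCDEF"), frozenset({"E", "F"})),
    ],
)
def test_nj_recovers_additive_trees(edges, taxa, split):
    dm = DistanceMatrix(taxa, tree_distances(edges, taxa))
    tree = neighbor_joining(dm)
    assert split in tree.bipartitions() or (frozenset(taxa) - split) in tree.bipartitions()
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            assert tree.path_length(a, b) == pytest.approx(
                dm.values[taxa.index(a), taxa.index(b)], abs=1e-9
            )


def test_nj_four_taxon_against_topology_enumeration():
    """Brute-force oracle: of the three unrooted 4-taxon topologies, NJ picks
    the one whose split satisfies the four-point condition."""
    taxa = list("ABCD")
    D = tree_distances(FOUR_TAXON, taxa)
    sums = {
        frozenset({"A", "B"}): D[0, 1] + D[2, 3],
        frozenset({"A", "C"}): D[0, 2] + D[1, 3],
        frozenset({"A", "D"}): D[0, 3] + D[1, 2],
    }
    best_pair = min(sums, key=sums.get)  # split pairing with minimal sum
    tree = neighbor_joining(DistanceMatrix(taxa, D))
    bps = tree.bipartitions()
    side = next(iter(bps))
    assert best_pair == side or best_pair == frozenset(taxa) - side


def test_nj_invariant_to_taxon_order():
    taxa = list("ABCDEF")
    D = tree_distances(SIX_TAXON, taxa)
    t1 = neighbor_joining(DistanceMatrix(taxa, D))
    perm = [3, 0, 5, 2, 4, 1]
    taxa2 = [taxa[i] for i in perm]
    D2 = D[np.ix_(perm, perm)]
    t2 = neighbor_joining(DistanceMatrix(taxa2, D2))
    assert t1.bipartitions() == t2.bipartitions()
    for a in taxa:
        for b in taxa:
            if a < b:
                assert t1.path_length(a, b) == pytest.approx(t2.path_length(a, b))


def test_nj_input_validation():
    with pytest.raises(InputError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))  # asymmetric
    with pytest.raises(InputError):
        DistanceMatrix(["a", "b"], np.array([[0, -1], [-1, 0]], float))
    with pytest.raises(InputError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


# --- bootstrap -------------------------------------------------------------------


def planted_two_clade_msa(seed=4, within=0.01, between=0.20, n_per_clade=4):
    from ervclock.simulate import default_template

    base = default_template().sequence[:600]
    msa_a, _ = simulate_msa_from_consensus(base, [between], seed=seed)
    other = msa_a.members[0].residues
    clade1, _ = simulate_msa_from_consensus(base, [within] * n_per_clade, seed=seed + 1)
    clade2, _ = simulate_msa_from_consensus(other, [within] * n_per_clade, seed=seed + 2)
    members = [GappedSequence(f"I{i}", m.residues) for i, m in enumerate(clade1.members)]
    members += [GappedSequence(f"II{i}", m.residues) for i, m in enumerate(clade2.members)]
    return MultipleAlignment(members)


def test_bootstrap_single_replicate_supports_are_binary():
    m = planted_two_clade_msa()
    tree = bootstrap_support(m, "p", n=1, seed=3)
    supports = [
        int(n.label)
        for n in tree.tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None and n.label is not None
    ]
    assert supports and set(supports) <= {0, 100}


def test_bootstrap_deterministic_under_seed():
    m = planted_two_clade_msa()
    t1 = bootstrap_support(m, "p", n=30, seed=11)
    t2 = bootstrap_support(m, "p", n=30, seed=11)
    assert t1.as_newick() == t2.as_newick()


def test_separated_clades_get_high_support():
    m = planted_two_clade_msa()
    tree = bootstrap_support(m, "k2p", n=200, seed=5)
    split = frozenset(l for l in tree.taxa if l.startswith("II"))
    support = tree.support_for(split)
    assert support is not None and support >= 95


# --- Newick and clusters ----------------------------------------------------------


def test_newick_round_trip(tmp_path):
    m = planted_two_clade_msa()
    tree = bootstrap_support(m, "p", n=50, seed=6)
    path = tmp_path / "t.nwk"
    write_newick(tree, path)
    back = read_newick(path)
    assert back.bipartitions() == tree.bipartitions()
    for a in tree.taxa:
        for b in tree.taxa:
            if a < b:
                assert back.path_length(a, b) == pytest.approx(
                    max(0.0, tree.path_length(a, b)), abs=1e-9
                )
    split = frozenset(l for l in tree.taxa if l.startswith("II"))
    assert back.support_for(split) == tree.support_for(split)


def test_cluster_membership_planted(rng):
    m = planted_two_clade_msa()
    tree = bootstrap_support(m, "p", n=100, seed=7)
    assignments = cluster_membership(
        tree, {"I": {"I0", "I1"}, "II": {"II0", "II1"}}, support_threshold=70
    )
    assert assignments["I2"] == "I" and assignments["I3"] == "I"
    assert assignments["II2"] == "II" and assignments["II3"] == "II"


def test_cluster_membership_requires_exemplars():
    m = planted_two_clade_msa()
    tree = neighbor_joining(distance_matrix(m, "p"))
    with pytest.raises(InputError):
        cluster_membership(tree, {"I": {"missing"}})
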