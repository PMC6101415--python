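"""K2P distances against the closed form, NJ against brute-force topology
oracles on additive matrices, bootstrap reproducibility, and monophyly."""

import itertools
import math

import numpy as np
import pytest

from barcodiag.errors import (
    ContractError,
    MissingOverlapError,
    SaturationError,
    UnknownSpeciesError,
)
from barcodiag.phylo import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    distance_matrix,
    is_monophyletic,
    k2p_distance,
    nj_tree,
    pairwise_diff,
    parse_newick,
)
from barcodiag.simulate import FixtureParams, simulate_panel

from conftest import make_alignment


# ---------------------------------------------------------------------------
# K2P


def test_k2p_zero_divergence():
    assert k2p_distance((0.0, 0.0)) == 0.0


def test_k2p_closed_form_value():
    assert k2p_distance((0.1, 0.05)) == pytest.approx(0.170181, abs=1e-6)


def test_k2p_saturation():
    with pytest.raises(SaturationError):
        k2p_distance((0.5, 0.0))
    with pytest.raises(SaturationError):
        k2p_distance((0.0, 0.5))


def test_k2p_grid_matches_closed_form_and_dominates_p_plus_q():
    for p in np.linspace(0, 0.35, 8):
        for q in np.linspace(0, 0.25, 6):
            if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
                continue
            d = k2p_distance((p, q))
            want = -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)
            assert d == pytest.approx(want, abs=1e-12)
            assert d >= p + q - 1e-12
            if p == 0 and q == 0:
                assert d == 0.0


def test_k2p_strictly_increasing_in_each_argument():
    assert k2p_distance((0.11, 0.05)) > k2p_distance((0.10, 0.05))
    assert k2p_distance((0.10, 0.06)) > k2p_distance((0.10, 0.05))


def test_pairwise_diff_counts_and_pairwise_deletion():
    d = pairwise_diff("AAGCT-", "AGGCAN", ("x", "y"))
    # comparable columns: 1,2,3,4,5 minus gap col6 and N col5 -> cols 1-4... wait
    # residues: A/A same, A/G transition, G/G same, C/C same, T/A transversion?,
    # last col gap/N excluded; col5 T vs A = transversion
    assert d.sites_compared == 5
    assert d.p_transition == pytest.approx(1 / 5)
    assert d.q_transversion == pytest.approx(1 / 5)


def test_distance_matrix_identical_and_single_transition():
    aln = make_alignment({"a": "AAAA", "b": "AAAA"})
    assert distance_matrix(aln).get("a", "b") == 0.0
    aln2 = make_alignment({"a": "AAAA", "b": "GAAA"})
    # P = 0.25, Q = 0 -> d = -0.5 ln(0.5) = 0.346574
    assert distance_matrix(aln2).get("a", "b") == pytest.approx(0.346574, abs=1e-6)


def test_distance_matrix_row_reordering_permutes_values():
    rows = {"a": "AAGCTT", "b": "AGGCTA", "c": "AAGATT"}
    d1 = distance_matrix(make_alignment(rows))
    d2 = distance_matrix(make_alignment(dict(reversed(rows.items()))))
    for x, y in itertools.combinations(rows, 2):
        assert d1.get(x, y) == pytest.approx(d2.get(x, y))


def test_distance_matrix_missing_overlap_names_pair():
    aln = make_alignment({"a": "AC--", "b": "--GT"})
    with pytest.raises(MissingOverlapError, match="a.*b"):
        distance_matrix(aln)


# ---------------------------------------------------------------------------
# NJ with brute-force oracles


def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(
        taxa=["A", "B", "C"],
        d=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
    )
    tree = nj_tree(dm)
    lengths = {c.name: c.length for c in tree.root.children}
    assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_requires_three_taxa():
    with pytest.raises(ContractError):
        nj_tree(DistanceMatrix(taxa=["A", "B"], d=np.array([[0, 1.0], [1.0, 0]])))


def _random_additive_tree(n_leaves: int, rng):
    """Random unrooted binary tree as an edge list; independent of any
    package tree code.  Returns (edges {(u,v): length}, leaves {node: name})."""
    edges = {}
    center = 1000
    for leaf in range(3):
        edges[(leaf, center)] = rng.uniform(0.05, 0.6)
    next_internal = center + 1
    for leaf in range(3, n_leaves):
        u, v = list(edges)[rng.integers(0, len(edges))]
        length = edges.pop((u, v))
        mid = next_internal
        next_internal += 1
        split = rng.uniform(0.2, 0.8)
        edges[(u, mid)] = length * split
        edges[(mid, v)] = length * (1 - split)
        edges[(leaf, mid)] = rng.uniform(0.05, 0.6)
    leaves = {i: f"t{i}" for i in range(n_leaves)}
    return edges, leaves


def _path_distances(edges, leaves):
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    dist = {}
    for src in leaves:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen[nxt] = seen[node] + w
                    stack.append(nxt)
        for dst in leaves:
            dist[(leaves[src], leaves[dst])] = seen[dst]
    return dist


def _true_splits(edges, leaves):
    """Nontrivial bipartitions of the generating tree, by edge removal."""
    adj = {}
    for (u, v) in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    names = frozenset(leaves.values())
    ref = min(names)
    splits = set()
    for (u, v) in edges:
        # leaves reachable from u with node v (hence the edge u-v) removed
        seen = {u}
        stack = [u]
        while stack:
            node = stack.pop()
            for nxt in adj[node]:
                if nxt != v and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(leaves[x] for x in seen if x in leaves)
        side = names - side if ref in side else frozenset(side)
        if 2 <= len(side) <= len(names) - 2:
            splits.add(side)
    return splits


def _ls_best_topology_4taxa(taxa, dist):
    """Brute force: fit branch lengths of each of the 3 unrooted 4-taxon
    topologies by least squares; return the split of the best fit."""
    a, b, c, d = taxa
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    best = None
    for (x, y), (u, v) in pairings:
        # unknowns: ex, ey, eu, ev, em (internal)
        rows, rhs = [], []
        order = [x, y, u, v]
        idx = {t: i for i, t in enumerate(order)}

        def coeff(p, q):
            row = [0.0] * 5
            row[idx[p]] = 1
            row[idx[q]] = 1
            same_side = {p, q} in ({x, y}, {u, v})
            if not same_side:
                row[4] = 1
            return row

        for p, q in itertools.combinations(order, 2):
            rows.append(coeff(p, q))
            rhs.append(dist[(p, q)])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
        residual = float(res[0]) if len(res) else 0.0
        key = (residual, tuple(sorted((x, y))))
        if best is None or key < best[0]:
            best = (key, frozenset((x, y)))
    return best[1]


@pytest.mark.parametrize("seed", range(30))
def test_nj_recovers_generating_4taxon_topology(seed):
    rng = np.random.default_rng(seed)
    edges, leaves = _random_additive_tree(4, rng)
    dist = _path_distances(edges, leaves)
    taxa = sorted(leaves.values())
    n = len(taxa)
    D = np.array([[dist[(x, y)] if x != y else 0.0 for y in taxa] for x in taxa])
    tree = nj_tree(DistanceMatrix(taxa=taxa, d=D))
    true = _true_splits(edges, leaves)
    assert tree.splits(nontrivial_only=True) == true
    # ... and the independent least-squares enumeration agrees
    ls_split = _ls_best_topology_4taxa(taxa, dist)
    names = frozenset(taxa)
    ref = min(names)
    ls_split = names - ls_split if ref in ls_split else ls_split
    assert ls_split in true


@pytest.mark.parametrize("seed", range(50))
def test_nj_recovers_generating_5taxon_topology_and_path_lengths(seed):
    rng = np.random.default_rng(1000 + seed)
    edges, leaves = _random_additive_tree(5, rng)
    dist = _path_distances(edges, leaves)
    taxa = sorted(leaves.values())
    D = np.array([[dist[(x, y)] if x != y else 0.0 for y in taxa] for x in taxa])
    tree = nj_tree(DistanceMatrix(taxa=taxa, d=D))
    assert tree.splits(nontrivial_only=True) == _true_splits(edges, leaves)
    # additive input -> NJ reproduces the path lengths exactly
    tree_dist = _tree_path_distances(tree)
    for x, y in itertools.combinations(taxa, 2):
        assert tree_dist[(x, y)] == pytest.approx(dist[(x, y)], abs=1e-9)


def _tree_path_distances(tree: PhyloTree):
    edges = {}
    counter = itertools.count()

    def visit(node, my_id):
        for child in node.children:
            cid = child.name if child.is_leaf else f"i{next(counter)}"
            edges[(my_id, cid)] = child.length or 0.0
            visit(child, cid)

    visit(tree.root, "root")
    leaves = {t: t for t in tree.taxa}
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    out = {}
    for src in leaves:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            nd = stack.pop()
            for nxt, w in adj[nd]:
                if nxt not in seen:
                    seen[nxt] = seen[nd] + w
                    stack.append(nxt)
        for dst in leaves:
            out[(src, dst)] = seen[dst]
    return out


def test_nj_topology_agrees_with_skbio_on_random_matrices():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(17)
    for _ in range(5):
        edges, leaves = _random_additive_tree(6, rng)
        dist = _path_distances(edges, leaves)
        taxa = sorted(leaves.values())
        D = np.array([[dist[(x, y)] if x != y else 0.0 for y in taxa] for x in taxa])
        D = (D + D.T) / 2  # BFS summation order leaves ~1e-16 asymmetry
        ours = nj_tree(DistanceMatrix(taxa=taxa, d=D)).splits(nontrivial_only=True)
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids=taxa))
        theirs = parse_newick(str(sk).strip()).splits(nontrivial_only=True)
        assert ours == theirs


# ---------------------------------------------------------------------------
# bootstrap


def _two_clade_alignment(seed=0):
    params = FixtureParams(
        n_species=6, per_species=1, locus_len=300, seed=seed, interspecies_rate=0.04
    )
    _, aln, _ = simulate_panel(params)
    # manufacture two deeply divergent clades: flip a disjoint 60-column block
    # to a fixed divergent state in rows 0-2
    from barcodiag.records import Alignment, SeqRecord

    rows = []
    for i, r in enumerate(aln.rows):
        residues = r.residues
        if i < 3:
            residues = residues[:200] + "G" * 60 + residues[260:]
        else:
            residues = residues[:200] + "T" * 60 + residues[260:]
        rows.append(SeqRecord(r.id, residues, r.species))
    return Alignment(rows), {r.id for r in rows[:3]}


def test_bootstrap_same_seed_reproducible_and_deep_clade_supported():
    aln, clade = _two_clade_alignment()
    t1 = bootstrap_support(aln, replicates=100, seed=7)
    t2 = bootstrap_support(aln, replicates=100, seed=7)
    assert t1.newick() == t2.newick()

    def supports(tree):
        out = {}

        def visit(node):
            for c in node.children:
                if not c.is_leaf:
                    out[frozenset(c.leaves())] = c.support
                visit(c)

        visit(tree.root)
        return out

    sup = supports(t1)
    all_taxa = frozenset(aln.ids)
    hit = [v for k, v in sup.items() if k in (clade, all_taxa - clade)]
    assert hit and hit[0] == 100


def test_bootstrap_single_replicate_supports_are_extreme():
    aln, _ = _two_clade_alignment(seed=3)
    tree = bootstrap_support(aln, replicates=1, seed=1)

    vals = []

    def visit(node):
        for c in node.children:
            if not c.is_leaf and c.support is not None:
                vals.append(c.support)
            visit(c)

    visit(tree.root)
    assert vals and set(vals) <= {0, 100}


# ---------------------------------------------------------------------------
# monophyly


def _tree(newick: str) -> PhyloTree:
    return parse_newick(newick)


def test_monophyly_simple_cases():
    t = _tree("((A:1,B:1):1,(C:1,D:1):1);")
    assert is_monophyletic(t, {"A", "B"}, {"C", "D"})
    assert not is_monophyletic(t, {"A", "C"}, {"B", "D"})
    assert is_monophyletic(t, {"A"})  # a single leaf is trivially a clade


def test_monophyly_unknown_taxon_and_overlap():
    t = _tree("((A:1,B:1):1,C:1);")
    with pytest.raises(UnknownSpeciesError):
        is_monophyletic(t, {"A", "Z"})
    with pytest.raises(ContractError):
        is_monophyletic(t, {"A"}, {"A", "B"})


@pytest.mark.parametrize("seed", range(10))
def test_monophyly_agrees_with_exhaustive_split_enumeration(seed):
    rng = np.random.default_rng(seed)
    edges, leaves = _random_additive_tree(8, rng)
    dist = _path_distances(edges, leaves)
    taxa = sorted(leaves.values())
    D = np.array([[dist[(x, y)] if x != y else 0.0 for y in taxa] for x in taxa])
    tree = nj_tree(DistanceMatrix(taxa=taxa, d=D))
    true = _true_splits(edges, leaves)
    names = frozenset(taxa)
    ref = min(names)
    for r in range(2, 5):
        for group in itertools.combinations(taxa, r):
            g = frozenset(group)
            norm = names - g if ref in g else g
            expected = (
                norm in true
                or len(norm) <= 1
                or len(norm) >= len(names) - 1
            )
            assert is_monophyletic(tree, set(group)) == expected
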