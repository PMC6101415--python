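"""Kimura two-parameter distances, neighbor-joining and bootstrap support.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T, proportion P) from transversions
(all other base pairs, proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Columns where either row is a gap or an ambiguity code are deleted pairwise
(not list-wise), so indel-rich spacer alignments keep most of their signal.
Trees are built by Saitou-Nei neighbor-joining with lexicographic
tie-breaking on the Q-criterion, which makes every run reproducible;
nonparametric bootstrap resamples alignment columns with replacement using
a seeded NumPy generator and reports, for each internal bipartition of the
full-data tree, the percentage of replicate trees that contain it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContractError,
    FormatError,
    MissingOverlapError,
    SaturationError,
    UnknownSpeciesError,
)
from .records import Alignment

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_PLAIN = frozenset("ACGT")


@dataclass(frozen=True)
class PairwiseDiff:
    """Transition/transversion proportions for one taxon pair."""

    taxa: tuple[str, str]
    sites_compared: int
    p_transition: float
    q_transversion: float


def pairwise_diff(row_a, row_b, ids: tuple[str, str] = ("a", "b")) -> PairwiseDiff:
    """Count transitions/transversions over pairwise-complete columns."""
    n = ts = tv = 0
    for x, y in zip(row_a, row_b):
        if x not in _PLAIN or y not in _PLAIN:
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise MissingOverlapError(f"no comparable sites between {ids[0]} and {ids[1]}")
    return PairwiseDiff(taxa=ids, sites_compared=n, p_transition=ts / n, q_transversion=tv / n)


def k2p_distance(diff: PairwiseDiff | tuple[float, float]) -> float:
    """Kimura two-parameter distance from (P, Q).

    Raises :class:`SaturationError` when 1-2P-Q <= 0 or 1-2Q <= 0 (the
    correction diverges: the sequences are saturated).
    """
    if isinstance(diff, PairwiseDiff):
        p, q = diff.p_transition, diff.q_transversion
    else:
        p, q = diff
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P distance undefined for P={p}, Q={q}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric distances with zero diagonal, indexed by taxon id."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ContractError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0.0):
            raise ContractError("distance matrix must be symmetric with zero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


def _pair_codes(alignment: Alignment) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Per-column comparison codes for every taxon pair.

    code 0 = identical, 1 = transition, 2 = transversion, 3 = excluded
    (gap/ambiguity in either row).  Shape (n_pairs, L).
    """
    rows = [np.frombuffer(r.residues.encode(), dtype=np.uint8) for r in alignment.rows]
    plain = np.zeros(128, dtype=bool)
    for b in "ACGT":
        plain[ord(b)] = True
    purine = np.zeros(128, dtype=bool)
    for b in "AG":
        purine[ord(b)] = True
    pairs = [
        (i, j) for i in range(len(rows)) for j in range(i + 1, len(rows))
    ]
    codes = np.empty((len(pairs), alignment.length), dtype=np.int8)
    for k, (i, j) in enumerate(pairs):
        a, b = rows[i], rows[j]
        ok = plain[a] & plain[b]
        same = a == b
        ts = purine[a] == purine[b]  # differing but same purine/pyrimidine class
        code = np.where(~ok, 3, np.where(same, 0, np.where(ts, 1, 2)))
        codes[k] = code
    return pairs, codes


def _matrix_from_counts(
    taxa: list[str], pairs: list[tuple[int, int]], counts: np.ndarray
) -> DistanceMatrix:
    """counts[k] = (#identical, #ts, #tv) for pair k."""
    n = len(taxa)
    d = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        same, ts, tv = counts[k]
        m = same + ts + tv
        if m == 0:
            raise MissingOverlapError(
                f"no comparable sites between {taxa[i]} and {taxa[j]}"
            )
        dist = k2p_distance((ts / m, tv / m))
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=taxa, d=d)


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All pairwise K2P distances with pairwise deletion."""
    if len(alignment) < 2:
        raise ContractError("need >= 2 rows")
    pairs, codes = _pair_codes(alignment)
    counts = np.stack([(codes == c).sum(axis=1) for c in (0, 1, 2)], axis=1)
    return _matrix_from_counts(alignment.ids, pairs, counts)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None  # branch length to parent
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name] if self.name else []
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree (rooted representation at a trivalent basal node)."""

    root: TreeNode

    @property
    def taxa(self) -> list[str]:
        return self.root.leaves()

    def splits(self, nontrivial_only: bool = False) -> set[frozenset[str]]:
        """Edge bipartitions, each as the leaf set on the child side,
        normalised to the side not containing the reference taxon."""
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out: set[frozenset[str]] = set()

        def visit(node: TreeNode):
            for child in node.children:
                below = frozenset(child.leaves())
                side = all_taxa - below if ref in below else below
                if not nontrivial_only or 2 <= len(side) <= len(all_taxa) - 2:
                    out.add(side)
                visit(child)

        visit(self.root)
        return out

    def newick(self, *, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = f"({inner})" + ("" if node.support is None else str(node.support))
            if node.length is not None:
                label += f":{node.length:.{decimals}g}"
            return label

        return fmt(self.root) + ";"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining, deterministic.

    The pair minimising the Q-criterion is joined at each step, ties broken
    lexicographically on the smallest leaf label of each cluster; negative
    branch lengths are clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ContractError("neighbor-joining needs >= 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    reps = [t for t in dm.taxa]  # smallest leaf label under each active node
    D = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best_key = None
        best_pair = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                a, b = sorted((reps[i], reps[j]))
                key = (q, a, b)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        i, j = best_pair
        vi = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        vi, vj = max(vi, 0.0) + 0.0, max(vj, 0.0) + 0.0  # +0.0 kills -0.0
        nodes[i].length, nodes[j].length = vi, vj
        new = TreeNode(children=[nodes[i], nodes[j]])
        # grow matrix by one row/col for the new node
        m = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[m, k] = D[k, m] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [m]

    a, b, c = active
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, v in zip((a, b, c), (va, vb, vc)):
        nodes[idx].length = max(v, 0.0) + 0.0
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


def bootstrap_support(
    alignment: Alignment, replicates: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree on the full data, internal edges annotated with bootstrap %.

    Columns are resampled with replacement ``replicates`` times with
    ``numpy.random.default_rng(seed)`` (PCG64), so runs are reproducible
    across platforms.  Replicates in which a distance is undefined
    (saturation or empty overlap) are dropped from the denominator.
    """
    if replicates < 1:
        raise ContractError("replicates must be >= 1")
    pairs, codes = _pair_codes(alignment)
    taxa = alignment.ids
    counts = np.stack([(codes == c).sum(axis=1) for c in (0, 1, 2)], axis=1)
    tree = nj_tree(_matrix_from_counts(taxa, pairs, counts))
    targets = tree.splits(nontrivial_only=True)
    hits = {s: 0 for s in targets}
    rng = np.random.default_rng(seed)
    L = alignment.length
    ok = 0
    onehot = np.stack([(codes == c) for c in (0, 1, 2)], axis=0)  # (3, P, L)
    for _ in range(replicates):
        idx = rng.integers(0, L, size=L)
        cnt = onehot[:, :, idx].sum(axis=2).T  # (P, 3)
        try:
            rep_tree = nj_tree(_matrix_from_counts(taxa, pairs, cnt))
        except (SaturationError, MissingOverlapError):
            continue
        ok += 1
        rep_splits = rep_tree.splits(nontrivial_only=True)
        for s in targets:
            if s in rep_splits:
                hits[s] += 1
    denom = max(ok, 1)
    support = {s: round(100.0 * hits[s] / denom) for s in targets}

    all_taxa = frozenset(taxa)
    ref = min(all_taxa)

    def annotate(node: TreeNode):
        for child in node.children:
            if not child.is_leaf:
                below = frozenset(child.leaves())
                side = all_taxa - below if ref in below else below
                if side in support:
                    child.support = support[side]
            annotate(child)

    annotate(tree.root)
    return tree


def is_monophyletic(
    tree: PhyloTree, group: set[str], outgroup: set[str] | None = None
) -> bool:
    """True iff some edge separates exactly ``group`` from all other taxa."""
    taxa = set(tree.taxa)
    group = set(group)
    outgroup = set(outgroup or ())
    unknown = (group | outgroup) - taxa
    if unknown:
        raise UnknownSpeciesError(f"taxa not in tree: {sorted(unknown)}")
    if group & outgroup:
        raise ContractError("group and outgroup overlap")
    if not group:
        raise ContractError("empty group")
    if group == taxa:
        return True
    target = frozenset(group)
    all_taxa = frozenset(taxa)
    return target in tree.splits() or (all_taxa - target) in tree.splits()


# ---------------------------------------------------------------------------
# Newick I/O

_TOKEN = re.compile(r"\(|\)|,|;|[^(),;:]+|:")


def write_newick(tree: PhyloTree, path) -> None:
    """Write standard Newick (branch lengths; integer supports as internal
    node labels), terminated by a newline."""
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string with optional branch lengths and integer
    internal-node support labels."""
    s = text.strip()
    if not s.endswith(";"):
        raise FormatError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_clade() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_clade())
                if pos >= len(s):
                    raise FormatError("unbalanced parentheses in Newick")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise FormatError(f"unexpected character {s[pos]!r} in Newick")
        # label
        m = re.match(r"[^(),:;]+", s[pos:])
        if m:
            label = m.group(0)
            pos += len(label)
            if node.children:
                try:
                    node.support = int(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[-+0-9.eE]+", s[pos:])
            if not m:
                raise FormatError("missing branch length after ':'")
            node.length = float(m.group(0))
            pos += len(m.group(0))
        return node

    root = parse_clade()
    if pos != len(s):
        raise FormatError(f"trailing characters in Newick: {s[pos:]!r}")
    return PhyloTree(root=root)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())
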