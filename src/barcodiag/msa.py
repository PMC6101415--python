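"""Desk-scale multiple alignment for barcode panels.

Global pairwise alignment with affine gaps (Gotoh three-state DP), and a
progressive multiple aligner on top of it: UPGMA guide tree from pairwise
p-distances, profile-profile merge through column consensus strings, and the
classic "once a gap, always a gap" rule.  It targets panels of tens of
records and loci up to a few kb — enough for barcode loci — and makes no
attempt to reproduce any particular external aligner column-for-column;
externally produced alignments are always accepted as input instead.

A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ContractError, ParameterError
from .records import GAP, Alignment, SeqRecord, SpeciesPanel


@dataclass(frozen=True)
class AlignParams:
    """Scoring for global DNA alignment; gap penalties are non-positive."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ParameterError("require gap_open <= gap_extend <= 0")


_NEG = -1e30


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, go, ge):  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            x = M[i - 1, j] + go
            if X[i - 1, j] + ge > x:
                x = X[i - 1, j] + ge
            if Y[i - 1, j] + go > x:
                x = Y[i - 1, j] + go
            X[i, j] = x
            y = M[i, j - 1] + go
            if X[i, j - 1] + go > y:
                y = X[i, j - 1] + go
            if Y[i, j - 1] + ge > y:
                y = Y[i, j - 1] + ge
            Y[i, j] = y
    return M, X, Y


@njit(cache=True)
def _gotoh_traceback(a, b, M, X, Y, match, mismatch, go, ge):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    # state: 0=M, 1=X, 2=Y; prefer M, then X, then Y on ties (deterministic)
    i, j = n, m
    if M[i, j] >= X[i, j] and M[i, j] >= Y[i, j]:
        state = 0
    elif X[i, j] >= Y[i, j]:
        state = 1
    else:
        state = 2
    ops = np.empty(n + m, dtype=np.int8)  # 0 diag, 1 up (gap in b), 2 left
    k = 0
    while i > 0 or j > 0:
        if state == 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = M[i, j] - s
            ops[k] = 0
            k += 1
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - prev) < 1e-9:
                state = 0
            elif abs(X[i, j] - prev) < 1e-9:
                state = 1
            else:
                state = 2
        elif state == 1:
            cur = X[i, j]
            ops[k] = 1
            k += 1
            if abs(M[i - 1, j] + go - cur) < 1e-9:
                state = 0
            elif abs(X[i - 1, j] + ge - cur) < 1e-9:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            cur = Y[i, j]
            ops[k] = 2
            k += 1
            if abs(M[i, j - 1] + go - cur) < 1e-9:
                state = 0
            elif abs(X[i, j - 1] + go - cur) < 1e-9:
                state = 1
            else:
                state = 2
            j -= 1
    return ops[:k]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _align_strings(
    a: str, b: str, params: AlignParams
) -> tuple[str, str, float]:
    ea, eb = _encode(a), _encode(b)
    M, X, Y = _gotoh_fill(
        ea, eb, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    n, m = len(a), len(b)
    score = max(M[n, m], X[n, m], Y[n, m])
    ops = _gotoh_traceback(
        ea, eb, M, X, Y, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    out_a: list[str] = []
    out_b: list[str] = []
    i = j = 0
    for op in ops[::-1]:
        if op == 0:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif op == 1:
            out_a.append(a[i])
            out_b.append(GAP)
            i += 1
        else:
            out_a.append(GAP)
            out_b.append(b[j])
            j += 1
    return "".join(out_a), "".join(out_b), float(score)


def pairwise_align(
    a: SeqRecord, b: SeqRecord, params: AlignParams | None = None
) -> tuple[SeqRecord, SeqRecord, float]:
    """Optimal global alignment of two records under affine gap scoring.

    Returns the two aligned records (equal length, '-' for gaps) and the
    optimal score.  De-gapping either output recovers its input exactly.
    """
    params = params or AlignParams()
    if not a.residues or not b.residues:
        raise ContractError("pairwise_align requires non-empty sequences")
    row_a, row_b, score = _align_strings(a.residues, b.residues, params)
    return (
        SeqRecord(a.id, row_a, a.species, a.locus),
        SeqRecord(b.id, row_b, b.species, b.locus),
        score,
    )


def _p_distance(row_a: str, row_b: str) -> float:
    diffs = sum(1 for x, y in zip(row_a, row_b) if x != y)
    return diffs / len(row_a) if row_a else 0.0


def _consensus_string(rows: list[str]) -> str:
    """Majority non-gap base per column; all-gap columns become 'N'.

    Ties break to the lexicographically smallest base so merges are
    deterministic.
    """
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            out.append("N")
        else:
            best = max(sorted(counts), key=lambda ch: counts[ch])
            out.append(best)
    return "".join(out)


def _merge_profiles(
    prof_a: list[SeqRecord], prof_b: list[SeqRecord], params: AlignParams
) -> list[SeqRecord]:
    cons_a = _consensus_string([r.residues for r in prof_a])
    cons_b = _consensus_string([r.residues for r in prof_b])
    aln_a, aln_b, _ = _align_strings(cons_a, cons_b, params)

    def expand(rows: list[SeqRecord], aligned_consensus: str) -> list[SeqRecord]:
        out = []
        for r in rows:
            residues = []
            k = 0
            for ch in aligned_consensus:
                if ch == GAP:
                    residues.append(GAP)  # once a gap, always a gap
                else:
                    residues.append(r.residues[k])
                    k += 1
            out.append(SeqRecord(r.id, "".join(residues), r.species, r.locus))
        return out

    return expand(prof_a, aln_a) + expand(prof_b, aln_b)


def _upgma_order(ids: list[str], dist: dict[tuple[str, str], float]) -> list[tuple[int, int]]:
    """UPGMA merge schedule over cluster indices; ties lexicographic.

    Clusters are identified by their smallest member id; returns a list of
    (i, j) index pairs into a growing cluster list (initial clusters 0..n-1).
    """
    clusters: list[list[str]] = [[i] for i in ids]
    active = list(range(len(ids)))
    rep = {i: ids[i] for i in range(len(ids))}

    def d(ci: int, cj: int) -> float:
        tot = 0.0
        for x in clusters[ci]:
            for y in clusters[cj]:
                tot += dist[(x, y) if (x, y) in dist else (y, x)]
        return tot / (len(clusters[ci]) * len(clusters[cj]))

    schedule: list[tuple[int, int]] = []
    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        best_pair: tuple[int, int] | None = None
        for ii, ci in enumerate(active):
            for cj in active[ii + 1 :]:
                key = (d(ci, cj), min(rep[ci], rep[cj]), max(rep[ci], rep[cj]))
                if best is None or key < best:
                    best = key
                    best_pair = (ci, cj)
        assert best_pair is not None
        ci, cj = best_pair
        clusters.append(clusters[ci] + clusters[cj])
        new = len(clusters) - 1
        rep[new] = min(rep[ci], rep[cj])
        active = [c for c in active if c not in (ci, cj)] + [new]
        schedule.append((ci, cj))
    return schedule


def progressive_align(
    panel: SpeciesPanel | list[SeqRecord], params: AlignParams | None = None
) -> Alignment:
    """Progressive multiple alignment of a small panel.

    Guide order is UPGMA on p-distances of all pairwise global alignments
    with lexicographic tie-breaking, so the result is deterministic for a
    fixed input.  Every row de-gaps back to its input residues.
    """
    params = params or AlignParams()
    records = list(panel)
    if len(records) < 2:
        raise ContractError("progressive_align requires >= 2 records")
    ids = [r.id for r in records]
    by_id = {r.id: r for r in records}
    dist: dict[tuple[str, str], float] = {}
    for i, ra in enumerate(records):
        for rb in records[i + 1 :]:
            row_a, row_b, _ = _align_strings(ra.residues, rb.residues, params)
            dist[(ra.id, rb.id)] = _p_distance(row_a, row_b)
    schedule = _upgma_order(ids, dist)
    profiles: list[list[SeqRecord] | None] = [[by_id[i]] for i in ids]
    for ci, cj in schedule:
        pa, pb = profiles[ci], profiles[cj]
        assert pa is not None and pb is not None
        profiles.append(_merge_profiles(pa, pb, params))
        profiles[ci] = profiles[cj] = None
    final = profiles[-1]
    assert final is not None
    order = {rid: k for k, rid in enumerate(ids)}
    final.sort(key=lambda r: order[r.id])
    return Alignment(final)
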