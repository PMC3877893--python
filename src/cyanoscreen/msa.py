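"""Progressive multiple sequence alignment (internal MUSCLE stand-in).

Pairwise and profile-profile global alignment under affine gap costs
(Gotoh), merged up a k-mer-distance average-linkage guide tree. Adequate
for conserved coding genes at desk scale; externally produced alignments
can always be imported as aligned FASTA instead.

Determinism contract: traceback prefers diagonal, then up (gap in the
second profile), then left; guide-tree ties break lexicographically on
cluster labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .gene_classify import canonical_kmers
from .seq_io import GAP, Alignment, SequenceRecord, as_alignment

__all__ = ["ScoringScheme", "pairwise_global", "guide_tree", "progressive_align", "GuideNode"]

_NEG = -1e30


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -4     # cost of the first residue of a gap
    gap_extend: int = -1   # cost of each further residue

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0 < self.match):
            raise ValueError("require gap_open <= gap_extend <= 0 < match")


class _Profile:
    """A set of aligned rows plus per-column residue counts."""

    def __init__(self, rows: list[str], ids: list[str]):
        self.rows = rows
        self.ids = ids
        symbols = sorted({c for row in rows for c in row if c != GAP})
        self.symbols = symbols
        idx = {s: i for i, s in enumerate(symbols)}
        ncol = len(rows[0]) if rows else 0
        counts = np.zeros((ncol, max(len(symbols), 1)), dtype=np.float64)
        gaps = np.zeros(ncol, dtype=np.float64)
        for row in rows:
            for j, c in enumerate(row):
                if c == GAP:
                    gaps[j] += 1
                else:
                    counts[j, idx[c]] += 1
        self.counts = counts
        self.gaps = gaps
        self.n = len(rows)
        self.ncol = ncol


def _column_scores(px: _Profile, py: _Profile, scheme: ScoringScheme) -> np.ndarray:
    """S[i, j] = mean pair score between column i of px and column j of py.

    Residue-residue pairs score match/mismatch (ambiguity codes are
    distinct symbols); pairs involving an existing gap score 0.
    """
    symbols = sorted(set(px.symbols) | set(py.symbols))
    sx = np.zeros((px.ncol, len(symbols)))
    sy = np.zeros((py.ncol, len(symbols)))
    for k, s in enumerate(symbols):
        if s in px.symbols:
            sx[:, k] = px.counts[:, px.symbols.index(s)]
        if s in py.symbols:
            sy[:, k] = py.counts[:, py.symbols.index(s)]
    same = sx @ sy.T
    res_x = px.n - px.gaps
    res_y = py.n - py.gaps
    total = np.outer(res_x, res_y)
    S = (scheme.match * same + scheme.mismatch * (total - same)) / (px.n * py.n)
    return S


def _gotoh(S: np.ndarray, scheme: ScoringScheme):
    """Vectorised affine-gap global DP over a column-score matrix.

    Returns (M, IX, IY, score): IX = gap columns inserted into the second
    profile (consuming rows of the first), IY the converse.
    """
    lx, ly = S.shape
    op, ext = float(scheme.gap_open), float(scheme.gap_extend)
    M = np.full((lx + 1, ly + 1), _NEG)
    IX = np.full((lx + 1, ly + 1), _NEG)
    IY = np.full((lx + 1, ly + 1), _NEG)
    M[0, 0] = 0.0
    if lx:
        IX[1:, 0] = op + ext * np.arange(lx)
    if ly:
        IY[0, 1:] = op + ext * np.arange(ly)
    js = np.arange(1, ly + 1)
    for i in range(1, lx + 1):
        best_prev = np.maximum(np.maximum(M[i - 1, :ly], IX[i - 1, :ly]), IY[i - 1, :ly])
        M[i, 1:] = S[i - 1, :] + best_prev
        IX[i, 1:] = np.maximum(M[i - 1, 1:] + op, IX[i - 1, 1:] + ext)
        # IY[i, j] = max(M[i, j-1] + op, IY[i, j-1] + ext) unrolls to a
        # prefix-max scan: IY[i, j] = ext*j + max_{k<j} (M[i, k] + op - ext*(k+1))
        g = M[i, :ly] + op - ext * np.arange(1, ly + 1)
        IY[i, 1:] = ext * js + np.maximum.accumulate(g)
    score = max(M[lx, ly], IX[lx, ly], IY[lx, ly])
    return M, IX, IY, score


def _traceback(M, IX, IY, scheme: ScoringScheme) -> list[str]:
    """Alignment path as a list of moves 'D' (both), 'U' (row of x), 'L'."""
    lx, ly = M.shape[0] - 1, M.shape[1] - 1
    op, ext = float(scheme.gap_open), float(scheme.gap_extend)
    i, j = lx, ly
    vals = (M[i, j], IX[i, j], IY[i, j])
    state = int(np.argmax([vals[0], vals[1], vals[2]]))  # prefers M, then IX, then IY
    moves: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            moves.append("D")
            i, j = i - 1, j - 1
            cand = (M[i, j], IX[i, j], IY[i, j])
            state = int(np.argmax(cand))
        elif state == 1:
            moves.append("U")
            state = 0 if M[i - 1, j] + op >= IX[i - 1, j] + ext else 1
            i -= 1
        else:
            moves.append("L")
            state = 0 if M[i, j - 1] + op >= IY[i, j - 1] + ext else 2
            j -= 1
    moves.reverse()
    return moves


def _merge(px: _Profile, py: _Profile, moves: list[str]) -> _Profile:
    rows_x = [[] for _ in px.rows]
    rows_y = [[] for _ in py.rows]
    i = j = 0
    for mv in moves:
        if mv in ("D", "U"):
            for r, row in zip(rows_x, px.rows):
                r.append(row[i])
            i += 1
        else:
            for r in rows_x:
                r.append(GAP)
        if mv in ("D", "L"):
            for r, row in zip(rows_y, py.rows):
                r.append(row[j])
            j += 1
        else:
            for r in rows_y:
                r.append(GAP)
    return _Profile(["".join(r) for r in rows_x] + ["".join(r) for r in rows_y],
                    px.ids + py.ids)


def _align_profiles(px: _Profile, py: _Profile, scheme: ScoringScheme):
    S = _column_scores(px, py, scheme)
    M, IX, IY, score = _gotoh(S, scheme)
    moves = _traceback(M, IX, IY, scheme)
    return _merge(px, py, moves), score


def pairwise_global(a: SequenceRecord, b: SequenceRecord,
                    scheme: ScoringScheme = ScoringScheme()) -> tuple[str, str, float]:
    """Optimal global alignment of two ungapped sequences under affine gaps."""
    if GAP in a.residues or GAP in b.residues:
        raise ValueError("inputs must be ungapped")
    if not a.residues or not b.residues:
        raise ValueError("empty sequence")
    merged, score = _align_profiles(_Profile([a.residues], [a.id]),
                                    _Profile([b.residues], [b.id]), scheme)
    return merged.rows[0], merged.rows[1], float(score)


@dataclass(frozen=True)
class GuideNode:
    """Rooted binary guide-tree node; leaves carry a record id."""

    id: str | None = None
    left: "GuideNode | None" = None
    right: "GuideNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.id is not None

    def label(self) -> str:
        if self.is_leaf:
            return self.id
        return min(self.left.label(), self.right.label())


def kmer_distance_matrix(records: Sequence[SequenceRecord], k: int = 6) -> np.ndarray:
    """1 - Jaccard similarity of canonical k-mer sets, all pairs."""
    sets = [canonical_kmers(r.ungapped, k) for r in records]
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            jac = len(sets[i] & sets[j]) / union if union else 1.0
            D[i, j] = D[j, i] = 1.0 - jac
    return D


def guide_tree(records: Sequence[SequenceRecord], k: int = 6) -> GuideNode:
    """Average-linkage clustering on k-mer distances; lexicographic ties."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    D = kmer_distance_matrix(records, k)
    clusters: list[tuple[GuideNode, list[int]]] = [
        (GuideNode(id=r.id), [i]) for i, r in enumerate(records)
    ]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                mi, mj = clusters[i][1], clusters[j][1]
                d = float(np.mean([D[a, b] for a in mi for b in mj]))
                li, lj = sorted((clusters[i][0].label(), clusters[j][0].label()))
                key = (d, li, lj)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        ni, nj = clusters[i], clusters[j]
        left, right = sorted((ni[0], nj[0]), key=lambda n: n.label())
        merged = (GuideNode(left=left, right=right), ni[1] + nj[1])
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)] + [merged]
    return clusters[0][0]


def progressive_align(records: Sequence[SequenceRecord],
                      scheme: ScoringScheme = ScoringScheme(),
                      k: int = 6) -> Alignment:
    """Align records by merging profiles up the guide tree.

    Every input sequence is recoverable by deleting gaps from its aligned
    row; rows come back in the original input order.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    by_id = {r.id: r for r in records}
    tree = guide_tree(records, k)

    def build(node: GuideNode) -> _Profile:
        if node.is_leaf:
            rec = by_id[node.id]
            return _Profile([rec.ungapped], [rec.id])
        px, py = build(node.left), build(node.right)
        merged, _ = _align_profiles(px, py, scheme)
        return merged

    prof = build(tree)
    rows = dict(zip(prof.ids, prof.rows))
    out = [SequenceRecord(r.id, rows[r.id], r.description) for r in records]
    return as_alignment(out)
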