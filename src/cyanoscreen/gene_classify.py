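"""A-gene vs G-gene triage by canonical k-mer containment.

The two cyanobactin protease genes (N-terminal A, C-terminal G) are
homologous over parts of their length, so a primer screen can recover
either; amplicons must be disambiguated before phylogenetics. Here a
query's k-mer set is compared against per-class reference profiles:

    score_X = |kmers(query) ∩ profile_X| / |kmers(query)|

with canonical (strand-merged) k-mers, so classification is strand
invariant. The winning class must beat the loser by a margin, otherwise
the call is "ambiguous" and surfaced rather than silently dropped.

Containment (not Jaccard) keeps the score length-robust when short
amplicons are judged against full-length references. k = 11 separates
paralogous families at the 20-40%+ divergence that splits A from G; it is
NOT a remote-homology search, and needs a reference panel containing close
relatives of the expected queries (the role GenBank played for the
original BLASTn triage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .seq_io import SequenceRecord, revcomp

__all__ = ["ReferencePanel", "ClassifyResult", "build_panel", "classify", "scan_genome",
           "canonical_kmers"]

_PLAIN = frozenset("ACGT")


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Canonical (lexicographic min of kmer / revcomp) k-mer set.

    K-mers containing ambiguity codes or gaps are skipped.
    """
    s = seq.upper().replace("U", "T")
    out: set[str] = set()
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if set(kmer) <= _PLAIN:
            rc = revcomp(kmer)
            out.add(kmer if kmer <= rc else rc)
    return out


@dataclass(frozen=True)
class ReferencePanel:
    a_refs: tuple[SequenceRecord, ...]
    g_refs: tuple[SequenceRecord, ...]
    k: int
    a_profile: frozenset[str]
    g_profile: frozenset[str]


def build_panel(a_refs: Sequence[SequenceRecord], g_refs: Sequence[SequenceRecord],
                k: int = 11) -> ReferencePanel:
    """Build strand-merged per-class k-mer profiles from labelled references."""
    if not a_refs or not g_refs:
        raise ValueError("both reference classes (A and G) must be non-empty")
    shortest = min(len(r.ungapped) for r in list(a_refs) + list(g_refs))
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest reference ({shortest} bases)")
    a_prof: set[str] = set()
    for r in a_refs:
        a_prof |= canonical_kmers(r.ungapped, k)
    g_prof: set[str] = set()
    for r in g_refs:
        g_prof |= canonical_kmers(r.ungapped, k)
    return ReferencePanel(tuple(a_refs), tuple(g_refs), k, frozenset(a_prof), frozenset(g_prof))


@dataclass(frozen=True)
class ClassifyResult:
    query_id: str
    label: str        # "A" | "G" | "ambiguous"
    score_a: float
    score_g: float

    @property
    def margin(self) -> float:
        return abs(self.score_a - self.score_g)


def classify(query: SequenceRecord, panel: ReferencePanel,
             threshold: float = 0.05) -> ClassifyResult:
    """Containment-score a query against both class profiles.

    Calls "ambiguous" when the winner's lead is below ``threshold``
    (including the no-information case where both scores are ~0).
    """
    if "-" in query.residues:
        raise ValueError("query must be ungapped")
    if len(query) < panel.k:
        raise ValueError(f"query {query.id!r} shorter than k={panel.k}")
    kmers = canonical_kmers(query.residues, panel.k)
    if not kmers:
        return ClassifyResult(query.id, "ambiguous", 0.0, 0.0)
    score_a = len(kmers & panel.a_profile) / len(kmers)
    score_g = len(kmers & panel.g_profile) / len(kmers)
    if abs(score_a - score_g) < threshold:
        label = "ambiguous"
    else:
        label = "A" if score_a > score_g else "G"
    return ClassifyResult(query.id, label, score_a, score_g)


def scan_genome(contigs: Sequence[SequenceRecord], panel: ReferencePanel,
                window: int = 900, step: int = 300,
                threshold: float = 0.05) -> list[tuple[str, int, int, str, float]]:
    """Sliding-window classification of genome-scale contigs.

    Windows that classify unambiguously are merged (per contig, per label)
    into maximal intervals; each interval carries the best window score.
    Returns (contig_id, start, end, label, score) sorted by contig then
    start.
    """
    if window < 2 * panel.k:
        raise ValueError("window must be at least 2k")
    raw: list[tuple[str, int, int, str, float]] = []
    for contig in contigs:
        n = len(contig)
        starts = list(range(0, max(n - window, 0) + 1, step))
        if not starts:
            starts = [0]
        for s in starts:
            e = min(s + window, n)
            if e - s < panel.k:
                continue
            sub = SequenceRecord(f"{contig.id}_w{s}", contig.residues[s:e])
            res = classify(sub, panel, threshold)
            if res.label != "ambiguous":
                raw.append((contig.id, s, e, res.label,
                            res.score_a if res.label == "A" else res.score_g))
    # merge overlapping/adjacent same-label windows per contig
    raw.sort(key=lambda t: (t[0], t[3], t[1]))
    merged: list[tuple[str, int, int, str, float]] = []
    for cid, s, e, lab, sc in raw:
        if merged and merged[-1][0] == cid and merged[-1][3] == lab and s <= merged[-1][2]:
            pc, ps, pe, pl, psc = merged[-1]
            merged[-1] = (pc, ps, max(pe, e), pl, max(psc, sc))
        else:
            merged.append((cid, s, e, lab, sc))
    merged.sort(key=lambda t: (t[0], t[1], t[2]))
    return merged
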