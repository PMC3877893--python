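"""Gene-tree / species-tree comparison: supported clades, Robinson-Foulds
incongruence, lateral-transfer candidates, novel-clade flags.

A gene tree that disagrees with the 16S rRNA reference phylogeny is the
classic signature of horizontal transfer of the biosynthetic gene cluster.
This module formalizes the screen's interpretive steps: clades are
bootstrap-supported bipartitions at a display threshold (70% for gene
trees, 50% for 16S trees), incongruence is the unrooted Robinson-Foulds
distance after pruning to the shared taxa, transfer candidates are found
greedily as the leaves whose removal most reduces that distance, and a
"novel clade" is a maximal supported clade composed only of query taxa
with no known-chemotype member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .phylo import PhyloTree

__all__ = ["Clade", "CladeSet", "IncongruenceReport", "extract_clades",
           "prune_shared", "robinson_foulds", "displaced_taxa", "flag_novel_clades"]


@dataclass(frozen=True)
class Clade:
    leaves: frozenset
    support: float
    annotations: tuple = ()


@dataclass(frozen=True)
class CladeSet:
    clades: tuple[Clade, ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.clades)

    def leaf_sets(self) -> set[frozenset]:
        return {c.leaves for c in self.clades}


def extract_clades(tree: PhyloTree, threshold: float = 70.0,
                   annotations: Mapping[str, str] | None = None) -> CladeSet:
    """All internal-edge bipartitions with bootstrap support >= threshold.

    Each clade is an edge's smaller-side leaf set (lexicographic tie-break
    at an even split). Raises on a supportless tree.
    """
    splits = tree.splits()
    if splits and all(node.support is None for node in splits.values()):
        raise ValueError("tree has no bootstrap supports; run bootstrap first")
    n = len(tree.leaf_names())
    all_leaves = frozenset(tree.leaf_names())
    out = []
    seen = set()
    for side, node in sorted(splits.items(), key=lambda kv: tuple(sorted(kv[0]))):
        if node.support is None or node.support < threshold:
            continue
        other = all_leaves - side
        if len(side) < len(other):
            clade = side
        elif len(other) < len(side):
            clade = other
        else:
            clade = min(side, other, key=lambda s: tuple(sorted(s)))
        if clade in seen:
            continue
        seen.add(clade)
        ann = tuple(sorted((l, annotations.get(l, "")) for l in clade)) if annotations else ()
        out.append(Clade(clade, float(node.support), ann))
    return CladeSet(tuple(out), threshold)


class IncomparableTreesError(ValueError):
    pass


def prune_shared(t1: PhyloTree, t2: PhyloTree) -> tuple[PhyloTree, PhyloTree]:
    """Restrict both trees to their shared leaf set (>= 4 required);
    suppressed degree-2 nodes get their branch lengths summed."""
    shared = set(t1.leaf_names()) & set(t2.leaf_names())
    if len(shared) < 4:
        raise IncomparableTreesError(
            f"only {len(shared)} shared leaves; need at least 4")
    return t1.prune_to(shared), t2.prune_to(shared)


@dataclass(frozen=True)
class IncongruenceReport:
    shared_taxa: int
    rf_distance: int
    max_rf: int
    displaced: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    @property
    def normalized_rf(self) -> float:
        return self.rf_distance / self.max_rf if self.max_rf else 0.0


def _rf(t1: PhyloTree, t2: PhyloTree) -> int:
    s1, s2 = set(t1.splits()), set(t2.splits())
    return len(s1 ^ s2)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> IncongruenceReport:
    """Unrooted RF distance between two trees after pruning to shared taxa.

    Counts non-trivial bipartitions present in exactly one tree; supports
    and branch lengths are ignored.
    """
    p1, p2 = prune_shared(t1, t2)
    n = len(p1.leaf_names())
    return IncongruenceReport(n, _rf(p1, p2), 2 * (n - 3))


def displaced_taxa(t1: PhyloTree, t2: PhyloTree,
                   budget: int = 4) -> list[tuple[str, int]]:
    """Greedy lateral-transfer candidates.

    Repeatedly remove the single shared leaf whose removal most reduces the
    RF distance (ties broken lexicographically) until the trees agree, no
    removal helps, the budget is spent, or fewer than 5 leaves would
    remain. Returns the removal order with the RF value after each removal
    (a strictly decreasing trajectory).
    """
    p1, p2 = prune_shared(t1, t2)
    current = _rf(p1, p2)
    out: list[tuple[str, int]] = []
    while current > 0 and len(out) < budget:
        taxa = sorted(set(p1.leaf_names()))
        if len(taxa) <= 4:
            break
        best: tuple[int, str] | None = None
        for taxon in taxa:
            keep = set(taxa) - {taxon}
            rf = _rf(p1.prune_to(keep), p2.prune_to(keep))
            if best is None or (rf, taxon) < best:
                best = (rf, taxon)
        rf_after, taxon = best
        if rf_after >= current:
            break
        keep = set(taxa) - {taxon}
        p1, p2 = p1.prune_to(keep), p2.prune_to(keep)
        current = rf_after
        out.append((taxon, rf_after))
    return out


def flag_novel_clades(gene_clades: CladeSet,
                      annotations: Mapping[str, str]) -> list[Clade]:
    """Supported clades made only of query taxa (no known chemotype).

    A clade is novel when it has >= 2 query members, no member annotated
    with a known chemotype, and is maximal with that property. Singleton
    query sequences ("loners") are not clades and are reported elsewhere.
    """
    for clade in gene_clades.clades:
        for leaf in clade.leaves:
            if leaf not in annotations:
                raise ValueError(f"taxon {leaf!r} lacks an annotation")
    qualifying = [c for c in gene_clades.clades
                  if len(c.leaves) >= 2
                  and all(annotations[l] == "query" for l in c.leaves)]
    maximal = [c for c in qualifying
               if not any(c is not d and c.leaves < d.leaves for d in qualifying)]
    maximal.sort(key=lambda c: tuple(sorted(c.leaves)))
    return maximal
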