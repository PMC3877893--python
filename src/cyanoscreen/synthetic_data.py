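"""Synthetic study generator with recorded ground truth.

Emulates everything the screen consumes: a Yule species tree, an A-gene
tree derived from it by horizontal transfer (leaf SPR) events, gene cores
evolved under K2P+Γ+I, degenerate primer sites implanted around each core
inside random genomic flanks, a diverged paralogous G-gene family sharing
the primer sites (so the in-silico PCR recovers both families and the
classifier must separate them), and reference panels.

Every operation is a pure function of (spec, seed); a fixed seed gives
byte-identical outputs. Trees are rescaled to a fixed root-to-tip height
(default 0.3 substitutions/site) so distances stay inside the K2P
estimator's range while leaving strong phylogenetic signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .insilico_pcr import pcr_products
from .phylo import (PhyloNode, PhyloTree, SubstitutionModel,
                    transition_probability, write_newick)
from .primer_design import CBT_PAIR, PrimerPair, expansions
from .seq_io import Alignment, SequenceRecord, revcomp, write_fasta, write_tsv

__all__ = ["SimulationSpec", "TruthBundle", "simulate_species_tree", "apply_hgt",
           "evolve_sequences", "implant_amplicon", "emit_paralogs", "emit_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic screen."""

    n_taxa: int = 12
    birth_rate: float = 1.0
    tree_height: float = 0.3          # root-to-tip rescaling, subs/site
    n_hgt_events: int = 2
    model: SubstitutionModel = field(default_factory=SubstitutionModel)
    core_length: int = 769            # bases between the primer footprints (804 bp product)
    primer_pair: PrimerPair = CBT_PAIR
    paralog_divergence: float = 1.0   # expected subs/site separating the G family
    indel_rate: float = 0.0
    flank_length: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if self.n_hgt_events >= self.n_taxa:
            raise ValueError("n_hgt_events must be < n_taxa")
        if min(self.birth_rate, self.tree_height) <= 0 or self.indel_rate < 0:
            raise ValueError("rates must be positive (indel rate >= 0)")


@dataclass(frozen=True)
class TruthBundle:
    species_tree: PhyloTree
    gene_tree: PhyloTree
    hgt_events: tuple[tuple[str, str], ...]   # (recipient leaf, donor edge label)
    true_alignment: Alignment
    a_cores: dict
    g_cores: dict
    templates: tuple[SequenceRecord, ...]
    amplicon_coords: dict                      # taxon -> list of (label, start, end)
    class_labels: dict                         # locus id -> "A" | "G"


def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0,
                          height: float | None = 0.3) -> PhyloTree:
    """Yule pure-birth tree with leaves t001..tN, optionally rescaled so the
    maximum root-to-tip path equals ``height``."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = PhyloNode()
    active = [root]
    while len(active) < n_taxa:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length = (node.length or 0.0) + wait
        idx = int(rng.integers(0, len(active)))
        parent = active.pop(idx)
        left, right = PhyloNode(length=0.0), PhyloNode(length=0.0)
        parent.add(left)
        parent.add(right)
        active.extend([left, right])
    final = rng.exponential(1.0 / (birth_rate * n_taxa))
    for node in active:
        node.length = (node.length or 0.0) + final
    root.length = None

    tree = PhyloTree(root)
    width = len(str(n_taxa))
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.name = f"t{i:0{width}d}"
    if height is not None:
        depth = _max_depth(root)
        scale = height / depth if depth > 0 else 1.0
        for node in tree.postorder():
            if node.length is not None:
                node.length *= scale
    return tree


def _max_depth(node: PhyloNode) -> float:
    own = node.length or 0.0
    if node.is_leaf:
        return own
    return own + max(_max_depth(c) for c in node.children)


def _min_leaf(node: PhyloNode) -> str:
    return node.name if node.is_leaf else min(_min_leaf(c) for c in node.children)


def apply_hgt(species_tree: PhyloTree, n_events: int, seed: int = 0,
              max_retries: int = 20) -> tuple[PhyloTree, list[tuple[str, str]]]:
    """Derive a gene tree by seeded leaf-SPR transfer events.

    Each event prunes a random leaf (the transfer recipient) and regrafts
    it at the midpoint of a random non-adjacent edge (the donor lineage),
    guaranteed to change at least one bipartition. Returns the gene tree
    and the events as (recipient leaf, donor edge label) where the label is
    the donor clade's smallest leaf.
    """
    n_leaves = len(species_tree.leaf_names())
    if n_events >= n_leaves - 2:
        raise ValueError("n_events must be < leaves - 2")
    rng = np.random.default_rng(seed)
    gene = species_tree.copy()
    events: list[tuple[str, str]] = []
    for _ in range(n_events):
        for attempt in range(max_retries):
            before = _nontrivial_splits_set(gene)
            candidate = gene.copy()
            leaves = sorted(candidate.leaves(), key=lambda l: l.name)
            x = leaves[int(rng.integers(0, len(leaves)))]
            p = x.parent
            excluded = {id(x), id(p)} | {id(c) for c in p.children}
            targets = [nd for nd in candidate.postorder()
                       if nd is not candidate.root and id(nd) not in excluded]
            if not targets:
                continue
            targets.sort(key=_min_leaf)
            t = targets[int(rng.integers(0, len(targets)))]
            donor_label = _min_leaf(t)
            _spr_leaf(candidate, x, t)
            if _nontrivial_splits_set(candidate) != before:
                gene = candidate
                events.append((x.name, donor_label))
                break
        else:
            raise RuntimeError("could not place an HGT event that changes the topology")
    return gene, events


def _nontrivial_splits_set(tree: PhyloTree) -> frozenset:
    return frozenset(tree.splits())


def _spr_leaf(tree: PhyloTree, x: PhyloNode, target: PhyloNode) -> None:
    """Prune leaf x and regraft it at the midpoint of target's edge."""
    p = x.parent
    x.detach()
    if len(p.children) == 1:
        only = p.children[0]
        if p.parent is None:
            only.parent = None
            only.length = None
            tree.root = only
        else:
            gp = p.parent
            only.length = (only.length or 0.0) + (p.length or 0.0)
            gp.children[gp.children.index(p)] = only
            only.parent = gp
    q = target.parent
    mid = PhyloNode(length=(target.length or 0.0) / 2.0)
    target.length = (target.length or 0.0) / 2.0
    q.children[q.children.index(target)] = mid
    mid.parent = q
    mid.add(target)
    mid.add(x)


def evolve_sequences(tree: PhyloTree, model: SubstitutionModel, length: int,
                     indel_rate: float = 0.0, seed: int = 0,
                     root_seq: np.ndarray | None = None,
                     ) -> tuple[Alignment, dict, np.ndarray]:
    """Evolve sequences down a tree under K2P+Γ+I (and optional deletions).

    Per site a rate category (or the invariant state) is drawn once and
    shared across the whole tree; children mutate from their parent via the
    K80 transition matrix at the branch's effective length. Indels are
    single-base deletion events (probability ``indel_rate * t`` per site
    per branch) propagated to all descendants; columns deleted in every
    leaf are dropped from the true alignment. Returns (true alignment,
    {leaf: ungapped sequence}, root sequence as base indices).
    """
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    rates = np.array(model.category_rates)
    invariant = rng.random(length) < model.p_inv
    cats = rng.integers(0, len(rates), size=length)
    site_rates = np.where(invariant, 0.0, rates[cats])

    # the root is always drawn so the stream stays aligned whether or not a
    # caller supplies one: paralog families evolved with the same seed then
    # share every substitution whose parent states coincide
    default_root = rng.integers(0, 4, size=length)
    if root_seq is None:
        root_seq = default_root
    states: dict[int, np.ndarray] = {id(tree.root): root_seq.copy()}
    deleted: dict[int, np.ndarray] = {id(tree.root): np.zeros(length, dtype=bool)}

    def preorder(node):
        yield node
        for c in node.children:
            yield from preorder(c)

    for node in preorder(tree.root):
        if node is tree.root:
            continue
        t = node.length or 0.0
        parent_state = states[id(node.parent)]
        child = parent_state.copy()
        if t > 0:
            for k, r in enumerate(rates):
                idx = np.nonzero((~invariant) & (cats == k))[0]
                if idx.size == 0:
                    continue
                P = transition_probability(model, t, float(r))
                cum = P.cumsum(axis=1)
                u = rng.random(idx.size)
                child[idx] = (u[:, None] > cum[parent_state[idx]]).sum(axis=1)
        dele = deleted[id(node.parent)].copy()
        if indel_rate > 0 and t > 0:
            dele |= rng.random(length) < indel_rate * t
        states[id(node)] = child
        deleted[id(node)] = dele

    leaves = tree.leaves()
    rows = {}
    for leaf in leaves:
        s = states[id(leaf)]
        d = deleted[id(leaf)]
        rows[leaf.name] = np.where(d, "-", _BASES[s])
    keep = ~np.all(np.stack([rows[l.name] == "-" for l in leaves]), axis=0)
    records = [SequenceRecord(l.name, "".join(rows[l.name][keep])) for l in leaves]
    aln = Alignment(tuple(records))
    ungapped = {r.id: r.ungapped for r in records}
    return aln, ungapped, root_seq


def implant_amplicon(leaf_sequences: dict, primer_pair: PrimerPair, seed: int = 0,
                     flank_length: int = 400,
                     omit_forward: set | None = None,
                     ) -> tuple[dict, dict]:
    """Embed each core between primer binding sites inside random flanks.

    Per taxon, one random expansion of the forward primer and the reverse
    complement of one random expansion of the reverse primer are written at
    fixed loci flanking the core. Taxa in ``omit_forward`` get random bases
    in place of the forward site (a PCR-negative control). Returns
    ({taxon: template string}, {taxon: (start, end)}) with the recorded
    product footprint start/end (end - start = fwd + core + rev lengths).
    """
    if primer_pair.forward.degeneracy > 10_000 or primer_pair.reverse.degeneracy > 10_000:
        raise ValueError("primer degeneracy too high to enumerate expansions")
    rng = np.random.default_rng(seed)
    fwd_exp = list(expansions(primer_pair.forward.sequence))
    rev_exp = list(expansions(primer_pair.reverse.sequence))
    omit_forward = omit_forward or set()
    templates, coords = {}, {}
    for taxon in sorted(leaf_sequences):
        core = leaf_sequences[taxon]
        left = "".join(rng.choice(_BASES, size=flank_length))
        right = "".join(rng.choice(_BASES, size=flank_length))
        fwd = fwd_exp[int(rng.integers(0, len(fwd_exp)))]
        rev = rev_exp[int(rng.integers(0, len(rev_exp)))]
        if taxon in omit_forward:
            fwd_site = "".join(rng.choice(_BASES, size=len(fwd)))
        else:
            fwd_site = fwd
        template = left + fwd_site + core + revcomp(rev) + right
        start = flank_length
        end = start + len(fwd) + len(core) + len(rev)
        templates[taxon] = template
        coords[taxon] = (start, end)
    return templates, coords


def emit_paralogs(root_seq: np.ndarray, paralog_divergence: float,
                  tree: PhyloTree, model: SubstitutionModel, length: int,
                  seed: int = 0, tree_seed: int | None = None) -> tuple[Alignment, dict]:
    """Evolve the paralogous G family: mutate the A root along an elongated
    branch of the given length, then evolve down the same gene tree.

    Passing the A family's seed as ``tree_seed`` couples the two families'
    within-tree histories, so the tip-level A-vs-G divergence reflects the
    duplication branch alone (the families differ only where that branch
    substituted); with an independent ``tree_seed`` the families also
    accumulate 2x the tree height of incidental divergence.
    """
    if paralog_divergence <= 0:
        raise ValueError("paralog divergence must be > 0")
    rng = np.random.default_rng(seed)
    # the duplication branch mutates every variable site at its own rate
    rates = np.array(model.category_rates)
    invariant = rng.random(length) < model.p_inv
    cats = rng.integers(0, len(rates), size=length)
    g_root = root_seq.copy()
    for k, r in enumerate(rates):
        idx = np.nonzero((~invariant) & (cats == k))[0]
        if idx.size == 0:
            continue
        P = transition_probability(model, paralog_divergence, float(r))
        cum = P.cumsum(axis=1)
        u = rng.random(idx.size)
        g_root[idx] = (u[:, None] > cum[root_seq[idx]]).sum(axis=1)
    down_seed = tree_seed if tree_seed is not None else seed + 1
    aln, cores, _ = evolve_sequences(tree, model, length, indel_rate=0.0,
                                     seed=down_seed, root_seq=g_root)
    return aln, cores


def emit_dataset(spec: SimulationSpec, out_dir: str | Path | None = None) -> TruthBundle:
    """Generate one complete synthetic screen; optionally write all files.

    Each taxon's genomic template carries an A locus and a G locus, both
    flanked by primer binding sites, so the in-silico PCR recovers two
    products per strain and classification decides which feed the
    phylogeny. Byte-identical outputs for a fixed spec.
    """
    species = simulate_species_tree(spec.n_taxa, spec.birth_rate, spec.seed,
                                    height=spec.tree_height)
    gene, events = apply_hgt(species, spec.n_hgt_events, spec.seed + 1)
    true_aln, a_cores, root_seq = evolve_sequences(
        gene, spec.model, spec.core_length, spec.indel_rate, spec.seed + 2)
    _, g_cores = emit_paralogs(root_seq, spec.paralog_divergence, gene,
                               spec.model, spec.core_length, spec.seed + 3,
                               tree_seed=spec.seed + 2)
    a_templates, a_coords = implant_amplicon(a_cores, spec.primer_pair,
                                             spec.seed + 4, spec.flank_length)
    g_templates, g_coords = implant_amplicon(g_cores, spec.primer_pair,
                                             spec.seed + 5, spec.flank_length)

    spacer_rng = np.random.default_rng(spec.seed + 6)
    templates = []
    coords: dict = {}
    labels: dict = {}
    for taxon in sorted(a_templates):
        spacer = "".join(spacer_rng.choice(_BASES, size=500))
        seq = a_templates[taxon] + spacer + g_templates[taxon]
        offset = len(a_templates[taxon]) + len(spacer)
        a_s, a_e = a_coords[taxon]
        g_s, g_e = g_coords[taxon]
        coords[taxon] = [("A", a_s, a_e), ("G", offset + g_s, offset + g_e)]
        labels[f"{taxon}_A"] = "A"
        labels[f"{taxon}_G"] = "G"
        templates.append(SequenceRecord(taxon, seq, "synthetic genomic template"))

    bundle = TruthBundle(
        species_tree=species, gene_tree=gene, hgt_events=tuple(events),
        true_alignment=true_aln, a_cores=a_cores, g_cores=g_cores,
        templates=tuple(templates), amplicon_coords=coords, class_labels=labels,
    )
    if out_dir is not None:
        _write_bundle(bundle, spec, Path(out_dir))
    return bundle


def _write_bundle(bundle: TruthBundle, spec: SimulationSpec, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(list(bundle.templates), out / "templates.fasta")
    write_fasta([SequenceRecord(f"{t}_A", s) for t, s in sorted(bundle.a_cores.items())],
                out / "panel_a.fasta")
    write_fasta([SequenceRecord(f"{t}_G", s) for t, s in sorted(bundle.g_cores.items())],
                out / "panel_g.fasta")
    write_fasta(list(bundle.true_alignment.records), out / "true_alignment.fasta")
    (out / "species_tree.nwk").write_text(write_newick(bundle.species_tree) + "\n")
    (out / "gene_tree.nwk").write_text(write_newick(bundle.gene_tree) + "\n")
    write_tsv(out / "hgt_events.tsv", ["recipient", "donor_edge"],
              list(bundle.hgt_events))
    rows = []
    for taxon in sorted(bundle.amplicon_coords):
        for label, s, e in bundle.amplicon_coords[taxon]:
            rows.append([taxon, label, s, e, e - s])
    write_tsv(out / "amplicon_coords.tsv",
              ["taxon", "locus", "start", "end", "length"], rows)
    write_tsv(out / "class_labels.tsv", ["locus_id", "label"],
              sorted(bundle.class_labels.items()))


def verify_self_consistency(bundle: TruthBundle, spec: SimulationSpec) -> bool:
    """Truth coordinates are exactly what the in-silico PCR recovers."""
    for rec in bundle.templates:
        hits = pcr_products(spec.primer_pair, rec, max_mismatch=0,
                            product_length_range=(100, 2000))
        expected = {(s, e) for _, s, e in bundle.amplicon_coords[rec.id]}
        if {(h.start, h.end) for h in hits} != expected:
            return False
    return True
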