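"""Clade extraction, Robinson-Foulds (vs dendropy oracle), HGT candidates."""

import itertools

import dendropy
import numpy as np
import pytest

from cyanoscreen.phylo import read_newick
from cyanoscreen.synthetic_data import apply_hgt, simulate_species_tree
from cyanoscreen.tree_compare import (IncomparableTreesError, displaced_taxa,
                                      extract_clades, flag_novel_clades,
                                      prune_shared, robinson_foulds)


def _with_supports(nwk):
    return read_newick(nwk)


def test_extract_clades_all_supported():
    t = _with_supports("((a:1,b:1)100:1,(c:1,(d:1,e:1)100:1)100:1,f:1);")
    cs = extract_clades(t, 70.0)
    assert len(cs) == len(t.leaf_names()) - 3  # every internal edge of a binary tree


def test_extract_clades_threshold_filtering_and_monotonicity():
    t = _with_supports("((a:1,b:1)95:1,((c:1,d:1)60:1,(e:1,f:1)40:1)95:1,g:1);")
    at70 = extract_clades(t, 70.0)
    assert {frozenset(c.leaves) for c in at70.clades} >= {frozenset("ab")}
    assert all(c.support >= 70 for c in at70.clades)
    sizes = [len(extract_clades(t, thr)) for thr in (0, 40, 60, 70, 95, 101)]
    assert sizes == sorted(sizes, reverse=True)
    assert len(extract_clades(t, 101.0)) == 0


def test_extract_clades_requires_supports():
    t = read_newick("((a:1,b:1):1,c:1,d:1);")
    with pytest.raises(ValueError, match="bootstrap"):
        extract_clades(t, 70.0)


def test_rf_identical_and_maximally_different_quartets():
    t1 = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    t2 = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
    assert robinson_foulds(t1, t1).rf_distance == 0
    rep = robinson_foulds(t1, t2)
    assert rep.rf_distance == 2
    assert rep.max_rf == 2
    assert rep.normalized_rf == 1.0


def _random_binary_newick(names, rng):
    nodes = [f"{n}:1" for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):1")
    return f"({nodes[0]},{nodes[1]},{nodes[2]});"


def test_rf_matches_dendropy_on_fuzzed_pairs():
    rng = np.random.default_rng(77)
    taxa = dendropy.TaxonNamespace()
    for rep in range(100):
        n = int(rng.integers(4, 11))
        names = [f"t{i}" for i in range(n)]
        nwk1 = _random_binary_newick(names, rng)
        nwk2 = _random_binary_newick(names, rng)
        ours = robinson_foulds(read_newick(nwk1), read_newick(nwk2)).rf_distance
        d1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=taxa)
        d2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=taxa)
        theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert ours == theirs


def test_rf_is_a_metric_on_small_trees():
    rng = np.random.default_rng(13)
    names = [f"t{i}" for i in range(7)]
    trees = [read_newick(_random_binary_newick(names, rng)) for _ in range(12)]
    for a, b, c in itertools.combinations(trees, 3):
        ab = robinson_foulds(a, b).rf_distance
        bc = robinson_foulds(b, c).rf_distance
        ac = robinson_foulds(a, c).rf_distance
        assert ab == robinson_foulds(b, a).rf_distance
        assert ac <= ab + bc
    assert robinson_foulds(trees[0], trees[0]).rf_distance == 0


def test_prune_shared_sums_suppressed_branch_lengths():
    t1 = read_newick("((A:0.1,B:0.2):0.3,(C:0.4,D:0.5):0.6,E:0.7);")
    t2 = read_newick("((A:1,C:1):1,(D:1,E:1):1);")  # no B
    p1, p2 = prune_shared(t1, t2)
    assert sorted(p1.leaf_names()) == ["A", "C", "D", "E"]
    # A's pendant edge absorbs the suppressed node: 0.1 + 0.3
    a = next(l for l in p1.leaves() if l.name == "A")
    assert a.length == pytest.approx(0.4)


def test_prune_shared_rejects_insufficient_overlap():
    t1 = read_newick("((A:1,B:1):1,C:1,D:1);")
    t2 = read_newick("((A:1,B:1):1,C:1,X:1);")
    with pytest.raises(IncomparableTreesError):
        prune_shared(t1, t2)


def test_displaced_taxa_empty_for_congruent_trees():
    t = read_newick("((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);")
    assert displaced_taxa(t, t.copy()) == []


def test_displaced_taxa_finds_single_moved_leaf():
    species = simulate_species_tree(10, seed=3)
    gene, events = apply_hgt(species, 1, seed=4)
    moved = displaced_taxa(gene, species, budget=3)
    assert moved, "one SPR must leave measurable incongruence"
    recipients = {r for r, _ in events}
    assert moved[0][0] in recipients
    assert moved[-1][1] == 0  # removing the recipient restores congruence


def test_displaced_trajectory_strictly_decreases():
    rng = np.random.default_rng(5)
    for seed in range(6):
        species = simulate_species_tree(9, seed=seed)
        gene, _ = apply_hgt(species, 2, seed=seed + 50)
        traj = [rf for _, rf in displaced_taxa(gene, species, budget=5)]
        start = robinson_foulds(gene, species).rf_distance
        assert all(b < a for a, b in zip([start] + traj, traj))


def test_displaced_recovery_over_seeds():
    """With up to 3 transfers among 12 taxa the greedy removal recovers at
    least 2/3 of the true recipients on average."""
    fractions = []
    for seed in range(20):
        h = (seed % 3) + 1
        species = simulate_species_tree(12, seed=100 + seed)
        gene, events = apply_hgt(species, h, seed=200 + seed)
        recipients = {r for r, _ in events}
        removed = {t for t, _ in displaced_taxa(gene, species, budget=h)}
        fractions.append(len(removed & recipients) / h)
    assert np.mean(fractions) >= 2 / 3


def _supported_cladeset():
    t = _with_supports(
        "((q1:1,(q2:1,q3:1)90:1)95:1,((k1:1,q4:1)88:1,(k2:1,k3:1)91:1)85:1,out:1);")
    ann = {"q1": "query", "q2": "query", "q3": "query", "q4": "query",
           "k1": "anacyclamide", "k2": "piricyclamide", "k3": "microcyclamide",
           "out": "query"}
    return t, ann


def test_flag_novel_clades_requires_pure_query_membership():
    t, ann = _supported_cladeset()
    clades = extract_clades(t, 70.0, ann)
    novel = flag_novel_clades(clades, ann)
    leaf_sets = {frozenset(c.leaves) for c in novel}
    assert frozenset({"q1", "q2", "q3"}) in leaf_sets        # maximal pure-query clade
    assert frozenset({"q2", "q3"}) not in leaf_sets          # not maximal
    assert not any("k1" in s for s in leaf_sets)             # chemotype member blocks


def test_flag_novel_clades_errors_on_missing_annotation():
    t, ann = _supported_cladeset()
    clades = extract_clades(t, 70.0, ann)
    del ann["q4"]
    with pytest.raises(ValueError, match="annotation"):
        flag_novel_clades(clades, ann)


def test_flag_novel_clades_empty_cases():
    t, ann = _supported_cladeset()
    assert flag_novel_clades(extract_clades(t, 101.0), ann) == []
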