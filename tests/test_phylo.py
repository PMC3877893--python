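"""ML phylogenetics: closed-form, exhaustive and simulation oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from cyanoscreen.phylo import (BootstrapConfig, NewickError, SaturationError,
                               SubstitutionModel, UndefinedDistanceError,
                               bootstrap_support, build_ml_tree,
                               discrete_gamma_rates, k2p_distance,
                               log_likelihood, nj_tree, nni_search, optimize,
                               read_newick, transition_probability, write_newick)
from cyanoscreen.seq_io import GAP, IUPAC_SETS, Alignment, SequenceRecord
from cyanoscreen.synthetic_data import evolve_sequences

BASE = "ACGT"
IDX = {b: i for i, b in enumerate(BASE)}


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------

def test_k2p_distance_closed_form():
    a = "A" * 85 + "G" * 10 + "C" * 5
    b = "A" * 100
    r = k2p_distance(a, b)
    assert r.p_transitions == pytest.approx(0.1)
    assert r.q_transversions == pytest.approx(0.05)
    assert r.sites_compared == 100
    assert r.distance == pytest.approx(
        -0.5 * math.log(0.75) - 0.25 * math.log(0.90), abs=1e-10)


def test_k2p_identical_rows_and_pairwise_deletion():
    assert k2p_distance("ACGT", "ACGT").distance == 0.0
    r = k2p_distance("ACG-N", "ACGTA")
    assert r.sites_compared == 3  # gap and N columns dropped


def test_k2p_error_conditions():
    with pytest.raises(UndefinedDistanceError):
        k2p_distance("---N", "ACGT")
    with pytest.raises(SaturationError):
        k2p_distance("A" * 10, "G" * 10)  # P=1: log argument <= 0


def test_k2p_distance_is_symmetric():
    rng = np.random.default_rng(1)
    for _ in range(30):
        a = "".join(rng.choice(list("ACGT-N"), p=[.23, .23, .23, .23, .05, .03],
                               size=120))
        b = "".join(rng.choice(list("ACGT-N"), p=[.23, .23, .23, .23, .05, .03],
                               size=120))
        try:
            ra, rb = k2p_distance(a, b), k2p_distance(b, a)
        except (SaturationError, UndefinedDistanceError):
            continue
        assert ra == rb


# --------------------------------------------------------------------------
# model
# --------------------------------------------------------------------------

def test_discrete_gamma_rates_average_exactly_one():
    for alpha in (0.1, 0.5, 1.0, 5.0, 50.0):
        for K in (1, 2, 5, 8):
            rates = discrete_gamma_rates(alpha, K)
            assert len(rates) == K
            assert np.mean(rates) == pytest.approx(1.0, abs=1e-12)
            assert all(r > 0 for r in rates)
            assert list(rates) == sorted(rates)


def test_transition_probability_limits():
    m = SubstitutionModel(kappa=4.0)
    assert np.allclose(transition_probability(m, 0.0), np.eye(4))
    assert np.allclose(transition_probability(m, 500.0), np.full((4, 4), 0.25),
                       atol=1e-12)


def _k80_rate_matrix(kappa):
    b = 1.0 / (kappa + 2.0)      # transversion rate; mean total rate 1
    a = kappa * b
    Q = np.full((4, 4), b)
    pairs = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for x, y in pairs.items():
        Q[IDX[x], IDX[y]] = a
    np.fill_diagonal(Q, 0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def test_transition_probability_matches_matrix_exponential():
    for kappa in (0.5, 1.0, 2.0, 4.0, 10.0):
        Q = _k80_rate_matrix(kappa)
        m = SubstitutionModel(kappa=kappa)
        for t in (0.01, 0.1, 0.5, 1.0, 3.0):
            for r in (0.2, 1.0, 2.5):
                P = transition_probability(m, t, r)
                assert np.allclose(P, expm(Q * t * r), atol=1e-10)
                assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)


def test_kappa_one_reduces_to_jukes_cantor():
    m = SubstitutionModel(kappa=1.0)
    for t in (0.05, 0.2, 1.0):
        P = transition_probability(m, t)
        e = math.exp(-4.0 * t / 3.0)
        assert P[0, 0] == pytest.approx(0.25 + 0.75 * e, abs=1e-12)
        assert P[0, 1] == pytest.approx(0.25 - 0.25 * e, abs=1e-12)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def test_nj_three_taxa_closed_form():
    D = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
    t = nj_tree(D, ["A", "B", "C"])
    lengths = {n.name: n.length for n in t.leaves()}
    assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def _path_lengths(tree):
    import collections
    adj = collections.defaultdict(list)
    for n in tree.postorder():
        for c in n.children:
            adj[id(n)].append((id(c), c.length or 0.0))
            adj[id(c)].append((id(n), c.length or 0.0))
    leaves = tree.leaves()
    out = {}
    for a in leaves:
        dist = {id(a): 0.0}
        stack = [id(a)]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for b in leaves:
            out[(a.name, b.name)] = dist[id(b)]
    return out


def test_nj_recovers_additive_five_taxon_tree_exactly():
    src = read_newick("((A:0.11,B:0.23):0.05,(C:0.15,D:0.08):0.07,E:0.31);")
    D_map = _path_lengths(src)
    labels = ["A", "B", "C", "D", "E"]
    D = np.array([[D_map[(a, b)] for b in labels] for a in labels])
    t = nj_tree(D, labels)
    assert set(t.splits()) == set(src.splits())
    got = _path_lengths(t)
    for pair, d in D_map.items():
        assert got[pair] == pytest.approx(d, abs=1e-12)


def test_nj_topology_invariant_under_taxon_permutation():
    rng = np.random.default_rng(6)
    src = read_newick("((A:0.1,B:0.2):0.06,(C:0.12,D:0.18):0.09,(E:0.25,F:0.1):0.04);")
    D_map = _path_lengths(src)
    labels = ["A", "B", "C", "D", "E", "F"]
    ref_splits = None
    for _ in range(5):
        perm = list(rng.permutation(labels))
        D = np.array([[D_map[(a, b)] for b in perm] for a in perm])
        t = nj_tree(D, perm)
        if ref_splits is None:
            ref_splits = set(t.splits())
        assert set(t.splits()) == ref_splits


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0.0, np.inf], [np.inf, 0.0]]), ["a", "b"])
    with pytest.raises(ValueError):
        nj_tree(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def brute_loglik(tree, aln, model):
    """Exhaustive internal-state enumeration oracle (tiny trees only)."""
    rates = model.category_rates
    leaves = {r.id: r.residues for r in aln.records}
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    total = 0.0
    for site in range(aln.columns):
        inter = set(BASE)
        for r in aln.records:
            c = r.residues[site]
            inter &= set(IUPAC_SETS[c]) if c != GAP else set(BASE)
        linv = 0.25 * len(inter)
        lvar = 0.0
        for rate in rates:
            acc = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                st = dict(zip([id(n) for n in internal], assign))
                p = 0.25
                for n in nodes:
                    if n is tree.root:
                        continue
                    P = transition_probability(model, n.length or 0.0, rate)
                    par = st[id(n.parent)]
                    if n.is_leaf:
                        c = leaves[n.name][site]
                        bs = IUPAC_SETS[c] if c != GAP else BASE
                        p *= sum(P[par, IDX[b]] for b in bs)
                    else:
                        p *= P[par, st[id(n)]]
                acc += p
            lvar += acc / len(rates)
        total += math.log(model.p_inv * linv + (1 - model.p_inv) * lvar)
    return total


def test_two_identical_sequences_at_zero_length():
    aln = Alignment((SequenceRecord("a", "ACGTACGT"),
                     SequenceRecord("b", "ACGTACGT")))
    t = read_newick("(a:0.0,b:0.0);")
    m = SubstitutionModel(p_inv=0.0)
    assert log_likelihood(t, aln, m) == pytest.approx(8 * math.log(0.25))


def test_pruning_equals_exhaustive_enumeration():
    rng = np.random.default_rng(8)
    newicks = ["((a:0.1,b:0.2):0.05,(c:0.15,d:0.3):0.07);",
               "((a:0.1,b:0.2):0.05,(c:0.15,d:0.3):0.07,e:0.4);",
               "(((a:0.1,b:0.1):0.1,c:0.2):0.1,d:0.3,e:0.1);"]
    for nwk in newicks:
        t = read_newick(nwk)
        names = sorted(t.leaf_names())
        for draw in range(3):
            m = SubstitutionModel(kappa=float(rng.uniform(0.5, 8)),
                                  alpha=float(rng.uniform(0.2, 3)),
                                  p_inv=float(rng.uniform(0, 0.5)),
                                  n_categories=int(rng.integers(1, 5)))
            recs = [SequenceRecord(n, "".join(
                rng.choice(list("ACGTN-"), p=[.22, .22, .22, .22, .06, .06],
                           size=7))) for n in names]
            try:
                aln = Alignment(tuple(recs))
            except ValueError:
                continue
            assert log_likelihood(t, aln, m) == pytest.approx(
                brute_loglik(t, aln, m), abs=1e-10)


def test_likelihood_is_rooting_invariant():
    """Pulley principle: the same unrooted tree rooted at different internal
    edges gives the same likelihood under the reversible model."""
    m = SubstitutionModel()
    rng = np.random.default_rng(12)
    recs = [SequenceRecord(n, "".join(rng.choice(list(BASE), size=60)))
            for n in "abcd"]
    aln = Alignment(tuple(recs))
    rootings = [
        "((a:0.1,b:0.2):0.07,(c:0.15,d:0.3):0.0);",
        "((c:0.15,d:0.3):0.07,(a:0.1,b:0.2):0.0);",
        "(a:0.1,b:0.2,(c:0.15,d:0.3):0.07);",
    ]
    vals = [log_likelihood(read_newick(nwk), aln, m) for nwk in rootings]
    assert vals[0] == pytest.approx(vals[1], abs=1e-9)
    assert vals[0] == pytest.approx(vals[2], abs=1e-9)


def test_gamma_with_huge_alpha_reduces_to_plain_k2p():
    rng = np.random.default_rng(3)
    recs = [SequenceRecord(n, "".join(rng.choice(list(BASE), size=200)))
            for n in "abcd"]
    aln = Alignment(tuple(recs))
    t = read_newick("((a:0.1,b:0.2):0.05,(c:0.15,d:0.3):0.07);")
    rich = SubstitutionModel(kappa=3.0, alpha=1e6, p_inv=0.0, n_categories=5)
    plain = SubstitutionModel(kappa=3.0, alpha=1.0, p_inv=0.0, n_categories=1)
    per_site_rich = log_likelihood(t, aln, rich) / aln.columns
    per_site_plain = log_likelihood(t, aln, plain) / aln.columns
    assert per_site_rich == pytest.approx(per_site_plain, abs=1e-6)


def test_two_taxon_ml_branch_length_equals_k2p_distance():
    m = SubstitutionModel(kappa=4.0, alpha=1.0, p_inv=0.0, n_categories=1)
    tree = read_newick("(a:0.1,b:0.1);")
    _, leaves, _ = evolve_sequences(read_newick("(a:0.12,b:0.12);"), m, 3000,
                                    seed=3)
    aln = Alignment(tuple(SequenceRecord(k, v) for k, v in sorted(leaves.items())))
    fit_tree, _, _ = optimize(tree, aln, m, fit_model=True,
                              fit_params=("kappa",), xatol=1e-8)
    total = sum(n.length for n in fit_tree.leaves())
    d = k2p_distance(aln.records[0].residues, aln.records[1].residues).distance
    assert total == pytest.approx(d, abs=1e-4)


def test_optimize_never_decreases_loglik_and_is_a_fixed_point(small_model):
    tree = read_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.05);")
    aln, _, _ = evolve_sequences(tree, small_model, 500, seed=21)
    start = read_newick("((a:0.5,b:0.01):0.5,(c:0.5,d:0.01):0.5);")
    before = log_likelihood(start, aln, small_model)
    fit_tree, fitted, logl = optimize(start, aln, small_model)
    assert logl >= before
    # fixed point of the converged branch-length optimizer
    bl_tree, _, bl_logl = optimize(fit_tree, aln, fitted, fit_model=False)
    _, _, bl_logl2 = optimize(bl_tree, aln, fitted, fit_model=False)
    assert abs(bl_logl2 - bl_logl) < 1e-5


def test_nni_keeps_true_tree_and_never_decreases_loglik(small_model):
    true = read_newick("((a:0.2,b:0.2):0.15,(c:0.2,d:0.2):0.05);")
    aln, _, _ = evolve_sequences(true, small_model, 1500, seed=31)
    fit_tree, fit_model, logl = optimize(true, aln, small_model)
    out, out_logl = nni_search(fit_tree, aln, fit_model)
    assert out_logl >= logl - 1e-9
    assert set(out.splits()) == set(true.splits())


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def test_bootstrap_is_deterministic_and_supports_clean_splits(small_model):
    true = read_newick(
        "(((a:0.15,b:0.15):0.12,(c:0.15,d:0.15):0.12):0.1,e:0.2,f:0.2);")
    aln, _, _ = evolve_sequences(true, small_model, 600, seed=41)
    best, fitted, _ = build_ml_tree(aln, small_model)
    cfg = BootstrapConfig(n_replicates=20, seed=7)
    t1 = bootstrap_support(aln, fitted, cfg, best)
    t2 = bootstrap_support(aln, fitted, cfg, best)
    s1 = {s: n.support for s, n in t1.splits().items()}
    s2 = {s: n.support for s, n in t2.splits().items()}
    assert s1 == s2
    for s in true.splits():
        if s in s1:
            assert s1[s] >= 80.0  # strong signal at modest replicate count


# --------------------------------------------------------------------------
# Newick I/O
# --------------------------------------------------------------------------

def test_newick_round_trip_byte_identical():
    src = "(A:0.1,B:0.2,(C:0.3,D:0.4)95:0.05);"
    assert write_newick(read_newick(src)) == src


@pytest.mark.parametrize("bad", [
    "(A,B;", "(A,B))C;", "(A:0.1,B:0.2)", "(A,);", ";", "(A,B);junk"])
def test_newick_parse_errors_carry_offsets(bad):
    with pytest.raises(NewickError) as exc:
        read_newick(bad)
    assert exc.value.offset >= 0


def test_newick_fuzzed_round_trip():
    rng = np.random.default_rng(55)

    def random_tree(names):
        if len(names) == 1:
            return f"{names[0]}:{rng.uniform(0.01, 2):.6f}"
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        sup = int(rng.integers(0, 101))
        return (f"({random_tree(left)},{random_tree(right)})"
                f"{sup}:{rng.uniform(0.01, 2):.6f}")

    for rep in range(25):
        n = int(rng.integers(3, 9))
        names = [f"t{i}" for i in range(n)]
        nwk = f"({random_tree(names[:1])},{random_tree(names[1:2])},{random_tree(names[2:])});"
        once = write_newick(read_newick(nwk))
        assert write_newick(read_newick(once)) == once
        t = read_newick(nwk)
        u = read_newick(once)
        assert set(t.splits()) == set(u.splits())
        assert sorted(t.leaf_names()) == sorted(u.leaf_names())
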