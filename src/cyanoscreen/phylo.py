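"""Maximum-likelihood phylogenetics under K2P+Γ+I.

The tree-building core of the screen: Kimura 2-parameter distances with
pairwise deletion, neighbor-joining starting trees, log-likelihood by
Felsenstein pruning under the K80 model with discrete-gamma rate
heterogeneity (default 5 categories) plus a proportion of invariant
sites, coordinate-ascent optimization of branch lengths and model
parameters, NNI hill climbing, and nonparametric bootstrap supports
mapped onto the best tree. Trees are unrooted (stored rooted at an
arbitrary trifurcation) and Newick-serializable with supports as internal
node labels.

Conventions: base order A, C, G, T; equal base frequencies are implied by
K2P and never parameterized; branch lengths in expected substitutions per
site; supports in [0, 100].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable, Iterator, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, gammaincinv

from .seq_io import GAP, IUPAC_SETS, Alignment, SequenceRecord

__all__ = [
    "SubstitutionModel", "DistanceResult", "PhyloNode", "PhyloTree",
    "BootstrapConfig", "UndefinedDistanceError", "SaturationError", "NewickError",
    "discrete_gamma_rates", "k2p_distance", "distance_matrix", "nj_tree",
    "transition_probability", "log_likelihood", "LikelihoodEngine", "optimize",
    "nni_search", "build_ml_tree", "bootstrap_support", "read_newick", "write_newick",
]

_PLAIN = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_PLAIN)}
_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


class UndefinedDistanceError(ValueError):
    """No comparable sites between two rows."""


class SaturationError(ValueError):
    """K2P log argument non-positive: divergence beyond the estimator's range."""


class NewickError(ValueError):
    def __init__(self, message: str, offset: int):
        self.offset = offset
        super().__init__(f"{message} (offset {offset})")


# --------------------------------------------------------------------------
# substitution model
# --------------------------------------------------------------------------

@lru_cache(maxsize=128)
def discrete_gamma_rates(alpha: float, n_categories: int) -> tuple[float, ...]:
    """Mean rates of equal-probability slices of Gamma(alpha, alpha).

    Renormalized so the rates average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    K = int(n_categories)
    if K < 1:
        raise ValueError("need at least one rate category")
    if K == 1:
        return (1.0,)
    # slice boundaries of Gamma(shape=alpha, rate=alpha)
    qs = np.arange(1, K) / K
    bounds = gammaincinv(alpha, qs) / alpha
    # mean of a slice via the shape alpha+1 regularized incomplete gamma
    cum = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * bounds), [1.0]])
    rates = K * np.diff(cum)
    rates = rates / rates.mean()
    return tuple(float(r) for r in rates)


@dataclass(frozen=True)
class SubstitutionModel:
    """K2P+Γ+I parameters: kappa, gamma shape alpha, p_inv, K categories."""

    kappa: float = 4.0
    alpha: float = 0.5
    p_inv: float = 0.1
    n_categories: int = 5

    def __post_init__(self):
        if self.kappa <= 0 or self.alpha <= 0:
            raise ValueError("kappa and alpha must be > 0")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")

    @property
    def category_rates(self) -> tuple[float, ...]:
        return discrete_gamma_rates(self.alpha, self.n_categories)


_TI_MASK = np.zeros((4, 4), dtype=bool)
_EYE = np.eye(4, dtype=bool)
for _b, _i in _BASE_INDEX.items():
    _TI_MASK[_i, _BASE_INDEX[_TRANSITION_PARTNER[_b]]] = True
_TV_MASK = ~(_TI_MASK | _EYE)


def _k80_batch(kappa: float, t: float, rates: np.ndarray) -> np.ndarray:
    """K80 transition matrices for one branch at several rates: (K, 4, 4)."""
    rt = t * rates
    e1 = np.exp(-4.0 * rt / (kappa + 2.0))
    e2 = np.exp(-2.0 * rt * (kappa + 1.0) / (kappa + 2.0))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.empty((len(rates), 4, 4))
    P[:, _EYE] = p_same[:, None]
    P[:, _TI_MASK] = p_ti[:, None]
    P[:, _TV_MASK] = np.repeat(p_tv[:, None], 8, axis=1)
    return P


def transition_probability(model: SubstitutionModel, t: float, r: float = 1.0) -> np.ndarray:
    """K80 transition matrix at effective branch length r*t (rows sum to 1)."""
    if t < 0 or r <= 0:
        raise ValueError("require t >= 0 and r > 0")
    k = model.kappa
    rt = r * t
    e1 = math.exp(-4.0 * rt / (k + 2.0))
    e2 = math.exp(-2.0 * rt * (k + 1.0) / (k + 2.0))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.full((4, 4), p_tv)
    for b, i in _BASE_INDEX.items():
        P[i, i] = p_same
        P[i, _BASE_INDEX[_TRANSITION_PARTNER[b]]] = p_ti
    return P


# --------------------------------------------------------------------------
# K2P distances
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceResult:
    p_transitions: float
    q_transversions: float
    sites_compared: int
    distance: float


def k2p_distance(row_a: str, row_b: str) -> DistanceResult:
    """Kimura 2-parameter distance with pairwise deletion.

    Sites where either row carries a gap or an ambiguity code are excluded.
    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    n = ti = tv = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a not in _BASE_INDEX or b not in _BASE_INDEX:
            continue
        n += 1
        if a != b:
            if _TRANSITION_PARTNER[a] == b:
                ti += 1
            else:
                tv += 1
    if n == 0:
        raise UndefinedDistanceError("no comparable (ungapped, unambiguous) sites")
    P, Q = ti / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined for P={P:.4f}, Q={Q:.4f} (saturated)")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceResult(P, Q, n, d)


def distance_matrix(alignment: Alignment, on_saturation: str = "error",
                    cap: float = 5.0) -> np.ndarray:
    """All-pairs K2P distance matrix.

    ``on_saturation="cap"`` substitutes ``cap`` for saturated or undefined
    pairs instead of raising — used by the bootstrap driver, where column
    resampling can push a pair past the estimator's range.
    """
    n = len(alignment)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = k2p_distance(alignment.records[i].residues,
                                 alignment.records[j].residues).distance
            except (SaturationError, UndefinedDistanceError):
                if on_saturation != "cap":
                    raise
                d = cap
            D[i, j] = D[j, i] = d
    return D


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

class PhyloNode:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[PhyloNode] = []
        self.parent: PhyloNode | None = None

    def add(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    def detach(self) -> "PhyloNode":
        if self.parent is not None:
            self.parent.children.remove(self)
            self.parent = None
        return self

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree stored with an arbitrary rooting; Newick-serializable."""

    def __init__(self, root: PhyloNode):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[PhyloNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[PhyloNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def copy(self) -> "PhyloTree":
        def rec(node: PhyloNode) -> PhyloNode:
            new = PhyloNode(node.name, node.length, node.support)
            for c in node.children:
                new.add(rec(c))
            return new
        return PhyloTree(rec(self.root))

    # -- splits ------------------------------------------------------------

    def splits(self) -> dict[frozenset, PhyloNode]:
        """Canonical non-trivial bipartitions -> node below the defining edge.

        A split is represented by the leaf set on the side *not* containing
        the lexicographically smallest leaf.
        """
        all_leaves = frozenset(self.leaf_names())
        if len(all_leaves) != len(self.leaves()):
            raise ValueError("duplicate leaf labels")
        ref = min(all_leaves)
        below: dict[int, frozenset] = {}
        out: dict[frozenset, PhyloNode] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                clade = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = clade
                if node is self.root:
                    continue
                if 2 <= len(clade) <= len(all_leaves) - 2:
                    side = clade if ref not in clade else all_leaves - clade
                    out[side] = node
        return out

    def clade_leaves(self, node: PhyloNode) -> frozenset:
        out = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.add(n.name)
            stack.extend(n.children)
        return frozenset(out)

    # -- pruning -----------------------------------------------------------

    def prune_to(self, keep: set[str]) -> "PhyloTree":
        """Restrict to a leaf subset; degree-2 nodes are suppressed with
        branch lengths summed."""

        def rec(node: PhyloNode) -> PhyloNode | None:
            if node.is_leaf:
                if node.name in keep:
                    return PhyloNode(node.name, node.length, node.support)
                return None
            kept = [rec(c) for c in node.children]
            kept = [c for c in kept if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if child.length is not None or node.length is not None:
                    child.length = (child.length or 0.0) + (node.length or 0.0)
                return child
            new = PhyloNode(node.name, node.length, node.support)
            for c in kept:
                new.add(c)
            return new

        new_root = rec(self.root)
        if new_root is None:
            raise ValueError("pruning removed every leaf")
        # a root left with a single child is collapsed into that child
        while not new_root.is_leaf and len(new_root.children) == 1:
            new_root = new_root.children[0]
            new_root.parent = None
            new_root.length = None
        return PhyloTree(new_root)


# -- Newick ----------------------------------------------------------------

def _fmt_num(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def write_newick(tree: PhyloTree) -> str:
    """Serialize with canonical child ordering (by smallest leaf label);
    supports written as internal node labels, lengths to 6 decimals."""

    def min_leaf(node: PhyloNode) -> str:
        return node.name if node.is_leaf else min(min_leaf(c) for c in node.children)

    def rec(node: PhyloNode) -> str:
        if node.is_leaf:
            s = node.name
        else:
            kids = sorted(node.children, key=min_leaf)
            s = "(" + ",".join(rec(c) for c in kids) + ")"
            if node.support is not None:
                sup = node.support
                s += str(int(sup)) if float(sup).is_integer() else _fmt_num(sup)
            elif node.name:
                s += node.name
        if node.length is not None:
            s += ":" + _fmt_num(node.length)
        return s

    return rec(tree.root) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse Newick; numeric internal labels become bootstrap supports."""
    s = text.strip()
    pos = 0

    def err(msg: str):
        raise NewickError(msg, pos)

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_number(what: str) -> float:
        nonlocal pos
        start = pos
        while pos < len(s) and (s[pos] in "+-.eE" or s[pos].isdigit()):
            pos += 1
        try:
            return float(s[start:pos])
        except ValueError:
            err(f"malformed {what}")

    def parse_node() -> PhyloNode:
        nonlocal pos
        node = PhyloNode()
        if peek() == "(":
            pos += 1
            node.add(parse_node())
            while peek() == ",":
                pos += 1
                node.add(parse_node())
            if peek() != ")":
                err("unbalanced parenthesis")
            pos += 1
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            name = parse_label()
            if not name:
                err("expected a leaf label")
            node.name = name
        if peek() == ":":
            pos += 1
            node.length = parse_number("branch length")
        return node

    root = parse_node()
    if peek() != ";":
        err("expected ';' at end of tree")
    pos += 1
    if s[pos:].strip():
        err("trailing characters after ';'")
    if root.is_leaf:
        err("tree must have more than one leaf")
    return PhyloTree(root)


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def nj_tree(D: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaks.

    Pair choice minimizes the Q criterion, ties broken lexicographically on
    the joined clusters' labels (a cluster's label is its smallest leaf).
    Negative branch lengths are clamped to 0. Returns an unrooted tree
    (trifurcating root) for n >= 3.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distance entries")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(labels)) != n:
        raise ValueError("duplicate taxon labels")

    if n == 2:
        root = PhyloNode()
        for l in labels:
            root.add(PhyloNode(name=l, length=max(D[0, 1] / 2.0, 0.0)))
        return PhyloTree(root)

    # preallocate for all 2n-3 clusters created along the way
    total = 2 * n - 2
    M = np.zeros((total, total))
    M[:n, :n] = D
    nodes = [PhyloNode(name=l) for l in labels] + [None] * (total - n)
    clabel = list(labels) + [""] * (total - n)
    active = list(range(n))
    nxt = n

    while len(active) > 3:
        m = len(active)
        sub = M[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - r[ai] - r[aj]
                la, lb = sorted((clabel[active[ai]], clabel[active[aj]]))
                key = (q, la, lb)
                if best is None or key < best[0]:
                    best = (key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(dij - li, 0.0)
        new = PhyloNode()
        new.add(nodes[i])
        new.add(nodes[j])
        for k in active:
            if k not in (i, j):
                M[nxt, k] = M[k, nxt] = max(0.5 * (M[i, k] + M[j, k] - dij), 0.0)
        nodes[nxt] = new
        clabel[nxt] = min(clabel[i], clabel[j])
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    i, j, k = active
    root = PhyloNode()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        nodes[a].length = max(0.5 * (M[a, b] + M[a, c] - M[b, c]), 0.0)
        root.add(nodes[a])
    return PhyloTree(root)


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

_CODE_VECTOR = {
    code: np.array([1.0 if b in bases else 0.0 for b in _PLAIN])
    for code, bases in IUPAC_SETS.items()
}
_CODE_VECTOR[GAP] = np.ones(4)


class LikelihoodEngine:
    """Pattern-compressed pruning likelihood for one alignment.

    Site likelihood under K2P+Γ+I:

        L(site) = p_inv * L_inv(site) + (1 - p_inv) * (1/K) * sum_k L(site | r_k)

    where L_inv is 1/4 per base compatible with every leaf (0 when the
    per-leaf base sets have empty intersection) and L(.|r_k) is the pruning
    likelihood at category rate r_k with uniform root frequencies.
    """

    def __init__(self, alignment: Alignment):
        self.ids = alignment.ids()
        codes = np.array([[c for c in r.residues] for r in alignment.records])
        patterns, weights = np.unique(codes, axis=1, return_counts=True)
        self.weights = weights.astype(float)
        self.npat = patterns.shape[1]
        self.leaf_partials: dict[str, np.ndarray] = {}
        for row, rid in zip(patterns, self.ids):
            self.leaf_partials[rid] = np.stack([_CODE_VECTOR[c] for c in row])
        # invariant-site component: 1/4 per base compatible with all leaves
        inter = np.ones((self.npat, 4), dtype=bool)
        for rid in self.ids:
            inter &= self.leaf_partials[rid] > 0
        self.inv_lik = 0.25 * inter.sum(axis=1)

    def _site_to_loglik(self, site_var: np.ndarray, p_inv: float) -> float:
        site = p_inv * self.inv_lik + (1.0 - p_inv) * site_var
        return float(np.dot(self.weights, np.log(np.maximum(site, 1e-300))))

    def log_likelihood(self, tree: PhyloTree, model: SubstitutionModel) -> float:
        rates = np.array(model.category_rates)
        K = len(rates)
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                if node.name not in self.leaf_partials:
                    raise ValueError(f"leaf {node.name!r} absent from alignment")
                continue
            acc = np.ones((self.npat, K, 4))
            for child in node.children:
                t = child.length if child.length is not None else 0.0
                P = _k80_batch(model.kappa, t, rates)
                if child.is_leaf:
                    contrib = np.einsum("pj,kij->pki", self.leaf_partials[child.name], P)
                else:
                    contrib = np.einsum("pkj,kij->pki", partial.pop(id(child)), P)
                acc *= contrib
            partial[id(node)] = acc
        root = partial[id(tree.root)]
        site_var = 0.25 * root.sum(axis=2).mean(axis=1)
        return self._site_to_loglik(site_var, model.p_inv)

    # -- edge-vector caching for fast branch-length optimization ----------

    def _edge_vectors(self, tree: PhyloTree, model: SubstitutionModel):
        """Below/above conditional-likelihood vectors for every edge.

        ``below[e]`` conditions on the state at the child end of edge e,
        ``above[e]`` on the state at the parent end (root frequencies 1/4
        folded in), so the likelihood is bilinear in the edge's transition
        matrix:  L_k(site) = above_e . P_k(t) . below_e.
        """
        rates = np.array(model.category_rates)
        K = len(rates)
        below: dict[int, np.ndarray] = {}
        contrib: dict[int, np.ndarray] = {}
        order = list(tree.postorder())
        for node in order:
            if node.is_leaf:
                below[id(node)] = self.leaf_partials[node.name][:, None, :] * np.ones((1, K, 1))
                continue
            acc = np.ones((self.npat, K, 4))
            for child in node.children:
                t = child.length if child.length is not None else 0.0
                P = _k80_batch(model.kappa, t, rates)
                con = np.einsum("pkj,kij->pki", below[id(child)], P)
                contrib[id(child)] = con
                acc = acc * con
            below[id(node)] = acc
        above: dict[int, np.ndarray] = {id(tree.root): np.full((self.npat, K, 4), 0.25)}
        for node in order[::-1]:
            if node.is_leaf:
                continue
            a_u = above[id(node)]
            if node is not tree.root:
                # carry the outside partial through this node's own edge
                P = _k80_batch(model.kappa, node.length or 0.0, rates)
                a_u = np.einsum("pki,kij->pkj", a_u, P)
            for c in node.children:
                prod = a_u
                for s in node.children:
                    if s is not c:
                        prod = prod * contrib[id(s)]
                above[id(c)] = prod
        return below, above, rates

    def edge_loglik_fn(self, tree: PhyloTree, model: SubstitutionModel,
                       node: PhyloNode) -> Callable[[float], float]:
        """Log-likelihood as a function of one branch length, with the rest
        of the tree held fixed (vectors recomputed on call)."""
        below, above, rates = self._edge_vectors(tree, model)
        b, a = below[id(node)], above[id(node)]
        half = np.einsum("pki,pkj->pkij", a, b)

        def f(t: float) -> float:
            P = _k80_batch(model.kappa, t, rates)
            site_var = np.einsum("pkij,kij->p", half, P) / len(rates)
            return self._site_to_loglik(site_var, model.p_inv)

        return f

    def sweep_branches(self, tree: PhyloTree, model: SubstitutionModel,
                       xatol: float, nodes: Sequence[PhyloNode] | None = None,
                       ) -> float:
        """One coordinate-ascent pass over branch lengths (in place).

        Each branch is refit by bounded scalar maximization against fresh
        edge vectors; a proposal is kept only if it improves. Returns the
        full log-likelihood of the final configuration.
        """
        targets = nodes if nodes is not None else _branch_nodes(tree)
        for node in targets:
            f = self.edge_loglik_fn(tree, model, node)
            orig = node.length if node.length is not None else 0.0
            x, val = _maximize_scalar(f, *_BL_BOUNDS, xatol)
            if val > f(orig):
                node.length = x
        return self.log_likelihood(tree, model)


def log_likelihood(tree: PhyloTree, alignment: Alignment, model: SubstitutionModel) -> float:
    """Log-likelihood of an alignment on a tree under K2P+Γ+I."""
    leaf_set = set(tree.leaf_names())
    if leaf_set != set(alignment.ids()):
        raise ValueError("tree leaves and alignment ids differ")
    return LikelihoodEngine(alignment).log_likelihood(tree, model)


def _maximize_scalar(f: Callable[[float], float], lo: float, hi: float,
                     xatol: float) -> tuple[float, float]:
    res = minimize_scalar(lambda x: -f(x), bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    return float(res.x), float(-res.fun)


_BL_BOUNDS = (1e-8, 10.0)


def _branch_nodes(tree: PhyloTree) -> list[PhyloNode]:
    return [n for n in tree.postorder() if n is not tree.root]


def optimize(tree: PhyloTree, alignment: Alignment, model: SubstitutionModel,
             tol: float = 1e-6, max_sweeps: int = 50,
             fit_model: bool = True, xatol: float = 1e-6,
             engine: LikelihoodEngine | None = None,
             fit_params: tuple[str, ...] = ("kappa", "alpha", "p_inv"),
             ) -> tuple[PhyloTree, SubstitutionModel, float]:
    """Coordinate-ascent fit of branch lengths (and optionally kappa, alpha,
    p_inv) by repeated bounded scalar maximization.

    Sweeps repeat until the log-likelihood gain drops below ``tol``; the
    log-likelihood never decreases across sweeps (a proposed update is kept
    only when it improves). Non-convergence after ``max_sweeps`` warns and
    returns the best configuration so far.
    """
    tree = tree.copy()
    eng = engine or LikelihoodEngine(alignment)
    cur_model = model
    cur = eng.log_likelihood(tree, cur_model)
    converged = False
    for _ in range(max_sweeps):
        start = cur
        val = eng.sweep_branches(tree, cur_model, xatol)
        cur = max(cur, val)
        if fit_model:
            for attr, lo, hi in (("kappa", 0.1, 100.0), ("alpha", 0.05, 50.0),
                                 ("p_inv", 0.0, 0.99)):
                if attr not in fit_params:
                    continue

                def g(v: float, attr=attr) -> float:
                    return eng.log_likelihood(tree, replace(cur_model, **{attr: v}))

                x, val = _maximize_scalar(g, lo, hi, xatol)
                if val > cur:
                    cur_model, cur = replace(cur_model, **{attr: x}), val
        if cur - start < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"optimize: no convergence after {max_sweeps} sweeps; "
                      "returning best configuration so far")
    return tree, cur_model, cur


def _internal_edges(tree: PhyloTree) -> list[PhyloNode]:
    """Internal (non-root) nodes whose edge to the parent is internal,
    ordered by the sorted leaf tuple of their clade (deterministic)."""
    edges = [n for n in tree.postorder()
             if not n.is_leaf and n is not tree.root]
    return sorted(edges, key=lambda n: tuple(sorted(tree.clade_leaves(n))))


def nni_search(tree: PhyloTree, alignment: Alignment, model: SubstitutionModel,
               xatol: float = 1e-6, max_rounds: int = 20,
               engine: LikelihoodEngine | None = None,
               ) -> tuple[PhyloTree, float]:
    """NNI hill climbing with quartet branch-length re-optimization.

    For every internal edge both rearrangements are evaluated with the five
    edges around the swap re-optimized; the single best strictly improving
    move is accepted and the scan repeats until no edge improves. The
    returned log-likelihood is never below the starting one.
    """
    eng = engine or LikelihoodEngine(alignment)
    tree = tree.copy()
    cur = eng.log_likelihood(tree, model)

    def quartet_opt(work: PhyloTree, v: PhyloNode, u: PhyloNode) -> float:
        score = eng.log_likelihood(work, model)
        local = list(v.children) + [v] + [c for c in u.children if c is not v]
        if u is not work.root:
            local.append(u)
        for _ in range(2):
            val = eng.sweep_branches(work, model, xatol, nodes=local)
            if val - score < 1e-6:
                return max(score, val)
            score = val
        return score

    def min_leaf(node: PhyloNode) -> str:
        return node.name if node.is_leaf else min(min_leaf(c) for c in node.children)

    def clades_of(t: PhyloTree) -> dict[frozenset, PhyloNode]:
        return {t.clade_leaves(nd): nd
                for nd in t.postorder() if not nd.is_leaf and nd is not t.root}

    for _ in range(max_rounds):
        best_move: tuple[float, PhyloTree] | None = None
        edge_clades = [tree.clade_leaves(v) for v in _internal_edges(tree)]
        for vclade in edge_clades:
            for which_child in (0, 1):
                work = tree.copy()
                v = clades_of(work)[vclade]
                u = v.parent
                siblings = sorted((c for c in u.children if c is not v), key=min_leaf)
                y = siblings[0]
                x = sorted(v.children, key=min_leaf)[which_child]
                # swap subtree x (below v) with subtree y (beside v)
                xi, yi = v.children.index(x), u.children.index(y)
                v.children[xi], u.children[yi] = y, x
                x.parent, y.parent = u, v
                val = quartet_opt(work, v, u)
                if val > cur + 1e-9 and (best_move is None or val > best_move[0]):
                    best_move = (val, work)
        if best_move is None:
            break
        cur, tree = best_move
    return tree, cur


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def _resample_alignment(alignment: Alignment, rng: np.random.Generator) -> Alignment:
    ncol = alignment.columns
    idx = rng.integers(0, ncol, size=ncol)
    recs = [SequenceRecord(r.id, "".join(r.residues[j] for j in idx), r.description)
            for r in alignment.records]
    return Alignment(tuple(recs))


def build_ml_tree(alignment: Alignment, model: SubstitutionModel,
                  fit_model: bool = True, tol: float = 1e-6,
                  max_sweeps: int = 50, xatol: float = 1e-6,
                  ) -> tuple[PhyloTree, SubstitutionModel, float]:
    """NJ starting tree -> branch/model optimization -> NNI search."""
    D = distance_matrix(alignment, on_saturation="cap")
    start = nj_tree(D, alignment.ids())
    eng = LikelihoodEngine(alignment)
    tree, fitted, _ = optimize(start, alignment, model, tol=tol,
                               max_sweeps=max_sweeps, fit_model=fit_model,
                               xatol=xatol, engine=eng)
    tree, logl = nni_search(tree, alignment, fitted, xatol=xatol, engine=eng)
    return tree, fitted, logl


def bootstrap_support(alignment: Alignment, model: SubstitutionModel,
                      config: BootstrapConfig, best_tree: PhyloTree,
                      refit_per_replicate: bool = False,
                      replicate_tol: float = 1e-4,
                      replicate_sweeps: int = 8,
                      replicate_xatol: float = 1e-4) -> PhyloTree:
    """Nonparametric bootstrap supports mapped onto the best tree.

    Replicate r resamples columns with a generator seeded ``seed + r``,
    reruns NJ -> optimize -> NNI (model parameters fixed at the fit from
    the original alignment unless ``refit_per_replicate``), and each
    internal edge's support is the percentage of replicate trees containing
    the same bipartition.
    """
    if set(best_tree.leaf_names()) != set(alignment.ids()):
        raise ValueError("best tree leaves and alignment ids differ")
    counts: dict[frozenset, int] = {s: 0 for s in best_tree.splits()}
    for r in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + r)
        rep = _resample_alignment(alignment, rng)
        with warnings.catch_warnings():
            # replicates run with deliberately loose convergence settings
            warnings.simplefilter("ignore")
            rep_tree, _, _ = build_ml_tree(rep, model, fit_model=refit_per_replicate,
                                           tol=replicate_tol, max_sweeps=replicate_sweeps,
                                           xatol=replicate_xatol)
        rep_splits = set(rep_tree.splits())
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    out = best_tree.copy()
    for split, node in out.splits().items():
        node.support = 100.0 * counts[split] / config.n_replicates
    return out
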