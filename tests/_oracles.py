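"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — enumeration, closed forms, direct
summation — and shares no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# hypergeometric tail probabilities from log-factorials

def log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeom_pmf(j: int, N: int, K: int, n: int) -> float:
    lp = log_comb(K, j) + log_comb(N - K, n - j) - log_comb(N, n)
    return 0.0 if lp == -math.inf else math.exp(lp)


def hypergeom_tails(k: int, N: int, K: int, n: int) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)) by direct pmf summation."""
    upper = sum(hypergeom_pmf(j, N, K, n) for j in range(k, n + 1))
    lower = sum(hypergeom_pmf(j, N, K, n) for j in range(0, k + 1))
    return min(upper, 1.0), min(lower, 1.0)


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini–Hochberg by the literal min-over-suffix formula."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = math.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, m * p[order[rank]] / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


# ---------------------------------------------------------------------------
# simple nested-tuple trees for enumeration oracles
#
# A tree is either a leaf (any non-tuple payload) or a tuple of subtrees.

def topologies(leaves: tuple) -> list:
    """All rooted binary topologies over an ordered leaf sequence."""
    if len(leaves) == 1:
        return [leaves[0]]
    out = []
    for i in range(1, len(leaves)):
        for l in topologies(leaves[:i]):
            for r in topologies(leaves[i:]):
                out.append((l, r))
    return out


def tuple_nodes(t):
    """Post-order list of all nodes (subtrees) of a nested-tuple tree."""
    if not isinstance(t, tuple):
        return [t]
    out = []
    for child in t:
        out += tuple_nodes(child)
    return out + [t]


def tuple_to_newick(t, lengths=None) -> str:
    def render(x):
        if not isinstance(x, tuple):
            core = str(x)
        else:
            core = "(" + ",".join(render(c) for c in x) + ")"
        L = 1.0 if lengths is None else lengths.get(x, 1.0)
        return f"{core}:{L}"
    return render(t)[: -len(":1.0")] + ";" if lengths is None else render(t) + ";"


# ---------------------------------------------------------------------------
# duplication-loss reconciliation cost by exhaustive enumeration
#
# species tree given in the same nested-tuple form with string leaves.

def _sp_index(sp):
    """(nodes, parent index, leaf clade bitmask helpers) for a tuple tree."""
    nodes = tuple_nodes(sp)
    pos = {id(n): i for i, n in enumerate(nodes)}
    parent = [-1] * len(nodes)
    for i, n in enumerate(nodes):
        if isinstance(n, tuple):
            for c in n:
                parent[pos[id(c)]] = i
    depth = [0] * len(nodes)
    for i in range(len(nodes) - 1, -1, -1):  # post-order ids: parents come later
        if parent[i] != -1:
            depth[i] = depth[parent[i]] + 1
    return nodes, pos, parent, depth


def _ancestors(i, parent):
    out = []
    while i != -1:
        out.append(i)
        i = parent[i]
    return out


def dl_min_cost(gene, species) -> int:
    """Minimum duplications + losses over all monotone reconciliations.

    *gene* is a nested-tuple gene tree with species-name string leaves;
    *species* a nested-tuple species tree with string leaves.
    """
    sp_nodes, sp_pos, sp_parent, sp_depth = _sp_index(species)
    leaf_id = {n: i for i, n in enumerate(sp_nodes) if not isinstance(n, tuple)}

    g_nodes = tuple_nodes(gene)
    g_pos = {id(n): i for i, n in enumerate(g_nodes)}
    g_children = [[g_pos[id(c)] for c in n] if isinstance(n, tuple) else []
                  for n in g_nodes]
    internal = [i for i, n in enumerate(g_nodes) if isinstance(n, tuple)]

    # fixed leaf mappings
    base_map = {}
    for i, n in enumerate(g_nodes):
        if not isinstance(n, tuple):
            base_map[i] = leaf_id[n]

    anc_sets = [set(_ancestors(i, sp_parent)) for i in range(len(sp_nodes))]

    best = math.inf
    for assign in itertools.product(range(len(sp_nodes)), repeat=len(internal)):
        M = dict(base_map)
        for i, s in zip(internal, assign):
            M[i] = s
        ok = True
        for v in internal:
            for c in g_children[v]:
                if M[v] not in anc_sets[M[c]]:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        # a node is a speciation only when its children diverge exactly at
        # its mapped species node; anything else is a duplication
        def sp_lca(a, b):
            aa = _ancestors(a, sp_parent)
            for x in _ancestors(b, sp_parent):
                if x in aa:
                    return x
            raise AssertionError("disconnected species tree")

        dup = {}
        for v in internal:
            cs = [M[c] for c in g_children[v]]
            dup[v] = (M[v] != sp_lca(cs[0], cs[1])) or any(c == M[v] for c in cs)
        cost = sum(dup.values())
        for v in range(len(g_nodes)):
            for c in g_children[v]:
                if M[c] == M[v]:
                    continue
                d = sp_depth[M[c]] - sp_depth[M[v]]
                cost += d - 1
                if dup[v]:
                    cost += 1
        best = min(best, cost)
    return int(best)


# ---------------------------------------------------------------------------
# Sankoff parsimony by exhaustive ancestral-assignment enumeration

def parsimony_min_cost(parent: list[int], leaves: dict[int, int],
                       n_states: int, cost=None) -> float:
    """Minimum total change cost over all ancestral assignments.

    *parent* gives the tree (root has parent -1); *leaves* maps leaf node ids
    to their fixed states; every other node ranges over 0..n_states-1.
    """
    if cost is None:
        cost = lambda i, j: abs(i - j)
    n = len(parent)
    free = [v for v in range(n) if v not in leaves]
    best = math.inf
    for assign in itertools.product(range(n_states), repeat=len(free)):
        state = dict(leaves)
        state.update(zip(free, assign))
        c = sum(cost(state[parent[v]], state[v]) for v in range(n) if parent[v] != -1)
        best = min(best, c)
    return best


def wagner_root_interval(parent, children, leaves: dict[int, int]) -> tuple[int, int]:
    """Farris-interval (Wagner) parsimony root state interval."""
    lo, hi = {}, {}
    for v in range(len(parent)):  # ids are post-order: children first
        if v in leaves:
            lo[v], hi[v] = leaves[v], leaves[v]
        else:
            los = sorted(lo[c] for c in children[v])
            his = sorted(hi[c] for c in children[v])
            # intersection of child intervals if nonempty, else the gap
            a, b = max(los), min(his)
            if a <= b:
                lo[v], hi[v] = a, b
            else:
                lo[v], hi[v] = b, a
    root = len(parent) - 1
    return lo[root], hi[root]


# ---------------------------------------------------------------------------
# Mk likelihood by brute-force summation over ancestral assignments

def mk_loglik_bruteforce(parent, length, tip_state: dict[int, int],
                         Q: np.ndarray, prior: np.ndarray) -> float:
    """log P(tips) by summing path probabilities over all ancestral states."""
    k = Q.shape[0]
    n = len(parent)
    P = {v: expm(Q * length[v]) for v in range(n) if parent[v] != -1}
    free = [v for v in range(n) if v not in tip_state]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(free)):
        state = dict(tip_state)
        state.update(zip(free, assign))
        prob = prior[state[n - 1]]
        for v in range(n):
            if parent[v] != -1:
                prob *= P[v][state[parent[v]], state[v]]
        total += prob
    return math.log(total)


def mk_marginals_bruteforce(parent, length, tip_state: dict[int, int],
                            Q: np.ndarray, prior: np.ndarray) -> dict[int, np.ndarray]:
    """Marginal ancestral distributions by exhaustive path summation."""
    k = Q.shape[0]
    n = len(parent)
    P = {v: expm(Q * length[v]) for v in range(n) if parent[v] != -1}
    free = [v for v in range(n) if v not in tip_state]
    acc = {v: np.zeros(k) for v in range(n)}
    for assign in itertools.product(range(k), repeat=len(free)):
        state = dict(tip_state)
        state.update(zip(free, assign))
        prob = prior[state[n - 1]]
        for v in range(n):
            if parent[v] != -1:
                prob *= P[v][state[parent[v]], state[v]]
        for v in range(n):
            acc[v][state[v]] += prob
    return {v: a / a.sum() for v, a in acc.items()}


# ---------------------------------------------------------------------------
# ordinary least squares closed form

def ols_slope_intercept(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = ((x - x.mean()) ** 2).sum()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = (resid ** 2).sum() / (n - 2)
    se_slope = math.sqrt(s2 / sxx)
    se_inter = math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return slope, intercept, se_slope, se_inter


# ---------------------------------------------------------------------------
# random rooted trees + an independent canonical form

def random_tuple_tree(rng, labels):
    """Random rooted binary tree over *labels* by sequential attachment."""
    items = list(labels)
    rng.shuffle(items)
    t = items[0]
    for lab in items[1:]:
        t = _attach(rng, t, lab)
    return t


def _attach(rng, t, lab):
    if not isinstance(t, tuple) or rng.random() < 0.5:
        return (t, lab) if rng.random() < 0.5 else (lab, t)
    i = rng.randrange(len(t))
    kids = list(t)
    kids[i] = _attach(rng, kids[i], lab)
    return tuple(kids)


def canonical(newick_tree) -> tuple:
    """Order-independent canonical form of a package Tree (labels + lengths)."""
    t = newick_tree

    def go(i):
        if t.is_leaf(i):
            key = ("L", t.label[i])
        else:
            key = ("N", tuple(sorted(go(c) for c in t.children[i])))
        if t.parent[i] != -1:
            key = (key, round(t.length[i], 9))
        return key

    return go(t.root)
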