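"""Ancestral gene-copy-number reconstruction and count–trait regression.

Ancestral counts are reconstructed by Sankoff parsimony: a bottom-up dynamic
program over integer copy-number states with a per-branch change cost
(linear |i - j| by default, so the result coincides with Wagner/Farris
interval parsimony), followed by a deterministic top-down backtrack.

Associations between per-species gene counts and traits are fitted by
phylogenetic generalized least squares (PGLS) under a Brownian-motion
covariance, optionally scaled by Pagel's lambda (fixed or estimated by
restricted maximum likelihood). Subfamilies that are mostly single-copy
across species carry no expansion signal and can be filtered out before
fitting to avoid spurious correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .errors import ConfigurationError, RankError
from .selection_enrichment import bh_correct
from .treeio import Tree

__all__ = ["AncestralCounts", "PGLSFit", "sankoff_counts", "branch_deltas",
           "pgls_fit", "filter_families", "phylo_covariance", "pgls_families"]


@dataclass
class AncestralCounts:
    tree: Tree
    states: dict[int, int]     # node id -> copy number
    cost: float                # minimal total change cost


@dataclass
class PGLSFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    t_slope: float
    p_slope: float
    lam: float
    lam_mode: str
    n: int
    loglik_reml: float | None = None


def sankoff_counts(tree: Tree, leaf_counts: dict[str, int],
                   cost: str | np.ndarray = "linear",
                   max_count: int | None = None) -> AncestralCounts:
    """Minimum-cost ancestral copy numbers by the Sankoff dynamic program.

    Parameters
    ----------
    leaf_counts
        Species label -> observed copy number; required for every leaf.
    cost
        ``"linear"`` for |i - j| (gain and loss of one copy cost 1 each), or
        a square matrix ``cost[i, j]`` = cost of a parent state *i* changing
        to child state *j* along a branch.
    max_count
        Upper bound of the state space (default: max observed count).

    Tie-breaking is deterministic: the root takes the midpoint of its
    optimal-state interval (rounded down); each descendant takes the optimal
    state closest to its parent's chosen state, preferring the smaller on a
    distance tie.
    """
    leaves = tree.leaves
    missing = [tree.label[i] for i in leaves if tree.label[i] not in leaf_counts]
    if missing:
        raise ConfigurationError(f"missing leaf counts for: {missing}")
    observed_max = max(leaf_counts[tree.label[i]] for i in leaves)
    if max_count is None:
        max_count = observed_max
    if max_count < observed_max:
        raise ConfigurationError(
            f"max_count {max_count} below the largest leaf count {observed_max}")

    S = max_count + 1
    states = np.arange(S)
    if isinstance(cost, str):
        if cost != "linear":
            raise ConfigurationError(f"unknown cost model {cost!r}")
        C = np.abs(states[:, None] - states[None, :]).astype(float)
    else:
        C = np.asarray(cost, dtype=float)
        if C.shape != (S, S):
            raise ConfigurationError(f"cost matrix must be {S}x{S}, got {C.shape}")

    INF = np.inf
    down = np.zeros((tree.n_nodes, S))
    for v in tree.postorder():
        if tree.is_leaf(v):
            down[v] = INF
            down[v, leaf_counts[tree.label[v]]] = 0.0
        else:
            acc = np.zeros(S)
            for c in tree.children[v]:
                # cost of subtree under c given this node in state i
                acc += (C + down[c][None, :]).min(axis=1)
            down[v] = acc

    chosen: dict[int, int] = {}
    root = tree.root
    best = down[root].min()
    opt = np.flatnonzero(down[root] == best)
    chosen[root] = int(opt[(len(opt) - 1) // 2])  # interval midpoint, rounded down
    for v in tree.preorder():
        if v == root:
            continue
        p_state = chosen[tree.parent[v]]
        total = C[p_state] + down[v]
        m = total.min()
        cand = np.flatnonzero(total == m)
        # closest to the parent's state; smaller state on a tie
        chosen[v] = int(cand[np.argmin(np.abs(cand - p_state))])
    return AncestralCounts(tree=tree, states=chosen, cost=float(best))


def branch_deltas(anc: AncestralCounts) -> dict[int, int]:
    """Signed copy-number change per branch: count(child) - count(parent)."""
    tree = anc.tree
    return {v: anc.states[v] - anc.states[tree.parent[v]]
            for v in tree.postorder() if tree.parent[v] != -1}


def phylo_covariance(tree: Tree, species: list[str]) -> np.ndarray:
    """Brownian covariance among tips: shared root-to-LCA path length."""
    idx = tree.leaf_index()
    missing = [s for s in species if s not in idx]
    if missing:
        raise ConfigurationError(f"species not in tree: {missing}")
    times = tree.node_times()
    n = len(species)
    V = np.empty((n, n))
    nodes = [idx[s] for s in species]
    for i in range(n):
        for j in range(i, n):
            anc = tree.lca(nodes[i], nodes[j])
            V[i, j] = V[j, i] = times[anc]
    np.fill_diagonal(V, [times[nd] for nd in nodes])
    return V


def _apply_lambda(V: np.ndarray, lam: float) -> np.ndarray:
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _gls(X: np.ndarray, y: np.ndarray, V: np.ndarray):
    n, p = X.shape
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise RankError(f"covariance matrix not positive definite: {exc}") from exc
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    if np.linalg.matrix_rank(XtX) < p:
        raise RankError("design matrix is rank deficient")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtX)
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    return beta, cov_beta, sigma2, logdetV, XtX


def _reml_loglik(X: np.ndarray, y: np.ndarray, V: np.ndarray) -> float:
    n, p = X.shape
    beta, cov_beta, sigma2, logdetV, XtX = _gls(X, y, V)
    if sigma2 <= 0:
        return -np.inf
    sign, logdetXtX = np.linalg.slogdet(XtX)
    return -0.5 * ((n - p) * np.log(sigma2) + logdetV + logdetXtX + (n - p))


def pgls_fit(tree: Tree, x, y, species: list[str],
             lambda_mode: str = "fixed", lam: float = 1.0) -> PGLSFit:
    """PGLS regression of *y* on *x* under a Brownian (Pagel-lambda) covariance.

    Parameters
    ----------
    species
        Tip labels aligned with *x* and *y*; the tree is used only through
        these tips, so supplying a subset prunes implicitly.
    lambda_mode
        ``"fixed"`` (use *lam*; 0 recovers ordinary least squares on an
        ultrametric tree, 1 is plain Brownian motion) or ``"ML"`` (restricted
        maximum likelihood over [0, 1]).

    The slope is tested against zero with a t-test on n - 2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(species) != len(x) or len(x) != len(y):
        raise ConfigurationError("species, x, y must be aligned")
    if len(x) < 4:
        raise ConfigurationError("PGLS needs at least 4 species")
    if min(tree.length[v] for v in tree.postorder() if tree.parent[v] != -1) < 0:
        raise ConfigurationError("negative branch lengths")
    V = phylo_covariance(tree, species)
    X = np.column_stack([np.ones_like(x), x])
    loglik = None
    if lambda_mode == "ML":
        res = minimize_scalar(lambda l: -_reml_loglik(X, y, _apply_lambda(V, l)),
                              bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-8})
        lam = float(res.x)
        loglik = float(-res.fun)
    elif lambda_mode != "fixed":
        raise ConfigurationError(f"lambda_mode must be 'fixed' or 'ML', got {lambda_mode!r}")
    Vl = _apply_lambda(V, lam)
    if lam == 0.0:
        # diagonal covariance: equal tip variances on an ultrametric tree
        Vl = np.diag(np.diag(V))
    beta, cov_beta, _, _, _ = _gls(X, y, Vl)
    se = np.sqrt(np.diag(cov_beta))
    df = len(x) - 2
    t_slope = beta[1] / se[1] if se[1] > 0 else np.inf * np.sign(beta[1])
    p_slope = 2.0 * float(t_dist.sf(abs(t_slope), df))
    return PGLSFit(slope=float(beta[1]), intercept=float(beta[0]),
                   slope_se=float(se[1]), intercept_se=float(se[0]),
                   t_slope=float(t_slope), p_slope=p_slope, lam=lam,
                   lam_mode=lambda_mode, n=len(x), loglik_reml=loglik)


def filter_families(counts: pd.DataFrame, single_copy_frac: float = 0.8) -> pd.DataFrame:
    """Drop mostly-single-copy families (species × family count matrix).

    A family is removed when the fraction of species with count <= 1 is
    strictly greater than *single_copy_frac*.
    """
    frac = (counts <= 1).mean(axis=0)
    return counts.loc[:, frac.values <= single_copy_frac]


def pgls_families(tree: Tree, counts: pd.DataFrame, trait: pd.Series,
                  lambda_mode: str = "fixed", lam: float = 1.0,
                  single_copy_frac: float | None = 0.8) -> pd.DataFrame:
    """PGLS of each family's counts on one trait, with BH-corrected q-values.

    Species are intersected across tree tips, count matrix rows, and the
    trait vector (missing trait values dropped).
    """
    tips = set(tree.leaf_labels)
    trait = trait.dropna()
    species = [s for s in counts.index if s in tips and s in trait.index]
    if single_copy_frac is not None:
        counts = filter_families(counts.loc[species], single_copy_frac)
    rows = []
    for fam in counts.columns:
        fit = pgls_fit(tree, trait.loc[species].to_numpy(),
                       counts.loc[species, fam].to_numpy(), species,
                       lambda_mode=lambda_mode, lam=lam)
        rows.append({"family": fam, "slope": fit.slope, "se": fit.slope_se,
                     "t": fit.t_slope, "p": fit.p_slope, "lambda": fit.lam,
                     "n": fit.n})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_correct(out["p"].to_numpy())
    return out
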