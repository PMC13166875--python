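"""Ancestral reconstruction of traits and transition-branch calling.

Discrete traits evolve under a continuous-time Markov (Mk) model: either a
single symmetric rate (ER) or one rate per ordered state pair (ARD). Rates
are fitted by maximizing the Felsenstein pruning likelihood with a uniform
root prior; the two model classes are compared by AIC. Marginal ancestral
state probabilities combine the likelihood of the data below a node with the
likelihood of everything else, via the standard up-down pass.

Continuous traits are reconstructed under Brownian motion: ancestral values
are the GLS conditional expectations given the tips, which for the root
reduces to the precision-weighted average of the tips.

Branches on which the reconstruction changes state (discrete, with a
confidence floor on both endpoint marginals) or moves by more than a
threshold (continuous) are called "transition branches"; branches sharing
the same labeled change form the pooling unit for the enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .errors import ConfigurationError, OptimizationError
from .selection_enrichment import TransitionSet
from .treeio import Tree

__all__ = ["MkFit", "mk_fit", "marginal_states", "brownian_ancestral",
           "detect_transitions", "mk_model_select"]


@dataclass
class MkFit:
    tree: Tree
    states: list[str]
    model: str                    # "ER" or "ARD"
    Q: np.ndarray
    loglik: float
    aic: float
    n_params: int
    tip_states: dict[str, str]
    root_prior: np.ndarray
    selected: bool = False


def _build_q(rates: np.ndarray, k: int, model: str) -> np.ndarray:
    Q = np.zeros((k, k))
    if model == "ER":
        Q[:] = rates[0]
    else:
        idx = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[idx]
                    idx += 1
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _down_partials(tree: Tree, Q: np.ndarray, tip_idx: dict[int, int | None], k: int):
    """Conditional likelihood of the data below each node, per state."""
    P = {}
    for v in tree.postorder():
        if tree.parent[v] != -1:
            P[v] = expm(Q * tree.length[v])
    L = np.zeros((tree.n_nodes, k))
    for v in tree.postorder():
        if tree.is_leaf(v):
            s = tip_idx[v]
            if s is None:  # missing observation: uninformative tip
                L[v] = 1.0
            else:
                L[v, s] = 1.0
        else:
            acc = np.ones(k)
            for c in tree.children[v]:
                acc *= P[c] @ L[c]
            L[v] = acc
    return L, P


def _loglik(tree: Tree, Q: np.ndarray, tip_idx, k: int, prior: np.ndarray) -> float:
    L, _ = _down_partials(tree, Q, tip_idx, k)
    lik = float(prior @ L[tree.root])
    if lik <= 0 or not np.isfinite(lik):
        return -np.inf
    return np.log(lik)


def mk_fit(tree: Tree, tip_states: dict[str, str], states: list[str] | None = None,
           model: str = "ER", root_prior: str = "uniform") -> MkFit:
    """Fit an Mk model to discrete tip states by maximum likelihood.

    Parameters
    ----------
    tip_states
        Species label -> observed state; species missing from the mapping
        (or mapped to None) are treated as unobserved.
    model
        ``"ER"`` (equal rates, 1 parameter) or ``"ARD"`` (all rates
        different, k(k-1) parameters).
    root_prior
        ``"uniform"`` over states (default) — configurable hook for a
        stationary prior, which for these reversible parameterizations is
        also uniform.

    Rates are optimized on a log scale by L-BFGS-B from a heuristic start
    (one expected change over the total tree length). A single observed
    state is degenerate: the rate is driven to the lower bound and flagged.
    """
    if model not in ("ER", "ARD"):
        raise ConfigurationError(f"model must be 'ER' or 'ARD', got {model!r}")
    observed = sorted({s for s in tip_states.values() if s is not None})
    if states is None:
        states = observed
    if any(s not in states for s in observed):
        raise ConfigurationError("tip states outside the declared state set")
    k = len(states)
    if k < 2:
        raise ConfigurationError("need at least 2 states in the state set")
    state_pos = {s: i for i, s in enumerate(states)}
    tip_idx = {}
    for leaf in tree.leaves:
        lab = tree.label[leaf]
        s = tip_states.get(lab)
        tip_idx[leaf] = None if s is None else state_pos[s]

    total_len = sum(tree.length[v] for v in tree.postorder() if tree.parent[v] != -1)
    if total_len <= 0:
        raise ConfigurationError("tree has no positive branch lengths")
    prior = np.full(k, 1.0 / k)
    n_par = 1 if model == "ER" else k * (k - 1)
    start = np.full(n_par, np.log(max(1.0 / total_len, 1e-8)))
    bounds = [(np.log(1e-9), np.log(1e4))] * n_par

    def neg(logr):
        Q = _build_q(np.exp(logr), k, model)
        return -_loglik(tree, Q, tip_idx, k, prior)

    res = minimize(neg, start, method="L-BFGS-B", bounds=bounds)
    if not np.isfinite(res.fun):
        raise OptimizationError(f"non-finite Mk likelihood: {res}")
    Q = _build_q(np.exp(res.x), k, model)
    loglik = -float(res.fun)
    aic = 2.0 * n_par - 2.0 * loglik
    return MkFit(tree=tree, states=list(states), model=model, Q=Q,
                 loglik=loglik, aic=aic, n_params=n_par,
                 tip_states=dict(tip_states), root_prior=prior)


def mk_model_select(tree: Tree, tip_states: dict[str, str],
                    states: list[str] | None = None) -> tuple[MkFit, MkFit]:
    """Fit ER and ARD and flag the lower-AIC model as selected."""
    er = mk_fit(tree, tip_states, states, model="ER")
    ard = mk_fit(tree, tip_states, states, model="ARD")
    if er.aic <= ard.aic:
        er.selected = True
    else:
        ard.selected = True
    return er, ard


def marginal_states(fit: MkFit) -> dict[int, np.ndarray]:
    """Marginal ancestral state probabilities per node (each sums to 1).

    Combines the downward conditional likelihoods with an upward pass
    carrying the likelihood of everything outside each node's subtree.
    """
    tree, k = fit.tree, len(fit.states)
    state_pos = {s: i for i, s in enumerate(fit.states)}
    tip_idx = {leaf: (None if fit.tip_states.get(tree.label[leaf]) is None
                      else state_pos[fit.tip_states[tree.label[leaf]]])
               for leaf in tree.leaves}
    L, P = _down_partials(tree, fit.Q, tip_idx, k)
    U = np.zeros((tree.n_nodes, k))
    U[tree.root] = fit.root_prior
    for v in tree.preorder():
        for c in tree.children[v]:
            sib = np.ones(k)
            for s in tree.children[v]:
                if s != c:
                    sib *= P[s] @ L[s]
            U[c] = (U[v] * sib) @ P[c]
    out = {}
    for v in tree.postorder():
        m = U[v] * L[v]
        total = m.sum()
        if total <= 0:
            raise OptimizationError(f"zero marginal mass at node {v}")
        out[v] = m / total
    return out


def brownian_ancestral(tree: Tree, values: dict[str, float],
                       eps: float = 1e-8) -> dict[int, float]:
    """ML ancestral means under Brownian motion (GLS conditional expectation).

    The estimate at an internal node a is
    ``mu + C_aL C_LL^{-1} (x - mu)`` where C is the shared-path-length
    covariance and ``mu`` the GLS root estimate. Zero-length cherries make
    C singular and are regularized by *eps* with a warning-free fallback.
    """
    leaves = tree.leaves
    missing = [tree.label[i] for i in leaves if tree.label[i] not in values]
    if missing:
        raise ConfigurationError(f"missing trait values for leaves: {missing}")
    times = np.asarray(tree.node_times())
    x = np.array([values[tree.label[i]] for i in leaves])
    n = len(leaves)
    C = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            C[a, b] = C[b, a] = times[tree.lca(leaves[a], leaves[b])]
    np.fill_diagonal(C, times[leaves])
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Cinv = np.linalg.inv(C + eps * np.eye(n))
    one = np.ones(n)
    denom = one @ Cinv @ one
    mu = float(one @ Cinv @ x / denom)
    est = {leaves[i]: float(x[i]) for i in range(n)}
    internal = [v for v in tree.postorder() if not tree.is_leaf(v)]
    for v in internal:
        cov = np.array([times[tree.lca(v, lf)] for lf in leaves])
        est[v] = mu + float(cov @ Cinv @ (x - mu))
    return est


def detect_transitions(tree: Tree, reconstruction, kind: str,
                       dataset_id: str = "all", trait_name: str = "trait",
                       confidence_floor: float = 0.7, delta: float = 0.5,
                       states: list[str] | None = None) -> list[TransitionSet]:
    """Call transition branches from an ancestral reconstruction.

    Discrete (*kind* = "discrete"): *reconstruction* maps node -> marginal
    probability vector; branch b is a transition for the change s -> s' when
    the parent's and child's argmax states differ and both maxima reach
    *confidence_floor*. Continuous (*kind* = "continuous"): *reconstruction*
    maps node -> estimate; a branch is an "increase"/"decrease" when the
    child-parent difference exceeds +/- *delta* (trait units).

    Returns one :class:`TransitionSet` per change label, members keyed by
    (dataset_id, species branch id), ready for pooling.
    """
    groups: dict[str, list] = {}
    if kind == "discrete":
        if states is None:
            raise ConfigurationError("discrete transition calling needs the state list")
        for v in tree.postorder():
            u = tree.parent[v]
            if u == -1:
                continue
            pu, pv = np.asarray(reconstruction[u]), np.asarray(reconstruction[v])
            su, sv = int(pu.argmax()), int(pv.argmax())
            if su != sv and pu[su] >= confidence_floor and pv[sv] >= confidence_floor:
                label = f"{trait_name}:{states[su]}->{states[sv]}"
                groups.setdefault(label, []).append((dataset_id, v))
    elif kind == "continuous":
        for v in tree.postorder():
            u = tree.parent[v]
            if u == -1:
                continue
            diff = reconstruction[v] - reconstruction[u]
            if diff > delta:
                groups.setdefault(f"{trait_name}:increase", []).append((dataset_id, v))
            elif diff < -delta:
                groups.setdefault(f"{trait_name}:decrease", []).append((dataset_id, v))
    else:
        raise ConfigurationError(f"kind must be 'discrete' or 'continuous', got {kind!r}")
    return [TransitionSet(label=lab, members=mem) for lab, mem in sorted(groups.items())]
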