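"""Seeded generators for species trees, gene families, selection p-values
and traits.

These emulate the statistical structure of the study inputs: a clade of a
handful of species, a few hundred gene-family trees evolved down the species
tree by duplication and loss, a per-gene-branch p-value from an upstream
branch-site test with a small baseline significant fraction, and a planted
fold enrichment of significance on designated "transition" species branches.
The generator records ground truth (true species-branch assignment of every
gene branch, true selection status, true ancestral trait states), so every
pipeline stage can be scored against what was planted.

The p-value model is calibrated: a branch is drawn "selected" with
probability ``p0`` (``f * p0`` on transition branches); selected branches
draw p ~ Uniform(0, alpha) and unselected ones p ~ Uniform(alpha, 1).
Because ``p0`` defaults to ``alpha``, the marginal p-value distribution under
no planted signal (f = 1) is exactly Uniform(0, 1), and "selected" coincides
with "called at alpha", so a planted fold is directly comparable to the fold
the enrichment test estimates. A Beta(a, 1) alternative for the selected
branches is available for power studies of a weaker upstream test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .selection_enrichment import TransitionSet
from .treeio import Tree

__all__ = ["SimulationConfig", "simulate_species_tree", "simulate_gene_family",
           "plant_selection", "simulate_traits", "simulate_dataset",
           "SyntheticDataset"]


@dataclass
class SimulationConfig:
    """Study-condition knobs for one synthetic dataset.

    Defaults mirror the structure of the real inputs: clades of about eight
    species, a couple hundred gene trees per clade, a baseline significant
    fraction of a few percent, and moderate duplication/loss turnover.
    """

    seed: int = 0
    n_species: int = 8
    n_gene_trees: int = 200
    dup_rate: float = 0.1       # events per unit branch length
    loss_rate: float = 0.1
    p0: float = 0.05            # baseline per-branch selection probability
    fold: float = 1.0           # planted fold on transition branches
    alpha: float = 0.05
    transition_branches: list[int] | None = None   # None: one random internal branch
    p_model: str = "conditional"                   # or "uniform", "beta"
    beta_a: float = 0.2
    length_mean: float = 0.1    # gene branch lengths (substitutions/site)
    length_selection_rho: float = 0.0  # >0: selected branches drawn longer
    bm_sigma2: float = 1.0
    mk_rate: float = 0.5
    trait_shift_branches: list[int] = field(default_factory=list)
    family_cap: int = 10_000

    def __post_init__(self):
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ConfigurationError("rates must be nonnegative")
        if not 0 <= self.p0 < 1:
            raise ConfigurationError("p0 must lie in [0, 1)")
        if self.fold < 0 or self.p0 * self.fold > 1:
            raise ConfigurationError("need fold >= 0 and p0 * fold <= 1")


# ---------------------------------------------------------------------------
# species trees

def simulate_species_tree(n: int, seed_or_rng) -> Tree:
    """Ultrametric pure-birth (Yule) species tree with depth normalized to 1.

    Lineages split at unit rate; after the n-th tip appears the present is
    set one more exponential holding time later, so no branch has length 0.
    Tips are labeled ``s1 .. sn`` left to right.
    """
    if n < 3:
        raise ConfigurationError(f"need at least 3 species, got {n}")
    rng = _as_rng(seed_or_rng)
    # node: [birth_time, children]
    root = [0.0, []]
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node = active.pop(int(i))
        kids = [[t, []], [t, []]]
        node[1].extend(kids)
        active.extend(kids)
    t += rng.exponential(1.0 / n)
    depth = t

    parent, children, length, label = [], [], [], []
    counter = {"leaf": 0}

    def build(node, parent_time):
        birth, kids = node
        kid_ids = [build(k, birth) for k in kids]
        my = len(parent)
        parent.append(-1)
        children.append(kid_ids)
        for k in kid_ids:
            parent[k] = my
        if kids:
            length.append((birth - parent_time) / depth)
            label.append(None)
        else:
            length.append((depth - parent_time) / depth)
            counter["leaf"] += 1
            label.append(f"s{counter['leaf']}")
        return my

    build(root, 0.0)
    return Tree(parent, children, length, label, kind="species")


# ---------------------------------------------------------------------------
# gene families

class _GNode:
    __slots__ = ("time", "children", "sp_branch", "species", "alive")

    def __init__(self, time, sp_branch, species=None):
        self.time = time
        self.children = []
        self.sp_branch = sp_branch   # species branch id where this node arose
        self.species = species       # species leaf id for extant gene leaves
        self.alive = False


def simulate_gene_family(species_tree: Tree, dup_rate: float, loss_rate: float,
                         seed_or_rng, family_cap: int = 10_000,
                         label_prefix: str = "g") -> tuple[Tree, dict[int, int], int]:
    """Evolve one gene family down the species tree by birth–death.

    A single gene lineage starts at the species root; along every species
    branch it duplicates at rate *dup_rate* and dies at rate *loss_rate*
    (per unit species branch length); surviving lineages speciate at species
    nodes. Families extinct in all species are redrawn (the redraw count is
    returned). Branch lengths of the returned gene tree are time spans in
    species-tree units.

    Returns
    -------
    (gene_tree, true_assignment, redraws)
        ``true_assignment`` maps every gene branch id to the species branch
        id on which the event at its child end occurred — the ground truth
        the reconciliation stage should recover.
    """
    rng = _as_rng(seed_or_rng)
    expect = species_tree.n_nodes / 2 * math.exp(max(dup_rate - loss_rate, 0.0))
    if expect * math.exp(dup_rate) > family_cap:
        raise ConfigurationError(
            f"expected family size exceeds cap {family_cap}; lower the rates")
    node_times = species_tree.node_times()
    total_rate = dup_rate + loss_rate

    def along_branch(sp_child: int, t_now: float) -> _GNode | None:
        """Lineage at absolute time t_now on the branch into sp_child."""
        t_end = node_times[sp_child]
        while True:
            if total_rate > 0:
                t_now = t_now + rng.exponential(1.0 / total_rate)
            else:
                t_now = t_end
            if t_now >= t_end:
                return at_node(sp_child)
            if rng.random() < (dup_rate / total_rate if total_rate else 0.0):
                node = _GNode(t_now, sp_child)
                for _ in range(2):
                    child = along_branch(sp_child, t_now)
                    if child is not None:
                        node.children.append(child)
                if not node.children:
                    return None
                if len(node.children) == 1:  # suppress unifurcation
                    return node.children[0]
                return node
            return None  # loss

    def at_node(sp: int) -> _GNode | None:
        if species_tree.is_leaf(sp):
            leaf = _GNode(node_times[sp], sp, species=sp)
            leaf.alive = True
            return leaf
        node = _GNode(node_times[sp], sp)
        for c in species_tree.children[sp]:
            child = along_branch(c, node_times[sp])
            if child is not None:
                node.children.append(child)
        if not node.children:
            return None
        if len(node.children) == 1:
            return node.children[0]
        return node

    redraws = 0
    while True:
        root = at_node(species_tree.root)
        if root is not None and (root.children or root.species is not None):
            if root.species is not None:
                # single surviving gene: not a tree; redraw
                redraws += 1
                continue
            break
        redraws += 1
        if redraws > 10_000:
            raise ConfigurationError("family goes extinct in virtually every draw")

    # flatten post-order into a Tree + truth table
    parent, children, length, label = [], [], [], []
    truth: dict[int, int] = {}
    per_species_count: dict[int, int] = {}
    sp_root = species_tree.root

    def build(node: _GNode, parent_time: float, parent_id_holder) -> int:
        kid_ids = [build(c, node.time, None) for c in node.children]
        my = len(parent)
        parent.append(-1)
        children.append(kid_ids)
        for k in kid_ids:
            parent[k] = my
        length.append(node.time - parent_time)
        if node.species is not None:
            per_species_count[node.species] = per_species_count.get(node.species, 0) + 1
            sp_label = species_tree.label[node.species]
            label.append(f"{sp_label}|{label_prefix}{per_species_count[node.species]}")
        else:
            label.append(None)
        truth[my] = "root" if node.sp_branch == sp_root else node.sp_branch
        return my

    build(root, root.time, None)
    gene_tree = Tree(parent, children, length, label, kind="gene")
    truth.pop(gene_tree.root, None)  # the root has no incoming branch
    return gene_tree, truth, redraws


# ---------------------------------------------------------------------------
# selection p-values

def plant_selection(assignments: list[dict[int, object]],
                    p0: float, fold: float, transition_branches,
                    seed_or_rng, alpha: float = 0.05,
                    p_model: str = "conditional", beta_a: float = 0.2,
                    length_mean: float = 0.1, length_selection_rho: float = 0.0,
                    dataset_id: str = "d0") -> pd.DataFrame:
    """Draw branch-test records with a planted enrichment signal.

    Parameters
    ----------
    assignments
        One ``{gene branch id: species branch id}`` dict per gene tree (the
        simulator's ground truth, or a reconciliation's branch map).
    transition_branches
        Species branch ids carrying the planted signal: selection probability
        is ``min(1, fold * p0)`` there and ``p0`` elsewhere.
    p_model
        ``"conditional"`` (default): selected branches draw
        p ~ U(0, alpha), unselected p ~ U(alpha, 1) — uniform marginal at
        f = 1 and a planted fold equal to the expected estimated fold.
        ``"uniform"``: unselected branches draw p ~ U(0, 1) instead (the
        upstream test then contributes its own false positives).
        ``"beta"``: selected branches draw p ~ Beta(a, 1) (weaker signal).

    Returns a dataframe of records with the truth column ``selected``,
    branch lengths drawn Exponential(mean *length_mean*), optionally
    inflated for selected branches via *length_selection_rho* to stress the
    normalization.
    """
    if not 0 <= p0 < 1:
        raise ConfigurationError("p0 must lie in [0, 1)")
    if min(1.0, fold * p0) > 1:
        raise ConfigurationError("fold * p0 must not exceed 1")
    rng = _as_rng(seed_or_rng)
    trans = set(transition_branches)
    rows_tree, rows_branch, rows_on = [], [], []
    for gi, amap in enumerate(assignments):
        for b, sb in amap.items():
            rows_tree.append(gi)
            rows_branch.append(b)
            rows_on.append(sb in trans)
    m = len(rows_branch)
    on = np.asarray(rows_on, dtype=bool)
    prob = np.where(on, min(1.0, fold * p0), p0)
    selected = rng.random(m) < prob
    p = np.empty(m)
    if p_model == "conditional":
        p[selected] = rng.uniform(0.0, alpha, selected.sum())
        p[~selected] = rng.uniform(alpha, 1.0, (~selected).sum())
    elif p_model == "uniform":
        p[selected] = rng.uniform(0.0, alpha, selected.sum())
        p[~selected] = rng.uniform(0.0, 1.0, (~selected).sum())
    elif p_model == "beta":
        p[selected] = rng.beta(beta_a, 1.0, selected.sum())
        p[~selected] = rng.uniform(0.0, 1.0, (~selected).sum())
    else:
        raise ConfigurationError(f"unknown p_model {p_model!r}")
    lengths = rng.exponential(length_mean, m)
    if length_selection_rho:
        lengths[selected] *= 1.0 + length_selection_rho
    return pd.DataFrame({
        "dataset_id": dataset_id,
        "gene_tree_id": [f"g{t}" for t in rows_tree],
        "gene_branch_id": rows_branch,
        "branch_length": lengths,
        "p_value": p,
        "species_branch_id": [a for amap in assignments for a in amap.values()],
        "selected": selected,
    })


# ---------------------------------------------------------------------------
# traits

def simulate_traits(species_tree: Tree, model: str, params: dict,
                    shift_branches, seed_or_rng) -> tuple[pd.Series, dict[int, object]]:
    """Simulate one trait on the species tree with optional planted shifts.

    ``model="BM"``: Brownian motion with variance rate ``params["sigma2"]``
    and mean jumps of ``params.get("jump", 2.0)`` at the start of each shift
    branch. ``model="Mk"``: a continuous-time Markov chain over
    ``params["states"]`` at equal rate ``params["rate"]``, with a forced
    state change at the start of each shift branch.

    Returns (tip values indexed by species label, true value/state per node).
    """
    rng = _as_rng(seed_or_rng)
    shifts = set(shift_branches)
    truth: dict[int, object] = {}
    if model == "BM":
        sigma2 = float(params.get("sigma2", 1.0))
        jump = float(params.get("jump", 2.0))
        root_value = float(params.get("root", 0.0))
        for v in species_tree.preorder():
            if species_tree.parent[v] == -1:
                truth[v] = root_value
                continue
            base = truth[species_tree.parent[v]]
            if v in shifts:
                base += jump
            truth[v] = base + (rng.normal(0.0, math.sqrt(sigma2 * species_tree.length[v]))
                               if sigma2 > 0 and species_tree.length[v] > 0 else 0.0)
    elif model == "Mk":
        states = list(params["states"])
        if len(states) < 2:
            raise ConfigurationError("Mk simulation needs >= 2 states")
        rate = float(params.get("rate", 0.5))
        for v in species_tree.preorder():
            if species_tree.parent[v] == -1:
                truth[v] = states[0]
                continue
            s = truth[species_tree.parent[v]]
            if v in shifts:
                s = rng.choice([x for x in states if x != s])
            # jump chain at total leave-rate rate*(k-1)
            t = species_tree.length[v]
            k = len(states)
            while rate > 0:
                t -= rng.exponential(1.0 / (rate * (k - 1)))
                if t <= 0:
                    break
                s = rng.choice([x for x in states if x != s])
            truth[v] = s
    else:
        raise ConfigurationError(f"unknown trait model {model!r}")
    tips = pd.Series({species_tree.label[i]: truth[i] for i in species_tree.leaves})
    return tips, truth


# ---------------------------------------------------------------------------
# one full dataset

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    species_tree: Tree
    gene_trees: list[Tree]
    true_assignments: list[dict[int, object]]
    records: pd.DataFrame
    transition: TransitionSet
    redraws: int


def simulate_dataset(config: SimulationConfig, dataset_id: str = "d0") -> SyntheticDataset:
    """Simulate one clade-level dataset: species tree, gene families, records.

    When ``config.transition_branches`` is None, one internal non-root
    species branch is chosen at random as the (single-member) transition set.
    """
    rng = np.random.default_rng(config.seed)
    sp = simulate_species_tree(config.n_species, rng)
    if config.transition_branches is None:
        internal = [v for v in sp.postorder()
                    if not sp.is_leaf(v) and sp.parent[v] != -1]
        trans = [int(rng.choice(internal))]
    else:
        trans = list(config.transition_branches)
    gene_trees, truths = [], []
    redraws = 0
    for _ in range(config.n_gene_trees):
        gt, truth, rd = simulate_gene_family(sp, config.dup_rate, config.loss_rate,
                                             rng, family_cap=config.family_cap)
        gt.dataset_id = dataset_id
        gene_trees.append(gt)
        truths.append(truth)
        redraws += rd
    records = plant_selection(truths, config.p0, config.fold, trans, rng,
                              alpha=config.alpha, p_model=config.p_model,
                              beta_a=config.beta_a, length_mean=config.length_mean,
                              length_selection_rho=config.length_selection_rho,
                              dataset_id=dataset_id)
    transition = TransitionSet(label="planted",
                               members=[(dataset_id, b) for b in trans])
    return SyntheticDataset(config=config, species_tree=sp, gene_trees=gene_trees,
                            true_assignments=truths, records=records,
                            transition=transition, redraws=redraws)


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
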