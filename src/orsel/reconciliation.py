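"""Gene-tree / species-tree reconciliation by duplication–loss (LCA) parsimony.

Each gene node is mapped to the most recent common ancestor of the species of
its descendant leaves; a node is a duplication exactly when it maps to the
same species node as one of its children. Losses are read off each gene
branch (u, v): descending from M(u) to M(v) skips ``depth(M(v)) - depth(M(u))``
species branches, of which all but the first imply a lost lineage, plus one
more when u itself is a duplication that did not resolve on the same species
branch. LCA mapping attains the minimum duplication + loss count among all
valid (monotone) reconciliations.

Gene branches are attributed to a single species branch — the branch leading
into the species node the child maps to — because a selection event on a gene
branch spanning several species branches (implied losses) is observable only
in the surviving descendants. Branches whose child maps to the species root
receive the synthetic id ``"root"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import dendropy

from .errors import FormatError
from .treeio import Tree, _from_dendropy, map_gene_leaves

__all__ = ["ReconciliationMap", "lca_reconcile", "assign_branches",
           "read_external_reconciliation", "ROOT_BRANCH"]

ROOT_BRANCH = "root"

SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass
class ReconciliationMap:
    gene_tree: Tree
    species_tree: Tree
    node_map: dict[int, int]          # gene node -> species node
    event: dict[int, str]             # gene internal node -> speciation|duplication
    dup_count: int
    loss_count: int
    validated: bool = True            # False when imported and LCA invariants differ

    def branch_map(self) -> dict[int, object]:
        """Gene branch id -> species branch id (``"root"`` at the species root)."""
        return assign_branches(self)


def lca_reconcile(gene_tree: Tree, species_tree: Tree,
                  leaf_map: dict[int, int] | None = None) -> ReconciliationMap:
    """Reconcile *gene_tree* into *species_tree* by LCA parsimony.

    Parameters
    ----------
    leaf_map
        Gene leaf node id -> species leaf node id (from
        :func:`orsel.treeio.map_gene_leaves`). Computed with the default
        ``"|"`` delimiter when omitted.
    """
    if leaf_map is None:
        leaf_map = map_gene_leaves(gene_tree, species_tree)
    node_map: dict[int, int] = {}
    event: dict[int, str] = {}
    for v in gene_tree.postorder():
        if gene_tree.is_leaf(v):
            node_map[v] = leaf_map[v]
        else:
            node_map[v] = species_tree.lca_many(node_map[c] for c in gene_tree.children[v])
            dup = any(node_map[c] == node_map[v] for c in gene_tree.children[v])
            event[v] = DUPLICATION if dup else SPECIATION
    dup_count = sum(1 for e in event.values() if e == DUPLICATION)
    loss_count = _count_losses(gene_tree, species_tree, node_map, event)
    return ReconciliationMap(gene_tree, species_tree, node_map, event,
                             dup_count, loss_count)


def _count_losses(gene_tree: Tree, species_tree: Tree,
                  node_map: dict[int, int], event: dict[int, str]) -> int:
    depth = species_tree.depths()
    losses = 0
    for v in gene_tree.postorder():
        u = gene_tree.parent[v]
        if u == -1:
            continue
        mu, mv = node_map[u], node_map[v]
        if mu == mv:
            continue
        d = depth[mv] - depth[mu]
        losses += d - 1
        if event[u] == DUPLICATION:
            losses += 1
    return losses


def assign_branches(rec: ReconciliationMap) -> dict[int, object]:
    """Attribute every gene branch to one species branch id.

    The branch into gene node v goes to the species branch into ``M(v)``
    (species branch ids are the species child-node ids); when ``M(v)`` is the
    species root there is no such branch and the synthetic id ``"root"`` is
    used.
    """
    sp_root = rec.species_tree.root
    out: dict[int, object] = {}
    for v in rec.gene_tree.postorder():
        if rec.gene_tree.parent[v] == -1:
            continue
        mv = rec.node_map[v]
        out[v] = ROOT_BRANCH if mv == sp_root else mv
    return out


_NHX_RE = re.compile(r"&&NHX:?(.*)", re.S)


def _parse_nhx(comment: str) -> dict[str, str]:
    m = _NHX_RE.search(comment)
    if not m:
        return {}
    fields = {}
    for item in m.group(1).split(":"):
        if "=" in item:
            k, v = item.split("=", 1)
            fields[k.strip()] = v.strip()
    return fields


def read_external_reconciliation(path, species_tree: Tree,
                                 delimiter: str = "|",
                                 dataset_id: str | None = None) -> ReconciliationMap:
    """Import a precomputed reconciliation from an NHX-annotated gene tree.

    Expected per-node NHX tags: ``S=<species label or node id>`` giving the
    species assignment and ``D=Y|N`` (or ``Ev=D|S``) giving the event.
    Invariants of the LCA mapping are re-checked; disagreements (external
    probabilistic models may legally differ) downgrade to a warning recorded
    in ``rec.validated`` rather than an error. A file with no NHX comments at
    all is a format error.
    """
    try:
        dtree = dendropy.Tree.get(path=str(path), schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True,
                                  extract_comment_metadata=False)
    except Exception as exc:
        raise FormatError(f"cannot read NHX tree: {exc}") from exc

    dnodes = list(dtree.postorder_node_iter())
    tags = []
    any_nhx = False
    for nd in dnodes:
        comment = "".join(nd.comments or [])
        fields = _parse_nhx(comment)
        any_nhx = any_nhx or bool(fields)
        tags.append(fields)
    if not any_nhx:
        raise FormatError(f"{path}: no NHX comments found")

    gene_tree = _from_dendropy(dtree, "gene", dataset_id)
    # species labels -> node ids: leaves by label; internal nodes by label or id
    sp_by_label: dict[str, int] = {}
    for i in range(species_tree.n_nodes):
        if species_tree.label[i]:
            sp_by_label[species_tree.label[i]] = i

    leaf_map = map_gene_leaves(gene_tree, species_tree, delimiter)
    node_map: dict[int, int] = {}
    event: dict[int, str] = {}
    for v, fields in zip(gene_tree.postorder(), tags):
        if gene_tree.is_leaf(v):
            node_map[v] = leaf_map[v]
            continue
        if "S" not in fields:
            raise FormatError(f"internal node without NHX S= species tag at node {v}")
        s = fields["S"]
        if s in sp_by_label:
            node_map[v] = sp_by_label[s]
        elif s.isdigit() and int(s) < species_tree.n_nodes:
            node_map[v] = int(s)
        else:
            raise FormatError(f"unknown species tag S={s!r}")
        if fields.get("D", "").upper() == "Y" or fields.get("Ev", "").upper() == "D":
            event[v] = DUPLICATION
        else:
            event[v] = SPECIATION

    validated = True
    for v in gene_tree.postorder():
        if gene_tree.is_leaf(v):
            continue
        lca = species_tree.lca_many(node_map[c] for c in gene_tree.children[v])
        want = DUPLICATION if any(node_map[c] == node_map[v]
                                  for c in gene_tree.children[v]) else SPECIATION
        if node_map[v] != lca or event[v] != want:
            validated = False
    dup_count = sum(1 for e in event.values() if e == DUPLICATION)
    loss_count = _count_losses(gene_tree, species_tree, node_map, event)
    return ReconciliationMap(gene_tree, species_tree, node_map, event,
                             dup_count, loss_count, validated=validated)
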