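"""Rooted-tree containers and Newick I/O.

Trees are stored as flat arrays indexed by a stable post-order node id:
every child has a smaller id than its parent and the root is ``n_nodes - 1``.
The branch *leading into* a node shares the node's id, so one id namespace
serves both nodes and branches; all downstream tables (reconciliation maps,
branch test records, transition sets) use these ids.

Parsing and serialization are delegated to :mod:`dendropy`; this module only
adds the id convention, validation, and the species-of-origin resolution for
gene-tree leaves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

from .errors import NewickParseError, UnresolvedLeafError

__all__ = ["Tree", "parse_newick", "write_newick", "map_gene_leaves", "trees_isomorphic"]


@dataclass
class Tree:
    """A rooted tree in post-order array form.

    Attributes
    ----------
    parent : list[int]
        ``parent[i]`` is the id of node *i*'s parent; ``-1`` for the root.
    children : list[list[int]]
        Child ids per node, in the order they appeared in the source Newick.
    length : list[float]
        Length of the branch leading into each node (root entry is the root
        edge length, usually 0).
    label : list[str | None]
        Leaf labels; ``None`` for internal nodes unless the source named them.
    kind : str
        ``"species"`` or ``"gene"``.
    missing_lengths : list[int]
        Ids of branches whose length was absent from the input (read as 0).
    dataset_id : str | None
        For gene trees: which species-clade × subfamily dataset the tree
        belongs to.
    """

    parent: list[int]
    children: list[list[int]]
    length: list[float]
    label: list[str | None]
    kind: str = "species"
    missing_lengths: list[int] = field(default_factory=list)
    dataset_id: str | None = None

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.label[i] for i in self.leaves]

    def postorder(self) -> range:
        """Node ids bottom-up (children always precede parents)."""
        return range(self.n_nodes)

    def preorder(self) -> range:
        return range(self.n_nodes - 1, -1, -1)

    # -- derived quantities ------------------------------------------------
    def depths(self) -> list[int]:
        """Edge-count depth of every node (root = 0)."""
        d = [0] * self.n_nodes
        for i in self.preorder():
            if self.parent[i] >= 0:
                d[i] = d[self.parent[i]] + 1
        return d

    def node_times(self) -> list[float]:
        """Cumulative branch length from the root to each node."""
        t = [0.0] * self.n_nodes
        for i in self.preorder():
            if self.parent[i] >= 0:
                t[i] = t[self.parent[i]] + self.length[i]
        return t

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when *a* is an ancestor of, or equal to, *b*."""
        while b != -1:
            if b == a:
                return True
            b = self.parent[b]
        return False

    def lca(self, a: int, b: int) -> int:
        seen = set()
        while a != -1:
            seen.add(a)
            a = self.parent[a]
        while b not in seen:
            b = self.parent[b]
        return b

    def lca_many(self, nodes) -> int:
        it = iter(nodes)
        acc = next(it)
        for n in it:
            acc = self.lca(acc, n)
        return acc

    def subtree_leaves(self, i: int) -> list[int]:
        out, stack = [], [i]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def leaf_index(self) -> dict[str, int]:
        return {self.label[i]: i for i in self.leaves}


def _from_dendropy(dtree: "dendropy.Tree", kind: str, dataset_id: str | None) -> Tree:
    nodes = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent, children, length, label = [], [], [], []
    missing = []
    for i, nd in enumerate(nodes):
        parent.append(index[id(nd.parent_node)] if nd.parent_node is not None else -1)
        children.append([index[id(c)] for c in nd.child_nodes()])
        if nd.edge.length is None:
            length.append(0.0)
            missing.append(i)
        else:
            if nd.edge.length < 0:
                raise NewickParseError(f"negative branch length {nd.edge.length!r}")
            length.append(float(nd.edge.length))
        if nd.is_leaf():
            if nd.taxon is not None:
                label.append(nd.taxon.label)
            elif nd.label:
                label.append(nd.label)
            else:
                raise NewickParseError("unlabeled leaf")
        else:
            label.append(nd.label or None)
    return Tree(parent, children, length, label, kind=kind,
                missing_lengths=missing, dataset_id=dataset_id)


def parse_newick(text: str, kind: str = "species", dataset_id: str | None = None) -> Tree:
    """Parse a single rooted Newick string into a :class:`Tree`.

    Branch ids are assigned by post-order traversal following the child order
    of the source string, so re-parsing the same string yields identical ids.
    Missing branch lengths are read as 0 and recorded in
    ``tree.missing_lengths``.
    """
    if kind not in ("species", "gene"):
        raise ValueError(f"kind must be 'species' or 'gene', got {kind!r}")
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    stripped = text.strip()
    if stripped.count("(") != stripped.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs {stripped.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"Newick parse failure: {exc}") from exc
    if dtree.seed_node is None or dtree.seed_node.is_leaf():
        raise NewickParseError("input is not a rooted tree with at least one split")
    tree = _from_dendropy(dtree, kind, dataset_id)
    labels = tree.leaf_labels
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes and kind == "species":
        raise NewickParseError("duplicate leaf labels: " + ", ".join(dupes))
    return tree


def _fmt_len(x: float) -> str:
    # repr round-trips doubles exactly; force a decimal point for integers
    s = repr(float(x))
    return s


def write_newick(tree: Tree) -> str:
    """Serialize a :class:`Tree` back to Newick.

    Zero-length branches are written explicitly (``:0.0``); the root edge
    length is emitted only when nonzero. ``parse_newick(write_newick(t))``
    is isomorphic to ``t`` with branch lengths preserved to float precision.
    """
    def render(i: int) -> str:
        if tree.is_leaf(i):
            core = tree.label[i]
        else:
            core = "(" + ",".join(render(c) for c in tree.children[i]) + ")"
            if tree.label[i]:
                core += tree.label[i]
        if tree.parent[i] == -1:
            if tree.length[i]:
                core += f":{_fmt_len(tree.length[i])}"
            return core
        return f"{core}:{_fmt_len(tree.length[i])}"

    return render(tree.root) + ";"


def split_gene_label(leaf_label: str, delimiter: str = "|") -> tuple[str, str]:
    """Split ``species<delim>gene`` on the *first* delimiter occurrence."""
    if delimiter not in leaf_label:
        return leaf_label, ""
    sp, gid = leaf_label.split(delimiter, 1)
    return sp, gid


def map_gene_leaves(gene_tree: Tree, species_tree: Tree, delimiter: str = "|") -> dict[int, int]:
    """Resolve each gene-tree leaf to a species-tree leaf node id.

    Leaf labels take the form ``species_id<delimiter>gene_id``; only the first
    delimiter occurrence splits. Raises :class:`UnresolvedLeafError` listing
    all labels whose species id is absent from the species tree.
    """
    sp_index = species_tree.leaf_index()
    mapping: dict[int, int] = {}
    offenders = []
    for leaf in gene_tree.leaves:
        sp, _ = split_gene_label(gene_tree.label[leaf], delimiter)
        if sp in sp_index:
            mapping[leaf] = sp_index[sp]
        else:
            offenders.append(gene_tree.label[leaf])
    if offenders:
        raise UnresolvedLeafError(offenders)
    return mapping


def _canonical(tree: Tree, i: int, with_lengths: bool, tol: float):
    if tree.is_leaf(i):
        key = ("leaf", tree.label[i])
    else:
        key = ("node", tuple(sorted(_canonical(tree, c, with_lengths, tol)
                                    for c in tree.children[i])))
    if with_lengths and tree.parent[i] != -1:
        key = (key, round(tree.length[i] / tol) if tol else tree.length[i])
    return key


def trees_isomorphic(a: Tree, b: Tree, lengths: bool = True, tol: float = 1e-9) -> bool:
    """Topological (and optionally branch-length) isomorphism of rooted trees.

    Children are compared as unordered sets; lengths are compared after
    quantization at *tol*.
    """
    return _canonical(a, a.root, lengths, tol) == _canonical(b, b.root, lengths, tol)


def read_newick_file(path, kind: str = "species") -> list[Tree]:
    """Read one tree per line (or a single multi-line tree) from a file."""
    with io.open(path, "r") as fh:
        text = fh.read()
    chunks = [c.strip() + ";" for c in text.split(";") if c.strip()]
    return [parse_newick(c, kind=kind) for c in chunks]
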