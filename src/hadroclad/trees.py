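"""Rooted phylogenetic trees: Newick I/O, bipartition algebra, strict
consensus, Robinson-Foulds distance, and enumeration of the binary
resolutions of a polytomy.

Trees are rooted throughout.  Unrooted comparisons (Robinson-Foulds, the
Newick round-trip checks) are made on bipartitions after discarding the
root edge.  Child order is preserved on input but is never semantically
meaningful: every equality or set operation here is order-insensitive.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import dendropy


class TreeError(ValueError):
    """A structural problem with a tree or an operation's preconditions."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class Node:
    """One node of a rooted tree.

    ``label`` is the tip name for leaves and an optional free label for
    internal nodes.  ``annotations`` is an open key -> value map used by
    downstream stages (support values, area vectors, age bounds).
    """

    __slots__ = ("label", "children", "parent", "length", "annotations")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.annotations: dict = {}

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)}-furcation"
        return f"<Node {self.label!r} ({kind})>"


class Tree:
    """A rooted tree with uniquely labelled tips and optional multifurcations."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    # -- structure ---------------------------------------------------------

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.annotations = dict(node.annotations)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return Tree(rec(self.root))

    def validate(self) -> None:
        labels = self.tip_labels()
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        if not labels:
            raise TreeError("tree has no tips")

    # -- clades and bipartitions ------------------------------------------

    def clade_map(self) -> dict[Node, frozenset[str]]:
        """Tip set subtended by every node (rooted view)."""
        out: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.label])
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= out[c]
                out[node] = frozenset(acc)
        return out

    def clades(self, include_trivial: bool = False) -> set[frozenset[str]]:
        """Clades (rooted splits) of internal non-root nodes.

        Trivial clades (single tips and the full tip set) are excluded
        unless ``include_trivial``.
        """
        cmap = self.clade_map()
        full = cmap[self.root]
        out = set()
        for node, clade in cmap.items():
            if node is self.root:
                continue
            if not include_trivial and (len(clade) < 2 or len(clade) >= len(full)):
                continue
            out.add(clade)
        if include_trivial:
            out.add(full)
            out |= {frozenset([t]) for t in full}
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions in unrooted canonical form.

        Each internal edge splits the tip set in two; the side not
        containing the lexicographically smallest tip is used as the
        canonical representative, and the (redundant) root edge collapses
        onto a single entry automatically.
        """
        cmap = self.clade_map()
        full = cmap[self.root]
        ref = min(full)
        out = set()
        for node, clade in cmap.items():
            if node is self.root:
                continue
            side = clade if ref not in clade else full - clade
            if len(side) < 2 or len(side) > len(full) - 2:
                continue
            out.add(side)
        return out

    def find_clade(self, labels: Iterable[str]) -> Node | None:
        """Return the node whose subtended tip set equals ``labels``, if any."""
        target = frozenset(labels)
        for node, clade in self.clade_map().items():
            if clade == target:
                return node
        return None

    def extract_subtree(self, labels: Iterable[str]) -> "Tree":
        """Induced rooted subtree on a subset of tips (unary nodes suppressed)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels())
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")

        def rec(node: Node) -> Node | None:
            if node.is_leaf:
                if node.label in keep:
                    new = Node(node.label, node.length)
                    new.annotations = dict(node.annotations)
                    return new
                return None
            kids = [k for k in (rec(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = Node(node.label, node.length)
            new.annotations = dict(node.annotations)
            for k in kids:
                new.add_child(k)
            return new

        root = rec(self.root)
        if root is None:
            raise TreeError("no requested tips present")
        return Tree(root)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree with {len(self.tips())} tips>"


# -- Newick I/O -------------------------------------------------------------


def read_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Multifurcations and child order are preserved; branch lengths are kept
    on ``Node.length``; internal labels on ``Node.label``.  Square-bracket
    comments are ignored.  Malformed input raises
    :class:`NewickParseError` with the underlying parser message (which
    names the offending position).
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"Newick parse error: {exc}") from None

    def rec(dnode) -> Node:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = Node(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    tree = Tree(rec(dtree.seed_node))
    tree.validate()
    return tree


def _quote_label(label: str) -> str:
    specials = set(" (){}[]',;:")
    if any(ch in specials for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, include_lengths: bool = True,
                 include_internal_labels: bool = True) -> str:
    """Serialize a :class:`Tree` as a Newick string (reparseable)."""

    def rec(node: Node) -> str:
        if node.is_leaf:
            s = _quote_label(node.label if node.label is not None else "")
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if include_internal_labels and node.label:
                s += _quote_label(str(node.label))
        if include_lengths and node.length is not None and node.parent is not None:
            s += f":{node.length:g}"
        return s

    # give serialization a parent view for the root-length rule
    for n in tree.preorder():
        for c in n.children:
            c.parent = n
    tree.root.parent = None
    return rec(tree.root) + ";"


def read_newick_file(path) -> list[Tree]:
    """Read one tree per non-empty line (multi-Newick file)."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(read_newick(line))
    if not trees:
        raise NewickParseError(f"no trees found in {path}")
    return trees


def write_newick_file(trees: Sequence[Tree], path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# -- consensus and distances -------------------------------------------------


def _check_same_tips(trees: Sequence[Tree]) -> frozenset[str]:
    ref = frozenset(trees[0].tip_labels())
    for t in trees[1:]:
        other = frozenset(t.tip_labels())
        if other != ref:
            diff = sorted(ref ^ other)
            raise TreeError(f"tip sets differ; symmetric difference: {diff}")
    return ref


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Strict consensus of rooted trees on one tip set.

    The result contains exactly the clades present in every input tree;
    conflicting regions collapse to polytomies.
    """
    if not trees:
        raise TreeError("strict consensus of an empty tree list")
    full = _check_same_tips(trees)
    common = trees[0].clades()
    for t in trees[1:]:
        common &= t.clades()

    tip_rank = {label: i for i, label in enumerate(trees[0].tip_labels())}

    nodes: dict[frozenset[str], Node] = {full: Node()}
    # parents before children: create big clades first
    for clade in sorted(common, key=len, reverse=True):
        nodes[clade] = Node()
    for clade in sorted(common, key=len, reverse=True):
        parent = min(
            (c for c in nodes if len(c) > len(clade) and clade < c),
            key=len,
        )
        nodes[parent].add_child(nodes[clade])
    for label in full:
        tip = Node(label)
        candidates = [c for c in nodes if label in c]
        nodes[min(candidates, key=len)].add_child(tip)

    def sort_children(node: Node) -> None:
        node.children.sort(
            key=lambda c: min(tip_rank[l] for l in _tipset(c))
        )
        for c in node.children:
            sort_children(c)

    def _tipset(node: Node) -> set[str]:
        if node.is_leaf:
            return {node.label}
        out: set[str] = set()
        for c in node.children:
            out |= _tipset(c)
        return out

    root = nodes[full]
    sort_children(root)
    return Tree(root)


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    _check_same_tips([a, b])
    return len(a.bipartitions() ^ b.bipartitions())


# -- polytomy resolutions ----------------------------------------------------

DEFAULT_RESOLUTION_LIMIT = 8


def n_resolutions(k: int) -> int:
    """(2k-3)!! : the number of rooted binary trees on k labelled leaves."""
    out = 1
    for i in range(3, 2 * k - 2, 2):
        out *= i
    return out


def _insertions(shape, item):
    yield (shape, item)
    if isinstance(shape, tuple):
        left, right = shape
        for s in _insertions(left, item):
            yield (s, right)
        for s in _insertions(right, item):
            yield (left, s)


def enumerate_resolutions(k: int, limit: int = DEFAULT_RESOLUTION_LIMIT) -> list:
    """Every rooted binary tree shape over ``k`` labelled subclades.

    Shapes are nested 2-tuples whose leaves are the integers ``0..k-1``
    (indices into the caller's subclade list).  The count is (2k-3)!!.
    A polytomy wider than ``limit`` raises :class:`TreeError` advising
    manual scenario specification, because the enumeration grows as a
    double factorial.
    """
    if k < 2:
        raise TreeError("a polytomy has at least 2 subclades")
    if k > limit:
        raise TreeError(
            f"polytomy of {k} subclades exceeds the resolution limit {limit} "
            f"({n_resolutions(k)} scenarios); specify scenarios manually or "
            "raise the limit"
        )
    shapes: list = [0]
    for item in range(1, k):
        shapes = [s for shape in shapes for s in _insertions(shape, item)]
    return shapes


def shape_leaves(shape) -> list[int]:
    """Flatten a resolution shape into its leaf indices."""
    if not isinstance(shape, tuple):
        return [shape]
    return shape_leaves(shape[0]) + shape_leaves(shape[1])


def canonical_shape(shape):
    """Order-insensitive canonical form of a resolution shape."""
    if not isinstance(shape, tuple):
        return shape
    a, b = canonical_shape(shape[0]), canonical_shape(shape[1])
    return (a, b) if str(a) <= str(b) else (b, a)
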