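"""Phylogenetic tree representation, Newick I/O, and split-based comparisons.

Trees here are topology-only objects (branch lengths are carried through I/O
for the simulator but have no comparison semantics): rooted or unrooted,
polytomies allowed.  All comparisons — Robinson-Foulds distance, backbone
refinement, topology deduplication — operate on *unrooted nontrivial splits*
(bipartitions of the tip set induced by internal edges).

The Robinson-Foulds convention is the plain symmetric-difference count of
nontrivial splits, not halved and not normalized, so two binary unrooted
n-tip trees with no shared resolution are at distance 2*(n-3).
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "parse_newick",
    "read_newick_trees",
    "write_newick_trees",
    "to_newick",
    "root_at",
    "unrooted_splits",
    "robinson_foulds",
    "is_refinement_of",
    "prune_and_dedup",
    "split_compatible_with_tree",
    "is_monophyletic",
]


class Node:
    """A tree node: ``label`` for tips (and optionally internals), ``length``
    is the length of the edge above the node (``None`` if absent)."""

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.length = length

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Tree:
    """A phylogeny with uniquely labeled tips.

    ``rooted`` is a semantic flag: unrooted trees are stored rooted at an
    arbitrary node but are always compared through their unrooted split sets.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def tip_set(self) -> frozenset[str]:
        labels = self.tip_labels()
        return frozenset(labels)

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def __len__(self) -> int:
        return len(self.leaves())

    # -- structure ---------------------------------------------------------
    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            clone = Node(node.label, node.length)
            for child in node.children:
                clone.add_child(_copy(child))
            return clone

        return Tree(_copy(self.root), rooted=self.rooted)

    def validate(self) -> None:
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")

    def suppress_unifurcations(self) -> None:
        """Remove degree-2 internal nodes (and a degree-1 root chain)."""
        while len(self.root.children) == 1 and not self.root.is_leaf:
            child = self.root.children[0]
            if child.is_leaf:
                break
            child.parent = None
            if child.length is not None and self.root.length is not None:
                child.length += self.root.length
            self.root = child
        for node in list(self.postorder()):
            if node is self.root or node.is_leaf:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                parent = node.parent
                idx = parent.children.index(node)
                if child.length is not None and node.length is not None:
                    child.length += node.length
                child.parent = parent
                parent.children[idx] = child
                node.children = []
                node.parent = None

    def prune_taxa(self, drop: Iterable[str]) -> None:
        """Remove the named tips and suppress the unifurcations this creates."""
        drop = set(drop)
        if not drop:
            return
        present = self.tip_set()
        missing = drop - present
        if missing:
            raise ValueError(f"cannot prune absent taxa: {sorted(missing)}")
        keep_leaves = {id(n) for n in self.leaves() if n.label not in drop}
        for leaf in self.leaves():
            if leaf.label in drop:
                parent = leaf.parent
                if parent is None:
                    raise ValueError("cannot prune the only node of a tree")
                parent.remove_child(leaf)
        # drop internal nodes whose children all vanished, bottom-up
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf and id(node) not in keep_leaves \
                        and node.parent is not None:
                    node.parent.remove_child(node)
                    changed = True
        self.suppress_unifurcations()

    def is_binary(self) -> bool:
        """True if every internal node is bifurcating (root included when
        rooted; an unrooted tree may have a trifurcating root)."""
        for node in self.internal_nodes():
            k = len(node.children)
            if node is self.root:
                limit = 2 if self.rooted else 3
                if k > limit or k < 2:
                    return False
            elif k != 2:
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({to_newick(self)!r}, rooted={self.rooted})"


# ---------------------------------------------------------------------------
# Newick I/O (parsing delegated to dendropy; canonical serialization is ours)
# ---------------------------------------------------------------------------

def _from_dendropy(dnode: "dendropy.Node") -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label, dnode.edge.length)
    else:
        node = Node(dnode.label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str, rooted: bool = False) -> Tree:
    """Parse a single Newick string into a :class:`Tree`.

    Raises ``ValueError`` on empty or unbalanced input.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty Newick string")
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text if text.endswith(";") else text + ";",
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise ValueError(f"malformed Newick string: {exc}") from exc
    tree = Tree(_from_dendropy(dtree.seed_node), rooted=rooted)
    tree.validate()
    return tree


def _quote_label(label: str) -> str:
    if any(c in label for c in " \t()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(
    tree: Tree,
    canonical: bool = True,
    lengths: bool = False,
) -> str:
    """Serialize to Newick.  With ``canonical=True`` children are ordered by
    their lexicographically smallest descendant tip, giving byte-stable output
    for topologically identical rooted trees."""

    def _min_tip(node: Node) -> str:
        if node.is_leaf:
            return node.label
        return min(_min_tip(c) for c in node.children)

    def _fmt(node: Node) -> str:
        suffix = ""
        if lengths and node.length is not None:
            suffix = f":{node.length:g}"
        if node.is_leaf:
            return _quote_label(node.label) + suffix
        children = node.children
        if canonical:
            children = sorted(children, key=_min_tip)
        inner = ",".join(_fmt(c) for c in children)
        label = _quote_label(node.label) if node.label else ""
        return f"({inner}){label}{suffix}"

    return _fmt(tree.root) + ";"


def read_newick_trees(path: str, rooted: bool = False) -> list[Tree]:
    """Read a multi-tree file: one Newick per line, or a NEXUS TREES block."""
    with open(path) as fh:
        content = fh.read()
    if content.lstrip().upper().startswith("#NEXUS"):
        tlist = dendropy.TreeList.get(
            data=content, schema="nexus", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return [Tree(_from_dendropy(t.seed_node), rooted=rooted) for t in tlist]
    trees = []
    for line in content.splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line, rooted=rooted))
    return trees


def write_newick_trees(trees: Sequence[Tree], path: str) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(to_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _canonical_side(side: frozenset[str], universe: frozenset[str],
                    reference: str) -> frozenset[str]:
    return side if reference not in side else universe - side


def unrooted_splits(tree: Tree, restrict: Optional[frozenset[str]] = None
                    ) -> frozenset[frozenset[str]]:
    """Nontrivial unrooted splits as canonical tip-label sets.

    Each split is stored as the side *not* containing the reference taxon
    (lexicographically smallest tip).  With ``restrict``, splits are first
    intersected with the given tip subset (restriction of the tree to those
    tips); splits that become trivial vanish.
    """
    universe = tree.tip_set()
    if restrict is not None:
        universe = universe & restrict
    if len(universe) < 4:
        return frozenset()
    reference = min(universe)
    splits: set[frozenset[str]] = set()

    def _collect(node: Node) -> frozenset[str]:
        if node.is_leaf:
            below = frozenset((node.label,)) & universe
        else:
            below = frozenset().union(*(_collect(c) for c in node.children))
        if node.parent is not None and 2 <= len(below) <= len(universe) - 2:
            splits.add(_canonical_side(below, universe, reference))
        return below

    _collect(tree.root)
    return frozenset(splits)


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance: number of nontrivial splits unique to one of
    the two trees (symmetric difference, not halved)."""
    if t1.tip_set() != t2.tip_set():
        only1 = sorted(t1.tip_set() - t2.tip_set())
        only2 = sorted(t2.tip_set() - t1.tip_set())
        raise ValueError(
            f"tip sets differ: only in first {only1}, only in second {only2}"
        )
    return len(unrooted_splits(t1) ^ unrooted_splits(t2))


def is_refinement_of(candidate: Tree, constraint: Tree) -> bool:
    """True iff every nontrivial split of ``constraint`` is present in
    ``candidate`` restricted to the constraint's tips.

    Taxa absent from the constraint float freely; polytomies in the constraint
    may be resolved arbitrarily by the candidate.
    """
    ctips = constraint.tip_set()
    missing = ctips - candidate.tip_set()
    if missing:
        raise ValueError(f"constraint taxa absent from candidate: {sorted(missing)}")
    need = unrooted_splits(constraint)
    if not need:
        return True
    have = unrooted_splits(candidate, restrict=ctips)
    return need <= have


def topology_key(tree: Tree) -> tuple[frozenset[str], frozenset[frozenset[str]]]:
    """Hashable identity of an unrooted topology."""
    return (tree.tip_set(), unrooted_splits(tree))


def prune_and_dedup(trees: Sequence[Tree], drop: Iterable[str]) -> list[Tree]:
    """Prune ``drop`` from every tree and keep one representative per distinct
    unrooted topology, in order of first occurrence."""
    drop = set(drop)
    seen: set[tuple] = set()
    out: list[Tree] = []
    for tree in trees:
        pruned = tree.copy()
        if drop:
            pruned.prune_taxa(drop & pruned.tip_set())
        key = topology_key(pruned)
        if key not in seen:
            seen.add(key)
            out.append(pruned)
    return out


# ---------------------------------------------------------------------------
# Rooting and clade tests
# ---------------------------------------------------------------------------

def root_at(tree: Tree, outgroup: str) -> Tree:
    """Return a rooted copy with ``outgroup`` as sister to everything else.

    The unrooted split set is unchanged.
    """
    work = tree.copy()
    leaf = next((n for n in work.leaves() if n.label == outgroup), None)
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} is not a tip of the tree")
    # Reorient: new root sits on the edge above the outgroup tip.
    parent = leaf.parent
    if parent is None:
        raise ValueError("cannot root a single-tip tree")
    parent.remove_child(leaf)
    # reverse parent pointers from `parent` up to the old root
    path = []
    node = parent
    while node is not None:
        path.append(node)
        node = node.parent
    for i in range(len(path) - 1):
        path[i + 1].remove_child(path[i])
    for i in range(len(path) - 1, 0, -1):
        path[i - 1].add_child(path[i])
    new_root = Node()
    new_root.add_child(leaf)
    new_root.add_child(parent)
    rooted = Tree(new_root, rooted=True)
    rooted.suppress_unifurcations()
    return rooted


def is_monophyletic(tree: Tree, taxa: Iterable[str]) -> bool:
    """True iff ``taxa`` form a clade of the rooted tree (singletons always do)."""
    target = frozenset(taxa)
    if not target <= tree.tip_set():
        missing = sorted(target - tree.tip_set())
        raise ValueError(f"taxa absent from tree: {missing}")
    if len(target) <= 1:
        return True

    found = False

    def _below(node: Node) -> frozenset[str]:
        nonlocal found
        if node.is_leaf:
            return frozenset((node.label,))
        below = frozenset().union(*(_below(c) for c in node.children))
        if below == target:
            found = True
        return below

    whole = _below(tree.root)
    return found or whole == target


def split_compatible_with_tree(side: frozenset[str], tree: Tree) -> bool:
    """Can the bipartition ``side | rest`` be added to ``tree``'s splits?

    Standard pairwise compatibility: two splits on the same taxon set are
    compatible iff at least one of the four side-intersections is empty.
    """
    universe = tree.tip_set()
    other = universe - side
    if not side or not other:
        return True
    for tside in unrooted_splits(tree):
        tother = universe - tside
        if (side & tside and side & tother and other & tside and other & tother):
            return False
    return True
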