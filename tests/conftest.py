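"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own algorithms: parsimony
lengths and MPR sets come from exhaustive enumeration of all internal state
assignments, and Robinson-Foulds distances from dendropy.  They are only
feasible on tiny trees, which is the point.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pseudoext.matrix_io import CharacterMatrix
from pseudoext.treespace import Node, Tree


# ---------------------------------------------------------------------------
# Random generators
# ---------------------------------------------------------------------------

def random_binary_tree(labels: list[str], rng: np.random.Generator) -> Tree:
    """Uniform-ish random unrooted binary topology by random insertion."""
    order = [labels[i] for i in rng.permutation(len(labels))]
    root = Node()
    root.add_child(Node(order[0]))
    inner = Node()
    inner.add_child(Node(order[1]))
    inner.add_child(Node(order[2]))
    root.add_child(inner)
    tree = Tree(root, rooted=False)
    for label in order[3:]:
        edges = [n for n in tree.preorder()
                 if n is not tree.root and n is not tree.root.children[1]]
        w = edges[rng.integers(len(edges))]
        parent = w.parent
        idx = parent.children.index(w)
        u = Node()
        u.parent = parent
        parent.children[idx] = u
        w.parent = u
        u.children = [w]
        tip = Node(label)
        tip.parent = u
        u.children.append(tip)
    return tree


def random_matrix(taxa: list[str], n_char: int, k: int,
                  rng: np.random.Generator, p_missing: float = 0.15,
                  p_inapplicable: float = 0.05) -> CharacterMatrix:
    cells = []
    for _ in taxa:
        row = []
        for _ in range(n_char):
            u = rng.random()
            if u < p_missing:
                row.append("?")
            elif u < p_missing + p_inapplicable:
                row.append("-")
            else:
                row.append(str(int(rng.integers(k))))
        cells.append(row)
    return CharacterMatrix(list(taxa), cells)


# ---------------------------------------------------------------------------
# Brute-force parsimony oracles
# ---------------------------------------------------------------------------

def _allowed_states(token: str, k: int) -> frozenset[int]:
    states = frozenset(int(c) for c in token if c.isdigit())
    return states if states else frozenset(range(k))


def brute_force_length(tree: Tree, matrix: CharacterMatrix, k: int) -> int:
    """Exhaustive minimum over all internal-node state assignments."""
    internals = [n for n in tree.postorder() if not n.is_leaf]
    idx = {id(n): i for i, n in enumerate(internals)}
    edges = []  # (child, parent) pairs; child may be a tip
    for node in tree.preorder():
        if node.parent is not None:
            edges.append((node, node.parent))
    total = 0
    for j in range(matrix.n_char):
        tip_states = {
            t: _allowed_states(matrix.row(t)[j], k) for t in tree.tip_labels()
        }
        best = None
        for assign in itertools.product(range(k), repeat=len(internals)):
            cost = 0
            for child, parent in edges:
                p_state = assign[idx[id(parent)]]
                if child.is_leaf:
                    if p_state not in tip_states[child.label]:
                        cost += 1
                elif assign[idx[id(child)]] != p_state:
                    cost += 1
            if best is None or cost < best:
                best = cost
        total += best
    return total


def brute_force_mpr(tree: Tree, matrix: CharacterMatrix, k: int
                    ) -> list[dict[int, frozenset[str]]]:
    """Per character: node-index -> set of states over all minimal
    assignments (node indices follow the package's preorder numbering)."""
    internals = [n for n in tree.preorder() if not n.is_leaf]
    n_tips = len(tree)
    node_ids = {id(n): n_tips + 1 + i for i, n in enumerate(internals)}
    idx = {id(n): i for i, n in enumerate(internals)}
    edges = []
    for node in tree.preorder():
        if node.parent is not None:
            edges.append((node, node.parent))
    out: list[dict[int, frozenset[str]]] = []
    for j in range(matrix.n_char):
        tip_states = {
            t: _allowed_states(matrix.row(t)[j], k) for t in tree.tip_labels()
        }
        costs: dict[tuple, int] = {}
        for assign in itertools.product(range(k), repeat=len(internals)):
            cost = 0
            for child, parent in edges:
                p_state = assign[idx[id(parent)]]
                if child.is_leaf:
                    if p_state not in tip_states[child.label]:
                        cost += 1
                elif assign[idx[id(child)]] != p_state:
                    cost += 1
            costs[assign] = cost
        best = min(costs.values())
        sets: dict[int, set[str]] = {node_ids[id(n)]: set() for n in internals}
        for assign, cost in costs.items():
            if cost == best:
                for n in internals:
                    sets[node_ids[id(n)]].add(str(assign[idx[id(n)]]))
        out.append({nid: frozenset(s) for nid, s in sets.items()})
    return out


def dendropy_rf(t1: Tree, t2: Tree) -> int:
    """Independent Robinson-Foulds oracle via dendropy."""
    import dendropy
    from pseudoext.treespace import to_newick

    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=to_newick(t1), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d2 = dendropy.Tree.get(data=to_newick(t2), schema="newick",
                           taxon_namespace=tns, preserve_underscores=True)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
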