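"""Parsimony ancestral-state reconstruction and hypothetical predicted
ancestors (HPAs).

An HPA is a pseudo-taxon whose character row is the parsimony reconstruction
at an internal node of the molecular scaffold species tree (MSST).  The
reconstruction pipeline is: MPR state sets at every internal node
(:func:`fitch_mpr_sets`), masking of ambiguous cells to ``?``
(:func:`mask_ambiguous`), and an inapplicability repair driven by a
character-dependency map (:func:`repair_inapplicable`) so that no ancestor is
scored for a character that is inapplicable given its reconstructed state at
a controlling character.

MPR semantics follow the union-over-all-most-parsimonious-reconstructions
definition (Swofford-Maddison MPR sets), the behavior of parsimony
"trace all characters" in interactive ancestral-state tools; the Fitch final
(up-pass) sets are available behind ``method="fitch_final"``.

Internal nodes are numbered in preorder starting at ``n_tips + 1`` (the root
is ``n_tips + 1``); HPA rows are labeled ``HPA_<node id>``.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .matrix_io import CharacterMatrix, DependencyMap
from .treespace import Node, Tree

__all__ = [
    "AncestorTable",
    "fitch_mpr_sets",
    "mask_ambiguous",
    "repair_inapplicable",
    "generate_hpas",
    "number_internal_nodes",
]

_N_STATES = 10
_BIG = 1 << 20


@dataclass
class AncestorTable:
    """Per-internal-node reconstructions.

    ``mpr[node_id][j]`` is the MPR state set (frozenset of symbols) for
    0-based character ``j``; ``masked[node_id][j]`` is the single MPR state
    when unambiguous, else ``?``.
    """

    node_ids: list[int]
    n_char: int
    mpr: dict[int, list[frozenset[str]]]
    masked: dict[int, list[str]] = field(default_factory=dict)
    masked_cells: int = 0
    repaired_cells: int = 0

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tcharacter\tmpr_states\tmasked\n")
            for nid in self.node_ids:
                for j in range(self.n_char):
                    states = "".join(sorted(self.mpr[nid][j]))
                    masked = self.masked.get(nid, ["?"] * self.n_char)[j]
                    fh.write(f"{nid}\t{j + 1}\t{states}\t{masked}\n")


def number_internal_nodes(tree: Tree) -> dict[int, Node]:
    """Preorder numbering of internal nodes, starting at ``n_tips + 1``."""
    n_tips = len(tree)
    ids: dict[int, Node] = {}
    next_id = n_tips + 1
    for node in tree.preorder():
        if not node.is_leaf:
            ids[next_id] = node
            next_id += 1
    return ids


def _observed_alphabets(matrix: CharacterMatrix, taxa: list[str]
                        ) -> list[frozenset[str]]:
    rows = [matrix.row(t) for t in taxa]
    out = []
    for j in range(matrix.n_char):
        observed = {row[j] for row in rows} - {"?", "-"}
        observed = {ch for tok in observed for ch in tok if ch.isdigit()}
        out.append(frozenset(observed))
    return out


def fitch_mpr_sets(tree: Tree, matrix: CharacterMatrix,
                   method: str = "mpr") -> AncestorTable:
    """MPR state sets at every internal node of a rooted bifurcating tree.

    ``method="mpr"``: state *s* is in the set iff some most-parsimonious
    reconstruction of the character assigns *s* to the node (computed from
    unit-cost down- and up-pass tables).  ``method="fitch_final"``: the
    classical Fitch final sets after the up-pass, which can be a subset of
    the MPR sets on ties.  Tips scored ``?``/``-`` contribute the universal
    state set; MPR sets are reported intersected with the character's
    observed alphabet (unobserved states are never uniquely optimal under
    symmetric unit costs).
    """
    if method not in ("mpr", "fitch_final"):
        raise ValueError(f"unknown method {method!r}")
    for node in tree.internal_nodes():
        if len(node.children) != 2:
            raise ValueError(
                "ancestral reconstruction requires a fully bifurcating rooted tree"
            )
    taxa = tree.tip_labels()
    missing = [t for t in taxa if t not in matrix.taxa]
    if missing:
        raise ValueError(f"tips not scored in matrix: {missing}")
    n_char = matrix.n_char
    alphabets = _observed_alphabets(matrix, taxa)

    # down-pass: unit-cost DP tables, (10, n_char) per node
    down: dict[int, np.ndarray] = {}
    contrib: dict[int, np.ndarray] = {}

    def _down(node: Node) -> np.ndarray:
        if node.is_leaf:
            row = matrix.row(node.label)
            bits = np.zeros((_N_STATES, n_char), dtype=np.int64)
            for j, tok in enumerate(row):
                allowed = {int(c) for c in tok if c.isdigit()}
                if not allowed:
                    continue  # ? or -: all states free
                for s in range(_N_STATES):
                    if s not in allowed:
                        bits[s, j] = _BIG
            table = bits
        else:
            table = np.zeros((_N_STATES, n_char), dtype=np.int64)
            for child in node.children:
                table = table + contrib[id(child)]
        down[id(node)] = table
        if node.parent is not None:
            contrib[id(node)] = np.minimum(
                table, table.min(axis=0, keepdims=True) + 1
            )
        return table

    for node in tree.postorder():
        _down(node)

    # up-pass
    up: dict[int, np.ndarray] = {id(tree.root): np.zeros((_N_STATES, n_char),
                                                         dtype=np.int64)}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        a_total = up[id(node)] + down[id(node)]
        for child in node.children:
            b = a_total - contrib[id(child)]
            bmin = b.min(axis=0, keepdims=True)
            up[id(child)] = np.minimum(b, bmin + 1)

    best = (down[id(tree.root)]).min(axis=0)

    ids = number_internal_nodes(tree)
    mpr: dict[int, list[frozenset[str]]] = {}
    for nid, node in ids.items():
        total = down[id(node)] + up[id(node)]
        if method == "mpr":
            optimal = total == best[None, :]
        else:
            # Fitch final sets: states within the node's own optimal margin
            optimal = total == total.min(axis=0, keepdims=True)
        sets: list[frozenset[str]] = []
        for j in range(n_char):
            states = frozenset(str(s) for s in np.nonzero(optimal[:, j])[0])
            if alphabets[j]:
                states = states & alphabets[j] or states
            sets.append(states)
        mpr[nid] = sets
    return AncestorTable(node_ids=sorted(ids), n_char=n_char, mpr=mpr)


def mask_ambiguous(at: AncestorTable) -> AncestorTable:
    """Replace every ambiguous reconstruction (two or more MPR states) with
    ``?``; unambiguous cells keep their single state."""
    masked: dict[int, list[str]] = {}
    count = 0
    for nid in at.node_ids:
        row: list[str] = []
        for states in at.mpr[nid]:
            if len(states) == 1:
                row.append(next(iter(states)))
            else:
                row.append("?")
                count += 1
        masked[nid] = row
    return AncestorTable(
        node_ids=list(at.node_ids), n_char=at.n_char, mpr=at.mpr,
        masked=masked, masked_cells=count, repaired_cells=at.repaired_cells,
    )


def repair_inapplicable(at: AncestorTable, dep: DependencyMap) -> AncestorTable:
    """Mask dependent characters whose controller is in a trigger state.

    For each (controller, trigger states, dependent) entry and each ancestor
    row: if the controller's masked symbol is a trigger state *or* is ``?``
    (applicability cannot be certified), the dependent becomes ``?``.
    Applied to a fixed point so chained dependencies propagate; cyclic
    dependency maps are rejected.
    """
    if not at.masked:
        raise ValueError("run mask_ambiguous before repair_inapplicable")
    dep.validate(at.n_char)
    ts = graphlib.TopologicalSorter()
    for ctrl, _trig, dpt in dep.entries:
        ts.add(dpt, ctrl)
    try:
        ts.prepare()
    except graphlib.CycleError as exc:
        raise ValueError(f"cyclic character dependency: {exc.args[1]}") from exc

    masked = {nid: list(row) for nid, row in at.masked.items()}
    changed = 0
    dirty = True
    while dirty:
        dirty = False
        for ctrl, trig, dpt in dep.entries:
            for nid in at.node_ids:
                row = masked[nid]
                symbol = row[ctrl - 1]
                if (symbol in trig or symbol == "?") and row[dpt - 1] != "?":
                    row[dpt - 1] = "?"
                    changed += 1
                    dirty = True
    return AncestorTable(
        node_ids=list(at.node_ids), n_char=at.n_char, mpr=at.mpr,
        masked=masked, masked_cells=at.masked_cells, repaired_cells=changed,
    )


def generate_hpas(
    species_tree: Tree,
    matrix: CharacterMatrix,
    drop_order: Optional[set[str]] = None,
    dep: Optional[DependencyMap] = None,
    method: str = "mpr",
) -> tuple[CharacterMatrix, AncestorTable, Tree]:
    """Reconstruct one HPA row per internal node of the (pruned) species tree.

    The focal order's taxa are pruned from the tree before reconstruction —
    ancestors are predicted without any information from the pseudoextinct
    clade, as they would have to be for a genuinely extinct one.  A rooted
    binary tree with k tips yields k-1 HPA rows.  Deterministic.

    Returns (HPA rows as a CharacterMatrix, the ancestor table, the pruned
    tree with internal nodes labeled by their HPA number).
    """
    drop = set(drop_order or ())
    pruned = species_tree.copy()
    if drop:
        pruned.prune_taxa(drop & pruned.tip_set())
    if len(pruned) < 3:
        raise ValueError("pruning the focal order leaves fewer than 3 tips")
    table = fitch_mpr_sets(pruned, matrix, method=method)
    table = mask_ambiguous(table)
    if dep is not None and dep.entries:
        table = repair_inapplicable(table, dep)
    ids = number_internal_nodes(pruned)
    for nid, node in ids.items():
        node.label = str(nid)
    labels = [f"HPA_{nid}" for nid in table.node_ids]
    rows = [table.masked[nid] for nid in table.node_ids]
    hpa_matrix = CharacterMatrix(labels, rows, matrix.partition,
                                 metadata={"kind": "hpa"})
    return hpa_matrix, table, pruned
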