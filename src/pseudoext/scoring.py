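"""Placement scoring: misplacement categories, RF aggregation, tallies.

A pseudoextinct order's placement in an inferred tree is scored against the
molecular scaffold and the molecular scaffold species tree (MSST) with five
misplacement categories:

1. incorrect sister-group relationship — operationalized as a scaffold split
   that is incompatible with the inferred tree but becomes compatible once
   the focal order is removed from both (the violation is *attributable* to
   the focal order; scaffold polytomies therefore never flag a congruent
   resolution);
2. the focal order's superorder is not monophyletic;
3. the focal superorder is monophyletic but some other superorder is not;
4. the focal order itself is polyphyletic or paraphyletic (orders with >= 2
   taxa only);
5. the focal order is monophyletic and attached congruently (no category 1)
   but its internal topology differs from the MSST's (orders with >= 3 taxa).

Monophyly is judged on the tree rooted at the extant outgroup after pruning
fossils and ancestor pseudo-taxa.  RF summary tables aggregate multiple
equally parsimonious trees per cell by the cell mean, then take row/column
means (rounded half-up to 2 decimals) and medians (exact) over cell values.
"""

from __future__ import annotations

import csv
import importlib.resources
import statistics
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

from .treespace import (
    Tree,
    is_monophyletic,
    root_at,
    split_compatible_with_tree,
    unrooted_splits,
)

__all__ = [
    "TREATMENTS",
    "CladeMap",
    "MisplacementRecord",
    "RFSummary",
    "CategoryTally",
    "classify_placement",
    "summarize_rf",
    "tally_categories",
    "load_published_rf",
    "load_published_categories",
]

#: Canonical treatment order (columns of the summary tables).
TREATMENTS = (
    "scaffold+fossils+hpas",
    "fossils+hpas",
    "scaffold+fossils",
    "scaffold+hpas",
    "fossils",
    "hpas",
    "scaffold",
)


@dataclass(frozen=True)
class CladeMap:
    """Order and superorder membership of the extant taxa.

    ``orders`` maps order name -> extant taxa; ``superorders`` maps
    superorder name -> order names; ``outgroup_taxa`` are the non-placental
    extant taxa (marsupials and monotremes).
    """

    orders: dict[str, frozenset[str]]
    superorders: dict[str, frozenset[str]]
    outgroup_taxa: frozenset[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, taxa in self.orders.items():
            if seen & taxa:
                raise ValueError(f"order {name} overlaps another order")
            seen |= taxa
        assigned: set[str] = set()
        for sup, members in self.superorders.items():
            for order in members:
                if order not in self.orders:
                    raise ValueError(f"superorder {sup} lists unknown order {order}")
                if order in assigned:
                    raise ValueError(f"order {order} is in two superorders")
                assigned.add(order)
        if assigned != set(self.orders):
            raise ValueError("every order must belong to exactly one superorder")

    def superorder_of(self, order: str) -> str:
        for sup, members in self.superorders.items():
            if order in members:
                return sup
        raise KeyError(order)

    def superorder_taxa(self, sup: str) -> frozenset[str]:
        out: set[str] = set()
        for order in self.superorders[sup]:
            out |= self.orders[order]
        return frozenset(out)

    @property
    def placental_taxa(self) -> frozenset[str]:
        out: set[str] = set()
        for taxa in self.orders.values():
            out |= taxa
        return frozenset(out)


@dataclass
class MisplacementRecord:
    """Categories assigned to one (order, treatment) cell, with evidence."""

    order: str
    treatment: str
    categories: frozenset[int]
    violated_splits: tuple[tuple[str, ...], ...] = ()
    non_monophyletic: tuple[str, ...] = ()


def _rooted_clades(tree: Tree) -> frozenset[frozenset[str]]:
    clades: set[frozenset[str]] = set()

    def _below(node) -> frozenset[str]:
        if node.is_leaf:
            return frozenset((node.label,))
        below = frozenset().union(*(_below(c) for c in node.children))
        clades.add(below)
        return below

    _below(tree.root)
    return frozenset(clades)


def _induced_rooted(tree: Tree, keep: frozenset[str]) -> frozenset[frozenset[str]]:
    """Rooted clade sets of the tree restricted to ``keep`` (nesting kept)."""
    sub = tree.copy()
    sub.prune_taxa(sub.tip_set() - keep)
    return frozenset(c for c in _rooted_clades(sub) if 1 < len(c) < len(keep))


def classify_placement(
    inferred: Tree,
    scaffold: Tree,
    msst: Tree,
    cmap: CladeMap,
    focal_order: Optional[str],
    outgroup: str,
) -> MisplacementRecord:
    """Score one pruned, extant-taxa tree against scaffold and MSST.

    ``inferred`` must cover exactly the extant taxa of the MSST; fossils and
    ancestor pseudo-taxa must already be pruned.  With no focal order the
    category set is empty (baseline bookkeeping only).
    """
    if inferred.tip_set() != msst.tip_set():
        raise ValueError("inferred tree and MSST must share their tip set")
    if focal_order is None:
        return MisplacementRecord(order="", treatment="", categories=frozenset())
    focal_taxa = cmap.orders[focal_order]
    rooted = root_at(inferred, outgroup)
    rooted_msst = root_at(msst, outgroup)
    categories: set[int] = set()
    nonmono: list[str] = []

    # 4: focal order polyphyletic/paraphyletic
    if len(focal_taxa) >= 2 and not is_monophyletic(rooted, focal_taxa):
        categories.add(4)
        nonmono.append(focal_order)

    # 2/3: superorder monophyly
    focal_sup = cmap.superorder_of(focal_order)
    if not is_monophyletic(rooted, cmap.superorder_taxa(focal_sup)):
        categories.add(2)
        nonmono.append(focal_sup)
    else:
        others_broken = [
            sup for sup in cmap.superorders
            if sup != focal_sup
            and not is_monophyletic(rooted, cmap.superorder_taxa(sup))
        ]
        if others_broken:
            categories.add(3)
            nonmono.extend(others_broken)

    # 1: attributable scaffold-split violation
    universe = inferred.tip_set()
    reduced_inferred = inferred.copy()
    reduced_inferred.prune_taxa(focal_taxa & reduced_inferred.tip_set())
    violated: list[tuple[str, ...]] = []
    for side in unrooted_splits(scaffold):
        rest = universe - side
        if side <= focal_taxa or rest <= focal_taxa:
            continue  # intraordinal split: category 5's domain, not 1's
        if split_compatible_with_tree(side, inferred):
            continue
        reduced_side = side - focal_taxa
        reduced_rest = rest - focal_taxa
        if len(reduced_side) < 2 or len(reduced_rest) < 2:
            attributable = True
        else:
            attributable = split_compatible_with_tree(reduced_side,
                                                      reduced_inferred)
        if attributable:
            violated.append(tuple(sorted(side)))
    if violated:
        categories.add(1)

    # 5: monophyletic, congruently attached, internally rearranged
    if (len(focal_taxa) >= 3 and 4 not in categories and 1 not in categories):
        if (_induced_rooted(rooted, focal_taxa)
                != _induced_rooted(rooted_msst, focal_taxa)):
            categories.add(5)

    return MisplacementRecord(
        order=focal_order,
        treatment="",
        categories=frozenset(categories),
        violated_splits=tuple(violated),
        non_monophyletic=tuple(nonmono),
    )


# ---------------------------------------------------------------------------
# RF aggregation
# ---------------------------------------------------------------------------

def _round_half_up(x: float, places: int = 2) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RFSummary:
    """Cell values (means of per-tree RF lists) and marginal statistics."""

    orders: list[str]
    treatments: list[str]
    cells: dict[tuple[str, str], list[float]]
    cell_values: dict[tuple[str, str], float] = field(default_factory=dict)
    row_mean: dict[str, float] = field(default_factory=dict)
    row_median: dict[str, float] = field(default_factory=dict)
    col_mean: dict[str, float] = field(default_factory=dict)
    col_median: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["order", *self.treatments, "row_mean", "row_median"])
            for order in self.orders:
                row = [order]
                for tr in self.treatments:
                    row.append(",".join(_fmt_num(v)
                                        for v in self.cells[(order, tr)]))
                row.append(_fmt_num(self.row_mean[order]))
                row.append(_fmt_num(self.row_median[order]))
                writer.writerow(row)
            footer_mean = ["column_mean"]
            footer_median = ["column_median"]
            for tr in self.treatments:
                footer_mean.append(_fmt_num(self.col_mean[tr]))
                footer_median.append(_fmt_num(self.col_median[tr]))
            writer.writerow(footer_mean + ["", ""])
            writer.writerow(footer_median + ["", ""])


def _fmt_num(v: float) -> str:
    if v == int(v):
        return str(int(v))
    return repr(v)


def summarize_rf(
    cells: dict[tuple[str, str], Sequence[float]],
    orders: Optional[Sequence[str]] = None,
    treatments: Optional[Sequence[str]] = None,
) -> RFSummary:
    """Aggregate per-cell RF lists into row/column means and medians.

    The value of a cell with several equally parsimonious trees is the mean
    of its RF list; row and column means are means of cell values, rounded
    half-up to two decimals; medians are exact.  Every cell must be nonempty.
    """
    if orders is None:
        orders = sorted({o for o, _ in cells})
    if treatments is None:
        treatments = [t for t in TREATMENTS if any(k[1] == t for k in cells)]
    for order in orders:
        for tr in treatments:
            if not cells.get((order, tr)):
                raise ValueError(f"empty cell ({order!r}, {tr!r})")
    summary = RFSummary(orders=list(orders), treatments=list(treatments),
                        cells={k: list(v) for k, v in cells.items()})
    for key, values in summary.cells.items():
        summary.cell_values[key] = sum(values) / len(values)
    for order in orders:
        vals = [summary.cell_values[(order, tr)] for tr in treatments]
        summary.row_mean[order] = _round_half_up(sum(vals) / len(vals))
        summary.row_median[order] = statistics.median(vals)
    for tr in treatments:
        vals = [summary.cell_values[(order, tr)] for order in orders]
        summary.col_mean[tr] = _round_half_up(sum(vals) / len(vals))
        summary.col_median[tr] = statistics.median(vals)
    return summary


# ---------------------------------------------------------------------------
# Category tallies
# ---------------------------------------------------------------------------

@dataclass
class CategoryTally:
    """Occurrence counts of the five categories per order and treatment."""

    orders: list[str]
    treatments: list[str]
    cells: dict[tuple[str, str], frozenset[int]]
    row_counts: dict[str, Counter] = field(default_factory=dict)
    col_counts: dict[str, Counter] = field(default_factory=dict)
    congruent_per_treatment: dict[str, int] = field(default_factory=dict)
    always_category1: list[str] = field(default_factory=list)
    never_category1: list[str] = field(default_factory=list)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["order", *self.treatments, "row_totals"])
            for order in self.orders:
                row = [order]
                for tr in self.treatments:
                    row.append(",".join(str(c) for c in
                                        sorted(self.cells[(order, tr)])))
                totals = "; ".join(
                    f"{cat}: {n}X" for cat, n in
                    sorted(self.row_counts[order].items())
                )
                row.append(totals)
                writer.writerow(row)
            footer = ["column_totals"]
            for tr in self.treatments:
                footer.append("; ".join(
                    f"{cat}: {n}X" for cat, n in
                    sorted(self.col_counts[tr].items())
                ))
            writer.writerow(footer + [""])


def tally_categories(records: Iterable[MisplacementRecord]) -> CategoryTally:
    """Tally category occurrences per order (rows) and treatment (columns).

    An order *retains its correct interordinal placement* in a treatment iff
    category 1 is absent from its record; the tally derives, per treatment,
    how many orders are congruent, plus which orders carry category 1 in
    every treatment and which never do.
    """
    cells: dict[tuple[str, str], frozenset[int]] = {}
    for rec in records:
        key = (rec.order, rec.treatment)
        if key in cells:
            raise ValueError(f"duplicate record for {key}")
        cells[key] = rec.categories
    orders = sorted({o for o, _ in cells})
    treatments = [t for t in TREATMENTS if any(k[1] == t for k in cells)]
    extra = sorted({t for _, t in cells} - set(treatments))
    treatments += extra
    tally = CategoryTally(orders=orders, treatments=treatments, cells=cells)
    for order in orders:
        counter: Counter = Counter()
        for tr in treatments:
            for cat in cells.get((order, tr), frozenset()):
                counter[cat] += 1
        tally.row_counts[order] = counter
    for tr in treatments:
        counter = Counter()
        for order in orders:
            for cat in cells.get((order, tr), frozenset()):
                counter[cat] += 1
        tally.col_counts[tr] = counter
        tally.congruent_per_treatment[tr] = sum(
            1 for order in orders
            if 1 not in cells.get((order, tr), frozenset())
        )
    for order in orders:
        flags = [1 in cells.get((order, tr), frozenset()) for tr in treatments]
        if all(flags):
            tally.always_category1.append(order)
        if not any(flags):
            tally.never_category1.append(order)
    return tally


# ---------------------------------------------------------------------------
# Published reference tables (shipped fixtures)
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return (importlib.resources.files("pseudoext") / "data" / name).read_text()


def load_published_rf() -> dict[tuple[str, str], list[float]]:
    """Published RF distances of the 19 pseudoextinct placental orders under
    the seven treatments (cells list one value per most parsimonious tree)."""
    cells: dict[tuple[str, str], list[float]] = {}
    rows = _data_text("placental_rf_distances.tsv").strip().splitlines()
    header = rows[0].split("\t")[1:]
    for line in rows[1:]:
        parts = line.split("\t")
        order = parts[0]
        for tr, cell in zip(header, parts[1:]):
            cells[(order, tr)] = [float(x) for x in cell.split(",")]
    return cells


def load_published_categories() -> list[MisplacementRecord]:
    """Published misplacement categories for the same design."""
    records: list[MisplacementRecord] = []
    rows = _data_text("placental_misplacements.tsv").strip().splitlines()
    header = rows[0].split("\t")[1:]
    for line in rows[1:]:
        parts = line.split("\t")
        order = parts[0]
        cats = parts[1:] + [""] * (len(header) - len(parts) + 1)
        for tr, cell in zip(header, cats):
            categories = frozenset(int(c) for c in cell.split(",") if c)
            records.append(MisplacementRecord(order=order, treatment=tr,
                                              categories=categories))
    return records
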