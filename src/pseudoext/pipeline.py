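"""Orchestration of the pseudoextinction experiment.

The full design crosses seven treatments — every non-empty combination of
molecular scaffold (S), fossil taxa (F) and hypothetical predicted ancestors
(H) — with each placental order treated in turn as pseudoextinct, plus one
baseline run per treatment with no pseudoextinction.  For each run:

1. the focal order's soft characters are recoded to missing and its taxa are
   dropped from the scaffold (it must be placeable from bones alone);
2. with H, ancestor rows are reconstructed on the MSST *minus the focal
   order* (fossils never inform ancestor reconstruction);
3. a parsimony search runs with the reduced scaffold as backbone (S only),
   rooted at the fossil outgroup when fossils are present, else the extant
   outgroup;
4. saved trees are pruned of fossils and ancestor rows, deduplicated, and
   every unique topology is scored against the MSST (Robinson-Foulds) and
   the scaffold (misplacement categories).

All per-run seeds derive deterministically from the single study seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .ancestors import generate_hpas
from .matrix_io import (
    CharacterMatrix,
    DependencyMap,
    apply_pseudoextinction_coding,
)
from .parsimony import SearchConfig, SearchResult, heuristic_search
from .scoring import (
    TREATMENTS,
    CladeMap,
    MisplacementRecord,
    classify_placement,
    summarize_rf,
    tally_categories,
)
from .treespace import (
    Tree,
    prune_and_dedup,
    robinson_foulds,
    root_at,
    to_newick,
    write_newick_trees,
)

__all__ = [
    "TreatmentSpec",
    "StudyDesign",
    "RunResult",
    "build_msst",
    "build_treatment_inputs",
    "run_treatment",
    "run_study",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """One cell of the treatment design."""

    use_scaffold: bool
    use_fossils: bool
    use_hpas: bool
    focal_order: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.use_scaffold or self.use_fossils or self.use_hpas):
            raise ValueError("at least one of scaffold/fossils/hpas required")

    @property
    def name(self) -> str:
        parts = []
        if self.use_scaffold:
            parts.append("scaffold")
        if self.use_fossils:
            parts.append("fossils")
        if self.use_hpas:
            parts.append("hpas")
        return "+".join(parts)

    @classmethod
    def from_name(cls, name: str, focal_order: Optional[str] = None
                  ) -> "TreatmentSpec":
        parts = set(name.split("+"))
        unknown = parts - {"scaffold", "fossils", "hpas"}
        if unknown:
            raise ValueError(f"unknown treatment component(s): {sorted(unknown)}")
        return cls("scaffold" in parts, "fossils" in parts, "hpas" in parts,
                   focal_order)


@dataclass
class StudyDesign:
    """Everything a study needs: data, trees, groupings, and settings.

    ``matrix`` is the analysis-ready matrix (recoded, constants removed)
    containing extant and fossil rows; ``scaffold`` covers the extant taxa
    (polytomies allowed) and contains no fossil.
    """

    matrix: CharacterMatrix
    scaffold: Tree
    orders: dict[str, frozenset[str]]
    superorders: dict[str, frozenset[str]]
    fossil_taxa: list[str]
    extant_outgroup: str
    fossil_outgroup: str
    search: SearchConfig
    dependencies: DependencyMap = field(default_factory=DependencyMap)
    msst: Optional[Tree] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fossils = set(self.fossil_taxa)
        scaffold_tips = self.scaffold.tip_set()
        if fossils & scaffold_tips:
            raise ValueError("fossil taxa must be absent from the scaffold")
        missing = scaffold_tips - set(self.matrix.taxa)
        if missing:
            raise ValueError(f"scaffold taxa not in matrix: {sorted(missing)}")

    @property
    def extant_taxa(self) -> list[str]:
        fossils = set(self.fossil_taxa)
        return [t for t in self.matrix.taxa if t not in fossils]

    @property
    def clade_map(self) -> CladeMap:
        placental = frozenset().union(*self.orders.values())
        outgroup_taxa = frozenset(self.extant_taxa) - placental
        return CladeMap(orders=dict(self.orders),
                        superorders=dict(self.superorders),
                        outgroup_taxa=outgroup_taxa)

    def extant_matrix(self) -> CharacterMatrix:
        return self.matrix.subset_taxa(self.extant_taxa)


@dataclass
class RunResult:
    """Outcome of one (treatment, focal order) run."""

    treatment: str
    focal_order: Optional[str]
    best_length: int
    n_saved_trees: int
    pruned_trees: list[Tree]
    rf_to_msst: list[int]
    categories: frozenset[int]
    records: list[MisplacementRecord]
    replicates_hitting_best: int
    truncated: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.rf_to_msst) != len(self.pruned_trees):
            raise ValueError("one RF value per pruned tree required")


def build_msst(extant_matrix: CharacterMatrix, scaffold: Tree,
               config: SearchConfig, outgroup: str) -> Tree:
    """Parsimony search under the scaffold backbone; returns one fully
    bifurcating optimal tree rooted at the extant outgroup.

    Ties between equally parsimonious resolutions are broken by canonical
    Newick order (and logged by the search driver).
    """
    result = heuristic_search(extant_matrix, config, constraint=scaffold)
    winner = min(result.trees, key=to_newick)
    return root_at(winner, outgroup)


def build_treatment_inputs(
    design: StudyDesign, spec: TreatmentSpec
) -> tuple[CharacterMatrix, Optional[Tree], str]:
    """Assemble (matrix, constraint, outgroup) for one run.

    The matrix always holds every extant taxon (focal order soft-coded to
    missing), plus fossil rows iff fossils are in the treatment, plus one
    ancestor row per internal node of the MSST-minus-focal-order iff HPAs
    are.  The constraint (scaffold minus the focal order) never contains
    fossils or HPAs.
    """
    if spec.focal_order is not None and spec.focal_order not in design.orders:
        raise ValueError(f"unknown focal order {spec.focal_order!r}")
    focal_taxa = (set(design.orders[spec.focal_order])
                  if spec.focal_order else set())
    taxa = list(design.extant_taxa)
    if spec.use_fossils:
        taxa += list(design.fossil_taxa)
    matrix = design.matrix.subset_taxa(taxa)
    if focal_taxa:
        matrix = apply_pseudoextinction_coding(matrix, focal_taxa)
    if spec.use_hpas:
        if design.msst is None:
            raise ValueError("design has no MSST; run build_msst first")
        hpa_rows, _table, _pruned = generate_hpas(
            design.msst, design.extant_matrix(), drop_order=focal_taxa,
            dep=design.dependencies,
        )
        matrix = matrix.add_rows(hpa_rows.taxa, hpa_rows.cells)
    constraint: Optional[Tree] = None
    if spec.use_scaffold:
        constraint = design.scaffold.copy()
        if focal_taxa:
            constraint.prune_taxa(focal_taxa & constraint.tip_set())
    outgroup = (design.fossil_outgroup if spec.use_fossils
                else design.extant_outgroup)
    return matrix, constraint, outgroup


def _derive_seed(base_seed: int, treatment: str, order: Optional[str]) -> int:
    import zlib

    tag = zlib.crc32(f"{treatment}/{order or ''}".encode())
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(tag,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_treatment(design: StudyDesign, spec: TreatmentSpec) -> RunResult:
    """Search one treatment cell, prune, deduplicate, and score."""
    if design.msst is None:
        raise ValueError("design has no MSST; run build_msst first")
    matrix, constraint, outgroup = build_treatment_inputs(design, spec)
    seed = _derive_seed(design.search.seed, spec.name, spec.focal_order)
    config = replace(design.search, seed=seed, outgroup=outgroup)
    result: SearchResult = heuristic_search(matrix, config, constraint)

    extant = set(design.extant_taxa)
    drop = {t for t in matrix.taxa if t not in extant}
    pruned = prune_and_dedup(result.trees, drop)
    rf = [robinson_foulds(t, design.msst) for t in pruned]

    records: list[MisplacementRecord] = []
    categories: set[int] = set()
    cmap = design.clade_map
    for tree in pruned:
        rec = classify_placement(tree, design.scaffold, design.msst, cmap,
                                 spec.focal_order, design.extant_outgroup)
        rec.treatment = spec.name
        records.append(rec)
        categories |= rec.categories
    return RunResult(
        treatment=spec.name,
        focal_order=spec.focal_order,
        best_length=result.best_length,
        n_saved_trees=len(result.trees),
        pruned_trees=pruned,
        rf_to_msst=rf,
        categories=frozenset(categories),
        records=records,
        replicates_hitting_best=result.replicates_hitting_best,
        truncated=result.truncated,
        degenerate=result.best_length == 0,
    )


def run_study(design: StudyDesign, out_dir: Optional[str] = None,
              treatments: tuple[str, ...] = TREATMENTS,
              include_baselines: bool = True) -> list[RunResult]:
    """Run every treatment for every order (plus baselines) and collect
    Table-1-style RF and Table-2-style category matrices.

    Individual run failures are recorded (as a result with empty trees) and
    the study continues.  With ``out_dir``, writes ``rf_matrix.tsv``,
    ``categories.tsv``, per-run Newick archives (pre-pruning trees are the
    search output; post-pruning the deduplicated extant trees) and a JSON
    run log.
    """
    if design.msst is None:
        design.msst = build_msst(design.extant_matrix(), design.scaffold,
                                 design.search, design.extant_outgroup)
    results: list[RunResult] = []
    failures: list[dict] = []
    order_names = sorted(design.orders)
    for tname in treatments:
        focal_orders: list[Optional[str]] = list(order_names)
        if include_baselines:
            focal_orders = [None] + focal_orders
        for order in focal_orders:
            spec = TreatmentSpec.from_name(tname, order)
            try:
                run = run_treatment(design, spec)
            except Exception as exc:  # record and continue
                failures.append({"treatment": tname, "order": order,
                                 "error": repr(exc)})
                continue
            results.append(run)
            if out_dir:
                tag = f"{tname.replace('+', '-')}_{order or 'baseline'}"
                tree_dir = os.path.join(out_dir, "trees")
                os.makedirs(tree_dir, exist_ok=True)
                write_newick_trees(
                    run.pruned_trees,
                    os.path.join(tree_dir, f"{tag}.pruned.nwk"),
                )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        cells = {
            (r.focal_order, r.treatment): [float(x) for x in r.rf_to_msst]
            for r in results if r.focal_order is not None
        }
        if cells:
            summary = summarize_rf(cells, orders=order_names,
                                   treatments=list(treatments))
            summary.to_tsv(os.path.join(out_dir, "rf_matrix.tsv"))
            tally = tally_categories([
                MisplacementRecord(order=r.focal_order, treatment=r.treatment,
                                   categories=r.categories)
                for r in results if r.focal_order is not None
            ])
            tally.to_tsv(os.path.join(out_dir, "categories.tsv"))
        log = {
            "msst": to_newick(design.msst),
            "runs": [
                {
                    "treatment": r.treatment,
                    "focal_order": r.focal_order,
                    "best_length": r.best_length,
                    "n_saved": r.n_saved_trees,
                    "n_unique_pruned": len(r.pruned_trees),
                    "rf_to_msst": r.rf_to_msst,
                    "categories": sorted(r.categories),
                    "replicates_hitting_best": r.replicates_hitting_best,
                    "truncated": r.truncated,
                    "degenerate": r.degenerate,
                }
                for r in results
            ],
            "failures": failures,
        }
        with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
            json.dump(log, fh, indent=1)
    return results
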