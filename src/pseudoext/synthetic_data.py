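"""Synthetic morphological matrices with known generating history.

Characters evolve on a known species tree under the symmetric k-state Markov
model (Mk) with optional gamma rate heterogeneity across characters — the
simplest process consistent with unordered, equally weighted characters.
Each character is independently flagged osteological or non-osteological
(soft); fossil tips evolve from a chosen attachment point along a stem and
are scored ``?`` for every soft character (plus a random fraction of their
osteological ones), mimicking taxa known only from skeletal remains.

True ancestral states are retained so ancestral-state reconstruction accuracy
is directly testable, and study fixtures at three sizes wire everything into
a ready-to-run pseudoextinction design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .matrix_io import CharacterMatrix, CharacterPartition, DependencyMap
from .parsimony import SearchConfig
from .treespace import Node, Tree
from .ancestors import number_internal_nodes

__all__ = [
    "SimConfig",
    "SimResult",
    "FossilSpec",
    "simulate_matrix",
    "add_fossil_tips",
    "make_fixture_study",
]


@dataclass(frozen=True)
class FossilSpec:
    """One fossil tip: attach point (tip label, internal-node label, or a
    tuple of tip labels whose MRCA is used), stem length in expected
    substitutions, and the fraction of osteological characters additionally
    scored as missing."""

    name: str
    attach: tuple[str, ...]
    stem_length: float = 0.05
    osteo_missing: float = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    ``tree`` must be rooted and carry branch lengths in expected
    substitutions per character (at rate multiplier 1).  ``rate_gamma_shape``
    of ``None`` means equal rates; otherwise per-character multipliers are
    gamma(shape, mean 1).  ``rate_scale`` multiplies every branch length and
    is the homoplasy dial used by degradation experiments.
    """

    tree: Tree
    n_char: int = 500
    n_states: int = 3
    soft_fraction: float = 0.2
    rate_gamma_shape: Optional[float] = None
    rate_scale: float = 1.0
    fossil_specs: tuple[FossilSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_states <= 10:
            raise ValueError("n_states must be between 2 and 10")
        if not 0.0 <= self.soft_fraction <= 1.0:
            raise ValueError("soft_fraction must be in [0, 1]")


@dataclass
class SimResult:
    """A simulated matrix plus its generating truth.

    ``node_states[label]`` holds the integer state vector of every node of
    the (labeled) true tree; internal nodes are labeled with their preorder
    numbers (``n_tips + 1`` is the root), matching the HPA numbering.
    """

    matrix: CharacterMatrix
    tree: Tree
    node_states: dict[str, np.ndarray]
    rates: np.ndarray
    config: SimConfig


def _p_same(path_length: float, k: int) -> float:
    """Mk probability that the state is unchanged after ``path_length``
    expected substitutions."""
    return 1.0 / k + (k - 1) / k * math.exp(-path_length * k / (k - 1))


def _evolve(parent_states: np.ndarray, branch: float, rates: np.ndarray,
            k: int, rng: np.random.Generator) -> np.ndarray:
    lam = rates * branch
    p_same = 1.0 / k + (k - 1) / k * np.exp(-lam * k / (k - 1))
    stay = rng.random(parent_states.shape) < p_same
    jump = rng.integers(1, k, size=parent_states.shape)
    return np.where(stay, parent_states, (parent_states + jump) % k)


def simulate_matrix(cfg: SimConfig) -> SimResult:
    """Evolve ``n_char`` independent Mk characters on the configured tree.

    Root states are uniform; a gamma-drawn rate multiplier (if configured)
    scales every branch for that character.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    tree = cfg.tree.copy()
    ids = number_internal_nodes(tree)
    for nid, node in ids.items():
        node.label = str(nid)
    k = cfg.n_states
    if cfg.rate_gamma_shape:
        rates = rng.gamma(cfg.rate_gamma_shape, 1.0 / cfg.rate_gamma_shape,
                          size=cfg.n_char)
    else:
        rates = np.ones(cfg.n_char)

    node_states: dict[str, np.ndarray] = {}
    root_states = rng.integers(0, k, size=cfg.n_char)
    node_states[tree.root.label] = root_states
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = node_states[node.parent.label]
        branch = (node.length or 0.0) * cfg.rate_scale
        node_states[node.label] = _evolve(parent_states, branch, rates, k, rng)

    soft = rng.random(cfg.n_char) < cfg.soft_fraction
    partition = CharacterPartition.from_osteological(
        frozenset(int(j) + 1 for j in np.flatnonzero(~soft)), cfg.n_char
    )
    taxa = tree.tip_labels()
    cells = [[str(int(s)) for s in node_states[t]] for t in taxa]
    matrix = CharacterMatrix(taxa, cells, partition,
                             metadata={"kind": "simulated", "seed": cfg.seed})
    result = SimResult(matrix=matrix, tree=tree, node_states=node_states,
                       rates=rates, config=cfg)
    if cfg.fossil_specs:
        result = add_fossil_tips(result, cfg.fossil_specs, rng)
    return result


def _find_attach_node(tree: Tree, attach: tuple[str, ...]) -> Node:
    if len(attach) == 1:
        for node in tree.preorder():
            if node.label == attach[0]:
                return node
        raise ValueError(f"attachment node {attach[0]!r} not found")
    want = set(attach)
    best: Optional[Node] = None

    def _below(node: Node) -> set[str]:
        nonlocal best
        if node.is_leaf:
            out = {node.label}
        else:
            out = set()
            for c in node.children:
                out |= _below(c)
        if want <= out and best is None:
            best = node
        return out

    _below(tree.root)
    if best is None:
        raise ValueError(f"attachment taxa {sorted(want)} not all present")
    return best


def add_fossil_tips(sim: SimResult, specs: Sequence[FossilSpec],
                    rng: Optional[np.random.Generator] = None) -> SimResult:
    """Evolve fossil rows from their attachment points and add them as tips.

    Every soft character of a fossil is ``?``; a further ``osteo_missing``
    fraction of its osteological characters is ``?`` at random.  Fossils are
    appended to the matrix and grafted onto the true tree (on the edge above
    their attachment node) but are never part of any scaffold.
    """
    if rng is None:
        rng = np.random.default_rng(sim.config.seed + 1)
    cfg = sim.config
    k = cfg.n_states
    tree = sim.tree.copy()
    # relabel map is preserved by copy (labels are on the nodes)
    node_states = dict(sim.node_states)
    soft_idx = sorted(sim.matrix.partition.non_osteological)
    osteo_idx = sorted(sim.matrix.partition.osteological)
    new_taxa: list[str] = []
    new_rows: list[list[str]] = []
    for spec in specs:
        origin = _find_attach_node(tree, spec.attach)
        states = _evolve(node_states[origin.label],
                         spec.stem_length * cfg.rate_scale,
                         sim.rates, k, rng)
        row = [str(int(s)) for s in states]
        for j in soft_idx:
            row[j - 1] = "?"
        if spec.osteo_missing > 0:
            hide = rng.random(len(osteo_idx)) < spec.osteo_missing
            for j, h in zip(osteo_idx, hide):
                if h:
                    row[j - 1] = "?"
        new_taxa.append(spec.name)
        new_rows.append(row)
        node_states[spec.name] = states
        # graft onto the true tree
        tip = Node(spec.name, spec.stem_length)
        if origin is tree.root:
            new_root = Node()
            new_root.add_child(tree.root)
            new_root.add_child(tip)
            tree.root = new_root
        else:
            parent = origin.parent
            idx = parent.children.index(origin)
            mid = Node()
            mid.parent = parent
            parent.children[idx] = mid
            mid.children = [origin, tip]
            origin.parent = mid
            tip.parent = mid
    matrix = sim.matrix.add_rows(new_taxa, new_rows)
    return SimResult(matrix=matrix, tree=tree, node_states=node_states,
                     rates=sim.rates, config=cfg)


# ---------------------------------------------------------------------------
# Study fixtures
# ---------------------------------------------------------------------------

def _balanced_clade(labels: list[str], edge: float) -> Node:
    if len(labels) == 1:
        return Node(labels[0], edge)
    mid = len(labels) // 2
    node = Node(None, edge)
    node.add_child(_balanced_clade(labels[:mid], edge))
    node.add_child(_balanced_clade(labels[mid:], edge))
    return node


@dataclass
class _Profile:
    orders: dict[str, list[str]]          # placental orders
    superorders: dict[str, list[str]]     # superorder -> order names
    marsupials: list[str]
    monotremes: list[str]
    n_fossils: int
    n_char: int
    collapse_polytomies: int              # scaffold nodes to collapse


def _tiny_profile() -> _Profile:
    orders = {
        "OrdA1": ["A1a"], "OrdA2": ["A2a", "A2b"],
        "OrdB1": ["B1a"], "OrdB2": ["B2a", "B2b"],
        "OrdC1": ["C1a"], "OrdC2": ["C2a"],
        "OrdD1": ["D1a"], "OrdD2": ["D2a"],
    }
    supers = {"SupA": ["OrdA1", "OrdA2"], "SupB": ["OrdB1", "OrdB2"],
              "SupC": ["OrdC1", "OrdC2"], "SupD": ["OrdD1", "OrdD2"]}
    return _Profile(orders, supers, ["Marsupial1"], ["Monotreme1"],
                    n_fossils=4, n_char=200, collapse_polytomies=1)


def _default_profile() -> _Profile:
    orders = {}
    supers = {}
    for s in "ABCD":
        big = [f"{s}1{chr(97 + i)}" for i in range(3)]
        small = [f"{s}2{chr(97 + i)}" for i in range(2)]
        orders[f"Ord{s}1"] = big
        orders[f"Ord{s}2"] = small
        supers[f"Sup{s}"] = [f"Ord{s}1", f"Ord{s}2"]
    return _Profile(orders, supers, ["Marsupial1", "Marsupial2"],
                    ["Monotreme1", "Monotreme2"],
                    n_fossils=8, n_char=1000, collapse_polytomies=2)


def _paper_scale_profile() -> _Profile:
    orders = {
        # Afrotheria (7 placental taxa)
        "Afrosoricida": ["Tenrec", "Chrysochloris"],
        "Macroscelidea": ["Rhynchocyon"],
        "Tubulidentata": ["Orycteropus"],
        "Hyracoidea": ["Procavia"],
        "Proboscidea": ["Loxodonta"],
        "Sirenia": ["Trichechus"],
        # Xenarthra (2)
        "Cingulata": ["Dasypus"],
        "Pilosa": ["Tamandua"],
        # Laurasiatheria (20)
        "Eulipotyphla": ["Talpa", "Erinaceus", "Sorex", "Solenodon"],
        "Chiroptera": ["Pteropus", "Rhinopoma", "Saccopteryx", "Nycteris",
                       "Myotis", "Pteronotus"],
        "Carnivora": ["Canis", "Felis"],
        "Pholidota": ["Manis"],
        "Perissodactyla": ["Equus", "Tapirus"],
        "Cetartiodactyla": ["Bos", "Sus", "Hippopotamus", "Tursiops",
                            "Balaenoptera"],
        # Euarchontoglires (13)
        "Primates": ["Homo", "Saimiri", "Lemur", "Tarsius"],
        "Dermoptera": ["Cynocephalus"],
        "Scandentia": ["Tupaia"],
        "Lagomorpha": ["Oryctolagus", "Ochotona"],
        "Rodentia": ["Mus", "Rattus", "Cavia", "Sciurus", "Castor"],
    }
    supers = {
        "Afrotheria": ["Afrosoricida", "Macroscelidea", "Tubulidentata",
                       "Hyracoidea", "Proboscidea", "Sirenia"],
        "Xenarthra": ["Cingulata", "Pilosa"],
        "Laurasiatheria": ["Eulipotyphla", "Chiroptera", "Carnivora",
                           "Pholidota", "Perissodactyla", "Cetartiodactyla"],
        "Euarchontoglires": ["Primates", "Dermoptera", "Scandentia",
                             "Lagomorpha", "Rodentia"],
    }
    return _Profile(orders, supers, ["Didelphis", "Macropus"],
                    ["Ornithorhynchus", "Tachyglossus"],
                    n_fossils=40, n_char=4134, collapse_polytomies=6)


_PROFILES = {
    "tiny": _tiny_profile,
    "default": _default_profile,
    "paper_scale": _paper_scale_profile,
}


def _build_true_tree(profile: _Profile, edge: float) -> Tree:
    """Rooted binary species tree: (monotremes, (marsupials, placentals))."""
    sup_nodes = []
    for sup, order_names in profile.superorders.items():
        order_nodes = [
            _balanced_clade(profile.orders[o], edge) for o in order_names
        ]
        node = order_nodes[0] if len(order_nodes) == 1 else None
        while len(order_nodes) > 1:
            a = order_nodes.pop()
            b = order_nodes.pop()
            join = Node(None, edge)
            join.add_child(a)
            join.add_child(b)
            order_nodes.append(join)
        sup_nodes.append(order_nodes[0])
    while len(sup_nodes) > 1:
        a = sup_nodes.pop()
        b = sup_nodes.pop()
        join = Node(None, edge)
        join.add_child(a)
        join.add_child(b)
        sup_nodes.append(join)
    placentals = sup_nodes[0]
    theria = Node(None, edge)
    theria.add_child(_balanced_clade(profile.marsupials, edge))
    theria.add_child(placentals)
    root = Node(None, None)
    root.add_child(_balanced_clade(profile.monotremes, edge))
    root.add_child(theria)
    return Tree(root, rooted=True)


def _make_scaffold(true_tree: Tree, n_collapse: int) -> Tree:
    """Extant scaffold: the true tree, topology only, with the deepest
    ``n_collapse`` non-root internal edges collapsed into polytomies."""
    scaffold = true_tree.copy()
    for node in scaffold.preorder():
        node.length = None
        if not node.is_leaf:
            node.label = None
    internal = [n for n in scaffold.preorder()
                if not n.is_leaf and n.parent is not None
                and n.parent.parent is not None]
    for node in internal[:n_collapse]:
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx:idx + 1] = node.children
        for c in node.children:
            c.parent = parent
        node.children = []
    scaffold.rooted = False
    return scaffold


def make_fixture_study(profile: str = "tiny", seed: int = 0,
                       rate_scale: float = 1.0,
                       search: Optional[SearchConfig] = None):
    """Build a ready-to-run :class:`~pseudoext.pipeline.StudyDesign`.

    Profiles: ``tiny`` (12 extant taxa in 8 orders / 4 pseudo-superorders,
    4 fossils, 200 characters), ``default`` (24 extant, 8 fossils, 1,000
    characters), ``paper_scale`` (46 extant — 42 placentals in 19 orders,
    2 marsupials, 2 monotremes — 40 fossils, 4,134 characters of which 3,371
    osteological, scaffold with six polytomies).  Branch lengths are set so
    the expected number of changes per character is ~1.2 (low homoplasy);
    ``rate_scale`` multiplies them.
    """
    from .pipeline import StudyDesign  # local import to avoid a cycle

    if profile not in _PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    prof = _PROFILES[profile]()
    n_extant = (sum(len(v) for v in prof.orders.values())
                + len(prof.marsupials) + len(prof.monotremes))
    n_edges = 2 * n_extant - 2
    edge = 1.2 / n_edges
    true_tree = _build_true_tree(prof, edge)
    scaffold = _make_scaffold(true_tree, prof.collapse_polytomies)

    # fossils: one near the root (the fossil outgroup analogue), the rest
    # attached to order ancestors in rotation
    order_names = sorted(prof.orders)
    specs = [FossilSpec(name="Fossil_root",
                        attach=(prof.monotremes[0],
                                next(iter(prof.orders[order_names[0]]))),
                        stem_length=edge, osteo_missing=0.1)]
    for i in range(prof.n_fossils - 1):
        order = order_names[i % len(order_names)]
        taxa = prof.orders[order]
        attach = tuple(taxa) if len(taxa) > 1 else (taxa[0],)
        specs.append(FossilSpec(name=f"Fossil_{i + 1:02d}", attach=attach,
                                stem_length=2 * edge, osteo_missing=0.3))

    if profile == "paper_scale":
        matrix = _exact_paper_scale_matrix(prof, true_tree, specs, seed,
                                           rate_scale)
        sim_tree = true_tree
    else:
        from .matrix_io import recode_for_analysis, remove_constant_characters

        n_sim = int(prof.n_char * 1.6) + 50
        for attempt in range(6):
            cfg = SimConfig(tree=true_tree, n_char=n_sim,
                            n_states=3, soft_fraction=0.2,
                            rate_gamma_shape=2.0, rate_scale=rate_scale,
                            fossil_specs=tuple(specs), seed=seed)
            sim = simulate_matrix(cfg)
            recoded, _ = recode_for_analysis(sim.matrix)
            filtered, _ = remove_constant_characters(recoded)
            if filtered.n_char >= prof.n_char:
                break
            n_sim *= 2
        sim_tree = sim.tree
        matrix = _trim_characters(filtered, prof.n_char)

    fossil_names = [s.name for s in specs]
    return StudyDesign(
        matrix=matrix,
        scaffold=scaffold,
        orders={k: frozenset(v) for k, v in prof.orders.items()},
        superorders={k: frozenset(v) for k, v in prof.superorders.items()},
        fossil_taxa=fossil_names,
        extant_outgroup=prof.monotremes[0],
        fossil_outgroup="Fossil_root",
        search=search or SearchConfig(n_addition_sequences=4,
                                      trees_held_per_replicate=3,
                                      max_saved_trees=200, seed=seed),
        dependencies=DependencyMap(),
        extras={"true_tree": sim_tree, "profile": profile,
                "rate_scale": rate_scale},
    )


def _trim_characters(m: CharacterMatrix, n_keep: int) -> CharacterMatrix:
    """Keep the first ``n_keep`` characters (osteological indices remapped)."""
    if m.n_char < n_keep:
        raise ValueError(
            f"only {m.n_char} informative characters available, need {n_keep}"
        )
    cells = [row[:n_keep] for row in m.cells]
    osteo = frozenset(j for j in m.partition.osteological if j <= n_keep)
    part = CharacterPartition.from_osteological(osteo, n_keep)
    return CharacterMatrix(m.taxa, cells, part, m.metadata)


def _exact_paper_scale_matrix(prof: _Profile, true_tree: Tree,
                              specs: list[FossilSpec], seed: int,
                              rate_scale: float) -> CharacterMatrix:
    """Two-block simulation with exact post-filter counts: 3,371 osteological
    characters followed by 763 soft ones (total 4,134), all variable."""
    from .matrix_io import remove_constant_characters

    n_osteo, n_soft = 3371, prof.n_char - 3371
    blocks = []
    for block_i, (target, soft) in enumerate(((n_osteo, False), (n_soft, True))):
        cfg = SimConfig(tree=true_tree, n_char=int(target * 1.6) + 50,
                        n_states=3, soft_fraction=1.0 if soft else 0.0,
                        rate_gamma_shape=2.0, rate_scale=rate_scale,
                        fossil_specs=tuple(specs), seed=seed + block_i)
        sim = simulate_matrix(cfg)
        filtered, _ = remove_constant_characters(sim.matrix)
        if filtered.n_char < target:
            raise RuntimeError("simulation produced too few variable characters")
        blocks.append((filtered, target))
    (osteo_m, _), (soft_m, _) = blocks
    taxa = osteo_m.taxa
    cells = [
        osteo_m.cells[i][:n_osteo] + soft_m.row(t)[:n_soft]
        for i, t in enumerate(taxa)
    ]
    part = CharacterPartition.from_osteological(
        frozenset(range(1, n_osteo + 1)), prof.n_char
    )
    return CharacterMatrix(taxa, cells, part,
                           metadata={"kind": "simulated", "profile": "paper_scale"})
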