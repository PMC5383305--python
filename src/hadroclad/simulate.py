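"""Synthetic inputs with the statistical structure the pipeline assumes.

Provides Yule trees, unordered multistate characters evolved under a
symmetric Mk-style change process with missing data, tip areas evolved as
a Markov walk on the continental adjacency graph (forbidden pairs never
traversed in one step), and the hadrosaurine consensus fixture (topology,
tip areas, stage-level stratigraphic ranges) used by the worked examples.

Every simulator is fully deterministic under its seed.  Default
dimensions mirror the empirical matrix the pipeline targets (62 taxa,
346 unordered characters); the change rate and missingness defaults are
chosen to emulate a morphological matrix with substantial homoplasy and
missing data rather than any particular dataset.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .biogeography import AreaModel, TipAreaTable
from .chronogram import StageTable, read_ranges_tsv
from .nexus import MISSING, CharacterMatrix
from .trees import Node, Tree, TreeError, read_newick


@dataclass
class SimConfig:
    """Generator settings; the seed fully determines all output."""

    n_taxa: int = 62
    n_char: int = 346
    state_counts: tuple = (2, 3, 4)
    change_rate: float = 0.03
    change_model: str = "per_branch"  # or "per_length"
    missing_fraction: float = 0.30
    area_switch_prob: float = 0.15  # per-branch move on the adjacency graph
    seed: int = 0
    ensure_informative: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must be in [0, 1]")
        if not 0 <= self.area_switch_prob <= 1:
            raise ValueError("area_switch_prob must be in [0, 1]")
        if self.change_rate < 0:
            raise ValueError("change_rate must be >= 0")
        if self.change_model not in ("per_branch", "per_length"):
            raise ValueError("change_model must be per_branch or per_length")


def simulate_tree(n: int, seed: int, birth_rate: float = 1.0) -> Tree:
    """Rooted binary Yule tree with ``n`` tips labelled ``t01..``.

    Starting from a two-lineage root, a uniformly chosen extant lineage
    splits after an exponential waiting time with total rate
    ``birth_rate * k`` (k extant lineages), until n tips exist.
    """
    if n < 3:
        raise TreeError("a Yule tree needs at least 3 tips")
    rng = np.random.default_rng([seed, 11])
    root = Node()
    first, second = Node(), Node()
    root.add_child(first)
    root.add_child(second)
    extant = [first, second]
    pending = {first: 0.0, second: 0.0}  # branch length accumulated so far
    while len(extant) < n:
        k = len(extant)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for node in extant:
            pending[node] += wait
        idx = rng.integers(k)
        parent = extant.pop(idx)
        parent.length = pending.pop(parent)
        kids = [Node(), Node()]
        for kid in kids:
            parent.add_child(kid)
            pending[kid] = 0.0
        extant.extend(kids)
    # terminal stub so final tips have nonzero length
    wait = rng.exponential(1.0 / (birth_rate * len(extant)))
    for node in extant:
        node.length = pending[node] + wait
    width = len(str(n))
    for i, node in enumerate(Tree(root).tips()):
        node.label = f"t{i + 1:0{width}d}"
    return Tree(root)


def simulate_matrix(tree: Tree, cfg: SimConfig) -> CharacterMatrix:
    """Unordered multistate characters evolved independently on ``tree``.

    Each character draws its state count from ``cfg.state_counts``, a
    uniform root state, and evolves along every branch: a change event
    picks a uniformly random different state.  Morphological characters
    carry no molecular clock, so the default change model gives every
    branch the same change probability (``cfg.change_rate`` per branch);
    ``change_model="per_length"`` instead uses
    1 - exp(-rate * branch_length) for clock-like evolution on the
    simulated branch lengths.  Cells are then masked to MISSING at
    ``cfg.missing_fraction``.  With ``cfg.ensure_informative``,
    characters that come out constant are resimulated (bounded retries).
    """
    rng = np.random.default_rng([cfg.seed, 13])
    tips = tree.tips()
    n_char = cfg.n_char
    k = rng.choice(np.asarray(cfg.state_counts), size=n_char)
    max_tries = 40 if cfg.ensure_informative else 1
    tip_states = _evolve(tree, k, cfg, rng)
    for _ in range(max_tries - 1):
        variable = np.array([
            len({row[c] for row in tip_states.values()}) > 1
            for c in range(n_char)
        ])
        if variable.all():
            break
        redo = ~variable
        new = _evolve(tree, k, cfg, rng)
        for tip in tip_states:
            tip_states[tip] = np.where(redo, new[tip], tip_states[tip])
    mask = rng.random((len(tips), n_char)) < cfg.missing_fraction
    taxa, cells = [], []
    for t_i, tip in enumerate(tips):
        taxa.append(tip.label)
        row = []
        for c in range(n_char):
            if mask[t_i, c]:
                row.append(MISSING)
            else:
                row.append(frozenset([str(int(tip_states[tip.label][c]))]))
        cells.append(row)
    return CharacterMatrix(taxa, cells)


def _evolve(tree: Tree, k: np.ndarray, cfg: SimConfig, rng) -> dict:
    n_char = len(k)
    states: dict[Node, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    tree.root.parent = None
    for node in tree.preorder():
        for c in node.children:
            c.parent = node
    for node in tree.preorder():
        if node is tree.root:
            states[node] = rng.integers(0, k)
        else:
            if cfg.change_model == "per_branch":
                p_change = min(cfg.change_rate, 0.95)
            else:
                length = node.length if node.length is not None else 1.0
                p_change = 1.0 - np.exp(-cfg.change_rate * length)
            change = rng.random(n_char) < p_change
            shift = rng.integers(1, np.maximum(k - 1, 1) + 1)
            states[node] = np.where(
                change, (states[node.parent] + shift) % k, states[node.parent]
            )
        if node.is_leaf:
            out[node.label] = states[node]
    return out


def simulate_tip_areas(tree: Tree, cfg: SimConfig,
                       model: AreaModel | None = None) -> TipAreaTable:
    """Tip areas from a root-to-tip Markov walk on the area adjacency graph.

    Per branch, with probability ``cfg.area_switch_prob`` the lineage
    moves to a uniformly chosen adjacent area; forbidden pairs are never
    traversed in a single step.
    """
    model = model or AreaModel()
    rng = np.random.default_rng([cfg.seed, 17])
    neighbors = {
        a: [b for b in model.areas
            if b != a and frozenset((a, b)) not in model.forbidden_sets]
        for a in model.areas
    }
    tree.root.parent = None
    for node in tree.preorder():
        for c in node.children:
            c.parent = node
    area: dict[Node, str] = {}
    table = {}
    for node in tree.preorder():
        if node is tree.root:
            area[node] = model.areas[rng.integers(len(model.areas))]
        else:
            current = area[node.parent]
            if neighbors[current] and rng.random() < cfg.area_switch_prob:
                area[node] = neighbors[current][rng.integers(len(neighbors[current]))]
            else:
                area[node] = current
        if node.is_leaf:
            table[node.label] = area[node]
    return TipAreaTable(table)


# ---------------------------------------------------------------------------
# the hadrosaurine fixture


def _data_text(name: str) -> str:
    return (importlib.resources.files("hadroclad") / "data" / name).read_text()


def _data_path(name: str):
    return importlib.resources.files("hadroclad") / "data" / name


def fixture_hadrosaurinae() -> tuple[Tree, TipAreaTable, dict]:
    """The hadrosaurine strict-consensus fixture.

    Returns the 21-tip consensus topology (basal polytomy of *Hadrosaurus
    foulkii*, Brachylophosaurini, and Kritosaurini + (Saurolophini +
    Edmontosaurini); Edmontosaurini pectinate with *Kerberosaurus* basal
    and the two *Edmontosaurus* species as sisters), the tip-area table,
    and stage-level stratigraphic ranges.  The ranges are synthetic
    stage-level reconstructions shipped as an editable TSV.
    """
    tree = read_newick(_data_text("hadrosaurinae_consensus.nwk"))
    areas = TipAreaTable.from_tsv(_data_path("hadrosaurinae_tip_areas.tsv"))
    ranges = read_ranges_tsv(_data_path("hadrosaurinae_strat_ranges_synthetic.tsv"))
    return tree, areas, ranges


def default_stage_table() -> StageTable:
    """The GTS 2009 stage boundary table shipped with the package."""
    return StageTable.from_tsv(_data_path("gts2009_stages.tsv"))


#: Named subclades of the fixture, keyed by their tip sets.
FIXTURE_CLADES = {
    "Edmontosaurini": (
        "Kerberosaurus_manakini", "Shantungosaurus_giganteus",
        "Edmontosaurus_regalis", "Edmontosaurus_annectens",
    ),
    "Kritosaurini": (
        "Gryposaurus_notabilis", "Gryposaurus_monumentensis",
        "Gryposaurus_latidens", "Rhinorex_condrupus",
        "Kritosaurus_navajovius", "Secernosaurus_koerneri",
        "Willinakaqe_salitralensis",
    ),
    "Saurolophini": (
        "Lophorhothon_atopus", "Prosaurolophus_maximus",
        "Saurolophus_osborni", "Saurolophus_angustirostris",
    ),
    "Brachylophosaurini": (
        "Wulagasaurus_dongi", "Acristavus_gagslarsoni",
        "Maiasaura_peeblesorum", "Brachylophosaurus_canadensis",
        "Probrachylophosaurus_bergei",
    ),
}
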