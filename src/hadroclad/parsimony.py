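"""Maximum-parsimony scoring, heuristic tree search, and node support.

The engine reproduces a classic TNT-style analysis natively: Fitch
two-pass scoring of unordered characters, random-addition Wagner trees
followed by branch swapping (TBR by default, SPR/NNI selectable),
ensemble consistency and retention indices, nonparametric bootstrap
proportions, Bremer decay values, and unambiguous synapomorphy mapping.

Trees are handled rooted on a designated outgroup; because Fitch length
is invariant to rooting, the search explores unrooted topologies through
their rooted-on-outgroup representatives.  During the search, topologies
live as nested index tuples ("shapes") over matrix rows, which are
immutable, hashable and structure-shared, so Fitch state sets memoize
across the swap neighborhood.

Randomness contract: every stochastic stage derives an independent
deterministic stream from ``(seed, stage, replicate)``, so identical
configurations give bit-identical output and increasing a replicate
count never reshuffles earlier replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .nexus import CharacterMatrix
from .trees import Node, Tree, TreeError, strict_consensus

_STREAM_SEARCH = 1
_STREAM_BOOTSTRAP = 2
_STREAM_BREMER = 3


@dataclass
class SearchConfig:
    """Settings for the heuristic parsimony search.

    Defaults mirror a traditional full-scale analysis (1000 random-addition
    replicates, TBR, 100 trees held per replicate, seed 1); desk-scale runs
    pass smaller ``replicates``/``hold``.
    """

    outgroup: str
    replicates: int = 1000
    hold: int = 100
    seed: int = 1
    swap: str = "tbr"  # tbr | spr | nni
    collapse: bool = True  # collapse zero-minimum-length branches in MPTs
    bootstrap_search_replicates: int = 3
    bootstrap_search_hold: int = 20
    bremer_margin_ceiling: int = 10

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.swap not in ("tbr", "spr", "nni"):
            raise ValueError(f"unknown swap method {self.swap!r}")


@dataclass
class ParsimonyResult:
    """Outcome of a parsimony search.

    ``steps`` holds per-character Fitch steps on the first (binary) MPT;
    ``ci_all`` includes every character in the ensemble consistency index
    while ``ci_informative`` excludes parsimony-uninformative ones (both
    conventions circulate in the literature).  ``ri`` is identical under
    the two conventions and is ``None`` when no informative variation
    exists.
    """

    length: int
    mpts: list[Tree]
    binary_mpts: list[Tree] = field(repr=False)
    steps: np.ndarray = field(repr=False)
    min_steps: np.ndarray = field(repr=False)
    max_steps: np.ndarray = field(repr=False)
    ci_all: float
    ci_informative: float | None
    ri: float | None


@dataclass
class SupportTable:
    """Per-bipartition support values keyed by the clade's tip set.

    Entries map ``frozenset(tips) -> {"bootstrap": %, "bremer": steps,
    "bremer_is_lower_bound": bool}`` (keys present as computed).
    """

    entries: dict[frozenset, dict]

    def merge(self, other: "SupportTable") -> "SupportTable":
        merged = {k: dict(v) for k, v in self.entries.items()}
        for k, v in other.entries.items():
            merged.setdefault(k, {}).update(v)
        return SupportTable(merged)

    def to_tsv(self) -> str:
        lines = ["clade\tbootstrap_pct\tbremer"]
        for clade in sorted(self.entries, key=lambda c: (len(c), sorted(c))):
            vals = self.entries[clade]
            boot = vals.get("bootstrap")
            brem = vals.get("bremer")
            brem_s = "" if brem is None else (
                f">={brem}" if vals.get("bremer_is_lower_bound") else str(brem)
            )
            lines.append(
                ",".join(sorted(clade))
                + "\t" + ("" if boot is None else f"{boot:.1f}")
                + "\t" + brem_s
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# matrix encoding


class EncodedMatrix:
    """Bitmask encoding of a character matrix for vectorized Fitch passes.

    Each cell becomes a bitmask over the states observed in its column;
    missing and inapplicable cells carry the full column alphabet (they
    never force a change).  Columns with no observed state collapse to a
    single dummy state.
    """

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.taxa = list(matrix.taxa)
        self.taxon_index = {t: i for i, t in enumerate(self.taxa)}
        n_taxa, n_char = matrix.n_taxa, matrix.n_char
        self.alphabets: list[str] = []
        masks = np.zeros((n_taxa, n_char), dtype=np.uint16)
        for c in range(n_char):
            column = [row[c] for row in matrix.cells]
            observed = sorted(
                set().union(*[s for s in column if isinstance(s, frozenset)])
                if any(isinstance(s, frozenset) for s in column)
                else set()
            )
            self.alphabets.append("".join(observed))
            if not observed:
                masks[:, c] = 1
                continue
            bit = {sym: 1 << i for i, sym in enumerate(observed)}
            full = (1 << len(observed)) - 1
            for t, cell in enumerate(column):
                if isinstance(cell, frozenset):
                    masks[t, c] = sum(bit[s] for s in cell)
                else:
                    masks[t, c] = full
        self.masks = masks

    @property
    def n_char(self) -> int:
        return self.masks.shape[1]

    def resampled(self, indices: np.ndarray) -> np.ndarray:
        """Column-resampled mask array (whole columns, preserving missingness)."""
        return np.ascontiguousarray(self.masks[:, indices])


# ---------------------------------------------------------------------------
# Fitch scoring on shapes


class _Fitch:
    """Memoizing Fitch evaluator over nested index-tuple shapes."""

    def __init__(self, masks: np.ndarray):
        self.masks = masks
        self.cache: dict = {}

    def _eval(self, shape):
        if not isinstance(shape, tuple):
            return self.masks[shape], 0
        hit = self.cache.get(shape)
        if hit is not None:
            return hit
        sa, na = self._eval(shape[0])
        sb, nb = self._eval(shape[1])
        inter = sa & sb
        zero = inter == 0
        steps = na + nb + int(zero.sum())
        states = np.where(zero, sa | sb, inter)
        out = (states, steps)
        self.cache[shape] = out
        return out

    def length(self, shape) -> int:
        return self._eval(shape)[1]


def _shape_clades(shape, acc: set) -> frozenset:
    if not isinstance(shape, tuple):
        return frozenset([shape])
    left = _shape_clades(shape[0], acc)
    right = _shape_clades(shape[1], acc)
    clade = left | right
    acc.add(clade)
    return clade


def _shape_key(shape) -> frozenset:
    acc: set = set()
    _shape_clades(shape, acc)
    return frozenset(acc)


def _shape_to_tree(shape, og_index: int, taxa: Sequence[str]) -> Tree:
    def rec(s) -> Node:
        if not isinstance(s, tuple):
            return Node(taxa[s])
        node = Node()
        node.add_child(rec(s[0]))
        node.add_child(rec(s[1]))
        return node

    root = Node()
    root.add_child(Node(taxa[og_index]))
    root.add_child(rec(shape))
    return Tree(root)


# ---------------------------------------------------------------------------
# neighborhood moves on shapes


def _prune_options(shape) -> list:
    """(subtree, remainder) for every proper subtree of ``shape``."""
    res: list = []

    def walk(s, rebuild):
        if not isinstance(s, tuple):
            return
        left, right = s
        res.append((left, rebuild(right)))
        res.append((right, rebuild(left)))
        walk(left, lambda x, right=right, rb=rebuild: rb((x, right)))
        walk(right, lambda x, left=left, rb=rebuild: rb((left, x)))

    walk(shape, lambda x: x)
    return res


def _rerootings(shape) -> list:
    """All rooted representatives of the unrooted tree underlying ``shape``.

    One representative per unrooted edge (2m - 3 for m leaves): the root
    edge itself, then every edge inside either child subtree, visited by
    carrying the complement ("everything above this edge, rooted here")
    down the tree.
    """
    if not isinstance(shape, tuple):
        return [shape]
    res = [shape]

    def walk(sub, comp):
        res.append((sub, comp))
        if isinstance(sub, tuple):
            a, b = sub
            walk(a, (b, comp))
            walk(b, (a, comp))

    left, right = shape
    if isinstance(left, tuple):
        a, b = left
        walk(a, (b, right))
        walk(b, (a, right))
    if isinstance(right, tuple):
        a, b = right
        walk(a, (b, left))
        walk(b, (a, left))
    return res


def _insertions(shape, item) -> Iterator:
    yield (item, shape)
    if isinstance(shape, tuple):
        left, right = shape
        for s in _insertions(left, item):
            yield (s, right)
        for s in _insertions(right, item):
            yield (left, s)


def _neighbors(shape, method: str) -> Iterator:
    if not isinstance(shape, tuple):
        return
    if method == "nni":
        def walk(s, rebuild):
            if not isinstance(s, tuple):
                return
            left, right = s
            for inner, outer, side in ((left, right, 0), (right, left, 1)):
                if isinstance(inner, tuple):
                    a, b = inner
                    if side == 0:
                        yield rebuild(((a, outer), b))
                        yield rebuild(((b, outer), a))
                    else:
                        yield rebuild((b, (a, outer)))
                        yield rebuild((a, (b, outer)))
            yield from walk(left, lambda x, right=right, rb=rebuild: rb((x, right)))
            yield from walk(right, lambda x, left=left, rb=rebuild: rb((left, x)))

        yield from walk(shape, lambda x: x)
        return
    for sub, remainder in _prune_options(shape):
        if method == "tbr":
            for rerooted in _rerootings(sub):
                yield from _insertions(remainder, rerooted)
        else:  # spr
            yield from _insertions(remainder, sub)


# ---------------------------------------------------------------------------
# tree construction and enumeration


def _wagner_shape(order: Sequence[int], og: int, fitch: _Fitch, rng) -> object:
    """Random-addition Wagner tree: greedy best insertion, random tie-break."""
    shape = order[0]
    for taxon in order[1:]:
        candidates = list(_insertions(shape, taxon))
        lengths = np.array([fitch.length((og, c)) for c in candidates])
        best = np.flatnonzero(lengths == lengths.min())
        shape = candidates[best[rng.integers(len(best))]]
    return shape


def _all_shapes(ingroup: Sequence[int]) -> Iterator:
    """Every rooted-on-outgroup topology over the ingroup indices."""
    shapes: list = [ingroup[0]]
    for taxon in ingroup[1:]:
        shapes = [s for shape in shapes for s in _insertions(shape, taxon)]
    return iter(shapes)


def _count_topologies(n_ingroup: int) -> int:
    out = 1
    for i in range(3, 2 * n_ingroup - 2, 2):
        out *= i
    return out


# ---------------------------------------------------------------------------
# public scoring operations


def _require_tips_in_matrix(tree: Tree, enc: EncodedMatrix) -> None:
    for label in tree.tip_labels():
        if label not in enc.taxon_index:
            raise TreeError(f"tip {label!r} absent from matrix")


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> tuple[int, np.ndarray]:
    """Fitch length of a binary rooted tree: (total steps S, per-character s_i).

    Missing and inapplicable tips contribute the full column alphabet;
    polymorphic tips contribute their state set.  Polytomies are rejected.
    """
    enc = matrix if isinstance(matrix, EncodedMatrix) else EncodedMatrix(matrix)
    _require_tips_in_matrix(tree, enc)
    if not tree.is_binary():
        raise TreeError("fitch_length requires a fully binary tree")
    steps = np.zeros(enc.n_char, dtype=np.int64)
    states: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            states[node] = enc.masks[enc.taxon_index[node.label]]
        else:
            a, b = (states[c] for c in node.children)
            inter = a & b
            zero = inter == 0
            steps += zero
            states[node] = np.where(zero, a | b, inter)
    return int(steps.sum()), steps


def char_min_steps(column: Sequence) -> int:
    """Minimum Fitch steps of one character over all possible trees.

    Equals the size of the smallest state set hitting every non-missing
    cell, minus one (for singleton-only columns: distinct observed states
    minus one).
    """
    sets = [c for c in column if isinstance(c, frozenset)]
    if not sets:
        return 0
    alphabet = sorted(set().union(*sets))
    for size in range(1, len(alphabet) + 1):
        for combo in itertools.combinations(alphabet, size):
            chosen = set(combo)
            if all(chosen & s for s in sets):
                return size - 1
    return len(alphabet) - 1  # pragma: no cover - loop always returns


def char_max_steps(column: Sequence) -> int:
    """Maximum Fitch steps of one character over all possible trees.

    For an unordered character this is the non-missing cell count minus
    the best achievable count of the modal state (polymorphic cells side
    with the modal candidate).
    """
    sets = [c for c in column if isinstance(c, frozenset)]
    if not sets:
        return 0
    alphabet = set().union(*sets)
    best_modal = max(sum(1 for s in sets if sym in s) for sym in alphabet)
    return len(sets) - best_modal


@dataclass
class EnsembleIndices:
    ci_all: float
    ci_informative: float | None
    ri: float | None
    sum_min: int
    sum_max: int


def ensemble_indices(matrix: CharacterMatrix, length: int,
                     steps: np.ndarray | None = None) -> EnsembleIndices:
    """Ensemble CI and RI at tree length ``length``.

    ``ci_all`` uses every character (CI = sum(m_i)/S); ``ci_informative``
    drops parsimony-uninformative characters (those with m_i = g_i) from
    numerator and realized length.  RI = (G - S)/(G - M) is unaffected by
    uninformative characters and is ``None`` when G = M.
    """
    mins = np.array([char_min_steps(matrix.column(c + 1)) for c in range(matrix.n_char)])
    maxs = np.array([char_max_steps(matrix.column(c + 1)) for c in range(matrix.n_char)])
    sum_min, sum_max = int(mins.sum()), int(maxs.sum())
    ci_all = sum_min / length if length else 1.0
    uninformative = mins == maxs
    # on any most-parsimonious tree an uninformative character realizes m_i
    length_inf = length - int(mins[uninformative].sum())
    sum_min_inf = int(mins[~uninformative].sum())
    ci_inf = (sum_min_inf / length_inf) if length_inf > 0 else None
    ri = (sum_max - length) / (sum_max - sum_min) if sum_max > sum_min else None
    return EnsembleIndices(ci_all, ci_inf, ri, sum_min, sum_max)


# ---------------------------------------------------------------------------
# search


def _swap_to_optimum(shape, og: int, fitch: _Fitch, method: str,
                     hold: int, margin: int = 0):
    """Branch swapping from ``shape``; returns (best_length, pool dict).

    Equal-length (or within ``margin``) trees accumulate until the hold
    limit; a strictly better tree restarts the pool.  The pool maps
    topology keys to (shape, length).
    """
    best = fitch.length((og, shape))
    pool: dict[frozenset, tuple] = {_shape_key(shape): (shape, best)}
    swapped: set[frozenset] = set()
    while True:
        pending = [k for k in pool if k not in swapped]
        if not pending:
            return best, pool
        key = pending[0]
        swapped.add(key)
        current = pool[key][0]
        for nb in _neighbors(current, method):
            length = fitch.length((og, nb))
            if length > best + margin:
                continue
            nb_key = _shape_key(nb)
            if nb_key in pool:
                continue
            if length < best:
                best = length
                pool = {k: v for k, v in pool.items() if v[1] <= best + margin}
                swapped &= set(pool)
                pool[nb_key] = (nb, length)
            elif len(pool) < hold:
                pool[nb_key] = (nb, length)


def _search_shapes(enc_masks: np.ndarray, og: int, ingroup: list[int],
                   cfg: SearchConfig, replicates: int, hold: int,
                   margin: int = 0, stream: int = _STREAM_SEARCH,
                   stream_salt: int = 0) -> tuple[int, dict]:
    global_best = None
    global_pool: dict[frozenset, tuple] = {}
    for rep in range(replicates):
        rng = np.random.default_rng([cfg.seed, stream, stream_salt, rep])
        fitch = _Fitch(enc_masks)
        order = [ingroup[i] for i in rng.permutation(len(ingroup))]
        start = _wagner_shape(order, og, fitch, rng)
        best, pool = _swap_to_optimum(start, og, fitch, cfg.swap, hold, margin)
        if global_best is None or best < global_best:
            global_best = best
            global_pool = {
                k: v for k, v in pool.items() if v[1] <= best + margin
            }
        elif best <= global_best + margin:
            for k, v in pool.items():
                if v[1] <= global_best + margin and k not in global_pool:
                    global_pool[k] = v
    return global_best, global_pool


def _sorted_shapes(pool: dict) -> list:
    return [
        shape for shape, _ in sorted(
            pool.values(), key=lambda sv: sorted(map(sorted, _shape_key(sv[0])))
        )
    ]


def _assemble_result(matrix: CharacterMatrix, enc: EncodedMatrix, og: int,
                     best: int, pool: dict, collapse: bool) -> ParsimonyResult:
    shapes = [s for s in _sorted_shapes(pool)]
    binary_mpts = [_shape_to_tree(s, og, enc.taxa) for s in shapes]
    if collapse:
        seen: dict[frozenset, Tree] = {}
        for tree in binary_mpts:
            collapsed = collapse_zero_length_branches(tree, enc)
            key = frozenset(collapsed.clades(include_trivial=True))
            seen.setdefault(key, collapsed)
        mpts = list(seen.values())
    else:
        mpts = [t.copy() for t in binary_mpts]
    _, steps = fitch_length(binary_mpts[0], enc)
    idx = ensemble_indices(matrix, best)
    mins = np.array([char_min_steps(matrix.column(c + 1)) for c in range(matrix.n_char)])
    maxs = np.array([char_max_steps(matrix.column(c + 1)) for c in range(matrix.n_char)])
    return ParsimonyResult(
        length=best, mpts=mpts, binary_mpts=binary_mpts, steps=steps,
        min_steps=mins, max_steps=maxs, ci_all=idx.ci_all,
        ci_informative=idx.ci_informative, ri=idx.ri,
    )


def _setup(matrix: CharacterMatrix, cfg: SearchConfig):
    if matrix.n_taxa < 4:
        raise TreeError("search requires at least 4 taxa")
    enc = EncodedMatrix(matrix)
    if cfg.outgroup not in enc.taxon_index:
        raise TreeError(f"outgroup {cfg.outgroup!r} absent from matrix")
    og = enc.taxon_index[cfg.outgroup]
    ingroup = [i for i in range(matrix.n_taxa) if i != og]
    return enc, og, ingroup


def heuristic_search(matrix: CharacterMatrix, cfg: SearchConfig) -> ParsimonyResult:
    """Random-addition + branch-swapping search for most parsimonious trees.

    Per replicate a Wagner tree is built from a random addition sequence
    and swapped to a local optimum, holding up to ``cfg.hold`` equal-length
    trees; the global pool across replicates is unbounded and deduplicated
    (after optional collapsing of zero-minimum-length branches).  Results
    are rooted on the configured outgroup.
    """
    enc, og, ingroup = _setup(matrix, cfg)
    best, pool = _search_shapes(
        enc.masks, og, ingroup, cfg, cfg.replicates, cfg.hold
    )
    return _assemble_result(matrix, enc, og, best, pool, cfg.collapse)


def exhaustive_search(matrix: CharacterMatrix, cfg: SearchConfig) -> ParsimonyResult:
    """Exact search enumerating every topology (small taxon counts only)."""
    enc, og, ingroup = _setup(matrix, cfg)
    if _count_topologies(len(ingroup)) > 200_000:
        raise TreeError("too many topologies for exhaustive enumeration")
    fitch = _Fitch(enc.masks)
    best = None
    pool: dict[frozenset, tuple] = {}
    for shape in _all_shapes(ingroup):
        length = fitch.length((og, shape))
        if best is None or length < best:
            best = length
            pool = {_shape_key(shape): (shape, length)}
        elif length == best:
            pool[_shape_key(shape)] = (shape, length)
    return _assemble_result(matrix, enc, og, best, pool, cfg.collapse)


# ---------------------------------------------------------------------------
# supports


def bootstrap_support(matrix: CharacterMatrix, cfg: SearchConfig,
                      n_reps: int) -> SupportTable:
    """Nonparametric bootstrap proportions (percent of replicates).

    Characters are resampled whole (with replacement, same character
    count, missingness patterns preserved); each replicate runs a reduced
    search and contributes the bipartitions of its MPT consensus.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    enc, og, ingroup = _setup(matrix, cfg)
    counts: dict[frozenset, int] = {}
    n_char = enc.n_char
    for rep in range(n_reps):
        rng = np.random.default_rng([cfg.seed, _STREAM_BOOTSTRAP, rep])
        indices = rng.integers(0, n_char, n_char)
        masks = enc.resampled(indices)
        _, pool = _search_shapes(
            masks, og, ingroup, cfg, cfg.bootstrap_search_replicates,
            cfg.bootstrap_search_hold, stream=_STREAM_BOOTSTRAP,
            stream_salt=rep + 1,
        )
        keys = [_shape_key(shape) for shape, _ in pool.values()]
        common = set.intersection(*map(set, keys))
        full = len(ingroup)
        for clade in common:
            if 2 <= len(clade) <= full - 1:
                label_set = frozenset(enc.taxa[i] for i in clade)
                counts[label_set] = counts.get(label_set, 0) + 1
    entries = {
        clade: {"bootstrap": 100.0 * n / n_reps} for clade, n in counts.items()
    }
    return SupportTable(entries)


def bremer_support(matrix: CharacterMatrix, mpts: Sequence[Tree],
                   cfg: SearchConfig) -> SupportTable:
    """Bremer decay values for the clades of the MPT strict consensus.

    Bremer(B) is the length excess of the shortest tree lacking clade B.
    Small problems are solved exactly by enumerating every topology;
    otherwise suboptimal trees are retained under an increasing margin
    until every clade is contradicted (clades never contradicted within
    the margin ceiling are reported as lower bounds).
    """
    enc, og, ingroup = _setup(matrix, cfg)
    consensus = strict_consensus(list(mpts))
    og_label = cfg.outgroup
    # the whole ingroup is implied by outgroup rooting; it cannot decay
    clades = {
        c for c in consensus.clades()
        if og_label not in c and len(c) < matrix.n_taxa - 1
    }
    if not clades:
        return SupportTable({})

    def clade_indices(clade: frozenset) -> frozenset:
        return frozenset(enc.taxon_index[t] for t in clade)

    targets = {clade: clade_indices(clade) for clade in clades}
    entries: dict[frozenset, dict] = {}

    if _count_topologies(len(ingroup)) <= 15_000:
        fitch = _Fitch(enc.masks)
        best = None
        worst: dict[frozenset, int] = {}
        for shape in _all_shapes(ingroup):
            length = fitch.length((og, shape))
            if best is None or length < best:
                best = length
            key = _shape_key(shape)
            for clade, idx_set in targets.items():
                if idx_set not in key:
                    if clade not in worst or length < worst[clade]:
                        worst[clade] = length
        for clade in clades:
            entries[clade] = {
                "bremer": worst[clade] - best, "bremer_is_lower_bound": False,
            }
        return SupportTable(entries)

    best, _ = _search_shapes(enc.masks, og, ingroup, cfg,
                             min(cfg.replicates, 5), cfg.hold,
                             stream=_STREAM_BREMER)
    remaining = set(clades)
    for margin in range(1, cfg.bremer_margin_ceiling + 1):
        if not remaining:
            break
        _, pool = _search_shapes(
            enc.masks, og, ingroup, cfg, min(cfg.replicates, 5),
            cfg.hold * 5, margin=margin, stream=_STREAM_BREMER,
            stream_salt=margin,
        )
        for clade in list(remaining):
            idx_set = targets[clade]
            lacking = [
                length for (shape, length) in pool.values()
                if idx_set not in _shape_key(shape)
            ]
            if lacking:
                entries[clade] = {
                    "bremer": min(lacking) - best,
                    "bremer_is_lower_bound": False,
                }
                remaining.discard(clade)
    for clade in remaining:
        entries[clade] = {
            "bremer": cfg.bremer_margin_ceiling, "bremer_is_lower_bound": True,
        }
    return SupportTable(entries)


# ---------------------------------------------------------------------------
# per-edge optimization (synapomorphies and branch collapsing)

_INF = float("inf")


def _char_edge_dp(tree: Tree, enc: EncodedMatrix, char: int):
    """Optimal state-pair sets for every edge of one character.

    Runs the uniform-cost (Sankoff) inside/outside dynamic program and
    yields, per non-root node, the set of (parent_state, child_state)
    pairs realized by at least one most-parsimonious reconstruction.
    """
    alphabet = enc.alphabets[char]
    k = len(alphabet)
    if k == 0:
        return None, {}
    col = enc.masks[:, char]
    nodes = list(tree.postorder())
    # inside pass: up[v][a] = min cost of subtree(v) with v in state a;
    # cost through a child edge is min_b(up[b] + [a != b]) = min(up[a], min(up) + 1)
    up: dict[Node, np.ndarray] = {}
    for node in nodes:
        if node.is_leaf:
            mask = col[enc.taxon_index[node.label]]
            up[node] = np.array(
                [0.0 if mask & (1 << i) else _INF for i in range(k)]
            )
        else:
            vec = np.zeros(k)
            for c in node.children:
                child = up[c]
                vec = vec + np.minimum(child, child.min() + 1)
            up[node] = vec
    total = up[tree.root].min()

    down: dict[Node, np.ndarray] = {tree.root: np.zeros(k)}
    sib_cost: dict[Node, np.ndarray] = {}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        child_costs = {
            c: np.minimum(up[c], up[c].min() + 1) for c in node.children
        }
        total_cost = sum(child_costs.values())
        for c in node.children:
            sibs = total_cost - child_costs[c]
            sib_cost[c] = sibs
            base = down[node] + sibs  # cost outside subtree(c), parent state a
            down[c] = np.minimum(base, base.min() + 1)

    pairs: dict[Node, set] = {}
    for node in nodes:
        if node is tree.root:
            continue
        parent = node.parent
        base = down[parent] + sib_cost[node]
        opt = set()
        for a in range(k):
            if base[a] == _INF:
                continue
            for b in range(k):
                if up[node][b] == _INF:
                    continue
                if base[a] + (a != b) + up[node][b] == total:
                    opt.add((a, b))
        pairs[node] = opt
    return alphabet, pairs


def _link_parents(tree: Tree) -> None:
    tree.root.parent = None
    for node in tree.preorder():
        for c in node.children:
            c.parent = node


def map_synapomorphies(tree: Tree, matrix: CharacterMatrix) -> dict[Node, list]:
    """Unambiguous state changes per branch.

    A change is reported on the branch above a node when every
    most-parsimonious reconstruction changes state there and derives the
    same state - i.e. the change is identical under accelerated and
    delayed optimization.  Characters are numbered 1-based; entries are
    ``(character_number, derived_state_symbol)``.
    """
    enc = matrix if isinstance(matrix, EncodedMatrix) else EncodedMatrix(matrix)
    _require_tips_in_matrix(tree, enc)
    _link_parents(tree)
    out: dict[Node, list] = {n: [] for n in tree.preorder() if n.parent is not None}
    for char in range(enc.n_char):
        alphabet, pairs = _char_edge_dp(tree, enc, char)
        if alphabet is None:
            continue
        for node, opt in pairs.items():
            if not opt:
                continue
            if all(a != b for a, b in opt):
                derived = {b for _, b in opt}
                if len(derived) == 1:
                    out[node].append((char + 1, alphabet[derived.pop()]))
    return out


def min_branch_lengths(tree: Tree, matrix: CharacterMatrix) -> dict[Node, int]:
    """Minimum optimized length of each branch over all reconstructions.

    Per character a branch contributes one step only when every
    most-parsimonious reconstruction changes state across it.
    """
    enc = matrix if isinstance(matrix, EncodedMatrix) else EncodedMatrix(matrix)
    _require_tips_in_matrix(tree, enc)
    _link_parents(tree)
    out: dict[Node, int] = {n: 0 for n in tree.preorder() if n.parent is not None}
    for char in range(enc.n_char):
        alphabet, pairs = _char_edge_dp(tree, enc, char)
        if alphabet is None:
            continue
        for node, opt in pairs.items():
            if opt and all(a != b for a, b in opt):
                out[node] += 1
    return out


def collapse_zero_length_branches(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Copy of ``tree`` with internal branches of minimum length zero collapsed.

    This is the collapse rule applied before counting distinct MPTs: a
    branch that can be assigned zero changes in some most-parsimonious
    reconstruction carries no topological evidence.
    """
    work = tree.copy()
    lengths = min_branch_lengths(work, matrix)
    for node in list(work.postorder()):
        if node.is_leaf or node.parent is None:
            continue
        if lengths[node] == 0:
            parent = node.parent
            i = parent.children.index(node)
            parent.children[i:i + 1] = node.children
            for c in node.children:
                c.parent = parent
    return work
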