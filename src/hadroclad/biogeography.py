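"""Ancestral-area probability inference by pairwise multiplication/addition.

Each tip is certain of the single continental region where its fossil
material occurs.  Moving rootward, the probability vector of an ancestor
is assembled from its two subclades by expanding every ordered pair of
child areas: a pair (a, b) contributes its product mass to area a when
a = b, and half to each of a and b otherwise (the subclades are treated
equally, so a split between two areas is ambiguous about which side kept
the ancestral range).  With no dispersal constraint this rule reduces
exactly to the arithmetic mean of the child vectors.

A dispersal constraint excludes product terms pairing two areas with no
direct land connection (by default Asia and South America, whose only
Late Cretaceous routes run through North America); the surviving mass is
renormalized to a probability vector.  Polytomies are expanded into every
binary resolution scenario, each scenario is evaluated independently,
and the focal node's vector is the equal-weight mean over scenarios.
Arithmetic is exact (rational) throughout; rendering to percentages
happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .trees import (
    DEFAULT_RESOLUTION_LIMIT,
    Node,
    Tree,
    enumerate_resolutions,
)

#: Probability vector over areas (exact rationals).
AreaVector = dict


class DispersalError(ValueError):
    """Every product term of a combination is forbidden (no allowed route)."""


DEFAULT_AREAS = ("Asia", "NorthAmerica", "SouthAmerica")
DEFAULT_FORBIDDEN = (("Asia", "SouthAmerica"),)


@dataclass(frozen=True)
class AreaModel:
    """Area set, dispersal constraints, and combination policy.

    ``forbidden`` lists unordered area pairs whose direct product terms
    are excluded.  ``constraint_scope`` applies the exclusion at
    ``"every_node"`` (default: dispersal impossibility is a property of
    every split) or ``"root_only"`` (the alternative reading in which only
    the final addition is constrained).  ``fallback`` chooses what to do
    when *all* mass of a combination is forbidden: ``"error"`` (default)
    or ``"unconstrained"`` (fall back to the plain average).
    ``renormalize`` rescales each combined vector to sum 1 after the
    exclusion.
    """

    areas: tuple = DEFAULT_AREAS
    forbidden: tuple = DEFAULT_FORBIDDEN
    constraint_scope: str = "every_node"
    fallback: str = "error"
    renormalize: bool = True

    def __post_init__(self) -> None:
        for pair in self.forbidden:
            if len(pair) != 2 or any(a not in self.areas for a in pair):
                raise ValueError(f"forbidden pair {pair} outside area set")
        if self.constraint_scope not in ("every_node", "root_only"):
            raise ValueError("constraint_scope must be every_node or root_only")
        if self.fallback not in ("error", "unconstrained"):
            raise ValueError("fallback must be error or unconstrained")
        n = len(self.areas)
        if len({frozenset(p) for p in self.forbidden}) >= n * (n - 1) // 2 and n > 1:
            raise ValueError("at least one allowed area pair is required")

    @property
    def forbidden_sets(self) -> frozenset:
        return frozenset(frozenset(p) for p in self.forbidden)


@dataclass
class TipAreaTable:
    """Taxon -> single area of fossil occurrence."""

    areas: dict

    def __post_init__(self) -> None:
        self.areas = dict(self.areas)

    def __getitem__(self, taxon: str) -> str:
        return self.areas[taxon]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.areas

    @classmethod
    def from_tsv(cls, path) -> "TipAreaTable":
        areas = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("taxon\t"):
                    continue
                taxon, area = line.split("\t")[:2]
                areas[taxon] = area
        return cls(areas)

    def to_tsv(self) -> str:
        lines = ["taxon\tarea"]
        lines += [f"{t}\t{a}" for t, a in self.areas.items()]
        return "\n".join(lines) + "\n"


def tip_vector(taxon: str, table: TipAreaTable, model: AreaModel) -> AreaVector:
    """Certainty vector: probability 1 at the taxon's recorded area."""
    if taxon not in table:
        raise KeyError(f"taxon {taxon!r} missing from the tip-area table")
    area = table[taxon]
    if area not in model.areas:
        raise ValueError(f"area {area!r} of {taxon!r} not in the area model")
    return {a: Fraction(1) if a == area else Fraction(0) for a in model.areas}


def combine_children(p_left: AreaVector, p_right: AreaVector,
                     model: AreaModel, constrained: bool = True) -> AreaVector:
    """Combine two subclade vectors into their ancestor's vector.

    Expands all ordered child-area pairs (a, b): weight 1 to area a when
    a = b, else 1/2 to each of a and b; pairs in the model's forbidden set
    are dropped when ``constrained``.  The result is renormalized to sum 1
    (if the model says so).  If every pair with positive mass is forbidden
    a :class:`DispersalError` is raised, or the unconstrained average is
    returned when the model's fallback allows it.
    """
    forbidden = model.forbidden_sets if constrained else frozenset()
    out = {a: Fraction(0) for a in model.areas}
    half = Fraction(1, 2)
    for a, pa in p_left.items():
        if not pa:
            continue
        for b, pb in p_right.items():
            if not pb:
                continue
            if frozenset((a, b)) in forbidden:
                continue
            mass = pa * pb
            if a == b:
                out[a] += mass
            else:
                out[a] += mass * half
                out[b] += mass * half
    total = sum(out.values())
    if total == 0:
        if model.fallback == "unconstrained" and constrained:
            return combine_children(p_left, p_right, model, constrained=False)
        raise DispersalError(
            "all child-area combinations are forbidden (disconnected dispersal)"
        )
    if model.renormalize and total != 1:
        out = {a: v / total for a, v in out.items()}
    return out


def _combine_shape(shape, vectors: list, model: AreaModel,
                   at_root: bool) -> AreaVector:
    """Evaluate one binary resolution shape over subclade vectors."""
    if not isinstance(shape, tuple):
        return vectors[shape]
    scope_all = model.constraint_scope == "every_node"
    left = _combine_shape(shape[0], vectors, model, False)
    right = _combine_shape(shape[1], vectors, model, False)
    return combine_children(left, right, model,
                            constrained=scope_all or at_root)


def _mean_vectors(vectors: list, model: AreaModel) -> AreaVector:
    n = len(vectors)
    return {
        a: sum((v[a] for v in vectors), Fraction(0)) / n for a in model.areas
    }


def ancestral_areas(tree: Tree, table: TipAreaTable, model: AreaModel | None = None,
                    resolution_limit: int = DEFAULT_RESOLUTION_LIMIT,
                    ) -> dict[Node, AreaVector]:
    """Ancestral-area vectors for every internal node of ``tree``.

    Propagation is post-order (tips to root).  Binary nodes combine their
    two child vectors directly; a polytomy of k subclades is expanded into
    all (2k-3)!! binary resolution scenarios, and the polytomy node's
    vector is the equal-weight mean of the scenario root vectors (the
    subclades themselves are evaluated once - nested polytomies resolve
    independently).  Vectors are reported for the original tree's nodes
    only, and are also stored on each node under ``annotations["areas"]``.
    """
    model = model or AreaModel()
    result: dict[Node, AreaVector] = {}

    def rec(node: Node, at_root: bool) -> AreaVector:
        if node.is_leaf:
            vec = tip_vector(node.label, table, model)
            result[node] = vec
            return vec
        child_vecs = [rec(c, False) for c in node.children]
        if len(child_vecs) == 1:
            vec = child_vecs[0]
        elif len(child_vecs) == 2:
            constrained = model.constraint_scope == "every_node" or at_root
            vec = combine_children(child_vecs[0], child_vecs[1], model,
                                   constrained=constrained)
        else:
            shapes = enumerate_resolutions(len(child_vecs), resolution_limit)
            scenario_vecs = [
                _combine_shape(shape, child_vecs, model, at_root)
                for shape in shapes
            ]
            vec = _mean_vectors(scenario_vecs, model)
        result[node] = vec
        node.annotations["areas"] = vec
        return vec

    rec(tree.root, True)
    return result


def areas_report(tree: Tree, result: Mapping[Node, AreaVector],
                 clade_names: Mapping[frozenset, str] | None = None,
                 include_tips: bool = False) -> str:
    """TSV report of node area probabilities in percent (2 decimals)."""
    clade_names = clade_names or {}
    cmap = tree.clade_map()
    areas = None
    lines = []
    for node in tree.preorder():
        if node.is_leaf and not include_tips:
            continue
        vec = result.get(node)
        if vec is None:
            continue
        if areas is None:
            areas = list(vec)
            lines.insert(0, "clade\tname\t" + "\t".join(f"{a}_pct" for a in areas))
        clade = cmap[node]
        name = clade_names.get(clade, node.label or "")
        lines.append(
            ",".join(sorted(clade)) + "\t" + name + "\t"
            + "\t".join(f"{float(vec[a]) * 100:.2f}" for a in areas)
        )
    return "\n".join(lines) + "\n"


def annotate_newick_labels(tree: Tree, result: Mapping[Node, AreaVector]) -> Tree:
    """Copy of ``tree`` with internal labels like ``Asia=75.00|NA=25.00``."""
    out = tree.copy()
    for orig, copy in zip(tree.preorder(), out.preorder()):
        vec = result.get(orig)
        if vec is not None and not copy.is_leaf:
            copy.label = "|".join(
                f"{a}={float(v) * 100:.2f}" for a, v in vec.items() if v > 0
            )
    return out
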