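"""Stratigraphic time calibration of a cladogram.

Split events are postulated to predate the oldest first appearance datum
(FAD) among a clade's members, so every internal node receives a minimum
split-age bound: the maximum FAD over its descendant tips.  Bounds are
"no later than"-style minima, never point estimates - the procedure
defines no branch durations.  Each bound is located in a geological stage
from a user-supplied boundary table (GTS 2009 by default, shipped as an
editable data file because time-scale revisions recalibrate taxon ages).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .trees import Node, Tree


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class StratRange:
    """First/last appearance ages of one taxon, in Ma (FAD >= LAD > 0)."""

    taxon: str
    fad: float
    lad: float

    def __post_init__(self) -> None:
        if not self.fad >= self.lad > 0:
            raise CalibrationError(
                f"{self.taxon}: need FAD >= LAD > 0, got {self.fad}/{self.lad}"
            )


class StageTable:
    """Ordered geological stages with boundary ages in Ma (older to younger).

    An age lying exactly on a boundary maps to the older stage, so a
    bound at the Santonian-Campanian boundary reads "end of Santonian".
    """

    def __init__(self, stages: list[tuple[str, float, float]]):
        if not stages:
            raise CalibrationError("empty stage table")
        ages = []
        for name, base, top in stages:
            if not base > top:
                raise CalibrationError(f"stage {name}: base {base} must exceed top {top}")
            ages.append((base, top))
        for (b1, t1), (b2, t2) in zip(ages, ages[1:]):
            if t1 != b2:
                raise CalibrationError(
                    "stage boundaries must decrease contiguously from older to younger"
                )
        self.stages = list(stages)

    def stage_of(self, age: float) -> str:
        oldest_base = self.stages[0][1]
        for name, base, top in self.stages:
            if top <= age < base or (age == base and base == self.stages[0][1]):
                return name
        if age == self.stages[0][1]:
            return self.stages[0][0]
        raise CalibrationError(f"age {age} Ma outside the stage table")

    @classmethod
    def from_tsv(cls, path) -> "StageTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            [(r["stage"], float(r["base_Ma"]), float(r["top_Ma"]))
             for _, r in df.iterrows()]
        )


def read_ranges_tsv(path) -> dict[str, StratRange]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        r["taxon"]: StratRange(r["taxon"], float(r["fad_Ma"]), float(r["lad_Ma"]))
        for _, r in df.iterrows()
    }


@dataclass
class Chronogram:
    """A calibrated tree plus per-node minimum split-age bounds."""

    tree: Tree
    bounds: dict  # Node -> (age_Ma, stage_name)

    def to_tsv(self) -> str:
        cmap = self.tree.clade_map()
        lines = ["clade\tmin_age_Ma\tstage"]
        for node in self.tree.preorder():
            if node.is_leaf:
                continue
            age, stage = self.bounds[node]
            lines.append(",".join(sorted(cmap[node])) + f"\t{age:g}\t{stage}")
        return "\n".join(lines) + "\n"


def calibrate(tree: Tree, ranges: dict[str, StratRange],
              stages: StageTable) -> Chronogram:
    """Attach minimum split-age bounds to every internal node.

    bound(node) = max FAD over descendant tips; nesting of descendant
    sets makes parent bounds automatically >= child bounds.  Bounds and
    containing stages are stored on ``annotations`` (keys ``min_age_Ma``
    and ``stage``) of a calibrated copy of the tree.
    """
    missing = [t for t in tree.tip_labels() if t not in ranges]
    if missing:
        raise CalibrationError(f"no stratigraphic range for: {sorted(missing)}")
    work = tree.copy()
    bounds: dict[Node, tuple] = {}
    fad: dict[Node, float] = {}
    for node in work.postorder():
        if node.is_leaf:
            fad[node] = ranges[node.label].fad
        else:
            fad[node] = max(fad[c] for c in node.children)
            stage = stages.stage_of(fad[node])
            bounds[node] = (fad[node], stage)
            node.annotations["min_age_Ma"] = fad[node]
            node.annotations["stage"] = stage
    return Chronogram(work, bounds)
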