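"""Criteria weights from qualitative swing comparisons.

Swing weighting asks which attribute's full reference swing (x_l -> x_h)
is the most valuable improvement, and by how much the swings differ in
attractiveness.  With a fictitious null swing ("no improvement") included
as the bottom stimulus, the MACBETH machinery converts those judgments
into a ratio scale whose normalised scores are the criteria weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .macbeth import JudgmentMatrix, derive_scale
from .tree import ValueTree

NULL_SWING = "null"


@dataclass(frozen=True)
class Swing:
    """The improvement from x_l to x_h on one attribute."""

    attribute: str
    description: str = ""


@dataclass(frozen=True)
class WeightVector:
    """Normalised non-negative criteria weights summing to one."""

    weights: Mapping[str, float]
    normalization: float = 1.0  # sum of the raw weights supplied

    def __getitem__(self, attribute: str) -> float:
        return self.weights[attribute]

    def as_series(self) -> pd.Series:
        s = pd.Series(dict(self.weights), dtype=float)
        s.index.name = "attribute"
        return s

    def as_percent(self) -> pd.Series:
        return self.as_series() * 100.0


def normalize(raw: Mapping[str, float]) -> WeightVector:
    """Proportionally scale raw weights to sum 1; zeros are retained."""
    if not raw:
        raise ValueError("degenerate weights: empty weight set")
    vals = {k: float(v) for k, v in raw.items()}
    if any(v < 0 for v in vals.values()):
        raise ValueError("weights must be non-negative")
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("degenerate weights: all weights zero")
    return WeightVector({k: v / total for k, v in vals.items()}, normalization=total)


def weights_from_swings(matrix: JudgmentMatrix,
                        null_swing: str = NULL_SWING) -> WeightVector:
    """Derive normalised weights from a swing judgment matrix.

    The matrix must include the null swing as its least preferred stimulus;
    its score anchors zero, and the remaining MACBETH scores, normalised,
    are the weights.
    """
    if null_swing not in matrix.stimuli:
        raise ValueError(f"swing matrix must include the null swing {null_swing!r}")
    if matrix.stimuli[-1] != null_swing:
        raise ValueError("the null swing must be the least preferred stimulus")
    scale = derive_scale(matrix)
    raw = {s: scale[s] for s in matrix.stimuli if s != null_swing}
    if all(v == 0 for v in raw.values()):
        # every swing judged "no difference" against the null swing
        raise ValueError("degenerate weights: every swing judged worthless")
    return normalize(raw)


def cluster_weights(w: WeightVector, tree: ValueTree) -> pd.Series:
    """Cluster weights as sums of their member attributes' weights."""
    missing = set(tree.leaf_ids) - set(w.weights)
    if missing:
        raise ValueError(f"weights missing for attributes {sorted(missing)}")
    out = {c.id: float(sum(w[a] for a in c.attributes)) for c in tree.clusters}
    s = pd.Series(out, dtype=float)
    s.index.name = "cluster"
    return s
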