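"""Per-attribute value functions and partial preference value scores.

A value function maps raw performance (months of survival, % of patients
with a Grade 4 adverse event, ...) to a preference value on the interval
scale anchored at the attribute's reference levels: v(x_l) = 0 and
v(x_h) = 100.  Performances worse than x_l score below 0 and better than
x_h above 100 — both are legitimate on an interval scale.

Continuous attributes use piecewise-linear interpolation between elicited
anchor points; ordinal and binary attributes use a direct level -> score
lookup.  Evaluating outside the anchored range is an error, never a silent
linear extension: elicited curves are routinely non-linear beyond the
anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .macbeth import CardinalScale
from .tree import Attribute, INCREASING, PerformanceTable

_REF_TOL = 1e-9


class ExtrapolationError(ValueError):
    """Performance lies outside the value function's anchor coverage."""


@dataclass(frozen=True)
class ValueFunction:
    """Monotone anchor-point map from performance to partial value.

    For continuous attributes ``anchors`` holds (performance, score) pairs
    sorted by ascending performance; for ordinal/binary attributes
    ``levels`` maps each label to its score.
    """

    attribute: str
    anchors: tuple[tuple[float, float], ...] = ()
    levels: Mapping[str, float] | None = None

    @property
    def is_ordinal(self) -> bool:
        return self.levels is not None

    def __call__(self, performance) -> float:
        return score_option(self, performance)


def build_value_function(attr: Attribute,
                         anchors: Iterable[tuple[float, float]] | None = None,
                         scale: CardinalScale | None = None,
                         level_scores: Mapping[str, float] | None = None) -> ValueFunction:
    """Construct and validate an attribute's value function.

    Anchors may be given directly, or as an anchored MACBETH
    :class:`CardinalScale` whose stimuli are performance levels (numeric
    strings for continuous attributes, labels for ordinal ones).  The
    anchor set must include both reference levels at scores 0 and 100 and
    be monotone in the attribute's preference direction.
    """
    if scale is not None:
        if not scale.anchored:
            raise ValueError("cardinal scale must be anchored before building a value function")
        if attr.is_numeric:
            anchors = [(float(k), v) for k, v in scale.scores.items()]
        else:
            level_scores = dict(scale.scores)

    if attr.is_numeric:
        if not anchors:
            raise ValueError("reference anchors missing")
        pts = sorted((float(x), float(v)) for x, v in anchors)
        xs = [p[0] for p in pts]
        if len(set(xs)) != len(xs):
            raise ValueError("duplicate anchor performance levels")
        _require_reference(pts, float(attr.lower_ref), 0.0, "x_l")
        _require_reference(pts, float(attr.higher_ref), 100.0, "x_h")
        vs = np.array([p[1] for p in pts])
        diffs = np.diff(vs)
        ok = (diffs >= -_REF_TOL).all() if attr.direction == INCREASING else (diffs <= _REF_TOL).all()
        if not ok:
            raise ValueError("non-monotone anchors")
        return ValueFunction(attr.id, anchors=tuple(pts))

    if level_scores is None:
        raise ValueError("reference anchors missing")
    missing = set(attr.levels) - set(level_scores)
    if missing:
        raise ValueError(f"scores missing for levels {sorted(missing)}")
    lo, hi = str(attr.lower_ref), str(attr.higher_ref)
    if abs(level_scores[lo]) > _REF_TOL or abs(level_scores[hi] - 100.0) > _REF_TOL:
        raise ValueError("reference anchors missing")
    ordered = [float(level_scores[lev]) for lev in attr.levels]
    diffs = np.diff(ordered)
    ok = (diffs >= -_REF_TOL).all() if attr.direction == INCREASING else (diffs <= _REF_TOL).all()
    if not ok:
        raise ValueError("non-monotone anchors")
    return ValueFunction(attr.id, levels={k: float(v) for k, v in level_scores.items()})


def _require_reference(pts: Sequence[tuple[float, float]], x: float,
                       target: float, tag: str) -> None:
    for px, pv in pts:
        if abs(px - x) <= _REF_TOL:
            if abs(pv - target) > 1e-6:
                raise ValueError(f"reference anchors missing: {tag} scored {pv}, expected {target}")
            return
    raise ValueError(f"reference anchors missing: no anchor at {tag}={x}")


def score_option(vf: ValueFunction, performance) -> float:
    """Partial preference value of a single performance level."""
    if vf.is_ordinal:
        try:
            return float(vf.levels[str(performance)])
        except KeyError:
            raise ExtrapolationError(
                f"{vf.attribute}: level {performance!r} has no elicited score") from None
    x = float(performance)
    xs = np.array([p[0] for p in vf.anchors])
    vs = np.array([p[1] for p in vf.anchors])
    if x < xs[0] - _REF_TOL or x > xs[-1] + _REF_TOL:
        raise ExtrapolationError(
            f"{vf.attribute}: extrapolation required for performance {x} "
            f"outside [{xs[0]}, {xs[-1]}]")
    return float(np.interp(x, xs, vs))


def score_table(perf: PerformanceTable,
                value_functions: Mapping[str, ValueFunction]) -> pd.DataFrame:
    """Apply value functions cell-wise: options x attributes partial scores."""
    missing = set(perf.attributes) - set(value_functions)
    if missing:
        raise ValueError(f"no value function for attributes {sorted(missing)}")
    out = pd.DataFrame(index=list(perf.options), columns=list(perf.attributes), dtype=float)
    out.index.name = "option"
    for aid in perf.attributes:
        vf = value_functions[aid]
        out[aid] = [score_option(vf, perf.value(opt, aid)) for opt in perf.options]
    return out
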