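"""Deterministic weight sensitivity and robustness analysis.

One-way weight sensitivity asks: for an attribute with baseline weight w0,
at what weight w* (all other weights rescaled proportionally so the vector
stays normalised) do two options' overall values equalise?  Crossing w*
reverses their ranking.  The threshold has a closed form: writing a and b
for the two options' partial scores on the attribute and

    R_X = (V_X - w0 * x) / (1 - w0)        (the "rest value" of option X)

the overall values under a new weight w are V_X(w) = w*x + (1-w)*R_X, so

    w* = (R_B - R_A) / ((a - b) - (R_A - R_B)).

A threshold outside [0, 1) — including the degenerate w*=1 case where every
pair equalises trivially when a == b — means that attribute alone cannot
reverse the pair.

The robustness margin is the smallest relative weight change |w*-w0|/w0
over all adjacent-rank pairs: a margin above 0.5 means no single baseline
weight moved by 50% or less can change the ranking.

``reference_perturbation_check`` probes score uncertainty instead: for each
attribute independently, each option's partial score on that attribute is
shifted adversarially by +/- delta value points and the check reports
whether any adjacent ranks can swap.  (A simultaneous adversarial shift on
*all* attributes at once is a strictly stronger — and for realistic deltas
uninformative — test; this check is deliberately per-attribute.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import pandas as pd

from .aggregation import overall_value
from .weighting import WeightVector

_EQ_TOL = 1e-6


@dataclass(frozen=True)
class ThresholdEntry:
    attribute: str
    better: str            # option ranked above at baseline
    worse: str
    baseline_weight: float  # w0, on the 0-1 scale
    threshold: float | None  # w*, on the 0-1 scale; None if no reversal in [0,1)
    direction: str | None    # "increase" / "decrease" relative to w0
    relative_change: float | None  # |w* - w0| / w0


@dataclass
class SensitivityReport:
    entries: list[ThresholdEntry] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        rows = [{
            "attribute": e.attribute, "better": e.better, "worse": e.worse,
            "w0": e.baseline_weight * 100.0,
            "w_star": None if e.threshold is None else e.threshold * 100.0,
            "direction": e.direction, "relative_change": e.relative_change,
        } for e in self.entries]
        return pd.DataFrame(rows)

    def reversals(self) -> list[ThresholdEntry]:
        return [e for e in self.entries if e.threshold is not None]


def reweight(w: WeightVector, attribute: str, new_weight: float) -> WeightVector:
    """Set one attribute's weight, rescaling the rest proportionally."""
    w0 = w[attribute]
    if not 0.0 <= new_weight <= 1.0:
        raise ValueError("weight must lie in [0, 1]")
    if w0 >= 1.0 - 1e-12:
        raise ValueError("degenerate renormalization: remaining weights are zero")
    rest = (1.0 - new_weight) / (1.0 - w0)
    return WeightVector({a: (new_weight if a == attribute else v * rest)
                         for a, v in w.weights.items()})


def value_difference(attribute: str, opt_a: str, opt_b: str,
                     scores: pd.DataFrame, w: WeightVector, weight: float) -> float:
    """V_A - V_B with the attribute's weight set to ``weight`` (renormalised)."""
    w2 = reweight(w, attribute, weight)
    res = overall_value(scores, w2)
    return float(res.overall[opt_a] - res.overall[opt_b])


def weight_threshold(attribute: str, opt_a: str, opt_b: str,
                     scores: pd.DataFrame, w: WeightVector) -> float | None:
    """Weight (0-1 scale) at which the two options' overall values equalise.

    ``opt_a`` must be ranked above ``opt_b`` at baseline.  Returns None when
    no weight in [0, 1) reverses the pair through this attribute.
    """
    w0 = w[attribute]
    if w0 >= 1.0 - 1e-12:
        raise ValueError("degenerate renormalization: remaining weights are zero")
    res = overall_value(scores, w)
    va, vb = float(res.overall[opt_a]), float(res.overall[opt_b])
    a = float(scores.at[opt_a, attribute])
    b = float(scores.at[opt_b, attribute])
    ra = (va - w0 * a) / (1.0 - w0)
    rb = (vb - w0 * b) / (1.0 - w0)
    denom = (a - b) - (ra - rb)
    if abs(denom) < 1e-15:
        return None
    w_star = (rb - ra) / denom
    if not (0.0 <= w_star < 1.0):
        return None
    if abs(a - b) < _EQ_TOL and abs(ra - rb) < _EQ_TOL:
        return None  # identical options, not a genuine reversal
    return float(w_star)


def one_way_report(scores: pd.DataFrame, w: WeightVector,
                   pairs: Sequence[tuple[str, str]]) -> SensitivityReport:
    """Thresholds for every attribute x requested (better, worse) pair."""
    report = SensitivityReport()
    for opt_a, opt_b in pairs:
        for attribute in scores.columns:
            w0 = w[attribute]
            w_star = weight_threshold(attribute, opt_a, opt_b, scores, w)
            if w_star is None:
                entry = ThresholdEntry(attribute, opt_a, opt_b, w0, None, None, None)
            else:
                direction = "increase" if w_star > w0 else "decrease"
                rel = abs(w_star - w0) / w0 if w0 > 0 else float("inf")
                entry = ThresholdEntry(attribute, opt_a, opt_b, w0, w_star, direction, rel)
            report.entries.append(entry)
    return report


def adjacent_pairs(ranking: Sequence[str]) -> list[tuple[str, str]]:
    return [(ranking[i], ranking[i + 1]) for i in range(len(ranking) - 1)]


def robustness_margin(report: SensitivityReport) -> float:
    """Smallest relative weight change that reverses any reported pair.

    Tied options (a zero threshold distance) give margin 0; a report with
    no attainable reversal returns +inf.
    """
    rels = [e.relative_change for e in report.reversals()
            if e.relative_change is not None]
    return min(rels) if rels else float("inf")


@dataclass
class PerturbationReport:
    stable: bool
    delta: float
    flagged: list[tuple[str, str, str]] = field(default_factory=list)
    # (attribute, better option, worse option) triples that can swap


def reference_perturbation_check(scores: pd.DataFrame, w: WeightVector,
                                 delta_points: float) -> PerturbationReport:
    """Can +/- delta value points on any single attribute swap adjacent ranks?

    For each attribute independently, every signed combination of shifts
    (+delta or -delta per option, applied to that attribute's score column
    only) is enumerated and the overall values recomputed; any adjacent
    pair of the baseline ranking that can reverse is flagged.
    """
    if delta_points < 0:
        raise ValueError("delta_points must be non-negative")
    base = overall_value(scores, w)
    pairs = adjacent_pairs(base.ranking)
    flagged: list[tuple[str, str, str]] = []
    for attribute in scores.columns:
        for opt_a, opt_b in pairs:
            swapped = False
            for sa, sb in product((-delta_points, delta_points), repeat=2):
                shifted = scores.copy()
                shifted.at[opt_a, attribute] += sa
                shifted.at[opt_b, attribute] += sb
                res = overall_value(shifted, w)
                if res.overall[opt_a] < res.overall[opt_b] - _EQ_TOL:
                    swapped = True
                    break
            if swapped:
                flagged.append((attribute, opt_a, opt_b))
    return PerturbationReport(stable=not flagged, delta=delta_points, flagged=flagged)
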