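"""Random decision problems with the structure the analysis assumes.

The generator emulates a facilitated appraisal: per-attribute monotone
latent value functions (random piecewise-linear curves with 3-6 knots),
positive normalised weights, option performances inside the attribute
ranges, and reference levels placed at or strictly inside the range ends
(the lower reference mimicking a "satisfactory performance" benchmark
rather than the worst case).  Because the latent truth is known, every
pipeline stage is testable: scoring against the latent curves, aggregation
against the latent weighted sum, MACBETH recovery against judgment
matrices binned from latent value differences.

All randomness flows through a single ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .macbeth import JudgmentMatrix, N_CATEGORIES
from .scoring import ValueFunction, build_value_function, score_table
from .tree import Attribute, Cluster, PerformanceTable, ValueTree
from .weighting import WeightVector, normalize


@dataclass
class GeneratorConfig:
    """Tunables of the problem generator.

    interior_references : probability that a reference level sits strictly
        inside the range (as with a best-supportive-care benchmark) rather
        than at a range end.
    knots : inclusive range for the number of value-function knots.
    n_clusters : number of value clusters the attributes are spread over.
    """

    interior_references: float = 0.5
    knots: tuple[int, int] = (3, 6)
    n_clusters: int = 4


@dataclass
class SyntheticProblem:
    """A generated decision problem with its latent ground truth."""

    tree: ValueTree
    attributes: dict[str, Attribute]
    value_functions: dict[str, ValueFunction]
    weights: WeightVector
    performance: PerformanceTable
    true_scores: pd.DataFrame
    true_values: pd.Series
    seed: int | None
    config: GeneratorConfig = field(default_factory=GeneratorConfig)


def _monotone_curve(rng: np.random.Generator, lo: float, hi: float,
                    n_knots: int) -> tuple[np.ndarray, np.ndarray]:
    """Strictly increasing piecewise-linear curve over [lo, hi] in [0, 1]."""
    x = np.sort(rng.uniform(lo, hi, size=n_knots - 2)) if n_knots > 2 else np.empty(0)
    xs = np.concatenate([[lo], x, [hi]])
    # force distinct knot abscissae
    for i in range(1, len(xs)):
        if xs[i] - xs[i - 1] < 1e-9 * max(1.0, abs(hi - lo)):
            xs[i] = xs[i - 1] + 1e-6 * max(1.0, abs(hi - lo))
    ys = np.cumsum(rng.uniform(0.2, 1.0, size=len(xs)))
    ys = (ys - ys[0]) / (ys[-1] - ys[0])
    return xs, ys


def generate_problem(n_options: int, n_attributes: int,
                     seed: int | None = None,
                     config: GeneratorConfig | None = None,
                     rng: np.random.Generator | None = None) -> SyntheticProblem:
    """Generate a reproducible random decision problem.

    Attribute ranges are random, each latent value function is a random
    monotone piecewise-linear curve rescaled so the reference levels score
    0 and 100, weights are positive and normalised, and option performances
    are uniform within the reference interval of each attribute (so true
    partial scores stay within anchor coverage).
    """
    if n_options < 2 or n_attributes < 1:
        raise ValueError("need at least 2 options and 1 attribute")
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    n_clusters = min(config.n_clusters, n_attributes)
    cluster_of = np.sort(rng.integers(0, n_clusters, size=n_attributes))
    # make sure every cluster is inhabited
    cluster_of[:n_clusters] = np.arange(n_clusters)

    attributes: dict[str, Attribute] = {}
    value_functions: dict[str, ValueFunction] = {}
    perf: dict[str, dict[str, float]] = {f"opt{o + 1}": {} for o in range(n_options)}

    for j in range(n_attributes):
        aid = f"attr{j + 1}"
        lo = rng.uniform(-50.0, 50.0)
        width = rng.uniform(1.0, 100.0)
        hi = lo + width
        direction = "increasing" if rng.random() < 0.5 else "decreasing"
        n_knots = int(rng.integers(config.knots[0], config.knots[1] + 1))
        xs, ys = _monotone_curve(rng, lo, hi, n_knots)
        if direction == "decreasing":
            ys = 1.0 - ys

        # reference levels: at range ends, or strictly inside
        interior = rng.random() < config.interior_references
        if interior and len(xs) >= 4:
            i_lo, i_hi = 1, len(xs) - 2
        else:
            i_lo, i_hi = 0, len(xs) - 1
        if direction == "increasing":
            x_l, x_h = float(xs[i_lo]), float(xs[i_hi])
            y_l, y_h = ys[i_lo], ys[i_hi]
        else:
            x_l, x_h = float(xs[i_hi]), float(xs[i_lo])
            y_l, y_h = ys[i_hi], ys[i_lo]
        anchors = [(float(x), float(100.0 * (y - y_l) / (y_h - y_l)))
                   for x, y in zip(xs, ys)]

        attributes[aid] = Attribute(
            id=aid, name=f"Attribute {j + 1}", cluster=f"cluster{cluster_of[j] + 1}",
            kind="continuous", direction=direction,
            minimum=lo, maximum=hi, lower_ref=x_l, higher_ref=x_h)
        value_functions[aid] = build_value_function(attributes[aid], anchors=anchors)

        p_lo, p_hi = min(x_l, x_h), max(x_l, x_h)
        for o in range(n_options):
            perf[f"opt{o + 1}"][aid] = float(rng.uniform(p_lo, p_hi))

    clusters = tuple(
        Cluster(id=f"cluster{c + 1}", name=f"Cluster {c + 1}",
                attributes=tuple(f"attr{j + 1}" for j in range(n_attributes)
                                 if cluster_of[j] == c))
        for c in range(n_clusters))
    tree = ValueTree(root_id="overall", root_name="Overall value", clusters=clusters)

    weights = normalize({f"attr{j + 1}": float(rng.uniform(0.05, 1.0))
                         for j in range(n_attributes)})
    performance = PerformanceTable.from_dict(perf)
    true_scores = score_table(performance, value_functions)
    ws = weights.as_series().reindex(true_scores.columns)
    true_values = true_scores.mul(ws, axis=1).sum(axis=1)
    true_values.name = "overall_value"

    return SyntheticProblem(tree=tree, attributes=attributes,
                            value_functions=value_functions, weights=weights,
                            performance=performance, true_scores=true_scores,
                            true_values=true_values, seed=seed, config=config)


def generate_judgments(latent: Mapping[str, float],
                       n_categories: int = N_CATEGORIES,
                       corruption_rate: float = 0.0,
                       rng: np.random.Generator | None = None) -> JudgmentMatrix:
    """Bin latent value differences into semantic judgment categories.

    The category of a pair is the equal-width bin index of its latent value
    difference over (0, max difference], mapped to 1..n_categories; zero
    differences map to category 0 ("no difference").  With
    ``corruption_rate`` > 0, that fraction of cells is perturbed by one
    category (clamped to 1..n_categories) to create near-inconsistent
    matrices for error-path testing.
    """
    if len(latent) < 2:
        raise ValueError("need at least 2 stimuli")
    if rng is None:
        rng = np.random.default_rng()
    stimuli = sorted(latent, key=lambda s: (-latent[s], s))
    max_diff = latent[stimuli[0]] - latent[stimuli[-1]]
    judgments: dict[tuple[str, str], int] = {}
    for i, a in enumerate(stimuli):
        for b in stimuli[i + 1:]:
            diff = latent[a] - latent[b]
            if diff <= 0 or max_diff <= 0:
                k = 0
            else:
                k = int(np.ceil(n_categories * diff / max_diff))
                k = min(max(k, 1), n_categories)
            if corruption_rate > 0 and k >= 1 and rng.random() < corruption_rate:
                k = int(np.clip(k + rng.choice([-1, 1]), 1, n_categories))
            judgments[(a, b)] = k
    return JudgmentMatrix(tuple(stimuli), judgments)
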