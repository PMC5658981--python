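"""Additive aggregation of weighted partial scores into overall values.

The overall weighted preference value of option a is the simple additive
model V(a) = sum_i w_i * v_i(a), with normalised weights w_i and partial
value scores v_i on the 0/100 reference-anchored scale.  Rankings use
descending V; exact ties (|dV| below a small threshold) form tie groups and
are broken lexicographically by option id for deterministic output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .weighting import WeightVector

TIE_TOL = 1e-6


@dataclass
class EvaluationResult:
    """Overall values, weighted contributions and ranking of the options."""

    overall: pd.Series          # option -> V(a)
    contributions: pd.DataFrame  # options x attributes, w_i * v_i(a)
    ranks: pd.Series            # option -> 1-based rank (ties share a rank)
    tie_groups: list[list[str]]

    @property
    def ranking(self) -> list[str]:
        """Options best to worst (deterministic tie-break by id)."""
        return [opt for group in self.tie_groups for opt in group]


def overall_value(scores: pd.DataFrame, w: WeightVector) -> EvaluationResult:
    """Aggregate a score matrix (options x attributes) under weights."""
    score_attrs = set(scores.columns)
    weight_attrs = set(w.weights)
    if score_attrs != weight_attrs:
        raise ValueError(
            "model mismatch: score and weight attribute sets differ "
            f"(only-in-scores={sorted(score_attrs - weight_attrs)}, "
            f"only-in-weights={sorted(weight_attrs - score_attrs)})")
    if scores.isna().any().any():
        raise ValueError("model mismatch: score matrix incomplete")
    ws = w.as_series().reindex(scores.columns)
    contributions = scores.astype(float).mul(ws, axis=1)
    overall = contributions.sum(axis=1)
    overall.name = "overall_value"
    tie_groups = _tie_groups(overall)
    rank_of: dict[str, int] = {}
    pos = 1
    for group in tie_groups:
        for opt in group:
            rank_of[opt] = pos
        pos += len(group)
    ranks = pd.Series({o: rank_of[o] for o in overall.index}, dtype=int)
    return EvaluationResult(overall=overall, contributions=contributions,
                            ranks=ranks, tie_groups=tie_groups)


def _tie_groups(overall: pd.Series, tol: float = TIE_TOL) -> list[list[str]]:
    ordered = sorted(overall.index, key=lambda o: (-overall[o], o))
    groups: list[list[str]] = []
    for opt in ordered:
        if groups and abs(overall[groups[-1][0]] - overall[opt]) < tol:
            groups[-1].append(opt)
        else:
            groups.append([opt])
    for g in groups:
        g.sort()
    return groups


def decompose(result: EvaluationResult, option: str) -> pd.Series:
    """Per-attribute weighted contributions of one option, largest first.

    Contributions are signed and re-sum to V(a); negative entries (scores
    below the lower reference level) sort last.
    """
    if option not in result.contributions.index:
        raise KeyError(f"unknown option id {option!r}")
    contrib = result.contributions.loc[option].astype(float)
    return contrib.sort_values(ascending=False, kind="mergesort")


def rank_options(result: EvaluationResult) -> list[list[str]]:
    """Ranking as tie groups, best to worst."""
    return [list(g) for g in result.tie_groups]
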