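"""MACBETH-style conversion of qualitative judgments into cardinal scales.

The MACBETH protocol (Measuring Attractiveness by a Categorical Based
Evaluation Technique) asks a group for qualitative judgments of the
*difference of attractiveness* between pairs of stimuli, on the semantic
ladder ``no < very weak < weak < moderate < strong < very strong < extreme``.
A consistent, complete set of judgments is converted into a cardinal value
scale by linear programming.

The LP solved here is the basic formulation: with stimuli ordered from most
to least preferred and v(bottom) = 0,

* every pair judged in category k >= 1 satisfies v(a) - v(b) >= k * delta
  (delta = 1),
* for any two pairs whose categories differ, the difference of the pair in
  the larger category exceeds that of the smaller-category pair by at least
  (k1 - k2) * delta,
* pairs judged "no difference" are constrained equal,

minimising the top stimulus' score.  Any positive delta yields the same
scale after anchoring, since anchoring is affine-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

CATEGORIES = ("no", "very weak", "weak", "moderate", "strong", "very strong", "extreme")
CATEGORY_CODE = {name: k for k, name in enumerate(CATEGORIES)}
N_CATEGORIES = 6  # largest code; "no difference" is 0
DELTA = 1.0
_EQ_TOL = 1e-9


class IncompatibleJudgments(ValueError):
    """Raised when no cardinal scale can satisfy the judgment matrix."""

    def __init__(self, message: str, constraints: Sequence[str] = ()):  # noqa: D107
        super().__init__(message)
        self.constraints = tuple(constraints)


def category_code(category: int | str) -> int:
    """Normalize a category given as code 0..6 or semantic label."""
    if isinstance(category, str):
        try:
            return CATEGORY_CODE[category.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown judgment category {category!r}") from None
    k = int(category)
    if not 0 <= k <= N_CATEGORIES:
        raise ValueError(f"judgment category code must be 0..6, got {k}")
    return k


@dataclass(frozen=True)
class JudgmentMatrix:
    """Complete upper-triangular matrix of pairwise difference judgments.

    ``stimuli`` are ordered most to least preferred; ``judgments`` maps each
    ordered pair (more preferred, less preferred) to a category code 0..6.
    """

    stimuli: tuple[str, ...]
    judgments: Mapping[tuple[str, str], int]

    @classmethod
    def from_judgments(cls, stimuli: Sequence[str],
                       judgments: Mapping[tuple[str, str], int | str]) -> "JudgmentMatrix":
        coded = {(a, b): category_code(k) for (a, b), k in judgments.items()}
        return cls(tuple(stimuli), coded)

    def pairs(self) -> list[tuple[str, str]]:
        n = len(self.stimuli)
        return [(self.stimuli[i], self.stimuli[j]) for i in range(n) for j in range(i + 1, n)]

    def category(self, a: str, b: str) -> int:
        return self.judgments[(a, b)]

    def require_complete(self) -> None:
        missing = [p for p in self.pairs() if p not in self.judgments]
        if missing:
            raise ValueError(f"judgment matrix incomplete: missing pairs {missing}")


@dataclass(frozen=True)
class CardinalScale:
    """Stimulus -> score map, optionally anchored at reference levels."""

    scores: Mapping[str, float]
    anchored: bool = False

    def __getitem__(self, stimulus: str) -> float:
        return self.scores[stimulus]

    def as_dict(self) -> dict[str, float]:
        return dict(self.scores)


@dataclass
class ConsistencyReport:
    ordinal_violations: list[tuple[tuple[str, str], tuple[str, str], str]] = field(default_factory=list)
    cardinal_feasible: bool = True

    @property
    def consistent(self) -> bool:
        return not self.ordinal_violations and self.cardinal_feasible


def check_consistency(matrix: JudgmentMatrix) -> ConsistencyReport:
    """Ordinal monotonicity check plus cardinal (LP feasibility) check.

    Ordinal: with stimuli ordered best to worst, a wider span must never be
    judged a strictly smaller category than a span it contains — along a row
    categories weakly increase away from the diagonal, down a column they
    weakly decrease.  Each violated cell pair is reported.
    """
    matrix.require_complete()
    report = ConsistencyReport()
    s = matrix.stimuli
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n - 1):
            k_narrow = matrix.category(s[i], s[j])
            k_wide = matrix.category(s[i], s[j + 1])
            if k_wide < k_narrow:
                report.ordinal_violations.append(
                    ((s[i], s[j + 1]), (s[i], s[j]),
                     "wider span judged a smaller category along the row"))
    for j in range(2, n):
        for i in range(j - 1):
            k_wide = matrix.category(s[i], s[j])
            k_narrow = matrix.category(s[i + 1], s[j])
            if k_wide < k_narrow:
                report.ordinal_violations.append(
                    ((s[i], s[j]), (s[i + 1], s[j]),
                     "wider span judged a smaller category down the column"))
    # "no difference" only between stimuli the ordering declares equal is
    # subsumed by the cardinal check: category-0 pairs are constrained equal.
    try:
        _solve_lp(matrix)
    except IncompatibleJudgments:
        report.cardinal_feasible = False
    return report


def _lp_system(matrix: JudgmentMatrix):
    """Assemble the inequality/equality system of the MACBETH LP."""
    s = matrix.stimuli
    idx = {name: i for i, name in enumerate(s)}
    pairs = matrix.pairs()
    n = len(s)

    A_ub: list[np.ndarray] = []
    b_ub: list[float] = []
    A_eq: list[np.ndarray] = []
    b_eq: list[float] = []
    labels: list[str] = []

    def d_row(a: str, b: str) -> np.ndarray:
        row = np.zeros(n)
        row[idx[a]] = 1.0
        row[idx[b]] = -1.0
        return row

    for (a, b) in pairs:
        k = matrix.category(a, b)
        if k == 0:
            A_eq.append(d_row(a, b))
            b_eq.append(0.0)
        else:
            # v(a) - v(b) >= k * delta
            A_ub.append(-d_row(a, b))
            b_ub.append(-k * DELTA)
            labels.append(f"v({a})-v({b}) >= {k}")

    # inter-pair dominance: larger category => larger difference, by the gap
    for p1 in pairs:
        k1 = matrix.category(*p1)
        for p2 in pairs:
            k2 = matrix.category(*p2)
            if k1 > k2 >= 1:
                A_ub.append(-(d_row(*p1) - d_row(*p2)))
                b_ub.append(-(k1 - k2) * DELTA)
                labels.append(f"d{p1} >= d{p2} + {k1 - k2}")
    return idx, A_ub, b_ub, A_eq, b_eq, labels


def _solve_lp(matrix: JudgmentMatrix,
              objective: np.ndarray | None = None,
              bounds_override: Mapping[str, tuple[float, float]] | None = None):
    s = matrix.stimuli
    idx, A_ub, b_ub, A_eq, b_eq, labels = _lp_system(matrix)
    n = len(s)
    c = objective if objective is not None else _unit(n, idx[s[0]])
    bounds = [(0.0, None)] * n
    bounds[idx[s[-1]]] = (0.0, 0.0)  # v(bottom) = 0
    if bounds_override:
        for name, bd in bounds_override.items():
            bounds[idx[name]] = bd
    res = linprog(c,
                  A_ub=np.array(A_ub) if A_ub else None,
                  b_ub=np.array(b_ub) if b_ub else None,
                  A_eq=np.array(A_eq) if A_eq else None,
                  b_eq=np.array(b_eq) if b_eq else None,
                  bounds=bounds, method="highs")
    if res.status == 2:  # infeasible
        raise IncompatibleJudgments("incompatible judgments: no cardinal scale exists", labels)
    if res.status == 3:  # unbounded
        return None, idx
    if not res.success:  # pragma: no cover - solver hiccup
        raise RuntimeError(f"LP solver failed: {res.message}")
    return res, idx


def _unit(n: int, i: int) -> np.ndarray:
    c = np.zeros(n)
    c[i] = 1.0
    return c


def derive_scale(matrix: JudgmentMatrix) -> CardinalScale:
    """Solve the MACBETH LP, returning the minimising cardinal scale.

    The bottom stimulus is fixed at 0 and the top stimulus' score is
    minimised subject to all pairwise and inter-pair constraints.
    """
    matrix.require_complete()
    res, idx = _solve_lp(matrix)
    scores = {name: float(np.round(res.x[i], 9)) + 0.0 for name, i in idx.items()}
    return CardinalScale(scores, anchored=False)


def feasible_bounds(matrix: JudgmentMatrix, stimulus: str,
                    ceiling: float = 1e6) -> tuple[float, float]:
    """Score interval keeping the LP feasible with all other stimuli fixed.

    The derived scale is computed first; every other stimulus is pinned at
    its derived score and two LPs (min and max of the target's score) give
    the interval.  An unbounded maximum is capped at ``ceiling``.
    """
    if stimulus not in matrix.stimuli:
        raise KeyError(stimulus)
    base = derive_scale(matrix)
    pins = {name: (v, v) for name, v in base.scores.items() if name != stimulus}
    n = len(matrix.stimuli)
    i = matrix.stimuli.index(stimulus)
    lo_res, _ = _solve_lp(matrix, objective=_unit(n, i), bounds_override=pins)
    lo = float(lo_res.x[i])
    hi_res, _ = _solve_lp(matrix, objective=-_unit(n, i), bounds_override=pins)
    hi = ceiling if hi_res is None else float(hi_res.x[i])
    return (round(lo, 9) + 0.0, min(round(hi, 9) + 0.0, ceiling))


def anchor_scale(scale: CardinalScale, lower_ref: str, higher_ref: str) -> CardinalScale:
    """Anchor an interval scale so v(x_l) = 0 and v(x_h) = 100.

    Applies v'(x) = 100 * (v(x) - v(x_l)) / (v(x_h) - v(x_l)); stimuli
    outside the reference interval map below 0 or above 100.
    """
    s = scale.scores
    lo, hi = s[lower_ref], s[higher_ref]
    if hi <= lo:
        raise ValueError("reference levels not increasing in preference")
    scores = {k: round(100.0 * (v - lo) / (hi - lo), 9) + 0.0 for k, v in s.items()}
    return CardinalScale(scores, anchored=True)


def satisfies_constraints(matrix: JudgmentMatrix, scale: CardinalScale,
                          tol: float = 1e-6) -> bool:
    """Check a scale against every LP constraint by substitution."""
    s = scale.scores
    pairs = matrix.pairs()
    for (a, b) in pairs:
        k = matrix.category(a, b)
        d = s[a] - s[b]
        if k == 0:
            if abs(d) > tol:
                return False
        elif d < k * DELTA - tol:
            return False
    for p1 in pairs:
        k1 = matrix.category(*p1)
        for p2 in pairs:
            k2 = matrix.category(*p2)
            if k1 > k2 >= 1:
                d1 = s[p1[0]] - s[p1[1]]
                d2 = s[p2[0]] - s[p2[1]]
                if d1 < d2 + (k1 - k2) * DELTA - tol:
                    return False
    return True
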