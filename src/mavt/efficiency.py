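"""Cost-per-value and incremental cost-value analysis.

Purchasing and administration costs are kept outside the value model (only
attributes of benefit act as criteria); they meet the overall value scores
only here, on the value-cost plane.  The analysis reports cost per value
point, pairwise dominance or incremental cost-value ratios (ICVR), and the
efficiency frontier of non-dominated options under (max value, min cost).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class CostProfile:
    """Drug plus administration cost of one option, in GBP.

    ``total`` defaults to drug + administration but may be supplied
    explicitly (e.g. the rounded headline totals used for reporting).
    """

    option: str
    drug_cost: float
    admin_cost: float
    total: float | None = None

    def __post_init__(self):
        if self.drug_cost < 0 or self.admin_cost < 0:
            raise ValueError("costs must be non-negative")
        if self.total is None:
            object.__setattr__(self, "total", self.drug_cost + self.admin_cost)
        elif self.total < 0:
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class Dominance:
    winner: str
    loser: str

    def __str__(self) -> str:
        return f"{self.winner} dominates {self.loser}"


class EquivalentOptions(ValueError):
    """Both options have identical value and cost."""


def cost_per_value_unit(cost: CostProfile, value: float) -> float:
    """Total cost divided by overall value: GBP per value point."""
    if value <= 0:
        raise ValueError("undefined efficiency for non-positive value")
    return cost.total / value


def icvr(opt_a: str, opt_b: str,
         costs: Mapping[str, CostProfile],
         values: Mapping[str, float]) -> float | Dominance:
    """Incremental cost-value ratio of A vs B, or a dominance verdict.

    Returns (cost_A - cost_B) / (V_A - V_B) when one option is both more
    valuable and more expensive (a genuine trade-off); otherwise the
    dominance verdict.
    """
    ca, cb = costs[opt_a].total, costs[opt_b].total
    va, vb = values[opt_a], values[opt_b]
    if va == vb and ca == cb:
        raise EquivalentOptions(f"{opt_a} and {opt_b} have equal value and cost")
    if va >= vb and ca <= cb:
        return Dominance(opt_a, opt_b)
    if vb >= va and cb <= ca:
        return Dominance(opt_b, opt_a)
    return (ca - cb) / (va - vb)


def frontier(costs: Mapping[str, CostProfile],
             values: Mapping[str, float]) -> tuple[list[str], pd.DataFrame]:
    """Non-dominated options and the value-cost plane coordinates.

    An option is dominated if another has at least as high value and no
    higher cost, with at least one strict.  Coordinates for all options are
    returned for plotting, sorted by ascending cost.
    """
    if not costs:
        raise ValueError("at least one option required")
    ids = list(costs)
    efficient: list[str] = []
    for o in ids:
        dominated = any(
            (values[p] >= values[o] and costs[p].total <= costs[o].total and
             (values[p] > values[o] or costs[p].total < costs[o].total))
            for p in ids if p != o)
        if not dominated:
            efficient.append(o)
    coords = pd.DataFrame({
        "option": ids,
        "value": [values[o] for o in ids],
        "cost": [costs[o].total for o in ids],
        "efficient": [o in efficient for o in ids],
    }).sort_values("cost", kind="mergesort").reset_index(drop=True)
    return sorted(efficient), coords


def efficiency_report(costs: Mapping[str, CostProfile],
                      values: Mapping[str, float]) -> pd.DataFrame:
    """Cost, value and cost-per-value table, cheapest first."""
    rows = []
    for o, c in costs.items():
        v = values[o]
        rows.append({
            "option": o, "drug_cost": c.drug_cost, "admin_cost": c.admin_cost,
            "total_cost": c.total, "value": v,
            "cost_per_value_unit": cost_per_value_unit(c, v) if v > 0 else float("nan"),
        })
    return pd.DataFrame(rows).sort_values("total_cost", kind="mergesort").reset_index(drop=True)
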