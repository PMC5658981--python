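"""Model/Results surface tying the evaluation pipeline together.

:class:`AdditiveValueModel` bundles a validated value tree, attribute set,
value functions, weights and performance table; :meth:`~AdditiveValueModel.fit`
scores the table, aggregates, and returns an :class:`EvaluationResults`
object carrying the overall values, weighted contributions, ranking, and
methods for sensitivity, robustness and cost-value efficiency analysis —
the pattern familiar from statistical modelling packages, adapted to a
deterministic preference model whose "uncertainty" lives in the weights
and scores rather than in sampling error.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .aggregation import EvaluationResult, decompose, overall_value
from .efficiency import CostProfile, efficiency_report, frontier, icvr
from .io import ModelDefinition, load_costs, load_model, load_performance
from .scoring import ValueFunction, score_table
from .sensitivity import (PerturbationReport, SensitivityReport, adjacent_pairs,
                          one_way_report, reference_perturbation_check,
                          robustness_margin)
from .tree import Attribute, PerformanceTable, ValueTree, validate_model, validate_performance
from .weighting import WeightVector, cluster_weights, normalize


class ModelValidationError(ValueError):
    """The model or its inputs failed structural validation."""

    def __init__(self, report):  # noqa: D107
        self.report = report
        msgs = "; ".join(str(v) for v in report.violations)
        super().__init__(f"validation failed: {msgs}")


class AdditiveValueModel:
    """An additive multi-attribute value model over a set of options.

    Parameters
    ----------
    tree, attributes : the value structure (validated on construction).
    value_functions : attribute id -> :class:`ValueFunction`.
    weights : raw weights (any positive scale); normalised internally.
    performance : options x attributes table of raw performance levels.
    """

    def __init__(self, tree: ValueTree, attributes: Mapping[str, Attribute],
                 value_functions: Mapping[str, ValueFunction],
                 weights: Mapping[str, float] | WeightVector,
                 performance: PerformanceTable):
        self.tree = tree
        self.attributes = dict(attributes)
        self.value_functions = dict(value_functions)
        self.weights = weights if isinstance(weights, WeightVector) else normalize(weights)
        self.performance = performance

        report = validate_model(tree, self.attributes.values())
        if not report.passed:
            raise ModelValidationError(report)
        report = validate_performance(performance, tree, self.attributes.values())
        if not report.passed:
            raise ModelValidationError(report)
        missing_vf = set(tree.leaf_ids) - set(self.value_functions)
        if missing_vf:
            raise ValueError(f"no value function for attributes {sorted(missing_vf)}")
        missing_w = set(tree.leaf_ids) - set(self.weights.weights)
        if missing_w:
            raise ValueError(f"no weight for attributes {sorted(missing_w)}")

    @classmethod
    def from_definition(cls, definition: ModelDefinition,
                        performance: PerformanceTable,
                        weights: Mapping[str, float] | None = None) -> "AdditiveValueModel":
        return cls(definition.tree, definition.attributes, definition.value_functions,
                   weights if weights is not None else definition.weights, performance)

    @classmethod
    def from_files(cls, model_path, performance_path) -> "AdditiveValueModel":
        return cls.from_definition(load_model(model_path), load_performance(performance_path))

    @classmethod
    def from_case_study(cls, weights: str = "precise") -> "AdditiveValueModel":
        """The packaged mCRC case study, ready to fit."""
        from .datasets import load_case_study

        cs = load_case_study(weights=weights)
        return cls(cs.model.tree, cs.model.attributes, cs.model.value_functions,
                   cs.weights, cs.performance)

    def fit(self) -> "EvaluationResults":
        """Score the performance table and aggregate to overall values."""
        scores = score_table(self.performance, self.value_functions)
        result = overall_value(scores, self.weights)
        return EvaluationResults(self, scores, result)


class EvaluationResults:
    """Fitted evaluation: scores, overall values, ranking, diagnostics."""

    def __init__(self, model: AdditiveValueModel, scores: pd.DataFrame,
                 result: EvaluationResult):
        self.model = model
        self.scores = scores
        self._result = result

    # -- estimates ---------------------------------------------------------
    @property
    def overall_values(self) -> pd.Series:
        """Overall weighted preference value V(a) per option."""
        return self._result.overall

    @property
    def contributions(self) -> pd.DataFrame:
        """Weighted contributions w_i * v_i(a), options x attributes."""
        return self._result.contributions

    @property
    def ranking(self) -> list[str]:
        return self._result.ranking

    @property
    def ranks(self) -> pd.Series:
        return self._result.ranks

    def decompose(self, option: str) -> pd.Series:
        """One option's signed weighted contributions, largest first."""
        return decompose(self._result, option)

    def cluster_weights(self) -> pd.Series:
        return cluster_weights(self.model.weights, self.model.tree)

    # -- diagnostics -------------------------------------------------------
    def sensitivity(self, pairs: Sequence[tuple[str, str]] | None = None) -> SensitivityReport:
        """One-way weight thresholds; defaults to all ordered option pairs."""
        if pairs is None:
            ranking = self.ranking
            pairs = [(a, b) for i, a in enumerate(ranking) for b in ranking[i + 1:]]
        return one_way_report(self.scores, self.model.weights, pairs)

    def robustness_margin(self) -> float:
        """Smallest relative weight change reversing any adjacent pair."""
        report = one_way_report(self.scores, self.model.weights,
                                adjacent_pairs(self.ranking))
        return robustness_margin(report)

    def perturbation_check(self, delta_points: float = 5.0) -> PerturbationReport:
        return reference_perturbation_check(self.scores, self.model.weights, delta_points)

    # -- efficiency --------------------------------------------------------
    def efficiency(self, costs: Mapping[str, CostProfile] | str) -> pd.DataFrame:
        """Cost-per-value table; ``costs`` may be a mapping or a CSV path."""
        if isinstance(costs, str):
            costs = load_costs(costs)
        return efficiency_report(costs, dict(self.overall_values))

    def frontier(self, costs: Mapping[str, CostProfile]):
        return frontier(costs, dict(self.overall_values))

    def icvr(self, opt_a: str, opt_b: str, costs: Mapping[str, CostProfile]):
        return icvr(opt_a, opt_b, costs, dict(self.overall_values))

    # -- reporting ---------------------------------------------------------
    def summary_table(self) -> pd.DataFrame:
        """Results-table layout: attribute rows (partial scores) with the
        reference-level columns, an overall row, and the weights column."""
        attrs = list(self.scores.columns)
        opts = list(self.scores.index)
        w = self.model.weights.as_percent()
        table = pd.DataFrame(index=["Overall WPV score"] + attrs,
                             columns=["lower_ref", *opts, "higher_ref", "weight"],
                             dtype=float)
        table.loc["Overall WPV score"] = [0.0, *[self.overall_values[o] for o in opts],
                                          100.0, 100.0]
        for aid in attrs:
            table.loc[aid] = [0.0, *[self.scores.at[o, aid] for o in opts], 100.0, w[aid]]
        return table.round(1)

    def summary(self) -> str:
        """Human-readable evaluation summary."""
        lines = ["Additive multi-attribute value model",
                 f"  options:    {len(self.scores.index)}",
                 f"  attributes: {len(self.scores.columns)}",
                 f"  clusters:   {len(self.model.tree.clusters)}",
                 "",
                 "Overall weighted preference values (best first):"]
        for opt in self.ranking:
            lines.append(f"  {self.ranks[opt]:>2}. {opt:<24} V = {self.overall_values[opt]:7.1f}")
        lines.append("")
        lines.append("Cluster weights:")
        for cid, v in self.cluster_weights().items():
            lines.append(f"  {cid:<24} {100.0 * v:5.1f}")
        margin = self.robustness_margin()
        lines.append("")
        lines.append(f"Robustness margin (min relative weight change to any rank flip): "
                     f"{'none attainable' if margin == float('inf') else f'{margin:.2f}'}")
        return "\n".join(lines)
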