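"""One-way weight thresholds, robustness margin and score perturbation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from mavt.aggregation import overall_value
from mavt.sensitivity import (adjacent_pairs, one_way_report,
                              reference_perturbation_check, robustness_margin,
                              value_difference, weight_threshold)
from mavt.synthetic import generate_problem


def _pair_entries(report, better, worse):
    return {e.attribute: e for e in report.entries
            if e.better == better and e.worse == worse}


class TestWeightThreshold:
    @pytest.mark.parametrize("attribute,printed", [
        ("posology", 11.8),
        ("g4ae", 7.5),
        ("med_costs", 21.0),
        ("os", 59.8),
        ("pfs", 47.7),
        ("atc_l4", 2.5),
    ])
    def test_printed_pan_vs_cet_thresholds(self, mcrc_fitted, attribute, printed):
        """Closed-form thresholds match the published one-decimal values
        within 0.7 weight points (inputs are printed at one decimal)."""
        w_star = weight_threshold(attribute, "cetuximab", "panitumumab",
                                  mcrc_fitted.scores, mcrc_fitted.model.weights)
        assert w_star is not None
        assert w_star * 100 == pytest.approx(printed, abs=0.7)

    def test_equal_scores_cannot_reverse(self, mcrc_fitted):
        """HRQoL scores 15.0 for every option: no weight in [0,1) reverses."""
        w_star = weight_threshold("hrqol", "cetuximab", "panitumumab",
                                  mcrc_fitted.scores, mcrc_fitted.model.weights)
        assert w_star is None

    def test_values_equal_at_threshold_by_substitution(self, mcrc_fitted):
        for attribute in ("posology", "g4ae", "os"):
            w_star = weight_threshold(attribute, "cetuximab", "panitumumab",
                                      mcrc_fitted.scores, mcrc_fitted.model.weights)
            diff = value_difference(attribute, "cetuximab", "panitumumab",
                                    mcrc_fitted.scores, mcrc_fitted.model.weights,
                                    w_star)
            assert abs(diff) < 1e-6

    def test_closed_form_matches_bisection_oracle_on_random_problems(self):
        """Root of V_A(w) - V_B(w) found by bisection agrees to 1e-6."""
        checked = 0
        for seed in range(40):
            problem = generate_problem(3, 6, seed=seed)
            res = overall_value(problem.true_scores, problem.weights)
            better, worse = res.ranking[0], res.ranking[1]
            for attribute in problem.true_scores.columns:
                w_star = weight_threshold(attribute, better, worse,
                                          problem.true_scores, problem.weights)
                f = lambda w: value_difference(attribute, better, worse,
                                               problem.true_scores,
                                               problem.weights, w)
                eps = 1e-9
                if w_star is None:
                    # no sign change anywhere in [0, 1)
                    grid = np.linspace(eps, 1 - eps, 101)
                    signs = np.sign([f(w) for w in grid])
                    assert (signs >= 0).all() or (signs <= 0).all()
                else:
                    lo, hi = max(eps, w_star - 0.05), min(1 - eps, w_star + 0.05)
                    root = brentq(f, lo, hi, xtol=1e-12)
                    assert abs(root - w_star) < 1e-6
                    checked += 1
        assert checked >= 40

    def test_invariant_to_uniform_weight_rescaling(self, mcrc):
        from mavt.weighting import WeightVector, normalize

        scaled = normalize({k: 7.0 * v for k, v in mcrc.weights.weights.items()})
        from mavt.scoring import score_table

        scores = score_table(mcrc.performance, mcrc.model.value_functions)
        for attribute in ("posology", "g4ae"):
            t1 = weight_threshold(attribute, "cetuximab", "panitumumab",
                                  scores, mcrc.weights)
            t2 = weight_threshold(attribute, "cetuximab", "panitumumab",
                                  scores, scaled)
            assert t1 == pytest.approx(t2, abs=1e-12)

    def test_degenerate_single_attribute_weight(self):
        import pandas as pd

        from mavt.weighting import WeightVector

        scores = pd.DataFrame({"only": [10.0, 20.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="degenerate renormalization"):
            weight_threshold("only", "b", "a", scores, WeightVector({"only": 1.0}))


class TestOneWayReport:
    def test_pan_vs_cet_reversal_set_and_directions(self, mcrc, mcrc_fitted):
        """The attributes that can reverse panitumumab vs cetuximab, and the
        direction of the required change, match the published set."""
        report = one_way_report(mcrc_fitted.scores, mcrc.weights,
                                [("cetuximab", "panitumumab")])
        entries = _pair_entries(report, "cetuximab", "panitumumab")
        reversals = {a: e for a, e in entries.items() if e.threshold is not None}
        assert set(reversals) == {"os", "pfs", "g4ae", "atc_l4", "posology", "med_costs"}
        assert reversals["os"].direction == "increase"
        assert reversals["pfs"].direction == "increase"
        assert reversals["g4ae"].direction == "decrease"
        assert reversals["atc_l4"].direction == "decrease"
        assert reversals["posology"].direction == "increase"
        assert reversals["med_costs"].direction == "increase"

    @pytest.mark.parametrize("worse,published", [
        ("cetuximab", {"os": 60.3, "pfs": 47.3, "g4ae": 5.6, "mkt_auth": 33.3}),
    ])
    def test_afli_vs_cet_thresholds(self, mcrc_fitted, worse, published):
        report = one_way_report(mcrc_fitted.scores, mcrc_fitted.model.weights,
                                [(worse, "aflibercept_folfiri")])
        entries = _pair_entries(report, worse, "aflibercept_folfiri")
        reversals = {a: e for a, e in entries.items() if e.threshold is not None}
        assert set(reversals) == set(published)
        for a, v in published.items():
            assert reversals[a].threshold * 100 == pytest.approx(v, abs=0.7)

    def test_afli_vs_pan_thresholds(self, mcrc_fitted):
        published = {"os": 60.4, "pfs": 47.2, "g4ae": 5.4, "atc_l4": 26.4,
                     "phase3": 49.0, "mkt_auth": 24.6}
        report = one_way_report(mcrc_fitted.scores, mcrc_fitted.model.weights,
                                [("panitumumab", "aflibercept_folfiri")])
        entries = _pair_entries(report, "panitumumab", "aflibercept_folfiri")
        reversals = {a: e for a, e in entries.items() if e.threshold is not None}
        assert set(reversals) == set(published)
        for a, v in published.items():
            assert reversals[a].threshold * 100 == pytest.approx(v, abs=0.7)

    def test_uniform_scores_give_empty_report(self):
        import pandas as pd

        from mavt.weighting import normalize

        scores = pd.DataFrame({"a1": [40.0, 40.0], "a2": [60.0, 60.0]},
                              index=["x", "y"])
        report = one_way_report(scores, normalize({"a1": 1, "a2": 1}), [("x", "y")])
        assert report.reversals() == []

    def test_reported_thresholds_verified_by_substitution(self):
        problem = generate_problem(3, 5, seed=77)
        res = overall_value(problem.true_scores, problem.weights)
        pairs = [(a, b) for i, a in enumerate(res.ranking)
                 for b in res.ranking[i + 1:]]
        report = one_way_report(problem.true_scores, problem.weights, pairs)
        for e in report.reversals():
            diff = value_difference(e.attribute, e.better, e.worse,
                                    problem.true_scores, problem.weights,
                                    e.threshold)
            assert abs(diff) < 1e-6


class TestRobustness:
    def test_mcrc_margin_exceeds_fifty_percent(self, mcrc_fitted):
        """No single baseline weight moved by <=50% changes the ranking."""
        report = one_way_report(mcrc_fitted.scores, mcrc_fitted.model.weights,
                                adjacent_pairs(mcrc_fitted.ranking))
        assert robustness_margin(report) > 0.5

    def test_posology_and_medical_costs_relative_changes(self, mcrc_fitted):
        """The published "most sensitive" attributes need ~69% and ~81%."""
        report = one_way_report(mcrc_fitted.scores, mcrc_fitted.model.weights,
                                [("cetuximab", "panitumumab")])
        entries = _pair_entries(report, "cetuximab", "panitumumab")
        assert entries["posology"].relative_change == pytest.approx(0.69, abs=0.02)
        assert entries["med_costs"].relative_change == pytest.approx(0.81, abs=0.02)

    def test_tied_options_have_zero_margin(self):
        import pandas as pd

        from mavt.weighting import normalize

        # equal overall values from different score profiles
        scores = pd.DataFrame({"a1": [80.0, 20.0], "a2": [20.0, 80.0]},
                              index=["x", "y"])
        res = overall_value(scores, normalize({"a1": 1, "a2": 1}))
        report = one_way_report(scores, normalize({"a1": 1, "a2": 1}),
                                adjacent_pairs(res.ranking))
        assert robustness_margin(report) == pytest.approx(0.0, abs=1e-9)

    def test_margin_equals_brute_force_minimum(self):
        problem = generate_problem(4, 5, seed=13)
        res = overall_value(problem.true_scores, problem.weights)
        report = one_way_report(problem.true_scores, problem.weights,
                                adjacent_pairs(res.ranking))
        brute = min(e.relative_change for e in report.reversals())
        assert robustness_margin(report) == pytest.approx(brute)


class TestPerturbation:
    def test_mcrc_stable_at_five_value_points(self, mcrc_fitted):
        report = reference_perturbation_check(mcrc_fitted.scores,
                                              mcrc_fitted.model.weights, 5.0)
        assert report.stable

    def test_zero_delta_always_stable(self, mcrc_fitted):
        assert reference_perturbation_check(mcrc_fitted.scores,
                                            mcrc_fitted.model.weights, 0.0).stable

    def test_close_options_are_flagged_with_the_attribute(self):
        import pandas as pd

        from mavt.weighting import normalize

        # dV = 1 but w_1 * 2 * delta = 0.5 * 2 * 5 = 5 > 1: swap possible
        scores = pd.DataFrame({"a1": [51.0, 50.0], "a2": [50.0, 50.0]},
                              index=["x", "y"])
        w = normalize({"a1": 1, "a2": 1})
        report = reference_perturbation_check(scores, w, 5.0)
        assert not report.stable
        assert ("a1", "x", "y") in report.flagged
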