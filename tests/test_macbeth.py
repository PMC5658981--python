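"""MACBETH judgment matrices: consistency, scale derivation, anchoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mavt.macbeth import (IncompatibleJudgments, JudgmentMatrix, anchor_scale,
                          check_consistency, derive_scale, feasible_bounds,
                          satisfies_constraints)
from mavt.synthetic import generate_judgments


def matrix_3(k_ab, k_bc, k_ac):
    return JudgmentMatrix.from_judgments(
        ["a", "b", "c"], {("a", "b"): k_ab, ("b", "c"): k_bc, ("a", "c"): k_ac})


class TestConsistency:
    def test_compatible_categories_are_consistent(self):
        # weak + strong spans judged very strong overall
        assert check_consistency(matrix_3("weak", "strong", "very strong")).consistent

    def test_longer_span_judged_smaller_is_flagged(self):
        report = check_consistency(matrix_3("strong", "strong", "weak"))
        assert not report.consistent
        flagged = {pair for pair, _, _ in report.ordinal_violations}
        assert ("a", "c") in flagged

    def test_all_no_difference_is_consistent(self):
        m = JudgmentMatrix.from_judgments(["a", "b"], {("a", "b"): "no"})
        report = check_consistency(m)
        assert report.consistent
        assert derive_scale(m).as_dict() == {"a": 0.0, "b": 0.0}

    def test_ordinally_fine_but_cardinally_infeasible(self):
        # every row/column is monotone, yet the inter-pair rules force
        # d(a,b) >= d(c,d) + 2 (from (a,c) vs (b,d)) and
        # d(c,d) >= d(a,b) + 2 (from (c,d) vs (a,b)) simultaneously
        m = JudgmentMatrix.from_judgments(
            ["a", "b", "c", "d"],
            {("a", "b"): 1, ("a", "c"): 5, ("a", "d"): 6,
             ("b", "c"): 1, ("b", "d"): 3, ("c", "d"): 3})
        report = check_consistency(m)
        assert not report.ordinal_violations
        assert not report.cardinal_feasible
        assert not report.consistent
        with pytest.raises(IncompatibleJudgments):
            derive_scale(m)

    def test_incomplete_matrix_rejected(self):
        m = JudgmentMatrix.from_judgments(["a", "b", "c"], {("a", "b"): 2})
        with pytest.raises(ValueError, match="incomplete"):
            check_consistency(m)


class TestDeriveScale:
    def test_single_pair_forced_to_its_bound(self):
        m = JudgmentMatrix.from_judgments(["a", "b"], {("a", "b"): "moderate"})
        assert derive_scale(m).as_dict() == {"b": 0.0, "a": 3.0}

    def test_three_stimulus_example(self):
        # weak(2) + strong(4) spans with a very strong(5) total: the minimal
        # feasible scale is c=0, b=4, a=6 (brute-force enumeration below)
        m = matrix_3("weak", "strong", "very strong")
        scale = derive_scale(m)
        assert scale.as_dict() == {"c": 0.0, "b": 4.0, "a": 6.0}

    def test_three_stimulus_example_against_enumeration_oracle(self):
        """Brute-force search over an integer grid agrees with the LP."""
        m = matrix_3("weak", "strong", "very strong")
        best = None
        for a in range(0, 20):
            for b in range(0, a + 1):
                scale = {"a": float(a), "b": float(b), "c": 0.0}
                if satisfies_constraints(m, type("S", (), {"scores": scale})()):
                    if best is None or a < best["a"]:
                        best = scale
        assert best == derive_scale(m).as_dict()

    def test_infeasible_judgments_raise(self):
        with pytest.raises(IncompatibleJudgments):
            derive_scale(matrix_3("strong", "strong", "weak"))

    def test_derived_scale_satisfies_every_constraint(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            latent = {f"s{i}": float(v) for i, v in
                      enumerate(np.sort(rng.uniform(0, 100, size=5))[::-1])}
            m = generate_judgments(latent, rng=rng)
            scale = derive_scale(m)
            assert satisfies_constraints(m, scale)


class TestFeasibleBounds:
    def test_top_stimulus_unbounded_above_reports_ceiling(self):
        m = JudgmentMatrix.from_judgments(["a", "b"], {("a", "b"): "moderate"})
        lo, hi = feasible_bounds(m, "a", ceiling=1000.0)
        assert lo == 3.0
        assert hi == 1000.0

    def test_bottom_stimulus_pinned_at_zero(self):
        m = matrix_3("weak", "strong", "very strong")
        assert feasible_bounds(m, "c") == (0.0, 0.0)

    def test_middle_stimulus_interval_contains_derived_score(self):
        m = matrix_3("weak", "strong", "very strong")
        lo, hi = feasible_bounds(m, "b")
        assert lo <= 4.0 <= hi


class TestAnchoring:
    def test_anchor_to_interior_references(self):
        scale = derive_scale(matrix_3("weak", "strong", "very strong"))
        anchored = anchor_scale(scale, "c", "a")
        assert anchored["c"] == 0.0
        assert anchored["a"] == 100.0
        assert anchored["b"] == pytest.approx(66.666666667)

    def test_values_outside_reference_interval_leave_0_100(self):
        from mavt.macbeth import CardinalScale

        scale = CardinalScale({"d": 0.0, "c": 2.0, "b": 5.0, "a": 6.0})
        anchored = anchor_scale(scale, "c", "a")
        assert [anchored[s] for s in "dcba"] == [-50.0, 0.0, 75.0, 100.0]

    def test_reversed_references_rejected(self):
        from mavt.macbeth import CardinalScale

        scale = CardinalScale({"a": 6.0, "b": 0.0})
        with pytest.raises(ValueError, match="not increasing"):
            anchor_scale(scale, "a", "b")

    @given(alpha=st.floats(0.1, 50.0), beta=st.floats(-100.0, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_anchoring_is_affine_invariant(self, alpha, beta):
        from mavt.macbeth import CardinalScale

        base = {"c": 0.0, "b": 4.0, "a": 6.0}
        transformed = CardinalScale({k: alpha * v + beta for k, v in base.items()})
        a1 = anchor_scale(CardinalScale(base), "c", "a")
        a2 = anchor_scale(transformed, "c", "a")
        for s in base:
            assert a1[s] == pytest.approx(a2[s], abs=1e-6)


class TestLatentRecovery:
    def test_uncorrupted_judgments_recover_latent_ordering_and_values(self):
        """Scales derived from binned latent differences reproduce the latent
        ordering exactly and, anchored to common references, agree with the
        anchored latent scale within one category bin width."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 7))
            latent = {f"s{i}": float(v) for i, v in
                      enumerate(np.sort(rng.uniform(0, 100, size=n))[::-1])}
            m = generate_judgments(latent, rng=rng)
            scale = derive_scale(m)
            order_derived = sorted(latent, key=lambda s: -scale[s])
            order_latent = sorted(latent, key=lambda s: -latent[s])
            assert order_derived == order_latent
            bot, top = m.stimuli[-1], m.stimuli[0]
            anchored = anchor_scale(scale, bot, top)
            lat_anchored = {s: 100.0 * (latent[s] - latent[bot]) / (latent[top] - latent[bot])
                            for s in latent}
            for s in latent:
                assert abs(anchored[s] - lat_anchored[s]) <= 100.0 / 6.0 + 1e-9
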