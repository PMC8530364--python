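"""Unit and property tests for the exact statistical tier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olfeedback.analytic import (
    FeedbackSpec,
    OdorPairCounts,
    ThresholdSpec,
    classify_regime,
    derive_feedback_probabilities,
    initial_similarity,
    joint_shift_contributions,
    linear_coefficients,
    phase_diagram,
    similarity_after_feedback,
    single_odor_shift,
    special_case_slope,
)
from olfeedback.errors import (
    DegenerateRegimeError,
    RegimeError,
    UndefinedSimilarityError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# feedback probability structure
# ---------------------------------------------------------------------------


class TestFeedbackProbabilities:
    def test_full_overlap_no_flip_gives_unit_similarity(self):
        fb = FeedbackSpec(dr=0.1, p_plus_a=0.3, p_minus_a=0.3, p_both=1.0, p_flip=0.0)
        assert fb.rho_fb == 1.0

    def test_half_overlap_quarter_flip_gives_zero_similarity(self):
        fb = FeedbackSpec(dr=0.1, p_plus_a=0.2, p_minus_a=0.2, p_both=0.5, p_flip=0.25)
        assert fb.rho_fb == 0.0

    def test_coverage_equality_of_derived_b_probabilities(self):
        fb = derive_feedback_probabilities(
            FeedbackSpec(dr=0.2, p_plus_a=0.125, p_minus_a=0.375,
                         p_both=0.5, p_flip=0.2)
        )
        assert fb.p_plus_b + fb.p_minus_b == pytest.approx(fb.coverage, abs=1e-14)

    def test_bayes_relation_for_flip_of_a(self):
        fb = FeedbackSpec(dr=0.2, p_plus_a=0.125, p_minus_a=0.375,
                          p_both=0.5, p_flip=0.2)
        # p_flip_A * p_plus_B = p_flip * p_minus_A
        assert fb.p_flip_a * fb.p_plus_b == pytest.approx(fb.p_flip * fb.p_minus_a)

    def test_derived_b_marginals_match_monte_carlo_sign_frequencies(self):
        # 10^6-module random sign assignment as the independent oracle
        from olfeedback.population import assign_feedback

        fb = FeedbackSpec(dr=0.2, p_plus_a=0.125, p_minus_a=0.375,
                          p_both=0.5, p_flip=0.2)
        rng = np.random.default_rng(42)
        n = 1_000_000
        _, sign_b, _ = assign_feedback(n, fb, rng)
        for expected, observed in (
            (fb.p_plus_b, (sign_b == 1).mean()),
            (fb.p_minus_b, (sign_b == -1).mean()),
        ):
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se

    def test_flip_exceeding_overlap_is_rejected(self):
        with pytest.raises(ValidationError, match="p_flip"):
            FeedbackSpec(dr=0.1, p_plus_a=0.2, p_minus_a=0.2, p_both=0.3, p_flip=0.5)

    def test_full_coverage_requires_full_overlap(self):
        with pytest.raises(ValidationError, match="coverage"):
            FeedbackSpec(dr=0.1, p_plus_a=0.6, p_minus_a=0.4, p_both=0.5, p_flip=0.0)

    def test_p_flip_a_defined_as_zero_for_fully_opposite_feedback(self):
        fb = FeedbackSpec(dr=0.1, p_plus_a=1.0, p_minus_a=0.0, p_both=1.0, p_flip=1.0)
        assert fb.p_plus_b == 0.0
        assert fb.p_flip_a == 0.0


# ---------------------------------------------------------------------------
# thresholds, counts, densities
# ---------------------------------------------------------------------------


class TestGeometryInvariants:
    def test_threshold_ordering_is_enforced(self):
        with pytest.raises(ValidationError, match="theta_m < theta_c"):
            ThresholdSpec(theta_m=0.9, theta_c=0.8, r_max=2.0)

    def test_density_conservation_sums_to_n(self, reference_thresholds):
        th = reference_thresholds
        c = OdorPairCounts(n=1000, n_a=600, n_b=550, n_ab=300)
        total = (
            c.rho_ab(th) * th.d_rm**2
            + c.rho_a_nb(th) * th.d_rm * th.theta_m
            + c.rho_na_b(th) * th.d_rm * th.theta_m
            + c.rho_na_nb(th) * th.theta_m**2
        )
        assert total == pytest.approx(c.n, rel=1e-12)

    def test_overlap_cannot_exceed_marginals(self):
        with pytest.raises(ValidationError, match="n_ab"):
            OdorPairCounts(n=100, n_a=40, n_b=30, n_ab=35)


# ---------------------------------------------------------------------------
# similarity before feedback
# ---------------------------------------------------------------------------


class TestInitialSimilarity:
    def test_fully_overlapping_odors_reach_the_q0_ceiling(self, reference_thresholds):
        c = OdorPairCounts(n=100, n_a=50, n_b=50, n_ab=50)
        assert initial_similarity(c, reference_thresholds) == pytest.approx(
            reference_thresholds.q0
        )

    def test_disjoint_odors_have_zero_similarity(self, reference_thresholds):
        c = OdorPairCounts(n=200, n_a=50, n_b=50, n_ab=0)
        assert initial_similarity(c, reference_thresholds) == 0.0

    def test_hand_arithmetic_example(self):
        # theta_m=0.3, r_max=2, theta_c=0.8: q0 = 1.2/1.7
        th = ThresholdSpec(theta_m=0.3, theta_c=0.8, r_max=2.0)
        c = OdorPairCounts(n=1000, n_a=100, n_b=100, n_ab=50)
        expected = (1.2 / 1.7) * 50 / math.sqrt(100 * 100)
        assert initial_similarity(c, th) == pytest.approx(expected, rel=1e-12)

    def test_zero_responsive_count_is_an_error(self, reference_thresholds):
        c = OdorPairCounts(n=100, n_a=0, n_b=50, n_ab=0)
        with pytest.raises(UndefinedSimilarityError):
            initial_similarity(c, reference_thresholds)


# ---------------------------------------------------------------------------
# count shifts
# ---------------------------------------------------------------------------


class TestCountShifts:
    def test_zero_feedback_shifts_nothing(self, reference_thresholds, generic_counts):
        fb = FeedbackSpec(dr=0.0, p_plus_a=0.3, p_minus_a=0.2, p_both=0.5, p_flip=0.1)
        assert single_odor_shift(generic_counts, reference_thresholds, fb, "A") == 0.0
        contrib, total = joint_shift_contributions(generic_counts, reference_thresholds, fb)
        assert np.all(contrib == 0.0) and total == 0.0

    def test_pure_positive_small_feedback_reduces_to_one_term(self, reference_thresholds):
        # dR below the threshold gap: shift = dR * N_A / d_rm
        c = OdorPairCounts(n=1000, n_a=400, n_b=400, n_ab=200)
        fb = FeedbackSpec(dr=0.3, p_plus_a=1.0, p_minus_a=0.0, p_both=1.0, p_flip=0.0)
        got = single_odor_shift(c, reference_thresholds, fb, "A")
        assert got == pytest.approx(0.3 * 400 / reference_thresholds.d_rm, rel=1e-12)

    def test_gated_rows_vanish_at_high_cortical_threshold(
        self, reference_thresholds, reference_feedback, generic_counts
    ):
        # theta_c = 0.8 >= theta_m + dR = 0.7: rows 9-15 are exactly zero
        contrib, _ = joint_shift_contributions(
            generic_counts, reference_thresholds, reference_feedback
        )
        assert np.all(contrib[8:] == 0.0)

    def test_gated_rows_activate_below_the_gap(self, generic_counts):
        th = ThresholdSpec(theta_m=0.3, theta_c=0.6, r_max=2.0)
        fb = FeedbackSpec(dr=0.4, p_plus_a=0.3, p_minus_a=0.1, p_both=0.5, p_flip=0.1)
        contrib, _ = joint_shift_contributions(generic_counts, th, fb)
        assert np.any(contrib[8:] != 0.0)

    def test_single_odor_shift_matches_population_count_change(self):
        # empirical count change in a 10^6-module uniform population
        from olfeedback.population import PopulationSpec, sample_population

        th = ThresholdSpec(theta_m=0.3, theta_c=0.8, r_max=2.0)
        fb = FeedbackSpec(dr=0.4, p_plus_a=0.2, p_minus_a=0.3, p_both=0.5, p_flip=0.2)
        n = 1_000_000
        counts = OdorPairCounts(n=n, n_a=600_000, n_b=600_000, n_ab=350_000)
        pop = PopulationSpec(n=n, response_model="uniform", thresholds=th)
        rng = np.random.default_rng(11)
        diffs = []
        for _ in range(8):
            draw = sample_population(pop, counts, fb, rng)
            before = (draw.responses[:, 0] >= th.theta_c).sum()
            after = (draw.responses[:, 0] + draw.changes[:, 0] >= th.theta_c).sum()
            diffs.append(after - before)
        predicted = single_odor_shift(counts, th, fb, "A")
        diffs = np.asarray(diffs, dtype=float)
        se = diffs.std(ddof=1) / math.sqrt(len(diffs))
        assert abs(diffs.mean() - predicted) < 3 * max(se, 1.0)


# ---------------------------------------------------------------------------
# post-feedback similarity and the linear law
# ---------------------------------------------------------------------------


class TestLinearLaw:
    def test_zero_feedback_leaves_similarity_unchanged(
        self, reference_thresholds, generic_counts
    ):
        fb = FeedbackSpec(dr=0.0, p_plus_a=0.3, p_minus_a=0.2, p_both=0.5, p_flip=0.1)
        res = similarity_after_feedback(generic_counts, reference_thresholds, fb)
        assert res.rho_f == pytest.approx(res.rho_i, rel=1e-12)
        q1, q2, _ = linear_coefficients(
            reference_thresholds, fb, generic_counts.n, generic_counts.n_a, generic_counts.n_b
        )
        assert q1 == pytest.approx(0.0, abs=1e-12)
        assert q2 == pytest.approx(0.0, abs=1e-12)

    def test_delta_rho_equals_q2_rho_i_plus_q1(
        self, reference_thresholds, reference_feedback, generic_counts
    ):
        res = similarity_after_feedback(generic_counts, reference_thresholds, reference_feedback)
        assert res.delta_rho == pytest.approx(res.q2 * res.rho_i + res.q1, abs=1e-12)

    def test_identical_feedback_matches_closed_form(self):
        # r_max=2, theta_c=1.0, dR=0.4, rho_i=0.5 -> delta_rho = 0.2
        th = ThresholdSpec(theta_m=0.3, theta_c=1.0, r_max=2.0)
        fb = FeedbackSpec(dr=0.4, p_plus_a=1.0, p_minus_a=0.0, p_both=1.0, p_flip=0.0)
        n_a = n_b = 600_000.0
        n_ab = 0.5 * math.sqrt(n_a * n_b) / th.q0  # rho_i = 0.5
        counts = OdorPairCounts(n=1_000_000, n_a=n_a, n_b=n_b, n_ab=n_ab)
        res = similarity_after_feedback(counts, th, fb)
        assert res.rho_i == pytest.approx(0.5, rel=1e-12)
        assert res.delta_rho == pytest.approx(0.2, rel=1e-10)

    def test_opposite_feedback_matches_closed_form(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=1.0, r_max=2.0)
        fb = FeedbackSpec(dr=0.4, p_plus_a=1.0, p_minus_a=0.0, p_both=1.0, p_flip=1.0)
        counts = OdorPairCounts(n=1_000_000, n_a=600_000, n_b=600_000, n_ab=350_000)
        res = similarity_after_feedback(counts, th, fb)
        expected_slope = math.sqrt(1.0 - 0.4**2) - 1.0  # d_rc = 1
        assert res.q2 == pytest.approx(expected_slope, abs=1e-10)
        assert res.q1 == pytest.approx(0.0, abs=1e-12)

    def test_full_inhibitory_slope_is_minus_dr_over_drc(self, reference_thresholds):
        fb = FeedbackSpec(dr=0.4, p_plus_a=0.0, p_minus_a=1.0, p_both=1.0, p_flip=0.0)
        _, q2, _ = linear_coefficients(reference_thresholds, fb, 1.0, 0.6, 0.6)
        assert q2 == pytest.approx(-0.4 / reference_thresholds.d_rc, abs=1e-10)

    def test_coefficients_are_independent_of_the_probe_counts(
        self, reference_thresholds, reference_feedback
    ):
        # evaluating delta_rho at several feasible overlaps recovers the same line
        q1, q2, _ = linear_coefficients(reference_thresholds, reference_feedback, 1.0, 0.6, 0.6)
        for p_ab in (0.25, 0.4, 0.55):
            counts = OdorPairCounts(n=1.0, n_a=0.6, n_b=0.6, n_ab=p_ab)
            res = similarity_after_feedback(counts, reference_thresholds, reference_feedback)
            assert res.delta_rho == pytest.approx(q2 * res.rho_i + q1, abs=1e-10)

    def test_degenerate_collapse_raises_rather_than_clamps(self):
        # full inhibition with dR reaching the whole above-threshold band
        th = ThresholdSpec(theta_m=0.3, theta_c=1.9, r_max=2.0)
        fb = FeedbackSpec(dr=0.4, p_plus_a=0.0, p_minus_a=1.0, p_both=1.0, p_flip=0.0)
        counts = OdorPairCounts(n=1000, n_a=600, n_b=600, n_ab=350)
        with pytest.raises(DegenerateRegimeError, match="C_"):
            similarity_after_feedback(counts, th, fb)

    def test_monotone_slope_in_feedback_strength_for_identical_feedback(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=1.0, r_max=2.0)
        slopes = []
        for dr in np.linspace(0.0, min(th.delta_theta, th.d_rc), 8):
            fb = FeedbackSpec(dr=float(dr), p_plus_a=1.0, p_minus_a=0.0,
                              p_both=1.0, p_flip=0.0)
            _, q2, _ = linear_coefficients(th, fb, 1.0, 0.6, 0.6)
            slopes.append(q2)
        assert np.all(np.diff(slopes) >= -1e-12)


# ---------------------------------------------------------------------------
# closed-form special slopes
# ---------------------------------------------------------------------------


class TestSpecialCaseSlopes:
    def test_identical_slope_value(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=1.0, r_max=2.0)
        assert special_case_slope("identical", th, 0.4) == pytest.approx(0.4)

    def test_opposite_slope_value(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=1.0, r_max=2.0)
        assert special_case_slope("opposite", th, 0.4) == pytest.approx(
            -0.0835, abs=5e-5
        )

    def test_zero_feedback_has_zero_slope(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=1.0, r_max=2.0)
        assert special_case_slope("identical", th, 0.0) == 0.0
        assert special_case_slope("opposite", th, 0.0) == 0.0

    def test_outside_regime_raises(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=0.5, r_max=2.0)
        with pytest.raises(RegimeError):
            special_case_slope("identical", th, 0.4)  # dr > delta_theta

    @pytest.mark.parametrize("kind,p_flip", [("identical", 0.0), ("opposite", 1.0)])
    def test_closed_forms_equal_general_machinery(self, kind, p_flip):
        for theta_c, dr in [(1.0, 0.4), (1.2, 0.2), (0.9, 0.55)]:
            th = ThresholdSpec(theta_m=0.3, theta_c=theta_c, r_max=2.0)
            if dr > min(th.delta_theta, th.d_rc):
                continue
            fb = FeedbackSpec(dr=dr, p_plus_a=1.0, p_minus_a=0.0,
                              p_both=1.0, p_flip=p_flip)
            _, q2, _ = linear_coefficients(th, fb, 1.0, 0.6, 0.6)
            assert q2 == pytest.approx(special_case_slope(kind, th, dr), abs=1e-10)


# ---------------------------------------------------------------------------
# regimes and the phase diagram
# ---------------------------------------------------------------------------


class TestPhaseDiagram:
    def test_correlated_feedback_at_realistic_threshold_is_convergent(self):
        # theta_c giving ~10% cortical activation (0.6 * d_rc / d_rm = 0.1)
        th = ThresholdSpec(theta_m=0.3, theta_c=0.8, r_max=2.0)
        table = phase_diagram(
            th, dr=0.4, theta_c_grid=np.array([2.0 - 1.7 / 6.0]),
            p_flip_grid=np.array([0.0]),
        )
        assert table.iloc[0]["regime"] == "convergence"

    def test_anticorrelated_feedback_at_realistic_threshold_is_divergent(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=0.8, r_max=2.0)
        table = phase_diagram(
            th, dr=0.4, theta_c_grid=np.array([2.0 - 1.7 / 6.0]),
            p_flip_grid=np.array([0.5]),
        )
        assert table.iloc[0]["regime"] == "divergence"

    def test_below_the_gap_q1_is_positive_and_regime_mixed(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=0.8, r_max=2.0)
        table = phase_diagram(
            th, dr=0.4, theta_c_grid=np.array([0.5]), p_flip_grid=np.array([0.0, 0.5]),
        )
        assert (table["q1"] > 0).all()
        assert (table["regime"] == "mixed").all()

    def test_rho_fb_column_follows_the_overlap_minus_two_flips_rule(self):
        th = ThresholdSpec(theta_m=0.3, theta_c=0.8, r_max=2.0)
        flips = np.array([0.0, 0.1, 0.25, 0.5])
        table = phase_diagram(
            th, dr=0.4, theta_c_grid=np.array([0.8]), p_flip_grid=flips,
        )
        assert np.allclose(table["rho_fb"], 0.5 - 2 * flips)

    def test_regime_classifier_tolerance(self):
        assert classify_regime(q1=5e-10, q2=1.0) == "convergence"
        assert classify_regime(q1=2e-9, q2=-1.0) == "mixed"
        assert classify_regime(q1=0.0, q2=-0.2) == "divergence"


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    theta_m=st.floats(0.1, 0.5),
    gap=st.floats(0.1, 1.0),
    head=st.floats(0.2, 1.0),
    dr=st.floats(0.0, 0.6),
    p_plus=st.floats(0.05, 0.45),
    p_minus=st.floats(0.05, 0.45),
    p_both=st.floats(0.1, 0.9),
    flip_frac=st.floats(0.0, 1.0),
)
def test_q1_vanishes_whenever_the_gate_is_closed(
    theta_m, gap, head, dr, p_plus, p_minus, p_both, flip_frac
):
    """Q1 = 0 exactly for theta_c >= theta_m + dR (spec invariant)."""
    th = ThresholdSpec(theta_m=theta_m, theta_c=theta_m + gap, r_max=theta_m + gap + head)
    cov = p_plus + p_minus
    if cov * (1.0 - p_both) > (1.0 - cov):
        p_both = 1.0 - (1.0 - cov) / cov  # push into the feasible region
        p_both = min(max(p_both, 0.0) + 1e-6, 1.0)
    fb = FeedbackSpec(dr=dr, p_plus_a=p_plus, p_minus_a=p_minus,
                      p_both=p_both, p_flip=p_both * flip_frac)
    if th.theta_c < th.theta_m + fb.dr:
        return  # gate open; Q1 may be positive
    try:
        q1, _, _ = linear_coefficients(th, fb, 1.0, 0.6, 0.6)
    except DegenerateRegimeError:
        return
    assert abs(q1) < 1e-9


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_linear_law_is_exact_for_random_valid_settings(seed):
    """delta_rho = Q2 rho_i + Q1 holds to numerical tolerance everywhere."""
    from tests.conftest import random_valid_setting

    rng = np.random.default_rng(seed)
    th, fb, counts = random_valid_setting(rng)
    res = similarity_after_feedback(counts, th, fb)
    assert res.delta_rho == pytest.approx(res.q2 * res.rho_i + res.q1, abs=1e-9)
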