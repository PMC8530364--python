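import numpy as np
import pytest

from olfeedback.analytic import FeedbackSpec, OdorPairCounts, ThresholdSpec


@pytest.fixture
def reference_thresholds() -> ThresholdSpec:
    """High-threshold working point of the general phase-diagram setting."""
    return ThresholdSpec(theta_m=0.3, theta_c=0.8, r_max=2.0)


@pytest.fixture
def reference_feedback() -> FeedbackSpec:
    """Coverage 0.5, inhibitory fraction 0.75, p_both 0.5, dR = r_max / 5."""
    return FeedbackSpec(dr=0.4, p_plus_a=0.125, p_minus_a=0.375,
                        p_both=0.5, p_flip=0.2)


@pytest.fixture
def generic_counts() -> OdorPairCounts:
    return OdorPairCounts(n=1_000_000, n_a=600_000, n_b=600_000, n_ab=350_000)


def random_valid_setting(rng: np.random.Generator):
    """A random (thresholds, feedback, counts) triple satisfying all invariants.

    Spans both the high- and low-threshold regimes; rejects settings where a
    feedback-shifted count collapses.
    """
    from olfeedback.analytic import similarity_after_feedback
    from olfeedback.errors import DegenerateRegimeError

    while True:
        r_max = rng.uniform(1.5, 3.0)
        theta_m = rng.uniform(0.1, 0.4) * r_max
        theta_c = rng.uniform(theta_m + 0.05 * r_max, 0.8 * r_max)
        th = ThresholdSpec(theta_m=theta_m, theta_c=theta_c, r_max=r_max)
        dr = rng.uniform(0.05, 0.4) * r_max
        coverage = rng.uniform(0.2, 0.9)
        p_plus = coverage * rng.uniform(0.1, 0.9)
        # coverage equality needs coverage*(1-p_both) <= 1-coverage
        p_both_lo = max(0.0, 2.0 - 1.0 / coverage)
        p_both = rng.uniform(p_both_lo + 1e-6, 1.0)
        p_flip = p_both * rng.uniform(0.0, 1.0)
        fb = FeedbackSpec(dr=dr, p_plus_a=p_plus, p_minus_a=coverage - p_plus,
                          p_both=p_both, p_flip=p_flip)
        n = 1_000_000
        p_a = rng.uniform(0.3, 0.7)
        p_b = rng.uniform(0.3, 0.7)
        lo = max(0.0, p_a + p_b - 1.0)
        hi = min(p_a, p_b)
        p_ab = rng.uniform(lo + 0.1 * (hi - lo), lo + 0.9 * (hi - lo))
        counts = OdorPairCounts(
            n=n, n_a=round(p_a * n), n_b=round(p_b * n), n_ab=round(p_ab * n)
        )
        try:
            similarity_after_feedback(counts, th, fb)
        except DegenerateRegimeError:
            continue
        return th, fb, counts
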