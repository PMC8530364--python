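"""Exact statistical model of feedback-driven cortical pattern convergence/divergence.

The olfactory bulb is abstracted as ``N`` modules (sets of mitral cells
projecting to one cortical unit).  A module's response to an odor is a rate
in ``(0, R_max)``; the module drives its cortical unit iff the rate exceeds
the cortical activation threshold ``theta_c``, and counts as odor-responsive
iff the rate exceeds the (much lower) response threshold ``theta_m``.
Responses to an odor pair (A, B) are jointly uniform within the four regions
delimited by ``theta_m``, so all cortical counts reduce to areas times region
densities.

Contextual feedback perturbs every affected module's rate by a fixed
magnitude ``dR`` with random signs; the joint sign/coverage structure of the
feedback for the two odors is summarized by ``(p_plus_A, p_minus_A, p_both,
p_flip)``.  The central result implemented here is that the change in cosine
similarity between the two cortical activation patterns is linear in the
initial similarity::

    delta_rho = Q2 * rho_i + Q1

with the intercept ``Q1`` vanishing exactly in the high-threshold regime
``theta_c >= theta_m + dR`` and becoming positive (mixed effects) below it.

The fifteen-case decomposition of the joint count shift, the affine
extraction of ``(Q1, Q2, Q3)``, the two closed-form special slopes and the
phase diagram over ``(theta_c, p_flip)`` are all exposed as plain functions
over small frozen dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateRegimeError,
    RegimeError,
    UndefinedSimilarityError,
    ValidationError,
)

__all__ = [
    "ThresholdSpec",
    "FeedbackSpec",
    "OdorPairCounts",
    "SimilarityResult",
    "derive_feedback_probabilities",
    "initial_similarity",
    "single_odor_shift",
    "joint_shift_contributions",
    "similarity_after_feedback",
    "linear_coefficients",
    "special_case_slope",
    "phase_diagram",
    "classify_regime",
]

#: tolerance used when deciding whether the intercept Q1 is zero
Q1_ZERO_TOL = 1e-9


def _heaviside(x: float) -> float:
    """H(x) = 0 for x < 0 and 1 for x >= 0."""
    return 0.0 if x < 0.0 else 1.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdSpec:
    """Response ceiling and the two activation thresholds (rate units).

    ``theta_m`` is the module response threshold (a module is odor-responsive
    above it); ``theta_c`` is the cortical activation threshold implementing
    coincidence gating; ``r_max`` caps module responses.
    """

    theta_m: float
    theta_c: float
    r_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_m < self.theta_c < self.r_max):
            raise ValidationError(
                "thresholds must satisfy 0 < theta_m < theta_c < r_max, got "
                f"theta_m={self.theta_m}, theta_c={self.theta_c}, r_max={self.r_max}"
            )

    @property
    def delta_theta(self) -> float:
        """Gap between cortical and response thresholds, theta_c - theta_m."""
        return self.theta_c - self.theta_m

    @property
    def d_rc(self) -> float:
        """Response range above the cortical threshold, r_max - theta_c."""
        return self.r_max - self.theta_c

    @property
    def d_rm(self) -> float:
        """Response range above the response threshold, r_max - theta_m."""
        return self.r_max - self.theta_m

    @property
    def q0(self) -> float:
        """Scale factor relating cortical to responsive counts, d_rc / d_rm."""
        return self.d_rc / self.d_rm


@dataclass(frozen=True)
class FeedbackSpec:
    """Magnitude and joint sign/coverage statistics of the feedback pair.

    ``dR`` is the (single) rate change magnitude for affected modules.
    ``p_plus_a``/``p_minus_a`` are the fractions of modules whose rate the
    odor-A feedback increases/decreases.  ``p_both`` is the conditional
    probability that a module affected for A is also affected for B, and
    ``p_flip`` the conditional probability that the B effect opposes the A
    effect.  The B-side marginals and the feedback similarity ``rho_fb`` are
    derived, under the coverage-equality assumption (both feedbacks reach the
    same number of modules).
    """

    dr: float
    p_plus_a: float
    p_minus_a: float
    p_both: float
    p_flip: float

    def __post_init__(self) -> None:
        for name in ("p_plus_a", "p_minus_a", "p_both", "p_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.dr < 0.0:
            raise ValidationError(f"dr must be nonnegative, got {self.dr}")
        if self.p_flip > self.p_both + 1e-15:
            raise ValidationError(
                f"p_flip <= p_both violated: p_flip={self.p_flip} > p_both={self.p_both}"
            )
        if self.p_plus_a + self.p_minus_a > 1.0 + 1e-15:
            raise ValidationError(
                "feedback coverage p_plus_a + p_minus_a must not exceed 1, got "
                f"{self.p_plus_a + self.p_minus_a}"
            )
        cov = self.coverage
        if cov < 1.0 and cov * (1.0 - self.p_both) > (1.0 - cov) + 1e-12:
            # modules affected for B but not A would need to outnumber the
            # A-unaffected pool; coverage equality cannot hold
            raise ValidationError(
                "coverage equality infeasible: coverage*(1-p_both) exceeds 1-coverage "
                f"(coverage={cov}, p_both={self.p_both})"
            )
        if cov == 1.0 and self.p_both < 1.0 and cov > 0.0:
            raise ValidationError(
                "coverage equality infeasible: full coverage for A requires p_both = 1"
            )

    @property
    def coverage(self) -> float:
        """Fraction of modules each feedback reaches, p_plus + p_minus."""
        return self.p_plus_a + self.p_minus_a

    @property
    def p_same(self) -> float:
        return self.p_both - self.p_flip

    @property
    def p_plus_b(self) -> float:
        if self.p_both == 0.0:
            return self.p_plus_a
        return (self.p_same * self.p_plus_a + self.p_flip * self.p_minus_a) / self.p_both

    @property
    def p_minus_b(self) -> float:
        if self.p_both == 0.0:
            return self.p_minus_a
        return (self.p_same * self.p_minus_a + self.p_flip * self.p_plus_a) / self.p_both

    @property
    def p_flip_a(self) -> float:
        """P(A feedback negative | B feedback positive), by Bayes' rule.

        Equals p_flip * p_minus_a / p_plus_b; defined as 0 when p_plus_b = 0
        (every term using it then carries a vanishing p_plus_b factor).
        """
        if self.p_plus_b == 0.0:
            return 0.0
        return self.p_flip * self.p_minus_a / self.p_plus_b

    @property
    def rho_fb(self) -> float:
        """Cosine similarity of the two feedback change vectors (constant dR)."""
        return self.p_both - 2.0 * self.p_flip


def derive_feedback_probabilities(spec: FeedbackSpec) -> FeedbackSpec:
    """Validate ``spec`` and return it with derived quantities accessible.

    Derived fields (``p_same``, ``p_plus_b``, ``p_minus_b``, ``p_flip_a``,
    ``rho_fb``) are exposed as properties; this function exists to make the
    validation step explicit and to assert the coverage equality.
    """
    # construction re-runs validation; properties are pure functions
    out = replace(spec)
    cov_b = out.p_plus_b + out.p_minus_b
    if not math.isclose(cov_b, out.coverage, rel_tol=0.0, abs_tol=1e-12):
        raise ValidationError(
            f"derived B coverage {cov_b} does not match A coverage {out.coverage}"
        )
    return out


@dataclass(frozen=True)
class OdorPairCounts:
    """Module counts for an odor pair and the implied region densities.

    ``n`` is the total number of modules, ``n_a``/``n_b`` the counts
    responsive to each odor (rate above theta_m) and ``n_ab`` the overlap.
    Counts may be fractional (expected counts); only ratios matter.
    """

    n: float
    n_a: float
    n_b: float
    n_ab: float

    def __post_init__(self) -> None:
        if min(self.n, self.n_a, self.n_b, self.n_ab) < 0:
            raise ValidationError("module counts must be nonnegative")
        if self.n_ab > min(self.n_a, self.n_b) + 1e-12:
            raise ValidationError(
                f"n_ab <= min(n_a, n_b) violated: n_ab={self.n_ab}, "
                f"n_a={self.n_a}, n_b={self.n_b}"
            )
        if self.n_a + self.n_b - self.n_ab > self.n + 1e-12:
            raise ValidationError(
                "n_a + n_b - n_ab must not exceed n "
                f"(got {self.n_a + self.n_b - self.n_ab} > {self.n})"
            )

    # region densities (modules per unit rate, or per unit rate^2 for joint
    # regions), following the uniform-within-region assumption
    def rho_a(self, th: ThresholdSpec) -> float:
        return self.n_a / th.d_rm

    def rho_b(self, th: ThresholdSpec) -> float:
        return self.n_b / th.d_rm

    def rho_not_a(self, th: ThresholdSpec) -> float:
        return (self.n - self.n_a) / th.theta_m

    def rho_not_b(self, th: ThresholdSpec) -> float:
        return (self.n - self.n_b) / th.theta_m

    def rho_ab(self, th: ThresholdSpec) -> float:
        return self.n_ab / th.d_rm**2

    def rho_a_nb(self, th: ThresholdSpec) -> float:
        """Responsive to A but not to B."""
        return (self.n_a - self.n_ab) / (th.d_rm * th.theta_m)

    def rho_na_b(self, th: ThresholdSpec) -> float:
        """Responsive to B but not to A."""
        return (self.n_b - self.n_ab) / (th.d_rm * th.theta_m)

    def rho_na_nb(self, th: ThresholdSpec) -> float:
        return (self.n - self.n_a - self.n_b + self.n_ab) / th.theta_m**2


@dataclass(frozen=True)
class SimilarityResult:
    """Similarity before/after feedback plus the linear-law coefficients."""

    rho_i: float
    rho_f: float
    delta_rho: float
    q0: float
    q1: float
    q2: float
    q3: float
    contributions: tuple[float, ...]  # the 15 joint-shift terms


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def initial_similarity(counts: OdorPairCounts, th: ThresholdSpec) -> float:
    """Cosine similarity of the two binary cortical patterns before feedback.

    Equals ``q0 * n_ab / sqrt(n_a * n_b)`` with q0 = d_rc / d_rm.
    """
    if counts.n_a == 0 or counts.n_b == 0:
        raise UndefinedSimilarityError(
            "similarity undefined: no modules responsive to "
            + ("A" if counts.n_a == 0 else "B")
        )
    return th.q0 * counts.n_ab / math.sqrt(counts.n_a * counts.n_b)


def single_odor_shift(
    counts: OdorPairCounts, th: ThresholdSpec, fb: FeedbackSpec, odor: str = "A"
) -> float:
    """Total change in the count of cortically active modules for one odor.

    Sum of the within-responsive-range term (positive feedback promotes
    modules within dR below theta_c, negative feedback demotes modules within
    dR above it) and, when dR exceeds the threshold gap, the promotion of
    previously unresponsive modules.
    """
    if odor not in ("A", "B"):
        raise ValidationError(f"odor must be 'A' or 'B', got {odor!r}")
    if odor == "A":
        p_plus, p_minus = fb.p_plus_a, fb.p_minus_a
        rho_resp, rho_unresp = counts.rho_a(th), counts.rho_not_a(th)
    else:
        p_plus, p_minus = fb.p_plus_b, fb.p_minus_b
        rho_resp, rho_unresp = counts.rho_b(th), counts.rho_not_b(th)

    dr, dth, drc, thm = fb.dr, th.delta_theta, th.d_rc, th.theta_m
    delta = (p_plus * min(dr, dth) - p_minus * min(dr, drc)) * rho_resp
    gate = _heaviside(dr - dth)
    if gate:
        delta += p_plus * min(dr - dth, thm) * rho_unresp
    return delta


def joint_shift_contributions(
    counts: OdorPairCounts, th: ThresholdSpec, fb: FeedbackSpec
) -> tuple[np.ndarray, float]:
    """The fifteen contributions to the shift in the both-odors count.

    Each term is (probability of the required sign pattern) x (area of the
    response-space region from which modules can cross the cortical threshold
    for both odors) x (module density in that region).  Cases 9-15 involve
    modules unresponsive to at least one odor and carry the H(dR - delta_theta)
    gate.  Returns the length-15 vector and its sum.
    """
    dr, dth, drc, thm = fb.dr, th.delta_theta, th.d_rc, th.theta_m
    p_pa, p_ma = fb.p_plus_a, fb.p_minus_a
    p_pb, p_mb = fb.p_plus_b, fb.p_minus_b
    p_same, p_flip, p_flip_a = fb.p_same, fb.p_flip, fb.p_flip_a

    w_in = min(dr, dth)       # reach below theta_c within the responsive band
    w_out = min(dr, drc)      # reach above theta_c (demotion window)
    w_safe = max(0.0, drc - dr)  # band safely above theta_c + dR
    gate = _heaviside(dr - dth)
    w_sub = min(dr - dth, thm) if gate else 0.0  # reach below theta_m

    r_ab = counts.rho_ab(th)
    r_anb = counts.rho_a_nb(th)
    r_nab = counts.rho_na_b(th)
    r_nanb = counts.rho_na_nb(th)

    c = np.zeros(15)
    # both responses in (theta_m, theta_c): need + for both
    c[0] = p_pa * p_same * w_in**2 * r_ab
    # A in (theta_m, theta_c), B in (theta_c, theta_c + dR): A up, B not down
    c[1] = p_pa * (1.0 - p_flip) * w_in * w_out * r_ab
    # mirror of case 2
    c[2] = p_pb * (1.0 - p_flip_a) * w_in * w_out * r_ab
    # A in (theta_m, theta_c), B safely above: A up suffices
    c[3] = p_pa * w_in * w_safe * r_ab
    c[4] = p_pb * w_in * w_safe * r_ab
    # both in (theta_c, theta_c + dR): lost if either goes down
    c[5] = -(p_ma + p_mb - p_ma * p_same) * w_out**2 * r_ab
    # one in the demotion window, the other safely above
    c[6] = -p_ma * w_out * w_safe * r_ab
    c[7] = -p_mb * w_out * w_safe * r_ab
    if gate:
        # both below theta_m but within reach of theta_c
        c[8] = p_pa * p_same * w_sub**2 * r_nanb
        # one below theta_m, the other in (theta_m, theta_c); within the gate
        # the responsive-band window min(dR, dtheta) equals dtheta
        c[9] = p_pa * p_same * w_sub * dth * r_nab
        c[10] = p_pa * p_same * w_sub * dth * r_anb
        # one below theta_m, the other in the demotion window
        c[11] = p_pa * (1.0 - p_flip) * w_sub * w_out * r_nab
        c[12] = p_pb * (1.0 - p_flip_a) * w_sub * w_out * r_anb
        # one below theta_m, the other safely above
        c[13] = p_pa * w_sub * w_safe * r_nab
        c[14] = p_pb * w_sub * w_safe * r_anb
    return c, float(c.sum())


def _shifted_counts(
    counts: OdorPairCounts, th: ThresholdSpec, fb: FeedbackSpec
) -> tuple[float, float, float, tuple[float, ...]]:
    """Post-feedback cortical counts (C_A', C_B', C_AB') and the 15 terms."""
    q0 = th.q0
    c_a = q0 * counts.n_a + single_odor_shift(counts, th, fb, "A")
    c_b = q0 * counts.n_b + single_odor_shift(counts, th, fb, "B")
    contrib, total = joint_shift_contributions(counts, th, fb)
    c_ab = q0**2 * counts.n_ab + total
    return c_a, c_b, c_ab, tuple(contrib)


def similarity_after_feedback(
    counts: OdorPairCounts, th: ThresholdSpec, fb: FeedbackSpec
) -> SimilarityResult:
    """Similarity before and after feedback, with the linear-law coefficients.

    Raises :class:`DegenerateRegimeError` (rather than clamping) if a shifted
    count collapses to zero or below.
    """
    rho_i = initial_similarity(counts, th)
    c_a, c_b, c_ab, contrib = _shifted_counts(counts, th, fb)
    for name, val in (("C_A", c_a), ("C_B", c_b), ("C_AB", c_ab)):
        if val <= 0.0 and not (name == "C_AB" and val == 0.0):
            raise DegenerateRegimeError(
                f"shifted count {name} collapsed to {val}; the linear analysis "
                "does not apply in this regime"
            )
    rho_f = c_ab / math.sqrt(c_a * c_b)
    q1, q2, q3 = linear_coefficients(th, fb, counts.n, counts.n_a, counts.n_b)
    return SimilarityResult(
        rho_i=rho_i,
        rho_f=rho_f,
        delta_rho=rho_f - rho_i,
        q0=th.q0,
        q1=q1,
        q2=q2,
        q3=q3,
        contributions=contrib,
    )


def _rho_f_raw(
    counts: OdorPairCounts, th: ThresholdSpec, fb: FeedbackSpec
) -> float:
    """Post-feedback similarity without the positivity checks (for probing)."""
    c_a, c_b, c_ab, _ = _shifted_counts(counts, th, fb)
    if c_a <= 0.0 or c_b <= 0.0:
        raise DegenerateRegimeError(
            f"shifted marginal count collapsed (C_A'={c_a}, C_B'={c_b})"
        )
    return c_ab / math.sqrt(c_a * c_b)


def linear_coefficients(
    th: ThresholdSpec,
    fb: FeedbackSpec,
    n: float,
    n_a: float,
    n_b: float,
    check_tol: float = 1e-10,
) -> tuple[float, float, float]:
    """Coefficients (Q1, Q2, Q3) of the law delta_rho = Q2 rho_i + Q1.

    The post-feedback similarity is affine in ``n_ab`` (its numerator is
    affine in ``n_ab`` and its denominator is ``n_ab``-free), so Q1 and Q3
    are extracted exactly from two probe evaluations at n_ab = 0 and one
    interior n_ab; a third probe verifies affinity to ``check_tol``.
    """
    if n_a <= 0 or n_b <= 0 or n <= 0:
        raise ValidationError("linear_coefficients requires positive n, n_a, n_b")
    # probe n_ab within its feasible range (overlap cannot be smaller than
    # n_a + n_b - n nor larger than min(n_a, n_b))
    lo = max(0.0, n_a + n_b - n)
    hi = min(n_a, n_b)
    if hi - lo <= 1e-12 * max(1.0, hi):
        raise ValidationError(
            "n_ab is fully determined by the marginals; affine extraction "
            f"needs a nondegenerate feasible range (lo={lo}, hi={hi})"
        )
    probes = [lo, 0.5 * (lo + hi), 0.75 * lo + 0.25 * hi]
    vals = []
    for n_ab in probes:
        counts = OdorPairCounts(n=n, n_a=n_a, n_b=n_b, n_ab=n_ab)
        vals.append(_rho_f_raw(counts, th, fb))
    scale = math.sqrt(n_a * n_b)
    q3 = (vals[1] - vals[0]) * scale / (probes[1] - probes[0])
    q1 = vals[0] - q3 * probes[0] / scale
    # affinity check at the third probe
    pred = q1 + q3 * probes[2] / scale
    if abs(pred - vals[2]) > check_tol * max(1.0, abs(vals[2])):
        raise RuntimeError(
            "rho_f is not affine in n_ab to the requested tolerance "
            f"(residual {pred - vals[2]:.3e}); this indicates an internal error"
        )
    q2 = q3 / th.q0 - 1.0
    return q1, q2, q3


def special_case_slope(kind: str, th: ThresholdSpec, dr: float) -> float:
    """Closed-form slope for full identical or full opposite feedback.

    Valid only in the high-threshold regime ``dr <= min(delta_theta, d_rc)``.
    Identical full positive feedback is an effective cortical-threshold
    decrease by dR for both odors, giving slope ``dr / (r_max - theta_c)``;
    opposite feedback shifts the threshold down for one odor and up for the
    other, giving ``sqrt((r_max - theta_c)^2 - dr^2) / (r_max - theta_c) - 1``.
    """
    if kind not in ("identical", "opposite"):
        raise ValidationError(f"kind must be 'identical' or 'opposite', got {kind!r}")
    if dr < 0:
        raise ValidationError("dr must be nonnegative")
    if dr > min(th.delta_theta, th.d_rc):
        raise RegimeError(
            "closed-form slopes require dr <= min(delta_theta, d_rc); got "
            f"dr={dr}, delta_theta={th.delta_theta}, d_rc={th.d_rc}"
        )
    if kind == "identical":
        return dr / th.d_rc
    return math.sqrt(th.d_rc**2 - dr**2) / th.d_rc - 1.0


def classify_regime(q1: float, q2: float, q1_tol: float = Q1_ZERO_TOL) -> str:
    """Label the (Q1, Q2) pair: convergence, divergence, mixed or neutral."""
    if q1 > q1_tol:
        return "mixed"
    if q2 > 0.0:
        return "convergence"
    if q2 < 0.0:
        return "divergence"
    return "neutral"


def phase_diagram(
    th_base: ThresholdSpec,
    dr: float,
    theta_c_grid: np.ndarray,
    p_flip_grid: np.ndarray,
    coverage: float = 0.5,
    inhibitory_fraction: float = 0.75,
    p_both: float = 0.5,
    p_odor: float = 0.6,
) -> pd.DataFrame:
    """(Q1, Q2, regime) over a grid of cortical thresholds and flip rates.

    ``th_base`` supplies theta_m and r_max; theta_c sweeps ``theta_c_grid``.
    Coverage, the inhibitory fraction for odor A and p_both are held fixed;
    the y-axis sweeps p_flip, with the feedback similarity rho_fb reported
    for each row.  Marginal responsiveness is ``p_odor`` for both odors.
    Columns: theta_c, p_flip, rho_fb, q1, q2, regime.
    """
    p_minus = coverage * inhibitory_fraction
    p_plus = coverage - p_minus
    rows = []
    for theta_c in np.asarray(theta_c_grid, dtype=float):
        th = ThresholdSpec(theta_m=th_base.theta_m, theta_c=float(theta_c), r_max=th_base.r_max)
        for p_flip in np.asarray(p_flip_grid, dtype=float):
            fb = FeedbackSpec(
                dr=dr, p_plus_a=p_plus, p_minus_a=p_minus,
                p_both=p_both, p_flip=float(p_flip),
            )
            q1, q2, _ = linear_coefficients(th, fb, n=1.0, n_a=p_odor, n_b=p_odor)
            rows.append(
                {
                    "theta_c": float(theta_c),
                    "p_flip": float(p_flip),
                    "rho_fb": fb.rho_fb,
                    "q1": q1,
                    "q2": q2,
                    "regime": classify_regime(q1, q2),
                }
            )
    return pd.DataFrame(rows)
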