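"""Finite-population Monte-Carlo simulator of modules and feedback.

Brute-force counterpart of :mod:`olfeedback.analytic`: draw ``N`` module
responses to an odor pair (jointly uniform within the threshold regions, or
Gaussian), assign feedback signs per the joint probability structure, apply
the rate changes, pass everything through a transfer function (step at
``theta_c``, sigmoid, or identity for a single-layer control) and measure
cosine similarities directly.  Used as the independent oracle for the
analytic linear law and for its numerical generalizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .analytic import FeedbackSpec, OdorPairCounts, ThresholdSpec
from .errors import UndefinedSimilarityError, ValidationError

__all__ = [
    "StepTransfer",
    "SigmoidTransfer",
    "IdentityTransfer",
    "PopulationSpec",
    "PopulationDraw",
    "sample_population",
    "assign_feedback",
    "empirical_similarity",
    "run_regression_experiment",
    "RegressionResult",
]

CASE_LABELS = (
    "none",
    "A-only+",
    "A-only-",
    "B-only+",
    "B-only-",
    "both-same",
    "both-flip",
)


# ---------------------------------------------------------------------------
# transfer functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepTransfer:
    """Binary gate: 1 iff the rate reaches the cortical threshold."""

    theta_c: float

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return (r >= self.theta_c).astype(float)


@dataclass(frozen=True)
class SigmoidTransfer:
    """Logistic gate with inflection at ``theta_c``.

    ``steepness`` is the logistic scale beta; the default makes the 10-90%
    rise span 10% of ``r_max`` (rise = beta * ln 81).
    """

    theta_c: float
    steepness: float

    @classmethod
    def for_range(cls, theta_c: float, r_max: float, rise_fraction: float = 0.1):
        return cls(theta_c=theta_c, steepness=rise_fraction * r_max / np.log(81.0))

    def __call__(self, r: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-(r - self.theta_c) / self.steepness))


@dataclass(frozen=True)
class IdentityTransfer:
    """Single-layer control: the bulb rates are read out directly."""

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return np.asarray(r, dtype=float)


# ---------------------------------------------------------------------------
# population specification and draws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """Module count plus the response and feedback distribution families.

    ``response_model`` is "uniform" (jointly uniform within the four
    threshold regions given exact counts) or "gaussian" (iid normal
    responses with a configurable shared fraction between the two odors).
    ``feedback_model`` is "fixed" (constant magnitude ``fb.dr``) or
    "gaussian" (magnitudes drawn per module and odor).  ``sigma1`` /
    ``sigma2`` are standard deviations by default; set ``sigmas_are_sd``
    False to read them as variances.
    """

    n: int
    response_model: str = "uniform"
    thresholds: ThresholdSpec | None = None  # required by the uniform model
    mu1: float = 1.15
    sigma1: float = 0.42
    feedback_model: str = "fixed"
    mu2: float = 0.57
    sigma2: float = 0.28
    sigmas_are_sd: bool = True
    shared_fraction: float = 0.0  # gaussian model: fraction of modules with identical responses

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError(f"population size n must be positive, got {self.n}")
        if self.response_model == "uniform" and self.thresholds is None:
            raise ValidationError("uniform response model requires thresholds")
        if self.response_model not in ("uniform", "gaussian"):
            raise ValidationError(f"unknown response_model {self.response_model!r}")
        if self.feedback_model not in ("fixed", "gaussian"):
            raise ValidationError(f"unknown feedback_model {self.feedback_model!r}")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValidationError("gaussian sigmas must be positive")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValidationError("shared_fraction must lie in [0, 1]")

    @property
    def sd1(self) -> float:
        return self.sigma1 if self.sigmas_are_sd else float(np.sqrt(self.sigma1))

    @property
    def sd2(self) -> float:
        return self.sigma2 if self.sigmas_are_sd else float(np.sqrt(self.sigma2))


@dataclass
class PopulationDraw:
    """One realization: responses, feedback changes and per-module case labels."""

    responses: np.ndarray  # (n, 2)
    changes: np.ndarray  # (n, 2)
    cases: np.ndarray  # (n,) int index into CASE_LABELS
    case_labels: tuple[str, ...] = field(default=CASE_LABELS)


def assign_feedback(
    n: int, fb: FeedbackSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-module feedback signs for the odor pair.

    Returns integer sign arrays (values -1, 0, +1) for odors A and B and the
    case-label index array.  The assignment realizes the conditional
    structure behind the joint probabilities: a module is affected for A with
    probability ``coverage``; given that, it is affected for B with
    probability ``p_both`` with the B sign flipping with conditional
    probability ``p_flip / p_both``; modules unaffected for A receive B
    feedback at the rate required by coverage equality, with the same sign
    split as the shared modules.
    """
    cov = fb.coverage
    sign_a = np.zeros(n, dtype=np.int8)
    sign_b = np.zeros(n, dtype=np.int8)

    u = rng.random(n)
    hit_a = u < cov
    n_hit = int(hit_a.sum())
    if cov > 0:
        plus_a = rng.random(n_hit) < fb.p_plus_a / cov
        sign_a[hit_a] = np.where(plus_a, 1, -1).astype(np.int8)

    # B feedback on A-affected modules
    if n_hit and fb.p_both > 0:
        both = rng.random(n_hit) < fb.p_both
        flip = rng.random(n_hit) < (fb.p_flip / fb.p_both)
        sb = np.where(both, np.where(flip, -1, 1), 0).astype(np.int8)
        sign_b[hit_a] = sb * sign_a[hit_a]

    # B feedback on A-unaffected modules, honoring coverage equality
    miss_a = ~hit_a
    n_miss = int(miss_a.sum())
    if n_miss and cov > 0 and cov < 1.0:
        p_b_only = cov * (1.0 - fb.p_both) / (1.0 - cov)
        hit_b = rng.random(n_miss) < p_b_only
        if fb.p_both > 0:
            frac_plus_b = fb.p_plus_b / cov
        else:
            frac_plus_b = fb.p_plus_a / cov if cov > 0 else 0.5
        plus_b = rng.random(n_miss) < frac_plus_b
        sign_b[miss_a] = np.where(hit_b, np.where(plus_b, 1, -1), 0).astype(np.int8)

    cases = np.zeros(n, dtype=np.int8)
    a, b = sign_a != 0, sign_b != 0
    cases[a & ~b & (sign_a > 0)] = 1
    cases[a & ~b & (sign_a < 0)] = 2
    cases[~a & b & (sign_b > 0)] = 3
    cases[~a & b & (sign_b < 0)] = 4
    cases[a & b & (sign_a == sign_b)] = 5
    cases[a & b & (sign_a != sign_b)] = 6
    return sign_a, sign_b, cases


def _uniform_region_responses(
    counts: OdorPairCounts, th: ThresholdSpec, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(counts.n))
    n_a, n_b, n_ab = int(round(counts.n_a)), int(round(counts.n_b)), int(round(counts.n_ab))
    n_ao = n_a - n_ab  # responsive to A only
    n_bo = n_b - n_ab
    n_no = n - n_a - n_b + n_ab
    if min(n_ao, n_bo, n_no, n_ab) < 0:
        raise ValidationError(
            f"infeasible counts: region sizes ({n_ab}, {n_ao}, {n_bo}, {n_no})"
        )
    lo, hi, top = 0.0, th.theta_m, th.r_max
    r = np.empty((n, 2))
    blocks = [
        (n_ab, (hi, top), (hi, top)),
        (n_ao, (hi, top), (lo, hi)),
        (n_bo, (lo, hi), (hi, top)),
        (n_no, (lo, hi), (lo, hi)),
    ]
    i = 0
    for size, (a0, a1), (b0, b1) in blocks:
        r[i : i + size, 0] = rng.uniform(a0, a1, size)
        r[i : i + size, 1] = rng.uniform(b0, b1, size)
        i += size
    return r


def sample_population(
    pop: PopulationSpec,
    counts: OdorPairCounts | None,
    fb: FeedbackSpec,
    rng: np.random.Generator | int,
) -> PopulationDraw:
    """Draw responses and feedback changes for one odor pair.

    For the uniform-by-region model the region memberships equal the
    requested counts exactly (the randomness is within-region placement).
    For the Gaussian model, ``pop.shared_fraction`` of the modules respond
    identically to the two odors and the rest independently.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if pop.response_model == "uniform":
        if counts is None:
            raise ValidationError("uniform response model requires counts")
        responses = _uniform_region_responses(counts, pop.thresholds, rng)
    else:
        n_shared = int(round(pop.shared_fraction * pop.n))
        ra = rng.normal(pop.mu1, pop.sd1, pop.n)
        rb = rng.normal(pop.mu1, pop.sd1, pop.n)
        rb[:n_shared] = ra[:n_shared]
        responses = np.column_stack([ra, rb])

    sign_a, sign_b, cases = assign_feedback(pop.n, fb, rng)
    if pop.feedback_model == "fixed":
        mag = np.full((pop.n, 2), fb.dr)
    else:
        mag = rng.normal(pop.mu2, pop.sd2, (pop.n, 2))
    changes = mag * np.column_stack([sign_a, sign_b])
    return PopulationDraw(responses=responses, changes=changes, cases=cases)


def empirical_similarity(
    draw: PopulationDraw, transfer: Callable[[np.ndarray], np.ndarray]
) -> tuple[float, float, float]:
    """(rho_i, rho_f, delta_rho) via cosine similarity of transferred vectors."""
    k_before = np.column_stack(
        [transfer(draw.responses[:, 0]), transfer(draw.responses[:, 1])]
    )
    after = draw.responses + draw.changes
    k_after = np.column_stack([transfer(after[:, 0]), transfer(after[:, 1])])
    rho_i = _cosine(k_before[:, 0], k_before[:, 1])
    rho_f = _cosine(k_after[:, 0], k_after[:, 1])
    return rho_i, rho_f, rho_f - rho_i


def _cosine(v: np.ndarray, w: np.ndarray) -> float:
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        raise UndefinedSimilarityError("cosine similarity of a zero vector is undefined")
    return float(v @ w / (nv * nw))


# ---------------------------------------------------------------------------
# regression experiments (numerical generalizations)
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Per-pair scatter, quantile-binned means and the least-squares line."""

    points: pd.DataFrame  # columns: rho_i, delta_rho, condition value
    binned: pd.DataFrame  # columns: rho_i_mean, delta_rho_mean, sem, n
    slope: float
    intercept: float
    r_value: float

    @property
    def r_squared(self) -> float:
        return self.r_value**2


def run_regression_experiment(
    pop: PopulationSpec,
    fb: FeedbackSpec,
    transfer: Callable[[np.ndarray], np.ndarray],
    similarity_grid: np.ndarray,
    trials: int,
    rng: np.random.Generator | int,
    counts_for: Callable[[float], OdorPairCounts] | None = None,
    min_bin: int = 10,
) -> RegressionResult:
    """Scatter and fit of delta_rho against rho_i over a similarity grid.

    ``similarity_grid`` parameterizes odor-pair generation: for the Gaussian
    model it is the shared-module fraction; for the uniform model it is
    passed to ``counts_for`` which must return the region counts.  Each grid
    value is realized ``trials`` times.  Points are binned into quantile bins
    of rho_i with at least ``min_bin`` pairs per bin (mirroring grouped
    averaging of pairs with close similarity values); the fitted line is
    least squares over the raw points.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    grid = np.asarray(similarity_grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("similarity grid must be nonempty")
    rows = []
    for g in grid:
        for _ in range(trials):
            if pop.response_model == "gaussian":
                pop_g = PopulationSpec(
                    n=pop.n, response_model="gaussian", mu1=pop.mu1, sigma1=pop.sigma1,
                    feedback_model=pop.feedback_model, mu2=pop.mu2, sigma2=pop.sigma2,
                    sigmas_are_sd=pop.sigmas_are_sd, shared_fraction=float(g),
                )
                draw = sample_population(pop_g, None, fb, rng)
            else:
                counts = counts_for(float(g))  # type: ignore[misc]
                draw = sample_population(pop, counts, fb, rng)
            rho_i, _, d_rho = empirical_similarity(draw, transfer)
            rows.append({"condition": float(g), "rho_i": rho_i, "delta_rho": d_rho})
    points = pd.DataFrame(rows)

    n_bins = max(1, min(len(points) // max(min_bin, 1), 20))
    q = pd.qcut(points["rho_i"], q=n_bins, duplicates="drop")
    binned = (
        points.groupby(q, observed=True)
        .agg(
            rho_i_mean=("rho_i", "mean"),
            delta_rho_mean=("delta_rho", "mean"),
            sem=("delta_rho", "sem"),
            n=("delta_rho", "size"),
        )
        .reset_index(drop=True)
    )
    if points["rho_i"].nunique() > 1:
        fit = stats.linregress(points["rho_i"], points["delta_rho"])
        slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    else:
        slope, intercept, r = float("nan"), float(points["delta_rho"].mean()), float("nan")
    return RegressionResult(points=points, binned=binned, slope=slope,
                            intercept=intercept, r_value=r)
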