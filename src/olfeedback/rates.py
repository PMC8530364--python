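"""Distribution-based reduced model with a threshold-gated cortical readout.

Full spiking simulations of the bulb at the sizes needed for stable cortical
statistics (M > 8000 mitral cells, K > 80000 cortical units) are summarized
by three fitted firing-rate(-change) laws, all in spikes per sniff
(sniff = 1/6 s):

* odor-evoked MC rates: generalized Pareto (shape k, scale sigma, location
  theta), draws clipped at zero;
* direct excitatory feedback to MCs: zero-elevated skew normal (probability
  ``p_nz`` of a nonzero change, then skew normal (alpha, omega, xi));
* disynaptic inhibitory feedback through granule cells: a lognormal fitted
  to the spike losses, shifted and sign-flipped onto [-2, 0] and applied
  only to MCs firing at least 2 spikes per sniff (the maximum observed loss
  being 2 spikes).

Large odor/feedback ensembles drawn from these laws drive a random cortical
readout: each of K units sums the rates of round(q M) randomly sampled MCs,
the mean cortical input is subtracted (balancing), and a sigmoid gate is
applied whose threshold is calibrated either high (a target fraction of
units strongly active, the sparse-coding regime) or low (broad activity,
the increased-excitability regime).  Cosine similarities of the cortical
vectors before/after feedback yield the pattern convergence/divergence
experiments: delta_rho against rho_i per feedback-similarity condition, and
the second-level regression of the per-condition slope against the feedback
similarity rho_FB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._seeds import child_seed
from .errors import ValidationError

__all__ = [
    "DistributionSet",
    "ReadoutSpec",
    "CorticalReadout",
    "ExperimentResult",
    "sample_odor_pair",
    "sample_feedback_pair",
    "cortical_readout",
    "run_similarity_experiment",
    "fit_generalized_pareto",
    "fit_zero_elevated_skew_normal",
    "fit_shifted_lognormal",
    "fit_rate_distributions",
    "cosine_similarity",
]

SNIFF_SECONDS = 1.0 / 6.0


def cosine_similarity(v: np.ndarray, w: np.ndarray) -> float:
    nv, nw = float(np.linalg.norm(v)), float(np.linalg.norm(w))
    if nv == 0.0 or nw == 0.0:
        raise ValidationError("cosine similarity of a zero vector is undefined")
    return float(v @ w / (nv * nw))


# ---------------------------------------------------------------------------
# fitted distribution laws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSet:
    """The three firing-rate(-change) laws, with packaged reference defaults.

    The shipped parameter values are the maximum-likelihood fits obtained
    from spiking simulations of a 3,550-MC / 53,250-GC network (8 odors,
    each targeting 20 of 178 glomeruli).  ``gc_shift_q`` records the affine
    map used to place the lognormal on its negative support: a draw x maps
    to ``-clip(x - x_q, 0, gc_loss_bound)`` with x_q the ``gc_shift_q``
    quantile of the fitted lognormal.
    """

    # odor-evoked rate: generalized Pareto
    odor_shape: float = -0.281
    odor_scale: float = 3.331
    odor_loc: float = -0.4
    # MC excitatory feedback change: zero-elevated skew normal
    mc_p_nonzero: float = 0.31
    mc_alpha: float = 4.232
    mc_omega: float = 2.687
    mc_xi: float = 0.7785
    # GC-mediated inhibitory change: shifted/flipped lognormal
    gc_mu: float = 0.7957
    gc_sigma: float = 0.2548
    gc_shift_q: float = 0.01
    gc_loss_bound: float = 2.0  # spikes per sniff
    gc_eligible_min: float = 2.0  # spikes per sniff

    def __post_init__(self) -> None:
        if not 0.0 <= self.mc_p_nonzero <= 1.0:
            raise ValidationError("mc_p_nonzero must lie in [0, 1]")
        if self.odor_scale <= 0 or self.mc_omega <= 0 or self.gc_sigma <= 0:
            raise ValidationError("scale parameters must be positive")
        if self.gc_loss_bound <= 0:
            raise ValidationError("gc_loss_bound must be positive")

    def sample_odor(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Odor-evoked rates (spikes/sniff); draws below zero are clipped."""
        x = stats.genpareto.rvs(
            c=self.odor_shape, loc=self.odor_loc, scale=self.odor_scale,
            size=size, random_state=rng,
        )
        return np.clip(x, 0.0, None)

    def sample_mc_change(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Direct-feedback rate changes: zero with prob 1 - p_nz, else skew normal."""
        nz = rng.random(size) < self.mc_p_nonzero
        out = np.zeros(size)
        n_nz = int(nz.sum())
        if n_nz:
            out[nz] = stats.skewnorm.rvs(
                a=self.mc_alpha, loc=self.mc_xi, scale=self.mc_omega,
                size=n_nz, random_state=rng,
            )
        return out

    def sample_gc_change(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """GC-mediated changes: nonpositive, bounded below at -gc_loss_bound."""
        x = stats.lognorm.rvs(
            s=self.gc_sigma, scale=math.exp(self.gc_mu), size=size, random_state=rng
        )
        x_q = stats.lognorm.ppf(self.gc_shift_q, s=self.gc_sigma,
                                scale=math.exp(self.gc_mu))
        return -np.clip(x - x_q, 0.0, self.gc_loss_bound)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_generalized_pareto(x: np.ndarray, min_samples: int = 50) -> tuple[float, float, float]:
    """Fit (shape k, scale sigma, location theta) to rate data.

    The location (threshold) parameter makes the full MLE non-regular, so
    it is profiled out as the sample minimum (its MLE converges there from
    above at rate 1/n) and shape/scale are maximum-likelihood with the
    location held fixed.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < min_samples:
        raise ValidationError("too few samples for a generalized Pareto fit")
    loc = float(x.min()) - 1e-9
    c, _, scale = stats.genpareto.fit(x, floc=loc)
    return float(c), float(scale), float(loc)


def fit_zero_elevated_skew_normal(
    changes: np.ndarray, zero_tol: float = 1e-9, min_samples: int = 50
) -> tuple[float, float, float, float]:
    """(p_nz, alpha, omega, xi): zero fraction separate, skew normal on the rest."""
    changes = np.asarray(changes, dtype=float)
    nz = changes[np.abs(changes) > zero_tol]
    p_nz = len(nz) / len(changes) if len(changes) else 0.0
    if p_nz == 0.0:
        return 0.0, float("nan"), float("nan"), float("nan")
    if len(nz) < min_samples:
        raise ValidationError("too few nonzero samples for a skew normal fit")
    a, loc, scale = stats.skewnorm.fit(nz)
    return float(p_nz), float(a), float(scale), float(loc)


def fit_shifted_lognormal(losses: np.ndarray, min_samples: int = 50) -> tuple[float, float, float]:
    """(mu, sigma, loc) of a shifted lognormal fitted to positive spike losses."""
    losses = np.asarray(losses, dtype=float)
    losses = losses[losses > 0]
    if len(losses) < min_samples:
        raise ValidationError("too few positive losses for a lognormal fit")
    s, loc, scale = stats.lognorm.fit(losses)
    return float(math.log(scale)), float(s), float(loc)


def fit_rate_distributions(
    odor_rates: np.ndarray,
    mc_changes: np.ndarray | None = None,
    gc_changes: np.ndarray | None = None,
    eligible_rates: np.ndarray | None = None,
    defaults: DistributionSet | None = None,
    min_samples: int = 50,
) -> tuple[DistributionSet, dict]:
    """Fit the three laws from spiking-run summaries (all in spikes/sniff).

    ``odor_rates``: odor-evoked MC rates; ``mc_changes``: rate changes under
    direct MC feedback; ``gc_changes``: rate changes under GC feedback, with
    ``eligible_rates`` the corresponding baseline rates (the lognormal is
    fitted only over MCs at or above the eligibility minimum).  Returns a
    DistributionSet carrying the fitted values (unfitted laws keep the
    packaged defaults) plus a detail dict.
    """
    d = defaults or DistributionSet()
    detail: dict = {}
    k, sig, th = fit_generalized_pareto(odor_rates, min_samples=min_samples)
    detail["odor"] = {"shape": k, "scale": sig, "loc": th, "n": len(odor_rates)}
    kwargs = dict(odor_shape=k, odor_scale=sig, odor_loc=th)
    if mc_changes is not None:
        p_nz, a, w, xi = fit_zero_elevated_skew_normal(mc_changes,
                                                       min_samples=min_samples)
        detail["mc_feedback"] = {
            "p_nonzero": p_nz, "alpha": a, "omega": w, "xi": xi, "n": len(mc_changes),
        }
        if p_nz > 0:
            kwargs.update(mc_p_nonzero=p_nz, mc_alpha=a, mc_omega=w, mc_xi=xi)
        else:
            kwargs.update(mc_p_nonzero=0.0)
    if gc_changes is not None:
        gc_changes = np.asarray(gc_changes, dtype=float)
        if eligible_rates is not None:
            mask = np.asarray(eligible_rates) >= d.gc_eligible_min
            gc_changes = gc_changes[mask]
        mu, sigma, loc = fit_shifted_lognormal(-gc_changes, min_samples=min_samples)
        detail["gc_feedback"] = {"mu": mu, "sigma": sigma, "loc": loc,
                                 "n": len(gc_changes)}
        kwargs.update(gc_mu=mu, gc_sigma=sigma)
    fitted = DistributionSet(
        **{
            **{f: getattr(d, f) for f in d.__dataclass_fields__},
            **kwargs,
        }
    )
    return fitted, detail


# ---------------------------------------------------------------------------
# cortical readout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadoutSpec:
    """Sizes and gating regime of the random cortical readout.

    Reference scale: 10,000 MCs in 500 glomeruli, 100,000 cortical units
    each sampling 7% of the MCs, odors targeting 12% of the glomeruli and
    positive feedback targeting 8% of the MCs.
    """

    m: int = 10_000
    k_units: int = 100_000
    g: int = 500
    q: float = 0.07
    f_odor: float = 0.12
    p_fb: float = 0.08
    regime: str = "high"  # "high" (sparse) or "low" (broad activity)
    active_fraction: float = 0.10  # high-regime strongly-active target
    low_quantile: float = 0.50  # low-regime threshold quantile
    rise_fraction: float = 0.10  # sigmoid 10-90% rise as a fraction of input range

    def __post_init__(self) -> None:
        for name in ("q", "f_odor", "p_fb"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.m <= 0 or self.k_units <= 0 or self.g <= 0:
            raise ValidationError("m, k_units and g must be positive")
        if self.m % self.g != 0:
            raise ValidationError("m must be divisible by g (equal glomeruli)")
        if round(self.q * self.m) < 1:
            raise ValidationError("round(q*m) must be at least 1")
        if self.regime not in ("high", "low"):
            raise ValidationError(f"regime must be 'high' or 'low', got {self.regime!r}")

    @property
    def mcs_per_glomerulus(self) -> int:
        return self.m // self.g

    @property
    def mcs_per_unit(self) -> int:
        return int(round(self.q * self.m))

    @property
    def glomeruli_per_odor(self) -> int:
        return int(round(self.f_odor * self.g))

    def glomerulus_members(self, glom: int) -> slice:
        w = self.mcs_per_glomerulus
        return slice(glom * w, (glom + 1) * w)


class CorticalReadout:
    """Fixed random sampling of MCs by cortical units, plus the gated transfer.

    The sampling (round(q m) MCs per unit, without replacement) is drawn
    once from the seed and shared across all odors and feedback conditions
    so that pre/post vectors are comparable.  The sigmoid threshold/steepness
    are calibrated against a pool of baseline inputs via :meth:`calibrate`.
    """

    def __init__(self, spec: ReadoutSpec, seed: int | np.random.SeedSequence):
        self.spec = spec
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        rng = np.random.Generator(np.random.PCG64(ss))
        k, m, n_s = spec.k_units, spec.m, spec.mcs_per_unit
        # sample n_s of m without replacement per unit, chunked to bound the
        # transient key matrix; indices stored int32 and row-sorted (canonical CSR)
        chunk = max(1, min(k, int(2e7) // m))
        indices = np.empty(k * n_s, dtype=np.int32)
        for start in range(0, k, chunk):
            nc = min(chunk, k - start)
            keys = rng.random((nc, m), dtype=np.float32)
            part = np.argpartition(keys, n_s - 1, axis=1)[:, :n_s]
            part = np.sort(part.astype(np.int32), axis=1)
            indices[start * n_s : (start + nc) * n_s] = part.ravel()
        indptr = (np.arange(k + 1, dtype=np.int32) * n_s).astype(np.int32)
        data = np.ones(k * n_s, dtype=np.float32)
        self.sampling = sparse.csr_matrix((data, indices, indptr), shape=(k, m))
        self.theta: float | None = None
        self.beta: float | None = None

    def inputs(
        self, rates: np.ndarray, offset: np.ndarray | float | None = None
    ) -> np.ndarray:
        """Balanced cortical inputs: sampled-rate sums minus the mean input.

        ``rates`` is (m,) or (m, n_vectors).  With ``offset=None`` each
        vector's own mean over units is subtracted (cortical balancing of
        odor intensity).  Post-feedback vectors must instead pass their
        baseline odor vector's mean as ``offset``: balancing normalizes the
        odor drive, while a feedback-induced common shift of the cortical
        input survives relative to the calibrated gate (it is this shift
        that implements the effective threshold change of correlated
        feedback).
        """
        r = np.asarray(rates, dtype=np.float32)
        one_d = r.ndim == 1
        if one_d:
            r = r[:, None]
        u = self.sampling @ r
        if offset is None:
            u -= u.mean(axis=0, keepdims=True)
        else:
            u -= np.asarray(offset, dtype=np.float32)
        return u[:, 0] if one_d else u

    def calibrate(self, pooled_inputs: np.ndarray) -> tuple[float, float]:
        """Set the sigmoid steepness (and reference threshold) from baseline inputs.

        The threshold quantile — (1 - active_fraction) in the high regime so
        the target fraction of units is strongly active, ``low_quantile`` in
        the low-excitability regime — is applied per response vector by
        :meth:`activity_from_inputs`, implementing competitive normalization
        of cortical activity.  Steepness: the 10-90% sigmoid rise spans
        ``rise_fraction`` of the robust baseline input range (1st-99th
        percentile), fixed across conditions.
        """
        x = np.asarray(pooled_inputs, dtype=float).ravel()
        self.theta = float(np.quantile(x, self._quantile))
        q01, q99 = np.quantile(x, [0.01, 0.99])
        span = max(float(q99 - q01), 1e-12)
        self.beta = self.spec.rise_fraction * span / math.log(81.0)
        return self.theta, self.beta

    @property
    def _quantile(self) -> float:
        if self.spec.regime == "high":
            return 1.0 - self.spec.active_fraction
        return self.spec.low_quantile

    def activity(
        self, rates: np.ndarray, offset: np.ndarray | float | None = None
    ) -> np.ndarray:
        """Cortical activity: sigmoid gate over the balanced inputs."""
        return self.activity_from_inputs(self.inputs(rates, offset=offset))

    def activity_from_inputs(self, u: np.ndarray) -> np.ndarray:
        """Sigmoid gate with the threshold taken per response vector.

        Each vector's threshold sits at its own input quantile (the target
        strongly-active fraction), so cortical sparseness is maintained
        across feedback conditions — a competitive normalization; the
        steepness is fixed by :meth:`calibrate`.
        """
        if self.beta is None:
            raise ValidationError("readout not calibrated; call calibrate() first")
        u = np.asarray(u, dtype=float)
        theta = np.quantile(u, self._quantile, axis=0, keepdims=u.ndim > 1)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-(u - theta) / self.beta))


def cortical_readout(
    rates: np.ndarray, spec: ReadoutSpec, seed: int
) -> np.ndarray:
    """One-shot readout of a single rate vector (self-calibrated)."""
    ro = CorticalReadout(spec, seed)
    u = ro.inputs(rates)
    ro.calibrate(u)
    return ro.activity_from_inputs(u)


# ---------------------------------------------------------------------------
# odor and feedback ensembles
# ---------------------------------------------------------------------------


def sample_odor_pair(
    spec: ReadoutSpec,
    dists: DistributionSet,
    overlap: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rate vectors (length m) for two odors sharing a glomerulus fraction.

    Each odor targets round(f_odor g) glomeruli; ``overlap`` is the shared
    fraction of those targets.  Shared glomeruli carry identical rate draws
    for both odors (so overlap 1 gives identical vectors); MCs outside the
    targeted glomeruli are exactly zero.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValidationError(f"overlap must lie in [0, 1], got {overlap}")
    n_t = spec.glomeruli_per_odor
    n_shared = int(round(overlap * n_t))
    need = 2 * n_t - n_shared
    if need > spec.g:
        raise ValidationError(
            f"odor pair needs {need} distinct glomeruli but only {spec.g} exist"
        )
    perm = rng.permutation(spec.g)
    shared = perm[:n_shared]
    only_a = perm[n_shared : n_t]
    only_b = perm[n_t : need]
    ra = np.zeros(spec.m)
    rb = np.zeros(spec.m)
    w = spec.mcs_per_glomerulus
    for glom in shared:
        draws = dists.sample_odor(w, rng)
        ra[spec.glomerulus_members(glom)] = draws
        rb[spec.glomerulus_members(glom)] = draws
    for glom in only_a:
        ra[spec.glomerulus_members(glom)] = dists.sample_odor(w, rng)
    for glom in only_b:
        rb[spec.glomerulus_members(glom)] = dists.sample_odor(w, rng)
    meta = {"shared": shared, "only_a": only_a, "only_b": only_b}
    return ra, rb, meta


def sample_feedback_pair(
    spec: ReadoutSpec,
    dists: DistributionSet,
    kind: str,
    share: float,
    rng: np.random.Generator,
    rates_a: np.ndarray | None = None,
    rates_b: np.ndarray | None = None,
    responsive_only: bool = True,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-MC rate-change vectors for the two odors' contexts.

    ``share`` in [0, 1] controls the similarity of the two change vectors:
    that fraction of targets/draws is common to both contexts (identical
    values), the remainder independent.  With ``responsive_only`` (default)
    a feedback-induced rate change materializes only on MCs that are
    odor-responsive in that context (rate > 0): the change laws were fitted
    on rate changes during combined odor-plus-feedback drive, and feedback
    modulating silent mitral cells cannot move their evoked rate.  This
    gating is what keeps the high-threshold regime intact (feedback cannot
    summon cortical activity out of odor-silent channels); set it False to
    let the changes reach every targeted MC.  Kinds:

    * ``mc_exc``: round(p_fb m) target MCs, zero-elevated skew-normal draws;
      unshared targets are disjoint between the contexts.
    * ``gc_inh``: negative shifted-lognormal changes applied to every
      eligible MC (baseline rate >= the eligibility minimum, so the rate
      vectors are required); sharing controls the draw overlap.
    * ``combined``: the excitatory pattern plus GC inhibition of all
      eligible MCs with fully shared draws — excitatory feedback to MCs
      necessarily recruits disynaptic inhibition through the granule-cell
      network, and that inhibition is diffuse and highly correlated across
      contexts; ``share`` varies only the excitatory component.
    * ``mixed``: excitatory for odor A, GC-inhibitory for odor B.

    Returns (delta_a, delta_b, realized cosine similarity of the net changes).
    """
    if kind not in ("mc_exc", "gc_inh", "combined", "mixed"):
        raise ValidationError(f"unknown feedback kind {kind!r}")
    if not 0.0 <= share <= 1.0:
        raise ValidationError(f"share must lie in [0, 1], got {share}")

    def excitatory_pair() -> tuple[np.ndarray, np.ndarray]:
        n_t = int(round(spec.p_fb * spec.m))
        n_sh = int(round(share * n_t))
        need = 2 * n_t - n_sh
        perm = rng.permutation(spec.m)[:need]
        shared, pa, pb = perm[:n_sh], perm[n_sh:n_t], perm[n_t:]
        da = np.zeros(spec.m)
        db = np.zeros(spec.m)
        common = dists.sample_mc_change(n_sh, rng)
        da[shared] = common
        db[shared] = common
        da[pa] = dists.sample_mc_change(len(pa), rng)
        db[pb] = dists.sample_mc_change(len(pb), rng)
        return da, db

    def inhibitory(rates: np.ndarray, common_draws: np.ndarray,
                   shared_mask: np.ndarray) -> np.ndarray:
        delta = np.where(shared_mask, common_draws,
                         dists.sample_gc_change(spec.m, rng))
        delta = delta.copy()
        delta[np.asarray(rates) < dists.gc_eligible_min] = 0.0
        return delta

    if responsive_only and kind in ("mc_exc", "combined", "mixed"):
        if rates_a is None or rates_b is None:
            raise ValidationError(
                "responsive_only feedback gating requires the baseline rate vectors"
            )

    if kind == "mc_exc":
        da, db = excitatory_pair()
        if responsive_only:
            da = np.where(np.asarray(rates_a) > 0, da, 0.0)
            db = np.where(np.asarray(rates_b) > 0, db, 0.0)
    elif kind == "gc_inh":
        if rates_a is None or rates_b is None:
            raise ValidationError("gc_inh feedback requires the baseline rate vectors")
        shared_mask = rng.random(spec.m) < share
        common = dists.sample_gc_change(spec.m, rng)
        da = inhibitory(rates_a, common, shared_mask)
        db = inhibitory(rates_b, common, shared_mask)
    elif kind == "combined":
        if rates_a is None or rates_b is None:
            raise ValidationError("combined feedback requires the baseline rate vectors")
        da, db = excitatory_pair()
        if responsive_only:
            da = np.where(np.asarray(rates_a) > 0, da, 0.0)
            db = np.where(np.asarray(rates_b) > 0, db, 0.0)
        shared_mask = np.ones(spec.m, dtype=bool)
        common = dists.sample_gc_change(spec.m, rng)
        da = da + inhibitory(rates_a, common, shared_mask)
        db = db + inhibitory(rates_b, common, shared_mask)
    else:  # mixed
        if rates_b is None:
            raise ValidationError("mixed feedback requires the baseline rate vector for B")
        da, _ = excitatory_pair()
        if responsive_only:
            da = np.where(np.asarray(rates_a) > 0, da, 0.0)
        shared_mask = np.zeros(spec.m, dtype=bool)
        db = inhibitory(rates_b, np.zeros(spec.m), shared_mask)

    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    rho_fb = float(da @ db / (na * nb)) if na > 0 and nb > 0 else 0.0
    return da, db, rho_fb


# ---------------------------------------------------------------------------
# similarity experiments
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    """Per-pair rows, per-condition linear fits and the second-level fit."""

    rows: pd.DataFrame
    condition_fits: pd.DataFrame
    second_level: dict | None = None
    calibration: dict = field(default_factory=dict)


def run_similarity_experiment(
    spec: ReadoutSpec,
    dists: DistributionSet,
    overlap_grid: np.ndarray,
    share_grid: np.ndarray,
    kind: str = "combined",
    repeats: int = 2,
    seed: int = 0,
    responsive_only: bool = True,
) -> ExperimentResult:
    """The in-silico pattern convergence/divergence experiment.

    For each glomerular-overlap value (x ``repeats``), a pair of odor rate
    vectors is drawn and read out; for each feedback-share condition the
    post-feedback vectors are read out with the same sampling and gating.
    Per condition, delta_rho is regressed on rho_i; across conditions the
    per-condition slope is regressed on the mean realized feedback
    similarity (the second-level law).
    """
    overlap_grid = np.asarray(overlap_grid, dtype=float)
    share_grid = np.asarray(share_grid, dtype=float)
    if overlap_grid.size == 0 or share_grid.size == 0:
        raise ValidationError("overlap and share grids must be nonempty")

    readout = CorticalReadout(spec, child_seed(seed, "sampling"))
    pair_rng = np.random.Generator(np.random.PCG64(child_seed(seed, "pairs")))
    fb_rng = np.random.Generator(np.random.PCG64(child_seed(seed, "feedback")))

    pairs = []
    for overlap in overlap_grid:
        for rep in range(repeats):
            ra, rb, _ = sample_odor_pair(spec, dists, float(overlap), pair_rng)
            pairs.append((float(overlap), rep, ra, rb))

    # baseline inputs, balanced by their own means and pooled for calibration;
    # the same means later balance the post-feedback inputs so that a common
    # feedback-induced input shift survives relative to the calibrated gate
    base = np.column_stack([np.column_stack([ra, rb]) for _, _, ra, rb in pairs])
    u_raw = readout.sampling @ base.astype(np.float32)  # (K, 2 * n_pairs)
    mu_base = u_raw.mean(axis=0, keepdims=True)
    u_base = u_raw - mu_base
    theta, beta = readout.calibrate(u_base)
    act_base = readout.activity_from_inputs(u_base)

    rows = []
    for ci, share in enumerate(share_grid):
        for pi, (overlap, rep, ra, rb) in enumerate(pairs):
            a0 = act_base[:, 2 * pi]
            b0 = act_base[:, 2 * pi + 1]
            rho_i = cosine_similarity(a0, b0)
            da, db, rho_fb = sample_feedback_pair(
                spec, dists, kind, float(share), fb_rng,
                rates_a=ra, rates_b=rb, responsive_only=responsive_only,
            )
            post = np.column_stack(
                [np.clip(ra + da, 0.0, None), np.clip(rb + db, 0.0, None)]
            )
            act_post = readout.activity(post, offset=mu_base[:, 2 * pi : 2 * pi + 2])
            rho_f = cosine_similarity(act_post[:, 0], act_post[:, 1])
            rows.append(
                {
                    "pair_id": pi,
                    "overlap": overlap,
                    "condition": float(share),
                    "rho_fb": rho_fb,
                    "rho_i": rho_i,
                    "rho_f": rho_f,
                    "delta_rho": rho_f - rho_i,
                    "kind": kind,
                    "seed": seed,
                }
            )
    table = pd.DataFrame(rows)

    fits = []
    for share, grp in table.groupby("condition"):
        if grp["rho_i"].nunique() > 2:
            fit = stats.linregress(grp["rho_i"], grp["delta_rho"])
            slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue) ** 2
        else:
            slope = intercept = r2 = float("nan")
        fits.append(
            {
                "condition": float(share),
                "rho_fb_mean": float(grp["rho_fb"].mean()),
                "slope": slope,
                "intercept": intercept,
                "r_squared": r2,
                "n_pairs": len(grp),
            }
        )
    condition_fits = pd.DataFrame(fits).sort_values("condition").reset_index(drop=True)

    second = None
    ok = condition_fits.dropna(subset=["slope"])
    if len(ok) >= 3 and ok["rho_fb_mean"].nunique() > 1:
        fit = stats.linregress(ok["rho_fb_mean"], ok["slope"])
        second = {
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r_squared": float(fit.rvalue) ** 2,
        }
    return ExperimentResult(
        rows=table,
        condition_fits=condition_fits,
        second_level=second,
        calibration={"theta": theta, "beta": beta, "regime": spec.regime},
    )
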