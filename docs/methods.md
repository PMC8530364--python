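# Methods

This note documents the models implemented in `olfeedback`, the choices made
where the underlying design was open, and what the synthetic test conditions
do and do not establish.

## The statistical model (`olfeedback.analytic`)

The olfactory bulb is reduced to `N` modules, each the set of mitral cells
(MCs) projecting to one piriform neuron. A module's response to an odor is a
rate `R ∈ (0, R_max)`; the module's cortical unit fires iff `R ≥ θ_c`
(coincidence gating) and the module counts as odor-responsive iff `R > θ_m`,
with `θ_m ≪ θ_c`. For an odor pair (A, B), responses are jointly uniform
within the four regions delimited by `θ_m`, so the counts of cortically
active modules are areas times region densities:

    C_A = (ΔR_c/ΔR_m) N_A,   C_AB = (ΔR_c/ΔR_m)² N_AB,
    ΔR_c = R_max − θ_c,  ΔR_m = R_max − θ_m,

and the initial cortical similarity (cosine of the binary activation
patterns) is `ρ_i = Q0 · N_AB/√(N_A N_B)` with `Q0 = ΔR_c/ΔR_m`. Note that
even fully overlapping odors (`N_AB = N_A = N_B`) have `ρ_i = Q0 < 1`: the
joint-uniform assumption makes the two responses of a doubly-responsive
module conditionally independent.

Contextual feedback perturbs each affected module's rate by `±ΔR`. Its joint
structure over the odor pair is specified by `(p₊^A, p₋^A, p_both, p_flip)`;
the B-side marginals follow from feedback-coverage equality and the two
independence assumptions, e.g. `p₊^B = (p_same p₊^A + p_flip p₋^A)/p_both`,
and the feedback similarity is `ρ_FB = p_both − 2 p_flip`. Two degenerate
corners need conventions: `p_flip^A = p_flip p₋^A / p₊^B` is `0/0` when
`p₊^B = 0` and is defined as 0 (every term that uses it carries a factor
`p₊^B`); `p_both = 0` leaves the B sign split unconstrained and defaults to
the A split.

The feedback-driven change in the doubly-active count decomposes into
fifteen cases indexed by which of the four rate bands
`(θ_c − ΔR, θ_m), (θ_m, θ_c), (θ_c, θ_c + ΔR), (θ_c + ΔR, R_max)` each
odor's response occupies; each term is a sign-pattern probability × region
area × region density. Cases involving the sub-`θ_m` band exist only when
`ΔR > θ_c − θ_m` (the Heaviside gate). The both-demoted case uses the
inclusion–exclusion probability `p₋^A + p₋^B − p₋^A p_same` (probability
that at least one feedback is negative).

The central result is the linear law `Δρ = Q2 ρ_i + Q1`. Because the
post-feedback numerator is affine in `N_AB` and the denominator is
`N_AB`-free, `(Q1, Q3)` are extracted *numerically exactly* from two probe
evaluations at feasible overlaps (plus a third probe verifying affinity to
1e−10), rather than by symbolic expansion of the fifteen cases. This makes
the implementation immune to transcription slips in any individual term,
and every term is separately validated against the Monte-Carlo population
oracle. `Q2 = Q3/Q0 − 1`.

Closed forms in the high-threshold regime `ΔR ≤ min(θ_c − θ_m, ΔR_c)`:
identical full positive feedback gives `Q2 = ΔR/ΔR_c` (an effective
threshold decrease), and fully opposite feedback gives
`Q2 = √(ΔR_c² − ΔR²)/ΔR_c − 1` (thresholds shifted in opposite directions;
the radical spans the full difference of squares, reconstructed from the
uniform-density geometry and verified against the general machinery to
1e−10 and against the population oracle).

Regime labels use `Q1 > 10⁻⁹` for "mixed"; `Q1` is exactly zero above the
gap, so the tolerance only guards floating-point noise. The phase diagram
sweeps `θ_c` and `p_flip` (not `ρ_FB` directly, which is a derived quantity
bounded by `p_both`), and reports `ρ_FB` per row. Within the reference
parameter set (coverage 0.5, inhibitory fraction 0.75, `p_both` 0.5,
`ΔR = R_max/5`, `p_odor = 0.6`), convergence appears only at cortical
thresholds in the experimentally realistic range — activating roughly 15%
to 3% of cortex, i.e. `θ_c ≈ 1.57–1.92` for `R_max = 2` — and only for
correlated feedback; anticorrelated feedback yields divergence, and any
`θ_c < θ_m + ΔR` yields mixed effects (`Q1 > 0`, `Q2 < 0`).

## The population oracle (`olfeedback.population`)

A brute-force realization of the same assumptions: region membership counts
are exact (randomness is only within-region placement), feedback signs are
assigned by the conditional scheme above, and similarities are measured as
cosines of transferred response vectors. The step transfer reproduces the
counting formula identically; sigmoid and identity transfers support the
numerical generalizations (Gaussian responses, graded gates, single-layer
control).

Gaussian conditions use mean 1.15 / SD 0.42 for odor responses and mean
0.57 / SD 0.28 for feedback magnitudes, with `θ_c = 1.6` (≈ 10–14% baseline
activation). The printed notation for these spreads is ambiguous between
SDs and variances; they are read as **SDs** because only that reading
reproduces the stated feedback similarity for identical-sign feedback with
independent amplitudes, `ρ_FB = μ₂²/(μ₂² + σ₂²) = 0.57²/(0.57² + 0.28²) ≈
0.81 ≈ 0.8` (the variance reading gives 0.54). The interpretation is
config-switchable (`sigmas_are_sd`).

Feedback magnitudes are drawn independently per module *and per odor* (this
is what makes `|ρ_FB| < 1` even for identical sign patterns); Gaussian
responses and magnitudes are not clipped — the transfer handles extremes.
Note that with these magnitudes the feedback mean (0.57) exceeds the
gap `θ_c − μ₁ = 0.45`, so the Gaussian setting sits in the saturating
regime in which convergence under identical feedback *decreases* with
initial similarity; the regression tests assert that reversal signature
rather than the uniform-model high-threshold one. "Close similarity"
averaging uses quantile bins of `ρ_i` with ≥ 10 pairs per bin.

## Geometric connectivity (`olfeedback.geometry`)

MC lateral dendritic trees are laminar discs with radial length density
`ρ_m(r)` (μm dendrite/μm²); granule cell (GC) trees are inverted cones
carrying spines with height profile `N_s(z)` (spines/μm). For a pair, the
dendritic length in the overlap is `l = ∫ ρ_m dA` over the lens where the
disc meets the cone cross-section at the disc's z-plane, computed by
adaptive polar quadrature (`∫ ρ_m(r) φ(r) r dr` with `φ` the included
angle, integration split at the geometric kinks); a fixed-grid trapezoid
variant serves bulk builds. The expected synapse count is
`λ = ρ_g(z_int) · q · π · l` with `ρ_g(z) = N_s(z)/(π r_cone(z)²)` taken
constant across the interaction shell, and the connection probability is
`1 − e^(−λ)` (at most one synapse per pair). Each realized synapse samples
its radial distance `L` from the soma with density `ρ_m(r) φ(r) r`, which
later attenuates GABA as `e^(−L/λ_length)`.

The shell cross-section constant defaults to the printed `q = 2.32 μm²`.
Recomputing it from the shell geometry, `(d_shell + r_dend)² − r_dend²`
with `d_shell = 1.02`, `r_dend = 0.5` μm, gives 2.0604 μm² instead; the
discrepancy is preserved, not silently fixed — both values are selectable
(`q_mode`).

The parametric shapes of `ρ_m` and `N_s` are not specified by their data
sources at the level needed here; the defaults are honest placeholders
calibrated by totals: a linearly decaying disc profile normalized to a
total lateral dendritic length of 15 mm per MC (disc radius 425 μm
default), and a piecewise-linear spine profile normalized to 150 spines
per GC, peaking toward the external plexiform layer. Both are
config-swappable, and the test suite validates the machinery through
integrals, limits and Monte-Carlo agreement rather than through profile
shapes. Coordinates are right-handed with z increasing from the deep
granule layer (0) toward the glomerular surface; Type I (deep, z = 270 μm)
and Type II (superficial, z = 310 μm) MC discs sit under their glomerular
columns; deep-type GC vertices occupy the lower half of the space.

## The spiking network (`olfeedback.spiking`)

Izhikevich dynamics `C dv/dt = k(v−v_r)(v−v_t) − u + I`,
`du/dt = a(b(v−v_r) − u)`, reset `v ← c, u ← u + d` at `v ≥ v_c`. MCs use
the class II parameter set (abrupt onset ≈ 5–10 Hz at threshold); GCs are
class I, with `(b, k)` mapping one-to-one onto input resistance `R` and
rheobase `ρ`: `k = 1/(4R²ρ)`, `b = (v_r − v_t + 4Rρ)/(4R²ρ)`, so the
implied `R` and `ρ` are recoverable from any sampled pair and are
constrained to `b < 0`, `ρ ∈ [10, 70]` pA, `R ∈ [0.25, 1.5]` GΩ.
Heterogeneity is Normal(mean, |mean|/10) for all parameters except GC
`(b, k)` which use SD = 2/3·|mean| under rejection. Rejection redraws the
*whole cell*: with an unlucky `(v_r, v_t)` pair the `(b, k)` window can be
unreachable, so constraining only `(b, k)` would deadlock. Enforcing
`v_r < v_t < v_c` truncates the voltage marginals slightly (~1 mV on MC
`v_r`); the tests quantify this against an independent rejection oracle.

Synapses are AMPA + NMDA (onto GCs) and GABA (onto MCs) conductances with
gating ODEs `ds/dt = −s/τ` (AMPA, GABA), the two-variable NMDA rise/decay
system, and the magnesium block `1/(1 + [Mg²⁺] e^(−0.062V)/3.57)` at 1 mM.
On an MC spike: `s ← s + W(1−s)` (W = 0.5) for AMPA and the NMDA rise
variable at its GC synapses, plus a κ-scaled GABA bump
`s ← s + κW(1−s)` at *every* MC synapse sharing those GCs — the
spike-independent (graded) granule release. This bump is applied in the
same integration step as the spike and includes the spiking MC's own
reciprocal synapses (dendrodendritic self-inhibition); multiple
simultaneous spikes compose multiplicatively,
`s ← 1 − (1−κW)^k (1−s)`. On a GC spike the full `W` bump applies at its
MC synapses. GABA current is attenuated by `e^(−L/λ_length)`
(λ_length = 675 μm). Within a step the order is: currents from
start-of-step gating → Euler membrane update → spike detection/reset →
gating decay → spike-triggered bumps.

Integration is forward Euler at dt = 0.1 ms. The fixture network's spike
counts change by at most one spike per neuron when dt is halved, and an
isolated GC at 1.05× rheobase matches a dt = 0.01 ms integration within
10%.

Odor input is a half-wave-rectified 6 Hz sinusoid (one sniff = 1/6 s) with
amplitude drawn once per glomerulus from U[300, 500] pA (per-MC draws are
config-selectable; a raised-cosine waveform likewise); feedback is a
constant pulse to a random fraction of MCs (U[0, 300] pA) and/or GCs
(U[0, 200] pA). The reference fractions — feedback to 1/5 of MCs and 1/8
of GCs — are configuration values, not hard-coded.

## The reduced rate model (`olfeedback.rates`)

Three fitted laws summarize the spiking tier, all in spikes per sniff:
odor-evoked MC rates ~ generalized Pareto (k = −0.281, σ = 3.331,
θ = −0.4; draws clipped at 0, an interpretation — the law's support dips
slightly below zero); direct excitatory feedback changes ~ zero-elevated
skew normal (p_nz = 0.31, α = 4.232, ω = 2.687, ξ = 0.7785); GC-mediated
inhibitory changes ~ lognormal (μ = 0.7957, σ = 0.2548) flipped onto
negative support. The flip/shift map is `x ↦ −clip(x − x₀.₀₁, 0, 2)` with
`x₀.₀₁` the 1% quantile of the fitted lognormal, honoring the observed
maximum loss of 2 spikes per sniff; the exact affine map is an
implementation choice recorded in the `DistributionSet` (`gc_shift_q`,
`gc_loss_bound`). Inhibitory changes apply only to MCs firing ≥ 2
spikes/sniff.

Refitting: the generalized-Pareto location is profiled as the sample
minimum (the free-location MLE is non-regular) with shape/scale ML at
fixed location; the zero fraction of the feedback law is estimated
separately from the skew-normal ML fit of the nonzero changes.

The cortical readout: `K` units each sum the rates of `round(qM)` MCs
sampled without replacement, fixed per experiment seed and shared across
odors and conditions. Balancing subtracts the mean cortical input of each
**baseline odor** vector — from that vector and from its post-feedback
version. Re-balancing each post-feedback vector by its own mean would
cancel exactly the common input shift through which correlated feedback
acts as an effective threshold change, severing the mechanism the model is
about. The gate is a sigmoid whose threshold sits at a per-vector input
quantile — the (1 − 0.10) quantile in the high-threshold (sparse-coding)
regime, the median in the low-threshold (raised-excitability) regime — a
competitive normalization that keeps cortical sparseness stable across
conditions; the steepness is fixed from the pooled baseline inputs (10–90%
rise spanning 10% of the robust input range).

Odor pairs: each odor targets `round(f_odor G)` glomeruli; shared glomeruli
carry identical per-MC draws (overlap 1 ⇒ identical vectors); untargeted
MCs are exactly 0. Feedback pairs: excitatory feedback targets
`round(p_FB M)` MCs with zero-elevated skew-normal draws, a `share`
fraction of targets/draws common to the two contexts; GC inhibition
applies to all eligible MCs with fully shared draws. The default
experiment condition (`kind="combined"`) superimposes both: excitatory
feedback to MCs necessarily recruits disynaptic inhibition through the
granule network, and that inhibition is diffuse and highly correlated
across contexts. `share` then varies only the excitatory component, and
the reported `ρ_FB` is the realized cosine of the net change vectors.

Feedback changes materialize only on odor-responsive MCs
(`responsive_only=True`, switchable): the change laws were fitted from
rate changes under combined odor-plus-feedback drive, and modulatory
feedback cannot move the evoked rate of an odor-silent channel. This
gating is what preserves the high-threshold regime in the reduced model
(near-zero intercepts; feedback cannot summon cortical activity from
odor-silent channels); applying the changes to all MCs regardless of odor
drive produces per-unit feedback fluctuations comparable to the gap
between the gate and the bulk of the input distribution, which pushes the
model into the mixed/low-threshold signature at any calibrated sparseness.

At the reference scale (M = 10,000, G = 500, K = 100,000, q = 0.07,
f_odor = 0.12, p_FB = 0.08), strongly correlated feedback yields pure
convergence whose magnitude grows with initial similarity at low-to-
moderate ρ_i and tapers toward zero as ρ_i → 1 (identical representations
cannot converge further — a ceiling the analytic tier avoids because its
ρ_i is capped at Q0 < 1); uncorrelated feedback yields divergence
increasing with ρ_i; and the per-condition slope is linear in the realized
feedback similarity (the second-level regression), with the low-threshold
regime reversing the correlated-feedback trend (negative slope, positive
intercept), sign-stably across seeds.

## Problem sizes and statistical conventions

Monte-Carlo oracle checks run at 10⁶ modules with ≈ 12 trials per setting
and 3-standard-error bands that account for the oracle's own sampling
noise; geometry quadrature checks use 4·10⁵-point importance samples inside
the cone cross-section. Reduced-model experiments use 6 glomerular-overlap
levels × 2 repeats × 6 feedback-share conditions per seed, averaged over 5
seeds. The scaled-down spiking demonstration (60 MCs, 240 GCs, one sniff)
exercises the fit pipeline end-to-end and reports bootstrap confidence
intervals; it is far below the 3,550-MC network behind the packaged
reference parameters, so its fitted values are reported, not asserted.

## Known limitations

* The uniform-response analytic tier holds ΔR constant across modules by
  construction; magnitude variability lives in the population tier.
* The dendritic-field profiles are calibrated by totals only; absolute
  connection probabilities inherit that uncertainty (the Poisson chain and
  its monotonicity/limits are what the tests pin down).
* The Gaussian-response reference conditions sit in the saturating-feedback
  regime (see above); conclusions there are about trend reversals, not the
  high-threshold linear law.
* Spiking-to-distribution fits at demonstration scale are illustrative; recovering
  the packaged parameter values requires the full-size network.
* No synaptic plasticity, conduction delays, tufted cells, periglomerular
  or deep short-axon cells; cortical recurrence is outside scope.
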