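"""Izhikevich spiking network of the mitral-granule cell circuit.

Membrane dynamics follow the two-variable Izhikevich model

    C dv/dt = k (v - v_r)(v - v_t) - u + I
      du/dt = a (b (v - v_r) - u),        v >= v_c  ->  v <- c, u <- u + d

with mitral cells (MCs) parameterized as class II (abrupt firing onset) and
granule cells (GCs) as class I, where the GC ``b`` and ``k`` map one-to-one
onto input resistance R and rheobase rho via

    k = 1 / (4 R^2 rho),    b = (v_r - v_t + 4 R rho) / (4 R^2 rho).

Dendrodendritic synapses carry AMPA + NMDA conductances onto GCs and a GABA
conductance back onto MCs, attenuated by ``exp(-L / lambda_length)`` with L
the synapse's somatic distance.  MC spikes bump the AMPA gating and the NMDA
rise variable at their GC synapses (s <- s + W (1 - s)) and additionally
apply a kappa-scaled GABA bump at every MC synapse sharing those GCs,
modeling spike-independent granule release; GC spikes apply the full GABA
bump at their MC synapses.  NMDA currents carry the magnesium-block factor
at [Mg2+] = 1 mM.  Integration is forward Euler, dt = 0.1 ms by default.

Odor input is an oscillatory current into the MCs of targeted glomeruli
(6 Hz respiratory rhythm, one sniff = 1/6 s); external feedback is a
constant current pulse to random subsets of MCs and/or GCs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .geometry import ConnectivityGraph

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "SynapseTable",
    "StimulusProgram",
    "Stimulus",
    "SpikeRecord",
    "MC_MEANS",
    "GC_MEANS",
    "SYNAPSE_MEANS",
    "sample_neuron_parameters",
    "sample_synapse_parameters",
    "make_stimulus",
    "simulate",
    "simulate_isolated",
    "gc_rheobase",
    "gc_input_resistance",
    "f_i_curve",
    "SNIFF_SECONDS",
]

SNIFF_SECONDS = 1.0 / 6.0  # one respiratory cycle at 6 Hz
V_SANITY = 1000.0  # mV, numerical blow-up bound


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich parameters for one cell (units as in the tables)."""

    k: float  # nS/mV
    a: float  # 1/ms
    b: float  # nS
    c: float  # mV
    d: float  # pA
    v_r: float  # mV
    v_t: float  # mV
    v_c: float  # mV
    cap: float  # pF
    cell_class: str = "MC"

    def __post_init__(self) -> None:
        if self.cap <= 0:
            raise ValidationError(f"membrane capacitance must be positive, got {self.cap}")
        if not self.v_r < self.v_t < self.v_c:
            raise ValidationError(
                f"v_r < v_t < v_c violated: {self.v_r}, {self.v_t}, {self.v_c}"
            )


MC_MEANS = NeuronParams(
    k=2.5, a=0.02, b=12.0, c=-70.0, d=13.0, v_r=-58.0, v_t=-49.0, v_c=30.0,
    cap=191.0, cell_class="MC",
)
GC_MEANS = NeuronParams(
    k=0.067, a=0.01, b=-0.133, c=-75.0, d=2.0, v_r=-71.0, v_t=-39.0, v_c=25.0,
    cap=48.0, cell_class="GC",
)


def gc_rheobase(p: NeuronParams) -> float:
    """Saddle-node current (pA) of a class I cell: (k (v_t - v_r) + b)^2 / 4k."""
    s = p.k * (p.v_t - p.v_r) + p.b
    return s * s / (4.0 * p.k)


def gc_input_resistance(p: NeuronParams) -> float:
    """Steady-state input resistance (GOhm) at rest: 1 / (k (v_t - v_r) + b)."""
    return 1.0 / (p.k * (p.v_t - p.v_r) + p.b)


def sample_neuron_parameters(
    cell_class: str,
    n: int,
    rng: np.random.Generator | int,
    means: NeuronParams | None = None,
    max_tries: int = 10_000,
) -> list[NeuronParams]:
    """Heterogeneous parameter draws around the table means.

    Every parameter is Normal(mean, |mean|/10), except GC ``b`` and ``k``
    which are Normal(mean, 2|mean|/3) rejection-sampled under b < 0, rheobase
    in [10, 70] pA and input resistance in [0.25, 1.5] GOhm (each evaluated
    with the cell's own sampled v_r, v_t).
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if cell_class not in ("MC", "GC"):
        raise ValidationError(f"cell_class must be 'MC' or 'GC', got {cell_class!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    mu = means or (MC_MEANS if cell_class == "MC" else GC_MEANS)

    def draw(mean: float, sd_frac: float = 0.1) -> float:
        return float(rng.normal(mean, abs(mean) * sd_frac))

    out: list[NeuronParams] = []
    for _ in range(n):
        for _tries in range(max_tries):
            a = draw(mu.a)
            c = draw(mu.c)
            d = draw(mu.d)
            v_r = draw(mu.v_r)
            v_t = draw(mu.v_t)
            v_c = draw(mu.v_c)
            cap = abs(draw(mu.cap))
            if not v_r < v_t < v_c:
                continue
            if cell_class == "MC":
                p = NeuronParams(k=draw(mu.k), a=a, b=draw(mu.b), c=c, d=d,
                                 v_r=v_r, v_t=v_t, v_c=v_c, cap=cap,
                                 cell_class="MC")
                break
            # GC: b and k use the wider spread and must satisfy b < 0 plus
            # the implied rheobase and input-resistance windows; with an
            # unlucky (v_r, v_t) the (b, k) window can be unreachable, so
            # the whole cell is redrawn, not just (b, k)
            b = draw(mu.b, 2.0 / 3.0)
            k = draw(mu.k, 2.0 / 3.0)
            if b >= 0.0 or k <= 0.0:
                continue
            slope = k * (v_t - v_r) + b
            if slope <= 0.0:
                continue
            rho = slope * slope / (4.0 * k)
            r_in = 1.0 / slope
            if not (10.0 <= rho <= 70.0 and 0.25 <= r_in <= 1.5):
                continue
            p = NeuronParams(k=k, a=a, b=b, c=c, d=d, v_r=v_r, v_t=v_t,
                             v_c=v_c, cap=cap, cell_class="GC")
            break
        else:
            raise RuntimeError(
                f"neuron parameter sampling exceeded {max_tries} tries; "
                "constraints infeasible with the given means"
            )
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# synapses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynapseParams:
    """Mean synaptic parameters (Table values) plus fixed constants."""

    g_ampa: float = 0.73  # nS
    g_nmda: float = 0.84  # nS
    g_gaba: float = 0.13  # nS
    kappa: float = 0.006  # dimensionless, spike-independent release scale
    tau_ampa: float = 5.5  # ms
    tau_nmda_rise: float = 10.0  # ms
    tau_nmda_decay: float = 80.0  # ms
    tau_gaba: float = 18.0  # ms
    lambda_length: float = 675.0  # um, GABA somatic attenuation constant
    alpha: float = 0.1  # 1/ms, NMDA rise coupling
    w: float = 0.5  # gating bump size
    e_exc: float = 0.0  # mV (AMPA and NMDA reversal)
    e_inh: float = -70.0  # mV
    mg: float = 1.0  # mM

    def __post_init__(self) -> None:
        for name in ("g_ampa", "g_nmda", "g_gaba", "tau_ampa", "tau_nmda_rise",
                     "tau_nmda_decay", "tau_gaba", "lambda_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 < self.kappa < 1.0:
            raise ValidationError(f"kappa must lie in (0, 1), got {self.kappa}")


@dataclass
class SynapseTable:
    """Per-edge heterogeneous parameters (arrays over graph edges)."""

    g_ampa: np.ndarray
    g_nmda: np.ndarray
    g_gaba: np.ndarray
    kappa: np.ndarray
    tau_ampa: np.ndarray
    tau_nmda_rise: np.ndarray
    tau_nmda_decay: np.ndarray
    tau_gaba: np.ndarray
    alpha: np.ndarray
    means: SynapseParams = field(default_factory=SynapseParams)


def sample_synapse_parameters(
    syn: SynapseParams, n_edges: int, rng: np.random.Generator | int
) -> SynapseTable:
    """Normal(mean, mean/10) per edge, truncated at zero from below."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    def draw(mean: float) -> np.ndarray:
        return np.clip(rng.normal(mean, 0.1 * mean, n_edges), 1e-12, None)

    return SynapseTable(
        g_ampa=draw(syn.g_ampa), g_nmda=draw(syn.g_nmda), g_gaba=draw(syn.g_gaba),
        kappa=np.clip(draw(syn.kappa), None, 1.0 - 1e-9),
        tau_ampa=draw(syn.tau_ampa), tau_nmda_rise=draw(syn.tau_nmda_rise),
        tau_nmda_decay=draw(syn.tau_nmda_decay), tau_gaba=draw(syn.tau_gaba),
        alpha=draw(syn.alpha), means=syn,
    )


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusProgram:
    """Odor and feedback current specification.

    Odor: MCs of targeted glomeruli receive an oscillatory current at the
    sniff frequency with amplitude drawn uniformly from ``odor_amp_range``
    (one draw per glomerulus by default).  Feedback: constant current pulses
    to a random fraction of MCs (amplitudes from ``fb_mc_amp_range``) and/or
    GCs (``fb_gc_amp_range``) during [onset, onset + duration).
    """

    odor_glomeruli: tuple[int, ...] = ()
    odor_amp_range: tuple[float, float] = (300.0, 500.0)  # pA
    amp_per_glomerulus: bool = True
    sniff_hz: float = 6.0
    waveform: str = "halfsine"  # or "raisedcos"
    fb_mc_fraction: float = 0.0  # 1/5 of MCs in the reference runs
    fb_mc_amp_range: tuple[float, float] = (0.0, 300.0)  # pA
    fb_gc_fraction: float = 0.0  # 1/8 of GCs in the reference runs
    fb_gc_amp_range: tuple[float, float] = (0.0, 200.0)  # pA
    fb_onset_ms: float = 0.0
    fb_duration_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.waveform not in ("halfsine", "raisedcos"):
            raise ValidationError(f"unknown waveform {self.waveform!r}")
        for name in ("fb_mc_fraction", "fb_gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.sniff_hz <= 0:
            raise ValidationError("sniff_hz must be positive")


@dataclass
class Stimulus:
    """Compiled per-neuron amplitudes plus the shared time profiles."""

    odor_amp_mc: np.ndarray  # (n_mc,), pA
    fb_amp_mc: np.ndarray  # (n_mc,), pA
    fb_amp_gc: np.ndarray  # (n_gc,), pA
    program: StimulusProgram

    def currents(self, t_ms: float) -> tuple[np.ndarray, np.ndarray]:
        """(I_mc, I_gc) in pA at time t (ms)."""
        p = self.program
        phase = 2.0 * math.pi * p.sniff_hz * t_ms / 1000.0
        if p.waveform == "halfsine":
            w = max(0.0, math.sin(phase))
        else:
            w = 0.5 * (1.0 - math.cos(phase))
        fb_on = p.fb_onset_ms <= t_ms < p.fb_onset_ms + p.fb_duration_ms
        i_mc = self.odor_amp_mc * w
        if fb_on:
            i_mc = i_mc + self.fb_amp_mc
            i_gc = self.fb_amp_gc
        else:
            i_gc = np.zeros_like(self.fb_amp_gc)
        return i_mc, i_gc


def make_stimulus(
    program: StimulusProgram,
    mc_glomeruli: np.ndarray,
    n_gc: int,
    rng: np.random.Generator | int,
) -> Stimulus:
    """Compile a stimulus program against a network's glomerular partition."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    mc_glomeruli = np.asarray(mc_glomeruli)
    n_mc = len(mc_glomeruli)
    odor_amp = np.zeros(n_mc)
    lo, hi = program.odor_amp_range
    if program.odor_glomeruli:
        targets = set(int(g) for g in program.odor_glomeruli)
        if program.amp_per_glomerulus:
            amp_by_glom = {g: rng.uniform(lo, hi) for g in sorted(targets)}
            for i, g in enumerate(mc_glomeruli):
                if int(g) in targets:
                    odor_amp[i] = amp_by_glom[int(g)]
        else:
            mask = np.isin(mc_glomeruli, list(targets))
            odor_amp[mask] = rng.uniform(lo, hi, int(mask.sum()))

    fb_mc = np.zeros(n_mc)
    n_fb_mc = int(round(program.fb_mc_fraction * n_mc))
    if n_fb_mc:
        idx = rng.choice(n_mc, n_fb_mc, replace=False)
        fb_mc[idx] = rng.uniform(*program.fb_mc_amp_range, n_fb_mc)

    fb_gc = np.zeros(n_gc)
    n_fb_gc = int(round(program.fb_gc_fraction * n_gc))
    if n_fb_gc:
        idx = rng.choice(n_gc, n_fb_gc, replace=False)
        fb_gc[idx] = rng.uniform(*program.fb_gc_amp_range, n_fb_gc)

    return Stimulus(odor_amp_mc=odor_amp, fb_amp_mc=fb_mc, fb_amp_gc=fb_gc,
                    program=program)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass
class SpikeRecord:
    """Spike times (ms) per neuron, plus optional voltage traces."""

    mc_spikes: list[np.ndarray]
    gc_spikes: list[np.ndarray]
    duration_ms: float
    dt_ms: float
    v_traces: dict[str, np.ndarray] = field(default_factory=dict)

    def mc_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.mc_spikes])

    def gc_counts(self) -> np.ndarray:
        return np.array([len(s) for s in self.gc_spikes])

    def mc_counts_per_sniff(self) -> np.ndarray:
        """Mean spike count per sniff cycle for each MC."""
        sniffs = self.duration_ms / (SNIFF_SECONDS * 1000.0)
        return self.mc_counts() / sniffs


def _arrays(params: list[NeuronParams]) -> dict[str, np.ndarray]:
    return {
        name: np.array([getattr(p, name) for p in params])
        for name in ("k", "a", "b", "c", "d", "v_r", "v_t", "v_c", "cap")
    }


def simulate(
    graph: ConnectivityGraph,
    mc_params: list[NeuronParams],
    gc_params: list[NeuronParams],
    syn: SynapseParams | SynapseTable,
    stim: Stimulus,
    duration_ms: float,
    dt_ms: float = 0.1,
    rng: np.random.Generator | int | None = None,
    record_v: tuple[str, ...] = (),
) -> SpikeRecord:
    """Forward-Euler integration of the full MC-GC network.

    Per step: synaptic + external currents are evaluated with the
    start-of-step gating states, membrane states advance one Euler step,
    threshold crossings are reset, gating variables decay, and the
    spike-triggered gating bumps of the step's spikes are applied.

    ``syn`` may be mean parameters (heterogeneity sampled from ``rng``) or a
    pre-sampled :class:`SynapseTable`.  ``record_v`` names neurons like
    "mc3" or "gc0" whose voltage traces are kept.
    """
    n_mc, n_gc = len(mc_params), len(gc_params)
    ei = np.asarray(graph.mc_index, dtype=np.int64)
    ej = np.asarray(graph.gc_index, dtype=np.int64)
    n_e = len(ei)
    if n_e and (ei.max() >= n_mc or ej.max() >= n_gc):
        raise ValidationError("graph indices exceed the parameter table sizes")
    if len(stim.odor_amp_mc) != n_mc or len(stim.fb_amp_gc) != n_gc:
        raise ValidationError("stimulus sizes do not match the network")

    if isinstance(syn, SynapseTable):
        tab = syn
        if len(tab.g_ampa) != n_e:
            raise ValidationError("synapse table size does not match the edge count")
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        tab = sample_synapse_parameters(syn, n_e, rng)
    means = tab.means

    mc = _arrays(mc_params)
    gc = _arrays(gc_params)
    v_m, u_m = mc["v_r"].copy(), np.zeros(n_mc)
    v_g, u_g = gc["v_r"].copy(), np.zeros(n_gc)

    s_ampa = np.zeros(n_e)
    s_nmda = np.zeros(n_e)
    n_rise = np.zeros(n_e)
    s_gaba = np.zeros(n_e)
    gaba_att = tab.g_gaba * np.exp(-np.asarray(graph.distance) / means.lambda_length)

    w = means.w
    steps = int(round(duration_ms / dt_ms))
    mc_spk: list[list[float]] = [[] for _ in range(n_mc)]
    gc_spk: list[list[float]] = [[] for _ in range(n_gc)]
    traces = {name: np.empty(steps) for name in record_v}

    for step in range(steps):
        t = step * dt_ms
        i_mc_ext, i_gc_ext = stim.currents(t)

        # synaptic receptor currents with start-of-step gating
        if n_e:
            vg_e = v_g[ej]
            mg_block = 1.0 / (1.0 + means.mg * np.exp(-0.062 * vg_e) / 3.57)
            i_exc_e = (
                s_ampa * tab.g_ampa * (vg_e - means.e_exc)
                + s_nmda * tab.g_nmda * (vg_e - means.e_exc) * mg_block
            )
            i_gc_syn = np.zeros(n_gc)
            np.add.at(i_gc_syn, ej, i_exc_e)
            i_inh_e = s_gaba * gaba_att * (v_m[ei] - means.e_inh)
            i_mc_syn = np.zeros(n_mc)
            np.add.at(i_mc_syn, ei, i_inh_e)
        else:
            i_gc_syn = np.zeros(n_gc)
            i_mc_syn = np.zeros(n_mc)

        i_m = i_mc_ext - i_mc_syn
        i_g = i_gc_ext - i_gc_syn

        # Euler membrane update
        v_m = v_m + dt_ms / mc["cap"] * (
            mc["k"] * (v_m - mc["v_r"]) * (v_m - mc["v_t"]) - u_m + i_m
        )
        u_m = u_m + dt_ms * mc["a"] * (mc["b"] * (v_m - mc["v_r"]) - u_m)
        v_g = v_g + dt_ms / gc["cap"] * (
            gc["k"] * (v_g - gc["v_r"]) * (v_g - gc["v_t"]) - u_g + i_g
        )
        u_g = u_g + dt_ms * gc["a"] * (gc["b"] * (v_g - gc["v_r"]) - u_g)

        # spike detection and reset
        fired_m = v_m >= mc["v_c"]
        fired_g = v_g >= gc["v_c"]
        if fired_m.any():
            for i in np.nonzero(fired_m)[0]:
                mc_spk[i].append(t)
            v_m[fired_m] = mc["c"][fired_m]
            u_m[fired_m] += mc["d"][fired_m]
        if fired_g.any():
            for j in np.nonzero(fired_g)[0]:
                gc_spk[j].append(t)
            v_g[fired_g] = gc["c"][fired_g]
            u_g[fired_g] += gc["d"][fired_g]

        bad_m = np.abs(v_m) > V_SANITY
        bad_g = np.abs(v_g) > V_SANITY
        if bad_m.any() or bad_g.any():
            which = (
                f"mc{np.nonzero(bad_m)[0][0]}" if bad_m.any()
                else f"gc{np.nonzero(bad_g)[0][0]}"
            )
            raise RuntimeError(
                f"numerical blow-up: |v| exceeded {V_SANITY} mV for neuron "
                f"{which} at t = {t:.2f} ms (dt too large?)"
            )

        # gating decay (forward Euler)
        if n_e:
            s_ampa -= dt_ms * s_ampa / tab.tau_ampa
            s_gaba -= dt_ms * s_gaba / tab.tau_gaba
            s_nmda += dt_ms * (
                -s_nmda / tab.tau_nmda_decay + tab.alpha * n_rise * (1.0 - s_nmda)
            )
            n_rise -= dt_ms * n_rise / tab.tau_nmda_rise

            # spike-triggered bumps
            if fired_m.any():
                e_from_spk = fired_m[ei]
                s_ampa[e_from_spk] += w * (1.0 - s_ampa[e_from_spk])
                n_rise[e_from_spk] += w * (1.0 - n_rise[e_from_spk])
                # kappa-scaled GABA at all synapses of the GCs the spiking
                # MCs touch (spike-independent granule release)
                n_hits = np.zeros(n_gc)
                np.add.at(n_hits, ej[e_from_spk], 1.0)
                hit_e = n_hits[ej] > 0
                if hit_e.any():
                    fac = (1.0 - tab.kappa[hit_e] * w) ** n_hits[ej][hit_e]
                    s_gaba[hit_e] = 1.0 - fac * (1.0 - s_gaba[hit_e])
            if fired_g.any():
                e_from_g = fired_g[ej]
                s_gaba[e_from_g] += w * (1.0 - s_gaba[e_from_g])

        for name in record_v:
            pop_tag, idx = name[:2], int(name[2:])
            traces[name][step] = v_m[idx] if pop_tag == "mc" else v_g[idx]

    return SpikeRecord(
        mc_spikes=[np.array(s) for s in mc_spk],
        gc_spikes=[np.array(s) for s in gc_spk],
        duration_ms=duration_ms,
        dt_ms=dt_ms,
        v_traces=traces,
    )


def simulate_isolated(
    params: list[NeuronParams],
    currents_pa: np.ndarray,
    duration_ms: float,
    dt_ms: float = 0.1,
) -> list[np.ndarray]:
    """Constant-current integration of unconnected neurons (f-I probing).

    ``currents_pa`` holds one constant current per neuron; returns spike
    times per neuron.
    """
    arr = _arrays(params)
    n = len(params)
    currents = np.broadcast_to(np.asarray(currents_pa, dtype=float), (n,))
    v = arr["v_r"].copy()
    u = np.zeros(n)
    steps = int(round(duration_ms / dt_ms))
    spikes: list[list[float]] = [[] for _ in range(n)]
    for step in range(steps):
        v = v + dt_ms / arr["cap"] * (
            arr["k"] * (v - arr["v_r"]) * (v - arr["v_t"]) - u + currents
        )
        u = u + dt_ms * arr["a"] * (arr["b"] * (v - arr["v_r"]) - u)
        fired = v >= arr["v_c"]
        if fired.any():
            t = step * dt_ms
            for i in np.nonzero(fired)[0]:
                spikes[i].append(t)
            v[fired] = arr["c"][fired]
            u[fired] += arr["d"][fired]
        if (np.abs(v) > V_SANITY).any():
            raise RuntimeError(
                f"numerical blow-up in isolated integration at t = {step * dt_ms:.2f} ms"
            )
    return [np.array(s) for s in spikes]


def f_i_curve(
    p: NeuronParams,
    currents_pa: np.ndarray,
    duration_ms: float = 1000.0,
    dt_ms: float = 0.1,
    discard_ms: float = 200.0,
) -> np.ndarray:
    """Steady firing rate (Hz) of one neuron across constant current steps."""
    reps = [replace(p) for _ in currents_pa]
    spikes = simulate_isolated(reps, np.asarray(currents_pa, dtype=float),
                               duration_ms, dt_ms)
    window = (duration_ms - discard_ms) / 1000.0
    return np.array([np.sum(s >= discard_ms) / window for s in spikes])
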