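"""Membrane biophysics, synapses, and the time-domain cable simulation API.

The model is a spatially discretized cable with passive leak, Hodgkin-Huxley
style Na and K currents (rates Q10-adjusted to 35 C), and AMPA/NMDA synapses
whose conductance time course is a peak-normalized difference of
exponentials. The NMDA conductance is gated by the instantaneous
voltage-dependent magnesium block ``B(V) = 1 / (1 + exp(-(V + half)/slope))``.

Voltage is advanced with a backward-Euler step on the cable system (solved
exactly on the tree at every step), with channel gates advanced by
exponential (Rush-Larsen) integration and the Mg block evaluated at the
previous step's voltage -- the staggered semi-implicit scheme standard in
compartmental simulators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .morphology import Morphology, SectionKind
from . import _engine

__all__ = [
    "MembraneParams",
    "ChannelParams",
    "SynapseSpec",
    "AMPA_DEFAULT",
    "NMDA_SINGLE_PULSE",
    "Site",
    "StimulusEvent",
    "SimResult",
    "mg_block",
    "dual_exp_g",
    "dual_exp_peak_time",
    "place_cluster",
    "synapse_events",
    "simulate",
    "double_pulse",
    "peak_depolarization",
    "ParameterError",
    "PlacementError",
]


class ParameterError(ValueError):
    pass


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane properties by region.

    ``r_m`` in kOhm*cm^2, ``c_m`` in uF/cm^2, ``r_a`` in Ohm*cm, ``e_leak``
    in mV. Dendrites (basal/apical) use the dendritic values, axon nodes the
    node leak, myelinated internodes the myelin capacitance; everything else
    (soma, hillock) uses the "other" values.
    """

    r_m_dend: float = 10.0
    r_m_axon_node: float = 0.05
    r_m_other: float = 20.0
    c_m_dend: float = 2.0
    c_m_myelin: float = 0.05
    c_m_other: float = 1.0
    r_a: float = 100.0
    e_leak: float = -70.0

    def __post_init__(self):
        for name in ("r_m_dend", "r_m_axon_node", "r_m_other",
                     "c_m_dend", "c_m_myelin", "c_m_other", "r_a"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")

    def r_m_for(self, kind: SectionKind) -> float:
        if kind in (SectionKind.BASAL, SectionKind.APICAL):
            return self.r_m_dend
        if kind is SectionKind.AXON_NODE:
            return self.r_m_axon_node
        return self.r_m_other

    def c_m_for(self, kind: SectionKind) -> float:
        if kind in (SectionKind.BASAL, SectionKind.APICAL):
            return self.c_m_dend
        if kind is SectionKind.AXON_MYELIN:
            return self.c_m_myelin
        return self.c_m_other


@dataclass(frozen=True)
class ChannelParams:
    """Active (Na/K) conductance densities by region, in S/cm^2.

    Dendritic sodium density decreases linearly to zero at ``na_taper_end``
    um from the soma. ``v_shift`` displaces the HH rate functions along the
    voltage axis (positive = depolarized); together with ``q10_factor`` it is
    the one-time calibration of the axo-somatic spike mechanism, set so the
    cell rests stably near -70 mV and fires single spikes to strong input.
    ``k_gate_exponent`` selects n^4 (classic) or n^1 potassium activation.
    """

    gbar_na_dend: float = 0.006
    gbar_na_axon: float = 5.0
    gbar_na_myelin: float = 0.006
    gbar_na_soma: float = 0.25
    gbar_k_dend: float = 0.0003
    gbar_k_axon: float = 0.05
    gbar_k_soma: float = 0.03
    e_na: float = 60.0
    e_k: float = -90.0
    na_taper_end: float = 200.0
    v_shift: float = 10.0
    q10_factor: float = 2.3 ** ((35.0 - 23.0) / 10.0)
    k_gate_exponent: int = 4

    def __post_init__(self):
        for name in ("gbar_na_dend", "gbar_na_axon", "gbar_na_myelin",
                     "gbar_na_soma", "gbar_k_dend", "gbar_k_axon",
                     "gbar_k_soma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.k_gate_exponent not in (1, 4):
            raise ParameterError("k_gate_exponent must be 1 or 4")

    def gbar_na_for(self, kind: SectionKind, path_um: float) -> float:
        if kind in (SectionKind.BASAL, SectionKind.APICAL):
            taper = max(0.0, 1.0 - path_um / self.na_taper_end)
            return self.gbar_na_dend * taper
        if kind is SectionKind.SOMA:
            return self.gbar_na_soma
        if kind is SectionKind.AXON_MYELIN:
            return self.gbar_na_myelin
        return self.gbar_na_axon  # hillock and nodes: non-myelinated axon

    def gbar_k_for(self, kind: SectionKind) -> float:
        if kind in (SectionKind.BASAL, SectionKind.APICAL):
            return self.gbar_k_dend
        if kind is SectionKind.SOMA:
            return self.gbar_k_soma
        if kind is SectionKind.AXON_MYELIN:
            return 0.0
        return self.gbar_k_axon


# -- synapses --------------------------------------------------------------

@dataclass(frozen=True)
class SynapseSpec:
    """A difference-of-exponentials synaptic conductance.

    The waveform ``exp(-t/tau_fall) - exp(-t/tau_rise)`` is normalized so
    its maximum equals ``g_max`` (nS). NMDA kinds carry the Mg-block
    parameters; AMPA kinds ignore them.
    """

    kind: str  # "AMPA" | "NMDA"
    g_max: float
    tau_rise: float
    tau_fall: float
    e_rev: float = 0.0
    mg_half: float = 12.0
    mg_slope: float = 10.0

    def __post_init__(self):
        if self.kind not in ("AMPA", "NMDA"):
            raise ParameterError(f"unknown synapse kind {self.kind!r}")
        if self.g_max < 0:
            raise ParameterError("g_max must be >= 0")
        if not (self.tau_fall > self.tau_rise > 0):
            raise ParameterError("require tau_fall > tau_rise > 0")

    @property
    def peak_factor(self) -> float:
        tstar = dual_exp_peak_time(self.tau_rise, self.tau_fall)
        return math.exp(-tstar / self.tau_fall) - math.exp(-tstar / self.tau_rise)


def AMPA_DEFAULT(g_max: float = 1.5) -> SynapseSpec:
    return SynapseSpec("AMPA", g_max, 0.05, 0.5)


def NMDA_SINGLE_PULSE(g_max: float = 3.56) -> SynapseSpec:
    return SynapseSpec("NMDA", g_max, 2.1, 18.8)


def dual_exp_peak_time(tau_rise: float, tau_fall: float) -> float:
    """Time of the maximum of ``exp(-t/tau_fall) - exp(-t/tau_rise)``."""
    return (math.log(tau_fall / tau_rise)
            * tau_rise * tau_fall / (tau_fall - tau_rise))


def dual_exp_g(t, spec: SynapseSpec):
    """Synaptic conductance (nS) at time ``t`` (ms) after onset."""
    t = np.asarray(t, dtype=float)
    g = np.where(
        t >= 0,
        (np.exp(-np.maximum(t, 0.0) / spec.tau_fall)
         - np.exp(-np.maximum(t, 0.0) / spec.tau_rise)) / spec.peak_factor,
        0.0,
    )
    out = spec.g_max * g
    return float(out) if out.ndim == 0 else out


def mg_block(v, mg_half: float = 12.0, mg_slope: float = 10.0):
    """Voltage-dependent fraction of unblocked NMDA conductance, in [0, 1]."""
    if mg_slope == 0:
        raise ParameterError("mg_slope must be nonzero")
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v + mg_half) / mg_slope))
    return float(out) if out.ndim == 0 else out


# -- stimulus placement ----------------------------------------------------

@dataclass(frozen=True)
class Site:
    """A point on the morphology: section id + path distance (um) from soma."""

    section_id: int
    path_um: float


@dataclass(frozen=True)
class StimulusEvent:
    site: Site
    spec: SynapseSpec
    onset: float  # ms

    def __post_init__(self):
        if self.onset < 0:
            raise ParameterError("onset must be >= 0")


def place_cluster(m: Morphology, branch: int, center: float, n: int,
                  spacing: float = 0.5) -> list[Site]:
    """``n`` synapse sites at ``spacing`` um, symmetric about ``center``.

    ``center`` is a path distance from the soma on section ``branch``.
    """
    if n < 1:
        raise PlacementError("cluster must contain at least one synapse")
    sec = m.section(branch)
    start = m.path_start(branch)
    offsets = center + spacing * (np.arange(n) - (n - 1) / 2.0)
    lo, hi = offsets[0] - start, offsets[-1] - start
    if lo < -1e-9 or hi > sec.length + 1e-9:
        raise PlacementError(
            f"cluster [{offsets[0]:.2f}, {offsets[-1]:.2f}] um exceeds section "
            f"{branch} spanning [{start:.2f}, {start + sec.length:.2f}] um"
        )
    return [Site(branch, float(o)) for o in offsets]


def synapse_events(sites: Sequence[Site], onset: float,
                   nmda_g_max: float, ampa_g_max: float = 1.5,
                   mg_half: float = 12.0, mg_slope: float = 10.0) -> list[StimulusEvent]:
    """One AMPA + one NMDA activation per site at a common onset."""
    events = []
    ampa = AMPA_DEFAULT(ampa_g_max)
    nmda = replace(NMDA_SINGLE_PULSE(nmda_g_max), mg_half=mg_half, mg_slope=mg_slope)
    for s in sites:
        if ampa_g_max > 0:
            events.append(StimulusEvent(s, ampa, onset))
        if nmda_g_max > 0:
            events.append(StimulusEvent(s, nmda, onset))
    return events


# -- simulation ------------------------------------------------------------

@dataclass
class SimResult:
    dt: float
    duration: float
    t: np.ndarray
    traces: dict[object, np.ndarray]  # site key -> V (mV)
    rest: dict[object, float] = field(default_factory=dict)
    spike_times: np.ndarray | None = None

    def trace(self, key) -> np.ndarray:
        return self.traces[key]


def simulate(
    m: Morphology,
    membrane: MembraneParams,
    channels: ChannelParams | None,
    events: Sequence[StimulusEvent] = (),
    bias=None,
    duration: float = 100.0,
    dt: float = 0.1,
    record: Sequence[Site] | None = None,
    equilibrate: float = 200.0,
) -> SimResult:
    """Simulate the discretized cable and return voltage traces.

    ``channels=None`` runs a purely passive membrane. ``bias`` is either a
    constant somatic current (nA), a precomputed per-step current array, or a
    :class:`dendsum.spike_rate.NoisyBias`. The initial condition is the
    resting state obtained by ``equilibrate`` ms of stimulus-free settling
    (cached per parameter set). Traces are recorded at the soma (key
    ``"soma"``) and at each requested site (keyed by the Site).
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    cc = _engine.compiled_cell(m, membrane, channels)
    state0 = _engine.resting_state(cc, dt, equilibrate)
    record = list(record or [])
    record_nodes = [cc.soma_node] + [cc.node_at(s.section_id, s.path_um) for s in record]
    keys = ["soma"] + list(record)

    ev = _engine.compile_events(cc, events)
    nsteps = int(round(duration / dt))
    bias_arr = _make_bias_array(bias, nsteps, dt)
    traces = _engine.run(cc, state0, ev, nsteps, dt, bias_arr, np.array(record_nodes))
    t = np.arange(nsteps + 1) * dt
    out = {k: traces[i] for i, k in enumerate(keys)}
    rest = {k: float(traces[i][0]) for i, k in enumerate(keys)}
    return SimResult(dt=dt, duration=duration, t=t, traces=out, rest=rest)


def _make_bias_array(bias, nsteps: int, dt: float):
    if bias is None:
        return None
    if np.isscalar(bias):
        return np.full(nsteps, float(bias))
    arr = getattr(bias, "current_array", None)
    if callable(arr):
        return bias.current_array(nsteps, dt)
    bias = np.asarray(bias, dtype=float)
    if bias.shape != (nsteps,):
        raise ParameterError(f"bias array must have shape ({nsteps},)")
    return bias


def double_pulse_events(
    sites: Sequence[Site],
    t0: float = 5.0,
    interval: float = 20.0,
    nmda_g_max_1: float = 2.23,
    nmda_g_max_2: float = 4.46,
    ampa_g_max: float = 1.5,
    nmda_scale: float = 1.0,
) -> list[StimulusEvent]:
    """Event schedule of the 50 Hz double-pulse facilitation protocol.

    The second pulse's NMDA peak conductance is twice the first
    (2.23 -> 4.46 nS); the AMPA conductance is identical on both pulses.
    ``nmda_scale`` multiplies both NMDA conductances (0 simulates NMDA
    receptor block).
    """
    return (
        synapse_events(sites, t0, nmda_g_max_1 * nmda_scale, ampa_g_max)
        + synapse_events(sites, t0 + interval, nmda_g_max_2 * nmda_scale,
                         ampa_g_max)
    )


def double_pulse(
    m: Morphology,
    membrane: MembraneParams,
    channels: ChannelParams | None,
    sites: Sequence[Site],
    t0: float = 5.0,
    interval: float = 20.0,
    nmda_g_max_1: float = 2.23,
    nmda_g_max_2: float = 4.46,
    ampa_g_max: float = 1.5,
    nmda_scale: float = 1.0,
    duration: float = 90.0,
    dt: float = 0.1,
    record: Sequence[Site] | None = None,
) -> SimResult:
    """Simulate the two-pulse (50 Hz) NMDA-facilitation protocol."""
    events = double_pulse_events(sites, t0, interval, nmda_g_max_1,
                                 nmda_g_max_2, ampa_g_max, nmda_scale)
    return simulate(m, membrane, channels, events, duration=duration, dt=dt,
                    record=record)


def peak_depolarization(r: SimResult, site="soma") -> float:
    """Maximum depolarization (mV) of a trace relative to its resting value."""
    v = r.traces[site]
    return float(np.max(v - r.rest[site]))
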