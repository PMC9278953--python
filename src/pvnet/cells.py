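"""Single-compartment cell models and the fixed-step integrator.

Provides the fast-spiking PV interneuron model (HH sodium + Kv3 + leak), a
bursting pyramidal-cell model (HH sodium + delayed rectifier + slowly
inactivating persistent sodium + leak), alpha synapses, gap junctions and
in-silico dynamic-clamp conductances, together with a vectorized
exponential-Euler integrator that advances any number of uncoupled (or
gap-coupled) copies of a model in lockstep.

Units: mV, ms, pF, nS, pA throughout the runtime state (pF·mV/ms = pA, so
the membrane equation needs no extra unit factors).  Channel densities in
S/cm^2 are converted to absolute nS via the compartment area when a model
is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .channels import (
    ChannelSpec,
    GateParams,
    GateState,
    gate_step,
    gate_targets,
)

__all__ = [
    "CompartmentSpec",
    "AlphaSynapseSpec",
    "GapJunctionSpec",
    "DynamicClampSpec",
    "CellModel",
    "Population",
    "Trace",
    "NumericalBlowup",
    "make_pv_cell",
    "make_pc_cell",
    "alpha_conductance",
    "simulate",
    "resting_potential",
]

DT_DEFAULT = 0.025  # ms, integrator resolution
V_GUARD = 150.0  # mV, |v| beyond this is treated as numerical blow-up


class NumericalBlowup(RuntimeError):
    """Raised when the membrane potential leaves the guard band."""

    def __init__(self, t_ms: float):
        super().__init__(f"membrane potential diverged at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


@dataclass(frozen=True)
class CompartmentSpec:
    """Geometry and passive properties of a single compartment.

    The default 20 um x 20 um compartment is read as a cylinder of length
    and diameter 20 um (lateral area pi*d*L, the convention of
    compartmental simulators); ``geometry="flat"`` selects the plain
    L x d rectangle instead.
    """

    length_um: float = 20.0
    diam_um: float = 20.0
    cm_uf_cm2: float = 1.0
    geometry: Literal["cylinder", "flat"] = "cylinder"

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diam_um <= 0 or self.cm_uf_cm2 <= 0:
            raise ValueError("geometry and capacitance must be positive")

    @property
    def area_cm2(self) -> float:
        if self.geometry == "cylinder":
            area_um2 = math.pi * self.diam_um * self.length_um
        else:
            area_um2 = self.diam_um * self.length_um
        return area_um2 * 1e-8

    @property
    def cap_pF(self) -> float:
        return self.cm_uf_cm2 * self.area_cm2 * 1e6


@dataclass(frozen=True)
class AlphaSynapseSpec:
    """Alpha-function conductance: peaks at gmax exactly tau after onset."""

    onset_ms: float
    gmax_nS: float = 10.0
    tau_ms: float = 0.5
    e_rev: float = 0.0

    def __post_init__(self) -> None:
        if self.gmax_nS < 0:
            raise ValueError("gmax must be nonnegative")
        if self.tau_ms <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class GapJunctionSpec:
    """Symmetric ohmic coupling between two cells."""

    g_gap_nS: float
    endpoints: tuple[int, int]

    def __post_init__(self) -> None:
        if self.g_gap_nS < 0:
            raise ValueError("g_gap must be nonnegative")


@dataclass(frozen=True)
class DynamicClampSpec:
    """In-silico dynamic clamp: a Kv3-gated conductance computed at the
    live membrane potential and injected as extra current.

    The gating equations are identical to the model Kv3 mechanism; only
    ``g_total`` (nS), the activation-voltage shift and the reversal are
    free.
    """

    g_total_nS: float = 20.0
    delta_shift: float = 0.0
    e_rev: float = -90.0
    kin_scale: float = 1.0
    tau_inact: float = 1000.0

    def __post_init__(self) -> None:
        if self.g_total_nS < 0:
            raise ValueError("g_total must be nonnegative")

    @property
    def gate_params(self) -> GateParams:
        return GateParams(delta_shift=self.delta_shift,
                          kin_scale=self.kin_scale,
                          tau_inact=self.tau_inact)


def alpha_conductance(t, spec: AlphaSynapseSpec):
    """Closed-form alpha conductance g(t) = gmax*(s/tau)*exp(1 - s/tau),
    s = t - onset; zero before onset."""
    s = np.asarray(t, float) - spec.onset_ms
    x = s / spec.tau_ms
    with np.errstate(over="ignore"):
        g = spec.gmax_nS * x * np.exp(1.0 - x)
    return np.where(s >= 0.0, g, 0.0)


@dataclass
class CellModel:
    """A named single-compartment model: compartment + channel set.

    Channels keep their spec units; ``channel_g_nS`` resolves a density
    to an absolute conductance via the compartment area.
    """

    name: str
    compartment: CompartmentSpec
    channels: list[ChannelSpec]
    params: dict = field(default_factory=dict)

    @property
    def cap_pF(self) -> float:
        return self.compartment.cap_pF

    def channel_g_nS(self, spec: ChannelSpec) -> float:
        if spec.gbar_mode == "absolute":
            return spec.gbar
        return spec.gbar * self.compartment.area_cm2 * 1e9


# ---------------------------------------------------------------------------
# Runtime population state
# ---------------------------------------------------------------------------

class _ReceptorGroup:
    """Per-population synaptic state for one (tau, e_rev) receptor class,
    integrated as the exact two-state alpha cascade."""

    def __init__(self, n: int, tau_ms: float, e_rev: float):
        self.tau = tau_ms
        self.e_rev = e_rev
        self.g = np.zeros(n)
        self.y = np.zeros(n)

    def decay(self, dt: float) -> None:
        d = math.exp(-dt / self.tau)
        self.g = d * (self.g + self.y * (dt / self.tau))
        self.y *= d

    def impulse(self, gmax_nS) -> None:
        """Register synaptic onsets; the cascade peaks at gmax after tau."""
        self.y += np.asarray(gmax_nS, float) * math.e


class Population:
    """n lock-stepped copies of one cell model with shared mechanisms.

    Holds voltages, gate states, receptor conductances and an optional
    dynamic clamp; used directly for vectorized single-cell sweeps and as
    the building block of the network simulation.
    """

    def __init__(self, model: CellModel, n: int = 1, v0: float = -70.0):
        self.model = model
        self.n = n
        self.v = np.full(n, float(v0))
        self.cap = model.cap_pF
        self.gates: dict[int, GateState] = {}
        self._g_abs = []
        for idx, ch in enumerate(model.channels):
            self._g_abs.append(model.channel_g_nS(ch))
            if ch.mechanism_id != "leak":
                m_inf, _, h_inf, _ = gate_targets(ch.mechanism_id, self.v, ch.gates)
                m = np.array(m_inf, float) if m_inf is not None else np.ones(n)
                h = np.array(h_inf, float) if h_inf is not None else np.ones(n)
                self.gates[idx] = GateState(m=m, h=h)
        self.receptors: dict[str, _ReceptorGroup] = {}
        self.dynclamp: DynamicClampSpec | None = None
        self._dc_state: GateState | None = None
        self.prev_v = self.v.copy()
        self._cond_cache: tuple | None = None

    # -- devices ----------------------------------------------------------

    def add_receptor(self, key: str, tau_ms: float, e_rev: float) -> _ReceptorGroup:
        grp = _ReceptorGroup(self.n, tau_ms, e_rev)
        self.receptors[key] = grp
        return grp

    def attach_dynamic_clamp(self, spec: DynamicClampSpec) -> None:
        self.dynclamp = spec
        m_inf, _, h_inf, _ = gate_targets("kv3", self.v, spec.gate_params)
        self._dc_state = GateState(m=np.array(m_inf, float),
                                   h=np.array(h_inf, float))

    # -- one integration step ---------------------------------------------

    def advance_gates(self, dt: float) -> None:
        """In-place exact-exponential gate update (the integrator's hot
        path; equivalent to channels.gate_step per channel)."""
        v = self.v
        for idx, st in self.gates.items():
            ch = self.model.channels[idx]
            m_inf, tau_m, h_inf, tau_h = gate_targets(ch.mechanism_id, v,
                                                      ch.gates)
            if m_inf is not None:
                st.m = m_inf + (st.m - m_inf) * np.exp(-dt / tau_m)
            if h_inf is not None:
                st.h = h_inf + (st.h - h_inf) * np.exp(-dt / tau_h)
        if self.dynclamp is not None:
            dc = self._dc_state
            p = self.dynclamp.gate_params
            m_inf, tau_m, h_inf, tau_h = gate_targets("kv3", v, p)
            dc.m = m_inf + (dc.m - m_inf) * np.exp(-dt / tau_m)
            dc.h = h_inf + (dc.h - h_inf) * np.exp(-dt / tau_h)
        for grp in self.receptors.values():
            grp.decay(dt)
        self._cond_cache = None

    def conductances(self):
        """Total conductance G (nS) and conductance-weighted reversal sum
        GE (nS*mV) from channels, receptors and dynamic clamp.

        Cached between gate updates (update_v and the LFP current read the
        same values within one step)."""
        if self._cond_cache is not None:
            return self._cond_cache
        G = np.zeros(self.n)
        GE = np.zeros(self.n)
        for idx, ch in enumerate(self.model.channels):
            gbar = self._g_abs[idx]
            if ch.mechanism_id == "leak":
                g = np.full(self.n, gbar)
            else:
                st = self.gates[idx]
                pm, ph = ch.gate_exponents
                g = gbar * st.m ** pm * st.h ** ph
            G += g
            GE += g * ch.e_rev
        for grp in self.receptors.values():
            G += grp.g
            GE += grp.g * grp.e_rev
        if self.dynclamp is not None and self.dynclamp.g_total_nS > 0:
            g = self.dynclamp.g_total_nS * self._dc_state.m * self._dc_state.h
            G += g
            GE += g * self.dynclamp.e_rev
        self._cond_cache = (G, GE)
        return G, GE

    def membrane_current_pA(self) -> np.ndarray:
        """Summed ionic + synaptic + clamp current (pA, positive outward);
        the per-cell contribution to the LFP proxy."""
        G, GE = self.conductances()
        return G * self.v - GE

    def update_v(self, dt: float, i_inj_pA=0.0, gap_G=None, gap_GE=None,
                 t_ms: float = 0.0) -> None:
        """Exponential-Euler voltage update.

        Treats all conductance sources (channels, synapses, dynamic clamp,
        gap junctions with the partner voltage frozen over the step) as a
        single equivalent conductance G with reversal GE/G, plus the
        injected current:  v -> v_inf + (v - v_inf) * exp(-dt*G/C).
        """
        G, GE = self.conductances()
        if gap_G is not None:
            G = G + gap_G
            GE = GE + gap_GE
        self.prev_v = self.v
        if np.all(G > 1e-12):
            v_inf = (GE + i_inj_pA) / G
            v_new = v_inf + (self.v - v_inf) * np.exp(-dt * G / self.cap)
        else:
            i = np.broadcast_to(np.asarray(i_inj_pA, float), (self.n,))
            tiny = G < 1e-12
            G_safe = np.where(tiny, 1.0, G)
            v_inf = (GE + i) / G_safe
            decay = np.exp(-dt * G_safe / self.cap)
            v_new = np.where(tiny, self.v + dt * i / self.cap,
                             v_inf + (self.v - v_inf) * decay)
        if not (np.abs(v_new) <= V_GUARD).all():
            raise NumericalBlowup(t_ms)
        self.v = v_new

    def crossings(self, thresh: float = -20.0) -> np.ndarray:
        """Upward threshold crossings on the last step (boolean per cell)."""
        return (self.v >= thresh) & (self.prev_v < thresh)


# ---------------------------------------------------------------------------
# Model factories
# ---------------------------------------------------------------------------

# Calibrated PV model densities (S/cm^2).  The passive background sets an
# input resistance near 100 MOhm and a -70 mV rest; sodium kinetics are
# uniformly accelerated (kin_scale < 1) to support fast non-adapting
# spiking at a depolarized threshold.
PV_DEFAULTS = dict(
    gna=0.3,
    gkv3=0.06,
    gleak=8.0e-4,
    e_na=50.0,
    e_k=-90.0,
    e_leak=-68.0,
    nav_shift=0.0,       # mV shift of the HH Na curves
    nav_kin_scale=0.15,  # uniform speed-up of HH Na kinetics
    nav_h_scale=0.4,     # alpha_h multiplier (<1 slows recovery only)
    kv3_shift=0.0,
    kv3_kin_scale=1.0,
    kv3_tau_inact=1000.0,
    kv3_inact_shift=0.0,
    gkv7=0.0,
    kv7_shift=0.0,
)

# Pyramidal-cell burster (absolute conductances, nS): a fast spiking
# subsystem with shared Na/K recovery gate plus a slowly inactivating
# persistent Na current as the burst clock.  The canonical constants are
# stated for a 21 pF pacemaker cell; scaling every conductance together
# with the capacitance leaves the dynamics invariant, so they are rescaled
# to this model's ~12.57 pF compartment.
_PC_CAP_SCALE = CompartmentSpec().cap_pF / 21.0
PC_DEFAULTS = dict(
    gna_nS=28.0 * _PC_CAP_SCALE,
    gk_nS=11.2 * _PC_CAP_SCALE,
    gnap_nS=2.8 * _PC_CAP_SCALE,
    gleak_nS=2.8 * _PC_CAP_SCALE,
    e_na=50.0,
    e_k=-85.0,
    e_leak=-60.0,
)


def make_pv_cell(config: dict | None = None) -> CellModel:
    """Build the calibrated fast-spiking PV interneuron model.

    ``config`` overrides any of the PV_DEFAULTS entries (densities in
    S/cm^2, shifts in mV).  The Kv3 knobs (``kv3_shift``,
    ``kv3_kin_scale``, ``kv3_tau_inact``, ``kv3_inact_shift``) are the
    perturbation surface used throughout the protocols.
    """
    p = dict(PV_DEFAULTS)
    if config:
        unknown = set(config) - set(p)
        if unknown:
            raise KeyError(f"unknown PV config keys: {sorted(unknown)}")
        p.update(config)
    comp = CompartmentSpec()
    channels = [
        ChannelSpec("nav_hh", p["gna"], p["e_na"],
                    gates=GateParams(delta_shift=p["nav_shift"],
                                     kin_scale=p["nav_kin_scale"],
                                     h_alpha_scale=p["nav_h_scale"]),
                    gate_exponents=(3, 1)),
        ChannelSpec("kv3", p["gkv3"], p["e_k"],
                    gates=GateParams(delta_shift=p["kv3_shift"],
                                     kin_scale=p["kv3_kin_scale"],
                                     tau_inact=p["kv3_tau_inact"],
                                     inact_shift=p["kv3_inact_shift"]),
                    gate_exponents=(1, 1)),
        ChannelSpec("leak", p["gleak"], p["e_leak"], gate_exponents=(0, 0)),
    ]
    if p["gkv7"] > 0:
        channels.append(
            ChannelSpec("kv7", p["gkv7"], p["e_k"],
                        gates=GateParams(delta_shift=p["kv7_shift"]),
                        gate_exponents=(1, 0)))
    return CellModel("pv", comp, channels, params=p)


def make_pc_cell(config: dict | None = None) -> CellModel:
    """Build the intrinsically bursting pyramidal-cell model.

    With default constants and a few pA of depolarizing bias the model
    produces clusters of >= 2 spikes separated by slow interburst
    intervals; mean rate grows monotonically with bias current.
    """
    p = dict(PC_DEFAULTS)
    if config:
        unknown = set(config) - set(p)
        if unknown:
            raise KeyError(f"unknown PC config keys: {sorted(unknown)}")
        p.update(config)
    comp = CompartmentSpec()
    channels = [
        ChannelSpec("burster_na", p["gna_nS"], p["e_na"],
                    gbar_mode="absolute", gate_exponents=(3, 1)),
        ChannelSpec("burster_k", p["gk_nS"], p["e_k"],
                    gbar_mode="absolute", gate_exponents=(4, 0)),
        ChannelSpec("nap", p["gnap_nS"], p["e_na"],
                    gbar_mode="absolute", gate_exponents=(1, 1)),
        ChannelSpec("leak", p["gleak_nS"], p["e_leak"],
                    gbar_mode="absolute", gate_exponents=(0, 0)),
    ]
    return CellModel("pc", comp, channels, params=p)


# ---------------------------------------------------------------------------
# Single-population runner
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """Uniformly sampled voltage traces, shape (n_samples, n_cells)."""

    t: np.ndarray
    v: np.ndarray
    dt: float

    def column(self, i: int = 0) -> np.ndarray:
        return self.v[:, i]


def simulate(model: CellModel,
             duration_ms: float,
             dt: float = DT_DEFAULT,
             i_inj_pA=0.0,
             synapses: Sequence[AlphaSynapseSpec] = (),
             dynclamp: DynamicClampSpec | None = None,
             gap_junctions: Sequence[GapJunctionSpec] = (),
             n: int | None = None,
             v0: float = -70.0,
             record_current: bool = False,
             settle_ms: float = 0.0,
             settle_i_inj_pA: float = 0.0):
    """Run n uncoupled (or gap-coupled) copies of a model.

    ``i_inj_pA`` may be a scalar, an array of shape (n,) (one constant per
    copy, the vectorized-sweep form) or a callable t -> scalar/array.
    ``synapses`` fire identically onto every copy.  ``settle_ms`` runs the
    model unrecorded before t=0 so traces start from the settled state.

    Returns a ``Trace`` (and the summed membrane current, pA, if
    ``record_current``).
    """
    if dt <= 0 or dt > 0.1:
        raise ValueError("dt must be in (0, 0.1] ms")
    inj_arr = None
    if not callable(i_inj_pA):
        inj_arr = np.atleast_1d(np.asarray(i_inj_pA, float))
    if n is None:
        n = 1 if inj_arr is None else inj_arr.shape[-1]
    pop = Population(model, n=n, v0=v0)
    if dynclamp is not None:
        pop.attach_dynamic_clamp(dynclamp)

    # group synapses by receptor class; bucket onsets into time bins
    n_steps = int(round(duration_ms / dt))
    onset_buckets: dict[str, dict[int, float]] = {}
    for syn in synapses:
        key = f"tau{syn.tau_ms}_e{syn.e_rev}"
        if key not in pop.receptors:
            pop.add_receptor(key, syn.tau_ms, syn.e_rev)
            onset_buckets[key] = {}
        b = int(round(syn.onset_ms / dt))
        onset_buckets[key][b] = onset_buckets[key].get(b, 0.0) + syn.gmax_nS

    gap_G = None
    gap_M = None
    if gap_junctions:
        gap_M = np.zeros((n, n))
        for gj in gap_junctions:
            a, b = gj.endpoints
            gap_M[a, b] += gj.g_gap_nS
            gap_M[b, a] += gj.g_gap_nS
        gap_G = gap_M.sum(axis=1)

    if settle_ms > 0:
        for k in range(int(round(settle_ms / dt))):
            pop.advance_gates(dt)
            gg, ge = (gap_G, gap_M @ pop.v) if gap_M is not None else (None, None)
            pop.update_v(dt, settle_i_inj_pA, gg, ge, t_ms=-settle_ms + k * dt)

    t = np.arange(n_steps + 1) * dt
    v_rec = np.empty((n_steps + 1, n))
    v_rec[0] = pop.v
    i_rec = np.empty((n_steps + 1, n)) if record_current else None
    if record_current:
        i_rec[0] = pop.membrane_current_pA()
    for k in range(n_steps):
        tk = k * dt
        pop.advance_gates(dt)
        for key, buckets in onset_buckets.items():
            if k in buckets:
                pop.receptors[key].impulse(buckets[k])
        if callable(i_inj_pA):
            inj = np.asarray(i_inj_pA(tk), float)
        else:
            inj = inj_arr
        gg, ge = (gap_G, gap_M @ pop.v) if gap_M is not None else (None, None)
        pop.update_v(dt, inj, gg, ge, t_ms=tk)
        v_rec[k + 1] = pop.v
        if record_current:
            i_rec[k + 1] = pop.membrane_current_pA()
    trace = Trace(t=t, v=v_rec, dt=dt)
    if record_current:
        return trace, i_rec
    return trace


def resting_potential(model: CellModel, duration_ms: float = 500.0,
                      dt: float = DT_DEFAULT, v0: float = -70.0) -> float:
    """Settled zero-input membrane potential (mV)."""
    tr = simulate(model, duration_ms, dt=dt, v0=v0)
    return float(tr.v[-1, 0])
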