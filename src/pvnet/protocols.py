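"""Declarative single-cell experiment runners and AP analysis metrics.

Covers the firing protocols used to characterize the PV model: F-I curves
from capacitance-normalized square pulses, voltage-clamp step families,
continuous synaptic bombardment, dynamic-clamp gEPSP trains, subthreshold
EPSP measurements, and the sodium / Kv7 / Kv3-inactivation parameter scans.
Every runner is a pure function of (configuration, seed).

Current amplitudes are expressed in pA/pF and converted with the protocol's
normalization capacitance, which defaults to the mean measured cellular
capacitance of the recorded interneurons (47 pF) rather than the model
compartment's own ~12.6 pF: the model reproduces the recorded cells'
current-normalized input-output relation, not their membrane area.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cells import (
    DT_DEFAULT,
    AlphaSynapseSpec,
    CellModel,
    DynamicClampSpec,
    Trace,
    make_pv_cell,
    simulate,
)
from .channels import gate_targets

__all__ = [
    "CAP_NORM_PF",
    "SquarePulseProtocol",
    "VClampStepProtocol",
    "BombardmentProtocol",
    "GEPSPTrainProtocol",
    "APMetrics",
    "SpikeTrain",
    "detect_spikes",
    "ap_metrics",
    "run_fi_curve",
    "run_vclamp_activation",
    "run_bombardment",
    "run_gepsp_train",
    "run_subthreshold_epsp",
    "scan_nav",
    "scan_kv7",
    "scan_kv3_inactivation",
    "near_threshold_amps",
]

CAP_NORM_PF = 47.0  # pF, capacitance used to convert pA/pF to pA

SPIKE_THRESH_MV = -20.0  # upward-crossing spike detection level
SPIKE_REFRACT_MS = 1.0
DVDT_CRIT = 20.0  # V/s, AP threshold criterion


@dataclass(frozen=True)
class SquarePulseProtocol:
    """300 ms square pulses at amplitudes in pA/pF (default 1-21 by 2)."""

    duration_ms: float = 300.0
    amplitudes_pA_per_pF: tuple = tuple(np.arange(1.0, 22.0, 2.0))
    capacitance_pF: float = CAP_NORM_PF
    baseline_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if not np.all(np.isfinite(self.amplitudes_pA_per_pF)):
            raise ValueError("amplitudes must be finite")


@dataclass(frozen=True)
class VClampStepProtocol:
    """Voltage-clamp family: hold -110 mV, step -90..+50 by 20, 300 ms."""

    holding_mV: float = -110.0
    steps_mV: tuple = tuple(np.arange(-90.0, 51.0, 20.0))
    step_duration_ms: float = 300.0
    pre_ms: float = 100.0

    def __post_init__(self) -> None:
        if list(self.steps_mV) != sorted(self.steps_mV):
            raise ValueError("steps must be sorted ascending")


@dataclass(frozen=True)
class BombardmentProtocol:
    """Continuous synaptic drive: 1000 excitatory (0 mV) + 500 inhibitory
    (-90 mV) alpha synapses, 10 nS each, uniform random onsets over 1 s.

    The synaptic time constants (excitatory 0.1 ms, inhibitory 1.8 ms) are
    calibration constants: they set the control firing rate of the PV model
    near its 30.6 Hz target under this drive.
    """

    duration_ms: float = 1000.0
    n_exc: int = 1000
    n_inh: int = 500
    gmax_nS: float = 10.0
    tau_exc_ms: float = 0.1
    tau_inh_ms: float = 1.8
    e_exc: float = 0.0
    e_inh: float = -90.0

    def __post_init__(self) -> None:
        if self.n_exc < 0 or self.n_inh < 0:
            raise ValueError("synapse counts must be nonnegative")


@dataclass(frozen=True)
class GEPSPTrainProtocol:
    """Regular train of excitatory conductance events (dynamic-clamp gEPSP)."""

    rate_hz: float = 10.0
    n_events: int = 10
    # calibrated so the unclamped control cell spikes on every event while
    # sitting close enough to threshold for a shifted 20 nS Kv3 conductance
    # to matter (comparable to the ~4.7 nS used experimentally)
    g_epsp_nS: float = 3.5
    tau_ms: float = 0.5
    suprathreshold: bool = True

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate must be positive")


@dataclass(frozen=True)
class APMetrics:
    """Waveform metrics of one action potential."""

    threshold_mV: float
    amplitude_mV: float
    half_width_ms: float
    max_dvdt_V_per_s: float
    ahp_mV: float


@dataclass(frozen=True)
class SpikeTrain:
    times_ms: np.ndarray
    duration_ms: float

    @property
    def rate_hz(self) -> float:
        return len(self.times_ms) / (self.duration_ms / 1000.0)


# ---------------------------------------------------------------------------
# Spike detection and AP metrics
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, column: int = 0,
                  thresh_mV: float = SPIKE_THRESH_MV,
                  refractory_ms: float = SPIKE_REFRACT_MS) -> SpikeTrain:
    """Spike times from upward threshold crossings with refractory
    enforcement; raises on non-uniform sampling."""
    t = trace.t
    if not np.allclose(np.diff(t), trace.dt, rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not uniformly sampled")
    v = trace.v[:, column]
    above = v >= thresh_mV
    idx = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    times = []
    last = -np.inf
    for i in idx:
        ti = t[i]
        if ti - last >= refractory_ms:
            times.append(ti)
            last = ti
    return SpikeTrain(times_ms=np.asarray(times), duration_ms=float(t[-1]))


def _spike_counts(v: np.ndarray, dt: float,
                  thresh_mV: float = SPIKE_THRESH_MV) -> np.ndarray:
    """Vectorized crossing counts per column (refractory-free; the AP
    upstroke is monotone at the resolutions used, so each spike crosses
    once)."""
    above = v >= thresh_mV
    return np.sum(above[1:] & ~above[:-1], axis=0)


def ap_metrics(trace: Trace, spike_index: int = 0, column: int = 0,
               dvdt_crit: float = DVDT_CRIT,
               window_ms: float = 4.0) -> APMetrics:
    """Metrics of the spike_index-th AP in a voltage trace.

    Threshold is the voltage at the first sample where dV/dt exceeds
    ``dvdt_crit`` (V/s); amplitude is peak minus threshold; the half-width
    is measured at threshold + amplitude/2 with sub-sample interpolation of
    both crossings; AHP is threshold minus the post-spike minimum.
    """
    v = trace.v[:, column]
    dt = trace.dt
    dv = np.gradient(v, dt)  # mV/ms == V/s
    onsets = np.nonzero((dv[1:] >= dvdt_crit) & (dv[:-1] < dvdt_crit))[0] + 1
    # group onsets into distinct APs (separated by > refractory)
    distinct = [i for k, i in enumerate(onsets)
                if k == 0 or (i - onsets[k - 1]) * dt > SPIKE_REFRACT_MS]
    if spike_index >= len(distinct):
        raise ValueError(f"spike {spike_index} not found")
    i0 = distinct[spike_index]
    iw = int(round(window_ms / dt))
    seg = v[i0:i0 + iw]
    if len(seg) < 3:
        raise ValueError("spike window exceeds trace")
    thr = v[i0]
    pk_i = int(np.argmax(seg))
    peak = seg[pk_i]
    if peak <= thr:
        raise ValueError("no peak found in AP window")
    amp = peak - thr
    half = thr + amp / 2.0
    # contiguous suprathreshold run containing the peak (the window may
    # hold a following spike at high rates)
    above = seg >= half
    a = pk_i
    while a > 0 and above[a - 1]:
        a -= 1
    b = pk_i
    while b + 1 < len(seg) and above[b + 1]:
        b += 1
    t_up = a - (seg[a] - half) / (seg[a] - seg[a - 1]) if a > 0 else float(a)
    if b + 1 < len(seg):
        t_dn = b + (seg[b] - half) / (seg[b] - seg[b + 1])
    else:
        t_dn = float(b)
    half_width = (t_dn - t_up) * dt
    trough_end = b + 1
    while trough_end < len(seg) - 1 and seg[trough_end + 1] < seg[trough_end]:
        trough_end += 1
    ahp = thr - float(seg[pk_i:trough_end + 1].min())
    max_dvdt = float(dv[i0:i0 + iw].max())
    return APMetrics(threshold_mV=float(thr), amplitude_mV=float(amp),
                     half_width_ms=float(half_width),
                     max_dvdt_V_per_s=max_dvdt, ahp_mV=float(ahp))


# ---------------------------------------------------------------------------
# F-I
# ---------------------------------------------------------------------------

def run_fi_curve(cell: CellModel,
                 protocol: SquarePulseProtocol = SquarePulseProtocol(),
                 dt: float = DT_DEFAULT) -> pd.DataFrame:
    """Firing frequency vs capacitance-normalized current amplitude.

    All amplitudes are integrated as one vectorized sweep after a settling
    period at zero input.  Frequency = spike count / pulse duration.
    """
    amps = np.asarray(protocol.amplitudes_pA_per_pF, float)
    inj = amps * protocol.capacitance_pF
    tr = simulate(cell, protocol.duration_ms, dt=dt, i_inj_pA=inj,
                  settle_ms=protocol.baseline_ms)
    counts = _spike_counts(tr.v, dt)
    return pd.DataFrame({
        "amplitude_pA_per_pF": amps,
        "frequency_hz": counts / (protocol.duration_ms / 1000.0),
    })


def near_threshold_amps(fi: pd.DataFrame, min_rate_hz: float = 1.0) -> np.ndarray:
    """The lowest two amplitudes eliciting at least one spike in a control
    F-I table (the operational definition of 'near-threshold')."""
    firing = fi[fi.frequency_hz >= min_rate_hz]
    return firing.amplitude_pA_per_pF.values[:2]


# ---------------------------------------------------------------------------
# Voltage clamp
# ---------------------------------------------------------------------------

def run_vclamp_activation(channel, protocol: VClampStepProtocol = VClampStepProtocol(),
                          dt: float = DT_DEFAULT, gbar_nS: float = 20.0):
    """Voltage-clamp current family of one channel mechanism.

    The voltage is imposed (holding, then each step); gates follow their
    ODEs by exact exponential updates.  Returns ``(t, currents, peaks)``
    with currents in nA, one column per step, and a peak I-V DataFrame.
    """
    from .channels import GateState, _exp_relax  # local: integration detail

    steps = np.asarray(protocol.steps_mV, float)
    n_pre = int(round(protocol.pre_ms / dt))
    n_step = int(round(protocol.step_duration_ms / dt))
    mech = channel.mechanism_id
    params = channel.gates
    m_inf, _, h_inf, _ = gate_targets(mech, protocol.holding_mV, params)
    m = np.full(len(steps), float(m_inf))
    h = np.full(len(steps), float(h_inf) if h_inf is not None else 1.0)
    m_inf_s, tau_m_s, h_inf_s, tau_h_s = gate_targets(mech, steps, params)
    t = np.arange(n_pre + n_step + 1) * dt - protocol.pre_ms
    cur = np.zeros((len(t), len(steps)))
    pm, ph = channel.gate_exponents
    e_rev = channel.e_rev

    def current(vv, m, h):
        return gbar_nS * m ** pm * h ** ph * (vv - e_rev) * 1e-3  # nA

    cur[:n_pre + 1, :] = current(protocol.holding_mV, m, h)
    for k in range(n_step):
        m = _exp_relax(m, m_inf_s, tau_m_s, dt)
        if h_inf_s is not None:
            h = _exp_relax(h, h_inf_s, tau_h_s, dt)
        cur[n_pre + 1 + k, :] = current(steps, m, h)
    post = cur[n_pre + 1:, :]
    peak_idx = np.argmax(np.abs(post), axis=0)
    peaks = post[peak_idx, np.arange(len(steps))]
    table = pd.DataFrame({"step_mV": steps, "i_peak_nA": peaks})
    return t, cur, table


# ---------------------------------------------------------------------------
# Bombardment / gEPSP / subthreshold EPSP
# ---------------------------------------------------------------------------

def _bombardment_synapses(protocol: BombardmentProtocol, rng) -> list[AlphaSynapseSpec]:
    syns = [AlphaSynapseSpec(onset_ms=float(x), gmax_nS=protocol.gmax_nS,
                             tau_ms=protocol.tau_exc_ms, e_rev=protocol.e_exc)
            for x in rng.uniform(0.0, protocol.duration_ms, protocol.n_exc)]
    syns += [AlphaSynapseSpec(onset_ms=float(x), gmax_nS=protocol.gmax_nS,
                              tau_ms=protocol.tau_inh_ms, e_rev=protocol.e_inh)
             for x in rng.uniform(0.0, protocol.duration_ms, protocol.n_inh)]
    return syns


def run_bombardment(cell_config: dict | None = None,
                    protocol: BombardmentProtocol = BombardmentProtocol(),
                    delta_shifts: Sequence[float] = (0.0,),
                    n_seeds: int = 10,
                    seed: int = 0,
                    dt: float = DT_DEFAULT,
                    i_bias_pA: float = 0.0) -> pd.DataFrame:
    """Mean firing rate (+- SEM over seeds) of the PV model under random
    synaptic bombardment, for each Kv3 activation-voltage shift.

    Synaptic event times are drawn independently per seed and shared across
    shift conditions, so shift effects are paired comparisons.
    """
    rows = []
    rates = np.zeros((len(delta_shifts), n_seeds))
    for s in range(n_seeds):
        rng = np.random.default_rng([seed, s])
        syns = _bombardment_synapses(protocol, rng)
        for i, shift in enumerate(delta_shifts):
            cfg = dict(cell_config or {})
            cfg["kv3_shift"] = shift
            cell = make_pv_cell(cfg)
            tr = simulate(cell, protocol.duration_ms, dt=dt, i_inj_pA=i_bias_pA,
                          synapses=syns, settle_ms=100.0)
            rates[i, s] = detect_spikes(tr).rate_hz
    for i, shift in enumerate(delta_shifts):
        rows.append({
            "delta_shift_mV": shift,
            "rate_hz": rates[i].mean(),
            "sem_hz": rates[i].std(ddof=1) / np.sqrt(n_seeds) if n_seeds > 1 else 0.0,
            "n_seeds": n_seeds,
        })
    return pd.DataFrame(rows)


def run_gepsp_train(cell: CellModel,
                    protocol: GEPSPTrainProtocol = GEPSPTrainProtocol(),
                    dynclamp: DynamicClampSpec | None = None,
                    dt: float = DT_DEFAULT) -> float:
    """Spike probability in response to a regular gEPSP train.

    Each event is an excitatory alpha conductance; an event counts as
    evoking a spike if a detected spike falls within 10 ms after its onset.
    The event times are identical across dynamic-clamp conditions.
    """
    period = 1000.0 / protocol.rate_hz
    onsets = 50.0 + period * np.arange(protocol.n_events)
    syns = [AlphaSynapseSpec(onset_ms=float(o), gmax_nS=protocol.g_epsp_nS,
                             tau_ms=protocol.tau_ms, e_rev=0.0)
            for o in onsets]
    duration = onsets[-1] + period
    tr = simulate(cell, duration, dt=dt, synapses=syns, dynclamp=dynclamp,
                  settle_ms=100.0)
    st = detect_spikes(tr)
    evoked = sum(1 for o in onsets
                 if np.any((st.times_ms >= o) & (st.times_ms < o + 10.0)))
    return evoked / protocol.n_events


def run_subthreshold_epsp(cell_config: dict | None = None,
                          g_epsp_nS: float = 2.0,
                          delta_shifts: Sequence[float] = (0.0, -5.0, -10.0),
                          dt: float = DT_DEFAULT) -> pd.DataFrame:
    """Peak subthreshold EPSP amplitude vs Kv3 activation shift.

    Raises if any condition spikes (the conductance must stay
    subthreshold everywhere).
    """
    rows = []
    for shift in delta_shifts:
        cfg = dict(cell_config or {})
        cfg["kv3_shift"] = shift
        cell = make_pv_cell(cfg)
        syn = AlphaSynapseSpec(onset_ms=20.0, gmax_nS=g_epsp_nS,
                               tau_ms=0.5, e_rev=0.0)
        tr = simulate(cell, 80.0, dt=dt, synapses=[syn], settle_ms=200.0)
        if len(detect_spikes(tr).times_ms):
            raise ValueError(f"condition shift={shift} mV spiked; "
                             "g_epsp is not subthreshold")
        v = tr.v[:, 0]
        base = v[int(round(20.0 / dt))]
        rows.append({"delta_shift_mV": shift,
                     "epsp_amplitude_mV": float(v.max() - base)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Parameter scans
# ---------------------------------------------------------------------------

def _fi_and_ap(cfg, protocol, dt, metric_amp_index=4):
    cell = make_pv_cell(cfg)
    fi = run_fi_curve(cell, protocol, dt=dt)
    amps = np.asarray(protocol.amplitudes_pA_per_pF, float)
    inj = amps * protocol.capacitance_pF
    tr = simulate(cell, protocol.duration_ms, dt=dt, i_inj_pA=inj,
                  settle_ms=protocol.baseline_ms)
    try:
        m = ap_metrics(tr, 0, column=metric_amp_index)
    except ValueError:
        m = None
    return fi, m


def scan_nav(cell_config: dict | None = None,
             density_factors: Sequence[float] = (0.5, 0.75, 1.0, 1.25, 1.5),
             protocol: SquarePulseProtocol = SquarePulseProtocol(),
             dt: float = DT_DEFAULT,
             metric_amp_index: int = 4) -> pd.DataFrame:
    """F-I families and AP metrics across sodium conductance densities.

    ``metric_amp_index`` selects the amplitude at which the first AP is
    analyzed; index 2 (a near-threshold step) compares first APs before
    use-dependent sodium run-down sets in at reduced densities.
    """
    base = dict(cell_config or {})
    gna0 = base.get("gna", make_pv_cell().params["gna"])
    rows = []
    for f in density_factors:
        cfg = dict(base)
        cfg["gna"] = gna0 * f
        fi, m = _fi_and_ap(cfg, protocol, dt, metric_amp_index)
        rows.append({
            "density_factor": f,
            "fi": fi,
            "freq_max_hz": fi.frequency_hz.iloc[-1],
            "half_width_ms": m.half_width_ms if m else np.nan,
            "threshold_mV": m.threshold_mV if m else np.nan,
            "max_dvdt_V_per_s": m.max_dvdt_V_per_s if m else np.nan,
            "amplitude_mV": m.amplitude_mV if m else np.nan,
        })
    return pd.DataFrame(rows)


def scan_kv7(cell_config: dict | None = None,
             g_kv7_S_cm2: Sequence[float] = (0.0, 2e-3),
             kv7_shifts: Sequence[float] = (0.0, -10.0),
             protocol: SquarePulseProtocol = SquarePulseProtocol(),
             dt: float = DT_DEFAULT) -> pd.DataFrame:
    """F-I and AP metrics across Kv7 densities and activation shifts."""
    rows = []
    for g in g_kv7_S_cm2:
        for shift in (kv7_shifts if g > 0 else (0.0,)):
            cfg = dict(cell_config or {})
            cfg["gkv7"] = g
            cfg["kv7_shift"] = shift
            fi, m = _fi_and_ap(cfg, protocol, dt)
            rows.append({"g_kv7_S_cm2": g, "kv7_shift_mV": shift, "fi": fi,
                         "freq_max_hz": fi.frequency_hz.iloc[-1],
                         "half_width_ms": m.half_width_ms if m else np.nan,
                         "amplitude_mV": m.amplitude_mV if m else np.nan})
    return pd.DataFrame(rows)


def scan_kv3_inactivation(cell_config: dict | None = None,
                          tau_inact_ms: Sequence[float] = (50.0, 200.0, 1000.0),
                          inact_shifts: Sequence[float] = (0.0,),
                          protocol: SquarePulseProtocol = SquarePulseProtocol(),
                          dt: float = DT_DEFAULT) -> pd.DataFrame:
    """F-I and AP metrics across Kv3 inactivation kinetics and voltage."""
    rows = []
    for ti in tau_inact_ms:
        for hs in inact_shifts:
            cfg = dict(cell_config or {})
            cfg["kv3_tau_inact"] = ti
            cfg["kv3_inact_shift"] = hs
            fi, m = _fi_and_ap(cfg, protocol, dt)
            rows.append({"tau_inact_ms": ti, "inact_shift_mV": hs, "fi": fi,
                         "freq_max_hz": fi.frequency_hz.iloc[-1],
                         "half_width_ms": m.half_width_ms if m else np.nan,
                         "amplitude_mV": m.amplitude_mV if m else np.nan})
    return pd.DataFrame(rows)
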