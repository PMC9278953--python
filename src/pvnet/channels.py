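"""Voltage-gated channel mechanisms as pure gating mathematics.

Implements the gating equations used throughout the package, decoupled from
any integrator: the fast-spiking interneuron Kv3 conductance (with
user-facing shift and kinetics knobs), the classic Hodgkin-Huxley sodium
channel, a Kv7/M-type potassium conductance, a slowly inactivating
persistent sodium current (used by the bursting pyramidal-cell model), and
passive leak.

Conventions
-----------
Voltages are in mV, time constants in ms, currents positive-outward.

``delta_shift`` is the user-facing shift of a mechanism's half-activation
voltage: negative values hyperpolarize (left-shift) the activation curve.
The Kv3 equations are written with an internal ``vshift`` term that enters
the exponent with the opposite sense, so ``vshift = -delta_shift``.  With
zero shift the Kv3 half-activation voltage is -5.0 mV; ``delta_shift=-10``
moves it to -15.0 mV, the "AD-like" condition.

``kin_scale`` multiplies activation/deactivation time constants: values
below 1 mean faster kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import exprel

__all__ = [
    "GateParams",
    "GateState",
    "ChannelSpec",
    "kv3_minf",
    "kv3_hinf",
    "kv3_mtau",
    "nav_hh_rates",
    "kv7_minf",
    "kv7_mtau",
    "nap_rates",
    "burster_na_rates",
    "burster_k_rates",
    "gate_targets",
    "gate_step",
    "channel_current",
]

MechanismId = Literal["kv3", "nav_hh", "kv7", "nap", "burster_na", "burster_k", "leak"]

# Kv3 gating constants (mV): half-activation -5, slope 12; half-inactivation
# -30, slope 10; time-constant bell centered at -25, width 25, floor 0.5 ms,
# peak amplitude 4 ms above the floor.
KV3_ACT_OFFSET = 5.0
KV3_ACT_SLOPE = 12.0
KV3_INACT_OFFSET = 30.0
KV3_INACT_SLOPE = 10.0
KV3_TAU_FLOOR = 0.5
KV3_TAU_PEAK = 4.0
KV3_TAU_CENTER_OFFSET = 25.0
KV3_TAU_WIDTH = 25.0

KV7_VHALF = -27.0  # mV, M-current half-activation


def _vshift(delta_shift: float) -> float:
    """Map the public half-activation shift to the formula's vshift term."""
    return -np.asarray(delta_shift, dtype=float)


@dataclass(frozen=True)
class GateParams:
    """Parameters of one gating mechanism.

    ``v_half_offset`` and ``slope`` are mechanism constants (they default to
    the Kv3 activation values); ``delta_shift`` and ``kin_scale`` are the
    user-facing perturbation knobs; ``tau_inact`` is the Kv3 inactivation
    time constant (1000 ms unless a figure states otherwise).
    """

    v_half_offset: float = KV3_ACT_OFFSET
    slope: float = KV3_ACT_SLOPE
    delta_shift: float = 0.0
    kin_scale: float = 1.0
    # multiplier on the HH sodium alpha_h rate only: values < 1 slow
    # inactivation recovery (use dependence) without touching the
    # depolarized closing rate that shapes the spike
    h_alpha_scale: float = 1.0
    tau_inact: float = 1000.0
    # shift applied to the inactivation curve only (independent of the
    # activation shift; used for the inactivation-voltage scans)
    inact_shift: float = 0.0
    # where kin_scale enters mtau: "gaussian" multiplies only the bell term,
    # "whole" multiplies the full expression (both coincide at scale=1)
    kin_scale_mode: Literal["gaussian", "whole"] = "gaussian"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if self.kin_scale <= 0:
            raise ValueError("kin_scale must be positive")
        if self.tau_inact <= 0:
            raise ValueError("tau_inact must be positive")

    def with_shift(self, delta_shift: float) -> "GateParams":
        return replace(self, delta_shift=delta_shift)


@dataclass
class GateState:
    """Activation (m) and inactivation (h) fractions, each in [0, 1]."""

    m: np.ndarray
    h: np.ndarray


@dataclass(frozen=True)
class ChannelSpec:
    """A conductance attached to a compartment.

    ``gbar`` is either a density in S/cm^2 (``gbar_mode="density"``) or an
    absolute conductance in nS (``gbar_mode="absolute"``).  ``gate_exponents``
    are the integer powers (p_m, p_h) applied to the gate fractions.
    """

    mechanism_id: MechanismId
    gbar: float
    e_rev: float
    gbar_mode: Literal["density", "absolute"] = "density"
    gates: GateParams = field(default_factory=GateParams)
    gate_exponents: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ValueError("gbar must be nonnegative")
        if any(p < 0 for p in self.gate_exponents):
            raise ValueError("gate exponents must be nonnegative")


# ---------------------------------------------------------------------------
# Kv3
# ---------------------------------------------------------------------------

def kv3_minf(v, delta_shift: float = 0.0):
    """Kv3 steady-state activation: 1 - 1/(1 + exp((v + 5 + vshift)/12)).

    Equals 0.5 at v = -5 + delta_shift; strictly increasing in v.
    """
    vs = _vshift(delta_shift)
    return 1.0 - 1.0 / (1.0 + np.exp((np.asarray(v, float) + KV3_ACT_OFFSET + vs) / KV3_ACT_SLOPE))


def kv3_hinf(v, delta_shift: float = 0.0):
    """Kv3 steady-state inactivation: 1/(1 + exp((v + 30 + vshift)/10)).

    Equals 0.5 at v = -30 + delta_shift; strictly decreasing in v.
    """
    vs = _vshift(delta_shift)
    return 1.0 / (1.0 + np.exp((np.asarray(v, float) + KV3_INACT_OFFSET + vs) / KV3_INACT_SLOPE))


def kv3_mtau(v, delta_shift: float = 0.0, kin_scale: float = 1.0,
             kin_scale_mode: str = "gaussian"):
    """Kv3 activation/deactivation time constant (ms).

    A Gaussian bell over voltage on a constant floor:

        mtau = 0.5 + 4 * exp(-0.5 * ((v + vshift + 25) / 25)^2) * scale

    peaking at 4.5 ms (scale=1) at v = -25 + delta_shift and decaying to the
    0.5 ms floor far from the peak.  ``kin_scale_mode`` selects whether the
    scale factor multiplies only the Gaussian term (default, matching the
    printed operator order) or the whole expression.
    """
    if kin_scale <= 0:
        raise ValueError("kin_scale must be positive")
    vs = _vshift(delta_shift)
    x = (np.asarray(v, float) + vs + KV3_TAU_CENTER_OFFSET) / KV3_TAU_WIDTH
    bell = KV3_TAU_PEAK * np.exp(-0.5 * x * x)
    if kin_scale_mode == "whole":
        return (KV3_TAU_FLOOR + bell) * kin_scale
    return KV3_TAU_FLOOR + bell * kin_scale


# ---------------------------------------------------------------------------
# Hodgkin-Huxley sodium
# ---------------------------------------------------------------------------

def nav_hh_rates(v, v_shift: float = 0.0, kin_scale: float = 1.0,
                 h_alpha_scale: float = 1.0):
    """Classic HH sodium steady states and time constants.

    Returns ``(m_inf, h_inf, tau_m, tau_h)`` evaluated at ``v - v_shift``
    (so a negative ``v_shift`` left-shifts the curves, same convention as
    ``delta_shift``), with both time constants multiplied by ``kin_scale``.
    ``h_alpha_scale`` rescales the recovery rate alpha_h alone, slowing
    recovery from inactivation (and lowering the h steady state) while the
    closing rate beta_h is untouched.  The alpha-function removable
    singularity at v = -40 mV is evaluated by its analytic limit.
    """
    if kin_scale <= 0:
        raise ValueError("kin_scale must be positive")
    u = np.asarray(v, float) - v_shift
    # alpha_m = 0.1*(u+40)/(1-exp(-(u+40)/10)) = 1/exprel(-(u+40)/10)
    alpha_m = 1.0 / exprel(-(u + 40.0) / 10.0)
    beta_m = 4.0 * np.exp(-(u + 65.0) / 18.0)
    alpha_h = h_alpha_scale * 0.07 * np.exp(-(u + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(u + 35.0) / 10.0))
    m_inf = alpha_m / (alpha_m + beta_m)
    h_inf = alpha_h / (alpha_h + beta_h)
    tau_m = kin_scale / (alpha_m + beta_m)
    tau_h = kin_scale / (alpha_h + beta_h)
    return m_inf, h_inf, tau_m, tau_h


# ---------------------------------------------------------------------------
# Kv7 / M-current
# ---------------------------------------------------------------------------

KV7_SLOPE = 5.0


def kv7_minf(v, delta_shift: float = 0.0):
    """Kv7 (M-current) steady-state activation; 0.5 at v = -27 + delta_shift."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - (KV7_VHALF + delta_shift)) / KV7_SLOPE))


def kv7_mtau(v, kin_scale: float = 1.0):
    """Kv7 activation time constant (ms), slow and bell-shaped.

    Yamada-style M-current kinetics: tau = 1000/(3.3*(exp((v+35)/40) +
    exp(-(v+35)/20))), giving ~150 ms near -35 mV.  Kept fixed across all
    shift conditions (the M-current is incorporated with its kinetics
    unchanged).
    """
    u = np.asarray(v, float) + 35.0
    return kin_scale * 1000.0 / (3.3 * (np.exp(u / 40.0) + np.exp(-u / 20.0)))


# ---------------------------------------------------------------------------
# Pyramidal-cell burster mechanisms
# ---------------------------------------------------------------------------
# A square-wave pacemaker-burster formulation: a fast spiking subsystem in
# which sodium activates instantaneously and shares its recovery variable
# with the delayed-rectifier gate (INa = gNa*m_inf^3*(1-n)*(V-ENa),
# IK = gK*n^4*(V-EK)), plus a persistent sodium current whose slow
# inactivation (seconds) paces burst onset and termination.

def nap_rates(v):
    """Persistent Na: instantaneous activation, slow inactivation.

    m_inf half -40 mV (slope 6); h_inf half -48 mV (slope 6, decreasing);
    tau_h = 10000/cosh((v+48)/12) ms.  The slow h gate is the burst clock.
    """
    u = np.asarray(v, float)
    m_inf = 1.0 / (1.0 + np.exp(-(u + 40.0) / 6.0))
    h_inf = 1.0 / (1.0 + np.exp((u + 48.0) / 6.0))
    tau_m = np.full_like(u, 0.05) if getattr(u, "ndim", 0) else 0.05
    tau_h = 10000.0 / np.cosh((u + 48.0) / 12.0)
    return m_inf, h_inf, tau_m, tau_h


def _burster_n(v):
    """Shared recovery gate n of the burster fast subsystem."""
    u = np.asarray(v, float)
    n_inf = 1.0 / (1.0 + np.exp(-(u + 29.0) / 4.0))
    tau_n = 10.0 / np.cosh((u + 29.0) / 8.0)
    return n_inf, tau_n


def burster_na_rates(v):
    """Fast Na of the burster: instantaneous m, recovery h = 1 - n."""
    u = np.asarray(v, float)
    m_inf = 1.0 / (1.0 + np.exp(-(u + 34.0) / 5.0))
    n_inf, tau_n = _burster_n(u)
    tau_m = np.full_like(u, 0.05) if getattr(u, "ndim", 0) else 0.05
    return m_inf, 1.0 - n_inf, tau_m, tau_n


def burster_k_rates(v):
    """Delayed rectifier of the burster: the n gate itself (exponent 4)."""
    n_inf, tau_n = _burster_n(v)
    return n_inf, None, tau_n, None


# ---------------------------------------------------------------------------
# Dispatch, gate integration, current
# ---------------------------------------------------------------------------

def gate_targets(mechanism_id: str, v, params: GateParams):
    """Steady states and time constants ``(m_inf, tau_m, h_inf, tau_h)``.

    The single dispatch point used by integrators; ``leak`` has no gates and
    returns ones/None placeholders.
    """
    if mechanism_id == "kv3":
        m_inf = kv3_minf(v, params.delta_shift)
        tau_m = kv3_mtau(v, params.delta_shift, params.kin_scale,
                         params.kin_scale_mode)
        h_inf = kv3_hinf(v, params.delta_shift + params.inact_shift)
        tau_h = params.tau_inact
        return m_inf, tau_m, h_inf, tau_h
    if mechanism_id == "nav_hh":
        m_inf, h_inf, tau_m, tau_h = nav_hh_rates(v, params.delta_shift,
                                                  params.kin_scale,
                                                  params.h_alpha_scale)
        return m_inf, tau_m, h_inf, tau_h
    if mechanism_id == "kv7":
        m_inf = kv7_minf(v, params.delta_shift)
        tau_m = kv7_mtau(v, params.kin_scale)
        return m_inf, tau_m, None, None
    if mechanism_id == "nap":
        m_inf, h_inf, tau_m, tau_h = nap_rates(v)
        return m_inf, tau_m * params.kin_scale, h_inf, tau_h * params.kin_scale
    if mechanism_id == "burster_na":
        m_inf, h_inf, tau_m, tau_h = burster_na_rates(v)
        return m_inf, tau_m, h_inf, tau_h * params.kin_scale
    if mechanism_id == "burster_k":
        n_inf, _, tau_n, _ = burster_k_rates(v)
        return n_inf, tau_n * params.kin_scale, None, None
    if mechanism_id == "leak":
        return None, None, None, None
    raise ValueError(f"unknown mechanism {mechanism_id!r}")


def _exp_relax(x, x_inf, tau, dt):
    """Exact exponential relaxation of dx/dt = (x_inf - x)/tau over dt."""
    return x_inf + (x - x_inf) * np.exp(-dt / tau)


def gate_step(state: GateState, v, dt: float, params: GateParams,
              mechanism_id: str = "kv3") -> GateState:
    """Advance gates by one exact-exponential step at fixed voltage.

    m' = m_inf + (m - m_inf)·exp(-dt/tau_m), likewise h.  Exact for
    constant v, hence unconditionally stable and semigroup-consistent
    (k substeps of dt equal one step of k·dt).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    m_inf, tau_m, h_inf, tau_h = gate_targets(mechanism_id, v, params)
    m = state.m if m_inf is None else _exp_relax(state.m, m_inf, tau_m, dt)
    h = state.h if h_inf is None else _exp_relax(state.h, h_inf, tau_h, dt)
    return GateState(m=np.clip(m, 0.0, 1.0), h=np.clip(h, 0.0, 1.0))


def channel_current(spec: ChannelSpec, state: GateState, v):
    """Ohmic channel current, positive outward; zero at v = e_rev.

    Returns nA for ``gbar_mode="absolute"`` (gbar in nS) and mA/cm^2 for
    ``gbar_mode="density"`` (gbar in S/cm^2).
    """
    pm, ph = spec.gate_exponents
    g = spec.gbar * state.m ** pm * state.h ** ph
    dv = np.asarray(v, float) - spec.e_rev
    if spec.gbar_mode == "absolute":
        return g * dv * 1e-3  # nS * mV = pA; report nA
    return g * dv  # S/cm^2 * mV = mA/cm^2
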