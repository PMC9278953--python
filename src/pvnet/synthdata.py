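"""Synthetic stand-ins for raw electrophysiology inputs.

Generates outside-out-patch-like K+ current families with known ground
truth (Boltzmann voltage dependence, mono-exponential activation, slow
inactivation, additive Gaussian noise) and homogeneous Poisson spike
trains, so every analysis stage can be tested against parameters it is
supposed to recover rather than against recordings.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .protocols import VClampStepProtocol

__all__ = [
    "PatchGeneratorSpec",
    "WT_PATCH",
    "AD_PATCH",
    "generate_patch_family",
    "generate_poisson_trains",
]


@dataclass(frozen=True)
class PatchGeneratorSpec:
    """Ground-truth parameters of a synthetic patch recording.

    Activation is Boltzmann (v_half, slope) with a mono-exponential
    approach to steady state whose time constant is a Gaussian bell over
    voltage (tau_floor + tau_peak * exp(-((v - tau_center)/tau_width)^2/2));
    inactivation is mono-exponential with ``tau_inact``.  Noise is additive
    white Gaussian on the current.
    """

    v_half_mV: float = -6.6
    slope_mV: float = 12.0
    gmax_nS: float = 20.0
    tau_peak_ms: float = 4.0
    tau_center_mV: float = -25.0
    tau_width_mV: float = 25.0
    tau_floor_ms: float = 0.5
    tau_inact_ms: float = 1000.0
    e_rev_mV: float = -90.0
    noise_sd_nA: float = 0.0
    protocol: VClampStepProtocol = field(default_factory=VClampStepProtocol)
    dt_ms: float = 0.025

    def __post_init__(self) -> None:
        if self.noise_sd_nA < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.gmax_nS <= 0:
            raise ValueError("gmax must be positive")


# The two reference conditions: a wild-type-like activation voltage and the
# AD-like hyperpolarized one (the ~9 mV left shift seen in the disease
# condition).
WT_PATCH = PatchGeneratorSpec(v_half_mV=-6.6)
AD_PATCH = PatchGeneratorSpec(v_half_mV=-15.5)


def _m_inf(v, spec: PatchGeneratorSpec):
    return 1.0 / (1.0 + np.exp(-(v - spec.v_half_mV) / spec.slope_mV))


def _tau_m(v, spec: PatchGeneratorSpec):
    x = (v - spec.tau_center_mV) / spec.tau_width_mV
    return spec.tau_floor_ms + spec.tau_peak_ms * np.exp(-0.5 * x * x)


def generate_patch_family(spec: PatchGeneratorSpec = WT_PATCH,
                          seed: int = 0):
    """Synthetic voltage-clamp current family with its ground truth.

    Returns ``(df, truth)``: a long-format DataFrame with columns
    ``t_ms``, ``step_mV``, ``i_nA`` (one step family per step voltage,
    t=0 at step onset) and a dict of the generating parameters.
    """
    rng = np.random.default_rng(seed)
    prot = spec.protocol
    steps = np.asarray(prot.steps_mV, float)
    n = int(round(prot.step_duration_ms / spec.dt_ms))
    t = np.arange(n + 1) * spec.dt_ms
    m0 = _m_inf(prot.holding_mV, spec)
    frames = []
    for v in steps:
        m_inf, tau = _m_inf(v, spec), _tau_m(v, spec)
        m = m_inf + (m0 - m_inf) * np.exp(-t / tau)
        h = np.exp(-t / spec.tau_inact_ms)
        i = spec.gmax_nS * m * h * (v - spec.e_rev_mV) * 1e-3  # nA
        if spec.noise_sd_nA > 0:
            i = i + rng.normal(0.0, spec.noise_sd_nA, size=i.shape)
        frames.append(pd.DataFrame({"t_ms": t, "step_mV": v, "i_nA": i}))
    df = pd.concat(frames, ignore_index=True)
    truth = asdict(spec)
    truth["protocol"] = {"holding_mV": prot.holding_mV,
                         "steps_mV": list(steps),
                         "step_duration_ms": prot.step_duration_ms}
    truth["seed"] = seed
    return df, truth


def generate_poisson_trains(rate_hz: float, duration_ms: float, n: int,
                            seed: int = 0) -> list[np.ndarray]:
    """n homogeneous Poisson spike trains (times in ms, sorted)."""
    if rate_hz < 0:
        raise ValueError("rate must be nonnegative")
    rng = np.random.default_rng(seed)
    trains = []
    lam = rate_hz * duration_ms / 1000.0
    for _ in range(n):
        k = rng.poisson(lam)
        trains.append(np.sort(rng.uniform(0.0, duration_ms, k)))
    return trains
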