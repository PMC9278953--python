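"""Curve fitting for voltage-clamp and trend analyses.

Chord conductance from peak currents, Boltzmann activation/inactivation
fits, mono-exponential rise fits for activation kinetics, and the
exponential trend fit (with R-squared) used for the gamma-power versus
voltage-shift relation.  All fitters are thin, deterministic wrappers
around ``scipy.optimize.curve_fit`` with data-driven initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GVPoint",
    "BoltzmannFit",
    "ExpFit",
    "MonoExpFit",
    "chord_conductance",
    "fit_boltzmann",
    "fit_monoexp_rise",
    "fit_exponential_trend",
]


@dataclass(frozen=True)
class GVPoint:
    """One conductance-voltage point (chord conductance at a step)."""

    v_mV: float
    g_nS: float
    g_norm: float = np.nan


@dataclass(frozen=True)
class BoltzmannFit:
    v_half_mV: float
    slope_mV: float
    gmax_nS: float
    rss: float
    converged: bool

    def g(self, v):
        return self.gmax_nS / (1.0 + np.exp(-(np.asarray(v, float) - self.v_half_mV) / self.slope_mV))


@dataclass(frozen=True)
class MonoExpFit:
    tau_ms: float
    amplitude: float
    offset: float
    rss: float
    converged: bool


@dataclass(frozen=True)
class ExpFit:
    amplitude: float
    rate: float
    offset: float
    r_squared: float
    converged: bool

    def y(self, x):
        return self.amplitude * np.exp(self.rate * np.asarray(x, float)) + self.offset


def chord_conductance(i_peak_nA, v_mV, e_rev_mV) -> np.ndarray | float:
    """g = I / (V - E_rev) in nS from peak current (nA) and voltages (mV).

    Negative conductances (current against the driving force, typically
    noise near the reversal) are clipped to zero with a warning.  Raises on
    v == e_rev where the chord is undefined.
    """
    v = np.asarray(v_mV, float)
    if np.any(v == e_rev_mV):
        raise ValueError("chord conductance undefined at v == e_rev")
    g = np.asarray(i_peak_nA, float) / (v - e_rev_mV) * 1e3  # nA/mV = uS -> nS
    if np.any(g < 0):
        warnings.warn("negative chord conductance clipped to 0", stacklevel=2)
        g = np.clip(g, 0.0, None)
    return g if g.ndim else float(g)


def _boltzmann(v, gmax, v_half, slope):
    return gmax / (1.0 + np.exp(-(v - v_half) / slope))


def fit_boltzmann(points) -> BoltzmannFit:
    """Least-squares Boltzmann fit g(v) = gmax / (1 + exp(-(v-v1/2)/k)).

    ``points`` is a sequence of GVPoint or an (v, g) array pair.
    Initialization: gmax from the plateau, v_half from the half-max
    crossing, slope from the 25-75% span.  Needs >= 4 distinct voltages.
    """
    if isinstance(points, tuple):
        v, g = (np.asarray(a, float) for a in points)
    else:
        v = np.array([p.v_mV for p in points], float)
        g = np.array([p.g_nS for p in points], float)
    if len(np.unique(v)) < 4:
        raise ValueError("need at least 4 distinct voltages")
    order = np.argsort(v)
    v, g = v[order], g[order]
    gmax0 = max(g.max(), 1e-12)
    gm = np.maximum.accumulate(g)  # monotonized for initialization
    v_half0 = float(np.interp(gmax0 / 2.0, gm, v))
    v25 = float(np.interp(0.25 * gmax0, gm, v))
    v75 = float(np.interp(0.75 * gmax0, gm, v))
    slope0 = max((v75 - v25) / 2.2, 0.5)  # logit(0.75)-logit(0.25) = 2.2
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            popt, _ = curve_fit(_boltzmann, v, g, p0=[gmax0, v_half0, slope0],
                                maxfev=10000)
        converged = popt[0] > 0 and popt[2] > 0
    except RuntimeError:
        popt = [gmax0, v_half0, slope0]
        converged = False
    resid = g - _boltzmann(v, *popt)
    rss = float(resid @ resid)
    # a "fit" that explains less than 3/4 of the variance is degenerate
    tss = float(np.sum((g - g.mean()) ** 2))
    if tss > 0 and rss > 0.25 * tss:
        converged = False
    return BoltzmannFit(v_half_mV=float(popt[1]), slope_mV=float(popt[2]),
                        gmax_nS=float(popt[0]), rss=rss,
                        converged=bool(converged))


def _rising_exp(t, amp, tau, offset):
    return amp * (1.0 - np.exp(-t / tau)) + offset


def fit_monoexp_rise(t_ms, i) -> MonoExpFit:
    """Fit I(t) = A*(1 - exp(-t/tau)) + C to a rising current segment.

    ``t_ms`` must start at the step onset (t=0).  The segment must be
    predominantly monotone rising (in magnitude); otherwise the fit is
    flagged as non-converged.
    """
    t = np.asarray(t_ms, float)
    y = np.asarray(i, float)
    if len(t) < 4:
        raise ValueError("need at least 4 samples")
    sgn = 1.0 if y[-1] >= y[0] else -1.0
    yy = sgn * y
    span = yy[-1] - yy[0]
    if span <= 0 or np.mean(np.diff(yy) > 0) < 0.5:
        raise ValueError("segment is not predominantly rising")
    # tau0 from the 63% crossing
    tau0 = float(np.interp(yy[0] + 0.632 * span,
                           np.maximum.accumulate(yy), t))
    tau0 = max(tau0, (t[1] - t[0]))
    try:
        popt, _ = curve_fit(_rising_exp, t, yy, p0=[span, tau0, yy[0]],
                            maxfev=10000)
        converged = popt[1] > 0
    except RuntimeError:
        popt = [span, tau0, yy[0]]
        converged = False
    resid = yy - _rising_exp(t, *popt)
    return MonoExpFit(tau_ms=float(abs(popt[1])), amplitude=float(sgn * popt[0]),
                      offset=float(sgn * popt[2]), rss=float(resid @ resid),
                      converged=bool(converged))


def _exp_trend(x, a, b, c):
    return a * np.exp(b * x) + c


def fit_exponential_trend(x, y) -> ExpFit:
    """Least-squares y = a*exp(b*x) + c with R^2 = 1 - RSS/TSS.

    TSS is taken about the mean of y (the convention noted in the fit
    report, since R^2 definitions for nonlinear fits differ).  Needs >= 4
    points; non-convergence is flagged and the degenerate fit returned.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 points")
    span = y.max() - y.min()
    c0 = y.min()
    a0 = max(span, 1e-12) * 0.1
    xs = x.max() - x.min()
    b0 = (np.log(max(span, 1e-9) / max(a0, 1e-12)) / xs) if xs > 0 else 1.0
    try:
        popt, _ = curve_fit(_exp_trend, x, y, p0=[a0, b0, c0], maxfev=20000)
        converged = True
    except RuntimeError:
        popt = [a0, b0, c0]
        converged = False
    resid = y - _exp_trend(x, *popt)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return ExpFit(amplitude=float(popt[0]), rate=float(popt[1]),
                  offset=float(popt[2]), r_squared=float(np.clip(r2, 0.0, 1.0)),
                  converged=bool(converged))
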