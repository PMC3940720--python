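"""Summary-kinetics extraction from whole-cell current traces.

Implements the standard electrophysiology analyses: peak-conductance
G-V curves (``G = I_peak / (V - E)``), Boltzmann fits of activation and
availability, single-exponential time constants (activation,
inactivation, deactivation tails) and fractional recovery from
two-pulse protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError
from .protocols import CurrentTrace, VoltageProtocol

__all__ = [
    "BoltzmannFit",
    "ExpFit",
    "RecoveryCurve",
    "peak_current",
    "gv_curve",
    "fit_boltzmann",
    "fit_exponential",
    "fractional_recovery",
]

#: Samples skipped at each segment start before peak detection, guarding
#: against the instantaneous-voltage transient of the first samples.
PEAK_GUARD_SAMPLES = 2


@dataclass(frozen=True)
class BoltzmannFit:
    """Two-state Boltzmann description of a (de)activation curve.

    Activation:   y = amplitude / (1 + exp(-(V - v50) / kappa))
    Availability: y = amplitude / (1 + exp(+(V - v50) / kappa))
    """

    v50_mV: float
    kappa_mV: float
    amplitude: float
    direction: str
    residual: float

    def __call__(self, v_mV):
        v = np.asarray(v_mV, dtype=float)
        sign = -1.0 if self.direction == "activation" else +1.0
        return self.amplitude / (1.0 + np.exp(sign * (v - self.v50_mV) / self.kappa_mV))


@dataclass(frozen=True)
class ExpFit:
    """Single exponential with offset: y(t) = offset + amplitude * exp(-t/tau)."""

    tau_ms: float
    amplitude: float
    offset: float
    residual: float

    def __call__(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        return self.offset + self.amplitude * np.exp(-t / self.tau_ms)

    @property
    def r_squared(self) -> float:
        return 1.0 - self.residual  # residual stored as 1 - R^2

    @property
    def tau_s(self) -> float:
        return self.tau_ms / 1000.0


@dataclass(frozen=True)
class RecoveryCurve:
    """Fractional recovery (P2 peak / P1 peak) versus interpulse interval."""

    intervals_s: np.ndarray
    fractions: np.ndarray
    v_rec_mV: float
    tau_s: float
    plateau: float
    residual: float


def peak_current(
    trace: CurrentTrace, window: slice | None = None, guard: int = PEAK_GUARD_SAMPLES
) -> float:
    """Signed current of largest magnitude inside ``window``.

    The first ``guard`` samples of the window are excluded to avoid the
    numerical transient at a voltage step.
    """
    i = trace.i_pA if window is None else trace.i_pA[window]
    i = i[guard:]
    if i.size == 0:
        raise DomainError("peak window is empty after guard samples")
    return float(i[np.argmax(np.abs(i))])


def gv_curve(
    sweeps: Sequence[CurrentTrace],
    protocols: Sequence[VoltageProtocol],
    e_rev_mV: float,
    step_index: int = 0,
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-conductance curve ``G = I_peak / (V_step - E)`` per sweep.

    Sweeps where the step voltage equals the reversal potential carry no
    conductance information and are excluded.  With ``normalize=True``
    the conductances are divided by their maximum.
    """
    v_out, g_out = [], []
    for trace, proto in zip(sweeps, protocols, strict=True):
        v_step = proto.segments[step_index].voltage_mV
        if abs(v_step - e_rev_mV) < 1e-9:
            continue  # zero driving force: G undefined at this point
        window = proto.segment_sample_slices(trace.dt_ms)[step_index]
        g = peak_current(trace, window) / (v_step - e_rev_mV)
        v_out.append(v_step)
        g_out.append(g)
    v = np.asarray(v_out)
    g = np.asarray(g_out)
    if normalize and g.size:
        g = g / g.max()
    return v, g


def _boltzmann(v, amplitude, v50, kappa, sign):
    return amplitude / (1.0 + np.exp(sign * (v - v50) / kappa))


def fit_boltzmann(
    v_mV: Sequence[float],
    y: Sequence[float],
    direction: Literal["activation", "availability"] = "activation",
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a G-V or availability curve."""
    v = np.asarray(v_mV, dtype=float)
    yv = np.asarray(y, dtype=float)
    if v.size < 4:
        raise DomainError("Boltzmann fit needs at least 4 points across the transition")
    sign = -1.0 if direction == "activation" else +1.0
    span = float(v.max() - v.min())
    amp0 = float(np.abs(yv).max()) or 1.0
    # mid-point initial guess: voltage where y crosses half amplitude
    half = np.argmin(np.abs(yv - 0.5 * yv.max()))
    v50_0 = float(v[half])
    last = None
    for kappa0 in (span / 20, span / 8, span / 3):
        try:
            popt, _ = curve_fit(
                lambda vv, a, v50, k: _boltzmann(vv, a, v50, k, sign),
                v,
                yv,
                p0=(amp0, v50_0, kappa0),
                bounds=([0.0, v.min() - 5 * span, 1e-3], [np.inf, v.max() + 5 * span, 10 * span]),
                maxfev=20000,
            )
            resid = float(np.sum((yv - _boltzmann(v, *popt, sign)) ** 2))
            if last is None or resid < last[1]:
                last = (popt, resid)
        except RuntimeError:
            continue
    if last is None:
        raise FitError("Boltzmann fit did not converge", last_iterate=(amp0, v50_0))
    (amp, v50, kappa), resid = last
    return BoltzmannFit(
        v50_mV=float(v50),
        kappa_mV=float(kappa),
        amplitude=float(amp),
        direction=direction,
        residual=resid,
    )


def fit_exponential(
    t_ms: Sequence[float],
    y: Sequence[float],
    n_starts: int = 5,
) -> ExpFit:
    """Single-exponential-with-offset least squares.

    Multi-start over ``n_starts`` log-spaced initial time constants
    (from one sample interval up to 10x the segment length) to avoid
    local minima; the best converged fit is returned.  Residual is
    reported as ``1 - R^2``.
    """
    t = np.asarray(t_ms, dtype=float)
    yv = np.asarray(y, dtype=float)
    if t.size < 5:
        raise DomainError("exponential fit needs at least 5 samples")
    t0 = t - t[0]
    y_span = float(yv.max() - yv.min())
    if y_span == 0.0:
        raise FitError("segment is flat; no exponential to fit")
    total = float(t0[-1]) or 1.0
    sst = float(np.sum((yv - yv.mean()) ** 2))
    amp0 = yv[0] - yv[-1]
    best = None
    model = lambda tt, off, amp, tau: off + amp * np.exp(-tt / tau)
    for tau0 in np.geomspace(max(total / t.size, 1e-6), 10 * total, n_starts):
        try:
            popt, _ = curve_fit(
                model,
                t0,
                yv,
                p0=(yv[-1], amp0, tau0),
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 1e6 * total]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((yv - model(t0, *popt)) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise FitError("exponential fit did not converge", last_iterate=(yv[-1], amp0))
    (off, amp, tau), resid = best
    return ExpFit(
        tau_ms=float(tau),
        amplitude=float(amp),
        offset=float(off),
        residual=resid / sst if sst > 0 else resid,
    )


def fractional_recovery(
    sweeps: Sequence[CurrentTrace],
    protocols: Sequence[VoltageProtocol],
    p1_index: int = 0,
    p2_index: int = 2,
) -> RecoveryCurve:
    """Recovery curve from a two-pulse family, with its time constant.

    Fraction = P2 peak / P1 peak per sweep.  The time course is fitted
    with a single exponential with a free plateau,
    ``f(t) = plateau - (plateau - f0) * exp(-t / tau)``,
    because at depolarized recovery voltages the steady-state
    availability (hence the plateau) stays below 1.
    """
    intervals, fractions = [], []
    for trace, proto in zip(sweeps, protocols, strict=True):
        slices = proto.segment_sample_slices(trace.dt_ms)
        p1 = peak_current(trace, slices[p1_index])
        p2 = peak_current(trace, slices[p2_index])
        if abs(p1) < 1e-12:
            raise DomainError("P1 peak is ~0; fractional recovery undefined")
        intervals.append(proto.segments[p2_index - 1].duration_ms / 1000.0)
        fractions.append(p2 / p1)
    tsec = np.asarray(intervals)
    frac = np.asarray(fractions)

    def model(t, plateau, f0, tau):
        return plateau - (plateau - f0) * np.exp(-t / tau)

    best = None
    for tau0 in np.geomspace(tsec.min(), 10 * tsec.max(), 5):
        try:
            popt, _ = curve_fit(
                model,
                tsec,
                frac,
                p0=(min(frac.max(), 1.0), frac.min(), tau0),
                bounds=([0.0, 0.0, 1e-6], [1.5, 1.5, 1e5]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        resid = float(np.sum((frac - model(tsec, *popt)) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise FitError("recovery-curve fit did not converge")
    (plateau, _f0, tau), resid = best
    return RecoveryCurve(
        intervals_s=tsec,
        fractions=frac,
        v_rec_mV=protocols[0].segments[p2_index - 1].voltage_mV,
        tau_s=float(tau),
        plateau=float(plateau),
        residual=resid,
    )
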