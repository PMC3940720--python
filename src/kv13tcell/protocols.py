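"""Voltage-clamp protocol builders and gating-to-current conversion.

The four protocols used to characterize Kv1.3 whole-cell currents:

* activation family  -- 1-s steps from -70 to +50 mV (15-mV increments)
  from a -90 mV holding potential;
* steady-state inactivation (availability) family -- long conditioning
  between -80 and -10 mV (5-mV increments, treated as analytic steady
  state), then a 150-ms test pulse to +50 mV;
* deactivation family -- 7-ms pre-pulse to +50 mV, then tails between
  -100 and -30 mV (10-mV increments);
* two-pulse recovery family -- P1 (+50 mV, 1 s), a variable gap at the
  recovery voltage, then P2 (+50 mV, 150 ms).

Whole-cell current follows the macroscopic relation
``I(t) = N * g * P_o(t) * (V(t) - E)`` with g in pS, V in mV and I in pA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .markov import GatingTrace

__all__ = [
    "Segment",
    "VoltageProtocol",
    "ChannelPopulation",
    "CurrentTrace",
    "activation_protocol",
    "ssi_protocol",
    "deactivation_protocol",
    "recovery_protocol",
    "whole_cell_current",
    "DEFAULT_DT_MS",
]

#: Default sampling interval, mirroring a 20 kHz digitization rate.
DEFAULT_DT_MS = 0.05

TEST_PULSE_MV = 50.0
HOLDING_MV = -90.0


@dataclass(frozen=True)
class Segment:
    duration_ms: float
    voltage_mV: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.duration_ms) and self.duration_ms > 0):
            raise DomainError(f"segment duration must be positive, got {self.duration_ms!r}")
        if not math.isfinite(self.voltage_mV):
            raise DomainError("segment voltage must be finite")


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered piecewise-constant voltage segments for one sweep.

    ``inter_sweep_ms=None`` means the inter-sweep rest at the holding
    voltage is treated as an analytic steady state (the sweep starts
    from the stationary distribution at ``holding_mV``), which is exact
    for the 60-90 s rests used experimentally.
    """

    holding_mV: float
    segments: tuple[Segment, ...]
    inter_sweep_ms: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise DomainError("protocol must contain at least one segment")
        if self.inter_sweep_ms is not None and self.inter_sweep_ms <= 0:
            raise DomainError("inter-sweep duration must be positive when given")

    @property
    def total_duration_ms(self) -> float:
        return sum(s.duration_ms for s in self.segments)

    def segment_sample_slices(self, dt_ms: float) -> list[slice]:
        """Index ranges of each segment in a trace sampled at ``dt_ms``.

        Sample 0 is the pre-step holding point; segment k covers the
        samples generated while its voltage is applied.
        """
        slices = []
        start = 1
        for seg in self.segments:
            n = max(1, int(round(seg.duration_ms / dt_ms)))
            slices.append(slice(start, start + n))
            start += n
        return slices


def activation_protocol(
    step_duration_ms: float = 1000.0,
    v_steps: Sequence[float] | None = None,
) -> list[VoltageProtocol]:
    """Nine 1-s depolarizing steps, -70..+50 mV by 15 mV, holding -90 mV."""
    if v_steps is None:
        v_steps = np.arange(-70.0, 50.0 + 1e-9, 15.0)
    return [
        VoltageProtocol(
            holding_mV=HOLDING_MV,
            segments=(Segment(step_duration_ms, float(v)),),
            label=f"act_{float(v):+.0f}mV",
        )
        for v in v_steps
    ]


def ssi_protocol(
    test_duration_ms: float = 150.0,
    v_conditioning: Sequence[float] | None = None,
) -> list[VoltageProtocol]:
    """Steady-state inactivation family: conditioning -80..-10 mV by 5 mV.

    The long conditioning pulse is encoded as the holding voltage with
    analytic steady-state initialization; the sweep itself is the
    150-ms test pulse at +50 mV.
    """
    if v_conditioning is None:
        v_conditioning = np.arange(-80.0, -10.0 + 1e-9, 5.0)
    return [
        VoltageProtocol(
            holding_mV=float(v),
            segments=(Segment(test_duration_ms, TEST_PULSE_MV),),
            label=f"ssi_cond_{float(v):+.0f}mV",
        )
        for v in v_conditioning
    ]


def deactivation_protocol(
    prepulse_ms: float = 7.0,
    tail_ms: float = 30.0,
    v_tails: Sequence[float] | None = None,
) -> list[VoltageProtocol]:
    """Tail-current family: +50 mV for 7 ms, tails -100..-30 mV by 10 mV."""
    if v_tails is None:
        v_tails = np.arange(-100.0, -30.0 + 1e-9, 10.0)
    return [
        VoltageProtocol(
            holding_mV=HOLDING_MV,
            segments=(Segment(prepulse_ms, TEST_PULSE_MV), Segment(tail_ms, float(v))),
            label=f"deact_{float(v):+.0f}mV",
        )
        for v in v_tails
    ]


def recovery_protocol(
    v_rec_mV: float,
    intervals_ms: Iterable[float],
    p1_ms: float = 1000.0,
    p2_ms: float = 150.0,
) -> list[VoltageProtocol]:
    """Two-pulse recovery family: P1 (+50, 1 s), gap at ``v_rec``, P2 (+50, 150 ms)."""
    intervals = [float(x) for x in intervals_ms]
    if not intervals:
        raise DomainError("recovery protocol needs at least one interpulse interval")
    if any(x <= 0 for x in intervals):
        raise DomainError("interpulse intervals must be positive")
    if any(b <= a for a, b in zip(intervals, intervals[1:])):
        raise DomainError("interpulse intervals must be strictly increasing")
    return [
        VoltageProtocol(
            holding_mV=HOLDING_MV,
            segments=(
                Segment(p1_ms, TEST_PULSE_MV),
                Segment(gap, v_rec_mV),
                Segment(p2_ms, TEST_PULSE_MV),
            ),
            label=f"rec_{v_rec_mV:+.0f}mV_{gap:.0f}ms",
        )
        for gap in intervals
    ]


@dataclass(frozen=True)
class ChannelPopulation:
    """A homogeneous population of N identical channels."""

    n_channels: float = 300
    g_pS: float = 15.0
    e_rev_mV: float = -73.0

    def __post_init__(self) -> None:
        if self.n_channels < 0 or abs(self.n_channels - round(self.n_channels)) > 1e-9:
            raise DomainError(f"channel count must be a non-negative integer, got {self.n_channels!r}")
        if self.g_pS <= 0:
            raise DomainError("single-channel conductance must be positive")

    @property
    def total_conductance_nS(self) -> float:
        return self.n_channels * self.g_pS * 1e-3

    @classmethod
    def from_total_conductance(
        cls, g_total_nS: float, g_pS: float = 15.0, e_rev_mV: float = -73.0
    ) -> "ChannelPopulation":
        return cls(round(g_total_nS * 1e3 / g_pS), g_pS, e_rev_mV)


@dataclass
class CurrentTrace:
    """A sampled whole-cell current with its companion voltage trace."""

    dt_ms: float
    t_ms: np.ndarray
    i_pA: np.ndarray
    v_mV: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.i_pA = np.asarray(self.i_pA, dtype=float)
        self.v_mV = np.asarray(self.v_mV, dtype=float)
        if not (self.t_ms.shape == self.i_pA.shape == self.v_mV.shape):
            raise DomainError("time, current and voltage arrays must have equal length")
        if not (np.all(np.isfinite(self.i_pA)) and np.all(np.isfinite(self.v_mV))):
            raise DomainError("current/voltage samples must be finite")


def whole_cell_current(
    gating: GatingTrace, pop: ChannelPopulation, label: str = ""
) -> CurrentTrace:
    """Convert a gating trace to macroscopic current.

    ``I(t) = N * g * P_o(t) * (V(t) - E)``; pS * mV = 1e-3 pA.
    """
    if gating.t_ms.shape != gating.v_mV.shape:
        raise DomainError("gating trace has misaligned time/voltage arrays")
    i = pop.n_channels * pop.g_pS * 1e-3 * gating.po * (gating.v_mV - pop.e_rev_mV)
    dt = float(gating.t_ms[1] - gating.t_ms[0]) if gating.t_ms.size > 1 else 0.0
    return CurrentTrace(dt_ms=dt, t_ms=gating.t_ms, i_pA=i, v_mV=gating.v_mV, label=label)
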