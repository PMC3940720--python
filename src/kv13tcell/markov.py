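"""Sequential Markov gating model of the Kv1.3 channel.

The channel is represented as a single linear chain of states

    C1 = C2 = ... = C_k = O = I

with voltage-dependent rates on the closed-closed transitions
(``alpha`` forward, ``beta`` backward), voltage-independent rates on the
final opening step (``A`` forward, ``B`` backward) and voltage-dependent
rates on the open-inactivated transition (``eta`` forward, ``phi``
backward).  Each voltage-dependent rate is a single exponential of the
membrane voltage,

    rate(V) = prefactor * exp(sign * V / scale),

so the whole gating model is specified by ten positive scalars: four
prefactors (``a, b, c, d``; ms^-1), two constant rates (``A, B``; ms^-1)
and four voltage scales (``m, n, p, q``; mV).

Macroscopic (expected-occupancy) behaviour only: the state distribution
is propagated with the matrix exponential of the generator, which is
exact for piecewise-constant voltage protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm, null_space

from .errors import ConfigurationError, DomainError, NumericalError

__all__ = [
    "RateConstants",
    "SignConvention",
    "RateSet",
    "KineticScheme",
    "Kv13Model",
    "voltage_rates",
    "build_generator",
    "evolve",
    "steady_state",
    "open_probability_trace",
    "GatingTrace",
]

#: Probability-conservation tolerance guaranteed by the propagators.
CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class RateConstants:
    """The ten scalars defining all Kv1.3 gating rates.

    Defaults are the published whole-cell fit for Kv1.3.  ``a..d`` are
    pre-exponential factors (ms^-1) of alpha/beta/eta/phi, ``A``/``B``
    the voltage-independent open/close rates of the last activation step
    (ms^-1) and ``m, n, p, q`` the voltage scales (mV) of
    alpha/beta/eta/phi respectively.
    """

    a: float = 0.448
    b: float = 0.043
    c: float = 0.003
    d: float = 0.00008
    A: float = 280.035
    B: float = 1.648
    m: float = 27.530
    n: float = 17.528
    p: float = 174.961
    q: float = 1016.330

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "A", "B", "m", "n", "p", "q"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise DomainError(
                    f"rate constant {name!r} must be strictly positive and "
                    f"finite, got {value!r}"
                )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("a", "b", "c", "d", "A", "B", "m", "n", "p", "q")}

    @classmethod
    def from_dict(cls, values: dict) -> "RateConstants":
        return cls(**values)

    def replace(self, **kwargs) -> "RateConstants":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SignConvention:
    """Signs of the voltage exponents of the four voltage-dependent rates.

    ``+1`` means the rate grows with depolarization (``exp(+V/scale)``),
    ``-1`` that it grows with hyperpolarization.  Activation (alpha) and
    open-to-inactivated entry (eta) grow with depolarization;
    deactivation (beta) grows with hyperpolarization.  The recovery rate
    phi has a very large voltage scale (q ~ 1000 mV) so recovery is only
    weakly voltage dependent either way; the shipped default (``+1``)
    is the variant selected by calibration against the published
    recovery time constants (see docs/methods.md).
    """

    alpha: int = +1
    beta: int = -1
    eta: int = +1
    phi: int = +1

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "eta", "phi"):
            if getattr(self, name) not in (-1, +1):
                raise ConfigurationError(f"sign for {name!r} must be +1 or -1")


@dataclass(frozen=True)
class RateSet:
    """Transition rates (ms^-1) of the scheme at one fixed voltage."""

    alpha: float
    beta: float
    eta: float
    phi: float
    A: float
    B: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "eta", "phi", "A", "B"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise DomainError(
                    f"rate {name!r} must be non-negative and finite, got {value!r}"
                )

    def __getitem__(self, label: str) -> float:
        try:
            return getattr(self, label)
        except AttributeError:
            raise KeyError(label) from None


def voltage_rates(
    params: RateConstants,
    v_mV: float,
    convention: SignConvention = SignConvention(),
) -> RateSet:
    """Evaluate all six transition rates at membrane voltage ``v_mV``.

    alpha = a*exp(s_a*V/m), beta = b*exp(s_b*V/n), eta = c*exp(s_e*V/p),
    phi = d*exp(s_p*V/q); A and B are voltage independent.
    """
    if not math.isfinite(v_mV):
        raise DomainError(f"membrane voltage must be finite, got {v_mV!r}")
    return RateSet(
        alpha=params.a * math.exp(convention.alpha * v_mV / params.m),
        beta=params.b * math.exp(convention.beta * v_mV / params.n),
        eta=params.c * math.exp(convention.eta * v_mV / params.p),
        phi=params.d * math.exp(convention.phi * v_mV / params.q),
        A=params.A,
        B=params.B,
    )


@dataclass(frozen=True)
class Edge:
    """One directed transition: ``source -> target`` at ``mult * rates[label]``."""

    source: int
    target: int
    label: str
    mult: float = 1.0


_LABELS = {"alpha", "beta", "eta", "phi", "A", "B"}


@dataclass(frozen=True)
class KineticScheme:
    """State list and transition topology of the sequential Kv1.3 model.

    States are ordered ``[C1 .. C_n_closed, O, I]``.  The edge list is
    fully explicit so alternative chain lengths and per-edge rate
    multiplicities can be compared against the published summary
    kinetics; :meth:`default` returns the calibrated shipped topology.
    """

    n_closed: int
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def n_states(self) -> int:
        return self.n_closed + 2

    @property
    def open_index(self) -> int:
        return self.n_closed

    @property
    def inactivated_index(self) -> int:
        return self.n_closed + 1

    def state_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_closed)] + ["O", "I"]

    def validate(self) -> None:
        if self.n_closed < 1:
            raise ConfigurationError("scheme needs at least one closed state")
        pairs = {}
        for e in self.edges:
            if e.label not in _LABELS:
                raise ConfigurationError(f"unknown rate label {e.label!r}")
            if not (0 <= e.source < self.n_states and 0 <= e.target < self.n_states):
                raise ConfigurationError(f"edge {e} references an unknown state")
            if abs(e.source - e.target) != 1:
                raise ConfigurationError(
                    "states must form a single linear chain; "
                    f"edge {e} skips a neighbour"
                )
            if e.mult <= 0:
                raise ConfigurationError(f"edge {e} has non-positive multiplicity")
            pairs[(e.source, e.target)] = e
        for (s, t) in pairs:
            if (t, s) not in pairs:
                raise ConfigurationError(f"edge {s}->{t} has no reverse edge")
        # every neighbouring pair along the chain must be connected
        for i in range(self.n_states - 1):
            if (i, i + 1) not in pairs:
                raise ConfigurationError(f"chain is disconnected between {i} and {i + 1}")
        # the inactivated state is reachable only from O
        for e in self.edges:
            if self.inactivated_index in (e.source, e.target):
                other = e.target if e.source == self.inactivated_index else e.source
                if other != self.open_index:
                    raise ConfigurationError("I must connect only to O")

    # -- constructors --------------------------------------------------
    @classmethod
    def linear(
        cls,
        n_closed: int,
        closed_fwd_mults: Sequence[float] | None = None,
        closed_bwd_mults: Sequence[float] | None = None,
    ) -> "KineticScheme":
        """Build ``C1 = .. = C_k (alpha/beta) = O (A/B) = I (eta/phi)``.

        ``closed_fwd_mults``/``closed_bwd_mults`` give the multiplicities
        of the ``n_closed - 1`` closed-closed transitions (default all 1).
        """
        k = n_closed - 1
        fwd = list(closed_fwd_mults) if closed_fwd_mults is not None else [1.0] * k
        bwd = list(closed_bwd_mults) if closed_bwd_mults is not None else [1.0] * k
        if len(fwd) != k or len(bwd) != k:
            raise ConfigurationError(
                f"expected {k} closed-transition multiplicities, "
                f"got {len(fwd)} forward / {len(bwd)} backward"
            )
        edges: list[Edge] = []
        for i in range(k):
            edges.append(Edge(i, i + 1, "alpha", fwd[i]))
            edges.append(Edge(i + 1, i, "beta", bwd[i]))
        o = n_closed
        edges.append(Edge(o - 1, o, "A"))
        edges.append(Edge(o, o - 1, "B"))
        edges.append(Edge(o, o + 1, "eta"))
        edges.append(Edge(o + 1, o, "phi"))
        return cls(n_closed=n_closed, edges=tuple(edges))

    @classmethod
    def default(cls) -> "KineticScheme":
        """The calibrated shipped topology.

        Four closed states with unit forward multiplicities and backward
        multiplicities (3, 2, 3) on the closed-closed steps.  Selected
        among the linear-chain variants as the one reproducing the
        published activation/availability midpoints and recovery time
        constants simultaneously (see docs/methods.md).
        """
        return cls.linear(4, closed_bwd_mults=(3.0, 2.0, 3.0))


def build_generator(scheme: KineticScheme, rates: RateSet) -> np.ndarray:
    """Assemble the transition-rate (generator) matrix Q for one voltage.

    ``Q[i, j]`` (i != j) is the i->j rate; diagonals are minus the row
    sums so each row sums to zero and probability is conserved.
    """
    q = np.zeros((scheme.n_states, scheme.n_states))
    for e in scheme.edges:
        try:
            rate = rates[e.label]
        except KeyError:
            raise ConfigurationError(f"rate label {e.label!r} missing from RateSet")
        q[e.source, e.target] += e.mult * rate
    np.fill_diagonal(q, q.diagonal() - q.sum(axis=1))
    return q


def _as_distribution(p0: np.ndarray, n_states: int) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (n_states,):
        raise DomainError(f"state distribution must have shape ({n_states},)")
    if np.any(p0 < -1e-12) or abs(p0.sum() - 1.0) > 1e-8:
        raise DomainError("state distribution must be non-negative and sum to 1")
    return p0


def evolve(Q: np.ndarray, p0: np.ndarray, t_ms: float) -> np.ndarray:
    """Propagate ``p0`` for ``t_ms`` under fixed-voltage generator ``Q``.

    Matrix-exponential semantics: returns ``p0 @ expm(Q * t)``, exact up
    to floating point for a constant generator.
    """
    Q = np.asarray(Q, dtype=float)
    p0 = _as_distribution(p0, Q.shape[0])
    if not math.isfinite(t_ms) or t_ms < 0:
        raise DomainError(f"duration must be a finite non-negative time, got {t_ms!r}")
    if t_ms == 0.0:
        return p0.copy()
    p = p0 @ expm(Q * t_ms)
    return np.clip(p, 0.0, None) / max(p.sum(), 1e-300)


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with ``pi @ Q = 0``.

    Unique for a connected chain; raises :class:`NumericalError` with a
    diagnostic if the null space is empty or degenerate.
    """
    Q = np.asarray(Q, dtype=float)
    ns = null_space(Q.T)
    if ns.shape[1] != 1:
        raise NumericalError(
            f"generator has a {ns.shape[1]}-dimensional null space; the "
            "scheme is singular or disconnected"
        )
    pi = ns[:, 0]
    pi = pi * np.sign(pi.sum())
    if np.any(pi < -1e-9):
        raise NumericalError("stationary vector has significant negative entries")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


class _SegmentPropagator:
    """Sample ``p0 @ expm(Q t)`` at many times via eigendecomposition.

    Falls back to repeated matrix exponentials when the eigenbasis is
    ill-conditioned (e.g. degenerate rates).
    """

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        try:
            w, U = np.linalg.eig(self.Q.T)
            Uinv = np.linalg.inv(U)
            cond = np.linalg.cond(U)
        except np.linalg.LinAlgError:
            cond = np.inf
        if np.isfinite(cond) and cond < 1e10:
            self._w, self._U, self._Uinv = w, U, Uinv
        else:
            self._w = None

    def occupancies(self, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        if self._w is not None:
            # p(t)^T = U exp(diag(w) t) U^-1 p0^T, vectorized over t
            coeff = self._Uinv @ p0
            occ = np.real(
                np.einsum("ij,tj,j->ti", self._U, np.exp(np.outer(times, self._w)), coeff)
            )
        else:
            occ = np.empty((times.size, p0.size))
            p = p0
            prev_t = 0.0
            for i, t in enumerate(times):
                if t > prev_t:
                    p = p @ expm(self.Q * (t - prev_t))
                    prev_t = t
                occ[i] = p
        occ = np.clip(occ, 0.0, None)
        occ /= occ.sum(axis=1, keepdims=True)
        return occ


@dataclass
class GatingTrace:
    """Time course of the gating-state distribution along a protocol."""

    t_ms: np.ndarray
    v_mV: np.ndarray
    occupancy: np.ndarray  # (n_samples, n_states)
    open_index: int
    inactivated_index: int

    @property
    def po(self) -> np.ndarray:
        """Open probability P_o(t)."""
        return self.occupancy[:, self.open_index]

    @property
    def p_inactivated(self) -> np.ndarray:
        return self.occupancy[:, self.inactivated_index]


def open_probability_trace(
    scheme: KineticScheme,
    params: RateConstants,
    protocol,
    dt_ms: float,
    convention: SignConvention = SignConvention(),
    p0: np.ndarray | None = None,
) -> GatingTrace:
    """Propagate the gating model along a piecewise-constant protocol.

    One generator per constant-voltage segment, matrix-exponential
    propagation, occupancies sampled on a uniform ``dt_ms`` grid.  The
    initial distribution defaults to the analytic steady state at the
    protocol's holding voltage (the long inter-sweep rest).
    """
    if dt_ms <= 0 or not math.isfinite(dt_ms):
        raise DomainError(f"sampling interval must be positive, got {dt_ms!r}")
    segments = list(protocol.segments)
    if not segments:
        raise DomainError("protocol has no segments")

    if p0 is None:
        q_hold = build_generator(scheme, voltage_rates(params, protocol.holding_mV, convention))
        p = steady_state(q_hold)
    else:
        p = _as_distribution(p0, scheme.n_states)

    t_parts: list[np.ndarray] = [np.array([0.0])]
    v_parts: list[np.ndarray] = [np.array([protocol.holding_mV])]
    occ_parts: list[np.ndarray] = [p[None, :]]
    t0 = 0.0
    for seg in segments:
        rates = voltage_rates(params, seg.voltage_mV, convention)
        prop = _SegmentPropagator(build_generator(scheme, rates))
        n = max(1, int(round(seg.duration_ms / dt_ms)))
        local = dt_ms * np.arange(1, n + 1)
        local[-1] = seg.duration_ms  # land exactly on the segment end
        occ = prop.occupancies(p, local)
        t_parts.append(t0 + local)
        v_parts.append(np.full(n, seg.voltage_mV))
        occ_parts.append(occ)
        p = occ[-1]
        t0 += seg.duration_ms

    return GatingTrace(
        t_ms=np.concatenate(t_parts),
        v_mV=np.concatenate(v_parts),
        occupancy=np.vstack(occ_parts),
        open_index=scheme.open_index,
        inactivated_index=scheme.inactivated_index,
    )


@dataclass(frozen=True)
class Kv13Model:
    """Scheme + rate constants + sign convention, bundled for convenience."""

    scheme: KineticScheme = field(default_factory=KineticScheme.default)
    params: RateConstants = field(default_factory=RateConstants)
    convention: SignConvention = field(default_factory=SignConvention)

    def rates(self, v_mV: float) -> RateSet:
        return voltage_rates(self.params, v_mV, self.convention)

    def generator(self, v_mV: float) -> np.ndarray:
        return build_generator(self.scheme, self.rates(v_mV))

    def steady_state(self, v_mV: float) -> np.ndarray:
        return steady_state(self.generator(v_mV))

    def trace(self, protocol, dt_ms: float, p0: np.ndarray | None = None) -> GatingTrace:
        return open_probability_trace(
            self.scheme, self.params, protocol, dt_ms, self.convention, p0=p0
        )
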