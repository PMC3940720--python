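"""Rate-constant estimation from families of macroscopic current traces.

The inverse problem: given whole-cell currents recorded under one or
more voltage-clamp protocol families, recover the gating rate constants
of the sequential Kv1.3 scheme.  The objective is the summed squared
error between simulated and observed currents; the per-cell amplitude
(N * g) is a nuisance linear scale and is profiled analytically at every
evaluation, mirroring the per-cell channel counts reported alongside
published fits.

Search strategy: particle-swarm global search over log10-rates (they
span ~7 orders of magnitude) followed by per-coordinate golden-section
refinement.  With a fixed seed the result is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError
from .markov import KineticScheme, RateConstants, SignConvention, open_probability_trace
from .protocols import CurrentTrace, VoltageProtocol

__all__ = ["ProtocolData", "FitProblem", "FitResult", "objective", "fit_rates"]

RATE_NAMES = ("a", "b", "c", "d", "A", "B", "m", "n", "p", "q")

#: Finite penalty returned when a candidate parameter set cannot be simulated.
SIMULATION_PENALTY = 1e12

#: Default log10 search bounds per rate constant (generous decades around
#: physically plausible gating rates / voltage scales).
DEFAULT_BOUNDS = {
    "a": (1e-3, 1e2), "b": (1e-4, 1e1), "c": (1e-5, 1e0), "d": (1e-6, 1e-2),
    "A": (1e0, 1e4), "B": (1e-2, 1e2),
    "m": (5.0, 200.0), "n": (5.0, 200.0), "p": (20.0, 2000.0), "q": (50.0, 5000.0),
}


@dataclass(frozen=True)
class ProtocolData:
    """One protocol family with its observed sweeps (one cell)."""

    protocols: tuple[VoltageProtocol, ...]
    observed: tuple[CurrentTrace, ...]
    e_rev_mV: float = -73.0

    def __post_init__(self) -> None:
        if len(self.protocols) != len(self.observed):
            raise DomainError("protocol/observation counts differ")
        if not self.protocols:
            raise DomainError("empty protocol family")


@dataclass(frozen=True)
class FitProblem:
    """Observed data, scheme, free parameters and their bounds."""

    families: tuple[ProtocolData, ...]
    scheme: KineticScheme = field(default_factory=KineticScheme.default)
    convention: SignConvention = field(default_factory=SignConvention)
    base_params: RateConstants = field(default_factory=RateConstants)
    free: tuple[str, ...] = RATE_NAMES
    bounds: dict = field(default_factory=dict)
    profile_amplitude: bool = True
    dt_ms: float = 0.5

    def __post_init__(self) -> None:
        if not self.families:
            raise DomainError("fit problem needs at least one protocol family")
        for name in self.free:
            if name not in RATE_NAMES:
                raise DomainError(f"unknown free parameter {name!r}")
        for name, (lo, hi) in self.bounds.items():
            if lo <= 0 or hi <= lo:
                raise DomainError(f"bounds for {name!r} must be positive with lo < hi")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])

    def params_from_vector(self, x_log10: np.ndarray) -> RateConstants:
        values = self.base_params.to_dict()
        for name, xv in zip(self.free, x_log10):
            values[name] = 10.0 ** xv
        return RateConstants(**values)

    def vector_from_params(self, params: RateConstants) -> np.ndarray:
        return np.array([math.log10(getattr(params, name)) for name in self.free])


def _family_sse(params: RateConstants, fam: ProtocolData, problem: FitProblem) -> tuple[float, float]:
    """(SSE, profiled amplitude) for one family.

    The model basis is ``u(t) = P_o(t) * (V - E)`` per sweep; the single
    linear amplitude ``s = N * g * 1e-3`` minimizing the family SSE is
    ``max(sum(u * y) / sum(u^2), 0)``.
    """
    num = 0.0
    den = 0.0
    bases = []
    for proto, obs in zip(fam.protocols, fam.observed):
        gt = open_probability_trace(
            problem.scheme, params, proto, obs.dt_ms, problem.convention
        )
        if gt.po.size != obs.i_pA.size:
            raise DomainError(
                f"simulated sweep has {gt.po.size} samples, observed {obs.i_pA.size}"
            )
        u = gt.po * (gt.v_mV - fam.e_rev_mV)
        bases.append(u)
        num += float(u @ obs.i_pA)
        den += float(u @ u)
    s = max(num / den, 0.0) if den > 0 else 0.0
    sse = 0.0
    for u, obs in zip(bases, fam.observed):
        sse += float(np.sum((obs.i_pA - s * u) ** 2))
    return sse, s


def objective(params: RateConstants, problem: FitProblem) -> float:
    """Summed squared current error across all families (deterministic).

    Simulation failures (overflowing rates, singular schemes) yield a
    large finite penalty rather than an exception, so global search can
    traverse bad regions.
    """
    total = 0.0
    for fam in problem.families:
        try:
            sse, _ = _family_sse(params, fam, problem)
        except (FloatingPointError, ValueError, ArithmeticError, DomainError):
            return SIMULATION_PENALTY
        if not math.isfinite(sse):
            return SIMULATION_PENALTY
        total += sse
    return total


@dataclass
class FitResult:
    """Outcome of a rate-constant fit."""

    params: RateConstants
    objective: float
    per_family_sse: list[float]
    amplitudes: list[float]
    history: list[tuple[int, float]]
    seed: int
    n_evaluations: int

    def report(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "objective": self.objective,
            "per_family_sse": self.per_family_sse,
            "amplitudes": self.amplitudes,
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
        }


_INV_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo: float, hi: float, n_iter: int = 30) -> tuple[float, float]:
    """Minimize a 1-D function on [lo, hi] by golden-section search."""
    x1 = hi - _INV_GOLDEN * (hi - lo)
    x2 = lo + _INV_GOLDEN * (hi - lo)
    f1, f2 = f(x1), f(x2)
    for _ in range(n_iter):
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _INV_GOLDEN * (hi - lo)
            f1 = f(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _INV_GOLDEN * (hi - lo)
            f2 = f(x2)
    return (x1, f1) if f1 <= f2 else (x2, f2)


def fit_rates(
    problem: FitProblem,
    seed: int = 0,
    n_particles: int = 20,
    n_iterations: int = 200,
    inertia: float = 0.7,
    cognitive: float = 1.5,
    social: float = 1.5,
    gss_passes: int = 2,
    gss_halfwidth: float = 0.2,
) -> FitResult:
    """Particle-swarm search over log10-rates + golden-section polish.

    The swarm is initialized uniformly inside the (log) bounds with the
    base parameter vector injected as one particle.  After the swarm
    budget, each free coordinate is refined by golden-section search in
    a ``+-gss_halfwidth`` log10 window (clipped to bounds),
    ``gss_passes`` times.  Fixed ``seed`` gives a bit-identical result.
    """
    if n_particles < 1 or n_iterations < 0:
        raise DomainError("budget must allow at least one evaluation")
    rng = np.random.default_rng(seed)
    n_evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        try:
            params = problem.params_from_vector(x)
        except DomainError:
            return SIMULATION_PENALTY
        return objective(params, problem)

    ndim = len(problem.free)
    history: list[tuple[int, float]] = []
    if ndim == 0:
        # degenerate problem: nothing to optimize
        best_x = np.empty(0)
        best_f = objective(problem.base_params, problem)
        n_evals = 1
    else:
        lo = np.array([math.log10(problem.bound(n)[0]) for n in problem.free])
        hi = np.array([math.log10(problem.bound(n)[1]) for n in problem.free])
        x = rng.uniform(lo, hi, size=(n_particles, ndim))
        x[0] = np.clip(problem.vector_from_params(problem.base_params), lo, hi)
        v = rng.uniform(-0.1, 0.1, size=(n_particles, ndim)) * (hi - lo)
        f = np.array([evaluate(xi) for xi in x])
        pbest_x, pbest_f = x.copy(), f.copy()
        g = int(np.argmin(f))
        best_x, best_f = x[g].copy(), float(f[g])
        history.append((0, best_f))
        for it in range(1, n_iterations + 1):
            r1 = rng.uniform(size=(n_particles, ndim))
            r2 = rng.uniform(size=(n_particles, ndim))
            v = (
                inertia * v
                + cognitive * r1 * (pbest_x - x)
                + social * r2 * (best_x[None, :] - x)
            )
            x = np.clip(x + v, lo, hi)
            f = np.array([evaluate(xi) for xi in x])
            improved = f < pbest_f
            pbest_x[improved] = x[improved]
            pbest_f[improved] = f[improved]
            g = int(np.argmin(pbest_f))
            if pbest_f[g] < best_f:
                best_x, best_f = pbest_x[g].copy(), float(pbest_f[g])
            history.append((it, best_f))
        # golden-section coordinate refinement
        for p in range(gss_passes):
            for k in range(ndim):
                a = max(lo[k], best_x[k] - gss_halfwidth)
                b = min(hi[k], best_x[k] + gss_halfwidth)

                def f1d(val, k=k):
                    xt = best_x.copy()
                    xt[k] = val
                    return evaluate(xt)

                xk, fk = _golden_section(f1d, a, b)
                if fk < best_f:
                    best_x[k], best_f = xk, fk
            history.append((n_iterations + 1 + p, best_f))

    best_params = problem.params_from_vector(best_x) if ndim else problem.base_params
    sses, amps = [], []
    for fam in problem.families:
        sse, s = _family_sse(best_params, fam, problem)
        sses.append(sse)
        amps.append(s * 1e3)  # back to N * g in pS
    return FitResult(
        params=best_params,
        objective=best_f,
        per_family_sse=sses,
        amplitudes=amps,
        history=history,
        seed=seed,
        n_evaluations=n_evals,
    )
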