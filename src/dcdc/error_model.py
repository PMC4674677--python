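"""Deterministic error model for distributed cell division counting.

A population of ``n`` cells contains ``p`` bright cells, each carrying a
single self-assembled fluorescent particle (at most one particle per cell).
Between divisions the particle pool changes through three error processes —
splitting (a division yields two bright daughters), decay (a particle
disappears) and false production (an uninduced dark cell spontaneously
assembles a particle) — while the cell pool grows with possibly different
rates for bright and dark cells:

    dp/dt = K_split * p + K_fp * (n - p) - p / tau_p
    dn/dt = mu_B * p + mu_D * (n - p)

All rates are per hour.  "Generations" always means dark-cell generations,
``mu_D * t / ln 2``.  The module exposes the model's three analytic results:
the steady-state on/off floor (which sets the counter's dynamic range), the
transient of the population growth rate when bright and dark cells grow at
different rates, and the decomposition of the counting-error budget into its
three source terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ParticleCellState",
    "ErrorModelParams",
    "integrate_error_model",
    "steady_state_on_fraction",
    "dynamic_range_generations",
    "relative_growth_trajectory",
    "error_contributions",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ParticleCellState:
    """Particle-bearing (bright) cell count, total cell count, and time.

    Counts are treated as continuous densities by the deterministic model;
    the invariant ``0 <= p <= n`` (one particle per cell) is enforced.
    """

    p: float
    n: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.p) and np.isfinite(self.n) and np.isfinite(self.t)):
            raise ValueError("state fields must be finite")
        if self.n <= 0:
            raise ValueError(f"total cell count must be positive, got n={self.n}")
        if not 0 <= self.p <= self.n:
            raise ValueError(f"need 0 <= p <= n, got p={self.p}, n={self.n}")
        if self.t < 0:
            raise ValueError(f"time must be >= 0, got t={self.t}")

    @property
    def on_fraction(self) -> float:
        return self.p / self.n


@dataclass(frozen=True)
class ErrorModelParams:
    """Raw per-hour rates of the particle/cell error model.

    ``tau_p`` is the particle decay timescale in hours; ``math.inf`` is a
    first-class value meaning no decay.  Properties with a ``_star`` suffix
    are the per-generation (per dark-cell division) normalized forms, i.e.
    the raw rates divided by ``mu_D``.
    """

    k_split: float = 0.0
    k_fp: float = 0.0
    tau_p: float = math.inf
    mu_bright: float = LN2
    mu_dark: float = LN2

    def __post_init__(self) -> None:
        for name in ("k_split", "k_fp", "mu_bright", "mu_dark"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.mu_dark <= 0:
            raise ValueError("mu_dark must be > 0")
        if not self.tau_p > 0:  # inf allowed
            raise ValueError(f"tau_p must be > 0 (may be inf), got {self.tau_p}")

    @property
    def k_split_star(self) -> float:
        return self.k_split / self.mu_dark

    @property
    def k_fp_star(self) -> float:
        return self.k_fp / self.mu_dark

    @property
    def decay_rate_star(self) -> float:
        """1/tau_p normalized per generation; zero when tau_p is infinite."""
        return 0.0 if math.isinf(self.tau_p) else 1.0 / (self.tau_p * self.mu_dark)

    @property
    def growth_ratio(self) -> float:
        """mu_B / mu_D."""
        return self.mu_bright / self.mu_dark

    @classmethod
    def from_per_generation(
        cls,
        k_fp_star: float = 0.0,
        k_split_star: float = 0.0,
        decay_star: float = 0.0,
        growth_ratio: float = 1.0,
        mu_dark: float = LN2,
    ) -> "ErrorModelParams":
        """Build raw-rate parameters from per-generation normalized rates."""
        tau_p = math.inf if decay_star == 0 else 1.0 / (decay_star * mu_dark)
        return cls(
            k_split=k_split_star * mu_dark,
            k_fp=k_fp_star * mu_dark,
            tau_p=tau_p,
            mu_bright=growth_ratio * mu_dark,
            mu_dark=mu_dark,
        )


def _decay_rate(params: ErrorModelParams) -> float:
    return 0.0 if math.isinf(params.tau_p) else 1.0 / params.tau_p


def integrate_error_model(
    params: ErrorModelParams,
    initial: ParticleCellState,
    duration: float,
    n_points: int = 200,
    rtol: float = 1e-10,
    atol: float = 1e-18,
) -> list[ParticleCellState]:
    """Integrate the particle/cell ODEs on an evenly spaced time grid.

    The system is integrated in the variables ``(f, ln n)`` with
    ``f = p/n``, which stays well-conditioned over many generations of
    exponential growth:

        df/dt     = K_split*f + K_fp*(1-f) - f/tau_p - f*(mu_B*f + mu_D*(1-f))
        d ln n/dt = mu_B*f + mu_D*(1-f)

    Returns states at ``n_points`` times including both endpoints.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    kd = _decay_rate(params)
    ks, kf = params.k_split, params.k_fp
    mb, md = params.mu_bright, params.mu_dark

    def rhs(_t: float, state: np.ndarray) -> list[float]:
        f = state[0]
        mu = mb * f + md * (1.0 - f)
        dfdt = ks * f + kf * (1.0 - f) - kd * f - f * mu
        return [dfdt, mu]

    t_eval = np.linspace(initial.t, initial.t + duration, n_points)
    sol = solve_ivp(
        rhs,
        (initial.t, initial.t + duration),
        [initial.on_fraction, math.log(initial.n)],
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    states = []
    for t, f, ln_n in zip(sol.t, sol.y[0], sol.y[1]):
        f = min(max(f, 0.0), 1.0)
        n = math.exp(ln_n)
        states.append(ParticleCellState(p=f * n, n=n, t=float(t)))
    return states


def steady_state_on_fraction(params: ErrorModelParams) -> float:
    """Long-time limit L of the on-fraction p/n — the counter's floor.

    L is the fixed point of

        L = [K*_split*L + K*_fp*(1-L) - L/tau*_p] / [1 + (mu_B/mu_D - 1)*L]

    obtained by applying L'Hopital's rule to p/n as both diverge.  For
    negligible splitting and decay and equal growth rates this reduces to
    L ~= K*_fp: the dynamic range is limited entirely by the false
    production rate.
    """
    kf = params.k_fp_star
    if kf >= 1.0:
        raise ValueError(
            "counting assumption violated: normalized false-production rate "
            f"K*_fp={kf} >= 1 (marker replicates as fast as cells)"
        )
    if kf == 0.0:
        return 0.0
    ks = params.k_split_star
    kd = params.decay_rate_star
    ratio = params.growth_ratio

    def g(L: float) -> float:
        return ks * L + kf * (1.0 - L) - kd * L - L * (1.0 + (ratio - 1.0) * L)

    # g(0) = K*_fp > 0; search upward from the small-L closed form for a
    # sign change.  g is continuous so a root exists below any upper bracket
    # where g < 0.
    hi = min(1.0 - 1e-15, max(4.0 * kf, 1e-6))
    while g(hi) > 0:
        hi = hi + 0.5 * (1.0 - hi)
        if 1.0 - hi < 1e-12:
            raise ValueError(
                "no on-fraction floor below 1: error rates overwhelm dilution"
            )
    return float(brentq(g, 0.0, hi, xtol=1e-12, rtol=8.9e-16))


def dynamic_range_generations(
    initial_on_fraction: float, params: ErrorModelParams
) -> float:
    """Number of clean on-fraction halvings before the floor is reached.

    Returns ``log2(f0 / L)`` where L is the steady-state on/off floor:
    inversely proportional to the log2 of the false production rate.
    """
    if not 0 < initial_on_fraction <= 1:
        raise ValueError("initial_on_fraction must be in (0, 1]")
    floor = steady_state_on_fraction(params)
    if floor >= initial_on_fraction:
        raise ValueError(
            f"steady-state floor {floor} is not below the initial fraction "
            f"{initial_on_fraction}: no dynamic range"
        )
    if floor == 0.0:
        return math.inf
    return math.log2(initial_on_fraction / floor)


def relative_growth_trajectory(
    params: ErrorModelParams,
    initial: ParticleCellState,
    duration: float,
    n_points: int = 200,
) -> list[tuple[float, float]]:
    """Population growth rate normalized by the dark-cell rate, over time.

    Returns (t, (1/n)(dn/dt)/mu_D) = (t, 1 + (mu_B/mu_D - 1) * p/n).  Any
    initial growth-rate disparity between bright and dark cells decays to 1
    in lockstep with the on-fraction, so the disparity is transient.
    """
    states = integrate_error_model(params, initial, duration, n_points)
    ratio = params.growth_ratio
    return [(s.t, 1.0 + (ratio - 1.0) * s.on_fraction) for s in states]


def error_contributions(
    params: ErrorModelParams, states: Sequence[ParticleCellState]
):
    """Per-time decomposition of dp/dt (normalized by n) into error sources.

    Columns: ``splitting`` = K_split*p/n, ``degradation`` = -(p/n)/tau_p,
    ``false_production`` = K_fp*(n-p)/n.  Splitting and degradation are
    proportional to the decaying on-fraction and so lose importance
    exponentially; false production asymptotes to its maximum K_fp.
    """
    import pandas as pd

    if len(states) == 0:
        raise ValueError("empty state sequence")
    kd = _decay_rate(params)
    f = np.array([s.on_fraction for s in states])
    t = np.array([s.t for s in states])
    return pd.DataFrame(
        {
            "time_h": t,
            "splitting": params.k_split * f,
            "degradation": -kd * f,
            "false_production": params.k_fp * (1.0 - f),
        }
    )
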