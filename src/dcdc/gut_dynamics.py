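"""Population dynamics of a focal bacterium colonizing the gut.

Seven one- and two-variable ODE cases describe a gavaged strain ``x``
(normalized density) subject to growth, washout with gut contents, and
various death mechanisms:

  no_feedback            dx/dt = (G - R - D) x
  nutrient_limitation    dx/dt = g x (1 - x/c) - (R + D) x
  interactions           dx/dt = G_x x (1 - x/c) - R x + k_p x y
                         dy/dt = G_y y (1 - y/c) - R y + k_p x y
  adaptation             dx/dt = g x (1 - x/c) - R x - D(t) x,
                         D(t) = d_min (1 + d_max e^(-t/tau_D))
  physiological_removal  dx/dt = (G - r - D) x
  immune_response        dx/dt = (G - R) x - k_I I x
                         dI/dt = k_I x (1 - I/c_I)
  bacteriophage          dx/dt = (G - R) x - k_B x B
                         dB/dt = k_BS k_B x B - R B

G is the exponential growth rate, R the removal (washout) rate, D the
death rate, g the logistic growth rate, c the carrying capacity (state is
normalized so c = 1 by default), k_p the signed symmetric interaction
strength between species, d_min the steady-state death rate with
(d_max + 1) d_min the maximal (initial) death rate decaying on timescale
tau_D, r the physiological removal rate, k_I / c_I the immune response
rate and ceiling, and k_B / k_BS the phage infection rate and burst size.
Phage are washed out at the removal rate R.

The linear cases and the logistic case are solved in closed form; the rest
numerically.  Rates are per hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "GutModelSpec",
    "Trajectory",
    "CASES",
    "solve_model",
    "steady_state",
    "bifurcation_death_rate",
    "classify_regime",
]

CASES = (
    "no_feedback",
    "nutrient_limitation",
    "interactions",
    "adaptation",
    "physiological_removal",
    "immune_response",
    "bacteriophage",
)

# parameters each case is allowed to set (beyond `case`)
_CASE_PARAMS: dict[str, set[str]] = {
    "no_feedback": {"G", "R", "D"},
    "nutrient_limitation": {"g", "R", "D", "c"},
    "interactions": {"G_x", "G_y", "R", "k_p", "c", "y0"},
    "adaptation": {"g", "R", "c", "d_max", "tau_D", "d_min"},
    "physiological_removal": {"G", "r", "D"},
    "immune_response": {"G", "R", "k_I", "c_I", "I0"},
    "bacteriophage": {"G", "R", "k_B", "k_BS", "B0"},
}


@dataclass(frozen=True)
class GutModelSpec:
    """One model case plus the parameters relevant to it.

    Defaults follow the measured colonization rates: growth 1/3 h^-1,
    removal 1/6 h^-1 (median transit time 6 h), carrying capacity
    normalized to 1.  Setting a parameter that the selected case does not
    use raises a validation error.
    """

    case: str
    G: Optional[float] = None
    R: Optional[float] = None
    D: Optional[float] = None
    g: Optional[float] = None
    c: Optional[float] = None
    G_x: Optional[float] = None
    G_y: Optional[float] = None
    k_p: Optional[float] = None
    d_max: Optional[float] = None
    tau_D: Optional[float] = None
    d_min: Optional[float] = None
    r: Optional[float] = None
    k_I: Optional[float] = None
    c_I: Optional[float] = None
    k_B: Optional[float] = None
    k_BS: Optional[float] = None
    y0: Optional[float] = None
    I0: Optional[float] = None
    B0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(f"unknown case {self.case!r}; valid: {CASES}")
        allowed = _CASE_PARAMS[self.case]
        all_params = set(self.__dataclass_fields__) - {"case"}
        for name in sorted(all_params - allowed):
            v = getattr(self, name)
            if v is not None:
                raise ValueError(
                    f"parameter {name!r} is not used by case {self.case!r}"
                )
        for name in sorted(allowed):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite")
        if self.c is not None and self.c <= 0:
            raise ValueError("carrying capacity c must be > 0")

    def value(self, name: str, default: float) -> float:
        v = getattr(self, name)
        return default if v is None else float(v)


# defaults anchored to the measured gut rates
_DEFAULTS = {
    "G": 1.0 / 3.0,
    "R": 1.0 / 6.0,
    "D": 0.0,
    "g": 1.0 / 3.0,
    "c": 1.0,
    "G_x": 1.0 / 3.0,
    "G_y": 0.5,
    "k_p": 0.0,
    "d_max": 30.0,
    "tau_D": 0.5,
    "d_min": 0.0,
    "r": 1.0 / 3.0,
    "k_I": 0.5,
    "c_I": 1.0,
    "k_B": 0.5,
    "k_BS": 50.0,
    "y0": 0.1,
    "I0": 0.0,
    "B0": 0.01,
}


def _p(spec: GutModelSpec, name: str) -> float:
    return spec.value(name, _DEFAULTS[name])


@dataclass
class Trajectory:
    """Time grid plus the state variables the case actually uses."""

    time_h: np.ndarray
    x: np.ndarray
    y: Optional[np.ndarray] = None
    I: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None
    case: str = ""

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.time_h, "x": self.x}
        for name in ("y", "I", "B"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


_DIVERGENCE_BOUND = 1e9


def _diverged(_t, s):
    return _DIVERGENCE_BOUND - float(np.max(s))


_diverged.terminal = True


def _solve_numeric(rhs, y0, t, rtol=1e-8, atol=1e-10):
    for tols in ((rtol, atol), (rtol * 1e-3, atol * 1e-3)):
        sol = solve_ivp(
            rhs,
            (t[0], t[-1]),
            y0,
            t_eval=t,
            method="LSODA",
            rtol=tols[0],
            atol=tols[1],
            events=_diverged,
        )
        if sol.status == 1:  # divergence event fired
            t_stop = float(sol.t_events[0][0])
            raise RuntimeError(
                f"trajectory diverged past {_DIVERGENCE_BOUND:g} at "
                f"t = {t_stop:.3g} h (finite-time blow-up); shorten the "
                "duration to inspect the transient"
            )
        if sol.success and np.all(sol.y >= -10 * tols[1]):
            return np.clip(sol.y, 0.0, None)
    raise RuntimeError(
        f"integration failed or produced negative states: {sol.message}"
    )


def solve_model(
    spec: GutModelSpec,
    x0: float,
    duration: float,
    n_points: int = 500,
) -> Trajectory:
    """Solve the selected case from initial density ``x0`` for ``duration`` h.

    Pure-exponential cases (no_feedback, physiological_removal) and the
    logistic case (nutrient_limitation) use their closed forms; the rest
    are integrated numerically with non-negativity enforced.
    """
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    if duration <= 0 or n_points < 2:
        raise ValueError("duration must be > 0 and n_points >= 2")
    t = np.linspace(0.0, duration, n_points)
    case = spec.case

    if case in ("no_feedback", "physiological_removal"):
        G, D = _p(spec, "G"), _p(spec, "D")
        loss = _p(spec, "R") if case == "no_feedback" else _p(spec, "r")
        net = G - loss - D
        return Trajectory(time_h=t, x=x0 * np.exp(net * t), case=case)

    if case == "nutrient_limitation":
        g, R, D, c = _p(spec, "g"), _p(spec, "R"), _p(spec, "D"), _p(spec, "c")
        # logistic with net low-density rate a = g - R - D and crowding g/c:
        # x(t) = a x0 e^{a t} / (a + (g/c) x0 (e^{a t} - 1))
        a = g - R - D
        b = g / c
        if x0 == 0:
            x = np.zeros_like(t)
        elif a == 0:
            x = x0 / (1.0 + b * x0 * t)
        else:
            e = np.exp(a * t)
            x = a * x0 * e / (a + b * x0 * (e - 1.0))
        return Trajectory(time_h=t, x=np.clip(x, 0.0, None), case=case)

    if case == "adaptation":
        g, R, c = _p(spec, "g"), _p(spec, "R"), _p(spec, "c")
        d_max, tau_D, d_min = _p(spec, "d_max"), _p(spec, "tau_D"), _p(spec, "d_min")

        def rhs(tt, s):
            death = d_min * (1.0 + d_max * math.exp(-tt / tau_D))
            return [g * s[0] * (1.0 - s[0] / c) - R * s[0] - death * s[0]]

        y = _solve_numeric(rhs, [x0], t)
        return Trajectory(time_h=t, x=y[0], case=case)

    if case == "interactions":
        Gx, Gy, R = _p(spec, "G_x"), _p(spec, "G_y"), _p(spec, "R")
        k_p, c, y0 = _p(spec, "k_p"), _p(spec, "c"), _p(spec, "y0")

        def rhs(tt, s):
            x_, y_ = s
            return [
                Gx * x_ * (1.0 - x_ / c) - R * x_ + k_p * x_ * y_,
                Gy * y_ * (1.0 - y_ / c) - R * y_ + k_p * x_ * y_,
            ]

        y = _solve_numeric(rhs, [x0, y0], t)
        return Trajectory(time_h=t, x=y[0], y=y[1], case=case)

    if case == "immune_response":
        G, R = _p(spec, "G"), _p(spec, "R")
        k_I, c_I, I0 = _p(spec, "k_I"), _p(spec, "c_I"), _p(spec, "I0")

        def rhs(tt, s):
            x_, i_ = s
            return [
                (G - R) * x_ - k_I * i_ * x_,
                k_I * x_ * (1.0 - i_ / c_I),
            ]

        y = _solve_numeric(rhs, [x0, I0], t)
        return Trajectory(time_h=t, x=y[0], I=y[1], case=case)

    # bacteriophage
    G, R = _p(spec, "G"), _p(spec, "R")
    k_B, k_BS, B0 = _p(spec, "k_B"), _p(spec, "k_BS"), _p(spec, "B0")

    def rhs(tt, s):
        x_, b_ = s
        return [
            (G - R) * x_ - k_B * x_ * b_,
            k_BS * k_B * x_ * b_ - R * b_,
        ]

    y = _solve_numeric(rhs, [x0, B0], t)
    return Trajectory(time_h=t, x=y[0], B=y[1], case=case)


def steady_state(spec: GutModelSpec):
    """Fixed-point analysis where a closed form exists.

    Returns a positive steady-state density, the string "zero-only" when
    extinction is the only fixed point, or "marginal: any x" at the
    bifurcation of the linear cases.  The two-variable cases have no
    supported closed form and raise ``NotImplementedError``.
    """
    case = spec.case
    if case in ("no_feedback", "physiological_removal"):
        G, D = _p(spec, "G"), _p(spec, "D")
        loss = _p(spec, "R") if case == "no_feedback" else _p(spec, "r")
        net = G - loss - D
        return "marginal: any x" if net == 0 else "zero-only"
    if case in ("nutrient_limitation", "adaptation"):
        g, R, c = _p(spec, "g"), _p(spec, "R"), _p(spec, "c")
        d_inf = _p(spec, "D") if case == "nutrient_limitation" else _p(spec, "d_min")
        x_star = c * (1.0 - (R + d_inf) / g)
        return x_star if x_star > 0 else "zero-only"
    raise NotImplementedError(
        f"case {case!r} has no analytic fixed point; use solve_model"
    )


def bifurcation_death_rate(G: float, R: float) -> float:
    """Death rate D* = G - R at which the no-feedback model is marginal.

    Below D* the population grows exponentially; above it, it declines.
    """
    if R < 0:
        raise ValueError("R must be >= 0")
    if G <= R:
        raise ValueError(
            "G must exceed R: the population declines for any death rate"
        )
    return G - R


def classify_regime(
    traj: Trajectory,
    rate_tol: float = 1e-3,
    dip_tol: float = 0.05,
    crash_floor: float = 1e-8,
) -> str:
    """Classify a trajectory's long-time behaviour.

    One of 'exponential_growth', 'exponential_decline', 'steady_state',
    'dip_then_recover', 'crash'.  The log-derivative of x is measured over
    the final 20% of the trajectory (>= 5 points required); a dip requires
    min(x) < (1 - dip_tol) * x0 followed by a positive plateau.
    """
    x = np.asarray(traj.x, dtype=float)
    t = np.asarray(traj.time_h, dtype=float)
    n_win = max(int(0.2 * len(x)), 0)
    if n_win < 5:
        raise ValueError("final 20% window has < 5 points; extend trajectory")
    x0 = x[0]
    scale = max(x0, np.max(x))
    if x[-1] <= crash_floor * scale:
        return "crash"
    xw, tw = x[-n_win:], t[-n_win:]
    if np.any(xw <= 0):
        return "crash"
    slope = np.polyfit(tw, np.log(xw), 1)[0]
    if abs(slope) < rate_tol:
        if x0 > 0 and np.min(x) < (1.0 - dip_tol) * x0:
            return "dip_then_recover"
        return "steady_state"
    return "exponential_growth" if slope > 0 else "exponential_decline"
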