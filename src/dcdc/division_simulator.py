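"""Stochastic simulation of dividing cells carrying segregating particles.

Generation-synchronous branching model: every cell divides once per
generation, a particle passes to exactly one daughter (so the bright count
is conserved under faithful segregation), and the per-generation error
events — particle splitting, false production in dark cells, particle decay
— are Bernoulli draws per cell.  A turbidostat-style wrapper grows the
culture exponentially between optical-density thresholds and thins it back
at each dilution event by independent per-cell retention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "PopulationSeries",
    "DilutionEvent",
    "simulate_generations",
    "sample_cells",
    "simulate_turbidostat",
]

DEFAULT_POPULATION_CAP = 10_000_000


@dataclass(frozen=True)
class SimulationParams:
    """Per-generation stochastic counterparts of the error-model rates."""

    doubling_time: float = 0.55
    initial_on: int = 70
    initial_off: int = 30
    p_false_per_gen: float = 0.0
    p_split_per_gen: float = 0.0
    p_decay_per_gen: float = 0.0
    bright_fitness_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ValueError("doubling_time must be > 0")
        if self.initial_on < 0 or self.initial_off < 0:
            raise ValueError("initial counts must be >= 0")
        if self.initial_on + self.initial_off < 1:
            raise ValueError("need at least one initial cell")
        for name in ("p_false_per_gen", "p_split_per_gen"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not 0 <= self.p_decay_per_gen <= 1:
            raise ValueError("p_decay_per_gen must be in [0, 1]")
        if self.bright_fitness_ratio <= 0:
            raise ValueError("bright_fitness_ratio must be > 0")


def matched_error_model(params: SimulationParams):
    """Continuous-rate error-model parameters matching a simulation.

    First-order correspondence between per-generation event probabilities
    and per-generation-normalized continuous rates: false production acts
    on the exponentially growing dark pool, so K*_fp equals the
    per-generation probability directly; splitting and decay act on the
    bright pool, which is constant within a generation under faithful
    segregation, so their probabilities carry a factor ln 2 relative to
    the normalized rates.
    """
    from .error_model import ErrorModelParams

    ln2 = math.log(2.0)
    return ErrorModelParams.from_per_generation(
        k_fp_star=params.p_false_per_gen,
        k_split_star=params.p_split_per_gen / ln2,
        decay_star=params.p_decay_per_gen / ln2,
        growth_ratio=params.bright_fitness_ratio,
        mu_dark=ln2 / params.doubling_time,
    )


@dataclass
class PopulationSeries:
    """Counts of bright and total cells over generations (or hours)."""

    generation: np.ndarray
    n_on: np.ndarray
    n_total: np.ndarray
    time_h: Optional[np.ndarray] = None

    @property
    def fraction_on(self) -> np.ndarray:
        return self.n_on / self.n_total

    def to_frame(self) -> pd.DataFrame:
        data = {"generation": self.generation}
        if self.time_h is not None:
            data["time_h"] = self.time_h
        data.update(
            {
                "n_on": self.n_on,
                "n_total": self.n_total,
                "fraction_on": self.fraction_on,
            }
        )
        return pd.DataFrame(data)


@dataclass(frozen=True)
class DilutionEvent:
    time_h: float
    pre_od: float
    post_od: float


def _step_generation(
    n_on: int, n_off: int, params: SimulationParams, rng: np.random.Generator
) -> tuple[int, int]:
    """One synchronous generation: error events, then synchronous division.

    Event probabilities are drawn against the start-of-generation pools.
    For false production this makes the per-generation probability coincide
    exactly with the per-generation-normalized continuous rate (the
    integral of K_fp over the growing dark pool during one generation is
    K*_fp times the starting dark count), so the stochastic floor matches
    the deterministic error model's steady state.
    """
    # False production turns dark cells bright; decay turns bright dark.
    gained = int(rng.binomial(n_off, params.p_false_per_gen)) if n_off else 0
    lost = int(rng.binomial(n_on, params.p_decay_per_gen)) if n_on else 0
    n_on += gained - lost
    n_off += lost - gained
    # Division with segregation: each bright cell yields one bright + one
    # dark daughter; with p_split both daughters are bright.
    extra_bright = int(rng.binomial(n_on, params.p_split_per_gen)) if n_on else 0
    # Differential fitness as fractional expected offspring: a bright
    # lineage produces 2**ratio total offspring per dark generation instead
    # of 2; the surplus (or deficit) lands in the dark daughter pool so the
    # particle-bearing count itself stays conserved.
    ratio = params.bright_fitness_ratio
    dark_from_bright = n_on * (2.0 ** ratio - 1.0) - extra_bright
    if dark_from_bright < 0:
        dark_from_bright = 0.0
    base = int(math.floor(dark_from_bright))
    frac = dark_from_bright - base
    n_dark_from_bright = base + (int(rng.random() < frac) if frac > 0 else 0)
    return n_on + extra_bright, 2 * n_off + n_dark_from_bright


def _subsample_to_cap(
    n_on: int, n_total: int, cap: int, rng: np.random.Generator
) -> tuple[int, int]:
    n_on_kept = int(rng.hypergeometric(n_on, n_total - n_on, cap))
    return n_on_kept, cap


def simulate_generations(
    params: SimulationParams,
    n_generations: int,
    population_cap: Optional[int] = DEFAULT_POPULATION_CAP,
) -> PopulationSeries:
    """Simulate ``n_generations`` synchronous generations.

    Above ``population_cap`` total cells the population is uniformly
    subsampled back to the cap (the recorded totals are the retained
    counts).  Pass ``population_cap=None`` to disable, in which case
    exceeding the default cap raises a resource error.  Identical params
    and seed give identical output.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(params.seed)
    n_on, n_off = params.initial_on, params.initial_off
    gens = [0]
    ons = [n_on]
    totals = [n_on + n_off]
    for g in range(1, n_generations + 1):
        n_on, n_off = _step_generation(n_on, n_off, params, rng)
        total = n_on + n_off
        if population_cap is not None and total > population_cap:
            n_on, total = _subsample_to_cap(n_on, total, population_cap, rng)
            n_off = total - n_on
        elif population_cap is None and total > DEFAULT_POPULATION_CAP:
            raise MemoryError(
                f"population {total} exceeds cap with subsampling disabled"
            )
        gens.append(g)
        ons.append(n_on)
        totals.append(total)
    gens_arr = np.array(gens)
    return PopulationSeries(
        generation=gens_arr,
        n_on=np.array(ons, dtype=np.int64),
        n_total=np.array(totals, dtype=np.int64),
        time_h=gens_arr * params.doubling_time,
    )


def sample_cells(
    n_on: int, n_total: int, sample_size: int, seed: int
) -> tuple[int, int]:
    """Draw a flow-cytometry-style subsample of the population.

    Hypergeometric draw without replacement; a binomial approximation is
    used when the population is at least 100x the sample.  Returns
    ``(n_on_sampled, sample_size)``.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    if not 0 <= n_on <= n_total:
        raise ValueError("need 0 <= n_on <= n_total")
    if sample_size > n_total:
        raise ValueError(
            f"sample_size {sample_size} exceeds population {n_total}"
        )
    rng = np.random.default_rng(seed)
    if sample_size == n_total:
        return n_on, sample_size
    if n_total >= 100 * sample_size:
        return int(rng.binomial(sample_size, n_on / n_total)), sample_size
    return (
        int(rng.hypergeometric(n_on, n_total - n_on, sample_size)),
        sample_size,
    )


def simulate_turbidostat(
    params: SimulationParams,
    od_band: tuple[float, float],
    sample_every: float,
    duration: float,
    od_per_cell: float = 1e-7,
) -> tuple[PopulationSeries, list[DilutionEvent]]:
    """Continuous-culture simulation with feedback dilution.

    The total population grows exponentially (doubling each
    ``doubling_time``); under faithful segregation the bright count is
    constant between events, so the on-fraction halves per generation.
    Per-generation error events fire at each generation boundary.  When OD
    (``n_total * od_per_cell``) crosses the top of the band the culture is
    thinned to the bottom by independent per-cell retention, which leaves
    the expected on-fraction unchanged.  Samples are recorded every
    ``sample_every`` hours.
    """
    low, high = od_band
    if not 0 < low < high:
        raise ValueError("need 0 < low < high for od_band")
    if duration <= 0 or sample_every <= 0:
        raise ValueError("duration and sample_every must be > 0")
    import warnings

    if high / low < 2.0:
        warnings.warn(
            "OD band narrower than one doubling: dilutions will fire more "
            "than once per generation",
            RuntimeWarning,
        )
    rng = np.random.default_rng(params.seed)
    tau = params.doubling_time
    rate = math.log(2.0) / tau  # h^-1
    n_on = params.initial_on
    n_total = float(params.initial_on + params.initial_off)

    t = 0.0
    next_sample = 0.0
    next_gen = tau
    times, ons, totals = [], [], []
    events: list[DilutionEvent] = []
    while t <= duration + 1e-12:
        # Next event: sample, generation boundary, or dilution crossing.
        od = n_total * od_per_cell
        t_dilute = t + math.log(high / od) / rate if od < high else t
        t_next = min(next_sample, next_gen, t_dilute, duration)
        # advance deterministic growth of the total population
        n_total *= math.exp(rate * (t_next - t))
        t = t_next
        if t >= t_dilute - 1e-12 and n_total * od_per_cell >= high - 1e-9:
            pre_od = n_total * od_per_cell
            keep = low / pre_od
            n_off = max(int(round(n_total)) - n_on, 0)
            n_on = int(rng.binomial(n_on, keep)) if n_on else 0
            n_off = int(rng.binomial(n_off, keep)) if n_off else 0
            n_total = float(n_on + n_off)
            events.append(
                DilutionEvent(time_h=t, pre_od=pre_od, post_od=n_total * od_per_cell)
            )
        if abs(t - next_gen) < 1e-12:
            # error events once per generation on the current counts
            n_off = max(int(round(n_total)) - n_on, 0)
            gained = (
                int(rng.binomial(n_off, params.p_false_per_gen)) if n_off else 0
            )
            lost = (
                int(rng.binomial(n_on, params.p_decay_per_gen)) if n_on else 0
            )
            split = (
                int(rng.binomial(n_on, params.p_split_per_gen)) if n_on else 0
            )
            n_on = n_on + gained - lost + split
            next_gen += tau
        if abs(t - next_sample) < 1e-12:
            times.append(t)
            ons.append(n_on)
            totals.append(int(round(n_total)))
            next_sample += sample_every
        if t >= duration - 1e-12:
            break
    times_arr = np.array(times)
    series = PopulationSeries(
        generation=times_arr / tau,
        n_on=np.array(ons, dtype=np.int64),
        n_total=np.array(totals, dtype=np.int64),
        time_h=times_arr,
    )
    return series, events
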