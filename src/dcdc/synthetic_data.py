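"""Synthetic experiments: gavage/faecal sampling and turbidostat traces.

These generators emulate the study designs the estimators are built for,
so every fit can be exercised end-to-end against known ground truth.

The gavage emulator mimics oral introduction of a GFP-tagged,
particle-induced strain into mice with faecal flow cytometry every 2 h:
the GFP+ fraction of faecal events follows a transit pulse (first
appearance ~4 h, peak ~6 h, then washout at the removal rate), while the
red-among-green fraction — induced cells still carrying a particle —
decays two-fold per generation of in-gut growth, down to a reinduction
floor.  Counts are multinomial draws per sample.

The turbidostat generator produces raw photodiode traces (readings below a
blank reference, dilution valve events at band crossings) consistent with
a chosen origin-forced quadratic calibration, so the OD calibration chain
can be round-tripped.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_inference import ODCalibration, OnFractionSeries, calibrated_od

__all__ = [
    "GavageParams",
    "GavageDataset",
    "simulate_gavage_experiment",
    "red_green_series",
    "gfp_fraction_series",
    "generate_turbidostat_trace",
    "generate_fixture_suite",
]


@dataclass(frozen=True)
class GavageParams:
    """Design of a synthetic gavage/faecal-sampling experiment.

    Defaults follow the measured in-gut kinetics: doubling time 2.91 h,
    removal rate 1/6 h^-1 (median transit 6 h, first faecal appearance
    4 h), faeces sampled every 2 h, ~70% of cells induced at gavage.
    """

    n_mice: int = 4
    true_doubling_time: float = 2.91
    removal_rate: float = 1.0 / 6.0
    sampling_interval: float = 2.0
    duration: float = 24.0
    initial_on_fraction: float = 0.7
    events_per_sample: int = 100_000
    reinduction_prob_per_gen: float = 0.0
    transit_peak_time: float = 6.0
    first_appearance_time: float = 4.0
    peak_gfp_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")
        if self.duration < self.sampling_interval:
            raise ValueError("duration shorter than one sampling interval")
        if self.events_per_sample < 100:
            raise ValueError("events_per_sample must be >= 100")
        if not 0 < self.initial_on_fraction <= 1:
            raise ValueError("initial_on_fraction must be in (0, 1]")
        if not 0 <= self.reinduction_prob_per_gen < 1:
            raise ValueError("reinduction_prob_per_gen must be in [0, 1)")
        if not self.first_appearance_time < self.transit_peak_time:
            raise ValueError("peak must come after first appearance")


@dataclass
class GavageDataset:
    """Per-mouse faecal flow-cytometry counts.

    Columns: mouse_id, time_h, n_gfp (GFP+ events), n_total_events,
    n_red_and_green (RFP+ & GFP+ events);
    n_red_and_green <= n_gfp <= n_total_events row-wise.
    """

    table: pd.DataFrame
    params: GavageParams

    def mice(self) -> list[str]:
        return sorted(self.table["mouse_id"].unique())

    def mouse(self, mouse_id: str) -> pd.DataFrame:
        return self.table[self.table["mouse_id"] == mouse_id].reset_index(
            drop=True
        )


def _transit_pulse(t: float, p: GavageParams) -> float:
    """Expected GFP+ fraction of faecal events at time t."""
    if t <= p.first_appearance_time:
        return 0.0
    if t <= p.transit_peak_time:
        rise = (t - p.first_appearance_time) / (
            p.transit_peak_time - p.first_appearance_time
        )
        return p.peak_gfp_fraction * rise
    return p.peak_gfp_fraction * math.exp(
        -p.removal_rate * (t - p.transit_peak_time)
    )


def _red_green_fraction(t: float, p: GavageParams) -> float:
    """Expected RFP+ fraction among GFP+ events at time t."""
    decay = 2.0 ** (-t / p.true_doubling_time)
    # per-generation reinduction accumulates toward a floor of ~2*prob
    floor = (
        2.0 * p.reinduction_prob_per_gen / (1.0 + p.reinduction_prob_per_gen)
    )
    return min(p.initial_on_fraction * decay + floor * (1.0 - decay), 1.0)


def simulate_gavage_experiment(params: GavageParams) -> GavageDataset:
    """Multinomial faecal counts for every mouse and sampling time."""
    rng = np.random.default_rng(params.seed)
    rows = []
    times = np.arange(
        params.sampling_interval,
        params.duration + 1e-9,
        params.sampling_interval,
    )
    for m in range(params.n_mice):
        mouse_id = f"mouse_{m + 1}"
        for t in times:
            gfp_frac = _transit_pulse(float(t), params)
            rg_frac = _red_green_fraction(float(t), params)
            n_gfp = int(rng.binomial(params.events_per_sample, gfp_frac))
            n_rg = int(rng.binomial(n_gfp, rg_frac)) if n_gfp else 0
            rows.append(
                {
                    "mouse_id": mouse_id,
                    "time_h": float(t),
                    "n_gfp": n_gfp,
                    "n_total_events": params.events_per_sample,
                    "n_red_and_green": n_rg,
                }
            )
    return GavageDataset(table=pd.DataFrame(rows), params=params)


def red_green_series(
    dataset: GavageDataset, min_gfp_events: int = 100
) -> dict[str, OnFractionSeries]:
    """Per-mouse red-among-green series (n_on = RFP+ & GFP+, n_total = GFP+).

    Samples with fewer than ``min_gfp_events`` GFP+ events carry no usable
    denominator (before first appearance, or after washout) and are dropped.
    """
    out: dict[str, OnFractionSeries] = {}
    for mouse in dataset.mice():
        d = dataset.mouse(mouse)
        d = d[d["n_gfp"] >= min_gfp_events]
        if len(d) < 3:
            continue
        out[mouse] = OnFractionSeries(
            time_h=d["time_h"].to_numpy(),
            n_on=d["n_red_and_green"].to_numpy(),
            n_total=d["n_gfp"].to_numpy(),
            source="in_vivo_red_green",
        )
    if not out:
        raise ValueError("no mouse retained >= 3 usable samples")
    return out


def gfp_fraction_series(
    dataset: GavageDataset,
) -> dict[str, list[tuple[float, float]]]:
    """Per-mouse (time, GFP+ fraction) sequences for transit-time estimation."""
    return {
        mouse: list(
            zip(
                dataset.mouse(mouse)["time_h"],
                dataset.mouse(mouse)["n_gfp"]
                / dataset.mouse(mouse)["n_total_events"],
            )
        )
        for mouse in dataset.mice()
    }


def generate_turbidostat_trace(
    doubling_time: float,
    cal: ODCalibration,
    od_band: tuple[float, float] = (0.2, 0.4),
    duration: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    reading_interval: float = 0.05,
    od0: float | None = None,
) -> pd.DataFrame:
    """Raw photodiode trace of an exponentially growing, diluted culture.

    True (calibrated) OD grows exponentially at ln2/doubling_time between
    band crossings and is reset to the bottom of the band at each crossing
    (valve_state 1 on that row).  Raw readings are the inverse of the
    calibration chain — reading = blank * 10**(-raw_od) with raw_od the
    positive root of C1*r + C2*r**2 = OD — plus multiplicative Gaussian
    noise of relative width ``noise_sd``.
    """
    low, high = od_band
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if doubling_time <= 0 or duration <= 0:
        raise ValueError("doubling_time and duration must be > 0")
    rng = np.random.default_rng(seed)
    rate = math.log(2.0) / doubling_time
    od = low if od0 is None else od0
    if not low <= od <= high:
        raise ValueError("initial OD outside the band")
    rows = []
    t = 0.0
    while t <= duration + 1e-9:
        valve = 0
        if od >= high - 1e-12:
            od = low
            valve = 1
        # invert the origin-forced quadratic for the raw device OD
        if cal.c2 == 0:
            raw_od = od / cal.c1
        else:
            raw_od = (-cal.c1 + math.sqrt(cal.c1**2 + 4.0 * cal.c2 * od)) / (
                2.0 * cal.c2
            )
        assert abs(calibrated_od(raw_od, cal) - od) < 1e-9
        reading = cal.blank * 10.0 ** (-raw_od)
        if noise_sd > 0:
            reading *= 1.0 + noise_sd * rng.standard_normal()
            reading = max(reading, 1e-9 * cal.blank)
        rows.append(
            {"time_h": t, "raw_reading": reading, "valve_state": valve}
        )
        t += reading_interval
        od *= math.exp(rate * reading_interval)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixture_suite(outdir: str | Path, seed: int = 0) -> dict:
    """Write a small, versioned set of CSV fixtures plus a JSON manifest.

    Fixtures: a labelled fluorescence mixture, noiseless on-fraction decay
    series at 0.5/1/2/5 h doubling times, a gavage dataset, a turbidostat
    trace, and a gut-model spec.  The manifest records every file with its
    generator parameters and SHA-256 checksum; identical seeds give
    identical checksums.
    """
    from .cytometry import generate_mixture
    from .division_simulator import SimulationParams, simulate_generations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    def record(name: str, params: dict) -> None:
        manifest["files"][name] = {
            "params": params,
            "sha256": _sha256(outdir / name),
        }

    mix_params = dict(
        n_on=2000, n_off=2000, fold_separation=20.0, log10_sd=0.25, seed=seed
    )
    generate_mixture(**mix_params).to_frame().to_csv(
        outdir / "mixture.csv", index=False
    )
    record("mixture.csv", mix_params)

    for tau in (0.5, 1.0, 2.0, 5.0):
        t = np.arange(0.0, 8.0 * tau + 1e-9, tau)
        frac = 0.7 * 2.0 ** (-t / tau)
        n_total = 100_000
        df = pd.DataFrame(
            {
                "time_h": t,
                "n_on": np.round(frac * n_total).astype(int),
                "n_total": n_total,
            }
        )
        name = f"on_fraction_tau{tau:g}h.csv"
        df.to_csv(outdir / name, index=False)
        record(name, {"doubling_time_h": tau, "noiseless": True})

    sim_params = SimulationParams(
        doubling_time=0.55, initial_on=70, initial_off=30, seed=seed
    )
    simulate_generations(sim_params, 10).to_frame().to_csv(
        outdir / "division_series.csv", index=False
    )
    record("division_series.csv", asdict(sim_params))

    gav_params = GavageParams(seed=seed, events_per_sample=10_000, duration=16.0)
    simulate_gavage_experiment(gav_params).table.to_csv(
        outdir / "gavage.csv", index=False
    )
    record("gavage.csv", asdict(gav_params))

    cal = ODCalibration(c1=0.8, c2=1.5, blank=1000.0)
    trace = generate_turbidostat_trace(
        doubling_time=0.55, cal=cal, duration=4.0, noise_sd=0.0, seed=seed
    )
    trace.to_csv(outdir / "turbidostat_trace.csv", index=False)
    record(
        "turbidostat_trace.csv",
        {"doubling_time_h": 0.55, "c1": 0.8, "c2": 1.5, "blank": 1000.0},
    )

    spec = {"case": "adaptation", "g": 1 / 3, "R": 1 / 6, "c": 1.0,
            "d_max": 30.0, "tau_D": 0.5, "d_min": 0.1}
    (outdir / "gut_model_spec.json").write_text(json.dumps(spec, indent=1))
    record("gut_model_spec.json", spec)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
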