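"""Readers and writers for the package's table and config formats.

CSV dialect: UTF-8, comma-separated, '.' decimal, mandatory header row;
times in hours as floats.  Schema violations are reported with the
offending row number.  FCS ingestion is read-only and optional: it
requires the ``fcsparser`` package and degrades with a clear message when
that is absent.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .cytometry import FlowSample
from .error_model import ErrorModelParams, ParticleCellState
from .growth_inference import OnFractionSeries

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "load_table",
    "load_series",
    "load_on_fraction_series",
    "load_flow_sample",
    "load_fcs",
    "load_error_model_params",
    "load_config",
    "write_trajectory",
]


class SchemaError(ValueError):
    """Input table violates its declared schema."""


# schema -> (required columns, optional columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "on_fraction": (("time_h", "n_on", "n_total"), ("mouse_id",)),
    "events": (
        ("event_id", "red_intensity"),
        ("green_intensity", "label"),
    ),
    "trace": (("time_h", "raw_reading", "valve_state"), ()),
    "trajectory": (("time_h", "x"), ("y", "I", "B")),
    "gavage": (
        ("mouse_id", "time_h", "n_gfp", "n_total_events", "n_red_and_green"),
        (),
    ),
}


def _require_numeric(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for col in cols:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        elif df[col].isna().any():
            row = int(np.nonzero(df[col].isna().to_numpy())[0][0]) + 2
        else:
            df[col] = coerced
            continue
        raise SchemaError(
            f"{path}: column {col!r} has a non-numeric or missing value "
            f"at line {row}"
        )


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; valid: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    required, optional = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    non_numeric = {"mouse_id", "label"}
    _require_numeric(
        df, [c for c in (*required, *optional) if c not in non_numeric], path
    )
    if schema == "on_fraction":
        _validate_counts(df, "n_on", "n_total", path)
        _validate_time(df, path, group="mouse_id" if "mouse_id" in df else None)
    elif schema == "gavage":
        _validate_counts(df, "n_red_and_green", "n_gfp", path)
        _validate_counts(df, "n_gfp", "n_total_events", path)
        _validate_time(df, path, group="mouse_id")
    elif schema == "trace":
        _validate_time(df, path)
    elif schema == "events":
        bad = ~np.isfinite(df["red_intensity"]) | (df["red_intensity"] <= 0)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2
            raise SchemaError(
                f"{path}: non-positive or non-finite intensity at line {row}"
            )
    return df


def _validate_counts(df: pd.DataFrame, low: str, high: str, path) -> None:
    bad = (df[low] < 0) | (df[low] > df[high])
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0]) + 2
        raise SchemaError(
            f"{path}: need 0 <= {low} <= {high}, violated at line {row}"
        )


def _validate_time(df: pd.DataFrame, path, group: str | None = None) -> None:
    frames = [g for _, g in df.groupby(group)] if group else [df]
    for frame in frames:
        t = frame["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            pos = int(np.nonzero(np.diff(t) <= 0)[0][0])
            row = int(frame.index[pos + 1]) + 2
            raise SchemaError(f"{path}: time not increasing at line {row}")


def load_series(path: str | Path, schema: str) -> pd.DataFrame:
    """Alias of :func:`load_table` (the schema names the series kind)."""
    return load_table(path, schema)


def load_on_fraction_series(
    path: str | Path,
) -> OnFractionSeries | dict[str, OnFractionSeries]:
    """Load an on-fraction CSV; per-mouse dict when a mouse_id column exists."""
    df = load_table(path, "on_fraction")
    if "mouse_id" in df.columns:
        return {
            str(mouse): OnFractionSeries(
                time_h=g["time_h"].to_numpy(),
                n_on=g["n_on"].to_numpy(),
                n_total=g["n_total"].to_numpy(),
                source="in_vivo_red_green",
            )
            for mouse, g in df.groupby("mouse_id")
        }
    return OnFractionSeries(
        time_h=df["time_h"].to_numpy(),
        n_on=df["n_on"].to_numpy(),
        n_total=df["n_total"].to_numpy(),
    )


def load_flow_sample(path: str | Path) -> FlowSample:
    df = load_table(path, "events")
    return FlowSample(
        red=df["red_intensity"].to_numpy(),
        green=df["green_intensity"].to_numpy()
        if "green_intensity" in df.columns
        else None,
        label=df["label"].to_numpy() if "label" in df.columns else None,
    )


def load_fcs(path: str | Path, red_channel: str) -> FlowSample:
    """Read an FCS 3.0/3.1 file into a FlowSample (requires fcsparser)."""
    try:
        import fcsparser  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "FCS ingestion requires the optional 'fcsparser' package; "
            "install it or convert the file to the events CSV schema "
            "(event_id, red_intensity[, green_intensity, label])"
        ) from exc
    _, data = fcsparser.parse(str(path))
    if red_channel not in data.columns:
        raise SchemaError(
            f"{path}: channel {red_channel!r} not present; "
            f"available: {list(data.columns)}"
        )
    values = data[red_channel].to_numpy(dtype=float)
    return FlowSample(red=np.clip(values, np.finfo(float).tiny, None))


def load_error_model_params(path: str | Path) -> ErrorModelParams:
    """Error-model rates from JSON or YAML with explicit per-hour keys.

    Keys: k_split_per_h, k_fp_per_h, tau_p_h (number or "inf"),
    mu_bright_per_h, mu_dark_per_h.
    """
    raw = load_config(path)
    tau = raw.get("tau_p_h", "inf")
    tau_p = math.inf if tau in ("inf", None) else float(tau)
    return ErrorModelParams(
        k_split=float(raw.get("k_split_per_h", 0.0)),
        k_fp=float(raw.get("k_fp_per_h", 0.0)),
        tau_p=tau_p,
        mu_bright=float(raw["mu_bright_per_h"]),
        mu_dark=float(raw["mu_dark_per_h"]),
    )


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    data = (
        json.loads(text)
        if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return data


def write_trajectory(
    states: Iterable[ParticleCellState], path: str | Path
) -> None:
    """Write error-model states as CSV: time_h, p, n, fraction_on."""
    df = pd.DataFrame(
        {
            "time_h": [s.t for s in states],
            "p": [s.p for s in states],
            "n": [s.n for s in states],
        }
    )
    df["fraction_on"] = df["p"] / df["n"]
    df.to_csv(path, index=False)
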