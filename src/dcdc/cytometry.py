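"""Synthetic flow cytometry, threshold classification, and ROC analysis.

Bright ('on') cells carrying an assembled fluorescent particle are 20- to
200-fold brighter on the red channel than dark ('off') cells.  This module
generates labelled two-population log-normal mixtures, classifies events by
an intensity threshold, and quantifies classifier quality with a
threshold-sweep ROC curve and its area (AUC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FlowSample",
    "RocCurve",
    "generate_mixture",
    "classify_events",
    "roc_curve",
    "auc",
    "on_fraction",
]


@dataclass
class FlowSample:
    """Per-event fluorescence intensities with optional class labels.

    ``label`` entries are 'bright', 'dark' or 'unknown' (synthetic samples
    keep their generating class).  Intensities are arbitrary units > 0.
    """

    red: np.ndarray
    green: Optional[np.ndarray] = None
    label: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        if self.red.size and not (
            np.all(np.isfinite(self.red)) and np.all(self.red > 0)
        ):
            raise ValueError("intensities must be finite and positive")
        if self.green is not None:
            self.green = np.asarray(self.green, dtype=float)
            if self.green.shape != self.red.shape:
                raise ValueError("green channel length mismatch")
        if self.label is not None:
            self.label = np.asarray(self.label)
            if self.label.shape != self.red.shape:
                raise ValueError("label length mismatch")

    def __len__(self) -> int:
        return self.red.size

    def to_frame(self) -> pd.DataFrame:
        data: dict = {"event_id": np.arange(len(self)), "red_intensity": self.red}
        if self.green is not None:
            data["green_intensity"] = self.green
        if self.label is not None:
            data["label"] = self.label
        return pd.DataFrame(data)


@dataclass
class RocCurve:
    """(FPR, TPR) pairs from a descending threshold sweep."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)
        for arr, name in ((self.fpr, "fpr"), (self.tpr, "tpr")):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} outside [0, 1]")
            if np.any(np.diff(arr) < -1e-12):
                raise ValueError(f"{name} must be non-decreasing along the sweep")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def generate_mixture(
    n_on: int,
    n_off: int,
    fold_separation: float = 20.0,
    log10_sd: float = 0.25,
    seed: int = 0,
    median_off: float = 100.0,
) -> FlowSample:
    """Two labelled log-normal populations on the red channel.

    The generating medians satisfy median(on)/median(off) ==
    ``fold_separation`` exactly; both classes share the same spread
    ``log10_sd`` in log10 intensity units.
    """
    if n_on < 0 or n_off < 0 or n_on + n_off == 0:
        raise ValueError("need a positive number of events in at least one class")
    if fold_separation <= 1:
        raise ValueError("fold_separation must be > 1")
    if log10_sd <= 0:
        raise ValueError("log10_sd must be > 0")
    rng = np.random.default_rng(seed)
    log_off = rng.normal(math.log10(median_off), log10_sd, size=n_off)
    log_on = rng.normal(
        math.log10(median_off * fold_separation), log10_sd, size=n_on
    )
    red = np.concatenate([10.0 ** log_on, 10.0 ** log_off])
    label = np.concatenate(
        [np.repeat("bright", n_on), np.repeat("dark", n_off)]
    )
    return FlowSample(red=red, label=label)


def classify_events(sample: FlowSample, threshold: float) -> tuple[int, int]:
    """Count 'on' (intensity >= threshold; ties are 'on') and 'off' events."""
    if len(sample) == 0:
        raise ValueError("empty sample")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n_on = int(np.count_nonzero(sample.red >= threshold))
    return n_on, len(sample) - n_on


def roc_curve(bright: FlowSample, dark: FlowSample) -> RocCurve:
    """ROC from a descending sweep over all observed intensities.

    Thresholds are the distinct observed intensities plus an above-maximum
    endpoint, so the curve runs from (0, 0) to (1, 1) and its trapezoidal
    area is exact for the sample.
    """
    if len(bright) == 0 or len(dark) == 0:
        raise ValueError("both samples must be non-empty")
    pos, neg = bright.red, dark.red
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    thresholds = np.concatenate([[thresholds[0] * 2.0], thresholds])
    # events >= threshold are classified 'on'
    tpr = np.searchsorted(np.sort(pos), thresholds, side="left")
    tpr = (len(pos) - tpr) / len(pos)
    fpr = np.searchsorted(np.sort(neg), thresholds, side="left")
    fpr = (len(neg) - fpr) / len(neg)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve; in [0, 1]."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def on_fraction(
    n_on: int, n_total: int, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """On-fraction point estimate with a Wilson score interval."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_on <= n_total:
        raise ValueError("need 0 <= n_on <= n_total")
    lo, hi = proportion_confint(n_on, n_total, alpha=1 - level, method="wilson")
    if n_on == 0:
        lo = 0.0
    if n_on == n_total:
        hi = 1.0
    return n_on / n_total, (float(lo), float(hi))
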