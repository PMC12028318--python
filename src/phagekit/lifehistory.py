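"""Life-history trait estimation from phage titer time series.

Adsorption assays track the loss of free phages after mixing with host
cells; the per-time free fraction (free / input titer) decays roughly
exponentially and a first-order rate constant is fitted by log-linear
least squares.  One-step growth curves track plaque counts through a
burst: the burst size is the mean count at the first post-rise plateau
divided by the mean count before the initial increase (the infection-
center baseline), and the latent period is the time of the last pre-rise
point plus the adsorption duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticSeries",
    "AdsorptionFit",
    "LifeHistoryEstimate",
    "adsorption_kinetics",
    "one_step_growth",
    "read_kinetic_csv",
]


@dataclass
class KineticSeries:
    """One replicate's titer time series (minutes, PFU/ml)."""

    times: np.ndarray
    values: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError(f"{self.replicate_id}: times and values differ in length")
        if len(self.times) < 3:
            raise ValueError(f"{self.replicate_id}: need at least 3 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError(f"{self.replicate_id}: times must be strictly increasing")
        if (self.values < 0).any():
            raise ValueError(f"{self.replicate_id}: negative counts")


@dataclass
class AdsorptionFit:
    """Free-phage fractions and the fitted first-order adsorption rate."""

    times: np.ndarray
    fractions: np.ndarray
    rate: float  # per minute
    r_squared: float


@dataclass
class LifeHistoryEstimate:
    """One-step growth estimates with change-point diagnostics."""

    burst_size: float  # particles per infected cell
    latent_period: float  # minutes
    baseline: float  # mean pre-rise plaque count
    rise_index: int  # first grid index past the initial increase
    plateau_window: tuple[int, int]  # [start, end) grid indices of the first plateau
    plateau_mean: float
    adsorption_duration: float

    def __post_init__(self) -> None:
        if not self.burst_size > 0:
            raise ValueError("burst size must be positive")
        if self.latent_period < self.adsorption_duration:
            raise ValueError("latent period cannot precede the adsorption duration")


def adsorption_kinetics(series: KineticSeries, input_titer: float) -> AdsorptionFit:
    """Free-phage fraction per time point and a fitted first-order rate.

    Fractions are ``value / input_titer``; the rate is the negated slope
    of a least-squares fit of ln(fraction) against time over points with a
    positive fraction.  Fractions above 1 (counting noise) are retained
    with a warning.
    """
    if not input_titer > 0:
        raise ValueError("input_titer must be positive")
    fractions = series.values / input_titer
    if np.all(series.values == 0):
        raise ValueError(f"{series.replicate_id}: no free phage measured at any time")
    if (fractions > 1).any():
        warnings.warn(
            f"{series.replicate_id}: free fraction exceeds 1 at some time points "
            "(counting noise); retained"
        )
    mask = fractions > 0
    if mask.sum() < 2:
        raise ValueError(f"{series.replicate_id}: fewer than 2 positive fractions to fit")
    t = series.times[mask]
    y = np.log(fractions[mask])
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return AdsorptionFit(series.times, fractions, rate=float(-slope), r_squared=r2)


def one_step_growth(
    replicates: Sequence[KineticSeries],
    adsorption_duration: float,
    rise_factor: float = 2.0,
    plateau_tol: float = 0.15,
) -> LifeHistoryEstimate:
    """Burst size and latent period from replicated one-step growth curves.

    Replicates must share one time grid and are averaged before
    change-point detection.  The rise index is the first point whose
    replicate-averaged count exceeds ``rise_factor`` times the running
    mean of all earlier points; the baseline is the mean over the pre-rise
    points.  The first plateau is the earliest maximal run of >= 2
    consecutive post-rise points whose relative spread (max - min over the
    run mean) stays within ``plateau_tol``.  Burst size = plateau mean /
    baseline; latent period = time of the last pre-rise point plus the
    adsorption duration.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if rise_factor < 1:
        raise ValueError("rise_factor must be >= 1")
    grid = replicates[0].times
    for rep in replicates[1:]:
        if not np.array_equal(rep.times, grid):
            raise ValueError(
                f"replicate {rep.replicate_id!r} is on a different time grid; "
                "interpolation is refused"
            )
    mean = np.mean([rep.values for rep in replicates], axis=0)

    rise = None
    for i in range(1, len(mean)):
        running = mean[:i].mean()
        if running > 0 and mean[i] > rise_factor * running:
            rise = i
            break
    if rise is None:
        raise ValueError("no burst observed (no point exceeds rise_factor x baseline)")
    if rise < 2:
        raise ValueError(f"only {rise} point(s) before the rise; need >= 2")
    baseline = float(mean[:rise].mean())

    window = _first_plateau(mean, rise, plateau_tol)
    if window is None:
        raise ValueError(
            "no plateau found after the rise "
            f"(rise index {rise}, post-rise values {mean[rise:].tolist()})"
        )
    lo, hi = window
    plateau_mean = float(mean[lo:hi].mean())
    return LifeHistoryEstimate(
        burst_size=plateau_mean / baseline,
        latent_period=float(grid[rise - 1]) + adsorption_duration,
        baseline=baseline,
        rise_index=rise,
        plateau_window=window,
        plateau_mean=plateau_mean,
        adsorption_duration=adsorption_duration,
    )


def _first_plateau(
    mean: np.ndarray, rise: int, tol: float
) -> tuple[int, int] | None:
    """Earliest maximal run of >= 2 consecutive post-rise points within tol spread."""
    n = len(mean)
    for start in range(rise, n - 1):
        end = start + 2
        if _spread(mean[start:end]) > tol:
            continue
        while end < n and _spread(mean[start : end + 1]) <= tol:
            end += 1
        return (start, end)
    return None


def _spread(window: np.ndarray) -> float:
    m = window.mean()
    if m == 0:
        return 0.0
    return float((window.max() - window.min()) / m)


def read_kinetic_csv(path: str | Path) -> list[KineticSeries]:
    """Read a (time, value, replicate) CSV into per-replicate series."""
    df = pd.read_csv(path)
    required = {"time", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = "rep1"
    out = []
    for rep, sub in df.groupby("replicate", sort=True):
        sub = sub.sort_values("time")
        out.append(
            KineticSeries(
                sub["time"].to_numpy(float), sub["value"].to_numpy(float), str(rep)
            )
        )
    return out
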