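"""Separation-event detection and speed estimation from H-bond time series.

Stage 1 of the pipeline.  A steered-MD (or synthetic) run yields the three
hydrogen-bond lengths of one base pair sampled at a constant time step.  The
analysis is:

1. optionally smooth each bond series with a Savitzky-Golay filter
   (window 63 frames, polynomial order 2);
2. reduce the three bonds to a scalar separation metric, the arithmetic mean
   of the bond extensions relative to their equilibrium lengths;
3. detect separation events as contiguous excursions of the metric above its
   baseline whose peak clears a noise floor;
4. fit a straight line to the first two Angstrom of each event -- beyond
   2 Angstrom the hydrogen bonds are considered broken -- whose slope is the
   separation speed;
5. discard fits with negative slope or a slope relative standard error above
   5%, then pool accepted speeds into per-group means and standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "BondSeries",
    "SeparationEvent",
    "SpeedStats",
    "BOND_NAMES",
    "smooth",
    "separation_metric",
    "baseline_equilibria",
    "estimate_noise_floor",
    "detect_events",
    "fit_event_speed",
    "ensemble_speed_stats",
]

BOND_NAMES = ("B1", "B2", "B3")


@dataclass
class BondSeries:
    """Uniformly sampled lengths of the three hydrogen bonds of one base pair.

    ``force`` is a metadata tag for the applied steering force (arbitrary
    units); it never enters the computation.
    """

    time: np.ndarray
    lengths: dict[str, np.ndarray]
    base_pair_id: str = "G1-C1"
    force: float = 0.0
    replica_id: str = "r0"
    injected: list = field(default_factory=list)  # synthetic-event metadata

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lengths = {k: np.asarray(v, dtype=float) for k, v in self.lengths.items()}
        missing = [b for b in BOND_NAMES if b not in self.lengths]
        if missing:
            raise ValueError(f"missing bond series: {missing}")
        n = self.time.size
        for name, arr in self.lengths.items():
            if arr.size != n:
                raise ValueError(f"bond {name} has {arr.size} frames, time has {n}")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                bad = np.flatnonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-9))
                raise ValueError(
                    f"time step is not uniform at rows {bad[:10].tolist()}"
                )

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_frames(self) -> int:
        return int(self.time.size)


@dataclass
class SeparationEvent:
    """One above-noise excursion of the separation metric.

    ``start_index``/``end_index`` bound the fit window (inclusive):
    from the first frame at or above the noise floor to the first frame at
    or above the fit limit.  ``onset_index`` records where the excursion
    last rose through the baseline; with correlated breathing noise the
    stretch between onset and floor crossing contains near-flat baseline
    frames, so the fit opens at the floor crossing (see docs/methods.md).
    After fitting, ``slope`` is the separation speed in Angstrom/ps.
    ``partial`` marks events that never reached the fit limit and were
    fitted to their peak instead.
    """

    start_index: int
    end_index: int
    onset_index: int | None = None
    peak_index: int | None = None
    slope: float | None = None
    slope_stderr: float | None = None
    accepted: bool = False
    reject_reason: str | None = None
    partial: bool = False

    def __post_init__(self) -> None:
        if self.start_index >= self.end_index:
            raise ValueError(
                f"start_index ({self.start_index}) must precede end_index ({self.end_index})"
            )


@dataclass(frozen=True)
class SpeedStats:
    """Arithmetic mean and standard error of accepted speeds in one group."""

    force: float
    base_pair_id: str
    n_events: int
    mean_speed: float
    stderr_speed: float


def smooth(series: BondSeries, window: int = 63, order: int = 2) -> BondSeries:
    """Savitzky-Golay smooth each bond series (least-squares local polynomial).

    The default (window 63 frames, order 2) reproduces any polynomial of
    degree <= 2 exactly at interior points.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if order >= window:
        raise ValueError(f"order ({order}) must be smaller than window ({window})")
    if series.n_frames < window:
        raise ValueError(
            f"series has {series.n_frames} frames, shorter than window {window}"
        )
    sm = {
        name: signal.savgol_filter(arr, window_length=window, polyorder=order)
        for name, arr in series.lengths.items()
    }
    return replace(series, lengths=sm)


def separation_metric(series: BondSeries, equilibria: Mapping[str, float]) -> np.ndarray:
    """Mean hydrogen-bond extension s(t) relative to equilibrium (Angstrom)."""
    missing = [b for b in BOND_NAMES if b not in equilibria]
    if missing:
        raise KeyError(f"no equilibrium length configured for bonds: {missing}")
    return np.mean(
        [series.lengths[b] - equilibria[b] for b in BOND_NAMES], axis=0
    )


def baseline_equilibria(series: BondSeries, fraction: float = 0.1) -> dict[str, float]:
    """Per-bond equilibrium estimate: median over the leading ``fraction`` of frames.

    The leading segment of a steered run is the pre-separation baseline, so
    its median tracks the force-field equilibrium of each bond without
    assuming electronic-structure values.
    """
    n = max(1, int(round(series.n_frames * fraction)))
    return {b: float(np.median(series.lengths[b][:n])) for b in BOND_NAMES}


def estimate_noise_floor(metric: np.ndarray) -> float:
    """Robust noise floor for event detection (Angstrom).

    floor = median(s) + 3 * 1.4826 * MAD(s restricted below its 90th
    percentile).  The percentile clip removes separation ramps so a run
    containing genuine events does not inflate its own floor; the scaled MAD
    is the robust sigma of the breathing noise.
    """
    metric = np.asarray(metric, dtype=float)
    if metric.size < 100:
        raise ValueError(f"need >= 100 frames to estimate a noise floor, got {metric.size}")
    baseline = float(np.median(metric))
    clipped = metric[metric < np.quantile(metric, 0.9)]
    if clipped.size == 0:  # constant series
        return baseline
    mad = float(np.median(np.abs(clipped - np.median(clipped))))
    return baseline + 3.0 * 1.4826 * mad


def detect_events(
    metric: np.ndarray,
    time: np.ndarray,
    noise_floor: float,
    fit_limit: float = 2.0,
    baseline: float | None = None,
) -> list[SeparationEvent]:
    """Detect separation events as baseline excursions peaking above the floor.

    A candidate event is one contiguous excursion of the metric above its
    baseline (default: the series median) whose maximum exceeds
    ``noise_floor``.  The excursion onset (last upward baseline crossing
    preceding the peak) is recorded as ``onset_index``; the fit window runs
    from the first frame at or above ``noise_floor`` to the first frame at
    or above ``fit_limit`` (else to the peak, flagged ``partial``).
    Events are returned sorted and non-overlapping.
    """
    metric = np.asarray(metric, dtype=float)
    time = np.asarray(time, dtype=float)
    if metric.size != time.size:
        raise ValueError("metric and time must have the same length")
    if noise_floor <= 0 and baseline is None:
        # a non-positive floor with default baseline would fire on pure noise
        raise ValueError(f"noise_floor must be positive, got {noise_floor}")
    if baseline is None:
        baseline = float(np.median(metric))

    above = metric > baseline
    if not np.any(above):
        return []
    # contiguous runs of metric > baseline
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1)
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [metric.size - 1]))

    events: list[SeparationEvent] = []
    for s, e in zip(starts, ends):
        peak = s + int(np.argmax(metric[s : e + 1]))
        if metric[peak] <= noise_floor:
            continue
        over_floor = np.flatnonzero(metric[s : peak + 1] >= noise_floor)
        fit_start = s + int(over_floor[0])
        reached = np.flatnonzero(metric[s : peak + 1] >= fit_limit)
        if reached.size:
            end = s + int(reached[0])
            partial = False
        else:
            end = peak
            partial = True
        if end <= fit_start:
            continue
        events.append(
            SeparationEvent(start_index=int(fit_start), end_index=int(end),
                            onset_index=int(s), peak_index=int(peak),
                            partial=partial)
        )
    return events


def fit_event_speed(
    event: SeparationEvent,
    metric: np.ndarray,
    time: np.ndarray,
    max_rel_err: float = 0.05,
) -> SeparationEvent:
    """Ordinary least-squares speed fit over the event window.

    The slope of s(t) over [start_index, end_index] estimates the separation
    speed; its standard error comes from the usual residual-variance
    estimator.  Fits with non-positive slope are rejected
    (``negative_slope``), as are fits whose relative standard error
    stderr/slope exceeds ``max_rel_err`` (``high_uncertainty``).
    """
    s, e = event.start_index, event.end_index
    if e - s + 1 < 3:
        raise ValueError(f"event window [{s}, {e}] has fewer than 3 frames")
    t = np.asarray(time, float)[s : e + 1]
    y = np.asarray(metric, float)[s : e + 1]
    if t[-1] == t[0]:
        raise ValueError("zero time span in event window")
    res = stats.linregress(t, y)
    slope = float(res.slope)
    stderr = float(res.stderr)
    if slope <= 0:
        accepted, reason = False, "negative_slope"
    elif stderr / slope > max_rel_err:
        accepted, reason = False, "high_uncertainty"
    else:
        accepted, reason = True, None
    return replace(event, slope=slope, slope_stderr=stderr,
                   accepted=accepted, reject_reason=reason)


def ensemble_speed_stats(
    records: pd.DataFrame | Iterable[Mapping],
) -> tuple[list[SpeedStats], SpeedStats]:
    """Per-(force, base_pair_id) mean/SE of accepted speeds, plus pooled stats.

    ``records`` needs columns ``force``, ``base_pair_id``, ``speed`` and
    should contain accepted events only.  Standard error is the sample
    standard deviation over sqrt(n); single-event groups report SE 0 with a
    warning.  Empty groups do not appear.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("no accepted events to pool")

    def _stats(speeds: np.ndarray) -> tuple[float, float]:
        n = speeds.size
        mean = float(np.mean(speeds))
        if n == 1:
            warnings.warn("single-event group: standard error reported as 0",
                          stacklevel=2)
            return mean, 0.0
        return mean, float(np.std(speeds, ddof=1) / np.sqrt(n))

    groups: list[SpeedStats] = []
    for (force, bp), sub in df.groupby(["force", "base_pair_id"], sort=True):
        mean, se = _stats(sub["speed"].to_numpy())
        groups.append(SpeedStats(float(force), str(bp), int(len(sub)), mean, se))
    mean, se = _stats(df["speed"].to_numpy())
    pooled = SpeedStats(float("nan"), "pooled", int(len(df)), mean, se)
    return groups, pooled
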