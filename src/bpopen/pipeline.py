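"""End-to-end pipeline: smooth -> metric -> detect -> fit -> filter -> stats.

``PipelineConfig`` carries every tunable with the published defaults
(Savitzky-Golay window 63 / order 2, 2.0 Angstrom fit limit, 5% maximum
relative slope error, 3 degree angle threshold).  ``run_pipeline`` applies
the stages to a collection of bond series and returns a machine-readable
report; given the same inputs, config and seed the report is byte-identical.

Event windows are located and fitted on the raw separation metric by
default.  The smoothed metric is available via ``fit_on="smoothed"``; see
docs/methods.md for why raw is the default at coarse sampling.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import angles as _angles
from . import timeseries as ts
from .geometry import BasePairGeometry

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline tunables; defaults are the published analysis parameters."""

    window: int = 63  # Savitzky-Golay window, frames
    order: int = 2  # Savitzky-Golay polynomial order
    fit_limit: float = 2.0  # Angstrom: fit the first 2 A of separation
    max_rel_err: float = 0.05  # slope stderr/slope acceptance cut
    noise_floor: float | None = None  # Angstrom; None = robust auto estimate
    angle_threshold: float = 3.0  # degrees, |theta| cut for asymmetry
    frame_choice: str = "onset"  # representative frame for event angles
    fit_on: str = "raw"  # {"raw", "smoothed"}: metric used for windows+fits
    equilibria: dict[str, float] | None = None  # None = per-series baseline median
    baseline_fraction: float = 0.1  # leading fraction for baseline equilibria
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fit_on not in ("raw", "smoothed"):
            raise ValueError("fit_on must be 'raw' or 'smoothed'")


@dataclass
class PipelineResult:
    events: pd.DataFrame
    stats: list[ts.SpeedStats]
    pooled: ts.SpeedStats | None
    angle_summary: dict | None
    report: dict


def _process_series(
    series: ts.BondSeries, config: PipelineConfig
) -> tuple[list[ts.SeparationEvent], np.ndarray, float]:
    eq = config.equilibria or ts.baseline_equilibria(series, config.baseline_fraction)
    raw_metric = ts.separation_metric(series, eq)
    if config.fit_on == "smoothed":
        metric = ts.separation_metric(
            ts.smooth(series, config.window, config.order), eq
        )
    else:
        metric = raw_metric
    floor = (
        config.noise_floor
        if config.noise_floor is not None
        else ts.estimate_noise_floor(raw_metric)
    )
    # a noise-free series estimates a zero floor; keep detection well-defined
    floor = max(floor, 1e-9)
    events = ts.detect_events(metric, series.time, floor, config.fit_limit)
    fitted = [
        ts.fit_event_speed(ev, metric, series.time, config.max_rel_err)
        for ev in events
        if ev.end_index - ev.start_index + 1 >= 3
    ]
    return fitted, metric, floor


def run_pipeline(
    series_list: Sequence[ts.BondSeries],
    config: PipelineConfig = PipelineConfig(),
    geometries: Mapping[str, Mapping[int, BasePairGeometry]] | None = None,
) -> PipelineResult:
    """Run detection, fitting, filtering and pooling over many bond series.

    ``geometries``, if given, maps replica_id -> {frame_index: geometry} and
    enables the opening-angle stage.  An empty input yields an empty report
    rather than an error.
    """
    rows = []
    thetas: list[float] = []
    for series in series_list:
        fitted, metric, floor = _process_series(series, config)
        for k, ev in enumerate(fitted):
            rows.append(
                {
                    "replica_id": series.replica_id,
                    "base_pair_id": series.base_pair_id,
                    "force": series.force,
                    "start_index": ev.start_index,
                    "end_index": ev.end_index,
                    "peak_index": ev.peak_index,
                    "slope": ev.slope,
                    "slope_stderr": ev.slope_stderr,
                    "speed": ev.slope,
                    "accepted": ev.accepted,
                    "reject_reason": ev.reject_reason or "",
                    "partial": ev.partial,
                }
            )
        if geometries and series.replica_id in geometries:
            ens = _angles.event_angles(
                fitted,
                geometries[series.replica_id],
                metric,
                floor,
                frame_choice=config.frame_choice,
                replica_id=series.replica_id,
            )
            thetas.extend(ens.thetas.tolist())

    events = pd.DataFrame(rows)
    stats: list[ts.SpeedStats] = []
    pooled: ts.SpeedStats | None = None
    if not events.empty:
        accepted = events[events["accepted"]]
        if not accepted.empty:
            stats, pooled = ts.ensemble_speed_stats(
                accepted[["force", "base_pair_id", "speed"]]
            )

    angle_summary = None
    if thetas:
        ens = _angles.AngleEnsemble(thetas=np.array(thetas))
        pos, neg = _angles.estimate_modes(ens, seed=config.seed)
        asym, asym_ci = _angles.asymmetric_fraction(
            ens, config.angle_threshold, seed=config.seed
        )
        direc, direc_ci = _angles.directional_fraction(
            ens, config.angle_threshold, seed=config.seed
        )
        angle_summary = {
            "n_angles": ens.n,
            "mode_positive": pos.location,
            "mode_positive_stderr": pos.location_stderr,
            "mode_negative": neg.location,
            "mode_negative_stderr": neg.location_stderr,
            "asymmetric_fraction": asym,
            "asymmetric_fraction_ci95": list(asym_ci),
            "directional_fraction": direc,
            "directional_fraction_ci95": list(direc_ci),
        }

    report = {
        "config": asdict(config),
        "n_series": len(series_list),
        "n_events": int(len(events)),
        "n_accepted": int(events["accepted"].sum()) if not events.empty else 0,
        "reject_reasons": (
            events.loc[~events["accepted"], "reject_reason"]
            .value_counts()
            .to_dict()
            if not events.empty
            else {}
        ),
        "pooled_mean_speed": pooled.mean_speed if pooled else None,
        "pooled_stderr_speed": pooled.stderr_speed if pooled else None,
        "group_stats": [vars(g) for g in stats],
        "angles": angle_summary,
    }
    return PipelineResult(
        events=events, stats=stats, pooled=pooled,
        angle_summary=angle_summary, report=report,
    )
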