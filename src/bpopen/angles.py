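"""Opening-angle ensembles and the bimodal distribution statistics.

Stage 2.  Each separation event contributes one signed opening angle theta,
evaluated at a representative frame of the event.  Across an ensemble of
events the distribution of theta is bimodal: a positive mode (B3 stays
closed, B1 opens) and a negative mode (B1 stays closed, B3 opens, the
direction static electronic-structure calculations favour).  This module
estimates the two mode locations by kernel density estimation, the fraction
of clearly asymmetric events (|theta| above a threshold), and the fraction
following the negative-angle direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .geometry import BasePairGeometry, opening_angle
from .timeseries import SeparationEvent

__all__ = [
    "AngleEnsemble",
    "ModeEstimate",
    "event_angles",
    "estimate_modes",
    "asymmetric_fraction",
    "directional_fraction",
]

N_BOOTSTRAP = 200  # resamples for all bootstrap uncertainties


@dataclass
class AngleEnsemble:
    """Signed opening angles (degrees), one per event, with provenance."""

    thetas: np.ndarray
    weights: np.ndarray | None = None
    provenance: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.thetas = np.asarray(self.thetas, dtype=float)
        if np.any(np.abs(self.thetas) > 180.0):
            raise ValueError("opening angles must lie in [-180, 180] degrees")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n(self) -> int:
        return int(self.thetas.size)


@dataclass(frozen=True)
class ModeEstimate:
    """Location (degrees) of one mode of the angle distribution."""

    location: float
    location_stderr: float
    side: str  # "positive" | "negative"
    missing: bool = False


def event_angles(
    events: Sequence[SeparationEvent],
    geometries: Mapping[int, BasePairGeometry],
    metric: np.ndarray,
    noise_floor: float,
    frame_choice: str = "onset",
    replica_id: str = "r0",
) -> AngleEnsemble:
    """One signed opening angle per event.

    The representative frame is, per ``frame_choice``:

    - ``onset``: first frame of the event at which the separation metric
      exceeds the noise floor (default);
    - ``peak``: the event's peak frame;
    - ``mean``: theta averaged over all event frames with a geometry.

    Events whose representative frame has no geometry are skipped with a
    warning.
    """
    metric = np.asarray(metric, dtype=float)
    thetas: list[float] = []
    prov: list[tuple[str, str]] = []
    for k, ev in enumerate(events):
        ref = f"event{k}"
        if frame_choice == "mean":
            frames = [i for i in range(ev.start_index, ev.end_index + 1) if i in geometries]
            if not frames:
                warnings.warn(f"{ref}: no geometry in window, skipped", stacklevel=2)
                continue
            vals = [opening_angle(geometries[i], i, ref).theta for i in frames]
            thetas.append(float(np.mean(vals)))
            prov.append((replica_id, ref))
            continue
        if frame_choice == "onset":
            over = np.flatnonzero(metric[ev.start_index : ev.end_index + 1] >= noise_floor)
            frame = ev.start_index + int(over[0]) if over.size else ev.end_index
        elif frame_choice == "peak":
            frame = ev.peak_index if ev.peak_index is not None else ev.end_index
        else:
            raise ValueError(f"unknown frame_choice: {frame_choice!r}")
        if frame not in geometries:
            warnings.warn(f"{ref}: no geometry at frame {frame}, skipped", stacklevel=2)
            continue
        thetas.append(opening_angle(geometries[frame], frame, ref).theta)
        prov.append((replica_id, ref))
    return AngleEnsemble(thetas=np.array(thetas), provenance=prov)


def _mode_bandwidth_factor(n: int) -> float:
    """Normal-reference bandwidth for mode *location*: h = 2 sigma n^(-1/7).

    Density-oriented rules (Silverman, h ~ n^(-1/5)) undersmooth for locating
    the argmax: the mode of a KDE built with a wider Gaussian kernel is
    unchanged for a symmetric peak, while its sampling variance falls as
    1/(n h^3).  The n^(-1/7) rate is the AMSE-optimal rate for mode
    estimation; the constant 2 was calibrated on synthetic two-mode Gaussian
    mixtures (component sd 3-8 degrees), where it gives mode-recovery RMSE
    ~0.2 degrees at n = 2000 with bias below 0.03 degrees (docs/methods.md).
    """
    return 2.0 * n ** (-1.0 / 7.0)


def _kde_mode(samples: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Argmax of a Gaussian KDE (mode-rate bandwidth) over a fine grid."""
    if np.ptp(samples) == 0:  # point mass: KDE degenerate, mode is the value
        return float(samples[0])
    kde = stats.gaussian_kde(samples, bw_method=_mode_bandwidth_factor(samples.size))
    if grid is None:
        pad = 3.0 * samples.std(ddof=1)
        grid = np.linspace(samples.min() - pad, samples.max() + pad, 2048)
    dens = kde(grid)
    i = int(np.argmax(dens))
    if 0 < i < grid.size - 1:
        # parabolic refinement between grid points
        y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            return float(grid[i] + 0.5 * (y0 - y2) / denom * (grid[1] - grid[0]))
    return float(grid[i])


def _side_mode(samples: np.ndarray, side: str, rng: np.random.Generator) -> ModeEstimate:
    if samples.size == 0:
        return ModeEstimate(location=float("nan"), location_stderr=float("nan"),
                            side=side, missing=True)
    if samples.size < 50:
        warnings.warn(
            f"only {samples.size} samples on the {side} side; mode estimate is unstable",
            stacklevel=3,
        )
    loc = _kde_mode(samples)
    if np.ptp(samples) == 0:
        return ModeEstimate(location=loc, location_stderr=0.0, side=side)
    # resampled modes only wander a few bandwidths around the full-sample
    # mode, so a local grid keeps the bootstrap cheap without losing accuracy
    spread = samples.std(ddof=1) * _mode_bandwidth_factor(samples.size) * 2.0 + 1e-6
    grid = np.linspace(loc - 3 * spread, loc + 3 * spread, 256)
    boots = np.empty(N_BOOTSTRAP)
    for b in range(N_BOOTSTRAP):
        boots[b] = _kde_mode(
            rng.choice(samples, size=samples.size, replace=True), grid=grid
        )
    return ModeEstimate(location=loc, location_stderr=float(boots.std(ddof=1)), side=side)


def estimate_modes(
    ensemble: AngleEnsemble, seed: int = 0
) -> tuple[ModeEstimate, ModeEstimate]:
    """Locate the positive and negative modes of a bimodal angle ensemble.

    The ensemble is partitioned by sign (samples exactly at zero are
    excluded from both sides); each side gets a Gaussian KDE with the
    mode-rate bandwidth h = 2 sigma n^(-1/7) whose argmax is the mode
    location, with a seeded bootstrap (200 resamples) standard error.  A
    side with no samples returns a ModeEstimate flagged ``missing``.
    """
    rng = np.random.default_rng(seed)
    pos = ensemble.thetas[ensemble.thetas > 0]
    neg = ensemble.thetas[ensemble.thetas < 0]
    return _side_mode(pos, "positive", rng), _side_mode(neg, "negative", rng)


def _bootstrap_ci(
    indicator: np.ndarray, seed: int
) -> tuple[float, tuple[float, float]]:
    frac = float(indicator.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(N_BOOTSTRAP)
    for b in range(N_BOOTSTRAP):
        boots[b] = rng.choice(indicator, size=indicator.size, replace=True).mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return frac, (float(lo), float(hi))


def asymmetric_fraction(
    ensemble: AngleEnsemble, threshold: float = 3.0, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Fraction of events with |theta| > threshold, with 95% bootstrap CI."""
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    return _bootstrap_ci((np.abs(ensemble.thetas) > threshold).astype(float), seed)


def directional_fraction(
    ensemble: AngleEnsemble, threshold: float = 3.0, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Fraction of events in the negative-angle mode (theta < -threshold).

    This is the share of events opening in the direction static
    electronic-structure optimisation predicts (B1 closed, B3 open).
    """
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    return _bootstrap_ci((ensemble.thetas < -threshold).astype(float), seed)
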