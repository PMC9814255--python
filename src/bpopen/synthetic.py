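"""Synthetic inputs with the statistical structure the analysis assumes.

The study's raw inputs are steered-MD hydrogen-bond time series and
electronic-structure reaction paths; neither is reproducible at desk scale.
This module generates stand-ins for every input the pipeline consumes:

* breathing: mean-reverting (Ornstein-Uhlenbeck) fluctuations of the three
  bond lengths around their equilibria, emulating thermal base-pair
  breathing;
* separation events: linear ramps of the separation metric at a prescribed
  speed, with the extension shared across bonds so a prescribed opening
  angle is implied (theta < 0: B1 stays closed, B3 carries roughly double
  the mean extension);
* opening-angle ensembles: a two-component Gaussian mixture with modes near
  +18.9 and -17.4 degrees and a negative-mode weight near 0.39;
* reaction paths: stepwise double-proton-transfer paths in which each
  proton hops 1 Angstrom over a single inter-image step centred at a
  tunable fraction of the reaction coordinate;
* energy-level tables whose first barrier grows linearly with separation.

Every generator is bit-reproducible given its config (including seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .angles import AngleEnsemble
from .energetics import EnergyLevels, ReactionPath
from .geometry import BasePairGeometry
from .timeseries import BOND_NAMES, BondSeries

__all__ = [
    "BreathingConfig",
    "EventConfig",
    "MixtureConfig",
    "DEFAULT_EQUILIBRIA",
    "ANGLE_SHEAR_DEG",
    "gen_breathing",
    "inject_event",
    "gen_event_series",
    "gen_event_ensemble",
    "gen_angle_mixture",
    "geometry_for_theta",
    "gen_reaction_path",
    "gen_energy_levels",
]

#: Unstrained bond lengths (Angstrom) of the canonical pair, used as the
#: synthetic equilibria.
DEFAULT_EQUILIBRIA = {"B1": 2.89, "B2": 2.96, "B3": 2.89}

#: Opening angle (degrees) at which the shear model fully unloads B1
#: (B1 extension 0, B3 extension twice the mean) -- the magnitude of the
#: negative mode observed in steered MD.
ANGLE_SHEAR_DEG = 17.4


@dataclass(frozen=True)
class BreathingConfig:
    """Ornstein-Uhlenbeck breathing noise around the bond equilibria.

    Defaults: 0.1 ps sampling over 20 ps, stationary amplitude 0.1 Angstrom
    and 1 ps correlation time -- small against the 2 Angstrom break
    threshold, as breathing is against real separation.
    """

    dt: float = 0.1  # ps
    duration: float = 20.0  # ps
    ou_sigma: float = 0.1  # Angstrom, stationary standard deviation
    ou_tau: float = 1.0  # ps, relaxation time
    equilibria: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EQUILIBRIA)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.ou_tau <= 0 or self.ou_sigma < 0:
            raise ValueError("dt and ou_tau must be positive, ou_sigma non-negative")


@dataclass(frozen=True)
class EventConfig:
    """One linear-ramp separation event.

    The ramp starts at ``start`` (ps) and raises the separation metric at
    ``speed`` (Angstrom/ps) until ``max_extension``, after which the pair
    stays open.  ``theta_true`` sets how the extension is shared across the
    three bonds (the implied opening angle).
    """

    speed: float = 1.2  # Angstrom / ps
    start: float = 14.0  # ps
    theta_true: float = 0.0  # degrees
    max_extension: float = 3.0  # Angstrom

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("event speed must be positive")
        if abs(self.theta_true) > 90:
            raise ValueError("theta_true must lie in [-90, 90] degrees")


@dataclass(frozen=True)
class MixtureConfig:
    """Two-component Gaussian mixture of signed opening angles."""

    mode_pos: float = 18.9
    mode_neg: float = -17.4
    sigma_pos: float = 5.0
    sigma_neg: float = 5.0
    weight_neg: float = 0.39
    n: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_neg <= 1.0:
            raise ValueError("weight_neg must lie in [0, 1]")


def gen_breathing(cfg: BreathingConfig) -> BondSeries:
    """Three independent OU series around the configured equilibria.

    Exact discretisation: x[k+1] = rho x[k] + sigma sqrt(1-rho^2) N(0,1)
    with rho = exp(-dt/tau), started from the stationary distribution, so
    the sample standard deviation matches ``ou_sigma`` at any dt.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration / cfg.dt))
    time = np.arange(n) * cfg.dt
    rho = np.exp(-cfg.dt / cfg.ou_tau)
    lengths: dict[str, np.ndarray] = {}
    for bond in BOND_NAMES:
        x = np.empty(n)
        x[0] = rng.normal(0.0, cfg.ou_sigma) if cfg.ou_sigma > 0 else 0.0
        shocks = rng.normal(0.0, 1.0, size=n - 1)
        scale = cfg.ou_sigma * np.sqrt(1.0 - rho**2)
        for k in range(1, n):
            x[k] = rho * x[k - 1] + scale * shocks[k - 1]
        lengths[bond] = cfg.equilibria[bond] + x
    return BondSeries(time=time, lengths=lengths)


def _bond_weights(theta: float) -> dict[str, float]:
    """Share of the mean extension carried by each bond (linear shear model).

    theta = 0 loads all bonds equally; theta = -ANGLE_SHEAR_DEG unloads B1
    entirely and doubles B3 (and mirrored for positive theta); beyond that
    the weights saturate.  The weights always average to 1 so the metric
    ramp speed is exact.
    """
    w1 = float(np.clip(1.0 + theta / ANGLE_SHEAR_DEG, 0.0, 2.0))
    return {"B1": w1, "B2": 1.0, "B3": 2.0 - w1}


def inject_event(series: BondSeries, ev: EventConfig) -> BondSeries:
    """Add one separation ramp to a bond series (returns a new series)."""
    t_end = ev.start + ev.max_extension / ev.speed
    if ev.start < series.time[0] or ev.start > series.time[-1]:
        raise ValueError("event start lies outside the series")
    for prior in series.injected:
        if ev.start < prior["t_end"] and t_end > prior["t_start"]:
            raise ValueError("overlapping injected events")
    ramp = np.clip(ev.speed * (series.time - ev.start), 0.0, ev.max_extension)
    w = _bond_weights(ev.theta_true)
    lengths = {b: series.lengths[b] + w[b] * ramp for b in BOND_NAMES}
    new = replace(series, lengths=lengths)
    new.injected = series.injected + [
        {
            "t_start": ev.start,
            "t_end": t_end,
            "speed": ev.speed,
            "theta_true": ev.theta_true,
            "max_extension": ev.max_extension,
        }
    ]
    return new


def gen_event_series(
    breathing: BreathingConfig, event: EventConfig
) -> BondSeries:
    """Breathing noise with one injected separation event."""
    return inject_event(gen_breathing(breathing), event)


def gen_event_ensemble(
    n_series: int,
    breathing: BreathingConfig = BreathingConfig(),
    event: EventConfig = EventConfig(),
    seed: int = 0,
) -> list[BondSeries]:
    """Independent replicas, one event each, with per-replica derived seeds."""
    children = np.random.SeedSequence(seed).spawn(n_series)
    out = []
    for k, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = replace(breathing, seed=sub_seed)
        s = gen_event_series(cfg, event)
        out.append(replace(s, replica_id=f"r{k}"))
    return out


def gen_angle_mixture(cfg: MixtureConfig) -> AngleEnsemble:
    """Sample signed opening angles from the two-mode Gaussian mixture."""
    rng = np.random.default_rng(cfg.seed)
    is_neg = rng.random(cfg.n) < cfg.weight_neg
    thetas = np.where(
        is_neg,
        rng.normal(cfg.mode_neg, cfg.sigma_neg, cfg.n),
        rng.normal(cfg.mode_pos, cfg.sigma_pos, cfg.n),
    )
    prov = [("synthetic", f"event{i}") for i in range(cfg.n)]
    return AngleEnsemble(thetas=thetas, provenance=prov)


def geometry_for_theta(theta: float, helix_axis=(0.0, 0.0, 1.0)) -> BasePairGeometry:
    """Planar base-pair geometry whose opening angle is exactly ``theta``.

    The guanine N2->O6 vector lies along +x; the cytosine O2->N4 vector is
    rotated by ``theta`` about the helix axis (+z), so the signed opening
    angle of the constructed geometry equals ``theta`` by the cross-product
    convention.
    """
    th = np.radians(theta)
    lg, lc = 5.0, 5.0  # donor-acceptor vector lengths, Angstrom (arbitrary)
    atoms = {
        "DG:N2": np.array([0.0, 0.0, 0.0]),
        "DG:O6": np.array([lg, 0.0, 0.0]),
        "DC:O2": np.array([8.0, 0.0, 0.0]),
        "DC:N4": np.array([8.0 + lc * np.cos(th), lc * np.sin(th), 0.0]),
    }
    return BasePairGeometry(atoms=atoms, helix_axis=np.asarray(helix_axis, float))


# Minimal planar G-C core used as the default reaction-path template:
# three heavy atoms per base plus the two transferring protons.  H41 is the
# B1 (top-bond) proton on the cytosine amino group, H1 the B2 (middle-bond)
# proton on guanine N1.
_PATH_TEMPLATE_LABELS = ["O6", "N1", "N2", "N4", "N3", "O2", "H41", "H1"]
_PATH_TEMPLATE_COORDS = np.array(
    [
        [0.0, 2.0, 0.0],  # O6
        [0.0, 0.0, 0.0],  # N1
        [0.0, -2.0, 0.0],  # N2
        [3.0, 2.0, 0.0],  # N4
        [3.0, 0.0, 0.0],  # N3
        [3.0, -2.0, 0.0],  # O2
        [2.0, 2.0, 0.0],  # H41 (canonical: bonded to N4)
        [1.0, 0.0, 0.0],  # H1  (canonical: bonded to N1)
    ]
)
# Transfer displacement of each proton across the hydrogen bond.
_PATH_TEMPLATE_JUMPS = {"H41": np.array([-1.0, 0.0, 0.0]),
                        "H1": np.array([1.0, 0.0, 0.0])}


def gen_reaction_path(
    n_images: int = 29,
    transfer_q_b1: float = 0.8,
    transfer_q_b2: float = 0.2,
    template: tuple[list[str], np.ndarray] | None = None,
    jumps: dict[str, np.ndarray] | None = None,
    q_step: float = 0.25,
) -> ReactionPath:
    """Stepwise DPT path: each proton hops over one inter-image step.

    The B1 proton (H41) transfers in the segment whose position is the
    fraction ``transfer_q_b1`` of the total reaction coordinate, the B2
    proton (H1) at ``transfer_q_b2``; heavy atoms stay fixed and q_IRC is
    uniform with spacing ``q_step``.  Coincident fractions give a
    synchronous path.
    """
    if n_images < 3:
        raise ValueError("need at least 3 images")
    for f in (transfer_q_b1, transfer_q_b2):
        if not 0.0 <= f <= 1.0:
            raise ValueError("transfer fractions must lie in [0, 1]")
    labels, base = (
        (list(_PATH_TEMPLATE_LABELS), _PATH_TEMPLATE_COORDS)
        if template is None
        else (list(template[0]), np.asarray(template[1], float))
    )
    jumps = dict(_PATH_TEMPLATE_JUMPS) if jumps is None else jumps

    def segment(fraction: float) -> int:
        return int(np.clip(np.floor(fraction * (n_images - 1)), 0, n_images - 2))

    seg = {"H41": segment(transfer_q_b1), "H1": segment(transfer_q_b2)}
    coords = np.repeat(base[None, :, :], n_images, axis=0)
    for proton, s in seg.items():
        if proton not in labels:
            raise KeyError(f"template lacks proton {proton!r}")
        idx = labels.index(proton)
        coords[s + 1 :, idx, :] += jumps[proton]
    q = np.arange(n_images) * q_step
    return ReactionPath(labels=labels, coords=coords, q_irc=q)


def gen_energy_levels(
    separations: Sequence[float],
    slope1: float = 1.41,
    base: EnergyLevels | None = None,
) -> list[EnergyLevels]:
    """Level tables whose first barrier grows linearly with separation.

    E(TS1) rises at ``slope1`` (eV/Angstrom); the other levels follow
    deterministic sub-unit multiples of the same trend so the full profile
    deforms smoothly.  slope1 = 0 reproduces ``base`` at every separation.
    """
    if slope1 < 0:
        raise ValueError("slope1 must be non-negative")
    if base is None:
        from .energetics import published_levels_eq

        base = published_levels_eq()
    out = []
    for s in separations:
        rise = slope1 * float(s)
        out.append(
            EnergyLevels(
                separation=float(s),
                e_canonical=0.0,
                e_ts1=base.e_ts1 + rise,
                e_intermediate=base.e_intermediate + 0.6 * rise,
                e_ts2=base.e_ts2 + 0.9 * rise,
                e_tautomer=base.e_tautomer + 0.3 * rise,
            )
        )
    return out
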