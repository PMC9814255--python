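"""Double-proton-transfer energetics along a strand-separation coordinate.

Stage 3.  The G-C pair can tautomerise by a stepwise double proton transfer
(DPT): the middle (B2) proton moves first, creating a single-proton-transfer
intermediate, then the top (B1) proton follows.  Three quantities summarise
the mechanism:

* **asynchronicity** alpha: how far apart along the reaction coordinate
  q_IRC the two proton-transfer events occur,
  alpha = |alpha_B1 - alpha_B2| / ||q_IRC||, where alpha_i is the q_IRC
  position at which proton i moves fastest (argmax of the squared derivative
  of its Cartesian position with respect to q_IRC).  alpha = 0 is a
  synchronous transfer; alpha -> 1 when the transfers sit at opposite ends
  of the path.
* **barrier bookkeeping**: from the five stationary-state energies
  (canonical, TS1, intermediate, TS2, tautomer, all relative to canonical)
  the forward/reverse barriers of both steps and the reaction asymmetry
  (tautomer energy) follow by subtraction.
* **survival threshold**: the minimum tautomer lifetime for it to outlive
  strand separation, i.e. the time for the pair to separate past the
  distance at which reverse transfer stops, break_distance / speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReactionPath",
    "AsynchronicityResult",
    "EnergyLevels",
    "BarrierSummary",
    "BarrierTrend",
    "asynchronicity",
    "barrier_summary",
    "barrier_trend",
    "survival_threshold",
    "read_energy_levels",
    "published_levels_eq",
]

LEVEL_FIELDS = ("e_canonical", "e_ts1", "e_intermediate", "e_ts2", "e_tautomer")


@dataclass
class ReactionPath:
    """An ordered series of geometries along a proton-transfer path.

    ``coords`` has shape (n_images, n_atoms, 3) in Angstrom; ``labels`` names
    the atoms (shared by every image).  ``q_irc`` is the cumulative reaction
    coordinate; when absent it is computed as the cumulative all-atom
    Cartesian displacement between consecutive images (plain, not
    mass-weighted).  ``energies`` (eV, optional) are per-image.
    """

    labels: list[str]
    coords: np.ndarray
    energies: np.ndarray | None = None
    q_irc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_images, n_atoms, 3)")
        if self.coords.shape[0] < 3:
            raise ValueError("a reaction path needs at least 3 images")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("labels and coords disagree on atom count")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if self.energies.size != self.n_images:
                raise ValueError("energies must be per-image")
        if self.q_irc is None:
            steps = np.linalg.norm(
                np.diff(self.coords, axis=0).reshape(self.n_images - 1, -1), axis=1
            )
            self.q_irc = np.concatenate(([0.0], np.cumsum(steps)))
        else:
            self.q_irc = np.asarray(self.q_irc, dtype=float)
            if self.q_irc.size != self.n_images:
                raise ValueError("q_irc must be per-image")
            if np.any(np.diff(self.q_irc) < 0):
                raise ValueError("q_irc must be non-decreasing")
        if self.q_irc[-1] <= 0:
            raise ValueError("total path length ||q_IRC|| must be positive")

    @property
    def n_images(self) -> int:
        return int(self.coords.shape[0])

    def atom_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"atom label {label!r} not on path (available: {self.labels})"
            ) from None

    @classmethod
    def from_xyz(cls, path: str | Path) -> "ReactionPath":
        """Read a multi-frame XYZ file.

        Comment lines may carry ``energy=<eV>`` and ``q=<Angstrom>`` tokens;
        when ``q=`` is absent the reaction coordinate is recomputed as
        cumulative displacement.
        """
        lines = Path(path).read_text().splitlines()
        labels: list[str] = []
        frames: list[np.ndarray] = []
        energies: list[float] = []
        qs: list[float] = []
        have_energy = True
        have_q = True
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            n = int(lines[i].split()[0])
            comment = lines[i + 1]
            e = q = None
            for tok in comment.replace(",", " ").split():
                if tok.startswith("energy="):
                    e = float(tok.split("=", 1)[1])
                elif tok.startswith("q="):
                    q = float(tok.split("=", 1)[1])
            if e is None:
                have_energy = False
            else:
                energies.append(e)
            if q is None:
                have_q = False
            else:
                qs.append(q)
            block = lines[i + 2 : i + 2 + n]
            frame_labels = [ln.split()[0] for ln in block]
            if not labels:
                labels = frame_labels
            elif frame_labels != labels:
                raise ValueError("images disagree on atom labels/order")
            frames.append(
                np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
            )
            i += 2 + n
        return cls(
            labels=labels,
            coords=np.stack(frames),
            energies=np.array(energies) if have_energy else None,
            q_irc=np.array(qs) if have_q else None,
        )

    def to_xyz(self, path: str | Path) -> None:
        out: list[str] = []
        for k in range(self.n_images):
            out.append(str(len(self.labels)))
            comment = f"image {k} q={float(self.q_irc[k])!r}"
            if self.energies is not None:
                comment += f" energy={float(self.energies[k])!r}"
            out.append(comment)
            for lab, (x, y, z) in zip(self.labels, self.coords[k]):
                out.append(f"{lab} {float(x)!r} {float(y)!r} {float(z)!r}")
        Path(path).write_text("\n".join(out) + "\n")


@dataclass(frozen=True)
class AsynchronicityResult:
    """alpha = |alpha_B1 - alpha_B2| / ||q_IRC||, dimensionless in [0, 1]."""

    alpha: float
    alpha_b1: float  # q_IRC position (Angstrom) of maximal B1-proton motion
    alpha_b2: float
    q_total: float


def asynchronicity(
    path: ReactionPath, proton_b1: str, proton_b2: str
) -> AsynchronicityResult:
    """Asynchronicity of a double proton transfer along a reaction path.

    For each transferring proton, the derivative of its Cartesian position
    with respect to q_IRC is taken by finite differences per path segment
    (evaluated at the segment midpoint in q_IRC); the proton's transfer
    position alpha_i is the midpoint where the squared norm of that
    derivative is maximal.  Segments with no q_IRC advance are skipped; a
    tied argmax resolves to the earliest midpoint with a warning.
    """
    q = path.q_irc

    def transfer_position(label: str) -> float:
        x = path.coords[:, path.atom_index(label), :]
        dq = np.diff(q)
        keep = dq > 0
        if not np.any(keep):
            raise ValueError("q_irc never advances; derivatives undefined")
        deriv = np.diff(x, axis=0)[keep] / dq[keep, None]
        speed2 = np.einsum("ij,ij->i", deriv, deriv)
        mids = (q[:-1] + q[1:])[keep] / 2.0
        best = np.flatnonzero(speed2 == speed2.max())
        if best.size > 1:
            warnings.warn(
                f"tied maximal motion for {label}; taking the earliest segment",
                stacklevel=3,
            )
        return float(mids[best[0]])

    a1 = transfer_position(proton_b1)
    a2 = transfer_position(proton_b2)
    return AsynchronicityResult(
        alpha=abs(a1 - a2) / float(q[-1]),
        alpha_b1=a1,
        alpha_b2=a2,
        q_total=float(q[-1]),
    )


@dataclass
class EnergyLevels:
    """Stationary-state energies (eV, relative to canonical) at one separation.

    ``None`` marks a level that is not available; derived barriers involving
    it come back NaN and are listed in the summary's ``missing`` field.
    """

    separation: float
    e_canonical: float = 0.0
    e_ts1: float | None = None
    e_intermediate: float | None = None
    e_ts2: float | None = None
    e_tautomer: float | None = None

    def shifted(self) -> "EnergyLevels":
        """Re-reference so the canonical state sits at zero."""
        ref = self.e_canonical
        vals = {
            f: (None if getattr(self, f) is None else getattr(self, f) - ref)
            for f in LEVEL_FIELDS
        }
        return EnergyLevels(separation=self.separation, **vals)


@dataclass(frozen=True)
class BarrierSummary:
    """Forward/reverse barriers of the stepwise DPT and the reaction asymmetry.

    forward_1 = E(TS1) - E(canonical)      first-step activation
    reverse_1 = E(TS1) - E(intermediate)   intermediate back to canonical
    forward_2 = E(TS2) - E(intermediate)   second-step activation
    reverse_2 = E(TS2) - E(tautomer)       tautomer back to intermediate
    asymmetry = E(tautomer) - E(canonical) reaction energy of the full DPT
    """

    forward_1: float
    forward_2: float
    reverse_1: float
    reverse_2: float
    asymmetry: float
    missing: tuple[str, ...] = ()


def barrier_summary(levels: EnergyLevels) -> BarrierSummary:
    """Derive the stepwise-DPT barriers from one set of energy levels."""
    lv = levels.shifted()

    def diff(a: float | None, b: float | None) -> float:
        return float("nan") if a is None or b is None else float(a - b)

    missing = tuple(f for f in LEVEL_FIELDS if getattr(lv, f) is None)
    if missing:
        warnings.warn(f"missing energy levels: {missing}; partial summary",
                      stacklevel=2)
    return BarrierSummary(
        forward_1=diff(lv.e_ts1, lv.e_canonical),
        forward_2=diff(lv.e_ts2, lv.e_intermediate),
        reverse_1=diff(lv.e_ts1, lv.e_intermediate),
        reverse_2=diff(lv.e_ts2, lv.e_tautomer),
        asymmetry=diff(lv.e_tautomer, lv.e_canonical),
        missing=missing,
    )


@dataclass(frozen=True)
class BarrierTrend:
    """OLS fit of the first forward barrier against separation distance."""

    slope: float  # eV / Angstrom
    intercept: float  # eV
    r_squared: float
    monotonic: bool  # forward_1 non-decreasing in separation


def barrier_trend(levels_list: Sequence[EnergyLevels]) -> BarrierTrend:
    """Linear trend of forward_1 vs separation (duplicates averaged first)."""
    rows = [
        (lv.separation, barrier_summary(lv).forward_1)
        for lv in levels_list
    ]
    df = (
        pd.DataFrame(rows, columns=["separation", "forward_1"])
        .groupby("separation", sort=True)
        .mean()
        .reset_index()
    )
    if len(df) < 2:
        raise ValueError("need at least 2 distinct separations for a trend fit")
    x = df["separation"].to_numpy()
    y = df["forward_1"].to_numpy()
    res = stats.linregress(x, y)
    if np.allclose(y, y[0]):
        r2 = 1.0  # constant data: the flat line is an exact fit
    else:
        r2 = float(res.rvalue**2)
    return BarrierTrend(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        monotonic=bool(np.all(np.diff(y) >= 0)),
    )


def survival_threshold(break_distance: float = 2.0, speed: float = 1.2) -> float:
    """Minimum tautomer lifetime (ps) to outlive separation past break_distance.

    Once the pair has separated ``break_distance`` (Angstrom) no reverse
    proton transfer occurs, so a tautomer formed at the start of an event
    survives if it lives longer than break_distance / speed.
    """
    if speed <= 0:
        raise ValueError(f"separation speed must be positive, got {speed}")
    return break_distance / speed


# ---------------------------------------------------------------------------
# Energy-level tables


def read_energy_levels(path: str | Path) -> list[EnergyLevels]:
    """Read a delimited level table with columns
    (separation_A, E_can, E_ts1, E_int, E_ts2, E_taut); energies re-referenced
    so E_can = 0 on load."""
    from .io import read_table

    df = read_table(path)
    required = ["separation_A", "E_can", "E_ts1", "E_int", "E_ts2", "E_taut"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"level table {path} lacks columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            EnergyLevels(
                separation=float(row["separation_A"]),
                e_canonical=float(row["E_can"]),
                e_ts1=float(row["E_ts1"]),
                e_intermediate=float(row["E_int"]),
                e_ts2=float(row["E_ts2"]),
                e_tautomer=float(row["E_taut"]),
            ).shifted()
        )
    return out


def write_energy_levels(levels: Sequence[EnergyLevels], path: str | Path) -> None:
    rows = [
        {
            "separation_A": lv.separation,
            "E_can": lv.e_canonical,
            "E_ts1": lv.e_ts1,
            "E_int": lv.e_intermediate,
            "E_ts2": lv.e_ts2,
            "E_taut": lv.e_tautomer,
        }
        for lv in levels
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def published_levels_eq() -> EnergyLevels:
    """Published B3LYP+XDM stationary-state energies at zero separation.

    Loaded from the packaged table ``data/gc_dpt_levels_eq.csv``.  Note the
    published numbers are not all mutually consistent: TS2 here is placed at
    E(tautomer) + reverse barrier = 0.565 eV, which reproduces the quoted
    first barrier, asymmetry and reverse barrier; the quoted "second barrier"
    of 0.516 eV fits no referencing convention of these levels and is left
    as-is in the source (see docs/methods.md).
    """
    table = Path(__file__).parent / "data" / "gc_dpt_levels_eq.csv"
    return read_energy_levels(table)[0]
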