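"""Beam orientations, the gantry-couch angular grid and angular separation.

Angle convention (fixed so results are bit-reproducible): IEC-style gantry
with 0 deg an anterior beam travelling posteriorly, increasing toward the
patient's left, and couch rotation about the room-vertical (patient
anterior-posterior) axis for a supine patient.  In the patient frame
(x = left, y = posterior, z = superior) the unit beam direction
(source -> isocenter) is

    d(g, c) = (-sin g * cos c,  cos g,  sin g * sin c).

Beams are parallel (source at infinity); no divergence is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeamOrientation",
    "AngularGrid",
    "beam_direction",
    "enumerate_grid",
    "central_angle",
]


def beam_direction(gantry_deg: float, couch_deg: float) -> np.ndarray:
    """Unit beam direction (source -> isocenter) in the patient frame."""
    g = np.deg2rad(gantry_deg)
    c = np.deg2rad(couch_deg)
    return np.array([-np.sin(g) * np.cos(c), np.cos(g), np.sin(g) * np.sin(c)])


@dataclass
class BeamOrientation:
    """A (gantry, couch) pair with its derived patient-frame direction."""

    gantry_deg: float
    couch_deg: float
    direction: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gantry_deg) and np.isfinite(self.couch_deg)):
            raise ValueError("gantry/couch angles must be finite")
        if self.direction is None:
            self.direction = beam_direction(self.gantry_deg, self.couch_deg)
        else:
            self.direction = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(self.direction) - 1.0) > 1e-12:
                raise ValueError("direction must be a unit vector")


@dataclass
class AngularGrid:
    """The gantry x couch search grid with a deliverability mask.

    ``deliverable`` has shape ``(len(couch_deg), len(gantry_deg))``; cells
    marked False are excluded from every downstream map and selection.
    """

    gantry_deg: np.ndarray
    couch_deg: np.ndarray
    deliverable: np.ndarray

    def __post_init__(self) -> None:
        self.gantry_deg = np.asarray(self.gantry_deg, dtype=float).ravel()
        self.couch_deg = np.asarray(self.couch_deg, dtype=float).ravel()
        self.deliverable = np.asarray(self.deliverable, dtype=bool)
        expected = (self.couch_deg.size, self.gantry_deg.size)
        if self.deliverable.shape != expected:
            raise ValueError(
                f"deliverable mask shape {self.deliverable.shape} != (n_couch, n_gantry) {expected}"
            )
        if not self.deliverable.any():
            raise ValueError("angular grid has no deliverable cell")

    @classmethod
    def default(
        cls,
        gantry_step_deg: float = 10.0,
        couch_step_deg: float = 15.0,
        remove_duplicate_directions: bool = True,
    ) -> "AngularGrid":
        """Gantry 0-350 / couch -90..90 grid.

        With duplicate removal on, gantry 0 and 180 at couch != 0 are marked
        non-deliverable: those cells repeat the couch-0 vertical beams (the
        couch rotation leaves a vertical beam invariant).
        """
        if gantry_step_deg <= 0 or couch_step_deg <= 0:
            raise ValueError("angle steps must be positive")
        if 360.0 % gantry_step_deg or 180.0 % couch_step_deg:
            raise ValueError("steps must divide the gantry (360) and couch (180) ranges evenly")
        gantry = np.arange(0.0, 360.0, gantry_step_deg)
        couch = np.arange(-90.0, 90.0 + 0.5 * couch_step_deg, couch_step_deg)
        deliverable = np.ones((couch.size, gantry.size), dtype=bool)
        if remove_duplicate_directions:
            dup_g = np.isin(gantry, (0.0, 180.0))
            dup_c = couch != 0.0
            deliverable[np.ix_(dup_c, dup_g)] = False
        return cls(gantry, couch, deliverable)

    def apply_deliverability_csv(self, path) -> None:
        """Apply a machine deliverability table (columns gantry_deg,couch_deg,deliverable)."""
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("gantry_deg", "couch_deg", "deliverable"):
            if col not in df.columns:
                raise ValueError(f"deliverability file {path} lacks column {col!r}")
        for _, row in df.iterrows():
            ig = np.flatnonzero(np.isclose(self.gantry_deg, float(row["gantry_deg"])))
            ic = np.flatnonzero(np.isclose(self.couch_deg, float(row["couch_deg"])))
            if ig.size != 1 or ic.size != 1:
                raise ValueError(
                    f"deliverability entry ({row['gantry_deg']}, {row['couch_deg']}) "
                    "does not match a grid cell"
                )
            self.deliverable[ic[0], ig[0]] = bool(row["deliverable"])
        if not self.deliverable.any():
            raise ValueError("deliverability table excludes every grid cell")

    def cells(self):
        """Deliverable cells as ``(ic, ig, couch_deg, gantry_deg)`` in row-major (couch, gantry) order."""
        for ic, c in enumerate(self.couch_deg):
            for ig, g in enumerate(self.gantry_deg):
                if self.deliverable[ic, ig]:
                    yield ic, ig, float(c), float(g)

    def n_deliverable(self) -> int:
        return int(self.deliverable.sum())


def enumerate_grid(grid: AngularGrid) -> list:
    """All deliverable beam orientations in row-major (couch, gantry) order."""
    return [BeamOrientation(g, c) for _, _, c, g in grid.cells()]


def central_angle(a, b) -> float:
    """Central angle (degrees, in [0, 180]) between two beam directions.

    Accepts :class:`BeamOrientation` objects or plain unit 3-vectors.
    """
    da = a.direction if isinstance(a, BeamOrientation) else np.asarray(a, dtype=float)
    db = b.direction if isinstance(b, BeamOrientation) else np.asarray(b, dtype=float)
    return float(np.degrees(np.arccos(np.clip(np.dot(da, db), -1.0, 1.0))))
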