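"""Hounsfield-unit to relative-stopping-power (RSP) conversion.

CT numbers are mapped to proton stopping power relative to water through a
piecewise-linear lookup table in the style of a stoichiometric calibration
curve.  The package ships a representative surrogate table anchored at
RSP(0 HU) = 1 (water); site-specific calibrations are supplied as a CSV
file with header ``hu,rsp`` and strictly increasing HU nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import VoxelVolume

__all__ = ["RSPTable", "default_table", "hu_to_rsp"]

# (HU, RSP) nodes of the built-in surrogate calibration: air, lung,
# adipose, water, soft tissue, trabecular and cortical bone.
DEFAULT_NODES = (
    (-1000.0, 0.001),
    (-750.0, 0.25),
    (-120.0, 0.93),
    (0.0, 1.000),
    (50.0, 1.05),
    (300.0, 1.15),
    (1000.0, 1.55),
    (3000.0, 2.40),
)


@dataclass(frozen=True)
class RSPTable:
    """Piecewise-linear HU -> RSP lookup table.

    HU values outside the node range are clamped to the end nodes, so any
    table covers the full CT number range after clamping.
    """

    hu: np.ndarray
    rsp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "hu", np.asarray(self.hu, dtype=float).ravel())
        object.__setattr__(self, "rsp", np.asarray(self.rsp, dtype=float).ravel())
        if self.hu.size < 2 or self.hu.size != self.rsp.size:
            raise ValueError("RSP table needs >= 2 (hu, rsp) node pairs")
        if not np.all(np.isfinite(self.hu)) or not np.all(np.isfinite(self.rsp)):
            raise ValueError("RSP table nodes must be finite")
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("RSP table HU nodes must be strictly increasing")
        if np.any(self.rsp < 0) or np.any(np.diff(self.rsp) < 0):
            raise ValueError("RSP values must be >= 0 and non-decreasing")

    def lookup(self, hu) -> np.ndarray:
        """Interpolate RSP at the given HU values (clamped to the end nodes)."""
        return np.interp(np.asarray(hu, dtype=float), self.hu, self.rsp)

    @classmethod
    def from_nodes(cls, nodes) -> "RSPTable":
        nodes = np.asarray(nodes, dtype=float)
        return cls(nodes[:, 0], nodes[:, 1])

    @classmethod
    def from_csv(cls, path) -> "RSPTable":
        import pandas as pd

        df = pd.read_csv(path)
        if not {"hu", "rsp"}.issubset(df.columns):
            raise ValueError(f"calibration file {path} must have columns 'hu,rsp'")
        return cls(df["hu"].to_numpy(), df["rsp"].to_numpy())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"hu": self.hu, "rsp": self.rsp}).to_csv(path, index=False)


def default_table() -> RSPTable:
    """The built-in surrogate calibration table."""
    return RSPTable.from_nodes(DEFAULT_NODES)


def hu_to_rsp(vol: VoxelVolume, table: RSPTable | None = None) -> VoxelVolume:
    """Convert an HU volume to an RSP volume, voxelwise."""
    if table is None:
        table = default_table()
    return VoxelVolume(table.lookup(vol.data), vol.spacing_mm.copy(), vol.origin_mm.copy())
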