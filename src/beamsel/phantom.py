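"""Synthetic 4DCT thorax phantom with a periodically moving tumour.

The phantom emulates the anatomy the beam-selection pipeline needs — a
soft-tissue body, two low-density lungs, a heart placed anteriorly, a
spinal cord running posteriorly along the superior-inferior axis, and a
spherical tumour in the left lung — painted into an air background in
priority order (body < lungs < heart/cord < tumour, later overwrites).

Respiratory motion is a rigid sinusoidal translation of the tumour only:
phase k of n displaces the tumour center by

    s_k = motion_axis * (amplitude / 2) * (1 - cos(2*pi*k / n)),

so the displacement sweeps from 0 (phase 0, e.g. end-exhale) to the full
peak-to-peak amplitude at mid-cycle.  Organs at risk are static; their
masks therefore coincide with the all-phase composite contours.  Optional
additive Gaussian HU noise is drawn independently per voxel and phase
from a seeded generator.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .volumes import StructureMask, VoxelVolume, write_mask, write_volume

__all__ = ["PhantomSpec", "Phantom4D", "generate_phantom", "write_phantom"]

HU_MIN, HU_MAX = -1024.0, 3071.0


def _vec3(x):
    return tuple(float(v) for v in np.asarray(x, dtype=float).reshape(3))


@dataclass
class PhantomSpec:
    """Geometry, tissue HU values and motion parameters of the phantom.

    All lengths are millimetres in the patient frame (x = left,
    y = posterior, z = superior); the grid is centered on the origin.
    Defaults give a 96^3 voxel, 2 mm isotropic thorax with a 10 mm
    tumour sphere moving 10 mm peak-to-peak along the superior axis.
    """

    grid_shape: tuple = (96, 96, 96)
    spacing_mm: tuple = (2.0, 2.0, 2.0)

    body_semiaxes_mm: tuple = (80.0, 65.0, 94.0)
    body_hu: float = 40.0
    lung_centers_mm: tuple = ((-42.0, 0.0, 10.0), (42.0, 0.0, 10.0))
    lung_semiaxes_mm: tuple = (30.0, 42.0, 60.0)
    lungs_hu: float = -750.0
    heart_center_mm: tuple = (-5.0, -25.0, -15.0)
    heart_semiaxes_mm: tuple = (30.0, 22.0, 28.0)
    heart_hu: float = 30.0
    cord_center_xy_mm: tuple = (0.0, 55.0)
    cord_radius_mm: float = 5.0
    cord_hu: float = 40.0
    tumour_center_mm: tuple = (-25.0, 10.0, -10.0)
    tumour_radius_mm: float = 10.0
    tumour_hu: float = 30.0
    air_hu: float = -1000.0

    motion_amplitude_mm: float = 10.0
    motion_axis: tuple = (0.0, 0.0, 1.0)
    n_phases: int = 10
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.spacing_mm = _vec3(self.spacing_mm)
        self.body_semiaxes_mm = _vec3(self.body_semiaxes_mm)
        self.lung_centers_mm = tuple(_vec3(c) for c in self.lung_centers_mm)
        self.lung_semiaxes_mm = _vec3(self.lung_semiaxes_mm)
        self.heart_center_mm = _vec3(self.heart_center_mm)
        self.heart_semiaxes_mm = _vec3(self.heart_semiaxes_mm)
        self.cord_center_xy_mm = tuple(float(v) for v in self.cord_center_xy_mm)
        self.tumour_center_mm = _vec3(self.tumour_center_mm)
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive counts, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if self.n_phases < 1:
            raise ValueError(f"n_phases must be >= 1, got {self.n_phases}")
        for name in ("body_hu", "lungs_hu", "heart_hu", "cord_hu", "tumour_hu", "air_hu"):
            hu = getattr(self, name)
            if not HU_MIN <= hu <= HU_MAX:
                raise ValueError(f"{name}={hu} outside the CT number range [{HU_MIN}, {HU_MAX}]")
        if self.tumour_radius_mm <= 0 or self.cord_radius_mm <= 0:
            raise ValueError("tumour and cord radii must be positive")
        for name in ("body_semiaxes_mm", "lung_semiaxes_mm", "heart_semiaxes_mm"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if self.motion_amplitude_mm < 0:
            raise ValueError("motion_amplitude_mm must be >= 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        axis = np.asarray(self.motion_axis, dtype=float).reshape(3)
        n = np.linalg.norm(axis)
        if n == 0:
            if self.motion_amplitude_mm > 0:
                raise ValueError("motion_axis must be nonzero when the amplitude is positive")
            axis = np.array([0.0, 0.0, 1.0])
            n = 1.0
        self.motion_axis = _vec3(axis / n)

    @property
    def origin_mm(self) -> np.ndarray:
        """Grid centered on the physical origin (voxel-center of mass at 0)."""
        return -0.5 * (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm)

    def displacement(self, phase: int) -> np.ndarray:
        frac = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / self.n_phases))
        return np.asarray(self.motion_axis) * self.motion_amplitude_mm * frac

    @classmethod
    def from_json(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class Phantom4D:
    """One generated case: phase HU volumes, per-phase GTV masks, static OAR masks."""

    phases: list
    gtv_masks: list
    oar_masks: dict = field(default_factory=dict)


def _coords(spec: PhantomSpec):
    org = spec.origin_mm
    sp = spec.spacing_mm
    x = org[0] + np.arange(spec.grid_shape[0]) * sp[0]
    y = org[1] + np.arange(spec.grid_shape[1]) * sp[1]
    z = org[2] + np.arange(spec.grid_shape[2]) * sp[2]
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _ellipsoid(X, Y, Z, center, semiaxes):
    cx, cy, cz = center
    ax, ay, az = semiaxes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Phantom4D:
    """Generate the phase volumes and structure masks for one phantom case."""
    X, Y, Z = _coords(spec)
    sp = np.asarray(spec.spacing_mm)
    org = spec.origin_mm

    body = _ellipsoid(X, Y, Z, (0.0, 0.0, 0.0), spec.body_semiaxes_mm)
    lungs = np.zeros(spec.grid_shape, dtype=bool)
    for c in spec.lung_centers_mm:
        lungs |= _ellipsoid(X, Y, Z, c, spec.lung_semiaxes_mm)
    heart = _ellipsoid(X, Y, Z, spec.heart_center_mm, spec.heart_semiaxes_mm)
    cx, cy = spec.cord_center_xy_mm
    cord = ((X - cx) ** 2 + (Y - cy) ** 2 <= spec.cord_radius_mm**2) & body

    base = np.full(spec.grid_shape, spec.air_hu)
    base[body] = spec.body_hu
    base[lungs] = spec.lungs_hu
    base[heart] = spec.heart_hu
    base[cord] = spec.cord_hu

    # physical extent of voxel centers, for the out-of-grid check
    lo = org
    hi = org + (np.asarray(spec.grid_shape) - 1) * sp

    rng = np.random.default_rng(spec.seed)
    phases, gtvs = [], []
    for k in range(spec.n_phases):
        center = np.asarray(spec.tumour_center_mm) + spec.displacement(k)
        if np.any(center - spec.tumour_radius_mm < lo) or np.any(center + spec.tumour_radius_mm > hi):
            raise ValueError(
                f"tumour sphere leaves the grid in phase {k} "
                f"(center {np.round(center, 2).tolist()} mm, radius {spec.tumour_radius_mm} mm)"
            )
        sphere = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        sphere = sphere <= spec.tumour_radius_mm**2
        vol = base.copy()
        vol[sphere] = spec.tumour_hu
        if spec.noise_sd_hu > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd_hu, size=spec.grid_shape)
        phases.append(VoxelVolume(vol, sp.copy(), org.copy()))
        gtvs.append(StructureMask(sphere, sp.copy(), org.copy(), role="GTV"))

    oars = {
        "lungs": StructureMask(lungs, sp.copy(), org.copy(), role="lungs"),
        "heart": StructureMask(heart, sp.copy(), org.copy(), role="heart"),
        "spinal_cord": StructureMask(cord, sp.copy(), org.copy(), role="spinal_cord"),
    }
    return Phantom4D(phases, gtvs, oars)


def write_phantom(phantom: Phantom4D, out_dir) -> None:
    """Write phases as ``phase_XX.nii.gz``, GTVs as ``gtv_phase_XX.nii.gz`` and OAR masks."""
    os.makedirs(out_dir, exist_ok=True)
    for k, (vol, gtv) in enumerate(zip(phantom.phases, phantom.gtv_masks)):
        write_volume(vol, os.path.join(out_dir, f"phase_{k:02d}.nii.gz"))
        write_mask(gtv, os.path.join(out_dir, f"gtv_phase_{k:02d}.nii.gz"))
    name_map = {"lungs": "lungs.nii.gz", "heart": "heart.nii.gz", "spinal_cord": "cord.nii.gz"}
    for name, mask in phantom.oar_masks.items():
        write_mask(mask, os.path.join(out_dir, name_map.get(name, f"{name}.nii.gz")))
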