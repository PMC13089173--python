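"""Per-orientation motion-sensitivity (dWEPL) and organ-exposure (PIV) maps.

dWEPL for a beam orientation is the mean absolute difference in WEPL
between the average-intensity CT and each breathing phase, averaged over
all rays of the bundle and all phases:

    dWEPL = (1 / (N_rays * N_phases)) * sum_p sum_r |WEPL_AIP(r) - WEPL_p(r)|

Rays and their distal stop points are built once per orientation on the
AIP-frame target (the ITV) and reused unchanged for every phase, so the
metric compares identical geometric paths across the breathing cycle.

PIV (percentage irradiated volume) of an organ at risk is the fraction of
its voxels traversed by at least one ray of the bundle, each ray truncated
at its distal stop point — a geometry-based surrogate for organ exposure.
It uses the composite (all-phase) OAR contour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import AngularGrid, BeamOrientation
from .raytrace import RayBundle, _trace_bundle, wepl
from .volumes import StructureMask, VoxelVolume, grids_match

__all__ = ["MetricMap", "CaseData", "MetricsConfig", "delta_wepl", "piv", "compute_metric_maps"]

log = logging.getLogger(__name__)

DEFAULT_OARS = ("heart", "lungs", "spinal_cord")


@dataclass
class MetricMap:
    """A scalar metric over the gantry x couch grid.

    ``values`` has shape ``(n_couch, n_gantry)`` with NaN on
    non-deliverable cells.  ``metric`` is ``delta_wepl_mm`` or
    ``piv_fraction`` (suffix ``_z`` once Z-score normalized), ``voi`` the
    structure it refers to (``target`` or an OAR name).
    """

    grid: AngularGrid
    values: np.ndarray
    metric: str
    voi: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.deliverable.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.deliverable.shape}"
            )
        v = self.values[self.grid.deliverable]
        if not np.all(np.isfinite(v)):
            raise ValueError("metric values must be finite on deliverable cells")

    def deliverable_values(self) -> np.ndarray:
        return self.values[self.grid.deliverable]


@dataclass
class CaseData:
    """Everything the map computation needs: RSP volumes and structures on one grid."""

    aip_rsp: VoxelVolume
    phase_rsps: list
    itv: StructureMask
    oars: dict

    def __post_init__(self) -> None:
        for k, vol in enumerate(self.phase_rsps):
            if not grids_match(self.aip_rsp, vol):
                raise ValueError(f"phase {k} RSP volume is not on the AIP grid")
        if not grids_match(self.aip_rsp, self.itv):
            raise ValueError("ITV mask is not on the AIP grid")
        for name, mask in self.oars.items():
            if not grids_match(self.aip_rsp, mask):
                raise ValueError(f"OAR mask {name!r} is not on the AIP grid")


@dataclass
class MetricsConfig:
    ray_pitch_mm: float = 2.0
    oars: tuple = DEFAULT_OARS
    log_every: int = 50


def delta_wepl(
    orientation: BeamOrientation,
    bundle: RayBundle,
    aip_rsp: VoxelVolume,
    phase_rsps,
) -> float:
    """Mean absolute AIP-vs-phase WEPL difference over rays and phases (mm)."""
    phase_rsps = list(phase_rsps)
    if not bundle.rays:
        raise ValueError("ray bundle is empty")
    if not phase_rsps:
        raise ValueError("at least one phase RSP volume is required")
    for k, vol in enumerate(phase_rsps):
        if not grids_match(aip_rsp, vol):
            raise ValueError(f"phase {k} RSP volume is not on the AIP grid")
    total = 0.0
    for ray in bundle.rays:
        w_aip = wepl(ray, aip_rsp)
        for vol in phase_rsps:
            total += abs(w_aip - wepl(ray, vol))
    return total / (len(bundle.rays) * len(phase_rsps))


def piv(
    orientation: BeamOrientation,
    bundle: RayBundle,
    oar: StructureMask,
    vol: VoxelVolume,
) -> float:
    """Fraction of OAR voxels traversed by >= 1 ray (truncated at its stop point)."""
    if not oar.data.any():
        raise ValueError(f"OAR mask {oar.role!r} is empty")
    if not grids_match(oar, vol):
        raise ValueError("OAR mask and volume grids differ")
    from .raytrace import traverse

    visited = np.zeros(int(np.prod(vol.shape)), dtype=bool)
    shape = vol.shape
    for ray in bundle.rays:
        for seg in traverse(ray, vol):
            i, j, k = seg.index
            visited[(i * shape[1] + j) * shape[2] + k] = True
    oar_flat = np.flatnonzero(oar.data.ravel())
    return float(visited[oar_flat].sum()) / oar_flat.size


def compute_metric_maps(
    case: CaseData,
    grid: AngularGrid,
    config: MetricsConfig | None = None,
) -> list:
    """One target dWEPL map plus one PIV map per configured OAR.

    Every deliverable orientation gets one ray bundle (built on the ITV in
    the AIP frame); each ray is traversed once and the traversal is shared
    between the per-phase WEPL integrals and the OAR voxel marking.
    """
    if config is None:
        config = MetricsConfig()
    for name in config.oars:
        if name not in case.oars:
            raise ValueError(f"configured OAR {name!r} has no mask in the case data")

    shape = case.aip_rsp.shape
    n_phases = len(case.phase_rsps)
    if n_phases == 0:
        raise ValueError("case has no phase RSP volumes")
    # per-phase RSP difference from the AIP, flat so traversal indices gather
    # directly; |sum(diff * chord)| == |WEPL_phase - WEPL_AIP| and is exactly
    # zero when a phase equals the AIP
    aip_flat = case.aip_rsp.data.ravel()
    diff_stack = np.stack([p.data.ravel() - aip_flat for p in case.phase_rsps])

    dwepl_vals = np.full(grid.deliverable.shape, np.nan)
    piv_vals = {name: np.full(grid.deliverable.shape, np.nan) for name in config.oars}
    oar_flat = {name: np.flatnonzero(case.oars[name].data.ravel()) for name in config.oars}

    visited = np.zeros(int(np.prod(shape)), dtype=bool)
    n_total = grid.n_deliverable()
    done = 0
    for ic, ig, couch, gantry in grid.cells():
        orientation = BeamOrientation(gantry, couch)
        _, traces = _trace_bundle(orientation, case.itv, config.ray_pitch_mm)
        visited[:] = False
        acc = 0.0
        for flat, lens in traces:
            acc += np.abs(diff_stack[:, flat] @ lens).sum()
            visited[flat] = True
        dwepl_vals[ic, ig] = acc / (len(traces) * n_phases)
        for name in config.oars:
            sel = oar_flat[name]
            piv_vals[name][ic, ig] = float(visited[sel].sum()) / sel.size
        done += 1
        if config.log_every and done % config.log_every == 0:
            log.info("metric maps: %d/%d orientations done", done, n_total)
    log.info("metric maps: %d/%d orientations done", done, n_total)

    maps = [MetricMap(grid, dwepl_vals, "delta_wepl_mm", "target")]
    for name in config.oars:
        maps.append(MetricMap(grid, piv_vals[name], "piv_fraction", name))
    return maps


# ---------------------------------------------------------------------------
# map export
# ---------------------------------------------------------------------------

def map_to_dict(m: MetricMap) -> dict:
    return {
        "metric": m.metric,
        "voi": m.voi,
        "gantry_deg": m.grid.gantry_deg.tolist(),
        "couch_deg": m.grid.couch_deg.tolist(),
        "deliverable": m.grid.deliverable.astype(int).tolist(),
        "values": [[None if not np.isfinite(v) else v for v in row] for row in m.values],
    }


def map_from_dict(d: dict) -> MetricMap:
    grid = AngularGrid(
        np.asarray(d["gantry_deg"]),
        np.asarray(d["couch_deg"]),
        np.asarray(d["deliverable"], dtype=bool),
    )
    values = np.asarray(
        [[np.nan if v is None else float(v) for v in row] for row in d["values"]]
    )
    return MetricMap(grid, values, d["metric"], d["voi"])


def map_to_csv(m: MetricMap, path) -> None:
    """Deliverable cells as ``gantry_deg,couch_deg,value`` rows."""
    import pandas as pd

    rows = [
        {"gantry_deg": g, "couch_deg": c, "value": m.values[ic, ig]}
        for ic, ig, c, g in m.grid.cells()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_heatmap(m: MetricMap, path, title: str | None = None) -> None:
    """Optional PNG heatmap over the gantry x couch grid (NaN cells blank)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    extent = [
        m.grid.gantry_deg[0],
        m.grid.gantry_deg[-1],
        m.grid.couch_deg[0],
        m.grid.couch_deg[-1],
    ]
    im = ax.imshow(m.values, origin="lower", aspect="auto", extent=extent, cmap="viridis")
    fig.colorbar(im, ax=ax, label=m.metric)
    ax.set_xlabel("gantry angle (deg)")
    ax.set_ylabel("couch angle (deg)")
    ax.set_title(title or f"{m.voi}: {m.metric}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
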