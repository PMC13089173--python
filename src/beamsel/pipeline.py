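"""End-to-end case driver: images -> structures -> maps -> risk -> beams.

A single JSON config describes one case.  Input images can be given as
files (NIfTI phases + masks) or as an inline phantom specification; the
remaining keys select the calibration table, the angular grid, the ray
pitch and one or more weighting/constraint scenarios.  Every stage error
aborts with the stage name and the underlying cause, and a run manifest
(config hash, package version, seed, resolved defaults) is written next
to the artifacts so a run can be reproduced from its output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

from . import __version__
from .calibration import RSPTable, default_table, hu_to_rsp
from .geometry import AngularGrid
from .metrics import (
    CaseData,
    MetricsConfig,
    compute_metric_maps,
    map_to_csv,
    map_to_dict,
    save_heatmap,
)
from .phantom import Phantom4D, PhantomSpec, generate_phantom
from .riskmap import Constraint, build_risk_map, riskmap_to_dict
from .selection import select_beams
from .volumes import itv_from_gtvs, read_mask, read_volume, write_mask, write_volume
from .volumes import average_intensity_projection

__all__ = ["run_case", "load_case_inputs", "DEFAULT_SCENARIOS"]

log = logging.getLogger(__name__)

#: example-case scenarios: identical weights, with and without the
#: spinal-cord intersection constraint, plus the worst-case benchmark
DEFAULT_SCENARIOS = {
    "scenario1": {
        "weights": {"target": 2.0, "heart": 1.5, "lungs": 1.5, "spinal_cord": 0.5},
        "constraints": {},
        "n_beams": 3,
        "min_sep_deg": 20.0,
        "mode": "best",
    },
    "scenario2": {
        "weights": {"target": 2.0, "heart": 1.5, "lungs": 1.5, "spinal_cord": 0.5},
        "constraints": {"spinal_cord": {"mode": "exclude_intersecting"}},
        "n_beams": 3,
        "min_sep_deg": 20.0,
        "mode": "best",
    },
    "scenario3": {
        "weights": {"target": 2.0, "heart": 1.5, "lungs": 1.5, "spinal_cord": 0.5},
        "constraints": {},
        "n_beams": 3,
        "min_sep_deg": 20.0,
        "mode": "worst",
    },
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with the stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorate


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@_stage("load_inputs")
def load_case_inputs(config: dict):
    """Phase HU volumes, per-phase GTVs and OAR masks, from files or a phantom spec."""
    if "phantom" in config:
        spec = PhantomSpec(**config["phantom"])
        ph = generate_phantom(spec)
        return ph.phases, ph.gtv_masks, ph.oar_masks
    phases = [read_volume(p) for p in config["phases"]]
    gtvs = [read_mask(p, role="GTV") for p in config["gtv_masks"]]
    if len(phases) != len(gtvs):
        raise ValueError(f"{len(phases)} phases but {len(gtvs)} GTV masks")
    oars = {name: read_mask(path, role=name) for name, path in config.get("oar_masks", {}).items()}
    return phases, gtvs, oars


def run_case(config: dict, out_dir) -> dict:
    """Run every stage for one case; returns a summary dict (also written to disk)."""
    os.makedirs(out_dir, exist_ok=True)

    phases, gtvs, oars = load_case_inputs(config)
    scenarios = config.get("scenarios", DEFAULT_SCENARIOS)
    for scen_name, scen in scenarios.items():
        for voi in scen.get("constraints", {}):
            if voi not in oars:
                raise StageError(
                    f"stage 'configure' failed: scenario {scen_name!r} constrains OAR "
                    f"{voi!r} but the case defines no such mask"
                )

    @_stage("structures")
    def _structures():
        ctvs, itv = itv_from_gtvs(gtvs, float(config.get("ctv_margin_mm", 5.0)))
        return ctvs, itv

    ctvs, itv = _structures()

    @_stage("calibration")
    def _calibrate():
        table = (
            RSPTable.from_csv(config["calibration_csv"])
            if config.get("calibration_csv")
            else default_table()
        )
        aip = average_intensity_projection(phases)
        return hu_to_rsp(aip, table), [hu_to_rsp(p, table) for p in phases], aip

    aip_rsp, phase_rsps, aip = _calibrate()

    @_stage("grid")
    def _grid():
        g = config.get("grid", {})
        grid = AngularGrid.default(
            gantry_step_deg=float(g.get("gantry_step_deg", 10.0)),
            couch_step_deg=float(g.get("couch_step_deg", 15.0)),
            remove_duplicate_directions=bool(g.get("remove_duplicate_directions", True)),
        )
        if g.get("deliverability_csv"):
            grid.apply_deliverability_csv(g["deliverability_csv"])
        return grid

    grid = _grid()

    @_stage("metric_maps")
    def _maps():
        cfg = MetricsConfig(
            ray_pitch_mm=float(config.get("ray_pitch_mm", 2.0)),
            oars=tuple(config.get("oars", sorted(oars))),
        )
        case = CaseData(aip_rsp, phase_rsps, itv, oars)
        return compute_metric_maps(case, grid, cfg)

    maps = _maps()

    @_stage("write_volumes")
    def _write():
        write_volume(aip, os.path.join(out_dir, "aip.nii.gz"))
        write_mask(itv, os.path.join(out_dir, "itv.nii.gz"))
        for k, ctv in enumerate(ctvs):
            write_mask(ctv, os.path.join(out_dir, f"ctv_phase_{k:02d}.nii.gz"))
        if config.get("write_rsp", False):
            write_volume(aip_rsp, os.path.join(out_dir, "rsp_aip.nii.gz"))
        for m in maps:
            stem = f"map_{m.voi}_{m.metric}"
            map_to_csv(m, os.path.join(out_dir, stem + ".csv"))
            with open(os.path.join(out_dir, stem + ".json"), "w") as fh:
                json.dump(map_to_dict(m), fh)
            if config.get("write_heatmaps", False):
                save_heatmap(m, os.path.join(out_dir, stem + ".png"))

    _write()

    summary = {"scenarios": {}}
    for scen_name, scen in scenarios.items():
        @_stage(f"scenario:{scen_name}")
        def _scenario(scen=scen, scen_name=scen_name):
            constraints = {
                voi: Constraint(**c) if not isinstance(c, Constraint) else c
                for voi, c in scen.get("constraints", {}).items()
            }
            risk = build_risk_map(maps, scen["weights"], constraints)
            beams = select_beams(
                risk,
                int(scen.get("n_beams", 3)),
                float(scen.get("min_sep_deg", 20.0)),
                scen.get("mode", "best"),
            )
            scen_dir = os.path.join(out_dir, scen_name)
            os.makedirs(scen_dir, exist_ok=True)
            with open(os.path.join(scen_dir, "riskmap.json"), "w") as fh:
                json.dump(riskmap_to_dict(risk), fh)
            beams_out = [
                {"gantry_deg": b.gantry_deg, "couch_deg": b.couch_deg, "score": b.score}
                for b in beams
            ]
            with open(os.path.join(scen_dir, "selected_beams.json"), "w") as fh:
                json.dump(beams_out, fh, indent=2)
            return beams_out

        summary["scenarios"][scen_name] = _scenario()

    manifest = {
        "package": "beamsel",
        "version": __version__,
        "config": config,
        "config_sha256": _config_hash(config),
        "seed": config.get("phantom", {}).get("seed") if "phantom" in config else config.get("seed"),
        "defaults": {
            "ctv_margin_mm": float(config.get("ctv_margin_mm", 5.0)),
            "ray_pitch_mm": float(config.get("ray_pitch_mm", 2.0)),
            "grid": {
                "gantry_step_deg": float(config.get("grid", {}).get("gantry_step_deg", 10.0)),
                "couch_step_deg": float(config.get("grid", {}).get("couch_step_deg", 15.0)),
            },
        },
        "n_orientations": grid.n_deliverable(),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    summary["manifest"] = manifest
    log.info("case complete: %d orientations, %d scenarios", grid.n_deliverable(), len(scenarios))
    return summary
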