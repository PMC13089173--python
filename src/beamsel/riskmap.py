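"""Z-score normalization, weighting, hard constraints and the unified risk map.

Each metric map (target dWEPL, per-OAR PIV) is normalized to Z-scores over
the deliverable cells so maps with different units become comparable
relative-risk maps.  Per-structure weights and optional hard constraints
(exclude any beam intersecting an OAR, or any beam whose PIV exceeds a
threshold) are then applied, and the weighted maps are summed into a single
unified risk map.  Lower score = lower relative risk = better.

Z-score statistics are computed over all deliverable cells *before*
constraint exclusion, so adding a constraint changes which cells are
admissible but not the normalization — per-structure maps stay comparable
across constraint scenarios.  Population (not sample) standard deviation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import AngularGrid
from .metrics import MetricMap

__all__ = [
    "Constraint",
    "ConstraintConfig",
    "RiskMap",
    "zscore",
    "apply_constraints",
    "unify",
    "build_risk_map",
    "SCENARIO_WEIGHTS",
]

#: the three-beam example weighting: tumour 2, heart/lungs 1.5, cord 0.5
SCENARIO_WEIGHTS = {"target": 2.0, "heart": 1.5, "lungs": 1.5, "spinal_cord": 0.5}

CONSTRAINT_MODES = ("none", "exclude_intersecting", "piv_threshold")


@dataclass(frozen=True)
class Constraint:
    mode: str = "none"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in CONSTRAINT_MODES:
            raise ValueError(f"unknown constraint mode {self.mode!r}; one of {CONSTRAINT_MODES}")
        if self.mode == "piv_threshold" and not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"PIV threshold must be in [0, 1], got {self.threshold}")


#: mapping OAR name -> Constraint
ConstraintConfig = dict


def _validate_weights(weights) -> dict:
    w = {str(k): float(v) for k, v in dict(weights).items()}
    if any(v < 0 for v in w.values()):
        raise ValueError(f"weights must be >= 0, got {w}")
    if not any(v > 0 for v in w.values()):
        raise ValueError("at least one weight must be positive")
    return w


@dataclass
class RiskMap:
    """Unified (weighted, constrained) risk scores over the angular grid.

    ``scores`` is NaN on non-deliverable and excluded cells; ``excluded``
    marks constraint-excluded cells and ``reasons`` carries the names of
    the OARs whose constraint fired, per cell.
    """

    grid: AngularGrid
    scores: np.ndarray
    excluded: np.ndarray
    reasons: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        shape = self.grid.deliverable.shape
        if self.scores.shape != shape or self.excluded.shape != shape:
            raise ValueError("scores/excluded shape does not match the angular grid")
        if self.reasons is None:
            self.reasons = np.full(shape, "", dtype=object)
        admissible = self.grid.deliverable & ~self.excluded
        if not np.all(np.isfinite(self.scores[admissible])):
            raise ValueError("risk scores must be finite on admissible cells")
        if np.any(self.excluded & (np.asarray(self.reasons) == "")):
            raise ValueError("every excluded cell must carry a reason")

    def admissible(self) -> np.ndarray:
        return self.grid.deliverable & ~self.excluded


def zscore(m: MetricMap) -> MetricMap:
    """Z-score normalize a metric map over its deliverable cells.

    Uses the population standard deviation.  A constant map carries no
    preference between beams: it becomes all-zero with a warning.
    """
    vals = m.deliverable_values()
    if vals.size < 2:
        raise ValueError("Z-score normalization needs >= 2 deliverable cells")
    mean = vals.mean()
    sd = vals.std()  # population sd
    out = np.full(m.values.shape, np.nan)
    if sd < 1e-15:
        warnings.warn(
            f"metric map ({m.voi}, {m.metric}) is constant over deliverable cells; "
            "its Z-scores are all zero and it expresses no beam preference",
            stacklevel=2,
        )
        out[m.grid.deliverable] = 0.0
    else:
        out[m.grid.deliverable] = (vals - mean) / sd
    metric = m.metric if m.metric.endswith("_z") else m.metric + "_z"
    return MetricMap(m.grid, out, metric, m.voi)


def _find_piv_map(maps, voi: str) -> MetricMap:
    for m in maps:
        if m.voi == voi and m.metric.startswith("piv_fraction"):
            return m
    raise ValueError(f"constraint names OAR {voi!r} but no PIV map for it was supplied")


def apply_constraints(maps, constraints: ConstraintConfig):
    """Evaluate hard constraints on the *raw* PIV maps.

    Returns ``(excluded, reasons)``: a boolean mask over the grid and an
    object array of comma-joined OAR names per excluded cell.  A cell is
    excluded iff a constrained OAR's PIV is > 0 (``exclude_intersecting``)
    or strictly above the threshold (``piv_threshold``).
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no metric maps supplied")
    grid = maps[0].grid
    excluded = np.zeros(grid.deliverable.shape, dtype=bool)
    reasons = np.full(grid.deliverable.shape, "", dtype=object)
    for voi, con in dict(constraints).items():
        if not isinstance(con, Constraint):
            con = Constraint(**con)
        if con.mode == "none":
            continue
        piv_map = _find_piv_map(maps, voi)
        threshold = 0.0 if con.mode == "exclude_intersecting" else con.threshold
        with np.errstate(invalid="ignore"):
            hit = grid.deliverable & (piv_map.values > threshold)
        for ic, ig in zip(*np.nonzero(hit)):
            reasons[ic, ig] = f"{reasons[ic, ig]},{voi}" if reasons[ic, ig] else voi
        excluded |= hit
    return excluded, reasons


def unify(maps, weights, excluded=None, reasons=None) -> RiskMap:
    """Weighted sum of Z-scored maps into the unified risk map.

    ``maps`` must already be Z-scored and share one grid; every supplied
    map's VOI must have a weight.  Excluded cells receive no score.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no metric maps supplied")
    w = _validate_weights(weights)
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid is not grid and not (
            np.array_equal(m.grid.gantry_deg, grid.gantry_deg)
            and np.array_equal(m.grid.couch_deg, grid.couch_deg)
            and np.array_equal(m.grid.deliverable, grid.deliverable)
        ):
            raise ValueError("metric maps live on different angular grids")
    if excluded is None:
        excluded = np.zeros(grid.deliverable.shape, dtype=bool)

    scores = np.zeros(grid.deliverable.shape)
    for m in maps:
        if m.voi not in w:
            raise ValueError(f"no weight supplied for map VOI {m.voi!r}")
        with np.errstate(invalid="ignore"):
            scores = scores + w[m.voi] * np.where(grid.deliverable, m.values, 0.0)
    scores[~grid.deliverable | excluded] = np.nan
    return RiskMap(grid, scores, np.asarray(excluded, dtype=bool), reasons)


def build_risk_map(metric_maps, weights, constraints: ConstraintConfig | None = None) -> RiskMap:
    """Normalize raw metric maps, apply constraints and sum: the full chain."""
    metric_maps = list(metric_maps)
    excluded, reasons = apply_constraints(metric_maps, constraints or {})
    zmaps = [zscore(m) for m in metric_maps]
    return unify(zmaps, weights, excluded, reasons)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def riskmap_to_dict(r: RiskMap) -> dict:
    return {
        "gantry_deg": r.grid.gantry_deg.tolist(),
        "couch_deg": r.grid.couch_deg.tolist(),
        "deliverable": r.grid.deliverable.astype(int).tolist(),
        "scores": [[None if not np.isfinite(v) else v for v in row] for row in r.scores],
        "excluded": r.excluded.astype(int).tolist(),
        "reasons": [[str(v) for v in row] for row in r.reasons],
    }


def riskmap_from_dict(d: dict) -> RiskMap:
    grid = AngularGrid(
        np.asarray(d["gantry_deg"]),
        np.asarray(d["couch_deg"]),
        np.asarray(d["deliverable"], dtype=bool),
    )
    scores = np.asarray([[np.nan if v is None else float(v) for v in row] for row in d["scores"]])
    excluded = np.asarray(d["excluded"], dtype=bool)
    reasons = np.asarray(d["reasons"], dtype=object)
    return RiskMap(grid, scores, excluded, reasons)


def save_riskmap(r: RiskMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(riskmap_to_dict(r), fh)


def load_riskmap(path) -> RiskMap:
    with open(path) as fh:
        return riskmap_from_dict(json.load(fh))
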