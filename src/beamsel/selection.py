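"""Beam-set selection from a unified risk map.

A greedy scan of the admissible cells sorted by score — ascending for the
best (lowest-risk) set, descending for the worst-case benchmark set — that
accepts a candidate only if its central angle to every already-selected
beam is at least the minimum separation.  Ties in score are broken by
(couch, gantry) lexicographic order so the output is deterministic.
"""

from __future__ import annotations

import numpy as np

from .geometry import BeamOrientation, central_angle
from .riskmap import RiskMap

__all__ = ["SelectedBeam", "select_beams"]


class SelectedBeam(BeamOrientation):
    """A selected beam orientation carrying its unified risk score."""

    def __init__(self, gantry_deg: float, couch_deg: float, score: float) -> None:
        super().__init__(gantry_deg, couch_deg)
        self.score = float(score)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SelectedBeam(gantry={self.gantry_deg:g}, couch={self.couch_deg:g}, "
            f"score={self.score:.4f})"
        )


def select_beams(
    risk: RiskMap,
    n_beams: int,
    min_sep_deg: float = 20.0,
    mode: str = "best",
) -> list:
    """Select ``n_beams`` mutually separated beams from a unified risk map.

    Parameters
    ----------
    risk
        Unified risk map; only admissible (deliverable, non-excluded) cells
        are candidates.
    n_beams
        Number of beams to return.
    min_sep_deg
        Minimum pairwise central angle between selected beams, degrees.
    mode
        ``"best"`` picks lowest scores, ``"worst"`` highest (the
        benchmark configuration maximising the risk score).

    Raises
    ------
    ValueError
        If fewer than ``n_beams`` mutually separated admissible beams
        exist (the message says how many were found).
    """
    if n_beams < 1:
        raise ValueError("n_beams must be >= 1")
    if mode not in ("best", "worst"):
        raise ValueError(f"mode must be 'best' or 'worst', got {mode!r}")
    admissible = risk.admissible()
    n_adm = int(admissible.sum())
    if n_adm == 0:
        raise ValueError("no admissible beam orientations remain after constraints")
    if n_adm < n_beams:
        raise ValueError(
            f"only {n_adm} admissible beam orientations exist, cannot select {n_beams}"
        )

    candidates = []
    for ic, ig in zip(*np.nonzero(admissible)):
        score = risk.scores[ic, ig]
        candidates.append(
            (score, float(risk.grid.couch_deg[ic]), float(risk.grid.gantry_deg[ig]))
        )
    sign = 1.0 if mode == "best" else -1.0
    candidates.sort(key=lambda t: (sign * t[0], t[1], t[2]))

    selected: list = []
    for score, couch, gantry in candidates:
        beam = SelectedBeam(gantry, couch, score)
        if all(central_angle(beam, prev) >= min_sep_deg - 1e-9 for prev in selected):
            selected.append(beam)
            if len(selected) == n_beams:
                return selected
    raise ValueError(
        f"only {len(selected)} beams with pairwise separation >= {min_sep_deg} deg "
        f"were found among {n_adm} admissible orientations; {n_beams} requested"
    )
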