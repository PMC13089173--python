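# Methods

`beamsel` implements a geometry-based pre-selection of proton beam angles
for moving thoracic targets. It deliberately contains no dose model: the
two metrics it computes are surrogates that rank beam orientations by (a)
how sensitive the radiological path to the target is to respiratory
motion and (b) how much of each organ at risk the beam passes through.
The intended use is to narrow the gantry-couch search space before robust
multi-field optimisation in a treatment planning system.

## Geometry and conventions

All geometry lives in a fixed patient frame: x = patient-left,
y = patient-posterior, z = patient-superior, with voxel centers at
`origin + index * spacing` (mm). Only axis-aligned volumes are accepted;
oblique acquisitions are rejected rather than silently resampled, so
every downstream number is defined on the native grid.

A beam orientation is a (gantry, couch) pair. Gantry 0° is an anterior
beam travelling posteriorly, increasing toward patient-left; the couch
rotates about the room-vertical axis for a supine patient. The unit beam
direction (source → isocenter) is

    d(g, c) = (−sin g · cos c,  cos g,  sin g · sin c).

Beams are parallel (source at infinity); divergence and lateral
scattering are out of scope by design. The search grid is gantry
0°–350° in 10° steps × couch −90°–90° in 15° steps (468 cells). Gantry 0°
and 180° describe vertical beams that are invariant under couch rotation,
so the 24 couch ≠ 0 repetitions of those two directions are removed by
default, leaving 444 unique-direction orientations. Machine-specific
collision limits can be expressed as a user-supplied deliverability CSV;
no general exclusion rule is built in because none can be derived from
geometry alone.

## Target and composite structures

Per-phase clinical target volumes are built from the gross tumour volume
by a 5 mm isotropic expansion, done in 3D on physical voxel-center
distances (a voxel joins the CTV exactly when its center is within the
margin of some GTV voxel center; `scipy.ndimage.distance_transform_edt`
with the voxel spacing as sampling makes this exact, and tests verify it
against brute-force distance enumeration). The internal target volume
(ITV) is the union of the per-phase CTVs; organs at risk use the
composite all-phase contour. The expansion is assumed 3D isotropic; a
per-slice 2D expansion is a clinical alternative we did not implement.

## HU → RSP calibration

CT numbers are converted to relative proton stopping power through a
piecewise-linear lookup table (nodes at air −1000 HU → 0.001, lung −750 →
0.25, adipose −120 → 0.93, water 0 → 1.000, soft tissue 50 → 1.05,
300 → 1.15, 1000 → 1.55, 3000 → 2.40; clamped outside). This is a
representative surrogate for a stoichiometric calibration — the ranking
behaviour of the framework depends only on having a monotone map anchored
at water, and a site-specific curve can be supplied as a `hu,rsp` CSV.

## Ray tracing and WEPL

Voxel traversal is Siddon-style: the parametric crossings of a ray with
the three families of boundary planes are merged and sorted; each
inter-crossing interval lies in exactly one voxel, identified by its
midpoint with half-open `[lower, upper)` voxel intervals per axis (the
deterministic tie-break for grazing rays). Chord lengths telescope to the
geometric in-grid path length to ~1e−12 mm, and WEPL is the chord-length
weighted sum of voxel RSP. Integration starts at the volume boundary, not
the skin: with air at RSP ≈ 0.001 the difference is negligible and the
rule is unambiguous.

For each orientation a bundle of parallel rays is seeded on a uniform
2 mm grid (the spot-grid scale; configurable) in the beam's-eye-view
plane, covering the ITV projection plus one pitch of margin. A ray
survives only if it actually traverses at least one target voxel (a
distance prefilter at half the voxel diagonal plus half a pitch merely
speeds this up), so the bundle thins to exactly the rays that can reach
the target and halving the pitch quadruples the ray count; each
surviving ray stops at the distal (last) exit of its axis from the ITV. Stop points are computed once on the AIP-frame ITV and
reused for every phase, so the motion metric compares identical geometric
paths; stopping per-phase at each phase's own distal edge would be the
main alternative reading and would mix geometric and anatomical changes.

## Metrics

* **ΔWEPL** (mm) — mean absolute difference between the AIP-CT WEPL and
  each phase WEPL, averaged over all rays and phases. Implemented on
  per-phase RSP *difference* volumes so that a phase identical to the AIP
  contributes exactly zero (this avoids summation-order noise at the
  1e−14 level and makes the motionless null exact).
* **PIV** (fraction) — the fraction of an OAR's voxels traversed by at
  least one ray of the bundle, rays truncated at their stop points, so
  tissue distal to the target's distal edge is never counted. Accuracy is
  limited by the finite ray pitch relative to a continuous aperture; at
  the default 2 mm pitch on a 2 mm grid every beam-path voxel column is
  visited.

Both metrics are computed per deliverable orientation from a single
traversal of each ray (shared between the phase WEPL integrals and the
OAR voxel marking), which is what keeps a full 444-orientation map of a
96³ case in the ten-second range on one CPU.

## Risk maps, constraints, selection

Each metric map is Z-score normalized over the deliverable cells
(population SD; a constant map becomes all-zero with a warning, since it
expresses no preference). Normalization is computed *before* constraint
exclusion, so adding a constraint changes admissibility but not the
scale of any map — per-structure maps stay comparable across scenarios.
Per-structure weights (the shipped example scenario uses tumour 2,
heart/lungs 1.5, spinal cord 0.5) multiply the Z-maps, which are summed
into the unified risk map; lower score = lower relative risk. Hard
constraints exclude any cell whose PIV for a constrained OAR is > 0
(`exclude_intersecting`) or strictly above a threshold (`piv_threshold`),
recording the OAR name as the reason.

Beam sets are chosen greedily: admissible cells sorted by score
(ascending; descending for the worst-case benchmark), accepting a
candidate only if its central angle — arccos of the dot product of unit
directions — to every accepted beam is ≥ the minimum separation (default
20°). Ties break by (couch, gantry) lexicographic order, so selection is
deterministic. Greedy rather than exhaustive subset search is the minimal
faithful reading of "pick the lowest-risk separated beams"; it does not
guarantee the globally optimal separated subset.

## The synthetic phantom

The phantom paints, into a −1000 HU air background and in priority order
(body < lungs < heart/cord < tumour), a soft-tissue body ellipsoid
(+40 HU), two −750 HU lung ellipsoids, an anteriorly placed +30 HU heart,
a +40 HU spinal cord cylinder running posteriorly along z, and a +30 HU
tumour sphere (default radius 10 mm) in the left lung. The default grid
is 96³ at 2 mm isotropic — large enough for ~190 mm of thorax, small
enough that a full angular map takes seconds. HU defaults are
representative thorax values spanning the calibration curve, and the
anterior heart / posterior cord layout reproduces the clinically familiar
contrast between anterior and posterior beams.

Motion is a rigid sinusoidal translation of the tumour alone:
phase k of n is displaced by `axis · (A/2)(1 − cos 2πk/n)`, sweeping from
0 to the full peak-to-peak amplitude A (default 10 mm along z, a typical
lung-tumour excursion). OARs are static, so their masks equal the
composite contours exactly. Optional i.i.d. Gaussian HU noise is seeded;
the default is 0 so the null case (no motion, no noise) is bit-exact.

What the phantom does **not** emulate: deformable anatomy and hysteresis,
tumour rotation or deformation, realistic CT texture and artefacts,
density changes of lung tissue over the cycle, and inter-fraction
anatomical change. Tests passing on the phantom therefore demonstrate the
correctness of the geometry, integration, normalization and selection
machinery — not clinical performance on patient 4DCTs, where metric-dose
correlation must be established against treatment-planning dose.

## Numerical choices and edge cases

* Traversal tolerances: crossing parameters are deduplicated only through
  zero-length-segment removal; chord sums are exact to ~1e−12 mm.
* Rays are validated to carry unit directions to 1e−9; beam directions
  are unit to 1e−12 by construction.
* A margin expansion reaching past the grid clips at the boundary and
  warns rather than failing.
* A DICOM series with an uneven slice gap raises an error naming the gap;
  NIfTI images with non-diagonal affines are rejected.
* Z-scoring a map with zero spread warns and returns zeros; selection on
  an all-excluded map raises instead of returning an empty set.
* All randomness (phantom noise) flows through one seeded
  `numpy.random.Generator`; identical configs reproduce bit-identical
  artifacts.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run the default conditions
end to end: the 96³ @ 2 mm phantom, all 444 unique-direction
orientations, 2 mm ray pitch, and motion amplitudes {0, 5, 10, 15} mm.
The traversal oracle draws 1000 random face-to-face rays through random
32³ RSP volumes and compares against 0.01 mm midpoint-rule sampling.
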