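# Methods

## Model overview

`phyllidsim` simulates the planar morphogenesis of a moss phyllid as a
growing 2D tissue.  The state has two coupled layers:

1. **Cell layer** — simple polygons tiling the organ over shared vertices.
   Cells carry identity (merophyte/clonal sector, tissue type: apical,
   blade, midrib, attachment), a developmental zone (attachment,
   proliferative, differentiation), a unit polarity vector and specified
   growth rates K_par/K_per (per day, parallel/perpendicular to polarity).
2. **Element layer** — each cell is refined into 3-node triangular membrane
   finite elements that never cross cell walls.  Star-shaped polygons get a
   centroid fan (which keeps triangle aspect ratios reasonable even when a
   wall carries many collinear points inherited from neighbour divisions);
   other polygons are ear-clipped.

The coordinate convention is y = longitudinal organ axis (base at y = 0,
apex toward +y), x = mediolateral; lengths are in µm and times in days.

## Growth and mechanics

Elements follow a St. Venant–Kirchhoff isotropic membrane under plane
stress with unit thickness: with F the deformation gradient from the
element's rest shape to its current shape and E = (FᵀF − I)/2 the Green
strain, the energy density is (λ/2) tr(E)² + μ tr(E²) per unit rest area,
with λ = Eν/(1−ν²), μ = E/(2(1+ν)), E = 100 MPa, ν = 0.3.  Single-element
uniaxial extension recovers exactly this E and ν (the package's material
test), which pins the plane-stress conversion.

Specified growth acts on rest configurations: each step of length dt maps
every element's rest shape about its centroid by
G = R diag(e^{K_par·dt}, e^{K_per·dt}) Rᵀ, R rotating the owning cell's
polarity onto the first axis.  Exponential-in-dt growth makes the rates
step-size independent (two half steps ≈ one full step, verified to 1%).
After growth, elastic equilibrium is found by L-BFGS minimization of the
total energy with analytic forces (verified against central finite
differences at 1e-6), subject to Dirichlet conditions: base vertices are
fixed longitudinally (free to slide mediolaterally) and one anchor vertex
is fully fixed to remove rigid-body modes.  Residual stresses are then
released (rest := current), so the tissue re-enters each step stress-free;
this also makes retriangulation after division force-neutral.

Numerical choices: the shipped solver tolerance is 0.1 (max residual force
component, MPa·µm) — about 10⁻³ of the typical per-step force scale, which
leaves organ shape unchanged against much tighter settings while keeping
runs fast.  Near-degenerate sliver triangles (unavoidable when walls
accumulate collinear points) can invert numerically during the solve; below
det F = 0.2 the energy is extended with a convex quadratic penalty on the
area ratio that pushes such elements back, and any element still inverted
at convergence is flagged with a warning.  The penalty is identically zero
for healthy configurations, so it does not affect the material tests or
force-consistency checks.

## Positional information and developmental rules

Two distance fields on the cell-adjacency graph drive the rules:

* **cell-count distance** from the attachment base (unit edge weights)
  defines zonation: cells within `d_prolif` cells of the base are
  proliferative; beyond it they differentiate (absorbing, with the entry
  time recorded).  In phase 3 every non-attachment cell differentiates.
* **Euclidean distance from the apical cell** (centroid-to-centroid edge
  weights — the package's dialect of Euclidean wall weights) yields
  polarity: per cell, a least-squares linear fit of neighbour distances at
  their centroids, negated and normalized, so polarity points base→apex.
  Degenerate neighbourhoods fall back to the global organ axis.

Three phases schedule behaviour: initiation (to 1.5 d), expansion (to
4.0 d), maturation (beyond).  Blade rates are near-isotropic and slow in
phase 1 and anisotropic in phase 2, attenuated basipetally — rates fall
linearly with cell-count distance from the base to a floor fraction — which
is what concentrates growth in the proximal sectors.  The midrib is
specified once at 2.0 d (blade cells within a mediolateral offset of the
midline and a base distance limit), is inherited by daughters, and has its
mediolateral rate multiplied by 0.25.  Differentiating cells boost K_par by
1.45× for 0.7 d, after which both rates decay with a 0.4 d timescale.

Cell division: proliferative, non-attachment cells divide on reaching a
threshold area (320 µm²), along the shorter of the two chords through the
centroid oriented parallel vs perpendicular to polarity (ties break to
perpendicular).  Chord endpoints landing within 2% of an edge's length from
an existing vertex are snapped onto it to avoid sliver walls; new wall
vertices are inserted into neighbouring rings so the tiling stays
conforming, and all cells whose rings changed are retriangulated
(stress-free, hence force-neutral).  At most one division per cell per
step.  The apical cell instead divides on a fixed schedule (every 0.35 d
from day 1) at 60° to its polarity axis, alternating sides (first division
to the left), with the wall positioned by bisection so the proximal
daughter — the next merophyte — takes 30% of the parent's area.  Apical
divisions stop at the phase-2→3 transition, which makes merophyte number an
emergent consequence of timing: the wild-type schedule yields 8 divisions
(10 merophytes including the two attachment sectors), the basal scenario's
earlier cessation yields 6 (8 merophytes).

Step order: phase update; distance and polarity fields; zones; midrib (when
due); growth rates; growth of rest shapes; equilibrium; stress release;
apical division; threshold divisions (ascending cell id); retriangulation.
Runs are fully deterministic: identical configurations give bit-identical
trajectories.

## Scenarios and calibration

All parameters live in YAML files shipped with the package
(`phyllidsim/params/*.yaml`); the schema is the contract and the shipped
numbers are the package's calibrated defaults.  Calibration targeted the
wild-type merophyte count (10) and proximal-sector dominance (merophytes
3+4 ≈ 80% of final area), the basal count (8) with the basal file differing
from wild type *only* in the phase-2→3 time (3.2 d vs 4.0 d), the mutant
division reductions, and the aspect-ratio ordering across scenarios:

* `wt_upper` — the reference parameter set.
* `pina_pinb` — smaller proliferative zone (2 vs 4 cells), earlier division
  cessation (3.4 d) and faster elongation (K_par 1.05 vs 0.90/d): the
  narrower mutant organ with roughly −49% longitudinal and −42%
  mediolateral divisions relative to wild type.
* `auxin_wt` — accelerated phase 2→3 (3.0 d) plus increased elongation and
  reduced mediolateral growth.
* `auxin_pina_pinb` — divisions eliminated after phase 1 and strongly
  increased growth anisotropy: the rod-like extreme.
* `basal` — earlier division cessation only.

The organ's aspect ratio is measured from the principal axes of the
area-weighted cell-centroid distribution (robust to the slight lean the
alternating apical divisions impart); the ordering wild type < *pina pinb*
< auxin-treated wild type < auxin-treated mutant holds on the shipped
defaults.

## Synthetic inputs

The day-1 template is generated, not measured: two rows of attachment cells
(5 columns, 80 µm wide, 6 µm tall; clonal sectors 1 and 2) under a single
apical cell tapering to the apex at 60 µm.  Optional vertex jitter (seeded,
with automatic retry at reduced amplitude if a ring self-intersects) makes
template families for property sweeps; the calibrated runs use the
jitter-free representative template.  Making the attachment rows the first
two merophytes reflects that the earliest apical derivatives form the stem
attachment, and it is what lets sectors 3 and 4 — the basal-most blade
sectors — dominate the final area.

Lineage fixtures for the quantification pipeline deform a conforming grid
tissue by a known global map (x′ = x·e^{K_per·dt}, y′ = ψ(y) with
ψ′ = e^{K_par(y)·dt} and K_par linear in initial height), so each cell's
ground-truth rates are known exactly; scheduled divisions and seeded
junction noise emulate segmentation artefacts.  These fixtures emulate the
*geometry* of segmented time-lapse data — they contain no imaging noise
model beyond junction jitter, no segmentation errors, and no 3D-to-2D
projection distortion — so passing recovery tests demonstrates correctness
of the quantification math, not robustness to real microscopy artefacts.

## Quantification

Per consecutive snapshot pair and parent cell: area expansion
((Σ daughter areas / parent area) − 1)·100 — the printed formula's
"relative area increase" reading; divisions = daughters − 1; new-wall
orientation classified against the local polarity axis with a 45° threshold
(≥45° mediolateral), replacing manual scoring; growth tensors from the ring
vertices that persist across the interval (least-squares affine fit, polar
decomposition F = RU, rates ln λ / Δt, anisotropy (λ₁−λ₂)/(λ₁+λ₂) ∈ [0,1));
distances from the base with Euclidean wall weights normalized by the
per-time-point maximum; ten equal bins with per-bin median and
interquartile range (any spline smoothing is presentation-only — all
statistics use raw bin medians).

## Problem sizes and runtime

The shipped runs use dt = 0.05 d from day 1 to day 5.5 (90 steps).  The
wild-type organ ends with 124 cells (≈ 10³ vertices, 2.5·10³ elements) —
a deliberately desk-scale organ, roughly one-seventh the cell count of a
real upper phyllid, chosen so a full scenario runs in about a minute on one
CPU; the developmental rules are resolution-independent (threshold area and
template size set the cell count).  The full test suite, including five
scenario simulations, runs in under two minutes.

## Known limitations

* Strictly 2D: no curvature, folding, or the midrib's multilayered
  anatomy — the midrib is a growth-rate identity only.
* Auxin is not modelled explicitly; scenarios encode its hypothesized
  *effects* (earlier differentiation, faster elongation) as parameter
  changes, so the model cannot distinguish transport mechanisms.
* Mechanical equilibrium is quasi-static with residual-stress release each
  step; no viscoelasticity or stress-feedback on growth.
* Hanging nodes created by a neighbour's division are resolved by
  retriangulating affected cells at the end of the same step; between
  sub-steps the FEM mesh of an unchanged neighbour may briefly not conform
  to the new wall vertex (consequences are bounded by one step's growth).
* The attachment zone never divides, and the apical cell's division
  schedule is time-based rather than size-based.
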