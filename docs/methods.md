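# Methods

## Coordinate frame and experiment geometry

All computations use a fixed right-handed frame: origin at the isocenter,
**+y** along the magnetic field (couch → bore), **+z** vertically up, **x**
completing the frame. The gantry rotates about **y**; at gantry angle *g* the
beam direction is (sin *g*, 0, −cos *g*) and the source sits at
−SAD·direction with SAD = 105 cm. The phantom (15 × 15 × 10 cm acrylic,
density 1.18 g/cm³, center of mass at the isocenter) tilts about **x** so
its entrance-surface normal is (0, sin θ, cos θ) for phantom angle θ. The
*front* panel plane is y = +d, the *end* panel y = −d (d = 10 or 17 cm);
panels are 30 × 30 cm with 1.36 mm pixels. Entrance and exit surface planes
pass through ±(h/2)·n̂ with h = 10 cm.

### Field-square convention (calibrated)

The four corner rays run from the source through the corners of the square
field at the isocenter. Two conventions are implemented for where that
square is drawn:

* `"transverse"` (default): on the fixed horizontal plane z = 0, with edges
  along x and y;
* `"bev"`: on the plane through the isocenter perpendicular to the central
  axis (the standard collimation convention).

They coincide at gantry 0 and differ by a cos *g* foreshortening at oblique
gantry. The published projected-area table and rank correlations select the
transverse convention decisively: under it the published area extremes are
reproduced (6.24 vs 6.2 cm² and 104.0 vs 109.4 cm², with the published
argmin/argmax geometries and exact 30°/330° mirror symmetry), and **all 16
published Spearman coefficients are reproduced to every printed decimal**
(minimum 0.757, maximum 0.938). The BEV convention reproduces only the
end-panel correlation rows and misses the largest area by 10%. The published
computation is not described in enough detail to decide a priori; the
package therefore documents the transverse convention as its default and
keeps BEV available.

### Clipping

Footprints are **not** clipped to the 15 × 15 cm phantom face by default:
at the exit side the beam cross-section lives on the larger support surface
beneath the phantom, and clipping both breaks the published gantry ordering
(the largest area would move to gantry 0) and misses the published maximum
by 34%. `clip_to_phantom=True` (a Sutherland–Hodgman-style intersection with
the face rectangle, via shapely) is retained as a sensitivity option; the
acceptance tests report the clip/no-clip difference at the extreme geometry.

### Projected area

The projection along **y** of a planar polygon is computed two ways — the
shoelace formula on the (x, z) vertex projections, and planar 3D area times
|n̂·ŷ| — and the routes must agree to 1e-9 relative (internal oracle; an
independent dense-ray convex-hull oracle was used during development). A
plane normal exactly orthogonal to **y** returns exactly 0.

## Dose maps and metrics

A `DoseMap` is a non-negative 2D cGy grid with isotropic pixel pitch (mm)
and a physical origin. Text-grid I/O (three header lines + rows) round-trips
bit-exactly; grayscale image import needs a JSON sidecar with `dpi` (or
`pixel_size_mm`) and `cgy_per_level`. Rebinning is block averaging (integer
factor from the pitch ratio); it preserves the covered-region mean to 1e-6
relative and cannot upsample.

* **Maximum point**: global argmax, row-major first on ties (deterministic).
* **D_Rx**: unweighted mean of pixels whose *centres* lie within x cm of the
  maximum pixel's centre. Partial-pixel weighting is deliberately not used
  (the simplest defensible rule; the analysis circles are ≥ 50 pixels
  across, so the boundary layer is a small perturbation). Circles truncated
  by the map edge use in-map pixels only.
* **A_y%**: count of pixels at or above y% of the prescription times the
  pixel area. For the simply-connected single-spot maps this equals the
  area enclosed by the isodose contour; no contour tracing is attempted.
  Zero is a valid area (printed as "-" in the reference tables).

## Gamma analysis

Global 2D gamma: for every reference point above the low-dose threshold
(default 10% of the normalisation dose, strictly-greater evaluated),

γ² = min over search disc of ( |Δr|²/DTA² + ΔD²/(tol·D_norm)² ),

with DTA = 3 mm, tol = 3%, and D_norm = the **reference-map maximum**
(global normalisation with absolute doses; the evaluated-map maximum is an
option). The evaluated map is sampled by bilinear interpolation on a
sub-grid of 0.1·DTA spacing inside a disc of radius 3·DTA — beyond 3 DTA the
distance term alone exceeds any gamma of interest. The search is an
exhaustive vectorised scan over that sub-grid, so the production path *is*
the brute-force computation; the test suite still pins it against an
independent triple-loop oracle to 1e-9. Gamma is reference-anchored and
deliberately asymmetric under map exchange. No published pass-rate value is
asserted anywhere: the film scans those rates came from do not exist in a
reusable form, so gamma correctness is property-based (identity → 100%,
3 mm rigid shift → 100%, uniform +3%-of-max → 100%, criteria-loosening
monotonicity, sub-grid refinement convergence).

## Monte Carlo electron-stream simulator

The generator's contract is *structural*: maps with a single dominant hot
spot whose magnitude tracks the projected footprint area and reproduces the
measured trend directions — not absolute dosimetry. Chain per photon:

1. **Source**: 1.17/1.33 MeV lines, equal weights; uniform point in the
   field square (transverse convention, matching the geometry default).
2. **Attenuation**: exponential free path along the in-phantom chord;
   frozen nominal PMMA linear attenuation 0.0753 / 0.0701 cm⁻¹ at the two
   lines. Compton is the only interaction (it dominates at these energies
   in low-Z media; no photoelectric/pair/bremsstrahlung, single scatter per
   photon, no photon history after the interaction).
3. **Compton kinematics**: scattering cosine by rejection from the
   Klein–Nishina cross-section (bound 2 at θ = 0); T = Eα(1−cos θ)/(1+α(1−cos θ)),
   cot φ = (1+α)tan(θ/2), azimuth uniform.
4. **Escape**: straight-line transport with a frozen log-log CSDA range
   table for acrylic; the path length to the surface is the geometric
   distance divided by a **detour factor 0.6** (sub-MeV electron paths are
   scatter-lengthened; straight-line CSDA alone over-estimates exit
   energies). Exit energy by inverse range.
5. **Exit-surface scattering**: a condensed Highland multiple-scattering
   kick (radiation length 34.4 cm, clamp 1.4 rad) followed by azimuthal
   diffusion — the exit direction's azimuth about the local face normal is
   redrawn uniformly, keeping the polar angle. Rationale: sub-MeV electrons
   traversing ≥ 1 mm of acrylic retain essentially no azimuthal memory of
   the primary kinematics; if that memory is kept, it couples coherently to
   the gyration sense and the re-entry cull and fabricates a large spurious
   gantry-30°/330° asymmetry that the measurements contradict.
6. **Helix**: analytic trajectory, gyroradius p<sub>⊥</sub>c/(eB) (1.355 cm
   at 1 MeV ⊥ 0.35 T), constant axial velocity; first crossing of the
   requested panel plane, miss if |v_y|/|v| < 1e-9 or the sign is wrong.
   **Re-entry culling** samples the helix at 36 points per turn (capped at
   20 turns) while inside the y-band the box occupies and absorbs electrons
   that graze back into the phantom; this cull is the model's mechanism for
   the growth of stream dose with phantom angle. A grazing-survival
   probability option exists (default 0).
7. **Air**: continuous slowing down along the helical arc with a frozen air
   CSDA table and the same detour factor; electrons whose residual range is
   exhausted before the panel are lost. This supplies the measured
   shorter-distance > longer-distance trend (low-energy electrons do not
   propagate far in air). A vacuum-air option (`air_interactions="none"`)
   exists.
8. **Scoring and normalisation**: residual kinetic energy per 1.36 mm pixel
   (fluence mode optional), then a 3 mm (1 σ) Gaussian response kernel —
   the finite spatial response of film/TPS maps, and the step that gives
   1e6-photon maps the smooth single-spot structure the D_Rx analysis
   assumes. Maps are scaled so the Compton energy transferred in a 1 cm³
   voxel at the isocenter corresponds to the 3 Gy prescription. This bridge
   is the package's own construction — no published quantity ties escaped
   fluence to film dose — so simulated doses are comparable across
   conditions, not against film readings.

Determinism: one `numpy` Generator seeded from `SimConfig.seed` drives the
whole chain; identical configurations are bit-identical.

### Trend evaluation

Trend statistics are **pooled over the 36-delivery study grid** (panel-summed
D_R1 per phantom angle; end-panel means per field size and distance), the
way the reference measurements report their trends as averages across
conditions. Per-condition hot-spot statistics at 10⁶ photons have Monte
Carlo noise comparable to the smaller published effects (the measured
20°→30° step is ~10%), so per-condition strict monotonicity is not a
meaningful assertion at this scale. Pooled, the suite is stable across
arbitrary seeds: tilt monotone, field 12.6 > 6.3 (~1.4×), 10 cm > 17 cm
(~1.1×), end > front (~3×), and end-panel D_R1 collapses by >5× (typically
7–10×) with the field off.

### Known limitations

* The measured *enhancement* of oblique gantry angles (30°/330° > 0°) is
  **not** reproduced: pooled oblique means come out statistically equal to
  gantry 0. The model has no mechanism for it once the spurious chirality
  coherence is removed; the 30°/330° near-symmetry is asserted instead.
* At the largest tilt/field combinations the beam overflows the phantom
  face and side-face escapes inflate the front-panel dose relative to the
  measurements (end/front ≈ 3 pooled, but ≈ 1 at the single most extreme
  geometry, where films show ≈ 3).
* Straight-line escape (even detour-corrected) has no backscatter channel,
  so entrance-surface escapes — the physical front-panel source at small
  fields — are rare; front-panel doses at field 6.3 are near zero where
  films show small but nonzero values.
* No electron return effect, no machine-head contaminant electrons, no
  photon interactions in air, MR-linac energies only as a config hook.

Passing trend tests therefore show the model reproduces the *direction and
rough magnitude* of the measured effects under the study geometry; they say
nothing about absolute out-of-field dose prediction for real patients.

## Study pipeline

* The packaged fixture transcribes the four printed circle-average tables
  (576 cells) with the captions' panel labels verbatim; a row count and a
  dose-sum checksum guard transcription drift. The source text's Discussion
  swaps the front/end attributions of the four mean-difference summaries
  relative to the captions; summaries here are keyed by source table and
  the discrepancy is left visible.
* Mean |calculated − measured| summaries use the **population** (n) SD —
  that is what the printed ± values reproduce (13.0/17.5/23.0/41.7 cGy).
  The gamma pass-rate summary uses the sample (n−1) SD, the QA convention.
* Spearman correlation is implemented directly (mid-rank ties, Pearson on
  ranks, two-sided *t* approximation on n−2 df, exact permutation p for
  n ≤ 8) and is pinned against `scipy.stats.spearmanr` to 1e-12 in tests.
  Projected areas are rounded to 1e-6 cm² before ranking so mirror-symmetric
  gantry pairs tie exactly.
* Percent differences default to comparator-in-denominator (`vs_second`);
  normalisation to a stated maximum (`vs_norm`) is explicit in reports.
* `run_study` derives one sub-seed per beam delivery from a master seed via
  `numpy.random.SeedSequence`; CSV outputs are written both at full
  precision and rounded to one decimal (the printed layout).

## Numerical choices

* Angles are degrees at every interface, radians internally.
* Ray–plane intersections treat |direction·normal| < 1e-12 as parallel and
  non-positive parameters as misses; both are distinct non-exceptional
  returns.
* Circle membership uses a +1e-12 slack on the squared radius so exact
  boundary pixels are included reproducibly.
* Gamma pass uses γ ≤ 1 + 1e-12 so boundary cases (exact 3 mm shift, exact
  +3% offset) pass as designed.
* CSDA tables interpolate log-log and clamp below 10 keV; electrons under
  0.1 keV are dropped.
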