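# Methods

## Scope and design

`conchmech` re-creates a comparative shell-biomechanics workflow end to end:
parametric shell geometry → TET4 volumetric mesh → static linear-elastic
solve → comparative stress statistics and the septal strength index.  The
real specimens this kind of study rests on are CT-scanned shells whose
geometries are not publicly available, so the geometry module generates
*synthetic stand-ins*: planispiral, multi-chambered shells carrying the
three septum morphotypes of interest (domed, synclastic, anticlastic
fluted).  Absolute stresses from these stand-ins are not comparable to
values measured on real shells; the package's claims are comparative
patterns, analytic validations, and exact replays of published arithmetic.

## Shell generator

Coordinates are right-handed with the coiling axis along z and the spiral
in the x–y plane; all lengths in mm; the shell is bilaterally symmetric
about z = 0.  The mid-surface wall is a logarithmic-spiral tube
`r(θ) = r₀·e^{wθ}` with an elliptical cross-section whose radial semi-axis
is a fixed fraction (0.38) of the spiral radius and whose aspect
(height/width) is a parameter.  Septa sit at equal angular spacing along
the phragmocone — real spacing is species-specific; equal spacing keeps the
generator minimal — with the final septum at the adapical end of the body
chamber (a parameter fraction of the last whorl).  Every septum is an
annulus from the wall ring to a circular siphuncular foramen.

Septum profiles: synclastic and anticlastic septa are spherical caps
(height 0.45 × the section's semi-minor axis, opposite signs: synclastic
bulges adapically/concave toward the aperture, anticlastic the reverse).
Domed septa are deeper (0.55×) and use a cosine profile with zero rim
slope: a near-hemispherical cap meets the wall tangentially, which a
conforming extrusion cannot mesh, so depth is traded against rim angle.

Anticlastic primary flutes (count `k`, amplitude `A` as a fraction of the
local section radius) are expressed three ways, all `cos(kφ)` in the
section angle φ:

* a spiral-direction wiggle of the suture ring with arc amplitude
  `0.5·A·h` (h = radial semi-axis), hat-blended onto neighbouring wall
  rings over a width that scales with the amplitude, not the ring count;
* an axial corrugation of the septal surface, continuous with the suture
  wiggle at the margin and fading to zero over the inner half of the
  annulus (flutes on real septa are strongest at the suture and die out
  centrally);
* a faint radial ribbing of the wall/margin at 0.3 × A (this carries the
  margin's radial waviness; a full-amplitude radial ripple creates groove
  concentrators that dominate point-load peaks and fold the offset
  surfaces).

Per-septum amplitude grows linearly with septum index — fluting deepens
through ontogeny — reaching the nominal amplitude on the final septum.

Septum margins *share vertices* with the wall ring at their station, so
the assembled surface extrudes into a single conforming volumetric model.
The junction edges are therefore 3-valent; the watertight/2-manifold audit
applies to closed components (validation spheres), while the shell is
audited for consistent orientation with margins exempted.

Presets (`spirula`, `nautilus`, `cadoceras5`, `cadoceras10`) encode the
three morphotypes with thin-shell thickness ratios (wall and septum ≈ 2–4%
of the local section radius), which is the regime of the real animals —
a hatchling ammonite septum is microns thick at a whorl size of hundreds
of microns.  The two ammonite presets differ in septum count and terminal
flute amplitude (0.12 vs 0.22), encoding "amplitude increases with septum
index" qualitatively; no quantitative published value exists.  The
`seed` parameter is threaded through for reproducibility, but the
generator is fully deterministic: identical parameters give bit-identical
meshes.

## Meshing

Each mid-surface triangle is extruded ±t/2 along per-vertex extrusion
directions into a wedge, split into 3 tetrahedra with the
lowest-global-node-index diagonal rule (shared quads triangulate
identically on both sides, so the mesh is conforming by construction;
several layers through the thickness are supported and used where bending
accuracy matters).  Extrusion directions are area-weighted vertex normals
*per structure* (wall vs septum), averaged with equal weight at junction
vertices — an area-weighted average there is wall-dominated and runs in
the septal plane, inverting the margin wedges — and relaxed with two
Jacobi passes so the direction field turns gradually near junctions.
Offsets that fold the surface (thickness exceeding the local curvature
radius) are rejected with the offending triangle indices.

Thickness is uniform per structure (one wall value, one septum value),
configurable per region; real shells vary continuously.

Down-sampling uses a deterministic shortest-edge-collapse decimator
(midpoint placement, link-condition and normal-flip guards, region-label
transfer) targeting `triangles/factor²` for factors 2/4/6; collapses that
would break manifoldness stop early with the achieved count reported.
Mesh quality reports per-element aspect ratio (longest edge / (2√6 ×
inradius); 1 for the regular tet) and dihedral-angle extrema.  The
convergence rule declares a refinement ladder converged when the two
finest peak stresses differ by ≤10% (relative to the finer) and selects
the coarsest level within 10% of the finest.  Two peak definitions exist
(final-septum peak vs global peak); the final-septum peak is the default.

## Solver

Constant-strain TET4 elements, Voigt order [xx, yy, zz, xy, yz, zx] with
engineering shear; isotropic elasticity; default material is nacre,
E = 50 000 MPa, ν = 0.29, in the consistent mm–N–MPa system.  Assembly is
vectorized into a sparse symmetric matrix; solves use SuperLU on the
constrained system with a residual check at 1e-6.  Pressure loads put
−p·A·n/3 on each node of a loaded face (positive pressure pushes against
the face).  Stress recovery is per-element σ = D B u; principal stresses
by symmetric eigen-decomposition sorted descending (tension positive);
nodal σ₁ is the volume-weighted average over adjacent elements
(arithmetic mean available — which definition a published "average"
uses is generally unstated, so summaries report both).

Hydrostatic cases on a closed shell are nearly self-equilibrated and run
without user constraints: a deterministic 3-2-1 constraint set (three
mutually distant nodes, 3+2+1 components) suppresses rigid modes, and the
reactions are verified small.  On the synthetic shell the wetted-face set
(external wall + body-chamber interior + final-septum adapertural face)
is not exactly closed — the aperture-rim annulus and the foramen disc are
unloaded — so the load retains a net resultant of order p × (missing
area): about 0.4–0.7% of the gross load on the presets.  The reactions
match that residual; on the truly closed sphere fixture they vanish to
1e-6.  An inertia-relief strategy (net force and moment balanced by a
rigid-body inertial body force over lumped nodal masses) is available for
loads with a larger residual.

Point loads are applied to a single node, as in the workflow being
re-created; the resulting singularity makes peak values mesh-dependent,
so comparisons are only meaningful at matched resolution (enforced by
comparing presets at their own fixed discretization).  The chamber-wall
bite targets the external-wall node nearest the flank midline (top of the
whorl section, z > 0) midway in spiral angle between the last two septa;
the suture bite targets the flank-midline node of the penultimate
septum's suture ring — the same azimuth as the chamber load, so the two
scenarios differ only in position along the spiral.  The load acts along
the inward surface normal; all external-wall nodes within an antipodal
cap (mirror image through the coiling plane, default half-angle 10°,
grown until ≥6 nodes) are fixed in x, y, z, since a single fixed node
cannot restrain rotation.

## Statistics and SSI

Case summaries report the volume-weighted global average of element σ₁,
regional nodal peaks (final septum; internal shell surface = wall
interior + body-chamber lining), through-thickness min/max at the septum
centre (node nearest the septum's area centroid) and at the ventral
margin (suture node farthest from the coiling axis), and the fraction of
septal nodes above the ≈130 MPa theoretical tensile strength of nacre.
Percent decreases are rounded half-up to integers, which reproduces every
printed integer in the reference tables.

SSI = 1000·δ/R with δ the minimum septal thickness and R a radius of
curvature from a circle through three points of the median-section
mid-curve (default placements 25/50/75% arc length, emulating manual
three-point picking).  Section curves are plane cuts of the final
septum's two face meshes; the outer 15% of each curve is trimmed before
measuring δ because the septum blends into the wall at the suture and
into the free rim at the foramen.  Depth = 30.0 m per SSI unit — the
conversion the published depth table implies (all 17 rows reproduce to
<0.05%; the source cites a conversion without printing it).
`ssi_sampling_spread` re-measures SSI under randomized point placements;
the spread on fluted septa is the index's documented instability, which
the package quantifies rather than hides.

## Validation

* Uniaxial patch test on a unit cube of tets: constant σ to round-off
  (the CST patch-test identity).
* Lamé thick-walled sphere (a = 9, b = 10 mm, external 8 MPa): inner-
  surface hoop stress −3pb³/(2(b³−a³)) = −44.28 MPa; the mid-surface
  extrusion at icosphere refinement 4 with 3 layers recovers it to ~0.15%.
* Linearity: the 2/4/6/8 MPa pressure series scales exactly with p
  (relative deviation < 1e-6), as a linear model must.
* Element/assembly oracles: quadrature-integrated B^T D B, dense scatter
  assembly, 6-dimensional rigid-body null space, frame invariance.

## What the synthetic models do and do not show

The four presets reproduce, at matched per-preset resolution:

* tension concentrating on the final septum (septal peak > 5 × |global
  mean| for every morphotype; for the concave cap morphotypes the global
  maximum sits on the final septum with elevated tension around the
  foramen — the anticlastic models concentrate tension at the saddle
  attachments to the wall instead);
* suture-directed point loads producing lower internal-surface peaks
  than chamber-wall loads, for every morphotype;
* hydrostatic septal peak stress increasing monotonically with flute
  amplitude on the anticlastic model.

One published trend does **not** reproduce: the suture point-load peak
*rises* mildly with flute amplitude here, where CT-based models show it
falling.  The single-node peak is dominated by the local singularity,
and the buttressing advantage of a corrugated suture appears to require
the interlocked, frilled suture geometry of real ammonites, which this
generator's single-harmonic flutes do not capture.  The corresponding
acceptance check is asserted in the published direction and fails; it is
kept failing deliberately as an honest negative result.

Other known limitations: no septal necks or siphuncular tube; uniform
pressure (no depth gradient along the shell) and no internal chamber gas
pressure; isotropic nacre; no fracture propagation; equal septal
spacing; discrete triangulation is not mirror-symmetric (quad-diagonal
and wedge-split rules), so bilaterally mirrored solutions agree
statistically (95% of nodes within 10% of the field max) rather than
pointwise.

## Problem sizes

Default presets mesh to roughly 16 000–39 000 elements (the fluted
ammonite presets use finer discretization, 72 rings/whorl and 40 ring
segments, to resolve ~7 elements per flute wavelength); a solve takes a
few seconds on one CPU.  Validation fixtures use icosphere refinements
2–4 (up to ~46 000 elements).  These sizes were chosen so the full test
suite and the acceptance script each run in about a minute while keeping
the qualitative patterns stable under refinement.
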