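# Methods

## Coordinate frame and units

All geometry is in millimetres. The anatomical frame is +Z occlusal/
superior, +Y anterior, +X patient-left. "Vertical plane" means a plane
containing the Z direction; "posterior" is −Y. STL files carry no unit
metadata, so coordinates are interpreted as millimetres verbatim; the CLI's
`--units` flag warns but never rescales.

## Design rules and their defaults

`PipelineConfig` is the single home of every numeric design rule:

| parameter | default | meaning |
|---|---|---|
| `interincisal_mm` | 20 | articulated opening validated in step 1 (± 0.5 mm) |
| `maxilla_plane_fraction` | 0.60 | maxillary plane position along the gum-to-occlusal extent |
| `mandible_plane_fraction` | 0.40 | mandibular plane position, from the lower gums |
| `hull_expand_fraction` | 0.015 | uniform hull inflation about its centroid |
| `separation_offset_mm` | 2 | separation plane height above the lower incisor tip |
| `tail_extension_mm` | 10 | tail reach beyond the second molar |
| `tongue_posterior_offset_mm` | 17.5 | posterior shift of the auto-placed tongue |
| `min_plate_thickness_mm` | 10 | hard floor enforced after the tongue carve |
| `protect_distance_mm` | 0.5 | impression-protection radius during smoothing |
| `smoothing_iterations` | 10 | Taubin passes in step 9 |

The "height" that the 60 %/40 % fractions refer to is operationalised as
the vertical extent from the arch's gum-baseline landmark to its occlusal
extreme (the vertex farthest from the baseline along Z); the fitted PCA
plane keeps its slope and is translated so that it crosses that fractional
height at the arch centroid's XY position. The hull expansion is isotropic
scaling by (1 + f) about the hull's volume centroid, which makes the
expansion exactly measurable (volume grows by (1 + f)³); a per-vertex
normal-offset mode is available via `expansion_mode="normal_offset"`. The
separation plane is taken parallel to the mandibular plane ("slope based
on" is read as parallel, the simplest consistent choice).

Step 5's three planes per side are our construction satisfying the stated
tooth list (canine, both premolars, first two molars): a transverse plane
1 mm mesial to the canine, a transverse plane 1 mm distal to the second
molar, and a parasagittal plane on the lingual side of the tooth row
(minimum |x| of the row minus a 4.5 mm clearance). When landmarks are
missing (hypodontia, edentulous) the planes fall back to arch-extent
fractions and a warning is recorded. The step-4 distal trim margin (1 mm
beyond the second molar) and the tail box cross-section (molar row width
plus 6 mm padding, spanning the plate band between the mandibular and
separation planes, overlapping 8 mm into the stent) are likewise package
choices where only the intent is fixed.

The default tongue is an ellipsoid with lateral semi-axis 0.8 × the
inter-first-molar half-width, anteroposterior semi-axis 25 mm and vertical
semi-axis 8 mm, centred on the lower tooth-landmark centroid shifted
17.5 mm posteriorly so the tip stays behind the incisors, and sunk 3 mm
below the plate top. With the default anatomy this leaves an ≈ 11 mm
plate, comfortably above the 10 mm floor; the step fails loudly
(`ConstraintError`, reporting the measured value) if a user-supplied
tongue violates it.

## CSG layer

Boolean robustness is treated as a first-class requirement. Two backends:

* **Exact BSP boolean** (small operands, ≤ 512 faces combined): the
  classic clip-each-mesh-against-the-other's-BSP algorithm. The two
  operands triangulate the common seam independently, leaving T-vertices;
  a stitching pass splits open edges at collinear boundary vertices until
  every edge is two-faced. Verified by inclusion–exclusion to 1e-6
  relative over 50 seeded cube poses.
* **Voxel-remeshing boolean** (large operands): both solids are rasterised
  onto a shared cubic grid (default 256 voxels along the longest axis,
  ~0.25 mm pitch at mouth scale) by vertical-ray parity counting, the
  boolean is applied to the occupancy arrays, and the surface is
  re-extracted with marching cubes. Accuracy is bounded by the pitch —
  volumes agree with the independent oracle to well under 2 % — and the
  result is watertight by construction. Binary fields occasionally produce
  checkerboard configurations where two sheets touch along a cell edge
  (four faces per edge); when detected, the surface is re-extracted from a
  lightly Gaussian-blurred field (σ = 0.8 voxel), which separates the
  sheets at negligible volume cost.

Plane cuts do not go through the boolean backends at all: they use exact
plane slicing with the cross-section capped by a fan to each boundary
loop's centroid. Because cap loops are planar, the fan reproduces the
section's signed area exactly, so half-space volumes are exact even for
non-convex sections. (This is equivalent to, but more accurate than,
subtracting a large angled box.)

All sampling lattices (voxelisation, the volume oracle, thickness rays)
are shifted by small distinct irrational fractions of the pitch per axis
so that mesh edges and face diagonals never coincide with ray positions,
which would corrupt crossing parity.

The parity ray-casting **volume oracle** (`voxelize_volume_oracle`) spans
exactly the mesh bounding box with per-axis pitch; it shares no code path
with the divergence-theorem volume it cross-checks.

## Watertight repair

Repair deduplicates vertices (1e-6 mm rounding — binary STL stores each
triangle's corners independently), drops degenerate and duplicate faces,
and fills each boundary loop by ear clipping against the loop's best-fit
plane. Two escalations handle scan-artifact pathologies: loops that touch
at a pinch vertex are widened by discarding the pinched faces first, and
an ear-clip patch whose diagonal would coincide with an existing mesh edge
is replaced by a fan to a fresh apex vertex, which cannot collide by
construction. Winding is made consistent and orientation fixed by making
the signed volume positive. Already-watertight input is returned
unchanged, making repair exactly idempotent. A damage gate rejects meshes
with more than 5 % boundary edges (with an absolute allowance of 24 edges
so small test meshes remain repairable); irreparable inputs such as a
single triangle fail the closed-positive-volume validation instead.

## Plate thickness

`min_plate_thickness` casts a vertical ray at every 0.5 mm lattice point
inside a footprint polygon and takes the minimum total inside-length; a
ray that misses the stent yields 0. The footprint used by step 7 is the
XY region where the tongue ellipsoid dips below the plate top,
intersected with the region where the pre-carve stent actually carries
plate-grade material (columns with at least `min_plate_thickness_mm` of
material, shrunk 0.75 mm from the walls). Dental-impression seats are thin
by design and are governed by the impression, not the tongue, so they are
excluded; the open posterior edge of the tongue space is likewise not
plate. Thickness is measured along the occlusal (Z) axis only.

## Smoothing

Step 9 applies Taubin λ/μ smoothing (λ = 0.5, μ = −0.53, 10 iterations,
uniform Laplacian) to every vertex farther than 0.5 mm from the dentition
surfaces; protected vertices are restored bit-identically afterwards.
Proximity is measured against a dense deterministic sampling of the
protected surfaces (vertices, face centroids, edge midpoints). Topology is
untouched, so watertightness survives, and the λ/μ pairing keeps the
volume within a fraction of a percent.

## Synthetic anatomy

The generator emulates intraoral scans of articulated stone models. Each
jaw is built implicitly on a voxel grid — a gum ridge swept along a
parabolic arch curve plus one superellipsoid per tooth station (7 per
side; third molars optional) — and remeshed by marching cubes, which makes
watertightness structural. The maxillary arch is 4 mm wider and 2 mm
deeper than the mandibular one, giving a ~2 mm overjet. Landmarks are the
analytic tooth apices, so they track the surface to within half a voxel
for any seed; per-tooth jitter (default σ = 0.2 mm on position, 2 % on
scale) perturbs the dentition without ever breaking landmark–mesh
consistency, and the jitter stream is drawn identically whether or not a
station is instantiated, so presets share tooth placement. Stations are
computed for one side by arc length and mirrored exactly, so the
zero-jitter model is bit-symmetric.

Presets: `normal`; `class3` advances the mandible 6 mm anteriorly;
`hypodontia` removes a seeded choice of 4 from 10 candidate stations
(lateral incisors, second premolars, upper second molars), exercising the
landmark-fallback paths; `edentulous` has no teeth — its interincisal
reference points sit on the ridge crests, and the residual ridge is
modelled taller (ridge + tooth height) and broader (6 mm half-width,
the full vestibular width a trimmed stone model presents) than the
dentate gum roll, as a resorbed arch whose envelope matches the dentate
model of the same patient. Default mesh resolution is 160 grid cells
along the longest axis (~0.4 mm pitch, 60–100 k triangles per jaw, the
scale of a real intraoral scan export).

What the generator does **not** emulate: real crown morphology (cusps,
fissures), soft tissue (tongue, palate, frenula), scan noise beyond
punched holes (`punch_holes` deletes face patches to exercise repair),
bite misregistration, and unit ambiguity. Passing tests therefore
demonstrate that the workflow's geometry and design rules behave correctly
on idealised but anatomically structured inputs — not that landmark-free
segmentation of real scans is solved (tooth identification is landmark-
driven by design; automatic segmentation is out of scope).

## Problem sizes in the test-suite

The parameter-echo tests run one full pipeline at default resolution
(anatomy 160, booleans 256). Suites that need many pipeline executions
(all four presets, damaged-scan robustness, repeated-run determinism) use
a reduced size — anatomy grid 96, boolean grid 128 — which preserves every
property under test while keeping the whole suite around four minutes.
The statistics module retains Welch's t and descriptive SEM for comparing
groups of stent volumes; mixed-effects modelling of human-operator studies
is out of scope because the automated pipeline has no operator effect to
model (its repeat-run SEM is identically zero).

## Known limitations

* Voxel-remeshed booleans quantise surfaces at ~0.25 mm; volumes are
  accurate to ~1 % and mating faces can be displaced by up to half a
  voxel. The exact BSP path has no such error but is practical only for
  small operands.
* Binary STL stores float32 coordinates, so save/load round-trips preserve
  volume only to ~1e-6 relative, not to double precision.
* The dental impression is carved by boolean subtraction with no cement
  gap or undercut analysis; seating mechanics are not simulated.
* `repair_watertight` targets scan-artifact holes; it is not a general
  mesh-healing tool and will reject grossly damaged shells.
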