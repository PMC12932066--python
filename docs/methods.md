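# Methods

This note records the geometric model behind `prostmould`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing its output.

## Conventions

All geometry is in millimetres in a patient-anatomical Cartesian frame,
default LPS (+x left, +y posterior, +z superior — the DICOM patient
convention).  Fusion-biopsy systems export STL without units or frame
metadata; fixing mm/LPS is this package's convention, carried as a tag on
every mesh and resolved through `prostmould.frames`, so RAS inputs are
supported by tagging.  Anatomical block-face names (superior, posterior,
left-lateral, right-lateral, anterior, inferior) resolve to axis/sign pairs
through the same tag.

A mesh is accepted only if it is watertight (every edge shared by exactly
two faces), consistently wound (signed volume > 0 after automatic winding
repair) and finite.  Loading merges the per-facet duplicate vertices that
STL stores (tolerance ~1e-6 mm) and repairs winding; it never fills holes —
a hole in a boundary segmentation is a data error to surface, not noise to
smooth over.  Note that binary STL stores float32 coordinates, so a
save/load round trip preserves vertices only to ~`eps32 * |coordinate|`
(about 5e-6 mm at 50 mm); ASCII output preserves full double precision.

## Mould model

A patient case is one closed prostate-boundary surface plus one closed
surface per target ROI, in a shared frame.  For each case three mould
variants are produced, with the cavity offset outward by 0, 1 and 2 mm; the
offsets tolerate slight boundary-segmentation error so that at least one
mould fits the explanted specimen.  The variants share a single block and a
single guide plan computed from the unoffset boundary, so all three target
identically; only the cavity (and each channel's terminal depth) changes.

The block is the cavity bounding box expanded by a wall margin (default
10 mm, minimum printable wall 3 mm) — a material-optimised tight block
rather than a literal cube.  The margin and minimum wall are engineering
choices for FDM print rigidity, not measured values, and are configurable.

The specimen enters through an open face, default anterior: the biopsy
approaches used (superior, posterior, both laterals) leave it free.  The
opening is the prism swept from the cavity's projected silhouette, from the
cavity's axial midplane out through the block — exactly the swept volume a
rigid convex-ish specimen needs to slide in along the face normal.  A
channel whose bore crosses the opening loses wall support there; the builder
fails with a layout error when the guided length that remains (tower plus
walled channel) drops below twice the channel diameter.  A two-piece or
hinged mould is out of scope.

## Guide planning and length calibration

Each ROI is targeted at its volumetric centre of mass (divergence-theorem
centroid of the closed surface).  For each ROI the `guides_per_roi` (default
2) approach faces with the smallest perpendicular centroid-to-face distance
are chosen, excluding the insertion face; exact ties break in the fixed
order superior, posterior, left-lateral, right-lateral for determinism.
Guide axes are the inward face normals through the centroid — matching how a
hand-held needle is used against a flat face; oblique trajectories are not
generated.  Two guides per lesion are implemented as two *approach faces*;
the alternative reading (two parallel offset holes in one face) is not
implemented.

The only free parameter left is the guide length, fixed by the calibration
identity at the configured insertion depth (default 50 mm, i.e. the needle
is inserted until its hub meets the guide top):

```
entry -> centroid distance = insertion_depth - tip_to_notch_center
```

`tip_to_notch_center` is a property of the needle model: 0 for the manual
14 G Tru-Cut style device (tip-targeted; notch 20 mm, OD 2.11 mm) and 13 mm
for the spring-fired 18 G device (fired notch centred behind the tip; notch
18 mm, throw 22 mm, OD 1.27 mm).  These notch geometries are nominal device
characteristics, configurable per needle.  When the centroid is shallower
than the reachable depth, the guide is extended above the block face by a
tower of exactly the missing height (annular wall 1.5 mm); when it is
deeper, no guide length can satisfy the identity and calibration fails with
the deficit.  The entry point is *constructed* at exactly the identity
distance from the centroid, so the identity holds to floating-point
round-off (tested at 1e-6 mm), not approximately.

Channel bores are the needle outer diameter plus 0.25 mm clearance per side,
and each channel ends where the cavity begins (probed by exact ray casting
along the axis) rather than continuing as a blind hole.  Channels are
checked pairwise for collision over their real extents — axes that converge
on a shared centroid inside the cavity void do not collide.

## Solid modelling

No exact mesh-boolean engine is assumed.  Solids are modelled as signed
distance fields (negative inside): analytic primitives (box, capped
cylinder, extruded silhouette polygon) and sampled fields for input meshes,
composed with the min/max CSG algebra, whose zero level set is the exact
boolean boundary.  The final surface is extracted by marching cubes on a
regular grid (default pitch 0.45 mm; 0.5–0.6 mm used for the large test
cohorts), which yields watertight, self-intersection-free meshes by
construction — printability is the binding requirement, accepted at the cost
of re-sampling geometry at the grid pitch.  Outward offsetting is the level
shift of the same field, so an offset surface can never self-intersect.

The mesh signed-distance field is computed on the grid as the exact
point-to-triangle distance (candidates from a k-d tree over triangle
centroids), signed by vertical-column crossing parity.  Two numerical
details make the parity exact rather than probabilistic:

- crossing tests use *canonical edge functions* — each shared edge's 2D edge
  function is evaluated once, keyed by vertex indices, so adjacent triangles
  see exactly complementary values and a column crossing is counted exactly
  once even when it grazes a shared edge;
- the grid origin carries a fixed irrational sub-voxel offset so columns
  never align exactly with mesh vertices or axis-aligned edges (icosphere
  poles and box edges otherwise do).

The same two devices make segment/mesh clipping in the simulator exact, with
ray origins additionally nudged laterally by 1e-9 mm so an axis cannot pass
exactly through a vertex.  Far from a surface the field falls back to a
Euclidean distance transform of the occupancy (half-voxel accuracy), which
cannot move a level set lying inside the exact band.

Accuracy at the defaults, measured against closed forms: reconstructed and
offset spheres agree with `(4/3)πr³` within 0.3 % at 0.4 mm pitch; carved
mould volumes agree with an independent 0.5 mm voxel-boolean oracle within
0.5 % (2 % is the asserted gate).  The voxel oracle shares only the
silhouette polygon with the production path; occupancy, offsetting (EDT
dilation) and volume measurement (voxel counting vs divergence theorem) are
independent routes.

## Targeting simulation

The needle is modelled as its axis plus the notch interval: inserted to the
fixed depth, the notch is the segment of length `notch_length` centred
`tip_to_notch_center` behind the tip.  A hit is a non-empty notch–ROI
intersection, computed by exact segment clipping against the ROI surface.
Ignoring the finite core diameter makes the criterion conservative by up to
the core radius (~0.7 mm).  By the calibration identity, the zero-error
notch centre coincides with the ROI centroid, so the zero-error hit rate is
1.0 on every well-formed case — the geometric analogue of a 100 % biopsy
yield, and the property the acceptance suite checks on a 12-case cohort.

Placement error is modelled as a rigid transform of the specimen relative to
the mould: per-axis Gaussian translation, Gaussian-angle rotation about a
random axis through the gland centroid, and (for `boundary_offset_error_mm`)
a uniform seating slack inside a ball of that radius.  Trials transform the
notch segment into the specimen frame by the inverse rigid map, which is
exact and cheap.  For a spherical ROI under pure translation error the hit
probability has a closed 2-D quadrature (axial normal × radial Rayleigh
displacement), used as the independent oracle: Monte-Carlo rates at 2000
trials agree within 3 points across error levels.  The largest idealisation
is the rigid-specimen assumption — tissue deformation on seating is not
modelled, so simulated hit rates bound geometric, not biological, yield.

## Synthetic cohort

The generator emulates fusion-biopsy exports with closed-form shapes:
ellipsoidal prostates (fixed 1 : 0.9 : 1.1 axis anisotropy, avoiding
degenerate pancakes) and spherical ROIs, so volume and centroid oracles are
free.  Default cohort draws: prostate mesh volumes uniform in 25.5–55.4 ml,
one or two ROIs per case with volumes uniform in 0.13–2.41 ml, placed
uniformly in the margin-eroded gland, non-overlapping; a second lesion's
size is re-drawn with its position until it fits, conditioning multifocal
lesion size on feasibility.  Semi-axes are scaled so the *mesh* volume (an
inscribed icosphere underestimates its ball by 0.2–0.9 % depending on
resolution) hits the drawn volume exactly, keeping every case inside the
stated ranges under either reading.  An optional boundary perturbation adds
a smooth low-frequency radial field (sum of a few long-wave cosine modes,
peak-normalised) — i.i.d. per-vertex noise would self-intersect; the default
is zero noise so closed-form oracles hold.  The generator does not emulate
lobed gland shapes, segmentation staircase artefacts, or any imaging
physics; passing tests certify the geometry pipeline, not segmentation
quality on real exports.

## Reported sizes

The test suite and `scripts/acceptance.py` run the full pipeline on a
12-case cohort at mesh resolution 3 (1280-face boundaries) and 0.55 mm
extraction pitch, with 2000 Monte-Carlo trials per error level — sizes at
which every asserted tolerance is met with margin while a complete run stays
in the minutes range on one CPU.  Production defaults (resolution 4,
0.45 mm pitch) are finer; accuracy figures above are quoted at those
defaults where stated.

## Known limitations

- One-piece mould with an open insertion face; no two-piece/hinged designs,
  no whole-mount slicing slits.
- No avoidance of urethra or neurovascular structures (no such segmentations
  in scope) and no oblique or curved trajectories.
- Rigid-specimen assumption in simulation; no deformation, no needle
  deflection, no histology model — concordance statistics in the cohort
  module are recomputed from a table, not predicted.
- Patient-frame axis alignment only: the prostate is not re-oriented inside
  the block.
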