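# Methods

## The model

The small and large intestines are long tubes whose biology varies along
their length far more than across it, while their 3D folding varies between
individuals and even within one individual over time.  `gutccf` therefore
uses a 1D "natural coordinate": distance along the gut centreline.  Each
intestine is one linear *path* of anatomical landmarks (anus, anorectal
junction, rectosigmoid junction, flexures, ileocaecal valve, …) joined by
*regions* (anal canal, rectum, sigmoid colon, …).  The large-intestine path
is referenced at the anus and runs to the appendix tip; the small-intestine
path is referenced at the ileocaecal valve on the ileum side (ICVi) and runs
to the gastro-duodenal junction.  On both paths the coordinate `s` (mm)
increases away from the reference, i.e. toward the mouth; "proximal" means
larger `s`, "distal" smaller `s`.

Two landmarks are *intermediate*: the anterior peritoneal reflection (APR)
inside the rectum and the ileocaecal valve projected on the large-intestine
centreline (ICVc) inside the caecum.  They delimit no region but bracket
locations like any other landmark.

A canonical location (`GcaLocation`) is the pair of adjacent landmarks
bracketing a point plus the fractional position between them, measured from
the distal landmark:

    s = s_distal + f * (s_proximal - s_distal),   f in [0, 1].

This proportional representation — not the absolute millimetre value — is
what transfers between models, because absolute distances are model- and
patient-dependent.

### Conventions decided here

The direction of the fraction is not dictated by the anatomy; we measure it
from the distal landmark so that it increases with `s` on both paths.
Clinical phrases quoted from either end ("two-thirds of the distance from
the ileocaecal valve to the hepatic flexure") are handled by
`proportion_location`'s explicit from/to arguments and canonicalized.  A
location exactly at an interior landmark is represented on its
proximal-side interval with fraction 0; the proximal terminus of a path uses
the last interval with fraction 1.  These tie-breaks make
`abs_to_location`/`location_to_abs` mutually inverse (the `s` value is
always preserved exactly) and make location order equal (interval, fraction)
lexicographic order.

The shipped consensus model (`data/human_consensus_1d.json`) carries
literature-typical adult distances (large intestine 1630 mm to the appendix
tip, small intestine 4450 mm).  These are *editable defaults*: models are
data, not code, and any clinic or atlas should substitute its own file.

### Patient-specific rescaling

`rescale_model` derives an individual model from measured landmark
distances.  Measured landmarks become anchors (the reference is always an
anchor at 0); unmeasured landmarks strictly between two anchors are placed
by preserving their proportional position in the original model; unmeasured
landmarks beyond the last anchor keep their original distance, since there
is nothing to interpolate against — if a measurement would reorder
landmarks the operation fails naming the offending pair.  Region lengths are
recomputed.  Because the canonical representation is proportional, every
location's (landmark pair, fraction) is invariant under rescaling.

## Mapping between models

Base-level mapping is piecewise linear and landmark-anchored.  If a
location's bracketing pair is adjacent in both models, the pair and fraction
transfer verbatim — round trips are exact identities, bit for bit.  If the
landmark sets differ (a finer patient model, or a sparser abstract model
used as the cross-species intermediate), the location is *re-bracketed*:

1. take the landmarks common to both models on that path (their relative
   order must agree, else the mapping fails);
2. find the two shared landmarks adjacent (in the shared set) around the
   location — the minimal shared bounding span;
3. transfer the proportional position within that span and re-express the
   result against the target's own adjacent pair.

Shared landmarks are fixed points of this rule, so it is symmetric and
reversible; round trips through a sparser model recover the original
position to floating-point precision (~1e-13 mm in practice).  Cross-species
mapping is the composition source→abstract→target.  A per-interval monotone
non-linear warp could replace the linear transfer within a span; only the
identity warp ships.

## Image domains and midline extraction

2D anatomogram-style and 3D radiological-style domains are integer label
grids (0 background, label *k* = region sub-domain *k*) with physical
spacing; cell centres sit at `index * spacing` mm.  2D domains are 16-bit
label PNGs, 3D domains integer NIfTI volumes (spacing from the header), each
with a JSON sidecar carrying the label→region map, connectivity and
adjacency overrides.  Connectivity is 8-neighbour in 2D and 26-neighbour in
3D, with step costs equal to the physical centre-to-centre distance.

The midline is found by best-first propagation: image locations are visited
in priority order with

    priority(x) = w_end * geodesic_to_end(x) - w_bnd * boundary_dist(x)

(lower first), where `geodesic_to_end` is the within-domain shortest-path
distance to the far endpoint (Dijkstra with physical step costs, cacheable
per endpoint) and `boundary_dist` the spacing-aware Euclidean distance
transform.  The endpoint term drives the front along the tube, the boundary
term holds it on the centre; the path is the predecessor back-trace from the
end.  Ties are broken by lexicographic grid index, so repeated runs are
bit-identical.

The two terms have incommensurate ranges: the geodesic spans the whole tube
length while the boundary distance spans only the tube radius, and the
geodesic saving from hugging the inner wall of a curved tube grows with tube
length.  Equal weights therefore let long curved tubes pull the path off
centre.  The default is `w_end=1, w_bnd=10`; on the synthetic fixtures the
recovered midline is insensitive to `w_bnd` over roughly 5–400 (Hausdorff
distance to the analytic centreline ≤ ~1.3 cells on all four fixtures), and
increasing `w_bnd` never worsens centring.

The discrete path is smoothed into a cubic B-spline (`splprep`), with the
smoothing parameter expressed as a maximum allowed deviation in mm (default
`2 * max(spacing)`; 0 requests interpolation); the spline's sum-of-squares
bound is shrunk geometrically until the deviation bound holds.  An
arc-length table at 0.1 mm resampling gives the parameter↔arc-length lookup
used everywhere downstream.

### Landmark embedding

An embedding anchors a 1D model's landmarks to arc lengths on a curve.  The
curve's samples are labelled by the sub-domain they fall in (isolated
background samples from smoothing inherit the previous label); the run
sequence must equal the model's region order, after reversing the curve if
it was extracted mouth-to-anus.  Each landmark shared by two consecutive
regions is placed at the midpoint of the crossing interval between the two
runs; the path-terminal landmarks anchor arc 0 and the total length.
Landmarks with no sub-domain boundary (the intermediates) are supplied as
manual overrides.  Because labels exist only on the cell grid, a placed
landmark is quantized to within about half a cell of the true boundary —
sub-cell placement is not obtainable from labels alone.

Between anchors, model distance and arc length are interpolated linearly in
both directions, giving `location_to_point` (evaluate the curve at the
location's arc length) and its inverse.

### Region-restricted projection

A sample taken off the midline (but within the gut wall) is assigned the
nearest midline point *of its own region sub-domain*, never the globally
nearest curve point: the looping of the gut makes plain 3D proximity
spurious (a sigmoid loop can pass millimetres from the transverse colon).
`MidlineProjectionIndex` precomputes this region-restricted nearest-arc
assignment for every foreground cell and agrees exactly with the direct
search at cell centres.

## ROIs, location cards and queries

A region of interest is an interval `[s_start, s_end]` on one path — the
spatial range within which a sample was collected.  A location card pairs an
ROI with term references and free-form metadata, serialized as JSON (stores
are JSON-lines).  Queries rank cards against a query ROI by 1D interval
Jaccard index (intersection length over union length); zero-length point
ROIs are dilated by ε = 0.5 mm per side so point samples can still overlap
and rank (configurable).  Cards referencing other models are mapped onto
the query's model first; unmappable cards are skipped with a warning.  Ties
are broken by card id, and cards on a different path are excluded rather
than force-ranked (there is no principled cross-path Jaccard).

## Semantic extension

The 1D coordinate is complemented by wall-layer terms (mucosa, submucosa,
muscularis propria, serosa) and cell types, following the ASCT+B table
style with UBERON/FMA/CL cross-references.  Identifiers are opaque strings
— terms are attached and rendered ("mucosa halfway between SF and HF"),
never reasoned over.  Annotation wraps the coordinate without modifying it.

## Synthetic phantoms

Because the gut is geometrically a tube, every image-side operation is
validated on generated tube masks with analytic ground truth: straight,
sinusoid and U-bend tubes in 2D and a helix in 3D, with the tube being all
cells within a half-width of a densely sampled analytic centreline and
region labels assigned by arc-length split fractions.  The generator refuses
specs whose centreline self-intersects at the requested width.  Default test
geometries are a 41×200 straight tube (half-width 10), a 61×200 sinusoid
(amplitude 12, period 100), a 120² U-bend (radius 30) and a 64³ helix
(radius 18, pitch 14, two turns) — small enough that the whole suite runs in
a few seconds on one CPU while still exercising curvature, bending and 3D
torsion.  Boundary noise is off by default and seeded when enabled.

What the phantoms do not emulate: real segmentation artefacts (holes,
stair-step aliasing from anisotropic CT, touching loops that require
cut-domains), intensity data, and anatomical asymmetries of tube width.
Passing tests therefore demonstrate correctness of the geometry and mapping
machinery, not robustness to segmentation error.

## Numerical choices

* millimetres everywhere; length-consistency tolerance 1e-6 mm.
* arc-length resampling 0.1 mm; point↔location round trips are exact to one
  resampling step.
* landmark placement tolerance: one cell (see quantization note above).
* JSON outputs use sorted keys and floats rounded to 9 significant digits,
  so identical invocations are byte-identical.
* degenerate inputs: a single-point midline request returns a single-point
  path; empty foregrounds, background endpoints and unreachable endpoints
  raise with both endpoints named; model validation reports *every*
  inconsistency, not just the first.

## Known limitations

* No radial or angular coordinate: a location is on the centreline, with
  the wall layer carried semantically, not geometrically.
* Cut-domain authoring (resolving overlapping anatomogram regions) is a
  manual step upstream of this package; domains are consumed already
  labelled.
* No image segmentation: label grids come from elsewhere.
* The oesophagus and stomach are out of scope; the framework covers
  gastro-duodenal junction to anus.
* Villus/crypt and left/right refinements are not represented.
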