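# Methods

This note records the modelling assumptions, numerical choices and
parameter defaults behind `prosthoface`, and what the synthetic study
conditions do and do not establish about real scan data.

## Surfaces, landmarks, frames

All surfaces are triangle meshes in millimetres. Landmarks travel in a
JSON sidecar because OBJ has no standard landmark dialect; the three
mandatory ones (bilateral tragus centres, nasal tip) mirror the skin marks
used when scanning patients, and the optional five (alae, menton,
commissures) are only needed by the boundary statistics.

The canonical face frame is defined entirely by the mandatory landmarks:
origin at the tragus midpoint, X along the tragus–tragus axis (patient's
left at +X), Z toward the nasal tip (orthogonalized against X), Y = Z × X.
By construction the nasal tip lies in the XZ plane, so its Y coordinate
cannot disambiguate up from down; the package instead requires the menton
(when present) or the mesh centroid to fall below the tragus line. The
same rule silently corrects swapped left/right tragus labels, which would
otherwise rotate the frame 180° about Z.

## Registration

Landmark alignment is the closed-form orthogonal-Procrustes solution with
a reflection guard; configurations whose second singular value vanishes
(collinear landmarks) are rejected. ICP is the classical point-to-point
form: nearest-neighbour correspondences over the masked source vertices
(the upper third of the face, cut at the mean height of the tragus and ala
landmarks), symmetric rejection of matches beyond 5 mm, closed-form
re-estimation, fixed processing order. Defaults: `tol = 1e-4 mm`,
`max_iter = 100`. The masked RMS is non-increasing over accepted
iterations; stalling within `tol` counts as convergence. The commercial
"best fit" routine used clinically is a black box; this implementation is
an independent realization of the same algorithm family, not a byte-level
reproduction.

## Curvature and the feature template

Mean curvature at a vertex is the neighbourhood average of edge-wise
normal-projection curvatures. With exact normals this estimator is exact
on spheres (|H| = 1/r) and on uniformly meshed cylinders away from the
ends (|H| = 1/2r); with the package's area-weighted normals the error on
a 2 562-vertex sphere is below 1%. Outward normals make convex regions
negative; feature detection only uses curvature *changes*, so the sign
convention never leaves the module.

Isolines are planar sections: each crossed triangle contributes a segment
by linear edge interpolation, segments are chained, and the component
nearest the seed point is kept. Vertices within `1e-9 × extent` of the
section plane are nudged to one side so crossings are well defined;
consecutive polyline points closer than 1e-6 mm are merged. Profile
curvature along an isoline is the circumscribed-circle (Menger) estimate
over sliding triples, smoothed with a 5-sample moving average.

Feature points are the k strongest local curvature extrema, strength being
the peak prominence. The prominence threshold is 10% of
`max(range, max |κ|)` of the profile: thresholding against the magnitude
as well as the range prevents sampling ripple on a constant-curvature
profile (a sphere section) from qualifying as a feature. Ties break toward
smaller arc length.

The 29-point template is assembled in the canonical frame (the mesh is
re-posed via its landmarks when given, making the construction equivariant
under rigid motions): nasal tip A; midline points 1, 3, 4, 5 (the four
strongest extrema below the nose, top-down) plus the exact midpoint
2 = (1+3)/2 and points 6, 7 obtained by reflecting 1 and 2 across the
horizontal line through 3 in the XY projection and re-projecting onto the
midline profile; lateral nasal-base points E (+X) and F (−X), each the
strongest extremum on its side of the horizontal profile through A, with
exact midpoints G, H; and 17 further points on the vertical profiles
through G (5 points), H, E, F (4 each). The per-line allocation is a fixed
design choice that keeps the template dimension stable; the odd 29th point
sits on the +X medial line, so mirror-symmetry checks compare the paired
points only. Midpoint constructions are exact by definition (they may sit
marginally off-surface); template points are bound to distinct nearest
mesh vertices for use as deformation controls.

## Deviation analysis and boundary statistics

Deviation is point-to-triangle (not point-to-point — the two scans sample
the skin differently): a KD-tree prefilter proposes candidate triangles
incident to the 12 nearest reference vertices, the exact closest point on
each is computed, and the sign follows the reference face normal at the
foot point. The critical value defaults to 0.2 mm, the smallest distance
the naked eye resolves. The deformation region is the largest
edge-connected component of the super-threshold vertex set (isolated noise
blobs are suppressed); an empty set yields a flagged empty region, not an
error.

The ala-tragus plane is the total-least-squares plane through the four
named landmarks, normal oriented superiorly. `upper_distance` is the
unsigned plane distance of the boundary vertex with the largest
superior-positive signed distance (the most superior boundary point —
one of two defensible readings of "uppermost boundary", chosen and fixed
here). `lower_distance` is the minimum boundary-to-menton distance.
Laterality for the commissure ratios is measured along the tragus–tragus
axis, which makes the statistics invariant under rigid motions applied
jointly to mesh, region and landmarks; ties at the extreme projection
break toward the vertex farthest from the ipsilateral commissure.

## Laplacian deformation

Uniform weights only (`w_ij = 1/d_i`, `L = I − D⁻¹A`); cotangent weights
are deliberately not implemented — the deformation model is plain
differential-coordinate editing, with δ taken from the undeformed mesh and
no rotation re-fitting (not ARAP). Constraints are soft: the stacked
system `[L; C] V′ = [δ; w]` is solved through its normal equations with a
sparse LU factorization, per coordinate, which is deterministic and — as
the tests verify against a dense `lstsq` oracle — agrees with brute force
to 1e-8 on small meshes. Default weights: 1 for the 29 template controls,
10 for the upper-third anchors; anchors must dominate for the upper face
to stay put (anchored vertices move < 0.01 mm in the shipped
configurations). The pipeline removes template-bound vertices from the
anchor set before solving, since a vertex cannot be both control and
anchor.

## Prediction model

PCA is fit on the n × 87 matrix of flattened template displacement fields
(sample covariance, n−1 normalization; scikit-learn backend). The retained
dimension k is the smallest count reaching `variance_kept` (default 0.95)
cumulative explained variance; a variance-free cohort gives k = 0, in
which case prediction degenerates to the mean field and no network is
trained. Component signs follow a deterministic convention (largest-
magnitude entry positive).

The regressor maps the flattened pre-operative template (87) to the PCA
scores: one hidden layer of 20 sigmoidal nodes, linear output, full-batch
gradient descent with classical momentum on z-standardized inputs and
targets. Defaults: learning rate 0.01, 5 000 epochs, momentum 0.9, seeded
initialization — identical seeds give bit-identical weights. The
composition "network predicts PCA scores" (rather than raw displacements)
is a design choice for n ≪ 87 cohorts; raw-displacement regression is
available by passing the fields themselves as targets. The hidden-layer
sweep utility retrains under a shared seeded split to compare candidate
widths.

## The synthetic study conditions

Faces are height fields over an ellipsoid cap with a Gaussian nose ridge
and six perioral features (subnasal crease, two lips, labial fissure,
mentolabial crease, chin), sampled on a 71 × 56 grid (≈ 4 000 vertices)
with a triangulation whose diagonal split mirrors across the midline, so
bilateral symmetry holds exactly down to feature detection. Feature
amplitudes were chosen so the curvature-prominence ranking of the
template's k-strongest selection is stable across the cohort's parameter
range — the ladder (fissure ≳ subnasale ≳ upper lip ≳ lower lip ≫
mentolabial ≫ chin) is separated by more than the perturbation the
collapse field itself adds.

A scan pair applies an inward (−Z) collapse field with compact support
below the nose base and above the menton: a raised-cosine vertical window
times smoothstep lateral ramps, scaled by a two-dimensional latent
(depth z₁, vertical-profile gradient z₂), plus support-tapered Gaussian
vertex noise (sd 0.02 mm ≈ 1% of a 2 mm collapse). The raised-cosine
window keeps the field's own curvature (≈ 0.02 mm⁻¹ at 2 mm depth) far
below feature curvature; steeper windows were tested and rejected because
their edges masquerade as anatomical features. A consequence, stated
openly: the > 0.2 mm deviation contour sits well inside the support, so
the cohort's boundary statistics (upper ≈ 10 mm below the ala-tragus
plane, lower ≈ 7 mm above the menton, commissure ratios ≈ 0.28) describe
a more conservative envelope than a clinical cohort would show; they
satisfy the qualitative envelope (below the plane, above the menton) but
are not calibrated to clinical magnitudes.

The latent also shifts the pre-operative lip and chin amplitudes
(coupling: upper lip −0.50 z₁, lower lip −0.25 z₁ − 0.25 z₂, chin
+0.25 z₂, plus independent nuisance jitter, sd 0.05 mm). This encodes the
modelling premise that collapse severity co-varies with pre-operative
perioral morphology — precisely the premise that makes post-operative
shape predictable from a pre-operative scan at all. Cohort draws:
z₁ ~ U(0.4, 1.0) × nominal depth (every patient collapses inward, none
fully), z₂ ~ N(0, 0.15 × depth). Passing tests on these conditions show
the pipeline recovers structure it is able to represent; they do not show
that two latent factors, −Z-directed displacement, or this coupling
strength describe real tissue.

Default study sizes: 10 subjects at nominal depth 2 mm for end-to-end
leave-one-out evaluation, 200 subjects for parameter-recovery statistics;
both chosen so the complete test suite and the acceptance script run in
well under a minute each on a single CPU.

## Known limitations

- Uniform Laplacian weights distort detail on highly irregular meshes;
  the synthetic grids are near-uniform, clinical scans may not be.
- Template extraction assumes a face-like topology in canonical pose with
  exactly one nasal prominence; occlusions, facial hair or strong
  asymmetry will break the k-strongest extremum selection, and detection
  positions are quantized to the isoline sampling (one grid step).
- The reflection construction of midline points 6 and 7 doubles any
  detection drift of points 1–3 between two extractions of the same face.
- The prediction model is cohort-bound: it extrapolates only within the
  shape variation spanned by its training displacement fields.
- Per-vertex colors are carried through I/O but unused by the method.
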