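# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `footacs`, in the spirit of a methods appendix: what the
pipeline assumes, which knobs matter, and what the test suite does and does
not demonstrate.

## The coordinate-assignment model

An anatomical coordinate system (ACS) here is an origin plus orthonormal,
right-handed ML/AP/SI axes attached to one bone. The construction is
template-driven: every bone (and every joint-specific variant of the talus
and calcaneus) has a canonical left-side template oriented medial +x,
anterior +y, superior +z, and the subject bone is *temporarily* rigidly
registered to it. All geometric rules are then expressed in this aligned
frame, which is what makes them bone-generic: "most superior region" is
simply the largest-z slab.

Assumptions worth stating:

* **Rigid anatomy, comparable scale.** Registration is rotation +
  translation only. Subjects and templates are in millimetres from
  comparable imaging resolutions; allowing scale would distort the
  equal-width region extents that anchor the axes.
* **Surface is the signal.** Region centroids are computed over area-weighted
  random samples of the surface, not vertices (robust to tessellation
  density, tolerant of open meshes) and not the enclosed volume (cropped
  bones have no well-defined volume).
* **Laterality by mirroring.** Right bones are reflected across x = 0 before
  alignment; winding is reversed so outward normals survive. When the ACS is
  mapped back to a right bone's own scanner space, the frame is kept
  right-handed by negating the mirrored ML axis — ML then points medially on
  either side.

### Axis construction

With the bone aligned, each anatomical plane is divided into N equal-width
slabs (N = 3 for talus/cuneiforms/metatarsals/tibia/fibula, 5 for
navicular/cuboid, 10 for the calcaneus). Extreme-slab centroids along a
bone-specific axis give the primary axis; the centroid of a designated third
region, projected orthogonally onto the primary line, gives the secondary;
the cross product completes the triad. Axes are relabelled to ML/AP/SI,
sign-corrected so ML·(+x) > 0 and AP·(+y) > 0, and SI is recomputed as
ML × AP. If the recomputed SI points inferiorly the run is aborted with an
alignment-failure error — that configuration cannot arise from a correctly
aligned left bone.

Two under-determined details were fixed as package conventions: the primary
axis points from the low- to the high-coordinate extreme centroid (posterior
to anterior, lateral to medial, inferior to superior), and the "anchor" of
the primary line used for the secondary-axis projection is the midpoint of
the two extreme centroids (any point on the line gives the same secondary
direction; the midpoint is the symmetric choice).

### Registration

* Initialization: principal axes of 2,000 area-weighted surface samples,
  matched template-to-subject. The four sign assignments that keep the
  rotation proper are each settled with up to 25 short ICP iterations on a
  500-point subsample and the candidate with the lowest RMS wins. The
  settling step matters: with nearly equal second/third principal spreads the
  eigenvectors are noisy, and raw candidate ranking can prefer a
  180°-flipped pose. If the two largest spreads are within 2% of each other
  the axes are considered meaningless and a centroid-only translation is
  returned with a warning.
* Refinement: point-to-surface ICP — area-weighted subject samples (2,000 by
  default) matched to exact closest points on the template surface
  (KD-tree-shortlisted candidate triangles, exact point-to-triangle
  projection), absolute pose refit by Kabsch each iteration. The residual is
  non-increasing by construction. Iteration stops when the RMS improvement
  drops below 1e-5 mm or after 200 iterations. The tight stopping rule is
  deliberate: bones with nearly circular cross-sections produce shallow
  "twist" valleys in which a looser stop (1e-4 mm) can halt several degrees
  short of the minimum.
* Determinism: every sampling operation takes an explicit seed; identical
  seeds give bitwise-identical outputs, which the batch driver exposes as a
  single `--seed` flag.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `region_samples` | 20,000 | surface samples for slab centroids; Monte-Carlo centroid error ≪ 0.1 mm at this count |
| `icp_sample_count` | 2,000 | subject samples driving ICP |
| `icp_tolerance` | 1e-5 mm | RMS-improvement stopping threshold |
| `max_iterations` | 200 | ICP budget; `converged` flags an improvement-based stop |
| partial-template ratio | 0.6 | below this subject/template extent ratio, tibia/fibula/metatarsals switch to the cropped template |
| cropping warning | 0.3 | below this ratio a too-cropped warning is raised |
| vertex merge tolerance | 1e-9 mm | duplicate-vertex collapse on mesh load |

The acceptance checks and the test suite run many pipelines and therefore use
a documented desk-scale profile (10,000 region samples, 1,500 ICP samples)
wherever the quantity under test is an invariance rather than an absolute
accuracy; accuracy-critical checks use the defaults.

## Comparison metrics

Angle differences between two ACSs are computed per labelled axis as the full
direction-sensitive angle, `atan2(‖u×v‖, u·v)` — a flipped axis reads ~180°
rather than 0°, which is a genuine failure signal, and the atan2 form is
exactly zero for identical axes and well-conditioned near zero. Comparisons
are made in the shared template-aligned frame, the only frame common to bones
segmented or generated in different scanner spaces.

For the correspondence-particle analysis, each axis is projected from the
origin to its first surface intersection; on the reference shape (overall
mean) the nearest particle index is recorded, and on each target shape (group
mean) the distance from the target's own projection to the particle *with
that same index* is measured — correspondence particle k marks the same
relative anatomical location on every shape.

Group statistics are the classical one-way ANOVA (F from sums of squares, p
from the F distribution) and Tukey's HSD via the studentized-range
distribution with pooled within-group variance (Tukey–Kramer for unequal
sizes). Summary tables report mean ± sample SD (n−1); SD is 0 for a single
observation.

## The synthetic study conditions

No patient bones or population templates can ship with the package, so the
generator defines the study conditions under which everything is verified:

* **Shape family.** A superellipsoid (exponent 2.5) with per-bone semi-axes
  elongated ~2:1 along the bone's primary anatomical axis, plus two Gaussian
  surface bumps (1.8 and 1.4 mm, angular width 0.45 rad) and a 12% radius
  taper along the primary axis. The bumps sit near the primary-axis equator
  so the extreme slabs that anchor the primary axis are essentially
  untouched; they break the 180° flip about the primary axis. The taper
  breaks end-for-end flips with a ~2 mm RMS signal and — because it is
  symmetric in the two transverse coordinates and its along-primary centroid
  shift is projected out — provably adds no bias to the slab-based axis
  construction. This is the minimal family whose ACS is unambiguous.
* **Ground truth.** The canonical shape is centred on its exact area-weighted
  surface centroid; its identity frame is the true ACS and is carried through
  mirroring, posing, noise and remeshing.
* **Joint variants.** Variant templates are the default template rotated 2°
  about the ML axis. The slab construction's secondary axis partially tracks
  the aligned frame, so a variant rotation of r° surfaces as roughly r° of
  deliberate deviation from the default frame; 2° keeps that effect visible
  without consuming the recovery tolerance.
* **Individuals and populations.** Individuals jitter semi-axes by 3% and
  bump amplitudes by 0.15 mm around their group mean; group means differ by
  bump-amplitude offsets of magnitude `group_effect_scale` (default 0.5 mm).
  Populations default to 3 groups × 8 individuals with 128 correspondence
  particles at fixed parametric directions (a deterministic Fibonacci sphere),
  which gives exact correspondence by construction. Group-mean surrogates are
  generated directly rather than computed by shape averaging — statistical
  shape modelling is out of scope.
* **Segmentation twins.** A "second segmentation" of the same bone is
  emulated by star-shaped resampling to a chosen face count (rays from the
  centroid through a fresh sphere tessellation; the family is star-shaped by
  construction) followed by 0.2 mm surface-normal noise.
* **Meshes.** Icosphere subdivision 3 (642 vertices, 1,280 faces) — the
  smallest tessellation at which slab centroids are stable to ≪ 0.1 mm with
  the default sampling.

**What passing tests show — and don't.** The synthetic family has smooth,
convex-ish, star-shaped geometry with exactly known axes; real bones have
concavities, articular facets, osteophytes, and no ground-truth frame. The
tests therefore demonstrate the *internal* correctness and invariances of the
pipeline (frame validity, rigid/mirror invariance, recovery of a known frame
under noise and remeshing, agreement of the numeric kernels with brute-force
oracles), not clinical accuracy on patient anatomy. The desk-scale
segmentation-twin experiment mirrors the *qualitative* finding that two
segmentations of the same bone yield low single-digit-degree axis differences
with no group effect; its numbers are not comparable to any cohort study.

## Degenerate inputs and edge cases

* Empty extreme or interior slab → degenerate-geometry error naming the axis
  (signals pathological cropping rather than returning a silent axis).
* Extreme-slab centroids closer than 1e-6 mm, or a third point on the primary
  line → degenerate-geometry error.
* Joint-surface origin ray missing the mesh → error (open/cropped mesh).
* ANOVA/Tukey with zero pooled within-group variance → degenerate-data error,
  surfaced by the batch driver as a documented status rather than a crash.
* Unidentifiable files in a batch are skipped and logged; they never change
  the exit code.

## Known limitations

* The `.k` reader supports only `*NODE` / `*ELEMENT_SHELL` cards (quads split
  along the 1–3 diagonal); XML VTK is limited to ASCII-encoded arrays.
  Anything else fails loudly.
* Point-to-surface queries shortlist candidate triangles through a centroid
  KD-tree (k = 10); for extremely anisotropic triangles the shortlist could
  miss the true nearest triangle. The near-uniform meshes this package
  produces and consumes are far from that regime.
* `.particles` files are treated purely as point sets, never as
  ACS-assignable geometry.
* No articulated (joint) coordinate systems between bone pairs, no cartilage,
  no non-rigid registration, no image segmentation — surface meshes in,
  coordinate frames out.
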