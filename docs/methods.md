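# Methods

## Signal model and ODF reconstruction

The pipeline assumes a single-shell acquisition (one effective b-value, here
1000 s/mm², with at least one b = 0 volume; b-values under 50 s/mm² count as
b = 0 to tolerate scanner-reported near-zero values). The b = 0 reference
S(0) is the mean of all b = 0 volumes. Each volume is first smoothed with an
isotropic Gaussian of σ = 0.8 mm (converted to voxels per axis, reflect
padding so mass is conserved near edges).

The per-voxel ratio S(u)/S(0) is clipped to [δ, 1−δ] with δ = 1e-3 before
the double-log transform — the constant-solid-angle estimator requires
0 < S/S0 < 1, and magnitude noise can push individual measurements outside
that range. ln(−ln S/S0) is fitted by linear least squares in the modified
real symmetric SH basis (even orders only; ordering l ascending, m ascending;
for m < 0 the √2-scaled real part, m = 0 the real Y_l0, m > 0 the √2-scaled
imaginary part). A Laplace–Beltrami ridge with weight λ = 0.006 (penalty
l²(l+1)² per coefficient) regularizes the order-6 fit on 64 directions;
λ = 0 is allowed and then requires at least R = 28 directions.

The CSA transform is applied analytically: coefficient j of order l > 0 is
multiplied by −l(l+1) · 2π P_l(0) / (16π²) (Laplace–Beltrami eigenvalue,
Funk–Radon eigenvalue, solid-angle normalization), and the constant
coefficient is set to 1/(2√π) so the ODF integrates to exactly 1. A unit
integral is a convention — only relative ODF shape feeds the clustering —
but it is enforced consistently and verified against a numerical Funk–Radon
great-circle quadrature oracle in the tests.

Residual bootstrapping: the fit residuals in the double-log domain are
resampled with replacement (unstudentized), the fit repeated 50 times, each
replicate CSA-transformed, and the coefficient-wise mean ODF retained.
Because the CSA transform is linear, averaging before or after the transform
is equivalent; we average transformed coefficients. The resampling RNG is
seeded, so the whole pipeline is bit-reproducible for a given seed.

The diffusion tensor is fitted log-linearly (ln S/S0 = −b gᵀDg, least
squares over all shell volumes); eigenvalues are clamped at zero before the
standard normalized-variance FA. The principal eigenvector feeds the
angular-difference baseline.

## Mask refinement

Two exclusion rules clean the thalamus mask before clustering: any voxel
with CSF probability ≥ 0.05 (strict `< 0.05` keeps, mirroring the rule's
wording), and any voxel within 2.0 mm of the mask border (boundary-inclusive,
measured by a Euclidean distance transform from in-mask voxel centers to
background voxel centers, anisotropic voxel sizes respected, one virtual
background layer beyond the array edge) whose FA exceeds 0.55. Removal counts
are logged per rule; refinement that empties the mask is an error.
Idempotence holds on the phantom (re-refining changes nothing) but is not a
theorem for adversarial maps: removing voxels creates new border, and a
pathological FA map could expose new border voxels above threshold.

## Clustering

Features per in-mask voxel: position in mm (voxel center through the image
affine — so anisotropic 2×2×2.5 mm voxels are honored) and the 28 mean ODF
coefficients multiplied by S_ODF = 55. The squared clustering distance is
the α-weighted sum of squared block distances with α = 0.5; this equals
plain squared-Euclidean k-means on [√α·pos, √(1−α)·S_ODF·c], so Lloyd
centroid updates are exact minimizers and the objective is provably
non-increasing (asserted at every iteration). S_ODF = 55 places ODF
distances inside the interval of spatial distances (on the default phantom:
median scaled ODF distance ≈ 6.6 mm-equivalents against spatial distances
spanning 2–39 mm); it is a configuration constant, not re-estimated per
subject.

Initialization runs 5000 position-only k-means by default (the acceptance
experiments use 200, which on ~1800 voxels leaves the averaged centroids
stable to well under a voxel). Each run is independently seeded and uses
k-means++ seeding — with uniform random-point seeding most individual runs
end in degenerate local optima (two tight clusters merged, one split) and
the average inherits that noise. Runs are aligned to the lowest-inertia run
by optimal one-to-one assignment before averaging; the best run is a
canonical, data-determined reference, whereas aligning to an arbitrary first
run makes the averaged topology depend on the master seed. The ODF block of
each initial centroid is the mean scaled ODF vector over the voxels in the
±1-voxel neighborhood of the averaged spatial centroid (nearest voxel as
fallback).

Lloyd iterations stop at an assignment fixpoint or `max_iter` (300). An
empty cluster is reseeded at the point farthest from its centroid (logged).
Final labels are deterministic: clusters sorted by descending size, ties by
lexicographic centroid order; all cross-run comparisons nevertheless go
through optimal label matching.

The angular-difference baseline replaces the ODF distance with
(6 · arccos|e1_v · d_C|)², the antipodally symmetric angle between the
voxel's principal tensor eigenvector and the cluster direction, scaled so
its range (≈ 0–9.4) is commensurate with mm-scale spatial distances. The
cluster direction updates as the principal eigenvector of the mean dyadic
(outer-product) tensor of member vectors — the correct axial average (the
vector mean of {+v, −v} would vanish). This update maximizes the mean
squared cosine rather than minimizing the mean squared arccos, so the AD
objective is not guaranteed monotone; iteration stops on assignment
fixpoint with the same iteration cap.

## Evaluation

Label matching maximizes total voxel overlap on the k×k contingency table
(Hungarian assignment), verified against exhaustive permutation search for
k ≤ 4. Cluster contours for the modified Hausdorff distance are 6-connectivity
boundary voxels mapped to mm; the metric is the Dubuisson–Jain max of the two
directed mean nearest-neighbor distances. Majority voting aligns each input
labeling to a reference by label matching and takes the per-voxel modal
label, ties broken to the lowest label with the tie count logged; it assumes
pre-aligned (co-registered) inputs, which the phantom provides natively.
Centroid border distances interpolate the mask's border-distance map
trilinearly at the (non-integer) centroid voxel coordinate. The hemispheric
symmetry test is a two-sided Wilcoxon signed-rank with Pratt handling of
zero differences; the degenerate all-identical case returns p = 1 directly
(no effect), since rank methods are undefined there.

## Synthetic phantom

The phantom emulates the target acquisition: 24×24×18 grid of 2×2×2.5 mm
voxels, 64 unique gradient directions (deterministic Fibonacci hemisphere —
antipodal symmetry makes a hemisphere sufficient) at b = 1000 s/mm² plus one
b = 0 volume, S0 = 1000, Rician noise with σ = S0/SNR (two independent
Gaussian channels), default SNR 30 referenced to S0.

Geometry: an oblate ellipsoid (semi-axes 23×21×9 mm, 1800 in-mask voxels —
thalamus-scale and deliberately flat, since the thalamus is roughly 20 mm
high for 30 mm length) partitioned into a central spherical core holding 1/7
of the volume plus six equal-angle azimuthal wedges. This layout keeps every
region spatially compact and separable — the working assumption of the
method. Two properties of the geometry matter for the data-driven
initialization and were checked explicitly: a partition in which all regions
meet on the central axis leaves spatial position uninformative there (a
central cluster then absorbs a mixed core and caps truth recovery around
ARI 0.7), and at z semi-axis 10 mm the position-only k-means optimum splits
the central column into two stacked cells (inertia within 0.4% of the
center-plus-ring layout), both of which disagree with any compact 7-region
anatomy; the chosen flatness makes the planar center-plus-ring layout the
clear optimum.

Tissue model: every region shares moderate-anisotropy tensor eigenvalues
(1.0, 0.5, 0.5)·10⁻³ mm²/s (FA ≈ 0.41, gray-matter-like, safely under the
0.55 refinement threshold). Wedge fibers lie in-plane at 30° steps; the core
fiber is axial, orthogonal to every wedge. Region 1 carries a 50/50
perpendicular crossing by default: in a crossing voxel the tensor is
degenerate (λ1 = λ2) and its principal eigenvector is noise-driven, which is
exactly the regime separating ODF features from the angular-difference
baseline — with single fibers only, the tensor carries the same information
and the comparison is vacuous. Contamination rims of 2 mm line the border:
CSF-like (isotropic 3·10⁻³ mm²/s, CSF probability 0.9) on the +x side and
internal-capsule-like ((1.7, 0.2, 0.2)·10⁻³, FA ≈ 0.86) on the −x side.

What the phantom does not emulate: partial-volume mixing at region borders,
spatially varying S0 or coil profiles, motion/eddy distortions, susceptibility
artifacts, anatomical thalamus shape, or inter-subject variability. Passing
tests therefore demonstrate correctness of the numerics and robust recovery
of compact orientation-distinct structure at realistic noise — not clinical
performance on patient data.

## Problem sizes in the standard experiments

Scan–rescan reproducibility runs the full pipeline (smoothing, FA/CSF
refinement, 50-sample bootstrap ODFs, 200-run initialization, combined
k-means) on both noise realizations of 3 independently seeded pairs and
averages per-cluster Dice after optimal matching; truth recovery uses a
rim-free phantom and reports the adjusted Rand index against the generative
regions. Both apply one pipeline configuration to the two scans of a pair,
as two acquisitions of one subject would be processed identically.

## Known limitations

- k is fixed (default 7); no model selection is provided.
- S_ODF and the AD scale are constants; data with very different diffusivity
  or voxel dimensions may need recalibration of both.
- The ODF normalization discards the isotropic magnitude: regions differing
  only in mean diffusivity are invisible to the ODF features.
- Majority voting requires externally co-registered inputs; no registration
  is implemented.
- The AD baseline's objective can in principle cycle (no monotonicity
  guarantee); in practice it reaches a fixpoint within a few iterations.
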