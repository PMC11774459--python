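# Methods

## Problem setting

A landmark pair is a matched anatomical point — here a vessel bifurcation —
identified in both images of a same-patient CT pair. Pairs are used to
compute target registration error (TRE): project the image-1 landmark
through a registration's deformation vector field (DVF) and measure the 3-D
Euclidean distance to the matched image-2 landmark. The value of such a
dataset hinges on how precisely the two members of a pair designate the
same anatomical point; `vesselmarks` automates that designation for
similar-diameter ("type 1") bifurcations and provides the geometric
definition for high-ratio ("type 2") ones.

## Coordinate conventions

Volumes carry spacing (mm/voxel), origin (mm) and an orthonormal direction
matrix; `world = orientation · diag(spacing) · index + origin`, matching the
NIfTI affine. Indices are 0-based and continuous; patches use half-open
voxel ranges snapped to the source grid so coincident voxels copy exactly.
Landmarks are always stored and serialised in world millimetres, never voxel
indices, so files remain valid across volumes with different spacings.
Resampling is trilinear for images and nearest-neighbour for masks;
out-of-bounds patch voxels are filled with −1000 HU (air), neutral under the
−160 HU window floor.

## Sphere growing

The refinement pipeline per landmark: extract a 100 mm cubic patch centred
on the current estimate, resample to 0.7 mm isotropic, clamp to
[−160, 240] HU, then iterate the sphere. The opposing force

u(X) = (1 − I_norm(X)) · ∇I(X) / (‖∇I(X)‖ + ε)

uses the window-normalised intensity I_norm ∈ [0, 1] and the σ = 1 voxel
Gaussian-smoothed gradient, so ‖u‖ ≤ 1 everywhere, u ≈ 0 deep inside bright
vessels (I_norm → 1) and u points inward across the vessel wall. Center and
radius updates average u, and its radial component, over a support shell of
half-width 1.5 voxels around the current sphere surface. The shell is
sampled at continuous points (Fibonacci directions at three radii,
≥ max(64, 4πr²) directions) with trilinear force interpolation: sub-voxel
center updates need smooth force estimates, and voxel rasterisation of the
shell would quantise them. Restricting the support to a local shell is
essential — averaging over the whole patch would let distant anatomy
dominate and the radial term would grow without bound with distance.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| λ₁ | 0.2 | – | center-update gain |
| λ₂ | 0.3 | – | radius-update gain |
| f_int | 0.15 | voxels/iter | see below |
| r₀ | 0.5 | voxels | initial radius |
| n_iter | 80 | – | see below |
| shell half-width | 1.5 | voxels | support thickness |
| radius cap | 25 | voxels | divergence bound |
| drift cap | 15 | voxels | divergence bound |
| window | −160, 240 | HU | vessel contrast |
| working spacing | 0.7 | mm | isotropic resample |

Because ‖u‖ ≤ 1, the inward radial force is bounded by λ₂, so an
equilibrium exists only for f_int < λ₂. The default f_int = λ₂/2 places the
equilibrium where the mean inward opposition is half its maximum — i.e. the
sphere border comes to rest on the half-intensity vessel surface; larger
ratios bias the converged radius outward, smaller ones inward. The
iteration budget must cover (r_target − r₀)/f_int plus settling; 80
iterations reach abdominal vessel radii up to ~8 working voxels with
margin. The center settles more slowly than the radius (its drive shrinks
as the configuration becomes symmetric), which is why tests that demand
sub-half-voxel center accuracy run 200 iterations.

### Divergence and the substrate ladder

A run is diverged when the radius exceeds its cap, the center drifts more
than the drift cap from the seed, the center (or the entire support shell)
leaves the patch, or the radius is still in free expansion — final step
> f_int/2, meaning the sphere never met opposing structure — when the
budget ends. The last condition is what makes structure-free patches fail
loudly instead of silently reporting the seed. Diverged runs are retried on
an automatically generated vessel mask (vesselness + region growing from
the seed), then on a user-supplied manual segmentation; masks are treated
as {0, 1} images with an identity window. If every substrate diverges the
landmark is returned unrefined and flagged.

## Vesselness fallback

The automatic mask uses the standard multiscale Frangi line measure on the
gamma-normalised Gaussian Hessian (eigenvalues |λ1| ≤ |λ2| ≤ |λ3|; bright
tubes need λ2, λ3 < 0), with α = β = 0.5 and the structure sensitivity set
per scale to half the maximum Hessian Frobenius norm. Scales default to
0.7–2.8 mm, spanning the thin end of contrast-enhanced abdominal vessels at
the working resolution. The image mean is removed before filtering because
the sampled derivative kernels have a small DC leak that would otherwise
break invariance to constant intensity shifts. Region growing takes the
26-connected component of {vesselness ≥ 0.05} containing the seed
(tolerating a seed a couple of voxels off the centerline); an empty
component signals fallback failure.

## Digital phantoms

`PhantomTransform` composes a rotation (random axis, angle uniform in
0–50°), an isotropic scaling uniform in [0.9, 1.1] — both about the patch
center — and a per-axis sinusoidal displacement applied in target space:

p′ = p_a + A ⊙ sin(2π p_a / P + φ),  p_a = pivot + s·R·(p − pivot).

The forward point map is closed-form and exact, which is what makes the
phantom study's ground truth trustworthy. Sinusoid amplitude and period are
unconstrained by any physical model; defaults (amplitude ≤ 5 mm, period
60–120 mm) give centimetre-scale smooth deformation while satisfying the
per-axis invertibility bound |A·2π/P| < 0.9, under which the sinusoidal
part is a contraction and the inverse is computed by fixed-point iteration
to 10⁻⁶ mm. Image 2 is synthesised by backward warping with that inverse
(trilinear), avoiding the hole/overlap artifacts of forward splatting.

The synthetic vessel phantom rasterises straight tube segments with a soft
one-voxel edge, combined by maximum, over a uniform soft-tissue background
(−80 HU), with optional Gaussian noise and Y-junction builders whose
junction coordinates are exact by construction. Branch diameters drive the
type-1/type-2 label through the inclusive ≥ 2.5 diameter-ratio rule.

What the phantoms do not emulate: curved and tapering vessels, surrounding
organs and overlapping anatomy, partial-volume and beam-hardening effects,
contrast-timing variation, and biomechanically plausible deformation.
Passing the phantom study therefore demonstrates the internal consistency
and deformation-robustness of the refinement under known ground truth, not
its accuracy on clinical images.

## Consistency study

`landmark_consistency_study` mirrors the phantom protocol end to end: per
case, a randomised Y-junction phantom (trunk radius 2.5–4 mm, branch radius
2–3.5 mm, branch angle 25–50°, random azimuth; 50 mm extent at 1 mm grid —
sizes chosen so a 50-case study runs in about a minute) is refined on
image 1; a seeded random transform produces image 2 and the exact ground
truth; refinement on image 2 is scored against the forward-mapped image-1
result. Cases whose clean-image run diverges or needs a mask substrate are
counted as failures, not silently dropped into the error average.

## Evaluation statistics

Error summaries report mean ± sample standard deviation (n−1 denominator)
of 3-D distances, with an opt-in hard outlier cutoff (default 5 mm) and an
explicit exclusion count — no iterative trimming. The paired t-test uses
the closed-form statistic t = mean(d)/(sd(d)/√n) with n−1 degrees of
freedom and a two-sided p-value; zero-variance differences raise instead of
returning a meaningless infinity. DVFs hold displacements in mm sampled at
image-1 world coordinates; landmarks outside the DVF grid are flagged
rather than extrapolated. The type-2 point is located by bisection on the
trilinearly interpolated mask at the 0.5 level (tolerance 10⁻³ mm), making
it insensitive to the polyline's sampling density.

## Numerical notes and limitations

* The growing loop is free of randomness: identical patch, seed and config
  give bit-identical trajectories.
* On constant-radius tube phantoms the distance transform is flat along the
  vessel axis, so "the widest point" is a plateau; junction tests score
  distance to the plateau set, and the converged center can sit ~1 voxel
  into the junction pocket relative to the tube-axis intersection. This
  offset is common to both images of a pair and cancels in pair consistency.
* The converged sphere radius at a junction exceeds the inscribed-sphere
  radius of the tubes (shell sectors inside the branch lumens feel no
  opposition); radius accuracy claims are therefore made on ball phantoms.
* Landmarks closer than half a patch to the volume border are refined on a
  partially air-filled patch; severe truncation can push runs to the mask
  fallback.
* Vessels thinner than ~2 working voxels in radius give weak, partial-volume
  borders; the phantom generator flags landmarks on sub-voxel tubes.
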