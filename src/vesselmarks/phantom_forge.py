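"""Synthetic vessel phantoms and digital deformation transforms.

Two roles:

* ``make_vessel_phantom`` rasterises bright tubular segments (contrast-
  enhanced vessels) into a CT-like volume with known junction landmarks, so
  every downstream algorithm can be scored against exact ground truth.
* ``PhantomTransform`` composes a random rotation (0-50 degrees about a random
  axis), an up/down scaling within 10 % and a sinusoidal displacement field
  into a deformation with an exact closed-form forward point map.  Warping a
  patch with it simulates a second clinical image whose ground-truth
  deformation is known, which is how the landmark-refinement accuracy is
  estimated without real repeat scans.

Forward map:  p' = p_a + A * sin(2 pi p_a / P + phi),
              p_a = pivot + s * R (p - pivot)

The per-axis constraint |A_i * 2 pi / P_i| < 0.9 makes the sinusoidal part a
contraction, so the inverse (needed for backward image warping) is obtained by
fixed-point iteration to 1e-6 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .image_core import AIR_HU, BifurcationType, Landmark, Volume, extract_patch
from .landmark_eval import classify_bifurcation

__all__ = [
    "PhantomTransform",
    "TubeSegment",
    "VesselPhantomSpec",
    "make_vessel_phantom",
    "y_junction_spec",
    "sample_phantom_transform",
    "map_point_forward",
    "map_point_inverse",
    "apply_transform_to_volume",
    "degrade_image",
    "make_observer_patch_pair",
]

#: paper-stated phantom patch side (mm) and observer patch side / offset
PHANTOM_PATCH_MM = 200.0
OBSERVER_PATCH_MM = 100.0
OBSERVER_MAX_OFFSET_SLICES = 3


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


@dataclass(frozen=True)
class PhantomTransform:
    """Rotation + scaling about a pivot, then a sinusoidal displacement."""

    rotation_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    rotation_angle_deg: float = 0.0
    scale: float = 1.0
    sinus_amplitude_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sinus_period_mm: np.ndarray = field(default_factory=lambda: np.full(3, 100.0))
    sinus_phase_rad: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pivot_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("rotation_axis", "sinus_amplitude_mm", "sinus_period_mm",
                     "sinus_phase_rad", "pivot_mm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(np.linalg.norm(self.rotation_axis) - 1.0) > 1e-9:
            object.__setattr__(
                self, "rotation_axis", self.rotation_axis / np.linalg.norm(self.rotation_axis)
            )
        if not 0.0 <= self.rotation_angle_deg <= 50.0:
            raise ValueError("rotation angle must lie in [0, 50] degrees")
        if not 0.9 <= self.scale <= 1.1:
            raise ValueError("scale must lie in [0.9, 1.1]")
        lip = np.abs(self.sinus_amplitude_mm) * 2.0 * np.pi / self.sinus_period_mm
        if np.any(lip >= 0.9):
            raise ValueError("sinusoid violates invertibility (|A*2pi/P| must be < 0.9)")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return _rotation_matrix(self.rotation_axis, self.rotation_angle_deg)

    def to_dict(self) -> dict:
        return {
            "rotation_axis": self.rotation_axis.tolist(),
            "rotation_angle_deg": float(self.rotation_angle_deg),
            "scale": float(self.scale),
            "sinus_amplitude_mm": self.sinus_amplitude_mm.tolist(),
            "sinus_period_mm": self.sinus_period_mm.tolist(),
            "sinus_phase_rad": self.sinus_phase_rad.tolist(),
            "pivot_mm": self.pivot_mm.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTransform":
        return cls(**{k: d[k] for k in d})


def map_point_forward(p, T: PhantomTransform) -> np.ndarray:
    """Exact forward map of world-mm point(s) through the transform."""
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    pts = np.atleast_2d(p)
    affine = T.pivot_mm + T.scale * (pts - T.pivot_mm) @ T.rotation_matrix.T
    out = affine + T.sinus_amplitude_mm * np.sin(
        2.0 * np.pi * affine / T.sinus_period_mm + T.sinus_phase_rad
    )
    return out[0] if single else out


def map_point_inverse(
    q, T: PhantomTransform, tol_mm: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Numeric inverse: fixed point on the sinusoid, then the exact affine
    inverse.  Converges because the sinusoidal part is a contraction."""
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    pts = np.atleast_2d(q)
    pa = pts.copy()
    for _ in range(max_iter):
        nxt = pts - T.sinus_amplitude_mm * np.sin(
            2.0 * np.pi * pa / T.sinus_period_mm + T.sinus_phase_rad
        )
        if np.max(np.abs(nxt - pa)) < tol_mm:
            pa = nxt
            break
        pa = nxt
    else:
        raise RuntimeError("sinusoid inversion did not converge (invariant violated?)")
    p = T.pivot_mm + (pa - T.pivot_mm) @ T.rotation_matrix / T.scale
    return p[0] if single else p


def sample_phantom_transform(
    rng,
    pivot_mm=(0.0, 0.0, 0.0),
    max_amplitude_mm: float = 5.0,
    min_period_mm: float = 60.0,
    max_period_mm: float = 120.0,
) -> PhantomTransform:
    """Draw a random transform: axis uniform on the sphere, angle U[0, 50]
    degrees, scale U[0.9, 1.1], sinusoid within the invertibility bound."""
    rng = np.random.default_rng(rng)
    v = rng.normal(size=3)
    axis = v / np.linalg.norm(v)
    angle = rng.uniform(0.0, 50.0)
    scale = rng.uniform(0.9, 1.1)
    period = rng.uniform(min_period_mm, max_period_mm, size=3)
    amp_cap = np.minimum(max_amplitude_mm, 0.85 * period / (2.0 * np.pi))
    amplitude = rng.uniform(0.0, amp_cap)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
    return PhantomTransform(axis, angle, scale, amplitude, period, phase,
                            np.asarray(pivot_mm, dtype=float))


def apply_transform_to_volume(vol: Volume, T: PhantomTransform, fill: float = AIR_HU) -> Volume:
    """Warp a volume with the transform (backward warping, trilinear).

    The output shares the input grid; the voxel at world q takes the source
    intensity at T^-1(q), so a structure at p appears at map_point_forward(p).
    """
    idx = np.indices(vol.shape).reshape(3, -1).T.astype(float)
    world = vol.voxel_to_world(idx)
    src = vol.world_to_voxel(map_point_inverse(world, T))
    out = ndimage.map_coordinates(
        vol.voxels, src.T, order=1, mode="constant", cval=fill
    ).reshape(vol.shape)
    return vol.with_voxels(out)


def degrade_image(vol: Volume, noise_sigma_hu: float = 0.0, smooth_sigma_vox: float = 0.0,
                  rng=None) -> Volume:
    """Simulate image-quality degradation: Gaussian smoothing followed by
    additive Gaussian noise (seeded)."""
    if noise_sigma_hu < 0 or smooth_sigma_vox < 0:
        raise ValueError("sigmas must be >= 0")
    out = vol.voxels
    if smooth_sigma_vox > 0:
        out = ndimage.gaussian_filter(out, smooth_sigma_vox)
    if noise_sigma_hu > 0:
        rng = np.random.default_rng(rng)
        out = out + rng.normal(0.0, noise_sigma_hu, size=vol.shape)
    return vol.with_voxels(np.array(out, dtype=float))


# ---------------------------------------------------------------------------
# Synthetic vessel phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeSegment:
    """Straight vessel segment: endpoints (world mm), radius (mm), peak HU."""

    start_mm: np.ndarray
    end_mm: np.ndarray
    radius_mm: float
    intensity_hu: float = 240.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_mm", np.asarray(self.start_mm, dtype=float))
        object.__setattr__(self, "end_mm", np.asarray(self.end_mm, dtype=float))
        if self.radius_mm <= 0:
            raise ValueError("tube radius must be positive")


@dataclass(frozen=True)
class JunctionSpec:
    """Ground-truth bifurcation: world position plus branch diameters."""

    position_mm: np.ndarray
    d_large_mm: float
    d_small_mm: float
    id: str = "J0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "position_mm", np.asarray(self.position_mm, dtype=float))

    @property
    def bifurcation_type(self) -> BifurcationType:
        return classify_bifurcation(self.d_large_mm, self.d_small_mm)


@dataclass(frozen=True)
class VesselPhantomSpec:
    """Declarative phantom: tube segments, junctions, background and noise."""

    segments: Sequence[TubeSegment] = ()
    junctions: Sequence[JunctionSpec] = ()
    background_hu: float = -80.0
    noise_sigma_hu: float = 0.0
    extent_mm: float = 60.0


def _segment_distance(points: np.ndarray, seg: TubeSegment) -> np.ndarray:
    d = seg.end_mm - seg.start_mm
    L2 = float(d @ d)
    if L2 == 0:
        return np.linalg.norm(points - seg.start_mm, axis=1)
    t = np.clip((points - seg.start_mm) @ d / L2, 0.0, 1.0)
    proj = seg.start_mm + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def make_vessel_phantom(spec: VesselPhantomSpec, spacing_mm: float = 1.0, rng=None):
    """Rasterise the phantom and return ``(Volume, landmarks)``.

    Each tube contributes a smooth profile: full intensity inside its radius
    with a soft one-voxel edge; overlapping tubes combine by maximum.  The
    junction landmarks carry the ground-truth positions and the diameter-ratio
    bifurcation type; tubes thinner than the voxel size flag their landmarks.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    n = int(round(spec.extent_mm / spacing_mm)) + 1
    vol = Volume(
        np.full((n, n, n), float(spec.background_hu)),
        np.full(3, float(spacing_mm)),
        np.zeros(3),
        np.eye(3),
    )
    if spec.segments:
        idx = np.indices(vol.shape).reshape(3, -1).T.astype(float)
        pts = vol.voxel_to_world(idx)
        acc = np.zeros(pts.shape[0])
        for seg in spec.segments:
            dist = _segment_distance(pts, seg)
            profile = np.clip((seg.radius_mm + 0.5 * spacing_mm - dist) / spacing_mm, 0.0, 1.0)
            np.maximum(acc, profile * (seg.intensity_hu - spec.background_hu), out=acc)
        vol.voxels += acc.reshape(vol.shape)
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(rng)
        vol.voxels += rng.normal(0.0, spec.noise_sigma_hu, size=vol.shape)

    min_radius = min((s.radius_mm for s in spec.segments), default=np.inf)
    landmarks = [
        Landmark(
            j.position_mm,
            j.id,
            bifurcation_type=j.bifurcation_type,
            flagged=bool(min_radius < spacing_mm),
        )
        for j in spec.junctions
    ]
    return vol, landmarks


def y_junction_spec(
    junction_mm=(30.0, 30.0, 30.0),
    trunk_radius_mm: float = 3.0,
    branch_radius_mm: float = 3.0,
    branch_angle_deg: float = 35.0,
    length_mm: float = 25.0,
    intensity_hu: float = 240.0,
    background_hu: float = -80.0,
    noise_sigma_hu: float = 0.0,
    extent_mm: float = 60.0,
    azimuth_deg: float = 0.0,
) -> VesselPhantomSpec:
    """Canonical Y-junction: a trunk along -z meeting two symmetric branches.

    The junction point is the tube-axis intersection; branch diameters give
    the type-1 / type-2 label via the >= 2.5 diameter-ratio rule.
    """
    j = np.asarray(junction_mm, dtype=float)
    a = np.radians(branch_angle_deg)
    az = np.radians(azimuth_deg)
    u = np.array([np.cos(az), np.sin(az), 0.0])
    b1 = np.sin(a) * u + np.cos(a) * np.array([0, 0, 1.0])
    b2 = -np.sin(a) * u + np.cos(a) * np.array([0, 0, 1.0])
    segments = (
        TubeSegment(j - np.array([0, 0, length_mm]), j, trunk_radius_mm, intensity_hu),
        TubeSegment(j, j + length_mm * b1, branch_radius_mm, intensity_hu),
        TubeSegment(j, j + length_mm * b2, branch_radius_mm, intensity_hu),
    )
    junction = JunctionSpec(j, 2 * max(trunk_radius_mm, branch_radius_mm),
                            2 * min(trunk_radius_mm, branch_radius_mm))
    return VesselPhantomSpec(segments, (junction,), background_hu, noise_sigma_hu, extent_mm)


# ---------------------------------------------------------------------------
# Landmark-consistency phantom study
# ---------------------------------------------------------------------------

def landmark_consistency_study(
    n_cases: int = 50,
    seed: int = 0,
    growth_config=None,
    spacing_mm: float = 1.0,
):
    """Estimate sphere-growing landmark precision on deformed digital phantoms.

    For each case a Y-junction phantom is built with a randomised geometry,
    the bifurcation is refined by sphere growing on image 1, the phantom is
    warped by a random seeded transform (rotation 0-50 degrees, scale within
    10 %, invertible sinusoid) to synthesise image 2, and the sphere is grown
    again there.  The exact forward point map provides the ground-truth
    position of the image-1 result in image 2; the per-case error is the
    distance between that ground truth and the image-2 sphere-grown position.

    Returns ``(errors_mm, n_diverged)``.
    """
    from .image_core import BifurcationType
    from .sphere_growing import GrowthConfig, refine_landmark

    cfg = growth_config or GrowthConfig(patch_size_mm=50.0, n_iter=80)
    errors = []
    n_diverged = 0
    for k in range(n_cases):
        rng = np.random.default_rng((seed + k) % 2**31)
        spec = y_junction_spec(
            azimuth_deg=rng.uniform(0.0, 360.0),
            branch_angle_deg=rng.uniform(25.0, 50.0),
            trunk_radius_mm=rng.uniform(2.5, 4.0),
            branch_radius_mm=rng.uniform(2.0, 3.5),
        )
        vol, (lm,) = make_vessel_phantom(spec, spacing_mm=spacing_mm)
        start = lm.moved_to(lm.position, bifurcation_type=BifurcationType.TYPE1)
        ref1, tr1 = refine_landmark(vol, start, cfg)

        pivot = vol.voxel_to_world((np.array(vol.shape) - 1) / 2.0)
        T = sample_phantom_transform(rng, pivot_mm=pivot)
        vol2 = apply_transform_to_volume(vol, T)
        seed2 = map_point_forward(lm.position, T)
        start2 = lm.moved_to(seed2, bifurcation_type=BifurcationType.TYPE1)
        ref2, tr2 = refine_landmark(vol2, start2, cfg)

        from .image_core import Substrate

        if (tr1.diverged or tr2.diverged
                or ref1.substrate != Substrate.IMAGE or ref2.substrate != Substrate.IMAGE):
            n_diverged += 1
            continue
        truth2 = map_point_forward(ref1.position, T)
        errors.append(float(np.linalg.norm(ref2.position - truth2)))
    return errors, n_diverged


# ---------------------------------------------------------------------------
# Observer-study patch preparation
# ---------------------------------------------------------------------------

def make_observer_patch_pair(
    vol1: Volume,
    vol2: Volume,
    lm1: Landmark,
    lm2: Landmark,
    size_mm: float = OBSERVER_PATCH_MM,
    max_offset_slices: int = OBSERVER_MAX_OFFSET_SLICES,
    rng=None,
):
    """Prepare an inter-observer patch pair around a landmark pair.

    Patch 1 is centered on the image-1 landmark (its position is exported);
    patch 2 is centered on the image-2 landmark shifted by a random integer
    offset of at most ``max_offset_slices`` voxels per axis, and the landmark
    position inside it is withheld from the observer but returned for scoring.
    """
    rng = np.random.default_rng(rng)
    offset_vox = rng.integers(-max_offset_slices, max_offset_slices + 1, size=3)
    center2 = vol2.voxel_to_world(vol2.world_to_voxel(lm2.position) + offset_vox)
    patch1 = extract_patch(vol1, lm1.position, size_mm)
    patch2 = extract_patch(vol2, center2, size_mm)
    return patch1, patch2, lm2.position.copy()
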