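"""Volume container, coordinate conventions and basic image operations.

A :class:`Volume` is a 3-D scalar grid with full geometric metadata: voxel
spacing (mm), world origin (mm) and an orthonormal direction matrix.  World
coordinates follow the NIfTI convention

    world = orientation @ diag(spacing) @ index + origin

with 0-based continuous indices.  All landmark positions in this package are
stored in world millimetres, never voxel indices, so that they remain portable
across volumes with heterogeneous spacings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "VectorField",
    "Landmark",
    "BifurcationType",
    "Substrate",
    "resample_isotropic",
    "hu_window",
    "smoothed_gradient",
    "extract_patch",
    "overwrite_organ_intensities",
    "read_nifti",
    "write_nifti",
    "DEFAULT_ISO_SPACING_MM",
    "DEFAULT_WINDOW_HU",
    "AIR_HU",
]

#: Isotropic resampling target used for sphere growing (mm).
DEFAULT_ISO_SPACING_MM = 0.7
#: HU window applied before sphere growing to enhance vessel contrast.
DEFAULT_WINDOW_HU = (-160.0, 240.0)
#: Fill value for out-of-bounds patch voxels (air).
AIR_HU = -1000.0

#: Tolerance for declaring two volume geometries identical (mm).
GEOMETRY_ATOL_MM = 1e-4


class BifurcationType(str, enum.Enum):
    """Bifurcation taxonomy: type 1 joins similar-diameter vessels and is
    refined automatically; type 2 joins vessels whose diameter ratio is >= 2.5
    and is placed manually at the small-vessel-centerline / large-vessel-surface
    intersection."""

    TYPE1 = "type1"
    TYPE2 = "type2"
    UNREFINED = "unrefined"


class Substrate(str, enum.Enum):
    """Image substrate on which a sphere-growing run converged."""

    IMAGE = "image"
    AUTO_MASK = "auto_mask"
    MANUAL_MASK = "manual_mask"
    NONE = "none"


@dataclass(frozen=True)
class Landmark:
    """A world-mm point with identity and refinement bookkeeping."""

    position: np.ndarray
    id: str
    bifurcation_type: BifurcationType = BifurcationType.UNREFINED
    flagged: bool = False
    substrate: Substrate = Substrate.NONE

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("landmark position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "bifurcation_type", BifurcationType(self.bifurcation_type))
        object.__setattr__(self, "substrate", Substrate(self.substrate))

    def moved_to(self, position: np.ndarray, **changes) -> "Landmark":
        return replace(self, position=np.asarray(position, dtype=float), **changes)


def _check_geometry(spacing, origin, orientation):
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    orientation = np.asarray(orientation, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError("spacing must be a positive 3-vector")
    if origin.shape != (3,) or not np.all(np.isfinite(origin)):
        raise ValueError("origin must be a finite 3-vector")
    if orientation.shape != (3, 3):
        raise ValueError("orientation must be a 3x3 matrix")
    if abs(abs(np.linalg.det(orientation)) - 1.0) > 1e-6 or not np.allclose(
        orientation @ orientation.T, np.eye(3), atol=1e-6
    ):
        raise ValueError("orientation must be orthonormal (|det| = 1)")
    return spacing, origin, orientation


@dataclass
class Volume:
    """3-D scalar grid (HU or mask values) with world geometry."""

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing, self.origin, self.orientation = _check_geometry(
            self.spacing, self.origin, self.orientation
        )

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 NIfTI-style affine mapping index -> world mm."""
        aff = np.eye(4)
        aff[:3, :3] = self.orientation @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, index) -> np.ndarray:
        """Map continuous 0-based indices to world mm (exact affine)."""
        index = np.asarray(index, dtype=float)
        return index @ (self.orientation @ np.diag(self.spacing)).T + self.origin

    def world_to_voxel(self, point) -> np.ndarray:
        """Exact affine inverse of :meth:`voxel_to_world`."""
        point = np.asarray(point, dtype=float)
        inv = np.diag(1.0 / self.spacing) @ self.orientation.T
        return (point - self.origin) @ inv.T

    def is_isotropic(self, atol: float = 1e-6) -> bool:
        return bool(np.ptp(self.spacing) <= atol)

    def same_geometry_as(self, other: "Volume", atol: float = GEOMETRY_ATOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=atol)
        )

    # -- sampling -----------------------------------------------------------
    def sample_world(self, points, order: int = 1, cval: float = AIR_HU) -> np.ndarray:
        """Trilinear (order=1) or nearest (order=0) sampling at world-mm points."""
        idx = self.world_to_voxel(np.atleast_2d(points))
        return ndimage.map_coordinates(
            self.voxels, idx.T, order=order, mode="constant", cval=cval
        )

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        return Volume(voxels, self.spacing.copy(), self.origin.copy(), self.orientation.copy())


@dataclass
class VectorField:
    """Per-voxel 3-vectors sharing the geometry of their source Volume.

    ``vectors`` has shape (*grid, 3); components are expressed along the
    volume's index axes (world axes when the orientation is identity).
    """

    vectors: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vector components must be finite")
        self.spacing, self.origin, self.orientation = _check_geometry(
            self.spacing, self.origin, self.orientation
        )

    @property
    def shape(self) -> tuple:
        return self.vectors.shape[:3]

    def sample_index(self, index_points) -> np.ndarray:
        """Trilinear interpolation of the field at continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(index_points, dtype=float))
        out = np.empty((pts.shape[0], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.vectors[..., c], pts.T, order=1, mode="constant", cval=0.0
            )
        return out

    def sample_world(self, points) -> np.ndarray:
        vol = Volume(np.zeros((2, 2, 2)), self.spacing, self.origin, self.orientation)
        return self.sample_index(vol.world_to_voxel(np.atleast_2d(points)))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample_isotropic(
    vol: Volume, target_spacing: float = DEFAULT_ISO_SPACING_MM, order: int = 1
) -> Volume:
    """Resample a volume onto an isotropic grid of ``target_spacing`` mm.

    The world-space extent is preserved to within one voxel; intensities are
    interpolated trilinearly (``order=1``; use 0 for binary masks).
    """
    if not np.isscalar(target_spacing) or target_spacing <= 0:
        raise ValueError("target_spacing must be a positive scalar")
    if any(n < 2 for n in vol.shape):
        raise ValueError("cannot resample a volume with a single-voxel axis")
    t = float(target_spacing)
    new_shape = tuple(
        max(2, int(round((n - 1) * s / t)) + 1) for n, s in zip(vol.shape, vol.spacing)
    )
    # new index i maps onto old index i * t / s along each axis
    scale = t / vol.spacing
    grids = np.meshgrid(*[np.arange(n) * sc for n, sc in zip(new_shape, scale)], indexing="ij")
    voxels = ndimage.map_coordinates(
        vol.voxels, np.stack([g.ravel() for g in grids]), order=order, mode="nearest"
    ).reshape(new_shape)
    return Volume(voxels, np.full(3, t), vol.origin.copy(), vol.orientation.copy())


def hu_window(vol: Volume, lo: float = DEFAULT_WINDOW_HU[0], hi: float = DEFAULT_WINDOW_HU[1]) -> Volume:
    """Clamp intensities to [lo, hi] HU; geometry unchanged. Idempotent."""
    if lo >= hi:
        raise ValueError("window requires lo < hi")
    return vol.with_voxels(np.clip(vol.voxels, lo, hi))


def smoothed_gradient(vol: Volume, sigma: float = 1.0) -> VectorField:
    """Gaussian-smoothed central-difference gradient, in HU/mm.

    ``sigma`` is in voxels; the gradient is taken per index axis and divided by
    the spacing, so components are along the volume's index axes in HU/mm.
    Adding a constant to the image leaves the output unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    smoothed = ndimage.gaussian_filter(vol.voxels, sigma) if sigma > 0 else vol.voxels
    grads = np.gradient(smoothed, *vol.spacing)
    return VectorField(np.stack(grads, axis=-1), vol.spacing, vol.origin, vol.orientation)


def extract_patch(vol: Volume, center, size, fill: float = AIR_HU) -> Volume:
    """Extract an axis-aligned patch of the given physical size (mm per axis).

    The patch grid is snapped to the source grid (integer index shift), so
    coincident voxels copy exactly; out-of-bounds voxels take ``fill``.
    """
    center = np.asarray(center, dtype=float)
    size = np.broadcast_to(np.asarray(size, dtype=float), (3,))
    if not np.all(np.isfinite(center)):
        raise ValueError("patch center must be finite")
    if np.any(size <= 0):
        raise ValueError("patch size must be positive")
    c_idx = vol.world_to_voxel(center)
    extent_idx = size / vol.spacing
    if np.any(c_idx < -extent_idx / 2) or np.any(
        c_idx > np.array(vol.shape) - 1 + extent_idx / 2
    ):
        raise ValueError("patch center lies outside the volume by more than size/2")
    n = np.maximum(2, np.round(size / vol.spacing).astype(int) + 1)
    start = np.round(c_idx - (n - 1) / 2.0).astype(int)
    patch = np.full(tuple(n), float(fill))
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + n, vol.shape)
    if np.all(src_hi > src_lo):
        dst_lo = src_lo - start
        dst_hi = src_hi - start
        patch[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = vol.voxels[
            src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
        ]
    origin = vol.voxel_to_world(start)
    return Volume(patch, vol.spacing.copy(), origin, vol.orientation.copy())


def overwrite_organ_intensities(vol: Volume, masks, constants) -> Volume:
    """Set voxels inside each binary mask to an organ-specific HU constant.

    Later masks take precedence on overlap; all other voxels are unchanged.
    """
    masks = list(masks)
    constants = list(constants)
    if len(masks) != len(constants):
        raise ValueError("need one constant per mask")
    out = vol.voxels.copy()
    for mask, value in zip(masks, constants):
        if not mask.same_geometry_as(vol):
            raise ValueError("mask geometry does not match the volume")
        out[mask.voxels > 0.5] = float(value)
    return vol.with_voxels(out)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path) -> Volume:
    """Load a NIfTI file as a Volume, decomposing its affine into
    spacing / origin / orientation."""
    img = nib.load(str(path))
    aff = np.asarray(img.affine, dtype=float)
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    orientation = lin / spacing
    return Volume(np.asarray(img.get_fdata(), dtype=float), spacing, aff[:3, 3], orientation)


def write_nifti(vol: Volume, path) -> None:
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float64), vol.affine), str(path))


def read_nifti_vector_field(path) -> VectorField:
    """Load a 4-D NIfTI (last axis length 3) as a displacement field in mm."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 5:  # SimpleITK-style (x, y, z, 1, 3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("expected a 4-D NIfTI with 3 components on the last axis")
    aff = np.asarray(img.affine, dtype=float)
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    return VectorField(data, spacing, aff[:3, 3], lin / spacing)


def write_nifti_vector_field(field: VectorField, path) -> None:
    aff = np.eye(4)
    aff[:3, :3] = field.orientation @ np.diag(field.spacing)
    aff[:3, 3] = field.origin
    nib.save(nib.Nifti1Image(field.vectors.astype(np.float64), aff), str(path))
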