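"""Voxel-volume I/O, reorientation, binarization and spherical VOI extraction.

Conventions
-----------
``VoxelVolume.voxels`` is indexed ``[z, x, y]`` where

* axis 0 (``z``) is the proximodistal long axis of the bone after
  reorientation (``+z`` is the canonical distal pole),
* axis 1 (``x``) is anteroposterior with anterior at **low** x indices
  (so sagittal images render with anterior on the left),
* axis 2 (``y``) is mediolateral.

3-vectors everywhere in the package are physical ``(x, y, z)`` tuples in
voxel units; voxel ``(iz, ix, iy)`` sits at position ``(ix, iy, iz)``.
Binary volumes store bone as 255 and background as 0 in uint8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile
from scipy import ndimage

from ._geometry import rotation_between, unit

BONE = 255
BACKGROUND = 0


class VolumeError(ValueError):
    """Raised on invalid volumes, VOIs or I/O contracts."""


@dataclass
class VoxelVolume:
    """A 3D scalar (gray) or binary voxel grid with isotropic spacing."""

    voxels: np.ndarray
    spacing_um: float
    side: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise VolumeError("voxels must be a non-empty 3D array")
        if not self.spacing_um > 0:
            raise VolumeError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def is_binary(self) -> bool:
        vals = np.unique(self.voxels)
        return bool(np.isin(vals, (BACKGROUND, BONE)).all())

    def bone_mask(self) -> np.ndarray:
        return self.voxels == BONE

    def validate_binary(self) -> None:
        if not self.is_binary:
            raise VolumeError("volume is not binary (values must be {0, 255})")


@dataclass(frozen=True)
class SphericalVOI:
    """A spherical volume of interest, addressed in ``(iz, ix, iy)`` indices."""

    center: tuple[float, float, float]
    diameter: float
    role: Literal["orientation", "morphometry"] = "orientation"
    side: Literal["medial", "lateral"] | None = None

    def __post_init__(self) -> None:
        if self.diameter < 10:
            raise VolumeError("VOI diameter must be at least 10 voxels")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


# ---------------------------------------------------------------------------
# I/O


def write_stack(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF stack plus a key/value sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = volume.voxels
    if arr.dtype not in (np.uint8, np.uint16):
        raise VolumeError(f"only 8/16-bit stacks are supported, got {arr.dtype}")
    tifffile.imwrite(path, arr)
    meta_lines = [f"spacing_um={volume.spacing_um!r}"]
    if volume.side is not None:
        meta_lines.append(f"side={volume.side}")
    for key, value in volume.metadata.items():
        meta_lines.append(f"{key}={value!r}")
    sidecar(path).write_text("\n".join(meta_lines) + "\n")
    return path


def sidecar(path: str | Path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".meta.txt")


def _parse_sidecar(path: Path) -> dict:
    meta: dict = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, raw = line.partition("=")
        try:
            import ast

            meta[key] = ast.literal_eval(raw)
        except (ValueError, SyntaxError):
            meta[key] = raw
    return meta


def read_stack(path: str | Path, spacing_um: float | None = None) -> VoxelVolume:
    """Read a TIFF stack; spacing comes from the sidecar or the argument."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise VolumeError(f"ragged stack: inconsistent slice shapes {shapes}")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    meta = _parse_sidecar(sidecar(path)) if sidecar(path).exists() else {}
    spacing = spacing_um if spacing_um is not None else meta.pop("spacing_um", None)
    if spacing is None:
        raise VolumeError("voxel spacing missing: pass spacing_um or provide a sidecar")
    side = meta.pop("side", None)
    return VoxelVolume(arr, float(spacing), side=side, metadata=meta)


# ---------------------------------------------------------------------------
# Long-axis estimation and reorientation


def estimate_long_axis(volume: VoxelVolume, degeneracy_tol: float = 0.05) -> np.ndarray:
    """Principal inertia axis of the bone voxels as a unit (x, y, z) vector.

    The axis of largest positional variance is canonicalized to a positive z
    component.  If the two largest inertia moments differ by less than
    ``degeneracy_tol`` (relative), the direction is ill-defined and an error
    is raised rather than returning an arbitrary axis.
    """
    volume.validate_binary()
    idx = np.argwhere(volume.bone_mask())
    if idx.size == 0:
        raise VolumeError("empty volume: no bone voxels")
    # index order (iz, ix, iy) -> physical (x, y, z)
    pts = idx[:, [1, 2, 0]].astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[2] <= 0:
        raise VolumeError("degenerate bone point cloud")
    if (evals[2] - evals[1]) / evals[2] < degeneracy_tol:
        raise VolumeError(
            "long axis is degenerate: the two largest inertia moments are "
            f"within {degeneracy_tol:.0%} of each other"
        )
    axis = evecs[:, 2]
    if axis[2] < 0:
        axis = -axis
    return axis


def reorient(volume: VoxelVolume, target_axis: np.ndarray, order: int = 1) -> VoxelVolume:
    """Rotate the volume so that ``target_axis`` maps onto +z.

    Linear interpolation with re-binarization at half level for binary
    inputs; the rotation is about the volume center.
    """
    import warnings

    axis = unit(target_axis)
    binary = volume.is_binary
    R = rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    if np.allclose(R, np.eye(3)):
        return VoxelVolume(
            volume.voxels.copy(), volume.spacing_um, side=volume.side,
            metadata=dict(volume.metadata),
        )
    if binary:
        # content outside the inscribed ball can rotate out of the grid
        zz, xx, yy = np.ogrid[: volume.shape[0], : volume.shape[1], : volume.shape[2]]
        c = (np.array(volume.shape) - 1) / 2.0
        r2 = (min(volume.shape) / 2.0) ** 2
        outside = ((zz - c[0]) ** 2 + (xx - c[1]) ** 2 + (yy - c[2]) ** 2) > r2
        frac = np.count_nonzero(volume.bone_mask() & outside) / max(
            1, np.count_nonzero(volume.bone_mask())
        )
        if frac > 0.01:
            warnings.warn(
                f"{frac:.0%} of bone voxels lie outside the inscribed ball and "
                "may be clipped by the rotation; voxel-count preservation only "
                "holds for contained structures",
                stacklevel=2,
            )
    # index (iz, ix, iy) <-> physical (x, y, z): permutation P
    P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)  # phys = P @ idx
    M_idx = P.T @ R @ P  # rotation acting on index vectors
    M_inv = M_idx.T
    center = (np.array(volume.shape, dtype=float) - 1) / 2.0
    offset = center - M_inv @ center
    src = volume.voxels.astype(np.float32)
    out = ndimage.affine_transform(src, M_inv, offset=offset, order=order, mode="constant", cval=0.0)
    if binary:
        out = np.where(out >= BONE / 2.0, BONE, BACKGROUND).astype(np.uint8)
    else:
        out = out.astype(volume.voxels.dtype)
    meta = dict(volume.metadata)
    meta["reoriented_from_axis"] = tuple(np.round(axis, 6))
    return VoxelVolume(out, volume.spacing_um, side=volume.side, metadata=meta)


# ---------------------------------------------------------------------------
# Gradient-based binarization (simplified ray-casting variant)


def binarize_gradient(
    gray: VoxelVolume, ray_step: int = 1, min_contrast: float | None = None
) -> VoxelVolume:
    """Binarize a gray volume from gray-level *gradients*, not absolute values.

    Along axis-aligned rays (cast along all three axes), edges are located
    where the gray-level difference between neighboring voxels reaches
    ``min_contrast``; each edge contributes the half-maximum midpoint
    between the plateau levels on its two sides.  The pooled median of
    those midpoints is the cut level, which makes the segmentation
    invariant to global additive brightness shifts.  ``ray_step``
    subsamples the ray grid used to estimate the cut.
    """
    arr = gray.voxels.astype(float)
    if min_contrast is None:
        spread = float(arr.max() - arr.min())
        if spread == 0:
            raise VolumeError("no edges: constant gray volume")
        min_contrast = spread / 4.0
    if ray_step < 1:
        raise VolumeError("ray_step must be >= 1")

    midpoints: list[float] = []
    for axis in range(3):
        rays = np.moveaxis(arr, axis, 0)[:, ::ray_step, ::ray_step]
        diffs = np.diff(rays, axis=0)
        n_along = rays.shape[0]
        edge_cols = np.argwhere(np.any(np.abs(diffs) >= min_contrast, axis=0))
        for ix, iy in edge_cols:
            ray = rays[:, ix, iy]
            d = diffs[:, ix, iy]
            cuts = np.where(np.abs(d) >= min_contrast)[0]
            # plateau segments between consecutive edges
            bounds = np.concatenate([[0], cuts + 1, [n_along]])
            levels = [
                float(np.median(ray[a:b])) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
            ]
            if len(levels) < 2:
                continue
            lo, hi = min(levels), max(levels)
            if hi - lo >= min_contrast:
                midpoints.append((lo + hi) / 2.0)
    if not midpoints:
        raise VolumeError("no edges: gray volume has insufficient contrast")
    cut = float(np.median(midpoints))
    out = np.where(arr >= cut, BONE, BACKGROUND).astype(np.uint8)
    meta = dict(gray.metadata)
    meta["binarize_cut_level"] = cut
    return VoxelVolume(out, gray.spacing_um, side=gray.side, metadata=meta)


# ---------------------------------------------------------------------------
# VOI extraction and sagittal slicing


def sphere_mask(shape: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within ``radius`` of ``center``."""
    zz, xx, yy = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (xx - center[1]) ** 2 + (yy - center[2]) ** 2
    return d2 <= radius**2


def extract_voi(volume: VoxelVolume, voi: SphericalVOI) -> tuple[VoxelVolume, np.ndarray]:
    """Crop the bounding cube of a spherical VOI; return (cube, sphere mask)."""
    c = np.asarray(voi.center, dtype=float)
    r = voi.radius
    shape = np.array(volume.shape)
    if np.any(c - r < 0) or np.any(c + r > shape - 1):
        raise VolumeError("VOI sphere touches or exits the volume boundary")
    lo = np.floor(c - r).astype(int)
    hi = np.ceil(c + r).astype(int) + 1
    cube = volume.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    mask = sphere_mask(cube.shape, c - lo, r)
    meta = dict(volume.metadata)
    meta.update(voi_center=tuple(c), voi_diameter=voi.diameter, voi_role=voi.role)
    out = VoxelVolume(cube.copy(), volume.spacing_um, side=voi.side or volume.side, metadata=meta)
    return out, mask


def middle_sagittal_slices(
    voi_volume: VoxelVolume, n: int = 10, mask: np.ndarray | None = None
) -> list[np.ndarray]:
    """The ``n`` sagittal (x-z) slices centered on the VOI mediolateral midplane.

    Each slice is a 2D array indexed ``[z, x]``.  If ``mask`` is given the
    matching mask slices are applied by the caller; this function only
    selects slice indices (centered window, ties toward the low side).
    """
    ny = voi_volume.shape[2]
    if ny < n:
        raise VolumeError(f"VOI mediolateral extent {ny} < requested {n} slices")
    start = (ny - n) // 2
    return [voi_volume.voxels[:, :, start + k] for k in range(n)]


def middle_sagittal_mask_slices(mask: np.ndarray, n: int = 10) -> list[np.ndarray]:
    """Mask counterpart of :func:`middle_sagittal_slices`."""
    ny = mask.shape[2]
    if ny < n:
        raise VolumeError(f"mask mediolateral extent {ny} < requested {n} slices")
    start = (ny - n) // 2
    return [mask[:, :, start + k] for k in range(n)]
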