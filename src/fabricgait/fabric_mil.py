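"""Mean-intercept-length (MIL) fabric analysis in 2D and 3D.

2D: test-line grids are swept over sagittal (x-z) slices at angular step
omega; lengths and bone/background interface crossings are pooled across
slices before division, and an ellipse fit of ``1/MIL(theta)^2`` yields the
in-plane principal trabecular orientation angle alpha.

3D: MIL is sampled along a quasi-uniform hemisphere of directions with
parallel line grids clipped to the spherical VOI mask; a symmetric
positive-definite tensor ``H`` is least-squares fitted to
``n . H n = 1 / MIL(n)^2`` and its eigensystem gives the PTO axis and the
degree of anisotropy DA = MIL1/MIL3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._geometry import fibonacci_hemisphere, orthonormal_frame
from .volume_io import VolumeError, VoxelVolume


class FabricError(ValueError):
    """Raised on unusable MIL inputs or indefinite fabric fits."""


# ---------------------------------------------------------------------------
# 2D profile


@dataclass
class MILProfile2D:
    """MIL as a function of test-line angle theta in [0, 180), step omega."""

    angles_deg: np.ndarray
    mil: np.ndarray  # voxel units unless spacing applied by caller
    counts: np.ndarray  # interface crossings pooled over slices
    lengths: np.ndarray  # total in-mask test-line length per angle (voxels)
    capped: np.ndarray  # angles where no crossing occurred (MIL capped)

    def valid(self) -> np.ndarray:
        return (~self.capped) & (self.counts > 0)


_SMOOTH_SIGMA = 0.8  # voxels of anti-alias smoothing before edge detection


def mil_profile_2d(
    slices: list[np.ndarray],
    line_spacing: int = 1,
    omega: float = 1.0,
    masks: list[np.ndarray] | None = None,
    step: float = 1.0,
    smooth_sigma: float = _SMOOTH_SIGMA,
) -> MILProfile2D:
    """Pooled 2D MIL profile over a set of sagittal slices.

    ``slices`` are ``[z, x]`` binary images (bone truthy).  For each
    test-line angle theta (measured from the +x axis toward +z) a grid of
    parallel lines is sampled directly on the images at ``step`` voxel
    increments; interface crossings are detected where the bilinearly
    interpolated, lightly smoothed (``smooth_sigma``) bone indicator
    crosses its half level.  The smoothing anti-aliases the voxel
    staircase, whose axis-aligned edges would otherwise anchor the MIL
    extrema to the image axes.  Lengths and crossings are summed across
    all lines and slices before division.
    """
    if not slices:
        raise FabricError("need at least one slice")
    if line_spacing < 1:
        raise FabricError("line_spacing must be >= 1 voxel")
    n_ang = round(180.0 / omega)
    if abs(n_ang * omega - 180.0) > 1e-9 or n_ang < 2:
        raise FabricError("omega must divide 180")
    stack = np.stack([np.asarray(s).astype(bool) for s in slices])
    if masks is None:
        mask = np.ones_like(stack, dtype=bool)
    else:
        mask = np.stack([np.asarray(m).astype(bool) for m in masks])
        if mask.shape != stack.shape:
            raise FabricError("masks must match slice shapes")
    in_bone = stack & mask
    if not np.any(in_bone) or np.all(stack[mask]):
        raise FabricError("no bone/background interface: slices are single-phase")

    n_sl, nz, nx = stack.shape
    smooth = np.empty((n_sl, nz, nx))
    for s in range(n_sl):
        smooth[s] = ndimage.gaussian_filter(stack[s].astype(float), smooth_sigma)
    mask_flat = mask.reshape(n_sl, -1)
    cz, cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    half_diag = float(np.hypot(nz, nx)) / 2.0 + 1.0
    t = np.arange(-half_diag, half_diag + step / 2, step)
    # fixed sub-voxel offset decorrelates the line grid from the voxel grid
    offs = np.arange(-half_diag, half_diag + line_spacing / 2, line_spacing) + 0.382

    angles = np.arange(n_ang) * omega
    mil = np.empty(n_ang)
    counts = np.zeros(n_ang, dtype=int)
    lengths = np.zeros(n_ang)
    capped = np.zeros(n_ang, dtype=bool)
    for k, theta in enumerate(angles):
        th = np.radians(theta)
        ux, uz = np.cos(th), np.sin(th)  # line direction in (x, z)
        px, pz = -uz, ux  # perpendicular
        x = cx + offs[:, None] * px + t[None, :] * ux
        z = cz + offs[:, None] * pz + t[None, :] * uz
        inside = (x >= 0) & (x <= nx - 1) & (z >= 0) & (z <= nz - 1)
        ix = np.clip(np.rint(x).astype(np.int64), 0, nx - 1)
        iz = np.clip(np.rint(z).astype(np.int64), 0, nz - 1)
        flat = iz * nx + ix
        coords = [z.ravel(), x.ravel()]
        total_len = 0.0
        total_cross = 0
        for s in range(n_sl):
            v = ndimage.map_coordinates(smooth[s], coords, order=1, cval=0.0).reshape(z.shape)
            m = mask_flat[s][flat] & inside
            both = m[:, 1:] & m[:, :-1]
            straddle = (v[:, 1:] - 0.5) * (v[:, :-1] - 0.5) < 0
            total_cross += int(np.count_nonzero(both & straddle))
            total_len += float(np.count_nonzero(m)) * step
        lengths[k] = total_len
        counts[k] = total_cross
        if total_cross == 0:
            capped[k] = True
            mil[k] = total_len  # capped at total line length, flagged
        else:
            mil[k] = total_len / total_cross
    return MILProfile2D(angles, mil, counts, lengths, capped)


@dataclass
class Orientation2D:
    """Sagittal-plane PTO: alpha from the transverse (x) reference line."""

    alpha_deg: float
    anisotropy_2d: float
    stable: bool
    residual: float = 0.0


def pto_2d(profile: MILProfile2D, instability_ratio: float = 1.05) -> Orientation2D:
    """Ellipse fit of the polar MIL profile; returns the major-axis angle.

    Fits ``1/MIL^2 = a + b cos 2t + c sin 2t`` by least squares over valid
    angles.  ``alpha`` is the direction of largest MIL measured from the
    transverse (x) axis toward the long (z) axis, in [0, 180); vertical
    struts (parallel to the long axis) give alpha = 90.  Profiles with
    in-plane anisotropy below ``instability_ratio`` are flagged unstable.
    """
    ok = profile.valid()
    if np.count_nonzero(ok) < 3:
        raise FabricError("profile has too few valid angles for an ellipse fit")
    t = np.radians(profile.angles_deg[ok])
    y = 1.0 / profile.mil[ok] ** 2
    X = np.column_stack([np.ones_like(t), np.cos(2 * t), np.sin(2 * t)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = coef
    resid = float(np.sqrt(np.mean((X @ coef - y) ** 2)) / max(np.mean(y), 1e-300))
    amp = float(np.hypot(b, c))
    lam_min = a - amp  # direction of largest MIL
    lam_max = a + amp
    if lam_max <= 0:
        raise FabricError("indefinite 2D fabric fit (non-positive MIL ellipse)")
    # lam_min <= 0 happens for perfectly straight struts (MIL diverges along
    # them): the ellipse degenerates and anisotropy is unbounded
    anis = float(np.sqrt(lam_max / lam_min)) if lam_min > 0 else float("inf")
    # 1/MIL^2 is minimized where a + amp*cos(2t - phase) is minimal:
    # 2t = phase + pi, phase = atan2(c, b)
    alpha = (np.degrees(np.arctan2(c, b)) + 180.0) / 2.0 % 180.0
    stable = anis >= instability_ratio
    if not stable:
        # orientation meaningless; keep the fitted value but flag it
        pass
    return Orientation2D(float(alpha), anis, stable, resid)


# ---------------------------------------------------------------------------
# 3D direction sampling


def mil_directions_3d(
    voi: VoxelVolume,
    mask: np.ndarray,
    n_directions: int = 257,
    line_spacing: float = 2.0,
    seed: int = 0,
    step: float = 1.0,
    max_dropped_frac: float = 0.10,
) -> list[tuple[np.ndarray, float]]:
    """Per-direction MIL over a quasi-uniform hemisphere inside a sphere mask.

    For each direction a parallel grid of test lines (spacing
    ``line_spacing`` with a seeded sub-voxel jitter) is clipped to the mask;
    samples are taken every ``step`` voxels and nearest-neighbor classified.
    Directions with zero crossings are dropped; more than
    ``max_dropped_frac`` dropped directions raises an error.
    """
    if n_directions < 6:
        raise FabricError("need at least 6 directions")
    voi.validate_binary()
    bone = voi.bone_mask()
    in_bone = bone & mask
    n_mask = int(np.count_nonzero(mask))
    if n_mask == 0:
        raise VolumeError("empty VOI mask")
    n_bone = int(np.count_nonzero(in_bone))
    if n_bone == 0 or n_bone == n_mask:
        raise FabricError("mask is single-phase: no bone/background interface")

    rng = np.random.default_rng(seed)
    shape = np.array(voi.shape)
    center_idx = (shape - 1) / 2.0
    radius = float(min(shape)) / 2.0
    dirs = fibonacci_hemisphere(n_directions)
    t = np.arange(-radius, radius + step / 2, step)
    smooth = ndimage.gaussian_filter(bone.astype(float), _SMOOTH_SIGMA)

    results: list[tuple[np.ndarray, float]] = []
    dropped = 0
    for u in dirs:
        _, v, w = orthonormal_frame(u)
        offs = np.arange(-radius, radius + line_spacing / 2, line_spacing)
        ja = rng.uniform(-0.5, 0.5)
        jb = rng.uniform(-0.5, 0.5)
        aa, bb = np.meshgrid(offs + ja, offs + jb, indexing="ij")
        origins = aa.ravel()[:, None] * v + bb.ravel()[:, None] * w  # (L, 3) xyz
        # points (L, T, 3) in physical xyz, then to (iz, ix, iy) indices
        pts = origins[:, None, :] + t[None, :, None] * u[None, None, :]
        pts_idx = np.empty_like(pts)
        pts_idx[..., 0] = pts[..., 2] + center_idx[0]  # z
        pts_idx[..., 1] = pts[..., 0] + center_idx[1]  # x
        pts_idx[..., 2] = pts[..., 1] + center_idx[2]  # y
        ii = np.rint(pts_idx).astype(np.int64)
        inside = np.all((ii >= 0) & (ii < shape), axis=-1)
        ii_c = np.clip(ii, 0, shape - 1)
        flat = (ii_c[..., 0] * shape[1] + ii_c[..., 1]) * shape[2] + ii_c[..., 2]
        m = mask.ravel()[flat] & inside
        vals = ndimage.map_coordinates(
            smooth,
            [pts_idx[..., 0].ravel(), pts_idx[..., 1].ravel(), pts_idx[..., 2].ravel()],
            order=1,
            cval=0.0,
        ).reshape(pts_idx.shape[:2])
        both = m[:, 1:] & m[:, :-1]
        straddle = (vals[:, 1:] - 0.5) * (vals[:, :-1] - 0.5) < 0
        crossings = int(np.count_nonzero(both & straddle))
        length = float(np.count_nonzero(m)) * step
        if crossings == 0 or length == 0:
            dropped += 1
            continue
        results.append((u.copy(), length / crossings))
    if dropped > max_dropped_frac * n_directions:
        raise FabricError(
            f"VOI unusable: {dropped}/{n_directions} directions had no crossings"
        )
    return results


# ---------------------------------------------------------------------------
# Fabric tensor fit


@dataclass
class FabricResult:
    """MIL fabric tensor eigensystem, PTO axis and degree of anisotropy."""

    tensor: np.ndarray  # H, symmetric positive definite, n.H.n = 1/MIL(n)^2
    eigenvalues: np.ndarray  # h1 <= h2 <= h3
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    mil_axes: np.ndarray  # MILi = 1/sqrt(hi), descending
    pto: "object"  # AxisOnSphere of the largest-MIL eigenvector
    da: float
    residual: float
    n_samples: int = 0
    metadata: dict = field(default_factory=dict)


def fit_fabric(samples: list[tuple[np.ndarray, float]]) -> FabricResult:
    """Least-squares MIL-ellipsoid fit ``n . H n = 1/MIL(n)^2``.

    Requires at least 6 well-spread directions.  Raises on indefinite fits
    and reports the relative RMS residual.
    """
    from .orientation_stats import AxisOnSphere

    if len(samples) < 6:
        raise FabricError("need at least 6 (direction, MIL) samples")
    dirs = np.array([d for d, _ in samples], dtype=float)
    mils = np.array([m for _, m in samples], dtype=float)
    if np.any(mils <= 0):
        raise FabricError("MIL values must be positive")
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    x, y, z = dirs.T
    X = np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z])
    target = 1.0 / mils**2
    if np.linalg.matrix_rank(X) < 6:
        raise FabricError("directions are not well-spread (rank-deficient fit)")
    coef, *_ = np.linalg.lstsq(X, target, rcond=None)
    H = np.array(
        [
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ]
    )
    resid = float(np.sqrt(np.mean((X @ coef - target) ** 2)) / np.mean(target))
    evals, evecs = np.linalg.eigh(H)
    if evals[0] <= 0:
        raise FabricError(
            f"indefinite fabric fit: eigenvalues {evals}, relative residual {resid:.3g}"
        )
    mil_axes = 1.0 / np.sqrt(evals)  # descending MIL1 >= MIL2 >= MIL3
    da = float(mil_axes[0] / mil_axes[2])
    pto = AxisOnSphere.from_vector(evecs[:, 0])
    return FabricResult(
        tensor=H,
        eigenvalues=evals,
        eigenvectors=evecs,
        mil_axes=mil_axes,
        pto=pto,
        da=da,
        residual=resid,
        n_samples=len(samples),
    )


def fabric_from_voi(
    voi: VoxelVolume,
    mask: np.ndarray,
    n_directions: int = 257,
    line_spacing: float = 2.0,
    seed: int = 0,
) -> FabricResult:
    """Convenience chain: 3D MIL sampling then the tensor fit."""
    samples = mil_directions_3d(voi, mask, n_directions, line_spacing, seed)
    result = fit_fabric(samples)
    result.metadata["n_directions_requested"] = n_directions
    result.metadata["n_directions_used"] = len(samples)
    return result


def alpha_from_axis(axis_vector: np.ndarray) -> float:
    """Sagittal-plane alpha (deg from transverse x line) of a 3D axis."""
    v = np.asarray(axis_vector, dtype=float)
    return float(np.degrees(np.arctan2(v[2], v[0])) % 180.0)
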