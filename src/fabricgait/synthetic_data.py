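"""Synthetic voxel volumes and gait trials with exact ground truth.

Every generator is a pure function of its spec plus seed.  Ground-truth
quantities (fabric axis, BV/TV, strut thickness, Euler characteristic,
windowed mean ankle angle) are exact by construction and stored in the
returned object's metadata; downstream estimators never see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._geometry import orthonormal_frame, rotation_between, unit
from .volume_io import BACKGROUND, BONE, VolumeError, VoxelVolume

DEFAULT_SPACING_UM = 32.8  # typical microCT resolution for distal-tibia work


class SpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# Rod lattices


@dataclass(frozen=True)
class RodLatticeSpec:
    """Jittered grid of cylindrical struts with one dominant fabric axis."""

    shape: tuple[int, int, int] = (96, 96, 96)
    rod_radius: float = 2.0
    spacing: float = 16.0
    primary_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    secondary_fill: float = 0.0
    jitter_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rod_radius < 1:
            raise SpecError("rod_radius must be >= 1 voxel")
        if not self.spacing > 2 * self.rod_radius:
            raise SpecError("spacing must exceed the rod diameter")
        if not 0 <= self.secondary_fill <= 1:
            raise SpecError("secondary_fill must be in [0, 1]")
        if abs(np.linalg.norm(self.primary_axis) - 1.0) > 1e-6:
            raise SpecError("primary_axis must be a unit vector")


def _rod_family_mask(
    coords: tuple[np.ndarray, np.ndarray, np.ndarray],
    axis: np.ndarray,
    spacing: float,
    radius: float,
    jitter_sd: float,
    rng: np.random.Generator,
    keep_fraction: float = 1.0,
) -> np.ndarray:
    """Union of cylinders along ``axis`` on a jittered square grid.

    For each voxel the 3x3 neighborhood of grid cells in the plane
    perpendicular to the axis is checked, which is exact as long as
    ``|jitter| + radius < spacing`` (enforced by clipping the jitter).
    """
    x, y, z = coords
    _, e1, e2 = orthonormal_frame(axis)
    u = (x * e1[0] + y * e1[1] + z * e1[2]).astype(np.float32)
    v = (x * e2[0] + y * e2[1] + z * e2[2]).astype(np.float32)
    iu = np.round(u / spacing).astype(np.int64)
    iv = np.round(v / spacing).astype(np.int64)
    iu_min, iu_max = int(iu.min()) - 1, int(iu.max()) + 1
    iv_min, iv_max = int(iv.min()) - 1, int(iv.max()) + 1
    nu = iu_max - iu_min + 1
    nv = iv_max - iv_min + 1
    jitter_cap = max(0.0, (spacing - 2 * radius) / 2.0 - 0.5)
    jit = rng.normal(0.0, jitter_sd, size=(nu, nv, 2)).astype(np.float32)
    np.clip(jit, -jitter_cap, jitter_cap, out=jit)
    keep = (
        np.ones((nu, nv), dtype=bool)
        if keep_fraction >= 1.0
        else rng.random((nu, nv)) < keep_fraction
    )
    out = np.zeros(u.shape, dtype=bool)
    r2 = np.float32(radius * radius)
    reach = np.float32(radius + jitter_cap + 1e-3)
    sp = np.float32(spacing)
    for du in (-1, 0, 1):
        for dv in (-1, 0, 1):
            # cheap band prefilter before the (expensive) jitter gather
            near = np.abs(u - (iu + du) * sp) <= reach
            near &= np.abs(v - (iv + dv) * sp) <= reach
            if not near.any():
                continue
            sel = np.nonzero(near.ravel())[0]
            gi = iu.ravel()[sel] + du - iu_min
            gj = iv.ravel()[sel] + dv - iv_min
            cu = (gi + iu_min) * sp + jit[gi, gj, 0]
            cv = (gj + iv_min) * sp + jit[gi, gj, 1]
            hit = (u.ravel()[sel] - cu) ** 2 + (v.ravel()[sel] - cv) ** 2 <= r2
            hit &= keep[gi, gj]
            flat = out.ravel()
            flat[sel[hit]] = True
    return out


def make_rod_lattice(spec: RodLatticeSpec, spacing_um: float = DEFAULT_SPACING_UM) -> VoxelVolume:
    """Binary rod-lattice volume whose dominant fabric axis is ``primary_axis``."""
    if min(spec.shape) < spec.spacing:
        raise SpecError("shape too small to contain one full spacing period")
    rng = np.random.default_rng(spec.seed)
    nz, nx, ny = spec.shape
    iz, ix, iy = np.meshgrid(
        np.arange(nz, dtype=np.float32),
        np.arange(nx, dtype=np.float32),
        np.arange(ny, dtype=np.float32),
        indexing="ij",
    )
    coords = (ix, iy, iz)  # physical (x, y, z)
    axis = unit(np.asarray(spec.primary_axis))
    bone = _rod_family_mask(coords, axis, spec.spacing, spec.rod_radius, spec.jitter_sd, rng)
    if spec.secondary_fill > 0:
        _, e1, e2 = orthonormal_frame(axis)
        for cross_axis in (e1, e2):
            bone |= _rod_family_mask(
                coords,
                cross_axis,
                spec.spacing,
                spec.rod_radius,
                spec.jitter_sd,
                rng,
                keep_fraction=spec.secondary_fill,
            )
    vox = np.where(bone, BONE, BACKGROUND).astype(np.uint8)
    bvtv = float(bone.sum()) / bone.size
    meta = {
        "truth_axis": tuple(np.round(axis, 9)),
        "truth_tb_th_voxels": 2.0 * spec.rod_radius,
        "truth_bvtv": bvtv,
        "generator": "rod_lattice",
        "seed": spec.seed,
    }
    return VoxelVolume(vox, spacing_um, metadata=meta)


# ---------------------------------------------------------------------------
# Anisotropic Gaussian random fields


def make_anisotropic_field(
    shape: tuple[int, int, int],
    axis: Sequence[float],
    elongation: float,
    bvtv_target: float,
    corr_length: float,
    seed: int = 0,
    spacing_um: float = DEFAULT_SPACING_UM,
) -> VoxelVolume:
    """Thresholded anisotropic Gaussian random field at an exact BV/TV.

    White noise is filtered in the Fourier domain with a Gaussian transfer
    function whose covariance is stretched by ``elongation`` along ``axis``
    (``elongation = 1`` is the isotropic control), then thresholded at the
    empirical quantile matching ``bvtv_target``, which hits the target up to
    voxel discreteness.
    """
    if not 0 < bvtv_target < 1:
        raise SpecError("bvtv_target must be in (0, 1)")
    if elongation < 1:
        raise SpecError("elongation must be >= 1")
    if corr_length <= 0:
        raise SpecError("corr_length must be positive")
    a = unit(np.asarray(axis, dtype=float))
    rng = np.random.default_rng(seed)
    nz, nx, ny = shape
    white = rng.standard_normal(shape)
    fz = np.fft.fftfreq(nz)[:, None, None]
    fx = np.fft.fftfreq(nx)[None, :, None]
    fy = np.fft.fftfreq(ny)[None, None, :]
    # physical wavevector components (x, y, z) in cycles/voxel
    k_par = fx * a[0] + fy * a[1] + fz * a[2]
    k2 = fx**2 + fy**2 + fz**2
    k_perp2 = np.clip(k2 - k_par**2, 0.0, None)
    sig_par = corr_length * elongation
    sig_perp = corr_length
    transfer = np.exp(-2 * np.pi**2 * (sig_par**2 * k_par**2 + sig_perp**2 * k_perp2))
    fld = np.real(np.fft.ifftn(np.fft.fftn(white) * transfer))
    if float(fld.std()) < 1e-12:
        raise SpecError("unreachable bvtv_target: filtered field is constant")
    thr = float(np.quantile(fld, 1.0 - bvtv_target))
    bone = fld > thr
    vox = np.where(bone, BONE, BACKGROUND).astype(np.uint8)
    bvtv = float(bone.sum()) / bone.size
    if abs(bvtv - bvtv_target) > 0.005:
        raise SpecError(
            f"achieved BV/TV {bvtv:.4f} misses target {bvtv_target:.4f} by > 0.5 pp"
        )
    meta = {
        "truth_axis": tuple(np.round(a, 9)) if elongation > 1 else None,
        "truth_bvtv": bvtv,
        "elongation": elongation,
        "generator": "anisotropic_field",
        "seed": seed,
    }
    return VoxelVolume(vox, spacing_um, metadata=meta)


# ---------------------------------------------------------------------------
# Analytic phantoms


def make_phantom(
    kind: str,
    shape: tuple[int, int, int] = (32, 32, 32),
    thickness: int = 5,
    diameter: int = 11,
    side: int = 8,
    ring_size: int = 9,
    spacing_um: float = DEFAULT_SPACING_UM,
) -> VoxelVolume:
    """Analytic phantom with exact thickness/topology metadata.

    kinds: ``plate`` (slab of ``thickness`` along z), ``cylinder``
    (``diameter`` along z), ``solid_cube`` (``side``), ``two_cubes``
    (two disjoint ``side`` cubes), ``voxel_ring`` (closed 1-voxel-wide
    square loop of outer size ``ring_size``).
    """
    nz, nx, ny = shape
    vox = np.zeros(shape, dtype=np.uint8)
    meta: dict = {"generator": f"phantom:{kind}"}
    if kind == "plate":
        if thickness < 1 or thickness > nz:
            raise SpecError("plate thickness out of range")
        z0 = (nz - thickness) // 2
        vox[z0 : z0 + thickness, :, :] = BONE
        meta.update(truth_thickness_voxels=float(thickness), truth_euler=1)
    elif kind == "cylinder":
        if diameter < 1:
            raise SpecError("cylinder diameter must be >= 1")
        # continuous cylinder of the stated diameter sampled at voxel centers
        r = diameter / 2.0
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        xx, yy = np.ogrid[:nx, :ny]
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2 + 1e-9
        vox[:, disk] = BONE
        meta.update(truth_thickness_voxels=float(diameter), truth_euler=1)
    elif kind == "solid_cube":
        if side < 1 or side > min(shape):
            raise SpecError("cube side out of range")
        o = [(n - side) // 2 for n in shape]
        vox[o[0] : o[0] + side, o[1] : o[1] + side, o[2] : o[2] + side] = BONE
        meta.update(truth_thickness_voxels=float(side), truth_euler=1)
    elif kind == "two_cubes":
        if 2 * side + 2 > nx:
            raise SpecError("volume too small for two disjoint cubes")
        z0 = (nz - side) // 2
        y0 = (ny - side) // 2
        vox[z0 : z0 + side, 0:side, y0 : y0 + side] = BONE
        vox[z0 : z0 + side, side + 2 : 2 * side + 2, y0 : y0 + side] = BONE
        meta.update(truth_euler=2)
    elif kind == "voxel_ring":
        if ring_size < 3:
            raise SpecError("ring_size must be >= 3")
        z0 = nz // 2
        x0 = (nx - ring_size) // 2
        y0 = (ny - ring_size) // 2
        sq = np.zeros((nx, ny), dtype=bool)
        sq[x0 : x0 + ring_size, y0 : y0 + ring_size] = True
        sq[x0 + 1 : x0 + ring_size - 1, y0 + 1 : y0 + ring_size - 1] = False
        vox[z0, sq] = BONE
        meta.update(truth_euler=0)
    else:
        raise SpecError(f"unknown phantom kind {kind!r}")
    return VoxelVolume(vox, spacing_um, metadata=meta)


# ---------------------------------------------------------------------------
# Axial (Watson-type) samples on the sphere


def sample_axes(
    mean_axis: Sequence[float], concentration: float, n: int, seed: int = 0
) -> list["AxisOnSphere"]:
    """Draw ``n`` axes from a bipolar Watson-type density about ``mean_axis``.

    Density on the sphere is proportional to ``exp(k * (mu . x)^2)``;
    dispersion decreases monotonically with ``concentration``.  Sampling
    uses a deterministic inverse-CDF on a dense colatitude grid, so results
    are reproducible under a fixed seed.
    """
    from .orientation_stats import AxisOnSphere

    if concentration <= 0:
        raise SpecError("concentration must be positive")
    if n < 1:
        raise SpecError("n must be >= 1")
    mu = unit(np.asarray(mean_axis, dtype=float))
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, np.pi / 2, 200_001)
    logw = concentration * np.cos(theta) ** 2
    w = np.exp(logw - logw.max()) * np.sin(theta)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    u = rng.random(n)
    th = np.interp(u, cdf, theta)
    phi = rng.random(n) * 2 * np.pi
    local = np.column_stack(
        [np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), np.cos(th)]
    )
    R = rotation_between(np.array([0.0, 0.0, 1.0]), mu)
    vecs = local @ R.T
    return [AxisOnSphere.from_vector(v) for v in vecs]


# ---------------------------------------------------------------------------
# Gait trials


AngleProfile = Callable[[np.ndarray], np.ndarray]


def constant_angle(deg: float) -> AngleProfile:
    return lambda s: np.full_like(np.asarray(s, dtype=float), deg)


def linear_angle(start_deg: float, end_deg: float) -> AngleProfile:
    return lambda s: start_deg + (end_deg - start_deg) * np.asarray(s, dtype=float)


@dataclass(frozen=True)
class GaitTrialSpec:
    """Double-peaked vertical GRF trace plus a prescribed ankle-angle profile."""

    stance_duration: float = 0.7
    sample_rate_force: float = 1000.0
    sample_rate_kin: float = 125.0
    peak1: float = 1.1
    peak2: float = 1.1
    trough: float = 0.65
    angle_profile: AngleProfile = field(default_factory=lambda: constant_angle(85.6))
    noise_sd_deg: float = 0.0
    noise_sd_bw: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.peak1 > self.trough and self.peak2 > self.trough):
            raise SpecError("no double peak: trough must lie below both peaks")
        if self.trough < 0:
            raise SpecError("trough must be non-negative")
        if self.sample_rate_force <= 0 or self.sample_rate_kin <= 0:
            raise SpecError("sample rates must be positive")
        if self.stance_duration <= 0:
            raise SpecError("stance_duration must be positive")


_GRF_ANCHORS = (0.25, 0.5, 0.75)  # stance fractions of peak1, trough, peak2


def _cos_ease(a: float, b: float, tau: np.ndarray) -> np.ndarray:
    return a + (b - a) * (1.0 - np.cos(np.pi * tau)) / 2.0


def grf_shape(s: np.ndarray, peak1: float, peak2: float, trough: float) -> np.ndarray:
    """Piecewise-cosine double-peaked GRFv (body weights) over stance fraction."""
    s = np.asarray(s, dtype=float)
    s1, s2, s3 = _GRF_ANCHORS
    out = np.empty_like(s)
    m = s < s1
    out[m] = _cos_ease(0.0, peak1, s[m] / s1)
    m = (s >= s1) & (s < s2)
    out[m] = _cos_ease(peak1, trough, (s[m] - s1) / (s2 - s1))
    m = (s >= s2) & (s < s3)
    out[m] = _cos_ease(trough, peak2, (s[m] - s2) / (s3 - s2))
    m = s >= s3
    out[m] = _cos_ease(peak2, 0.0, np.clip((s[m] - s3) / (1 - s3), 0, 1))
    return out


def _ease_crossing(a: float, b: float, level: float) -> float:
    """tau in [0, 1] where the cosine ease from a to b crosses ``level``."""
    return float(np.arccos(1.0 - 2.0 * (level - a) / (b - a)) / np.pi)


def grf_threshold_windows(
    peak1: float, peak2: float, trough: float, level: float = 0.75
) -> list[tuple[float, float]]:
    """Exact stance-fraction intervals where the analytic GRFv exceeds ``level``."""
    s1, s2, s3 = _GRF_ANCHORS
    if max(peak1, peak2) <= level:
        return []
    intervals: list[tuple[float, float]] = []
    if peak1 > level:
        enter = s1 * _ease_crossing(0.0, peak1, level)
        if trough >= level:
            exit_ = None  # stays above through the trough
        else:
            exit_ = s1 + (s2 - s1) * _ease_crossing(peak1, trough, level)
    else:
        enter = exit_ = None
    if peak2 > level:
        if trough >= level and enter is not None:
            # one contiguous window across both peaks
            leave = s3 + (1 - s3) * _ease_crossing(peak2, 0.0, level)
            return [(enter, leave)]
        enter2 = s2 + (s3 - s2) * _ease_crossing(trough, peak2, level)
        leave2 = s3 + (1 - s3) * _ease_crossing(peak2, 0.0, level)
        if enter is not None and exit_ is not None:
            intervals.append((enter, exit_))
        intervals.append((enter2, leave2))
        return intervals
    # only peak1 exceeds the level
    assert enter is not None and exit_ is not None
    return [(enter, exit_)]


def _windowed_mean_angle(profile: AngleProfile, windows: list[tuple[float, float]]) -> float:
    total_w = sum(b - a for a, b in windows)
    if total_w == 0:
        raise SpecError("no peak-loading window: GRFv never exceeds threshold")
    acc = 0.0
    for a, b in windows:
        s = np.linspace(a, b, 20_001)
        acc += float(np.trapezoid(profile(s), s))
    return acc / total_w


def make_gait_trial(spec: GaitTrialSpec):
    """Synthesize a gait trial whose noiseless ankle angle equals the profile.

    Landmarks are lateral-view (horizontal, vertical) meter coordinates for
    the lateral femoral epicondyle, lateral malleolus, tuber calcaneus and
    5th metatarsal head.  The analytic mean angle over the GRFv > 0.75 BW
    window is stored as ``truth_mean_angle_deg``.
    """
    from .gait_kinematics import GaitTrial

    rng = np.random.default_rng(spec.seed)
    T = spec.stance_duration
    t_force = np.arange(0.0, T, 1.0 / spec.sample_rate_force)
    t_kin = np.arange(0.0, T, 1.0 / spec.sample_rate_kin)
    grfv = grf_shape(t_force / T, spec.peak1, spec.peak2, spec.trough)
    if spec.noise_sd_bw > 0:
        grfv = np.clip(grfv + rng.normal(0.0, spec.noise_sd_bw, grfv.shape), 0.0, None)

    s_kin = t_kin / T
    angles = np.asarray(spec.angle_profile(s_kin), dtype=float)
    if spec.noise_sd_deg > 0:
        angles = angles + rng.normal(0.0, spec.noise_sd_deg, angles.shape)

    # Geometry: shank fixed pointing straight down; the foot line is the
    # shank line rotated by the ankle angle, so the inter-line angle equals
    # the profile exactly before noise.
    n = len(t_kin)
    walk_x = 1.2 * t_kin
    epi = np.column_stack([walk_x + 0.0, np.full(n, 0.45)])
    mall = np.column_stack([walk_x + 0.0, np.full(n, 0.05)])
    calc = np.column_stack([walk_x - 0.06, np.full(n, 0.03)])
    th = np.radians(angles)
    # shank direction (epi -> mall) is (0, -1); rotate it by +theta
    foot_dir = np.column_stack([np.sin(th), -np.cos(th)])
    meta5 = calc + 0.15 * foot_dir
    landmarks = {
        "lateral_femoral_epicondyle": epi,
        "lateral_malleolus": mall,
        "tuber_calcaneus": calc,
        "metatarsal5_head": meta5,
    }
    windows = grf_threshold_windows(spec.peak1, spec.peak2, spec.trough, 0.75)
    meta = {
        "generator": "gait_trial",
        "seed": spec.seed,
        "truth_windows_stance_fraction": windows,
    }
    if windows:
        meta["truth_mean_angle_deg"] = _windowed_mean_angle(spec.angle_profile, windows)
    return GaitTrial(
        time_force=t_force,
        grfv_bw=grfv,
        time_kin=t_kin,
        landmarks=landmarks,
        sample_rate_force=spec.sample_rate_force,
        sample_rate_kin=spec.sample_rate_kin,
        metadata=meta,
    )
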