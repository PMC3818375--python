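"""Shared small-vector geometry helpers (internal)."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector has no direction")
    return v / n


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ a = b for unit vectors a, b (Rodrigues)."""
    a = unit(a)
    b = unit(b)
    c = float(np.dot(a, b))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees: rotate about any axis perpendicular to a
        p = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        k = unit(np.cross(a, p))
        return 2.0 * np.outer(k, k) - np.eye(3)
    k = np.cross(a, b)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + kx + kx @ kx / (1.0 + c)


def rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_deg`` (right-handed)."""
    k = unit(axis)
    t = np.radians(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * (kx @ kx)


def orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (u, v, w): u = axis, v/w an orthonormal basis of its plane."""
    u = unit(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = unit(np.cross(u, helper))
    w = np.cross(u, v)
    return u, v, w


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """Quasi-uniform directions on the upper (z >= 0) hemisphere, shape (n, 3)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    # golden-angle spiral on the full sphere mapped to z in (0, 1]
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
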