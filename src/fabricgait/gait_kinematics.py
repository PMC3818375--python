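"""Ankle angle at peak vertical ground-reaction-force loading.

The ankle angle is the lateral-view angle between the shank line (lateral
femoral epicondyle to lateral malleolus) and the foot line (posterior tuber
calcaneus to 5th metatarsal head).  Force and kinematic streams are
filtered with a zero-lag low-pass Butterworth design (defaults 200 Hz and
12 Hz), the angle stream is resampled onto the force time base, and the
mean is taken over the stance frames where GRFv exceeds 75% of body
weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

G_MPS2 = 9.81

LANDMARKS = (
    "lateral_femoral_epicondyle",
    "lateral_malleolus",
    "tuber_calcaneus",
    "metatarsal5_head",
)


class GaitError(ValueError):
    """Raised on invalid gait-trial inputs."""


@dataclass
class GaitTrial:
    """Synchronized landmark trajectories and body-weight-normalized GRFv."""

    time_force: np.ndarray
    grfv_bw: np.ndarray
    time_kin: np.ndarray
    landmarks: dict[str, np.ndarray]  # name -> (n_frames, 2) lateral-view x, y
    sample_rate_force: float
    sample_rate_kin: float
    body_weight_n: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sample_rate_force <= 0 or self.sample_rate_kin <= 0:
            raise GaitError("sample rates must be positive")
        if np.any(np.asarray(self.grfv_bw) < 0):
            raise GaitError("GRFv must be non-negative")
        missing = [k for k in LANDMARKS if k not in self.landmarks]
        if missing:
            raise GaitError(f"missing landmarks: {missing}")

    # -- flat CSV round trip (single table on the force time base) ---------
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        data = {"time_s": self.time_force, "grfv_bw": self.grfv_bw}
        for name in LANDMARKS:
            traj = self.landmarks[name]
            for k, comp in enumerate(("x", "y")):
                data[f"{name}_{comp}"] = np.interp(
                    self.time_force, self.time_kin, traj[:, k]
                )
        pd.DataFrame(data).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, body_weight_n: float | None = None) -> "GaitTrial":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise GaitError("trial CSV must contain at least two samples")
        rate = 1.0 / float(np.median(np.diff(t)))
        landmarks = {
            name: df[[f"{name}_x", f"{name}_y"]].to_numpy() for name in LANDMARKS
        }
        return cls(
            time_force=t,
            grfv_bw=df["grfv_bw"].to_numpy(),
            time_kin=t,
            landmarks=landmarks,
            sample_rate_force=rate,
            sample_rate_kin=rate,
            body_weight_n=body_weight_n,
        )


# ---------------------------------------------------------------------------
# Filtering


def butterworth_zero_lag(
    sig: np.ndarray,
    cutoff_hz: float,
    rate_hz: float,
    order: int = 4,
    halved_order: bool = False,
) -> np.ndarray:
    """Forward-backward low-pass Butterworth filter (zero phase shift).

    By default the stated order is the design order applied in each
    direction (effective 8th-order magnitude for order 4).  With
    ``halved_order=True`` the design order is halved so the forward-backward
    pass has the stated effective order — both conventions exist in the
    gait literature.
    """
    nyquist = rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise GaitError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    design_order = max(1, order // 2) if halved_order else order
    b, a = signal.butter(design_order, cutoff_hz / nyquist, btype="low")
    sig = np.asarray(sig, dtype=float)
    padlen = min(3 * (max(len(a), len(b)) - 1), len(sig) - 1)
    return signal.filtfilt(b, a, sig, padlen=padlen)


# ---------------------------------------------------------------------------
# Angles and windows


def ankle_angle(landmarks: dict[str, np.ndarray]) -> np.ndarray:
    """Per-frame angle (deg, in [0, 180]) between shank and foot lines.

    The shank vector runs epicondyle -> malleolus, the foot vector
    calcaneus -> metatarsal head; the reported angle is the angle between
    those directed vectors (0 = foot folded onto the shank direction).
    """
    shank = landmarks["lateral_malleolus"] - landmarks["lateral_femoral_epicondyle"]
    foot = landmarks["metatarsal5_head"] - landmarks["tuber_calcaneus"]
    ns = np.linalg.norm(shank, axis=1)
    nf = np.linalg.norm(foot, axis=1)
    bad = (ns == 0) | (nf == 0)
    if np.any(bad):
        raise GaitError(f"coincident landmark pair at frames {np.nonzero(bad)[0][:5]}")
    cosang = np.sum(shank * foot, axis=1) / (ns * nf)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def peak_loading_window(grfv_bw: np.ndarray, threshold: float = 0.75) -> np.ndarray:
    """Boolean mask of frames with GRFv above ``threshold`` body weights.

    Double-peaked traces may yield one or two disjoint intervals; all are
    retained.
    """
    grfv_bw = np.asarray(grfv_bw, dtype=float)
    mask = grfv_bw > threshold
    if not mask.any():
        raise GaitError(
            f"no peak-loading window: GRFv never exceeds {threshold:.2f} BW"
        )
    return mask


@dataclass
class PeakLoadingAngle:
    mean_deg: float
    coverage_fraction: float  # share of stance frames inside the window
    n_intervals: int


def mean_angle_at_peak_loading(
    trial: GaitTrial,
    cutoff_kin_hz: float | None = 12.0,
    cutoff_force_hz: float | None = 200.0,
    threshold: float = 0.75,
    halved_order: bool = False,
) -> PeakLoadingAngle:
    """Mean (filtered) ankle angle over the GRFv > 75% BW window.

    Angles are computed on the kinematic stream, low-pass filtered, then
    linearly resampled onto the force time base before masking.  Pass
    ``None`` for either cutoff to skip that filter.
    """
    grf = trial.grfv_bw
    if cutoff_force_hz is not None:
        grf = np.clip(
            butterworth_zero_lag(
                grf, cutoff_force_hz, trial.sample_rate_force, halved_order=halved_order
            ),
            0.0,
            None,
        )
    angles = ankle_angle(trial.landmarks)
    if cutoff_kin_hz is not None:
        angles = butterworth_zero_lag(
            angles, cutoff_kin_hz, trial.sample_rate_kin, halved_order=halved_order
        )
    angles_on_force = np.interp(trial.time_force, trial.time_kin, angles)
    mask = peak_loading_window(grf, threshold)
    n_intervals = int(np.count_nonzero(np.diff(mask.astype(int)) == 1)) + int(mask[0])
    return PeakLoadingAngle(
        mean_deg=float(angles_on_force[mask].mean()),
        coverage_fraction=float(mask.mean()),
        n_intervals=n_intervals,
    )


def froude_number(speed_mps: float, limb_length_m: float) -> float:
    """Dimensionless gait speed v^2 / (g L)."""
    if limb_length_m <= 0:
        raise GaitError("limb length must be positive")
    return speed_mps**2 / (G_MPS2 * limb_length_m)


def validate_trial(trial: GaitTrial, max_impulse_asymmetry: float = 0.10) -> list[str]:
    """Trial acceptance checks (clean contact, speed constancy); returns issues.

    This is a validator flag, not a silent filter: callers decide what to do
    with flagged trials.
    """
    issues: list[str] = []
    if trial.grfv_bw[0] > 0.05 * trial.grfv_bw.max() or trial.grfv_bw[-1] > 0.05 * trial.grfv_bw.max():
        issues.append("force trace does not start/end near zero (unclean contact)")
    fore_aft = trial.metadata.get("fore_aft_force_bw")
    if fore_aft is not None:
        fa = np.asarray(fore_aft, dtype=float)
        braking = float(np.trapezoid(np.clip(fa, None, 0.0), trial.time_force))
        propulsion = float(np.trapezoid(np.clip(fa, 0.0, None), trial.time_force))
        denom = max(abs(braking), abs(propulsion), 1e-12)
        if abs(abs(braking) - propulsion) / denom > max_impulse_asymmetry:
            issues.append("fore-aft impulse asymmetry exceeds 10% (speed not constant)")
    return issues
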