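"""Mean-squared-displacement analysis of 3D single-particle tracks.

Tracks of labelled myosin VI acquired by multifocal 3D imaging are
reduced to time-averaged MSD curves and fitted with the anomalous
diffusion model

    MSD(tau) = 2 * dim * D * tau^alpha

where D is the generalized diffusion coefficient (µm^2 s^-1) and alpha
classifies the motion: alpha < 1 confined, alpha = 1 Brownian,
alpha > 1 directed.  Per-track D values are binned into three mobility
classes (static/slow D < 0.1, mobile 0.1-2, hyper-mobile D > 2, in
µm^2 s^-1) and turning-angle distributions report back-and-forth motion
(angles enriched near 180 degrees for confined molecules).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory3D",
    "DiffusionFit",
    "MobilityClasses",
    "filter_tracks",
    "msd_curve",
    "fit_anomalous",
    "classify_mobility",
    "turning_angles",
    "analyze_tracks",
]

MIN_FRAMES = 10  # tracks shorter than this are excluded
MAX_STEP_UM = 0.4  # linking limit: consecutive displacements above this split a track
DEFAULT_DT = 0.032  # s, frame interval of the 3D acquisition
# mobility class boundaries (µm^2/s); boundary values fall in the middle class
D_SLOW = 0.1
D_FAST = 2.0


@dataclass
class Trajectory3D:
    """One particle's time-ordered 3D positions at a fixed frame interval."""

    track_id: int
    frames: np.ndarray
    t: np.ndarray  # s
    xyz: np.ndarray  # (n, 3) µm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.frames), 3):
            raise ValueError("xyz must be (n_frames, 3)")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frame gaps are forbidden; split tracks at gaps")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if len(self.t) > 1 else np.nan


@dataclass
class DiffusionFit:
    track_id: int
    D: float  # µm^2 s^-1
    alpha: float
    n_lags: int
    r_squared: float


@dataclass
class MobilityClasses:
    static_slow: float
    mobile: float
    hyper_mobile: float

    def as_dict(self) -> dict:
        return {
            "static_slow": self.static_slow,
            "mobile": self.mobile,
            "hyper_mobile": self.hyper_mobile,
        }


def filter_tracks(
    df: pd.DataFrame,
    min_frames: int = MIN_FRAMES,
    max_step: float = MAX_STEP_UM,
) -> list[Trajectory3D]:
    """Apply the tracking filters to a trajectory table.

    ``df`` columns: track_id, frame, t_s, x_um, y_um, z_um.  Tracks are
    split at frame gaps and at displacements above ``max_step`` (the
    linking limit), then segments shorter than ``min_frames`` frames are
    dropped.
    """
    out: list[Trajectory3D] = []
    next_id = 0
    for _, g in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        frames = g["frame"].to_numpy(dtype=int)
        t = g["t_s"].to_numpy(dtype=float)
        xyz = g[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        gap = (np.diff(frames) != 1) | (steps > max_step)
        # segment boundaries where a gap or over-limit step occurs
        starts = np.concatenate([[0], np.flatnonzero(gap) + 1])
        ends = np.concatenate([np.flatnonzero(gap) + 1, [len(frames)]])
        for a, b in zip(starts, ends):
            if b - a >= min_frames:
                out.append(Trajectory3D(next_id, frames[a:b], t[a:b], xyz[a:b]))
                next_id += 1
    return out


def msd_curve(
    traj: Trajectory3D, max_lag_fraction: float = 0.25, min_lags: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over overlapping windows.

    MSD(k dt) = mean_i |r(i+k) - r(i)|^2 for lags k = 1 ..
    floor(n * max_lag_fraction) (at least ``min_lags``).  Returns
    (lag times in s, MSD in µm^2).
    """
    n = traj.n_frames
    if n < MIN_FRAMES:
        raise ValueError(f"track {traj.track_id} shorter than {MIN_FRAMES} frames")
    n_lags = max(int(n * max_lag_fraction), min_lags)
    n_lags = min(n_lags, n - 1)
    lags = np.arange(1, n_lags + 1)
    msd = np.empty(n_lags)
    for i, k in enumerate(lags):
        d = traj.xyz[k:] - traj.xyz[:-k]
        msd[i] = np.mean(np.sum(d * d, axis=1))
    return lags * traj.dt, msd


def fit_anomalous(
    tau: np.ndarray, msd: np.ndarray, dim: int = 3, track_id: int = -1
) -> DiffusionFit:
    """Log-log linear fit of the anomalous diffusion model.

    alpha is the slope of log MSD vs log tau and
    D = exp(intercept) / (2 * dim).  Deterministic (ordinary least
    squares); tracks with nonpositive MSD values cannot be fitted.
    """
    tau = np.asarray(tau, dtype=float)
    msd = np.asarray(msd, dtype=float)
    if len(tau) < 3:
        raise ValueError("need at least 3 lag points")
    if np.any(msd <= 0):
        raise ValueError("nonpositive MSD values; track not fittable in log space")
    lx, ly = np.log(tau), np.log(msd)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum((ly - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return DiffusionFit(
        track_id=track_id,
        D=float(np.exp(intercept) / (2 * dim)),
        alpha=float(slope),
        n_lags=len(tau),
        r_squared=float(r2),
    )


def classify_mobility(fits: Iterable[DiffusionFit]) -> MobilityClasses:
    """Fractions of tracks in the three mobility classes.

    Strict inequalities on the outer classes: D < 0.1 static/slow,
    D > 2 hyper-mobile; the boundary values belong to the mobile class.
    """
    D = np.array([f.D for f in fits], dtype=float)
    if len(D) == 0:
        raise ValueError("empty fit collection")
    slow = np.mean(D < D_SLOW)
    fast = np.mean(D > D_FAST)
    return MobilityClasses(
        static_slow=float(slow), mobile=float(1.0 - slow - fast), hyper_mobile=float(fast)
    )


def turning_angles(
    traj: Trajectory3D, projection: str = "xy", signed: bool = True
) -> np.ndarray:
    """Angles between consecutive displacement vectors, in degrees.

    Default: signed 2D angle on the xy projection in [0, 360) (the
    convention of a planar roseplot), so straight motion gives 0 and
    strict reversals give 180.  ``projection="3d"`` returns the unsigned
    3D angle in [0, 180].  Zero-length displacements are skipped.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames for a turning angle")
    if projection == "3d":
        v = np.diff(traj.xyz, axis=0)
    elif projection == "xy":
        v = np.diff(traj.xyz[:, :2], axis=0)
    else:
        raise ValueError("projection must be 'xy' or '3d'")
    norms = np.linalg.norm(v, axis=1)
    keep = norms > 0
    v = v[keep]
    if len(v) < 2:
        return np.empty(0)
    a, b = v[:-1], v[1:]
    dot = np.sum(a * b, axis=1)
    if projection == "3d":
        cosang = dot / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        return np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    ang = np.degrees(np.arctan2(cross, dot))
    if signed:
        return np.mod(ang, 360.0)
    return np.abs(ang)


def analyze_tracks(
    tracks: Iterable[Trajectory3D],
    dim: int = 3,
    max_lag_fraction: float = 0.25,
) -> pd.DataFrame:
    """Per-track anomalous-diffusion fits as a tidy table."""
    rows = []
    for tr in tracks:
        try:
            tau, msd = msd_curve(tr, max_lag_fraction=max_lag_fraction)
            fit = fit_anomalous(tau, msd, dim=dim, track_id=tr.track_id)
        except ValueError:
            continue
        rows.append(
            {
                "track_id": tr.track_id,
                "n_frames": tr.n_frames,
                "D_um2_s": fit.D,
                "alpha": fit.alpha,
                "n_lags": fit.n_lags,
                "r_squared": fit.r_squared,
            }
        )
    return pd.DataFrame(rows)
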