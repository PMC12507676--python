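"""Image-to-track pipeline: background subtraction, blob detection and
track clean-up.

The pipeline mirrors a standard single-animal video workflow: a rolling
background is the per-pixel 95th percentile of the previous window of
frames; the fish is the largest connected component of the thresholded
absolute difference with area of at least ``min_area`` (inclusive,
default 100 px); frames without a detection are linearly interpolated;
frame-to-frame jumps beyond 200 px are treated as tracking artifacts and
replaced by the mean of the surrounding +/-5 frames (1 s at 10 Hz),
iterated to a fixed point; x and y are then smoothed with a centred 0.5-s
boxcar and calibrated from pixels to millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skimage import measure

from .synth.tracks import Trajectory

__all__ = ["TrackingConfig", "compute_background", "detect", "track",
           "despike", "smooth", "calibrate", "CalibratedTrack"]


@dataclass(frozen=True)
class TrackingConfig:
    background_window_min: float = 60.0
    intensity_threshold: float = 60.0   # |frame - background| cut; data-dependent
    min_area_px: int = 100
    jump_threshold_px: float = 200.0
    smooth_window_s: float = 0.5
    px_per_mm: float = 2.0
    weighted_centroid: bool = True


def compute_background(frames: np.ndarray, percentile: float = 95.0) -> np.ndarray:
    """Per-pixel 95th-percentile background over a window of frames."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) < 2:
        raise ValueError("need a (n, h, w) stack with >= 2 frames")
    return np.percentile(frames, percentile, axis=0)


def detect(frame, background, intensity_threshold: float = 60.0,
           min_area: int = 100, weighted: bool = True):
    """Largest above-threshold blob; ``None`` when nothing qualifies.

    Returns ``(x, y, area)`` with an intensity-weighted (or binary)
    centroid of the largest connected component of
    ``|frame - background| > threshold`` whose area is at least
    ``min_area`` (boundary inclusive).
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background dimensions differ")
    diff = np.abs(frame - background)
    mask = diff > intensity_threshold
    if not mask.any():
        return None
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(counts.argmax())
    area = int(counts[best])
    if area < min_area:
        return None
    ys, xs = np.nonzero(labels == best)
    if weighted:
        w = diff[ys, xs]
        cx = float((xs * w).sum() / w.sum())
        cy = float((ys * w).sum() / w.sum())
    else:
        cx, cy = float(xs.mean()), float(ys.mean())
    return cx, cy, area


def track(stack, config: TrackingConfig = TrackingConfig()) -> Trajectory:
    """Detect the fish in every frame against a rolling background.

    The stack is split into consecutive background windows; each window is
    matched against the 95th-percentile background of the *previous*
    window (the first window uses itself).  Missing runs are linearly
    interpolated between flanking detections; leading/trailing runs take
    the nearest detection.
    """
    frames = np.asarray(stack.frames)
    n = len(frames)
    fps = getattr(stack, "fps", 10.0)
    win = max(2, int(round(config.background_window_min * 60.0 * fps)))
    if win > n:
        win = n

    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    areas = np.zeros(n)
    for start in range(0, n, win):
        prev = slice(max(0, start - win), start) if start > 0 else slice(0, win)
        bg = compute_background(frames[prev])
        for i in range(start, min(n, start + win)):
            hit = detect(frames[i], bg, config.intensity_threshold,
                         config.min_area_px, config.weighted_centroid)
            if hit is not None:
                xs[i], ys[i], areas[i] = hit
    missing = np.isnan(xs)
    if missing.all():
        raise ValueError("no detections in the entire stack")
    idx = np.arange(n)
    good = ~missing
    xs = np.interp(idx, idx[good], xs[good])
    ys = np.interp(idx, idx[good], ys[good])
    t = np.arange(n) / fps
    return Trajectory(t, xs, ys, areas, missing, fps=fps)


def _displacement(x, y):
    d = np.hypot(np.diff(x), np.diff(y))
    return np.concatenate([[0.0], d])


def despike(traj: Trajectory, jump_threshold: float = 200.0,
            half_window: int = 5, max_passes: int = 10) -> Trajectory:
    """Replace single-frame jumps with the local +/-5-frame average.

    A frame whose displacement from the previous frame exceeds the
    threshold gets its x, y replaced by the mean over the surrounding
    ``half_window`` frames on each side, excluding itself (truncated at
    the sequence edges).  The pass repeats until no displacement exceeds
    the threshold or ``max_passes`` is reached.
    """
    if len(traj.timestamps) < 2 * half_window + 1:
        raise ValueError("track too short to despike")
    x = traj.x.astype(float).copy()
    y = traj.y.astype(float).copy()
    n = len(x)
    for _ in range(max_passes):
        disp = _displacement(x, y)
        bad = np.nonzero(disp > jump_threshold)[0]
        if bad.size == 0:
            break
        for i in bad:
            lo, hi = max(0, i - half_window), min(n, i + half_window + 1)
            sel = np.r_[lo:i, i + 1:hi]
            x[i] = x[sel].mean()
            y[i] = y[sel].mean()
    return replace(traj, x=x, y=y)


def smooth(traj: Trajectory, window_s: float = 0.5) -> Trajectory:
    """Centred moving-average of x and y over ``window_s`` seconds."""
    w = max(1, int(round(window_s * traj.fps)))
    x = pd.Series(traj.x).rolling(w, center=True, min_periods=1).mean().to_numpy()
    y = pd.Series(traj.y).rolling(w, center=True, min_periods=1).mean().to_numpy()
    return replace(traj, x=x, y=y)


@dataclass
class CalibratedTrack:
    """Track in millimetres; y is still image-convention (downward)."""

    timestamps: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    missing: np.ndarray
    fps: float
    px_per_mm: float

    def uncalibrate(self) -> Trajectory:
        return Trajectory(self.timestamps, self.x_mm * self.px_per_mm,
                          self.y_mm * self.px_per_mm,
                          np.zeros_like(self.x_mm), self.missing,
                          fps=self.fps, px_per_mm=self.px_per_mm)


def calibrate(traj: Trajectory, px_per_mm: float | None = None) -> CalibratedTrack:
    """Convert pixel positions to millimetres."""
    scale = traj.px_per_mm if px_per_mm is None else px_per_mm
    if scale <= 0:
        raise ValueError("px_per_mm must be > 0")
    return CalibratedTrack(traj.timestamps, traj.x / scale, traj.y / scale,
                           traj.missing, traj.fps, scale)
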