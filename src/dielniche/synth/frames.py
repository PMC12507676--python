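"""Render synthetic grayscale frame stacks from a trajectory.

A dark, roughly circular fish blob moves over a brighter sandy background
that can drift slowly (emulating sand displaced by the fish, the reason
the tracking stage supports shorter background windows).  Used to
exercise the image-to-track pipeline end to end against known centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import Trajectory

__all__ = ["FrameStack", "render_frames"]


@dataclass
class FrameStack:
    frames: np.ndarray        # (n, h, w) uint8
    true_x: np.ndarray        # ground-truth centroid, px
    true_y: np.ndarray
    fps: float = 10.0

    def __len__(self):
        return len(self.frames)

    def to_tiff(self, path) -> None:
        """Multi-frame TIFF plus a ground-truth CSV next to it."""
        import pandas as pd
        import tifffile

        tifffile.imwrite(path, self.frames)
        pd.DataFrame({"true_x": self.true_x, "true_y": self.true_y}).to_csv(
            str(path) + ".truth.csv", index=False)

    @classmethod
    def from_tiff(cls, path, fps: float = 10.0) -> "FrameStack":
        import pandas as pd
        import tifffile

        frames = tifffile.imread(path)
        try:
            truth = pd.read_csv(str(path) + ".truth.csv")
            tx = truth["true_x"].to_numpy()
            ty = truth["true_y"].to_numpy()
        except FileNotFoundError:
            tx = np.full(len(frames), np.nan)
            ty = np.full(len(frames), np.nan)
        return cls(frames, tx, ty, fps=fps)


def render_frames(
    trajectory: Trajectory,
    arena: tuple = (120, 160),     # (height, width) px
    blob_area: float = 200.0,      # px^2
    drift: float = 0.0,            # background drift, px per frame
    seed: int | None = None,
    noise_sd: float = 3.0,
    bg_level: float = 180.0,
    fish_level: float = 60.0,
) -> FrameStack:
    """Rasterize a trajectory into noisy grayscale frames.

    The blob is a disc of the requested area.  ``drift`` translates a
    fixed sand texture across the arena over time.  Ground-truth centroids
    are recorded per frame; frames the trajectory marks missing are drawn
    without a blob.
    """
    h, w = arena
    n = len(trajectory.timestamps)
    x = np.asarray(trajectory.x, dtype=float)
    y = np.asarray(trajectory.y, dtype=float)
    r = np.sqrt(blob_area / np.pi)
    if np.any((x < 0) | (x >= w) | (y < 0) | (y >= h)):
        raise ValueError("blob centre outside the arena")

    rng = np.random.default_rng(seed)
    # static sand texture, tiled so a drifting crop always exists
    texture = rng.normal(bg_level, 8.0, (h, 2 * w)).clip(0, 255)
    yy, xx = np.mgrid[0:h, 0:w]

    frames = np.empty((n, h, w), dtype=np.uint8)
    for i in range(n):
        off = int(round(drift * i)) % w
        frame = texture[:, off:off + w].copy()
        if not trajectory.missing[i]:
            mask = (xx - x[i]) ** 2 + (yy - y[i]) ** 2 <= r * r
            frame[mask] = fish_level
        frame += rng.normal(0.0, noise_sd, (h, w))
        frames[i] = frame.clip(0, 255).astype(np.uint8)
    return FrameStack(frames, x.copy(), y.copy(), fps=trajectory.fps)
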