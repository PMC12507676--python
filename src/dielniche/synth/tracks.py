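"""Synthetic swim tracks with diel activity modulation and rest bouts.

A species archetype is described by a :class:`DielTemplate`: a baseline
swim speed, a day/night contrast, extra activity bumps at dawn and dusk,
and phase-dependent rest-bout statistics.  ``simulate_track`` turns a
template into a 10 Hz (configurable) position trace with contiguous rest
bouts, optional missing-detection gaps and single-frame tracking spikes,
plus the ground truth needed to score every downstream stage.

The instantaneous expected speed is the light intensity mapped through the
day/night contrast plus Gaussian bumps centred on the dawn and dusk ramps
— a minimal parameterization of the four diel guilds (diurnal, nocturnal,
crepuscular, cathemeral).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedule import DAY_S, LightSchedule

__all__ = ["DielTemplate", "GroundTruth", "Trajectory", "simulate_track",
           "diel_intensity", "template_for_guild", "GUILD_TEMPLATES"]

MOVEMENT_THRESHOLD_MMS = 15.0  # rest speeds are kept safely below this


@dataclass(frozen=True)
class DielTemplate:
    """Speed/rest archetype of one synthetic species."""

    archetype: str                     # diurnal | nocturnal | crepuscular | cathemeral
    base_speed: float = 40.0           # mm/s while active, mid contrast
    day_night_contrast: float = 0.8    # 0 = none; 1 = full on/off
    crepuscular_gain: float = 0.0      # bump height relative to base_speed
    rest_bout_rate: dict = field(      # bouts per hour, by light state
        default_factory=lambda: {"day": 6.0, "night": 6.0,
                                 "dawn-ramp": 6.0, "dusk-ramp": 6.0})
    rest_bout_mean_duration: float = 120.0  # s

    def __post_init__(self):
        if self.day_night_contrast < 0 or self.crepuscular_gain < 0:
            raise ValueError("contrast and gain must be >= 0")
        if self.archetype == "cathemeral" and (
                self.day_night_contrast != 0 or self.crepuscular_gain != 0):
            raise ValueError("cathemeral template must have zero contrast and gain")


def template_for_guild(guild: str, **overrides) -> DielTemplate:
    t = GUILD_TEMPLATES[guild]
    return replace(t, **overrides) if overrides else t


GUILD_TEMPLATES = {
    "diurnal": DielTemplate(
        "diurnal", day_night_contrast=0.8,
        rest_bout_rate={"day": 2.0, "night": 12.0,
                        "dawn-ramp": 4.0, "dusk-ramp": 4.0},
        rest_bout_mean_duration=240.0),
    "nocturnal": DielTemplate(
        "nocturnal", day_night_contrast=0.8,
        rest_bout_rate={"day": 12.0, "night": 2.0,
                        "dawn-ramp": 4.0, "dusk-ramp": 4.0},
        rest_bout_mean_duration=240.0),
    "crepuscular": DielTemplate(
        "crepuscular", day_night_contrast=0.1, crepuscular_gain=1.2,
        rest_bout_rate={"day": 8.0, "night": 8.0,
                        "dawn-ramp": 0.5, "dusk-ramp": 0.5},
        rest_bout_mean_duration=240.0),
    "cathemeral": DielTemplate(
        "cathemeral", day_night_contrast=0.0, crepuscular_gain=0.0,
        rest_bout_rate={"day": 6.0, "night": 6.0,
                        "dawn-ramp": 6.0, "dusk-ramp": 6.0},
        rest_bout_mean_duration=240.0),
}


def diel_intensity(template: DielTemplate, schedule: LightSchedule, t):
    """Expected active-swim speed (mm/s) at time(s) t.

    Day/night square wave follows the light ramps (the light intensity is
    already the ramp-convolved square wave); crepuscular activity enters
    as Gaussian bumps centred on the dawn and dusk ramps.
    """
    t = np.asarray(t, dtype=float)
    light = np.asarray(schedule.intensity(t), dtype=float)
    c = template.day_night_contrast
    if template.archetype == "nocturnal":
        wave = 1.0 - c * light
    else:
        wave = 1.0 - c * (1.0 - light)
    tod = t % DAY_S
    width = max(schedule.ramp, 600.0)
    dawn_c = schedule.day_start + schedule.ramp / 2.0
    dusk_c = schedule.day_end - schedule.ramp / 2.0
    bumps = np.exp(-0.5 * ((tod - dawn_c) / width) ** 2)
    bumps += np.exp(-0.5 * ((tod - dusk_c) / width) ** 2)
    out = template.base_speed * (wave + template.crepuscular_gain * bumps)
    return np.maximum(out, 0.0)


@dataclass
class Trajectory:
    """Per-frame track of one individual (pixel coordinates)."""

    timestamps: np.ndarray   # s, strictly increasing; 0 = local midnight day 0
    x: np.ndarray            # px
    y: np.ndarray            # px
    area: np.ndarray         # px^2
    missing: np.ndarray      # bool: frame had no detection (position interpolated)
    fps: float = 10.0
    px_per_mm: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "x": self.x,
                             "y": self.y, "area": self.area,
                             "missing": self.missing.astype(int)})


@dataclass
class GroundTruth:
    """Truth emitted next to every synthetic track; never read by the pipeline."""

    true_x_mm: np.ndarray
    true_y_mm: np.ndarray
    rest: np.ndarray            # bool per frame
    expected_speed: np.ndarray  # mm/s per frame (active state)
    spike_frames: np.ndarray
    gap_frames: np.ndarray


def _rest_state_series(template, schedule, t, rng):
    """Two-state (active/rest) semi-Markov process with phase-dependent rates.

    Active dwell times are exponential with mean chosen so that a bout
    rate of r per hour and mean rest duration d give a long-run rest
    fraction r*d/3600 in that phase; rest dwell times are exponential
    with mean d.
    """
    n = len(t)
    rest = np.zeros(n, dtype=bool)
    d = template.rest_bout_mean_duration
    i = 0
    state_rest = False
    while i < n:
        if state_rest:
            dwell = rng.exponential(d)
        else:
            r = template.rest_bout_rate.get(str(schedule.state(t[i])), 0.0)
            if r <= 0:
                dwell = np.inf
            else:
                frac = min(r * d / 3600.0, 0.95)
                mean_active = d * (1.0 - frac) / frac
                dwell = rng.exponential(mean_active)
        dt = (t[-1] - t[0]) / (n - 1) if n > 1 else 1.0
        j = n if not np.isfinite(dwell) else min(
            n, i + max(1, int(round(dwell / dt))))
        rest[i:j] = state_rest
        state_rest = not state_rest
        i = j
    return rest


def simulate_track(
    template: DielTemplate,
    schedule: LightSchedule,
    days: int = 6,
    fps: float = 10.0,
    seed: int | None = None,
    px_per_mm: float = 2.0,
    arena_mm: tuple = (250.0, 400.0),   # (height, width): 25 cm x 40 cm arena
    gap_rate: float = 0.0,              # missing-detection runs per hour
    gap_mean_frames: int = 10,
    spike_rate: float = 0.0,            # single-frame spikes per hour
    spike_px: float = 250.0,
    start_time: float = 0.0,            # s after midnight of day 0
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one individual's positional track plus ground truth.

    Returns pixel-space positions (image convention: y grows downward) at
    the requested frame rate.  Rest bouts are contiguous intervals where
    the fish barely moves (speed well below the movement threshold);
    optional artifacts emulate detection gaps and background-subtraction
    jumps of more than 200 px.
    """
    if days < 1 or fps <= 0:
        raise ValueError("days >= 1 and fps > 0 required")
    rng = np.random.default_rng(seed)
    n = int(round(days * DAY_S * fps))
    t = start_time + np.arange(n) / fps
    dt = 1.0 / fps

    rest = _rest_state_series(template, schedule, t, rng)
    mu = diel_intensity(template, schedule, t)
    if template.base_speed == 0:
        rest[:] = True   # a fish that never swims is at rest throughout
    # active speed keeps a floor safely above the movement threshold so the
    # sliding-window rest detector sees exactly the generated bout structure
    speed = np.where(
        rest,
        np.abs(rng.normal(0.0, 2.0, n)),               # sub-threshold jitter
        mu * rng.gamma(8.0, 1 / 8.0, n) + MOVEMENT_THRESHOLD_MMS * 1.5,
    )
    # correlated random walk inside the arena
    heading = np.cumsum(rng.normal(0.0, 0.6, n))
    dx = speed * dt * np.cos(heading)
    dy = speed * dt * np.sin(heading)
    h, w = arena_mm
    x_mm = np.empty(n)
    y_mm = np.empty(n)
    x_mm[0] = w / 2.0
    y_mm[0] = h / 2.0
    xx = np.cumsum(np.concatenate([[x_mm[0]], dx[1:]]))
    yy = np.cumsum(np.concatenate([[y_mm[0]], dy[1:]]))
    # reflect into the arena
    x_mm = np.abs((xx % (2 * w)) - w)
    y_mm = np.abs((yy % (2 * h)) - h)

    x_px = x_mm * px_per_mm
    y_px = y_mm * px_per_mm
    area = np.maximum(rng.normal(220.0, 12.0, n), 120.0)
    missing = np.zeros(n, dtype=bool)

    hours = days * 24.0
    gap_frames = np.empty(0, dtype=int)
    if gap_rate > 0:
        starts = rng.choice(n, size=rng.poisson(gap_rate * hours), replace=False)
        idx = []
        for s in starts:
            ln = max(1, int(round(rng.exponential(gap_mean_frames))))
            idx.extend(range(s, min(n, s + ln)))
        gap_frames = np.unique(np.asarray(idx, dtype=int))
        missing[gap_frames] = True

    spike_frames = np.empty(0, dtype=int)
    if spike_rate > 0:
        cand = np.setdiff1d(np.arange(1, n - 1), gap_frames)
        k = min(len(cand), rng.poisson(spike_rate * hours))
        spike_frames = np.sort(rng.choice(cand, size=k, replace=False))
        ang = rng.uniform(0, 2 * np.pi, len(spike_frames))
        x_px = x_px.copy()
        y_px = y_px.copy()
        x_px[spike_frames] += spike_px * 1.25 * np.cos(ang)
        y_px[spike_frames] += spike_px * 1.25 * np.sin(ang)

    traj = Trajectory(t, x_px, y_px, area, missing, fps=fps, px_per_mm=px_per_mm)
    gt = GroundTruth(x_mm, y_mm, rest, mu, spike_frames, gap_frames)
    return traj, gt
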