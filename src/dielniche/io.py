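"""File formats: track CSVs with YAML metadata, profile and result tables.

Tracks follow the recording layout: a comma-separated file with
timestamp (s), x (px), y (px) and area (px^2) columns next to a YAML
metadata file (species code, frame rate, pixel scale, light schedule).
Species profiles are CSVs with one row per species and 48 bin columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activity import N_BINS, SpeciesProfile
from .synth.schedule import LightSchedule
from .synth.tracks import Trajectory

__all__ = ["write_track", "read_track", "write_profiles", "read_profiles",
            "write_metadata", "read_metadata"]


def write_track(path, traj: Trajectory) -> None:
    df = pd.DataFrame({
        "timestamp": traj.timestamps, "x": traj.x, "y": traj.y,
        "area": traj.area, "missing": traj.missing.astype(int)})
    df.to_csv(path, index=False, float_format="%.6f")


def read_track(path, fps: float | None = None, px_per_mm: float = 1.0) -> Trajectory:
    df = pd.read_csv(path)
    t = df["timestamp"].to_numpy(dtype=float)
    if fps is None:
        fps = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 10.0
    missing = (df["missing"].to_numpy(dtype=bool)
               if "missing" in df else np.zeros(len(df), dtype=bool))
    area = df["area"].to_numpy(dtype=float) if "area" in df else np.zeros(len(df))
    return Trajectory(t, df["x"].to_numpy(float), df["y"].to_numpy(float),
                      area, missing, fps=fps, px_per_mm=px_per_mm)


def write_metadata(path, species: str, fps: float, px_per_mm: float,
                   schedule: LightSchedule, extra: dict | None = None) -> None:
    meta = {
        "species": species, "fps": fps, "px_per_mm": px_per_mm,
        "schedule": {"day_start_s": schedule.day_start,
                     "day_end_s": schedule.day_end, "ramp_s": schedule.ramp},
    }
    meta.update(extra or {})
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_metadata(path) -> dict:
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    s = meta.get("schedule", {})
    meta["schedule"] = LightSchedule(
        s.get("day_start_s", 7 * 3600.0), s.get("day_end_s", 19 * 3600.0),
        s.get("ramp_s", 1800.0))
    return meta


def write_profiles(path, profiles: list[SpeciesProfile]) -> None:
    """Species x 48-bin table of mean speed, plus SD columns."""
    rows = []
    for p in profiles:
        row = {"species": p.species, "n_individuals": p.n_individuals}
        row.update({f"bin{j:02d}": p.mean[j] for j in range(N_BINS)})
        row.update({f"sd{j:02d}": p.sd_individuals[j] for j in range(N_BINS)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_profiles(path) -> list[SpeciesProfile]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        mean = np.array([r[f"bin{j:02d}"] for j in range(N_BINS)])
        sd = np.array([r[f"sd{j:02d}"] for j in range(N_BINS)])
        out.append(SpeciesProfile(str(r["species"]), mean, sd, sd.copy(),
                                  int(r["n_individuals"])))
    return out
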