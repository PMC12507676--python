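"""Run configuration: one YAML document, per-stage sections.

Defaults mirror the assay and analysis constants: 10 Hz tracking, 100-px
minimum blob, 200-px jump threshold, 0.5-s smoothing, 15 mm/s movement
threshold, 60-s/5% rest windows, 30-min bins, 10 PCA components, three
Ward clusters, 07:00-19:00 lights with 30-min ramps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


def _default_stages() -> dict:
    return {
        "schedule": {"day_start": "07:00", "day_end": "19:00", "ramp_min": 30.0},
        "tracking": {"background_window_min": 60.0, "intensity_threshold": 60.0,
                     "min_area_px": 100, "jump_threshold_px": 200.0,
                     "smooth_window_s": 0.5, "px_per_mm": 2.0, "fps": 10.0},
        "activity": {"movement_threshold_mms": 15.0, "rest_window_s": 60.0,
                     "rest_max_frac": 0.05, "bin_minutes": 30.0,
                     "min_day_coverage": 0.95},
        "niche": {"n_components": 10, "n_clusters": 3, "sd_source": "individuals"},
        "cohort": {"n_species": 60, "n_individuals": 8, "days": 6},
        "variants": {"n_sites": 2000, "n_assoc": 50, "beta": 2.0,
                     "mean_depth": 10.0, "base_error": 0.01,
                     "pgls_quantile": 0.01, "glm_cutoff": 1e-3},
        "phylo": {"n_restarts": 5, "n_perm": 999, "n_sim": 1000},
    }


@dataclass
class RunConfig:
    seed: int = 0
    stages: dict = field(default_factory=_default_stages)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "RunConfig":
        if hasattr(src, "read"):
            data = yaml.safe_load(src)
        else:
            try:
                with open(src) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(str(src))
        base = cls()
        if not data:
            return base
        if "seed" in data:
            base.seed = int(data["seed"])
        for stage, vals in (data.get("stages") or {}).items():
            base.stages.setdefault(stage, {}).update(vals or {})
        return base

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
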