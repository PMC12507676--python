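"""Light schedules: day/night cycle with linear dawn and dusk ramps.

The behavioural room runs a 12:12 h light:dark cycle with lights ramping
on over 07:00-07:30 and off over 18:30-19:00 (a 14:10 variant is used for
constant-darkness work).  A schedule maps time-of-day to a light state in
{night, dawn-ramp, day, dusk-ramp} and to a light intensity in [0, 1];
both are periodic with 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LightSchedule", "make_light_schedule"]

DAY_S = 86400.0

NIGHT, DAWN, DAY, DUSK = "night", "dawn-ramp", "day", "dusk-ramp"


def _parse_clock(t) -> float:
    """Clock time -> seconds after midnight. Accepts 'HH:MM' or hours."""
    if isinstance(t, str):
        hh, mm = t.split(":")
        return 3600.0 * int(hh) + 60.0 * float(mm)
    return float(t) * 3600.0


@dataclass(frozen=True)
class LightSchedule:
    day_start: float   # s after midnight: dawn ramp begins
    day_end: float     # s after midnight: dusk ramp ends (lights fully off)
    ramp: float        # ramp duration, s

    @property
    def day_length_h(self) -> float:
        return (self.day_end - self.day_start) / 3600.0

    def state(self, t):
        """Light state at time t (seconds; any epoch with midnight at 0)."""
        tod = np.asarray(t, dtype=float) % DAY_S
        out = np.full(tod.shape, NIGHT, dtype=object)
        out[(tod >= self.day_start) & (tod < self.day_start + self.ramp)] = DAWN
        out[(tod >= self.day_start + self.ramp) & (tod < self.day_end - self.ramp)] = DAY
        if self.ramp > 0:
            out[(tod >= self.day_end - self.ramp) & (tod < self.day_end)] = DUSK
        else:
            out[(tod >= self.day_start) & (tod < self.day_end)] = DAY
        return out if out.ndim else out.item()

    def intensity(self, t):
        """Light intensity in [0, 1]; linear within the ramps."""
        tod = np.asarray(t, dtype=float) % DAY_S
        if self.ramp == 0:
            val = ((tod >= self.day_start) & (tod < self.day_end)).astype(float)
        else:
            up = np.clip((tod - self.day_start) / self.ramp, 0.0, 1.0)
            down = np.clip((self.day_end - tod) / self.ramp, 0.0, 1.0)
            val = np.minimum(up, down)
        return val if val.ndim else float(val)

    def bin_states(self, bin_minutes: float = 30.0):
        """Light state of each time-of-day bin (state at the bin centre)."""
        width = bin_minutes * 60.0
        centers = np.arange(width / 2.0, DAY_S, width)
        return self.state(centers)


def make_light_schedule(day_start="07:00", day_end="19:00",
                        ramp_min: float = 30.0) -> LightSchedule:
    """Build a light schedule from clock times and a ramp in minutes."""
    s, e = _parse_clock(day_start), _parse_clock(day_end)
    ramp = float(ramp_min) * 60.0
    if not 0.0 < e - s < DAY_S:
        raise ValueError("day_end must come after day_start within one day")
    if ramp < 0 or 2 * ramp > e - s:
        raise ValueError("ramps overlap: 2*ramp exceeds the day length")
    return LightSchedule(s, e, ramp)
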