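"""Behavioural measures derived from calibrated tracks.

Speed is the Euclidean displacement between subsequent positions divided
by the frame interval.  "Movement" is speed strictly above 15 mm/s
(below that, apparent motion is mostly tracking noise and fin
undulation); "rest" marks time points with strictly less than 5% movement
in a centred sliding 60-s window — the inactivity proxy for sleep.  Speed
and rest are summarized in 30-min bins anchored at local midnight (48
bins per day), averaged across days and then individuals into a species
profile, and scanned for periodicity with a Fisher g-test periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth.schedule import DAY_S
from .tracking import CalibratedTrack

__all__ = [
    "SpeedSeries", "BinnedDay", "SpeciesProfile",
    "speed", "movement_flags", "rest_flags", "total_rest", "bin30",
    "daily_profile", "vertical_scaled", "rest_position_test", "periodogram",
]

MOVEMENT_THRESHOLD = 15.0     # mm/s
REST_WINDOW_S = 60.0
REST_MAX_FRAC = 0.05
BIN_MINUTES = 30.0
N_BINS = 48


@dataclass
class SpeedSeries:
    timestamps: np.ndarray
    speed: np.ndarray            # mm/s, same length as positions
    fps: float


@dataclass
class BinnedDay:
    """Per-day x 48-bin summary of one series for one individual."""

    values: np.ndarray           # (days, 48), NaN where no samples
    counts: np.ndarray           # (days, 48) sample counts
    bin_minutes: float = BIN_MINUTES

    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    def coverage(self) -> np.ndarray:
        """Fraction of the expected samples present, per day."""
        expected = self.counts.max() if self.counts.size else 0
        full = np.median(self.counts[self.counts > 0]) if (self.counts > 0).any() else 1
        return self.counts.sum(axis=1) / (full * N_BINS)

    def day_means(self, min_coverage: float = 0.95) -> np.ndarray:
        """(complete_days, 48) matrix; days under the coverage floor dropped."""
        keep = self.coverage() >= min_coverage
        return self.values[keep]


@dataclass
class SpeciesProfile:
    species: str
    mean: np.ndarray             # 48-vector, across-day then across-individual mean
    sd_individuals: np.ndarray   # per-bin SD across individuals' daily means
    sd_days: np.ndarray          # per-bin SD across all days of all individuals
    n_individuals: int


def speed(track: CalibratedTrack) -> SpeedSeries:
    """Swim speed from subsequent x/y positions.

    The speed of each frame pair is assigned to the later frame; the first
    frame gets 0 so the series aligns with the positions.
    """
    t = np.asarray(track.timestamps, dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 frames")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    d = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm))
    s = np.concatenate([[0.0], d / dt])
    return SpeedSeries(t, s, track.fps)


def movement_flags(s: SpeedSeries, threshold: float = MOVEMENT_THRESHOLD) -> np.ndarray:
    """Movement = speed strictly greater than the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return s.speed > threshold


def rest_flags(movement: np.ndarray, fps: float,
               window_s: float = REST_WINDOW_S,
               max_frac: float = REST_MAX_FRAC) -> np.ndarray:
    """Rest = strictly less than ``max_frac`` movement in a centred window."""
    w = max(1, int(round(window_s * fps)))
    frac = (pd.Series(movement.astype(float))
            .rolling(w, center=True, min_periods=1).mean().to_numpy())
    # strict boundary: exactly max_frac movement is not rest
    return frac < max_frac - 1e-12


def _day_index(t: np.ndarray):
    return np.floor_divide(t, DAY_S).astype(int)


def bin30(timestamps: np.ndarray, values: np.ndarray,
          bin_minutes: float = BIN_MINUTES) -> BinnedDay:
    """Midnight-anchored 30-min bin means of a per-frame series."""
    t = np.asarray(timestamps, dtype=float)
    v = np.asarray(values, dtype=float)
    width = bin_minutes * 60.0
    nbins = int(round(DAY_S / width))
    day = _day_index(t)
    day -= day.min()
    binidx = ((t % DAY_S) / width).astype(int)
    ndays = day.max() + 1
    sums = np.zeros((ndays, nbins))
    counts = np.zeros((ndays, nbins), dtype=int)
    np.add.at(sums, (day, binidx), v)
    np.add.at(counts, (day, binidx), 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedDay(means, counts, bin_minutes)


def total_rest(rest: np.ndarray, timestamps: np.ndarray,
               min_coverage: float = 0.95) -> float:
    """Mean hours of rest per complete day."""
    t = np.asarray(timestamps, dtype=float)
    day = _day_index(t)
    day -= day.min()
    hours = []
    dt = np.median(np.diff(t))
    expected = DAY_S / dt
    for d in range(day.max() + 1):
        sel = day == d
        if sel.sum() < min_coverage * expected:
            continue   # partial day
        hours.append(rest[sel].mean() * 24.0)
    if not hours:
        raise ValueError("no complete day of data")
    return float(np.mean(hours))


def daily_profile(binned: list[BinnedDay], species: str = "",
                  min_coverage: float = 0.95) -> SpeciesProfile:
    """Species profile: mean across days, then across individuals.

    Per-bin SD is reported both across individuals (SD of the individual
    across-day means) and across all retained days pooled over
    individuals.
    """
    per_ind = []
    all_days = []
    for b in binned:
        days = b.day_means(min_coverage)
        if len(days) == 0:
            continue
        per_ind.append(np.nanmean(days, axis=0))
        all_days.append(days)
    if not per_ind:
        raise ValueError("no individual with a complete day")
    M = np.vstack(per_ind)
    pooled = np.vstack(all_days)
    sd_ind = (np.nanstd(M, axis=0, ddof=1) if len(M) > 1
              else np.nanstd(pooled, axis=0, ddof=1))
    return SpeciesProfile(
        species=species,
        mean=np.nanmean(M, axis=0),
        sd_individuals=sd_ind,
        sd_days=np.nanstd(pooled, axis=0, ddof=1) if len(pooled) > 1 else np.zeros(N_BINS),
        n_individuals=len(M),
    )


def vertical_scaled(track: CalibratedTrack) -> np.ndarray:
    """Vertical position scaled to [0, 1]; 0 = lowest, 1 = highest.

    Image y grows downward, so the axis is inverted before scaling.
    """
    import warnings

    h = -np.asarray(track.y_mm, dtype=float)
    rng = h.max() - h.min()
    if rng <= 0:
        warnings.warn("constant vertical position; returning 0.5")
        return np.full_like(h, 0.5)
    return (h - h.min()) / rng


def rest_position_test(per_individual: dict, n_species_tested: int | None = None):
    """Paired t-test of vertical position, rest vs active, per species.

    ``per_individual`` maps species -> list of (mean_rest_height,
    mean_active_height) pairs, one per individual.  Species with fewer
    than two individuals are skipped.  p-values are Bonferroni-multiplied
    by the number of species tested (capped at 1).
    """
    results = {}
    tested = {sp: pairs for sp, pairs in per_individual.items() if len(pairs) >= 2}
    m = n_species_tested if n_species_tested is not None else len(tested)
    for sp, pairs in tested.items():
        a = np.asarray([p[0] for p in pairs], dtype=float)
        b = np.asarray([p[1] for p in pairs], dtype=float)
        if np.allclose(a, b):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a, b)
        results[sp] = {"t": float(t), "p_raw": float(p),
                       "p_adj": float(min(1.0, p * m)),
                       "n": len(pairs)}
    return results


def _fisher_g_pvalue(g: float, m: int) -> float:
    """Exact tail probability of Fisher's g statistic for m periodogram bins.

    P(G > g) = sum_k (-1)^{k-1} C(m, k) (1 - k g)^{m-1} over k with kg < 1.
    """
    from math import lgamma

    k_max = int(np.floor(1.0 / g)) if g > 0 else m
    p = 0.0
    for k in range(1, min(k_max, m) + 1):
        base = 1.0 - k * g
        if base <= 0:
            break
        log_term = (lgamma(m + 1) - lgamma(k + 1) - lgamma(m - k + 1)
                    + (m - 1) * np.log(base))
        p += (-1) ** (k - 1) * np.exp(log_term)
    return float(min(max(p, 0.0), 1.0))


def periodogram(binned_speed: np.ndarray, bin_minutes: float = BIN_MINUTES,
                threshold: float = 0.05, max_peaks: int = 5):
    """Fisher g-test periodogram of a binned speed series.

    The concatenated (multi-day) series is detrended (mean removed, linear
    trend removed), the FFT power computed at Fourier frequencies, and
    peaks tested iteratively: the largest remaining spectral component is
    tested with Fisher's exact g distribution; testing stops at the first
    non-significant peak.  Returns a list of ``(period_h, power,
    significant)`` sorted by power.
    """
    v = np.asarray(binned_speed, dtype=float).ravel()
    v = v[~np.isnan(v)]
    n = len(v)
    if n < 2 * N_BINS:
        raise ValueError("need >= 2 days of bins")
    x = np.arange(n)
    v = v - np.polyval(np.polyfit(x, v, 1), x)
    power = np.abs(np.fft.rfft(v)[1:]) ** 2
    freqs = np.fft.rfftfreq(n, d=bin_minutes * 60.0)[1:]
    if n % 2 == 0:   # drop the Nyquist term (not exponentially distributed)
        power = power[:-1]
        freqs = freqs[:-1]
    periods_h = 1.0 / freqs / 3600.0
    order = np.argsort(power)[::-1]
    remaining = power.copy()
    results = []
    for rank, idx in enumerate(order[:max_peaks]):
        g = remaining[idx] / remaining.sum()
        m = int((remaining > 0).sum())
        p = _fisher_g_pvalue(g, m)
        sig = p < threshold
        results.append((float(periods_h[idx]), float(power[idx]), bool(sig)))
        if not sig:
            break
        remaining[idx] = 0.0
    return results
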