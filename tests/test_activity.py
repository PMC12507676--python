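"""Speed, movement, rest, binning, profiles, vertical position, rhythm."""

import numpy as np
import pytest

from dielniche import activity as act
from dielniche.synth import make_light_schedule, simulate_track, template_for_guild
from dielniche.tracking import CalibratedTrack, calibrate


def _cal(x, y, fps=10.0, t0=0.0):
    x = np.asarray(x, dtype=float)
    n = len(x)
    return CalibratedTrack(t0 + np.arange(n) / fps, x,
                           np.asarray(y, dtype=float),
                           np.zeros(n, dtype=bool), fps, 1.0)


class TestSpeed:
    def test_stationary_is_zero(self):
        s = act.speed(_cal(np.full(20, 3.0), np.full(20, 4.0)))
        assert np.array_equal(s.speed, np.zeros(20))

    def test_constant_displacement(self):
        x = np.arange(20) * 3.0            # 3 mm per 0.1 s frame
        s = act.speed(_cal(x, x * 0))
        assert np.allclose(s.speed[1:], 30.0)
        assert s.speed[0] == 0.0

    def test_circular_path_speed_is_r_omega(self):
        r, omega, fps = 50.0, 0.5, 20.0
        t = np.arange(0, 200) / fps
        track = _cal(r * np.cos(omega * t), r * np.sin(omega * t), fps=fps)
        s = act.speed(track)
        assert np.allclose(s.speed[1:], r * omega, rtol=1e-3)

    def test_non_monotone_timestamps_rejected(self):
        c = _cal(np.zeros(5), np.zeros(5))
        c.timestamps[3] = c.timestamps[2]
        with pytest.raises(ValueError):
            act.speed(c)


class TestMovementAndRest:
    def test_strict_threshold_boundary(self):
        s = act.SpeedSeries(np.arange(3.0), np.array([14.9, 15.0, 15.1]), 1.0)
        assert list(act.movement_flags(s)) == [False, False, True]

    def test_all_still_is_all_rest(self):
        m = np.zeros(600, dtype=bool)
        assert act.rest_flags(m, fps=1.0).all()

    def test_exactly_five_percent_is_not_rest(self):
        # one movement frame per 20 at 1 Hz: every centred 60-s window
        # holds exactly 3/60 = 5% movement
        m = np.zeros(1200, dtype=bool)
        m[::20] = True
        r = act.rest_flags(m, fps=1.0)
        assert not r[100:-100].any()

    def test_just_under_five_percent_is_rest(self):
        m = np.zeros(1200, dtype=bool)
        m[::30] = True                      # exactly 2/60 = 3.33% per window
        r = act.rest_flags(m, fps=1.0)
        interior = r[100:-100]
        assert interior.mean() > 0.9

    def test_alternating_blocks_match_bruteforce_window_oracle(self):
        # 10 min active / 10 min still at 1 Hz; oracle recomputes the
        # centred-window movement fraction frame by frame
        block = 600
        m = np.tile(np.concatenate([np.ones(block), np.zeros(block)]),
                    4).astype(bool)
        r = act.rest_flags(m, fps=1.0)
        n = len(m)
        oracle = np.empty(n, dtype=bool)
        for i in range(n):
            lo, hi = max(0, i - 30), min(n, i + 30)
            oracle[i] = m[lo:hi].mean() < 0.05
        assert np.array_equal(r, oracle)
        # rest fraction is 0.5 minus <= 60 s erosion per transition
        assert 0.5 - (8 * 60) / n <= r.mean() < 0.5

    def test_rest_monotone_in_max_frac(self, rng):
        m = rng.random(2000) < 0.06
        r_low = act.rest_flags(m, fps=1.0, max_frac=0.05)
        r_high = act.rest_flags(m, fps=1.0, max_frac=0.10)
        assert (r_high | ~r_low).all()      # raising max_frac never removes rest


class TestTotalRest:
    def test_always_rest_is_24h(self):
        n = 86400
        t = np.arange(n, dtype=float)
        assert act.total_rest(np.ones(n, dtype=bool), t) == 24.0

    def test_never_rest_is_0h(self):
        n = 86400
        t = np.arange(n, dtype=float)
        assert act.total_rest(np.zeros(n, dtype=bool), t) == 0.0

    def test_rest_plus_active_is_24h_exactly(self, rng):
        n = 2 * 86400
        t = np.arange(n, dtype=float)
        r = rng.random(n) < 0.3
        assert act.total_rest(r, t) + act.total_rest(~r, t) == pytest.approx(24.0, abs=1e-12)

    def test_partial_days_excluded(self):
        n = 86400 + 3600                   # one full day + one hour
        t = np.arange(n, dtype=float)
        r = np.zeros(n, dtype=bool)
        r[86400:] = True                   # rest only in the partial day
        assert act.total_rest(r, t) == 0.0

    def test_two_state_generator_target_recovered(self, schedule):
        # long bouts keep the window-edge erosion small
        rates = {k: 5 / 6 for k in ("day", "night", "dawn-ramp", "dusk-ramp")}
        tmpl = template_for_guild("cathemeral", rest_bout_rate=rates,
                                  rest_bout_mean_duration=1800.0)
        # expected rest fraction (5/6)*1800/3600 = 5/12 -> 10 h/day
        traj, gt = simulate_track(tmpl, schedule, days=4, fps=1.0, seed=8)
        cal = calibrate(traj)
        rest = act.rest_flags(act.movement_flags(act.speed(cal)), fps=1.0)
        got = act.total_rest(rest, cal.timestamps)
        realized = gt.rest.mean() * 24.0
        assert got == pytest.approx(realized, abs=0.5)
        # the bout process itself scatters around the 10 h design target
        assert realized == pytest.approx(10.0, abs=2.0)


class TestBinning:
    def test_constant_series(self):
        t = np.arange(0, 86400, 2.0)
        b = act.bin30(t, np.full(len(t), 5.5))
        assert b.values.shape == (1, 48)
        assert np.allclose(b.values, 5.5)

    def test_day_night_square_wave(self):
        sch = make_light_schedule("07:00", "19:00", 0)
        t = np.arange(0, 86400, 10.0)
        v = (np.asarray(sch.state(t)) == "day").astype(float)
        b = act.bin30(t, v)
        assert b.values.sum() == 24.0       # 24 day bins of 1, 24 night of 0
        assert set(np.unique(b.values)) == {0.0, 1.0}

    def test_missing_hour_flagged_by_counts(self):
        t = np.arange(0, 86400, 1.0)
        keep = (t < 3600 * 10) | (t >= 3600 * 11)
        b = act.bin30(t[keep], np.ones(keep.sum()))
        assert (b.counts[0, 20:22] == 0).all()
        assert np.isnan(b.values[0, 20:22]).all()
        assert (b.counts[0, :20] == 1800).all()

    def test_midnight_anchoring_over_days(self):
        t = np.arange(0, 2 * 86400, 30.0)
        v = np.cos(2 * np.pi * t / 86400.0)
        b = act.bin30(t, v)
        assert b.values.shape == (2, 48)
        assert np.allclose(b.values[0], b.values[1], atol=1e-9)


class TestDailyProfile:
    def _bd(self, mat):
        mat = np.atleast_2d(np.asarray(mat, dtype=float))
        return act.BinnedDay(mat, np.full(mat.shape, 1800, dtype=int))

    def test_identical_days_give_that_day(self):
        day = np.sin(np.linspace(0, 2 * np.pi, 48)) + 2
        p = act.daily_profile([self._bd(np.tile(day, (4, 1)))], species="spXXXX")
        assert np.allclose(p.mean, day)

    def test_two_individuals_average(self):
        a = np.full(48, 2.0)
        b = np.full(48, 6.0)
        p = act.daily_profile([self._bd(a), self._bd(b)])
        assert np.allclose(p.mean, 4.0)
        assert np.allclose(p.sd_individuals, np.std([2.0, 6.0], ddof=1))

    def test_sd_matches_direct_formula_on_three_individuals(self, rng):
        mats = [rng.random((3, 48)) + 1 for _ in range(3)]
        p = act.daily_profile([self._bd(m) for m in mats])
        ind_means = np.vstack([m.mean(axis=0) for m in mats])
        assert np.allclose(p.sd_individuals, ind_means.std(axis=0, ddof=1))
        assert np.allclose(p.mean, ind_means.mean(axis=0))


class TestVerticalPosition:
    def test_scaling_and_inversion(self):
        # image y grows downward: largest y is the lowest position
        track = _cal(np.zeros(5), np.array([100.0, 75.0, 50.0, 25.0, 0.0]))
        v = act.vertical_scaled(track)
        assert v[0] == 0.0 and v[-1] == 1.0 and v[2] == pytest.approx(0.5)
        assert (np.diff(v) > 0).all()

    def test_constant_height_warns_and_returns_half(self):
        track = _cal(np.zeros(5), np.full(5, 10.0))
        with pytest.warns(UserWarning):
            v = act.vertical_scaled(track)
        assert np.allclose(v, 0.5)

    def test_paired_test_matches_textbook_formula(self):
        rest = [0.10, 0.15, 0.12, 0.08, 0.11]
        active = [0.22, 0.25, 0.20, 0.19, 0.24]
        res = act.rest_position_test({"spAAAA": list(zip(rest, active))},
                                     n_species_tested=1)
        d = np.array(rest) - np.array(active)
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res["spAAAA"]["t"] == pytest.approx(t_hand)

    def test_identical_positions_and_bonferroni(self):
        pairs = [(0.3, 0.3)] * 4
        res = act.rest_position_test({"spAAAA": pairs}, n_species_tested=5)
        assert res["spAAAA"]["t"] == 0.0 and res["spAAAA"]["p_adj"] == 1.0
        rest = [0.1, 0.2, 0.15, 0.12, 0.18]
        active = [r + 0.1 for r in rest]
        res2 = act.rest_position_test({"spBBBB": list(zip(rest, active))},
                                      n_species_tested=5)
        assert res2["spBBBB"]["p_adj"] == pytest.approx(
            min(1.0, res2["spBBBB"]["p_raw"] * 5))

    def test_single_individual_species_skipped(self):
        res = act.rest_position_test({"spCCCC": [(0.1, 0.2)]})
        assert "spCCCC" not in res


class TestPeriodogram:
    def test_24h_rhythm_detected(self, rng):
        t = np.arange(4 * 48) * 0.5        # hours
        v = 3 + np.sin(2 * np.pi * t / 24.0) + rng.normal(0, 0.2, len(t))
        peaks = act.periodogram(v)
        assert peaks[0][2] is True
        assert peaks[0][0] == pytest.approx(24.0, rel=0.05)

    def test_two_superposed_periods_both_found(self, rng):
        t = np.arange(8 * 48) * 0.5
        v = (np.sin(2 * np.pi * t / 24.0) + 0.8 * np.sin(2 * np.pi * t / 12.0)
             + rng.normal(0, 0.15, len(t)))
        peaks = act.periodogram(v)
        sig_periods = sorted(p for p, _, s in peaks if s)
        assert any(abs(p - 12.0) < 0.5 for p in sig_periods)
        assert any(abs(p - 24.0) < 1.0 for p in sig_periods)

    def test_white_noise_type_one_error_rate(self):
        rng = np.random.default_rng(123)
        n_rep = 1000
        hits = 0
        for _ in range(n_rep):
            v = rng.normal(0, 1, 96)
            peaks = act.periodogram(v)
            hits += any(s for _, _, s in peaks)
        rate = hits / n_rep
        assert 0.03 <= rate <= 0.07        # ~ the 0.05 threshold
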