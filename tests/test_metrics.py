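import itertools

import numpy as np
import pytest

from myoforce.metrics import (
    PeakSet,
    alignment_window,
    build_report,
    detect_peaks,
    match_peaks,
    r_squared,
    rise_fall_times,
)

FS = 1000.0


def _bumps(n, centers, heights, width=40.0):
    x = np.zeros(n)
    i = np.arange(n)
    for c, h in zip(centers, heights):
        x += h * np.exp(-0.5 * ((i - c) / width) ** 2)
    return x


class TestDetectPeaks:
    def test_constant_series(self):
        assert len(detect_peaks(np.full(100, 3.0))) == 0

    def test_single_triangle(self):
        x = np.concatenate([np.zeros(50), np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:], np.zeros(50)])
        ps = detect_peaks(x)
        assert len(ps) == 1
        assert ps.indices[0] == 100

    def test_dc_offset_invariance(self):
        x = _bumps(5000, [500, 1500, 2500, 3500, 4500], [1.0, 1.1, 0.9, 1.05, 1.0])
        a = detect_peaks(x)
        b = detect_peaks(x + 10.0)
        np.testing.assert_array_equal(a.indices, b.indices)
        assert len(a) == 5

    def test_plateau_first_max_sample(self):
        x = np.zeros(50)
        x[20:25] = 1.0
        ps = detect_peaks(x)
        assert len(ps) == 1
        assert ps.indices[0] == 20

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.array([1.0, 2.0]))

    def test_heights_meet_threshold(self):
        x = _bumps(3000, [400, 1400, 2400], [1.0, 0.8, 1.2])
        ps = detect_peaks(x)
        assert np.all(ps.heights >= ps.threshold)


class TestMatchPeaks:
    def _sets(self, m_idx, e_idx, n=5000):
        m = PeakSet(np.array(m_idx), np.ones(len(m_idx)), 0.0, n)
        e = PeakSet(np.array(e_idx), np.ones(len(e_idx)), 0.0, n)
        return m, e

    def test_identical_sets(self):
        m, e = self._sets([500, 1500, 2500], [500, 1500, 2500])
        pairs, missed, extra = match_peaks(m, e)
        assert len(pairs) == 3 and not missed and not extra

    def test_shift_beyond_window_all_unmatched(self):
        # intervals all 1000 -> window = 450; a 500-sample shift leaves every
        # estimated peak 500 samples from both neighboring measured peaks
        m, e = self._sets([500, 1500, 2500], [1000, 2000, 3000])
        pairs, missed, extra = match_peaks(m, e)
        assert not pairs
        assert missed == [500, 1500, 2500]
        assert extra == [1000, 2000, 3000]

    def test_closest_wins_other_is_extra(self):
        m, e = self._sets([1000, 2000], [980, 1100, 2000])
        pairs, missed, extra = match_peaks(m, e)
        assert (1000, 980) in pairs
        assert extra == [1100]

    def test_window_value(self):
        m, _ = self._sets([0, 1000, 2000, 3000], [])
        assert alignment_window(m) == pytest.approx(0.45 * 1000)

    def test_fallback_window_single_peak(self):
        m = PeakSet(np.array([100]), np.ones(1), 0.0, 1000)
        assert alignment_window(m) == pytest.approx(0.45 * 1000 / 1)

    def test_swap_exchanges_missed_extra(self):
        m, e = self._sets([500, 1500, 2500], [510, 1490, 4000])
        _, missed, extra = match_peaks(m, e)
        _, missed2, extra2 = match_peaks(e, m, window=alignment_window(m))
        assert missed == extra2 and extra == missed2

    def test_mismatched_series_length_rejected(self):
        m = PeakSet(np.array([1]), np.ones(1), 0.0, 100)
        e = PeakSet(np.array([1]), np.ones(1), 0.0, 200)
        with pytest.raises(ValueError):
            match_peaks(m, e)


class TestRiseFallTimes:
    def test_symmetric_triangle(self):
        # linear rise over 0.1 s: half-height crossing 0.05 s before peak
        x = np.concatenate([np.zeros(100), np.linspace(0, 1, 101), np.linspace(1, 0, 101)[1:], np.zeros(100)])
        rise, fall = rise_fall_times(x, 200, FS, debaseline=False)
        assert rise == pytest.approx(0.05, abs=1e-6)
        assert fall == pytest.approx(0.05, abs=1e-6)

    def test_half_cosine_pulse(self):
        # x(t) = cos(pi t / T) on [-T/2, T/2]: 50% crossings at t = -T/3, +T/3
        T = 0.3
        t = np.arange(-T / 2, T / 2 + 1e-9, 1 / FS)
        x = np.cos(np.pi * t / T)
        pad = np.zeros(50)
        x = np.concatenate([pad, np.clip(x, 0, None), pad])
        peak = int(np.argmax(x))
        rise, fall = rise_fall_times(x, peak, FS, debaseline=False)
        assert rise == pytest.approx(T / 3, abs=2e-3)
        assert fall == pytest.approx(T / 3, abs=2e-3)

    def test_level_never_crossed(self):
        x = np.ones(100)
        x[50] = 1.001
        rise, fall = rise_fall_times(x, 50, FS, debaseline=False)
        assert rise is None and fall is None

    def test_interpolation_between_samples(self):
        x = np.array([0.0, 0.0, 0.2, 0.8, 1.0, 0.8, 0.2, 0.0, 0.0])
        rise, fall = rise_fall_times(x, 4, FS, debaseline=False)
        # crossing of 0.5 between samples 2 and 3: frac = 0.3/0.6
        assert rise == pytest.approx((4 - 2.5) / FS)
        assert fall == pytest.approx((5.5 - 4) / FS)


class TestRSquared:
    def test_perfect(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == 1.0

    def test_mean_predictor(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0)) == 0.0

    def test_large_offset_negative(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, np.full(3, 2.0) + 10.0) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.ones(5))


class TestBuildReport:
    def test_perfect_predictions(self):
        f = _bumps(4000, [500, 1500, 2500, 3500], [2.0, 2.2, 1.9, 2.1])
        rep = build_report([(f, f.copy())], f_max=2.0, fs=FS)
        row = rep.per_trial.iloc[0]
        assert row["rmse_norm"] == 0.0
        assert row["r2"] == 1.0
        assert row["missed_pct"] == 0.0 and row["extra_pct"] == 0.0
        assert row["rise_rmse"] == 0.0 and row["fall_rmse"] == 0.0

    def test_rrmse_scale_invariance(self):
        f = _bumps(3000, [500, 1500, 2500], [2.0, 2.2, 1.9])
        g = _bumps(3000, [520, 1480, 2500], [1.8, 2.3, 2.0])
        r1 = build_report([(f, g)], f_max=2.0, fs=FS)
        r2 = build_report([(10 * f, 10 * g)], f_max=20.0, fs=FS)
        assert r1.per_trial["rrmse_pct"][0] == pytest.approx(r2.per_trial["rrmse_pct"][0])
        assert r1.per_trial["rmse_norm"][0] == pytest.approx(r2.per_trial["rmse_norm"][0])

    def test_two_trial_bookkeeping_matches_enumeration(self):
        # trial 1: 3 measured / 3 estimated, one shifted out of window
        f1 = _bumps(4000, [500, 1500, 2500], [2.0, 2.0, 2.0], width=30)
        g1 = _bumps(4000, [500, 1500, 3200], [2.0, 2.0, 2.0], width=30)
        # trial 2: 2 measured, 3 estimated
        f2 = _bumps(4000, [1000, 3000], [2.0, 2.0], width=30)
        g2 = _bumps(4000, [1000, 2000, 3000], [2.0, 2.0, 2.0], width=30)
        rep = build_report([(f1, g1), (f2, g2)], f_max=2.0, fs=FS)
        assert rep.per_trial["missed_pct"].tolist() == [pytest.approx(100 / 3), 0.0]
        assert rep.per_trial["extra_pct"].tolist() == [pytest.approx(100 / 3), pytest.approx(100 / 3)]
        assert rep.aggregates["missed_pct_mean"] == pytest.approx((100 / 3) / 2)

    def test_aggregate_consistency(self):
        f = _bumps(3000, [500, 1500, 2500], [2.0, 2.2, 1.9])
        g = np.roll(f, 15)
        rep = build_report([(f, g), (f, f.copy())], f_max=2.0, fs=FS)
        vals = rep.per_trial["rmse_norm"].to_numpy()
        assert rep.aggregates["rmse_norm_mean"] == pytest.approx(vals.mean())
        assert rep.aggregates["r2_median"] == pytest.approx(np.median(rep.per_trial["r2"]))
        assert rep.aggregates["r2_min"] <= rep.aggregates["r2_median"] <= rep.aggregates["r2_max"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_report([], f_max=1.0, fs=FS)

    def test_json_csv_output(self, tmp_path):
        f = _bumps(3000, [500, 1500, 2500], [2.0, 2.2, 1.9])
        rep = build_report([(f, np.roll(f, 5))], f_max=2.0, fs=FS)
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "r.csv")
        assert (tmp_path / "r.json").exists()
        assert (tmp_path / "r.csv").read_text().startswith("rmse_norm")


def brute_force_match(m_idx, e_idx, window):
    """Exhaustive search over one-to-one pairings: maximize matches, then
    minimize total distance."""
    best = (0, 0.0, [])
    m_idx, e_idx = list(m_idx), list(e_idx)
    k_max = min(len(m_idx), len(e_idx))
    for k in range(k_max, -1, -1):
        found = None
        for m_sub in itertools.combinations(range(len(m_idx)), k):
            for e_perm in itertools.permutations(range(len(e_idx)), k):
                if all(abs(m_idx[m] - e_idx[e]) < window for m, e in zip(m_sub, e_perm)):
                    dist = sum(abs(m_idx[m] - e_idx[e]) for m, e in zip(m_sub, e_perm))
                    if found is None or dist < found[0]:
                        found = (dist, list(zip(m_sub, e_perm)))
        if found is not None:
            return k, found[0], found[1]
    return 0, 0.0, []


class TestMatchAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = 10000
        m_idx = np.sort(rng.choice(np.arange(200, 9800), size=rng.integers(2, 6), replace=False))
        e_idx = np.sort(rng.choice(np.arange(200, 9800), size=rng.integers(1, 6), replace=False))
        m = PeakSet(m_idx, np.ones(m_idx.size), 0.0, n)
        e = PeakSet(e_idx, np.ones(e_idx.size), 0.0, n)
        window = alignment_window(m)
        pairs, missed, extra = match_peaks(m, e, window=window)
        k, dist, _ = brute_force_match(m_idx, e_idx, window)
        assert len(pairs) == k
        assert len(missed) == len(m_idx) - k
        assert len(extra) == len(e_idx) - k
        assert sum(abs(a - b) for a, b in pairs) == pytest.approx(dist)
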