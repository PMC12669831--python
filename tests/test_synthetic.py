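import numpy as np
import pytest

from myoforce.hill import HillParams, hill_force
from myoforce.io import load_dataset, read_trial, save_dataset, write_trial
from myoforce.synthetic import (
    SyntheticConfig,
    Trial,
    generate_activation,
    generate_dataset,
    generate_fascicle,
    generate_raw_emg,
    synthesize_force,
)

FS = 1000.0
PARAMS = HillParams(W=0.25, v_max=7.0, A_rel=0.27, g_max=1.5, k_pee=4.0, l_slack_pee=1.0)


class TestGenerateActivation:
    def test_no_jitter_identical_bursts(self):
        a = generate_activation(3, 0.5, 0.4, FS, jitter=0.0, seed=0)
        n_per = 500
        strides = a.reshape(3, n_per)
        np.testing.assert_array_equal(strides[0], strides[1])
        np.testing.assert_array_equal(strides[1], strides[2])
        assert a.max() == 1.0

    def test_burst_support_samples(self):
        # duty 0.4 of a 0.5 s stride at 1 kHz -> 200 samples above zero
        a = generate_activation(3, 0.5, 0.4, FS, jitter=0.0, seed=0)
        for stride in a.reshape(3, 500):
            assert np.count_nonzero(stride > 0) == 200

    def test_determinism(self):
        a = generate_activation(5, 0.4, 0.3, FS, jitter=0.2, seed=42)
        b = generate_activation(5, 0.4, 0.3, FS, jitter=0.2, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_range(self):
        a = generate_activation(6, 0.4, 0.3, FS, jitter=0.3, seed=1)
        assert a.min() >= 0.0 and a.max() == 1.0

    @pytest.mark.parametrize("bad", [dict(duty=0.0), dict(duty=1.0), dict(stride_duration=-1.0)])
    def test_invalid_args(self, bad):
        kwargs = dict(n_strides=3, stride_duration=0.5, duty=0.4, fs=FS, jitter=0.0, seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            generate_activation(**kwargs)


class TestGenerateFascicle:
    def test_zero_amplitude_constant(self):
        lce, vce = generate_fascicle(3, 0.5, FS, amp=0.0, mean_l=1.0, seed=0)
        np.testing.assert_allclose(lce, 1.0)
        np.testing.assert_allclose(vce, 0.0, atol=1e-9)

    def test_bounds(self):
        lce, vce = generate_fascicle(6, 0.5, FS, amp=0.08, mean_l=1.0, seed=1)
        assert lce.min() >= 1.0 - 0.08 - 1e-12
        assert lce.max() <= 1.0 + 0.08 + 1e-12

    def test_velocity_bounded_for_defaults(self):
        # brute-force scan across seeds and gait-like stride durations
        worst = 0.0
        for seed in range(5):
            for dur in (0.3, 0.4, 0.5):
                _, vce = generate_fascicle(6, dur, FS, amp=0.08, mean_l=1.0, seed=seed)
                worst = max(worst, float(np.max(np.abs(vce))))
        assert worst <= 10.0

    def test_amp_exceeding_mean_rejected(self):
        with pytest.raises(ValueError):
            generate_fascicle(3, 0.5, FS, amp=1.2, mean_l=1.0, seed=0)

    def test_velocity_integrates_back_to_length(self):
        lce, vce = generate_fascicle(6, 0.5, FS, amp=0.08, mean_l=1.0, seed=3)
        rebuilt = lce[0] + np.concatenate([[0.0], np.cumsum((vce[1:] + vce[:-1]) / 2) / FS])
        rms = np.sqrt(np.mean((rebuilt - lce) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(lce**2))


class TestGenerateRawEmg:
    def test_zero_activation_zero_output(self):
        emg = generate_raw_emg(np.zeros(2000), FS, noise_sd=0.0, seed=0)
        np.testing.assert_array_equal(emg, 0.0)

    def test_zero_mean(self):
        a = generate_activation(6, 0.5, 0.4, FS, 0.05, seed=1)
        emg = generate_raw_emg(a, FS, noise_sd=0.0, seed=2)
        assert abs(emg.mean()) < 0.01 * emg.std()

    def test_determinism(self):
        a = generate_activation(3, 0.5, 0.4, FS, 0.05, seed=1)
        e1 = generate_raw_emg(a, FS, delay=0.02, noise_sd=0.01, seed=7)
        e2 = generate_raw_emg(a, FS, delay=0.02, noise_sd=0.01, seed=7)
        np.testing.assert_array_equal(e1, e2)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            generate_raw_emg(np.zeros(100), 200.0, carrier_band=(80.0, 150.0), seed=0)
        with pytest.raises(ValueError):
            generate_raw_emg(np.zeros(100), 1000.0, carrier_band=(10.0, 100.0), seed=0)


class TestSynthesizeForce:
    def _inputs(self, n=1500):
        t = np.arange(n) / FS
        a = np.clip(np.sin(2 * np.pi * 2 * t), 0, None)
        lce = 1.0 + 0.1 * np.sin(2 * np.pi * 1.3 * t)
        vce = np.gradient(lce) * FS
        return a, lce, vce

    def test_reduces_to_hill(self):
        a, lce, vce = self._inputs()
        f = synthesize_force(a, lce, vce, PARAMS, 5.0, history_gain=0.0, noise_sd_force=0.0)
        np.testing.assert_allclose(f, hill_force(a, lce, vce, PARAMS, 5.0), atol=1e-12)

    def test_zero_activation_below_slack(self):
        n = 500
        a = np.zeros(n)
        lce = np.full(n, 0.95)
        vce = np.zeros(n)
        f = synthesize_force(a, lce, vce, PARAMS, 5.0)
        np.testing.assert_array_equal(f, 0.0)

    def test_history_dissociates_identical_states(self):
        # same (a, l, v) at two times, but one follows an active stretch
        n = 4000
        a = np.full(n, 0.8)
        lce = np.ones(n)
        vce = np.zeros(n)
        vce[1000:1500] = 2.0  # stretch episode before t1
        t0, t1 = 500, 1600
        assert (a[t0], lce[t0], vce[t0]) == (a[t1], lce[t1], vce[t1])
        f = synthesize_force(a, lce, vce, PARAMS, 5.0, history_gain=0.2, fs=FS)
        assert f[t1] > f[t0] + 1e-3

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            synthesize_force(np.zeros(10), np.ones(11), np.zeros(10), PARAMS, 5.0)

    def test_nonnegative_with_noise(self):
        a, lce, vce = self._inputs()
        f = synthesize_force(a, lce, vce, PARAMS, 5.0, noise_sd_force=0.5, seed=1, fs=FS)
        assert np.all(f >= 0.0)


class TestGenerateDataset:
    def test_grid_size(self):
        cfg = SyntheticConfig(
            n_birds=2,
            muscles=("LG", "DF"),
            speeds=(1.8, 3.0, 4.5),
            obstacle_heights=(0,),
            n_strides=2,
            fs=500.0,
            carrier_band=(80.0, 200.0),
        )
        assert len(generate_dataset(cfg)) == 12

    def test_byte_identical_under_seed(self, small_config, small_dataset, tmp_path):
        trials2 = generate_dataset(small_config)
        save_dataset(small_dataset, tmp_path / "a")
        save_dataset(trials2, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_trial_invariants(self, small_dataset):
        for tr in small_dataset:
            assert np.all(tr.lce > 0)
            assert np.all(np.isfinite(tr.force))
            assert tr.meta["muscle"] in ("LG", "DF")

    def test_obstacle_trials_differ(self, small_config):
        cfg_level = SyntheticConfig(**{**small_config.__dict__, "obstacle_heights": (0,)})
        cfg_obst = SyntheticConfig(**{**small_config.__dict__, "obstacle_heights": (7,)})
        level = generate_dataset(cfg_level)[0]
        obst = generate_dataset(cfg_obst)[0]
        assert obst.lce.max() > level.lce.max()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(muscles=())


class TestTrial:
    def test_validation(self):
        with pytest.raises(ValueError):
            Trial(
                t=np.array([0.0, 1.0, 1.0]),
                emg_raw=np.zeros(3),
                activation=np.zeros(3),
                lce=np.ones(3),
                vce=np.zeros(3),
                force=np.zeros(3),
            )
        with pytest.raises(ValueError):
            Trial(
                t=np.arange(3.0),
                emg_raw=np.zeros(2),
                activation=np.zeros(3),
                lce=np.ones(3),
                vce=np.zeros(3),
                force=np.zeros(3),
            )

    def test_slice(self, small_dataset):
        tr = small_dataset[0]
        sub = tr.slice(10, 100)
        assert sub.n_samples == 90
        assert sub.fs == pytest.approx(tr.fs)


class TestIO:
    def test_trial_roundtrip(self, small_dataset, tmp_path):
        tr = small_dataset[0]
        write_trial(tr, tmp_path / "t.csv")
        back = read_trial(tmp_path / "t.csv", meta=tr.meta)
        np.testing.assert_allclose(back.force, tr.force, rtol=1e-9)
        assert back.meta == tr.meta

    def test_dataset_roundtrip(self, small_dataset, tmp_path):
        manifest = save_dataset(small_dataset, tmp_path / "ds", fmt="yaml")
        back = load_dataset(manifest)
        assert len(back) == len(small_dataset)
        assert back[3].meta == small_dataset[3].meta
        np.testing.assert_allclose(back[3].lce, small_dataset[3].lce, rtol=1e-9)
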