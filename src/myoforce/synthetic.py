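"""Synthetic gait trials with the statistical structure of the in vivo dataset.

Generates multi-bird, two-muscle trial grids: cyclic raised-cosine
activation bursts with stride-to-stride jitter, fascicle length oscillating
near the optimal length, amplitude-modulated band-limited raw EMG, and
tendon force produced by a ground-truth Hill model plus an optional
history-dependent (force-enhancement) term and sensor noise.  Obstacle
trials perturb every 4th-5th stride (elevated activation, offset length) to
dissociate activation from force.  Everything is reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .hill import HillParams, hill_force
from .preprocessing import DEFAULT_DELAY_S, lowpass_6hz, velocity_from_length

__all__ = [
    "Trial",
    "SyntheticConfig",
    "generate_activation",
    "generate_fascicle",
    "generate_raw_emg",
    "synthesize_force",
    "generate_dataset",
    "default_ground_truth",
]

#: Time constant of the history (force-enhancement) leaky integrator, s.
HISTORY_TAU_S = 0.1
#: Obstacle-stride perturbation: activation gain and length offset (L0).
OBSTACLE_ACT_GAIN = 1.3
OBSTACLE_LEN_OFFSET = 0.05


@dataclass
class Trial:
    """One recording: uniformly sampled series plus metadata.

    ``lce``/``vce`` are normalized to optimal fiber length (L0, L0/s),
    ``force`` is in Newtons, ``activation`` is the scaled envelope (may
    exceed 1), ``emg_raw`` is in arbitrary units.
    """

    t: np.ndarray
    emg_raw: np.ndarray
    activation: np.ndarray
    lce: np.ndarray
    vce: np.ndarray
    force: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = [self.t, self.emg_raw, self.activation, self.lce, self.vce, self.force]
        arrays = [np.asarray(a, dtype=float) for a in arrays]
        self.t, self.emg_raw, self.activation, self.lce, self.vce, self.force = arrays
        n = self.t.size
        if n < 2:
            raise ValueError("trial must contain at least 2 samples")
        if any(a.size != n for a in arrays):
            raise ValueError("all trial series must have the same length")
        if any(not np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("trial series must be finite")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("t must be strictly increasing with a constant step")
        if np.any(self.lce <= 0):
            raise ValueError("lce must be positive")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    def slice(self, start: int, stop: int) -> "Trial":
        """Sub-trial over sample range [start, stop)."""
        return Trial(
            t=self.t[start:stop],
            emg_raw=self.emg_raw[start:stop],
            activation=self.activation[start:stop],
            lce=self.lce[start:stop],
            vce=self.vce[start:stop],
            force=self.force[start:stop],
            meta=dict(self.meta),
        )


def default_ground_truth() -> dict[str, HillParams]:
    """Ground-truth Hill parameters per muscle (distinct W/v_max per muscle)."""
    return {
        "LG": HillParams(W=0.25, v_max=7.0, A_rel=0.27, g_max=1.5, k_pee=4.0, l_slack_pee=1.0),
        "DF": HillParams(W=0.18, v_max=9.0, A_rel=0.2, g_max=1.4, k_pee=6.0, l_slack_pee=0.98),
    }


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic trial grid."""

    n_birds: int = 2
    muscles: tuple = ("LG", "DF")
    speeds: tuple = (1.8, 4.5)  # m/s
    obstacle_heights: tuple = (0, 7)  # cm
    fs: float = 1000.0  # Hz
    n_strides: int = 8
    ground_truth: dict = field(default_factory=default_ground_truth)
    pcsa: dict = field(default_factory=dict)  # (bird_id, muscle) -> mm^2
    activation_scale_error: dict = field(default_factory=dict)  # (bird_id, muscle) -> factor
    history_gain: float = 0.0
    noise_sd_force: float = 0.0  # fraction of F_max
    noise_sd_emg: float = 0.0
    seed: int = 0
    duty: float = 0.4
    fascicle_amp: float = 0.08  # L0
    fascicle_mean: float = 1.0  # L0
    jitter: float = 0.05
    emg_delay: float = DEFAULT_DELAY_S
    carrier_band: tuple = (80.0, 240.0)  # Hz

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.history_gain < 0:
            raise ValueError("history_gain must be >= 0")
        if self.n_birds < 1 or not self.muscles or not self.speeds or not self.obstacle_heights:
            raise ValueError("empty generation grid")
        for key, val in self.activation_scale_error.items():
            if not val > 0:
                raise ValueError(f"activation_scale_error must be positive ({key})")
        for key, val in self.pcsa.items():
            if not val > 0:
                raise ValueError(f"pcsa must be positive ({key})")

    @property
    def bird_ids(self) -> list[str]:
        return [f"bird{i + 1}" for i in range(self.n_birds)]

    def pcsa_for(self, bird_id: str, muscle: str) -> float:
        if (bird_id, muscle) in self.pcsa:
            return float(self.pcsa[(bird_id, muscle)])
        # distinct default PCSAs per muscle, slight spread across birds
        base = {"LG": 30.0, "DF": 10.0}.get(muscle, 20.0)
        rank = self.bird_ids.index(bird_id)
        return base * (1.0 + 0.05 * rank)

    def scale_error_for(self, bird_id: str, muscle: str) -> float:
        return float(self.activation_scale_error.get((bird_id, muscle), 1.0))


def _burst_window(n_b: int) -> np.ndarray:
    """Raised-cosine burst of n_b strictly positive samples (peak near 1)."""
    k = np.arange(1, n_b + 1, dtype=float)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n_b + 1)))


def stride_boundaries(n_strides: int, stride_duration: float, fs: float) -> np.ndarray:
    """Sample indices delimiting strides, length n_strides + 1."""
    n_per = int(round(stride_duration * fs))
    return np.arange(n_strides + 1) * n_per


def generate_activation(
    n_strides: int,
    stride_duration: float,
    duty: float,
    fs: float,
    jitter: float,
    seed,
) -> np.ndarray:
    """Cyclic raised-cosine activation bursts in [0, 1].

    One burst per stride spanning ``duty * stride_duration``; ``jitter``
    scales stride-to-stride amplitude and onset variability.  The series is
    normalized so the maximum is exactly 1.
    """
    if fs <= 0 or stride_duration <= 0:
        raise ValueError("fs and stride_duration must be positive")
    if not 0 < duty < 1:
        raise ValueError("duty must lie in (0, 1)")
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    rng = np.random.default_rng(seed)
    n_per = int(round(stride_duration * fs))
    n_b = int(round(duty * stride_duration * fs))
    if n_b < 2 or n_b > n_per:
        raise ValueError("duty cycle resolves to a degenerate burst length")
    out = np.zeros(n_strides * n_per)
    window = _burst_window(n_b)
    base_onset = (n_per - n_b) // 2
    for i in range(n_strides):
        amp = max(0.0, 1.0 + jitter * rng.uniform(-1.0, 1.0))
        shift = int(round(jitter * 0.2 * n_per * rng.uniform(-1.0, 1.0)))
        onset = i * n_per + base_onset + shift
        lo = max(onset, 0)
        hi = min(onset + n_b, out.size)
        if hi > lo:
            out[lo:hi] = np.maximum(out[lo:hi], amp * window[lo - onset : hi - onset])
    peak = out.max()
    if peak > 0:
        out /= peak
    return out


def generate_fascicle(
    n_strides: int,
    stride_duration: float,
    fs: float,
    amp: float,
    mean_l: float,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Fascicle length oscillating near ``mean_l`` and its filtered velocity.

    Length stays within ``[mean_l - amp, mean_l + amp]``; velocity is the
    central-difference derivative passed through the 6 Hz zero-phase
    low-pass.  Per-stride amplitude varies mildly (80-100 % of ``amp``) to
    emulate stride-to-stride variability.
    """
    if amp < 0:
        raise ValueError("amp must be non-negative")
    if amp >= mean_l:
        raise ValueError("amp must be smaller than mean_l")
    rng = np.random.default_rng(seed)
    n_per = int(round(stride_duration * fs))
    n = n_strides * n_per
    t = np.arange(n) / fs
    # smooth per-stride amplitude profile in [0.8 amp, amp]
    stride_amp = amp * (1.0 - 0.2 * rng.uniform(size=n_strides))
    knots = np.arange(n_strides) * stride_duration + 0.5 * stride_duration
    amp_t = np.interp(t, knots, stride_amp) if n_strides > 1 else np.full(n, stride_amp[0])
    lce = mean_l + amp_t * np.sin(2.0 * np.pi * t / stride_duration - 0.5 * np.pi)
    vce = velocity_from_length(lce, fs)
    return lce, vce


def _bandlimited_noise(n: int, fs: float, band: tuple, rng) -> np.ndarray:
    lo, hi = band
    if not (30.0 < lo < hi < fs / 2.0):
        raise ValueError(f"carrier band {band} must lie within (30, fs/2) Hz")
    white = rng.standard_normal(n)
    sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, white)
    sd = carrier.std()
    return carrier / sd if sd > 0 else carrier


def generate_raw_emg(
    activation,
    fs: float,
    delay: float = 0.0,
    carrier_band: tuple = (80.0, 240.0),
    noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Amplitude-modulated band-limited noise emulating raw EMG.

    The carrier is modulated by ``activation`` advanced by ``delay`` seconds
    (so applying the excitation-contraction delay downstream re-aligns the
    recovered envelope with the driving activation), the mean is removed,
    and white baseline noise of SD ``noise_sd`` is added.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    a = np.asarray(activation, dtype=float)
    rng = np.random.default_rng(seed)
    carrier = _bandlimited_noise(a.size, fs, carrier_band, rng)
    shift = int(round(fs * delay))
    if shift:
        a_adv = np.empty_like(a)
        a_adv[: a.size - shift] = a[shift:]
        a_adv[a.size - shift :] = a[-1]
    else:
        a_adv = a
    emg = a_adv * carrier
    if emg.any():
        emg = emg - emg.mean()
    if noise_sd > 0:
        emg = emg + noise_sd * rng.standard_normal(a.size)
    return emg


def history_component(activation, vce, fs: float, tau: float = HISTORY_TAU_S) -> np.ndarray:
    """Leaky integrator of active lengthening, max(0, vce) * a.

    First-order low-pass with time constant ``tau``; a minimal surrogate for
    force enhancement following active stretch.
    """
    a = np.asarray(activation, dtype=float)
    v = np.asarray(vce, dtype=float)
    x = np.maximum(v, 0.0) * a
    alpha = (1.0 / fs) / tau
    return signal.lfilter([alpha], [1.0, alpha - 1.0], x)


def synthesize_force(
    activation,
    lce,
    vce,
    params: HillParams,
    f_max: float,
    history_gain: float = 0.0,
    noise_sd_force: float = 0.0,
    seed=None,
    fs: float | None = None,
) -> np.ndarray:
    """Ground-truth tendon force: Hill model + optional history term + noise.

    With ``history_gain = 0`` and no noise this is exactly the Hill model's
    output (shared code path).  The force is clipped at 0 N.
    """
    a = np.asarray(activation, dtype=float)
    l = np.asarray(lce, dtype=float)
    v = np.asarray(vce, dtype=float)
    if not (a.size == l.size == v.size):
        raise ValueError("activation, lce and vce must have the same length")
    force = hill_force(a, l, v, params, f_max)
    if history_gain > 0:
        if fs is None:
            raise ValueError("fs is required when history_gain > 0")
        force = force + history_gain * f_max * history_component(a, v, fs)
    if noise_sd_force > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(a.size)
        if fs is not None and fs > 50:
            # tendon-buckle noise is smooth: band-limit below 20 Hz
            sos = signal.butter(2, 20.0, btype="lowpass", fs=fs, output="sos")
            noise = signal.sosfiltfilt(sos, noise)
            sd = noise.std()
            if sd > 0:
                noise = noise / sd
        force = force + noise_sd_force * f_max * noise
    return np.maximum(force, 0.0)


def _stride_duration_for_speed(speed: float) -> float:
    # stride frequency grows roughly linearly with speed
    return 1.0 / (1.4 + 0.35 * speed)


def _obstacle_strides(n_strides: int, rng) -> list[int]:
    """Indices of perturbed strides: every 4th-5th stride."""
    out, i = [], int(rng.integers(3, 5))
    while i < n_strides:
        out.append(i)
        i += int(rng.integers(4, 6))
    return out


def _smooth_stride_bump(n_per: int) -> np.ndarray:
    k = np.arange(n_per, dtype=float)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (k + 0.5) / n_per))


def generate_dataset(config: SyntheticConfig) -> list[Trial]:
    """One Trial per (bird, muscle, speed, obstacle) combination.

    Obstacle trials perturb every 4th-5th stride with elevated activation
    and an offset length trajectory.  The per-muscle activation scale error
    dissociates stored activation from force: the force-generating drive is
    ``scale_error`` times the stored (peak-normalized) activation, so an
    estimator trained on a matched-scale muscle underestimates the force of
    a muscle with ``scale_error > 1``.  Peak normalization of the EMG
    envelope downstream cannot cancel this, mirroring non-equivalent
    activation scaling between muscles.
    """
    ss = np.random.SeedSequence(config.seed)
    trials: list[Trial] = []
    combos = [
        (bird, muscle, speed, obstacle)
        for bird in config.bird_ids
        for muscle in config.muscles
        for speed in config.speeds
        for obstacle in config.obstacle_heights
    ]
    children = ss.spawn(len(combos))
    for (bird, muscle, speed, obstacle), child in zip(combos, children):
        seeds = child.spawn(5)
        stride_duration = _stride_duration_for_speed(speed)
        n_per = int(round(stride_duration * config.fs))
        a_true = generate_activation(
            config.n_strides, stride_duration, config.duty, config.fs, config.jitter, seeds[0]
        )
        lce, _ = generate_fascicle(
            config.n_strides,
            stride_duration,
            config.fs,
            config.fascicle_amp,
            config.fascicle_mean,
            seeds[1],
        )
        if obstacle:
            rng = np.random.default_rng(seeds[2])
            bump = _smooth_stride_bump(n_per)
            offset = OBSTACLE_LEN_OFFSET * (obstacle / 7.0)
            for s in _obstacle_strides(config.n_strides, rng):
                sl = slice(s * n_per, (s + 1) * n_per)
                a_true[sl] = a_true[sl] * OBSTACLE_ACT_GAIN
                lce[sl] = lce[sl] + offset * bump
        vce = velocity_from_length(lce, config.fs)
        f_max = config.pcsa_for(bird, muscle) * 0.29
        a_stored = a_true
        a_drive = a_true * config.scale_error_for(bird, muscle)
        force = synthesize_force(
            a_drive,
            lce,
            vce,
            config.ground_truth[muscle],
            f_max,
            history_gain=config.history_gain,
            noise_sd_force=config.noise_sd_force,
            seed=seeds[3],
            fs=config.fs,
        )
        emg_raw = generate_raw_emg(
            a_stored,
            config.fs,
            delay=config.emg_delay,
            carrier_band=config.carrier_band,
            noise_sd=config.noise_sd_emg,
            seed=seeds[4],
        )
        t = np.arange(a_true.size) / config.fs
        trials.append(
            Trial(
                t=t,
                emg_raw=emg_raw,
                activation=a_stored,
                lce=lce,
                vce=vce,
                force=force,
                meta={
                    "bird_id": bird,
                    "muscle": muscle,
                    "speed": speed,
                    "obstacle": obstacle,
                    "day": 1,
                },
            )
        )
    return trials
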