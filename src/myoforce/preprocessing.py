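"""Signal chain from raw EMG and raw tendon force to model-ready inputs.

The chain is: zero-phase third-order Butterworth high-pass at 30 Hz,
rectification, zero-phase third-order low-pass at 6 Hz; scaling of the
resulting envelope to the average peak activation of the highest-speed
trials; a 23.6 ms excitation-contraction-coupling delay; force
normalization by the maximal isometric force (PCSA times maximum stress);
and z-scoring of CE length and velocity with training-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "MuscleSpec",
    "NormStats",
    "NoPeaksError",
    "process_emg",
    "compute_activation_scale",
    "finalize_activation",
    "normalize_force",
    "fit_norm_stats",
    "apply_norm",
    "lowpass_6hz",
    "velocity_from_length",
]

#: Maximum isometric muscle stress (N / mm^2).
DEFAULT_SIGMA_MAX = 0.29
#: Excitation-contraction coupling delay (s).
DEFAULT_DELAY_S = 0.0236
#: Default peak-detection threshold on the activation envelope.
DEFAULT_PEAK_THRESHOLD = 0.1

HIGHPASS_HZ = 30.0
LOWPASS_HZ = 6.0
FILTER_ORDER = 3


class NoPeaksError(ValueError):
    """No peaks above threshold; the caller may retry with a lower one."""


@dataclass
class MuscleSpec:
    """Per bird-and-muscle physiology and normalization constants."""

    bird_id: str
    muscle: str
    pcsa: float  # mm^2
    sigma_max: float = DEFAULT_SIGMA_MAX  # N / mm^2
    f_max: float | None = None  # N; pcsa * sigma_max when omitted
    activation_scale: float | None = None  # average peak envelope
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD
    l0: float = 1.0  # lengths arrive pre-normalized

    def __post_init__(self) -> None:
        if not self.pcsa > 0:
            raise ValueError("pcsa must be positive")
        if not self.sigma_max > 0:
            raise ValueError("sigma_max must be positive")
        if self.f_max is None:
            self.f_max = self.pcsa * self.sigma_max
        elif abs(self.f_max - self.pcsa * self.sigma_max) > 1e-9:
            raise ValueError("f_max inconsistent with pcsa * sigma_max")
        if self.activation_scale is not None and not self.activation_scale > 0:
            raise ValueError("activation_scale must be positive")


@dataclass(frozen=True)
class NormStats:
    """Training-set z-scoring statistics for CE length and velocity."""

    mean_l: float
    sd_l: float
    mean_v: float
    sd_v: float

    def __post_init__(self) -> None:
        if not (self.sd_l > 0 and self.sd_v > 0):
            raise ValueError("standard deviations must be positive")

    def to_dict(self) -> dict:
        return {
            "mean_l": self.mean_l,
            "sd_l": self.sd_l,
            "mean_v": self.mean_v,
            "sd_v": self.sd_v,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(**{k: float(d[k]) for k in ("mean_l", "sd_l", "mean_v", "sd_v")})


def _sos(cutoff_hz: float, fs: float, btype: str):
    return signal.butter(FILTER_ORDER, cutoff_hz, btype=btype, fs=fs, output="sos")


def _filtfilt(sos, x: np.ndarray, cutoff_hz: float, fs: float) -> np.ndarray:
    # reflective padding spanning ~9 periods of the cutoff frequency;
    # scipy's default padlen is too short for low cutoffs and breaks
    # zero-phase (time-reversal) symmetry at the edges
    padlen = min(x.size - 1, int(9 * fs / cutoff_hz))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def _check_length(x: np.ndarray, fs: float) -> None:
    # sosfiltfilt needs > 3 * (2 * n_sections + 1) samples with default padding
    padlen = 3 * (2 * FILTER_ORDER // 2 + 1 + 1)
    if x.size <= 3 * padlen:
        raise ValueError(f"series too short for zero-phase filtering ({x.size} samples)")


def process_emg(emg_raw, fs: float) -> np.ndarray:
    """Raw EMG -> unnormalized activation envelope.

    30 Hz high-pass (zero phase), full-wave rectification, 6 Hz low-pass
    (zero phase).  Negative low-pass undershoot is clipped at zero so the
    envelope is a valid (non-negative) activation signal.
    """
    if fs <= 2 * HIGHPASS_HZ:
        raise ValueError(f"fs must exceed {2 * HIGHPASS_HZ} Hz, got {fs}")
    x = np.asarray(emg_raw, dtype=float)
    _check_length(x, fs)
    x = _filtfilt(_sos(HIGHPASS_HZ, fs, "highpass"), x, HIGHPASS_HZ, fs)
    x = np.abs(x)
    env = _filtfilt(_sos(LOWPASS_HZ, fs, "lowpass"), x, LOWPASS_HZ, fs)
    return np.clip(env, 0.0, None)


def lowpass_6hz(x, fs: float) -> np.ndarray:
    """The 6 Hz zero-phase low-pass, as applied to CE velocity."""
    x = np.asarray(x, dtype=float)
    _check_length(x, fs)
    return _filtfilt(_sos(LOWPASS_HZ, fs, "lowpass"), x, LOWPASS_HZ, fs)


def velocity_from_length(lce, fs: float) -> np.ndarray:
    """CE velocity (L0/s) from CE length by central differences + 6 Hz LP."""
    lce = np.asarray(lce, dtype=float)
    v = np.gradient(lce) * fs
    return lowpass_6hz(v, fs)


def _detect_envelope_peaks(env: np.ndarray, threshold: float) -> np.ndarray:
    """Local maxima above threshold, separated by >= 0.25 * median period."""
    idx, _ = signal.find_peaks(env, height=threshold)
    if idx.size >= 3:
        min_sep = int(round(0.25 * float(np.median(np.diff(idx)))))
        if min_sep > 1:
            idx, _ = signal.find_peaks(env, height=threshold, distance=min_sep)
    return idx


def compute_activation_scale(envelopes, peak_threshold: float) -> float:
    """Mean height of envelope peaks across the highest-speed trials.

    Raises :class:`NoPeaksError` when no peak clears the threshold, so the
    caller can lower it (as done for one low-amplitude muscle).
    """
    if isinstance(envelopes, np.ndarray) and envelopes.ndim == 1:
        envelopes = [envelopes]
    heights: list[float] = []
    for env in envelopes:
        env = np.asarray(env, dtype=float)
        idx = _detect_envelope_peaks(env, peak_threshold)
        heights.extend(env[idx].tolist())
    if not heights:
        raise NoPeaksError(
            f"no envelope peaks above threshold {peak_threshold}; "
            "consider lowering the threshold"
        )
    return float(np.mean(heights))


def finalize_activation(
    envelope, activation_scale: float, fs: float, delay: float = DEFAULT_DELAY_S
) -> np.ndarray:
    """Scale the envelope and apply the excitation-contraction delay.

    The envelope is divided by ``activation_scale`` (values above 1 pass
    through) and shifted *later* by ``round(fs * delay)`` samples with
    edge-value padding at the start.
    """
    if not activation_scale > 0:
        raise ValueError("activation_scale must be positive")
    if delay < 0:
        raise ValueError("delay must be non-negative")
    a = np.asarray(envelope, dtype=float) / activation_scale
    shift = int(round(fs * delay))
    if shift == 0:
        return a.copy()
    out = np.empty_like(a)
    out[:shift] = a[0]
    out[shift:] = a[: a.size - shift]
    return out


def normalize_force(force_n, f_max: float) -> np.ndarray:
    """Measured tendon force (N) divided by maximal isometric force."""
    if not f_max > 0:
        raise ValueError("f_max must be positive")
    return np.asarray(force_n, dtype=float) / f_max


def fit_norm_stats(lce, vce) -> NormStats:
    """Mean/SD of CE length and velocity over the training samples.

    ``lce``/``vce`` may be single arrays or sequences of per-trial arrays.
    """
    l = np.concatenate([np.ravel(x) for x in lce]) if _is_seq(lce) else np.ravel(lce)
    v = np.concatenate([np.ravel(x) for x in vce]) if _is_seq(vce) else np.ravel(vce)
    if l.size < 2 or v.size < 2:
        raise ValueError("need at least 2 samples to fit normalization stats")
    sd_l = float(np.std(l))
    sd_v = float(np.std(v))
    if sd_l == 0 or sd_v == 0:
        raise ValueError("zero variance in length or velocity")
    return NormStats(float(np.mean(l)), sd_l, float(np.mean(v)), sd_v)


def apply_norm(lce, vce, stats: NormStats):
    """z-score length and velocity using (frozen) training statistics."""
    zl = (np.asarray(lce, dtype=float) - stats.mean_l) / stats.sd_l
    zv = (np.asarray(vce, dtype=float) - stats.mean_v) / stats.sd_v
    return zl, zv


def _is_seq(x) -> bool:
    return isinstance(x, (list, tuple))
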