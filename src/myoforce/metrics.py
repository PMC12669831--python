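"""Evaluation metrics: force errors, determination coefficient, and the
bespoke peak detection / alignment / rise-fall-time procedures.

Peaks are detected on the baseline-removed force using a threshold of
mean + 1.5 SD; measured and estimated peaks are aligned within a window of
45 % of the 25th percentile of consecutive measured-peak intervals, with
the closest candidate winning; rise and fall times span the 50 %-of-peak
crossings around each peak (linear interpolation between samples).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSet",
    "MetricsReport",
    "detect_peaks",
    "match_peaks",
    "rise_fall_times",
    "r_squared",
    "evaluate_trial",
    "build_report",
]

PEAK_SD_FACTOR = 1.5
ALIGN_FRACTION = 0.45
BASELINE_PERCENTILE = 1.0
_BIG = 1e15


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks of one series: indices, debaselined heights, threshold."""

    indices: np.ndarray
    heights: np.ndarray
    threshold: float
    n_samples: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "heights", h)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if np.any(h < self.threshold - 1e-12):
            raise ValueError("peak heights must be >= threshold")

    def __len__(self) -> int:
        return int(self.indices.size)


def remove_baseline(x: np.ndarray) -> np.ndarray:
    """Subtract a robust minimum (1st percentile) as the baseline offset."""
    x = np.asarray(x, dtype=float)
    return x - np.percentile(x, BASELINE_PERCENTILE)


def detect_peaks(force) -> PeakSet:
    """Local maxima above mean + 1.5 SD of the baseline-removed series.

    Plateaus count as single peaks located at their first maximum sample.
    """
    x = np.asarray(force, dtype=float)
    if x.size < 3:
        raise ValueError("series must contain at least 3 samples")
    xb = remove_baseline(x)
    threshold = float(np.mean(xb) + PEAK_SD_FACTOR * np.std(xb))
    _, props = signal.find_peaks(xb, height=threshold, plateau_size=(1, None))
    idx = props["left_edges"].astype(int)
    return PeakSet(indices=idx, heights=xb[idx], threshold=threshold, n_samples=x.size)


def alignment_window(measured: PeakSet) -> float:
    """Alignment window in samples: 45 % of the 25th percentile of the
    intervals between consecutive measured peaks.

    With fewer than two measured peaks the window is undefined; fall back to
    ``0.45 * n_samples / max(1, n_measured)`` with a logged warning.
    """
    if len(measured) >= 2:
        intervals = np.diff(measured.indices)
        return ALIGN_FRACTION * float(np.percentile(intervals, 25))
    logger.warning(
        "fewer than 2 measured peaks; falling back to a duration-based alignment window"
    )
    return ALIGN_FRACTION * measured.n_samples / max(1, len(measured))


def match_peaks(
    measured: PeakSet, estimated: PeakSet, window: float | None = None
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one alignment of measured and estimated peaks.

    Returns ``(pairs, missed, extra)`` where pairs hold (measured index,
    estimated index) sample positions, missed lists unmatched measured
    peaks and extra lists unmatched estimated peaks.  The pairing maximizes
    the number of in-window matches and, among those, minimizes the total
    location difference, so the closest candidate wins.
    """
    if measured.n_samples != estimated.n_samples:
        raise ValueError("peak sets must come from same-length series")
    if window is None:
        window = alignment_window(measured)
    mi = measured.indices
    ei = estimated.indices
    if mi.size == 0 or ei.size == 0:
        return [], mi.tolist(), ei.tolist()
    dist = np.abs(mi[:, None] - ei[None, :]).astype(float)
    cost = np.where(dist < window, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    pairs = [
        (int(mi[r]), int(ei[c])) for r, c in zip(rows, cols) if cost[r, c] < _BIG
    ]
    matched_m = {p[0] for p in pairs}
    matched_e = {p[1] for p in pairs}
    missed = [int(i) for i in mi if i not in matched_m]
    extra = [int(i) for i in ei if i not in matched_e]
    return pairs, missed, extra


def rise_fall_times(
    force,
    peak_index: int,
    fs: float,
    lo: int = 0,
    hi: int | None = None,
    debaseline: bool = True,
) -> tuple[float | None, float | None]:
    """Rise and fall time (s) around a peak: 50 %-of-peak crossing to peak
    and peak to crossing, with linear interpolation between samples.

    ``lo``/``hi`` bound the search (e.g. the neighboring peaks).  When the
    50 % level is never crossed within the span, the corresponding time is
    ``None`` (metric undefined for that peak).
    """
    x = np.asarray(force, dtype=float)
    if hi is None:
        hi = x.size - 1
    if debaseline:
        x = remove_baseline(x)
    h = x[peak_index]
    level = 0.5 * h
    rise = fall = None
    j = peak_index - 1
    while j >= lo:
        if x[j] < level:
            frac = (level - x[j]) / (x[j + 1] - x[j])
            rise = (peak_index - (j + frac)) / fs
            break
        j -= 1
    j = peak_index + 1
    while j <= hi:
        if x[j] < level:
            frac = (x[j - 1] - level) / (x[j - 1] - x[j])
            fall = ((j - 1 + frac) - peak_index) / fs
            break
        j += 1
    return rise, fall


def r_squared(measured, estimated) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (may be negative)."""
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(estimated, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("measured variance is zero; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class MetricsReport:
    """Per-trial metric rows and their aggregates.

    RMSE-type metrics aggregate as mean +/- SD; R^2 as median [min, max].
    """

    per_trial: pd.DataFrame
    aggregates: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_trial": self.per_trial.to_dict(orient="records"),
            "aggregates": self.aggregates,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))

    def to_csv(self, path: str | Path) -> None:
        self.per_trial.to_csv(path, index=False)


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _peak_time_errors(
    f_meas: np.ndarray, f_est: np.ndarray, pairs, meas_peaks: PeakSet, est_peaks: PeakSet, fs: float
) -> tuple[list[float], list[float]]:
    rise_err, fall_err = [], []
    for m_idx, e_idx in pairs:
        m_pos = int(np.searchsorted(meas_peaks.indices, m_idx))
        e_pos = int(np.searchsorted(est_peaks.indices, e_idx))
        m_lo = int(meas_peaks.indices[m_pos - 1]) if m_pos > 0 else 0
        m_hi = (
            int(meas_peaks.indices[m_pos + 1])
            if m_pos + 1 < len(meas_peaks)
            else f_meas.size - 1
        )
        e_lo = int(est_peaks.indices[e_pos - 1]) if e_pos > 0 else 0
        e_hi = (
            int(est_peaks.indices[e_pos + 1]) if e_pos + 1 < len(est_peaks) else f_est.size - 1
        )
        m_rise, m_fall = rise_fall_times(f_meas, m_idx, fs, lo=m_lo, hi=m_hi)
        e_rise, e_fall = rise_fall_times(f_est, e_idx, fs, lo=e_lo, hi=e_hi)
        if m_rise is not None and e_rise is not None:
            rise_err.append(e_rise - m_rise)
        if m_fall is not None and e_fall is not None:
            fall_err.append(e_fall - m_fall)
    return rise_err, fall_err


def evaluate_trial(f_meas, f_est, f_max: float, fs: float, meta: dict | None = None) -> dict:
    """All seven metrics for one (measured, estimated) force pair in N."""
    f_meas = np.asarray(f_meas, dtype=float)
    f_est = np.asarray(f_est, dtype=float)
    if f_meas.size != f_est.size:
        raise ValueError("measured and estimated series must have the same length")
    rmse = float(np.sqrt(np.mean((f_meas - f_est) ** 2)))
    row = dict(meta or {})
    row["rmse_norm"] = rmse / f_max
    max_meas = float(np.max(f_meas))
    row["rrmse_pct"] = 100.0 * rmse / max_meas if max_meas > 0 else np.nan
    row["r2"] = r_squared(f_meas, f_est)
    meas_peaks = detect_peaks(f_meas)
    est_peaks = detect_peaks(f_est)
    pairs, missed, extra = match_peaks(meas_peaks, est_peaks)
    row["n_measured_peaks"] = len(meas_peaks)
    row["n_estimated_peaks"] = len(est_peaks)
    row["missed_pct"] = 100.0 * len(missed) / len(meas_peaks) if len(meas_peaks) else np.nan
    row["extra_pct"] = 100.0 * len(extra) / len(est_peaks) if len(est_peaks) else np.nan
    rise_err, fall_err = _peak_time_errors(f_meas, f_est, pairs, meas_peaks, est_peaks, fs)
    row["rise_rmse"] = float(np.sqrt(np.mean(np.square(rise_err)))) if rise_err else np.nan
    row["fall_rmse"] = float(np.sqrt(np.mean(np.square(fall_err)))) if fall_err else np.nan
    return row


MEAN_SD_METRICS = ("rmse_norm", "rrmse_pct", "missed_pct", "extra_pct", "rise_rmse", "fall_rmse")


def build_report(trial_pairs, f_max: float, fs: float, metas=None) -> MetricsReport:
    """Evaluate a list of (measured, estimated) pairs and aggregate.

    ``metas`` optionally supplies a metadata dict per pair (copied into the
    per-trial rows).  Missing rise/fall values (no matched peaks) are left
    absent (NaN) and excluded from the aggregates.
    """
    if not trial_pairs:
        raise ValueError("trial_pairs must be nonempty")
    metas = metas or [None] * len(trial_pairs)
    rows = [
        evaluate_trial(fm, fe, f_max, fs, meta=meta)
        for (fm, fe), meta in zip(trial_pairs, metas)
    ]
    df = pd.DataFrame(rows)
    agg: dict[str, float] = {}
    for m in MEAN_SD_METRICS:
        vals = df[m].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        agg[f"{m}_mean"] = float(np.mean(vals)) if vals.size else np.nan
        agg[f"{m}_sd"] = float(np.std(vals)) if vals.size else np.nan
    r2 = df["r2"].to_numpy(dtype=float)
    agg["r2_median"] = float(np.median(r2))
    agg["r2_min"] = float(np.min(r2))
    agg["r2_max"] = float(np.max(r2))
    return MetricsReport(per_trial=df, aggregates=agg)
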