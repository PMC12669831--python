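"""Orchestration of the two studies: the small head-to-head comparison
(network vs Hill model trained on a single trial) and the leave-one-bird-out
study, each evaluated across the four test scenarios (same/other bird x
same/other muscle).

A master seed fans out to per-stage seeds through a recorded seed sequence;
training and test manifests are asserted disjoint at the trial level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import DEFAULT_INIT, FitResult, fit_cmaes
from .hill import HillParams, hill_force
from .metrics import MetricsReport, build_report
from .nn import NNConfig, NNModel, predict, search_and_train
from .preprocessing import (
    MuscleSpec,
    NoPeaksError,
    compute_activation_scale,
    finalize_activation,
    process_emg,
)
from .synthetic import SyntheticConfig, Trial

__all__ = [
    "ProcessedTrial",
    "muscle_specs_for",
    "preprocess_dataset",
    "trial_xy",
    "ScenarioSpec",
    "HeadToHeadResult",
    "run_head_to_head",
    "LeaveOneOutResult",
    "run_leave_one_out",
    "SCENARIOS",
]

SCENARIOS = (
    "same_bird_same_muscle",
    "same_bird_other_muscle",
    "other_bird_same_muscle",
    "other_bird_other_muscle",
)

#: Fallback peak threshold for low-amplitude envelopes.
FALLBACK_PEAK_THRESHOLD = 0.035


@dataclass
class ProcessedTrial:
    """A trial after the full preprocessing chain (model-ready)."""

    activation: np.ndarray  # scaled, delayed envelope
    lce: np.ndarray
    vce: np.ndarray
    force_n: np.ndarray  # measured force, N
    f_max: float
    fs: float
    meta: dict = field(default_factory=dict)

    @property
    def force_norm(self) -> np.ndarray:
        return self.force_n / self.f_max


def muscle_specs_for(config: SyntheticConfig) -> dict[tuple[str, str], MuscleSpec]:
    """Build per bird-and-muscle physiology specs from a synthetic config."""
    specs = {}
    for bird in config.bird_ids:
        for muscle in config.muscles:
            specs[(bird, muscle)] = MuscleSpec(
                bird_id=bird, muscle=muscle, pcsa=config.pcsa_for(bird, muscle)
            )
    return specs


def _group_key(trial: Trial) -> tuple[str, str]:
    return (trial.meta["bird_id"], trial.meta["muscle"])


def preprocess_dataset(
    trials: list[Trial],
    specs: dict[tuple[str, str], MuscleSpec],
    use_emg: bool = True,
) -> list[ProcessedTrial]:
    """Apply the full chain to a dataset, preserving trial order.

    With ``use_emg`` the activation is recovered from raw EMG (filtering,
    rectification, scaling to the average peak of the highest-speed trials,
    excitation-contraction delay); otherwise the stored activation series is
    used as-is.  The computed activation scale is stored on each spec.
    """
    envelopes: dict[int, np.ndarray] = {}
    if use_emg:
        groups: dict[tuple[str, str], list[int]] = {}
        for i, tr in enumerate(trials):
            groups.setdefault(_group_key(tr), []).append(i)
        for key, idxs in groups.items():
            spec = specs[key]
            for i in idxs:
                envelopes[i] = process_emg(trials[i].emg_raw, trials[i].fs)
            top_speed = max(trials[i].meta["speed"] for i in idxs)
            top = [envelopes[i] for i in idxs if trials[i].meta["speed"] == top_speed]
            try:
                scale = compute_activation_scale(top, spec.peak_threshold)
            except NoPeaksError:
                scale = compute_activation_scale(top, FALLBACK_PEAK_THRESHOLD)
            spec.activation_scale = scale
    out = []
    for i, tr in enumerate(trials):
        spec = specs[_group_key(tr)]
        if use_emg:
            a = finalize_activation(envelopes[i], spec.activation_scale, tr.fs)
        else:
            a = tr.activation.copy()
        out.append(
            ProcessedTrial(
                activation=a,
                lce=tr.lce.copy(),
                vce=tr.vce.copy(),
                force_n=tr.force.copy(),
                f_max=spec.f_max,
                fs=tr.fs,
                meta=dict(tr.meta),
            )
        )
    return out


def trial_xy(ptrials: list[ProcessedTrial]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-trial (X, y) pairs: X = (a, lce, vce), y = normalized force."""
    return [
        (np.column_stack([p.activation, p.lce, p.vce]), p.force_norm) for p in ptrials
    ]


def _scenario_filter(
    ptrials: list[ProcessedTrial],
    scenario: str,
    train_bird: str,
    train_muscle: str,
    exclude: set[int],
) -> list[int]:
    out = []
    for i, p in enumerate(ptrials):
        if i in exclude:
            continue
        same_bird = p.meta["bird_id"] == train_bird
        same_muscle = p.meta["muscle"] == train_muscle
        match scenario:
            case "same_bird_same_muscle":
                ok = same_bird and same_muscle
            case "same_bird_other_muscle":
                ok = same_bird and not same_muscle
            case "other_bird_same_muscle":
                ok = not same_bird and same_muscle
            case "other_bird_other_muscle":
                ok = not same_bird and not same_muscle
            case _:
                raise ValueError(f"unknown scenario {scenario!r}")
        if ok:
            out.append(i)
    return out


@dataclass
class ScenarioSpec:
    """Train/test bookkeeping for one experiment."""

    train_indices: list[int]
    test_indices: dict[str, list[int]]  # scenario or group name -> trial indices
    seeds: dict = field(default_factory=dict)
    repeats: int = 1

    def __post_init__(self) -> None:
        train = set(self.train_indices)
        for name, idxs in self.test_indices.items():
            overlap = train & set(idxs)
            if overlap:
                raise ValueError(f"train/test overlap in {name!r}: {sorted(overlap)}")


def _hill_pairs(ptrials, idxs, params: HillParams):
    return [
        (
            ptrials[i].force_n,
            hill_force(
                ptrials[i].activation, ptrials[i].lce, ptrials[i].vce, params, ptrials[i].f_max
            ),
        )
        for i in idxs
    ]


def _nn_pairs(ptrials, idxs, models: list[NNModel]):
    pairs, metas = [], []
    for model in models:
        for i in idxs:
            p = ptrials[i]
            est = predict(model, p.activation, p.lce, p.vce) * p.f_max
            pairs.append((p.force_n, est))
            metas.append(dict(p.meta))
    return pairs, metas


def _report(pairs, metas, f_max, fs) -> MetricsReport | None:
    if not pairs:
        return None
    return build_report(pairs, f_max=f_max, fs=fs, metas=metas)


@dataclass
class HeadToHeadResult:
    hill_fit: FitResult
    nn_models: list[NNModel]
    reports: dict  # scenario -> {"hill": MetricsReport, "nn": MetricsReport}
    table: pd.DataFrame
    spec: ScenarioSpec


def _result_table(reports: dict) -> pd.DataFrame:
    rows = []
    for scenario, by_model in reports.items():
        for model_name, rep in by_model.items():
            if rep is None:
                continue
            row = {"scenario": scenario, "model": model_name}
            row.update(rep.aggregates)
            rows.append(row)
    return pd.DataFrame(rows)


def run_head_to_head(
    trials: list[Trial],
    specs: dict[tuple[str, str], MuscleSpec],
    train_bird: str,
    train_muscle: str,
    train_trial: int,
    nn_config: NNConfig | None = None,
    n_iter: int = 100,
    seed: int = 0,
    use_emg: bool = True,
    hill_init: HillParams = DEFAULT_INIT,
) -> HeadToHeadResult:
    """Fit the Hill model and train network repeats on one trial, then
    evaluate both on the four test scenarios.

    ``train_trial`` indexes the trials of (train_bird, train_muscle) in
    dataset order.  Scenarios without data are skipped (report ``None``).
    """
    ptrials = preprocess_dataset(trials, specs, use_emg=use_emg)
    group = [
        i
        for i, p in enumerate(ptrials)
        if p.meta["bird_id"] == train_bird and p.meta["muscle"] == train_muscle
    ]
    if train_trial >= len(group):
        raise ValueError("train_trial out of range for the selected bird/muscle")
    train_idx = group[train_trial]
    p_train = ptrials[train_idx]

    ss = np.random.SeedSequence(seed)
    fit_seed, nn_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))

    hill_fit = fit_cmaes(
        [(p_train.activation, p_train.lce, p_train.vce, p_train.force_n)],
        f_max=p_train.f_max,
        init=hill_init,
        n_iter=n_iter,
        seed=fit_seed,
    )
    nn_config = nn_config or NNConfig(n_repeats=10)
    nn_models = search_and_train(trial_xy([p_train]), nn_config, seed=nn_seed)

    test_indices = {
        s: _scenario_filter(ptrials, s, train_bird, train_muscle, {train_idx})
        for s in SCENARIOS
    }
    spec = ScenarioSpec(
        train_indices=[train_idx],
        test_indices=test_indices,
        seeds={"master": seed, "fit": fit_seed, "nn": nn_seed},
        repeats=nn_config.n_repeats,
    )
    reports: dict[str, dict] = {}
    for scenario, idxs in test_indices.items():
        if not idxs:
            reports[scenario] = {"hill": None, "nn": None}
            continue
        f_max = ptrials[idxs[0]].f_max
        fs = ptrials[idxs[0]].fs
        hill_pairs = _hill_pairs(ptrials, idxs, hill_fit.params)
        hill_metas = [dict(ptrials[i].meta) for i in idxs]
        nn_pairs, nn_metas = _nn_pairs(ptrials, idxs, nn_models)
        reports[scenario] = {
            "hill": _report(hill_pairs, hill_metas, f_max, fs),
            "nn": _report(nn_pairs, nn_metas, f_max, fs),
        }
    return HeadToHeadResult(
        hill_fit=hill_fit,
        nn_models=nn_models,
        reports=reports,
        table=_result_table(reports),
        spec=spec,
    )


@dataclass
class LeaveOneOutResult:
    nn_models: list[NNModel]
    reports: dict  # (bird, muscle) -> MetricsReport
    table: pd.DataFrame
    spec: ScenarioSpec


def run_leave_one_out(
    trials: list[Trial],
    specs: dict[tuple[str, str], MuscleSpec],
    excluded_bird: str,
    nn_config: NNConfig | None = None,
    seed: int = 0,
    train_muscle: str = "LG",
    use_emg: bool = True,
) -> LeaveOneOutResult:
    """Train on the training muscle of all birds but one, test per subgroup.

    Training uses all but the last trial of each included bird; tests cover
    the held-out trials of training birds, every training-muscle trial of
    the excluded bird, and every other-muscle trial.  Reports are grouped
    per (bird, muscle) and pooled over network repeats.
    """
    ptrials = preprocess_dataset(trials, specs, use_emg=use_emg)
    by_bird: dict[str, list[int]] = {}
    for i, p in enumerate(ptrials):
        if p.meta["muscle"] == train_muscle:
            by_bird.setdefault(p.meta["bird_id"], []).append(i)
    train_birds = [b for b in by_bird if b != excluded_bird]
    if len(train_birds) < 1:
        raise ValueError("need at least 2 birds with the training muscle")

    train_indices: list[int] = []
    heldout: dict[str, list[int]] = {}
    for bird in train_birds:
        idxs = by_bird[bird]
        if len(idxs) > 1:
            train_indices.extend(idxs[:-1])
            heldout[bird] = [idxs[-1]]
        else:
            train_indices.extend(idxs)
            heldout[bird] = []

    groups: dict[tuple[str, str], list[int]] = {}
    for bird in train_birds:
        if heldout[bird]:
            groups[(bird, train_muscle)] = heldout[bird]
    if excluded_bird in by_bird:
        groups[(excluded_bird, train_muscle)] = by_bird[excluded_bird]
    for i, p in enumerate(ptrials):
        if p.meta["muscle"] != train_muscle:
            groups.setdefault((p.meta["bird_id"], p.meta["muscle"]), []).append(i)

    spec = ScenarioSpec(
        train_indices=train_indices,
        test_indices={f"{b}/{m}": idxs for (b, m), idxs in groups.items()},
        seeds={"master": seed},
        repeats=(nn_config.n_repeats if nn_config else 5),
    )
    nn_config = nn_config or NNConfig(n_repeats=5)
    nn_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    models = search_and_train(
        trial_xy([ptrials[i] for i in train_indices]), nn_config, seed=nn_seed
    )
    reports: dict[tuple[str, str], MetricsReport] = {}
    rows = []
    for (bird, muscle), idxs in groups.items():
        pairs, metas = _nn_pairs(ptrials, idxs, models)
        rep = _report(pairs, metas, ptrials[idxs[0]].f_max, ptrials[idxs[0]].fs)
        reports[(bird, muscle)] = rep
        row = {"bird": bird, "muscle": muscle, "n_trials": len(idxs)}
        row.update(rep.aggregates)
        rows.append(row)
    return LeaveOneOutResult(
        nn_models=models, reports=reports, table=pd.DataFrame(rows), spec=spec
    )
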