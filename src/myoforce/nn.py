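"""Per-timepoint feed-forward force estimators with hyperparameter search.

Each estimator maps (activation, z-scored CE length, z-scored CE velocity)
at a single time point to normalized tendon force.  Hyperparameters (1-3
hidden layers, 5-300 nodes each, relu/tanh/sigmoid) are selected by a
seeded random search scored on a chronological 80/20 validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPRegressor

from .preprocessing import NormStats, apply_norm, fit_norm_stats

__all__ = [
    "NNConfig",
    "NNModel",
    "split_train_validation",
    "search_and_train",
    "train_single",
    "predict",
    "save_model",
    "load_model",
]

ACTIVATION_CHOICES = ("relu", "tanh", "logistic")
#: Above this many training samples, switch from L-BFGS to Adam.
LBFGS_SAMPLE_LIMIT = 100_000


@dataclass
class NNConfig:
    """Search-space and training configuration.

    ``hidden_layers``/``activation_fn`` pin the architecture (no search);
    when left ``None`` the random search draws from the configured ranges.
    """

    hidden_layers: tuple | None = None
    activation_fn: str | None = None
    max_search_evals: int = 30
    n_repeats: int = 10
    seed: int = 0
    layer_range: tuple = (1, 3)
    node_range: tuple = (5, 300)
    activations: tuple = ACTIVATION_CHOICES
    max_iter: int = 500
    alpha: float = 1e-6  # L2 penalty

    def __post_init__(self) -> None:
        if self.hidden_layers is not None:
            n = len(self.hidden_layers)
            if not 1 <= n <= 3:
                raise ValueError("hidden_layers must contain 1-3 layers")
            if any(not (1 <= k) for k in self.hidden_layers):
                raise ValueError("node counts must be positive")
        if self.activation_fn is not None and self.activation_fn not in ACTIVATION_CHOICES:
            raise ValueError(f"activation_fn must be one of {ACTIVATION_CHOICES}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.max_search_evals < 1:
            raise ValueError("max_search_evals must be >= 1")


@dataclass
class NNModel:
    """A trained estimator with its input normalization and provenance."""

    regressor: MLPRegressor
    norm_stats: NormStats
    hidden_layers: tuple
    activation_fn: str
    train_loss: float
    val_loss: float
    loss_curve: list = field(default_factory=list)
    seed: int | None = None
    f_max: float | None = None
    activation_scale: float | None = None

    @property
    def architecture(self) -> dict:
        return {
            "hidden_layers": list(self.hidden_layers),
            "activation_fn": self.activation_fn,
        }


def _as_xy(trial_xy) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalize input into a list of per-trial (X, y) pairs, X: (n, 3)."""
    out = []
    for item in trial_xy:
        X, y = item
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must have shape (n_samples, 3): (a, lce, vce)")
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        out.append((X, y))
    return out


def split_train_validation(trial_xy, train_frac: float = 0.8):
    """Chronological per-trial split: first 80 % train, last 20 % validation.

    The split is by time within each trial, so no validation sample precedes
    a training sample of the same trial; the per-trial parts are pooled.
    Returns ``(X_train, y_train, X_val, y_val)``.
    """
    pairs = _as_xy(trial_xy)
    n_total = sum(y.size for _, y in pairs)
    if n_total < 5:
        raise ValueError("need at least 5 samples to split")
    xs_tr, ys_tr, xs_va, ys_va = [], [], [], []
    for X, y in pairs:
        k = int(np.floor(train_frac * y.size))
        if k == 0 or k == y.size:
            raise ValueError("trial too short for an 80/20 split")
        xs_tr.append(X[:k])
        ys_tr.append(y[:k])
        xs_va.append(X[k:])
        ys_va.append(y[k:])
    return (
        np.vstack(xs_tr),
        np.concatenate(ys_tr),
        np.vstack(xs_va),
        np.concatenate(ys_va),
    )


def _normalize_inputs(X: np.ndarray, stats: NormStats) -> np.ndarray:
    zl, zv = apply_norm(X[:, 1], X[:, 2], stats)
    return np.column_stack([X[:, 0], zl, zv])


def _fit_one(
    X_tr, y_tr, X_va, y_va, stats: NormStats, arch: tuple, act: str, cfg: NNConfig, seed: int
) -> NNModel:
    n = y_tr.size
    solver = "lbfgs" if n <= LBFGS_SAMPLE_LIMIT else "adam"
    reg = MLPRegressor(
        hidden_layer_sizes=tuple(arch),
        activation=act,
        solver=solver,
        alpha=cfg.alpha,
        max_iter=cfg.max_iter,
        random_state=int(seed),
        tol=1e-7,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings are expected mid-search
        reg.fit(_normalize_inputs(X_tr, stats), y_tr)
    pred_tr = reg.predict(_normalize_inputs(X_tr, stats))
    pred_va = reg.predict(_normalize_inputs(X_va, stats))
    train_loss = float(np.mean((pred_tr - y_tr) ** 2))
    val_loss = float(np.mean((pred_va - y_va) ** 2))
    return NNModel(
        regressor=reg,
        norm_stats=stats,
        hidden_layers=tuple(arch),
        activation_fn=act,
        train_loss=train_loss,
        val_loss=val_loss,
        loss_curve=list(getattr(reg, "loss_curve_", [])),
        seed=int(seed),
    )


def _draw_architecture(rng, cfg: NNConfig) -> tuple[tuple, str]:
    if cfg.hidden_layers is not None:
        arch = tuple(cfg.hidden_layers)
    else:
        n_layers = int(rng.integers(cfg.layer_range[0], cfg.layer_range[1] + 1))
        lo, hi = cfg.node_range
        # log-uniform node counts
        arch = tuple(
            int(round(np.exp(rng.uniform(np.log(lo), np.log(hi))))) for _ in range(n_layers)
        )
    act = cfg.activation_fn or str(rng.choice(list(cfg.activations)))
    return arch, act


def train_single(trial_xy, cfg: NNConfig, seed: int | None = None) -> NNModel:
    """Train one model (fixed or singly-drawn architecture), no search."""
    one = NNConfig(**{**cfg.__dict__, "max_search_evals": 1})
    return search_and_train(trial_xy, one, n_repeats=1, seed=seed)[0]


def search_and_train(
    trial_xy, cfg: NNConfig, n_repeats: int | None = None, seed: int | None = None
) -> list[NNModel]:
    """Random hyperparameter search, one selected model per repeat.

    For each repeat, ``max_search_evals`` architectures are drawn and
    trained on the chronological training split; the model with the lowest
    validation MSE is kept.  Repeats differ only by seed, so identical
    seeds give identical selections.
    """
    n_repeats = cfg.n_repeats if n_repeats is None else n_repeats
    seed = cfg.seed if seed is None else seed
    X_tr, y_tr, X_va, y_va = split_train_validation(trial_xy)
    stats = fit_norm_stats(X_tr[:, 1], X_tr[:, 2])
    master = np.random.SeedSequence(seed)
    models: list[NNModel] = []
    for rep_ss in master.spawn(n_repeats):
        rng = np.random.default_rng(rep_ss)
        fit_seeds = rep_ss.spawn(cfg.max_search_evals)
        best: NNModel | None = None
        for k in range(cfg.max_search_evals):
            arch, act = _draw_architecture(rng, cfg)
            fit_seed = int(fit_seeds[k].generate_state(1)[0] % (2**31 - 1))
            model = _fit_one(X_tr, y_tr, X_va, y_va, stats, arch, act, cfg, fit_seed)
            if np.isfinite(model.val_loss) and (best is None or model.val_loss < best.val_loss):
                best = model
        if best is None:
            raise RuntimeError("hyperparameter search produced no finite-loss model")
        models.append(best)
    return models


def predict(model: NNModel, a, lce, vce) -> np.ndarray:
    """Normalized force from per-timepoint inputs (output unclipped)."""
    a = np.asarray(a, dtype=float)
    lce = np.asarray(lce, dtype=float)
    vce = np.asarray(vce, dtype=float)
    if not (a.size == lce.size == vce.size):
        raise ValueError("a, lce and vce must have the same length")
    X = np.column_stack([a, lce, vce])
    return model.regressor.predict(_normalize_inputs(X, model.norm_stats))


# -- persistence (JSON metadata + plain-text weight arrays) -----------------

def save_model(model: NNModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "hidden_layers": list(model.hidden_layers),
        "activation_fn": model.activation_fn,
        "norm_stats": model.norm_stats.to_dict(),
        "train_loss": model.train_loss,
        "val_loss": model.val_loss,
        "seed": model.seed,
        "f_max": model.f_max,
        "activation_scale": model.activation_scale,
        "n_layers_total": len(model.regressor.coefs_),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    for i, (W, b) in enumerate(zip(model.regressor.coefs_, model.regressor.intercepts_)):
        np.savetxt(directory / f"coef_{i}.txt", W)
        np.savetxt(directory / f"intercept_{i}.txt", np.atleast_1d(b))
    return directory / "model.json"


def load_model(directory: str | Path) -> NNModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    arch = tuple(meta["hidden_layers"])
    reg = MLPRegressor(hidden_layer_sizes=arch, activation=meta["activation_fn"])
    coefs, intercepts = [], []
    for i in range(meta["n_layers_total"]):
        W = np.loadtxt(directory / f"coef_{i}.txt")
        if W.ndim == 1:
            W = W.reshape(-1, 1)
        coefs.append(W)
        intercepts.append(np.atleast_1d(np.loadtxt(directory / f"intercept_{i}.txt")))
    # rebuild the fitted state without retraining
    reg.coefs_ = coefs
    reg.intercepts_ = intercepts
    reg.n_layers_ = len(coefs) + 1
    reg.n_outputs_ = 1
    reg.out_activation_ = "identity"
    reg.n_features_in_ = coefs[0].shape[0]
    return NNModel(
        regressor=reg,
        norm_stats=NormStats.from_dict(meta["norm_stats"]),
        hidden_layers=arch,
        activation_fn=meta["activation_fn"],
        train_loss=meta["train_loss"],
        val_loss=meta["val_loss"],
        seed=meta.get("seed"),
        f_max=meta.get("f_max"),
        activation_scale=meta.get("activation_scale"),
    )
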