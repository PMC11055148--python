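"""Autoregressive feed-forward baselines (NNET and D-NNET).

The comparison models are multilayer perceptrons that map ``m`` lagged
samples (lag spacing ``d``) of a z-scored series to the value ``s`` steps
ahead:

    x_{t+s} = b0 + sum_j b_j * g(c_{0j} + sum_i c_{ij} x_{t-(i-1)d})

with logistic-sigmoid hidden units ``g`` and a linear output.  NNET has a
single hidden layer of ``D`` units; D-NNET stacks two or more.  Both the
embedding dimension ``m`` and the hidden sizes are genuine hyperparameters
and are chosen by grid search on held-out training data — exactly the
optimisation burden the topological forecaster avoids.

Fitting minimises the full-batch sum of squared one-step errors with
L-BFGS-B (scipy) from a seed-controlled small-uniform initialisation, so
a given seed reproduces a fit bit-for-bit while different seeds give the
run-to-run variation that the dispersion protocol measures.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .exceptions import DegenerateWindowError, TooShortError

__all__ = [
    "NNetSpec",
    "NNetModel",
    "GridSearchResult",
    "fit_nnet",
    "grid_search",
    "forecast_nnet",
    "update_nnet",
    "default_grid",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NNetSpec:
    """Architecture of an autoregressive MLP.

    ``m`` lagged inputs spaced ``d`` apart predict the sample ``s`` steps
    ahead; ``hidden`` lists the units per hidden layer (length 1 for NNET,
    two or more for D-NNET).
    """

    m: int
    hidden: tuple[int, ...]
    d: int = 1
    s: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden", tuple(int(h) for h in self.hidden))
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if len(self.hidden) < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("every hidden layer needs at least one unit")
        if self.d < 1 or self.s < 1:
            raise ValueError("lag spacing d and forecast step s must be >= 1")

    @property
    def n_params(self) -> int:
        sizes = (self.m, *self.hidden, 1)
        return sum((a + 1) * b for a, b in zip(sizes[:-1], sizes[1:]))

    @property
    def span(self) -> int:
        """Number of past samples a single prediction consumes."""
        return (self.m - 1) * self.d + 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NNetModel:
    """A fitted autoregressive MLP plus its training-scale parameters."""

    spec: NNetSpec
    weights: list[np.ndarray] = field(repr=False)  # per layer, shape (fan_in+1, fan_out)
    train_mean: float
    train_sd: float
    constant: float | None = None  # set when training data had zero variance

    def predict_scaled(self, lags: np.ndarray) -> np.ndarray:
        """One-step outputs for rows of lagged inputs, in z-score space."""
        h = np.atleast_2d(np.asarray(lags, dtype=float))
        for w in self.weights[:-1]:
            h = _sigmoid(h @ w[:-1] + w[-1])
        out = h @ self.weights[-1][:-1] + self.weights[-1][-1]
        return out.ravel()


def _design(y: np.ndarray, spec: NNetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Lag-embedded design matrix and targets for one-step-ahead fitting."""
    m, d, s = spec.m, spec.d, spec.s
    first = (m - 1) * d  # earliest time with a full lag vector
    t_idx = np.arange(first, len(y) - s)
    if len(t_idx) < 1:
        raise TooShortError(
            f"series of length {len(y)} is too short for m={m}, d={d}, s={s}"
        )
    lag_cols = [y[t_idx - (i - 1) * d] for i in range(1, m + 1)]
    return np.column_stack(lag_cols), y[t_idx + s]


def _init_weights(spec: NNetSpec, rng: np.random.Generator) -> list[np.ndarray]:
    sizes = (spec.m, *spec.hidden, 1)
    return [rng.uniform(-0.5, 0.5, size=(a + 1, b)) for a, b in zip(sizes[:-1], sizes[1:])]


def _flatten(weights: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([w.ravel() for w in weights])


def _unflatten(theta: np.ndarray, spec: NNetSpec) -> list[np.ndarray]:
    sizes = (spec.m, *spec.hidden, 1)
    weights, pos = [], 0
    for a, b in zip(sizes[:-1], sizes[1:]):
        k = (a + 1) * b
        weights.append(theta[pos : pos + k].reshape(a + 1, b))
        pos += k
    return weights


def _sse_and_grad(theta: np.ndarray, spec: NNetSpec, x: np.ndarray, y: np.ndarray):
    """Half sum-of-squares objective with analytic backprop gradient."""
    weights = _unflatten(theta, spec)
    acts = [x]
    h = x
    for w in weights[:-1]:
        h = _sigmoid(h @ w[:-1] + w[-1])
        acts.append(h)
    pred = (h @ weights[-1][:-1] + weights[-1][-1]).ravel()
    resid = pred - y
    loss = 0.5 * float(resid @ resid)

    grads = [np.empty_like(w) for w in weights]
    delta = resid[:, None]  # linear output
    grads[-1][:-1] = acts[-1].T @ delta
    grads[-1][-1] = delta.sum(axis=0)
    for layer in range(len(weights) - 2, -1, -1):
        a = acts[layer + 1]
        delta = (delta @ weights[layer + 1][:-1].T) * a * (1.0 - a)
        grads[layer][:-1] = acts[layer].T @ delta
        grads[layer][-1] = delta.sum(axis=0)
    return loss, _flatten(grads)


def fit_nnet(
    train: Sequence[float] | np.ndarray,
    spec: NNetSpec,
    seed: int,
    max_iter: int = 200,
) -> NNetModel:
    """Fit an autoregressive MLP on a training series.

    The series is z-scored first (the stored mean/SD travel with the model);
    weights minimise the sum of squared one-step errors over the lag-embedded
    design, by full-batch L-BFGS-B from a seeded small-uniform start.  A
    zero-variance series yields a degenerate constant predictor instead of a
    fit.
    """
    y_raw = np.asarray(train, dtype=float)
    if len(y_raw) <= spec.m * spec.d + spec.s:
        raise TooShortError(
            f"training series of length {len(y_raw)} is too short for spec {spec}"
        )
    mean = float(np.mean(y_raw))
    sd = float(np.std(y_raw, ddof=1))
    if sd == 0.0:
        weights = [np.zeros((a + 1, b)) for a, b in
                   zip((spec.m, *spec.hidden), (*spec.hidden, 1))]
        return NNetModel(spec=spec, weights=weights, train_mean=mean, train_sd=sd,
                         constant=mean)
    y = (y_raw - mean) / sd
    x_mat, targets = _design(y, spec)
    theta0 = _flatten(_init_weights(spec, np.random.default_rng(seed)))
    res = minimize(
        _sse_and_grad,
        theta0,
        args=(spec, x_mat, targets),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    return NNetModel(
        spec=spec,
        weights=_unflatten(res.x, spec),
        train_mean=mean,
        train_sd=sd,
    )


def forecast_nnet(
    model: NNetModel,
    window: Sequence[float] | np.ndarray,
    horizon: int,
) -> np.ndarray:
    """Recursive multi-step forecast from an input window.

    The window is z-scored with its own mean/SD before entering the network,
    each one-step prediction is appended and reused as a lagged input, and
    the outputs are rescaled back to the sensor scale with the same window
    statistics.
    """
    w = np.asarray(window, dtype=float)
    if horizon == 0:
        return np.empty(0)
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if model.constant is not None:
        return np.full(horizon, model.constant)
    spec = model.spec
    if len(w) < spec.m * spec.d:
        raise TooShortError(
            f"window of length {len(w)} is shorter than m*d = {spec.m * spec.d}"
        )
    mean = float(np.mean(w))
    sd = float(np.std(w, ddof=1))
    if sd == 0.0:
        raise DegenerateWindowError("input window has zero variance")
    buf = list((w - mean) / sd)
    out = []
    for _ in range(horizon):
        lags = np.array([buf[-1 - (i - 1) * spec.d] for i in range(1, spec.m + 1)])
        nxt = float(model.predict_scaled(lags)[0])
        buf.append(nxt)
        out.append(nxt)
    return np.asarray(out) * sd + mean


def update_nnet(
    model: NNetModel,
    window: Sequence[float] | np.ndarray,
    epochs: int = 50,
) -> NNetModel:
    """Retrain a copy of the model on one z-scored window (warm start).

    ``epochs`` caps the L-BFGS-B iterations of the refit; ``epochs=0``
    returns an identical copy.  The input model is never mutated — the
    evaluation harness calls this per sliding window so every window starts
    from the same pretrained weights.
    """
    new = copy.deepcopy(model)
    if epochs == 0 or model.constant is not None:
        return new
    w = np.asarray(window, dtype=float)
    if len(w) <= model.spec.m * model.spec.d + model.spec.s:
        raise TooShortError("window too short to retrain on")
    mean = float(np.mean(w))
    sd = float(np.std(w, ddof=1))
    if sd == 0.0:
        raise DegenerateWindowError("cannot retrain on a zero-variance window")
    y = (w - mean) / sd
    x_mat, targets = _design(y, model.spec)
    res = minimize(
        _sse_and_grad,
        _flatten(model.weights),
        args=(model.spec, x_mat, targets),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": epochs},
    )
    new.weights = _unflatten(res.x, model.spec)
    return new


@dataclass(frozen=True)
class GridSearchResult:
    """Outcome of a hyperparameter grid search."""

    chosen: NNetSpec
    trials: tuple[tuple[NNetSpec, float], ...]
    seed: int


def default_grid(
    kind: str = "nnet",
    m_values: Iterable[int] = range(1, 11),
    unit_values: Iterable[int] = range(1, 11),
    layer_values: Iterable[int] = (2, 3),
) -> list[NNetSpec]:
    """Candidate architectures: single hidden layer for ``kind="nnet"``,
    stacked equal-width layers for ``kind="dnnet"``."""
    grid = []
    for m in m_values:
        for u in unit_values:
            if kind == "nnet":
                grid.append(NNetSpec(m=m, hidden=(u,)))
            elif kind == "dnnet":
                grid.extend(NNetSpec(m=m, hidden=(u,) * L) for L in layer_values)
            else:
                raise ValueError(f"unknown model kind: {kind!r}")
    return grid


def grid_search(
    train: Sequence[float] | np.ndarray,
    grid: Sequence[NNetSpec],
    seed: int,
    val_frac: float = 0.25,
    max_iter: int = 200,
) -> GridSearchResult:
    """Select the architecture with the lowest held-out one-step RMSE.

    Each candidate is fitted on the head of the training split and scored by
    teacher-forced one-step predictions over the final ``val_frac`` tail
    (in the head's z-scale).  Ties go to the smaller parameter count.
    """
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    y = np.asarray(train, dtype=float)
    n_val = max(1, int(round(val_frac * len(y))))
    head = y[:-n_val]
    trials: list[tuple[NNetSpec, float]] = []
    for spec in grid:
        model = fit_nnet(head, spec, seed=seed, max_iter=max_iter)
        if model.train_sd == 0.0:
            z = y - model.train_mean
        else:
            z = (y - model.train_mean) / model.train_sd
        first = max(len(head), spec.s + (spec.m - 1) * spec.d)
        t_idx = np.arange(first, len(y))
        lag_cols = [z[t_idx - spec.s - (i - 1) * spec.d] for i in range(1, spec.m + 1)]
        preds = model.predict_scaled(np.column_stack(lag_cols))
        rmse = float(np.sqrt(np.mean((preds - z[t_idx]) ** 2)))
        trials.append((spec, rmse))
    chosen = min(trials, key=lambda t: (t[1], t[0].n_params))[0]
    return GridSearchResult(chosen=chosen, trials=tuple(trials), seed=seed)


def naive_validation_rmse(train: Sequence[float] | np.ndarray, val_frac: float = 0.25) -> float:
    """One-step last-value-carried-forward RMSE over the same validation tail
    (z-scaled with the head statistics), the reference level any selected
    architecture should beat."""
    y = np.asarray(train, dtype=float)
    n_val = max(1, int(round(val_frac * len(y))))
    head = y[:-n_val]
    sd = float(np.std(head, ddof=1))
    z = (y - float(np.mean(head))) / (sd if sd else 1.0)
    t_idx = np.arange(len(head), len(y))
    return float(np.sqrt(np.mean((z[t_idx - 1] - z[t_idx]) ** 2)))


# ---------------------------------------------------------------------------
# JSON serialization (deployability of pretrained subject-specific models)

def model_to_dict(model: NNetModel) -> dict:
    return {
        "spec": {"m": model.spec.m, "hidden": list(model.spec.hidden),
                 "d": model.spec.d, "s": model.spec.s},
        "weights": [w.tolist() for w in model.weights],
        "train_mean": model.train_mean,
        "train_sd": model.train_sd,
        "constant": model.constant,
    }


def model_from_dict(payload: dict) -> NNetModel:
    spec = NNetSpec(m=payload["spec"]["m"], hidden=tuple(payload["spec"]["hidden"]),
                    d=payload["spec"]["d"], s=payload["spec"]["s"])
    return NNetModel(
        spec=spec,
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        train_mean=payload["train_mean"],
        train_sd=payload["train_sd"],
        constant=payload["constant"],
    )


def save_model(model: NNetModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> NNetModel:
    return model_from_dict(json.loads(Path(path).read_text()))
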