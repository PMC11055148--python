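"""Sliding-window forecast evaluation.

The protocol: slide an input window of fixed length over the test series
one sample at a time; at each position a forecaster sees only the input
window and predicts the next ``horizon`` samples, which are scored against
the true output window by NRMSE (RMSE divided by the observed range of the
true output window).  The whole pass is repeated (10 times by default) and
the standard deviation of the per-pass mean NRMSE is the *dispersion* —
exactly zero for deterministic forecasters, nonzero for seeded neural
models.  Models are finally compared in a z-scaled performance space
(accuracy, dispersion, time per forecast) by Euclidean distance to the
transformed ideal of a perfect, instantaneous, perfectly repeatable model.

Two experiment presets are built in: experiment 1 = 50-sample input /
15-sample output windows, experiment 2 = 80 / 20.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np

from .exceptions import DegenerateWindowError
from .nnet import NNetModel, forecast_nnet, update_nnet
from .topology import fret_forecast

__all__ = [
    "WindowConfig",
    "EXPERIMENTS",
    "ForecastRecord",
    "ModelSummary",
    "PerformancePoint",
    "CohortSummary",
    "Forecaster",
    "FretForecaster",
    "NNetForecaster",
    "zscore_window",
    "rescale_forecast",
    "nrmse",
    "evaluate_series",
    "repeat_evaluation",
    "performance_distance",
    "summarize_cohort",
]


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: input length, forecast horizon, stride."""

    input_len: int
    horizon: int
    stride: int = 1

    def n_windows(self, test_len: int) -> int:
        return test_len - self.input_len - self.horizon + 1


#: The two window geometries evaluated in the study.
EXPERIMENTS: dict[int, WindowConfig] = {
    1: WindowConfig(input_len=50, horizon=15),
    2: WindowConfig(input_len=80, horizon=20),
}


def zscore_window(window: Sequence[float] | np.ndarray) -> tuple[np.ndarray, float, float]:
    """Z-score a window with its own mean and sample SD.

    Returns ``(scaled, mean, sd)`` so the transform can be inverted on the
    forecast; a zero-variance window raises ``DegenerateWindowError``.
    """
    w = np.asarray(window, dtype=float)
    mean = float(np.mean(w))
    sd = float(np.std(w, ddof=1))
    if sd == 0.0:
        raise DegenerateWindowError("window has zero variance, cannot z-score")
    return (w - mean) / sd, mean, sd


def rescale_forecast(scaled: Sequence[float] | np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Map z-scored forecast values back to the sensor scale: ``x*sd + mean``."""
    if sd <= 0.0:
        raise ValueError("sd must be positive to rescale")
    return np.asarray(scaled, dtype=float) * sd + mean


def nrmse(forecast: Sequence[float] | np.ndarray, observed: Sequence[float] | np.ndarray) -> float:
    """Root-mean-square error normalised by the observed range.

    The denominator is ``max(observed) - min(observed)`` of the *true*
    output-window values, which makes the metric unit-free and invariant
    under joint affine rescaling of both sequences.
    """
    f = np.asarray(forecast, dtype=float)
    o = np.asarray(observed, dtype=float)
    if f.shape != o.shape or f.ndim != 1 or len(f) < 1:
        raise ValueError(f"forecast and observed must be equal-length 1-D, got {f.shape} vs {o.shape}")
    rng = float(o.max() - o.min())
    if rng == 0.0:
        raise DegenerateWindowError("observed output window has zero range; NRMSE undefined")
    return float(np.sqrt(np.mean((f - o) ** 2)) / rng)


class Forecaster(Protocol):
    """Anything that maps an input window to a multi-step forecast."""

    name: str

    def forecast(self, window: np.ndarray, horizon: int) -> np.ndarray: ...


class FretForecaster:
    """Adapter running FReT on each input window (always up to date by
    construction; ignores seeds)."""

    def __init__(self, offset: int = 3, partition: str = "quantile",
                 mode: str = "top1", name: str = "fret"):
        self.offset = offset
        self.partition = partition
        self.mode = mode
        self.name = name

    def forecast(self, window: np.ndarray, horizon: int) -> np.ndarray:
        return fret_forecast(window, horizon, offset=self.offset,
                             partition=self.partition, mode=self.mode).values


class NNetForecaster:
    """Adapter around a pretrained MLP.

    ``update_epochs=0`` is the static condition (fixed weights);
    ``update_epochs>0`` retrains a copy on every input window first
    (the updated condition).  The wrapped model is never mutated.
    """

    def __init__(self, model: NNetModel, update_epochs: int = 0, name: str = "nnet"):
        self.model = model
        self.update_epochs = update_epochs
        self.name = name

    def forecast(self, window: np.ndarray, horizon: int) -> np.ndarray:
        model = self.model
        if self.update_epochs > 0:
            model = update_nnet(model, window, epochs=self.update_epochs)
        return forecast_nnet(model, window, horizon)


@dataclass(frozen=True)
class ForecastRecord:
    """Outcome of one sliding-window position."""

    start: int            # 0-based index of the first input-window sample
    nrmse: float          # NaN when the position was skipped
    elapsed: float        # seconds spent inside the forecast call
    skipped: bool = False


@dataclass(frozen=True)
class ModelSummary:
    """Per-model accuracy/precision/time summary of repeated evaluation."""

    name: str
    mean_nrmse: float
    dispersion: float
    mean_time: float
    iterations: int


@dataclass(frozen=True)
class PerformancePoint:
    """A model's z-scaled coordinates and distance to the transformed ideal."""

    name: str
    coords: tuple[float, float, float]
    distance_to_ideal: float


def evaluate_series(
    test: Sequence[float] | np.ndarray,
    forecaster: Forecaster,
    config: WindowConfig,
) -> list[ForecastRecord]:
    """One full sliding-window pass over a test series.

    Positions whose input window has zero variance or whose true output
    window has zero range are logged as skipped without calling the
    forecaster, so the skip set is identical for every model and
    comparisons stay paired.  Timing wraps the forecast call only.
    """
    x = np.asarray(test, dtype=float)
    n_win = config.n_windows(len(x))
    if n_win < 1:
        raise ValueError(
            f"test series of length {len(x)} is too short for "
            f"input_len={config.input_len}, horizon={config.horizon}"
        )
    records: list[ForecastRecord] = []
    for k in range(n_win):
        start = k * config.stride
        window = x[start : start + config.input_len]
        observed = x[start + config.input_len : start + config.input_len + config.horizon]
        if np.std(window, ddof=1) == 0.0 or observed.max() == observed.min():
            records.append(ForecastRecord(start=start, nrmse=np.nan, elapsed=0.0, skipped=True))
            continue
        t0 = time.perf_counter()
        fc = forecaster.forecast(window, config.horizon)
        elapsed = time.perf_counter() - t0
        records.append(ForecastRecord(start=start, nrmse=nrmse(fc, observed), elapsed=elapsed))
    return records


def mean_nrmse(records: Sequence[ForecastRecord]) -> float:
    vals = [r.nrmse for r in records if not r.skipped]
    if not vals:
        raise DegenerateWindowError("every window position was skipped")
    return float(np.mean(vals))


def repeat_evaluation(
    test: Sequence[float] | np.ndarray,
    forecaster_factory: Callable[[int], Forecaster],
    config: WindowConfig,
    iterations: int = 10,
    seed_base: int = 0,
    name: str | None = None,
) -> ModelSummary:
    """The repeated-pass protocol: mean NRMSE and its dispersion.

    ``forecaster_factory(seed)`` builds the forecaster for each pass;
    pass ``k`` (1-based) receives ``seed_base + k``, which is where
    run-to-run variation of seeded neural models enters.  Deterministic
    forecasters ignore the seed, so their dispersion (the sample SD of the
    per-pass mean NRMSE) is exactly zero.
    """
    if iterations < 2:
        raise ValueError("need at least 2 iterations for a defined dispersion")
    means, times = [], []
    label = name
    for k in range(1, iterations + 1):
        forecaster = forecaster_factory(seed_base + k)
        label = label or forecaster.name
        records = evaluate_series(test, forecaster, config)
        means.append(mean_nrmse(records))
        times.append(float(np.mean([r.elapsed for r in records if not r.skipped])))
    # Sample SD of identical values is zero by definition; computing it via
    # np.std can round to ~1e-17 because the mean of n identical floats need
    # not equal them bit-for-bit.  Deterministic forecasters must report an
    # exact 0.0 dispersion, so identical passes short-circuit.
    dispersion = 0.0 if min(means) == max(means) else float(np.std(means, ddof=1))
    return ModelSummary(
        name=label or "model",
        mean_nrmse=float(np.mean(means)),
        dispersion=dispersion,
        mean_time=float(np.mean(times)),
        iterations=iterations,
    )


def performance_distance(summaries: Sequence[ModelSummary]) -> list[PerformancePoint]:
    """Distances to the ideal model in z-scaled performance space.

    The three raw coordinates per model are (mean NRMSE, dispersion, mean
    time per forecast).  Each is z-scored across models (sample SD); the
    ideal point is the raw origin — zero error, zero dispersion, zero time —
    pushed through the same per-variable transform, and each model's score
    is its 3-D Euclidean distance to that transformed ideal.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 models to define the performance space")
    raw = np.array([[s.mean_nrmse, s.dispersion, s.mean_time] for s in summaries])
    mu = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        bad = [("nrmse", "dispersion", "time")[i] for i in np.flatnonzero(sd == 0.0)]
        raise ValueError(
            f"zero cross-model variance in {bad}; drop the variable or add models"
        )
    z = (raw - mu) / sd
    ideal = (0.0 - mu) / sd
    dists = np.sqrt(((z - ideal) ** 2).sum(axis=1))
    return [
        PerformancePoint(name=s.name, coords=tuple(zi), distance_to_ideal=float(di))
        for s, zi, di in zip(summaries, z, dists)
    ]


@dataclass(frozen=True)
class CohortSummary:
    """Cross-subject view of one model: per-subject means plus their spread."""

    values: tuple[float, ...]
    mean: float
    sd: float


def summarize_cohort(subject_means: Sequence[float]) -> CohortSummary:
    """Aggregate subject-level mean NRMSE values across a cohort.

    The returned vector feeds distribution-density views of inter-individual
    variability; mean and sample SD summarise generalisability.
    """
    vals = tuple(float(v) for v in subject_means)
    if len(vals) < 2:
        raise ValueError("need at least 2 subjects to summarise a cohort")
    sd = 0.0 if min(vals) == max(vals) else float(np.std(vals, ddof=1))
    return CohortSummary(values=vals, mean=float(np.mean(vals)), sd=sd)
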