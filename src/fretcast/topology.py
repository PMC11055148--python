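"""Forecasting through Recurrent Topology (FReT).

FReT is a hyperparameter-free analogue forecaster for one-dimensional,
uniformly sampled signals.  The pipeline is:

1. Build the pairwise Euclidean distance matrix ``D`` of the signal
   (for scalar samples, absolute differences).
2. Re-encode every cell of ``D`` by an 8-neighbour binary positional code
   (a local-binary-pattern operator on the matrix surface), giving an
   integer code in ``0..255`` per cell.
3. Partition the codes into sextiles, yielding the local topological
   matrix ``T'`` with entries in ``{1..6}``.
4. Compare every prior row of ``T'`` with the last row (the system's
   current state) by the fraction of equal entries, giving a similarity
   weight in ``[0, 1]`` per prior time point.
5. The best-matching prior row is the *archetype*; the signal samples that
   followed it are copied out as the multi-step forecast, on the original
   sensor scale.

Everything here is deterministic: identical inputs give bit-identical
forecasts, which is why the repeated-evaluation dispersion of FReT is
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import HorizonError, InvalidSignalError, TooShortError

__all__ = [
    "NEIGHBOUR_OFFSETS",
    "ArchetypeResult",
    "FretForecast",
    "distance_matrix",
    "local_code",
    "encode_codes",
    "partition_sextiles",
    "similarity_weights",
    "identify_archetype",
    "fret_forecast",
]

#: Fixed traversal of the eight neighbours of a 3x3 block, row-major with the
#: centre excluded; neighbour q (1-based) carries positional weight 2**(q-1).
NEIGHBOUR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)

PartitionScheme = Literal["quantile", "fixed"]


@dataclass(frozen=True)
class ArchetypeResult:
    """Best-matching prior row and where its forecast trace starts.

    ``raw_index`` is the 1-based position in the similarity vector;
    ``forecast_start`` is the 1-based signal index ``raw_index + offset``.
    """

    raw_index: int
    forecast_start: int
    similarity: float


@dataclass(frozen=True)
class FretForecast:
    """A FReT forecast with its archetype provenance."""

    values: np.ndarray
    source: ArchetypeResult


def _as_signal(values: Sequence[float] | np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidSignalError(f"signal must be one-dimensional, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidSignalError("signal contains non-finite values")
    return x


def distance_matrix(signal: Sequence[float] | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix of a scalar signal.

    For scalar samples the Euclidean distance reduces to the absolute
    difference, so ``D[i, j] = |x_i - x_j|``: symmetric, zero-diagonal,
    non-negative.
    """
    x = _as_signal(signal)
    return np.abs(x[:, None] - x[None, :])


def local_code(neighbourhood: np.ndarray) -> int:
    """8-bit positional code of a single 3x3 neighbourhood.

    Each neighbour ``g_q`` (q = 1..8, ordering per :data:`NEIGHBOUR_OFFSETS`)
    contributes ``2**(q-1)`` when ``g_q - g_0 >= 0`` relative to the centre
    ``g_0``; the code is the sum of the contributions, an integer in 0..255.
    """
    nb = np.asarray(neighbourhood, dtype=float)
    if nb.shape != (3, 3):
        raise ValueError(f"neighbourhood must be 3x3, got shape {nb.shape}")
    centre = nb[1, 1]
    code = 0
    for q, (di, dj) in enumerate(NEIGHBOUR_OFFSETS, start=1):
        if nb[1 + di, 1 + dj] - centre >= 0:
            code += 1 << (q - 1)
    return code


def encode_codes(d: np.ndarray, pad: bool = True) -> np.ndarray:
    """Apply the 8-neighbour binary coding to every cell of a matrix.

    With ``pad=True`` (default) the matrix is first padded with one
    replicated edge layer so the code matrix keeps the input dimensions.
    With ``pad=False`` codes are computed for interior cells only and the
    output is ``(n-2) x (m-2)`` ("valid" mode) — the mode the forecasting
    pipeline uses, since it keeps the archetype index bookkeeping exact.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {d.shape}")
    if min(d.shape) < 3:
        raise TooShortError(f"matrix must be at least 3x3, got {d.shape}")
    padded = np.pad(d, 1, mode="edge") if pad else d
    centre = padded[1:-1, 1:-1]
    h, w = centre.shape
    codes = np.zeros((h, w), dtype=np.int64)
    for q, (di, dj) in enumerate(NEIGHBOUR_OFFSETS, start=1):
        nb = padded[1 + di : 1 + di + h, 1 + dj : 1 + dj + w]
        codes += ((nb - centre) >= 0).astype(np.int64) << (q - 1)
    return codes


def partition_sextiles(codes: np.ndarray, scheme: PartitionScheme = "quantile") -> np.ndarray:
    """Flatten integer codes into six layers ``{1..6}``.

    ``scheme="quantile"`` (default) uses empirical sextiles of the matrix's
    own code distribution, with ties assigned to the lower bin;
    ``scheme="fixed"`` uses six equal-width bins of the full 0..255 range.
    Both are monotone in the code value.
    """
    c = np.asarray(codes)
    if scheme == "quantile":
        edges = np.quantile(c, np.arange(1, 6) / 6.0)
        layers = 1 + (c[..., None] > edges).sum(axis=-1)
    elif scheme == "fixed":
        layers = np.minimum(np.floor_divide(c * 6, 256), 5) + 1
    else:
        raise ValueError(f"unknown partition scheme: {scheme!r}")
    return layers.astype(np.int64)


def similarity_weights(t: np.ndarray) -> np.ndarray:
    """Similarity of every prior row of ``T'`` to the last row.

    The weight of prior row ``i`` is the fraction of positions at which it
    equals the last row — 1 for an identical row, 0 for a row differing
    everywhere.  Returns one weight per prior row (the last row itself is
    excluded).
    """
    t = np.asarray(t)
    if t.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {t.shape}")
    if t.shape[0] < 2:
        raise TooShortError("need at least two rows to compare")
    return (t[:-1] == t[-1]).mean(axis=1)


def identify_archetype(
    weights: np.ndarray,
    n: int,
    horizon: int,
    offset: int = 3,
    tie: Literal["latest", "earliest"] = "latest",
) -> ArchetypeResult:
    """Pick the eligible prior row with maximal similarity.

    A row index ``i`` (1-based position in ``weights``) is eligible when a
    full forecast trace fits inside the observed signal:
    ``i + offset + horizon - 1 <= n``.  Ties are broken towards the most
    recent eligible index by default (closest to the current dynamical
    regime); ``tie="earliest"`` flips that.
    """
    w = np.asarray(weights, dtype=float)
    if horizon < 1:
        raise ValueError("horizon must be a positive integer")
    n_eligible = min(len(w), n - offset - horizon + 1)
    if n_eligible < 1:
        raise HorizonError(
            f"no eligible archetype: horizon {horizon} with offset {offset} "
            f"does not fit in a signal of length {n}"
        )
    w_el = w[:n_eligible]
    best = w_el.max()
    candidates = np.flatnonzero(w_el == best)
    pick = candidates[-1] if tie == "latest" else candidates[0]
    raw_index = int(pick) + 1
    return ArchetypeResult(
        raw_index=raw_index,
        forecast_start=raw_index + offset,
        similarity=float(best),
    )


def fret_forecast(
    signal: Sequence[float] | np.ndarray,
    horizon: int,
    offset: int = 3,
    mode: Literal["top1", "weighted_topk"] = "top1",
    partition: PartitionScheme = "quantile",
    top_k: int = 3,
    tie: Literal["latest", "earliest"] = "latest",
) -> FretForecast:
    """Multi-step FReT forecast of the next ``horizon`` samples.

    Runs the full pipeline (distance matrix -> 8-neighbour codes on the
    interior cells -> sextile layers -> row similarity -> archetype) and
    copies the contiguous signal segment starting at the archetype's
    ``forecast_start``.  Values stay on the original sensor scale; no
    z-scoring is involved anywhere.

    ``mode="weighted_topk"`` instead averages the traces of the ``top_k``
    most similar eligible archetypes, weighted by their similarity (uniform
    fallback when all similarities are zero).
    """
    x = _as_signal(signal)
    n = len(x)
    if n < 4:
        raise TooShortError(f"need at least 4 samples to forecast, got {n}")
    d = distance_matrix(x)
    codes = encode_codes(d, pad=False)
    t = partition_sextiles(codes, scheme=partition)
    w = similarity_weights(t)
    arch = identify_archetype(w, n=n, horizon=horizon, offset=offset, tie=tie)
    start0 = arch.forecast_start - 1  # 1-based signal index -> 0-based slice
    if mode == "top1":
        values = x[start0 : start0 + horizon].copy()
    elif mode == "weighted_topk":
        n_eligible = min(len(w), n - offset - horizon + 1)
        w_el = w[:n_eligible]
        order = np.argsort(w_el, kind="stable")[::-1][:top_k]
        sims = w_el[order]
        weights = sims if sims.sum() > 0 else np.ones_like(sims)
        traces = np.stack(
            [x[i + offset : i + offset + horizon] for i in order]
        )  # order is 0-based, so i + offset == (i+1) + offset - 1
        values = np.average(traces, axis=0, weights=weights)
    else:
        raise ValueError(f"unknown forecast mode: {mode!r}")
    return FretForecast(values=values, source=arch)
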