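"""Synthetic hip flexion/extension signals.

Participant sensor recordings are not redistributable, so this module
generates quasi-periodic stand-ins with the same cohort geometry: 15
subjects, 600 samples each at 37.5 Hz, split 300/300 into training and
testing halves.  The waveform is a small harmonic sum at a stride
frequency near 0.9 Hz with cycle-wise random-walk phase and amplitude
jitter plus additive Gaussian sensor noise — enough structure (drifting
quasi-periodicity) to exercise analogue matching, window scaling, and the
full evaluation protocol.  With all jitter and noise at zero the signal is
exactly periodic, which is what the periodicity-exactness tests rely on.

All generation is a pure function of the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["GaitSimSpec", "generate_subject", "generate_cohort", "split_train_test"]


@dataclass(frozen=True)
class GaitSimSpec:
    """Parameters of one synthetic subject's gait-angle series.

    Units: ``sampling_rate`` and ``fundamental`` in Hz, ``amplitude``,
    ``baseline`` and ``noise_sd`` in degrees, ``phase_jitter_sd`` in radians
    per gait cycle, ``amplitude_jitter_sd`` relative per cycle.
    """

    n_samples: int = 600
    sampling_rate: float = 37.5
    fundamental: float = 0.9
    amplitude: float = 35.0
    baseline: float = 5.0
    harmonics: tuple[float, ...] = (1.0, 0.3, 0.1)
    phase_jitter_sd: float = 0.05
    amplitude_jitter_sd: float = 0.05
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.sampling_rate <= 0 or self.fundamental <= 0:
            raise ValueError("sampling_rate and fundamental must be positive")
        if min(self.phase_jitter_sd, self.amplitude_jitter_sd, self.noise_sd) < 0:
            raise ValueError("jitter and noise SDs must be non-negative")
        if len(self.harmonics) < 1:
            raise ValueError("need at least one harmonic amplitude")


def generate_subject(spec: GaitSimSpec) -> np.ndarray:
    """One subject's hip-angle series (degrees), deterministic in the seed.

    Each gait cycle k carries a random-walk phase offset and amplitude
    factor, held constant within the cycle, so consecutive cycles resemble
    but never exactly repeat each other — the quasi-periodicity of real
    self-paced walking.
    """
    rng = np.random.default_rng(spec.seed)
    period = spec.sampling_rate / spec.fundamental
    noise_free = (spec.phase_jitter_sd == 0 and spec.amplitude_jitter_sd == 0
                  and spec.noise_sd == 0)
    if noise_free and abs(period - round(period)) < 1e-9:
        # Exactly periodic case: build one cycle and tile it so repeats are
        # bit-identical (per-sample sin() evaluation drifts in the last ulp,
        # which would break analogue matching at machine precision).
        p = int(round(period))
        tc = np.arange(p) / spec.sampling_rate
        one = np.zeros(p)
        for k, rel in enumerate(spec.harmonics, start=1):
            one += rel * np.sin(2 * np.pi * k * spec.fundamental * tc)
        one = spec.baseline + spec.amplitude * one
        reps = -(-spec.n_samples // p)
        return np.tile(one, reps)[: spec.n_samples]
    t = np.arange(spec.n_samples) / spec.sampling_rate
    cycle = np.floor(spec.fundamental * t).astype(int)
    n_cycles = int(cycle.max()) + 1
    phase_walk = np.cumsum(rng.normal(0.0, spec.phase_jitter_sd, size=n_cycles))
    amp_walk = np.cumprod(1.0 + rng.normal(0.0, spec.amplitude_jitter_sd, size=n_cycles))
    phase = phase_walk[cycle]
    amp = spec.amplitude * amp_walk[cycle]
    x = np.zeros(spec.n_samples)
    for k, rel in enumerate(spec.harmonics, start=1):
        x += rel * np.sin(2 * np.pi * k * spec.fundamental * t + k * phase)
    x = spec.baseline + amp * x
    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
    return x


def generate_cohort(
    n_subjects: int = 15,
    base_seed: int = 0,
    spec: GaitSimSpec = GaitSimSpec(),
    cadence_sd: float = 0.08,
    amplitude_sd: float = 5.0,
    noise_sd_sd: float = 0.15,
) -> list[tuple[GaitSimSpec, np.ndarray]]:
    """A cohort of subjects with individual cadence, amplitude and noise.

    Subject-level parameters are drawn around ``spec`` from a generator
    seeded by ``base_seed``; each subject's series then gets its own
    spawned seed, so regeneration with the same base seed is identical and
    distinct subjects differ.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    rng = np.random.default_rng(base_seed)
    subjects = []
    for i in range(n_subjects):
        sub_spec = replace(
            spec,
            fundamental=max(0.4, spec.fundamental + rng.normal(0.0, cadence_sd)),
            amplitude=max(5.0, spec.amplitude + rng.normal(0.0, amplitude_sd)),
            noise_sd=abs(spec.noise_sd + rng.normal(0.0, noise_sd_sd)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append((sub_spec, generate_subject(sub_spec)))
    return subjects


def split_train_test(series: Sequence[float] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-half training, second-half testing (floor rule for odd length).

    A 600-sample series splits 300/300; 601 samples split 300/301.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("series must have at least 2 samples to split")
    half = len(x) // 2
    return x[:half].copy(), x[half:].copy()
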