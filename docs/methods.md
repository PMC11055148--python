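# Methods

This note records the model, the conventions the implementation fixes
where more than one reading is defensible, the synthetic-data assumptions,
and the numerical choices that matter for reproducing results.

## The FReT forecaster

FReT treats a one-dimensional window **x** ∈ ℝⁿ as a surface — its
pairwise distance matrix D, dᵢⱼ = |xᵢ − xⱼ| — and looks for past moments
whose local surface shape matches the present one. Shape is captured by an
8-neighbour binary positional code: for each interior cell, neighbour
q ∈ {1..8} contributes 2^(q−1) when its value is greater than or equal to
the centre's. The comparison uses s(x) = 1 for x ≥ 0, so a flat
neighbourhood saturates at code 255, and enumerating all 2⁸ sign patterns
produces each integer 0..255 exactly once. The codes are flattened into
six sextile layers, giving the topological matrix T′ over Z = {1..6}; row
similarity to the last row (fraction of equal entries) identifies the
archetype, and the samples that followed it are the forecast.

### Conventions fixed here

- **Neighbour traversal.** The q-ordering is row-major over the 3×3 block
  with the centre excluded. Any fixed consistent ordering yields a
  bijection between sign patterns and codes, and the equality-based row
  similarity is invariant to the choice; it is configurable in
  `NEIGHBOUR_OFFSETS` only as documentation of the convention.
- **Sextile partition.** Default is empirical sextiles (quantile edges of
  the matrix's own code distribution, ties to the lower bin), with an
  equal-width 0..255 partition (`scheme="fixed"`) as an alternative
  dialect. Both are monotone in the code. A constant code matrix collapses
  to a single layer, which the tie rule downstream absorbs.
- **Border handling and the +3 offset.** `encode_codes` supports both a
  shape-preserving mode (one replicated edge layer of padding) and a
  "valid" mode that encodes interior cells only, producing an
  (n−2)×(n−2) matrix. The forecasting pipeline uses valid mode, because it
  makes the index bookkeeping exact: trimmed row k corresponds to signal
  sample k+1, the last trimmed row to sample n−1, so the continuation of
  an archetype at row k begins at signal index k+3 — one for the border
  shift, two to step from the current-state row to the first unseen
  sample. With this convention a noise-free signal of integer period p
  (window ≥ 2p + horizon... in practice ≥ p + horizon + 3) has an
  archetype row of similarity exactly 1 one period back, and the copied
  segment equals the true continuation sample-for-sample. Under the
  shape-preserving convention the last row is edge-padded and that
  exactness is unattainable, which is why valid mode is the pipeline
  default; `offset` remains an independent parameter (default 3).
- **Eligibility and ties.** Only archetypes whose full trace lies inside
  the window are eligible (i + offset + horizon − 1 ≤ n). Ties in the
  maximal similarity go to the most recent eligible index — the closest
  match to the current dynamical regime — configurable to earliest. A
  constant window makes every weight 1 and returns a constant forecast
  rather than an error.
- **Single vs multiple archetypes.** Default is the single maximiser
  (top-1, a copied contiguous segment). A similarity-weighted average of
  the top-k traces is exposed (`mode="weighted_topk"`) but off by default.

FReT performs no scaling anywhere: forecasts are actual past signal
values, so the method is covariant under affine maps of its input.

## Network baselines

NNET (one hidden layer) and D-NNET (two or more) are autoregressive MLPs
mapping m consecutive lags (spacing d = 1) of the z-scored series to the
next value, with logistic hidden units and a linear output. Fitting
minimises the full-batch sum of squared one-step errors by L-BFGS-B
(analytic gradients) from a small-uniform init drawn from a seeded
generator, capped at 200 iterations by default — deterministic per seed,
dispersing across seeds, which is exactly what the repeated-evaluation
protocol measures. Grid search fits each candidate on the head of the
training split and scores teacher-forced one-step RMSE on the final 25%;
ties go to the smaller parameter count. Default grids are m ∈ 1..10,
units ∈ 1..10, and 2–3 layers for D-NNET; the cohort-scale tests use a
reduced grid (m ∈ {2,4}, units ∈ {2,4}, one layer) to keep a 15-subject ×
10-replicate run at desk scale.

Multi-step forecasts are recursive: each one-step output is appended and
reused as a lag. Each input window is z-scored with its own mean and
sample SD before entering the network and the outputs are rescaled with
the same statistics, so forecasts are location-equivariant in the window.
The *updated* condition retrains a copy of the pretrained model on every
input window (warm start, 50 L-BFGS-B iterations by default; epochs = 0 is
a bit-exact no-op); the wrapped model is never mutated. A zero-variance
training series yields a constant predictor; a zero-variance input window
is a degenerate-window error that the harness records and skips.

## Evaluation protocol

Two window geometries: experiment 1 = 50-sample input / 15-sample output,
experiment 2 = 80 / 20, both with stride 1, giving
`test_len − input_len − horizon + 1` positions (236 and 201 on a
300-sample test half). Accuracy per position is NRMSE — RMSE of the
forecast against the true output window divided by that window's observed
range — which is invariant under joint affine maps of both series. A full
pass is repeated 10 times; iteration k hands seed base+k to the forecaster
factory (neural models are refit from that seed; FReT ignores it). The
dispersion is the sample SD of the 10 per-pass mean NRMSE values.

Positions whose input window has zero variance or whose output window has
zero range are skipped before any forecaster is called, so the skip set is
identical across models and comparisons stay paired. Timing wraps the
forecast call only (excluding window slicing and metric computation) and
is reported but never asserted, being hardware-bound.

Model comparison z-scores the three per-model summary variables (mean
NRMSE, dispersion, mean time) across models within an experiment — sample
SD throughout — and measures each model's 3-D Euclidean distance to the
raw origin (a perfect, perfectly repeatable, instantaneous model) pushed
through the same transform. Distances are computed per experiment in 3-D,
matching the two-column reporting of the study design. FReT is evaluated
on the current input window only, not the accumulated test history
(configurable as an extension).

## Synthetic cohort

Real recordings are unavailable, so the generator emulates their geometry
and gross structure: 600 samples per subject at 37.5 Hz (derived from 15
samples ≈ 400 ms), first 300 training / last 300 testing, 15 subjects.
The waveform is baseline + amplitude × Σₖ hₖ sin(2πk f t + kφ), with
stride frequency f = 0.9 Hz, amplitude 35°, baseline 5°, harmonic weights
(1.0, 0.3, 0.1), a per-cycle random-walk phase offset (SD 0.05 rad/cycle)
and amplitude factor (SD 5%/cycle), and additive Gaussian sensor noise
(SD 0.5°). Cohorts draw subject-level cadence (SD 0.08 Hz), amplitude
(SD 5°) and noise level (SD 0.15°) around those defaults, each subject
seeded from the cohort generator so regeneration is exact.

These defaults give hip-angle excursions, cadence, and cycle-to-cycle
drift plausible for self-paced adult walking, but the generator does not
reproduce real sensor characteristics: no gait events or asymmetry, no
drift or quantisation in the sensor model, no variable walking speed, no
pathological gait. Passing tests therefore show that the pipeline and its
guarantees (determinism, exactness, ordering of methods on quasi-periodic
data) hold, not that the absolute NRMSE values transfer to any clinical
population.

One numerical subtlety: with all jitter and noise at zero and an integer
number of samples per cycle, the generator builds one cycle and tiles it,
because per-sample `sin` evaluation drifts in the last ulp between
repeats, which would silently break the machine-precision periodicity
guarantees the tests assert.

## Numerical choices

- Sample standard deviation (ddof = 1) everywhere: z-scores, dispersion,
  performance space, cohort spread.
- The sample SD of identical values is returned as exactly 0.0 rather
  than computed, since the mean of n identical floats need not equal them
  bit-for-bit and the residual ~1e-17 would misreport a deterministic
  forecaster's dispersion.
- Quantile sextile ties go to the lower bin; code comparisons use ≥ so a
  tied neighbour counts as "at or above" the centre.
- Degenerate inputs: constant training series → constant predictor;
  constant input window → error for the scaled network path, constant
  forecast for FReT (whose tie rule handles it); zero-range output window
  → position skipped for every model.

## Problem sizes used

Unit and property tests run on windows of 20–150 samples and matrices of
size 3–12; the dispersion protocol uses one 600-sample subject (236
windows × 10 passes); the cohort-ordering check runs 10 replicates of 15
subjects under both geometries with the reduced grid. These sizes were
chosen so the full suite runs in about a minute on one CPU while still
exercising every code path at the study's window geometry.

## Known limitations

- The similarity metric compares full topology rows; very long windows
  dilute local mismatches (no row truncation is implemented).
- The weighted top-k mode averages traces without phase alignment.
- The update schedule for the *updated* networks (50 iterations/window)
  is a declared default, not an estimate from the original deployment.
- Absolute timing comparisons depend on hardware and are advisory only.
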