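# Methods

## Model

The circuit couples an alternative sigma factor (σ^V) to its
anti-sigma factor (RsiV) through a mixed feedback loop. The state is
the copy-number triple (free σ^V, free RsiV, σ^V–RsiV complex); the
seven wild-type reaction channels are listed in the README. Key
modelling assumptions, shared with the deterministic companion:

- Production of σ^V and RsiV is a single operon-level channel emitting
  both partners together, at rate v₀ + v·sⁿ/(sⁿ+Kⁿ) in the free σ^V
  copy number s. Transcription and translation are not modelled
  separately; noise is the intrinsic event noise of the channels.
- All three species dilute at the same rate k_deg, standing in for
  growth-driven dilution of stable proteins; there is no explicit
  division partitioning in the circuit (division noise is not part of
  the model; the synthetic generator adds divisions only to the
  length channel).
- Lysozyme is a dimensionless input L that scales the cleavage rate of
  the complex (L·k_C per complex); cleavage releases σ^V and destroys
  RsiV, so it conserves total σ^V and removes one RsiV. There is no
  explicit lysozyme–RsiV binding, protease cascade, or cell-wall
  modification feedback.
- Ultrasensitivity (n = 2) in the production term is required for
  heterogeneous, fluctuation-triggered activation; the
  `hill_override` variant exposes this check.

Default parameters (units: molecules, minutes): v₀ = 0.1, v = 2.5,
K = 60, n = 2, k_deg = 0.01, k_B = 10, k_D = 5, k_C = 0.05. At these
values the unstressed fixed point holds ~2 free σ^V, ~2 free RsiV and
~8 complexes per cell (total σ^V ≈ 10), and the stressed (L = 1)
fixed point ~199 free σ^V — plausible sigma-factor copy numbers. All
times are minutes throughout; the model's arbitrary time units are
identified with minutes, consistent with k_deg being matched to the
experimental division rate.

## Simulators

**SSA.** Gillespie's direct method, exact for the piecewise-constant
stress protocols: at each protocol segment boundary the exponential
clock is re-drawn with the updated propensities, which is exact when
rates are constant within segments. States are recorded on a uniform
grid (default 10 min, the imaging cadence) by
last-event-carried-forward. The inner loop is numba-compiled; a pure
Python fallback keeps the package importable without numba.

**CLE.** Euler–Maruyama over channels: per step the state increment is
Gaussian with mean Σ νⱼaⱼdt and covariance dt·Σ aⱼνⱼνⱼᵀ. The
per-channel noises are aggregated into that exact 3×3 covariance and
sampled by Cholesky factorization — identical in law to independent
per-channel noises, at three normal draws per step. Step size: by
default adaptive with max-propensity·dt = 0.1 (capped at 0.5 min);
an explicit `dt` fixes the step (used in the large-system
deterministic-limit check, where the adaptive rule becomes needlessly
fine). Negative excursions are handled by full truncation:
propensities are evaluated on a zero-clamped copy of the state while
the state itself keeps its small negative excursions; recorded samples
are clamped at zero. Clamping the state itself instead would bias
near-zero species (free RsiV sits at ~0.1 copies in the activated
state) upward and spuriously deactivate the circuit.

**Mean-field oracle.** The ODE right-hand side is assembled channel-
by-channel from the same network object, so each term corresponds
one-to-one to a reaction channel. Steady states are found by long-time
LSODA integration refined with a root solve, probed from both the
empty state and a high-σ^V state; a flag reports bistability (at the
default parameters the system is monostable at every L probed, with
the free-σ^V fixed point rising from ~2 at L = 0 through 165/187/199/
221/233 at L = 0.5/0.75/1/2/4). Under the system-size scaling
Ω·(v₀, v, K), k_B/Ω the intensive dynamics are invariant and the SSA
ensemble mean converges to the ODE; the verification uses the
time-averaged relative error along unstressed and stress-step paths
(time-averaging rather than a pointwise maximum keeps the metric from
being dominated by ensemble sampling noise).

**Reproducibility.** Every ensemble expands one base seed into
distinct per-trajectory seeds via `numpy.random.SeedSequence`;
identical (network, protocol, seed) give bit-identical paths for both
simulators.

## In-silico experiments

Problem sizes follow the study design: dose–response N = 100 per
level at L ∈ {0.5, 0.75, 1, 2, 4}; copy-number snapshots N = 999 per
variant with the 30-min assay; memory N = 99 per arm; feedback
comparison N = 100 per constitutive rate; error bars by 1,000
bootstrap resamples. Two activation criteria are used and named
explicitly:

- **Half-max rule** (time courses): a cell activates when its readout
  first reaches half of its own final level, the final level being the
  mean over a trailing window (default 500 min for model experiments;
  the "final value" is per-cell). Cells that never cross, or whose
  final level does not exceed their pre-stress mean, are censored and
  stay in denominators.
- **6σ snapshot rule**: activated means above the wild-type pre-stress
  mean plus six (sample, N−1) standard deviations.

Choices the design left open, fixed here once:

- Burn-in 500 min from the empty state before stress (the pre-stress
  window in the step experiments); post-stress window 5,000 min for
  dose–response and the Hill check so that even the slowest L = 0.5
  cells mostly activate, 2,000 min for the feedback comparison,
  1,500 min for the robustness scan, 3,000 min for memory arms.
- Memory protocol: cells start at the rounded activated mean-field
  steady state under stress, which is removed at t = 500 min; after a
  gap g ∈ {50, 200, 400, 800} min the same stress returns, and
  activation times are measured from the restress onset (the restress
  sub-trace has no pre-stress segment, so the non-responder censor
  does not apply). The naive control is a first stress after the
  unstressed burn-in. Heterogeneity is reported as the s.d. of
  activation times (primary) and the time to 90% activation
  (secondary).
- Feedback-broken constitutive rates {0.1, 0.5, 1, 2.5}/min: chosen so
  the broken-circuit total σ^V steady states (rate/k_deg = 10…250)
  bracket the wild-type pre-stress (~10) and post-stress (~260)
  totals. Fold change is per-cell (trailing-window mean over
  pre-stress-window mean); cells with an exactly zero pre-stress mean
  are flagged undefined and excluded, never pseudo-counted.
- Leak scan deltas {0, 0.05, 0.1, 0.2}/min — fractions of the maximal
  operon activity comparable to v₀ itself, emulating "small increases
  in baseline production"; N = 1,000 per arm keeps the monotone
  ordering of activated fractions above counting noise.
- Robustness scan: each parameter ×2 and ÷2, one at a time, N = 30 per
  point, flagged as retaining dispersed activation when the
  activation-time s.d. exceeds a 20-min floor (two frames).

## Trace statistics

Implemented as stated rules: cumulative activation curves (censored
cells in denominators); snapshot activation fractions (strict
inequality, so a zero-variance pre-stress sample with post equal to
the mean yields 0); fold change; sample CV; instantaneous growth rate
(log-length difference per frame within one cell cycle, never across
a marked division); overshooting-cell removal (Gaussian-smoothed
width maxima, bandwidth 2 frames, against the pooled pre-stress mean
+ 6 s.d.); the pre-stress/response-time association (groups split at
pooled mean + 1 s.d. of per-cell pre-stress means, two-sided
two-sample KS, α = 0.05, censored cells excluded from the KS
samples); and priming survival under two counting rules — top-3 cells
per channel with one (longest) surviving lineage counted per cell, or
all cells minus those whose last position lies within 6 s.d. of the
estimated channel end (estimated from pre-stress exit positions).
Sample standard deviations (N−1) are used for every mean+k·s.d.
threshold.

## Synthetic data generator

The generator emulates mother-machine data for testability, not
inference: frames every 10 min; a YFP-like reporter driven by the
operon production term through an immature→mature cascade (maturation
time 15 min, interpreted as the mean first-order delay 1/k_m) with
both pools diluted at k_deg, integrated exactly per frame for
piecewise-constant input; multiplicative lognormal measurement noise
(σ = 0.05 by default); per-cell cell-cycle times N(51, 13) min driving
exponential length growth with halving at division; a width channel
whose "sick" fraction (10% by default) widens 1.5× after stress; and
channel lineage forests with divisions pushing the bottom cell out
(washout events) and survival draws at lethal-stress onset.

Deliberate simplifications, and what passing tests therefore do and
do not show: divisions affect only the length channel (molecule counts
are not partitioned — dilution inside the circuit already stands in
for division); all descendants of a channel founder share the
founder's circuit trajectory in the priming forests (clonal
approximation); lengths are noise-free by default, so recovered
growth rates are exact rather than estimator-robust; the
survival-vs-expression rule is a free knob (default constant 0.5)
because no quantitative dose curve exists to emulate — survival tests
check recovery of programmed fractions, not biology. Ground truth
records two switch times per cell: the free-σ^V half-max crossing and
the noise-free reporter half-max crossing. The reporter crossing lags
the σ^V crossing systematically (maturation plus the ~1/k_deg
reporter rise), so estimator-recovery tolerances (±1 frame for ≥95%
of non-censored cells at the default noise) are stated against the
reporter-level truth — the quantity an estimator of the measured
fluorescence can identify. Parametric sigmoid-step traces with a
programmed pre-stress-level/switch-delay correlation
(`prestress_correlation`) cover the association test, where the
circuit-driven traces would entangle the programmed and emergent
effects.

## Numerical notes and limitations

- SSA/CLE kernels special-case n ∈ {1, 2} in the Hill term; the Hill
  function is evaluated in a ratio form that cannot overflow at either
  extreme of σ^V.
- KS p-values use scipy's exact/asymptotic auto rule; with pooled
  repeated stationary samples (CLE-vs-SSA check) only the distance D
  is interpreted, not the p-value.
- The CLE is an approximation by construction in the low-copy regime
  (free RsiV ~0.1 in the activated state); with the default step rule
  its stationary mean and s.d. match the SSA within ~1%, but exact
  distributional agreement should not be expected.
- Mean activation times at low stress depend mildly on the simulated
  window through censoring (cells slower than the window are censored
  out); the 5,000-min window keeps this negligible at L ≥ 0.5.
- The steady-state finder returns the branch reached from the empty
  state and flags, but does not exhaustively map, multistability.
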