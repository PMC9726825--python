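# Methods

This note records the models, estimators, and design choices behind
`coldlife`, the assumptions they rest on, and what the synthetic-data
experiments do and do not demonstrate.

## The speed-limit model

A cell's doubling time is τ = t + Δt. The floor t = c_t·r(T)^−α is set by
the global protein-synthesis rate r(T); the delay Δt = (c_Δ/r)·exp(ROS/s_ROS)
is the extra time needed to clear reactive oxygen species, which requires
synthesizing ROS-reducing enzymes and therefore also scales with 1/r. ROS is
a per-cell scalar (fluorescence, arbitrary units), log-normally distributed
across a population; no ROS biochemistry is modelled. A cell divides iff its
ROS is below a threshold; otherwise it remains in G1, grows, and bursts.

**Functional forms.** r(T) is a plain two-parameter Arrhenius function in
Kelvin, r(T) = r_ref·exp(−(E_a/R)(1/T − 1/T_ref)). The delay exponent uses
an explicit fluorescence scale s_ROS because "exp(ROS)" is dimensionless
only after scaling; s_ROS defaults to 1000 arb. units. Only the product
c_Δ·exp(threshold/s_ROS) is identified by the calibration anchors, so the
choice of s_ROS moves c_Δ but nothing observable. α is fixed at 0.77 (a
measured constant, not re-fit).

**Calibration** (`core_model.calibrate`) is an exact closed-form solve from
four anchors: minimum doubling times at two temperatures (defaults 3 d at
5 °C with ample antioxidant, 28.4 d at 1 °C — the replicative-phase
duration, since G1 can be arbitrarily short), one longest allowed doubling
time (35 d at 5 °C, the slowest observed population: a ROS-reduction-
deficient knockout), and the ROS threshold (6000 arb. units). Solve order:
the power law converts the two floors into a rate ratio, fixing E_a; r_ref
is set to 1 at the τ_max anchor temperature, fixing c_t; the delay part of
the τ_max anchor fixes c_Δ. The system is exactly identified; the round
trip params → anchors → params is exact to 1e−9. With these anchors
τ_max(1 °C) evaluates to ≈ 1.7 years — the multi-year scale at which
replicative life near freezing becomes possible but improbable.

**Simulation** (`simulate_cohort`) samples cells directly (ROS draw →
fate → τ), not time-stepped: the marginal distributions are identical and
the construction makes the hard invariant τ ∈ [τ_min, τ_max] checkable on
every run. One seeded generator per cohort; the seed is recorded in the
run manifest. `prob_slower_than` inverts the delay for the ROS level at
which τ = τ₀ and integrates the log-normal density, giving a closed form
the simulation is tested against.

## Single-cell reconstructions

Inputs are pre-segmented tables (no image processing): per-frame size and
annotations for *tracks*, Whi5 nuclear/cytoplasmic ratio and normalized DNA
copy number for *traces*, both at the movie cadence (2 frames/day by
default).

**Fates** are mutually exclusive per observation window with precedence
dies > duplicates > begins_life > grows, so per-bin event probabilities
partition to 1. **Doubling times** are bud-to-bud intervals; divisions
unfinished at movie end enter as censored values at their elapsed time (the
movie-based definition), with a Kaplan–Meier restricted mean available as
an alternative. **Event-probability curves** use log-spaced ROS bins (the
fluorescence spans decades) or linear size bins, at least 10 cells per
reported bin, and a seeded 1000-resample bootstrap over cells for standard
errors — a stand-in for the replicate-population s.e.m. of a real
experiment, which synthetic data cannot reproduce.

**Phase extraction.** G1 exit is marked by Whi5 leaving the nucleus. The
smoothed (3-point median) ratio is classified into low/high plateaus by
iterated two-means clustering — unlike percentile plateaus, cluster means do
not depend on how long the trace dwells on either plateau, which matters
for month-long traces with short G1. A cell whose plateau separation is
below 30 % of the high level never exited G1 and is reported as censored
("stuck in G1"). S phase is the DNA-copy ramp from 1 to 2. Plateau levels
are anchored on cell-cycle structure (pre-S = median DNA during G1, post-S
= median after mitosis onset) and the ramp is located by a least-squares
piecewise-linear change-point fit (flat, rise, flat), with the ramp start
constrained to the one-frame interval containing the Whi5 crossing — the
two channels mark the same G1-to-S transition, and the constraint removes
the degeneracy an unconstrained change-point fit has when S spans only one
or two frames. The fitted ramp start is used as the G1 boundary because it
carries sub-frame information (the Whi5 drop is a step between frames).
G2 runs from S end to the bud/mitosis-onset annotation, M+cytokinesis from
there to separation; boundaries are clamped monotone so durations are
non-negative and the S-G2-M sum telescopes to (separation − S start).

At the 12 h cadence each recovered *boundary* is accurate to one frame on
noiseless traces; with a single interior ramp sample the (start, width)
pair is under-determined along a one-frame family, so individual S
*durations* can err by up to two frames while phase means remain unbiased
(verified against generator truth across seeds).

**Life curves** align tracks at birth and average size per age bin while
enough cells remain observed, then chain forward using the mean growth
increment observed at each size (pooled over all tracks); the lifespan is
the age at which the mean curve reaches the mean burst size. This
size-aligned chaining is a documented stand-in for the original
construction, whose exact averaging is not published. **Replicative
lifespan** partitions the lifetime into mean-cycle-time windows and sums
the division probability at the mean size in each window.

## Population dynamics

**Doubling times** come from a log-linear fit inside the window between
2× the initial density and half the carrying capacity K. Because a
saturating culture's per-capita rate at density L is depressed by
(1 − L/K), the slope is re-estimated (when K is known) by regressing the
local log-slope on density and extrapolating to L → 0 — exact for both
pure-exponential and logistic curves, and unbiased to ≈ 5 % on the
synthetic logistic panels. **Growth classification** calls a culture
growing iff its final density reaches max(8× initial, K/2); the original
criterion ("grows to carrying capacity") needs an operational cutoff for
truncated series, and both thresholds are configurable.

**Birth–death model.** Each live cell divides at rate g and dies at rate d
(per day, constant). The exact simulator is event-driven (Gillespie) with
an event budget, switching to tau-leaping for large populations; the mean
mode uses the closed forms L(t) = L₀e^{(g−d)t} and
D(t) = dL₀(e^{(g−d)t} − 1)/(g − d) (limit dL₀t at g = d). Fitting uses the
deterministic means — live counts in log space, dead counts linearly,
jointly — because the original likelihood is not published; a bootstrap
over time points supplies confidence intervals. Constant rates are a
documented stand-in for possibly time-varying ones.

**Oxidation rates** are OLS slopes of plate-reader fluorescence after a
10-minute settling window, over about an hour; fold-changes are relative
to an untreated-medium control and undefined (None) if the control slope
is not positive.

## Expression kinetics

Labeled mRNA per cell follows M(t) = (k_syn/k_deg)(1 − e^{−k_deg t}).
Fitting is least squares on the log1p scale (multiplicative noise across
700–58,000 copies/h) with positive log-parameterization; replicates are
pooled as repeated time points. Courses with no detectable curvature
(k_deg·t_max < 0.1) return the initial-slope synthesis rate with k_deg
flagged non-identifiable. The model ignores dilution by division — safe at
frigid temperatures where doubling times vastly exceed the labeling
window, biased for k_deg at 30 °C (where a denser early time grid should
be used, as in `examples/expression_kinetics.py`). Every fit satisfies
half_life·k_deg = ln 2 identically.

TPM values convert to copies per cell by the median over smFISH anchor
genes of (FISH copies / TPM); the median resists a discordant anchor and
the uniform factor conserves relative abundances. An optional per-sample
scale column (spike-in normalization) can be applied before fitting.

Induction traces fit f(t) = A(1 − e^{−k(t−t₀)}) with an explicit onset
delay t₀ absorbing transcription/translation/maturation lags (the original
equation is not published); the protein-synthesis rate is the initial
slope A·k. Arrhenius fits regress ln rate on 1/T; E_a = −slope·R.
Characteristic times are quantum/rate (10,000 mRNAs or 100 reporter
units), reported as fractions of the doubling time; across the frigid
range the mRNA fraction falls while the protein fraction rises as
temperature drops.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (scenario config, seed): same inputs,
byte-identical tables, with a manifest recording all ground truth. Defaults:
2 frames/day cadence; 5 % multiplicative Gaussian noise on fluorescence
channels; Poisson noise on copy counts; gamma jitter (CV 0.2) on phase
durations and division intervals; annotations at the nearest frame.
Scenario anchors: low-GSH 5 °C (median ROS 2000, G1 32 h), high-GSH 5 °C
(10-fold lower ROS, G1 14.7 h), phases S/G2/M = 25/6/22 h at 5 °C, S-G2-M
= 28.4 d at 1 °C (same proportions), 5 °C kinetics 2000 mRNA/h with 7 h
half-life (700/h, 14 h at 1 °C; 58,000/h, 20 min at 30 °C), growth
threshold 3000 cells/ml at 5 °C, carrying capacity 1e5 cells/ml (the scale
growth curves saturate at), knockout doubling 35 d. Cell-to-cell variance
parameters are configurable defaults; the measured values are not
published.

The generators reproduce the *statistical structure* the estimators assume
(log-normal ROS, threshold fates, step Whi5, linear DNA ramp, linear size
growth, constant-rate birth–death, saturating-exponential kinetics).
Passing round-trip tests therefore shows the pipeline recovers truth under
those assumptions at realistic noise and cadence; it does not validate the
assumptions themselves against real microscopy or sequencing data, nor
cover segmentation errors, photobleaching, focus drift, or pedigree
mistakes that real movies contain.

## Numerical choices and problem sizes

Internally hours and Kelvin everywhere; the CLI converts °C and days.
Phase-pipeline experiments use n = 100 cells per scenario; labeling
round-trips use 8 points over 48 h × 3 replicates × 100 seeds; birth–death
checks use 200 exact replicates against the closed form and 20 replicates
for rate recovery — sizes at which the estimator standard errors are a few
percent of the anchored values and the full suite runs in well under a
minute. Degenerate inputs (flat density series, constant DNA, monotone-
decreasing induction, all-zero counts) return flagged results or typed
errors (`InvalidInputError`, `InsufficientDataError`, `CalibrationError`,
`SchemaError`) rather than numbers.

## Known limitations

- The speed-limit calibration rests on printed anchors only; the original
  supplementary parameterization (including behaviour of the
  "Arrhenius-type" rate as T → freezing) is not reproduced, and the
  Arrhenius extrapolation far above ~12 °C is outside the validated range.
- Event classification assumes one primary fate per cell per window; cells
  that both begin life and duplicate are counted as duplicating.
- Below-threshold cells always divide in the simulator; per-time-step
  stochastic death of below-threshold cells is not modelled.
- The birth–death fit treats rates as constant over weeks.
- At 2 frames/day, single-cell S durations carry up-to-two-frame
  uncertainty when S spans fewer than three frames (means are unbiased).
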