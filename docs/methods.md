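# Methods

This note records the modelling choices behind `lonnrec`, what the synthetic
fixtures do and do not emulate, and the numerical decisions a maintainer
should know about.

## Squashing activation and nilpotent gates

The logic layers use the squashing function
`S_β(x) = (1/β)·ln((1+e^{βx})/(1+e^{β(x−1)}))`. We evaluate it as a softplus
difference, `(softplus(βx) − softplus(β(x−1)))/β`, which is identical in
exact arithmetic but immune to overflow for large |βx|; the result is clipped
to [0, 1] to absorb one-ulp rounding excursions (the exact range is the open
interval). Its derivative is the closed form
`σ(βx) − σ(β(x−1))` with `σ` the logistic function; no finite differences are
used anywhere in training.

Gates follow the nilpotent (Łukasiewicz) family: conjunction
`cut(Σx − (k−1))`, disjunction `cut(Σx)`, negation `1 − x`, each realised as
one fixed-weight unit with a squashing activation. For two inputs these are
the classical (w, b) pairs AND ((1,1), −1), OR ((1,1), 0), NOT ((−1), 1),
NOR ((−1,−1), 1); for other fan-ins we generalise within the same family,
which reproduces the crisp truth tables exhaustively for fan-in 1–3 at
β = 50. The printed unary-gate convention with a zero weight would yield a
constant unit, so negation is uniformly the `1 − x` form. β is a per-layer
constant (`beta_int`, default 1.5), never trained.

## Reference architecture and the frozen block

The reference LONN is pinned to the only wiring consistent with the target
parameter counts (116 trainable / 59 frozen; dense control 293):
10→10 ELU (trainable, 110) → 10→4 M-nodes (frozen, 44) → 4→3 AND gates
(frozen, 15) → 3→2 OR stage (fixed, uncounted) → 2→2 sigmoid head
(trainable, 6).

Design choices where the design was genuinely open:

* **M-node weights.** The M-nodes are frozen "hypothesis" aggregations of the
  first layer's outputs. We draw each node's weights once from a seeded
  Uniform(0, 1) and normalise them to sum to one (bias 0): a fixed convex
  mixture, fully reproducible from the model seed.
* **AND wiring.** Giving every AND gate the full M-layer fan-in would make
  all gates identical (all-ones weights), collapsing the layer to one
  effective unit. Each AND gate therefore conjoins one consecutive pair of
  M-nodes (zero weights elsewhere, bias −1). The weight matrices are stored
  dense, so the parameter counts are unchanged.
* **OR stage.** Parameter-free by construction: two fixed unit-weight
  disjunction groups over overlapping contiguous windows of the AND outputs
  ({A1, A2} and {A2, A3} at the default widths). Its structural weights are
  excluded from parameter counts.
* **Initialisation.** Trainable weights are Glorot-uniform from the model
  seed, biases zero; ELU uses α = 1.
* **Optimiser.** ADAM with β₁ = 0.9, β₂ = 0.999, ε = 1e−8; learning rate
  0.02, batch 50, 100 epochs by default. The loss is the MSE averaged over
  samples and both outputs. The last incomplete mini-batch is used (240
  training rows at batch 50 would otherwise lose data). Data order is
  reshuffled every epoch from a dedicated shuffle seed.

Gradients are computed analytically end to end (verified against central
finite differences to 1e−4 in the suite) and propagate *through* the frozen
layers; only trainable layers receive updates, so the frozen block is
bit-identical before and after any training run — this is asserted, not
assumed.

A practical observation about the dense ReLU control (widths 10, 10, 4, 3, 2
plus sigmoid head): at learning rate 0.02 the narrow width-3 layer dies (all
pre-activations driven negative for all inputs, zero gradient) in roughly
half of seed replicates, leaving a constant predictor whose error sits at the
mean-prediction level. When the control escapes this collapse it trains to a
substantially lower error than the LONN, as expected from its 2.5× parameter
count; comparisons between the two families should therefore be read per
seed, not as single runs.

## Cohort schema, normalization, splits

Binary covariates pass through as {0, 1}; continuous covariates and the
therapy time are normalised affinely, `(x − min)/(max − min)`, with the
ranges fitted on the training split only and reused (with clamping) for test
and serving data — fitting before the split would leak test information into
the transform; a caller can still fit on the full table by passing a
pre-fitted spec. A constant column maps to 0 with a logged warning. The
80/20 split shuffles uniformly from a seed with training size ⌈0.8 n⌉.

The positive-outcome filter keeps survivors with therapy time ≥ 60 days; the
floor is configurable (the observation window is six months, 183 days, and
short times are ambiguous between late entry and a negative outcome).

## Fixture generator

The generator emulates the *structure* of a heart-failure cohort, not any
real dataset: Bernoulli binaries (sex 0.65, hypertension 0.35, smoking 0.32,
anemia 0.43), truncated-normal age (60 ± 12, [40, 95]), log-normal CPK and
serum creatinine, truncated-normal platelets (2.6e5 ± 9.5e4), and a
two-component ejection-fraction mixture (reduced N(30, 5) w.p. 0.6 vs
preserved N(55, 5), clipped to [0, 80]). Serum sodium declines mildly with
age (slope −0.1 mEq/L per year, noise SD 3.82 so the marginal SD stays near
4) — this is the one planted continuous–continuous dependence, giving the
synthesizer's regression a known coefficient to recover. The treatment key
is Bernoulli(0.9) below the 40% ejection-fraction threshold (systolic heart
failure) and Bernoulli(0.6) above; death follows a logistic model in EF,
serum creatinine and age (intercept −1.2, slopes −0.07, 0.8, 0.035 about
clinically centred values, giving ≈ 30% deaths); therapy time is
Uniform(4, 120) days for deaths and Uniform(60, 183) for survivors.

What passing tests on this fixture show: that the pipeline recovers planted
mechanisms (the EF→treatment rule, the sodium–age slope), that the
synthesizer preserves marginals, and that training behaves as specified.
What they do not show: calibration on real heart-failure data — the fixture
has no missingness, no measurement error, independent labs (beyond the
planted link), and a cleanly separable treatment mechanism.

## Sequential synthesis and the distance metric

The synthesizer visits variables in table order (V1…V10, time, treatment
key, death; configurable). The first variable uses its empirical marginal;
later binaries use unpenalised logistic regression on their predecessors
(sampling from the fitted probability — no posterior uncertainty, as no
Bayesian machinery is specified); later continuous variables use OLS with
the residual SD, and each normal predictive draw is replaced by the
empirical quantile of matching rank ("norm-rank"), interpolated when the
synthetic sample is larger than the fitting sample. Consequences: synthetic
continuous values never leave the observed range, marginal shapes are
preserved by construction, and dependence enters through the regression
means. Degenerate fits (constant columns, separation, singular designs) fall
back to the marginal, logged.

The QA metric bins each variable (natural bins {0, 1} for binaries, 10
equal-width bins over the pooled range for continuous variables) and reports
the mean absolute difference of relative frequencies × 100. At the default
fixture scale (n = 299, m = 2990) the overall mean lands around 0.3–0.5%,
and it decreases with m as sampling noise shrinks.

## Recommender

"Matching" between the two models is defined on the binarised treatment key
only (threshold 0.5 under the sigmoid head); predicted times are logged for
both models but do not affect confidence, since no time-matching tolerance
is defined for the procedure. An optional time-agreement tolerance could be
added at the call site; it is deliberately off by default. The full-data
model supplies the high-confidence prediction; the positive-outcome model
supplies the low-confidence one with the alternative attached. The
recommendation log is an append-only CSV with a timestamp, the prediction,
the confidence, the alternative and the (optional) acceptance flag.

## Evaluation conventions

* *Training error* = mean absolute error on the normalised outputs × 100
  (MSE remains the optimisation loss).
* *Therapy accuracy / precision / recall* = confusion-matrix metrics on the
  positive treatment-key class at threshold 0.5; precision is reported as
  absent (not 0) when there are no positive predictions.
* *Time RMS* = root-mean-square error on the normalised time × 100.
* *β sweep*: a fresh default LONN per (β, seed), 50 epochs, mean final
  training error per β. On the fixture the spread across β ∈ [0.5, 5] is
  about 2 percentage points — the slope parameter barely moves the final
  training error.
* *Input importance* = column sums of absolute first-layer weights,
  normalised to sum to one, ranked with a stable tie-break by column order.
  Only the first layer is read because every deeper layer is frozen.

## Problem sizes

The test suite and the acceptance script run at fixture scales chosen for
desk reproducibility: cohorts of 299–2,000 patients, synthesis up to ten
times the fitting sample, and 3–10 seed replicates per statistical check.
These sizes keep every check well-powered for the planted effect sizes while
completing in seconds to a couple of minutes on one CPU.

## Known limitations

* The fixture's generative laws are plausible stand-ins, not estimates from
  any real registry; absolute metric values on the fixture do not transfer.
* The binary treatment key collapses drug identity into one class contrast.
* The dense control's dead-ReLU collapse (above) makes single-run
  comparisons against it unstable at the default learning rate.
* The synthesizer provides empirical anonymisation properties only (fresh
  random IDs, rank-mapped values); it carries no formal privacy guarantee.
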