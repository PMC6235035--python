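# Methods

## Observer model

The model treats one-back serial dependence as statistically optimal cue
integration. On trial *t* the observer holds noisy internal estimates of
the current and previous orientation, `x_curr ~ N(s_t, σ_curr)` and
`x_prev ~ N(s_{t−1}, σ_prev)`, and reports the weighted combination
`(1 − w) x_curr + w x_prev`. The total expected squared error

```
E(w) = (1 − w)² σ_curr² + w² σ_prev² + (w d)²
```

is quadratic in `w`; its minimiser is
`w* = σ_curr² / (σ_curr² + σ_prev² + d²)`. Only the immediately preceding
trial is integrated — no Kalman-style accumulation over deeper history, and
no fitting of priors. All orientation arithmetic is on the 180°-periodic
circle of undirected orientations: differences are wrapped to (−90°, +90°]
(exactly ±90° maps to +90°, a half-open tie-break), and integration is
applied to the wrapped difference, never to raw angles. The observer's
weight is computed from the *true* stimulus distance `d`; an internal-noisy-
distance variant exists behind `ObserverParams.use_internal_distance`
(default off) because the two readings cannot be distinguished from the
closed form alone, and the true-distance version is the one the predictions
below assume.

`optimal_weight_numeric` is an independent oracle — a 201-point grid scan
plus bounded scalar minimisation of `E(w)` — kept separate from the closed
form so that tests can verify the algebra (the two agree to < 1e−6
everywhere in (0.5, 30]² × [−90, 90]). Since the variance and bias closed
forms are the load-bearing assumptions, they are additionally pinned by the
special cases `w*(10, 10, 10) = 1/3`, `w*(10, 10, 40) = 1/18`,
`w*(σ, σ, 0) = 0.5` and `w*(σ, σ, σ) = 1/3`.

Predicted response scatter adds a motor (response-stage) noise `σ_m` in
quadrature: `scatter(d) = sqrt((1 − w*)²σ² + w*²σ² + σ_m²)`, and
`RMSE² = bias² + scatter²` (checked to 1e−9 on every prediction curve).
The predicted bias `w*(d)·d` peaks at `d = σ√2` for equal reliabilities.

## Synthetic experiments

The generator emulates two designs with i.i.d. uniform draws from the
condition's orientation set (the inter-trial transition statistics of the
original adjustment paradigms are not public; i.i.d. uniform is the
simplest scheme consistent with the analysis):

* **exp1** — 6 observers × 4 conditions × 280 reproduction trials;
  cardinal orientations {−20°…+20° in 10° steps} or oblique
  {25°…65° in 10° steps}, crossed with low/high spatial frequency. Spatial
  frequency enters only through the condition's sensory noise — no Gabor
  rendering, masking, contrast or eye-movement modelling. A companion
  sequential 2-AFC task (80 trials per observer per condition, probe
  offsets 0, ±6°, ±12°, ±18°) measures reliability.
* **exp2** — orientations all around the clock in 15° steps, 6 observers ×
  2000 trials (≈12 000 total), single spatial frequency.

Default noise values: exp1 conditions use σ = 4.5° (cardinal/high SF),
5.6° (cardinal/low), 6.7° (oblique/high) and 8.2° (oblique/low) — the two
low-SF values and their ≈6.7° average anchor the scale, and the high-SF
values preserve the cardinal-better-than-oblique and high-SF-better-than-low
threshold orderings. exp2 uses σ = 6.7°. Motor noise defaults to
σ_m = 6.2°. The weight policy is `optimal` (w*(d) at the true distance,
optionally multiplied by a global `scale_k`, default 1) or `fixed`.
Each observer × condition is one session; the session's first trial has no
predecessor and is generated with w = 0.

Noise is Gaussian on the circle, wrapped only at readout; for σ ≤ ~10° the
wrapping correction is negligible at these designs. Response times follow
an explicitly invented model, `(rt_base + rt_slope·|d|) · LogNormal(0,
rt_noise_sd)` with defaults 1.2 s, 0.005 s/°, 0.2: no generative RT model
accompanies the behavioural finding being emulated, so the generator only
guarantees the qualitative signature (median RT minimal at d = 0) needed to
exercise the RT aggregation stage. Passing tests on these synthetics show
that the *pipeline* is correct and that parameters are recoverable when the
model is true; they say nothing about lapses, drift, oblique-dependent
response biases or temporally correlated noise in real observers.

## Analysis pipeline

Exclusions keep trials with response time ≤ 3.5 s and wrapped reproduction
error ≤ 30° (boundaries inclusive; a trial violating both counts under the
RT rule). Signed error is response − stimulus, wrapped; the difference
abscissa is previous − current *stimulus* orientation (positive = previous
more clockwise). An alternative abscissa using the previous-stimulus-vs-
current-response difference is available (`use_response_abscissa`, default
off) but not the documented path.

The weight of the past is the OLS slope (with intercept, which absorbs any
clockwise/counter-clockwise response asymmetry) of error against `d`
restricted to |d| ≤ 10°, fitted by default on the per-difference mean
errors — in the exp1 designs the three points −10°/0°/+10°, giving each
difference level equal weight; a raw-trials mode exists. Per-observer fits
are computed first and averaged afterwards where condition-level numbers
are needed. Because the measured slope across {−10, 0, +10} of the odd
function `w(d)·d` equals `w(10)`, JND-based predictions use an effective
distance `d_eff = 10°`.

Difference profiles group paired trials by exact difference level (the
designs are discrete grids, so no binning heuristics are needed). Within a
bin: mean bias, scatter (s.d. of errors about the bin mean, population
convention ddof = 0 so that `rmse² = bias² + scatter²` holds exactly), RMSE
about the true stimulus, median RT and count. Absolute mode folds ±d
together after multiplying errors by sign(d), so attraction toward the
previous stimulus stays positive.

## Psychometrics

2-AFC data are fitted with `P(clockwise | Δ) = Φ((Δ − pse)/σ)` by maximum
likelihood under the binomial model; no lapse rate is estimated (a known
limitation: a single extreme-probability cell can steepen or flatten the
fit noticeably at n = 480). The optimiser is Nelder-Mead restarted from a
fixed 5 × 6 grid of (pse, log σ) values, ties broken by likelihood then by
smaller σ, so fits are deterministic given the data. One fitted s.d. is the
JND; dividing by √2 converts the two-presentation discrimination noise to
single-presentation reliability. All-identical responses or fewer than two
distinct offsets raise a degenerate-fit error.

## Model evaluation

`predict_weight_from_jnd` maps a measured reliability to the zero-parameter
predicted weight `σ²/(2σ² + d_eff²)`. Agreement is summarised by ordinary
R² (about the observed mean, possibly negative), by the closed-form
least-squares scaling `k = Σ(w_obs·w_pred)/Σ(w_pred²)`, and by a
one-parameter bounded least-squares fit of `σ_m` to an observed scatter
profile (returning 0 with a warning when the predicted perceptual scatter
already exceeds the observations everywhere).

`zero_parameter_experiment` wires the whole loop together: simulate exp1
with an optimal-policy observer, estimate weights per observer × condition,
fit JNDs per condition with observers pooled, predict weights from the
fitted JNDs alone, and compare on the per-condition means. Its validation
design widens the condition noise levels to σ ∈ {4.0, 5.6, 8.2, 11.0} and
turns motor noise off: at the study size of 280 trials per condition the
per-observer slope estimate carries an s.e. of roughly 0.05–0.08 weight
units, so a wide reliability range and condition-level averaging are needed
for the between-condition signal to dominate estimation noise even when the
model is exactly true; motor noise would only dilute the slopes further
without changing their expectation. With those choices the zero-parameter
prediction explains > 80% of the between-condition variance, and the
generator's `scale_k` and `σ_m` are recovered to ±0.05 and ±0.3°
respectively. The empirical bias peak near 15° reported for human
observers is a data feature the equal-reliability model does not exactly
reproduce (its peak sits at σ√2 ≈ 9.5° for σ = 6.7°); empirical R² values
and scatter-dip magnitudes from human data depend on those raw data and are
out of scope here.

## Numerical choices and limitations

* Half-open wrap: differences of exactly ±90° map to +90°.
* Bounded scalar minimisations use `xatol ≤ 1e−9`; the numeric weight
  oracle brackets the 201-point grid minimum before refining.
* Profiles use population (ddof = 0) standard deviations.
* Simulation sizes in tests follow the emulated designs (280 trials ×
  4 conditions × 6 observers; ≈12 000 exp2 trials); recovery tests that
  the designs leave unspecified use 5000 fixed-weight trials, 50 × 480
  2-AFC replicates, and 2000 trials/condition for scaling-factor recovery —
  sizes at which estimator noise is several times smaller than the
  tolerance being asserted.
* The generator shares the package's own integration code path; the tests
  that matter for correctness therefore pin the *analysis* side to
  closed-form or hand-constructed oracles (exact lines, exact curves,
  enumerated wraps) rather than to the generator.
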