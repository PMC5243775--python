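# Methods

## The model

`gobypass` predicts the binary outcome "ascends / does not ascend" for
individual benthic fish facing an in-stream barrier, as the conjunction
of three a-priori criteria, followed by a statistical layer that relates
the outcome to the measured predictors.

**Swim criterion.** Critical swimming speed (Ucrit) is the maximum flow
a fish can sustainably swim against; across juvenile-to-adult sizes of
small benthic fish it scales approximately linearly with total length
(TL).  The default line is `Ucrit = 0.05·TL` m/s (TL in cm), i.e. about
five body lengths per second, calibrated so a 12.2 cm fish has
Ucrit = 0.61 m/s — the single anchor available for the motivating
round-goby case.  Both coefficients are configuration
(`SwimModel.speed_slope/speed_intercept`), never hidden constants,
because the underlying cross-species regression is not published
numerically.  The decision passes when Ucrit strictly exceeds the
barrier's maximum near-bottom flow velocity.  Bottom flow is the
relevant threshold for a swim-bladderless, bottom-dwelling fish; it is
also conservative, since substrate roughness in real riffle-pool
bypasses lowers the velocities fish actually experience.

**Endurance criterion.** Endurance at flow `v` is log10-linear in flow
and length: `log10 E[min] = −0.027·v[cm/s] + 0.007·TL[cm] + 0.516`
(defaults from laboratory endurance trials on 9.1–15.4 cm round goby).
The traversable distance is `Ucrit · E` with Ucrit treated as ground
speed (no flow subtraction); the decision passes when it strictly
exceeds the largest spacing between two resting pools — the worst gap,
not the mean.  A `ground_speed="ucrit_minus_flow"` switch exists for
sensitivity analysis, and `write_sensitivity_table` tabulates distance
against the choice of flow velocity.  The flow entering the endurance
formula defaults to the same maximum near-bottom velocity used by the
swim criterion (in cm/s), configurable per call.

*Known discrepancy:* the hand-worked reference calculation for the
12.2 cm example individual reports a traversable distance of 13 m.
Direct evaluation of the endurance formula gives
E = 10^(−1.35 + 0.0854 + 0.516) ≈ 0.178 min and hence
0.61 m/s · 0.178 min ≈ 6.5 m, and no documented choice of `v` between
40 and 52 cm/s reaches 13 m.  The package reports its own computed
distance; the decision outcome is unaffected (6.5 m > 4.54 m either
way).

**Personality criterion.** Three assay-derived indices:

- *boldness* = `log(t_max) − log(latency to first movement)` after a
  simulated predator attack, `t_max` = 3600 s; base-10 logs by default
  (`log_base="natural"` available; the printed index scale is
  consistent with either, so the base is recorded in output metadata);
- *asociability* = mean distance (cm) to a conspecific stimulus pair
  over a 1 h recording sampled at one frame per 6 s, starting at the
  first frame with movement; distances are measured to a single stimulus
  point (the compartment-wall midpoint) and converted from pixels with
  an explicit `px_per_cm` calibration, never inferred; a normalized
  (arena-width-relative) form is emitted alongside;
- *activity* = count of inter-frame displacements strictly longer than
  1 cm, also available as percent of displacement intervals for
  cross-protocol comparability.

Fish without any movement in the first 30 min are excluded (asociability
cannot be observed long enough); a displacement counts as inside the
window only if the later frame of its pair falls at or before 1800 s.
Thresholds are the arithmetic trait means of an invasion-front reference
cohort — front individuals are the "good dispersers" — and the decision
passes when at least `min_traits_above` (default 2) of the 3 traits
strictly exceed their means.  The rule is a blind count, not a weighted
score: no trait dominates.  All comparisons in the matrix are strict;
ties fail.

Swim and endurance limits are evaluated against the global profile
maxima (the conservative reading), not per station.

## Statistical layer

Implemented in the package, with scipy/statsmodels used only as test
oracles:

- **Binary logit by IRLS** (max 100 iterations, stop when the deviance
  changes by < 1e-8).  Because the matrix outcome is a deterministic
  function of the predictors, quasi-complete separation is the expected
  regime, so the fitter uses deviance-monitored step-halving (a raw IRLS
  step diverges under separation), caps coefficient magnitudes at 25 on
  the logit scale (|η| = 25 puts probabilities within ~1e-11 of 0/1,
  beyond any data resolution), flags `separation_warning`, and reports
  deviance/AIC at the capped solution.  A one-class outcome yields a
  flagged degenerate fit rather than an exception.  The
  likelihood-ratio χ² compares against the intercept-only model;
  classification accuracy uses a fixed 0.5 probability cut.
- **AIC convention:** `AIC = deviance + 2(k+1)`, counting the intercept.
  `deviance = −2·logLik` throughout.
- **Hosmer–Lemeshow**: deciles of risk (sort by fitted probability,
  near-equal groups), `χ² = Σ (O−E)²/(E(1−E/n_g))`, df = groups − 2.
  Groups with numerically zero expected variance (a separated fit
  predicting exactly 0/1) are merged into a neighbour and counted; a
  fully degenerate group contributes nothing when observed equals
  expected.  The grouping follows the standard deciles-of-risk
  definition; proprietary software may tie-break differently.
- **Spearman correlations** as Pearson on average-rank transforms (ties
  get average ranks); pairs involving a constant column are reported as
  undefined, never silently NaN-propagated.
- **All-subset model table**: one logit fit per nonempty predictor
  subset (capped at 12 predictors), rows sorted by subset size
  descending then AIC ascending, with per-row degeneracy flags.
- **Moment check**: sample skewness `g1 = m3/m2^1.5` and excess
  kurtosis `g2 = m4/m2² − 3`; |g1| > 1 flags that the arithmetic mean
  (and hence a mean-based threshold) may not represent the
  distribution's centre.

## Synthetic data

The generator reproduces the study conditions, not any particular
dataset:

- **Lengths**: truncated normal on [7.3, 15.3] cm with mean 9.9 cm and
  sd 1.5 cm (only the range and mean are published; the sd is chosen so
  the bounds sit at roughly ±2σ).
- **Traits**: trivariate normal on the index scale — the indices are
  already log-type transforms and their skew/kurtosis screens support
  approximate symmetry — with marginal sds (0.30, 0.30, 0.25) chosen so
  the published index ranges (boldness up to ~1.76, asociability down
  to ~0.47) are ~2σ excursions, and correlations set to the published
  rank intracorrelations (bold–act 0.366, bold–asoc −0.093, act–asoc
  0.261).  Negative draws are rejected and redrawn (indices are
  nonnegative by construction); with the default means this affects a
  negligible fraction.  Front means sit at the published thresholds
  (1.13, 1.17, 0.95); center means default to one sd lower per trait —
  an assumption, since no numeric center means are published.
- **Recordings**: a lazy random walk at one frame per 6 s inside a
  pixel-calibrated 80 × 26.5 cm arena — per frame the fish moves with
  probability `movement_rate` by an exponential step in a uniform
  direction, reflected at the walls; latency comes from a configurable
  truncated distribution.
- **Flow profiles**: stations at regular spacing with
  near_shore ≤ near_bottom ≤ center enforced per station.
- A single pipeline seed fans out into per-generator substreams via
  `SeedSequence` spawning, so adding a generator does not perturb the
  others.

What passing tests on this data do **not** show: real assay recordings
have autocorrelated, wall-following trajectories, tracking noise and
occlusions; real trait distributions may be skewed or multimodal; real
barrier hydraulics vary with discharge.  The generator makes the
pipeline's arithmetic and statistics testable, not its ecological
calibration.

The shipped reference barrier fixture encodes the published summary
values of the motivating site (11 stations over 65 m at 3.75 % slope,
maximum near-bottom flow 0.50 m/s, centre up to 1.4 m/s, near-shore up
to 0.16 m/s, 33 pool gaps with 4.54 m maximum); the station-level
numbers between those summaries are representative interpolations, as
the full measurement tables were never published.  The 0.50 m/s maximum
is the value used in the reference worked example; a 0.52 m/s bottom
maximum is quoted elsewhere in the source material — the package always
uses the profile's computed maximum, so the fixture pins 0.50.

## Numerical choices and degenerate inputs

- Strict inequalities at every threshold; a trait exactly at its mean,
  or Ucrit exactly at the flow limit, fails.
- Missing (NaN) traits exclude an individual with a recorded reason;
  individuals are never silently dropped, and cohort summaries report
  `n = scored + excluded`.
- Probabilities are clipped to [1e-12, 1−1e-12] inside likelihoods;
  linear predictors to ±700 before exponentiation.
- The monotonicity guarantee (growing a fish at fixed traits can never
  flip success to failure) holds for positive swim-model slopes and the
  default endurance coefficients, and is property-tested over 10⁴
  random individuals.
- Statistical outputs are skipped (with a logged reason) for cohorts of
  fewer than 10 scored individuals; the decision matrix itself runs for
  any cohort size ≥ 1.
- Problem sizes in the test suite — 10⁴-individual cohorts for
  distributional recovery and monotonicity, 200-replicate Monte-Carlo
  calibrations at n = 500–1000 for the likelihood-ratio and
  Hosmer–Lemeshow null checks — were chosen as the smallest sizes at
  which the sampling-theory bounds used in the assertions (3 standard
  errors; Kolmogorov distance 0.1) are comfortably valid.

## Limitations

- The length→Ucrit line and the endurance formula are borrowed
  empirical relationships with no uncertainty propagated; temperature
  effects on Ucrit are not modelled.
- The decision matrix is hard-threshold by design; probabilistic
  softening (logistic smoothing of the criteria) is out of scope.
- No penalized (Firth) regression, mixed models or cross-validation in
  the statistical layer.
- Cross-protocol activity normalization beyond the percent-of-
  observations form is not implemented (the original normalization
  details are unavailable).
- No hydraulic simulation: flow profiles are measured (or generated)
  tables, never computed from discharge.
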