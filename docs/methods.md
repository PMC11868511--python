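# Methods

## Model

The package models one-sided, dynein-driven vesicle motion as a discrete
random walk on a lattice of step size *a* (µm) with step time τ (s): at each
step the cargo advances with probability *p* or pauses with probability
1 − *p*.  Heterogeneity across the vesicle population — differing cargo
size, motor activity, local cytoskeletal environment — is absorbed into a
single random movement probability: each track draws its own *p* from
Beta(α, β) and keeps it for life.  α measures the propensity for successful
movement, β the degree of immobilization.

Marginalizing the conditional binomial over *p* gives the beta-binomial
displacement law; marginalizing the conditional negative binomial gives the
beta-negative-binomial (BNB) first-passage law with the same (α, β).  The
model's scientific content is exactly this sharing of parameters between the
two observables, which the acceptance suite tests end to end.

Assumptions worth keeping in mind: *p* is constant within a track (no
pausing-state memory, no spatial dependence), steps are one-sided (reversals
are clamped to zero during discretization), and localization error is
ignored by the likelihood.

## Parameters

| name | meaning | unit | default | why |
|---|---|---|---|---|
| α, β | beta-density shapes of *p* | – | per-strain presets (8.19, 12.95 / 3.18, 4.15 / 5.12, 12.87) | MLE fits to the three recorded strains |
| *a* (`step_size_um`) | lattice step | µm | 0.092 | camera pixel size; one step spans one pixel |
| τ (`step_time_s`) | step time | s | 0.01563 | 1/10 of the 0.1563 s frame interval, so t = 1.563 s is exactly n = 100 steps |
| `steps_per_frame` | model steps per camera frame | – | 10 | links τ to the frame interval |
| `retro_threshold_px_per_frame` | mean-speed cut for directed tracks | px/frame | 1.6 (wild-type), 1.0 (mutants) | separates the retrograde and stationary speed modes per strain |
| `lags_s` | displacement analysis lags | s | 1.563, 3.126 | 10 and 20 frames |
| `fpt_thresholds_um` | first-passage thresholds L | µm | 1.84, 3.68 | 20 and 40 pixels |

The classification rule reads "net displacement of at least threshold ×
frames spanned" (boundary inclusive) — a mean-speed cut, the only reading of
the filtering prescription with consistent units.  The sign that counts as
retrograde is configurable (`direction_sign`) because kymograph orientation
depends on how the line was traced.

## Pipeline conventions

* Frames are 0-based integers; times are frame × 0.1563 s; pixel positions
  stay real-valued until step conversion.
* Duplicate time points (two positions at one frame) are replaced by their
  arithmetic mean before anything else.
* Displacement-at-lag is measured once per track, from its first point —
  not with sliding windows, which would inflate and correlate samples.  The
  integer step count is round(|Δx|/a) clamped to [0, n]; negative
  excursions clamp to 0.
* First passage is the first *frame* at which cumulative retrograde
  displacement reaches the threshold; the comparison carries a sub-nanometre
  slack so that px→µm rounding cannot push an exact 20-pixel crossing one
  frame late.  Track ends before crossing are reported as censored and
  excluded from histograms.
* Because the one-sided walk is monotone, the frame-resolution first
  passage is exactly the step-resolution one rounded up to the next frame;
  the theoretical frame-bin probabilities aggregate the BNB pmf over the 10
  steps inside each frame.

## Fitting

The likelihood of a displacement sample is the product of beta-binomial
pmfs at the shared trial count n = t/τ.  Optimization runs in
(log α, log β) — positivity without constraints — with L-BFGS-B, the
analytic digamma gradient, and a method-of-moments start; the box
|log shape| ≤ 7 only guards against runaways.  Standard errors invert the
analytic polygamma observed-information matrix and are reported as
approximate.  A joint fit across lags sums the per-lag likelihoods under
one (α, β); it ignores the overlap between one track's displacements at
different lags, as does the single-lag default (t = 1.563 s).  Samples with
every count at a support boundary (all 0 or all n) are rejected as
non-identifiable.

Goodness of fit uses Pearson χ² with adjacent bins merged until every
expected count is ≥ 5 (dof reduced by 2 when the shapes were fitted to the
same sample), plus the total-variation distance between empirical and
fitted pmfs.

## Numerical choices

* All pmfs are evaluated as exponentials of log-gamma differences;
  factorials at n ≈ several hundred would overflow otherwise.
* The first-passage variance is implemented with the factors
  (k + α − 1)(α + β − 1).  A variant with (k + α + 1)(α + β + 1)
  circulates; direct pmf summation rejects it (≈18% high at the wild-type
  shapes, k = 20) and confirms the −1 form to 1e−6 relative.  The
  summation oracle accumulates moments in chunks until an analytic
  power-law tail bound (pmf tail ∝ n^−(α+1)) is negligible or a term cap
  (10⁶·k) is hit, then appends the integral of the matched power law from
  the last term — needed because for α near 2 the plain second-moment sum
  converges only like 1/N.
* Degenerate movement probabilities are reachable through the simulator's
  `fixed_p` mode, which bypasses the beta draw; it provides the homogeneous
  (plain binomial) baseline for limit tests.
* The simulator spawns one child RNG stream per track from the root seed,
  so ensembles are reproducible independent of execution order.

## Synthetic data

The generator emulates what the analysis needs from the recordings and no
more.  Retrograde tracks are heterogeneous walks; per-frame increments are
drawn as Binomial(10, p), the exact law of the elementary walk observed
every 10th step.  Stationary tracks jitter (σ = 0.3 px) about a fixed
position; anterograde tracks drift at a constant 3 px/frame — enough to
exercise the classifier, with no claim about kinesin statistics.  Track
lengths are uniform on 10–500 frames (acquisitions were 500 frames);
additive Gaussian localization noise (default σ = 0.5 px) is applied to
every written position.  Class fractions default to 0.5/0.35/0.15
(retrograde/stationary/anterograde); the recordings do not pin the latter
two, so these are placeholders.  Preset track counts put the *expected*
retrograde count at the order observed per strain (851/438/1118).

What passing tests on these data do **not** show about real recordings:
robustness to reversals, to within-track pause-state changes, to tracker
linking errors, or to non-Gaussian localization artefacts — none of which
the generator produces.

## Known limitations and honest discrepancies

* **Finite-window superdiffusion exponent.**  The variance law
  var(n) = A·n + B·n² has B/A = 1/(α+β).  At the wild-type shapes
  (α+β ≈ 21) the linear term still carries ~15% of the variance at
  t = 1.563 s, so the log–log slope measured over t ∈ [1.5, 5.5] s is
  ≈ 1.90, approaching the asymptotic exponent 2 only at later times.  The
  acceptance script reports the honestly measured slope; the simulation
  uses 10⁴ walkers × 360 steps, where the Monte-Carlo scatter of the slope
  is ≈ ±0.01.
* **Selection bias of the track filter.**  The mean-speed cut that isolates
  retrograde tracks truncates the slow tail of the beta density
  (0.7–1.9% of its mass at the preset shapes).  The MLE then describes the
  *selected* population: α̂ and β̂ sit a few percent above the generating
  values, an offset that exceeds 3 standard errors once samples reach
  ~10⁴ tracks.  With ground-truth labels the same pipeline recovers the
  shapes within sampling error, so the bias belongs to the filtering
  procedure, not the estimator.  The same caveat applies to parameters
  fitted from filtered experimental data.  For the displacement→FPT
  self-consistency check the filter is therefore bypassed (labels from the
  generator manifest): with it, the χ² test detects the truncation rather
  than any displacement/FPT inconsistency.
* FPT moments require α > 1 (mean) and α > 2 (variance); the fitted mutant
  shapes satisfy both, but strongly immobilized populations may not.
* Standard errors assume a locally quadratic likelihood; near-boundary
  samples (nearly all-zero counts) make them unreliable.

## Problem sizes used by the test and acceptance suites

Distribution oracles run at n up to 500 (normalization), 10⁶ walkers
(BNB Monte-Carlo check), and 10⁶–10⁷ summation terms (moment oracles).
End-to-end recovery runs 2×10⁴ generated tracks per strain (≈10⁴
retrograde); the self-consistency check uses 10⁴ retrograde tracks of 150
frames.  The full pytest suite completes in a few minutes on one CPU.
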