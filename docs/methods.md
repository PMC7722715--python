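# Methods

## The measurement chain

Binocular gaze (1000 Hz; positions in degrees, pupil in arbitrary units,
missing samples as NaN) is processed per block:

1. **Low-pass filter.** Position channels are filtered with a zero-phase
   (forward–backward) 4th-order Butterworth at 60 Hz. Zero phase
   preserves event timing, on which every downstream statistic depends.
   Contiguous missing spans are preserved; finite runs shorter than 24
   samples pass through unfiltered (too short for stable padding).
2. **Segmentation.** One segment per trial from 300 ms before cue onset
   to 300 ms after target onset, both endpoints inclusive (a foreperiod
   of F ms gives F + 601 samples; t = 0 at the cue). Trials whose window
   leaves the recording are dropped and counted in the log.
3. **Blink detection.** Blinks are the union of (a) missing-data spans —
   the stand-in for a video tracker's proprietary online blink flagging,
   which is observable only through dropout — and (b) samples where
   *both* eyes' pupil deviates from the segment mean by more than 2.5 SD
   for at least 3 consecutive samples. Mean and SD are computed per eye
   over non-missing samples only (otherwise dropout dominates the SD);
   per-eye rather than pooled SD is used, configurable. Overlapping or
   touching events merge before masking.
4. **Exclusion.** Samples inside a blink or within 200 ms on either side
   are invalid and excluded from both event detection and rate
   denominators. Padded intervals are merged, so exclusion is a true set
   union.
5. **Saccade detection.** Velocity is the centered 5-sample
   moving-average kernel v_t = (x_{t+2}+x_{t+1}−x_{t−1}−x_{t−2})/(6Δt),
   shrinking symmetrically at segment edges. Each component is
   standardized by its segment median and the median-based robust SD
   σ = sqrt(median(v²) − median(v)²) over valid samples. The detection
   statistic is the norm of the standardized velocity. Two threshold
   modes exist because "median + 6 SD of the *norm*" is degenerate under
   the same median-based estimator (the median commutes with squaring a
   nonnegative variable, making that SD exactly zero): the default
   `norm_median` mode thresholds at median(norm) + λ·(1.4826·MAD of the
   norm); `elliptic` is the classic criterion norm > λ. λ = 6. An event
   needs ≥ 6 consecutive valid supra-threshold samples; onset/offset are
   the run bounds; amplitude is the straight-line onset→offset
   displacement (standard main-sequence convention, not path length);
   peak velocity is the maximal speed in the run.
6. **Binocular conjunction.** Only saccades present in both eyes
   (temporal overlap ≥ 1 sample) are kept, as one event with the earlier
   onset, later offset, and across-eye mean amplitude/peak velocity. An
   event starting < 50 ms after the previous retained offset is
   discarded as an overshoot (discarded, not merged: it is an artifact
   of the preceding saccade). All amplitudes are analyzed; no ceiling.
7. **Rates.** The saccade rate at relative time t is (trials with an
   onset at t among trials valid at t) / n_valid(t) × 1000 — onsets, not
   durations. The dependent measure is the unweighted mean rate over the
   inclusive −100…0 ms window before target onset (101 samples), per
   subject × condition × foreperiod. Trials with no valid window sample
   contribute nothing; a cell with no contributing trial is flagged NaN
   and rejected by the statistics with the cell named. Rate averaged
   across trials per sample first, then across window samples
   (pooled-then-windowed); the alternative order differs only under
   missing data. The 50 ms running-mean smoother exists for display
   only; no statistic is computed on smoothed traces.

## Conditions and hypotheses

Five block designs define the foreperiod distributions (100/0, 0/100,
80/20, 20/80 over {1, 2} s, and uniform over {1, 1.5, 2, 2.5, 3} s).
Condition labels per trial: full-certainty (both full blocks),
high-certainty-frequent (the block's 80% duration), high-certainty-rare
(the 20% duration), low-certainty. The hazard of a discrete foreperiod
distribution is evaluated exactly at support points,
h(t) = P(FP = t)/P(FP ≥ t) — "slightly before t" is modeled as: no
target at any earlier support point.

Predictions are ordinal only (the accounts specify orderings and
equalities, not magnitudes). The verdict rule: each planned contrast is
assigned its predicted relation from the hypothesis' level table; a
predicted inequality passes when FDR-adjusted p < α (0.05) and the mean
difference has the predicted sign; a predicted equality passes when the
contrast is non-significant *and* BF01 > 1/3. The Bayes-factor gate is
deliberately "no substantial evidence against the null" (Jeffreys'
1/3) rather than BF01 > 1: with 20 subjects an exactly-true null still
yields BF01 < 1 about 9% of the time per contrast, so gating equalities
at 1 would make a jointly-correct verdict fail ~17% of the time under
its own generative model. Both α and the BF threshold are configurable.

## Statistics

* **RM-ANOVA** (one- and two-way within-subject) by direct sums-of-squares
  decomposition, each effect tested against its subject × effect
  interaction. Sphericity per effect via Mauchly's W on the
  orthonormal-contrast covariance (second-order chi-square
  approximation); on violation (p < .05) the p-value is corrected with
  Greenhouse–Geisser when ε̂_GG < 0.7 and Huynh–Feldt otherwise.
  Two-level effects have ε ≡ 1 and are never corrected. Partial η² with
  a 95% CI by noncentral-F inversion.
* **Planned contrasts**: paired t on subject cell means (df = n − 1;
  combined cells averaged within subject first), Benjamini–Hochberg FDR
  within each foreperiod's family (three contrasts at 1 s, two at 2 s),
  Cohen's dz = mean(diff)/SD(diff) with a 95% CI by noncentral-t
  inversion.
* **BF01**: Jeffreys–Zellner–Siow Bayes factor for the paired t, Cauchy
  (0, √2/2) prior on the standardized effect, computed by adaptive
  quadrature of the noncentral-t likelihood over the prior (tangent
  substitution makes the domain finite); the reported percentage error
  is the propagated quadrature error. Cross-checked in tests against
  the independent Zellner-g mixture integral and pingouin.
* **Within-subject SEM**: subject-centered (grand mean restored) cell
  SD/√n, inflated by √(M/(M−1)) for M cells.
* **Foreperiod trend**: one-way RM-ANOVA over the five low-certainty
  foreperiods plus a linear contrast (−2,−1,0,1,2); a negative trend
  score is the hazard signature (inhibition grows with elapsed time).

## The synthetic-data generator

The generator is the package's stand-in for real recordings; it emulates
the features the pipeline is sensitive to and no more.

* **Fixational drift**: 2-D Gaussian random walk, diffusion scale
  `drift_sd` = 0.05 deg/√s (≈ 0.8 deg/s robust velocity spread after
  filtering — realistic fixation noise for video-oculography).
* **Saccades**: onsets from an inhomogeneous Bernoulli process with a
  physiological refractory period (`min_isi_ms` = 100 after each
  offset). `base_saccade_rate` (default 2.2 /s) is the *realized*
  steady-state rate; the underlying intensity is corrected by the
  renewal dead-time relation λ = r/(1 − r·τ_dead). A pure memoryless
  process would emit ~15% of onsets inside the detector's 50 ms
  overshoot window and is also physiologically wrong. Amplitudes are
  lognormal (median 0.4°, log-SD 0.35, clipped to 0.08–1.5°, i.e. the
  microsaccade-to-small-saccade range under fixation); peak velocity
  follows the main sequence vp = 45·A (slope in (deg/s)/deg, linear
  regime below ~1°) with 10% multiplicative lognormal noise; the
  waveform is minimum-jerk with duration D = 1.875·A/vp (the min-jerk
  identity; ≈ 42 ms at defaults). Directions are weakly corrective
  (biased toward fixation when gaze is > 0.3° off-center) so position
  stays bounded. Saccades are suppressed within 50 ms of blinks.
* **Inhibition**: during each foreperiod the rate is scaled by
  1 − d·a(t), where a(t) is the conditional probability that the target
  arrives within `inhibition_window_ms` (300 ms) after t given that it
  has not yet — the simplest law whose pre-target window values
  reproduce the orienting orderings at both foreperiods and the
  decreasing low-certainty foreperiod profile. `inhibition_depth`
  d = 0.85 by default: the effect this literature reports is large
  (full-vs-low standardized differences well above 1), and no
  generative magnitude is stated anywhere, so the default is a
  calibration choice, not an empirical claim.
* **Blinks**: Poisson (0.1 /s), ~150 ms; pupil ramps to 0 over 20 ms
  raised-cosine flanks and positions drop out (NaN), which is exactly
  the signature the blink detector consumes.
* **Noise**: white 0.005° per eye per sample; pupil baseline 1000 with a
  slow common sinusoid (1%) and 0.5% white noise.
* **Sessions**: 17 blocks (1 + 1 + 5 + 5 + 5), 80 trials each, ITI
  uniform 700–1200 ms, foreperiod counts exactly counterbalanced per
  block (the designs state exact percentages). Between-subject rate
  heterogeneity: lognormal factor with CV 0.15 on the base rate. All
  randomness fans out from one master seed via `SeedSequence` spawning.

What the generator does **not** emulate: pupillary light responses,
smooth pursuit, post-saccadic oscillations, drift-rate or pupil-size
inhibition components, calibration error, head motion, session-order or
learning effects, and any reaction-time structure. Passing tests
therefore demonstrate that the pipeline recovers the generative law
from data with these characteristics — not that real recordings satisfy
that law.

## Numerical conventions and edge cases

* Segment endpoints and the pre-target window are inclusive; sample
  index = millisecond.
* Degenerate inputs: all-invalid masks and zero-variance velocity yield
  zero detections (logged), not errors; an all-missing pupil flags the
  whole segment as one blink; zero-variance contrast differences flag
  dz as not computable; missing table cells raise with the offending
  subject and cell named.
* The staircase (start 15°, log₁₀ steps of 0.1, 1-up-3-down, stop at 4
  reversals or 100 trials) returns the final tilt; across 500 simulated
  runs against a smooth Weibull observer the observer's accuracy at the
  returned threshold averages ≈ 78%, near the 0.5^(1/3) ≈ 79.4%
  convergence point. The mean of reversal tilts was evaluated and is
  biased high here (few reversals after a long descent), so the final
  tilt is used.
* Problem sizes in the test suite: the end-to-end recovery check runs
  20 replicate experiments at 20 subjects × 17 blocks × 20 trials per
  block; detector calibration uses ≥ 1000 injected events; type-I
  control uses 500 replicates of the statistics layer on simulated SR
  tables. These scaled sizes keep the full suite comfortably
  reproducible on a single CPU while leaving every estimate's sampling
  error far below the margins being asserted.

## Known limitations

* The blink stand-in equates tracker-flagged blinks with missing data;
  real EyeLink blink events have hysteresis the stand-in lacks.
* The velocity-threshold reading "median of the norm + λ robust SD"
  required a scale-estimator substitution (see above); the `elliptic`
  mode is provided for sensitivity analyses.
* Contrast t statistics use paired-t degrees of freedom (n − 1), not
  pooled-error df from the omnibus model; p-values and verdicts are
  insensitive to this choice at these sample sizes, but reported df
  differ from mixed-model conventions.
* With very small cells (few trials, heavy blinking) cell means are
  Poisson-noisy and may be NaN; the statistics refuse incomplete tables
  rather than imputing.
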