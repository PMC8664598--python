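# Methods

This note documents the models and conventions behind `overlapgaze`: what
the scoring pipeline computes, what the synthetic-cohort generator emulates
(and what it deliberately does not), and the numerical and design choices
made where the published procedure leaves room.

## 1. Overlap-task protocol and geometry

A session has 24 trials, 6 per face condition (happy, fearful, neutral with
eyes open, neutral with eyes closed).  The face (15.8° × 11.4°) is shown
alone for 1000 ms, then together with a lateral distractor (15.8° × 4.0°)
for 3000 ms.  Trial order is random subject to two constraints — no more
than 4 consecutive trials of one emotion, no more than 3 consecutive
distractors on one side — implemented by rejection sampling over random
permutations (cap 10 000) with a deterministic swap repair as fallback;
generation is a pure function of (spec, seed).  Side counts are balanced
12/12; the sources do not state the true counts, and balance is the neutral
choice.

Coordinates are degrees of visual angle, screen-centered, x rightward, y
upward.  The stated 13.6° face–distractor distance is read as a
nearest-edge separation (so the right distractor's inner edge sits at
x = 7.9 + 13.6 = 21.5°); a center-to-center reading is available as a
config switch but is geometrically inconsistent with the stated stimulus
widths (the rectangles would overlap, which the AOI validator flags).  AOI
rectangles are closed; a point on a shared boundary labels as central.

## 2. Trial scoring

The disengagement latency x is the time of the last gaze sample inside the
central AOI before the first gaze transition that lands in the cued
distractor AOI, minus distractor onset.  "Lands" is operationalized with a
200-ms landing window: a departure from the face counts as the saccade only
if gaze registers inside the distractor AOI within 200 ms of leaving;
a departure that returns to the face within that window is a tolerated
wobble (it lowers the fixation fraction, below); a departure that does
neither rejects the trial as not directed at the distractor.  This
tolerance is what makes the 24-month "> 70% central fixation before
disengagement" rule non-vacuous: without it any off-face excursion would
end the trial and pre-saccade fixation would always be 100%.

Per-trial index: timeout → 1; otherwise clamp((x − 160)/840, 0, 1), which
is algebraically the printed 1 − (1000 − x)/840 on [160, 1000].  The
normalization constants are kept at 160/840 for both ages even though the
24-month anticipatory threshold is 150 ms; latencies in [150, 160) ms
produce a negative raw term and are clamped to 0.  Timeout trials count as
scorable, both in the condition mean and toward the ≥ 2-scorable inclusion
rule, because the index formula folds the no-saccade case into its upper
endpoint.

Age-mode specifics:

* **infant8** — sample times are floored to the 40-ms video-frame grid
  (anchored at distractor onset, first sample per frame kept) before
  scoring, emulating manual frame-by-frame coding; anticipatory threshold
  160 ms.  "Excessive movements" has no published quantitative definition;
  it is implemented as a configurable ceiling (default 2) on the number of
  departures from the face during the central-solo period, and is clearly a
  convention of this package.
* **toddler24** — runs of invalid samples whose flanking-valid span is
  ≤ 200 ms are linearly interpolated; longer runs stay invalid and are
  reported.  A trial is rejected when the saccade falls inside an unfilled
  gap, when an unfilled gap > 200 ms overlaps the pre-disengagement window,
  or when central fixation is < 70% of the time from distractor onset to
  the last on-face sample (or the whole window, for timeouts), counted over
  valid samples.  Anticipatory threshold 150 ms.

The scorer is deterministic, order-independent across trials, and is
checked against an independently written brute-force walk (per-sample AOI
labeling plus first-transition scan) on both random piecewise trajectories
and simulator-emitted sessions.

## 3. Synthetic cohort generator

The generator's defaults are the study conditions: 77 waking / 69 nonwaking
children, 83% retention at 24 months, awakening counts from truncated
Poisson distributions (mean 3.8 conditioned on ≥ 3; mean 0.9 conditioned on
≤ 1 — conditioning raises the realized waking mean to ≈ 4.2, an inherent
consequence of truncating at the printed mean), covariate frequencies from
the published demographics table, and CES-D/STAI covariates as opaque
truncated-normal sums.

**Dwell model.**  For child j, group g, condition c, each trial draws a
latent index s = m[g,c] + u_j + e with u_j ~ N(0, 0.10²) between children
and e ~ N(0, 0.25²) within.  The location m is found by monotone
root-finding on the closed-form censored-normal mean so that
E[clamp(s, 0, 1)] equals the target condition mean μ[g,c] (the published
group × emotion dwell means, constant over age because no age interactions
were found; an optional age-trend parameter exists for sensitivity work).
Emission: s ≥ 1 → a timeout trial; s < 0 → a saccade at the 160-ms floor;
otherwise a saccade at x = 160 + 840·s.  x is snapped to the session's
sample grid — 40-ms frames at 8 months, 300-Hz samples at 24 months — and
the snapped value is recorded as ground truth, so the scoring pipeline
recovers every clean trial's latency exactly on both paths and the
round-trip of condition means carries no quantization bias.  Exact-mean
recovery in the degenerate noiseless case therefore holds for targets on
the frame grid (multiples of 1/21 in index units), which is how the
property is tested.

Unscorable trials are injected at rate 0.10 (chosen so the mean scorable
count per condition at 8 months is ≈ 5.4 of 6, matching the reported trial
counts) by sampling one violation uniformly — late initial fixation,
wrong-direction saccade, anticipatory latency, or (24 months only) a
> 200-ms gap straddling the saccade — plus an extra 0.03 gap rate at 24
months.  Injections are independent of the latent index, so they thin the
scorable trials without biasing condition means.

**BITSEA model.**  Each domain has a unit-variance child latent
T_d = shift_g + 0.3·F + resid, where F is a single shared child factor
(loading 0.3 — a stated convention; within-child domain correlations are
not published).  The competence latent additionally loads on the child's
standardized 8-month dwell intercept with weight 0.337, reproducing the
published dwell–competence association at the latent level (the observable
correlation is attenuated by trial noise and item discretization).  Items
discretize T_d + σ_item·ε at two thresholds into {0, 1, 2}.  Thresholds and
σ_item per domain were calibrated once by Gauss–Hermite moment matching
against the published pooled domain means/SDs and internal consistencies
(α = .650/.515/.660/.657) and frozen as code constants; the two sleep items
get their own, higher-endorsement thresholds.  Group shifts are solved at
run time so the expected domain-sum effect size equals the configured d
(defaults 0.72 dysregulation, −0.48 competence, 0.38 internalizing, 0.19
externalizing).  Because the sleep items carry no extra group shift beyond
the shared domain shift, the split of the dysregulation difference between
sleep and non-sleep items is only qualitatively reproduced.

What the generator does **not** emulate: real oculomotor kinematics (gaze
jumps between AOI centers with jitter rather than moving continuously),
calibration error and head movement, item-level BITSEA missingness,
actigraphy, and any genuine causal structure linking sleep to attention —
group differences are injected, not emergent.  Passing round-trip tests
therefore demonstrates that the scoring and statistics recover what the
generator encodes, not that the substantive findings would replicate.

## 4. Statistical layer

* **Mixed model.**  dwell ~ group + age + emotion + group:age +
  group:emotion + group:age:emotion with a child-level random intercept
  (the screening fixed-effect structure).  The covariance-structure
  candidate set is implemented on the random-effects side — random
  intercept (compound symmetry), intercept + random age effect, intercept +
  per-emotion variance components — because statsmodels' MixedLM has no
  residual-side covariance structures; ML fits are compared by AIC and the
  winner is always reported (a `structure` argument can force one).  Joint
  fixed-effect tests are Wald F statistics with denominator df
  n_obs − rank(X); a Satterthwaite approximation is not available in the
  backend, and the published fractional dfs depend on the real data and are
  not reproduction targets.  Estimated marginal means average the design
  over the free factors with covariates at their means; within-group
  emotion contrasts are Bonferroni-corrected over the 6 pairs per group,
  with Cohen's d = contrast / √(σ²_subject + σ²_resid) (a stated
  convention).  Degenerate inputs (constant response, empty design cells)
  raise named errors; optimizer fallbacks (lbfgs → bfgs → powell) guard
  boundary fits.
* **t-tests.**  Pooled by default (df = n₁+n₂−2, d on the pooled SD);
  Welch–Satterthwaite auto-selected when a Levene pretest rejects at .05 —
  matching the published fractional df for internalizing only.
  Recomputing the dysregulation test from the published 2-decimal summaries
  gives t = 3.547 against the printed 3.542; the residue is input rounding
  (and the printed df = 97 vs. 98 from the stated group sizes points to
  undocumented per-domain missingness, which is why summary-based checks
  are tolerance-bounded).
* **Chi-square.**  Pearson X² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) without
  continuity correction; this convention is pinned by reproducing both
  published demographics statistics (20.376, 16.454) exactly from the
  printed counts.
* **Correlations.**  Pairwise-complete Pearson r with unadjusted two-sided
  p, mirroring the published correlation table's layout and its explicit
  lack of multiplicity adjustment.

## 5. Problem sizes and tolerances

The round-trip acceptance check simulates 500 children (264/236, preserving
the 77:69 group ratio) and accepts each recovered marginal dwell mean
within 3 Monte-Carlo standard errors computed from child-level means — the
between-child intercept dominates that error, giving 3 SE ≈ 0.02 on the
overall margins.  The mixed-model type-I calibration uses 120 null cohorts
of 60 children with the interaction rejection rate required to lie within
±3 binomial SEs of 5%; the t-test power check uses 2000 replicates against
the closed-form noncentral-t power at d = 0.72, n = 53/47, within 2
percentage points.  Censored-mean calibration solves to 10⁻⁹; effect-size
shifts solve to 10⁻⁶ via 61-node Gauss–Hermite quadrature.  Gaze text I/O
writes 17 significant digits, making float64 round-trips bit-exact.

## 6. Known limitations

* The BITSEA item→domain map is synthetic (the licensed instrument is
  proprietary); all count constraints and the two published sleep items are
  honored, and a config path accepts the licensed mapping.
* The excessive-movement rule, landing window, and wobble tolerance are
  package conventions where the published procedure gives no numbers.
* Wald-F inference with residual df is slightly anticonservative relative
  to Satterthwaite/Kenward–Roger in small samples; the type-I calibration
  bounds the practical impact at the study's size.
* Saccades landing within ~3 ms of the 1000-ms window end are
  observationally identical to timeouts; both score an index of ≈ 1, so
  condition means are unaffected.
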