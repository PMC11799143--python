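# Methods

## The anchoring-and-adjustment simulator

### Model

Deliberation on the grid task is modelled as a Markov chain of small
adjustments to an internal estimate of the black-tile proportion.  The
chain starts from an anchor drawn from a prior N(0.5, *b*) — the question
itself ("more than 50%?") anchors the first guess at one half — and is
advanced *T* = 150 times.  Each step proposes an increment
δ ~ N(0, σ<sub>δ</sub>) and accepts it by the Metropolis–Hastings rule
under a target density N(*C*<sub>prop</sub>, *b*) truncated to [0, 1]:
accept always when the proposal is at least as probable as the current
value, otherwise accept with probability equal to the density ratio.  The
defaults are the study conditions: *b* = 0.1 (strength of belief, shared
by prior and target), σ<sub>δ</sub> = 0.05, *C*<sub>prop</sub> = 0.55
(difficult) or 0.65 (easy), 1,000 chains per simulated individual, 500
individuals per condition.

A chain is scored correct at step *t* if *v*<sub>t</sub> > 0.5, strictly;
equality counts as incorrect.  This is a measure-zero event under the
continuous proposal, but a deterministic rule is needed and all simulated
conditions have *C*<sub>prop</sub> > 0.5.  The per-step accuracy over
chains is the thinking benefit; it is rescaled by its maximum over all
steps *including step 0* (so the maximum is exactly 1), the linear cost
schedule *c*<sub>max</sub>·*t*/*T* is subtracted, and the per-individual
peak time is the argmax of the result over *t* ∈ {1, …, *T*} with ties
resolved to the earliest step.  Step 0 is excluded from the argmax — a
"peak after zero adjustments" is not a thinking-time recommendation — and
an identically-zero accuracy curve raises a degenerate-curve error rather
than silently rescaling.

### Truncation conventions

All prior and target normals are truncated to [0, 1].  Inside the support
the truncation constants cancel in the MH ratio, so the acceptance
probability is the plain Gaussian density ratio; proposals outside [0, 1]
have zero target density and are rejected with probability 1, which is
what keeps chains in range.  The proposal *increment* distribution is
deliberately not truncated: truncating a mean-zero increment to [0, 1]
would forbid downward moves entirely, and rejection through the target
density preserves the intended behaviour.

The optional bimodal prior (for the robustness arm) is an equal-weight
mixture of N(0.4, 0.05) and N(0.6, 0.05), each component truncated to
[0, 1].  Equal weights are a symmetry choice; nothing in the design singles
out either mode.

### Randomness and reproducibility

Individual *i* draws from `SeedSequence(entropy=seed, spawn_key=(i,))`.
This counter-based scheme makes populations bit-reproducible under a fixed
seed and extensible: enlarging `n_individuals` leaves earlier individuals'
chains unchanged (there is a regression test for this).  Because the
accuracy curve does not depend on the cost schedule,
`compare_cost_regimes` simulates each individual's chains once and scores
them under every cost ceiling, so SAT vs resource-rational contrasts are
paired at the individual level.

### What the peak-time means mean

With zero cost the accuracy curve is (noisily) non-decreasing and
plateaus; the argmax is then driven by binomial noise across the plateau,
which is why SAT peak times spread over most of the horizon and their mean
sits far right (≈ 93–99 of 150 steps at full scale).  With
*c*<sub>max</sub> = 0.5 the cost term tilts the curve and the argmax
concentrates where marginal accuracy gain falls below the marginal cost
(≈ 23–27 steps).  These are population means of an extreme-value statistic,
so they move by a few percent across seeds at *n* = 500; the tests assert
them within that between-seed variability.

## The behavioral pipeline

* **Outlier rule.**  Trials with RT strictly over 6 s are excluded
  ("over 6 s" is read strictly; an exactly-6 s trial is kept) and the
  excluded fraction is reported.
* **RT categories.**  [0, 1.0), [1.0, 2.5), [2.5, 4.0), [4.0, 6.0] seconds.
  Only the labels are conventional; the right-open edge rule is this
  package's deterministic choice, with the last bin closed at the outlier
  boundary.
* **Cumulative RT distributions.**  Bins (k·0.1, (k+1)·0.1], k = 0…59;
  each stratum (group × difficulty × correctness) is normalized by its own
  trial count, so every non-empty stratum's CDF ends at 1.  Empty strata
  are omitted with a warning rather than emitting NaNs.
* **Trajectory AUC.**  Trajectories are first time-normalized to 101 points
  by linear interpolation of x and y at equal time fractions (endpoints
  preserved exactly; duplicate timestamps collapsed to their last sample).
  The AUC rotates coordinates so the straight start→end line is the
  horizontal axis and integrates the perpendicular deviation along the
  line with the trapezoidal rule.  This equals the signed polygon area of
  the closed start→curve→end loop, which is what the shoelace-oracle test
  checks.  Sign convention: deviation toward the non-chosen button is
  positive, overshoot past the direct path subtracts.  Since the recorded
  tables do not name the non-chosen button, it is taken as the mirror
  image of the trajectory endpoint across the vertical line through the
  start — valid for symmetric two-button layouts, which is the geometry
  both the experiment and the generator use.  Computing AUC after time
  normalization (rather than on the raw samples) only changes the path's
  sampling density, not its polygon, and makes per-trial values comparable.
  Units are px² of the recording space.
* **Irritation.**  A participant's score is the maximum of their nine
  per-block ratings on the 0–100 visual-analog scale; participants rating
  0 in every block are flagged excluded (treated as non-responses).  A
  table with a block count other than nine is a malformed-input error, not
  a silently shorter maximum.
* **Group tests.**  The unit of analysis is per-participant accuracy, not
  pooled trials.  One-way ANOVA F and Mann–Whitney W come from scipy;
  η² = SS<sub>between</sub>/SS<sub>total</sub>, Cliff's
  δ = (#{x>y} − #{x<y})/(nm) and the Holm step-down adjustment are
  implemented here and cross-checked against statsmodels in the tests.
  The irritation contrast is computed as δ(2.5 s, 1 s), so a positive sign
  means the longer wait is the more irritating one.

## The synthetic-data generator

The generator emulates the experiment's *design* — 3 waiting-time groups
(0/1/2.5 s) × 40 participants × 9 blocks × 40 trials, four stimulus
proportions (35/45/55/65% black) balanced at 90 trials each — and injects
effects sized to the reported group means, which serve as calibration
defaults rather than as quantities the package claims to reproduce:

* **Accuracy**: Bernoulli correctness with per-(group, difficulty)
  probabilities 0.67/0.75/0.78 (difficult) and 0.91/0.99/0.99 (easy) for
  0 s/1 s/2.5 s.
* **Response times**: group waiting offset + a log-normal decision time
  (median 1.1 s, log-SD 0.55 — a conventional positively skewed choice;
  the true RT distributions are only summarized in the source data).  The
  in-range component is truncated at 6 s by resampling, and a separate
  2.1% outlier fraction is pushed past 6 s so the filter stage has known
  ground truth.  The offset reproduces the response lockout: every 1 s /
  2.5 s-group RT exceeds its wait.
* **Trajectories**: constant-speed paths from screen centre to the chosen
  button (±300, 300) px, sampled at 60 Hz, with a half-sine perpendicular
  excursion toward the non-chosen button whose integrated area equals the
  requested conflict, plus 1.5 px Gaussian jitter on interior samples.
  Conflict is `auc_slope` (60 px²/s) × RT, injecting the
  conflict-grows-with-time trend.  The generator is a geometric oracle,
  not a cognitive model: it exists so per-trial AUC has known ground
  truth.
* **Irritation**: participant-level mean 26 (1 s group) or 39 (2.5 s
  group) with SD 16, nine block ratings below that level with SD 7,
  rounded and clipped to [0, 100]; 5% of raters give all zeros to
  exercise the exclusion rule.

What passing the recovery tests shows is that the pipeline measures what
was injected at realistic sample sizes; it does not show that real mouse
trajectories look like half-sines, that real RTs are log-normal, or that
real effect sizes match (synthetic participants are far less variable than
people, so F and η² run much larger here than in any real dataset).

## Problem sizes and tolerances

The full-scale simulation (4 conditions × 500 individuals × 1,000 chains ×
150 steps) runs in a few minutes on one CPU; the acceptance script uses
this scale.  Unit tests use 100–200 chains and 10–100 individuals, which
already separate the two regimes cleanly.  The stationary-limit check uses
10⁴ chains against the closed-form truncated-normal tail (0.6915 at
*C*<sub>prop</sub> = 0.55, 0.9332 at 0.65) within 3 Monte-Carlo standard
errors.  Geometry checks run at 10⁻⁶ relative tolerance against the
shoelace oracle and 10⁻⁹ for rigid-motion invariance; accuracy recovery is
asserted within ±0.02 (≈ 4 binomial SEs at 7,200 trials per cell).

## Known limitations

* The simulator's peak-time distribution in the SAT regime is noise-driven
  by construction; its mean is meaningful only jointly with the chain count
  (1,000) that sets the plateau noise.
* AUC values depend on the recording geometry (px² of a particular screen
  layout); cross-dataset comparisons need a common layout or explicit
  rescaling (AUC scales quadratically with uniform spatial scaling).
* The pipeline implements AUC only — no maximum absolute deviation,
  velocity profiles, or trajectory averaging/flipping for plotting.
* The generator makes no attempt to match any real dataset's full
  distributions; its defaults are calibrated to printed group means only.
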