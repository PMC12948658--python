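# Methods

This note documents the models implemented in `emomap`, the synthetic
cohort generator that drives them, the numerical choices, and what the test
suite does and does not establish.

## Task designs

The four task plans are deterministic given a seed and reproduce the
battery's combinatorial structure exactly: 105 similarity pairs
(30 within-emotion, 75 between-emotion), 55 forced-choice trials per
condition (every unordered pair of the 11 targets exactly once), 108
point-light-face trials (full 3×4×3×3 crossing, 12 per spatial×kinematic
condition), and 20 vocabulary items. The valence tagging of the 20 emotion
words is fixed at 10 positive / 10 negative (the only split consistent with
the 45/45/100 pair-group sizes); *surprise* is tagged positive. Trap images
in the choice task are assigned uniformly with replacement from the trap
pool, and trial order is a uniform seeded permutation; neither is prescribed
by the task description beyond "randomised".

## Scoring

**Consistency.** Only the final non-redo event of each planned trial counts;
trap selections and other redo-flagged events are excluded categorically.
Rank scores are raw times-chosen counts (ties need no breaking — the
statistic never sorts). For a complete 11-image round robin the total equals
2·Σw² − 550, is even, lies in [0, 220], and reaches 220 iff choices are
strictly transitive. The control (colourfulness) condition is scored
identically but reported separately.

**Differentiation.** Dissimilarity δ = 10 − rating (the minimal affine
inversion on the instrument's own scale). Metric MDS minimises raw stress by
SMACOF majorisation: the Guttman transform guarantees a non-increasing
stress sequence, recorded per iteration. Defaults: k = 2 dimensions,
n_init = 8 seeded random starts, max_iter = 300, absolute stress-decrease
tolerance 1e-6. These are convergence controls, not scientific parameters;
exact-recovery tests tighten them. Embedding is per participant (scores are
per-participant in all analyses). Cluster distances are computed in the
embedded space; each within mean covers 10 pairs and each between mean 25
pairs (asserted).

**Concepts.** Conceptual distance is −cosine on unit-normalised definition
embeddings. Values outside the nominal [−1, 0] band are legal (logged, not
clipped): the band is an empirical property of real definition embeddings,
not a constraint. The within-valence aggregate is the unweighted mean of the
two same-valence group means, not the pooled 90-pair mean. Word count uses
whitespace tokenisation with punctuation-only tokens dropped. Human 0/1/2
scoring is an input (or simulated), never computed. Real transformer
embeddings can be supplied as a matrix; the core pipeline deliberately has
no language-model dependency.

**Recognition.** accuracy = correct rating − mean(two incorrect), in
[−10, 10]; the headline score is the grand mean. Incomplete trial sets are
scored over available trials with a logged warning.

**Reliability.** Split-half uses an odd/even item split by default (seeded
random splits available; the original split rule is not documented anywhere,
so the default favours determinism), Pearson r between half-sums, and the
Spearman–Brown correction 2r/(1+r). Cronbach's α is the unstandardised
form with sample (n−1) variances.

## Synthetic cohort

The generator's purpose is to realise, with known latent parameters, the
statistical structure the scoring assumes — not to model human affect.
Defaults are chosen once as the study conditions:

* group sizes 58 autistic / 59 non-autistic; covariates drawn from
  truncated normals with the groups' published means and SDs (age
  32–33 ± 12–15 y, non-verbal reasoning ~60 ± 14–19 %, AQ 20.8/35.3,
  TAS 49.5/61.8); AQ and TAS subscales split from the totals by Dirichlet
  weights; education years 16 ± 3 (not separately published).
* group effects on every latent parameter default to **zero**, matching the
  null group differences the cohort emulates; any effect can be switched on
  additively.
* affect geometry: three cluster centres on an equilateral triangle of side
  `cluster_separation` (5 ± 1 between participants), within-cluster spread
  1.5 ± 0.3; similarity rating = clamp(10 − g·d + ε, 0, 10) with the gain g
  mapping each participant's largest latent distance onto the 0–10 scale
  (so the task observes geometry up to scale, as a bounded instrument must)
  and ε Gaussian (sd 1.0 ± 0.2).
* forced choices: two-alternative Thurstone Case V — utility = latent
  intensity (a seeded permutation of 0…10 over the 11 targets) + Gaussian
  comparison noise (sd 1.0 ± 0.3); traps are chosen with a lapse
  probability (default 0) and logged as redo events followed by a valid
  re-choice, so the filtering stage has something to filter.
* definition embeddings: v = normalise(valence centroid + (emotion offset +
  ε)/κ). The two valence centroids have cosine 0.7 and the offset/centroid
  ratio is 1.22, chosen so that at the default concentration κ ≈ 4 the
  within- and between-valence aggregates land near the empirically observed
  −0.4 / −0.28 regime; embedding dimension 16 (real transformer spaces are
  768-d, but only the geometry matters here). Item scores are
  Binomial(2, ability), word counts shifted Poisson.
* recognition: correct-scale mean = base + signal, incorrect = base −
  signal/2, Gaussian noise, clamped to [0, 10]; additive-then-clamp was
  preferred over truncated resampling for monotonicity in the signal.
* `chain_strength` ρ installs a latent causal chain for direction tests:
  concept differentiation (−concentration factor) → experiential
  differentiation (cluster-separation factor) → recognition signal. The
  downstream link is driven by the *realised, scale-free* geometry (mean
  centroid separation mapped onto the 0–10 instrument scale), i.e. by the
  construct the similarity task actually measures; with ρ = 0 the three
  factors are independent. The standardisation of the realised ratio uses a
  first-order approximation of its mean and SD under the configured
  parameters — adequate because only the correlation structure matters.

What the generator does **not** emulate: response-time structure beyond a
constant-plus-noise placeholder, item-level heterogeneity in the vocabulary
test, ordinal rating granularity (ratings are continuous), session or
fatigue effects, and real definition text. Passing recovery tests therefore
show the pipeline is correct and well-calibrated under the assumed
structure; they say nothing about whether real data satisfy it.

## Inference

**Group comparisons.** The random-intercept mixed model is approximated by
two fixed-effects strata: the repeated factor and its group interaction are
tested in an OLS model with subject dummies absorbed (nested-model F tests
against the full-model residual — for the balanced designs here these
coincide with mixed-model ANOVA F ratios, e.g. interaction df (2, 230) at
n = 117), and group plus covariates are tested on subject-mean outcomes by
Type II ANOVA. Kenward–Roger df corrections and Bayes-factor analyses are
not implemented. A rank-transformed least-squares regression serves as the
non-parametric fallback for skewed outcomes (e.g. vocabulary totals).

**Shadow-feature selection.** Each iteration appends an independently
permuted copy of every live feature (padded to at least five shadows so the
shadow maximum stays a meaningful null reference late in a run), fits a
random-forest regressor (100 trees, min_samples_leaf = 10) on a 2/3 train
split, and scores out-of-sample permutation importance (R² drop on the
held-out third, 3 repeats, one batched predict). Permutation importance was
chosen over impurity importance for robustness to feature scale; the
regularised leaves keep weak chance correlations (|r| ≈ 0.1–0.2 arises
routinely at n ≈ 100) from parking features in the tentative band
indefinitely. A feature scores a hit when its importance exceeds the
iteration's shadow maximum; a two-sided binomial test against 0.5,
Bonferroni-corrected over the currently undecided features at α = 0.01,
confirms or rejects; rejected features leave the live pool and the loop
stops early once nothing is undecided. n_iter defaults to 100 (the
reference analyses ran 3000; the decision rule converges far earlier at
these problem sizes, and the config exposes the setting).

**Mediation.** Two OLS regressions (mediator ~ predictor + covariates;
outcome ~ mediator + predictor + covariates) give a, b, c′; the indirect
effect is a·b and covariates enter both equations. Participants are
resampled with replacement B = 2000 times (batched normal-equation solves);
bias-corrected 95% CIs use z₀ = Φ⁻¹(fraction of replicates below the point
estimate) and endpoints at percentiles Φ(2z₀ ± 1.96). Bootstrap proportions
are clipped to (1/(B+1), 1−1/(B+1)) to keep z₀ finite; BC intervals can in
principle exclude the point estimate under extreme skew. Significance is CI
excluding zero. Full SEM estimation is out of scope — for a single-mediator
linear model the two-regression form is algebraically equivalent.

**Full analysis runner.** Assembles the per-participant frame, fits the six
group-model families, runs the selector per group over the 19 predictors
(six task scores, AQ/TAS totals and 8 subscales, non-verbal reasoning,
education, age), refits follow-up linear models on confirmed + tentative
features twice — once without the between-cluster and once without the
within-cluster distance, which are too collinear to enter together — and
fits the two forward and two reversed mediation models on the non-autistic
group with six confound covariates.

## Problem sizes used in the test suite

Simulation-based tests are sized to settle their question, not to mimic the
study: type-I calibration uses 200 replicates at n = 55/group; selector
consistency 50 seeded runs at n = 120 with 10 features; mediation coverage
500 replicate datasets at n = 100 with B = 1000; null-cohort and
causal-chain pipeline checks use 8 and 3 cohorts of 50–72 participants with
2–4 MDS restarts. The joint "no significant group term in any family"
event multiplies six ~5%-level tests, so its per-cohort probability sits
near 0.95⁶ ≈ 0.74 under independence and somewhat higher with the observed
correlation between families; the null-pipeline test asserts both the
joint-clean majority and the pooled per-term rejection rate instead of an
arbitrary higher joint threshold.

## Known limitations

* The fixed-effects approximation reproduces mixed-model F tests only for
  balanced complete designs; unbalanced data would need true REML fits.
* The selector's decisions at very small n (< ~15 rows per group) are
  dominated by split noise; the runner still executes but decisions are
  mostly tentative/rejected.
* BC bootstrap intervals for near-zero indirect effects are conservative;
  under complete independence the empirical CI-exclusion rate is well below
  the nominal 5%.
* The generator's rating clamping induces mild floor/ceiling censoring, so
  latent noise SDs are recovered up to attenuation, not exactly.
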