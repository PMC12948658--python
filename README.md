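# emomap

Scoring and inference pipeline for a behavioural task battery measuring how
adults experience, differentiate and conceptualise emotions — built for
studies comparing autistic and non-autistic participants, and usable for any
cohort that completes the same tasks. Because real participant data are not
required, a synthetic cohort generator with known latent parameters drives
every stage, so all scoring and inference code is covered by
parameter-recovery tests.

## What it computes

**Emotional consistency** (forced-choice tournament). Per condition, 11
target images are shown pairwise in all C(11,2) = 55 combinations, with a
trap image as an attention check. An image's *rank score* w_i is the number
of trials in which it was chosen (0–10); each trial contributes the item
difference w_chosen − w_unchosen, and the total consistency score is their
sum over the 55 trials:

    total = Σ_trials (w_chosen − w_unchosen) = 2 Σ_i w_i² − 550

A strictly transitive chooser produces rank scores 10, 9, …, 0 and the
maximum total of 220.

**Emotion differentiation** (similarity task). All 105 pairs of 15
affect-inducing images (5 angry, 5 happy, 5 sad) are rated for similarity
(0–10). Ratings are inverted to dissimilarities δ = 10 − rating and embedded
by metric MDS (SMACOF majorisation of raw stress Σ_{i<j}(δ_ij − ‖x_i−x_j‖)²).
Scores are the mean embedded Euclidean distances within each emotion cluster
(10 pairs each) and between each cluster pair (25 pairs each).

**Concept measures** (vocabulary test). 20 emotion-word definitions are
scored 0/1/2 by a human rater (total 0–40) and embedded as unit vectors;
*conceptual distance* between two definitions is −cos(u, v). The
within-valence aggregate averages the 45 positive–positive and 45
negative–negative pair means; the between-valence aggregate averages the 100
cross-valence pairs.

**Recognition accuracy** (point-light faces). 108 trials cross 3 emotions ×
4 actors × 3 spatial × 3 kinematic levels; per trial, accuracy = correct
emotion rating − mean of the two incorrect ratings.

**Reliability**: Spearman–Brown split-half (2r/(1+r)) and Cronbach's α.

**Inference**: repeated-measures group comparisons (subject fixed-effects
within stratum + subject-means between stratum), an all-relevant
shadow-feature (Boruta-style) random-forest selector over 19 candidate
predictors of recognition accuracy, and product-of-coefficients mediation
with bias-corrected bootstrap confidence intervals.

## Worked example

```python
import emomap as em

# a transitive (zero comparison noise) participant scores exactly 220
cset = em.ImageSet.choice_default("angry")
plan = em.build_choice_trials(cset, seed=1)
profile = em.sample_profile(em.CohortConfig(seed=0), "non-autistic", "p001",
                            __import__("numpy").random.default_rng(0))
profile.comparison_noise_sd = 0.0
events = em.simulate_choices(profile, plan, seed=1)
final = em.filter_final_choices(events)
ranks = em.rank_scores(final)
print(sorted(ranks.tolist(), reverse=True))
print(em.consistency_total(final, ranks).total)
```

prints

```
[10, 9, 8, 7, 6, 5, 4, 3, 2, 1, 0]
220
```

— the perfect rank-score sequence and the maximum consistency total for a
complete 11-image round robin.

A whole-cohort run:

```python
data = em.simulate_cohort(em.CohortConfig(n_autistic=58, n_non_autistic=59,
                                          seed=7))
report = em.run_full_analysis(data, em.AnalysisConfig(seed=7))
```

`report["group_models"]` holds per-term F/t tables for the six
group-comparison families, `report["boruta"]` the confirmed / tentative /
rejected decision per predictor and group, and `report["mediation"]` the
path estimates with bias-corrected 95% CIs for the forward and reversed
mediation models.

The same operations are exposed on the command line:

```
emomap design --task similarity --seed 1 --out plan.csv
emomap simulate --seed 1 --out cohort/
emomap reliability --scores scores.csv --method alpha
emomap analyze --cohort cohort/ --seed 1 --out report/
```

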