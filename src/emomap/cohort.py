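"""Synthetic cohort generator.

Simulates raw trial-level data for the whole task battery from known latent
parameters, so that every downstream scoring and inference stage admits
parameter-recovery tests. The generative models are deliberately simple:

* similarity ratings: a participant holds a latent 2-D affect geometry
  (3 emotion clusters of 5 images); the rating of a pair is an affinely
  rescaled, noisy, clamped inverse of the latent Euclidean distance;
* forced choices: Thurstone Case V — each target has a latent intensity,
  a trial's choice is the argmax of intensity + Gaussian comparison noise
  over the two shown targets; traps are picked with a lapse probability
  (default 0) and recorded as redo events followed by a valid re-choice;
* definition embeddings: unit vectors around a valence centroid plus an
  emotion-specific offset, with isotropic noise shrunk by a concentration
  parameter; item scores 0/1/2 are Binomial(2, ability); word counts are
  shifted Poisson;
* recognition ratings: correct-emotion scale mean = base + signal,
  incorrect scales = base - signal/2, Gaussian noise, clamped to [0, 10].

Group effects on any latent parameter are configurable and default to zero,
mirroring the null group differences the cohort is meant to emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (EMOTIONS, ImageSet, TrialPlan, build_choice_trials,
                     build_plf_trials, build_similarity_pairs,
                     build_vocab_items)

CHOICE_CONDITIONS = ("control", "angry", "happy", "sad")

AQ_SUBSCALES = ("aq_social", "aq_switch", "aq_detail", "aq_comm", "aq_imag")
TAS_SUBSCALES = ("tas_ddf", "tas_dif", "tas_eot")


@dataclass
class ParticipantProfile:
    """Latent generative parameters for one simulated participant."""

    participant_id: str
    group: str
    image_coords: np.ndarray            # (15, 2) latent affect geometry
    image_ids: tuple[str, ...]
    rating_noise_sd: float
    intensities: dict                   # condition -> {image_id: intensity}
    comparison_noise_sd: float
    lapse_prob: float
    valence_centroids: np.ndarray       # (2, dim) unit rows: positive, negative
    emotion_offsets: np.ndarray         # (20, dim)
    concentration: float
    vocab_ability: float                # in (0, 1)
    mean_definition_words: float
    recognition_base: float
    recognition_signal: float
    recognition_noise_sd: float
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("rating_noise_sd", "comparison_noise_sd",
                     "recognition_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for cond, vals in self.intensities.items():
            if len(vals) != 11:
                raise ValueError(f"condition {cond!r}: need 11 intensities")
        aq = self.covariates.get("aq")
        if aq is not None and not (0 <= aq <= 50):
            raise ValueError("AQ must lie in [0, 50]")
        tas = self.covariates.get("tas")
        if tas is not None and not (20 <= tas <= 100):
            raise ValueError("TAS must lie in [20, 100]")


@dataclass
class CohortConfig:
    """Cohort size, latent-parameter baselines and (additive) group effects.

    ``group_effects`` maps a latent parameter name to the additive shift
    applied to the autistic group; all default to zero.
    """

    n_autistic: int = 58
    n_non_autistic: int = 59
    seed: int = 0
    embedding_dim: int = 16
    # latent baselines (mean, between-participant sd)
    cluster_separation: tuple[float, float] = (5.0, 1.0)
    within_spread: tuple[float, float] = (1.5, 0.3)
    rating_noise_sd: tuple[float, float] = (1.0, 0.2)
    comparison_noise_sd: tuple[float, float] = (1.0, 0.3)
    lapse_prob: float = 0.0
    centroid_cosine: float = 0.7
    offset_scale: float = 1.22
    concentration: tuple[float, float] = (4.0, 1.0)
    vocab_ability: tuple[float, float] = (0.7, 0.1)
    mean_definition_words: tuple[float, float] = (12.0, 3.0)
    recognition_base: tuple[float, float] = (3.0, 0.5)
    recognition_signal: tuple[float, float] = (2.5, 0.8)
    recognition_noise_sd: tuple[float, float] = (1.5, 0.3)
    #: correlation strength of the latent chain concept differentiation ->
    #: experiential differentiation -> recognition signal (0 = independent).
    chain_strength: float = 0.0
    group_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_autistic < 1 or self.n_non_autistic < 1:
            raise ValueError("group sizes must be >= 1")
        for k, v in self.group_effects.items():
            if not np.isfinite(v):
                raise ValueError(f"group effect {k!r} must be finite")


# covariate generators: Table-style means/sds per group
_COVARIATE_PARAMS = {
    # name: (non-autistic mean, sd), (autistic mean, sd), (lo, hi)
    "age": ((32.27, 15.30), (33.26, 11.54), (18, 75)),
    "nvr": ((59.50, 13.54), (61.11, 18.61), (0, 100)),
    "education_years": ((16.0, 3.0), (16.0, 3.0), (10, 25)),
    "aq": ((20.80, 8.54), (35.34, 7.80), (0, 50)),
    "tas": ((49.48, 14.25), (61.79, 11.60), (20, 100)),
}


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(x, lo, hi))


def _positive(rng, mean, sd, floor=1e-3):
    return max(floor, rng.normal(mean, sd))


def _sample_covariates(rng, group: str) -> dict:
    cov = {}
    for name, (na, au, bounds) in _COVARIATE_PARAMS.items():
        mean, sd = au if group == "autistic" else na
        cov[name] = _truncnorm(rng, mean, sd, *bounds)
    cov["sex"] = "female" if rng.random() < 0.55 else "male"
    # split totals into subscales with Dirichlet weights
    aq_w = rng.dirichlet(np.ones(len(AQ_SUBSCALES)))
    for sub, w in zip(AQ_SUBSCALES, aq_w):
        cov[sub] = cov["aq"] * w
    tas_excess = cov["tas"] - 20.0
    tas_w = rng.dirichlet(np.ones(len(TAS_SUBSCALES)))
    for sub, w in zip(TAS_SUBSCALES, tas_w):
        cov[sub] = tas_excess * w
    return cov


def _unit(v):
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def sample_profile(config: CohortConfig, group: str, participant_id: str,
                   rng: np.random.Generator) -> ParticipantProfile:
    """Draw one participant's latent parameters from the cohort config."""
    eff = config.group_effects if group == "autistic" else {}

    def draw(name):
        mean, sd = getattr(config, name)
        return _positive(rng, mean + eff.get(name, 0.0), sd)

    def located(name, z):
        mean, sd = getattr(config, name)
        return max(1e-3, mean + eff.get(name, 0.0) + sd * z)

    # latent chain: concept differentiation -> experiential differentiation
    # -> recognition signal; chain_strength = 0 decouples the three factors
    rho = config.chain_strength
    z_concept = rng.normal()
    z_exp = rho * z_concept + np.sqrt(1 - rho ** 2) * rng.normal()
    # lower concentration = more dispersed definition vectors = more
    # differentiated concepts, hence the sign flip on z_concept
    concentration = located("concentration", -z_concept)
    sep = located("cluster_separation", z_exp)
    spread = draw("within_spread")
    # three cluster centres on an equilateral triangle of side `sep`
    ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3,
                    np.pi / 2 + 4 * np.pi / 3])
    centres = (sep / np.sqrt(3)) * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    sim_set = ImageSet.similarity_default()
    coords = np.vstack([
        centres[EMOTIONS.index(e)] + rng.normal(0, spread, size=2)
        for e in sim_set.emotions
    ])
    # downstream chain link: recognition ability tracks how differentiated
    # the *realized* affect geometry is (the quantity the similarity task
    # measures), not the drawn separation parameter
    if rho != 0.0:
        # scale-free differentiation of the realized geometry: mean
        # centroid separation mapped onto the 0-10 instrument scale (the
        # similarity task only observes geometry up to its own gain)
        cl = [coords[[i for i, e in enumerate(sim_set.emotions) if e == emo]]
              .mean(axis=0) for emo in EMOTIONS]
        centroid_sep = np.mean([np.linalg.norm(cl[i] - cl[j])
                                for i in range(3) for j in range(i + 1, 3)])
        dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :],
                              axis=-1)
        ratio = 10.0 * centroid_sep / dmat.max()
        mean_s, sd_s = config.cluster_separation
        spread_m = config.within_spread[0]
        r0 = 10.0 * mean_s / (mean_s + 2.5 * spread_m)
        r_sd = 10.0 * 2.5 * spread_m / (mean_s + 2.5 * spread_m) ** 2 \
            * max(sd_s, 1e-6) + 0.3
        z_real = (ratio - r0) / r_sd
        z_rec = rho * z_real + np.sqrt(1 - rho ** 2) * rng.normal()
    else:
        z_rec = rng.normal()
    signal = located("recognition_signal", z_rec)

    intensities = {}
    for cond in CHOICE_CONDITIONS:
        cset = ImageSet.choice_default(cond)
        # intensities spread over [0, 10]; seeded random assignment to images
        vals = rng.permutation(np.linspace(0, 10, 11))
        intensities[cond] = dict(zip(cset.targets, vals))

    dim = config.embedding_dim
    cos = config.centroid_cosine
    pos = np.zeros(dim)
    pos[0] = 1.0
    neg = np.zeros(dim)
    neg[0], neg[1] = cos, np.sqrt(max(0.0, 1 - cos ** 2))
    offsets = rng.normal(0, 1, size=(20, dim))
    offsets = config.offset_scale * (offsets / np.linalg.norm(offsets, axis=1,
                                                             keepdims=True))
    vocab_mean = config.vocab_ability[0] + eff.get("vocab_ability", 0.0)
    ability = float(np.clip(rng.normal(vocab_mean, config.vocab_ability[1]),
                            0.02, 0.98))

    return ParticipantProfile(
        participant_id=participant_id,
        group=group,
        image_coords=coords,
        image_ids=sim_set.images,
        rating_noise_sd=draw("rating_noise_sd"),
        intensities=intensities,
        comparison_noise_sd=draw("comparison_noise_sd"),
        lapse_prob=config.lapse_prob,
        valence_centroids=np.stack([pos, neg]),
        emotion_offsets=offsets,
        concentration=concentration,
        vocab_ability=ability,
        mean_definition_words=draw("mean_definition_words"),
        recognition_base=draw("recognition_base"),
        recognition_signal=signal,
        recognition_noise_sd=draw("recognition_noise_sd"),
        covariates=_sample_covariates(rng, group),
    )


# ---------------------------------------------------------------- simulators

def simulate_similarity_ratings(profile: ParticipantProfile, plan: TrialPlan,
                                seed: int, gain: float | None = None
                                ) -> pd.DataFrame:
    """Noisy clamped similarity ratings from the latent affect geometry.

    rating = clamp(10 - g * d_ij + eps, 0, 10) with g mapping the largest
    latent pairwise distance onto the 0-10 instrument scale.
    """
    rng = np.random.default_rng(seed)
    ids = list(profile.image_ids)
    missing = (set(plan.trials["stimulus_a"]) | set(plan.trials["stimulus_b"])) \
        - set(ids)
    if missing:
        raise ValueError(f"plan images absent from profile: {sorted(missing)}")
    X = profile.image_coords
    dmat = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    if gain is None:
        dmax = dmat.max()
        gain = 10.0 / dmax if dmax > 0 else 0.0
    rows = []
    for t in plan.trials.itertuples():
        d = dmat[ids.index(t.stimulus_a), ids.index(t.stimulus_b)]
        eps = rng.normal(0, profile.rating_noise_sd) \
            if profile.rating_noise_sd > 0 else 0.0
        rating = float(np.clip(10.0 - gain * d + eps, 0.0, 10.0))
        rows.append(dict(participant=profile.participant_id, task="similarity",
                         trial_index=t.trial_index, stimulus_a=t.stimulus_a,
                         stimulus_b=t.stimulus_b, rating=rating,
                         rt_ms=1500.0 + rng.normal(0, 200), redo=False))
    return pd.DataFrame(rows)


def simulate_choices(profile: ParticipantProfile, plan: TrialPlan, seed: int,
                     condition: str | None = None) -> pd.DataFrame:
    """Thurstone Case V forced choices over each planned target pair.

    Trap selections occur with ``profile.lapse_prob`` and are recorded as
    redo-flagged events followed by a valid re-choice, matching the task's
    attention-check procedure.
    """
    rng = np.random.default_rng(seed)
    condition = condition or str(plan.trials["emotion"].iloc[0])
    inten = profile.intensities.get(condition)
    if inten is None:
        raise ValueError(f"no intensities for condition {condition!r}")
    rows = []
    for t in plan.trials.itertuples():
        a, b = t.stimulus_a, t.stimulus_b
        if a not in inten or b not in inten:
            raise ValueError(f"missing intensity for {a!r} or {b!r}")
        if profile.lapse_prob > 0 and rng.random() < profile.lapse_prob:
            rows.append(dict(participant=profile.participant_id, task="choice",
                             condition=condition, trial_index=t.trial_index,
                             stimulus_a=a, stimulus_b=b, trap_id=t.trap_id,
                             chosen=t.trap_id,
                             rt_ms=900.0 + rng.normal(0, 150), redo=True))
        sd = profile.comparison_noise_sd
        ua = inten[a] + (rng.normal(0, sd) if sd > 0 else 0.0)
        ub = inten[b] + (rng.normal(0, sd) if sd > 0 else 0.0)
        rows.append(dict(participant=profile.participant_id, task="choice",
                         condition=condition, trial_index=t.trial_index,
                         stimulus_a=a, stimulus_b=b, trap_id=t.trap_id,
                         chosen=a if ua >= ub else b,
                         rt_ms=1800.0 + rng.normal(0, 300), redo=False))
    return pd.DataFrame(rows)


def simulate_definition_embeddings(profile: ParticipantProfile,
                                   items=None, dim: int | None = None,
                                   seed: int = 0):
    """Unit definition embeddings + 0/1/2 item scores + word counts.

    Each emotion's vector is ``normalize(valence centroid + (offset + eps)
    / concentration)`` so that infinite concentration collapses vectors onto
    their valence centroid. Returns ``(vectors, scores, word_counts)``.
    """
    items = items or build_vocab_items()
    rng = np.random.default_rng(seed)
    dim = dim or profile.valence_centroids.shape[1]
    if dim < 2:
        raise ValueError("dim must be >= 2")
    pos, neg = profile.valence_centroids[:, :dim]
    kappa = profile.concentration
    vecs = np.empty((len(items), dim))
    for i, (word, valence) in enumerate(items):
        centroid = pos if valence == "positive" else neg
        if np.isinf(kappa):
            vecs[i] = _unit(centroid)
            continue
        jitter = (profile.emotion_offsets[i, :dim]
                  + rng.normal(0, 1, size=dim)) / kappa
        vecs[i] = _unit(centroid + jitter)
    scores = rng.binomial(2, profile.vocab_ability, size=len(items))
    counts = 1 + rng.poisson(max(0.0, profile.mean_definition_words - 1),
                             size=len(items))
    return vecs, scores, counts


def simulate_recognition_ratings(profile: ParticipantProfile, plan: TrialPlan,
                                 seed: int) -> pd.DataFrame:
    """Signal-plus-noise ratings on the three 0-10 emotion scales per trial."""
    rng = np.random.default_rng(seed)
    base, sig, sd = (profile.recognition_base, profile.recognition_signal,
                     profile.recognition_noise_sd)
    rows = []
    for t in plan.trials.itertuples():
        row = dict(participant=profile.participant_id, task="plf",
                   trial_index=t.trial_index, emotion=t.emotion,
                   actor=t.actor, spatial=t.spatial, kinematic=t.kinematic,
                   rt_ms=2500.0 + rng.normal(0, 400), redo=False)
        for emo in EMOTIONS:
            mean = base + sig if emo == t.emotion else base - sig / 2.0
            eps = rng.normal(0, sd) if sd > 0 else 0.0
            row[f"rating_{emo}"] = float(np.clip(mean + eps, 0.0, 10.0))
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- cohort

@dataclass
class CohortData:
    """Raw simulated data for a whole cohort, plus the latent-truth table."""

    participants: pd.DataFrame
    similarity: pd.DataFrame
    choices: pd.DataFrame
    plf: pd.DataFrame
    definitions: pd.DataFrame     # long: participant, word, valence, score, word_count
    embeddings: pd.DataFrame      # long: participant, word + e0..e{d-1}
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("participants", "similarity", "choices", "plf",
                     "definitions", "embeddings", "truth"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read(cls, in_dir) -> "CohortData":
        p = Path(in_dir)
        return cls(**{name: pd.read_csv(p / f"{name}.csv")
                      for name in ("participants", "similarity", "choices",
                                   "plf", "definitions", "embeddings",
                                   "truth")})


def simulate_cohort(config: CohortConfig,
                    profiles_only: bool = False) -> CohortData:
    """Simulate the full battery for every participant in the cohort.

    Deterministic given ``config.seed``. With ``profiles_only`` the trial
    simulations are skipped (only covariates + latent truth are produced),
    which is enough for latent-parameter recovery checks.
    """
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_autistic + config.n_non_autistic
    seeds = root.spawn(n_total)
    groups = (["autistic"] * config.n_autistic
              + ["non-autistic"] * config.n_non_autistic)

    part_rows, truth_rows = [], []
    sim_tables, choice_tables, plf_tables = [], [], []
    def_rows, emb_rows = [], []
    items = build_vocab_items()
    sim_plan = build_similarity_pairs()

    for i, (group, ss) in enumerate(zip(groups, seeds)):
        pid = f"p{i + 1:03d}"
        child = ss.spawn(8)
        rng = np.random.default_rng(child[0])
        prof = sample_profile(config, group, pid, rng)
        part_rows.append(dict(participant=pid, group=group, **prof.covariates))
        truth_rows.append(dict(
            participant=pid, group=group,
            cluster_separation=np.linalg.norm(
                prof.image_coords[:5].mean(0) - prof.image_coords[5:10].mean(0)),
            rating_noise_sd=prof.rating_noise_sd,
            comparison_noise_sd=prof.comparison_noise_sd,
            concentration=prof.concentration,
            vocab_ability=prof.vocab_ability,
            recognition_signal=prof.recognition_signal,
            recognition_base=prof.recognition_base,
            recognition_noise_sd=prof.recognition_noise_sd,
        ))
        if profiles_only:
            continue
        sub = [int(s.generate_state(1)[0] >> 1) for s in child[1:]]
        sim_tables.append(simulate_similarity_ratings(prof, sim_plan, sub[0]))
        for j, cond in enumerate(CHOICE_CONDITIONS):
            cset = ImageSet.choice_default(cond)
            cplan = build_choice_trials(cset, seed=sub[1] + j, condition=cond)
            choice_tables.append(simulate_choices(prof, cplan, sub[2] + j,
                                                  condition=cond))
        plf_plan = build_plf_trials(seed=sub[3])
        plf_tables.append(simulate_recognition_ratings(prof, plf_plan, sub[4]))
        vecs, scores, counts = simulate_definition_embeddings(
            prof, items, seed=sub[5])
        for (word, valence), s, c, v in zip(items, scores, counts, vecs):
            def_rows.append(dict(participant=pid, word=word, valence=valence,
                                 score=int(s), word_count=int(c)))
            emb_rows.append(dict(participant=pid, word=word,
                                 **{f"e{k}": v[k] for k in range(len(v))}))

    empty = pd.DataFrame()
    return CohortData(
        participants=pd.DataFrame(part_rows),
        similarity=pd.concat(sim_tables, ignore_index=True) if sim_tables else empty,
        choices=pd.concat(choice_tables, ignore_index=True) if choice_tables else empty,
        plf=pd.concat(plf_tables, ignore_index=True) if plf_tables else empty,
        definitions=pd.DataFrame(def_rows),
        embeddings=pd.DataFrame(emb_rows),
        truth=pd.DataFrame(truth_rows),
    )
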