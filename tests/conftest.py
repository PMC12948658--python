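import numpy as np
import pytest

import emomap as em


@pytest.fixture(scope="session")
def choice_set():
    return em.ImageSet.choice_default("angry")


@pytest.fixture(scope="session")
def choice_plan(choice_set):
    return em.build_choice_trials(choice_set, seed=42)


@pytest.fixture(scope="session")
def default_config():
    return em.CohortConfig(seed=0)


@pytest.fixture(scope="session")
def profile(default_config):
    rng = np.random.default_rng(123)
    return em.sample_profile(default_config, "non-autistic", "p001", rng)


def make_profile(**overrides):
    """A hand-built participant profile with fully controlled latents."""
    import pandas as pd

    sim_set = em.ImageSet.similarity_default()
    coords = np.zeros((15, 2))
    intensities = {}
    for cond in ("control", "angry", "happy", "sad"):
        cset = em.ImageSet.choice_default(cond)
        intensities[cond] = dict(zip(cset.targets, np.arange(11.0)))
    dim = 8
    pos = np.zeros(dim)
    pos[0] = 1.0
    neg = np.zeros(dim)
    neg[1] = 1.0
    defaults = dict(
        participant_id="p_test", group="non-autistic",
        image_coords=coords, image_ids=sim_set.images,
        rating_noise_sd=0.0, intensities=intensities,
        comparison_noise_sd=0.0, lapse_prob=0.0,
        valence_centroids=np.stack([pos, neg]),
        emotion_offsets=np.zeros((20, dim)),
        concentration=np.inf, vocab_ability=0.5,
        mean_definition_words=10.0,
        recognition_base=3.0, recognition_signal=2.0,
        recognition_noise_sd=0.0,
        covariates=dict(age=30.0, sex="female", nvr=60.0,
                        education_years=16.0, aq=20.0, tas=50.0),
    )
    defaults.update(overrides)
    return em.ParticipantProfile(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-participant cohort reused by scoring and pipeline tests."""
    return em.simulate_cohort(em.CohortConfig(n_autistic=6, n_non_autistic=6,
                                              seed=11))
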