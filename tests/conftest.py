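import numpy as np
import pytest

import rnflbase as rb
from rnflbase.cvae import CVAEHyperParams, train_model
from rnflbase.prep import PopulationStats


@pytest.fixture(scope="session")
def small_cohort():
    """120-participant default-config cohort with ground truth."""
    cfg = rb.SimConfig(n_participants=120, seed=42)
    eyes, truths = rb.generate_cohort(cfg)
    return cfg, eyes, truths


@pytest.fixture(scope="session")
def prepped_small(small_cohort):
    _, eyes, truths = small_cohort
    prepped, stats, log = rb.prep_cohort(eyes)
    kept = {e.eye_id for e in prepped}
    kept_truths = [t for e, t in zip(eyes, truths) if e.eye_id in kept]
    return prepped, kept_truths, stats


@pytest.fixture(scope="session")
def tiny_hp():
    """Desk-scale hyperparameters for fast training in unit tests."""
    return CVAEHyperParams(channels=(8, 16), fc_width=32, latent_vp=4,
                           latent_nfl=8, max_epochs=12, patience=12)


@pytest.fixture(scope="session")
def trained_mag_small(prepped_small, tiny_hp):
    """A small but genuinely trained MAG model shared across tests."""
    prepped, truths, stats = prepped_small
    model, log = train_model(prepped, "mag", tiny_hp, seed=1, stats=stats)
    return model, log


@pytest.fixture(scope="session")
def heldout_split():
    """Train/test participant-grouped split of a 300-participant cohort,
    shared by the training-quality and generation tests."""
    cfg = rb.SimConfig(n_participants=300, seed=7)
    eyes, truths = rb.generate_cohort(cfg)
    pids = sorted({e.participant_id for e in eyes})
    rng = np.random.default_rng(0)
    rng.shuffle(pids)
    test_p = set(pids[:60])
    train_raw = [e for e in eyes if e.participant_id not in test_p]
    test_raw = [e for e in eyes if e.participant_id in test_p]
    pop = PopulationStats.from_records(train_raw)
    train, stats, _ = rb.prep_cohort(train_raw, population_stats=pop)
    test, _, _ = rb.prep_cohort(test_raw, stats=stats, population_stats=pop)
    tmap = {e.eye_id: t for e, t in zip(eyes, truths)}
    return train, test, stats, tmap


@pytest.fixture(scope="session")
def trained_mag_heldout(heldout_split):
    """MAG model trained on the held-out split's training half."""
    train, test, stats, tmap = heldout_split
    hp = CVAEHyperParams(max_epochs=60, patience=15)
    model, log = train_model(train, "mag", hp, seed=3, stats=stats)
    return model, log
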