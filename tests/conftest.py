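import pytest

from adspeech import synthetic


@pytest.fixture(scope="session")
def freq_tables():
    """Toy reference n-gram tables shared across tests (20 tables)."""
    return synthetic.build_toy_frequency_tables(seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    """Ten-per-group synthetic transcript cohort with gold annotation."""
    return synthetic.generate_transcript_cohort(
        synthetic.ad_speech_params(), synthetic.chc_speech_params(),
        n_per_group=10, seed=7)


@pytest.fixture(scope="session")
def planted_cohort():
    """Feature-level cohort with d=1.5 planted on the seven default
    effect features (22 per group)."""
    cfg = synthetic.CohortConfig(
        n_per_group=22, effect_features=synthetic.DEFAULT_EFFECT_FEATURES,
        effect_size=1.5, seed=0)
    return synthetic.generate_feature_cohort(cfg)
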