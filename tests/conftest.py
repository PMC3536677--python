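import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_config():
    """Three well-separated planted clusters, 60 transcripts."""
    from notchpulse import synth

    return synth.SynthConfig(
        n_genes=60,
        cluster_spec=(("early_up", 2.0, 20), ("down", -1.5, 20), ("flat", 0.0, 20)),
        seed=101,
    )


@pytest.fixture(scope="session")
def chip_setup():
    """Gene models plus Su(H)/Pol II tracks with planted truth."""
    from notchpulse import synth

    cfg = synth.SynthConfig(
        n_genes=40, cluster_spec=(("early_up", 2.0, 40),), seed=202
    )
    transcripts, genome_length = synth.gen_gene_models(cfg)
    tracks, truth = synth.gen_chip(cfg, transcripts, genome_length)
    return cfg, transcripts, tracks, truth
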