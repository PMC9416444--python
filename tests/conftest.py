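import numpy as np
import pytest

from emats import corpus_io, synthetic


@pytest.fixture(scope="session")
def tiny_corpus():
    """3 speakers x 8 short sentences with default planted structure, split 2/2/4."""
    cfg = synthetic.SimConfig(
        n_speakers=3, n_sentences=8, duration_range=(0.6, 0.9), seed=7, gl_iters=24
    )
    corpora, profiles = synthetic.generate_corpus(cfg)
    corpora = [corpus_io.make_splits(c, n_test=2, n_val=2, seed=7) for c in corpora]
    return corpora, profiles


@pytest.fixture(scope="session")
def clean_corpus():
    """2 speakers x 4 sentences, planted transforms but no sensor noise."""
    cfg = synthetic.SimConfig(
        n_speakers=2, n_sentences=4, duration_range=(0.6, 0.8), seed=3, gl_iters=8
    )
    rng = np.random.default_rng(3)
    profiles = synthetic.random_profiles(2, rng, noise_sd=0.0)
    corpora, profiles = synthetic.generate_corpus(cfg, profiles)
    return corpora, profiles
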