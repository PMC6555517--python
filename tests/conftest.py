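import numpy as np
import pytest

from cstm import corpus as corpus_mod
from cstm import encoder as encoder_mod
from cstm import frontend as frontend_mod


@pytest.fixture(scope="session")
def tiny_corpus():
    """A 20-word, 2-voice, 5-word monosyllabic corpus at 8 kHz."""
    vocab = corpus_mod.make_vocabulary(5, 1, seed=7)
    voices = corpus_mod.make_voice_set(2, seed=7)
    spec = corpus_mod.CorpusSpec(vocab, voices, total_words=20, sample_rate=8000, seed=7)
    audio, track = corpus_mod.render_corpus(spec)
    return {"spec": spec, "audio": audio, "track": track}


@pytest.fixture(scope="session")
def tiny_stream(tiny_corpus):
    config = frontend_mod.FrontEndConfig(sample_rate=8000)
    return frontend_mod.process_audio(tiny_corpus["audio"], config)


@pytest.fixture()
def small_encoder_config():
    """3x3 columns of 5x5 units: sparse = 1 unit, massive = 5 units."""
    return encoder_mod.EncoderConfig(
        grid_shape=(3, 3),
        unit_shape=(5, 5),
        afferent_inputs=10,
        lateral_rf=(3, 3),
        linked_fraction=0.9,
        potential_per_dendrite=6,
        sparsity=0.96,
        proximal_activation_pct=0.2,
        enable_random_behaviour=False,
    )


def make_stream(values, sample_rate=16000):
    """Wrap raw (T, 5, 128) values as a determined FrameStream."""
    values = np.asarray(values, dtype=float)
    return frontend_mod.FrameStream(
        values=values,
        undetermined=np.zeros_like(values, dtype=bool),
        times=0.008 * (np.arange(len(values)) + 1),
        config=frontend_mod.FrontEndConfig(sample_rate=sample_rate),
    )
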