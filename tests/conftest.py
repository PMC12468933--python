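import numpy as np
import pytest

from abcurriculum import GeneratorConfig, generate, encode
from abcurriculum.model import EncoderConfig, TransformerEncoder


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small mixed repertoire: 12 paired + 10 heavy + 10 light records."""
    return generate(GeneratorConfig(
        n_paired=12, n_unpaired_heavy=10, n_unpaired_light=10,
        memory_fraction=0.5, seed=11))


@pytest.fixture(scope="session")
def paired_records():
    return generate(GeneratorConfig(n_paired=40, memory_fraction=0.5, seed=7))


@pytest.fixture(scope="session")
def tiny_encoder():
    return TransformerEncoder(EncoderConfig.tiny(), seed=0)


@pytest.fixture(scope="session")
def encoded_paired(paired_records):
    return [encode(r, dialect="cls", pad_to=256) for r in paired_records[:8]]
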