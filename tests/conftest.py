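import pytest

from clinlink import (
    PipelineConfig,
    QType,
    SynthSpec,
    aggregate_concepts,
    build_index,
    gen_notes,
    gen_vocab,
)


@pytest.fixture(scope="session")
def synth_world():
    """A mid-size synthetic world with homonyms and translation cases."""
    spec = SynthSpec(seed=11, n_concepts=40, n_notes=30, homonym_rate=0.2, typo_rate=0.0)
    vocab = gen_vocab(spec)
    corpus = gen_notes(vocab, spec)
    index = build_index(aggregate_concepts(vocab.records))
    return spec, vocab, corpus, index


@pytest.fixture()
def exact_config():
    return PipelineConfig(q_type=QType.EXACT)
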