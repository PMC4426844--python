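import pytest

from litconn.lexicon import merge_synonyms
from litconn.synth import SynthConfig, load_worked_examples, make_corpus, make_lexicon


@pytest.fixture(scope="session")
def synth_setup():
    """Small deterministic corpus + merged lexicon shared across tests."""
    cfg = SynthConfig(n_documents=60, seed=7)
    base, donors = make_lexicon(cfg)
    merged = merge_synonyms(base, donors)
    corpus, true_pairs = make_corpus(cfg, merged)
    return cfg, base, donors, merged, corpus, true_pairs


@pytest.fixture(scope="session")
def worked():
    """Bundled worked sentences, their lexicon and expected pair sets."""
    return load_worked_examples()
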