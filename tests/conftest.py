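import pytest

from cogehr.lexicon import compile_lexicon, default_lexicon
from cogehr.synthetic_ehr import generate_dataset, smoke_small_config

#: One suite-wide seed for stochastic checks: the study-window start date.
SUITE_SEED = 20160101


@pytest.fixture(scope="session")
def lex():
    return default_lexicon()


@pytest.fixture(scope="session")
def cl(lex):
    return compile_lexicon(lex)


@pytest.fixture(scope="session")
def smoke_ds():
    """Small synthetic dataset with decoys enabled (150 patients)."""
    cfg = smoke_small_config().updated({"n_patients": 150})
    return generate_dataset(cfg, seed=7)
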