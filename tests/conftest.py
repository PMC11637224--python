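import pytest

from sbarscore import (
    Lexicon,
    LexiconEntry,
    SynthConfig,
    compile_answer_key,
    generate_corpus,
    regression_fixture,
)


@pytest.fixture(scope="session")
def tiny_lexicon() -> Lexicon:
    """Base pieces at cost 10, as a hand-auditable segmentation playground."""
    return Lexicon(
        [
            LexiconEntry("ultra", "ultra", "noun", 10),
            LexiconEntry("sound", "sound", "noun", 10),
            LexiconEntry("cardiac", "cardiac", "noun", 10),
            LexiconEntry("echo", "echo", "noun", 10),
            LexiconEntry(" ", " ", "other", 1),
        ]
    )


@pytest.fixture(scope="session")
def user_lexicon() -> Lexicon:
    return Lexicon([LexiconEntry("ultrasound", "ultrasound", "noun", 1)])


@pytest.fixture(scope="session")
def fixture_bundle():
    return regression_fixture()


@pytest.fixture(scope="session")
def noiseless_bundle():
    cfg = SynthConfig(
        n_subjects=6, p_include=1.0, p_oov_synonym=0.0, p_misspell=0.0,
        p_fuse=0.0, human_error_fn=0.0, human_error_fp=0.0, seed=11,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_corpus(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def compiled_default(default_bundle):
    return compile_answer_key(default_bundle.answer_key, default_bundle.lexicon)
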