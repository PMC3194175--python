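import pytest

from negex_sv import (
    TriggerCategory,
    TriggerLexicon,
    TriggerPhrase,
    load_builtin_lexicon,
)


@pytest.fixture(scope="session")
def baseline_lexicon() -> TriggerLexicon:
    return load_builtin_lexicon("baseline")


@pytest.fixture(scope="session")
def refined_lexicon() -> TriggerLexicon:
    return load_builtin_lexicon("refined")


@pytest.fixture(scope="session")
def english_mini_lexicon() -> TriggerLexicon:
    """A tiny English lexicon for the classic worked example."""
    return TriggerLexicon(
        [
            TriggerPhrase("no", TriggerCategory.PREN),
            TriggerPhrase("no signs of", TriggerCategory.PREN),
            TriggerPhrase("without", TriggerCategory.PREN),
            TriggerPhrase("unlikely", TriggerCategory.POST),
            TriggerPhrase("not certain if", TriggerCategory.PSEU),
            TriggerPhrase("but", TriggerCategory.CONJ),
        ]
    )
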