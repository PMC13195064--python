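import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import guessability as g

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return g.load_default_table()


@pytest.fixture(scope="session")
def latvian_fixture():
    return g.load_synthetic_lexicon("latvian")


def make_word(concept_id, czech_ipa, foreign_ipa, *, czech_logfreq=3.0,
              foreign_logfreq=3.0, pos="noun", cognate_score=0.0,
              embedding=None, table=None):
    """Small WordRecord factory with consistent segment counts."""
    tab = table or g.load_default_table()
    return g.WordRecord(
        concept_id=concept_id,
        czech_form=czech_ipa,
        foreign_form=foreign_ipa,
        czech_ipa=czech_ipa,
        foreign_ipa=foreign_ipa,
        czech_len=len(g.segment_ipa(czech_ipa, tab)),
        foreign_len=len(g.segment_ipa(foreign_ipa, tab)),
        czech_logfreq=czech_logfreq,
        foreign_logfreq=foreign_logfreq,
        pos=pos,
        cognate_score=cognate_score,
        embedding=embedding,
    )


@pytest.fixture(scope="session")
def toy_lexicon(table):
    """Six concepts, enough for a full session machinery exercise."""
    words = [
        make_word("w0", "dɛn", "dɪn", cognate_score=1.0, embedding=(1.0, 0.0),
                  czech_logfreq=5.0, foreign_logfreq=4.5, table=table),
        make_word("w1", "smjɛr", "ɦoːkoː", embedding=(0.0, 1.0),
                  czech_logfreq=3.0, foreign_logfreq=2.5, table=table),
        make_word("w2", "voda", "mizu", embedding=(1.0, 1.0),
                  czech_logfreq=4.0, foreign_logfreq=4.2, table=table),
        make_word("w3", "zɛmɲɛ", "zɛmɛ", cognate_score=0.5, embedding=(2.0, 0.5),
                  pos="verb", czech_logfreq=2.0, foreign_logfreq=1.8, table=table),
        make_word("w4", "nɛbɛ", "sora", embedding=(0.5, 2.0),
                  czech_logfreq=1.0, foreign_logfreq=1.5, table=table),
        make_word("w5", "pɛs", "inu", embedding=(1.5, 1.5), pos="adj",
                  czech_logfreq=6.0, foreign_logfreq=5.5, table=table),
    ]
    return g.StudyLexicon(language_pair="czech-toy", records=tuple(words))
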