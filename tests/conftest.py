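import numpy as np
import pytest

from tagqa.annotation import WordPieceLikeTokenizer
from tagqa.corpus_io import (
    PassageRecord,
    QuestionRecord,
    QuestionType,
    SynonymGroup,
)
from tagqa.synthetic import SyntheticSpec, generate


@pytest.fixture
def tokenizer():
    return WordPieceLikeTokenizer()


@pytest.fixture
def subword_tokenizer():
    return WordPieceLikeTokenizer(max_piece_len=4, lowercase=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def drug_question():
    return QuestionRecord(
        question_id="q-drugs",
        body="Which drugs treat headaches?",
        qtype=QuestionType.LIST,
        gold_answers=(
            SynonymGroup.of("aspirin"),
            SynonymGroup.of("ibuprofen", "Advil"),
        ),
        passage_refs=("p1",),
    )


@pytest.fixture
def drug_passage():
    return PassageRecord(
        passage_id="p1",
        title="Analgesics.",
        abstract="Common options are aspirin and ibuprofen for most patients.",
    )


@pytest.fixture
def small_corpus():
    return generate(
        SyntheticSpec(
            n_questions=12,
            answers_per_question=(1, 2, 3),
            passages_per_question=2,
            synonym_probability=0.4,
            seed=7,
        )
    )
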