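"""Deterministic synthetic QA corpora with planted multi-answer questions.

Every generated question is a list-type (or factoid, when a question has
exactly one answer and ``factoid_singletons`` is set) question whose
pseudo-entity answers are embedded verbatim in each of its passages
among distractor sentences.  Ground-truth character spans are emitted
alongside for white-box tests.  Vocabularies are built so that no answer
string can occur by accident: entity words are 8-character capitalized
pseudo-words, distractor words are at most 5 characters, and answers are
space-separated entity-word pairs or triples that only ever appear where
they were planted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import (
    PassageRecord,
    QuestionRecord,
    QuestionType,
    SynonymGroup,
    abstract_offset,
)

__all__ = ["SyntheticSpec", "PlantedSpan", "SyntheticCorpus", "PlantReport", "generate", "plant_check"]

_ENTITY_SYLLABLES = (
    "za ve ro ku mi xa po tr dn fl gr lu qi wy sh bl ck mp st vr"
).split()
_DISTRACTOR_SYLLABLES = "ba lo ti ne mu sa ri do pe ga hu fe ce nu".split()
_CATEGORIES = ("agents", "factors", "markers", "proteins", "compounds", "pathways")
_LEAD_TEMPLATES = (
    "The {0} {1} remained {2} during the {3} phase .",
    "Earlier {0} reports described {1} changes in {2} levels .",
    "A {0} cohort showed {1} variation under {2} conditions .",
    "Measurements of {0} and {1} were stable across {2} sites .",
)
_CUE_TEMPLATES = (
    "Reported {category} include ",
    "Relevant {category} include ",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated corpus; the seed is mandatory.

    ``answers_per_question`` is either a point mass (an int) or a tuple
    of counts sampled uniformly.
    """

    n_questions: int
    answers_per_question: int | tuple[int, ...] = (1, 2, 3, 4)
    passages_per_question: int = 2
    distractor_vocab_size: int = 120
    entity_vocab_size: int = 80
    synonym_probability: float = 0.0
    answer_words: int = 2
    hard_mode: bool = False
    factoid_singletons: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = self.answer_counts
        if self.n_questions < 1 or self.passages_per_question < 1:
            raise ValueError("counts must be positive")
        if not counts or any(c < 1 for c in counts):
            raise ValueError("answers-per-question counts must be positive")
        if not (0.0 <= self.synonym_probability <= 1.0):
            raise ValueError("synonym_probability must lie in [0, 1]")
        if self.answer_words not in (2, 3):
            raise ValueError("answers are 2- or 3-word phrases")
        if max(counts) * self.answer_words > self.entity_vocab_size:
            raise ValueError(
                "entity vocabulary too small to guarantee distinct answers "
                f"({max(counts) * self.answer_words} words needed per "
                f"question, vocabulary holds {self.entity_vocab_size})"
            )

    @property
    def answer_counts(self) -> tuple[int, ...]:
        if isinstance(self.answers_per_question, int):
            return (self.answers_per_question,)
        return tuple(self.answers_per_question)


@dataclass(frozen=True)
class PlantedSpan:
    """Ground truth: one planted answer occurrence in passage coordinates."""

    group_index: int
    text: str
    start: int
    end: int


@dataclass(frozen=True)
class SyntheticCorpus:
    spec: SyntheticSpec
    questions: tuple[QuestionRecord, ...]
    passages: tuple[PassageRecord, ...]
    #: (question_id, passage_id) -> planted spans
    truth: dict[tuple[str, str], tuple[PlantedSpan, ...]]

    def passages_by_id(self) -> dict[str, PassageRecord]:
        return {p.passage_id: p for p in self.passages}


@dataclass(frozen=True)
class PlantReport:
    ok: bool
    failures: tuple[str, ...]
    answer_count_frequencies: dict[int, int] = field(default_factory=dict)


def _make_vocab(rng: random.Random, syllables: Sequence[str], n_syl: int,
                size: int, capitalize: bool = False) -> list[str]:
    words: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(words) < size:
        attempts += 1
        if attempts > 100 * size:
            raise ValueError("vocabulary too small for requested size")
        w = "".join(rng.choice(syllables) for _ in range(n_syl))
        if capitalize:
            w = w.capitalize()
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def generate(spec: SyntheticSpec) -> SyntheticCorpus:
    """Generate a corpus; byte-identical output for identical specs."""
    rng = random.Random(spec.seed)
    distractors = _make_vocab(
        rng, _DISTRACTOR_SYLLABLES, 2, spec.distractor_vocab_size
    )
    entities = _make_vocab(
        rng, _ENTITY_SYLLABLES, 4, spec.entity_vocab_size, capitalize=True
    )
    topics = _make_vocab(rng, _ENTITY_SYLLABLES, 3, max(spec.n_questions, 8),
                         capitalize=True)

    questions: list[QuestionRecord] = []
    passages: list[PassageRecord] = []
    truth: dict[tuple[str, str], tuple[PlantedSpan, ...]] = {}
    synonym_serial = 0

    for qi in range(spec.n_questions):
        qid = f"synth-q{qi}"
        k = rng.choice(spec.answer_counts)
        category = rng.choice(_CATEGORIES)
        topic = topics[qi % len(topics)]

        words = rng.sample(entities, k * spec.answer_words)
        answers = [
            " ".join(words[a * spec.answer_words : (a + 1) * spec.answer_words])
            for a in range(k)
        ]
        groups: list[list[str]] = [[a] for a in answers]
        synonyms: dict[int, str] = {}
        for gi, answer in enumerate(answers):
            if rng.random() < spec.synonym_probability:
                synonym_serial += 1
                parts = answer.split()
                abbrev = "".join(p[0] for p in parts) + f"-{synonym_serial}"
                groups[gi].append(abbrev)
                synonyms[gi] = abbrev
            if spec.hard_mode and rng.random() < 0.5:
                # a strict-prefix variant exercises longest-leftmost matching
                prefix = answer.rsplit(" ", 1)[0]
                if prefix not in groups[gi]:
                    groups[gi].append(prefix)

        refs = []
        for pj in range(spec.passages_per_question):
            pid = f"synth-q{qi}-p{pj}"
            refs.append(pid)
            title = f"Observations on {topic} ."
            plants: list[tuple[int, str, int]] = []  # (group, text, offset-in-abstract)
            abstract = ""

            def emit(sentence: str) -> int:
                nonlocal abstract
                start = len(abstract)
                abstract += sentence if not abstract else " " + sentence
                return len(abstract) - len(sentence)

            for _ in range(rng.randint(1, 2)):
                tpl = rng.choice(_LEAD_TEMPLATES)
                emit(tpl.format(*(rng.choice(distractors) for _ in range(4))))

            cue = rng.choice(_CUE_TEMPLATES).format(category=category)
            if k == 1:
                body_txt = answers[0] + " ."
            else:
                body_txt = ", ".join(answers[:-1]) + " and " + answers[-1] + " ."
            sent = cue + body_txt
            sent_off = emit(sent)
            pos = sent_off + len(cue)
            for gi, answer in enumerate(answers):
                plants.append((gi, answer, pos))
                pos += len(answer)
                pos += len(" .") if gi == k - 1 else (
                    len(" and ") if gi == k - 2 else len(", ")
                )

            for gi, abbrev in synonyms.items():
                if rng.random() < 0.5 or pj == 0:
                    syn_sent_prefix = "This group is also termed "
                    off = emit(syn_sent_prefix + abbrev + " .")
                    plants.append((gi, abbrev, off + len(syn_sent_prefix)))

            tpl = rng.choice(_LEAD_TEMPLATES)
            emit(tpl.format(*(rng.choice(distractors) for _ in range(4))))

            passage = PassageRecord(passage_id=pid, title=title, abstract=abstract)
            base = abstract_offset(title)
            truth[(qid, pid)] = tuple(
                PlantedSpan(gi, text, base + off, base + off + len(text))
                for gi, text, off in plants
            )
            passages.append(passage)

        qtype = QuestionType.LIST
        if spec.factoid_singletons and k == 1:
            qtype = QuestionType.FACTOID
        body = f"Which {category} are associated with {topic} ?"
        questions.append(
            QuestionRecord(
                question_id=qid,
                body=body,
                qtype=qtype,
                gold_answers=tuple(SynonymGroup(tuple(g)) for g in groups),
                passage_refs=tuple(refs),
            )
        )

    return SyntheticCorpus(
        spec=spec,
        questions=tuple(questions),
        passages=tuple(passages),
        truth=truth,
    )


def plant_check(corpus: SyntheticCorpus) -> PlantReport:
    """Verify planted truth against the corpus.

    Checks that every truth span slices to its answer string, that every
    gold answer is recoverable by exact search in every linked passage,
    and that the empirical answers-per-question distribution matches the
    spec (exactly for a point mass, within 3 standard errors otherwise).
    """
    failures: list[str] = []
    by_id = corpus.passages_by_id()
    counts: dict[int, int] = {}

    for q in corpus.questions:
        counts[len(q.gold_answers)] = counts.get(len(q.gold_answers), 0) + 1
        for pid in q.passage_refs:
            text = by_id[pid].text
            for span in corpus.truth.get((q.question_id, pid), ()):
                if text[span.start : span.end] != span.text:
                    failures.append(
                        f"{q.question_id}/{pid}: span ({span.start}, {span.end}) "
                        f"slices to {text[span.start:span.end]!r}, "
                        f"expected {span.text!r}"
                    )
            for group in q.gold_answers:
                if group.variants[0] not in text:
                    failures.append(
                        f"{q.question_id}/{pid}: answer "
                        f"{group.variants[0]!r} not found"
                    )

    allowed = corpus.spec.answer_counts
    n = len(corpus.questions)
    if len(allowed) == 1:
        if set(counts) != {allowed[0]}:
            failures.append(
                f"point-mass spec {allowed[0]} violated: counts {counts}"
            )
    else:
        p = 1.0 / len(allowed)
        se = (p * (1 - p) / n) ** 0.5
        for c in allowed:
            freq = counts.get(c, 0) / n
            if abs(freq - p) > 3 * se + 1e-12:
                failures.append(
                    f"answers-per-question={c}: frequency {freq:.4f} outside "
                    f"3 SE of {p:.4f}"
                )
        for c in counts:
            if c not in allowed:
                failures.append(f"unexpected answer count {c}")

    return PlantReport(
        ok=not failures,
        failures=tuple(failures),
        answer_count_frequencies=counts,
    )
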