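"""Reading, writing and sample construction for QA corpora.

Supports a BioASQ task-b style JSON dialect (a ``questions`` array plus an
inline ``passages`` array carrying title/abstract text, since passages are
supplied as text rather than fetched from URLs) and SQuAD v1 JSON (read
only; every question is mapped to a factoid record with one synonym group).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "QuestionType",
    "SynonymGroup",
    "QuestionRecord",
    "PassageRecord",
    "Sample",
    "SampleConfig",
    "CorpusFormatError",
    "PASSAGE_SEPARATOR",
    "build_passage_text",
    "abstract_offset",
    "read_bioasq",
    "write_bioasq",
    "read_squad",
    "build_samples",
]

#: Separator used to join a passage title and abstract into one string.
PASSAGE_SEPARATOR = " "


class CorpusFormatError(ValueError):
    """Raised when a corpus file violates the expected JSON dialect."""


class QuestionType(str, Enum):
    FACTOID = "factoid"
    LIST = "list"
    YESNO = "yesno"
    SUMMARY = "summary"

    @property
    def supports_tagging(self) -> bool:
        """Whether this question type has extractive (taggable) answers."""
        return self in (QuestionType.FACTOID, QuestionType.LIST)


def _normalize_variant(text: str) -> str:
    return " ".join(text.lower().split())


@dataclass(frozen=True)
class SynonymGroup:
    """Surface variants (synonyms, abbreviations) naming one gold answer."""

    variants: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("SynonymGroup requires at least one variant")
        if any(not v.strip() for v in self.variants):
            raise ValueError("SynonymGroup variants must be non-empty")
        normalized = [_normalize_variant(v) for v in self.variants]
        if len(set(normalized)) != len(normalized):
            raise ValueError(
                f"SynonymGroup variants must be distinct after "
                f"normalization: {self.variants!r}"
            )

    @classmethod
    def of(cls, *variants: str) -> "SynonymGroup":
        return cls(tuple(variants))


@dataclass(frozen=True)
class QuestionRecord:
    """One question with its gold answers and linked passages."""

    question_id: str
    body: str
    qtype: QuestionType
    gold_answers: tuple[SynonymGroup, ...] = ()
    passage_refs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.body.strip():
            raise ValueError(f"question {self.question_id!r}: empty body")
        if self.qtype is QuestionType.FACTOID and len(self.gold_answers) != 1:
            raise ValueError(
                f"question {self.question_id!r}: factoid questions carry "
                f"exactly one synonym group, got {len(self.gold_answers)}"
            )
        if self.qtype is QuestionType.LIST and not self.gold_answers:
            raise ValueError(
                f"question {self.question_id!r}: list questions need at "
                f"least one synonym group"
            )


@dataclass(frozen=True)
class PassageRecord:
    """A passage built from a title/abstract pair."""

    passage_id: str
    title: str
    abstract: str
    text: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "text", build_passage_text(self.title, self.abstract)
        )


class SampleConfig(str, Enum):
    """How question/passage/answer triplets are expanded into samples."""

    SINGLE_SPAN = "single_span"
    SEQ_TAG = "seq_tag"


@dataclass(frozen=True)
class Sample:
    """A question-passage pair with its matched answer span targets.

    ``spans`` holds ``(CharSpan, group_index)`` pairs into the passage
    text.  Under the sequence-tagging configuration one sample carries all
    matched spans of the passage; under the single-span configuration each
    sample carries exactly one span.
    """

    question_id: str
    passage_id: str
    spans: tuple = ()
    config: SampleConfig = SampleConfig.SEQ_TAG

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError("Sample must reference at least one matched span")
        if self.config is SampleConfig.SINGLE_SPAN and len(self.spans) != 1:
            raise ValueError("single_span samples carry exactly one span")


def build_passage_text(title: str, abstract: str) -> str:
    """Join title and abstract into the passage string.

    The join rule is ``title + " " + abstract`` when both parts are
    non-empty, otherwise the non-empty part alone; abstract character
    ``i`` lands at passage offset ``abstract_offset(title) + i``.
    """
    if not title and not abstract:
        raise ValueError("both title and abstract are empty")
    if not title:
        return abstract
    if not abstract:
        return title
    return title + PASSAGE_SEPARATOR + abstract


def abstract_offset(title: str) -> int:
    """Offset of the first abstract character within the passage text."""
    return len(title) + len(PASSAGE_SEPARATOR) if title else 0


# ---------------------------------------------------------------------------
# BioASQ dialect
# ---------------------------------------------------------------------------

def _passage_ref_from_document(doc: str) -> str:
    # Accept either bare identifiers or PubMed-style URLs; the trailing
    # path segment is the identifier.
    return doc.rstrip("/").rsplit("/", 1)[-1]


def _parse_exact_answer(raw, qtype: QuestionType, idx: int) -> tuple[SynonymGroup, ...]:
    try:
        if qtype is QuestionType.FACTOID:
            if isinstance(raw, str):
                raw = [raw]
            # flat array of variant strings -> one group
            if raw and isinstance(raw[0], list):
                # some dumps wrap factoid answers one level deeper
                raw = raw[0]
            return (SynonymGroup(tuple(str(v) for v in raw)),)
        groups = []
        for inner in raw:
            if isinstance(inner, str):
                inner = [inner]
            groups.append(SynonymGroup(tuple(str(v) for v in inner)))
        return tuple(groups)
    except (TypeError, ValueError, IndexError) as exc:
        raise CorpusFormatError(
            f"question #{idx}: malformed exact_answer {raw!r}: {exc}"
        ) from exc


def read_bioasq(path) -> tuple[list[QuestionRecord], list[PassageRecord]]:
    """Read a BioASQ-dialect corpus file.

    Returns questions in file order and the passage records declared in
    the file's ``passages`` array.  Factoid ``exact_answer`` (flat string
    array) becomes one synonym group; list ``exact_answer`` (array of
    string arrays) becomes one group per inner array.  yes/no and summary
    questions are parsed but carry no gold answer groups.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "questions" not in payload:
        raise CorpusFormatError(f"{path}: missing top-level 'questions' array")

    passages = []
    for entry in payload.get("passages", []):
        passages.append(
            PassageRecord(
                passage_id=str(entry["passage_id"]),
                title=entry.get("title", ""),
                abstract=entry.get("abstract", ""),
            )
        )

    questions = []
    for idx, entry in enumerate(payload["questions"]):
        if not isinstance(entry, dict) or "body" not in entry or "type" not in entry:
            raise CorpusFormatError(
                f"question #{idx}: entries require 'body' and 'type'"
            )
        try:
            qtype = QuestionType(entry["type"])
        except ValueError as exc:
            raise CorpusFormatError(
                f"question #{idx}: unknown question type {entry['type']!r}"
            ) from exc
        gold: tuple[SynonymGroup, ...] = ()
        if qtype.supports_tagging:
            if "exact_answer" not in entry:
                raise CorpusFormatError(
                    f"question #{idx}: {qtype.value} question is missing "
                    f"'exact_answer'"
                )
            gold = _parse_exact_answer(entry["exact_answer"], qtype, idx)
        refs = tuple(
            _passage_ref_from_document(d) for d in entry.get("documents", ())
        )
        questions.append(
            QuestionRecord(
                question_id=str(entry.get("id", f"q{idx}")),
                body=entry["body"],
                qtype=qtype,
                gold_answers=gold,
                passage_refs=refs,
            )
        )
    return questions, passages


def write_bioasq(
    questions: Iterable[QuestionRecord],
    passages: Iterable[PassageRecord],
    path,
) -> None:
    """Write records in the BioASQ dialect accepted by :func:`read_bioasq`."""
    entries = []
    for q in questions:
        entry = {
            "id": q.question_id,
            "body": q.body,
            "type": q.qtype.value,
            "documents": list(q.passage_refs),
        }
        if q.qtype is QuestionType.FACTOID:
            entry["exact_answer"] = list(q.gold_answers[0].variants)
        elif q.qtype is QuestionType.LIST:
            entry["exact_answer"] = [list(g.variants) for g in q.gold_answers]
        entries.append(entry)
    payload = {
        "questions": entries,
        "passages": [
            {"passage_id": p.passage_id, "title": p.title, "abstract": p.abstract}
            for p in passages
        ],
    }
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# SQuAD v1 (read only)
# ---------------------------------------------------------------------------

def read_squad(path) -> tuple[list[QuestionRecord], list[PassageRecord]]:
    """Read SQuAD v1 JSON as factoid records with one synonym group each.

    Each paragraph context becomes a passage with an empty title, so
    answer offsets in the file remain valid in the passage text.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"{path}: not valid JSON: {exc}") from exc

    questions: list[QuestionRecord] = []
    passages: list[PassageRecord] = []
    for ai, article in enumerate(payload.get("data", [])):
        for pi, para in enumerate(article.get("paragraphs", [])):
            pid = f"squad-{ai}-{pi}"
            passages.append(
                PassageRecord(passage_id=pid, title="", abstract=para["context"])
            )
            for qa in para.get("qas", []):
                texts: list[str] = []
                seen = set()
                for ans in qa.get("answers", []):
                    key = _normalize_variant(ans["text"])
                    if key and key not in seen:
                        seen.add(key)
                        texts.append(ans["text"])
                if not texts:
                    continue
                questions.append(
                    QuestionRecord(
                        question_id=str(qa["id"]),
                        body=qa["question"],
                        qtype=QuestionType.FACTOID,
                        gold_answers=(SynonymGroup(tuple(texts)),),
                        passage_refs=(pid,),
                    )
                )
    return questions, passages


# ---------------------------------------------------------------------------
# Sample construction
# ---------------------------------------------------------------------------

def build_samples(
    questions: Sequence[QuestionRecord],
    passages: Sequence[PassageRecord] | Mapping[str, PassageRecord],
    configuration: SampleConfig | str,
    *,
    match_mode: str = "uncased",
    expand_variants: bool = False,
) -> list[Sample]:
    """Expand questions into question-passage-answer samples.

    Passages in which no gold answer can be located contribute no sample.
    For a question with ``i`` matchable passages and ``j`` matched answer
    groups per passage this yields ``i*j`` samples under ``single_span``
    and ``i`` under ``seq_tag``.

    ``expand_variants`` switches single-span expansion from one sample per
    matched synonym group (the default, giving ``j`` = number of answers)
    to one sample per matched variant occurrence.
    """
    from . import annotation  # deferred to avoid import cycle

    configuration = SampleConfig(configuration)
    if isinstance(passages, Mapping):
        by_id = dict(passages)
    else:
        by_id = {p.passage_id: p for p in passages}

    samples: list[Sample] = []
    for q in questions:
        if not q.qtype.supports_tagging:
            continue
        for ref in q.passage_refs:
            if ref not in by_id:
                raise KeyError(
                    f"question {q.question_id!r} references unknown "
                    f"passage {ref!r}"
                )
            passage = by_id[ref]
            matches = annotation.find_answer_spans(
                passage.text, q.gold_answers, match_mode=match_mode
            )
            if not matches:
                continue
            if configuration is SampleConfig.SEQ_TAG:
                samples.append(
                    Sample(
                        question_id=q.question_id,
                        passage_id=passage.passage_id,
                        spans=tuple(matches),
                        config=configuration,
                    )
                )
            else:
                if expand_variants:
                    chosen = list(matches)
                else:
                    # first (leftmost) matched occurrence per group
                    first_by_group: dict[int, tuple] = {}
                    for span, gi in matches:
                        first_by_group.setdefault(gi, (span, gi))
                    chosen = [first_by_group[gi] for gi in sorted(first_by_group)]
                for span, gi in chosen:
                    samples.append(
                        Sample(
                            question_id=q.question_id,
                            passage_id=passage.passage_id,
                            spans=((span, gi),),
                            config=configuration,
                        )
                    )
    return samples
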