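"""List-question P/R/F1, factoid MRR and answer-count analyses.

Metrics are an independent reimplementation of the challenge-style
scoring: per list question each gold synonym group may be matched by at
most one prediction, scores are macro-averaged over questions, and the
factoid metric is mean reciprocal rank within a rank cap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus_io import QuestionRecord, QuestionType, SynonymGroup
from .decoding import QuestionPrediction, normalize_text

__all__ = [
    "ListEvalResult",
    "FactoidEvalResult",
    "DistributionReport",
    "match_answer",
    "eval_list",
    "eval_factoid_mrr",
    "answer_count_report",
    "question_contains_number",
    "to_submission_json",
]


@dataclass(frozen=True)
class ListEvalResult:
    per_question: dict[str, tuple[float, float, float]]
    precision: float
    recall: float
    f1: float
    n_questions: int


@dataclass(frozen=True)
class FactoidEvalResult:
    per_question: dict[str, float]
    mrr: float
    n_questions: int


@dataclass(frozen=True)
class DistributionReport:
    """Histograms of answers-per-question with half-open bins [1,3), [3,5)…

    Questions with zero answers are excluded from the histograms and
    counted separately.
    """

    bin_width: int
    predicted: dict[int, int] = field(default_factory=dict)  # bin start -> count
    gold: dict[int, int] = field(default_factory=dict)
    predicted_zero: int = 0
    gold_zero: int = 0

    @staticmethod
    def _modal(hist: Mapping[int, int]) -> int | None:
        if not hist:
            return None
        return min(hist, key=lambda b: (-hist[b], b))

    @property
    def predicted_modal_bin(self) -> int | None:
        return self._modal(self.predicted)

    @property
    def gold_modal_bin(self) -> int | None:
        return self._modal(self.gold)


def match_answer(prediction_text: str, group: SynonymGroup) -> bool:
    """True iff the prediction equals any variant after normalization."""
    pred = normalize_text(prediction_text)
    return any(pred == normalize_text(v) for v in group.variants)


def _index_gold(gold_questions: Sequence[QuestionRecord]) -> dict[str, QuestionRecord]:
    return {q.question_id: q for q in gold_questions}


def _max_matching(
    prediction_texts: Sequence[str], groups: Sequence[SynonymGroup]
) -> int:
    """Maximum one-to-one matching between predictions and gold groups.

    Augmenting-path search; problem sizes are tiny (answers per
    question), so no sophistication is needed.
    """
    match_of_group: dict[int, int] = {}

    def augment(pi: int, visited: set[int]) -> bool:
        for gi, group in enumerate(groups):
            if gi in visited or not match_answer(prediction_texts[pi], group):
                continue
            visited.add(gi)
            if gi not in match_of_group or augment(match_of_group[gi], visited):
                match_of_group[gi] = pi
                return True
        return False

    for pi in range(len(prediction_texts)):
        augment(pi, set())
    return len(match_of_group)


def eval_list(
    predictions: Sequence[QuestionPrediction],
    gold_questions: Sequence[QuestionRecord],
) -> ListEvalResult:
    """Macro-averaged precision/recall/F1 over list questions.

    Per question: each gold synonym group may be matched by at most one
    prediction; TP is the number of matched groups, precision divides by
    the number of predictions (0 when there are none) and recall by the
    number of groups.  F1 is the per-question harmonic mean, 0 when
    P + R = 0.
    """
    by_id = _index_gold(gold_questions)
    per_question: dict[str, tuple[float, float, float]] = {}
    for pred in predictions:
        if pred.question_id not in by_id:
            raise KeyError(f"prediction for unknown question {pred.question_id!r}")
        gold = by_id[pred.question_id]
        if gold.qtype is not QuestionType.LIST:
            raise ValueError(
                f"question {pred.question_id!r} is {gold.qtype.value}, not list"
            )
        tp = _max_matching(pred.answer_texts, gold.gold_answers)
        n_pred = len(pred.answers)
        p = tp / n_pred if n_pred else 0.0
        r = tp / len(gold.gold_answers)
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        per_question[pred.question_id] = (p, r, f)

    n = len(per_question)
    if n == 0:
        return ListEvalResult({}, 0.0, 0.0, 0.0, 0)
    precision = sum(v[0] for v in per_question.values()) / n
    recall = sum(v[1] for v in per_question.values()) / n
    f1 = sum(v[2] for v in per_question.values()) / n
    return ListEvalResult(per_question, precision, recall, f1, n)


def eval_factoid_mrr(
    predictions: Sequence[QuestionPrediction],
    gold_questions: Sequence[QuestionRecord],
    k: int = 5,
) -> FactoidEvalResult:
    """Mean reciprocal rank of the first correct answer within the top-k."""
    by_id = _index_gold(gold_questions)
    per_question: dict[str, float] = {}
    for pred in predictions:
        if pred.question_id not in by_id:
            raise KeyError(f"prediction for unknown question {pred.question_id!r}")
        gold = by_id[pred.question_id]
        rr = 0.0
        for rank, text in enumerate(pred.answer_texts[:k], start=1):
            if any(match_answer(text, g) for g in gold.gold_answers):
                rr = 1.0 / rank
                break
        per_question[pred.question_id] = rr
    n = len(per_question)
    mrr = sum(per_question.values()) / n if n else 0.0
    return FactoidEvalResult(per_question, mrr, n)


def answer_count_report(
    predictions: Sequence[QuestionPrediction],
    gold_questions: Sequence[QuestionRecord],
    bin_width: int = 2,
) -> DistributionReport:
    """Histogram answers-per-question (predicted vs gold) in width-2 bins."""
    report = DistributionReport(bin_width=bin_width)

    def bin_start(count: int) -> int:
        return 1 + ((count - 1) // bin_width) * bin_width

    for pred in predictions:
        n = len(pred.answers)
        if n == 0:
            object.__setattr__(report, "predicted_zero", report.predicted_zero + 1)
        else:
            b = bin_start(n)
            report.predicted[b] = report.predicted.get(b, 0) + 1
    for q in gold_questions:
        n = len(q.gold_answers)
        if n == 0:
            object.__setattr__(report, "gold_zero", report.gold_zero + 1)
        else:
            b = bin_start(n)
            report.gold[b] = report.gold.get(b, 0) + 1
    return report


_NUMBER_WORDS = (
    "one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen sixteen seventeen eighteen nineteen twenty"
).split()
_DIGIT_RE = re.compile(r"\d")
_WORD_RE = re.compile(r"[a-z]+")


def question_contains_number(question_text: str) -> bool:
    """Detect a digit or spelled-out cardinal (one..twenty) in a question."""
    if _DIGIT_RE.search(question_text):
        return True
    words = set(_WORD_RE.findall(question_text.lower()))
    return any(w in words for w in _NUMBER_WORDS)


def to_submission_json(predictions: Sequence[QuestionPrediction]) -> dict:
    """Predictions in the challenge submission shape, for external scoring."""
    return {
        "questions": [
            {
                "id": p.question_id,
                "exact_answer": [[a.text] for a in p.answers],
            }
            for p in predictions
        ]
    }
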