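"""From predicted tag sequences to ranked answer strings.

Candidate text is recovered by slicing the original passage with
character offsets, so sub-word reconstruction and punctuation spacing
are exact by construction.  Candidates from all passages of a question
are concatenated, deduplicated and ranked by score; there is no
probability threshold and no cap on the number of answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import annotation
from .annotation import B, CharSpan, I, O, TokenizedInput  # noqa: F401

__all__ = [
    "AnswerCandidate",
    "QuestionPrediction",
    "labels_to_spans",
    "detokenize",
    "span_confidence_softmax",
    "span_confidence_crf",
    "decode_candidates",
    "aggregate",
    "normalize_text",
    "threshold_filter",
]


def normalize_text(text: str) -> str:
    """Dedup/match normalization: lowercase, trim, collapse whitespace."""
    return " ".join(text.lower().split())


@dataclass(frozen=True)
class AnswerCandidate:
    """One decoded answer with its confidence and provenance."""

    text: str
    score: float
    passage_id: str = ""


@dataclass(frozen=True)
class QuestionPrediction:
    """Ranked, deduplicated answers for one question."""

    question_id: str
    answers: tuple[AnswerCandidate, ...] = ()

    @property
    def answer_texts(self) -> tuple[str, ...]:
        return tuple(a.text for a in self.answers)


def labels_to_spans(
    labels: Sequence[int],
    tokenized: TokenizedInput,
) -> list[CharSpan]:
    """Convert tags at the supervised passage positions into char spans.

    ``labels`` must be aligned to ``tokenized.supervised_indices``.  Each
    maximal run starting with B and continuing through I yields one span;
    an I without an open run is repaired to B.  Span ends are extended
    through the sub-word continuation tokens of the run's last word.
    """
    positions = tokenized.supervised_indices
    if len(labels) != len(positions):
        raise ValueError(
            f"{len(labels)} labels for {len(positions)} supervised positions"
        )
    runs: list[list[int]] = []  # runs of supervised-position *indices*
    open_run = False
    for k, lab in enumerate(labels):
        if lab == B:
            runs.append([k])
            open_run = True
        elif lab == I:
            if open_run:
                runs[-1].append(k)
            else:  # orphan I repairs to B
                runs.append([k])
                open_run = True
        else:
            open_run = False

    spans = []
    for run in runs:
        first_tok = positions[run[0]]
        last_tok = positions[run[-1]]
        start = tokenized.char_offsets[first_tok][0]  # type: ignore[index]
        end_tok = last_tok
        # continuation pieces of the last word belong to the span
        j = last_tok + 1
        while (
            j < len(tokenized)
            and tokenized.origins[j] is annotation.TokenOrigin.PASSAGE
            and tokenized.is_continuation[j]
        ):
            end_tok = j
            j += 1
        end = tokenized.char_offsets[end_tok][1]  # type: ignore[index]
        spans.append(CharSpan(start, end))
    return spans


def detokenize(span: CharSpan, passage_text: str) -> str:
    """Recover the literal passage substring covered by a span."""
    if span.end > len(passage_text):
        raise ValueError(
            f"span ({span.start}, {span.end}) exceeds passage length "
            f"{len(passage_text)}"
        )
    return passage_text[span.start : span.end]


def span_confidence_softmax(
    scores: np.ndarray,
    positions: Sequence[int],
    labels: Sequence[int],
) -> float:
    """Mean per-token softmax probability of the predicted labels."""
    from .tagger.loss import softmax

    probs = softmax(np.asarray(scores, dtype=np.float64))
    return float(
        np.mean([probs[p, l] for p, l in zip(positions, labels)])
    )


def span_confidence_crf(
    scores: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    positions: Sequence[int],
    labels: Sequence[int],
) -> float:
    """CRF span confidence: probability mass of paths with this labeling.

    The ratio of the constrained partition (span positions clamped to
    their predicted labels) to the unconstrained partition.
    """
    from .tagger.crf import span_log_marginal

    return float(
        math.exp(
            span_log_marginal(scores, transitions, start, end, positions, labels)
        )
    )


def decode_candidates(
    tagging,
    tokenized: TokenizedInput,
    passage_text: str,
    passage_id: str,
    head=None,
) -> list[AnswerCandidate]:
    """Decode one tagged sequence into scored answer candidates."""
    spans = labels_to_spans(tagging.labels, tokenized)
    positions = tokenized.supervised_indices
    pos_by_index = {p: k for k, p in enumerate(positions)}
    candidates = []
    for span in spans:
        span_positions = [
            p
            for p in positions
            if tokenized.char_offsets[p][0] < span.end  # type: ignore[index]
            and span.start < tokenized.char_offsets[p][1]  # type: ignore[index]
        ]
        span_labels = [tagging.labels[pos_by_index[p]] for p in span_positions]
        if head is not None and getattr(head, "has_crf", False):
            trans, start, end = head.transition_arrays()
            score = span_confidence_crf(
                tagging.scores, trans, start, end, span_positions, span_labels
            )
        else:
            score = span_confidence_softmax(
                tagging.scores, span_positions, span_labels
            )
        candidates.append(
            AnswerCandidate(
                text=detokenize(span, passage_text),
                score=score,
                passage_id=passage_id,
            )
        )
    return candidates


def aggregate(
    question_id: str,
    candidates: Sequence[AnswerCandidate],
) -> QuestionPrediction:
    """Concatenate per-passage candidates into one ranked answer list.

    Candidates equal after normalization are merged keeping the maximum
    score; the result is ordered by descending score then first-seen.
    The list is never truncated to a fixed count.
    """
    best: dict[str, AnswerCandidate] = {}
    order: dict[str, int] = {}
    for cand in candidates:
        key = normalize_text(cand.text)
        if not key:
            continue
        if key not in best:
            best[key] = cand
            order[key] = len(order)
        elif cand.score > best[key].score:
            best[key] = AnswerCandidate(
                text=best[key].text, score=cand.score, passage_id=cand.passage_id
            )
    ranked = sorted(
        best.items(), key=lambda kv: (-kv[1].score, order[kv[0]])
    )
    return QuestionPrediction(
        question_id=question_id, answers=tuple(c for _, c in ranked)
    )


def threshold_filter(
    prediction: QuestionPrediction, threshold: float
) -> QuestionPrediction:
    """Post-hoc probability-threshold filter, for comparison only.

    Scores are renormalized into a probability distribution over the
    candidates and only candidates with mass >= threshold survive, so at
    most floor(1/threshold) answers can remain — the bound this package's
    native decoder deliberately does not have.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    total = sum(a.score for a in prediction.answers)
    if total <= 0:
        return QuestionPrediction(question_id=prediction.question_id)
    kept = tuple(
        a for a in prediction.answers if a.score / total >= threshold
    )
    return QuestionPrediction(question_id=prediction.question_id, answers=kept)
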