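"""End-to-end orchestration: corpus -> instances -> training -> answers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import annotation, corpus_io, decoding
from .annotation import WordPieceLikeTokenizer
from .corpus_io import PassageRecord, QuestionRecord, SampleConfig
from .decoding import QuestionPrediction
from .tagger import HashEmbeddingEncoder, TaggerModel, TrainConfig, TrainingInstance, train

__all__ = ["QAPipeline", "build_instances"]


def build_instances(
    questions: Sequence[QuestionRecord],
    passages: Sequence[PassageRecord] | Mapping[str, PassageRecord],
    tokenizer,
    max_len: int = 512,
    match_mode: str = "uncased",
) -> list[TrainingInstance]:
    """Build labeled sequence-tagging instances, one per matchable passage."""
    if not isinstance(passages, Mapping):
        passages = {p.passage_id: p for p in passages}
    samples = corpus_io.build_samples(
        questions, passages, SampleConfig.SEQ_TAG, match_mode=match_mode
    )
    by_qid = {q.question_id: q for q in questions}
    instances = []
    for sample in samples:
        q = by_qid[sample.question_id]
        passage = passages[sample.passage_id]
        tokenized = annotation.tokenize_and_pack(
            q.body, passage.text, tokenizer, max_len=max_len
        )
        labels = annotation.assign_bio_labels(
            tokenized, [span for span, _ in sample.spans]
        )
        instances.append(TrainingInstance(tokenized=tokenized, labels=labels))
    return instances


@dataclass
class QAPipeline:
    """Train a tagger on QA records and predict ranked answer lists.

    A two-stage transfer schedule is two ``fit`` calls: first on the
    transfer corpus with ``transfer=True`` (higher learning rate), then
    on the target corpus at the fine-tuning rate.
    """

    config: TrainConfig = field(default_factory=TrainConfig)
    encoder: object | None = None
    tokenizer: object | None = None
    max_len: int = 512
    model: TaggerModel | None = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.encoder is None:
            self.encoder = HashEmbeddingEncoder(seed=self.config.seed)
        if self.tokenizer is None:
            self.tokenizer = WordPieceLikeTokenizer(
                max_piece_len=10, lowercase=not self.encoder.cased
            )

    @property
    def match_mode(self) -> str:
        return "cased" if self.encoder.cased else "uncased"

    def fit(
        self,
        questions: Sequence[QuestionRecord],
        passages,
        transfer: bool = False,
    ) -> "QAPipeline":
        instances = build_instances(
            questions, passages, self.tokenizer, self.max_len, self.match_mode
        )
        lr = self.config.transfer_learning_rate if transfer else None
        head = self.model.head if self.model is not None else None
        self.model, stage_log = train(
            instances, self.encoder, self.config, head=head, learning_rate=lr
        )
        self.log.extend(stage_log)
        return self

    def predict(
        self,
        questions: Sequence[QuestionRecord],
        passages,
    ) -> list[QuestionPrediction]:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        if not isinstance(passages, Mapping):
            passages = {p.passage_id: p for p in passages}
        predictions = []
        for q in questions:
            candidates = []
            for ref in q.passage_refs:
                passage = passages[ref]
                tokenized = annotation.tokenize_and_pack(
                    q.body, passage.text, self.tokenizer, max_len=self.max_len
                )
                tagging = self.model.predict(tokenized)
                candidates.extend(
                    decoding.decode_candidates(
                        tagging,
                        tokenized,
                        passage.text,
                        passage.passage_id,
                        head=self.model.head,
                    )
                )
            predictions.append(decoding.aggregate(q.question_id, candidates))
        return predictions
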