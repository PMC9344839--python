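"""Trained tagger state: encoder plus head, with tag prediction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import annotation
from .crf import viterbi_decode
from .loss import softmax

__all__ = ["TaggerModel", "Tagging"]


@dataclass(frozen=True)
class Tagging:
    """Predicted tags at the supervised passage positions of one input.

    ``positions`` are indices into the full token sequence; ``labels``
    and ``probs`` are aligned to them.  ``probs[k]`` is the model's
    probability for the predicted label at position k — the per-token
    softmax for linear/BiLSTM heads, the CRF posterior marginal for the
    CRF head.
    """

    positions: tuple[int, ...]
    labels: tuple[int, ...]
    probs: tuple[float, ...]
    scores: np.ndarray  # (L, 3) unary scores over the full sequence


@dataclass
class TaggerModel:
    encoder: object
    head: object

    def token_scores(self, tokenized: annotation.TokenizedInput) -> np.ndarray:
        return self.head.score(self.encoder.encode(tokenized)).data

    def predict(self, tokenized: annotation.TokenizedInput) -> Tagging:
        """Tag one packed sequence, reporting supervised positions only.

        Tags predicted at special-token, question-token and sub-word
        continuation positions are discarded.  Linear/BiLSTM heads take
        the per-token argmax; the CRF head decodes the full chain with
        the Viterbi algorithm first.
        """
        scores = self.token_scores(tokenized)
        positions = tokenized.supervised_indices
        if self.head.has_crf:
            trans, start, end = self.head.transition_arrays()
            path, _ = viterbi_decode(scores, trans, start, end)
            labels = tuple(path[i] for i in positions)
            from .crf import marginals

            unary_m, _ = marginals(scores, trans, start, end)
            probs = tuple(float(unary_m[i, path[i]]) for i in positions)
        else:
            probs_all = softmax(scores)
            labels = tuple(int(np.argmax(scores[i])) for i in positions)
            probs = tuple(float(probs_all[i, l]) for i, l in zip(positions, labels))
        return Tagging(
            positions=positions,
            labels=labels,
            probs=probs,
            scores=scores,
        )
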