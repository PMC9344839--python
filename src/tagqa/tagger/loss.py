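"""Masked cross-entropy over supervised token positions.

Positions labeled ``IGNORE`` contribute neither loss nor gradient, which
realises the supervision-masking rule: the model is never penalised for
its predictions at special-token, question-token or sub-word
continuation positions.
"""

from __future__ import annotations

import numpy as np

from .. import annotation
from .autograd import Tensor, custom_op

__all__ = ["masked_loss", "masked_ce_sum_op", "softmax"]


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _labels_array(labels) -> np.ndarray:
    if isinstance(labels, annotation.LabeledSequence):
        labels = labels.labels
    return np.asarray(labels, dtype=np.intp)


def masked_loss(scores, labels, mask=None) -> float:
    """Cross-entropy averaged over supervised (non-IGNORE) positions.

    ``mask`` may supply the supervised positions explicitly; by default
    it is derived as ``labels != IGNORE``.  Label values stored at
    masked-out positions never influence the result.  Raises
    ``ValueError`` when every position is masked (a sample without
    supervision) or when lengths disagree.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _labels_array(labels)
    if len(scores) != len(y):
        raise ValueError(
            f"scores ({len(scores)}) and labels ({len(y)}) length mismatch"
        )
    mask = (y != annotation.IGNORE) if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("sample carries no supervised positions")
    probs = softmax(scores[mask])
    picked = probs[np.arange(mask.sum()), y[mask]]
    return float(-np.mean(np.log(picked)))


def masked_ce_sum_op(scores: Tensor, labels) -> tuple[Tensor, int]:
    """Summed cross-entropy over supervised positions, as an autograd node.

    Returns ``(loss_sum, n_supervised)`` so a caller can implement the
    supervised-token-weighted batch mean by dividing summed losses by
    summed counts.
    """
    y = _labels_array(labels)
    mask = y != annotation.IGNORE
    n = int(mask.sum())
    if n == 0:
        raise ValueError("sample carries no supervised positions")
    probs_sup = softmax(scores.data[mask])
    picked = probs_sup[np.arange(n), y[mask]]
    loss_sum = float(-np.sum(np.log(picked)))

    def bw(g):
        grad = np.zeros_like(scores.data)
        local = probs_sup.copy()
        local[np.arange(n), y[mask]] -= 1.0
        grad[mask] = float(g) * local
        return ((scores, grad),)

    return custom_op(np.array(loss_sum), (scores,), bw), n
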