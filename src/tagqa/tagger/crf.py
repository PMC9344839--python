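"""Linear-chain CRF inference: Viterbi, log-partition and marginals.

A path ``y`` over per-token scores ``scores`` (L x K), transition matrix
``transitions`` (K x K) and boundary scores ``start``/``end`` (K,) has

    path_score(y) = start[y_0] + sum_t scores[t, y_t]
                    + sum_t transitions[y_{t-1}, y_t] + end[y_{L-1}]

All recursions run in log space.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .autograd import Tensor, custom_op

__all__ = [
    "path_score",
    "log_partition",
    "viterbi_decode",
    "crf_log_likelihood",
    "marginals",
    "span_log_marginal",
    "crf_nll_op",
]


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("CRF inputs must be finite")


def path_score(scores, transitions, start, end, labels) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = list(labels)
    total = start[labels[0]] + end[labels[-1]]
    total += sum(scores[t, y] for t, y in enumerate(labels))
    total += sum(
        transitions[a, b] for a, b in zip(labels, labels[1:])
    )
    return float(total)


def log_partition(scores, transitions, start, end) -> float:
    """Log of the sum of exponentiated path scores (forward algorithm)."""
    scores = np.asarray(scores, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    _check_finite(scores, transitions, start, end)
    alpha = start + scores[0]
    for t in range(1, len(scores)):
        alpha = logsumexp(alpha[:, None] + transitions, axis=0) + scores[t]
    return float(logsumexp(alpha + end))


def viterbi_decode(scores, transitions, start=None, end=None):
    """Return an argmax-scoring label path and its score.

    Ties are broken deterministically: the backward recursion keeps the
    lowest predecessor label index among equal-scoring extensions, which
    prefers the lower label index at the latest position where two
    optimal paths differ.  An empty score matrix yields an empty path.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        return [], 0.0
    K = scores.shape[1]
    transitions = np.zeros((K, K)) if transitions is None else np.asarray(transitions, dtype=np.float64)
    start = np.zeros(K) if start is None else np.asarray(start, dtype=np.float64)
    end = np.zeros(K) if end is None else np.asarray(end, dtype=np.float64)
    _check_finite(scores, transitions, start, end)

    L = len(scores)
    delta = start + scores[0]
    backptr = np.zeros((L, K), dtype=np.intp)
    for t in range(1, L):
        cand = delta[:, None] + transitions  # (from, to)
        backptr[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta = cand[backptr[t], np.arange(K)] + scores[t]
    delta = delta + end
    best_last = int(np.argmax(delta))
    best_score = float(delta[best_last])

    path = [best_last]
    for t in range(L - 1, 0, -1):
        path.append(int(backptr[t, path[-1]]))
    path.reverse()
    return path, best_score


def crf_log_likelihood(scores, transitions, start, end, labels) -> float:
    """Log-likelihood of a gold path: path score minus log-partition."""
    return path_score(scores, transitions, start, end, labels) - log_partition(
        scores, transitions, start, end
    )


def marginals(scores, transitions, start, end):
    """Posterior marginals via forward-backward.

    Returns ``(unary, pairwise)`` where ``unary[t, k] = P(y_t = k)`` and
    ``pairwise[i, j] = sum_t P(y_{t-1} = i, y_t = j)``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    transitions = np.asarray(transitions, dtype=np.float64)
    L, K = scores.shape
    alpha = np.zeros((L, K))
    alpha[0] = start + scores[0]
    for t in range(1, L):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + transitions, axis=0) + scores[t]
    beta = np.zeros((L, K))
    beta[L - 1] = end
    for t in range(L - 2, -1, -1):
        beta[t] = logsumexp(
            transitions + scores[t + 1] + beta[t + 1], axis=1
        )
    log_z = logsumexp(alpha[L - 1] + end)
    unary = np.exp(alpha + beta - log_z)
    pairwise = np.zeros((K, K))
    for t in range(1, L):
        joint = (
            alpha[t - 1][:, None]
            + transitions
            + scores[t][None, :]
            + beta[t][None, :]
            - log_z
        )
        pairwise += np.exp(joint)
    return unary, pairwise


def span_log_marginal(scores, transitions, start, end, positions, span_labels) -> float:
    """Log-probability that ``positions`` carry ``span_labels``.

    Computed as the clamped log-partition (labels fixed at the given
    positions, free elsewhere) minus the unconstrained log-partition.
    """
    scores = np.asarray(scores, dtype=np.float64)
    clamped = scores.copy()
    neg = -1e30  # effectively -inf without poisoning logsumexp
    for pos, lab in zip(positions, span_labels):
        keep = clamped[pos, lab]
        clamped[pos, :] = neg
        clamped[pos, lab] = keep
    return log_partition(clamped, transitions, start, end) - log_partition(
        scores, transitions, start, end
    )


def crf_nll_op(scores: Tensor, transitions: Tensor, start: Tensor, end: Tensor, labels) -> Tensor:
    """Negative log-likelihood as an autograd node.

    Gradients are the classic CRF expectations: posterior marginals minus
    gold indicators, for unary, transition and boundary scores alike.
    """
    labels = list(labels)
    nll = -crf_log_likelihood(
        scores.data, transitions.data, start.data, end.data, labels
    )

    def bw(g):
        g = float(g)
        unary_m, pair_m = marginals(
            scores.data, transitions.data, start.data, end.data
        )
        L, K = scores.data.shape
        unary_g = unary_m.copy()
        for t, y in enumerate(labels):
            unary_g[t, y] -= 1.0
        pair_g = pair_m.copy()
        for a, b in zip(labels, labels[1:]):
            pair_g[a, b] -= 1.0
        start_g = unary_m[0].copy()
        start_g[labels[0]] -= 1.0
        end_g = unary_m[L - 1].copy()
        end_g[labels[-1]] -= 1.0
        return (
            (scores, g * unary_g),
            (transitions, g * pair_g),
            (start, g * start_g),
            (end, g * end_g),
        )

    return custom_op(np.array(nll), (scores, transitions, start, end), bw)
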