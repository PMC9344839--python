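"""Sequence tagging heads: linear, BiLSTM and BiLSTM-CRF.

Every head maps per-token encoder vectors to per-token scores over the
three tags {B, I, O}.  The CRF variant additionally owns a transition
matrix with start/end boundary scores and is decoded with the Viterbi
algorithm.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, hstack, parameter, vstack

__all__ = ["N_LABELS", "LinearHead", "BiLSTMHead", "BiLSTMCRFHead", "score_tokens", "make_head"]

N_LABELS = 3


class LinearHead:
    """Per-token affine map (the feed-forward tagging layer)."""

    kind = "linear"
    has_crf = False

    def __init__(self, in_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.weight = parameter((in_dim, N_LABELS), rng=rng)
        self.bias = parameter(np.zeros(N_LABELS))

    def score(self, encodings: Tensor) -> Tensor:
        if encodings.data.shape[1] != self.in_dim:
            raise ValueError(
                f"encoder dim {encodings.data.shape[1]} != head dim {self.in_dim}"
            )
        return encodings @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class _LSTMDirection:
    """One direction of an LSTM; separate weight matrices per gate."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = {g: parameter((in_dim, hidden), rng=rng) for g in "ifog"}
        self.wh = {g: parameter((hidden, hidden), rng=rng) for g in "ifog"}
        self.b = {g: parameter(np.zeros(hidden)) for g in "ifog"}

    def run(self, encodings: Tensor, reverse: bool) -> list[Tensor]:
        L = encodings.data.shape[0]
        order = range(L - 1, -1, -1) if reverse else range(L)
        h = Tensor(np.zeros((1, self.hidden)))
        c = Tensor(np.zeros((1, self.hidden)))
        outputs: dict[int, Tensor] = {}
        for t in order:
            x = encodings.row(t)
            i = (x @ self.wx["i"] + h @ self.wh["i"] + self.b["i"]).sigmoid()
            f = (x @ self.wx["f"] + h @ self.wh["f"] + self.b["f"]).sigmoid()
            o = (x @ self.wx["o"] + h @ self.wh["o"] + self.b["o"]).sigmoid()
            g = (x @ self.wx["g"] + h @ self.wh["g"] + self.b["g"]).tanh()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return [outputs[t] for t in range(L)]

    def parameters(self) -> list[Tensor]:
        return (
            [self.wx[g] for g in "ifog"]
            + [self.wh[g] for g in "ifog"]
            + [self.b[g] for g in "ifog"]
        )


class BiLSTMHead:
    """Bidirectional recurrent pass followed by an affine map."""

    kind = "bilstm"
    has_crf = False

    def __init__(
        self,
        in_dim: int,
        hidden: int = 16,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.hidden = hidden
        self.forward = _LSTMDirection(in_dim, hidden, rng)
        self.backward = _LSTMDirection(in_dim, hidden, rng)
        self.out_weight = parameter((2 * hidden, N_LABELS), rng=rng)
        self.out_bias = parameter(np.zeros(N_LABELS))

    def score(self, encodings: Tensor) -> Tensor:
        if encodings.data.shape[1] != self.in_dim:
            raise ValueError(
                f"encoder dim {encodings.data.shape[1]} != head dim {self.in_dim}"
            )
        fwd = self.forward.run(encodings, reverse=False)
        bwd = self.backward.run(encodings, reverse=True)
        rows = [hstack(f, b) for f, b in zip(fwd, bwd)]
        return vstack(rows) @ self.out_weight + self.out_bias

    def parameters(self) -> list[Tensor]:
        return (
            self.forward.parameters()
            + self.backward.parameters()
            + [self.out_weight, self.out_bias]
        )


class BiLSTMCRFHead:
    """BiLSTM unary scores plus a trainable CRF transition structure.

    ``strict_bio`` adds a large penalty to transitions that break the
    BIO grammar (O -> I and start -> I) at decode time; by default all
    transitions are allowed because decoding repairs orphan I tags.
    """

    kind = "bilstm_crf"
    has_crf = True

    _STRICT_PENALTY = 1e4

    def __init__(
        self,
        in_dim: int,
        hidden: int = 16,
        rng: np.random.Generator | None = None,
        strict_bio: bool = False,
    ):
        rng = rng or np.random.default_rng(0)
        self.bilstm = BiLSTMHead(in_dim, hidden, rng=rng)
        self.in_dim = in_dim
        self.strict_bio = strict_bio
        self.transitions = parameter(np.zeros((N_LABELS, N_LABELS)))
        self.start = parameter(np.zeros(N_LABELS))
        self.end = parameter(np.zeros(N_LABELS))

    def score(self, encodings: Tensor) -> Tensor:
        return self.bilstm.score(encodings)

    def transition_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Transition/boundary scores as arrays, with strict-BIO penalties."""
        from ..annotation import I, O  # noqa: E741 - label constants

        trans = self.transitions.data.copy()
        start = self.start.data.copy()
        end = self.end.data.copy()
        if self.strict_bio:
            trans[O, I] -= self._STRICT_PENALTY
            start[I] -= self._STRICT_PENALTY
        return trans, start, end

    def parameters(self) -> list[Tensor]:
        return self.bilstm.parameters() + [self.transitions, self.start, self.end]


def score_tokens(head, encodings: Tensor) -> Tensor:
    """Score each token over {B, I, O} with the given head."""
    return head.score(encodings)


def make_head(kind: str, in_dim: int, hidden: int = 16, rng=None, strict_bio: bool = False):
    if kind == "linear":
        return LinearHead(in_dim, rng=rng)
    if kind == "bilstm":
        return BiLSTMHead(in_dim, hidden=hidden, rng=rng)
    if kind == "bilstm_crf":
        return BiLSTMCRFHead(in_dim, hidden=hidden, rng=rng, strict_bio=strict_bio)
    raise ValueError(f"unknown head kind {kind!r}")
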