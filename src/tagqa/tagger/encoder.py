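"""Pluggable contextual encoders.

Heavy pretrained language models are consumed behind the same contract:
anything that deterministically maps a packed token sequence to one
fixed-dimension vector per token can drive the tagging heads.  The
in-repo :class:`HashEmbeddingEncoder` is a small trainable encoder
(hashed token embeddings concatenated over a context window) so the full
method runs on one CPU.
"""

from __future__ import annotations

import zlib
from typing import Protocol, runtime_checkable

import numpy as np

from ..annotation import TokenizedInput
from .autograd import Tensor, parameter

__all__ = ["EncoderContract", "HashEmbeddingEncoder", "token_bucket"]


@runtime_checkable
class EncoderContract(Protocol):
    """Deterministic mapping from a TokenizedInput to per-token vectors."""

    @property
    def dim(self) -> int:
        """Dimension of each output token vector."""
        ...

    @property
    def cased(self) -> bool:
        """Whether the encoder distinguishes letter case."""
        ...

    def encode(self, tokenized: TokenizedInput) -> Tensor:
        """Return a (sequence length, dim) tensor of token vectors."""
        ...

    def parameters(self) -> list[Tensor]:
        """Trainable leaf tensors (empty for frozen encoders)."""
        ...


def token_bucket(token: str, n_buckets: int, cased: bool) -> int:
    """Stable hash bucket for a token (crc32; reproducible across runs)."""
    if not cased:
        token = token.lower()
    return zlib.crc32(token.encode("utf-8")) % n_buckets


class HashEmbeddingEncoder:
    """Trainable hashed-embedding encoder with context-window features.

    Each token is mapped to a bucket by a stable hash, the bucket row of
    a trainable embedding table is looked up, and the rows of the
    ``2*window + 1`` surrounding positions are concatenated, giving a
    local-context representation a linear head can exploit.
    """

    def __init__(
        self,
        embed_dim: int = 16,
        n_buckets: int = 4096,
        window: int = 2,
        cased: bool = False,
        seed: int = 0,
    ):
        if embed_dim < 1 or n_buckets < 1 or window < 0:
            raise ValueError("invalid encoder hyperparameters")
        self.embed_dim = embed_dim
        self.n_buckets = n_buckets
        self.window = window
        self._cased = cased
        rng = np.random.default_rng(seed)
        self.embedding = parameter((n_buckets, embed_dim), rng=rng, scale=0.1)

    @property
    def dim(self) -> int:
        return (2 * self.window + 1) * self.embed_dim

    @property
    def cased(self) -> bool:
        return self._cased

    def encode(self, tokenized: TokenizedInput) -> Tensor:
        ids = [
            token_bucket(tok, self.n_buckets, self._cased)
            for tok in tokenized.tokens
        ]
        rows = self.embedding.take_rows(ids)
        if self.window == 0:
            return rows
        return rows.window_concat(self.window)

    def parameters(self) -> list[Tensor]:
        return [self.embedding]
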