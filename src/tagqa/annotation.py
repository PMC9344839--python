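"""Answer localisation, input packing and BIO label assignment.

The input layout is ``[CLS] question [SEP] passage [SEP]``.  Supervision
is masked so that special tokens, question tokens and sub-word
continuation pieces never contribute to the loss: they carry the reserved
``IGNORE`` label.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Protocol, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "B",
    "I",
    "O",
    "IGNORE",
    "LABEL_NAMES",
    "CLS_TOKEN",
    "SEP_TOKEN",
    "CharSpan",
    "TokenOrigin",
    "TokenizedInput",
    "LabeledSequence",
    "Tokenizer",
    "WordPieceLikeTokenizer",
    "find_answer_spans",
    "tokenize_and_pack",
    "assign_bio_labels",
]

# Label indices over {B, I, O}; IGNORE is a reserved index excluded from
# loss and from decoding.
B, I, O = 0, 1, 2
IGNORE = -1
LABEL_NAMES = {B: "B", I: "I", O: "O", IGNORE: "IGNORE"}

CLS_TOKEN = "[CLS]"
SEP_TOKEN = "[SEP]"


@dataclass(frozen=True, order=True)
class CharSpan:
    """Half-open character interval ``[start, end)`` into a passage."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def overlaps(self, other: "CharSpan") -> bool:
        return self.start < other.end and other.start < self.end

    def __len__(self) -> int:
        return self.end - self.start


class TokenOrigin(str, Enum):
    SPECIAL = "special"
    QUESTION = "question"
    PASSAGE = "passage"


@dataclass(frozen=True)
class TokenizedInput:
    """A packed ``[CLS] question [SEP] passage [SEP]`` token sequence.

    ``char_offsets`` index into the origin string (question text for
    question tokens, passage text for passage tokens) and are ``None``
    for special tokens.  ``is_continuation`` marks non-initial sub-word
    pieces.
    """

    tokens: tuple[str, ...]
    origins: tuple[TokenOrigin, ...]
    char_offsets: tuple[tuple[int, int] | None, ...]
    is_continuation: tuple[bool, ...]

    def __post_init__(self) -> None:
        n = len(self.tokens)
        if not (len(self.origins) == len(self.char_offsets) == len(self.is_continuation) == n):
            raise ValueError("TokenizedInput fields must be aligned")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def passage_indices(self) -> tuple[int, ...]:
        return tuple(
            i for i, o in enumerate(self.origins) if o is TokenOrigin.PASSAGE
        )

    @property
    def supervised_indices(self) -> tuple[int, ...]:
        """Passage-token positions that carry supervision (non-continuation)."""
        return tuple(
            i
            for i, o in enumerate(self.origins)
            if o is TokenOrigin.PASSAGE and not self.is_continuation[i]
        )


@dataclass(frozen=True)
class LabeledSequence:
    """Per-token labels over {B, I, O, IGNORE} aligned to a TokenizedInput."""

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(l not in (B, I, O, IGNORE) for l in self.labels):
            raise ValueError("labels must be B, I, O or IGNORE")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def supervised_count(self) -> int:
        return sum(1 for l in self.labels if l != IGNORE)


class Tokenizer(Protocol):
    """Contract: map text to sub-word pieces with offsets and flags."""

    @property
    def lowercase(self) -> bool: ...

    def tokenize(self, text: str) -> list[tuple[str, int, int, bool]]:
        """Return ``(piece, start, end, is_continuation)`` tuples."""
        ...


_WORD_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


class WordPieceLikeTokenizer:
    """Whitespace/punctuation word splitter with sub-word chunking.

    Words longer than ``max_piece_len`` characters are split into fixed
    size pieces whose non-initial chunks are flagged as continuations —
    enough to exercise every sub-word code path without a learned
    vocabulary.  Offsets always refer to the original text.
    """

    def __init__(self, max_piece_len: int | None = None, lowercase: bool = False):
        if max_piece_len is not None and max_piece_len < 1:
            raise ValueError("max_piece_len must be positive")
        self.max_piece_len = max_piece_len
        self._lowercase = lowercase

    @property
    def lowercase(self) -> bool:
        return self._lowercase

    def tokenize(self, text: str) -> list[tuple[str, int, int, bool]]:
        pieces: list[tuple[str, int, int, bool]] = []
        for m in _WORD_RE.finditer(text):
            word, start, end = m.group(), m.start(), m.end()
            if self._lowercase:
                word = word.lower()
            if self.max_piece_len is None or len(word) <= self.max_piece_len:
                pieces.append((word, start, end, False))
                continue
            for i in range(0, len(word), self.max_piece_len):
                chunk = word[i : i + self.max_piece_len]
                pieces.append((chunk, start + i, start + i + len(chunk), i > 0))
        return pieces


# ---------------------------------------------------------------------------
# Answer matching
# ---------------------------------------------------------------------------

def _iter_occurrences(haystack: str, needle: str):
    pos = haystack.find(needle)
    while pos != -1:
        yield pos
        pos = haystack.find(needle, pos + 1)


def find_answer_spans(
    passage_text: str,
    synonym_groups: Sequence,
    match_mode: str = "uncased",
) -> list[tuple[CharSpan, int]]:
    """Locate every gold answer occurrence in a passage.

    All occurrences of any variant of any group are collected and
    overlaps are resolved longest-leftmost: among candidates the earliest
    start wins, ties broken by the longer match.  ``uncased`` mode
    lowercases both sides before searching but reports spans in original
    coordinates.  Returns ``(span, group_index)`` pairs sorted by start.
    """
    if not passage_text:
        raise ValueError("passage_text must be non-empty")
    if match_mode not in ("cased", "uncased"):
        raise ValueError(f"unknown match_mode {match_mode!r}")
    haystack = passage_text.lower() if match_mode == "uncased" else passage_text

    candidates: list[tuple[int, int, int]] = []  # (start, -length, group)
    for gi, group in enumerate(synonym_groups):
        variants = getattr(group, "variants", group)
        for variant in variants:
            needle = variant.lower() if match_mode == "uncased" else variant
            if not needle:
                continue
            for pos in _iter_occurrences(haystack, needle):
                candidates.append((pos, -len(needle), gi))

    candidates.sort()
    resolved: list[tuple[CharSpan, int]] = []
    last_end = 0
    for start, neg_len, gi in candidates:
        end = start - neg_len
        if start >= last_end:
            resolved.append((CharSpan(start, end), gi))
            last_end = end
    return resolved


# ---------------------------------------------------------------------------
# Input packing
# ---------------------------------------------------------------------------

def tokenize_and_pack(
    question_text: str,
    passage_text: str,
    tokenizer: Tokenizer,
    max_len: int = 512,
) -> TokenizedInput:
    """Build the ``[CLS] question [SEP] passage [SEP]`` sequence.

    Over-length sequences are truncated from the passage tail; question
    tokens are never truncated.  Raises ``ValueError`` when the question
    leaves no token budget for the passage.
    """
    q_pieces = tokenizer.tokenize(question_text)
    p_pieces = tokenizer.tokenize(passage_text)

    budget = max_len - 3 - len(q_pieces)  # [CLS], 2x[SEP]
    if budget <= 0:
        raise ValueError(
            f"question occupies {len(q_pieces)} tokens, leaving no room "
            f"for passage tokens within max_len={max_len}"
        )
    if len(p_pieces) > budget:
        p_pieces = p_pieces[:budget]
    if not p_pieces:
        raise ValueError("no passage tokens survive truncation")

    tokens: list[str] = [CLS_TOKEN]
    origins: list[TokenOrigin] = [TokenOrigin.SPECIAL]
    offsets: list[tuple[int, int] | None] = [None]
    cont: list[bool] = [False]

    for piece, s, e, c in q_pieces:
        tokens.append(piece)
        origins.append(TokenOrigin.QUESTION)
        offsets.append((s, e))
        cont.append(c)
    tokens.append(SEP_TOKEN)
    origins.append(TokenOrigin.SPECIAL)
    offsets.append(None)
    cont.append(False)
    for piece, s, e, c in p_pieces:
        tokens.append(piece)
        origins.append(TokenOrigin.PASSAGE)
        offsets.append((s, e))
        cont.append(c)
    tokens.append(SEP_TOKEN)
    origins.append(TokenOrigin.SPECIAL)
    offsets.append(None)
    cont.append(False)

    return TokenizedInput(
        tokens=tuple(tokens),
        origins=tuple(origins),
        char_offsets=tuple(offsets),
        is_continuation=tuple(cont),
    )


# ---------------------------------------------------------------------------
# BIO label assignment
# ---------------------------------------------------------------------------

def assign_bio_labels(
    tokenized: TokenizedInput,
    spans: Sequence[CharSpan],
) -> LabeledSequence:
    """Assign B/I/O labels to supervised passage tokens, IGNORE elsewhere.

    For each span the first supervised passage token overlapping it gets
    ``B`` and subsequent overlapping supervised tokens get ``I``; a token
    counts as inside a span when their character ranges overlap at all.
    Spans lying entirely beyond the truncated passage window are dropped
    with a logged warning.  Overlapping input spans are an error.
    """
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping spans {a} and {b}; resolve first")

    labels = [IGNORE] * len(tokenized)
    for idx in tokenized.supervised_indices:
        labels[idx] = O

    window_end = 0
    for idx in tokenized.passage_indices:
        off = tokenized.char_offsets[idx]
        assert off is not None
        window_end = max(window_end, off[1])

    for span in ordered:
        if span.start >= window_end:
            logger.warning(
                "span (%d, %d) lies beyond the truncated passage window "
                "(end %d); dropped", span.start, span.end, window_end
            )
            continue
        first = True
        for idx in tokenized.supervised_indices:
            s, e = tokenized.char_offsets[idx]  # type: ignore[misc]
            if s < span.end and span.start < e:
                labels[idx] = B if first else I
                first = False
        if first:
            logger.warning(
                "span (%d, %d) overlaps no supervised token; dropped",
                span.start, span.end,
            )
    return LabeledSequence(tuple(labels))
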