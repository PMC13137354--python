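"""Clinical-text processing: WordPiece tokenization, additive
token/segment/position embeddings, domain sentiment lexicons, and the
Estimated Association readability statistic.

The sentiment lexicons are the fixed domain lists for intracranial
hemorrhage narratives: positive outcome language ("favorable outcome",
"recovery"), negative findings ("coma", "large hematoma"), and neutral
clinical measurements ("Glasgow Coma Scale", "midline shift").
"""

from __future__ import annotations

import json
import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Vocabulary",
    "Lexicon",
    "TextEmbeddingTables",
    "DEFAULT_LEXICON",
    "UNK",
    "CLS",
    "SEP",
    "default_vocabulary",
    "wordpiece_tokenize",
    "embed_tokens",
    "encode_text",
    "lexicon_sentiment",
    "estimated_association",
    "default_complex_words",
]

logger = logging.getLogger(__name__)

CLS = "[CLS]"
SEP = "[SEP]"
UNK = "[UNK]"
SPECIALS = (CLS, SEP, UNK)

DEFAULT_MAX_LEN = 512


@dataclass(frozen=True)
class Vocabulary:
    """A WordPiece vocabulary: whole-word pieces plus "##"-prefixed
    continuation pieces, with the [CLS]/[SEP]/[UNK] specials."""

    pieces: frozenset[str]

    def __post_init__(self) -> None:
        if "" in self.pieces or "##" in self.pieces:
            raise ValueError("vocabulary contains an empty piece")
        missing = [s for s in SPECIALS if s not in self.pieces]
        if missing:
            raise ValueError(f"vocabulary missing special tokens: {missing}")

    @classmethod
    def from_pieces(cls, pieces) -> "Vocabulary":
        return cls(frozenset(pieces) | frozenset(SPECIALS))

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        return cls.from_pieces(p.strip() for p in lines if p.strip())

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "\n".join(sorted(self.pieces)) + "\n", encoding="utf-8"
        )

    def __contains__(self, piece: str) -> bool:
        return piece in self.pieces


@dataclass(frozen=True)
class Lexicon:
    """Pairwise-disjoint sets of lowercase sentiment phrases."""

    positive: frozenset[str]
    negative: frozenset[str]
    neutral: frozenset[str]

    def __post_init__(self) -> None:
        if (
            self.positive & self.negative
            or self.positive & self.neutral
            or self.negative & self.neutral
        ):
            raise ValueError("lexicon phrase sets must be pairwise disjoint")

    @classmethod
    def from_json(cls, path: str | Path) -> "Lexicon":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            frozenset(p.lower() for p in data["positive"]),
            frozenset(p.lower() for p in data["negative"]),
            frozenset(p.lower() for p in data["neutral"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "positive": sorted(self.positive),
                    "negative": sorted(self.negative),
                    "neutral": sorted(self.neutral),
                },
                indent=2,
            ),
            encoding="utf-8",
        )


DEFAULT_LEXICON = Lexicon(
    positive=frozenset(
        {
            "good outcome",
            "favorable outcome",
            "improved survival",
            "recovery",
            "stable",
        }
    ),
    negative=frozenset(
        {
            "coma",
            "large hematoma",
            "intraventricular hemorrhage",
            "posterior fossa hemorrhage",
            "old age",
        }
    ),
    neutral=frozenset(
        {
            "glasgow coma scale",
            "gcs",
            "ich score",
            "hematoma volume",
            "infratentorial",
            "supratentorial",
            "midline shift",
            "mass effect",
            "perihematomal edema",
        }
    ),
)

_PUNCT = string.punctuation.replace("#", "")


def _words(text: str) -> list[str]:
    out = []
    for raw in text.lower().split():
        w = raw.strip(_PUNCT)
        if w:
            out.append(w)
    return out


def wordpiece_tokenize(text: str, vocab: Vocabulary) -> list[str]:
    """Greedy longest-prefix WordPiece segmentation.

    Each whitespace-separated, lowercased word is segmented by repeatedly
    taking the longest vocabulary prefix (continuations carry the "##"
    marker).  If at any point no piece matches, the whole word becomes
    [UNK].  Deterministic.
    """
    tokens: list[str] = []
    for word in _words(text):
        tokens.extend(_segment_word(word, vocab))
    return tokens


def _segment_word(word: str, vocab: Vocabulary) -> list[str]:
    pieces: list[str] = []
    start = 0
    while start < len(word):
        prefix = "##" if start > 0 else ""
        end = len(word)
        match = None
        while end > start:
            cand = prefix + word[start:end]
            if cand in vocab:
                match = cand
                break
            end -= 1
        if match is None:
            return [UNK]
        pieces.append(match)
        start = end
    return pieces


@dataclass
class TextEmbeddingTables:
    """Token + segment + position embedding tables, deterministically
    initialized from a seed (Gaussian, sd 0.02)."""

    vocab: Vocabulary
    embed_dim: int = 32
    max_len: int = DEFAULT_MAX_LEN
    seed: int = 0
    token_index: dict[str, int] = field(init=False, repr=False)
    token_table: np.ndarray = field(init=False, repr=False)
    segment_table: np.ndarray = field(init=False, repr=False)
    position_table: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pieces = sorted(self.vocab.pieces)
        self.token_index = {p: i for i, p in enumerate(pieces)}
        rng = np.random.default_rng(self.seed)
        self.token_table = rng.normal(0.0, 0.02, (len(pieces), self.embed_dim))
        self.segment_table = rng.normal(0.0, 0.02, (2, self.embed_dim))
        self.position_table = rng.normal(0.0, 0.02, (self.max_len, self.embed_dim))


def embed_tokens(
    tokens: list[str],
    segment_ids: list[int],
    tables: TextEmbeddingTables,
) -> np.ndarray:
    """vector_i = token_table[tok_i] + segment_table[seg_i] + position_table[i]."""
    if len(tokens) != len(segment_ids):
        raise ValueError("tokens and segment_ids must have equal length")
    if len(tokens) > tables.max_len:
        raise ValueError(f"sequence length {len(tokens)} exceeds max_len {tables.max_len}")
    out = np.empty((len(tokens), tables.embed_dim))
    for i, (tok, seg) in enumerate(zip(tokens, segment_ids)):
        if tok not in tables.token_index:
            raise KeyError(f"token {tok!r} absent from embedding table")
        if seg not in (0, 1):
            raise ValueError("segment ids must be 0 or 1")
        out[i] = (
            tables.token_table[tables.token_index[tok]]
            + tables.segment_table[seg]
            + tables.position_table[i]
        )
    return out


def encode_text(
    text: str, tables: TextEmbeddingTables, max_len: int | None = None
) -> np.ndarray:
    """Tokenize and embed a note as a single-segment sequence (segment 0),
    truncating to max_len with a logged warning."""
    limit = min(max_len or tables.max_len, tables.max_len)
    tokens = wordpiece_tokenize(text, tables.vocab)
    if len(tokens) > limit:
        logger.warning("truncating note from %d to %d tokens", len(tokens), limit)
        tokens = tokens[:limit]
    return embed_tokens(tokens, [0] * len(tokens), tables)


def lexicon_sentiment(
    text: str, lexicon: Lexicon = DEFAULT_LEXICON
) -> tuple[int, int, int, str]:
    """Count lexicon phrase occurrences and derive a polarity.

    Matching is case-insensitive, longest-phrase-first, non-overlapping and
    word-boundary anchored.  Polarity: positive if pos > neg, negative if
    neg > pos; on a tie, neutral if any neutral phrase was seen, else
    uncertain.
    """
    normalized = " ".join(text.lower().split())
    phrases = sorted(
        [(p, "pos") for p in lexicon.positive]
        + [(p, "neg") for p in lexicon.negative]
        + [(p, "neu") for p in lexicon.neutral],
        key=lambda kv: len(kv[0]),
        reverse=True,
    )
    counts = {"pos": 0, "neg": 0, "neu": 0}
    for phrase, kind in phrases:
        pattern = r"\b" + re.escape(phrase) + r"\b"
        normalized, n = re.subn(pattern, " \x00 ", normalized)
        counts[kind] += n
    pos, neg, neu = counts["pos"], counts["neg"], counts["neu"]
    if pos > neg:
        polarity = "positive"
    elif neg > pos:
        polarity = "negative"
    elif neu > 0:
        polarity = "neutral"
    else:
        polarity = "uncertain"
    return pos, neg, neu, polarity


def default_complex_words(lexicon: Lexicon = DEFAULT_LEXICON) -> frozenset[str]:
    """Default "complex word" set for Estimated Association: the
    constituent words of the negative and neutral lexicon phrases."""
    words: set[str] = set()
    for phrase in lexicon.negative | lexicon.neutral:
        words.update(phrase.split())
    return frozenset(words)


def estimated_association(text: str, complex_word_set=None) -> float:
    """Estimated Association, EA = 100 * complex words / total words.

    Whitespace tokenization, case-insensitive; always in [0, 100].
    """
    words = _words(text)
    if not words:
        raise ValueError("empty text: EA undefined")
    complex_words = (
        default_complex_words() if complex_word_set is None else {w.lower() for w in complex_word_set}
    )
    n_complex = sum(1 for w in words if w in complex_words)
    return 100.0 * n_complex / len(words)


def default_vocabulary(extra_words=()) -> Vocabulary:
    """Vocabulary covering the packaged note templates and lexicons, plus a
    few continuation pieces for subword behavior."""
    from .synthetic_data import template_words  # deferred: avoids import cycle

    words: set[str] = set()
    for phrase in (
        DEFAULT_LEXICON.positive | DEFAULT_LEXICON.negative | DEFAULT_LEXICON.neutral
    ):
        words.update(phrase.split())
    words.update(template_words())
    words.update(w.lower() for w in extra_words)
    pieces = set(words)
    # continuation pieces so morphology like "hemato-ma" stays segmentable
    pieces.update({"hema", "##toma", "##s", "##ly", "##ing"})
    return Vocabulary.from_pieces(pieces)
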