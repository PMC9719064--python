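"""Simplification rewards: relevance, readability gain, and lexical simplicity.

Three scalar rewards judge a generated simplification G of a complex source
paragraph S against its reference simple paragraph T:

* ``relevance_reward`` — cosine similarity between sentence embeddings of G
  and T, measuring meaning preservation.  Any sentence-embedding model can
  be plugged in through the :class:`EmbeddingModel` contract; the packaged
  default is a deterministic hashed bag-of-words embedder so the reward runs
  with no model download.
* ``fkgl_reward`` — the relative reduction in Flesch-Kincaid grade level of
  G versus T, positive when the generation reads at a lower grade.
* ``lexical_simplicity_reward`` — a ramp on the Zipf-frequency shift
  ΔZ(S, G) = Z(G − S) − Z(S − G) between inserted and deleted word types:
  positive ΔZ means the rewrite swapped rare words for common ones.

The weighted sum of the three (``combined_reward``) is the scalar optimized
by self-critical sequence training in :mod:`simplerl.scst`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

import numpy as np

from .text_metrics import analyze_text, fkgl, words

__all__ = [
    "EmbeddingModel",
    "HashedBowEmbedding",
    "EMBEDDERS",
    "get_embedder",
    "FrequencyLexicon",
    "LexicalStats",
    "RewardWeights",
    "RewardBreakdown",
    "relevance_reward",
    "grade_relative_difference",
    "fkgl_reward",
    "lexical_stats",
    "lexical_simplicity_reward",
    "combined_reward",
    "RewardScorer",
]

#: ΔZ at which the lexical reward saturates; the corpus-typical shift between
#: complex medical paragraphs and their plain-language counterparts.
DELTA_Z_SATURATION = 0.4

#: Floor on |grade(T)| in the relative-difference denominator.
GRADE_EPSILON = 1e-6


@runtime_checkable
class EmbeddingModel(Protocol):
    """Contract for sentence-embedding backends: text -> fixed-size vector."""

    dimension: int

    def embed(self, text: str) -> np.ndarray: ...


class HashedBowEmbedding:
    """Deterministic hashed bag-of-words embedding.

    Each word token is hashed (BLAKE2, fixed salt) to a coordinate and a
    sign; the text embedding is the signed token-count vector.  This is a
    download-free stand-in satisfying the :class:`EmbeddingModel` contract:
    identical texts map to identical vectors and word overlap translates
    into cosine similarity.
    """

    def __init__(self, dimension: int = 256, seed: int = 0) -> None:
        if dimension < 1:
            raise ValueError("embedding dimension must be >= 1")
        self.dimension = int(dimension)
        self._salt = str(int(seed)).encode()

    def _slot(self, token: str) -> tuple[int, float]:
        digest = hashlib.blake2b(token.encode() + self._salt, digest_size=8).digest()
        value = int.from_bytes(digest, "big")
        return value % self.dimension, 1.0 if (value >> 62) & 1 else -1.0

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for token in words(text):
            idx, sign = self._slot(token)
            vec[idx] += sign
        return vec


#: Named embedding backends; external adapters may register here.
EMBEDDERS: dict[str, type] = {"hashed-bow": HashedBowEmbedding}


def get_embedder(name: str, **kwargs) -> EmbeddingModel:
    """Instantiate a registered embedding backend by name."""
    try:
        factory = EMBEDDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown embedder {name!r}; registered: {sorted(EMBEDDERS)}"
        ) from None
    return factory(**kwargs)


def relevance_reward(
    target_text: str, generated_text: str, model: EmbeddingModel
) -> float:
    """Cosine similarity of target and generated embeddings, clipped to [0, 1]."""
    if not target_text or not generated_text:
        raise ValueError("relevance reward requires non-empty texts")
    e_t = np.asarray(model.embed(target_text), dtype=float)
    e_g = np.asarray(model.embed(generated_text), dtype=float)
    nt, ng = np.linalg.norm(e_t), np.linalg.norm(e_g)
    if nt == 0 or ng == 0:
        raise ValueError("degenerate embedding: zero norm")
    return float(np.clip(e_t @ e_g / (nt * ng), 0.0, 1.0))


def grade_relative_difference(
    r_target: float, r_generated: float, eps: float = GRADE_EPSILON
) -> float:
    """(r(T) - r(G)) / max(|r(T)|, eps), clipped to [-1, 1]."""
    return float(np.clip((r_target - r_generated) / max(abs(r_target), eps), -1.0, 1.0))


def fkgl_reward(
    generated_text: str,
    target_text: str,
    coefficients: str | tuple[float, float, float] = "standard",
) -> float:
    """Relative FKGL reduction of the generation versus the target, in [-1, 1].

    Positive iff the generated text reads at a lower grade than the target.
    """
    r_t = fkgl(analyze_text(target_text), coefficients)
    r_g = fkgl(analyze_text(generated_text), coefficients)
    return grade_relative_difference(r_t, r_g)


class FrequencyLexicon:
    """Word -> Zipf frequency lookup (log10 occurrences per billion words).

    Unknown words map to ``oov_zipf`` (default 0.0, i.e. below measurable
    frequency).  Loadable from a two-column plain-text table or, when the
    optional ``wordfreq`` package is installed, from its frequency lists.
    """

    def __init__(self, table: Mapping[str, float], oov_zipf: float = 0.0) -> None:
        if oov_zipf < 0:
            raise ValueError("oov_zipf must be >= 0")
        clean: dict[str, float] = {}
        for word, value in table.items():
            if value < 0:
                raise ValueError(f"Zipf frequency must be >= 0 (word {word!r})")
            clean[word.lower()] = float(value)
        self._table = clean
        self.oov_zipf = float(oov_zipf)

    def zipf(self, word: str) -> float:
        return self._table.get(word.lower(), self.oov_zipf)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._table

    def __len__(self) -> int:
        return len(self._table)

    @classmethod
    def from_table(cls, path: str | Path, oov_zipf: float = 0.0) -> "FrequencyLexicon":
        """Read a whitespace-separated ``word zipf`` table; '#' starts a comment."""
        table: dict[str, float] = {}
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'word zipf', got {raw!r}")
            table[parts[0]] = float(parts[1])
        return cls(table, oov_zipf=oov_zipf)

    @classmethod
    def from_wordfreq(cls, lang: str = "en", oov_zipf: float = 0.0):
        """Adapter over the optional ``wordfreq`` package's Zipf frequencies."""
        try:
            import wordfreq
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "FrequencyLexicon.from_wordfreq requires the optional "
                "'wordfreq' package (pip install simplerl[wordfreq])"
            ) from exc

        lexicon = cls({}, oov_zipf=oov_zipf)
        lexicon.zipf = lambda word: float(  # type: ignore[method-assign]
            wordfreq.zipf_frequency(word.lower(), lang)
        )
        return lexicon


@dataclass(frozen=True)
class LexicalStats:
    """Zipf statistics of the word types a rewrite inserted and deleted."""

    inserted_words: frozenset[str]
    deleted_words: frozenset[str]
    z_inserted: float
    z_deleted: float

    @property
    def delta_z(self) -> float:
        return self.z_inserted - self.z_deleted


def _mean_zipf(word_set: frozenset[str], lexicon: FrequencyLexicon) -> float:
    if not word_set:
        return 0.0
    return sum(lexicon.zipf(w) for w in word_set) / len(word_set)


def lexical_stats(
    source_text: str, generated_text: str, lexicon: FrequencyLexicon
) -> LexicalStats:
    """Inserted/deleted word-type sets and their mean Zipf frequencies.

    Word types are unique lowercased tokens; an empty set contributes a mean
    of 0 by convention, so ΔZ is 0 when the generation copies the source.
    """
    s_types = frozenset(words(source_text))
    g_types = frozenset(words(generated_text))
    inserted = g_types - s_types
    deleted = s_types - g_types
    return LexicalStats(
        inserted_words=inserted,
        deleted_words=deleted,
        z_inserted=_mean_zipf(inserted, lexicon),
        z_deleted=_mean_zipf(deleted, lexicon),
    )


def lexical_simplicity_reward(
    stats: LexicalStats, saturation: float = DELTA_Z_SATURATION
) -> float:
    """Linear ramp on ΔZ, scaled to [0, 1] and saturating at ``saturation``."""
    if saturation <= 0:
        raise ValueError("saturation must be > 0")
    return float(np.clip(stats.delta_z / saturation, 0.0, 1.0))


@dataclass(frozen=True)
class RewardWeights:
    """Weights (alpha, beta, d) of relevance, readability and lexical rewards."""

    alpha: float = 1.0 / 3.0
    beta: float = 1.0 / 3.0
    d: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.d < 0:
            raise ValueError("reward weights must be >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.d)


@dataclass(frozen=True)
class RewardBreakdown:
    """The three reward components and their weighted total for one triple."""

    r_cosine: float
    r_flesch: float
    r_lexical: float
    total: float


def combined_reward(
    r_cosine: float, r_flesch: float, r_lexical: float, weights: RewardWeights
) -> float:
    """alpha*r_cosine + beta*r_flesch + d*r_lexical."""
    return (
        weights.alpha * r_cosine + weights.beta * r_flesch + weights.d * r_lexical
    )


class RewardScorer:
    """Scores (source, target, generated) triples into a RewardBreakdown.

    Bundles the embedding model, frequency lexicon, FKGL coefficient preset,
    ramp saturation and weights so reward computation during training and
    reporting is a single deterministic call.  A degenerate generation (no
    word tokens, or one on which a component is undefined) scores 0 on every
    component rather than raising, keeping training total.
    """

    def __init__(
        self,
        lexicon: FrequencyLexicon,
        embedder: EmbeddingModel | None = None,
        weights: RewardWeights | None = None,
        fkgl_coefficients: str | tuple[float, float, float] = "standard",
        saturation: float = DELTA_Z_SATURATION,
    ) -> None:
        self.lexicon = lexicon
        self.embedder = embedder if embedder is not None else HashedBowEmbedding()
        self.weights = weights if weights is not None else RewardWeights()
        self.fkgl_coefficients = fkgl_coefficients
        self.saturation = saturation

    def score(
        self, source_text: str, target_text: str, generated_text: str
    ) -> RewardBreakdown:
        if not words(generated_text):
            return RewardBreakdown(0.0, 0.0, 0.0, 0.0)
        try:
            r_cos = relevance_reward(target_text, generated_text, self.embedder)
        except ValueError:
            r_cos = 0.0
        try:
            r_fk = fkgl_reward(generated_text, target_text, self.fkgl_coefficients)
        except ValueError:
            r_fk = 0.0
        r_lex = lexical_simplicity_reward(
            lexical_stats(source_text, generated_text, self.lexicon),
            saturation=self.saturation,
        )
        total = combined_reward(r_cos, r_fk, r_lex, self.weights)
        return RewardBreakdown(r_cos, r_fk, r_lex, total)
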