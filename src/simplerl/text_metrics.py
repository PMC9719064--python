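"""Deterministic text statistics and automatic evaluation metrics.

This module provides the measurement layer used everywhere else in the
package: a canonical tokenizer, a syllable-counting heuristic, the
Flesch-Kincaid Grade Level (FKGL) and Automated Readability Index (ARI)
readability formulas, and the n-gram overlap metrics ROUGE-n and SARI used
to evaluate text simplification systems.

All functions are pure and dependency-free so that every number they
produce is reproducible from the input bytes alone.  The tokenizer is
deliberately simple (lowercasing, sentence boundaries at ``. ! ?`` with a
small abbreviation guard, words as maximal alphanumeric+apostrophe runs);
published readability values computed with other tokenizers will differ
slightly, which is expected and documented in the methods note.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "TextStats",
    "NGramOps",
    "RougeScore",
    "FKGL_PRESETS",
    "ARI_COEFFICIENTS",
    "sentences",
    "words",
    "count_syllables",
    "analyze_text",
    "fkgl",
    "ari",
    "rouge_n",
    "ngram_ops",
    "sari",
]


# Sentence-final periods after these strings do not end a sentence.
ABBREVIATIONS: frozenset[str] = frozenset(
    {
        "e.g.",
        "i.e.",
        "et al.",
        "etc.",
        "cf.",
        "vs.",
        "ca.",
        "dr.",
        "mr.",
        "mrs.",
        "ms.",
        "prof.",
        "fig.",
        "figs.",
        "no.",
        "vol.",
        "st.",
    }
)

# Words whose syllable count the vowel-group heuristic gets wrong.
_SYLLABLE_EXCEPTIONS: dict[str, int] = {
    "people": 2,
    "business": 2,
    "colonel": 2,
    "recipe": 3,
    "cafe": 2,
    "naive": 2,
    "apple": 2,
    "little": 2,
    "able": 2,
    "every": 2,
    "evening": 3,
    "area": 3,
    "idea": 3,
    "being": 2,
    "doing": 2,
    "queue": 1,
}

_WORD_RE = re.compile(r"[a-z0-9]+(?:'[a-z0-9]+)*")
_SENT_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")
_VOWEL_GROUP_RE = re.compile(r"[aeiouy]+")

FKGL_PRESETS: dict[str, tuple[float, float, float]] = {
    # Coefficient triple (a, b, c) in a*(words/sentence) + b*(syllables/word) - c.
    "paper": (0.38, 1.8, 15.59),
    "standard": (0.39, 11.8, 15.59),
}

#: ARI coefficients (characters/word, words/sentence, intercept).
ARI_COEFFICIENTS: tuple[float, float, float] = (4.71, 0.5, 21.43)


@dataclass(frozen=True)
class TextStats:
    """Word / sentence / syllable / character counts of one text."""

    n_sentences: int
    n_words: int
    n_syllables: int
    n_characters: int

    def __post_init__(self) -> None:
        for name in ("n_sentences", "n_words", "n_syllables", "n_characters"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_words > 0 and self.n_syllables < self.n_words:
            raise ValueError("every word has at least one syllable")

    @property
    def words_per_sentence(self) -> float:
        if self.n_sentences == 0:
            raise ValueError("words_per_sentence undefined: no sentences")
        return self.n_words / self.n_sentences

    @property
    def syllables_per_word(self) -> float:
        if self.n_words == 0:
            raise ValueError("syllables_per_word undefined: no words")
        return self.n_syllables / self.n_words

    @property
    def characters_per_word(self) -> float:
        if self.n_words == 0:
            raise ValueError("characters_per_word undefined: no words")
        return self.n_characters / self.n_words


class RougeScore(NamedTuple):
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class NGramOps:
    """Add / keep / delete n-gram sets for one (source, candidate, refs) triple.

    ``added`` are candidate n-grams absent from the source, ``kept`` are
    present in both, ``deleted`` are source n-grams the candidate dropped;
    ``ref_*`` are the corresponding sets judged against the references.
    """

    n: int
    added: frozenset[tuple[str, ...]]
    kept: frozenset[tuple[str, ...]]
    deleted: frozenset[tuple[str, ...]]
    ref_added: frozenset[tuple[str, ...]]
    ref_kept: frozenset[tuple[str, ...]]
    ref_deleted: frozenset[tuple[str, ...]]


def words(text: str) -> list[str]:
    """Lowercased word tokens: maximal alphanumeric+apostrophe runs."""
    return _WORD_RE.findall(text.lower())


def _ends_with_abbreviation(prefix: str) -> bool:
    tail = prefix[-10:].lower()
    return any(tail.endswith(abbr) for abbr in ABBREVIATIONS)


def sentences(text: str) -> list[str]:
    """Split on ``. ! ?`` followed by whitespace/end, guarding abbreviations.

    Only segments containing at least one word token count as sentences.
    """
    segments: list[str] = []
    start = 0
    for match in _SENT_BOUNDARY_RE.finditer(text):
        candidate = text[start : match.end()]
        if match.group().startswith(".") and _ends_with_abbreviation(candidate):
            continue
        segments.append(candidate)
        start = match.end()
    if start < len(text):
        segments.append(text[start:])
    return [seg for seg in segments if words(seg)]


def count_syllables(word: str) -> int:
    """Syllables of one lowercase token by the vowel-group heuristic.

    Counts maximal runs of ``aeiouy``, drops a trailing silent "e" unless it
    forms the only vowel group, floors at one, and consults a small table of
    common irregulars first.
    """
    if not word:
        raise ValueError("cannot count syllables of an empty token")
    word = word.lower()
    if word in _SYLLABLE_EXCEPTIONS:
        return _SYLLABLE_EXCEPTIONS[word]
    groups = _VOWEL_GROUP_RE.findall(word)
    n = len(groups)
    if n > 1 and word.endswith("e") and groups[-1] == "e":
        n -= 1
    return max(n, 1)


def analyze_text(text: str) -> TextStats:
    """Compute :class:`TextStats` for a text; empty text yields all zeros."""
    toks = words(text)
    n_syll = sum(count_syllables(w) for w in toks)
    n_chars = sum(len(w) - w.count("'") for w in toks)
    return TextStats(
        n_sentences=len(sentences(text)),
        n_words=len(toks),
        n_syllables=n_syll,
        n_characters=n_chars,
    )


def _resolve_fkgl_coefficients(
    coefficients: str | Sequence[float],
) -> tuple[float, float, float]:
    if isinstance(coefficients, str):
        try:
            return FKGL_PRESETS[coefficients]
        except KeyError:
            raise ValueError(
                f"unknown FKGL preset {coefficients!r}; "
                f"choose from {sorted(FKGL_PRESETS)}"
            ) from None
    a, b, c = coefficients
    return float(a), float(b), float(c)


def fkgl(stats: TextStats, coefficients: str | Sequence[float] = "standard") -> float:
    """Flesch-Kincaid Grade Level of a text's statistics.

    ``coefficients`` is a preset name ("standard" or "paper") or an explicit
    (a, b, c) triple for ``a*(words/sentence) + b*(syllables/word) - c``.
    The result is a US school grade and may be negative for trivially
    simple text.
    """
    if stats.n_words == 0 or stats.n_sentences == 0:
        raise ValueError("FKGL undefined for text without words or sentences")
    a, b, c = _resolve_fkgl_coefficients(coefficients)
    return a * stats.words_per_sentence + b * stats.syllables_per_word - c


def ari(stats: TextStats) -> float:
    """Automated Readability Index: 4.71*chars/word + 0.5*words/sentence - 21.43."""
    if stats.n_words == 0 or stats.n_sentences == 0:
        raise ValueError("ARI undefined for text without words or sentences")
    a, b, c = ARI_COEFFICIENTS
    return a * stats.characters_per_word + b * stats.words_per_sentence - c


def _ngrams(tokens: Sequence[str], n: int) -> list[tuple[str, ...]]:
    return [tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1)]


def rouge_n(candidate: str, reference: str, n: int) -> RougeScore:
    """ROUGE-n with multiset (clipped-count) overlap, no stemming.

    Returns precision, recall and their harmonic mean; all zero when either
    side has no n-grams.
    """
    if n < 1:
        raise ValueError("n-gram order must be >= 1")
    cand = Counter(_ngrams(words(candidate), n))
    ref = Counter(_ngrams(words(reference), n))
    if not cand or not ref:
        return RougeScore(0.0, 0.0, 0.0)
    overlap = sum((cand & ref).values())
    precision = overlap / sum(cand.values())
    recall = overlap / sum(ref.values())
    if precision + recall == 0:
        return RougeScore(0.0, 0.0, 0.0)
    f1 = 2 * precision * recall / (precision + recall)
    return RougeScore(precision, recall, f1)


def _ngram_set(text: str, n: int) -> frozenset[tuple[str, ...]]:
    return frozenset(_ngrams(words(text), n))


def ngram_ops(source: str, candidate: str, references: Sequence[str], n: int) -> NGramOps:
    """Enumerate the add/keep/delete n-gram operation sets used by SARI."""
    s = _ngram_set(source, n)
    c = _ngram_set(candidate, n)
    r: frozenset[tuple[str, ...]] = frozenset().union(
        *(_ngram_set(ref, n) for ref in references)
    )
    return NGramOps(
        n=n,
        added=c - s,
        kept=c & s,
        deleted=s - c,
        ref_added=r - s,
        ref_kept=r & s,
        ref_deleted=s - r,
    )


def _set_f1(predicted: frozenset, reference: frozenset) -> float:
    if not predicted and not reference:
        return 1.0
    if not predicted or not reference:
        return 0.0
    overlap = len(predicted & reference)
    precision = overlap / len(predicted)
    recall = overlap / len(reference)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _set_precision(predicted: frozenset, reference: frozenset) -> float:
    if not predicted and not reference:
        return 1.0
    if not predicted or not reference:
        return 0.0
    return len(predicted & reference) / len(predicted)


def sari(
    source: str,
    candidate: str,
    references: Iterable[str],
    max_n: int = 4,
) -> float:
    """SARI score of a simplification candidate against source and references.

    Each of the three edit operations is scored per n-gram order 1..``max_n``
    (additions and keeps by F1, deletions by precision only), averaged over
    orders, and the three operation scores are averaged.  Operation sets use
    unique-n-gram (set) semantics over the union of the references.  When
    both the predicted and the reference operation set are empty the
    component scores 1; when exactly one is empty it scores 0.
    """
    refs = list(references)
    if not refs:
        raise ValueError("SARI requires at least one reference")
    if not words(source):
        raise ValueError("SARI requires a non-empty source")
    add_scores, keep_scores, del_scores = [], [], []
    for n in range(1, max_n + 1):
        ops = ngram_ops(source, candidate, refs, n)
        add_scores.append(_set_f1(ops.added, ops.ref_added))
        keep_scores.append(_set_f1(ops.kept, ops.ref_kept))
        del_scores.append(_set_precision(ops.deleted, ops.ref_deleted))
    means = [sum(s) / len(s) for s in (add_scores, keep_scores, del_scores)]
    return sum(means) / 3.0
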