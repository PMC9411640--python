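"""Fallback subword segmentation of unknown terms.

When a term neither matches the vocabulary nor decomposes into medical
word parts, it is split into meaningful sub-word units (``seasickness`` →
``sea + sick + ness``) that can each be looked up in the embedding.  The
segmenter is a unigram model decoded with Viterbi over cut positions: each
candidate unit scores its log relative frequency in a training word list
(plus a closed set of common English affixes), and spans not in the model
pay a per-character penalty.  The repo is thus self-contained — no external
morphology toolkit or training corpus is needed — while an externally
trained segmentation model can be plugged in through the same contract
(any object with a compatible ``unit_log_prob`` table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Closed set of common English affix units always added to the model.
AFFIX_UNITS = ("ness", "less", "ful", "ing", "ed", "er", "s")


@dataclass
class SegmenterModel:
    """Unigram unit model: log relative frequencies over known units."""

    unit_log_prob: dict[str, float] = field(default_factory=dict)
    min_unit_len: int = 1
    unknown_penalty: float = 10.0  # per character of an unknown span


def train_segmenter(word_list: list[tuple[str, int]]) -> SegmenterModel:
    """Build a :class:`SegmenterModel` from (word, count) pairs.

    Counts of duplicate words are aggregated; the affix units in
    :data:`AFFIX_UNITS` are added with count 1 each; log probabilities are
    relative frequencies over the combined pool.  Order-independent and
    deterministic.
    """
    if not word_list:
        raise ValueError("word list must be non-empty")
    counts: dict[str, int] = {}
    for word, count in word_list:
        if count < 1:
            raise ValueError(f"count for {word!r} must be >= 1")
        w = word.strip().lower()
        counts[w] = counts.get(w, 0) + count
    for affix in AFFIX_UNITS:
        counts.setdefault(affix, 1)
    total = sum(counts.values())
    return SegmenterModel(
        unit_log_prob={w: math.log(c / total) for w, c in counts.items()}
    )


#: Two segmentation scores closer than this are treated as tied.
_SCORE_TOL = 1e-9


def _key_less(a: tuple, b: tuple) -> bool:
    """Lexicographic key comparison with score treated as tied within tolerance."""
    if a[0] < b[0] - _SCORE_TOL:
        return True
    if a[0] > b[0] + _SCORE_TOL:
        return False
    return a[1:] < b[1:]


def _unit_score(unit: str, model: SegmenterModel) -> float:
    known = model.unit_log_prob.get(unit)
    if known is not None and len(unit) >= model.min_unit_len:
        return known
    return -model.unknown_penalty * len(unit)


def segment(term: str, model: SegmenterModel) -> list[str]:
    """Maximum-likelihood segmentation of ``term`` into units.

    Viterbi over cut positions; ties broken by fewer units, then by
    leftmost-longest units.  Always returns a non-empty unit list whose
    concatenation is ``term`` (worst case the whole term as one unknown
    unit).
    """
    if not term or not term.isalpha() or term != term.lower():
        raise ValueError(f"term must be lowercase alphabetic, got {term!r}")
    n = len(term)
    # best[i]: (neg_score, n_units, neg_unit_lengths...) minimized, with the
    # unit list from position i to the end.  The lexicographic key encodes
    # score first, then fewer units, then leftmost-longest.  Scores within
    # _SCORE_TOL are ties (summation order must not decide a tie-break).
    best: list[tuple[tuple, list[str]] | None] = [None] * (n + 1)
    best[n] = ((0.0, 0, ()), [])
    for i in range(n - 1, -1, -1):
        cand_best = None
        for j in range(i + 1, n + 1):
            unit = term[i:j]
            tail = best[j]
            score = _unit_score(unit, model)
            neg_score = tail[0][0] - score
            n_units = tail[0][1] + 1
            lengths = (-len(unit),) + tail[0][2]
            key = (neg_score, n_units, lengths)
            if cand_best is None or _key_less(key, cand_best[0]):
                cand_best = (key, [unit] + tail[1])
        best[i] = cand_best
    return best[0][1]


def segmentation_score(units: list[str], model: SegmenterModel) -> float:
    """Total log score of a given segmentation under the model."""
    return sum(_unit_score(u, model) for u in units)
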