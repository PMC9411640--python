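"""Compound-term decomposition over the component lexicon.

An unknown medical term is split into an optional prefix, roots joined by
combining vowels, and an optional terminal suffix, where every non-vowel
segment must be a dictionary form (or one of its combining forms).  Each
component is then replaced by its dictionary meaning words, e.g.::

    choledocholithiasis -> choledoch + o + lithiasis
                        -> ["common", "bile", "duct", "calculus", "or", "stone"]

The search is exact over all cut positions, not greedy: greedy longest-match
fails on overlapping forms (``prostat`` + ``ism`` would be missed after
swallowing a longer spurious match).  Among complete segmentations the
preferred one has the fewest (non-vowel) components, then the longest
terminal suffix, then the lexicographically earliest component surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lexicon import ComponentEntry, Lexicon

#: Minimum surface length for a non-vowel component; suppresses spurious
#: single-letter matches.
MIN_COMPONENT_LEN = 2

Component = tuple[str, ComponentEntry | None, str]  # (surface, entry, role)


@dataclass(frozen=True)
class Decomposition:
    """A successful parse of a term into medical-terminology components."""

    term: str
    components: tuple[Component, ...]
    meaning_words: tuple[str, ...]
    score: tuple

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(s for s, _, _ in self.components)


def _surface_maps(lexicon: Lexicon):
    """Precompute surface → entry maps for each matching context.

    A surface is the entry's form or any of its combining forms.  At the
    term start, a form present as both prefix and root is labeled prefix.
    """
    initial: dict[str, tuple[ComponentEntry, str]] = {}
    medial: dict[str, tuple[ComponentEntry, str]] = {}
    terminal: dict[str, tuple[ComponentEntry, str]] = {}
    for entry in lexicon.roots.values():
        for surf in {entry.form, *entry.combining_forms}:
            medial[surf] = (entry, "root")
            initial[surf] = (entry, "root")
            terminal.setdefault(surf, (entry, "root"))
    for entry in lexicon.prefixes.values():
        for surf in {entry.form, *entry.combining_forms}:
            initial[surf] = (entry, "prefix")  # prefix label wins term-initially
    for entry in lexicon.suffixes.values():
        for surf in {entry.form, *entry.combining_forms}:
            terminal[surf] = (entry, "suffix")
    return initial, medial, terminal


def _enumerate(term: str, lexicon: Lexicon) -> list[tuple[Component, ...]]:
    """All complete segmentations of ``term`` under the component grammar."""
    n = len(term)
    initial, medial, terminal = _surface_maps(lexicon)
    vowels = lexicon.combining_vowels
    results: list[tuple[Component, ...]] = []

    def step(i: int, acc: list[Component], allow_vowel: bool) -> None:
        if i == n:
            if acc:
                results.append(tuple(acc))
            return
        # a single combining vowel may sit between two components
        if allow_vowel and term[i] in vowels and i + 1 < n:
            acc.append((term[i], None, "combining_vowel"))
            step(i + 1, acc, allow_vowel=False)
            acc.pop()
        table = initial if i == 0 else medial
        for j in range(i + MIN_COMPONENT_LEN, n + 1):
            surf = term[i:j]
            hit = terminal.get(surf) if j == n else table.get(surf)
            if j == n and hit is None:
                hit = table.get(surf) if i > 0 else initial.get(surf)
            if hit is None:
                continue
            entry, role = hit
            acc.append((surf, entry, role))
            step(j, acc, allow_vowel=True)
            acc.pop()

    step(0, [], allow_vowel=False)
    return results


def _score(components: tuple[Component, ...]) -> tuple:
    n_parts = sum(1 for _, _, role in components if role != "combining_vowel")
    suffix_len = len(components[-1][0]) if components[-1][2] == "suffix" else 0
    surfaces = tuple(s for s, _, _ in components)
    return (n_parts, -suffix_len, surfaces)


def decompose(term: str, lexicon: Lexicon) -> Decomposition | None:
    """Best decomposition of a lowercase alphabetic term, or None.

    Raises ValueError if the term contains non-alphabetic characters
    (normalization is assumed to have run upstream).
    """
    if not term or not term.isalpha() or term != term.lower():
        raise ValueError(f"term must be lowercase alphabetic, got {term!r}")
    parses = _enumerate(term, lexicon)
    if not parses:
        return None
    best = min(parses, key=_score)
    meaning = tuple(
        w for _, entry, role in best if role != "combining_vowel" for w in entry.meaning_words
    )
    return Decomposition(term=term, components=best, meaning_words=meaning, score=_score(best))


def meanings(term: str, lexicon: Lexicon) -> list[str] | None:
    """Meaning-word list of the best decomposition, or None if unparseable."""
    dec = decompose(term, lexicon)
    return None if dec is None else list(dec.meaning_words)
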