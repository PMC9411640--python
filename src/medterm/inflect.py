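"""Rule-based medical pluralizer and singularizer.

Greek/Latin medical nouns pluralize by suffix exchange (vertebra→vertebrae,
diagnosis→diagnoses, bacterium→bacteria).  Both directions are implemented
as a deterministic first-match-wins scan over an ordered rule table — a
finite-state transformation — with the singularizer running the same table
with the sides swapped.
"""

from __future__ import annotations

from typing import Sequence

from .lexicon import InflectionRule


def _apply_first(word: str, rules: Sequence[InflectionRule], reverse: bool) -> str | None:
    for rule in rules:
        src = rule.plural_suffix if reverse else rule.singular_suffix
        dst = rule.singular_suffix if reverse else rule.plural_suffix
        if word.endswith(src) and len(word) > len(src):
            return word[: len(word) - len(src)] + dst
    return None


def pluralize(word: str, rules: Sequence[InflectionRule]) -> str | None:
    """Return the medical plural of ``word``, or None if no rule matches.

    The first rule (in table order) whose singular suffix matches the end of
    the word is applied; only the suffix changes.
    """
    return _apply_first(word, rules, reverse=False)


def singularize(word: str, rules: Sequence[InflectionRule]) -> str | None:
    """Reverse of :func:`pluralize`: first matching plural suffix is swapped
    back to its singular form."""
    return _apply_first(word, rules, reverse=True)


def inflection_candidates(word: str, rules: Sequence[InflectionRule]) -> list[str]:
    """Singular and plural alternates of ``word`` for vocabulary re-lookup.

    The singular candidate comes first (an OOV plural whose singular is in
    vocabulary is the common case); duplicates and non-matches are dropped.
    Wrong candidates are harmless — downstream vocabulary lookup filters
    them.
    """
    out: list[str] = []
    for cand in (singularize(word, rules), pluralize(word, rules)):
        if cand is not None and cand != word and cand not in out:
            out.append(cand)
    return out
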