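"""OOV detection and lexical normalization.

A token from a clinical or biomedical text is first checked against the
embedding vocabulary as-is, then after normalization: case folding, removal
of leading/trailing symbols (intra-term punctuation such as the hyphen in
``x-ray`` is retained), and apostrophe clean-up so that ``Alzheimer's``
matches a vocabulary entry ``alzheimer``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_EDGE_PUNCT = re.compile(r"^[^a-z0-9]+|[^a-z0-9]+$")
_CURLY_APOSTROPHES = str.maketrans({"‘": "'", "’": "'", "ʼ": "'"})


class EmptyTokenError(ValueError):
    """Raised when a token is empty or whitespace-only."""


@dataclass(frozen=True)
class NormalizationResult:
    original: str
    normalized: str
    steps_applied: tuple[str, ...] = field(default=())


def normalize_token(token: str) -> NormalizationResult:
    """Normalize a single token for vocabulary lookup.

    Applies, in order: (1) lowercase folding; (2) stripping of leading and
    trailing non-alphanumeric characters while keeping internal punctuation;
    (3) apostrophe normalization (curly to ASCII, then a terminal ``'s`` or
    ``'`` is dropped).  Deterministic and idempotent; ``steps_applied``
    records only the steps that changed the string.
    """
    stripped = token.strip()
    if not stripped:
        raise EmptyTokenError(f"empty token: {token!r}")
    steps: list[str] = []

    lowered = stripped.lower()
    if lowered != stripped:
        steps.append("lowercase")

    # Strip edge punctuation; map curly apostrophes first so a trailing
    # curly quote is handled by the apostrophe step, not left behind.
    mapped = lowered.translate(_CURLY_APOSTROPHES)
    deedged = _EDGE_PUNCT.sub("", mapped)
    if deedged != lowered:
        steps.append("strip_edge_punct")

    out = deedged
    if out.endswith("'s"):
        out = out[:-2]
    elif out.endswith("'"):
        out = out[:-1]
    # possessive removal can expose new edge punctuation; re-strip
    out = _EDGE_PUNCT.sub("", out)
    if out != deedged or mapped != lowered:
        steps.append("apostrophe")

    return NormalizationResult(original=token, normalized=out, steps_applied=tuple(steps))


def is_known(token: str, vocabulary: set[str] | frozenset[str]) -> tuple[bool, str | None]:
    """Check whether a token is covered by an embedding vocabulary.

    Tries the raw token first, then its normalized form; returns the matched
    surface form so callers can look up the vector under the right key.
    """
    if token in vocabulary:
        return True, token
    norm = normalize_token(token).normalized
    if norm in vocabulary:
        return True, norm
    return False, None
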