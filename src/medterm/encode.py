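"""Vector synthesis for out-of-vocabulary terms.

The encoder chain tries, in order: (a) direct vocabulary lookup after
normalization; (b) re-lookup of the term's singular/plural alternate;
(c) decomposition into medical word parts, encoding the term as the mean
vector of its components' meaning words; (d) subword segmentation, encoding
the mean vector of the term's sub-word units.  The first stage that yields
a vector wins, and every encoded token records which stage produced it.

Unresolved tokens yield no vector rather than a random one — random filler
vectors corrupt similarity evaluation; callers that need a placeholder can
opt into zeros via ``zero_fill``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inflect import inflection_candidates
from .lexicon import Lexicon
from .normalize import is_known, normalize_token
from .parse import meanings
from .segment import SegmenterModel, segment

#: Pipeline stages in execution order; "unresolved" ranks after all of them
#: when the worst stage of a multi-word term is reported.
STAGE_ORDER = ("direct", "inflection", "parser", "segmenter", "unresolved")

ALL_STAGES = frozenset({"direct", "inflection", "parser", "segmenter"})


class EmbeddingFormatError(ValueError):
    """A word2vec text file is malformed."""


class EmbeddingSource:
    """A word → vector table with a fixed dimension.

    Thin deterministic wrapper over a dict of numpy vectors; exposes the
    vocabulary as a set for OOV detection.
    """

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding must be non-empty")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        self._vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dimension = dims.pop()
        self.vocabulary = frozenset(self._vectors)

    def get(self, word: str) -> np.ndarray | None:
        return self._vectors.get(word)

    def __contains__(self, word: str) -> bool:
        return word in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)


@dataclass
class EncodedToken:
    """A token with its synthesized vector and provenance.

    ``provenance`` is "unresolved" iff ``vector`` is None; ``trace`` logs
    each attempted stage; ``contributing_words`` lists the words averaged by
    the parser or segmenter stage with a found/missing flag each.
    """

    token: str
    vector: np.ndarray | None
    provenance: str
    trace: list[str] = field(default_factory=list)
    contributing_words: list[tuple[str, bool]] = field(default_factory=list)


def read_word2vec_text(path: str | Path) -> EmbeddingSource:
    """Read an embedding in word2vec text format.

    Accepts the standard ``<count> <dim>`` header or a headerless file; one
    token plus whitespace-separated floats per line.  A row whose length
    disagrees with the inferred dimension raises with its line number.
    """
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    dim = int(parts[1])
                    continue  # header line
                except ValueError:
                    pass
            word, values = parts[0], parts[1:]
            try:
                vec = np.array([float(v) for v in values], dtype=float)
            except ValueError as exc:
                raise EmbeddingFormatError(f"{path}:{lineno}: non-numeric value") from exc
            if dim is None:
                dim = len(vec)
            if len(vec) != dim:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: expected {dim} values, got {len(vec)}"
                )
            vectors[word] = vec
    if not vectors:
        raise EmbeddingFormatError(f"{path}: no vectors found")
    return EmbeddingSource(vectors)


def write_word2vec_text(emb: EmbeddingSource, path: str | Path) -> None:
    """Write an embedding in word2vec text format (with header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(emb)} {emb.dimension}\n")
        for word in sorted(emb.vocabulary):
            vec = " ".join(repr(float(x)) for x in emb.get(word))
            fh.write(f"{word} {vec}\n")


def mean_vector(
    words: list[str], emb: EmbeddingSource
) -> tuple[np.ndarray | None, list[tuple[str, bool]]]:
    """Element-wise mean of the vectors of the words found in ``emb``.

    Each word is normalized before lookup; words missing from the embedding
    are skipped (meaning phrases often contain function words absent from
    biomedical vocabularies).  Returns (None, flags) when nothing is found.
    """
    if not words:
        raise ValueError("words must be non-empty")
    found: list[np.ndarray] = []
    flags: list[tuple[str, bool]] = []
    for word in words:
        ok, surface = is_known(word, emb.vocabulary)
        flags.append((word, ok))
        if ok:
            found.append(emb.get(surface))
    if not found:
        return None, flags
    return np.mean(found, axis=0), flags


def encode_token(
    token: str,
    emb: EmbeddingSource,
    lexicon: Lexicon | None = None,
    seg: SegmenterModel | None = None,
    stages: frozenset[str] | set[str] = ALL_STAGES,
) -> EncodedToken:
    """Run the encoder chain on a single token.

    Stages run in the fixed order direct → inflection → parser → segmenter,
    skipping disabled ones (``stages`` must contain "direct"); the first
    stage producing a vector sets the provenance.  Never raises on ordinary
    OOV input: a token no stage resolves comes back with provenance
    "unresolved" and no vector.
    """
    stages = frozenset(stages)
    if "direct" not in stages or not stages <= ALL_STAGES:
        raise ValueError(f"stages must be a subset of {set(ALL_STAGES)} containing 'direct'")
    trace: list[str] = []
    norm = normalize_token(token).normalized

    ok, surface = is_known(token, emb.vocabulary)
    if "direct" in stages:
        if ok:
            trace.append(f"direct: hit as {surface!r}")
            return EncodedToken(token, emb.get(surface), "direct", trace)
        trace.append("direct: miss")

    if "inflection" in stages and lexicon is not None and norm.isalpha():
        for cand in inflection_candidates(norm, lexicon.inflection_rules):
            if cand in emb.vocabulary:
                trace.append(f"inflection: hit as {cand!r}")
                return EncodedToken(token, emb.get(cand), "inflection", trace)
        trace.append("inflection: miss")

    if "parser" in stages and lexicon is not None and norm.isalpha() and norm:
        words = meanings(norm, lexicon)
        if words:
            vec, flags = mean_vector(words, emb)
            if vec is not None:
                trace.append(f"parser: hit via {'+'.join(words)}")
                return EncodedToken(token, vec, "parser", trace, flags)
        trace.append("parser: miss")

    if "segmenter" in stages and seg is not None and norm.isalpha() and norm:
        units = segment(norm, seg)
        vec, flags = mean_vector(units, emb)
        if vec is not None:
            trace.append(f"segmenter: hit via {'+'.join(units)}")
            return EncodedToken(token, vec, "segmenter", trace, flags)
        trace.append("segmenter: miss")

    return EncodedToken(token, None, "unresolved", trace)


def encode_term(
    term: str,
    emb: EmbeddingSource,
    lexicon: Lexicon | None = None,
    seg: SegmenterModel | None = None,
    stages: frozenset[str] | set[str] = ALL_STAGES,
    zero_fill: bool = False,
) -> EncodedToken:
    """Encode a possibly multi-word term as the mean of its word vectors.

    Words that resolve to no vector are excluded from the mean; if none
    resolves the term is unresolved.  The provenance of a multi-word term is
    the worst (latest) stage any of its words needed.  With ``zero_fill``
    an unresolved term gets a zero vector instead of None (for pipelines
    that cannot carry missing values).
    """
    words = term.split()
    if not words:
        raise ValueError("term is empty")
    if len(words) == 1:
        enc = encode_token(words[0], emb, lexicon, seg, stages)
    else:
        parts = [encode_token(w, emb, lexicon, seg, stages) for w in words]
        resolved = [p for p in parts if p.vector is not None]
        trace = [f"{p.token}: {p.provenance}" for p in parts]
        contributing = [(p.token, p.vector is not None) for p in parts]
        if not resolved:
            enc = EncodedToken(term, None, "unresolved", trace, contributing)
        else:
            # worst stage among words that contributed a vector, so that
            # provenance stays "unresolved" iff the term has no vector
            worst = max((p.provenance for p in resolved), key=STAGE_ORDER.index)
            vec = np.mean([p.vector for p in resolved], axis=0)
            enc = EncodedToken(term, vec, worst, trace, contributing)
    if zero_fill and enc.vector is None:
        enc.vector = np.zeros(emb.dimension)
    return enc
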