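"""Synthetic compound terms, toy embeddings, and term-pair benchmarks.

Every stage of the encoder chain is testable without downloading real
embeddings or benchmark datasets: compound medical terms are coined by
concatenating fixture lexicon components the way real terms are coined
(optional prefix, roots with combining vowels, terminal suffix), a toy
embedding assigns seeded unit-norm random vectors to the meaning
vocabulary, and term-pair datasets synthesize "human" scores from the
ground-truth cosine of the expected mean-meaning vectors plus Gaussian
annotator noise.  At zero noise a correct pipeline must reach Spearman 1.0
and 100% coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encode import EmbeddingSource
from .evalkit import TermPair, cosine_similarity
from .lexicon import Lexicon

_VOWELS = set("aeiou")


@dataclass(frozen=True)
class SynthConfig:
    n_terms: int = 100
    max_components: int = 3
    seed: int = 0
    embedding_dim: int = 50
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_terms <= 0:
            raise ValueError("n_terms must be positive")
        if not 1 <= self.max_components <= 3:
            raise ValueError("max_components must be in [1, 3]")
        if self.embedding_dim <= 0:
            raise ValueError("embedding_dim must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _all_forms(lexicon: Lexicon) -> set[str]:
    forms = set()
    for entry in lexicon.entries():
        forms.add(entry.form)
        forms.update(entry.combining_forms)
    return forms


def _best_parse_meanings(term: str, lexicon: Lexicon) -> tuple[str, ...] | None:
    """Preference-best meaning list by direct enumeration of segmentations.

    Written independently of the parser module: plain recursion over the
    component grammar, collecting every complete segmentation, then ranked
    by (fewest non-vowel parts, longest terminal suffix, earliest surfaces).
    Used to reject ambiguous coinages whose best parse differs from the
    sampled components.
    """
    n = len(term)
    surf_pref = {}
    for e in lexicon.prefixes.values():
        for s in {e.form, *e.combining_forms}:
            surf_pref[s] = e
    surf_root = {}
    for e in lexicon.roots.values():
        for s in {e.form, *e.combining_forms}:
            surf_root[s] = e
    surf_suff = {}
    for e in lexicon.suffixes.values():
        for s in {e.form, *e.combining_forms}:
            surf_suff[s] = e

    complete: list[tuple[tuple, tuple[str, ...]]] = []

    def recurse(pos, surfaces, meanings, n_parts, after_part):
        if pos == n:
            if n_parts > 0:
                suffix_len = len(surfaces[-1]) if surfaces[-1] in surf_suff else 0
                complete.append(((n_parts, -suffix_len, surfaces), meanings))
            return
        if after_part and term[pos] in lexicon.combining_vowels and pos + 1 < n:
            recurse(pos + 1, surfaces + (term[pos],), meanings, n_parts, False)
        for end in range(pos + 2, n + 1):
            piece = term[pos:end]
            entry = None
            if end == n and piece in surf_suff:
                entry = surf_suff[piece]
            elif pos == 0 and piece in surf_pref:
                entry = surf_pref[piece]
            elif piece in surf_root:
                entry = surf_root[piece]
            if entry is not None:
                recurse(end, surfaces + (piece,), meanings + entry.meaning_words, n_parts + 1, True)

    recurse(0, (), (), 0, False)
    if not complete:
        return None
    return min(complete)[1]


def generate_terms(
    cfg: SynthConfig, lexicon: Lexicon
) -> list[tuple[str, tuple[str, ...]]]:
    """Coin ``cfg.n_terms`` compound terms with their expected meanings.

    Each term is an optional prefix, an optional root, and a terminal
    suffix (2 to ``max_components`` non-vowel components); a combining
    vowel is inserted after a root when the next component starts with a
    consonant.  Terms colliding with a lexicon form, and ambiguous coinages
    whose preference-best parse disagrees with the sampled components, are
    resampled.  Deterministic per seed.
    """
    if cfg.max_components < 2:
        raise ValueError(
            "max_components < 2 cannot produce out-of-vocabulary compounds: "
            "a single-component term is a lexicon form itself"
        )
    prefixes = sorted(lexicon.prefixes)
    roots = sorted(lexicon.roots)
    suffixes = sorted(lexicon.suffixes)
    if not prefixes or not roots or not suffixes:
        raise ValueError("lexicon must have prefixes, roots, and suffixes")
    rng = np.random.default_rng(cfg.seed)
    forms = _all_forms(lexicon)
    vowel = sorted(lexicon.combining_vowels)[0]

    out: list[tuple[str, tuple[str, ...]]] = []
    attempts = 0
    max_attempts = cfg.n_terms * 200
    while len(out) < cfg.n_terms:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not generate enough unambiguous terms from this lexicon")
        k = int(rng.integers(2, cfg.max_components + 1))
        if k == 2:
            pattern = ["prefix", "suffix"] if rng.random() < 0.5 else ["root", "suffix"]
        else:
            pattern = ["prefix", "root", "suffix"]
        parts = []
        for slot in pattern:
            pool = {"prefix": prefixes, "root": roots, "suffix": suffixes}[slot]
            form = pool[int(rng.integers(len(pool)))]
            parts.append((slot, lexicon.by_kind(slot)[form]))
        term = ""
        meaning: tuple[str, ...] = ()
        for idx, (slot, entry) in enumerate(parts):
            term += entry.form
            meaning += entry.meaning_words
            more = idx + 1 < len(parts)
            if more and slot == "root" and not parts[idx + 1][1].form[0] in _VOWELS:
                term += vowel
        if term in forms:
            continue
        if _best_parse_meanings(term, lexicon) != meaning:
            continue
        out.append((term, meaning))
    return out


def generate_embedding(words: list[str], cfg: SynthConfig) -> EmbeddingSource:
    """Seeded unit-norm random vectors of dimension ``cfg.embedding_dim``."""
    if not words:
        raise ValueError("words must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    vectors = {}
    for word in sorted(set(words)):
        v = rng.standard_normal(cfg.embedding_dim)
        vectors[word] = v / np.linalg.norm(v)
    return EmbeddingSource(vectors)


def meaning_vocabulary(lexicon: Lexicon) -> list[str]:
    """Every meaning word appearing in the lexicon, sorted and unique."""
    return sorted({w for e in lexicon.entries() for w in e.meaning_words})


def generate_pair_dataset(
    cfg: SynthConfig, lexicon: Lexicon
) -> tuple[list[TermPair], EmbeddingSource]:
    """Term-pair benchmark with ground-truth-derived human scores.

    The toy embedding covers every meaning word of the lexicon (so the
    parser stage can resolve any coined term) but none of the coined terms
    themselves, which are therefore genuinely OOV.  The human score of a
    pair is the cosine of the two terms' expected mean-meaning vectors plus
    Gaussian noise of sd ``cfg.noise_sd``; at zero noise a correct pipeline
    attains Spearman 1.0.
    """
    terms = generate_terms(cfg, lexicon)
    emb = generate_embedding(meaning_vocabulary(lexicon), cfg)
    terms = [(t, m) for t, m in terms if t not in emb.vocabulary]
    rng = np.random.default_rng(cfg.seed + 1)
    pairs: list[TermPair] = []
    n = len(terms)
    for _ in range(cfg.n_terms):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        (t1, m1), (t2, m2) = terms[i], terms[j]
        g1 = np.mean([emb.get(w) for w in m1], axis=0)
        g2 = np.mean([emb.get(w) for w in m2], axis=0)
        score = cosine_similarity(g1, g2) + float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd else cosine_similarity(g1, g2)
        pairs.append(TermPair(t1, t2, score))
    return pairs, emb
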