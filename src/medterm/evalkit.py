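"""Intrinsic evaluation of embeddings with and without the encoder chain.

Benchmarks of clinical term pairs scored by medical experts (UMNSRS-style)
are evaluated by encoding both terms of every pair, taking the cosine
similarity of the vectors, and correlating model similarities with the
human scores by Spearman rank correlation.  Coverage — the fraction of
pairs (or tokens) that receive a vector at all — is the second axis:
vocabulary-bound models leave rare compound terms unencoded, and the whole
point of the encoder chain is to close that gap.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .encode import ALL_STAGES, EmbeddingSource, encode_term
from .lexicon import Lexicon
from .segment import SegmenterModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermPair:
    """Two terms with a human similarity/relatedness score."""

    term1: str
    term2: str
    human_score: float

    def __post_init__(self) -> None:
        if not self.term1 or not self.term2:
            raise ValueError("terms must be non-empty")
        if not np.isfinite(self.human_score):
            raise ValueError("human score must be finite")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class EvalReport:
    """Result of evaluating an embedding on a term-pair benchmark."""

    n_total: int
    n_covered: int
    coverage_pct: float
    spearman: float | None
    per_pair: list[tuple[TermPair, float | None]] = field(default_factory=list)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a·b / (‖a‖‖b‖), in [-1, 1] up to rounding."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(np.dot(a, b) / (na * nb))


def spearman_correlation(x: list[float], y: list[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Requires equal lengths >= 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length lists with at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def precision_recall_f1(
    c: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """precision = TP/(TP+FP); recall = TP/(TP+FN); F1 their harmonic mean.

    A metric whose denominator is zero is None, and an undefined precision,
    recall, or zero-sum pair propagates None into F1.
    """
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def evaluate_pairs(
    pairs: list[TermPair],
    emb: EmbeddingSource,
    lexicon: Lexicon | None = None,
    seg: SegmenterModel | None = None,
    stages: frozenset[str] | set[str] = ALL_STAGES,
) -> EvalReport:
    """Encode both terms of every pair and score the embedding.

    A pair is covered iff both terms resolve to a vector; cosine model
    similarities and the Spearman correlation against human scores are
    computed over covered pairs only (unresolved terms are excluded rather
    than zero-filled, which would corrupt the cosine).  Spearman is None
    when fewer than 3 pairs are covered or either side is constant.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    per_pair: list[tuple[TermPair, float | None]] = []
    for pair in pairs:
        v1 = encode_term(pair.term1, emb, lexicon, seg, stages).vector
        v2 = encode_term(pair.term2, emb, lexicon, seg, stages).vector
        sim = None
        if v1 is not None and v2 is not None:
            try:
                sim = cosine_similarity(v1, v2)
            except ValueError:
                sim = None
        per_pair.append((pair, sim))
    covered = [(p.human_score, s) for p, s in per_pair if s is not None]
    n_total, n_covered = len(pairs), len(covered)
    spearman = None
    if n_covered >= 3:
        human, model = zip(*covered)
        try:
            spearman = spearman_correlation(list(human), list(model))
        except ValueError:
            spearman = None
    return EvalReport(
        n_total=n_total,
        n_covered=n_covered,
        coverage_pct=100.0 * n_covered / n_total,
        spearman=spearman,
        per_pair=per_pair,
    )


def token_coverage(
    tokens: list[str],
    emb: EmbeddingSource,
    lexicon: Lexicon | None = None,
    seg: SegmenterModel | None = None,
    stages: frozenset[str] | set[str] = ALL_STAGES,
) -> dict[str, int]:
    """Provenance histogram over a token list (token-level coverage)."""
    hist: dict[str, int] = {}
    for tok in tokens:
        prov = encode_term(tok, emb, lexicon, seg, stages).provenance
        hist[prov] = hist.get(prov, 0) + 1
    return hist


def read_term_pairs(
    path: str | Path,
    columns: tuple[int, int, int] = (0, 1, 2),
    delimiter: str | None = None,
) -> list[TermPair]:
    """Read a term-pair benchmark from delimited text.

    ``columns`` gives the (term1, term2, score) column positions.  The
    delimiter is sniffed from the first line when not given (comma vs tab).
    A header row is auto-skipped when its score cell is non-numeric;
    malformed rows are logged and skipped.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if delimiter is None:
            delimiter = "\t" if "\t" in first else ","
        fh.seek(0)
        rows = list(csv.reader(fh, delimiter=delimiter))
    pairs: list[TermPair] = []
    skipped = 0
    for i, row in enumerate(rows):
        try:
            t1 = row[columns[0]].strip()
            t2 = row[columns[1]].strip()
            score = float(row[columns[2]])
            pairs.append(TermPair(t1, t2, score))
        except (IndexError, ValueError):
            if i == 0:
                continue  # header
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    if not pairs:
        raise ValueError(f"{path}: no parsable term-pair rows")
    return pairs
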