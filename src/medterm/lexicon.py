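"""Component dictionaries for medical terminology.

Medical terms are coined from Greek/Latin word parts: prefixes (``dys-``),
roots with combining forms (``pneum/o``), and suffixes (``-itis``).  This
module defines the data model for those parts and their plain-English
meanings, a tab-separated file format for dictionaries of them, and a small
built-in fixture lexicon covering classic worked examples such as
``choledocholithiasis`` = choledoch + o + lithiasis = "common bile duct" +
"calculus or stone".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

KINDS = ("prefix", "root", "suffix")

#: Columns of the component dictionary TSV format, in order.
COMPONENT_COLUMNS = ("form", "kind", "combining_forms", "meanings", "organ_system")

#: Columns of the inflection rule TSV format, in order.
RULE_COLUMNS = ("rule_id", "singular_suffix", "plural_suffix")


class LexiconFormatError(ValueError):
    """A dictionary file does not conform to the TSV schema."""


@dataclass(frozen=True)
class ComponentEntry:
    """One prefix, root, or suffix with its combining forms and meaning words.

    Parameters
    ----------
    form : str
        The component as matched inside a term, lowercase alphabetic
        (e.g. ``"pnea"``).
    kind : str
        One of ``"prefix"``, ``"root"``, ``"suffix"``.
    combining_forms : tuple of str
        Surface variants that include a combining vowel (e.g. ``"pneumo"``
        for root ``"pneum"``).
    meaning_words : tuple of str
        Ordered plain-English meaning words (e.g. ``("common", "bile",
        "duct")``).
    organ_system : str or None
        Optional organ-system label (e.g. ``"respiratory"``).
    """

    form: str
    kind: str
    combining_forms: tuple[str, ...] = ()
    meaning_words: tuple[str, ...] = ()
    organ_system: str | None = None

    def __post_init__(self) -> None:
        if not self.form or not self.form.isalpha():
            raise ValueError(f"component form must be non-empty alphabetic, got {self.form!r}")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not self.meaning_words:
            raise ValueError(f"entry {self.form!r} has no meaning words")
        for cf in self.combining_forms:
            if not _valid_combining_form(self.form, cf):
                raise ValueError(
                    f"combining form {cf!r} is not derivable from form {self.form!r}"
                )


def _valid_combining_form(form: str, cf: str) -> bool:
    # cf must extend the form, or replace its terminal vowel.
    if cf.startswith(form):
        return True
    return len(cf) >= len(form) and cf[: len(form) - 1] == form[:-1] and form[-1] in "aeiouy"


@dataclass(frozen=True)
class InflectionRule:
    """A singular↔plural suffix exchange rule, e.g. ``a → ae``."""

    rule_id: str
    singular_suffix: str
    plural_suffix: str

    def __post_init__(self) -> None:
        if self.singular_suffix == self.plural_suffix:
            raise ValueError(f"rule {self.rule_id}: suffixes must differ")


@dataclass
class Lexicon:
    """The three component dictionaries plus the inflection rule table.

    All keys are lowercase; lookup is therefore case-insensitive provided
    queries are lowercased upstream (the normalizer does this).
    """

    prefixes: dict[str, ComponentEntry] = field(default_factory=dict)
    roots: dict[str, ComponentEntry] = field(default_factory=dict)
    suffixes: dict[str, ComponentEntry] = field(default_factory=dict)
    inflection_rules: list[InflectionRule] = field(default_factory=list)
    combining_vowels: set[str] = field(default_factory=lambda: {"o"})

    def by_kind(self, kind: str) -> dict[str, ComponentEntry]:
        return {"prefix": self.prefixes, "root": self.roots, "suffix": self.suffixes}[kind]

    def add(self, entry: ComponentEntry) -> None:
        self.by_kind(entry.kind)[entry.form] = entry

    def entries(self) -> Iterable[ComponentEntry]:
        for kind in KINDS:
            yield from self.by_kind(kind).values()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return (
            self.prefixes == other.prefixes
            and self.roots == other.roots
            and self.suffixes == other.suffixes
            and self.inflection_rules == other.inflection_rules
            and self.combining_vowels == other.combining_vowels
        )


def _split_list_cell(cell: str) -> tuple[str, ...]:
    return tuple(s.strip().lower() for s in cell.split(",") if s.strip())


def _parse_component_file(path: Path) -> list[ComponentEntry]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise LexiconFormatError(f"{path}: empty file (missing header)")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    for col in COMPONENT_COLUMNS:
        if col not in header:
            raise LexiconFormatError(f"{path}: missing column {col!r}")
    idx = {col: header.index(col) for col in COMPONENT_COLUMNS}
    entries: list[ComponentEntry] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        cells += [""] * (len(header) - len(cells))
        form = cells[idx["form"]].strip().lower()
        kind = cells[idx["kind"]].strip().lower()
        meanings = _split_list_cell(cells[idx["meanings"]])
        if not meanings:
            logger.warning("%s:%d: entry %r has empty meanings; skipped", path, lineno, form)
            continue
        combining = _split_list_cell(cells[idx["combining_forms"]])
        organ = cells[idx["organ_system"]].strip().lower() or None
        entries.append(
            ComponentEntry(
                form=form,
                kind=kind,
                combining_forms=combining,
                meaning_words=meanings,
                organ_system=organ,
            )
        )
    return entries


def _parse_rule_file(path: Path) -> list[InflectionRule]:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise LexiconFormatError(f"{path}: empty file (missing header)")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    for col in RULE_COLUMNS:
        if col not in header:
            raise LexiconFormatError(f"{path}: missing column {col!r}")
    idx = {col: header.index(col) for col in RULE_COLUMNS}
    rules = []
    for line in lines[1:]:
        cells = line.split("\t")
        rules.append(
            InflectionRule(
                rule_id=cells[idx["rule_id"]].strip().lower(),
                singular_suffix=cells[idx["singular_suffix"]].strip().lower(),
                plural_suffix=cells[idx["plural_suffix"]].strip().lower(),
            )
        )
    return rules


def _autogenerate_combining_forms(entry: ComponentEntry, vowels: set[str]) -> ComponentEntry:
    if entry.combining_forms:
        return entry
    return replace(entry, combining_forms=tuple(entry.form + v for v in sorted(vowels)))


def load_lexicon(paths: Sequence[str | Path], combining_vowels: set[str] | None = None) -> Lexicon:
    """Load a :class:`Lexicon` from TSV files.

    Component files have header columns ``form, kind, combining_forms,
    meanings, organ_system`` (lists comma-joined inside a cell); a file whose
    header is ``rule_id, singular_suffix, plural_suffix`` is read as the
    inflection rule table.  Later files override earlier ones on a
    ``(kind, form)`` collision.  Entries with an empty combining_forms cell
    get ``form + vowel`` auto-generated for each combining vowel.
    """
    lex = Lexicon(combining_vowels=set(combining_vowels or {"o"}))
    for raw in paths:
        path = Path(raw)
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        header = {h.strip().lower() for h in first.split("\t")}
        if set(RULE_COLUMNS) <= header:
            lex.inflection_rules = _parse_rule_file(path)
        else:
            for entry in _parse_component_file(path):
                lex.add(_autogenerate_combining_forms(entry, lex.combining_vowels))
    return lex


def write_lexicon(lex: Lexicon, directory: str | Path) -> list[Path]:
    """Write a Lexicon back to the TSV format; inverse of :func:`load_lexicon`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, fname in (("prefix", "prefixes.tsv"), ("root", "roots.tsv"), ("suffix", "suffixes.tsv")):
        path = directory / fname
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(COMPONENT_COLUMNS) + "\n")
            for form in sorted(lex.by_kind(kind)):
                e = lex.by_kind(kind)[form]
                fh.write(
                    "\t".join(
                        [
                            e.form,
                            e.kind,
                            ",".join(e.combining_forms),
                            ",".join(e.meaning_words),
                            e.organ_system or "",
                        ]
                    )
                    + "\n"
                )
        written.append(path)
    path = directory / "inflection_rules.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RULE_COLUMNS) + "\n")
        for r in lex.inflection_rules:
            fh.write(f"{r.rule_id}\t{r.singular_suffix}\t{r.plural_suffix}\n")
    written.append(path)
    return written


def fixture_lexicon() -> Lexicon:
    """The built-in fixture lexicon shipped with the package.

    Covers the classic compound-term examples (dyspnea, mastodynia,
    dermatitis, arteriosclerosis, prostatism, urethrorrhea,
    choledocholithiasis, blepharospasm, ...) plus the medical inflection
    rule table.  It is a small demonstration subset, not a complete
    medical-terminology dictionary.
    """
    data_dir = resources.files("medterm").joinpath("data")
    names = ["prefixes.tsv", "roots.tsv", "suffixes.tsv", "inflection_rules.tsv"]
    with resources.as_file(data_dir) as d:
        return load_lexicon([Path(d) / n for n in names])
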