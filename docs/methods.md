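# Methods

## Problem and model

A pre-trained word embedding is a map `V → R^d` over a fixed vocabulary
`V`. Clinical and biomedical text routinely contains tokens outside `V`,
most of them compound terms coined from a closed inventory of Greek/Latin
word parts. `medterm` synthesizes vectors for such tokens at run time by
exploiting the coining grammar: a term is (optional prefix) + (roots, each
optionally followed by a combining vowel) + (optional terminal suffix),
and each part has a dictionary meaning expressible in common words that
*are* in `V`. The synthesized vector of a term is the arithmetic mean of
the vectors of its parts' meaning words; a multi-word term is the mean of
its per-word vectors.

The chain tries four stages in a fixed order — direct lookup, inflection
exchange, component parsing, subword segmentation — and stops at the
first that yields a vector. Later stages are coarser approximations, so
the ordering encodes a preference for the most faithful vector available.
Unresolved tokens get no vector: silently substituting a random vector
would poison similarity evaluation, so missingness is explicit (an
optional `zero_fill` flag exists for pipelines that cannot carry `None`).

## Normalization

Three steps, in order: lowercase folding; removal of leading/trailing
characters outside `[a-z0-9]` (internal punctuation is kept — `x-ray`,
`q.i.d`, `her2/neu` survive); apostrophe handling (curly → ASCII, then a
terminal `'s` or `'` is dropped). Digits are preserved: tokens like `cd4`
would otherwise be destroyed. The transform is idempotent and never
lengthens a string (both property-tested).

## Inflection rules

The pluralizer/singularizer is a first-match-wins scan over an ordered
suffix-exchange table; the singularizer runs the same table with the
sides swapped. The shipped table is the standard Greek/Latin medical set:

| rule | singular | plural | example |
|------|----------|--------|---------|
| r01 | -ix | -ices | appendix → appendices |
| r02 | -nx | -nges | phalanx → phalanges |
| r03 | -x | -ges | coccyx-type forms |
| r04 | -y | -ies | deformity → deformities |
| r05 | -is | -es | diagnosis → diagnoses |
| r06 | -ma | -mata | carcinoma → carcinomata |
| r07 | -um | -a | bacterium → bacteria |
| r08 | -a | -ae | vertebra → vertebrae |
| r09 | -us | -i | fungus → fungi |

The order is chosen so that no earlier rule's suffix shadows a later
rule's output in either direction — a requirement for the round-trip
identities `singularize ∘ pluralize = id` and `pluralize ∘ singularize =
id` to hold. Two textbook rules are deliberately *not* shipped: `-ex →
-ices` (its plural collides with `-ix → -ices`) and `-on → -a` (collides
with `-um → -a`). With first-match-wins, a deterministic singularizer can
never pick the shadowed rule, so shipping it would only ever produce
wrong inverses; genuinely ambiguous plurals (`ganglia`, `criteria`) are
instead left to downstream vocabulary lookup, which tries candidates and
keeps the one the embedding knows. A default "append s" rule is likewise
omitted: it matches every word and collides with medical endings.
Residual ambiguity remains inherent (a plural in `-mata` could come from
`-ma` or a stem ending `mat` + `-um`); the round-trip tests therefore
generate words for which the rule under test is the first match in both
directions, which is exactly the set on which a deterministic inverse is
well-defined.

## Component lexicon and parser

Dictionaries are TSV files (`form, kind, combining_forms, meanings,
organ_system`; lists comma-joined in a cell), loaded case-insensitively,
with later files overriding earlier ones so users can layer corrections
over a base dictionary. An empty `combining_forms` cell auto-generates
`form + o` (the default combining vowel). The shipped fixture lexicon (5
prefixes, 17 roots, 13 suffixes) is a demonstration subset sufficient for
the classic worked examples, not a complete medical dictionary; real
deployments load their own files. The form `choledoch` is stored as both
prefix and root — usage in the literature varies — and the parser labels
a dual-kind form `prefix` when term-initial.

Decomposition is an exact search over all cut positions (plain recursion
with dictionary-hit pruning), not greedy longest-match, which fails on
overlapping forms. Every non-vowel segment must be a dictionary form or a
combining form of one, with minimum surface length 2 to suppress
single-letter matches; a single combining vowel may sit between
components; at most one suffix, terminal. Among complete parses the best
has (1) fewest non-vowel components, (2) longest terminal suffix, (3)
lexicographically earliest surface tuple — a deterministic total order.
The meaning list is the in-order concatenation of component meanings,
function words included (`prostatism → prostate, gland, state, of, or,
condition`); a stopword filter was considered and rejected as a default
because function words are skipped harmlessly at encoding time anyway
(words missing from the embedding are simply excluded from the mean).

## Segmenter

The fallback segmenter is a unigram model decoded with Viterbi over cut
positions: a unit scores its log relative frequency in a training word
list (plus the closed affix set `ness, less, ful, ing, ed, er, s`, count
1 each); an unknown span pays 10 per character (large enough that any
known unit beats any unknown span of equal length, small enough to stay
finite and comparable). Ties — which arise exactly, e.g. two unknown
splits of the same material — are broken by fewer units, then
leftmost-longest; scores within 1e-9 are treated as tied so that
floating-point summation order cannot decide a tie-break. The decoder is
verified against exhaustive enumeration of all 2^(n−1) segmentations on
short terms. An externally trained segmentation model can be supplied
through the same contract (any object exposing `unit_log_prob`,
`min_unit_len`, `unknown_penalty`).

## Synthetic data generator

`synthetic` coins compound terms by sampling fixture components
(patterns: prefix+suffix, root+suffix, prefix+root+suffix; a combining
vowel is inserted after a root when the next component starts with a
consonant), pairing each term with the concatenated meaning words as
ground truth. Coinages that collide with a lexicon form, and ambiguous
coinages whose preference-best parse (computed by an enumeration written
independently of the parser) disagrees with the sampled components, are
resampled — the expected meanings are therefore well-defined oracle
values. Toy embeddings are seeded unit-norm Gaussian vectors; term-pair
benchmarks take the cosine of the two terms' expected mean-meaning
vectors as the "human" score, plus Gaussian noise of sd `noise_sd`
(default 0) modelling annotator disagreement. At zero noise a correct
pipeline must reach coverage 100% and Spearman 1.0 — the generator's
acceptance surface.

What the generator does *not* emulate: real benchmark score
distributions, terms whose parts are missing from the component
dictionaries, spelling errors, abbreviations, and embeddings whose
meaning-word vectors are semantically structured rather than random.
Passing tests therefore demonstrate the mechanics of the chain —
coverage, provenance, exact parsing, metric correctness — not the
semantic quality of synthesized vectors on real clinical benchmarks,
which requires external embeddings and expert-scored datasets.

## Evaluation kit

Cosine similarity is the standard normalized dot product (zero-norm
input is an error, not a silent 0). Spearman is the Pearson correlation
of average ranks (scipy's implementation; ties get mean rank), checked
against an independent rank-then-Pearson brute force to 1e-9. A term
pair counts as covered only if *both* terms resolve; correlation is
computed over covered pairs, and unresolved terms are excluded rather
than zero-filled. Precision, recall and F1 follow the usual confusion
count definitions with `None` propagation when a denominator is zero.

## Problem sizes and determinism

The shipped test and acceptance workloads use 500 generated terms for
coverage, 200 for the parser oracle, 200 words per inflection rule, and
1000 random instances for the Spearman oracle — sizes at which every
exhaustive oracle is exact and the whole suite runs in seconds. All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
every generator is a pure function of its configuration, and the encoder
chain is deterministic end to end.
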