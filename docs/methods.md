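# Methods

This note records the models, parameter defaults, numerical choices and
known limitations behind `biodataseek`, in the order data flows through the
system.

## Corpus model and aggregation

Metadata records are arbitrary JSON objects. Flattening maps nested objects
to dot-joined field paths; array elements share their parent path in order;
numeric and boolean leaves are stringified in JSON spelling and nulls are
dropped. Flattening is lossless for leaf content: the multiset of leaf
strings equals the multiset of values across flattened fields.

The aggregated text field concatenates every value in **sorted field path
order** (original value order within a field). Sorting groups shared path
prefixes, which keeps hierarchically related fields adjacent — a deliberate
choice over insertion order, which would interleave unrelated fields.
Consecutive values are separated by a **positional gap** (default 10 token
positions) so that a phrase or proximity query with slop below the gap can
never match across a field/value boundary. The gap size is a trade-off: it
must exceed any slop used by the query side (the default relaxation
schedule tops out at slop 2) while keeping positions compact.

## Gazetteers and tagging

Dictionary entries come from two sources: a hierarchical MeSH-like
thesaurus (multiple parents allowed, cycles rejected at load) and a flat
gene dictionary whose entries may be case-sensitive. Term normalization
applies the comma-inversion rule: a single-comma entry "A, B" is stored as
both "A B" and "B A"; entries with two or more commas are stored verbatim;
all other punctuation is untouched. Both comma-stripped variants are kept
because the orientation that appears in running text is not predictable
from the dictionary form.

Tagging is a greedy leftmost-longest scan over dash-preserving word tokens:
at each position the longest matching entry wins and consumes its span, so
mention spans are disjoint and sorted by construction. Case-insensitive
entries match on lowercased tokens; case-sensitive gene symbols on verbatim
tokens; equal-length matches at one position merge their concept ids into a
single mention. No stemming or punctuation stripping is applied on either
side, and a dash inside a dictionary term must appear in the text
("tgf-beta" never matches "tgf beta") — the dash is a token-internal
character in the shared tokenizer, so this falls out of tokenization rather
than being a special case. Greedy left-to-right matching mirrors a
streaming token filter; it is not a globally optimal segmentation, and a
longer concept starting inside an already-consumed span is missed.

## Concept indexing

Each mention injects one index token per concept id at the position of the
mention's **last** word token, so identifiers ride along with phrases and
proximity windows and accumulate term frequency like ordinary words.
Ancestors of mesh-like concepts are injected at the same position as
**implicit** concept tokens, prefixed `i#` to keep the explicit and
implicit vocabularies disjoint. Word-token positions are never altered by
injection, so word-phrase matching is injection-invariant. Document length
counts word tokens only; concept tokens contribute tf/df but not length,
so injecting concepts does not dilute BM25 length normalization.

## Ranking

BM25 with k1 = 1.2, b = 0.75 and the non-negative idf
`ln(1 + (N - df + 0.5)/(df + 0.5))`, over the aggregated field by default.
Phrases match when an increasing position assignment exists whose span
width minus phrase length is at most the slop; a matching phrase scores the
sum of its member terms' BM25. Boolean AND sums child scores and requires
all children; OR requires at least `min_should_match` children (an absolute
count — unambiguous under the multiphase schedule, unlike percentages) and
sums the matching children. Boosts multiply; score ties break on ascending
doc id for determinism. Exact parity with any particular search engine's
scoring is a non-goal; the structural semantics (what matches) are the
contract, and the score oracles in the tests pin the BM25 arithmetic.

## Query construction

Defaults for the concept-expanded form, taken from the worked example the
pipeline is built around: phrase clause boost 20, AND-of-words 0.5,
explicit concept id 1, implicit id 0.5, descendant ids 1/0.5, other-term 2,
embedding-expansion clauses 0.3. A single-word concept takes the phrase
boost (there is no AND clause to distinguish it from). The boost of an
explicit concept clause is 1.0 — the worked form shows it unboosted.
Expansion clauses deliberately stay below 1 so an expansion can add
evidence but never outrank a document matching the original phrase with
otherwise equal clauses.

Part 2 of the concept query (field-tagged phrases and other terms) is
searched over the aggregated field; field restriction is the job of the
field-tagged strategy. The stop/interstitial list is the standard English
list plus dataset-search boilerplate (`related, versus, role, effect, data,
dataset(s), study/studies, search, find`); it is configurable, as is the
head/tail boilerplate pattern list. Chunking is rule-based (boundaries at
removed words) rather than parser-based; a dependency parser could split
chunks more accurately but adds a heavyweight dependency for marginal gain
at these query lengths.

## Embeddings

The expansion model is a subword skip-gram: each vocabulary word is a bag
of character n-grams (3–6 by default) plus a whole-word symbol; its vector
is the **sum** of the subword vectors; training is skip-gram with negative
sampling (5 negatives, unigram^0.75 table) by plain SGD, single-threaded
and fully deterministic for a fixed seed. Window 1 is the default: small
windows capture word function/relatedness rather than topical association,
which is what query expansion needs. Defaults (dim 100, min_count 5,
epochs 5) are sized for desk-scale corpora.

Multiword phrases are formed beforehand by one collocation-merge pass:
adjacent pair `a b` merges to `a_b` when
`(count(ab) - min_count) · N / (count(a)·count(b))` exceeds a threshold.
Trained neighbour lists are corpus-dependent, so the expansion backend is
an interface and a deterministic lexicon (synonym-table) backend is
provided for tests and for curated synonym lists.

## Multiphase execution

The default schedule relaxes, in decreasing-precision order: concept-part
minimum-should-match by one, then by one again; phrase slop 0 → 2;
descendant + implicit concept expansion on; unigram fallback. Phase 1 is
the strictest form (all sub-queries required, slop 0, no expansion). Each
phase retrieves the full `top_n` (default 1000) independently — phases are
side-effect-free and could run in parallel — and aggregation concatenates
them with earlier-phase precedence and deduplication. Scores are not
comparable across phases, so aggregated runs report the synthetic monotone
score `top_n - rank + 1` in TREC run files.

## Evaluation

Grades are 0/1/2; gains are linear in grade. P@10 divides by k regardless
of how many documents were retrieved; "+partial" counts grades {1,2},
"−partial" grade 2 only. NDCG@10 uses `gain/log2(rank+1)` with the ideal
ranking over all judged documents; unjudged documents count as non-relevant
in all exact metrics. Mean metrics are unweighted arithmetic means over
queries, including zero-relevant queries (configurable).

For pooled-then-sampled judgments the qrels dialect carries an optional
stratum id and sampling rate per line, and grade `-1` marks a pool member
that was not drawn for judging — inferred metrics must distinguish
sampled-out pool members from never-pooled documents.

**infAP** is the ratio of two inverse-sampling-rate (Horvitz–Thompson)
sums: the expected-precision mass at judged-relevant retrieved ranks (the
relevant count above a rank is HT-estimated from judged documents above)
over the HT estimate of the number of relevant documents. Both sums are
exactly unbiased; the first-order bias of their ratio — numerator and
denominator share the sampled relevant documents — is removed analytically:
`Cov(T, R̂)` and `Var(R̂)` are (bi)linear in the known Bernoulli inclusion
indicators, so both admit unbiased plug-in estimates from the sample
itself, leaving O(1/R²) residual bias. A smoothed judged-above ratio
estimator was considered and rejected: when no judged document lies above a
low rank it defaults to 1/2, which biases the estimate noticeably on
top-heavy rankings.

**infNDCG** HT-weights the judged gains at the retrieved top-k ranks
(`grade/(rate·log2(rank+1))`), which is exactly unbiased for the true DCG
under within-stratum uniform sampling — stratum-mean imputation of
unjudged ranks was rejected because it is biased whenever relevance
correlates with rank inside a stratum, which is the normal case. The ideal
DCG scales judged per-grade counts by inverse rates and fills rank
positions fractionally, so it varies smoothly and reduces to the exact
ideal at rate 1. Both inferred metrics reduce *exactly* to AP/NDCG at full
judgment, and both are clamped to [0, 1]; near the upper boundary the clamp
makes them conservative, since no [0, 1]-bounded estimator can be unbiased
when the truth approaches 1.

## Synthetic fixtures

The generators are pure functions of a seeded `FixtureSpec`. Defaults: 60
concepts (tree depth 4, 2 synonyms each, 20% written comma-inverted), 20
genes (30% case-sensitive), 300 records with 3 planted concept mentions
each, 15 queries of 1–3 target concepts (synonym surface with probability
0.5; with probability 0.3 a target is replaced by the planted concept's
parent so only descendant expansion reaches the relevant records). Grades
are a known function of concept overlap: 2 when a record covers every
queried concept directly or via a descendant, 1 for a strict non-empty
subset, 0 otherwise — mirroring graded judging guidance in which a more
specific form of a queried concept counts as relevant but a more generic
one does not.

Record text is template English ("Study of X in mouse samples"), not
prose. That suffices for exact-match tagging, BM25 and the end-to-end
discrimination property, but it means passing tests demonstrate the
*mechanics* — concept reachability, phase ordering, boost structure — and
not performance on real metadata, which has noisier surfaces (spelling
variants, abbreviations, passing references) that this generator does not
emulate. The test suite runs the end-to-end comparison at 300 records / 15
queries, a size chosen so the full suite completes in well under a minute
while still exercising every relaxation phase.

## Known limitations

* No statistical NER, abbreviation resolution or semantic disambiguation —
  a gene literally named "anxiety" will be tagged wherever the word occurs.
* No negation or contradiction handling; non-English content is indexed
  as-is.
* Conjunction distribution ("stage I, II and III breast cancer") is out of
  scope; such phrases tag only what matches literally.
* Duplicate records are indexed as distinct documents and not deduplicated.
* The index is in-memory with JSON persistence: fine for metadata-scale
  corpora (10⁴–10⁵ records), not engineered for web-scale collections.
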