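# Methods

## The statistic

The package quantifies *conceptual coverage*: how much of what ICI-treated
patients spontaneously write about their HRQoL is measured by the EORTC
QLQ-C30 and the FACT-G.  The inputs are a two-level taxonomy (8 domains →
42 subdomains) with, per subdomain, an occurrence count and a concept map
assigning each subdomain the set of questionnaire items that measure it
(empty set = uncovered; coverage is binary — no partial-coverage grading is
attempted because none is defined for the source table).

An **occurrence is a distinct patient**, not a post.  This is forced by the
published arithmetic: the Global-health domain partitions its 115
occurrences into 63 + 32 + 20 patients judging their state poor/stable/
good, and the per-domain patient counts (76 patients, 123 Symptoms
occurrences) only cohere if a patient counts once per subdomain but can
contribute several subdomains of one domain.  The mention aggregator
therefore deduplicates (patient, subdomain) pairs across posts while
keeping every contributing post as evidence.

Rates are exact `Fraction`s; percentages are produced only at presentation
(one decimal, half-up), which reproduces printed values like 68/123 → 55.3
and 7/49 → 14.3 without floating-point ambiguity.

### A known irreconcilability

Counting checkmarked rows of the packaged 42-row table gives 23/42
subdomains covered by the QLQ-C30 and 14/42 by the FACT-G.  The narrative
accompanying the original table instead prints 45 % (19/42) and 29 %
(12/42).  No assignment of checkmarks to the printed table yields those
numbers; the fixture follows the table as printed, the package reports the
row counts, and the discrepancy is deliberately left visible rather than
reconciled by guesswork.  These global percentages are the only published
quantities the pipeline does not reproduce.

## Corpus funnel

* **Inclusion** — a post is retained iff its date lies in the half-open
  study window (default 2011‑01‑01 ≤ d < 2018‑09‑01, covering the
  published collection period inclusive of its last day) and its text
  contains an ICI keyword.  Matching is accent/case-folded with word
  boundaries, so `IMMUNOTHÉRAPIE` matches but `nivolumabesque` does not.
  The original keyword appendix is not public; the packaged lexicon is a
  documented reconstruction covering the seven ICI compounds, their brand
  names and the class terms, and is config-replaceable.
* **Deduplication** — scoped to one alias (the rule targets users
  re-posting the same message on several platforms).  Exact matches on
  normalized text short-circuit; otherwise Jaccard similarity of the
  preprocessed token sets with threshold 0.9 (only "similar posts" is
  specified upstream; exact duplicates are the guaranteed case and the
  threshold is exposed in config).  The earliest-dated post wins, ties
  break on post id, and the operation is idempotent.
* **Deidentification** — four regex classes replaced by placeholders:
  emails (RFC-style `local@domain`), French phone numbers (ten digits
  starting 0 with optional separators, or `+33` form), standalone 5-digit
  postal codes, and proper names (a packaged dictionary matched
  capitalized, plus a capitalized-token heuristic after honorifics such as
  `Dr`/`Mme`).  Priority email > phone > postal > name resolves overlaps
  (postal codes are never carved out of phone numbers).  Placeholders match
  none of the patterns, so the operation is idempotent.
* **Cleaning** — fixed order: accent fold → lowercase → punctuation strip →
  whitespace tokenisation → stop-word removal → stemming.  The stop-word
  list is authored for this package (none is specified upstream) and is
  override-able; it deliberately contains function words and auxiliaries
  only.
* **Document-term matrix** — vocabulary keeps tokens with total corpus
  frequency ≥ 2 (default) minus an explicit exclusion list (the hook for
  "ambiguous/misspelled" words; empty by default — no spell checker is
  attempted).  Weighting is raw counts or sklearn's smoothed, L2-normalised
  tf-idf (default).  Export is Matrix Market + CSV sidecars.

## Stemming

The cleaning order folds accents *before* stemming, so the packaged French
Porter-family (Snowball) stemmer is expressed in accent-folded form: the
standard algorithm's regions (RV/R1/R2), vowel-marking (`u`/`i` between
vowels, `y` beside a vowel, `u` after `q`), longest-match semantics and
step structure are implemented as published, but suffix tables collapse
accented endings onto their folded counterparts (`-ée → -ee`, `-ité →
-ite`, …).  Folded suffixes that would collide with common nominal endings
(`-ât`, `-âmes`, `-îtes`) are dropped instead of being allowed to overstem
(e.g. *limites* keeps its stem `limit`).  Two behavioural consequences are
accepted and documented: accent-dependent protections vanish (*très* stems
to `tre` rather than `tres`), and all of *é/è/ê* behave as plain *e*.
Because the lexicon phrases run through the identical pipeline, annotation
is insensitive to these choices; the test suite freezes hand-traced
input/stem pairs as the regression oracle.

## Annotation

A subdomain is detected in a post iff one of its trigger phrases —
preprocessed with the same pipeline — occurs as a contiguous stem
sequence.  The packaged 42-entry French lexicon is seeded from the verbatim
patient quotes that illustrate the taxonomy and is curated so no processed
phrase is contained in another (a structural requirement for closed-world
precision 1.0, asserted in tests).  The upstream annotation was manual;
this lexicon annotator is the package's operationalisation, and its
validation surface is ground-truth recovery on synthetic corpora — not
agreement with human coders, which cannot be measured here.

Global-health polarity (poor/stable/good) is a phrasebook vote over the
patient's global-health evidence texts (folded substring counts); ties
break by the fixed priority poor > stable > good, and a patient with no
polarity phrase is called "stable" with a logged low-confidence flag.

## Synthetic corpus generator

The generator's defaults are the study conditions: 150 patients; reporter
split 0.593/0.407; gender 0.547/0.400/0.053; cancer mix
lung 0.307 / melanoma 0.273 / other 0.240 / undetermined 0.180; drug mix
matching the published keyword frequencies (48 % class-term
"immunothérapie"); global-health split 0.548/0.278/0.174; per-subdomain
mention prevalence = published occurrences / 150.  Posts-per-patient is
only pinned upstream by median 2 and max 11; the default family is a
geometric distribution truncated to [1, 11] with p = 0.38, which gives
median 2 with wide margin across seeds (the published mean of ≈1.78 posts
per patient is not jointly achievable with median 2 in this family; the
median/max constraints were kept).  This choice was made once, before any
validation was run, and is exposed in config.

Each non-decoy post embeds one ICI keyword and the trigger phrases of the
subdomains assigned to it (round-robin over the patient's posts, so every
planted mention is expressed at least once), inside filler sentences
verified not to contain any trigger sequence.  PII is injected at rate
0.10 using the deidentifier's four classes; duplicates re-emit a post's
exact text under another source at rate 0.08; decoys (no ICI keyword,
separate aliases) are added so they form 0.10 of the corpus.  A
**deterministic assignment mode** plants an exact occurrence vector
(choosing `occ(s)` patients per subdomain without replacement) and
apportions categorical margins by largest remainder, which makes the
published cohort table and occurrence vector exactly reproducible; the
63/32/20 global-health partition falls out of apportioning the published
percentages over the 115 global-health mentioners.

What the generator does **not** emulate: real discourse (posts are
template text), negation or hedging, misspellings, multi-alias users,
annotator disagreement, or lexical variation beyond the lexicon.  Passing
closed-world tests therefore demonstrates the pipeline's mechanics are
exact, not that the lexicon would reach human-level recall on real posts.

## Numerical / design choices

* All randomness flows from one `numpy` `default_rng(seed)`; corpora are
  byte-identical for equal configs.
* Duplicate similarity threshold 0.9, date tie-break by post id; funnel
  order filter → dedup → deidentify is fixed, and reordering dedup before
  filter provably leaves the final post set unchanged on generator corpora
  (tested).
* Zero-occurrence domains raise for single-domain queries and are flagged
  (never silently dropped) in full reports; fully covered/uncovered
  domains report 1.0/0.0 without special-casing.
* The Venn partition is computed exactly over all 2^8 domain subsets;
  rendering draws at most 3 circles (regions beyond that cannot be drawn
  faithfully) while the complete partition is always emitted as a table.
  Patient-level co-occurrence counts of the original cohort were never
  published, so the partition is validated against a brute-force
  enumeration oracle on synthetic data only.
* Validation scale: closed-world end-to-end runs use the 150-patient
  deterministic corpus (~420–500 posts); margin goodness-of-fit uses
  5 000 patients (χ², α = 0.001); oracle-equivalence checks use 200
  randomized small instances each.

## Limitations

The headline coverage statistics are exactly reproducible because the
published table is their complete input.  Everything corpus-side is
validated only against synthetic data; no claim is made about recall on
real social-media text, where a trigger lexicon without negation handling
or spelling normalisation would miss and miscount mentions.  The
deidentifier's name detection is dictionary + honorific heuristics and
will not catch arbitrary names.
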