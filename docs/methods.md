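# Methods note

This note records what each stage computes, the numerical choices behind it,
and the limits of what the synthetic fixtures can demonstrate.

## Tagging: linear-chain CRF with exact k-best decoding

Two first-order linear-chain CRFs over the label set {B, I, O} are trained by
L2-regularized maximum likelihood (objective: negative log-likelihood +
`0.5 * l2 * ||theta||^2`, default `l2 = 1.0`), with analytic gradients from
forward–backward marginals, optimized by scipy's L-BFGS-B (default
`max_iter = 150`, `ftol = 1e-9`, zero initialization — the objective is
convex, so the optimum is seed-independent). Features per token: identity,
lowercase form, 2–4 character affixes, orthographic flags, a character-shape
class, and a ±2 lowercase word window.

The backward model is trained and decoded on reversed token sequences with
labels *span-remapped* (not merely reversed), so IOB2 validity is preserved
in both directions and backward solutions map back to the same character
spans.

Decoding keeps, at every (position, label) state, the k best scored partial
hypotheses with full label history. Because the chain score decomposes over
transitions, a prefix not among the k best at some state cannot appear in any
top-k completion, so the k-best list is exact — no beam pruning error. Ties
are broken deterministically (higher score first, then lexicographic labels
with B < I < O). A `valid_only` flag restricts the search to IOB2-valid
sequences; the pipeline always sets it, while the default (`False`) exposes
the full `3^n` space that the enumeration oracle in the tests requires.

Both directions decode the top 20 solutions (`k = 20`); the 40 combined
solutions define each variant's frequency = (solutions containing that exact
span) / 40.

## Confidence scoring

Logistic regression (scikit-learn, liblinear-compatible default solver) over
a `DictVectorizer` of: the continuous frequency, nine morphology flags
(has/starts/ends × upper/lower/digit), bag-of-content tokens, and the two
tokens of context on each side. Regularization strength is selected from
`C ∈ {0.1, 1, 10}` by 5-fold stratified cross-validation (shuffled with the
run seed). Variants scoring below the threshold (default **0.2**) are
dropped; this is the recall/precision dial of the whole system, and the test
suite verifies that retained sets are *nested* as the threshold sweeps 0 → 1.

Hard selection (`select_nonoverlapping_max`) exists for consumers that need
non-overlapping mentions: repeatedly keep the highest-scoring variant
(ties: longer, then leftmost) and discard everything overlapping it.

## Abbreviation filtering

Abbreviation–definition pairs are detected with the Schwartz–Hearst
right-to-left alignment (short form 2–10 characters containing a letter;
long-form window of min(|SF| + 5, 2·|SF|) words). If a short form is tagged
as a gene but no variant overlaps its long form at the definition site, every
exact-text occurrence of the short form in the article is removed,
case-sensitively. This trades a small recall loss for the large precision
gain of suppressing non-gene acronyms (MRI, PCR, …) that look like gene
symbols.

## Species designation

A name → TaxID dictionary is matched longest-first with alphanumeric
boundaries; names of ≤ 4 characters match case-sensitively (short vernacular
forms collide with ordinary words), longer names case-insensitively. Rules in
strict precedence per variant:

1. a species mention inside the variant span, else the nearest *preceding*
   mention in the sentence, else a one-letter prefix (`h`, `y`, `m`, `r`,
   `d` → human, yeast, mouse, rat, fly) when the next character is an upper
   case letter or digit;
2. the nearest species mention in the sentence by character distance;
3. the article-majority species (ties: first seen).

Rule subsets are configurable (`PipelineConfig.species_rules`); ablation
{1} → {1,2} → {1,2,3} can only add assignments, so recall is monotone — a
property the tests check.

## Dictionary retrieval, regex filtering, resolution

Names from an NCBI `gene_info`-layout table (Symbol, Synonyms, dbXrefs,
description, authority symbol/full name, other designations; `|`-separated,
`-` = missing) are normalized by five rewrite rules applied in order: split
UPPER{2,}+lower{2,}, split lower{2,}+UPPER{2,}, replace non-word characters
except `.` with space, delimit digit/dot runs, collapse whitespace — then
lowercase. The rules are idempotent; e.g. `IL1-ALPHA` → `il 1 alpha`. Note
the case-split rule separates `ATPase` → `atp ase`; since query and record
are normalized identically, discrimination between names differing by a
trailing token (`Na,K-ATPase beta` vs `Na,K-ATPase`) is preserved.

Retrieval uses a per-TaxID inverted index over normalized tokens with
interchange classes (Arabic ↔ Roman numerals: Arabic → Roman generated up to
3999, Roman → Arabic recognized only for i–xx to avoid misreading words like
"mix"; Greek names ↔ Latin initials, alpha ↔ a). Candidates are scored
`sqrt(coverage_query × coverage_record)` with idf-weighted coverage
(`idf = log((N+1)/(df+1)) + 1`), capped at the top 50. This ranking is a
stand-in for an external search engine; its exact ordering is not the
correctness mechanism. The correctness mechanism is the **anchored regex
filter**: the query compiles to `^ tok1 tok2 … $` where each token is an
alternation of its interchange class, and only candidate names whose
normalized form matches in full survive.

Resolution: if all surviving records agree on one GeneID, assign it; else if
authority-column records (Symbol, nomenclature-authority symbol/full name)
single out one GeneID, assign that; else abstain. Overlapping variants that
resolve to different GeneIDs are disambiguated in favor of the longest
variant. One output row per (article, GeneID), keeping the maximum
confidence.

## Evaluation

Micro-averaged precision/recall/F over (article, GeneID) pairs, and TAP-k:
per article, the ranked list is truncated at the k-th false positive
(inclusive); the score is (Σ precision at each relevant rank + precision at
the truncation point) / (|gold| + 1), averaged over articles. The `+1`
terminal term rewards rankings that stop before accumulating false positives.

## What the synthetic fixtures do and do not show

The generator builds a closed world: gene symbols with dictionary entries,
species names, tagged training sentences (with curator-style *acceptable
alternative* spans), abbreviation decoys, cross-species symbol collisions,
and PMC-style XML articles with a gold key. It emulates the *mechanisms* the
pipeline must handle — boundary ambiguity, name variation within the rewrite
rules' reach, species ambiguity, non-gene acronyms — under a vocabulary and
grammar far simpler than real biomedical text. Metrics computed on it
(e.g. P = 1.0 / R = 0.96 on the demo world) measure internal consistency of
the implementation, not expected performance on real articles, which depends
on corpus-scale training data and a full Entrez Gene dump that are not
shipped here.

## Design resolutions

- k-best decoding is exact by construction; the tests compare it against full
  enumeration rather than trusting the derivation.
- `valid_only` defaults to off so the decoder's contract is the raw score
  order over all label sequences; the pipeline opts in to IOB2 validity.
- Roman-numeral interchange is asymmetric (generate any, recognize few) to
  keep precision on ordinary tokens.
- All randomness flows from explicit integer seeds (corpus generation, CV
  folds); CRF training is deterministic given the data. Two runs with the
  same seed and configuration produce byte-identical output files.

## Limitations

- The CRF is first-order with modest feature templates; no character-level
  model or external lexicon features.
- The abbreviation filter removes by exact text, so a string that is both a
  valid gene and a defined non-gene abbreviation in the same article is lost.
- Species designation has no document-structure prior beyond the majority
  rule; figure captions and references are treated like body text once
  sections pass the type filter.
- The retrieval cap (50) and threshold (0.2) are configuration defaults, not
  fitted values; on real data they would be tuned on held-out articles.
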