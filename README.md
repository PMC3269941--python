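# softgn — cross-species full-text gene normalization by soft tagging

`softgn` maps textual mentions of genes in full-text biomedical articles to
standard database identifiers (Entrez Gene GeneIDs). The central idea is
**soft tagging**: instead of committing to a single set of mention boundaries,
the tagger emits many overlapping candidate spans ("variants") with confidence
scores, and boundary ambiguity is resolved *late*, against the gene
dictionary, where the evidence to resolve it actually lives.

## The scientific problem

Gene normalization is hard for three compounding reasons:

1. **Boundary ambiguity.** Is the mention "Acetyl-CoA carboxylase",
   "CoA carboxylase", or just "carboxylase"? A hard tagger must pick one and
   propagates its mistake; dictionary lookup often only succeeds for one
   particular boundary choice.
2. **Name variation.** The dictionary says `IL1A`; the article says
   "IL-1 alpha". Hyphens, case, Greek letters, and Roman numerals all vary
   freely between authors and databases.
3. **Species ambiguity.** The same symbol names different genes in human,
   mouse, rat, yeast, and fly. Full-text articles rarely restate the species
   next to every mention.

## The model

The pipeline (one pass per article):

1. **n-best bidirectional CRF tagging.** Two linear-chain CRFs over IOB2
   labels — one reading left-to-right, one right-to-left — each decode the
   top-20 label sequences *exactly* (k-best Viterbi, no beam approximation).
   The 40 combined solutions yield overlapping variants, each with a
   *frequency* (fraction of solutions containing that exact span).
2. **Confidence scoring.** A logistic regression over the variant's
   frequency, morphology, content tokens, and ±2 context tokens produces a
   confidence score; variants below a threshold (default 0.2) are dropped.
3. **Abbreviation filtering.** Schwartz–Hearst abbreviation definitions are
   detected; if a short form is tagged as a gene but its long form at the
   definition site is not, every occurrence of that short form in the article
   is removed (it is an abbreviation of something that is not a gene).
4. **Species designation.** Each variant gets a TaxID by precedence:
   a species word inside/preceding the mention in the same sentence (Rule 1,
   including one-letter prefixes such as `hTERT`), the nearest species word
   in the sentence (Rule 2), or the article-majority species (Rule 3).
5. **Dictionary retrieval and resolution.** Gene names from an NCBI
   `gene_info`-layout table are normalized by five rewrite rules (case
   splits, punctuation, digit runs, whitespace, lowercasing) and indexed.
   Retrieval is coverage-scored token overlap with Roman/Greek interchange
   classes; a query-derived *anchored regular expression* then keeps only
   names that match the variant token-for-token; resolving rules assign a
   GeneID when it is unique or when an authority-column name breaks the tie.

Scoring of a run uses micro-averaged precision/recall/F and TAP-k
(threshold average precision).

## Worked example

The retrieval phase for the query (TaxID 9606, variant text `IL-1 alpha`)
produces 14 candidate name records; the anchored regex filter keeps only the
names that are token-for-token interchangeable with the query, and the
resolving phase assigns the GeneID:

```python
from softgn import regex_filter, resolve
from softgn.fixtures import worked_example_candidates

candidates = worked_example_candidates()
kept = regex_filter(candidates, "IL-1 alpha")
print(f"{len(candidates)} candidates -> {len(kept)} retained")
for c in kept:
    print(f"  {c.record.geneid}  {c.record.name!r:14} {c.record.column}")
print("resolved GeneID:", resolve(kept))
```

Output:

```text
14 candidates -> 6 retained
  3552  'IL1ALPHA'     Synonyms
  3552  'IL-1A'        Synonyms
  3552  'IL1A'         Symbol_from_nomenclature_authority
  3552  'IL1-ALPHA'    Synonyms
  3552  'IL1A'         Symbol
  3552  'IL-1 alpha'   Other_designations
resolved GeneID: 3552
```

Note what the filter rejects: `IL1` and `IL-1` (missing the `alpha` token,
and `IL-1` is ambiguous between GeneIDs 3552 and 3553), `IL-1R-alpha` (an
extra `R` token — the receptor, a different gene), and the near-miss `ILIA`
(normalizes to a single token, so the anchored pattern cannot match).

## End-to-end demo on synthetic data

The package ships a deterministic synthetic-world generator (gene symbols,
dictionaries, species names, tagged training sentences, and PMC-style XML
articles with a gold key), so the whole pipeline can be exercised without any
licensed corpus:

```bash
softgn make-fixtures fx --n-sentences 120 --n-articles 8 --seed 5
softgn train-scorer models.pkl --n-sentences 120 --seed 5
softgn build-index fx/gene_info.tsv index.pkl
softgn run fx/articles/*.xml --models models.pkl --index index.pkl \
    --species-dict fx/species.tsv --out pred.tsv
softgn evaluate pred.tsv fx/gold.tsv
```

Output of the final two commands on this configuration:

```text
25 gene ids written to pred.tsv
{
  "precision": 1.0,
  "recall": 0.9615,
  "f_score": 0.9804,
  "tap_5": 0.975,
  "tap_10": 0.975,
  "tap_20": 0.975
}
```

(Training prints `scorer CV accuracy 0.9937` for this world. Numbers measure
pipeline consistency on generated data, not performance on real articles.)

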