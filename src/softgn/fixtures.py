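"""Synthetic fixtures: tagged corpora, toy dictionaries, and worked examples.

Everything the pipeline needs — a tagged training corpus with
curator-acceptable alternative spans, a gene_info-layout dictionary, a
species-name dictionary, and full-text-style articles with a gold
article-to-GeneID answer key — is generated deterministically from a seed.
The generated world deliberately contains the hard cases the system is built
for: names differing only in a trailing Greek token, identical symbols shared
across two species, organism-prefixed symbols (hABC1), parenthesized
abbreviation definitions of non-genes, and mentions whose only species cue is
elsewhere in the article.

The module also freezes, as data, the worked retrieval example used
throughout: the 14 candidate rows for the query (TaxID:9606, "IL-1 alpha").
One row's name carries the typographical form "ILIA" as printed; a corrected
variant ("IL1A") is available separately.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .corpus import tokenize_fine
from .genedict import Candidate, GeneRecord

__all__ = [
    "SyntheticCorpusSpec",
    "TaggedSentence",
    "SyntheticGene",
    "worked_example_candidates",
    "worked_example_gene_info_text",
    "make_genes",
    "make_tagged_corpus",
    "make_gene_dict",
    "make_species_dict",
    "make_articles",
    "write_fixture_dir",
]

# ---------------------------------------------------------------------------
# Worked retrieval example: 14 candidates for (TaxID:9606, "IL-1 alpha")

_WORKED_EXAMPLE_ROWS = (
    ("9606", "3552", "ILIA", "Synonyms", 1.0000),
    ("9606", "3552", "IL1ALPHA", "Synonyms", 1.0000),
    ("9606", "3552", "IL-1A", "Synonyms", 1.0000),
    ("9606", "3552", "IL1A", "Symbol_from_nomenclature_authority", 1.0000),
    ("9606", "3552", "IL1-ALPHA", "Synonyms", 1.0000),
    ("9606", "3552", "IL1A", "Symbol", 1.0000),
    ("9606", "3552", "IL-1 alpha", "Other_designations", 1.0000),
    ("9606", "3554", "IL-1R-alpha", "Synonyms", 1.0000),
    ("9606", "26525", "IL1F5 (Canonical product IL-1F5a)", "Other_designations", 0.7459),
    ("9606", "27177", "IL1F8 (Canonical product IL-1F8a)", "Other_designations", 0.7459),
    ("9606", "84639", "IL-1F10 (canonical form IL-1F10a)", "Other_designations", 0.7459),
    ("9606", "3552", "IL1", "Synonyms", 0.6417),
    ("9606", "3553", "IL1", "Synonyms", 0.6417),
    ("9606", "3553", "IL-1", "Synonyms", 0.6417),
)


def worked_example_candidates(corrected: bool = False) -> list[Candidate]:
    """The frozen retrieval-phase candidate list for query (9606, "IL-1 alpha").

    With ``corrected=True`` the first row's name reads "IL1A" instead of the
    typographical "ILIA"."""
    out = []
    for taxid, geneid, name, column, score in _WORKED_EXAMPLE_ROWS:
        if corrected and name == "ILIA":
            name = "IL1A"
        out.append(Candidate(GeneRecord(taxid, geneid, name, column), score))
    return out


def worked_example_gene_info_text(corrected: bool = False) -> str:
    """The same 14 name records re-expressed as gene_info-layout rows, usable
    to build a searchable index reproducing the worked example."""
    first_syn = "IL1A" if corrected else "ILIA"
    rows = [
        # tax, GeneID, Symbol, LocusTag, Synonyms, dbXrefs, chr, map, desc,
        # type, SymAuth, FullAuth, NomStatus, OtherDesignations, ModDate
        ("9606", "3552", "IL1A", "-",
         f"{first_syn}|IL1ALPHA|IL-1A|IL1-ALPHA|IL1", "-", "2", "-",
         "-", "protein-coding", "IL1A", "-", "O",
         "IL-1 alpha", "20100522"),
        ("9606", "3553", "-", "-", "IL1|IL-1", "-", "2", "-", "-", "-",
         "-", "-", "-", "-", "20100522"),
        ("9606", "3554", "-", "-", "IL-1R-alpha", "-", "2", "-", "-", "-",
         "-", "-", "-", "-", "20100522"),
        ("9606", "26525", "-", "-", "-", "-", "2", "-", "-", "-", "-", "-",
         "-", "IL1F5 (Canonical product IL-1F5a)", "20100522"),
        ("9606", "27177", "-", "-", "-", "-", "2", "-", "-", "-", "-", "-",
         "-", "IL1F8 (Canonical product IL-1F8a)", "20100522"),
        ("9606", "84639", "-", "-", "-", "-", "2", "-", "-", "-", "-", "-",
         "-", "IL-1F10 (canonical form IL-1F10a)", "20100522"),
    ]
    return "\n".join("\t".join(r) for r in rows) + "\n"


# ---------------------------------------------------------------------------
# Synthetic world

SPECIES_TABLE = (
    # (taxid, canonical name, extra dictionary names)
    ("9606", "human", ("Homo sapiens",)),
    ("4932", "yeast", ("Saccharomyces cerevisiae",)),
    ("10090", "mouse", ("Mus musculus",)),
    ("10116", "rat", ("Rattus norvegicus",)),
    ("7227", "fruit fly", ("Drosophila melanogaster",)),
)

_ADJS = ("nuclear", "mitochondrial", "ribosomal", "cytosolic", "membrane",
         "zinc", "serum", "hepatic")
_NOUNS = ("kinase", "phosphatase", "receptor", "transporter", "carboxylase",
          "reductase", "synthase", "helicase")
_GREEK = ("alpha", "beta", "gamma", "delta")
_FILLERS = (
    "was measured after treatment",
    "regulates cell growth",
    "is an essential enzyme",
    "was strongly induced",
    "showed reduced activity in mutants",
    "binds the promoter region",
)
# non-gene abbreviation definitions for filter stress
_NONGENE_DEFS = (
    ("N-acetyl-aspartate", "NAA"),
    ("magnetic resonance imaging", "MRI"),
    ("polymerase chain reaction", "PCR"),
    ("total parenteral nutrition", "TPN"),
    ("blood brain barrier", "BBB"),
)


@dataclass(frozen=True)
class SyntheticGene:
    taxid: str
    geneid: str
    symbol: str
    full_name: str
    synonyms: tuple[str, ...]


@dataclass(frozen=True)
class TaggedSentence:
    text: str
    labels: tuple[str, ...]
    # curator-acceptable (start, end) spans: the gold mention plus alternatives
    acceptable: frozenset[tuple[int, int]]
    geneid: str | None = None
    taxid: str | None = None

    @property
    def tokens(self):
        return tokenize_fine(self.text)


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Study conditions for the generated corpus.

    ``ambiguity_rate`` is the fraction of gene symbols duplicated into a
    second species under a different GeneID; ``species_rate`` the fraction of
    sentences carrying an explicit species name; ``abbrev_rate`` the fraction
    of sentences that are non-gene abbreviation definitions; ``alt_rate`` the
    probability that a multi-word mention also lists a shorter
    curator-acceptable alternative span.
    """

    n_sentences: int = 200
    n_genes: int = 30
    species_rate: float = 0.7
    abbrev_rate: float = 0.1
    ambiguity_rate: float = 0.2
    alt_rate: float = 0.6
    seed: int = 0


def make_genes(spec: SyntheticCorpusSpec) -> list[SyntheticGene]:
    rng = random.Random(spec.seed)
    genes: list[SyntheticGene] = []
    used_symbols: set[str] = set()
    next_id = 1000
    species = [s[0] for s in SPECIES_TABLE]
    for i in range(spec.n_genes):
        while True:
            letters = "".join(rng.choice("ABCDEFGHKLMNPQRSTVWXYZ")
                              for _ in range(3))
            symbol = f"{letters}{rng.randint(1, 9)}"
            if symbol not in used_symbols:
                used_symbols.add(symbol)
                break
        adj, noun = rng.choice(_ADJS), rng.choice(_NOUNS)
        full = f"{adj} {noun}"
        if rng.random() < 0.5:
            full = f"{full} {rng.choice(_GREEK)}"
        hyphenated = f"{letters}-{symbol[len(letters):]}"
        taxid = species[i % len(species)]
        genes.append(SyntheticGene(taxid, str(next_id), symbol, full,
                                   (hyphenated,)))
        next_id += 1
        if rng.random() < spec.ambiguity_rate:
            other = rng.choice([s for s in species if s != taxid])
            genes.append(SyntheticGene(other, str(next_id), symbol,
                                       f"{adj} {noun} homolog", (hyphenated,)))
            next_id += 1
    return genes


def _species_name(rng: random.Random, taxid: str) -> str:
    for tid, canonical, extra in SPECIES_TABLE:
        if tid == taxid:
            return rng.choice((canonical,) + extra)
    raise KeyError(taxid)


def _label_span(text: str, start: int, end: int) -> tuple[str, ...]:
    labels = []
    inside = False
    for tok in tokenize_fine(text):
        if tok.start >= start and tok.end <= end:
            labels.append("I" if inside else "B")
            inside = True
        else:
            labels.append("O")
            inside = False
    return tuple(labels)


def _make_sentence(rng: random.Random, genes: list[SyntheticGene],
                   spec: SyntheticCorpusSpec) -> TaggedSentence:
    if rng.random() < spec.abbrev_rate:
        long_form, short = rng.choice(_NONGENE_DEFS)
        text = f"Levels of {long_form} ({short}) {rng.choice(_FILLERS)}."
        return TaggedSentence(text, tuple("O" for _ in tokenize_fine(text)),
                              frozenset())
    gene = rng.choice(genes)
    mention = rng.choice((gene.symbol, gene.symbol, gene.full_name,
                          gene.synonyms[0]))
    with_species = rng.random() < spec.species_rate
    sp = _species_name(rng, gene.taxid) if with_species else None
    template = rng.randint(0, 3)
    if template == 0 and sp:
        prefix = f"The {sp} gene "
        text = f"{prefix}{mention} {rng.choice(_FILLERS)}."
    elif template == 1 and sp:
        prefix = "Expression of "
        text = f"{prefix}{mention} in {sp} {rng.choice(_FILLERS)}."
    elif template == 2 and sp:
        prefix = ""
        text = f"{mention} from {sp} {rng.choice(_FILLERS)}."
    else:
        prefix = "We found that "
        text = f"{prefix}{mention} {rng.choice(_FILLERS)}."
    start = len(prefix)
    end = start + len(mention)
    assert text[start:end] == mention
    acceptable = {(start, end)}
    words = mention.split()
    if len(words) >= 2 and rng.random() < spec.alt_rate:
        # a shorter curator-acceptable alternative dropping the leading word
        alt_start = start + len(words[0]) + 1
        acceptable.add((alt_start, end))
    labels = _label_span(text, start, end)
    return TaggedSentence(text, labels, frozenset(acceptable),
                          geneid=gene.geneid, taxid=gene.taxid)


def make_tagged_corpus(spec: SyntheticCorpusSpec) -> list[TaggedSentence]:
    """Deterministic tagged corpus: sentence text, IOB2 labels over the fine
    tokenization, and the curator-acceptable span set per sentence."""
    rng = random.Random(spec.seed + 1)
    genes = make_genes(spec)
    return [_make_sentence(rng, genes, spec) for _ in range(spec.n_sentences)]


def make_gene_dict(spec: SyntheticCorpusSpec,
                   genes: list[SyntheticGene] | None = None) -> str:
    """gene_info-layout TSV text for the synthetic gene set, with the worked
    retrieval-example rows appended so both live in one dictionary."""
    genes = make_genes(spec) if genes is None else genes
    rows = []
    for g in genes:
        rows.append((
            g.taxid, g.geneid, g.symbol, "-", "|".join(g.synonyms), "-",
            "-", "-", f"{g.full_name} gene", "protein-coding", g.symbol,
            g.full_name, "O", "-", "20100522",
        ))
    body = "\n".join("\t".join(r) for r in rows)
    return body + "\n" + worked_example_gene_info_text()


def make_species_dict(spec: SyntheticCorpusSpec,
                      gene_taxids: set[str] | None = None) -> str:
    """Two-column species TSV covering every TaxID of the synthetic world
    (plus 9606 for the worked example).  If ``gene_taxids`` is given, raises
    when the dictionary would not cover one of them."""
    lines = ["# name\ttaxid"]
    covered = set()
    for taxid, canonical, extra in SPECIES_TABLE:
        for name in (canonical,) + extra:
            lines.append(f"{name}\t{taxid}")
        covered.add(taxid)
    if gene_taxids is not None:
        missing = set(gene_taxids) - covered
        if missing:
            raise ValueError(
                f"species dictionary does not cover TaxIDs: {sorted(missing)}"
            )
    return "\n".join(lines) + "\n"


def make_articles(spec: SyntheticCorpusSpec, n_articles: int = 10
                  ) -> list[tuple[str, str, set[str]]]:
    """Synthetic PMC-style articles: (article_id, xml_text, gold GeneID set).

    Each article is themed on one species: most sentences name it explicitly,
    some rely on the article-majority rule.  A typed methods section with
    decoy content is included and must be filtered out upstream.
    """
    rng = random.Random(spec.seed + 2)
    genes = make_genes(spec)
    by_tax: dict[str, list[SyntheticGene]] = {}
    for g in genes:
        by_tax.setdefault(g.taxid, []).append(g)
    articles = []
    taxids = sorted(by_tax)
    for a in range(n_articles):
        taxid = taxids[a % len(taxids)]
        pool = by_tax[taxid]
        gold: set[str] = set()
        sents = []
        n_mentions = rng.randint(3, 5)
        for j in range(n_mentions):
            gene = rng.choice(pool)
            gold.add(gene.geneid)
            mention = rng.choice((gene.symbol, gene.full_name))
            if j < n_mentions - 1 or n_mentions == 1:
                sp = _species_name(rng, taxid)
                sents.append(
                    f"The {sp} gene {mention} {rng.choice(_FILLERS)}."
                )
            else:
                # no species cue in this sentence: article majority applies
                sents.append(
                    f"We found that {mention} {rng.choice(_FILLERS)}."
                )
        if rng.random() < spec.abbrev_rate * 3:
            long_form, short = rng.choice(_NONGENE_DEFS)
            sents.append(f"Levels of {long_form} ({short}) were elevated.")
        intro = " ".join(sents)
        xml = (
            f'<article article-id="SYN{a:03d}"><body>'
            f"<sec><title>Findings</title><p>{intro}</p></sec>"
            f'<sec sec-type="methods"><p>Samples were processed with '
            f"standard buffers.</p></sec>"
            f"</body></article>"
        )
        articles.append((f"SYN{a:03d}", xml, gold))
    return articles


def write_fixture_dir(path, spec: SyntheticCorpusSpec,
                      n_articles: int = 10) -> dict[str, object]:
    """Write a self-contained fixture directory: training corpus (CoNLL),
    gene and species dictionaries, article XML files, and the gold key TSV.
    Returns the in-memory objects for convenience."""
    import os

    os.makedirs(path, exist_ok=True)
    corpus = make_tagged_corpus(spec)
    genes = make_genes(spec)
    with open(os.path.join(path, "train.conll"), "w", encoding="utf-8") as fh:
        for s in corpus:
            for tok, lab in zip(s.tokens, s.labels):
                fh.write(f"{tok.surface}\t{lab}\n")
            fh.write("\n")
    with open(os.path.join(path, "gene_info.tsv"), "w", encoding="utf-8") as fh:
        fh.write(make_gene_dict(spec, genes))
    with open(os.path.join(path, "species.tsv"), "w", encoding="utf-8") as fh:
        fh.write(make_species_dict(spec, {g.taxid for g in genes}))
    articles = make_articles(spec, n_articles)
    art_dir = os.path.join(path, "articles")
    os.makedirs(art_dir, exist_ok=True)
    gold_lines = []
    for art_id, xml, gold in articles:
        with open(os.path.join(art_dir, f"{art_id}.xml"), "w",
                  encoding="utf-8") as fh:
            fh.write(xml)
        for gid in sorted(gold):
            gold_lines.append(f"{art_id}\t{gid}")
    with open(os.path.join(path, "gold.tsv"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(gold_lines) + "\n")
    return {"corpus": corpus, "genes": genes, "articles": articles}
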