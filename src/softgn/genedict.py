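"""Gene-name dictionary: rule-normalized indexing, retrieval, and resolution.

Names are harvested from the gene_info columns {Symbol, Synonyms, dbXrefs,
description, Symbol from nomenclature authority, Full name from nomenclature
authority, Other designations} and normalized by five rules applied in order:

1. split an uppercase run (>=2) glued to a lowercase run (>=2): DNAbinding ->
   DNA binding;
2. the symmetric lowercase/uppercase split;
3. every non-word character except '.' becomes a space (hyphens, commas ...);
4. digit/dot runs are space-delimited: IL1 -> IL 1;
5. whitespace collapses; finally everything is lowercased.

A query additionally treats Arabic and Roman numerals as interchangeable, and
Greek-letter words as interchangeable with their Latin initials, so the
normalized variant "IL-1 alpha" compiles to the token pattern
[il, (1|i), (alpha|a)].  Retrieval returns the top-scoring index records for
the designated TaxID (exact normalized matches always rank first); a
query-derived anchored regular expression then removes partial matches, and
the resolving rules map the surviving candidate list to a single GeneID.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from math import log, sqrt

__all__ = [
    "GeneRecord",
    "Candidate",
    "Query",
    "GeneIndex",
    "AUTHORITY_COLUMNS",
    "load_gene_info",
    "normalize_name",
    "compile_query",
    "regex_filter",
    "resolve",
    "disambiguate_overlapping",
    "GENE_INFO_COLUMNS",
]


@dataclass(frozen=True)
class GeneRecord:
    taxid: str
    geneid: str
    name: str
    column: str


@dataclass(frozen=True)
class Candidate:
    record: GeneRecord
    score: float


@dataclass(frozen=True)
class Query:
    """Normalized token pattern with per-token alternation sets."""
    tokens: tuple[frozenset[str], ...]
    taxid: str | None


AUTHORITY_COLUMNS = frozenset({
    "Symbol",
    "Symbol_from_nomenclature_authority",
    "Full_name_from_nomenclature_authority",
    "AuthorizedSymbol",  # header used in candidate dumps
})

# gene_info layout (NCBI): tab-separated, '-' for missing
GENE_INFO_COLUMNS = (
    "tax_id", "GeneID", "Symbol", "LocusTag", "Synonyms", "dbXrefs",
    "chromosome", "map_location", "description", "type_of_gene",
    "Symbol_from_nomenclature_authority",
    "Full_name_from_nomenclature_authority", "Nomenclature_status",
    "Other_designations", "Modification_date",
)
_NAME_COLUMNS = {
    "Symbol": 2,
    "Synonyms": 4,
    "dbXrefs": 5,
    "description": 8,
    "Symbol_from_nomenclature_authority": 10,
    "Full_name_from_nomenclature_authority": 11,
    "Other_designations": 13,
}
_MULTI_VALUED = {"Synonyms", "dbXrefs", "Other_designations"}


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


def load_gene_info(path) -> list[GeneRecord]:
    """One GeneRecord per (row, name column, pipe-separated value).

    '-' fields are skipped; dbXrefs values lose their "SOURCE:" prefix.
    Raises ValueError naming the line on a malformed column count.
    """
    records: list[GeneRecord] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 14:
                raise ValueError(
                    f"{path}:{lineno}: expected >=14 tab-separated columns, "
                    f"got {len(parts)}"
                )
            taxid, geneid = parts[0].strip(), parts[1].strip()
            for column, idx in _NAME_COLUMNS.items():
                value = parts[idx].strip()
                if not value or value == "-":
                    continue
                names = value.split("|") if column in _MULTI_VALUED else [value]
                for name in names:
                    name = name.strip()
                    if column == "dbXrefs" and ":" in name:
                        name = name.split(":", 1)[1]
                    if name and name != "-":
                        records.append(GeneRecord(taxid, geneid, name, column))
    return records


# ---------------------------------------------------------------------------
# Normalization rules

_RULE1 = re.compile(r"([A-Z]{2,})([a-z]{2,})")
_RULE2 = re.compile(r"([a-z]{2,})([A-Z]{2,})")
_RULE3 = re.compile(r"[^\w.]|_")   # non-word chars (except '.') -> space
_RULE4 = re.compile(r"([\d.]+)")
_RULE5 = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Apply the five tokenization rules in order, then lowercase.  Idempotent."""
    s = _RULE1.sub(r"\1 \2", name)
    s = _RULE2.sub(r"\1 \2", s)
    s = _RULE3.sub(" ", s)
    s = _RULE4.sub(r" \1 ", s)
    s = _RULE5.sub(" ", s).strip()
    return s.lower()


def name_tokens(name: str) -> tuple[str, ...]:
    n = normalize_name(name)
    return tuple(n.split()) if n else ()


# ---------------------------------------------------------------------------
# Interchange classes

GREEK = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega",
)
_GREEK_BY_INITIAL: dict[str, tuple[str, ...]] = {}
for _g in GREEK:
    _GREEK_BY_INITIAL[_g[0]] = _GREEK_BY_INITIAL.get(_g[0], ()) + (_g,)

_ROMAN_VALUES = (
    (1000, "m"), (900, "cm"), (500, "d"), (400, "cd"), (100, "c"),
    (90, "xc"), (50, "l"), (40, "xl"), (10, "x"), (9, "ix"),
    (5, "v"), (4, "iv"), (1, "i"),
)


def _int_to_roman(n: int) -> str | None:
    if not 1 <= n <= 3999:
        return None
    out = []
    for val, sym in _ROMAN_VALUES:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


# Roman -> Arabic recognition is limited to i..xx to avoid misreading
# ordinary words ("mix", "did") as numerals.
_ROMAN_SMALL = {_int_to_roman(n): str(n) for n in range(1, 21)}


def token_alternates(token: str) -> frozenset[str]:
    """Interchange set of one normalized token: Arabic <-> Roman numerals and
    Greek words <-> Latin initials; the token itself is always included."""
    alts = {token}
    if token.isdigit():
        roman = _int_to_roman(int(token))
        if roman:
            alts.add(roman)
    elif token in _ROMAN_SMALL:
        alts.add(_ROMAN_SMALL[token])
    if token in GREEK:
        alts.add(token[0])
    elif len(token) == 1 and token in _GREEK_BY_INITIAL:
        alts.update(_GREEK_BY_INITIAL[token])
    return frozenset(alts)


def compile_query(variant_text: str, taxid: str | None = None) -> Query:
    """Normalize the variant text and attach per-token interchange sets plus
    the designated TaxID filter."""
    if not variant_text or not variant_text.strip():
        raise ValueError("empty variant text")
    return Query(
        tokens=tuple(token_alternates(t) for t in name_tokens(variant_text)),
        taxid=taxid,
    )


def query_regex(query: Query) -> re.Pattern:
    """Anchored whole-name pattern over a normalized name string: every query
    token (or an interchangeable form) in order, nothing else."""
    parts = [
        "(?:" + "|".join(re.escape(a) for a in sorted(alts)) + ")"
        for alts in query.tokens
    ]
    return re.compile("^" + " ".join(parts) + "$", re.IGNORECASE)


# ---------------------------------------------------------------------------
# Index + retrieval


class GeneIndex:
    """Inverted index over normalized gene names.

    The relevance score is a symmetric idf-weighted coverage product, so a
    record whose normalized name token-equals the query scores exactly 1.0
    and partial matches score strictly less.  Exactness of intermediate
    ranking is not contractual: the anchored regex filter downstream
    determines correctness.
    """

    def __init__(self, records: list[GeneRecord]):
        self.records = list(records)
        self.tokens: list[tuple[str, ...]] = []
        self.postings: dict[str, dict[str, list[int]]] = {}
        self._df: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            toks = name_tokens(rec.name)
            self.tokens.append(toks)
            for tok in set(toks):
                self.postings.setdefault(rec.taxid, {}).setdefault(
                    tok, []
                ).append(i)
                self._df[tok] = self._df.get(tok, 0) + 1
        self._n = max(len(self.records), 1)

    def _idf(self, token: str) -> float:
        return log((self._n + 1) / (self._df.get(token, 0) + 1)) + 1.0

    def retrieve(self, query: Query, cap: int = 50) -> list[Candidate]:
        """Top-``cap`` records of the query's TaxID sharing tokens with the
        query, in non-increasing score order (deterministic tie-break)."""
        by_tax = self.postings.get(query.taxid, {})
        hit_positions: dict[int, set[int]] = {}
        hit_tokens: dict[int, set[str]] = {}
        for pos, alts in enumerate(query.tokens):
            for alt in alts:
                for i in by_tax.get(alt, ()):
                    hit_positions.setdefault(i, set()).add(pos)
                    hit_tokens.setdefault(i, set()).add(alt)
        if not hit_positions:
            return []
        q_idf = [max(self._idf(a) for a in alts) for alts in query.tokens]
        q_total = sum(q_idf) or 1.0
        scored: list[Candidate] = []
        for i, positions in hit_positions.items():
            rec_toks = self.tokens[i]
            rec_idf = sum(self._idf(t) for t in set(rec_toks)) or 1.0
            cov_q = sum(q_idf[p] for p in positions) / q_total
            cov_r = sum(self._idf(t) for t in hit_tokens[i]) / rec_idf
            scored.append(Candidate(self.records[i], sqrt(cov_q * cov_r)))
        scored.sort(
            key=lambda c: (
                -c.score, c.record.geneid, c.record.column, c.record.name
            )
        )
        return scored[:cap]


def regex_filter(candidates: list[Candidate], variant_text: str
                 ) -> list[Candidate]:
    """Drop candidates whose full normalized name fails the anchored
    query-derived pattern — removes the retrieval phase's partial matches."""
    if not candidates:
        return []
    pattern = query_regex(compile_query(variant_text))
    return [
        c for c in candidates if pattern.match(normalize_name(c.record.name))
    ]


def resolve(filtered: list[Candidate]) -> str | None:
    """Resolving rules: a unique GeneID wins outright; otherwise the GeneID of
    an authority-column candidate (Symbol / nomenclature-authority columns);
    otherwise the list is ignored."""
    if not filtered:
        return None
    gene_ids = {c.record.geneid for c in filtered}
    if len(gene_ids) == 1:
        return next(iter(gene_ids))
    authority = [c for c in filtered if c.record.column in AUTHORITY_COLUMNS]
    if authority:
        best = max(authority, key=lambda c: (c.score, -filtered.index(c)))
        return best.record.geneid
    return None


def disambiguate_overlapping(group) -> tuple[str, float] | None:
    """Pick one GeneID for a set of overlapping variants.

    ``group`` is a list of (variant, geneid-or-None) pairs.  The longest
    resolved variant's match wins; equal lengths prefer the higher confidence
    score.  Returns (GeneID, variant confidence score) or None when nothing
    resolved.
    """
    resolved = [(v, gid) for v, gid in group if gid is not None]
    if not resolved:
        return None
    variant, geneid = max(
        resolved,
        key=lambda vg: (
            len(vg[0].text),
            vg[0].score if vg[0].score is not None else 0.0,
            -vg[0].start,
        ),
    )
    return geneid, float(variant.score if variant.score is not None else 0.0)
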