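"""Species designation: assign an NCBI taxonomy ID to each gene variant.

Ambiguous gene names are rare within one species, so resolving the species
first removes most of the need for gene-level disambiguation.  Designation
uses a species-name dictionary plus three precedence rules:

Rule 1 — a species named within the variant, the nearest species mention
         earlier in the same sentence, or a single-letter organism prefix on
         the variant (h/y/m/r/d for human/yeast/mouse/rat/fruit fly);
Rule 2 — a species mentioned elsewhere in the same sentence (nearest);
Rule 3 — the species mentioned most often in the whole article.

Rule 3 guarantees every variant gets a TaxID in any article that mentions at
least one species.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .corpus import Document
from .variants import Variant

__all__ = [
    "SpeciesDict",
    "SpeciesMention",
    "TaxAssignment",
    "load_species_dict",
    "find_species_mentions",
    "designate",
    "PREFIX_SPECIES",
]

logger = logging.getLogger(__name__)

# single-letter organism prefixes, e.g. hTAK1 -> human
PREFIX_SPECIES = {
    "h": "9606",    # human
    "y": "4932",    # yeast
    "m": "10090",   # mouse
    "r": "10116",   # rat
    "d": "7227",    # fruit fly
}


@dataclass(frozen=True)
class SpeciesMention:
    name: str
    taxid: str
    section_index: int
    sentence_index: int
    start: int
    end: int


@dataclass(frozen=True)
class TaxAssignment:
    variant: Variant
    taxid: str
    rule: int


class SpeciesDict:
    """Species-name -> TaxID lookup.

    Multi-word names match case-insensitively; short names (<= 4 characters,
    typically genus abbreviations) match case-sensitively to avoid false hits.
    """

    SHORT = 4

    def __init__(self, entries: dict[str, str],
                 prefix_map: dict[str, str] | None = None):
        if not entries:
            raise ValueError("species dictionary is empty")
        self.entries = dict(entries)
        self.prefix_map = dict(prefix_map or PREFIX_SPECIES)
        self._patterns = []
        # longest names first => longest-match wins at any position
        for name in sorted(self.entries, key=len, reverse=True):
            flags = 0 if len(name) <= self.SHORT else re.IGNORECASE
            pat = re.compile(
                r"(?<![0-9A-Za-z])" + re.escape(name) + r"(?![0-9A-Za-z])",
                flags,
            )
            self._patterns.append((pat, name))

    def taxid_of(self, name: str) -> str | None:
        hit = self.entries.get(name)
        if hit is not None:
            return hit
        if len(name) > self.SHORT:
            for k, v in self.entries.items():
                if k.lower() == name.lower():
                    return v
        return None

    def find_in(self, text: str) -> list[tuple[int, int, str, str]]:
        """Longest-match, non-overlapping occurrences: (start, end, name, taxid)."""
        taken: list[tuple[int, int]] = []
        hits: list[tuple[int, int, str, str]] = []
        for pat, name in self._patterns:
            for m in pat.finditer(text):
                span = (m.start(), m.end())
                if any(span[0] < e and s < span[1] for s, e in taken):
                    continue
                taken.append(span)
                hits.append((m.start(), m.end(), name, self.entries[name]))
        hits.sort()
        return hits


def load_species_dict(path) -> SpeciesDict:
    """Read a two-column TSV (name, TaxID); '#' lines are comments.  On a
    duplicate name with a different TaxID the first occurrence wins and a
    warning is logged."""
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            name, taxid = parts[0].strip(), parts[1].strip()
            if not name or not taxid:
                raise ValueError(f"{path}:{lineno}: empty field")
            if name in entries:
                if entries[name] != taxid:
                    logger.warning(
                        "duplicate species name %r: keeping TaxID %s, "
                        "ignoring %s", name, entries[name], taxid,
                    )
                continue
            entries[name] = taxid
    return SpeciesDict(entries)


def find_species_mentions(doc: Document, sdict: SpeciesDict
                          ) -> list[SpeciesMention]:
    """All longest-match species-name occurrences in the article."""
    out: list[SpeciesMention] = []
    for si, ti, sentence in doc.iter_sentences():
        for start, end, name, taxid in sdict.find_in(sentence.text):
            out.append(SpeciesMention(name, taxid, si, ti, start, end))
    return out


_PREFIX_RE_TMPL = r"^([{letters}])[A-Z0-9]"


def _prefix_taxid(text: str, prefix_map: dict[str, str]) -> str | None:
    """hTAK1-style prefixes: a mapped lowercase letter followed by an
    uppercase letter or digit."""
    if len(text) >= 2 and text[0] in prefix_map and (
        text[1].isupper() or text[1].isdigit()
    ):
        return prefix_map[text[0]]
    return None


def _majority_taxid(mentions: list[SpeciesMention]) -> str | None:
    if not mentions:
        return None
    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for i, m in enumerate(mentions):
        counts[m.taxid] = counts.get(m.taxid, 0) + 1
        first_seen.setdefault(m.taxid, i)
    return max(counts, key=lambda t: (counts[t], -first_seen[t]))


def designate(
    variant: Variant,
    sentence_loc: tuple[int, int],
    mentions: list[SpeciesMention],
    sdict: SpeciesDict,
    rules: frozenset[int] | set[int] = frozenset({1, 2, 3}),
    default_taxid: str | None = None,
) -> TaxAssignment | None:
    """Assign a TaxID to ``variant`` (located at section/sentence
    ``sentence_loc``) by the first applicable enabled rule.

    Returns None when no enabled rule applies and no ``default_taxid`` is
    configured; the caller drops such variants with a warning.
    """
    si, ti = sentence_loc
    in_sentence = [m for m in mentions
                   if m.section_index == si and m.sentence_index == ti]

    if 1 in rules:
        # species named inside the variant span
        inside = [m for m in in_sentence
                  if m.start >= variant.start and m.end <= variant.end]
        if inside:
            return TaxAssignment(variant, inside[0].taxid, 1)
        # nearest species mention ending before the variant starts
        preceding = [m for m in in_sentence if m.end <= variant.start]
        if preceding:
            nearest = max(preceding, key=lambda m: m.end)
            return TaxAssignment(variant, nearest.taxid, 1)
        pref = _prefix_taxid(variant.text, sdict.prefix_map)
        if pref is not None:
            return TaxAssignment(variant, pref, 1)

    if 2 in rules and in_sentence:
        # nearest mention anywhere in the sentence (following included)
        def distance(m: SpeciesMention) -> int:
            if m.end <= variant.start:
                return variant.start - m.end
            if m.start >= variant.end:
                return m.start - variant.end
            return 0

        nearest = min(in_sentence, key=lambda m: (distance(m), m.start))
        return TaxAssignment(variant, nearest.taxid, 2)

    if 3 in rules:
        taxid = _majority_taxid(mentions)
        if taxid is not None:
            return TaxAssignment(variant, taxid, 3)

    if default_taxid is not None:
        return TaxAssignment(variant, default_taxid, 3)
    return None
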