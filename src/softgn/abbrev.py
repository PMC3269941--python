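"""Abbreviation-definition filtering of tagged gene mention variants.

An article defining a short form parenthetically — "N-acetyl-aspartate (NAA)"
— gives away whether the short form is a gene: if the tagger marked the short
form at the definition site but not its long form, every occurrence of that
short form in the article is treated as a false positive and removed.

Pair detection uses the Schwartz-Hearst character-alignment heuristic: scan
the long-form candidate right-to-left, matching each short-form character,
requiring the first short-form character to start a word.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus import Document
from .variants import Variant

__all__ = ["AbbrevPair", "detect_pairs", "filter_by_abbrev"]


@dataclass(frozen=True)
class AbbrevPair:
    short_form: str
    long_form: str
    section_index: int
    sentence_index: int
    long_start: int  # long-form char offsets within the definition sentence
    long_end: int


_PAREN_RE = re.compile(r"\(([^()]+)\)")


def _is_valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10):
        return False
    if not any(c.isalpha() for c in sf):
        return False
    if len(sf.split()) > 2:
        return False
    return sf[0].isalnum()


def _find_long_form(candidate: str, short: str) -> str | None:
    """Schwartz-Hearst alignment: right-to-left match of short-form characters
    into the candidate text; the first character must begin a word."""
    s_idx = len(short) - 1
    l_idx = len(candidate) - 1
    while s_idx >= 0:
        c = short[s_idx].lower()
        if not c.isalnum():
            s_idx -= 1
            continue
        while l_idx >= 0 and (
            candidate[l_idx].lower() != c
            or (s_idx == 0 and l_idx > 0 and candidate[l_idx - 1].isalnum())
        ):
            l_idx -= 1
        if l_idx < 0:
            return None
        s_idx -= 1
        l_idx -= 1
    return candidate[l_idx + 1:]


def _max_long_words(short: str) -> int:
    n = sum(c.isalnum() for c in short)
    return min(n + 5, n * 2)


def detect_pairs(doc: Document) -> list[AbbrevPair]:
    """All (short form, long form) definition pairs in the article, each tied
    to its definition sentence; duplicates of the same (short, long) pair are
    reported once."""
    seen: set[tuple[str, str]] = set()
    pairs: list[AbbrevPair] = []
    for si, ti, sentence in doc.iter_sentences():
        for m in _PAREN_RE.finditer(sentence.text):
            sf = m.group(1).strip()
            if not _is_valid_short_form(sf):
                continue
            before = sentence.text[: m.start()].rstrip()
            if not before:
                continue
            words = before.split()
            candidate = " ".join(words[-_max_long_words(sf):])
            lf = _find_long_form(candidate, sf)
            if not lf:
                continue
            lf = lf.strip()
            if not lf or lf.lower() == sf.lower():
                continue
            # the long form must be longer than the short form and not
            # contain it as a standalone word
            if len(lf) <= len(sf):
                continue
            key = (sf, lf)
            if key in seen:
                continue
            seen.add(key)
            start = len(before) - len(lf)
            pairs.append(AbbrevPair(sf, lf, si, ti, start, start + len(lf)))
    return pairs


def filter_by_abbrev(
    variants: list[tuple[int, int, Variant]],
    pairs: list[AbbrevPair],
) -> list[tuple[int, int, Variant]]:
    """Remove article-wide all variants whose text equals a short form that
    was tagged at its definition sentence while its long form was not.

    ``variants`` are (section_index, sentence_index, variant) triples for one
    article.  "Long form tagged" means some variant in the definition sentence
    overlaps the long-form span (boundary variants of the long form count).
    Matching of short-form text is exact and case-sensitive.  The output is a
    subset of the input.
    """
    banned: set[str] = set()
    for pair in pairs:
        at_def = [
            v for si, ti, v in variants
            if si == pair.section_index and ti == pair.sentence_index
        ]
        short_tagged = any(v.text == pair.short_form for v in at_def)
        long_tagged = any(
            v.start < pair.long_end and pair.long_start < v.end
            and v.text != pair.short_form
            for v in at_def
        )
        if short_tagged and not long_tagged:
            banned.add(pair.short_form)
    if not banned:
        return list(variants)
    return [(si, ti, v) for si, ti, v in variants if v.text not in banned]
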