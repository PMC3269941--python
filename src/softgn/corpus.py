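"""Article ingestion: PMC-style XML or plain text into a sentence/token model.

Full-text articles arrive as JATS-like XML (``<sec>`` elements, optionally
carrying a ``sec-type`` attribute) or as plain UTF-8 text.  Downstream stages
operate on sentences and on a fine-grained tokenization in which maximal
alphabetic runs, maximal digit runs, and individual other characters each form
one token — gene names such as "IL2R" deliberately shatter into ["IL", "2",
"R"] so that boundary variants can be recombined freely.

All character offsets are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from lxml import etree

__all__ = [
    "Token",
    "Sentence",
    "Section",
    "Document",
    "parse_article",
    "filter_sections",
    "tokenize_fine",
    "split_sentences",
]


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("empty token surface")
        if self.end - self.start != len(self.surface):
            raise ValueError("token span does not match surface length")


@dataclass
class Sentence:
    text: str
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)


@dataclass
class Section:
    sec_type: str | None
    text: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Document:
    article_id: str
    sections: list[Section] = field(default_factory=list)

    def iter_sentences(self):
        for si, section in enumerate(self.sections):
            for ti, sentence in enumerate(section.sentences):
                yield si, ti, sentence


# Maximal letter runs (Unicode letters: Greek letters must survive), maximal
# ASCII digit runs, then any single remaining non-space character.
_TOKEN_RE = re.compile(r"[^\W\d_]+|[0-9]+|\S")


def tokenize_fine(text: str) -> list[Token]:
    """Fine-grained tokenization breaking at every letter/digit/other boundary."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# Sentence boundary: terminal punctuation, whitespace, then an uppercase letter
# or digit.  A stop-list guards common biomedical abbreviations.
_ABBREVIATIONS = (
    "et al.", "e.g.", "i.e.", "cf.", "vs.", "ca.", "approx.",
    "Fig.", "Figs.", "Eq.", "Ref.", "Refs.", "No.", "Dr.", "Prof.",
    "sp.", "spp.", "subsp.", "var.", "St.",
)
_BOUNDARY_RE = re.compile(r"[.?!]+(\s+)(?=[A-Z0-9])")
_SINGLE_INITIAL_RE = re.compile(r"\b[A-Z]\.$")


def split_sentences(text: str) -> list[Sentence]:
    """Rule-based sentence segmentation with offsets into ``text``."""
    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        prefix = text[: m.start(1)]
        if any(prefix.endswith(a) for a in _ABBREVIATIONS):
            continue
        # "S. aureus"-style genus initials: single capital + period.
        if _SINGLE_INITIAL_RE.search(prefix):
            continue
        boundaries.append(m.end(1))

    sentences: list[Sentence] = []
    prev = 0
    for b in boundaries + [len(text)]:
        raw = text[prev:b]
        stripped = raw.strip()
        if stripped:
            start = prev + raw.index(stripped[0])
            end = start + len(stripped)
            sent_text = text[start:end]
            sentences.append(
                Sentence(sent_text, start, end, tokens=tokenize_fine(sent_text))
            )
        prev = b
    return sentences


def _section_text(sec: etree._Element) -> str:
    # Paragraph-level text of this sec, excluding nested <sec> children
    # (they become their own sections).
    parts: list[str] = []
    if sec.text and sec.text.strip():
        parts.append(sec.text.strip())
    for child in sec:
        if isinstance(child.tag, str) and etree.QName(child).localname == "sec":
            continue
        chunk = " ".join(child.itertext()).strip()
        chunk = re.sub(r"\s+", " ", chunk)
        if chunk:
            parts.append(chunk)
        if child.tail and child.tail.strip():
            parts.append(child.tail.strip())
    return "\n".join(parts)


def _collect_secs(elem: etree._Element, out: list[etree._Element]) -> None:
    for sec in elem.iterfind("sec"):
        out.append(sec)
        _collect_secs(sec, out)


def parse_article(text: str, article_id: str = "article") -> Document:
    """Parse PMC-style XML into a :class:`Document`; plain text falls back to
    a single untyped section.

    Raises :class:`lxml.etree.XMLSyntaxError` (naming the offending position)
    on malformed XML, and :class:`ValueError` on empty input.
    """
    if not text or not text.strip():
        raise ValueError("empty article input")

    stripped = text.lstrip()
    if not stripped.startswith("<"):
        section = Section(None, text)
        section.sentences = split_sentences(section.text)
        return Document(article_id, [section])

    root = etree.fromstring(text.encode("utf-8"))
    body = root.find(".//body")
    scope = body if body is not None else root
    secs: list[etree._Element] = []
    _collect_secs(scope, secs)
    if not secs and etree.QName(scope).localname == "sec":
        secs = [scope]

    sections: list[Section] = []
    for sec in secs:
        sec_text = _section_text(sec)
        section = Section(sec.get("sec-type"), sec_text)
        section.sentences = split_sentences(sec_text)
        sections.append(section)
    doc_id = root.get("article-id") or article_id
    return Document(doc_id, sections)


def filter_sections(doc: Document) -> Document:
    """Keep only sections without a ``sec-type`` attribute.

    Typed sections (Methods, References, Materials ...) are dropped from the
    normalization input.  Idempotent.
    """
    return Document(doc.article_id, [s for s in doc.sections if s.sec_type is None])
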