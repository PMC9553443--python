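"""Hierarchical annotated-text data model and two-column BIO file I/O.

Text is organised as chapters -> paragraphs -> sentences -> characters, with
one gold BIO tag per character (character-level tokenisation, no word
segmentation).  The on-disk format is the CoNLL-like two-column dialect:

    <char>\\t<tag>        one line per character
    (blank line)          ends a sentence
    (two blank lines)     ends a paragraph
    -DOCSTART-            ends a chapter

Reserved vocabulary ids: 0 = padding, 1 = unknown.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import DOC_TYPES, EntityTypeCatalog

__all__ = [
    "PAD_ID",
    "UNK_ID",
    "ParseError",
    "BioValidationError",
    "AnnotatedDocument",
    "Vocabulary",
    "parse_tag",
    "validate_bio",
    "read_conll",
    "write_conll",
    "build_vocab",
    "encode",
    "iter_sentences",
]

PAD_ID = 0
UNK_ID = 1

# a sentence is a list of (character, tag) pairs
Sentence = list  # list[tuple[str, str]]

_TAG_RE = re.compile(r"^(O|[BI]-[A-Za-z0-9_]+)$")


class ParseError(ValueError):
    pass


class BioValidationError(ValueError):
    pass


def parse_tag(tag: str, catalog: EntityTypeCatalog) -> tuple[str, str | None]:
    """Split a scheme tag into (prefix, type_code); validates against catalog."""
    if not _TAG_RE.match(tag):
        raise BioValidationError(f"malformed tag {tag!r}")
    if tag == "O":
        return "O", None
    prefix, code = tag.split("-", 1)
    if code not in catalog.labels:
        raise BioValidationError(f"tag {tag!r}: type {code!r} not in catalog")
    return prefix, code


def validate_bio(tags: list[str], catalog: EntityTypeCatalog, where: str = "") -> None:
    """Check tag shapes and that every I-X follows B-X or I-X."""
    prev: str | None = None
    for i, tag in enumerate(tags):
        prefix, code = parse_tag(tag, catalog)
        if prefix == "I":
            ok = prev is not None and prev in (f"B-{code}", f"I-{code}")
            if not ok:
                raise BioValidationError(
                    f"I-{code} at position {i}{' of ' + where if where else ''} "
                    f"not preceded by B-{code}/I-{code}"
                )
        prev = tag


@dataclass
class AnnotatedDocument:
    """chapters -> paragraphs -> sentences -> (char, tag) pairs."""

    chapters: list = field(default_factory=list)
    doc_type: str = "comprehensive"

    def __post_init__(self):
        if self.doc_type not in DOC_TYPES:
            raise ValueError(f"unknown doc_type {self.doc_type!r}")

    def sentences(self):
        for chapter in self.chapters:
            for paragraph in chapter:
                yield from paragraph

    def n_sentences(self) -> int:
        return sum(1 for _ in self.sentences())

    def chars(self) -> list[str]:
        return [c for s in self.sentences() for c, _ in s]

    def tags(self) -> list[str]:
        return [t for s in self.sentences() for _, t in s]

    def validate(self, catalog: EntityTypeCatalog) -> None:
        for k, sent in enumerate(self.sentences()):
            if not sent:
                raise BioValidationError(f"sentence {k} is empty")
            for c, _ in sent:
                if len(c) != 1:
                    raise BioValidationError(f"token {c!r} is not a single character")
            validate_bio([t for _, t in sent], catalog, where=f"sentence {k}")


def iter_sentences(docs: list[AnnotatedDocument]):
    for doc in docs:
        yield from doc.sentences()


# -- file I/O -------------------------------------------------------------------


def read_conll(
    path: str | Path,
    catalog: EntityTypeCatalog,
    doc_type: str = "comprehensive",
    validate: bool = True,
) -> list[AnnotatedDocument]:
    """Parse a two-column BIO file into (at most one) annotated document.

    Returns an empty list for an empty file, else a single-element list.
    """
    text = Path(path).read_text(encoding="utf-8")
    chapters: list = []
    paragraphs: list = []
    sentences: list = []
    sentence: list = []
    blanks = 0

    def close_sentence():
        nonlocal sentence
        if sentence:
            sentences.append(sentence)
            sentence = []

    def close_paragraph():
        nonlocal sentences
        close_sentence()
        if sentences:
            paragraphs.append(sentences)
            sentences = []

    def close_chapter():
        nonlocal paragraphs
        close_paragraph()
        if paragraphs:
            chapters.append(paragraphs)
            paragraphs = []

    for lineno, line in enumerate(text.split("\n"), start=1):
        stripped = line.rstrip("\r")
        if stripped == "":
            blanks += 1
            close_sentence()
            if blanks >= 2:
                close_paragraph()
            continue
        if stripped == "-DOCSTART-":
            close_chapter()
            blanks = 0
            continue
        blanks = 0
        parts = stripped.split("\t")
        if len(parts) != 2 or len(parts[0]) != 1:
            raise ParseError(f"{path}:{lineno}: malformed line {stripped!r}")
        char, tag = parts
        if validate:
            parse_tag(tag, catalog)
        sentence.append((char, tag))
    close_chapter()

    if not chapters:
        return []
    doc = AnnotatedDocument(chapters=chapters, doc_type=doc_type)
    if validate:
        doc.validate(catalog)
    return [doc]


def write_conll(docs: list[AnnotatedDocument], path: str | Path) -> None:
    """Canonical writer inverting :func:`read_conll` (structure round trip)."""
    lines: list[str] = []
    for doc in docs:
        for paragraphs in doc.chapters:
            for sentences in paragraphs:
                for sent in sentences:
                    for char, tag in sent:
                        lines.append(f"{char}\t{tag}")
                    lines.append("")  # end of sentence
                lines.append("")  # second blank: end of paragraph
            lines.append("-DOCSTART-")  # end of chapter
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# -- vocabulary -----------------------------------------------------------------


@dataclass
class Vocabulary:
    char_to_id: dict
    id_to_char: list

    @property
    def size(self) -> int:
        return len(self.id_to_char)

    def lookup(self, char: str) -> int:
        return self.char_to_id.get(char, UNK_ID)


def build_vocab(docs: list[AnnotatedDocument], min_count: int = 1) -> Vocabulary:
    """Frequency-then-codepoint ordered vocabulary with reserved pad/unk ids."""
    if not docs:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    for doc in docs:
        for c in doc.chars():
            counts[c] = counts.get(c, 0) + 1
    kept = sorted(
        (c for c, n in counts.items() if n >= min_count),
        key=lambda c: (-counts[c], c),
    )
    id_to_char = ["<pad>", "<unk>"] + kept
    return Vocabulary(
        char_to_id={c: i for i, c in enumerate(id_to_char) if i >= 2},
        id_to_char=id_to_char,
    )


def encode(
    sentence: list, vocab: Vocabulary, pad_to: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Map a sentence's characters to ids; returns (ids, mask).

    `sentence` is a list of (char, tag) pairs or bare characters.  Padding
    positions carry id 0 and mask False.
    """
    if len(sentence) == 0:
        raise ValueError("cannot encode an empty sentence")
    chars = [item[0] if isinstance(item, tuple) else item for item in sentence]
    ids = [vocab.lookup(c) for c in chars]
    n = len(ids)
    total = max(n, pad_to or 0)
    out = np.full(total, PAD_ID, dtype=np.intp)
    out[:n] = ids
    mask = np.zeros(total, dtype=bool)
    mask[:n] = True
    return out, mask
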