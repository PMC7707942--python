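"""BIO-annotated corpus handling for character-level NER.

Clinical NER over Chinese electronic medical records is cast as
character-level sequence labeling: every unicode character of a sentence
carries one BIO tag (``B-c`` begins an entity of class ``c``, ``I-c``
continues it, ``O`` is outside any entity).  With the default four clinical
classes — disease, symptom, drug, operation — this yields nine labels.

This module owns the corpus container types, the CoNLL-style one-token-per-
line reader/writer, the span/tag conversions, and per-class corpus
statistics.  No word segmentation happens anywhere: the annotation unit is
the single character.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

__all__ = [
    "TagScheme",
    "TaggedSentence",
    "EntitySpan",
    "CorpusStats",
    "ParseError",
    "read_conll",
    "write_conll",
    "bio_to_spans",
    "spans_to_bio",
    "corpus_stats",
]

#: Default clinical entity classes: disease, symptom, drug, operation.
DEFAULT_CLASSES = ("dis", "sym", "dru", "ope")


class ParseError(ValueError):
    """Raised for malformed CoNLL input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class TagScheme:
    """An ordered set of entity classes and the BIO label set they induce.

    ``labels`` always has ``2 * len(classes) + 1`` entries: ``O`` first
    (index 0), then ``B-c``/``I-c`` pairs in class order.  Label indices are
    stable and used throughout the CRF and the projection layer.
    """

    classes: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self):
        if not self.classes:
            raise ValueError("TagScheme needs at least one class")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names")
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def labels(self) -> tuple[str, ...]:
        out = ["O"]
        for c in self.classes:
            out.append(f"B-{c}")
            out.append(f"I-{c}")
        return tuple(out)

    @property
    def n_labels(self) -> int:
        return 2 * len(self.classes) + 1

    def label_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r} for classes {self.classes}") from None

    def is_valid_label(self, label: str) -> bool:
        return label in self.labels

    def to_dict(self) -> dict:
        return {"classes": list(self.classes)}

    @classmethod
    def from_dict(cls, d: dict) -> "TagScheme":
        return cls(tuple(d["classes"]))


@dataclass(frozen=True)
class EntitySpan:
    """A typed half-open character interval ``[start, end)`` within a sentence."""

    start: int
    end: int
    cls: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TaggedSentence:
    """A character sequence with one BIO tag per character."""

    tokens: tuple[str, ...]
    tags: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "tags", tuple(self.tags))
        if len(self.tokens) == 0:
            raise ValueError("empty sentence")
        if len(self.tokens) != len(self.tags):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    def validate(self, scheme: TagScheme, strict: bool = False) -> None:
        """Check every tag against *scheme*; with ``strict`` also reject
        orphan ``I-c`` continuations (an I not preceded by B-c or I-c)."""
        for t in self.tags:
            if not scheme.is_valid_label(t):
                raise ValueError(f"unknown tag {t!r}")
        if strict:
            prev = "O"
            for i, t in enumerate(self.tags):
                if t.startswith("I-"):
                    cls = t[2:]
                    if prev not in (f"B-{cls}", f"I-{cls}"):
                        raise ValueError(
                            f"illegal BIO continuation {prev!r} -> {t!r} at position {i}"
                        )
                prev = t

    def spans(self, repair: str = "i_as_b") -> list[EntitySpan]:
        return bio_to_spans(self.tags, repair=repair)


def _as_line_iter(stream) -> Iterator[str]:
    if isinstance(stream, Path):
        return iter(stream.read_text(encoding="utf-8").splitlines())
    if isinstance(stream, str):
        # a one-line string without tabs/newlines is taken as a path
        if "\n" not in stream and "\t" not in stream and stream.strip():
            try:
                if Path(stream).is_file():
                    return iter(Path(stream).read_text(encoding="utf-8").splitlines())
            except OSError:
                pass
        return iter(stream.splitlines())
    if hasattr(stream, "read"):
        return iter(stream.read().splitlines())
    return iter(stream)


def read_conll(stream, scheme: TagScheme | None = None) -> list[TaggedSentence]:
    """Parse a CoNLL-style BIO file: ``<char><TAB><tag>`` per line, blank
    line between sentences, UTF-8, no comments.

    *stream* may be a path, an open text file, raw file content, or an
    iterable of lines.  Each sentence is validated against *scheme*
    (default: the four clinical classes).  Malformed lines raise
    :class:`ParseError` with the 1-based line number; zero-length sentences
    (consecutive blank lines) are skipped silently.
    """
    scheme = scheme or TagScheme()
    sentences: list[TaggedSentence] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush(lineno: int):
        if not tokens:
            return
        sent = TaggedSentence(tuple(tokens), tuple(tags))
        try:
            sent.validate(scheme)
        except ValueError as e:
            raise ParseError(str(e), lineno) from None
        sentences.append(sent)
        tokens.clear()
        tags.clear()

    lineno = 0
    for lineno, line in enumerate(_as_line_iter(stream), start=1):
        line = line.rstrip("\n")
        if line.strip() == "":
            flush(lineno)
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0]:
            raise ParseError(f"expected '<char>\\t<tag>', got {line!r}", lineno)
        char, tag = parts
        if len(char) != 1:
            raise ParseError(f"token {char!r} is not a single character", lineno)
        tokens.append(char)
        tags.append(tag)
    flush(lineno + 1)
    return sentences


def write_conll(sentences: Iterable[TaggedSentence], stream=None,
                scheme: TagScheme | None = None) -> str | None:
    """Serialize sentences in the CoNLL dialect read by :func:`read_conll`.

    Refuses to write tags outside *scheme*.  Returns the text if *stream*
    is None, otherwise writes to the path or file object.
    """
    scheme = scheme or TagScheme()
    buf = io.StringIO()
    for sent in sentences:
        sent.validate(scheme)
        for char, tag in zip(sent.tokens, sent.tags):
            buf.write(f"{char}\t{tag}\n")
        buf.write("\n")
    text = buf.getvalue()
    if stream is None:
        return text
    if isinstance(stream, (str, Path)):
        Path(stream).write_text(text, encoding="utf-8")
        return None
    stream.write(text)
    return None


def bio_to_spans(tags: Sequence[str], repair: str = "i_as_b") -> list[EntitySpan]:
    """Decode a BIO tag sequence into typed entity spans.

    Maximal runs ``B-c (I-c)*`` become one span of class ``c``.  Illegal
    continuations (an ``I-c`` not preceded by ``B-c``/``I-c``) are handled
    by *repair*:

    - ``"i_as_b"`` (default): the orphan I opens a new span, matching the
      permissive convention of common NER evaluation tooling;
    - ``"strict"``: raise ``ValueError``.

    Returned spans are sorted by start and never overlap.
    """
    if repair not in ("i_as_b", "strict"):
        raise ValueError(f"unknown repair policy {repair!r}")
    spans: list[EntitySpan] = []
    cur_cls: str | None = None
    cur_start = 0
    for i, tag in enumerate(tags):
        if tag == "O":
            if cur_cls is not None:
                spans.append(EntitySpan(cur_start, i, cur_cls))
                cur_cls = None
        elif tag.startswith("B-"):
            if cur_cls is not None:
                spans.append(EntitySpan(cur_start, i, cur_cls))
            cur_cls = tag[2:]
            cur_start = i
        elif tag.startswith("I-"):
            cls = tag[2:]
            if cur_cls == cls:
                continue  # legal continuation
            if repair == "strict":
                raise ValueError(f"orphan continuation {tag!r} at position {i}")
            # I-as-B: treat as the start of a new span
            if cur_cls is not None:
                spans.append(EntitySpan(cur_start, i, cur_cls))
            cur_cls = cls
            cur_start = i
        else:
            raise ValueError(f"not a BIO tag: {tag!r}")
    if cur_cls is not None:
        spans.append(EntitySpan(cur_start, len(tags), cur_cls))
    return spans


def spans_to_bio(length: int, spans: Iterable[EntitySpan]) -> list[str]:
    """Encode non-overlapping spans as a BIO tag sequence of *length* tags.

    Raises ``ValueError`` on out-of-range or overlapping spans.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    tags = ["O"] * length
    occupied = [False] * length
    for span in sorted(spans, key=lambda s: s.start):
        if span.end > length:
            raise ValueError(f"span {span} exceeds sentence length {length}")
        if any(occupied[span.start:span.end]):
            raise ValueError(f"span {span} overlaps a previous span")
        for i in range(span.start, span.end):
            occupied[i] = True
        tags[span.start] = f"B-{span.cls}"
        for i in range(span.start + 1, span.end):
            tags[i] = f"I-{span.cls}"
    return tags


@dataclass
class CorpusStats:
    """Per-class entity counts over a corpus; ``total`` is their sum."""

    per_class: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_class.values())

    def to_tsv(self) -> str:
        lines = ["class\tcount"]
        for cls, n in self.per_class.items():
            lines.append(f"{cls}\t{n}")
        lines.append(f"total\t{self.total}")
        return "\n".join(lines) + "\n"


def corpus_stats(sentences: Iterable[TaggedSentence],
                 scheme: TagScheme | None = None) -> CorpusStats:
    """Count entities per class across a corpus (spans decoded from tags)."""
    scheme = scheme or TagScheme()
    counts = {c: 0 for c in scheme.classes}
    for sent in sentences:
        for span in bio_to_spans(sent.tags):
            if span.cls not in counts:
                counts[span.cls] = 0
            counts[span.cls] += 1
    return CorpusStats(counts)
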