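"""Sentence splitting and dependency-parse attachment.

Parsing is behind an adapter contract: anything that yields, per sentence,
tokens aligned to the sentence text plus labeled head->dependent edges can
drive the downstream graph construction.  The package ships a deterministic
sidecar-file parser (the fixture adapter); the synthetic generator emits
sidecars in the same format, so no live parser is required anywhere.

Sidecar format, per sentence::

    #sent <doc_id> <sent_index>
    <index> TAB <text> TAB <lemma> TAB <pos> TAB <head_index> TAB <dep_label>
    ...
    #edge <label> <head_index> <dep_index>     (optional extra edges)

The root token has ``head_index`` -1 and label ``root``.  ``#edge`` lines let
gold numbered-argument or semantic edges be injected for fixture-driven tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Protocol

from .corpus_io import Document, Mention


@dataclass
class Token:
    index: int
    start: int
    end: int
    text: str
    lemma: str
    pos: str


@dataclass(frozen=True)
class DependencyEdge:
    """A collapsed-dependency edge; labels are opaque adapter-defined strings."""

    head_index: int
    dep_index: int
    label: str

    def __post_init__(self) -> None:
        if self.head_index == self.dep_index:
            raise ValueError("dependency self-loop")


@dataclass
class Sentence:
    start: int
    end: int
    tokens: list[Token] = field(default_factory=list)
    edges: list[DependencyEdge] = field(default_factory=list)
    extra_edges: list[tuple[str, int, int]] = field(default_factory=list)

    def text_of(self, document_text: str) -> str:
        return document_text[self.start:self.end]

    def tokens_in_span(self, start: int, end: int) -> list[Token]:
        """Tokens overlapping the document-offset span [start, end)."""
        return [t for t in self.tokens if t.start < end and t.end > start]


class ParseAdapter(Protocol):
    """Contract for anything that can supply a parse for a sentence."""

    def parse(self, doc_id: str, sent_index: int, sentence: Sentence,
              document_text: str) -> "ParseRecord | None": ...


@dataclass
class ParseRecord:
    """Adapter output: tokens (sentence-relative offsets implied by text
    alignment) and dependency edges, plus optional extra typed edges."""

    tokens: list[tuple[str, str, str]]  # (text, lemma, pos)
    heads: list[int]                    # head index per token, -1 for root
    labels: list[str]                   # dep label per token
    extra_edges: list[tuple[str, int, int]] = field(default_factory=list)


# Common sentence-final abbreviations that must not end a sentence.
_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "prof", "fig", "figs", "e.g", "i.e", "etc",
    "vs", "al", "approx", "no", "resp", "spp", "cf",
}

_BOUNDARY = re.compile(r"([.!?])(\s+)(?=[A-Z0-9(\[\"'])")


def split_sentences(document: Document) -> Document:
    """Split a document into sentences in place and return it.

    The title is always one sentence.  The abstract is split after
    sentence-final punctuation followed by whitespace and a capital (or
    digit/bracket), with an abbreviation stop-list.  Any boundary that would
    split a mention is merged away, so no mention straddles a sentence.
    """
    sentences: list[Sentence] = []
    if document.title:
        sentences.append(Sentence(0, len(document.title)))
    if document.abstract:
        offset = len(document.title) + 1
        for s, e in _split_spans(document.abstract):
            sentences.append(Sentence(offset + s, offset + e))
    sentences = _merge_straddled(sentences, document.mentions)
    document.sentences = sentences
    return document


def _split_spans(text: str) -> list[tuple[int, int]]:
    cuts = [0]
    for m in _BOUNDARY.finditer(text):
        before = text[:m.end(1)]
        last_word = re.findall(r"[\w.]+", before[-24:])
        if last_word:
            w = last_word[-1].rstrip(".").lower()
            if w in _ABBREVIATIONS or (len(w) == 1 and w.isalpha()):
                continue
        cuts.append(m.end())  # start of the next sentence, after the whitespace
    cuts.append(len(text))
    spans = []
    for a, b in zip(cuts, cuts[1:]):
        # trim trailing whitespace from the span, keep punctuation
        while b > a and text[b - 1].isspace():
            b -= 1
        if b > a:
            spans.append((a, b))
    return spans


def _merge_straddled(sentences: list[Sentence],
                     mentions: list[Mention]) -> list[Sentence]:
    sents = list(sentences)
    changed = True
    while changed:
        changed = False
        for i in range(len(sents) - 1):
            if any(m.start < sents[i].end and m.end > sents[i + 1].start
                   for m in mentions):
                merged = Sentence(sents[i].start, sents[i + 1].end)
                sents[i:i + 2] = [merged]
                changed = True
                break
    return sents


def attach_parse(sentence: Sentence, record: ParseRecord,
                 document_text: str) -> Sentence:
    """Attach adapter tokens/edges to a sentence, verifying character alignment.

    Tokens are located left-to-right in the sentence text; a token that cannot
    be found is a hard alignment error.
    """
    sent_text = sentence.text_of(document_text)
    tokens: list[Token] = []
    cursor = 0
    for i, (text, lemma, pos) in enumerate(record.tokens):
        at = sent_text.find(text, cursor)
        if at < 0:
            raise ValueError(
                f"token {i} {text!r} not found in sentence "
                f"{sent_text!r} after offset {cursor}"
            )
        tokens.append(Token(i, sentence.start + at,
                            sentence.start + at + len(text), text, lemma, pos))
        cursor = at + len(text)
    n = len(tokens)
    edges: list[DependencyEdge] = []
    for dep, (head, label) in enumerate(zip(record.heads, record.labels)):
        if head == -1:
            continue
        if not (0 <= head < n):
            raise ValueError(f"head index {head} out of range for token {dep}")
        edges.append(DependencyEdge(head, dep, label))
    for label, head, dep in record.extra_edges:
        if not (0 <= head < n and 0 <= dep < n):
            raise ValueError(f"extra edge ({label}, {head}, {dep}) out of range")
    sentence.tokens = tokens
    sentence.edges = edges
    sentence.extra_edges = list(record.extra_edges)
    return sentence


class SidecarParser:
    """Fixture adapter: parses read from a sidecar stream, keyed by
    (doc_id, sentence index)."""

    def __init__(self, records: dict[tuple[str, int], ParseRecord]):
        self.records = records

    @classmethod
    def from_stream(cls, stream: IO[str]) -> "SidecarParser":
        records: dict[tuple[str, int], ParseRecord] = {}
        key = None
        cur: ParseRecord | None = None

        def flush():
            if key is not None and cur is not None:
                records[key] = cur

        for raw in stream:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#sent"):
                flush()
                _, doc_id, idx = line.split()
                key = (doc_id, int(idx))
                cur = ParseRecord([], [], [])
            elif line.startswith("#edge"):
                _, label, h, d = line.split()
                assert cur is not None, "#edge before #sent"
                cur.extra_edges.append((label, int(h), int(d)))
            else:
                cols = line.split("\t")
                if len(cols) != 6:
                    raise ValueError(f"bad sidecar token line: {line!r}")
                idx, text, lemma, pos, head, label = cols
                assert cur is not None, "token line before #sent"
                if int(idx) != len(cur.tokens):
                    raise ValueError(f"token index out of order: {line!r}")
                cur.tokens.append((text, lemma, pos))
                cur.heads.append(int(head))
                cur.labels.append(label)
        flush()
        return cls(records)

    def parse(self, doc_id: str, sent_index: int, sentence: Sentence,
              document_text: str) -> ParseRecord | None:
        return self.records.get((doc_id, sent_index))


def write_sidecar(records: Iterable[tuple[str, int, ParseRecord]],
                  stream: IO[str]) -> None:
    """Serialize parse records in the sidecar format (the fixpoint inverse of
    :meth:`SidecarParser.from_stream`)."""
    for doc_id, sent_index, rec in records:
        stream.write(f"#sent {doc_id} {sent_index}\n")
        for i, ((text, lemma, pos), head, label) in enumerate(
                zip(rec.tokens, rec.heads, rec.labels)):
            stream.write(f"{i}\t{text}\t{lemma}\t{pos}\t{head}\t{label}\n")
        for label, h, d in rec.extra_edges:
            stream.write(f"#edge {label} {h} {d}\n")


def parse_document(document: Document, adapter: ParseAdapter) -> Document:
    """Split sentences (if needed) and attach parses from the adapter.

    Sentences the adapter has no record for are left untokenized; downstream
    feature extraction treats them as contributing no parse-based features.
    """
    if not document.sentences:
        split_sentences(document)
    for i, sent in enumerate(document.sentences):
        rec = adapter.parse(document.doc_id, i, sent, document.text)
        if rec is not None:
            attach_parse(sent, rec, document.text)
    return document
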