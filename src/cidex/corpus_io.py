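"""PubTator corpus reading/writing and the document data model.

The corpus format is the plain-text PubTator dialect used for chemical-disease
relation corpora: blank-line-separated document blocks with ``id|t|title`` and
``id|a|abstract`` header lines, tab-separated mention lines
(``id  start  end  text  type  conceptID``) and document-level relation lines
(``id  CID  chemicalID  diseaseID``).  Character offsets are 0-based half-open
over ``title + " " + abstract`` (abstract offsets start at ``len(title) + 1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

log = logging.getLogger(__name__)

CHEMICAL = "chemical"
DISEASE = "disease"

#: sentinel concept ID for mentions that failed normalization; such mentions
#: are kept on the document but never enter candidate-pair generation.
UNNORMALIZED = "-1"

# PubTator type column values accepted for each entity class.
_TYPE_ALIASES = {
    "chemical": CHEMICAL,
    "disease": DISEASE,
}


class CorpusFormatError(ValueError):
    """Raised on malformed PubTator or dictionary input."""


@dataclass
class Mention:
    """An offset-anchored entity span normalized to one or more concept IDs.

    Composite annotations (IDs joined by ``|`` in the source file) keep all
    IDs on one mention; each ID participates separately in candidate pairs.
    """

    start: int
    end: int
    text: str
    etype: str
    concept_ids: list[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"mention span empty: [{self.start}, {self.end})")
        if self.etype not in (CHEMICAL, DISEASE):
            raise ValueError(f"unknown entity type {self.etype!r}")
        if not self.concept_ids:
            raise ValueError("mention must carry at least one concept ID")

    @property
    def is_normalized(self) -> bool:
        return self.concept_ids != [UNNORMALIZED]


@dataclass(frozen=True, order=True)
class RelationPair:
    """A document-level chemical-induced-disease assertion between concept IDs."""

    chemical_id: str
    disease_id: str


@dataclass
class Document:
    """One title+abstract unit with its mentions and gold relation set."""

    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    relations: set[RelationPair] = field(default_factory=set)
    sentences: list = field(default_factory=list)  # filled by cidex.linguistic

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract if self.abstract else self.title

    def mention_ids(self, etype: str) -> set[str]:
        """Normalized concept IDs of the given type mentioned in this document."""
        out: set[str] = set()
        for m in self.mentions:
            if m.etype == etype and m.is_normalized:
                out.update(m.concept_ids)
        return out

    def validate(self) -> None:
        text = self.text
        for m in self.mentions:
            if text[m.start:m.end] != m.text:
                raise CorpusFormatError(
                    f"doc {self.doc_id}: mention text {m.text!r} does not match "
                    f"document span [{m.start}, {m.end}) = {text[m.start:m.end]!r}"
                )


class ConceptDictionary:
    """Case-insensitive name -> concept ID lookup (a MeSH-style vocabulary)."""

    def __init__(self) -> None:
        self._entries: dict[str, tuple[list[str], str]] = {}
        self._by_name: dict[str, list[str]] = {}

    def add(self, concept_id: str, etype: str, names: Iterable[str]) -> None:
        if etype not in (CHEMICAL, DISEASE):
            raise CorpusFormatError(f"unknown concept type {etype!r} for {concept_id}")
        if concept_id in self._entries and self._entries[concept_id][1] != etype:
            raise CorpusFormatError(
                f"concept {concept_id} declared both "
                f"{self._entries[concept_id][1]} and {etype}"
            )
        names = [n for n in names]
        if any(not n for n in names):
            raise CorpusFormatError(f"empty name for concept {concept_id}")
        stored, _ = self._entries.setdefault(concept_id, ([], etype))
        for n in names:
            if n not in stored:
                stored.append(n)
            self._by_name.setdefault(n.lower(), [])
            if concept_id not in self._by_name[n.lower()]:
                self._by_name[n.lower()].append(concept_id)

    def lookup(self, name: str) -> list[str]:
        """All concept IDs whose synonym list contains *name* (case-insensitive)."""
        return list(self._by_name.get(name.lower(), []))

    def etype(self, concept_id: str) -> str:
        return self._entries[concept_id][1]

    def names(self, concept_id: str) -> list[str]:
        return list(self._entries[concept_id][0])

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._entries

    def __iter__(self):
        return iter(self._entries)

    def all_names(self) -> dict[str, list[str]]:
        """Lowercased name -> concept IDs map (the reverse index)."""
        return {n: list(ids) for n, ids in self._by_name.items()}


def read_pubtator(stream: IO[str]) -> list[Document]:
    """Parse a PubTator stream into documents.

    Mention lines with a malformed or missing concept ID are kept with the
    sentinel ID ``-1`` (unnormalizable).  A span/text mismatch is a hard
    error; relation lines with an unknown tag are skipped with a warning.
    """
    docs: list[Document] = []
    lineno = 0

    def flush(block_lines: list[tuple[int, str]]) -> None:
        if not block_lines:
            return
        docs.append(_parse_block(block_lines))

    pending: list[tuple[int, str]] = []
    for raw in stream:
        lineno += 1
        line = raw.rstrip("\n")
        if not line.strip():
            flush(pending)
            pending = []
        else:
            pending.append((lineno, line))
    flush(pending)
    return docs


def _parse_block(lines: list[tuple[int, str]]) -> Document:
    title = abstract = None
    doc_id = None
    mentions: list[Mention] = []
    relations: set[RelationPair] = set()
    for lineno, line in lines:
        if "|t|" in line and title is None:
            doc_id, _, title = line.partition("|t|")
            continue
        if "|a|" in line and abstract is None and "\t" not in line:
            aid, _, abstract = line.partition("|a|")
            if doc_id is not None and aid != doc_id:
                raise CorpusFormatError(f"line {lineno}: abstract id {aid} != {doc_id}")
            continue
        cols = line.split("\t")
        if len(cols) == 4:
            did, tag, a, b = cols
            if tag != "CID":
                log.warning("line %d: unknown relation tag %r skipped", lineno, tag)
                continue
            relations.add(RelationPair(a, b))
            continue
        if len(cols) in (5, 6):
            did, start, end, text, etype = cols[:5]
            concept = cols[5] if len(cols) == 6 else UNNORMALIZED
            etype_norm = _TYPE_ALIASES.get(etype.lower())
            if etype_norm is None:
                raise CorpusFormatError(f"line {lineno}: unknown entity type {etype!r}")
            ids = [c for c in concept.split("|") if c]
            bad = [c for c in ids if not _valid_concept_id(c)]
            if bad or not ids:
                log.warning(
                    "line %d: malformed concept ID(s) %r; mention kept unnormalized",
                    lineno, concept,
                )
                ids = [UNNORMALIZED]
            mentions.append(Mention(int(start), int(end), text, etype_norm, ids))
            continue
        raise CorpusFormatError(f"line {lineno}: unrecognized line {line!r}")
    if doc_id is None or title is None:
        raise CorpusFormatError("document block missing |t| title line")
    doc = Document(doc_id, title, abstract or "", mentions, relations)
    doc.validate()
    return doc


def _valid_concept_id(concept_id: str) -> bool:
    # MeSH-style descriptor (D012345, C537543), synthetic (SC…/SD…), or the
    # explicit unnormalized sentinel.
    if concept_id == UNNORMALIZED:
        return True
    return concept_id[:1].isalpha() and concept_id.replace("+", "").isalnum()


def write_pubtator(docs: Iterable[Document], stream: IO[str]) -> None:
    """Serialize documents canonically: mentions sorted by (start, end),
    relations sorted lexicographically; one blank line after each block."""
    for doc in docs:
        doc.validate()
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in sorted(doc.mentions, key=lambda m: (m.start, m.end)):
            concept = "|".join(m.concept_ids)
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.text}\t{m.etype.capitalize()}\t{concept}\n"
            )
        for rel in sorted(doc.relations):
            stream.write(f"{doc.doc_id}\tCID\t{rel.chemical_id}\t{rel.disease_id}\n")
        stream.write("\n")


def load_dictionary(stream: IO[str]) -> ConceptDictionary:
    """Load a concept dictionary from TSV rows ``ID  type  name1|name2|...``."""
    d = ConceptDictionary()
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise CorpusFormatError(f"dictionary line {lineno}: expected 3 columns")
        concept_id, etype, names = cols
        etype_norm = _TYPE_ALIASES.get(etype.lower())
        if etype_norm is None:
            raise CorpusFormatError(f"dictionary line {lineno}: bad type {etype!r}")
        d.add(concept_id, etype_norm, [n for n in names.split("|") if n])
    return d
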