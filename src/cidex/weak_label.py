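"""Distant supervision: turn a curated document-level relation table plus
raw abstracts into a weakly labeled training corpus.

The procedure mirrors how curated chemical-disease databases are repurposed
for training: mentions are recovered with entity taggers and/or a
dictionary look-up against a controlled vocabulary; a curated relation is
kept for a document only if both its concept IDs actually appear among the
document's mentions (relations asserted only in the full text are thereby
filtered out); documents retaining no relation are dropped, as is anything
overlapping the gold evaluation corpus."""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .corpus_io import CHEMICAL, DISEASE, ConceptDictionary, Document, Mention, RelationPair

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeakRelationRow:
    doc_id: str
    chemical_id: str
    disease_id: str


class WeakRelationTable:
    """Unique curated (doc, chemical ID, disease ID) rows."""

    def __init__(self, rows: Iterable[WeakRelationRow] = ()):
        self.rows: list[WeakRelationRow] = []
        seen = set()
        for r in rows:
            if r not in seen:
                seen.add(r)
                self.rows.append(r)

    @classmethod
    def from_stream(cls, stream: IO[str]) -> "WeakRelationTable":
        rows = []
        for lineno, line in enumerate(stream, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ValueError(f"relation table line {lineno}: "
                                 f"expected 3 columns, got {len(cols)}")
            rows.append(WeakRelationRow(*cols))
        return cls(rows)

    def write(self, stream: IO[str]) -> None:
        for r in self.rows:
            stream.write(f"{r.doc_id}\t{r.chemical_id}\t{r.disease_id}\n")

    def by_doc(self) -> dict[str, list[WeakRelationRow]]:
        out: dict[str, list[WeakRelationRow]] = {}
        for r in self.rows:
            out.setdefault(r.doc_id, []).append(r)
        return out

    def __len__(self) -> int:
        return len(self.rows)


_WORD = re.compile(r"[0-9A-Za-z][0-9A-Za-z\-']*")


def dictionary_match(document: Document,
                     dictionary: ConceptDictionary) -> list[Mention]:
    """Case-insensitive longest-match scan over word boundaries.

    At each word start the longest dictionary name beginning there wins and
    the scan resumes after it, so nested shorter names are suppressed.  A
    name ambiguous between several IDs of one type yields one composite
    mention carrying all of them; ambiguity across types yields one mention
    per type.
    """
    text = document.text
    low = text.lower()
    names = dictionary.all_names()
    if not names:
        return []
    by_first_word: dict[str, list[str]] = {}
    for name in names:
        first = _WORD.match(name)
        key = first.group(0) if first else name
        by_first_word.setdefault(key, []).append(name)
    for cands in by_first_word.values():
        cands.sort(key=len, reverse=True)

    mentions: list[Mention] = []
    word_starts = [m.start() for m in _WORD.finditer(low)]
    pos = 0
    for start in word_starts:
        if start < pos:
            continue  # inside a previously matched name
        w = _WORD.match(low, start)
        for name in by_first_word.get(w.group(0), ()):
            end = start + len(name)
            if low[start:end] != name:
                continue
            if end < len(low) and re.match(r"[0-9A-Za-z]", low[end]):
                continue  # name must end at a word boundary
            ids = names[name]
            by_type: dict[str, list[str]] = {}
            for cid in ids:
                by_type.setdefault(dictionary.etype(cid), []).append(cid)
            for etype, cids in sorted(by_type.items()):
                mentions.append(Mention(start, end, text[start:end],
                                        etype, cids))
            pos = end
            break
    return mentions


def merge_mentions(tagger_mentions: Sequence[Mention],
                   dictionary_mentions: Sequence[Mention]) -> list[Mention]:
    """Union of tagger and dictionary mentions.

    Exact duplicate spans keep the tagger's IDs; overlapping conflicting
    spans keep the longer one (tagger wins ties).  Output sorted by offset.
    """
    candidates = (
        [(m, 0) for m in tagger_mentions] + [(m, 1) for m in dictionary_mentions])
    # longer spans first; tagger before dictionary on equal length
    candidates.sort(key=lambda p: (-(p[0].end - p[0].start), p[1], p[0].start))
    kept: list[Mention] = []
    for m, _src in candidates:
        clash = False
        for k in kept:
            if m.start < k.end and m.end > k.start:
                same_span = m.start == k.start and m.end == k.end
                if not (same_span and m.etype != k.etype):
                    clash = True
                    break
        if not clash:
            kept.append(m)
    kept.sort(key=lambda m: (m.start, m.end, m.etype))
    return kept


def build_weak_corpus(table: WeakRelationTable,
                      documents: Iterable[Document],
                      dictionary: ConceptDictionary | None = None,
                      exclude_doc_ids: Iterable[str] = ()) -> list[Document]:
    """Ground curated relations in documents and keep what survives.

    For each document (not in the exclusion list) the curated relations
    whose chemical and disease IDs both appear among its mentions become its
    positive labels; documents retaining none are dropped.  When a
    dictionary is given, dictionary matches are merged into the document's
    existing (tagger) mentions first.  Table rows naming absent documents
    are skipped with a warning.
    """
    exclude = set(exclude_doc_ids)
    rows_by_doc = table.by_doc()
    docs_by_id: dict[str, Document] = {}
    for d in documents:
        docs_by_id[d.doc_id] = d
    missing = set(rows_by_doc) - set(docs_by_id)
    for doc_id in sorted(missing):
        log.warning("relation table references absent document %s; skipped",
                    doc_id)
    out: list[Document] = []
    for doc_id, rows in rows_by_doc.items():
        if doc_id in exclude or doc_id not in docs_by_id:
            continue
        doc = copy.deepcopy(docs_by_id[doc_id])
        if dictionary is not None:
            doc.mentions = merge_mentions(
                doc.mentions, dictionary_match(doc, dictionary))
        chem_ids = doc.mention_ids(CHEMICAL)
        dis_ids = doc.mention_ids(DISEASE)
        grounded = {RelationPair(r.chemical_id, r.disease_id) for r in rows
                    if r.chemical_id in chem_ids and r.disease_id in dis_ids}
        if not grounded:
            continue
        doc.relations = grounded
        out.append(doc)
    return out
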