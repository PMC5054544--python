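"""Micro-averaged precision/recall/F1 for document-level relation sets and
normalized concept recognition, plus the co-occurrence baseline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from .corpus_io import CHEMICAL, DISEASE, Document, Mention, RelationPair


@dataclass
class PRF:
    tp: int
    fp: int
    fn: int
    #: True when a ratio was 0/0 and reported as 0 by convention
    undefined: bool = False

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PRF":
        return cls(tp, fp, fn, undefined=(tp + fp == 0 or tp + fn == 0))

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


def pair_prf(gold_by_doc: Mapping[str, set[RelationPair]],
             pred_by_doc: Mapping[str, set[RelationPair]]) -> PRF:
    """Micro-averaged P/R/F over documents; pairs match on exact
    (chemical ID, disease ID) equality.  A predicted document absent from
    the gold map is a corpus mismatch and a hard error."""
    unknown = set(pred_by_doc) - set(gold_by_doc)
    if unknown:
        raise KeyError(f"predictions for documents not in gold corpus: "
                       f"{sorted(unknown)[:5]}")
    tp = fp = fn = 0
    for doc_id, gold in gold_by_doc.items():
        pred = pred_by_doc.get(doc_id, set())
        tp += len(gold & pred)
        fp += len(pred - gold)
        fn += len(gold - pred)
    return PRF.from_counts(tp, fp, fn)


def concept_prf(gold_mentions: Mapping[str, Iterable[Mention]],
                pred_mentions: Mapping[str, Iterable[Mention]]
                ) -> dict[str, PRF]:
    """ID-level, offset-agnostic concept scores per entity type: for each
    document the set of normalized concept IDs of each type is compared."""
    unknown = set(pred_mentions) - set(gold_mentions)
    if unknown:
        raise KeyError(f"predictions for documents not in gold corpus: "
                       f"{sorted(unknown)[:5]}")
    counts = {etype: [0, 0, 0] for etype in (CHEMICAL, DISEASE)}

    def ids(mentions, etype):
        out = set()
        for m in mentions:
            if m.etype == etype and m.is_normalized:
                out.update(m.concept_ids)
        return out

    for doc_id, gold in gold_mentions.items():
        gold = list(gold)
        pred = list(pred_mentions.get(doc_id, ()))
        for etype in (CHEMICAL, DISEASE):
            g, p = ids(gold, etype), ids(pred, etype)
            counts[etype][0] += len(g & p)
            counts[etype][1] += len(p - g)
            counts[etype][2] += len(g - p)
    return {etype: PRF.from_counts(*c) for etype, c in counts.items()}


def cooccurrence_baseline(documents: Iterable[Document]
                          ) -> dict[str, set[RelationPair]]:
    """Predict every chemical-disease concept pair co-mentioned in a
    document — the recall-oriented baseline every same-document prediction
    set is a subset of."""
    out: dict[str, set[RelationPair]] = {}
    for doc in documents:
        out[doc.doc_id] = {
            RelationPair(c, d)
            for c in doc.mention_ids(CHEMICAL)
            for d in doc.mention_ids(DISEASE)
        }
    return out


def write_report(scores: Mapping[str, PRF], stream: IO[str]) -> None:
    """TSV report: one row per scored system/type."""
    stream.write("name\ttp\tfp\tfn\tprecision\trecall\tf1\n")
    for name, prf in scores.items():
        stream.write(
            f"{name}\t{prf.tp}\t{prf.fp}\t{prf.fn}"
            f"\t{prf.precision:.4f}\t{prf.recall:.4f}\t{prf.f1:.4f}\n")
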