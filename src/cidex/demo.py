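"""Small hand-parsed demonstration documents.

Three classic chemical-induced-disease constructions, each a synthetic
stand-in document built in code with its gold parse:

* :func:`collection_doc` — "A number of angiogenesis inhibitors such as
  sunitinib and sorafenib have been found to cause acute hemolysis": the
  trigger's agent is a generic quantifier noun whose argument must be
  propagated through member-collection/is-a edges onto the entities.
* :func:`coreterm_doc` — "A case of tardive dyskinesia caused by
  metoclopramide": the trigger's theme is a semantically light head noun
  ("case") whose argument must be propagated through its "of"-complement.
* :func:`bow_doc` — a synthetic two-occurrence abstract whose window and
  n-gram features are small enough to enumerate by hand.
* :func:`midazolam_doc` — a synthetic four-sentence abstract with one
  chemical and three diseases (one related in-sentence, one across
  sentences, one — "death" — unrelated), the canonical candidate-pair
  bookkeeping example.

Every function returns ``(document, sidecars)`` where the sidecars map
``(doc_id, sentence_index)`` to the parse record.
"""

from __future__ import annotations

from .corpus_io import CHEMICAL, DISEASE, Document, Mention, RelationPair
from .linguistic import ParseRecord, SidecarParser, split_sentences

SUNITINIB = "D000077210"
SORAFENIB = "C471405"
HEMOLYSIS = "D006461"
METOCLOPRAMIDE = "D008787"
TARDIVE_DYSKINESIA = "D004409"
MIDAZOLAM = "D008874"
CARDIORESPIRATORY_ARREST = "D006323"
RESPIRATORY_DEPRESSION = "D012140"
DEATH = "D003643"


def _doc(doc_id, title, abstract, mentions, relations, sidecars):
    doc = Document(doc_id, title, abstract, mentions, relations)
    doc.validate()
    split_sentences(doc)
    return doc, {(doc_id, i): rec for i, rec in enumerate(sidecars)}


def collection_doc() -> tuple[Document, dict]:
    title = ("A number of angiogenesis inhibitors such as sunitinib and "
             "sorafenib have been found to cause acute hemolysis")
    mentions = [
        Mention(44, 53, "sunitinib", CHEMICAL, [SUNITINIB]),
        Mention(58, 67, "sorafenib", CHEMICAL, [SORAFENIB]),
        Mention(93, 108, "acute hemolysis", DISEASE, [HEMOLYSIS]),
    ]
    relations = {RelationPair(SUNITINIB, HEMOLYSIS),
                 RelationPair(SORAFENIB, HEMOLYSIS)}
    parse = ParseRecord(
        tokens=[("A", "a", "DT"), ("number", "number", "NN"),
                ("of", "of", "IN"), ("angiogenesis", "angiogenesis", "NN"),
                ("inhibitors", "inhibitor", "NNS"), ("such", "such", "JJ"),
                ("as", "as", "IN"), ("sunitinib", "sunitinib", "NN"),
                ("and", "and", "CC"), ("sorafenib", "sorafenib", "NN"),
                ("have", "have", "VBP"), ("been", "be", "VBN"),
                ("found", "find", "VBN"), ("to", "to", "TO"),
                ("cause", "cause", "VB"), ("acute", "acute", "JJ"),
                ("hemolysis", "hemolysis", "NN")],
        heads=[1, 12, 1, 4, 1, 4, 4, 4, 7, 7, 12, 12, -1, 14, 12, 16, 14],
        labels=["det", "nsubjpass", "prep", "nn", "prep_of", "mwe", "mwe",
                "prep_such_as", "cc", "conj_and", "aux", "auxpass", "root",
                "aux", "xcomp", "amod", "dobj"],
    )
    return _doc("90000001", title, "", mentions, relations, [parse])


def coreterm_doc() -> tuple[Document, dict]:
    title = "A case of tardive dyskinesia caused by metoclopramide"
    mentions = [
        Mention(10, 28, "tardive dyskinesia", DISEASE, [TARDIVE_DYSKINESIA]),
        Mention(39, 53, "metoclopramide", CHEMICAL, [METOCLOPRAMIDE]),
    ]
    relations = {RelationPair(METOCLOPRAMIDE, TARDIVE_DYSKINESIA)}
    parse = ParseRecord(
        tokens=[("A", "a", "DT"), ("case", "case", "NN"), ("of", "of", "IN"),
                ("tardive", "tardive", "JJ"),
                ("dyskinesia", "dyskinesia", "NN"),
                ("caused", "cause", "VBN"), ("by", "by", "IN"),
                ("metoclopramide", "metoclopramide", "NN")],
        heads=[1, -1, 1, 4, 1, 1, 5, 5],
        labels=["det", "root", "prep", "amod", "prep_of", "partmod", "prep",
                "agent"],
        extra_edges=[("nsubjpass", 5, 1)],
    )
    return _doc("90000002", title, "", mentions, relations, [parse])


#: concept IDs of the bag-of-words demonstration pair
BOW_CHEMICAL = "D011899"
BOW_DISEASE = "D009395"


def bow_doc() -> tuple[Document, dict]:
    """Two occurrences of the chemical, each with "induced acute" to its
    right; contexts accumulate to {induce x2, acute x2, case, of,
    frequently, is}."""
    title = "A case of neuroleptin induced acute nephronecrosis"
    abstract = ("Nephronecrosis was confirmed by biopsy . "
                "Supportive care was provided . "
                "Renal function declined steadily . "
                "It frequently is neuroleptin induced acute illness .")
    off = len(title) + 1
    mentions = [
        Mention(10, 21, "neuroleptin", CHEMICAL, [BOW_CHEMICAL]),
        Mention(36, 50, "nephronecrosis", DISEASE, [BOW_DISEASE]),
        Mention(off, off + 14, "Nephronecrosis", DISEASE, [BOW_DISEASE]),
        Mention(off + 124, off + 135, "neuroleptin", CHEMICAL, [BOW_CHEMICAL]),
    ]
    relations = {RelationPair(BOW_CHEMICAL, BOW_DISEASE)}
    parses = [
        ParseRecord(  # title
            tokens=[("A", "a", "DT"), ("case", "case", "NN"),
                    ("of", "of", "IN"), ("neuroleptin", "neuroleptin", "NN"),
                    ("induced", "induce", "VBN"), ("acute", "acute", "JJ"),
                    ("nephronecrosis", "nephronecrosis", "NN")],
            heads=[1, -1, 1, 4, 6, 6, 1],
            labels=["det", "root", "prep", "npadvmod", "amod", "amod",
                    "prep_of"],
        ),
        ParseRecord(
            tokens=[("Nephronecrosis", "nephronecrosis", "NN"),
                    ("was", "be", "VBD"), ("confirmed", "confirm", "VBN"),
                    ("by", "by", "IN"), ("biopsy", "biopsy", "NN"),
                    (".", ".", ".")],
            heads=[2, 2, -1, 2, 2, 2],
            labels=["nsubjpass", "auxpass", "root", "prep", "agent", "punct"],
        ),
        ParseRecord(
            tokens=[("Supportive", "supportive", "JJ"),
                    ("care", "care", "NN"), ("was", "be", "VBD"),
                    ("provided", "provide", "VBN"), (".", ".", ".")],
            heads=[1, 3, 3, -1, 3],
            labels=["amod", "nsubjpass", "auxpass", "root", "punct"],
        ),
        ParseRecord(
            tokens=[("Renal", "renal", "JJ"), ("function", "function", "NN"),
                    ("declined", "decline", "VBD"),
                    ("steadily", "steadily", "RB"), (".", ".", ".")],
            heads=[1, 2, -1, 2, 2],
            labels=["amod", "nsubj", "root", "advmod", "punct"],
        ),
        ParseRecord(
            tokens=[("It", "it", "PRP"), ("frequently", "frequently", "RB"),
                    ("is", "is", "VBZ"), ("neuroleptin", "neuroleptin", "NN"),
                    ("induced", "induce", "VBN"), ("acute", "acute", "JJ"),
                    ("illness", "illness", "NN"), (".", ".", ".")],
            heads=[2, 2, -1, 4, 6, 6, 2, 2],
            labels=["nsubj", "advmod", "root", "npadvmod", "amod", "amod",
                    "attr", "punct"],
        ),
    ]
    return _doc("11431197", title, abstract, mentions, relations, parses)


def midazolam_doc() -> tuple[Document, dict]:
    title = "Adverse events after intravenous midazolam"
    abstract = ("Midazolam sedation caused cardiorespiratory arrest in two "
                "patients . "
                "Respiratory and cardiovascular depression developed "
                "gradually . One death was recorded .")
    off = len(title) + 1
    mentions = [
        Mention(33, 42, "midazolam", CHEMICAL, [MIDAZOLAM]),
        Mention(off, off + 9, "Midazolam", CHEMICAL, [MIDAZOLAM]),
        Mention(off + 26, off + 50, "cardiorespiratory arrest", DISEASE,
                [CARDIORESPIRATORY_ARREST]),
        Mention(off + 69, off + 110, "Respiratory and cardiovascular depression",
                DISEASE, [RESPIRATORY_DEPRESSION]),
        Mention(off + 137, off + 142, "death", DISEASE, [DEATH]),
    ]
    relations = {RelationPair(MIDAZOLAM, CARDIORESPIRATORY_ARREST),
                 RelationPair(MIDAZOLAM, RESPIRATORY_DEPRESSION)}
    parses = [
        ParseRecord(
            tokens=[("Adverse", "adverse", "JJ"), ("events", "event", "NNS"),
                    ("after", "after", "IN"),
                    ("intravenous", "intravenous", "JJ"),
                    ("midazolam", "midazolam", "NN")],
            heads=[1, -1, 1, 4, 1],
            labels=["amod", "root", "prep", "amod", "prep_after"],
        ),
        ParseRecord(
            tokens=[("Midazolam", "midazolam", "NN"),
                    ("sedation", "sedation", "NN"),
                    ("caused", "cause", "VBD"),
                    ("cardiorespiratory", "cardiorespiratory", "JJ"),
                    ("arrest", "arrest", "NN"), ("in", "in", "IN"),
                    ("two", "two", "CD"), ("patients", "patient", "NNS"),
                    (".", ".", ".")],
            heads=[1, 2, -1, 4, 2, 2, 7, 2, 2],
            labels=["nn", "nsubj", "root", "amod", "dobj", "prep", "num",
                    "prep_in", "punct"],
        ),
        ParseRecord(
            tokens=[("Respiratory", "respiratory", "JJ"), ("and", "and", "CC"),
                    ("cardiovascular", "cardiovascular", "JJ"),
                    ("depression", "depression", "NN"),
                    ("developed", "develop", "VBD"),
                    ("gradually", "gradually", "RB"), (".", ".", ".")],
            heads=[3, 0, 0, 4, -1, 4, 4],
            labels=["amod", "cc", "conj_and", "nsubj", "root", "advmod",
                    "punct"],
        ),
        ParseRecord(
            tokens=[("One", "one", "CD"), ("death", "death", "NN"),
                    ("was", "be", "VBD"), ("recorded", "record", "VBN"),
                    (".", ".", ".")],
            heads=[1, 3, 3, -1, 3],
            labels=["num", "nsubjpass", "auxpass", "root", "punct"],
        ),
    ]
    return _doc("2375138", title, abstract, mentions, relations, parses)


def all_demo_docs() -> tuple[list[Document], SidecarParser]:
    """Every demonstration document with a combined sidecar parser."""
    docs = []
    sidecars: dict = {}
    for fn in (collection_doc, coreterm_doc, bow_doc, midazolam_doc):
        doc, sc = fn()
        docs.append(doc)
        sidecars.update(sc)
    return docs, SidecarParser(sidecars)
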