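"""Deterministic synthetic corpora for the full pipeline.

Documents are assembled from sentence templates whose dependency parses are
emitted alongside the text, so every stage — corpus IO, sentence splitting,
parse attachment, EDG construction, feature extraction, training, weak
labeling — runs without any external parser or download.  Positive
chemical-disease pairs are expressed either by trigger-verb constructions
(active, collection "a number of X such as ...", core-term "a case of ...
caused by ...", and participle premodifier shapes) or asserted across
sentences; negative co-mentions appear as treatment distractor sentences.

The generator trades linguistic realism for exactness: templates emit their
own gold parses, surface names are single tokens, and vocabulary IDs use a
reserved synthetic prefix (SC…/SD…) so they can never collide with real
MeSH descriptors.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus_io import CHEMICAL, DISEASE, ConceptDictionary, Document, Mention, RelationPair
from .linguistic import ParseRecord, SidecarParser
from .weak_label import WeakRelationRow, WeakRelationTable


@dataclass
class SyntheticConfig:
    n_docs: int = 200
    n_chemicals: int = 30
    n_diseases: int = 30
    #: fraction of candidate (chemical, disease) pairs per document that are
    #: true chemical-induced-disease relations
    p_positive: float = 0.35
    #: fraction of true relations expressed by a trigger-verb sentence
    #: (the rest are asserted across sentences)
    p_trigger: float = 0.9
    #: fraction of negative co-mention opportunities realized as treatment
    #: distractor sentences
    p_distractor: float = 0.5
    min_entities: int = 2
    max_entities: int = 3
    seed: int = 0
    doc_id_base: int = 7_000_000

    def __post_init__(self) -> None:
        for name in ("p_positive", "p_trigger", "p_distractor"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_positive > 0 and (self.n_chemicals == 0 or self.n_diseases == 0):
            raise ValueError("positive pairs requested with an empty vocabulary")
        if self.n_docs < 0 or self.min_entities < 1 \
                or self.max_entities < self.min_entities:
            raise ValueError("bad corpus size configuration")


@dataclass
class TemplateInstance:
    """A named sentence template with its slot fillers (surface forms)."""

    name: str
    slots: dict[str, str] = field(default_factory=dict)


# Each builder returns (tokens=(text, lemma, pos), heads, labels,
# extra_edges, slot -> token index of the slot's mention).

_PAST = {"cause": "caused", "induce": "induced", "produce": "produced"}


def _t(text, lemma, pos):
    return (text, lemma, pos)


def _name_token(surface):
    return _t(surface, surface.lower(), "NN")


def _build_title(slots):
    tokens = [_t("A", "a", "DT"), _t("prospective", "prospective", "JJ"),
              _t("clinical", "clinical", "JJ"), _t("safety", "safety", "NN"),
              _t("report", "report", "NN")]
    heads = [4, 4, 4, 4, -1]
    labels = ["det", "amod", "amod", "nn", "root"]
    return tokens, heads, labels, [], {}


def _build_admin(slots):
    tokens = [_name_token(slots["chem"]), _t("was", "be", "VBD"),
              _t("administered", "administer", "VBN"),
              _t("daily", "daily", "RB"), _t(".", ".", ".")]
    heads = [2, 2, -1, 2, 2]
    labels = ["nsubjpass", "auxpass", "root", "advmod", "punct"]
    return tokens, heads, labels, [], {"chem": 0}


def _build_monitor(slots):
    tokens = [_name_token(slots["dis"]), _t("was", "be", "VBD"),
              _t("monitored", "monitor", "VBN"),
              _t("during", "during", "IN"),
              _t("follow-up", "follow-up", "NN"), _t(".", ".", ".")]
    heads = [2, 2, -1, 2, 2, 2]
    labels = ["nsubjpass", "auxpass", "root", "prep", "prep_during", "punct"]
    return tokens, heads, labels, [], {"dis": 0}


def _build_active(slots):
    trig = slots["trigger"]
    tokens = [_name_token(slots["chem"]),
              _t(_PAST[trig], trig, "VBD"),
              _name_token(slots["dis"]), _t("in", "in", "IN"),
              _t("several", "several", "JJ"),
              _t("subjects", "subject", "NNS"), _t(".", ".", ".")]
    heads = [1, -1, 1, 1, 5, 1, 1]
    labels = ["nsubj", "root", "dobj", "prep", "amod", "prep_in", "punct"]
    return tokens, heads, labels, [], {"chem": 0, "dis": 2}


def _build_collection(slots):
    trig = slots["trigger"]
    tokens = [_t("A", "a", "DT"), _t("number", "number", "NN"),
              _t("of", "of", "IN"), _t("agents", "agent", "NNS"),
              _t("such", "such", "JJ"), _t("as", "as", "IN"),
              _name_token(slots["chem"]), _t("have", "have", "VBP"),
              _t("been", "be", "VBN"), _t("found", "find", "VBN"),
              _t("to", "to", "TO"), _t(trig, trig, "VB"),
              _name_token(slots["dis"]), _t(".", ".", ".")]
    heads = [1, 9, 1, 1, 3, 3, 3, 9, 9, -1, 11, 9, 11, 9]
    labels = ["det", "nsubjpass", "prep", "prep_of", "mwe", "mwe",
              "prep_such_as", "aux", "auxpass", "root", "aux", "xcomp",
              "dobj", "punct"]
    return tokens, heads, labels, [], {"chem": 6, "dis": 12}


def _build_coreterm(slots):
    trig = slots["trigger"]
    tokens = [_t("A", "a", "DT"), _t("case", "case", "NN"),
              _t("of", "of", "IN"), _name_token(slots["dis"]),
              _t(_PAST[trig], trig, "VBN"), _t("by", "by", "IN"),
              _name_token(slots["chem"]), _t("was", "be", "VBD"),
              _t("reported", "report", "VBN"), _t(".", ".", ".")]
    heads = [1, 8, 1, 1, 1, 4, 4, 8, -1, 8]
    labels = ["det", "nsubjpass", "prep", "prep_of", "partmod", "prep",
              "agent", "auxpass", "root", "punct"]
    # the participle's passive subject, present in the collapsed
    # representation but not derivable from the head array alone
    extra = [("nsubjpass", 4, 1)]
    return tokens, heads, labels, extra, {"chem": 6, "dis": 3}


def _build_participle(slots):
    tokens = [_name_token(slots["chem"]),
              _t("induced", "induce", "VBN"), _name_token(slots["dis"]),
              _t("was", "be", "VBD"), _t("frequently", "frequently", "RB"),
              _t("observed", "observe", "VBN"), _t(".", ".", ".")]
    heads = [1, 2, 5, 5, 5, -1, 5]
    labels = ["npadvmod", "amod", "nsubjpass", "auxpass", "advmod", "root",
              "punct"]
    return tokens, heads, labels, [], {"chem": 0, "dis": 2}


def _build_develop(slots):
    tokens = [_t("Subsequently", "subsequently", "RB"), _t(",", ",", ","),
              _name_token(slots["dis"]), _t("developed", "develop", "VBD"),
              _t("in", "in", "IN"), _t("several", "several", "JJ"),
              _t("subjects", "subject", "NNS"), _t(".", ".", ".")]
    heads = [3, 3, 3, -1, 3, 6, 3, 3]
    labels = ["advmod", "punct", "nsubj", "root", "prep", "amod", "prep_in",
              "punct"]
    return tokens, heads, labels, [], {"dis": 2}


def _build_treatment(slots):
    tokens = [_name_token(slots["chem"]),
              _t("effectively", "effectively", "RB"),
              _t("treated", "treat", "VBD"),
              _t("patients", "patient", "NNS"), _t("with", "with", "IN"),
              _name_token(slots["dis"]), _t(".", ".", ".")]
    heads = [2, 2, -1, 2, 3, 3, 2]
    labels = ["nsubj", "advmod", "root", "dobj", "prep", "prep_with", "punct"]
    return tokens, heads, labels, [], {"chem": 0, "dis": 5}


def _build_closing(slots):
    tokens = [_t("These", "these", "DT"), _t("findings", "finding", "NNS"),
              _t("warrant", "warrant", "VBP"),
              _t("further", "further", "JJ"), _t("study", "study", "NN"),
              _t(".", ".", ".")]
    heads = [1, 2, -1, 4, 2, 2]
    labels = ["det", "nsubj", "root", "amod", "dobj", "punct"]
    return tokens, heads, labels, [], {}


def _build_heading(slots):
    return [_name_token(slots["word"])], [-1], ["root"], [], {}


TEMPLATES = {
    "title": _build_title,
    "admin": _build_admin,
    "monitor": _build_monitor,
    "active_trigger": _build_active,
    "collection_trigger": _build_collection,
    "coreterm_trigger": _build_coreterm,
    "participle_trigger": _build_participle,
    "develop": _build_develop,
    "treatment": _build_treatment,
    "closing": _build_closing,
    "heading": _build_heading,
}

TRIGGER_TEMPLATES = ("active_trigger", "collection_trigger",
                     "coreterm_trigger", "participle_trigger")


def generate_parse(instance: TemplateInstance) -> ParseRecord:
    """The parse a template instance deterministically carries (first token
    capitalized, as it will surface in a document).  Unknown template names
    are a hard error."""
    if instance.name not in TEMPLATES:
        raise ValueError(f"unknown sentence template {instance.name!r}")
    tokens, heads, labels, extra, _slots = TEMPLATES[instance.name](instance.slots)
    tokens = _capitalize_first(tokens)
    return ParseRecord(list(tokens), list(heads), list(labels), list(extra))


def _capitalize_first(tokens):
    (text, lemma, pos), *rest = tokens
    return [(text[:1].upper() + text[1:], lemma, pos)] + rest


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    sidecars: dict[tuple[str, int], ParseRecord]
    dictionary: ConceptDictionary
    relation_table: WeakRelationTable
    config: SyntheticConfig

    @property
    def parser(self) -> SidecarParser:
        return SidecarParser(self.sidecars)


def _vocabulary(config: SyntheticConfig) -> ConceptDictionary:
    d = ConceptDictionary()
    for i in range(config.n_chemicals):
        d.add(f"SC{i:04d}", CHEMICAL, [f"chemanol{i}", f"chemanolum{i}"])
    for i in range(config.n_diseases):
        d.add(f"SD{i:04d}", DISEASE, [f"maladitis{i}", f"acute maladitis{i}"])
    return d


def generate_corpus(config: SyntheticConfig | None = None) -> SyntheticCorpus:
    """Generate documents, sidecar parses, dictionary and relation table.

    Identical configs (including the seed) give byte-identical corpora.
    """
    cfg = config or SyntheticConfig()
    rng = random.Random(cfg.seed)
    dictionary = _vocabulary(cfg)
    chem_ids = [f"SC{i:04d}" for i in range(cfg.n_chemicals)]
    dis_ids = [f"SD{i:04d}" for i in range(cfg.n_diseases)]
    documents: list[Document] = []
    sidecars: dict[tuple[str, int], ParseRecord] = {}
    table_rows: list[WeakRelationRow] = []
    for n in range(cfg.n_docs):
        doc_id = str(cfg.doc_id_base + n)
        doc, parses, rows = _generate_document(doc_id, cfg, rng, dictionary,
                                               chem_ids, dis_ids)
        documents.append(doc)
        for idx, rec in enumerate(parses):
            sidecars[(doc_id, idx)] = rec
        table_rows.extend(rows)
    return SyntheticCorpus(documents, sidecars, dictionary,
                           WeakRelationTable(table_rows), cfg)


def _generate_document(doc_id, cfg, rng, dictionary, chem_ids, dis_ids):
    n_chem = rng.randint(cfg.min_entities,
                         min(cfg.max_entities, len(chem_ids)))
    n_dis = rng.randint(cfg.min_entities, min(cfg.max_entities, len(dis_ids)))
    chems = rng.sample(chem_ids, n_chem)
    diseases = rng.sample(dis_ids, n_dis)
    positives = []
    negatives = []
    for c in chems:
        for d in diseases:
            (positives if rng.random() < cfg.p_positive else negatives).append(
                (c, d))

    def surface(cid):
        return dictionary.names(cid)[0]

    plan: list[TemplateInstance] = []
    mentioned: set[str] = set()
    for c in chems:
        plan.append(TemplateInstance("admin", {"chem": surface(c)}))
        mentioned.add(c)
    pair_sents: list[TemplateInstance] = []
    for c, d in positives:
        if rng.random() < cfg.p_trigger:
            name = rng.choice(TRIGGER_TEMPLATES)
            trig = ("induce" if name == "participle_trigger"
                    else rng.choice(("cause", "induce", "produce")))
            pair_sents.append(TemplateInstance(
                name, {"chem": surface(c), "dis": surface(d), "trigger": trig}))
        else:
            pair_sents.append(TemplateInstance("develop", {"dis": surface(d)}))
        mentioned.add(d)
    for c, d in negatives:
        if rng.random() < cfg.p_distractor:
            pair_sents.append(TemplateInstance(
                "treatment", {"chem": surface(c), "dis": surface(d)}))
            mentioned.add(d)
    for d in diseases:
        if d not in mentioned:
            pair_sents.append(TemplateInstance("monitor", {"dis": surface(d)}))
            mentioned.add(d)
    rng.shuffle(pair_sents)
    plan = [TemplateInstance("title", {})] + plan + pair_sents + [
        TemplateInstance("closing", {})]

    name_to_id = {}
    for cid in chems + diseases:
        for nm in dictionary.names(cid):
            name_to_id[nm.lower()] = (cid, dictionary.etype(cid))

    parses = [generate_parse(inst) for inst in plan]
    title_text, title_mentions = _render(parses[0], 0, name_to_id)
    abstract_parts = []
    mentions = list(title_mentions)
    offset = len(title_text) + 1
    for rec in parses[1:]:
        text, ms = _render(rec, offset, name_to_id)
        abstract_parts.append(text)
        mentions.extend(ms)
        offset += len(text) + 1
    relations = {RelationPair(c, d) for c, d in positives}
    doc = Document(doc_id, title_text, " ".join(abstract_parts),
                   mentions, relations)
    doc.validate()
    rows = [WeakRelationRow(doc_id, c, d) for c, d in sorted(positives)]
    return doc, parses, rows


def _render(rec: ParseRecord, offset: int, name_to_id):
    """Join tokens with single spaces; emit a mention for every token whose
    surface is a known entity name."""
    pieces = []
    mentions = []
    pos = offset
    for i, (text, _lemma, _pos) in enumerate(rec.tokens):
        if i:
            pos += 1  # joining space
        hit = name_to_id.get(text.lower())
        if hit is not None:
            cid, etype = hit
            mentions.append(Mention(pos, pos + len(text), text, etype, [cid]))
        pieces.append(text)
        pos += len(text)
    return " ".join(pieces), mentions


def as_raw_documents(corpus: SyntheticCorpus) -> list[Document]:
    """Copies of the corpus documents stripped of mentions and relations —
    the shape a curated database's source abstracts arrive in before weak
    labeling."""
    return [Document(d.doc_id, d.title, d.abstract) for d in corpus.documents]


def corrupt_table(table: WeakRelationTable, dictionary: ConceptDictionary,
                  rate: float, seed: int) -> WeakRelationTable:
    """Simulate normalization noise on the curated rows: with the given
    rate, a row's disease ID is replaced by a uniformly random other disease
    ID from the vocabulary — the way a recognizer mis-normalizes a mention.
    A corrupted ID that does not actually occur in the source document will
    later fail relation grounding and drop out of the weak corpus; one that
    does occur produces a genuinely mislabeled training document."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("corruption rate must be in [0, 1]")
    rng = random.Random(seed)
    dis_ids = sorted(cid for cid in dictionary
                     if dictionary.etype(cid) == DISEASE)
    rows = []
    for r in table.rows:
        if rng.random() >= rate or len(dis_ids) < 2:
            rows.append(r)
            continue
        alts = [d for d in dis_ids if d != r.disease_id]
        rows.append(WeakRelationRow(r.doc_id, r.chemical_id,
                                    rng.choice(alts)))
    return WeakRelationTable(rows)
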