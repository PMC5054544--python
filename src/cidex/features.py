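"""Feature extraction for <ChemicalID, DiseaseID> candidate pairs.

Five families, each namespaced in the sparse feature map:

* ``bow:``   — lemma counts in a 5-token window (the mention plus two word
  tokens on either side) around every mention of a concept ID, accumulated
  over the document; windows never cross sentence boundaries.
* ``bon1:/bon2:/bon3:`` — uni/bi/trigrams over the lemma sequence spanning
  from the chemical to the disease mention in one sentence, with each
  mention replaced by its concept ID.
* ``pat:``   — four booleans, one per trigger (cause/induce/associate/
  produce): does ``Chemical <- arg0 <- trigger -> arg1 -> Disease`` match
  in the propagated EDG?
* ``path:``  — direction-annotated v-walks and e-walks over all minimal EDG
  paths between the pair, plus ``path:weight`` = mean of lambda^length.
* ``stat:``  — 19 document-level statistical features (mention counts,
  positional booleans, same-sentence co-occurrence, knowledge-base lookups,
  contextual keyword booleans).

Mention-level vectors are merged per concept pair: booleans by OR, numeric
singletons by arithmetic mean, bag features by summation; ID-level vectors
are appended unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import IO, Iterable, Protocol

from .corpus_io import CHEMICAL, DISEASE, Document, Mention
from .edg import EDG, NUMBERED_ARG, TRIGGER_LEMMAS, shortest_paths, trigger_of
from .linguistic import Sentence, Token

FeatureVector = dict[str, float]


@dataclass
class PathFeatureConfig:
    """Knobs shared by the lexical and path feature extractors.

    ``lam`` down-weights a shortest path of length L as lam**L; ``max_ngram``
    is the highest n-gram order extracted; ``window_radius`` is the number of
    word tokens taken on each side of a mention (radius 2 = window size 5).
    """

    lam: float = 0.9
    max_ngram: int = 3
    window_radius: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("lambda must be in (0, 1]")
        if self.max_ngram < 1 or self.window_radius < 0:
            raise ValueError("bad feature configuration")


class KnowledgeBase(Protocol):
    """Domain-resource lookups used by the statistical features."""

    provenance: str

    def has_ctd_relation(self, chemical_id: str, disease_id: str) -> bool: ...

    def comention_in_mesh_indexing(self, chemical_id: str,
                                   disease_id: str) -> bool: ...


class NullKnowledgeBase:
    """KB that knows nothing; every lookup is False."""

    provenance = "null"

    def has_ctd_relation(self, chemical_id: str, disease_id: str) -> bool:
        return False

    def comention_in_mesh_indexing(self, chemical_id: str,
                                   disease_id: str) -> bool:
        return False


class TsvKnowledgeBase:
    """KB backed by two pair lists: curated chemical-disease relations and
    co-indexing pairs, each a TSV of ``chemicalID TAB diseaseID`` rows."""

    def __init__(self, ctd_pairs: Iterable[tuple[str, str]] = (),
                 mesh_pairs: Iterable[tuple[str, str]] = (),
                 provenance: str = "unspecified"):
        self._ctd = set(ctd_pairs)
        self._mesh = set(mesh_pairs)
        self.provenance = provenance

    @classmethod
    def from_streams(cls, ctd_stream: IO[str] | None,
                     mesh_stream: IO[str] | None,
                     provenance: str = "unspecified") -> "TsvKnowledgeBase":
        def rows(stream):
            if stream is None:
                return []
            out = []
            for line in stream:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                out.append((a, b))
            return out
        return cls(rows(ctd_stream), rows(mesh_stream), provenance)

    def has_ctd_relation(self, chemical_id: str, disease_id: str) -> bool:
        return (chemical_id, disease_id) in self._ctd

    def comention_in_mesh_indexing(self, chemical_id: str,
                                   disease_id: str) -> bool:
        return (chemical_id, disease_id) in self._mesh


@dataclass
class KeywordConfig:
    """Editable keyword lists behind the contextual statistical features.

    The disease-context and dosage lists are seeded with the standard
    exemplars (therapy/complicating/affect; mg-style dose units plus a
    number+unit regex); all matching is on lowercased lemmas.
    """

    disease_context: frozenset[str] = frozenset(
        {"therapy", "complicating", "affect", "treatment", "complication"})
    dosage_units: frozenset[str] = frozenset(
        {"mg", "g", "kg", "ml", "l", "mcg", "meq/l", "meg/l", "mg/kg",
         "mg/day", "mmol/l"})
    increase_decrease: frozenset[str] = frozenset({"increase", "decrease"})
    demographic: frozenset[str] = frozenset({"men", "man", "women", "woman",
                                             "patient"})

    _DOSE_RE = re.compile(r"^\d+(\.\d+)?([a-z]+(/[a-z]+)?)?$")

    def is_dosage(self, token_text: str) -> bool:
        low = token_text.lower()
        return low in self.dosage_units or bool(self._DOSE_RE.match(low))


_WORD_RE = re.compile(r"[0-9A-Za-z]")


def _is_word(token: Token) -> bool:
    return bool(_WORD_RE.search(token.text))


def _find_sentence(document: Document, mention: Mention) -> Sentence | None:
    for s in document.sentences:
        if mention.start >= s.start and mention.end <= s.end:
            return s
    return None


def _window_tokens(sentence: Sentence, mention: Mention,
                   radius: int) -> list[Token]:
    """Up to *radius* word tokens on each side of the mention span, within
    the sentence; the mention's own tokens are excluded, punctuation tokens
    are skipped and do not consume window slots."""
    span = sentence.tokens_in_span(mention.start, mention.end)
    if not span:
        return []
    lo, hi = span[0].index, span[-1].index
    words = [t for t in sentence.tokens if _is_word(t)]
    left = [t for t in words if t.index < lo][-radius:] if radius else []
    right = [t for t in words if t.index > hi][:radius] if radius else []
    return left + right


def bow_features(document: Document, mention: Mention,
                 config: PathFeatureConfig | None = None) -> FeatureVector:
    """Context-lemma counts around every mention of this mention's concept
    ID(s) in the document (windows clipped at sentence boundaries)."""
    cfg = config or PathFeatureConfig()
    ids = set(mention.concept_ids)
    out: FeatureVector = {}
    for m in document.mentions:
        if m.etype != mention.etype or not ids & set(m.concept_ids):
            continue
        sent = _find_sentence(document, m)
        if sent is None or not sent.tokens:
            continue
        for t in _window_tokens(sent, m, cfg.window_radius):
            key = f"bow:{t.lemma.lower()}"
            out[key] = out.get(key, 0.0) + 1.0
    return out


def _span_lemma_sequence(sentence: Sentence, chem_mention: Mention,
                         dis_mention: Mention, chem_id: str,
                         dis_id: str) -> list[str]:
    first, second = sorted([(chem_mention, chem_id), (dis_mention, dis_id)],
                           key=lambda p: p[0].start)
    between = [t.lemma.lower() for t in sentence.tokens
               if t.start >= first[0].end and t.end <= second[0].start
               and _is_word(t)]
    return [first[1]] + between + [second[1]]


def bon_features(sentence: Sentence, chem_mention: Mention,
                 dis_mention: Mention,
                 config: PathFeatureConfig | None = None,
                 chem_id: str | None = None,
                 dis_id: str | None = None) -> FeatureVector:
    """N-grams (orders 1..max_ngram) over the lemma sequence from the
    chemical to the disease mention, both rendered as their concept IDs.
    Mentions in different sentences yield an empty vector."""
    cfg = config or PathFeatureConfig()
    for m in (chem_mention, dis_mention):
        if m.start < sentence.start or m.end > sentence.end:
            return {}
    chem_id = chem_id or chem_mention.concept_ids[0]
    dis_id = dis_id or dis_mention.concept_ids[0]
    seq = _span_lemma_sequence(sentence, chem_mention, dis_mention,
                               chem_id, dis_id)
    out: FeatureVector = {}
    for n in range(1, cfg.max_ngram + 1):
        for i in range(len(seq) - n + 1):
            key = f"bon{n}:" + "|".join(seq[i:i + n])
            out[key] = out.get(key, 0.0) + 1.0
    return out


def _mention_vertices(edg: EDG, mention: Mention) -> list[int]:
    return [i for i, v in enumerate(edg.vertices)
            if v.token.start < mention.end and v.token.end > mention.start
            and v.ne_label == mention.etype]


def pattern_features(edg: EDG, chem_mention: Mention,
                     dis_mention: Mention) -> FeatureVector:
    """Four booleans, one per trigger: 1 iff a vertex carrying that trigger
    lemma has an arg0 edge to the chemical vertex and an arg1 edge to the
    disease vertex (after propagation)."""
    chem_vs = set(_mention_vertices(edg, chem_mention))
    dis_vs = set(_mention_vertices(edg, dis_mention))
    out = {f"pat:{t}": 0.0 for t in TRIGGER_LEMMAS}
    for v, vertex in enumerate(edg.vertices):
        t = trigger_of(vertex.lemma)
        if t is None:
            continue
        args = edg.edges_from(v, NUMBERED_ARG)
        hits_chem = any(e.label == "arg0" and e.target in chem_vs for e in args)
        hits_dis = any(e.label == "arg1" and e.target in dis_vs for e in args)
        if hits_chem and hits_dis:
            out[f"pat:{t}"] = 1.0
    return out


def _walk_features(path, edg: EDG) -> list[str]:
    feats = []
    for edge, _direction in path.steps:
        src = edg.vertices[edge.source].render()
        tgt = edg.vertices[edge.target].render()
        feats.append(f"path:vwalk:{src}->{edge.label}->{tgt}")
    for k in range(1, len(path.vertices) - 1):
        w = path.vertices[k]
        left_edge, _ = path.steps[k - 1]
        right_edge, _ = path.steps[k]
        arrow_l = "<-" if left_edge.source == w else "->"
        arrow_r = "->" if right_edge.source == w else "<-"
        center = edg.vertices[w].render()
        feats.append(
            f"path:ewalk:{left_edge.label}{arrow_l}{center}{arrow_r}{right_edge.label}")
    return feats


def path_features(edgs_by_sentence: Iterable[EDG | None], chem_id: str,
                  dis_id: str,
                  config: PathFeatureConfig | None = None) -> FeatureVector:
    """Walk features over all minimal EDG paths between the pair's vertices
    in every co-mention sentence, plus ``path:weight`` = mean lambda^length.
    Empty when the IDs never co-occur (or are disconnected) in any sentence."""
    cfg = config or PathFeatureConfig()
    out: FeatureVector = {}
    weights: list[float] = []
    for edg in edgs_by_sentence:
        if edg is None:
            continue
        chem_vs = edg.vertices_with_concept(chem_id, CHEMICAL)
        dis_vs = edg.vertices_with_concept(dis_id, DISEASE)
        for cv in chem_vs:
            for dv in dis_vs:
                for path in shortest_paths(edg, cv, dv):
                    weights.append(cfg.lam ** path.length)
                    for feat in _walk_features(path, edg):
                        out[feat] = out.get(feat, 0.0) + 1.0
    if weights:
        out["path:weight"] = sum(weights) / len(weights)
    return out


_NUMERIC_STAT = {"stat:chem_mentions", "stat:dis_mentions"}

#: the 19 statistical feature names, in table order
STATISTICAL_FEATURES = (
    "stat:chem_mentions",            # 1  numeric
    "stat:dis_mentions",             # 2  numeric
    "stat:chem_in_title",            # 3
    "stat:dis_in_title",             # 4
    "stat:chem_in_first_abs_sent",   # 5
    "stat:dis_in_first_abs_sent",    # 6
    "stat:chem_in_last_abs_sent",    # 7
    "stat:dis_in_last_abs_sent",     # 8
    "stat:same_sentence",            # 9
    "stat:kb_ctd",                   # 10
    "stat:kb_mesh",                  # 11
    "stat:keyword_near_disease",     # 12
    "stat:dosage_near_chemical",     # 13
    "stat:incdec_near_chemical",     # 14
    "stat:incdec_near_disease",      # 15
    "stat:pvalue_near_chemical",     # 16
    "stat:pvalue_near_disease",      # 17
    "stat:demographic_near_chemical",  # 18
    "stat:demographic_near_disease",   # 19
)

_PVALUE_RE = re.compile(r"\bp[- ]?value", re.IGNORECASE)


def statistical_features(document: Document, chem_id: str, dis_id: str,
                         kb: KnowledgeBase | None = None,
                         config: PathFeatureConfig | None = None,
                         keywords: KeywordConfig | None = None
                         ) -> FeatureVector:
    """The 19 document-level statistical features for one concept pair.

    "Around" a mention means the same clipped window the bag-of-words
    features use.  Positional booleans and keyword booleans are OR-ed over
    all mentions of the concept ID.
    """
    kb = kb or NullKnowledgeBase()
    cfg = config or PathFeatureConfig()
    kw = keywords or KeywordConfig()
    chem_ms = [m for m in document.mentions
               if m.etype == CHEMICAL and chem_id in m.concept_ids]
    dis_ms = [m for m in document.mentions
              if m.etype == DISEASE and dis_id in m.concept_ids]
    sents = document.sentences
    title_sent = sents[0] if sents else None
    abs_sents = sents[1:] if len(sents) > 1 else []
    first_abs = abs_sents[0] if abs_sents else None
    last_abs = abs_sents[-1] if abs_sents else None

    def in_sent(ms, sent):
        return sent is not None and any(
            m.start >= sent.start and m.end <= sent.end for m in ms)

    def same_sentence() -> bool:
        return any(in_sent(chem_ms, s) and in_sent(dis_ms, s) for s in sents)

    def windows(ms):
        for m in ms:
            sent = _find_sentence(document, m)
            if sent is not None and sent.tokens:
                yield _window_tokens(sent, m, cfg.window_radius)

    def any_token(ms, pred) -> bool:
        return any(pred(t) for win in windows(ms) for t in win)

    def pvalue_near(ms) -> bool:
        for win in windows(ms):
            if _PVALUE_RE.search(" ".join(t.text for t in win)):
                return True
            if any(t.text.lower() == "p" for t in win):
                # "p < 0.05"-style: a bare p token adjacent to a comparator
                sent_texts = [t.text for t in win]
                if any(s in ("<", "=", ">") for s in sent_texts):
                    return True
        return False

    out = {
        "stat:chem_mentions": float(len(chem_ms)),
        "stat:dis_mentions": float(len(dis_ms)),
        "stat:chem_in_title": float(in_sent(chem_ms, title_sent)),
        "stat:dis_in_title": float(in_sent(dis_ms, title_sent)),
        "stat:chem_in_first_abs_sent": float(in_sent(chem_ms, first_abs)),
        "stat:dis_in_first_abs_sent": float(in_sent(dis_ms, first_abs)),
        "stat:chem_in_last_abs_sent": float(in_sent(chem_ms, last_abs)),
        "stat:dis_in_last_abs_sent": float(in_sent(dis_ms, last_abs)),
        "stat:same_sentence": float(same_sentence()),
        "stat:kb_ctd": float(kb.has_ctd_relation(chem_id, dis_id)),
        "stat:kb_mesh": float(kb.comention_in_mesh_indexing(chem_id, dis_id)),
        "stat:keyword_near_disease": float(any_token(
            dis_ms, lambda t: t.lemma.lower() in kw.disease_context)),
        "stat:dosage_near_chemical": float(any_token(
            chem_ms, lambda t: kw.is_dosage(t.text))),
        "stat:incdec_near_chemical": float(any_token(
            chem_ms, lambda t: t.lemma.lower() in kw.increase_decrease)),
        "stat:incdec_near_disease": float(any_token(
            dis_ms, lambda t: t.lemma.lower() in kw.increase_decrease)),
        "stat:pvalue_near_chemical": float(pvalue_near(chem_ms)),
        "stat:pvalue_near_disease": float(pvalue_near(dis_ms)),
        "stat:demographic_near_chemical": float(any_token(
            chem_ms, lambda t: t.lemma.lower() in kw.demographic)),
        "stat:demographic_near_disease": float(any_token(
            dis_ms, lambda t: t.lemma.lower() in kw.demographic)),
    }
    return out


# -- merging ---------------------------------------------------------------

BOOLEAN, NUMERIC, BAG = "boolean", "numeric", "bag"

_BAG_PREFIXES = ("bow:", "path:vwalk:", "path:ewalk:")


def feature_kind(name: str) -> str:
    """Merge class of a feature name: boolean (OR), numeric (mean), bag (sum)."""
    if name.startswith("pat:"):
        return BOOLEAN
    if name.startswith(_BAG_PREFIXES) or re.match(r"^bon\d+:", name):
        return BAG
    if name == "path:weight":
        return NUMERIC
    if name.startswith("stat:"):
        return NUMERIC if name in _NUMERIC_STAT else BOOLEAN
    raise ValueError(f"feature {name!r} belongs to no known namespace")


def merge_to_pair_vector(mention_level_vectors: Iterable[FeatureVector],
                         id_level_vector: FeatureVector | None = None
                         ) -> FeatureVector:
    """Merge mention-level vectors into one pair-level vector.

    Boolean features are OR-combined, numeric singleton features averaged
    over the vectors that carry them, bag features summed.  ID-level
    features are appended unchanged; a name colliding across the two levels
    with inconsistent kinds is a hard error (raised by feature_kind).
    """
    merged: FeatureVector = {}
    numeric_acc: dict[str, list[float]] = {}
    for vec in mention_level_vectors:
        for name, value in vec.items():
            kind = feature_kind(name)
            if kind == BOOLEAN:
                if value not in (0.0, 1.0):
                    raise ValueError(
                        f"boolean feature {name!r} has non-boolean value {value}")
                merged[name] = max(merged.get(name, 0.0), value)
            elif kind == BAG:
                merged[name] = merged.get(name, 0.0) + value
            else:
                numeric_acc.setdefault(name, []).append(value)
    for name, values in numeric_acc.items():
        merged[name] = sum(values) / len(values)
    if id_level_vector:
        for name, value in id_level_vector.items():
            feature_kind(name)  # namespace sanity
            merged[name] = value
    return merged


@dataclass
class FeatureFamilies:
    """Toggles for the five feature families (ablation support)."""

    bow: bool = True
    bon: bool = True
    pattern: bool = True
    path: bool = True
    statistical: bool = True
    #: optionally disable individual statistical features by name
    disabled_statistical: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not any((self.bow, self.bon, self.pattern, self.path,
                    self.statistical)):
            raise ValueError("at least one feature family must be enabled")

    def without(self, family: str) -> "FeatureFamilies":
        kwargs = {f: getattr(self, f) for f in
                  ("bow", "bon", "pattern", "path", "statistical")}
        if family not in kwargs:
            raise ValueError(f"unknown feature family {family!r}")
        kwargs[family] = False
        return FeatureFamilies(
            disabled_statistical=self.disabled_statistical, **kwargs)


def extract_pair_features(document: Document,
                          edgs_by_sentence: list[EDG | None],
                          chem_id: str, dis_id: str,
                          kb: KnowledgeBase | None = None,
                          config: PathFeatureConfig | None = None,
                          families: FeatureFamilies | None = None,
                          keywords: KeywordConfig | None = None
                          ) -> FeatureVector:
    """Assemble the full merged feature vector for one concept pair.

    N-gram and pattern features are mention-pair-level and go through the
    merge; bag-of-words (already accumulated document-wide per concept ID),
    path and statistical features are ID-level and appended once.
    """
    cfg = config or PathFeatureConfig()
    fam = families or FeatureFamilies()
    chem_ms = [m for m in document.mentions
               if m.etype == CHEMICAL and chem_id in m.concept_ids]
    dis_ms = [m for m in document.mentions
              if m.etype == DISEASE and dis_id in m.concept_ids]
    mention_level: list[FeatureVector] = []
    for si, sent in enumerate(document.sentences):
        s_chems = [m for m in chem_ms
                   if m.start >= sent.start and m.end <= sent.end]
        s_dis = [m for m in dis_ms
                 if m.start >= sent.start and m.end <= sent.end]
        if not s_chems or not s_dis:
            continue
        edg = edgs_by_sentence[si] if si < len(edgs_by_sentence) else None
        for cm in s_chems:
            for dm in s_dis:
                vec: FeatureVector = {}
                if fam.bon and sent.tokens:
                    vec.update(bon_features(sent, cm, dm, cfg,
                                            chem_id=chem_id, dis_id=dis_id))
                if fam.pattern and edg is not None:
                    vec.update(pattern_features(edg, cm, dm))
                if vec:
                    mention_level.append(vec)
    id_level: FeatureVector = {}
    if fam.bow:
        bag: FeatureVector = {}
        for mention_set in (chem_ms[:1], dis_ms[:1]):
            for m in mention_set:
                for k, v in bow_features(document, m, cfg).items():
                    bag[k] = bag.get(k, 0.0) + v
        id_level.update(bag)
    if fam.path:
        id_level.update(path_features(edgs_by_sentence, chem_id, dis_id, cfg))
    if fam.statistical:
        stats = statistical_features(document, chem_id, dis_id, kb, cfg,
                                     keywords)
        for name in fam.disabled_statistical:
            stats.pop(name, None)
        id_level.update(stats)
    return merge_to_pair_vector(mention_level, id_level)
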