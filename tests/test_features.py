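import pytest

from cidex import demo
from cidex.corpus_io import CHEMICAL, DISEASE, Document, Mention
from cidex.edg import shortest_paths
from cidex.features import (FeatureFamilies, KeywordConfig,
                            PathFeatureConfig, STATISTICAL_FEATURES,
                            TsvKnowledgeBase, bon_features, bow_features,
                            extract_pair_features, feature_kind,
                            merge_to_pair_vector, path_features,
                            pattern_features, statistical_features)
from cidex.linguistic import ParseRecord, attach_parse, split_sentences
from cidex.model import document_edgs


def _chem(doc, cid):
    return next(m for m in doc.mentions
                if m.etype == CHEMICAL and cid in m.concept_ids)


def _dis(doc, cid):
    return next(m for m in doc.mentions
                if m.etype == DISEASE and cid in m.concept_ids)


# -- bag of words ------------------------------------------------------------

def test_bow_worked_example(bow_doc):
    """Two occurrences, each flanked by 'induced acute': the accumulated
    context bag is {induce x2, acute x2, case, of, frequently, is}."""
    vec = bow_features(bow_doc, _chem(bow_doc, demo.BOW_CHEMICAL))
    assert vec == {"bow:induce": 2.0, "bow:acute": 2.0, "bow:case": 1.0,
                   "bow:of": 1.0, "bow:frequently": 1.0, "bow:is": 1.0}


def test_bow_empty_context_for_lone_mention():
    doc = Document("1", "Midazolam", "",
                   mentions=[Mention(0, 9, "Midazolam", CHEMICAL, ["D008874"])])
    split_sentences(doc)
    rec = ParseRecord([("Midazolam", "midazolam", "NN")], [-1], ["root"])
    attach_parse(doc.sentences[0], rec, doc.text)
    assert bow_features(doc, doc.mentions[0]) == {}


from _oracles import window_oracle as _window_oracle


@pytest.mark.parametrize("radius", [0, 1, 2, 3])
def test_bow_window_clipping_matches_oracle(bow_doc, midazolam_doc, radius):
    cfg = PathFeatureConfig(window_radius=radius)
    for doc in (bow_doc, midazolam_doc):
        for m in doc.mentions:
            assert bow_features(doc, m, cfg) == _window_oracle(doc, m, radius)


def test_bow_window_stays_in_sentence(midazolam_doc):
    """No context lemma can come from another sentence even with a huge
    radius: the midazolam title mention sees only its own sentence."""
    cfg = PathFeatureConfig(window_radius=50)
    vec = bow_features(midazolam_doc, midazolam_doc.mentions[0], cfg)
    # all title/first-sentence lemmas, none from sentences 2-3
    assert "bow:develop" not in vec and "bow:record" not in vec


# -- bag of n-grams ----------------------------------------------------------

def test_bon_worked_example(bow_doc):
    sent = bow_doc.sentences[0]
    vec = bon_features(sent, _chem(bow_doc, demo.BOW_CHEMICAL),
                       _dis(bow_doc, demo.BOW_DISEASE))
    bigrams = {k for k in vec if k.startswith("bon2:")}
    assert bigrams == {"bon2:D011899|induce", "bon2:induce|acute",
                       "bon2:acute|D009395"}
    assert vec["bon1:D011899"] == 1.0 and vec["bon3:D011899|induce|acute"] == 1.0


def test_bon_adjacent_mentions_single_bigram():
    doc = Document("1", "Midazolam arrest", "", mentions=[
        Mention(0, 9, "Midazolam", CHEMICAL, ["C1"]),
        Mention(10, 16, "arrest", DISEASE, ["D1"])])
    split_sentences(doc)
    rec = ParseRecord([("Midazolam", "midazolam", "NN"),
                       ("arrest", "arrest", "NN")], [-1, 0], ["root", "dep"])
    attach_parse(doc.sentences[0], rec, doc.text)
    vec = bon_features(doc.sentences[0], doc.mentions[0], doc.mentions[1])
    assert {k for k in vec if k.startswith("bon2:")} == {"bon2:C1|D1"}


def test_bon_cross_sentence_is_empty(midazolam_doc):
    chem = _chem(midazolam_doc, demo.MIDAZOLAM)
    dis = _dis(midazolam_doc, demo.RESPIRATORY_DEPRESSION)
    for sent in midazolam_doc.sentences:
        assert bon_features(sent, chem, dis) == {}


@pytest.mark.parametrize("n_between", range(0, 6))
def test_bon_counts_match_combinatorial_formula(n_between):
    words = " ".join(f"w{i}" for i in range(n_between))
    text = ("chemx " + words + " disy").replace("  ", " ")
    doc = Document("1", text, "", mentions=[
        Mention(0, 5, "chemx", CHEMICAL, ["C1"]),
        Mention(len(text) - 4, len(text), "disy", DISEASE, ["D1"])])
    split_sentences(doc)
    toks = [(w, w, "NN") for w in text.split()]
    rec = ParseRecord(toks, [-1] + [0] * (len(toks) - 1),
                      ["root"] + ["dep"] * (len(toks) - 1))
    attach_parse(doc.sentences[0], rec, doc.text)
    vec = bon_features(doc.sentences[0], doc.mentions[0], doc.mentions[1])
    span_len = n_between + 2
    for n in (1, 2, 3):
        total = sum(v for k, v in vec.items() if k.startswith(f"bon{n}:"))
        assert total == max(0, span_len - n + 1)


# -- patterns ----------------------------------------------------------------

def test_pattern_collection_pair(collection_doc, collection_edg):
    vec = pattern_features(collection_edg,
                           _chem(collection_doc, demo.SUNITINIB),
                           _dis(collection_doc, demo.HEMOLYSIS))
    assert vec == {"pat:cause": 1.0, "pat:induce": 0.0,
                   "pat:associate": 0.0, "pat:produce": 0.0}


def test_pattern_via_propagated_arg1(coreterm_doc, coreterm_edg):
    vec = pattern_features(coreterm_edg,
                           _chem(coreterm_doc, demo.METOCLOPRAMIDE),
                           _dis(coreterm_doc, demo.TARDIVE_DYSKINESIA))
    assert vec["pat:cause"] == 1.0
    assert sum(vec.values()) == 1.0


def test_pattern_all_zero_without_numbered_args(collection_doc):
    from cidex.edg import build_edg
    bare = build_edg(collection_doc.sentences[0], collection_doc.mentions)
    vec = pattern_features(bare, _chem(collection_doc, demo.SUNITINIB),
                           _dis(collection_doc, demo.HEMOLYSIS))
    assert set(vec.values()) == {0.0}


def test_pattern_implies_short_path(collection_doc, coreterm_doc):
    """Any firing trigger pattern guarantees a connecting path of length
    at most 2 between the pair in that sentence."""
    for doc in (collection_doc, coreterm_doc):
        edg = document_edgs(doc)[0]
        chems = [m for m in doc.mentions if m.etype == CHEMICAL]
        diss = [m for m in doc.mentions if m.etype == DISEASE]
        for cm in chems:
            for dm in diss:
                if any(v == 1.0 for v in pattern_features(edg, cm, dm).values()):
                    cv = edg.vertices_with_concept(cm.concept_ids[0], CHEMICAL)
                    dv = edg.vertices_with_concept(dm.concept_ids[0], DISEASE)
                    paths = shortest_paths(edg, cv[0], dv[0])
                    assert paths and paths[0].length <= 2


# -- shortest-path walks -----------------------------------------------------

def test_path_walks_worked_example(collection_doc, coreterm_doc):
    """Both figure sentences share the same canonical path, v-walks and
    e-walk despite different surface forms."""
    for doc, cid, did in ((collection_doc, demo.SUNITINIB, demo.HEMOLYSIS),
                          (coreterm_doc, demo.METOCLOPRAMIDE,
                           demo.TARDIVE_DYSKINESIA)):
        vec = path_features(document_edgs(doc), cid, did)
        assert vec == {"path:vwalk:cause->arg0->Chemical": 1.0,
                       "path:vwalk:cause->arg1->Disease": 1.0,
                       "path:ewalk:arg0<-cause->arg1": 1.0,
                       "path:weight": pytest.approx(0.81)}


def test_path_weight_lambda_one(collection_doc):
    vec = path_features(document_edgs(collection_doc), demo.SUNITINIB,
                        demo.HEMOLYSIS, PathFeatureConfig(lam=1.0))
    assert vec["path:weight"] == 1.0


def test_path_weight_decreasing_in_length():
    lam = 0.9
    weights = [lam ** k for k in range(1, 6)]
    assert all(a > b for a, b in zip(weights, weights[1:]))
    assert all(0 < w <= 1 for w in weights)


def test_path_empty_when_no_co_mention(midazolam_doc):
    vec = path_features(document_edgs(midazolam_doc), demo.MIDAZOLAM,
                        demo.RESPIRATORY_DEPRESSION)
    assert vec == {}


# -- statistical features ----------------------------------------------------

def test_statistical_worked_example(midazolam_doc):
    vec = statistical_features(midazolam_doc, demo.MIDAZOLAM,
                               demo.CARDIORESPIRATORY_ARREST)
    assert set(vec) == set(STATISTICAL_FEATURES) and len(vec) == 19
    assert vec["stat:same_sentence"] == 1.0
    assert vec["stat:chem_mentions"] == 2.0  # title + first sentence
    assert vec["stat:dis_mentions"] == 1.0
    assert vec["stat:chem_in_title"] == 1.0
    assert vec["stat:dis_in_title"] == 0.0
    assert vec["stat:chem_in_first_abs_sent"] == 1.0
    assert vec["stat:dis_in_first_abs_sent"] == 1.0
    assert vec["stat:kb_ctd"] == 0.0 and vec["stat:kb_mesh"] == 0.0
    assert vec["stat:demographic_near_disease"] == 0.0


def test_statistical_cross_sentence_pair(midazolam_doc):
    vec = statistical_features(midazolam_doc, demo.MIDAZOLAM,
                               demo.RESPIRATORY_DEPRESSION)
    assert vec["stat:same_sentence"] == 0.0
    assert vec["stat:dis_in_last_abs_sent"] == 0.0


def test_statistical_mention_count_matches_scan(midazolam_doc):
    expected = sum(1 for m in midazolam_doc.mentions
                   if demo.MIDAZOLAM in m.concept_ids)
    vec = statistical_features(midazolam_doc, demo.MIDAZOLAM, demo.DEATH)
    assert vec["stat:chem_mentions"] == float(expected)


def test_kb_lookups_feed_features(midazolam_doc):
    kb = TsvKnowledgeBase(
        ctd_pairs=[(demo.MIDAZOLAM, demo.CARDIORESPIRATORY_ARREST)],
        mesh_pairs=[(demo.MIDAZOLAM, demo.DEATH)], provenance="2015-01")
    vec = statistical_features(midazolam_doc, demo.MIDAZOLAM,
                               demo.CARDIORESPIRATORY_ARREST, kb)
    assert vec["stat:kb_ctd"] == 1.0 and vec["stat:kb_mesh"] == 0.0
    vec2 = statistical_features(midazolam_doc, demo.MIDAZOLAM, demo.DEATH, kb)
    assert vec2["stat:kb_ctd"] == 0.0 and vec2["stat:kb_mesh"] == 1.0


def test_keyword_and_dosage_detection():
    text = "Patients received chemx at 20 mg and maladix therapy was stopped ."
    doc = Document("1", "T", text)
    off = 2
    doc.mentions = [
        Mention(off + 18, off + 23, "chemx", CHEMICAL, ["C1"]),
        Mention(off + 37, off + 44, "maladix", DISEASE, ["D1"])]
    split_sentences(doc)
    toks = [(w, {"Patients": "patient", "mg": "mg"}.get(w, w.lower()), "NN")
            for w in text.split()]
    rec = ParseRecord(toks, [-1] + [0] * (len(toks) - 1),
                      ["root"] + ["dep"] * (len(toks) - 1))
    attach_parse(doc.sentences[1], rec, doc.text)
    vec = statistical_features(doc, "C1", "D1")
    assert vec["stat:dosage_near_chemical"] == 1.0      # "20" in window
    assert vec["stat:keyword_near_disease"] == 1.0      # "therapy" in window
    assert vec["stat:demographic_near_chemical"] == 1.0  # "Patients" in window


def test_dosage_regex():
    kw = KeywordConfig()
    for tok in ("mg", "3.0", "250", "mEq/L", "5mg"):
        assert kw.is_dosage(tok), tok
    for tok in ("dose", "p", "twice"):
        assert not kw.is_dosage(tok), tok


# -- merging -----------------------------------------------------------------

def test_merge_identity_for_single_vector():
    vec = {"pat:cause": 1.0, "bon2:a|b": 2.0, "path:weight": 0.81}
    assert merge_to_pair_vector([vec]) == vec


def test_merge_or_for_booleans_mean_for_numeric_sum_for_bags():
    merged = merge_to_pair_vector([
        {"pat:cause": 1.0, "path:weight": 0.81, "bon1:x": 1.0},
        {"pat:cause": 0.0, "path:weight": 0.9, "bon1:x": 2.0},
        {"pat:induce": 0.0, "path:weight": 0.729}])
    assert merged["pat:cause"] == 1.0
    assert merged["pat:induce"] == 0.0
    assert merged["path:weight"] == pytest.approx((0.81 + 0.9 + 0.729) / 3)
    assert merged["bon1:x"] == 3.0


def test_merge_or_monotone():
    base = [{"pat:cause": 1.0}, {"pat:cause": 0.0}]
    for extra in ({"pat:cause": 0.0}, {"pat:cause": 1.0}, {}):
        assert merge_to_pair_vector(base + [extra])["pat:cause"] == 1.0


def test_merge_rejects_non_boolean_boolean():
    with pytest.raises(ValueError, match="boolean"):
        merge_to_pair_vector([{"pat:cause": 0.5}])


def test_unknown_namespace_is_hard_error():
    with pytest.raises(ValueError, match="namespace"):
        feature_kind("mystery:thing")
    with pytest.raises(ValueError):
        merge_to_pair_vector([{"mystery:thing": 1.0}])


def test_id_level_appended_unchanged():
    merged = merge_to_pair_vector([{"pat:cause": 1.0}],
                                  {"stat:same_sentence": 1.0, "bow:acute": 2.0})
    assert merged == {"pat:cause": 1.0, "stat:same_sentence": 1.0,
                      "bow:acute": 2.0}


# -- assembled pair vectors --------------------------------------------------

def test_extract_pair_features_families_toggle(midazolam_doc):
    edgs = document_edgs(midazolam_doc)
    full = extract_pair_features(midazolam_doc, edgs, demo.MIDAZOLAM,
                                 demo.CARDIORESPIRATORY_ARREST)
    assert any(k.startswith("bow:") for k in full)
    assert any(k.startswith("stat:") for k in full)
    only_stat = extract_pair_features(
        midazolam_doc, edgs, demo.MIDAZOLAM, demo.CARDIORESPIRATORY_ARREST,
        families=FeatureFamilies(bow=False, bon=False, pattern=False,
                                 path=False))
    assert all(k.startswith("stat:") for k in only_stat)


def test_extract_is_deterministic(midazolam_doc):
    edgs = document_edgs(midazolam_doc)
    a = extract_pair_features(midazolam_doc, edgs, demo.MIDAZOLAM, demo.DEATH)
    b = extract_pair_features(midazolam_doc, edgs, demo.MIDAZOLAM, demo.DEATH)
    assert a == b


def test_all_families_disabled_rejected():
    with pytest.raises(ValueError):
        FeatureFamilies(bow=False, bon=False, pattern=False, path=False,
                        statistical=False)


def test_config_validation():
    with pytest.raises(ValueError):
        PathFeatureConfig(lam=0.0)
    with pytest.raises(ValueError):
        PathFeatureConfig(lam=1.5)
    with pytest.raises(ValueError):
        PathFeatureConfig(max_ngram=0)
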