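import random

import pytest

from cidex.corpus_io import CHEMICAL, DISEASE, Document
from cidex.edg import (IS_A, MEMBER_COLLECTION, NUMBERED_ARG, SEMANTIC,
                       SYNTACTIC, EdgConfig, EdgEdge, assign_numbered_args,
                       add_semantic_edges, build_edg, propagate_args,
                       shortest_paths)
from cidex.linguistic import ParseRecord, attach_parse, split_sentences


def _args(edg):
    return {(edg.vertices[e.source].lemma, e.label, edg.vertices[e.target].lemma)
            for e in edg.edges if e.layer == NUMBERED_ARG}


def _sem(edg):
    return {(edg.vertices[e.source].lemma, e.label, edg.vertices[e.target].lemma)
            for e in edg.edges if e.layer == SEMANTIC}


def test_build_edg_copies_tokens_and_labels(collection_doc):
    edg = build_edg(collection_doc.sentences[0], collection_doc.mentions)
    assert len(edg.vertices) == 17
    assert len([e for e in edg.edges if e.layer == SYNTACTIC]) == 16
    suni = edg.vertices[7]
    assert suni.lemma == "sunitinib" and suni.ne_label == CHEMICAL
    # multi-token mention: the head token carries the label
    hemo = edg.vertices[16]
    assert hemo.ne_label == DISEASE
    assert edg.vertices[15].ne_label is None  # "acute" is not the head


def test_no_mentions_no_ne_labels(collection_doc):
    edg = build_edg(collection_doc.sentences[0], [])
    assert all(v.ne_label is None for v in edg.vertices)


def test_numbered_args_collection_sentence(collection_doc):
    edg = build_edg(collection_doc.sentences[0], collection_doc.mentions)
    assign_numbered_args(edg)
    assert ("cause", "arg0", "number") in _args(edg)
    assert ("cause", "arg1", "hemolysis") in _args(edg)
    # the raising verb's surface subject is rerouted to the complement
    assert ("find", "arg1", "number") not in _args(edg)


def test_numbered_args_coreterm_sentence(coreterm_doc):
    edg = build_edg(coreterm_doc.sentences[0], coreterm_doc.mentions)
    assign_numbered_args(edg)
    assert ("cause", "arg1", "case") in _args(edg)
    assert ("cause", "arg0", "metoclopramide") in _args(edg)


def test_verbless_sentence_gets_no_args():
    doc = Document("1", "Severe headache", "")
    split_sentences(doc)
    rec = ParseRecord([("Severe", "severe", "JJ"), ("headache", "headache", "NN")],
                      [1, -1], ["amod", "root"])
    attach_parse(doc.sentences[0], rec, doc.text)
    edg = assign_numbered_args(build_edg(doc.sentences[0], []))
    assert _args(edg) == set()


@pytest.mark.parametrize("rule,expected_gone", [
    ("dobj", ("cause", "arg1", "hemolysis")),
    ("xcomp_control", ("cause", "arg0", "number")),
])
def test_rules_individually_switchable(collection_doc, rule, expected_gone):
    edg = build_edg(collection_doc.sentences[0], collection_doc.mentions)
    cfg = EdgConfig(rules=EdgConfig().rules - {rule})
    assign_numbered_args(edg, cfg)
    assert expected_gone not in _args(edg)


def test_semantic_edges_collection_sentence(collection_doc):
    edg = build_edg(collection_doc.sentences[0], collection_doc.mentions)
    add_semantic_edges(edg)
    sem = _sem(edg)
    assert ("number", MEMBER_COLLECTION, "inhibitor") in sem
    # one is-a per conjunct under "such as"
    assert ("sunitinib", IS_A, "inhibitor") in sem
    assert ("sorafenib", IS_A, "inhibitor") in sem
    assert len(sem) == 3


def test_semantic_edges_absent_when_no_construction(coreterm_doc):
    edg = build_edg(coreterm_doc.sentences[0], coreterm_doc.mentions)
    n_edges = len(edg.edges)
    add_semantic_edges(edg)
    assert len(edg.edges) == n_edges


def test_apposition_yields_is_a():
    doc = Document("1", "Sunitinib , an inhibitor", "")
    split_sentences(doc)
    rec = ParseRecord(
        [("Sunitinib", "sunitinib", "NN"), (",", ",", ","), ("an", "a", "DT"),
         ("inhibitor", "inhibitor", "NN")],
        [-1, 0, 3, 0], ["root", "punct", "det", "appos"])
    attach_parse(doc.sentences[0], rec, doc.text)
    edg = add_semantic_edges(build_edg(doc.sentences[0], []))
    assert ("sunitinib", IS_A, "inhibitor") in _sem(edg)


def test_propagation_collection_adds_exactly_two(collection_doc, collection_edg):
    before = build_edg(collection_doc.sentences[0], collection_doc.mentions)
    assign_numbered_args(before)
    add_semantic_edges(before)
    pre = set((e.source, e.target, e.label) for e in before.edges)
    propagate_args(before)
    added = {(before.vertices[s].lemma, lbl, before.vertices[t].lemma)
             for (s, t, lbl) in
             set((e.source, e.target, e.label) for e in before.edges) - pre}
    assert added == {("cause", "arg0", "sunitinib"),
                     ("cause", "arg0", "sorafenib")}


def test_propagation_coreterm_reaches_disease_head(coreterm_edg):
    assert ("cause", "arg1", "dyskinesia") in _args(coreterm_edg)
    prop = [e for e in coreterm_edg.edges if e.provenance == "propagated"]
    assert len(prop) == 1
    # derivation chain reconstructable
    chain = coreterm_edg.derivation(prop[0])
    assert len(chain) == 2 and chain[0].label == "arg1"


def test_propagation_idempotent_and_monotone(collection_doc):
    edg = build_edg(collection_doc.sentences[0], collection_doc.mentions)
    assign_numbered_args(edg)
    add_semantic_edges(edg)
    propagate_args(edg)
    once = set((e.source, e.target, e.label, e.layer) for e in edg.edges)
    propagate_args(edg)
    twice = set((e.source, e.target, e.label, e.layer) for e in edg.edges)
    assert once == twice


# -- shortest paths --------------------------------------------------------

from _oracles import brute_force_paths as _brute_force_paths
from _oracles import dummy_edg as _dummy_edg


def test_zero_length_path():
    edg = _dummy_edg(3, [(0, 1, "dep", SYNTACTIC)])
    (path,) = shortest_paths(edg, 1, 1)
    assert path.length == 0 and path.vertices == [1]


def test_disconnected_gives_empty():
    edg = _dummy_edg(4, [(0, 1, "dep", SYNTACTIC)])
    assert shortest_paths(edg, 0, 3) == []


def test_direction_recorded_against_orientation():
    edg = _dummy_edg(3, [(1, 0, "arg0", NUMBERED_ARG),
                         (1, 2, "arg1", NUMBERED_ARG)])
    (path,) = shortest_paths(edg, 0, 2)
    assert path.length == 2
    assert [d for _, d in path.steps] == [-1, +1]


def test_parallel_edges_collapse_by_layer():
    edg = _dummy_edg(2, [(0, 1, "agent", SYNTACTIC),
                         (0, 1, "arg0", NUMBERED_ARG)])
    paths = shortest_paths(edg, 0, 1)
    assert len(paths) == 1
    assert paths[0].steps[0][0].label == "arg0"


def test_shortest_paths_match_brute_force_on_random_graphs():
    rng = random.Random(42)
    labels = [("dep", SYNTACTIC), ("arg0", NUMBERED_ARG),
              ("arg1", NUMBERED_ARG), (MEMBER_COLLECTION, SEMANTIC),
              (IS_A, SEMANTIC), ("prep_of", SYNTACTIC)]
    for trial in range(500):
        n = rng.randint(2, 8)
        m = rng.randint(0, 2 * n)
        edges = []
        for _ in range(m):
            s, t = rng.sample(range(n), 2)
            lbl, layer = rng.choice(labels)
            edges.append((s, t, lbl, layer))
        edg = _dummy_edg(n, edges)
        a, b = rng.sample(range(n), 2)
        got = {tuple((e.source, e.target, e.label, d) for e, d in p.steps)
               for p in shortest_paths(edg, a, b)}
        assert got == _brute_force_paths(edg, a, b), f"trial {trial}"


def test_propagation_iteration_cap_is_hard_error():
    # a healthy graph terminates well inside the cap; simulate pathology by
    # patching add_edge to always report growth
    edg = _dummy_edg(3, [(0, 1, "arg0", NUMBERED_ARG),
                         (1, 2, "prep_of", SYNTACTIC)])
    edg.add_edge = lambda *a, **k: True  # every iteration claims growth
    with pytest.raises(RuntimeError, match="fixpoint"):
        propagate_args(edg)


def test_bad_layer_labels_rejected():
    with pytest.raises(ValueError):
        EdgEdge(0, 1, "arg9", NUMBERED_ARG)
    with pytest.raises(ValueError):
        EdgEdge(0, 1, "part-of", SEMANTIC)
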