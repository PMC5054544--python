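"""Desk-scale end-to-end experiments on synthetic corpora.

These drive the whole pipeline — generation, parsing, feature extraction,
training, prediction, scoring — at sizes (200 training / 50 test documents)
chosen so a full run takes seconds on one CPU.  The weak-augmentation
experiment additionally pushes 200 raw documents through the distant-
supervision path (dictionary grounding of a 10%-corrupted curated relation
table) and measures the effect of concatenating them to the gold training
set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .evaluate import PRF, cooccurrence_baseline, pair_prf
from .linguistic import parse_document
from .model import TrainConfig, build_corpus_instances, predict, train
from .synthetic import (SyntheticConfig, SyntheticCorpus, as_raw_documents,
                        corrupt_table, generate_corpus)
from .weak_label import build_weak_corpus

N_TRAIN_DOCS = 200
N_TEST_DOCS = 50
N_WEAK_DOCS = 200
CORRUPTION_RATE = 0.10

# disjoint doc-ID ranges for the three corpora of one experiment
_TEST_BASE = 8_000_000
_WEAK_BASE = 9_000_000


def _parsed_corpus(n_docs: int, seed: int, doc_id_base: int = 7_000_000
                   ) -> SyntheticCorpus:
    corpus = generate_corpus(SyntheticConfig(n_docs=n_docs, seed=seed,
                                             doc_id_base=doc_id_base))
    for doc in corpus.documents:
        parse_document(doc, corpus.parser)
    return corpus


@dataclass
class ExperimentResult:
    gold_only: PRF
    weak_augmented: PRF | None
    baseline: PRF
    n_train_instances: int
    n_weak_documents: int


def heldout_experiment(seed: int, with_weak: bool = True) -> ExperimentResult:
    """Train on a fresh synthetic corpus and score on a held-out one.

    ``seed`` drives every stochastic choice; derived seeds keep the train,
    test and weak corpora independent.  With ``with_weak``, a weakly labeled
    corpus is built through the full distant-supervision path and a second
    model is trained on the concatenation.
    """
    train_corpus = _parsed_corpus(N_TRAIN_DOCS, seed)
    test_corpus = _parsed_corpus(N_TEST_DOCS, seed + 1000, _TEST_BASE)
    gold = {d.doc_id: d.relations for d in test_corpus.documents}
    test_instances = build_corpus_instances(test_corpus.documents,
                                            labeled=False)
    train_instances = build_corpus_instances(train_corpus.documents)
    cfg = TrainConfig(seed=seed)
    model = train(train_instances, cfg)
    gold_only = pair_prf(gold, predict(model, test_instances))
    baseline = pair_prf(gold, cooccurrence_baseline(test_corpus.documents))
    weak_prf = None
    n_weak = 0
    if with_weak:
        weak_source = generate_corpus(SyntheticConfig(
            n_docs=N_WEAK_DOCS, seed=seed + 2000, doc_id_base=_WEAK_BASE))
        raw = as_raw_documents(weak_source)
        table = corrupt_table(weak_source.relation_table,
                              weak_source.dictionary, CORRUPTION_RATE, seed)
        weak_docs = build_weak_corpus(
            table, raw, weak_source.dictionary,
            exclude_doc_ids=[d.doc_id for d in train_corpus.documents])
        for doc in weak_docs:
            parse_document(doc, weak_source.parser)
        n_weak = len(weak_docs)
        weak_instances = build_corpus_instances(weak_docs, weak=True)
        augmented = train(train_instances + weak_instances, cfg)
        weak_prf = pair_prf(gold, predict(augmented, test_instances))
    return ExperimentResult(gold_only, weak_prf, baseline,
                            len(train_instances), n_weak)
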