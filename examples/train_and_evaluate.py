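"""Train the pair classifier on a synthetic corpus and score it held-out.

Generates 200 training and 50 test documents (with template-emitted
parses), trains the linear SVM on every <chemical ID, disease ID> candidate
pair, and compares the model against the co-occurrence baseline.
"""

from cidex.evaluate import cooccurrence_baseline, pair_prf
from cidex.linguistic import parse_document
from cidex.model import TrainConfig, build_corpus_instances, predict, train
from cidex.synthetic import SyntheticConfig, generate_corpus

train_corpus = generate_corpus(SyntheticConfig(n_docs=200, seed=1))
test_corpus = generate_corpus(SyntheticConfig(n_docs=50, seed=1001,
                                              doc_id_base=8_000_000))
for corpus in (train_corpus, test_corpus):
    for doc in corpus.documents:
        parse_document(doc, corpus.parser)

instances = build_corpus_instances(train_corpus.documents)
n_pos = sum(1 for i in instances if i.label)
print(f"training on {len(instances)} candidate pairs "
      f"({n_pos} positive) from {len(train_corpus.documents)} documents")

model = train(instances, TrainConfig(seed=1))
print(f"model has {len(model.index)} features")

test_instances = build_corpus_instances(test_corpus.documents, labeled=False)
gold = {d.doc_id: d.relations for d in test_corpus.documents}
prf = pair_prf(gold, predict(model, test_instances))
base = pair_prf(gold, cooccurrence_baseline(test_corpus.documents))

print(f"held-out pairs:  P={prf.precision:.3f} R={prf.recall:.3f} "
      f"F1={prf.f1:.3f}")
print(f"co-occurrence:   P={base.precision:.3f} R={base.recall:.3f} "
      f"F1={base.f1:.3f}")
print()
print("The baseline predicts every co-mentioned pair: perfect recall but")
print("poor precision. The classifier separates causal assertions from")
print("treatment co-mentions using the trigger patterns, path walks and")
print("statistical features.")
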