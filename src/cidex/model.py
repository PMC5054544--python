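"""Candidate-pair construction, vectorization, SVM training and prediction.

A candidate is every <chemical concept ID, disease concept ID> pair whose
IDs are both mentioned in a document; the classifier decides, per document,
whether the pair is asserted as a chemical-induced disease.  The learner is
a linear soft-margin SVM (liblinear); class weights are balanced by default
because true pairs are a minority among candidates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import IO, Iterable

import numpy as np
import scipy.sparse as sp
from sklearn.svm import LinearSVC

from .corpus_io import CHEMICAL, DISEASE, Document, RelationPair
from .edg import EDG, EdgConfig, build_full_edg
from .features import (FeatureFamilies, FeatureVector, KeywordConfig,
                       KnowledgeBase, PathFeatureConfig, extract_pair_features)


@dataclass
class PairInstance:
    doc_id: str
    chemical_id: str
    disease_id: str
    features: FeatureVector
    label: bool | None = None
    weak: bool = False

    @property
    def pair(self) -> RelationPair:
        return RelationPair(self.chemical_id, self.disease_id)


@dataclass
class TrainConfig:
    """SVM settings: linear kernel, C=1, balanced class weights, fixed seed.

    ``weak_weight`` < 1 down-weights weakly labeled instances; the default
    1.0 treats gold and weak data as one concatenated training set.
    """

    C: float = 1.0
    class_weight: str | None = "balanced"
    seed: int = 0
    weak_weight: float = 1.0
    max_iter: int = 5000
    tol: float = 1e-4


def document_edgs(document: Document,
                  edg_config: EdgConfig | None = None) -> list[EDG | None]:
    """Fully built EDG per sentence (None for unparsed sentences)."""
    out: list[EDG | None] = []
    for sent in document.sentences:
        if not sent.tokens:
            out.append(None)
        else:
            out.append(build_full_edg(sent, document.mentions, edg_config))
    return out


def build_instances(document: Document, labeled: bool = True,
                    kb: KnowledgeBase | None = None,
                    config: PathFeatureConfig | None = None,
                    families: FeatureFamilies | None = None,
                    edg_config: EdgConfig | None = None,
                    keywords: KeywordConfig | None = None,
                    weak: bool = False) -> list[PairInstance]:
    """One fully featurized instance per chemical-ID x disease-ID pair.

    When ``labeled`` is true, the label is membership of the pair in the
    document's relation set.  Documents with no chemicals or no diseases
    yield an empty list.
    """
    chem_ids = sorted(document.mention_ids(CHEMICAL))
    dis_ids = sorted(document.mention_ids(DISEASE))
    if not chem_ids or not dis_ids:
        return []
    edgs = document_edgs(document, edg_config)
    out = []
    for c in chem_ids:
        for d in dis_ids:
            feats = extract_pair_features(document, edgs, c, d, kb, config,
                                          families, keywords)
            label = (RelationPair(c, d) in document.relations
                     ) if labeled else None
            out.append(PairInstance(document.doc_id, c, d, feats, label, weak))
    return out


def build_corpus_instances(documents: Iterable[Document], labeled: bool = True,
                           **kwargs) -> list[PairInstance]:
    out: list[PairInstance] = []
    for doc in documents:
        out.extend(build_instances(doc, labeled, **kwargs))
    return out


class FeatureIndex:
    """Frozen feature-name -> column map built on the training instances;
    names unseen at training time are dropped at prediction time."""

    def __init__(self, names: Iterable[str] = ()):
        self.names = sorted(set(names))
        self._col = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def fit(cls, instances: Iterable[PairInstance]) -> "FeatureIndex":
        names: set[str] = set()
        for inst in instances:
            names.update(inst.features)
        return cls(names)

    def __len__(self) -> int:
        return len(self.names)

    def column(self, name: str) -> int | None:
        return self._col.get(name)


def vectorize(instances: list[PairInstance],
              index: FeatureIndex) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse design matrix (one row per instance, deterministic column
    order) and label vector (-1 for unlabeled instances)."""
    rows, cols, vals = [], [], []
    labels = np.full(len(instances), -1, dtype=np.int8)
    for r, inst in enumerate(instances):
        if inst.label is not None:
            labels[r] = int(inst.label)
        for name, value in sorted(inst.features.items()):
            c = index.column(name)
            if c is not None:
                rows.append(r)
                cols.append(c)
                vals.append(value)
    mat = sp.csr_matrix((vals, (rows, cols)),
                        shape=(len(instances), len(index)), dtype=np.float64)
    return mat, labels


@dataclass
class TrainedModel:
    """Linear decision function over the frozen feature index, with the
    training configuration snapshot; JSON-serializable and reloadable with
    bit-identical decision values."""

    index: FeatureIndex
    coef: np.ndarray
    intercept: float
    config: TrainConfig
    feature_config: PathFeatureConfig = field(default_factory=PathFeatureConfig)
    format_version: int = 1

    def decision_values(self, instances: list[PairInstance]) -> np.ndarray:
        X, _ = vectorize(instances, self.index)
        return X @ self.coef + self.intercept

    def save(self, stream: IO[str]) -> None:
        json.dump({
            "format_version": self.format_version,
            "train_config": asdict(self.config),
            "feature_config": asdict(self.feature_config),
            "feature_names": self.index.names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }, stream)

    @classmethod
    def load(cls, stream: IO[str]) -> "TrainedModel":
        blob = json.load(stream)
        if blob.get("format_version") != 1:
            raise ValueError("unsupported model format version")
        return cls(
            index=FeatureIndex(blob["feature_names"]),
            coef=np.asarray(blob["coef"], dtype=np.float64),
            intercept=float(blob["intercept"]),
            config=TrainConfig(**blob["train_config"]),
            feature_config=PathFeatureConfig(**blob["feature_config"]),
        )


def train(instances: list[PairInstance],
          config: TrainConfig | None = None,
          feature_config: PathFeatureConfig | None = None) -> TrainedModel:
    """Fit the linear SVM.  Requires at least one positive and one negative
    labeled instance; retraining on identical data and seed is bit-identical."""
    cfg = config or TrainConfig()
    labeled = [i for i in instances if i.label is not None]
    n_pos = sum(1 for i in labeled if i.label)
    if n_pos == 0 or n_pos == len(labeled):
        raise ValueError(
            f"training needs both classes (got {n_pos} positive of "
            f"{len(labeled)} labeled instances)")
    index = FeatureIndex.fit(labeled)
    X, y = vectorize(labeled, index)
    sample_weight = np.array(
        [cfg.weak_weight if i.weak else 1.0 for i in labeled])
    svm = LinearSVC(C=cfg.C, class_weight=cfg.class_weight,
                    random_state=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol)
    svm.fit(X, y, sample_weight=sample_weight)
    return TrainedModel(index=index, coef=svm.coef_.ravel().copy(),
                        intercept=float(svm.intercept_[0]), config=cfg,
                        feature_config=feature_config or PathFeatureConfig())


def predict(model: TrainedModel, instances: list[PairInstance],
            threshold: float = 0.0) -> dict[str, set[RelationPair]]:
    """Document-level relation sets: pairs whose decision value exceeds the
    threshold.  Every instance's document appears in the output (possibly
    with an empty set)."""
    out: dict[str, set[RelationPair]] = {}
    if not instances:
        return out
    scores = model.decision_values(instances)
    for inst, s in zip(instances, scores):
        out.setdefault(inst.doc_id, set())
        if s > threshold:
            out[inst.doc_id].add(inst.pair)
    return out


def predict_documents(model: TrainedModel, documents: Iterable[Document],
                      threshold: float = 0.0,
                      **build_kwargs) -> dict[str, set[RelationPair]]:
    """End-to-end prediction: featurize and classify each document."""
    out: dict[str, set[RelationPair]] = {}
    for doc in documents:
        instances = build_instances(doc, labeled=False, **build_kwargs)
        out[doc.doc_id] = set()
        if instances:
            out.update(predict(model, instances, threshold))
    return out
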