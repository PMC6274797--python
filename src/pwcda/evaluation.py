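"""Cross-validation and ROC/AUC evaluation of predicted associations.

Both schemes hold out verified associations (positives) and rebuild the
model from the remaining training associations only:

* **LOOCV** removes one association at a time. Diseases with a single
  known association are skipped (removing their only edge would leave the
  disease with no training signal) and reported in ``skipped_diseases``.
* **k-fold CV** partitions the positives uniformly at random into k folds
  under a caller-supplied seed; each fold is held out once.

Per fold, the GIP kernels, integrated similarities and thresholded
network are recomputed from the training association matrix only — the
kernel must never see the held-out edge, or the label would leak into its
own score. Annotation (Jaccard) similarities never touch associations and
are computed once.

Negative pairs (those absent from the full known set) are never held
out. Two scoring conventions for them are supported:

* ``negative_scoring="per_fold"`` (default) — each negative is rescored
  under the fold training models and its scores averaged (over the folds
  of its own disease in LOOCV; over all k folds in k-fold). This keeps
  positives and negatives comparable: a held-out positive is scored
  under a network where its endpoints have lost a degree, and pooling it
  against negatives scored on the full network systematically underranks
  it at sparse degrees.
* ``negative_scoring="full"`` — negatives scored once under the
  all-data model.

ROC/AUC is computed on the pooled labeled records, sweeping the
threshold over the distinct score values; the trapezoidal AUC equals the
Mann–Whitney statistic with tied scores counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .hetnet import apply_threshold, assemble
from .io import (
    AnnotationCatalog,
    AssociationMatrix,
    AssociationTable,
    build_association_matrix,
)
from .pathscore import ScoreParams, score_matrix
from .similarity import (
    SimilarityMatrix,
    annotation_similarity_matrix,
    gip_kernel_matrix,
    integrate_similarity,
)


@dataclass
class LabeledScores:
    """Per-pair prediction records: (disease_id, circ_id, score, label)."""

    records: list[tuple[str, str, float, int]]

    def __post_init__(self):
        pairs = [(d, c) for d, c, _, _ in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (disease, circRNA) pair in labeled scores")

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, _, s, _ in self.records])

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, _, y in self.records])


@dataclass
class RocCurve:
    """ROC sweep points and the area under the curve."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.fpr, self.tpr))


@dataclass
class CVResult:
    """Cross-validation output: pooled labeled scores, ROC and bookkeeping.

    ``roc`` is None for degenerate inputs where every candidate pair is a
    known association (no negatives to rank against); ``auc`` is then NaN.
    """

    scheme: str
    seed: int | None
    labeled: LabeledScores
    roc: RocCurve | None
    skipped_diseases: list[str] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return self.roc.auc if self.roc is not None else float("nan")


def roc_curve(labeled: LabeledScores) -> RocCurve:
    """ROC sweep over distinct score values, plus trapezoidal AUC.

    Requires at least one positive and one negative record.
    """
    y, s = labeled.labels, labeled.scores
    if y.min() == y.max():
        raise ValueError("ROC needs at least one positive and one negative record")
    fpr, tpr, thresholds = _skm.roc_curve(y, s, drop_intermediate=False)
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr)))


@dataclass(frozen=True)
class ModelConfig:
    """Network-construction parameters shared by all evaluation entry points."""

    params: ScoreParams = field(default_factory=ScoreParams)
    gamma_threshold: float = 0.5
    gip_gamma_prime_circ: float = 1.0
    gip_gamma_prime_dis: float = 1.0


def model_scores(
    m: np.ndarray,
    cs: SimilarityMatrix,
    ds: SimilarityMatrix,
    config: ModelConfig,
) -> np.ndarray:
    """Score all pairs from an association matrix and fixed Jaccard similarities.

    Rebuilds the GIP kernels, integrated similarities and thresholded
    network from ``m`` (which may be a training matrix with held-out
    entries zeroed) and returns the diseases × circRNAs score array.
    """
    assoc = AssociationMatrix(m, list(ds.ids), list(cs.ids))
    kc = gip_kernel_matrix(assoc, "circrna", config.gip_gamma_prime_circ)
    kd = gip_kernel_matrix(assoc, "disease", config.gip_gamma_prime_dis)
    ics = integrate_similarity(cs, kc)
    ids_ = integrate_similarity(ds, kd)
    net = apply_threshold(assemble(ics, ids_, assoc), config.gamma_threshold)
    return score_matrix(net, config.params).values


def _prepare(table, circ_catalog, dis_catalog, config):
    m = build_association_matrix(table).values
    cs = annotation_similarity_matrix(circ_catalog, table.circ_ids, "semantic")
    ds = annotation_similarity_matrix(dis_catalog, table.disease_ids, "functional")
    full = model_scores(m, cs, ds, config)
    return m, cs, ds, full


def _negatives(table: AssociationTable, m: np.ndarray, full_scores: np.ndarray):
    recs = []
    for i, d in enumerate(table.disease_ids):
        for j, c in enumerate(table.circ_ids):
            if m[i, j] == 0:
                recs.append((d, c, float(full_scores[i, j]), 0))
    return recs


def loocv(
    table: AssociationTable,
    circ_catalog: AnnotationCatalog,
    dis_catalog: AnnotationCatalog,
    config: ModelConfig | None = None,
    negative_scoring: str = "per_fold",
) -> CVResult:
    """Leave-one-association-out cross-validation.

    Each eligible positive is zeroed from the association matrix, the
    model is rebuilt from the remaining training associations, and the
    held-out pair's score is recorded as a positive. Diseases with
    exactly one known association are skipped. Under the default
    ``negative_scoring="per_fold"``, a negative pair's score is the mean
    of its scores under the fold models of its own disease (full-model
    score if that disease is never tested).
    """
    config = config or ModelConfig()
    if negative_scoring not in ("per_fold", "full"):
        raise ValueError("negative_scoring must be 'per_fold' or 'full'")
    if table.n_pairs < 2:
        raise ValueError("LOOCV needs at least 2 associations")
    m, cs, ds, full = _prepare(table, circ_catalog, dis_catalog, config)
    per_disease = m.sum(axis=1)
    skipped = [table.disease_ids[i] for i in np.flatnonzero(per_disease == 1)]
    records = []
    neg_sum = np.zeros_like(full)
    neg_folds = np.zeros(m.shape[0], dtype=int)
    for i, j in sorted(table.pairs):
        if per_disease[i] < 2:
            continue
        m_train = m.copy()
        m_train[i, j] = 0.0
        assert m_train[i, j] == 0.0  # leakage guard: test edge absent from training
        scores = model_scores(m_train, cs, ds, config)
        records.append((table.disease_ids[i], table.circ_ids[j], float(scores[i, j]), 1))
        neg_sum[i] += scores[i]
        neg_folds[i] += 1
    if not records:
        raise ValueError("no eligible test association (every disease has one pair)")
    if negative_scoring == "per_fold":
        neg_scores = np.where(
            neg_folds[:, None] > 0, neg_sum / np.maximum(neg_folds, 1)[:, None], full
        )
    else:
        neg_scores = full
    records.extend(_negatives(table, m, neg_scores))
    labeled = LabeledScores(records)
    roc = roc_curve(labeled) if labeled.labels.min() == 0 else None
    return CVResult("loocv", None, labeled, roc, skipped)


def kfold_cv(
    table: AssociationTable,
    circ_catalog: AnnotationCatalog,
    dis_catalog: AnnotationCatalog,
    k: int = 5,
    seed: int = 0,
    config: ModelConfig | None = None,
    negative_scoring: str = "per_fold",
) -> CVResult:
    """k-fold cross-validation over verified associations.

    Positives are partitioned uniformly at random into k folds under the
    given seed; per fold the test associations are zeroed from the
    training matrix, the model rebuilt, and the test positives scored.
    Under the default ``negative_scoring="per_fold"``, each negative's
    score is its mean over the k fold models.
    """
    config = config or ModelConfig()
    if negative_scoring not in ("per_fold", "full"):
        raise ValueError("negative_scoring must be 'per_fold' or 'full'")
    if k < 2:
        raise ValueError("k must be >= 2")
    if table.n_pairs < k:
        raise ValueError(f"k={k} exceeds the number of associations ({table.n_pairs})")
    m, cs, ds, full = _prepare(table, circ_catalog, dis_catalog, config)
    positives = sorted(table.pairs)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    folds = np.array_split(order, k)
    # sanity: folds partition the positives
    assert sorted(int(x) for f in folds for x in f) == list(range(len(positives)))
    records = []
    neg_sum = np.zeros_like(full)
    for fold in folds:
        m_train = m.copy()
        for idx in fold:
            i, j = positives[idx]
            m_train[i, j] = 0.0
        scores = model_scores(m_train, cs, ds, config)
        neg_sum += scores
        for idx in fold:
            i, j = positives[idx]
            assert m_train[i, j] == 0.0  # leakage guard
            records.append(
                (table.disease_ids[i], table.circ_ids[j], float(scores[i, j]), 1)
            )
    neg_scores = neg_sum / k if negative_scoring == "per_fold" else full
    records.extend(_negatives(table, m, neg_scores))
    labeled = LabeledScores(records)
    roc = roc_curve(labeled) if len(records) > int(labeled.labels.sum()) else None
    return CVResult(f"kfold({k})", seed, labeled, roc, [])
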