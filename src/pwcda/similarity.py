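"""Jaccard annotation similarity, GIP kernel similarity, and their fusion.

Two complementary similarity sources feed the heterogeneous network:

* **Annotation (Jaccard) similarity** — circRNA semantic similarity from
  shared GO terms of target genes, and disease functional similarity from
  shared disease-gene annotations. Both are the Jaccard index
  ``|A ∩ B| / |A ∪ B|``. Annotation catalogs are typically sparse, so many
  pairs score 0.
* **GIP kernel similarity** — the Gaussian Interaction Profile kernel
  ``K(i, j) = exp(-γ ‖p_i − p_j‖²)`` on binary association profiles, with
  bandwidth γ = γ′ divided by the mean squared profile norm. It rests on
  the guilt-by-association assumption that entities with similar
  association patterns are functionally similar, and is defined for every
  entity that appears in the association matrix.

Fusion keeps the annotation score wherever it is non-zero and falls back
to the GIP kernel otherwise, filling the holes the sparse annotation data
leaves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import AnnotationCatalog, AssociationMatrix

#: recognised similarity-matrix kinds
KINDS = ("semantic", "functional", "gip_circ", "gip_disease", "integrated_circ", "integrated_disease")


class DegenerateBandwidthError(ZeroDivisionError):
    """All association profiles are zero, so the GIP bandwidth is undefined."""


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise scores in [0, 1] for one entity class."""

    values: np.ndarray
    ids: list[str]
    kind: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match id list")
        if self.kind not in KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")


def jaccard(set_a, set_b) -> float:
    """Jaccard index |A∩B| / |A∪B|; two empty sets score 0.

    An entity with no annotations carries no evidence of similarity, and a
    zero correctly triggers the GIP fallback in :func:`integrate_similarity`.
    """
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def annotation_similarity_matrix(
    catalog: AnnotationCatalog, ids: list[str], kind: str = "semantic"
) -> SimilarityMatrix:
    """Pairwise Jaccard similarity over the entities listed in ``ids``.

    Entities missing from the catalog are treated as having empty term
    sets; their rows are all-zero (diagonal included), which hands them
    over to the GIP fallback downstream. Annotated entities get diagonal 1.
    """
    term_sets = [catalog.terms(e) for e in ids]
    vocab = sorted(set().union(*term_sets)) if term_sets else []
    n = len(ids)
    if not vocab:
        return SimilarityMatrix(np.zeros((n, n)), list(ids), kind)
    index = {t: k for k, t in enumerate(vocab)}
    incidence = np.zeros((n, len(vocab)))
    for row, terms in enumerate(term_sets):
        for t in terms:
            incidence[row, index[t]] = 1.0
    inter = incidence @ incidence.T
    sizes = incidence.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return SimilarityMatrix(values, list(ids), kind)


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Bandwidth γ = γ′ / mean(‖p_i‖²) over ALL entities, zero profiles included."""
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise ValueError("profiles must be a non-empty 2-D array")
    mean_sq_norm = float((profiles**2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise DegenerateBandwidthError(
            "all association profiles are zero; GIP bandwidth undefined"
        )
    return gamma_prime / mean_sq_norm


def gip_kernel_matrix(
    association: AssociationMatrix, axis: str, gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """GIP kernel over association profiles along one axis of M.

    ``axis='circrna'`` uses each circRNA's column of M (its profile over
    diseases); ``axis='disease'`` uses each disease's row. If M is entirely
    zero the bandwidth degenerates; the identity kernel is returned with a
    warning, preserving "no evidence → no off-diagonal similarity".
    """
    if axis in ("circrna", "circ"):
        profiles, ids, kind = association.values.T, association.col_ids, "gip_circ"
    elif axis == "disease":
        profiles, ids, kind = association.values, association.row_ids, "gip_disease"
    else:
        raise ValueError(f"axis must be 'circrna' or 'disease', got {axis!r}")
    try:
        gamma = gip_bandwidth(profiles, gamma_prime)
    except DegenerateBandwidthError:
        warnings.warn(
            "association matrix is all-zero; substituting identity GIP kernel",
            RuntimeWarning,
            stacklevel=2,
        )
        return SimilarityMatrix(np.eye(len(ids)), list(ids), kind)
    sq_dist = cdist(profiles, profiles, metric="sqeuclidean")
    values = np.exp(-gamma * sq_dist)
    values = (values + values.T) / 2.0  # exact symmetry
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(ids), kind)


def integrate_similarity(
    primary: SimilarityMatrix, fallback: SimilarityMatrix
) -> SimilarityMatrix:
    """Keep the annotation score where non-zero, else fall back to the GIP score."""
    if primary.ids != fallback.ids:
        raise ValueError("primary and fallback similarity matrices index different ids")
    kind = "integrated_circ" if fallback.kind == "gip_circ" else "integrated_disease"
    values = np.where(primary.values != 0.0, primary.values, fallback.values)
    return SimilarityMatrix(values, list(primary.ids), kind)
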