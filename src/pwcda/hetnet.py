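"""Heterogeneous network assembly and edge-weight thresholding.

The network has two node layers — circRNAs and diseases — and three edge
blocks: circRNA–circRNA edges weighted by integrated circRNA similarity,
disease–disease edges weighted by integrated disease similarity, and
bipartite circRNA–disease edges of weight 1 for every verified
association. Small similarity weights are treated as noise and removed by
a uniform threshold γ: an edge survives iff its weight ≥ γ. Self-loops
are masked at assembly; the path scorer only traverses simple paths, so
diagonals never contribute regardless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AssociationMatrix
from .similarity import SimilarityMatrix


@dataclass
class HetNet:
    """Weighted heterogeneous graph over circRNA and disease layers.

    Node indexing convention: circRNAs occupy indices ``0 .. n_circ-1``,
    diseases ``n_circ .. n_circ+n_diseases-1``. ``circ_dis`` is stored
    diseases × circRNAs, matching the association matrix orientation.
    """

    circ_ids: list[str]
    disease_ids: list[str]
    circ_circ: np.ndarray
    dis_dis: np.ndarray
    circ_dis: np.ndarray
    stage: str = "initial"

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_circ + self.n_diseases

    def node_index(self, entity_id: str) -> int:
        """Index of a node in the combined adjacency (circRNAs first)."""
        if entity_id in self.circ_ids:
            return self.circ_ids.index(entity_id)
        if entity_id in self.disease_ids:
            return self.n_circ + self.disease_ids.index(entity_id)
        raise KeyError(f"unknown entity id {entity_id!r}")

    def node_ids(self) -> list[str]:
        return list(self.circ_ids) + list(self.disease_ids)

    def combined_adjacency(self) -> np.ndarray:
        """Symmetric (n_circ + n_diseases)² adjacency with zero diagonal."""
        nc, nd = self.n_circ, self.n_diseases
        a = np.zeros((nc + nd, nc + nd))
        a[:nc, :nc] = self.circ_circ
        a[nc:, nc:] = self.dis_dis
        a[:nc, nc:] = self.circ_dis.T
        a[nc:, :nc] = self.circ_dis
        np.fill_diagonal(a, 0.0)
        return a

    def edge_list(self) -> list[tuple[str, str, float, str]]:
        """Undirected edges as (source_id, target_id, weight, edge_type) rows."""
        edges = []
        for i in range(self.n_circ):
            for j in range(i + 1, self.n_circ):
                w = self.circ_circ[i, j]
                if w > 0:
                    edges.append((self.circ_ids[i], self.circ_ids[j], float(w), "circ-circ"))
        for i in range(self.n_diseases):
            for j in range(i + 1, self.n_diseases):
                w = self.dis_dis[i, j]
                if w > 0:
                    edges.append((self.disease_ids[i], self.disease_ids[j], float(w), "dis-dis"))
        for i in range(self.n_diseases):
            for j in range(self.n_circ):
                w = self.circ_dis[i, j]
                if w > 0:
                    edges.append((self.circ_ids[j], self.disease_ids[i], float(w), "circ-dis"))
        return edges


def assemble(
    ics: SimilarityMatrix, ids_: SimilarityMatrix, m: AssociationMatrix
) -> HetNet:
    """Build the initial heterogeneous network from ICS, IDS and M.

    Association edges get weight 1 where M = 1 and are absent where M = 0;
    similarity diagonals are masked so no self-loop is ever exposed to
    traversal.
    """
    if len(ics.ids) != len(m.col_ids) or len(ids_.ids) != m.values.shape[0]:
        raise ValueError("similarity and association matrix dimensions disagree")
    if ics.ids != m.col_ids or ids_.ids != m.row_ids:
        raise ValueError("similarity and association matrix ids disagree")
    circ_circ = ics.values.copy()
    dis_dis = ids_.values.copy()
    np.fill_diagonal(circ_circ, 0.0)
    np.fill_diagonal(dis_dis, 0.0)
    return HetNet(
        circ_ids=list(ics.ids),
        disease_ids=list(ids_.ids),
        circ_circ=circ_circ,
        dis_dis=dis_dis,
        circ_dis=m.values.copy(),
        stage="initial",
    )


def apply_threshold(net: HetNet, gamma: float) -> HetNet:
    """Remove every edge of weight < γ, uniformly across all three blocks.

    The comparator is ≥, so a weight exactly equal to γ survives.
    Association edges weigh 1 and are unaffected for any γ ≤ 1; γ outside
    [0, 1] is rejected so known associations cannot be deleted silently.
    Idempotent at fixed γ.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"threshold gamma must lie in [0, 1], got {gamma}")

    def cut(block: np.ndarray) -> np.ndarray:
        return np.where(block >= gamma, block, 0.0)

    return HetNet(
        circ_ids=list(net.circ_ids),
        disease_ids=list(net.disease_ids),
        circ_circ=cut(net.circ_circ),
        dis_dis=cut(net.dis_dis),
        circ_dis=cut(net.circ_dis),
        stage="final",
    )
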