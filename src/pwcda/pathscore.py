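"""Path-weighted association scoring on the heterogeneous network.

The score of a circRNA–disease pair aggregates every node-simple path of
at most η edges connecting them. A path ``p`` with edge weights
``w_1 .. w_len`` contributes ``(∏ w_t) / (α · e^len)``: the numerator is
the product of traversed edge weights and the denominator is an
exponential length decay, so longer, more tenuous chains of evidence
count less. All node-type sequences the graph permits are admitted
(c–d, c–c–d, c–d–d, c–c–c–d, c–c–d–d, c–d–d–d at η = 3, and so on); the
only exclusion rule is the length bound.

Path enumeration is a depth-first search that marks nodes on entry and
unmarks them on backtrack, visiting neighbors in ascending node index so
output order is deterministic (lexicographic by node index sequence).
For the default η ≤ 3 the full score matrix is instead computed in
closed form from powers of the adjacency matrix: every length-1 and
length-2 walk between distinct endpoints is automatically simple (the
graph has no self-loops), and the non-simple length-3 walks — those
revisiting the source or passing through the target — are subtracted by
inclusion–exclusion. The two routes agree exactly and the DFS remains
the general fallback for η > 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hetnet import HetNet


@dataclass(frozen=True)
class ScoreParams:
    """Scoring parameters: decay factor α > 0 and maximum path length η ≥ 1.

    Defaults are the method's operating point: α = 1, η = 3. α rescales
    every score by the same constant, so rankings (and any AUC computed
    from them) do not depend on it; η bounds how far guilt-by-association
    evidence may propagate.
    """

    alpha: float = 1.0
    eta: int = 3

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not (isinstance(self.eta, (int, np.integer)) and self.eta >= 1):
            raise ValueError("eta must be an integer >= 1")


@dataclass
class Path:
    """A node-simple path with its traversed edge weights."""

    nodes: list[str]
    edge_weights: list[float]

    def __post_init__(self):
        if len(self.nodes) != len(self.edge_weights) + 1:
            raise ValueError("a path over k edges must list k+1 nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path revisits a node")

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.edge_weights)


@dataclass
class ScoreMatrix:
    """Predicted association scores, diseases × circRNAs."""

    values: np.ndarray
    disease_ids: list[str]
    circ_ids: list[str]
    params: ScoreParams = field(default_factory=ScoreParams)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.disease_ids), len(self.circ_ids)):
            raise ValueError("score matrix shape does not match id lists")


def decay(length: int, alpha: float = 1.0) -> float:
    """Length decay f(len) = α · e^len; path contributions are divided by it."""
    if length < 1:
        raise ValueError("path length must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return alpha * math.exp(length)


def path_score(path: Path) -> float:
    """Product of the path's edge weights."""
    return float(np.prod(path.edge_weights))


def enumerate_paths(net: HetNet, circ: str, disease: str, eta: int = 3) -> list[Path]:
    """All node-simple paths of ≤ eta edges from ``circ`` to ``disease``.

    Every edge on a returned path has positive weight in the (thresholded)
    network. Output order is lexicographic by node index sequence.
    """
    if eta < 1:
        raise ValueError("eta must be >= 1")
    start = net.node_index(circ)
    target = net.node_index(disease)
    adj = net.combined_adjacency()
    node_ids = net.node_ids()
    neighbors = [np.flatnonzero(adj[u] > 0) for u in range(adj.shape[0])]

    paths: list[Path] = []
    visited = [False] * adj.shape[0]
    stack_nodes = [start]
    stack_weights: list[float] = []

    def dfs(u: int) -> None:
        visited[u] = True
        for v in neighbors[u]:
            if visited[v]:
                continue
            stack_nodes.append(int(v))
            stack_weights.append(float(adj[u, v]))
            if v == target:
                paths.append(
                    Path([node_ids[k] for k in stack_nodes], list(stack_weights))
                )
            elif len(stack_weights) < eta:
                dfs(int(v))
            stack_nodes.pop()
            stack_weights.pop()
        visited[u] = False

    dfs(start)
    return paths


def association_score(net: HetNet, circ: str, disease: str, params: ScoreParams | None = None) -> float:
    """Sum of decayed path scores over all simple paths of ≤ η edges; 0 if none."""
    params = params or ScoreParams()
    return sum(
        path_score(p) / decay(p.length, params.alpha)
        for p in enumerate_paths(net, circ, disease, params.eta)
    )


def _closed_form_scores(adj: np.ndarray, nc: int, params: ScoreParams) -> np.ndarray:
    """Simple-path score sums for η ≤ 3 via adjacency-matrix powers.

    With a zero diagonal, every length-1 and length-2 walk between
    distinct endpoints is simple. A length-3 walk u→x→y→v fails to be
    simple only when y = u or x = v; those terms are A²[u,u]·A[u,v] and
    A[u,v]·A²[v,v], double-counting the u→v→u→v walk of weight A[u,v]³.
    """
    n = adj.shape[0]
    total = np.zeros((n, n))
    e = math.e
    total += adj / e
    if params.eta >= 2:
        a2 = adj @ adj
        total += a2 / e**2
    if params.eta >= 3:
        a3 = a2 @ adj
        d2 = np.diag(a2)
        simple3 = a3 - d2[:, None] * adj - adj * d2[None, :] + adj**3
        total += simple3 / e**3
    # circ rows, disease columns -> transpose to diseases × circRNAs
    return total[:nc, nc:].T / params.alpha


def score_matrix(net: HetNet, params: ScoreParams | None = None) -> ScoreMatrix:
    """Association scores for every (disease, circRNA) pair in the network."""
    params = params or ScoreParams()
    if params.eta <= 3:
        values = _closed_form_scores(net.combined_adjacency(), net.n_circ, params)
    else:
        values = np.array(
            [
                [association_score(net, c, d, params) for c in net.circ_ids]
                for d in net.disease_ids
            ]
        )
    return ScoreMatrix(values, list(net.disease_ids), list(net.circ_ids), params)
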