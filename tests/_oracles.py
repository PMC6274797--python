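"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own algorithms: path enumeration
iterates over all node sequences via ``itertools.permutations`` and AUC
counts concordant positive/negative pairs directly.
"""

import itertools
import math

import numpy as np

from pwcda import HetNet


def enumerate_simple_paths(adj, start, end, eta):
    """All node-simple paths of <= eta edges as (node sequence, weights)."""
    n = adj.shape[0]
    others = [x for x in range(n) if x not in (start, end)]
    found = []
    for length in range(1, eta + 1):
        for mids in itertools.permutations(others, length - 1):
            seq = (start, *mids, end)
            weights = [adj[a, b] for a, b in zip(seq, seq[1:])]
            if all(w > 0 for w in weights):
                found.append((seq, weights))
    return found


def pair_score(adj, start, end, eta, alpha):
    """Sum of weight-products divided by alpha * e^len over simple paths."""
    return sum(
        np.prod(ws) / (alpha * math.exp(len(ws)))
        for _, ws in enumerate_simple_paths(adj, start, end, eta)
    )


def score_matrix_oracle(net, eta=3, alpha=1.0):
    """Exhaustive-enumeration score matrix, diseases x circRNAs."""
    adj = net.combined_adjacency()
    nc = net.n_circ
    out = np.zeros((net.n_diseases, nc))
    for i in range(net.n_diseases):
        for j in range(nc):
            out[i, j] = pair_score(adj, j, nc + i, eta, alpha)
    return out


def auc_pair_counting(labels, scores):
    """Probability a random positive outranks a random negative, ties = 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    hits = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return hits / (len(pos) * len(neg))


def random_hetnet(rng, max_nodes=8, density=0.6):
    """A random weighted heterogeneous network with <= max_nodes nodes."""
    nc = int(rng.integers(2, max_nodes - 1))
    nd = int(rng.integers(2, max(3, max_nodes - nc + 1)))
    n = nc + nd
    upper = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), 1)
    adj = upper + upper.T
    return HetNet(
        circ_ids=[f"c{k}" for k in range(nc)],
        disease_ids=[f"d{k}" for k in range(nd)],
        circ_circ=adj[:nc, :nc],
        dis_dis=adj[nc:, nc:],
        circ_dis=adj[nc:, :nc],
        stage="final",
    )
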