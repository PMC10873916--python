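"""Exploratory graph analysis: walktrap communities on the estimated network.

The walktrap algorithm measures similarity between nodes by the
distribution of short random walks (here t = 4 steps) over the weighted
graph and agglomerates nodes bottom-up; the returned partition is the cut
of the merge dendrogram maximizing Newman's weighted modularity. Absolute
edge weights drive the walk — a transition probability cannot be negative —
while signed weights are kept for bridge centrality. Isolated nodes become
singleton communities. The procedure is fully deterministic.

The random-walk merging itself runs through igraph; dendrogram cut
selection by modularity is done here so the selection rule is explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .association import spearman_matrix
from .ggm import ZERO_TOL, WeightedNetwork, ebic_glasso_select


@dataclass
class CommunityPartition:
    """Node -> community assignment with the dendrogram that produced it."""

    membership: np.ndarray  # contiguous ints from 0
    labels: list
    modularity: float
    merges: list = field(default_factory=list)
    isolated: list = field(default_factory=list)

    def __post_init__(self):
        self.membership = np.asarray(self.membership, dtype=int)
        if len(self.membership) != len(self.labels):
            raise ValueError("membership/labels length mismatch")

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1 if len(self.membership) else 0

    def membership_dict(self, labels=None) -> dict:
        d = dict(zip(self.labels, self.membership.tolist()))
        if labels is not None:
            return {lab: d[lab] for lab in labels}
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.labels, "community": self.membership})


def _canonical_relabel(memb: np.ndarray) -> np.ndarray:
    """Relabel communities as contiguous ints in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(memb)
    for k, c in enumerate(memb):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[k] = mapping[c]
    return out


def modularity(W, membership) -> float:
    """Newman weighted modularity on absolute weights:
    Q = sum_c (e_cc - a_c^2), with e_cc the fraction of total edge weight
    inside community c and a_c its fraction of summed degrees."""
    A = np.abs(W.weights if isinstance(W, WeightedNetwork) else np.asarray(W, dtype=float))
    memb = np.asarray(membership, dtype=int)
    iu = np.triu_indices(A.shape[0], k=1)
    m = A[iu].sum()
    if m == 0:
        return 0.0
    deg = A.sum(axis=1)
    q = 0.0
    for c in np.unique(memb):
        inc = memb == c
        e_cc = A[np.ix_(inc, inc)][np.triu_indices(inc.sum(), k=1)].sum() / m
        a_c = deg[inc].sum() / (2 * m)
        q += e_cc - a_c ** 2
    return float(q)


def walktrap(W: WeightedNetwork, steps: int = 4) -> CommunityPartition:
    """Walktrap community detection with modularity-selected cut.

    Requires at least one edge. Isolated nodes are assigned singleton
    communities and listed in the result's ``isolated`` field.
    """
    A = np.abs(W.weights)
    p = A.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    keep = A[iu, ju] > ZERO_TOL
    if not keep.any():
        raise ValueError("network has no edges; walktrap undefined")
    g = ig.Graph(n=p, edges=list(zip(iu[keep].tolist(), ju[keep].tolist())))
    g.es["weight"] = A[iu[keep], ju[keep]].tolist()
    isolated = [W.labels[k] for k in range(p) if g.degree(k) == 0]
    dendro = g.community_walktrap(weights="weight", steps=steps)
    merges = [tuple(m) for m in dendro.merges]
    n_comp = len(g.connected_components())
    best_q, best_memb = -np.inf, None
    for k in range(n_comp, p + 1):
        memb = np.asarray(dendro.as_clustering(k).membership)
        q = modularity(W, memb)
        if q > best_q + 1e-12:
            best_q, best_memb = q, memb
    return CommunityPartition(membership=_canonical_relabel(best_memb),
                              labels=list(W.labels), modularity=best_q,
                              merges=merges, isolated=isolated)


def ega(data, gamma: float = 0.5, steps: int = 4, n_lambda: int = 100,
        min_ratio: float = 0.01) -> tuple[WeightedNetwork, CommunityPartition]:
    """Exploratory graph analysis: Spearman -> EBIC-glasso -> walktrap.

    An empty estimated network yields an all-singleton partition with a
    warning instead of an error.
    """
    C = spearman_matrix(data)
    net, _ = ebic_glasso_select(C, n=C.n_effective, gamma=gamma,
                                n_lambda=n_lambda, min_ratio=min_ratio,
                                labels=C.labels)
    if net.n_edges == 0:
        warnings.warn("estimated network is empty; every node is its own community")
        part = CommunityPartition(membership=np.arange(net.p),
                                  labels=list(net.labels), modularity=0.0,
                                  isolated=list(net.labels))
        return net, part
    return net, walktrap(net, steps=steps)


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two partitions (1 = identical up to
    relabeling, ~0 = chance agreement)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same nodes")
    n = len(a)
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    C = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(C, (ia, ib), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(C).sum()
    sum_a = comb2(C.sum(axis=1)).sum()
    sum_b = comb2(C.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
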