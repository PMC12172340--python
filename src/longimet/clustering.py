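"""Two-step co-variation clustering of analytes.

Step one builds a shared-nearest-neighbour (SNN) graph over analytes (each
analyte a point in sample space, profiles scaled to zero mean / unit
variance), connects analytes that share nearest neighbours, and partitions
it into communities with seeded Louvain modularity optimisation.  Step two
hierarchically merges the community mean profiles with Ward ("ward.D2")
linkage into a requested number of groups.

`SNNCommunityClusterer` wraps the whole procedure as a scikit-learn style
estimator (rows = analytes, columns = samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities as _nx_louvain
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "build_snn_graph",
    "louvain_communities",
    "merge_hierarchical",
    "CommunityAssignment",
    "SNNCommunityClusterer",
]


def build_snn_graph(
    profiles: pd.DataFrame | np.ndarray,
    k_nn: int = 20,
    k_snn: int = 5,
    min_shared: int = 1,
) -> nx.Graph:
    """Shared-nearest-neighbour graph over analytes.

    ``profiles`` has one row per analyte (columns are the scaled sample
    coordinates).  Nearest neighbours use exact Euclidean distance with ties
    broken by row order for determinism.  An undirected edge (u, v) is added
    when u and v share at least ``min_shared`` of their ``k_snn`` nearest
    neighbours; the edge weight is the shared-neighbour count.
    """
    X = np.asarray(profiles, dtype=float)
    ids = list(profiles.index) if isinstance(profiles, pd.DataFrame) else list(range(X.shape[0]))
    n = X.shape[0]
    if k_nn >= n:
        raise ValueError(f"k_nn ({k_nn}) must be < number of analytes ({n})")
    if not (1 <= k_snn <= k_nn):
        raise ValueError("k_snn must satisfy 1 <= k_snn <= k_nn")

    D = squareform(pdist(X, metric="euclidean"))
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    top = order[:, :k_snn]
    member = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_snn)
    member[rows, top.ravel()] = True
    shared = member.astype(np.int32) @ member.astype(np.int32).T

    G = nx.Graph()
    G.add_nodes_from(ids)
    iu, ju = np.triu_indices(n, k=1)
    sel = shared[iu, ju] >= min_shared
    G.add_weighted_edges_from(
        (ids[i], ids[j], int(shared[i, j])) for i, j in zip(iu[sel], ju[sel])
    )
    G.graph["k_nn"] = k_nn
    G.graph["k_snn"] = k_snn
    return G


def louvain_communities(graph: nx.Graph, seed: int = 0) -> dict:
    """Louvain community labels (deterministic given seed and node order).

    Communities are renumbered 1..K by their smallest node in graph order.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    comms = _nx_louvain(graph, weight="weight", seed=int(seed))
    node_order = {node: i for i, node in enumerate(graph.nodes)}
    comms = sorted(comms, key=lambda c: min(node_order[x] for x in c))
    return {node: k + 1 for k, comm in enumerate(comms) for node in comm}


@dataclass
class CommunityAssignment:
    initial: dict  # analyte -> initial community id
    merged: dict  # analyte -> merged group id
    community_profiles: pd.DataFrame  # community x feature mean profiles


def merge_hierarchical(
    communities: dict,
    profiles: pd.DataFrame,
    n_groups: int = 8,
) -> CommunityAssignment:
    """Ward ("ward.D2") merge of community mean profiles into n_groups."""
    labels = pd.Series(communities, name="community")
    uniq = sorted(labels.unique())
    if n_groups > len(uniq):
        raise ValueError(f"n_groups ({n_groups}) exceeds communities ({len(uniq)})")
    means = profiles.loc[labels.index].groupby(labels).mean()
    if n_groups == len(uniq):
        grp = {c: i + 1 for i, c in enumerate(uniq)}
    else:
        Z = linkage(means.to_numpy(float), method="ward")
        cut = fcluster(Z, t=n_groups, criterion="maxclust")
        grp = dict(zip(means.index, (int(x) for x in cut)))
    merged = {a: grp[c] for a, c in communities.items()}
    return CommunityAssignment(dict(communities), merged, means)


class SNNCommunityClusterer(ClusterMixin, BaseEstimator):
    """KNN -> SNN graph -> Louvain -> hierarchical merge, as one estimator.

    Parameters
    ----------
    k_nn : neighbour-list length for the SNN construction (must be smaller
        than the number of analytes).
    k_snn : number of nearest neighbours considered when counting shared
        neighbours.
    min_shared : minimum shared-neighbour count for an edge.
    n_groups : number of merged groups after the Ward step; ``None`` keeps
        the raw Louvain communities.
    random_state : Louvain seed.

    Attributes (after ``fit``)
    --------------------------
    labels_ : merged group per analyte (row order of X).
    communities_ : initial Louvain community per analyte.
    graph_ : the SNN graph.
    assignment_ : the full :class:`CommunityAssignment`.
    """

    def __init__(self, k_nn=20, k_snn=5, min_shared=1, n_groups=8, random_state=0):
        self.k_nn = k_nn
        self.k_snn = k_snn
        self.min_shared = min_shared
        self.n_groups = n_groups
        self.random_state = random_state

    def fit(self, X, y=None):
        profiles = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        self.graph_ = build_snn_graph(profiles, self.k_nn, self.k_snn, self.min_shared)
        initial = louvain_communities(self.graph_, seed=self.random_state)
        n_groups = self.n_groups
        if n_groups is None or n_groups >= len(set(initial.values())):
            n_groups = len(set(initial.values()))
        self.assignment_ = merge_hierarchical(initial, profiles, n_groups)
        self.communities_ = np.array([initial[i] for i in profiles.index])
        self.labels_ = np.array([self.assignment_.merged[i] for i in profiles.index])
        self.n_communities_ = len(set(initial.values()))
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
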