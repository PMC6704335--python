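"""Per-group functional co-occurrence networks.

Edges are called between pairs of predicted functions whose Pearson
correlation across the group's samples is stronger than expected under a
permutation null: every feature column is independently shuffled across
samples B times (default 10,000) and the two-sided p-value for a pair is
the smoothed exceedance fraction ``(#{|r_perm| >= |r_obs|} + 1)/(B + 1)``.
Pairs with p below the edge cutoff (default 0.01) form an undirected graph.

Reported edge and degree figures use ordered-pair (doubled) counts — the
convention under which density equals ``edges / (nodes * (nodes - 1))`` —
while the graph itself is stored undirected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class FunctionalNetwork:
    """Undirected graph over functions with per-edge (r, p) attributes."""

    graph: nx.Graph
    group: str = ""
    gender: str = ""
    n_permutations: int = 0
    alpha_edge: float = 0.01


@dataclass
class NetworkMetrics:
    """Topology summary; ``edges`` is the ordered-pair (doubled) count."""

    nodes: int
    edges: int
    density: float
    diameter: int
    centralization: float
    clustering_coefficient: float

    def to_series(self) -> pd.Series:
        return pd.Series({
            "Nodes": self.nodes, "Edges": self.edges,
            "Density": self.density, "Diameter": self.diameter,
            "Centralization": self.centralization,
            "Clustering coefficient": self.clustering_coefficient,
        })


@dataclass
class HubRecord:
    """A high-degree node; ``degree`` is the ordered-pair count."""

    function_id: str
    degree: int
    annotation: str = ""


def density(n_nodes: int, n_ordered_edges: int) -> float:
    """Graph density under the ordered-pair edge-count convention.

    ``density = edges / (nodes * (nodes - 1))`` with ``edges`` counting each
    undirected edge twice; identical to the standard undirected density.
    """
    if n_nodes < 2:
        return 0.0
    return n_ordered_edges / (n_nodes * (n_nodes - 1))


def pearson_matrix(profile: pd.DataFrame) -> pd.DataFrame:
    """Product-moment correlation between features over the group's samples.

    Needs at least 3 samples.  Zero-variance features get NaN rows/columns
    (they are excluded from edge calling downstream).
    """
    if profile.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    X = profile.to_numpy(dtype=float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    return pd.DataFrame(r, index=profile.columns, columns=profile.columns)


def _null_corr_abs(X: np.ndarray) -> np.ndarray:
    """|correlation| matrix of a matrix with already standardized columns."""
    n = X.shape[0]
    return np.abs(X.T @ X) / n


def permutation_pvalues(profile: pd.DataFrame, B: int = 10_000,
                        seed: int = 0) -> pd.DataFrame:
    """Two-sided permutation p-values for all feature pairs.

    Each iteration independently shuffles every feature column across the
    samples once; the same shuffled matrix serves all pairs.  p is the
    smoothed exceedance ``(count + 1)/(B + 1)``, never zero.  Zero-variance
    features get p = 1 for all their pairs; diagonal entries are 1
    (self-pairs are never tested).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    X = profile.to_numpy(dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    obs = _null_corr_abs(Z)
    exceed = np.zeros((m, m))
    for _ in range(B):
        perm = rng.permuted(Z, axis=0)  # independent shuffle per column
        exceed += _null_corr_abs(perm) >= obs
    p = (exceed + 1.0) / (B + 1.0)
    p[~ok, :] = 1.0
    p[:, ~ok] = 1.0
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=profile.columns, columns=profile.columns)


def build_network(r: pd.DataFrame, p: pd.DataFrame,
                  alpha_edge: float = 0.01, group: str = "",
                  gender: str = "", n_permutations: int = 0
                  ) -> FunctionalNetwork:
    """Retain pairs with p < ``alpha_edge`` as an undirected graph.

    Nodes are the endpoints of at least one retained edge; isolated
    features are dropped.  Both correlation signs are kept, stored on the
    edge.  An empty result triggers a warning, not an error.
    """
    g = nx.Graph()
    feats = list(r.columns)
    rv, pv = r.to_numpy(), p.to_numpy()
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            if pv[i, j] < alpha_edge and np.isfinite(rv[i, j]):
                g.add_edge(feats[i], feats[j],
                           r=float(rv[i, j]), p=float(pv[i, j]))
    if g.number_of_edges() == 0:
        warnings.warn("no edges survive the p-value cutoff; empty network",
                      stacklevel=2)
    return FunctionalNetwork(graph=g, group=group, gender=gender,
                             n_permutations=n_permutations,
                             alpha_edge=alpha_edge)


def compute_metrics(net: FunctionalNetwork | nx.Graph) -> NetworkMetrics:
    """Topology metrics of a functional network.

    Edge counts are ordered-pair (doubled); density uses the matching
    convention; diameter is taken on the largest connected component;
    centralization is Freeman degree centralization (simple degrees),
    reported as 0 for fewer than 3 nodes; the clustering coefficient is
    the global transitivity (3 x triangles / connected triples).
    """
    g = net.graph if isinstance(net, FunctionalNetwork) else net
    n = g.number_of_nodes()
    if n == 0:
        return NetworkMetrics(0, 0, 0.0, 0, 0.0, 0.0)
    e2 = 2 * g.number_of_edges()
    dens = density(n, e2)
    if g.number_of_edges() > 0:
        comp = max(nx.connected_components(g), key=len)
        diam = nx.diameter(g.subgraph(comp))
    else:
        diam = 0
    if n >= 3:
        degs = np.array([d for _, d in g.degree()])
        centralization = float((degs.max() - degs).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0
    return NetworkMetrics(
        nodes=n, edges=e2, density=dens, diameter=int(diam),
        centralization=centralization,
        clustering_coefficient=float(nx.transitivity(g)))


def top_hubs(net: FunctionalNetwork | nx.Graph, k: int = 10,
             annotations: dict[str, str] | None = None) -> list[HubRecord]:
    """Top-k nodes by ordered-pair degree; ties broken lexicographically."""
    g = net.graph if isinstance(net, FunctionalNetwork) else net
    annotations = annotations or {}
    ranked = sorted(g.degree(), key=lambda kv: (-kv[1], kv[0]))
    return [HubRecord(function_id=f, degree=2 * d,
                      annotation=annotations.get(f, ""))
            for f, d in ranked[:k]]


def hubs_to_frame(hubs: list[HubRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"function_id": h.function_id, "degree": h.degree,
          "annotation": h.annotation} for h in hubs],
        columns=["function_id", "degree", "annotation"])
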