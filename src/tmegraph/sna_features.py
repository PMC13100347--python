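"""Social-network-analysis descriptors of tissue graphs.

Six node-level metrics -- node degree (ND), clustering coefficient (CL),
closeness centrality (CC), degree centrality (DC), Katz centrality (KC),
and community structure (CS) -- are each summarized by a 10-bin histogram
plus five statistics (mean, population standard deviation, maximum,
minimum, median), giving 15 features per metric.  Network density (NED),
a graph-level metric, is appended directly, for a 91-dimensional feature
vector per tissue graph.

Conventions chosen for KNN graphs, which may be disconnected: closeness
uses the component-size-scaled (Wasserman-Faust) form; the node-level CS
value is the node's community size divided by the node count, so the "CS
histogram" summarizes the community-size distribution; histogram bins
span the per-graph [min, max] range and are emitted as frequencies so
graphs of different sizes stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .graph_construction import TissueGraph

__all__ = [
    "METRIC_ORDER", "N_FEATURES", "SNAParams", "NodeMetricVector",
    "SNAFeatureVector", "node_degrees", "degree_centralities",
    "clustering_coefficients", "closeness_centralities",
    "katz_centralities", "network_density", "community_sizes",
    "summarize_metric", "extract_sna_features", "feature_names",
]

METRIC_ORDER = ("ND", "CL", "CC", "DC", "KC", "CS")
SUMMARY_NAMES = ("mean", "std", "max", "min", "median")
N_FEATURES = 91  # 6 metrics x (10 histogram bins + 5 statistics) + NED


@dataclass(frozen=True)
class SNAParams:
    """Summarization and metric parameters.

    ``katz_alpha=None`` resolves per graph to min(0.1, 0.85 / lambda_max)
    where lambda_max is the largest adjacency eigenvalue, guaranteeing the
    Katz linear system is solvable.
    """

    n_bins: int = 10
    katz_alpha: float | None = None
    katz_beta: float = 1.0
    community_method: str = "greedy_modularity"

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.community_method != "greedy_modularity":
            raise ValueError(
                f"unknown community_method {self.community_method!r}"
            )


@dataclass
class NodeMetricVector:
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _as_nx(graph: TissueGraph | nx.Graph) -> nx.Graph:
    if isinstance(graph, TissueGraph):
        return graph.to_networkx()
    return graph


def node_degrees(graph: TissueGraph | nx.Graph) -> NodeMetricVector:
    """ND(v): number of incident edges."""
    G = _as_nx(graph)
    nodes = sorted(G.nodes)
    return NodeMetricVector("ND", np.array([G.degree(v) for v in nodes], float))


def degree_centralities(graph: TissueGraph | nx.Graph) -> NodeMetricVector:
    """DC(v) = deg(v)/(n-1); 0 by convention on a single-node graph."""
    G = _as_nx(graph)
    n = G.number_of_nodes()
    nd = node_degrees(G).values
    vals = nd / (n - 1) if n > 1 else np.zeros_like(nd)
    return NodeMetricVector("DC", vals)


def clustering_coefficients(graph: TissueGraph | nx.Graph) -> NodeMetricVector:
    """CL(v) = 2 T(v) / (deg(v)(deg(v)-1)); 0 when deg(v) < 2."""
    G = _as_nx(graph)
    cl = nx.clustering(G)
    return NodeMetricVector("CL", np.array([cl[v] for v in sorted(G.nodes)], float))


def closeness_centralities(graph: TissueGraph | nx.Graph) -> NodeMetricVector:
    """Component-size-scaled closeness.

    CC(v) = ((n_c - 1)/(n - 1)) * ((n_c - 1) / sum of distances within
    v's component); isolated nodes and single-node graphs give 0.
    """
    G = _as_nx(graph)
    cc = nx.closeness_centrality(G, wf_improved=True)
    return NodeMetricVector("CC", np.array([cc[v] for v in sorted(G.nodes)], float))


def katz_centralities(
    graph: TissueGraph | nx.Graph,
    katz_alpha: float | None = None,
    katz_beta: float = 1.0,
) -> NodeMetricVector:
    """Katz centrality by dense linear solve, scaled to unit norm.

    Solves (I - alpha A) x = beta 1 for the symmetric adjacency A, then
    divides by the Euclidean norm.  alpha defaults to
    min(0.1, 0.85 / lambda_max); an alpha at or beyond 1/lambda_max is
    rejected with instructions to lower it.
    """
    G = _as_nx(graph)
    nodes = sorted(G.nodes)
    n = len(nodes)
    A = nx.to_numpy_array(G, nodelist=nodes)
    lam_max = float(np.max(np.linalg.eigvalsh(A))) if n > 0 else 0.0
    if katz_alpha is None:
        alpha = min(0.1, 0.85 / lam_max) if lam_max > 0 else 0.1
    else:
        alpha = float(katz_alpha)
        if lam_max > 0 and alpha * lam_max >= 1.0:
            raise ValueError(
                f"katz_alpha={alpha} too large for spectral radius "
                f"{lam_max:.4f}; lower alpha below {1.0 / lam_max:.4f}"
            )
    x = np.linalg.solve(np.eye(n) - alpha * A, katz_beta * np.ones(n))
    norm = float(np.linalg.norm(x))
    if norm > 0:
        x = x / norm
    return NodeMetricVector("KC", x)


def network_density(graph: TissueGraph | nx.Graph) -> float:
    """NED = 2m / (n(n-1)) for n > 1, else 0."""
    G = _as_nx(graph)
    n = G.number_of_nodes()
    if n <= 1:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def community_sizes(
    graph: TissueGraph | nx.Graph, community_method: str = "greedy_modularity"
) -> NodeMetricVector:
    """CS(v) = |community(v)| / n under greedy modularity maximization.

    A graph without edges partitions into singleton communities.
    """
    if community_method != "greedy_modularity":
        raise ValueError(f"unknown community_method {community_method!r}")
    G = _as_nx(graph)
    nodes = sorted(G.nodes)
    n = len(nodes)
    if G.number_of_edges() == 0:
        return NodeMetricVector("CS", np.full(n, 1.0 / n))
    communities = nx.algorithms.community.greedy_modularity_communities(G)
    size_of = {}
    for comm in communities:
        for v in comm:
            size_of[v] = len(comm)
    vals = np.array([size_of[v] / n for v in nodes], float)
    return NodeMetricVector("CS", vals)


def summarize_metric(
    values: NodeMetricVector | Sequence[float] | np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Histogram frequencies over the per-graph [min, max] range plus the
    five summary statistics; 10 + 5 = 15 values per metric by default.

    The last bin is right-closed (numpy convention) and frequencies sum
    to 1.  An all-equal input collapses to frequency 1 in bin 0 with a
    standard deviation of 0.  Standard deviation is the population form.
    """
    v = values.values if isinstance(values, NodeMetricVector) else np.asarray(values, float)
    if v.size == 0:
        raise ValueError("summarize_metric requires at least one value")
    lo, hi = float(np.min(v)), float(np.max(v))
    freqs = np.zeros(n_bins)
    # ranges at float-noise scale collapse to bin 0 like exact ties do
    if hi - lo > 1e-12 * max(1.0, abs(hi), abs(lo)):
        counts, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
        freqs = counts / v.size
    else:
        freqs[0] = 1.0
    stats = np.array([np.mean(v), np.std(v), hi, lo, np.median(v)])
    return np.concatenate([freqs, stats])


@dataclass
class SNAFeatureVector:
    """The ordered 91-value structural descriptor of one tissue graph.

    Layout: for each metric in [ND, CL, CC, DC, KC, CS], 10 histogram
    frequencies then mean, std, max, min, median; the final slot is NED.
    ``valid`` is False for empty graphs, whose vector is all zeros.
    """

    values: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"SNA feature vector must have length {N_FEATURES}")


def feature_names(n_bins: int = 10) -> list[str]:
    """Column names matching the fixed feature order (for CSV audit)."""
    names = []
    for m in METRIC_ORDER:
        names += [f"{m}_hist_{b}" for b in range(n_bins)]
        names += [f"{m}_{s}" for s in SUMMARY_NAMES]
    names.append("NED")
    return names


def extract_sna_features(
    graph: TissueGraph | nx.Graph, params: SNAParams | None = None
) -> SNAFeatureVector:
    """Compute the full 91-dimensional SNA feature vector of a graph.

    Empty graphs yield an all-zero vector flagged invalid.  The result is
    deterministic and invariant under node relabeling (all metrics depend
    only on graph structure, and histograms are order-free).
    """
    params = params or SNAParams()
    G = _as_nx(graph)
    if G.number_of_nodes() == 0:
        return SNAFeatureVector(np.zeros(N_FEATURES), valid=False)
    metrics = {
        "ND": node_degrees(G),
        "CL": clustering_coefficients(G),
        "CC": closeness_centralities(G),
        "DC": degree_centralities(G),
        "KC": katz_centralities(G, params.katz_alpha, params.katz_beta),
        "CS": community_sizes(G, params.community_method),
    }
    parts = [summarize_metric(metrics[m], params.n_bins) for m in METRIC_ORDER]
    parts.append(np.array([network_density(G)]))
    return SNAFeatureVector(np.concatenate(parts), valid=True)
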