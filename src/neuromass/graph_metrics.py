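"""Structural network measures on binary adjacency graphs.

Three measures of network integration are computed from the binarized
structural connectome (all formulas on the unweighted graph, consistent
with a binary adjacency matrix ``a_ij``):

- average degree centrality: ``k_i = sum_j a_ij``, averaged over nodes;
- average betweenness centrality:
  ``b_i = 2 / ((n-1)(n-2)) * sum_{h!=j, h,j!=i} p_hj(i) / p_hj`` with
  fractional counting over multiple shortest paths (``p_hj`` = number of
  shortest h–j paths, ``p_hj(i)`` = those passing through ``i``);
  node pairs with no connecting path contribute 0;
- global efficiency: ``E_i = sum_{j!=i} d_ij^{-1} / (n-1)`` averaged
  over nodes, where ``d_ij`` is the unweighted shortest-path length and
  disconnected pairs contribute ``d_ij^{-1} = 0``.  A complete graph has
  E = 1; partial disconnection lowers E.

Shortest-path machinery is delegated to networkx (Brandes betweenness,
BFS path lengths); fully lesioned (isolated) nodes stay in ``n``.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .connectome import AdjacencyGraph

__all__ = [
    "average_degree_centrality",
    "average_betweenness_centrality",
    "global_efficiency",
    "metrics_table",
]


def _to_nx(g: AdjacencyGraph) -> nx.Graph:
    G = nx.from_numpy_array(g.a)
    G.add_nodes_from(range(g.n))  # keep isolated nodes
    return G


def average_degree_centrality(g: AdjacencyGraph) -> tuple[float, np.ndarray]:
    """Mean node degree and the per-node degree vector ``k_i``."""
    k_i = g.a.sum(axis=1).astype(float)
    return float(k_i.mean()), k_i


def average_betweenness_centrality(g: AdjacencyGraph) -> tuple[float, np.ndarray]:
    """Normalized betweenness (factor 2/((n-1)(n-2))) and its mean.

    Requires n >= 3; the normalization is undefined below that.
    """
    if g.n < 3:
        raise ValueError("betweenness normalization needs at least 3 nodes")
    bc = nx.betweenness_centrality(_to_nx(g), normalized=True)
    b_i = np.array([bc[i] for i in range(g.n)])
    return float(b_i.mean()), b_i


def global_efficiency(g: AdjacencyGraph) -> tuple[float, np.ndarray]:
    """Average inverse shortest-path length, and per-node efficiencies.

    ``E_i = mean_j (1/d_ij)`` over the other ``n - 1`` nodes, with
    disconnected pairs contributing 0; ``E`` is the mean of ``E_i``.
    Equals 1 exactly for a complete graph.
    """
    if g.n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    G = _to_nx(g)
    e_i = np.zeros(g.n)
    for i in range(g.n):
        dists = nx.single_source_shortest_path_length(G, i)
        inv = sum(1.0 / d for node, d in dists.items() if node != i and d > 0)
        e_i[i] = inv / (g.n - 1)
    return float(e_i.mean()), e_i


def metrics_table(cohort) -> pd.DataFrame:
    """One row per subject: group, fitted parameters, and the three
    graph metrics of the binarized connectome.

    ``cohort`` is a list of ``(AdjacencyGraph-yielding connectome info)``
    tuples ``(connectome, graph, fitted)`` where ``fitted`` may be None
    (metrics-only tables).  Rows are sorted by subject id; duplicate ids
    are rejected.
    """
    rows = []
    seen = set()
    for connectome, graph, fitted in cohort:
        sid = connectome.subject_id
        if sid in seen:
            raise ValueError(f"duplicate subject id {sid!r}")
        seen.add(sid)
        k_av, _ = average_degree_centrality(graph)
        b_av, _ = average_betweenness_centrality(graph)
        e, _ = global_efficiency(graph)
        rows.append({
            "subject_id": sid,
            "group": connectome.group_label,
            "G": fitted.G if fitted else np.nan,
            "v": fitted.v if fitted else np.nan,
            "K11": fitted.K11 if fitted else np.nan,
            "K12": fitted.K12 if fitted else np.nan,
            "K21": fitted.K21 if fitted else np.nan,
            "degree_centrality": k_av,
            "betweenness_centrality": b_av,
            "global_efficiency": e,
        })
    if not rows:
        raise ValueError("empty cohort")
    return pd.DataFrame(rows).sort_values("subject_id").reset_index(drop=True)
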