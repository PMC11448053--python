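"""Microbe-metabolite co-occurrence networks and two-state rewiring.

Networks connect microbe and metabolite features whose correlation clears a
magnitude threshold (default 0.75, inclusive). Rewiring between two states
(e.g. placebo vs treatment networks) is quantified by Jaccard overlap of
node and edge sets and a DyNet-style per-node Dn score: with binary
adjacency rows a1, a2 over the union node set and centroid (a1 + a2)/2,

    Dn(i) = ||a1 - c|| + ||a2 - c|| = sqrt(|N1(i) ^ N2(i)|)

(the symmetric difference of i's neighborhoods), zero iff the neighborhoods
are identical; the degree-corrected variant divides by the union degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import LedoitWolf

__all__ = [
    "BipartiteNetwork",
    "pairwise_correlation",
    "build_network",
    "network_overlap",
    "dn_rewiring",
    "write_edge_list",
    "read_edge_list",
]


@dataclass
class BipartiteNetwork:
    node_types: dict[str, str]  # node -> "microbe" | "metabolite"
    edges: dict[frozenset, float]  # unordered pair -> correlation weight
    threshold: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair in self.edges:
            for node in pair:
                if node not in self.node_types:
                    raise ValueError(f"edge references unknown node {node!r}")

    @property
    def nodes(self) -> set[str]:
        return set(self.node_types)

    @property
    def edge_set(self) -> set[frozenset]:
        return set(self.edges)

    def neighbors(self, node: str) -> set[str]:
        return {next(iter(pair - {node})) for pair in self.edges if node in pair}

    def degree(self, node: str) -> int:
        return len(self.neighbors(node))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node, t in self.node_types.items():
            g.add_node(node, bipartite=t)
        for pair, w in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, weight=w)
        return g


def pairwise_correlation(
    x: pd.DataFrame,
    y: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Microbe x metabolite correlation matrix over matched sample columns.

    ``pearson``: plain cross-correlation of rows. ``shrinkage_partial``:
    partial correlations from the inverse of a Ledoit-Wolf shrunk joint
    covariance of the stacked [X; Y] variables, reported for cross pairs only
    (a shrinkage stand-in for debiased sparse partial correlation; recorded
    as such in the result attrs). Constant rows yield NaN and are listed in
    ``attrs['constant']``.
    """
    common = [s for s in x.columns if s in set(y.columns)]
    if len(common) < 4:
        raise ValueError("need at least 4 matched samples")
    xv = x[common].to_numpy(dtype=float)
    yv = y[common].to_numpy(dtype=float)
    const_x = [f for f, v in zip(x.index, xv) if np.ptp(v) == 0]
    const_y = [f for f, v in zip(y.index, yv) if np.ptp(v) == 0]
    if method == "pearson":
        xs = (xv - xv.mean(axis=1, keepdims=True))
        ys = (yv - yv.mean(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            xs /= np.linalg.norm(xs, axis=1, keepdims=True)
            ys /= np.linalg.norm(ys, axis=1, keepdims=True)
            corr = xs @ ys.T
        out = pd.DataFrame(corr, index=x.index, columns=y.index)
    elif method == "shrinkage_partial":
        z = np.vstack([xv, yv]).T  # samples x variables
        keep = np.ptp(z, axis=0) > 0
        lw = LedoitWolf().fit(z[:, keep])
        prec = lw.precision_
        d = np.sqrt(np.diag(prec))
        partial = -prec / np.outer(d, d)
        np.fill_diagonal(partial, 1.0)
        full = np.full((z.shape[1], z.shape[1]), np.nan)
        idx = np.where(keep)[0]
        full[np.ix_(idx, idx)] = partial
        nx_ = x.shape[0]
        out = pd.DataFrame(full[:nx_, nx_:], index=x.index, columns=y.index)
        out.attrs["estimator"] = (
            "Ledoit-Wolf shrinkage partial correlation "
            "(stand-in for debiased sparse partial correlation)"
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    out.attrs["n_samples"] = len(common)
    out.attrs["constant"] = {"microbes": const_x, "metabolites": const_y}
    if const_x or const_y:
        out.loc[const_x, :] = np.nan
        out.loc[:, const_y] = np.nan
    return out


def build_network(coefficients: pd.DataFrame, threshold: float = 0.75) -> BipartiteNetwork:
    """Threshold a microbe x metabolite coefficient matrix into a network.

    Edges keep every pair with threshold <= |coefficient| <= 1 (both ends
    inclusive); nodes are the endpoints of retained edges only.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    vals = coefficients.to_numpy(dtype=float)
    node_types: dict[str, str] = {}
    edges: dict[frozenset, float] = {}
    with np.errstate(invalid="ignore"):
        mask = (np.abs(vals) >= threshold) & (np.abs(vals) <= 1.0 + 1e-12)
    for i, j in zip(*np.nonzero(mask)):
        m = str(coefficients.index[i])
        t = str(coefficients.columns[j])
        node_types[m] = "microbe"
        node_types[t] = "metabolite"
        edges[frozenset((m, t))] = float(vals[i, j])
    return BipartiteNetwork(node_types, edges, threshold)


@dataclass
class RewiringReport:
    shared_node_fraction: float
    shared_edge_fraction: float
    rewired_fraction: float
    n_nodes: tuple[int, int]
    n_edges: tuple[int, int]
    counts: dict = field(default_factory=dict)


def network_overlap(a: BipartiteNetwork, b: BipartiteNetwork) -> RewiringReport:
    """Jaccard overlap of node and edge sets between two network states."""
    if not a.nodes and not b.nodes:
        raise ValueError("both networks are empty")
    node_union = a.nodes | b.nodes
    node_inter = a.nodes & b.nodes
    edge_union = a.edge_set | b.edge_set
    edge_inter = a.edge_set & b.edge_set
    node_frac = len(node_inter) / len(node_union)
    edge_frac = len(edge_inter) / len(edge_union) if edge_union else 1.0
    return RewiringReport(
        shared_node_fraction=node_frac,
        shared_edge_fraction=edge_frac,
        rewired_fraction=1.0 - edge_frac,
        n_nodes=(len(a.nodes), len(b.nodes)),
        n_edges=(len(a.edge_set), len(b.edge_set)),
        counts={
            "shared_nodes": len(node_inter),
            "union_nodes": len(node_union),
            "shared_edges": len(edge_inter),
            "union_edges": len(edge_union),
        },
    )


def dn_rewiring(
    a: BipartiteNetwork,
    b: BipartiteNetwork,
    nodes: list[str] | None = None,
    allow_absent: bool = False,
) -> pd.DataFrame:
    """Per-node DyNet-style rewiring scores between two states.

    By default scores are computed for the union node set (a node absent from
    one state has an all-zero adjacency row there). Requesting a node absent
    from both states is an error unless ``allow_absent`` is set, in which case
    its Dn is 0 by the identical-(empty)-neighborhood convention. Columns:
    ``dn`` and ``degree_corrected_dn`` (dn / union degree).
    """
    union = sorted(a.nodes | b.nodes)
    if nodes is None:
        nodes = union
    else:
        absent = [n for n in nodes if n not in set(union)]
        if absent and not allow_absent:
            raise ValueError(f"node(s) absent from both states: {absent[:5]}")
        nodes = list(nodes)
    rows = []
    for node in nodes:
        n1 = a.neighbors(node) if node in a.nodes else set()
        n2 = b.neighbors(node) if node in b.nodes else set()
        sym = n1 ^ n2
        dn = float(np.sqrt(len(sym)))
        union_deg = len(n1 | n2)
        rows.append(
            {
                "node": node,
                "dn": dn,
                "degree_corrected_dn": dn / union_deg if union_deg else 0.0,
                "union_degree": union_deg,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def write_edge_list(network: BipartiteNetwork, path: str | Path) -> None:
    """Serialize a network as TSV (source, target, weight, source_type,
    target_type), one row per edge in stable lexicographic order."""
    rows = []
    for pair, w in network.edges.items():
        s, t = sorted(pair)
        rows.append((s, t, w, network.node_types[s], network.node_types[t]))
    rows.sort()
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "source_type", "target_type"])
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, threshold: float | None = None) -> BipartiteNetwork:
    df = pd.read_csv(path, sep="\t")
    node_types: dict[str, str] = {}
    edges: dict[frozenset, float] = {}
    for row in df.itertuples(index=False):
        node_types[str(row.source)] = str(row.source_type)
        node_types[str(row.target)] = str(row.target_type)
        edges[frozenset((str(row.source), str(row.target)))] = float(row.weight)
    return BipartiteNetwork(node_types, edges, threshold)
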