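"""Module-eigengene correlation networks across omics layers.

Module detection itself (co-expression clustering) is an upstream input: this
module takes feature -> module assignments, summarizes each module by its
eigengene (first principal component of the standardized member features),
links eigengenes across omics kinds by Spearman correlation with an absolute
threshold (default 0.3), and contrasts patient-subgroup networks against their
matched reference as correlation differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import OmicsMatrix


@dataclass
class ModuleAssignment:
    """feature id -> module label for one omics kind ("unassigned" allowed)."""

    mapping: dict[str, str]
    kind: str = "combined"

    def members(self, module: str) -> list[str]:
        return [f for f, m in self.mapping.items() if m == module]

    @property
    def modules(self) -> list[str]:
        seen = dict.fromkeys(self.mapping.values())
        return [m for m in seen if m != "unassigned"]


@dataclass
class EigengeneMatrix:
    """sample x module eigengene values with per-module variance explained."""

    data: pd.DataFrame
    variance_explained: pd.Series
    kind: str = "combined"
    module_sizes: dict[str, int] = field(default_factory=dict)


@dataclass
class NetworkEdge:
    node1: str
    node2: str
    rho: float
    p: float
    p_adj: float


@dataclass
class CorrelationNetwork:
    """Thresholded Spearman network over module eigengenes."""

    nodes: list[str]
    edges: list[NetworkEdge]
    threshold: float
    rho_matrix: pd.DataFrame          # full pre-threshold correlations
    degree: dict[str, int] = field(default_factory=dict)
    betweenness: dict[str, float] = field(default_factory=dict)

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"node1": e.node1, "node2": e.node2, "rho": e.rho, "p": e.p, "p_adj": e.p_adj}
                for e in self.edges
            ]
        )

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.node1, e.node2, rho=e.rho, p=e.p, p_adj=e.p_adj)
        nx.write_graphml(g, path)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def module_eigengene(X: OmicsMatrix, assignment: ModuleAssignment) -> EigengeneMatrix:
    """First principal component of each module's standardized features.

    Eigengenes are scaled to unit variance and sign-fixed so the mean
    correlation with member features is non-negative.  Singleton modules pass
    through as their standardized feature.  Variance explained is the leading
    eigenvalue's share of the module's total variance.
    """
    cols, ve, sizes = {}, {}, {}
    for module in assignment.modules:
        members = [f for f in assignment.members(module) if f in X.data.columns]
        if not members:
            raise ValueError(f"module {module!r} has no features in the matrix")
        Z = _zscore(X.data[members].to_numpy())
        if len(members) == 1:
            eig = Z[:, 0]
            ve[module] = 1.0
        else:
            U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
            eig = U[:, 0] * S[0]
            ve[module] = float(S[0] ** 2 / (S**2).sum())
        sd = eig.std()
        if sd > 0:
            eig = eig / sd
        corr = np.array([np.corrcoef(eig, Z[:, j])[0, 1] for j in range(Z.shape[1])])
        if np.nanmean(corr) < 0:
            eig = -eig
        cols[module] = eig
        sizes[module] = len(members)
    return EigengeneMatrix(
        data=pd.DataFrame(cols, index=X.sample_ids),
        variance_explained=pd.Series(ve),
        kind=X.kind,
        module_sizes=sizes,
    )


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (n - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def correlation_network(
    eigengenes: Sequence[EigengeneMatrix], threshold: float = 0.3
) -> CorrelationNetwork:
    """All pairwise Spearman correlations on shared samples; edges at |rho| >=
    threshold (inclusive).  Node names are kind-prefixed; degree and
    betweenness centrality are computed on the thresholded graph.  P-values are
    reported per edge family with Holm adjustment (metadata only — the edge
    rule is the |rho| threshold).
    """
    frames = []
    for em in eigengenes:
        df = em.data.copy()
        df.columns = [f"{em.kind}:{c}" for c in df.columns]
        frames.append(df)
    shared = frames[0].index
    for df in frames[1:]:
        shared = shared.intersection(df.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need >= 3")
    M = pd.concat([df.loc[shared] for df in frames], axis=1)

    nodes = list(M.columns)
    k = len(nodes)
    rho = np.eye(k)
    pvals = {}
    raw = []
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            r, p = spearmanr(M.iloc[:, i], M.iloc[:, j])
            rho[i, j] = rho[j, i] = r
            pairs.append((i, j))
            raw.append(p)
    p_adj = _holm(np.asarray(raw)) if raw else np.array([])

    edges = []
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for (i, j), p, pa in zip(pairs, raw, p_adj):
        if abs(rho[i, j]) >= threshold:
            edges.append(NetworkEdge(nodes[i], nodes[j], float(rho[i, j]), float(p), float(pa)))
            g.add_edge(nodes[i], nodes[j])
    return CorrelationNetwork(
        nodes=nodes,
        edges=edges,
        threshold=threshold,
        rho_matrix=pd.DataFrame(rho, index=nodes, columns=nodes),
        degree=dict(g.degree()),
        betweenness=nx.betweenness_centrality(g),
    )


def differential_network(
    net_subgroup: CorrelationNetwork,
    net_reference: CorrelationNetwork,
    delta_threshold: float = 0.3,
) -> pd.DataFrame:
    """Edge table of correlation differences subgroup - reference.

    Differences are taken on the full pre-threshold correlation matrices;
    pairs with |delta rho| >= ``delta_threshold`` are reported and flagged as
    increased, decreased, or reversed (sign flip with both |rho| >= the base
    threshold).
    """
    a, b = set(net_subgroup.nodes), set(net_reference.nodes)
    if a != b:
        raise ValueError(f"node sets differ: {sorted(a ^ b)}")
    nodes = net_subgroup.nodes
    R1 = net_subgroup.rho_matrix.loc[nodes, nodes].to_numpy()
    R0 = net_reference.rho_matrix.loc[nodes, nodes].to_numpy()
    rows = []
    thr = net_reference.threshold
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            d = R1[i, j] - R0[i, j]
            if abs(d) >= delta_threshold:
                if (
                    np.sign(R1[i, j]) * np.sign(R0[i, j]) < 0
                    and abs(R1[i, j]) >= thr
                    and abs(R0[i, j]) >= thr
                ):
                    change = "reversed"
                else:
                    change = "increased" if d > 0 else "decreased"
                rows.append(
                    {
                        "node1": nodes[i],
                        "node2": nodes[j],
                        "rho_subgroup": R1[i, j],
                        "rho_reference": R0[i, j],
                        "delta_rho": d,
                        "change": change,
                    }
                )
    return pd.DataFrame(
        rows, columns=["node1", "node2", "rho_subgroup", "rho_reference", "delta_rho", "change"]
    )
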