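"""Graph data model, I/O, normalizations, centralities, distances, modularity and ranking.

The gene/protein interaction network is a simple undirected graph over opaque
string node ids, held as an ordered node list plus a sparse symmetric 0/1
adjacency matrix.  All prioritization algorithms in this package consume this
container (or its heterogeneous extension :class:`HeteroNetwork`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "HeteroNetwork",
    "SeedSet",
    "Scores",
    "RankTable",
    "ModularityResult",
    "load_edge_list",
    "load_seed_list",
    "column_normalize",
    "symmetric_normalize",
    "centrality_profile",
    "pairwise_seed_distance",
    "two_community_modularity",
    "rank_scores",
    "degree_baseline",
]


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass(frozen=True)
class Network:
    """Simple undirected graph: ordered node ids + sparse symmetric 0/1 adjacency.

    Invariants: the adjacency is symmetric with zero diagonal, degrees are its
    row sums, and ``m`` counts each undirected edge once.
    """

    nodes: tuple[str, ...]
    adjacency: sp.csr_array
    node_index: dict[str, int] = field(repr=False)

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "Network":
        """Build from an iterable of (u, v) pairs; self-loops and duplicates collapse."""
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
        return cls.from_networkx(g)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        g = nx.Graph(g)  # drop multi/directed structure if any
        g.remove_edges_from(nx.selfloop_edges(g))
        node_list = tuple(sorted(g.nodes, key=str))
        adj = nx.to_scipy_sparse_array(g, nodelist=list(node_list), dtype=np.float64, format="csr")
        adj = sp.csr_array(adj)
        return cls(nodes=node_list, adjacency=adj, node_index={v: i for i, v in enumerate(node_list)})

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def m(self) -> int:
        return int(round(self.adjacency.sum() / 2))

    def to_networkx(self) -> nx.Graph:
        g = nx.from_scipy_sparse_array(self.adjacency)
        return nx.relabel_nodes(g, dict(enumerate(self.nodes)))

    def indices_of(self, ids) -> np.ndarray:
        missing = [i for i in ids if i not in self.node_index]
        if missing:
            raise KeyError(f"node ids not in network: {missing}")
        return np.array([self.node_index[i] for i in ids], dtype=np.intp)

    def largest_component(self) -> "Network":
        n_comp, labels = sp.csgraph.connected_components(self.adjacency, directed=False)
        if n_comp <= 1:
            return self
        keep = labels == np.bincount(labels).argmax()
        sub = self.adjacency[keep][:, keep]
        node_list = tuple(v for v, k in zip(self.nodes, keep) if k)
        return Network(node_list, sp.csr_array(sub), {v: i for i, v in enumerate(node_list)})


@dataclass(frozen=True)
class HeteroNetwork:
    """Gene network plus gene-disease association and disease-similarity layers.

    ``expanded`` stacks the layers into one symmetric block matrix::

        [ A      A_PD ]
        [ A_PD'  A_DD ]

    so that propagation and embedding methods can treat the heterogeneous
    network as a single graph.
    """

    gene_net: Network
    disease_ids: tuple[str, ...]
    gda: sp.csr_array  # n_genes x n_diseases, 0/1
    dsim: sp.csr_array  # n_diseases x n_diseases, 0/1 symmetric, zero diagonal

    def __post_init__(self):
        n, d = self.gene_net.n, len(self.disease_ids)
        if self.gda.shape != (n, d):
            raise ValueError(f"gda shape {self.gda.shape} != ({n}, {d})")
        if self.dsim.shape != (d, d):
            raise ValueError(f"dsim shape {self.dsim.shape} != ({d}, {d})")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def expanded(self) -> sp.csr_array:
        return sp.csr_array(
            sp.bmat(
                [[self.gene_net.adjacency, self.gda], [self.gda.T, self.dsim]],
                format="csr",
            )
        )

    def disease_index(self, disease: str) -> int:
        try:
            return self.disease_ids.index(disease)
        except ValueError:
            raise KeyError(f"disease id not in network: {disease!r}") from None

    def expanded_network(self) -> Network:
        """The expanded adjacency viewed as a plain :class:`Network` (gene + disease nodes)."""
        node_list = self.gene_net.nodes + self.disease_ids
        return Network(node_list, self.expanded, {v: i for i, v in enumerate(node_list)})

    def without_association(self, gene: str, disease: str) -> "HeteroNetwork":
        """Copy with one gene-disease edge removed (used to avoid LOOCV leakage)."""
        gi = self.gene_net.node_index[gene]
        di = self.disease_index(disease)
        gda = self.gda.tolil(copy=True)
        gda[gi, di] = 0
        return HeteroNetwork(self.gene_net, self.disease_ids, sp.csr_array(gda.tocsr()), self.dsim)


@dataclass(frozen=True)
class SeedSet:
    """Non-empty, duplicate-free set of known disease genes present in the network."""

    ids: tuple[str, ...]

    @classmethod
    def create(cls, ids, net: Network) -> "SeedSet":
        ids = tuple(dict.fromkeys(ids))  # dedupe, keep order
        if not ids:
            raise ValueError("seed set is empty")
        net.indices_of(ids)  # raises on missing
        return cls(ids)

    def __len__(self) -> int:
        return len(self.ids)

    def without(self, gene: str) -> "SeedSet":
        rest = tuple(i for i in self.ids if i != gene)
        if not rest:
            raise ValueError("removing the gene leaves an empty seed set")
        return SeedSet(rest)


@dataclass(frozen=True)
class Scores:
    """Per-gene prioritization scores. ``higher_is_better`` fixes the ranking direction."""

    values: pd.Series
    higher_is_better: bool = True

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate node ids in score vector")


@dataclass(frozen=True)
class RankTable:
    """Tie-aware ranks (1 = best; ties get the average of the spanned positions)."""

    ranks: pd.Series

    @property
    def n_ranked(self) -> int:
        return int(self.ranks.notna().sum())

    def rank_of(self, gene: str) -> float:
        return float(self.ranks.loc[gene])

    def top(self, k: int) -> list[str]:
        return list(self.ranks.sort_values().index[:k])


@dataclass(frozen=True)
class ModularityResult:
    Q: float
    membership: np.ndarray  # +/-1 per node; -1 marks the pathway community
    modularity_matrix: np.ndarray


def load_edge_list(path, score_threshold: float | None = None) -> Network:
    """Read a TSV edge list (``source  target  [score]``; ``#`` comments ignored).

    Edges whose score falls below ``score_threshold`` are dropped (e.g. the
    STRING-style confidence cut-off).  Self-loops and duplicate edges collapse
    to a simple undirected graph.
    """
    edges = []
    has_score = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeListError(f"{path}: malformed edge on line {lineno}: {line!r}")
            u, v = parts[0].strip(), parts[1].strip()
            score = None
            if len(parts) >= 3 and parts[2].strip():
                try:
                    score = float(parts[2])
                except ValueError:
                    raise EdgeListError(
                        f"{path}: non-numeric score on line {lineno}: {parts[2]!r}"
                    ) from None
                has_score = True
            edges.append((u, v, score))
    if score_threshold is not None:
        if not has_score:
            raise EdgeListError(f"{path}: score threshold given but file has no score column")
        edges = [e for e in edges if e[2] is not None and e[2] >= score_threshold]
    if not edges:
        raise EdgeListError(f"{path}: no edges remain after filtering")
    net = Network.from_edges((u, v) for u, v, _ in edges)
    if net.m == 0:
        raise EdgeListError(f"{path}: no edges remain after filtering")
    logger.info("loaded %s: %d nodes, %d edges", path, net.n, net.m)
    return net


def _read_scored_pairs(path, score_threshold=None):
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise EdgeListError(f"{path}: malformed line {lineno}: {line!r}")
            score = float(parts[2]) if len(parts) >= 3 and parts[2].strip() else None
            if score_threshold is not None and (score is None or score < score_threshold):
                continue
            pairs.append((parts[0].strip(), parts[1].strip()))
    return pairs


def load_hetero_network(
    net: Network,
    gda_path,
    dsim_path=None,
    gda_threshold: float | None = None,
    dsim_threshold: float | None = None,
) -> HeteroNetwork:
    """Assemble a heterogeneous network from gene-disease and disease-disease edge lists.

    ``gda_path`` rows are ``gene  disease  [score]``; ``dsim_path`` rows are
    ``disease  disease  [score]``.  Gene ids absent from the gene network are
    skipped with a log message; disease ids are the union of both files.
    """
    gda_pairs = _read_scored_pairs(gda_path, gda_threshold)
    dsim_pairs = _read_scored_pairs(dsim_path, dsim_threshold) if dsim_path else []
    diseases = sorted({d for _, d in gda_pairs} | {d for p in dsim_pairs for d in p})
    d_index = {d: i for i, d in enumerate(diseases)}
    gda = sp.lil_array((net.n, len(diseases)))
    n_skipped = 0
    for gene, dis in gda_pairs:
        gi = net.node_index.get(gene)
        if gi is None:
            n_skipped += 1
            continue
        gda[gi, d_index[dis]] = 1.0
    if n_skipped:
        logger.info("load_hetero_network: skipped %d association(s) with unknown genes", n_skipped)
    dsim = sp.lil_array((len(diseases), len(diseases)))
    for d1, d2 in dsim_pairs:
        if d1 != d2:
            dsim[d_index[d1], d_index[d2]] = 1.0
            dsim[d_index[d2], d_index[d1]] = 1.0
    return HeteroNetwork(
        gene_net=net,
        disease_ids=tuple(diseases),
        gda=sp.csr_array(gda.tocsr()),
        dsim=sp.csr_array(dsim.tocsr()),
    )


def load_seed_list(path, net: Network) -> SeedSet:
    """Read a seed-gene list (one id per line, ``#`` comments ignored)."""
    with open(path) as fh:
        ids = [ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    return SeedSet.create(ids, net)


def column_normalize(net_or_adj) -> sp.csr_array:
    """Column-stochastic transition matrix W = A D_k^-1.

    Columns of zero-degree nodes stay all-zero (logged); every other column
    sums to one.
    """
    adj = net_or_adj.adjacency if isinstance(net_or_adj, Network) else sp.csr_array(net_or_adj)
    deg = np.asarray(adj.sum(axis=0)).ravel()
    n_dangling = int((deg == 0).sum())
    if n_dangling:
        logger.info("column_normalize: %d zero-degree column(s) left all-zero", n_dangling)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float), where=deg > 0)
    return sp.csr_array(adj.multiply(inv[np.newaxis, :]))


def symmetric_normalize(adjacency) -> sp.csr_array:
    """Symmetric normalization K^{-1/2} A K^{-1/2}; zero-degree rows/cols stay zero."""
    adj = sp.csr_array(adjacency, dtype=float)
    asym = abs(adj - adj.T)
    if asym.nnz and asym.max() > 1e-12:
        raise ValueError("symmetric_normalize: input matrix is not symmetric")
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg, dtype=float), where=deg > 0)
    return sp.csr_array(adj.multiply(inv_sqrt[:, np.newaxis]).multiply(inv_sqrt[np.newaxis, :]))


def centrality_profile(net: Network, ids) -> pd.DataFrame:
    """Degree/eigenvector/betweenness/closeness centralities and clustering coefficient.

    Degree centrality is k/(n-1).  Betweenness and closeness are computed on
    the largest connected component.  Two summary rows ("graph median",
    "graph mean") aggregate over all nodes of the graph.
    """
    net.indices_of(ids)
    g = net.to_networkx()
    lcc_nodes = max(nx.connected_components(g), key=len) if g.number_of_edges() else set(g)
    g_lcc = g.subgraph(lcc_nodes)
    metrics = {
        "degree_centrality": nx.degree_centrality(g),
        "eigenvector_centrality": nx.eigenvector_centrality_numpy(g_lcc),
        "betweenness_centrality": nx.betweenness_centrality(g_lcc, normalized=True),
        "closeness_centrality": nx.closeness_centrality(g_lcc),
        "clustering_coefficient": nx.clustering(g),
    }
    df = pd.DataFrame(metrics)
    rows = df.loc[list(ids)]
    summary = pd.DataFrame(
        [df.median(), df.mean()], index=["graph median", "graph mean"]
    )
    return pd.concat([rows, summary])


def pairwise_seed_distance(net: Network, seeds: SeedSet, metric: str = "shortest_path",
                           r: float | None = None) -> pd.DataFrame:
    """Seed-by-seed distance (geodesic) or affinity (converged restart-walk probability).

    The restart-walk ("rwr") matrix need not be symmetric: entry (i, j) is the
    converged probability at j of a walk restarted at {i}.
    """
    idx = net.indices_of(seeds.ids)
    if metric == "shortest_path":
        dist = sp.csgraph.shortest_path(net.adjacency, method="D", unweighted=True, indices=idx)
        mat = dist[:, idx]
    elif metric == "rwr":
        if r is None:
            raise ValueError("rwr metric requires a restart probability r")
        from .propagation import RWRParams, rwr

        mat = np.empty((len(idx), len(idx)))
        for a, sid in enumerate(seeds.ids):
            scores = rwr(net, SeedSet((sid,)), RWRParams(restart=r))
            mat[a] = scores.values.loc[list(seeds.ids)].to_numpy()
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return pd.DataFrame(mat, index=list(seeds.ids), columns=list(seeds.ids))


def modularity_matrix(net: Network, standard_diagonal: bool = False) -> np.ndarray:
    """B_ij = A_ij - k_i k_j / (2m), with the diagonal zeroed unless ``standard_diagonal``."""
    k = net.degree
    m = net.m
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    B = net.adjacency.toarray() - np.outer(k, k) / (2.0 * m)
    if not standard_diagonal:
        np.fill_diagonal(B, 0.0)
    return B


def two_community_modularity(net: Network, pathway, standard_diagonal: bool = False) -> ModularityResult:
    """Modularity of the bipartition {pathway, rest}: Q = s'Bs / (4m).

    Membership s_i is -1 inside the pathway and +1 outside, so Q is invariant
    under complementing the pathway.  By default the modularity matrix has a
    zeroed diagonal; ``standard_diagonal=True`` keeps the Newman form
    ``A_ii - k_i^2/(2m)`` on the diagonal.
    """
    idx = net.indices_of(pathway)
    s = np.ones(net.n)
    s[idx] = -1.0
    B = modularity_matrix(net, standard_diagonal=standard_diagonal)
    Q = float(s @ B @ s) / (4.0 * net.m)
    return ModularityResult(Q=Q, membership=s, modularity_matrix=B)


def rank_scores(scores: Scores, exclude=None) -> RankTable:
    """Tie-aware ranking of a score vector; excluded ids are removed before ranking."""
    vals = scores.values
    if vals.isna().any():
        bad = list(vals.index[vals.isna()])
        raise ValueError(f"NaN scores for: {bad[:10]}")
    if exclude:
        vals = vals.drop(index=[i for i in exclude if i in vals.index])
    ranks = vals.rank(ascending=not scores.higher_is_better, method="average")
    return RankTable(ranks=ranks)


def degree_baseline(net: Network) -> Scores:
    """Seed-independent baseline: score each gene by its degree."""
    return Scores(pd.Series(net.degree, index=list(net.nodes), dtype=float))
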