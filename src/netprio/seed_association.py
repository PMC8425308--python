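"""Seed-association heuristics: hypergeometric module growth and degree-adjusted distance.

The module-growth algorithm (DIAMOnD) repeatedly absorbs the candidate node
whose number of links into the current seed set is least likely under a
hypergeometric null, ranking nodes by the step at which they are absorbed.
GenePanda scores each gene by how much closer it sits to the seed genes than
to the network at large, under a degree-adjusted geodesic distance
d_adj(i, j) = d_ij / sqrt(k_i k_j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .network import Network, Scores, SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "DiamondState",
    "connectivity_p",
    "diamond",
    "adjusted_distance_matrix",
    "genepanda",
]


@dataclass(frozen=True)
class DiamondState:
    """Outcome of the stepwise module growth.

    ``selection_order`` lists (node, step, p) in the order candidates were
    absorbed; a node's rank is its step.  Unselected nodes carry no rank
    ("na" in reports) unless a full ranking is forced, in which case they
    share averaged tail ranks.
    """

    original_seeds: tuple[str, ...]
    selection_order: tuple[tuple[str, int, float], ...]
    alpha: float
    max_steps: int

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(node for node, _, _ in self.selection_order)

    def rank_of(self, gene: str) -> float:
        """Selection-step rank, or NaN ("na") for genes never absorbed."""
        for node, step, _ in self.selection_order:
            if node == gene:
                return float(step)
        return float("nan")

    def full_ranks(self, universe) -> pd.Series:
        """Force a complete ranking: unselected genes share averaged tail ranks."""
        universe = [g for g in universe if g not in set(self.original_seeds)]
        ranks = pd.Series(np.nan, index=universe, dtype=float)
        for node, step, _ in self.selection_order:
            if node in ranks.index:
                ranks.loc[node] = float(step)
        unranked = ranks.index[ranks.isna()]
        if len(unranked):
            n_sel = int(ranks.notna().sum())
            tail_avg = n_sel + (len(unranked) + 1) / 2.0
            ranks.loc[unranked] = tail_avg
        return ranks


def connectivity_p(
    k: int,
    k_st: int,
    n_seeds: int,
    n: int,
    alpha: float = 1.0,
    k_s: int = 0,
    n_orig_seeds: int | None = None,
    tail: bool = False,
) -> float:
    """Probability that a degree-k node links to exactly k_st of the n_seeds seeds.

    The null draws the node's k link endpoints uniformly without replacement
    from the n network nodes, n_seeds of which are seeds — a hypergeometric
    point mass.  With ``alpha > 1`` links to the ``n_orig_seeds`` original
    seeds are weighted by inflating the counts: the seed pool becomes
    ``n_seeds + (alpha-1)*n_orig_seeds``, the node's seed links
    ``k_st + (alpha-1)*k_s``, and the population/draws inflate to match, so
    the weighted form is again a hypergeometric pmf and reduces to the plain
    one at alpha = 1.  ``tail=True`` returns the upper-tail sum P(X >= k_st)
    instead of the point mass.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if not 0 <= k_st <= min(k, n_seeds):
        raise ValueError(f"impossible arguments: k={k}, k_st={k_st}, n_seeds={n_seeds}")
    if n_seeds > n:
        raise ValueError("more seeds than network nodes")
    if n_orig_seeds is None:
        n_orig_seeds = n_seeds
    if not 0 <= k_s <= min(k_st, n_orig_seeds):
        raise ValueError(f"impossible arguments: k_s={k_s}, k_st={k_st}, |S|={n_orig_seeds}")
    w = int(round((alpha - 1) * n_orig_seeds))
    wk = int(round((alpha - 1) * k_s))
    M = n + w  # population
    K = n_seeds + w  # tagged (seed) pool
    N = k + wk  # draws
    x = k_st + wk
    if tail:
        return float(stats.hypergeom.sf(x - 1, M, K, N))
    return float(stats.hypergeom.pmf(x, M, K, N))


def diamond(
    net: Network,
    seeds: SeedSet,
    alpha: float = 1.0,
    max_steps: int = 5000,
    tail: bool = False,
) -> DiamondState:
    """Stepwise hypergeometric module growth from the seed genes.

    At each step the connectivity probability is evaluated for every non-seed
    node adjacent to the current module; the node with the lowest p is
    absorbed.  Ties break toward higher seed-connectivity ``k_st``, then
    lexicographically by node id (deterministic, logged).  Growth stops after
    ``max_steps`` selections or when no candidate touches the module.
    """
    n = net.n
    adj = net.adjacency
    idx_of = net.node_index
    degree = net.degree.astype(int)
    seed_idx = set(net.indices_of(seeds.ids).tolist())
    n_orig = len(seed_idx)

    # k_st / k_s: links of each node into the current/original seed set.
    k_st = np.zeros(n, dtype=int)
    for si in seed_idx:
        lo, hi = adj.indptr[si], adj.indptr[si + 1]
        k_st[adj.indices[lo:hi]] += 1
    k_s = k_st.copy()

    in_module = np.zeros(n, dtype=bool)
    in_module[list(seed_idx)] = True
    order: list[tuple[str, int, float]] = []
    for step in range(1, max_steps + 1):
        cand = np.flatnonzero(~in_module & (k_st > 0))
        if cand.size == 0:
            if step == 1:
                logger.warning("diamond: seeds have no non-seed neighbours; nothing selected")
            break
        n_mod = int(in_module.sum())
        # vectorized hypergeometric evaluation over all candidates at once
        w = int(round((alpha - 1) * n_orig))
        wk = np.rint((alpha - 1) * k_s[cand]).astype(int)
        x = k_st[cand] + wk
        M, K, N = n + w, n_mod + w, degree[cand] + wk
        if tail:
            p_all = stats.hypergeom.sf(x - 1, M, K, N)
        else:
            p_all = stats.hypergeom.pmf(x, M, K, N)
        tied = np.flatnonzero(p_all == p_all.min())
        if len(tied) > 1:  # break by higher seed connectivity, then node id
            tied = tied[k_st[cand[tied]] == k_st[cand[tied]].max()]
            if len(tied) > 1:
                tied = [min(tied, key=lambda i: net.nodes[cand[i]])]
                logger.debug("diamond step %d: tie broken lexicographically", step)
        sel = tied[0]
        chosen, p_chosen = int(cand[sel]), float(p_all[sel])
        order.append((net.nodes[chosen], step, p_chosen))
        in_module[chosen] = True
        lo, hi = adj.indptr[chosen], adj.indptr[chosen + 1]
        k_st[adj.indices[lo:hi]] += 1
    return DiamondState(
        original_seeds=tuple(seeds.ids),
        selection_order=tuple(order),
        alpha=alpha,
        max_steps=max_steps,
    )


def adjusted_distance_matrix(net: Network) -> np.ndarray:
    """All-pairs degree-adjusted distance d_ij / sqrt(k_i k_j).

    Geodesic lengths come from unweighted BFS; entries are inf across
    components and the diagonal is zero.
    """
    dist = sp.csgraph.shortest_path(net.adjacency, method="D", unweighted=True)
    k = net.degree
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = 1.0 / np.sqrt(np.outer(k, k))
    d_adj = dist * scale
    np.fill_diagonal(d_adj, 0.0)
    return d_adj


def genepanda(net: Network, seeds: SeedSet) -> Scores:
    """Distance-contrast score: mean adjusted distance to the network minus to the seeds.

    Higher scores mean the gene sits closer to the seed genes than to a
    typical gene.  Computed on the largest connected component; every seed
    must lie in it, and nodes outside it are left unranked.
    """
    lcc = net.largest_component()
    outside = [s for s in seeds.ids if s not in lcc.node_index]
    if outside:
        raise ValueError(f"seed genes outside the largest connected component: {outside}")
    d_adj = adjusted_distance_matrix(lcc)
    seed_idx = lcc.indices_of(seeds.ids)
    score = d_adj.mean(axis=1) - d_adj[:, seed_idx].mean(axis=1)
    return Scores(pd.Series(score, index=list(lcc.nodes)))
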