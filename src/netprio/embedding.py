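"""Node embedding by biased random walks + skip-gram, and max-cosine seed scoring.

Neighbourhoods are sampled with second-order ("node2vec") random walks whose
transition weights interpolate between breadth-first and depth-first
exploration: stepping back to the previous node is weighted 1/p, moving to a
common neighbour of the previous node 1, and moving further away 1/q.  The
walks are treated as sentences and fed to a skip-gram model with negative
sampling, trained by a single-threaded numba kernel so results are exactly
reproducible under a fixed seed.  A gene's prioritization score is its
maximum cosine similarity to any seed gene's vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .network import Network, Scores, SeedSet

logger = logging.getLogger(__name__)

__all__ = ["WalkParams", "EmbeddingModel", "sample_walks", "train_embedding", "n2v_score"]

NEG_TABLE_SIZE = 1_000_000
UNIGRAM_POWER = 0.75


@dataclass(frozen=True)
class WalkParams:
    """Walk-sampling hyperparameters.

    Defaults are the central grid point used for benchmarking: 20 walks of
    length 80 per node with unbiased second-order transitions (p = q = 1).
    The tuning grids are n_walks in (20, 40, 80), l_walks in (40, 80, 160)
    and p, q in (0.5, 1, 2).
    """

    n_walks: int = 20
    l_walks: int = 80
    p: float = 1.0
    q: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_walks < 1 or self.l_walks < 1:
            raise ValueError("n_walks and l_walks must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass(frozen=True)
class EmbeddingModel:
    """Per-node vectors (rows of ``vectors``, indexed by node id) plus training metadata."""

    vectors: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def to_tsv(self, path) -> None:
        """Persist as TSV ``node  v1..vd`` for reuse across runs."""
        self.vectors.to_csv(path, sep="\t", header=False)

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingModel":
        vectors = pd.read_csv(path, sep="\t", header=None, index_col=0)
        vectors.index.name = None
        vectors.columns = range(vectors.shape[1])
        return cls(vectors=vectors, metadata={"source": str(path)})


@numba.njit(cache=False)
def _contains(indices, lo, hi, x):  # binary search in a sorted CSR row slice
    while lo < hi:
        mid = (lo + hi) // 2
        if indices[mid] == x:
            return True
        if indices[mid] < x:
            lo = mid + 1
        else:
            hi = mid
    return False


@numba.njit(cache=False)
def _walk_kernel(indptr, indices, starts, n_walks, walk_len, p, q, seed):
    np.random.seed(seed)
    walks = np.full((starts.shape[0] * n_walks, walk_len), -1, dtype=np.int64)
    unbiased = p == 1.0 and q == 1.0
    row = 0
    for w in range(n_walks):
        for s_i in range(starts.shape[0]):
            cur = starts[s_i]
            prev = -1
            walks[row, 0] = cur
            for t in range(1, walk_len):
                lo, hi = indptr[cur], indptr[cur + 1]
                deg = hi - lo
                if deg == 0:
                    break  # dead end: terminate early
                if prev < 0 or unbiased:
                    nxt = indices[lo + np.random.randint(deg)]
                else:
                    total = 0.0
                    wts = np.empty(deg)
                    plo, phi = indptr[prev], indptr[prev + 1]
                    for j in range(deg):
                        nb = indices[lo + j]
                        if nb == prev:
                            wts[j] = 1.0 / p
                        elif _contains(indices, plo, phi, nb):
                            wts[j] = 1.0
                        else:
                            wts[j] = 1.0 / q
                        total += wts[j]
                    r = np.random.random() * total
                    acc = 0.0
                    jsel = deg - 1
                    for j in range(deg):
                        acc += wts[j]
                        if r <= acc:
                            jsel = j
                            break
                    nxt = indices[lo + jsel]
                walks[row, t] = nxt
                prev = cur
                cur = nxt
            row += 1
    return walks


def sample_walks(net: Network, params: WalkParams | None = None) -> list[list[str]]:
    """Sample ``n_walks`` biased random walks of ``l_walks`` nodes from every node.

    Zero-degree start nodes are skipped with a warning; walks that hit a dead
    end terminate early.  Byte-identical output under identical seeds.
    """
    params = params or WalkParams()
    if net.m == 0:
        raise ValueError("cannot sample walks on a graph with no edges")
    adj = net.adjacency.copy()
    adj.sort_indices()
    deg = net.degree
    starts = np.flatnonzero(deg > 0)
    skipped = net.n - starts.size
    if skipped:
        logger.warning("sample_walks: skipping %d zero-degree start node(s)", skipped)
    raw = _walk_kernel(
        adj.indptr.astype(np.int64),
        adj.indices.astype(np.int64),
        starts.astype(np.int64),
        params.n_walks,
        params.l_walks,
        float(params.p),
        float(params.q),
        params.rng_seed % (2**32),
    )
    nodes = net.nodes
    return [[nodes[i] for i in row if i >= 0] for row in raw]


@numba.njit(cache=False)
def _sgns_kernel(walks, vec_in, vec_out, window, negative, neg_table, lr0, epochs, seed):
    np.random.seed(seed)
    n_rows, L = walks.shape
    d = vec_in.shape[1]
    table_size = neg_table.shape[0]
    total_rows = epochs * n_rows
    done = 0
    for ep in range(epochs):
        for r in range(n_rows):
            lr = lr0 * (1.0 - done / total_rows)
            if lr < lr0 * 1e-4:
                lr = lr0 * 1e-4
            done += 1
            for i in range(L):
                center = walks[r, i]
                if center < 0:
                    break
                jlo = i - window if i - window > 0 else 0
                jhi = i + window + 1 if i + window + 1 < L else L
                for j in range(jlo, jhi):
                    ctx = walks[r, j]
                    if j == i or ctx < 0:
                        continue
                    # skip-gram pair (center -> ctx) with negative sampling
                    e = np.zeros(d)
                    for s in range(negative + 1):
                        if s == 0:
                            target = ctx
                            label = 1.0
                        else:
                            target = neg_table[np.random.randint(table_size)]
                            if target == ctx:
                                continue
                            label = 0.0
                        f = 0.0
                        for c in range(d):
                            f += vec_in[center, c] * vec_out[target, c]
                        if f > 8.0:
                            sig = 1.0
                        elif f < -8.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-f))
                        g = lr * (label - sig)
                        for c in range(d):
                            e[c] += g * vec_out[target, c]
                            vec_out[target, c] += g * vec_in[center, c]
                    for c in range(d):
                        vec_in[center, c] += e[c]


def _negative_table(counts: np.ndarray, size: int = NEG_TABLE_SIZE) -> np.ndarray:
    probs = counts.astype(np.float64) ** UNIGRAM_POWER
    probs /= probs.sum()
    boundaries = np.cumsum(probs) * size
    return np.searchsorted(boundaries, np.arange(size), side="right").astype(np.int64)


def train_embedding(
    walks: list[list[str]],
    d: int = 128,
    window: int = 10,
    epochs: int = 5,
    rng_seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.025,
    expected_nodes=None,
) -> EmbeddingModel:
    """Train a skip-gram negative-sampling embedding on walks-as-sentences.

    Deterministic for a fixed seed (single-threaded).  If ``expected_nodes``
    is given, every one of them must appear in at least one walk.
    """
    if not walks:
        raise ValueError("no walks supplied")
    vocab = sorted({node for walk in walks for node in walk})
    if expected_nodes is not None:
        missing = sorted(set(expected_nodes) - set(vocab))
        if missing:
            raise ValueError(f"nodes absent from all walks: {missing[:20]}")
    index = {v: i for i, v in enumerate(vocab)}
    max_len = max(len(w) for w in walks)
    mat = np.full((len(walks), max_len), -1, dtype=np.int64)
    counts = np.zeros(len(vocab), dtype=np.int64)
    for r, walk in enumerate(walks):
        for t, node in enumerate(walk):
            idx = index[node]
            mat[r, t] = idx
            counts[idx] += 1
    neg_table = _negative_table(counts)
    rng = np.random.default_rng(rng_seed)
    vec_in = ((rng.random((len(vocab), d)) - 0.5) / d).astype(np.float64)
    vec_out = np.zeros((len(vocab), d), dtype=np.float64)
    _sgns_kernel(
        mat, vec_in, vec_out, window, negative, neg_table,
        learning_rate, epochs, rng_seed % (2**32),
    )
    if not np.isfinite(vec_in).all():
        raise RuntimeError("embedding diverged: non-finite vectors (reduce learning rate)")
    vectors = pd.DataFrame(vec_in, index=vocab)
    meta = {
        "d": d, "window": window, "epochs": epochs, "negative": negative,
        "learning_rate": learning_rate, "rng_seed": rng_seed,
    }
    return EmbeddingModel(vectors=vectors, metadata=meta)


def n2v_score(model: EmbeddingModel, seeds: SeedSet) -> Scores:
    """Max cosine similarity of each embedded node to the seed gene vectors.

    Scores lie in [-1, 1]; seed genes score exactly 1 (self-similarity).
    """
    missing = [s for s in seeds.ids if s not in model.vectors.index]
    if missing:
        raise KeyError(f"seed genes missing from embedding: {missing}")
    V = model.vectors.to_numpy()
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        bad = list(model.vectors.index[norms == 0])
        raise ValueError(f"zero-norm embedding vectors: {bad[:10]}")
    unit = V / norms[:, None]
    seed_pos = model.vectors.index.get_indexer(list(seeds.ids))
    sims = unit @ unit[seed_pos].T
    scores = pd.Series(sims.max(axis=1), index=model.vectors.index)
    scores.loc[list(seeds.ids)] = 1.0  # self-similarity, exact by definition
    return Scores(scores)
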