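"""Synthetic desk-scale fixtures with known ground truth.

These generators emulate the shape of curated protein-gene interaction data
without any downloads: a scale-free (preferential-attachment) background
network with planted dense functional modules, a bipartite gene-disease
association layer with a designated query disease linked to the planted
module's seed genes, and GWAS-style SNP tables whose signal is enriched in
designated genes.  All randomness flows through one recorded seed, so every
fixture is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import HeteroNetwork, Network, SeedSet

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "generate_modular_network",
    "generate_hetero_fixture",
    "make_gene_regions",
    "generate_gwas_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic network family.

    The background is a preferential-attachment graph (``attach`` edges per
    new node), which reproduces the heavy-tailed degree distribution of real
    interaction networks; ``modules`` lists (size, within-module edge
    probability) pairs of planted Bernoulli-dense modules.
    """

    n_genes: int = 500
    attach: int = 3
    modules: tuple[tuple[int, float], ...] = ((30, 0.5),)
    n_diseases: int = 20
    gda_density: float = 0.01
    dsim_density: float = 0.1
    n_module_seeds: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        for size, p in self.modules:
            if size > self.n_genes:
                raise ValueError(f"module size {size} exceeds n_genes {self.n_genes}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"module edge probability {p} outside [0, 1]")
        if not 0.0 <= self.gda_density <= 1.0 or not 0.0 <= self.dsim_density <= 1.0:
            raise ValueError("densities must be in [0, 1]")
        if self.attach < 1 or self.attach >= self.n_genes:
            raise ValueError("attach must be in [1, n_genes)")


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _disease_id(i: int) -> str:
    return f"D{i:03d}"


def generate_modular_network(spec: FixtureSpec) -> tuple[Network, list[list[str]]]:
    """Scale-free background + planted dense modules; returns the module membership."""
    rng = np.random.default_rng(spec.rng_seed)
    g = nx.barabasi_albert_graph(spec.n_genes, spec.attach,
                                 seed=int(rng.integers(2**31)))
    members: list[list[str]] = []
    free = rng.permutation(spec.n_genes)
    cursor = 0
    for size, p_within in spec.modules:
        chosen = free[cursor:cursor + size]
        cursor += size
        if len(chosen) < size:
            raise ValueError("not enough distinct nodes for the requested modules")
        for a in range(size):
            for b in range(a + 1, size):
                if rng.random() < p_within:
                    g.add_edge(int(chosen[a]), int(chosen[b]))
        members.append(sorted(_gene_id(i) for i in chosen))
    g = nx.relabel_nodes(g, {i: _gene_id(i) for i in g.nodes})
    net = Network.from_networkx(g)
    logger.info("generated modular network: %d nodes, %d edges, %d module(s)",
                net.n, net.m, len(members))
    return net, members


def generate_hetero_fixture(spec: FixtureSpec) -> tuple[HeteroNetwork, str, SeedSet, list[list[str]]]:
    """Heterogeneous fixture: gene net + GDA and disease-similarity layers.

    A designated query disease (the last disease id) is associated in the GDA
    layer with ``n_module_seeds`` genes from the first planted module; those
    genes are returned as the seed set.
    """
    net, members = generate_modular_network(spec)
    rng = np.random.default_rng(spec.rng_seed + 1)
    d = spec.n_diseases + 1  # background diseases + the query disease
    disease_ids = tuple(_disease_id(i) for i in range(spec.n_diseases)) + ("QUERY",)
    gda = (rng.random((net.n, d - 1)) < spec.gda_density).astype(float)
    gda = np.hstack([gda, np.zeros((net.n, 1))])
    module = members[0]
    n_seeds = min(spec.n_module_seeds, len(module))
    seed_genes = sorted(rng.choice(module, size=n_seeds, replace=False).tolist())
    qcol = d - 1
    for gname in seed_genes:
        gda[net.node_index[gname], qcol] = 1.0
    dsim = (rng.random((d, d)) < spec.dsim_density).astype(float)
    dsim = np.triu(dsim, k=1)
    dsim = dsim + dsim.T
    dsim[qcol, :] = 0.0  # query disease similarity unknown a priori
    dsim[:, qcol] = 0.0
    hnet = HeteroNetwork(
        gene_net=net,
        disease_ids=disease_ids,
        gda=sp.csr_array(gda),
        dsim=sp.csr_array(dsim),
    )
    seeds = SeedSet.create(seed_genes, net)
    return hnet, "QUERY", seeds, members


def make_gene_regions(genes, rng_seed: int = 0, gene_length: int = 2000,
                      spacing: int = 10_000, per_chrom: int = 50) -> pd.DataFrame:
    """Lay genes on chromosomes as non-overlapping 1-based inclusive regions."""
    rows = []
    for i, gene in enumerate(genes):
        chrom = str(1 + i // per_chrom)
        start = 1 + (i % per_chrom) * spacing
        rows.append({"gene": gene, "chrom": chrom, "start": start,
                     "end": start + gene_length - 1})
    return pd.DataFrame(rows)


def generate_gwas_fixture(
    regions: pd.DataFrame,
    enriched_genes,
    n_snps_per_gene: int = 10,
    effect_p: float = 1e-8,
    rng_seed: int = 0,
    flank: int = 1000,
) -> pd.DataFrame:
    """GWAS-style SNP table: null p ~ U(0,1), enriched-gene p ~ U(0, effect_p).

    SNP positions fall uniformly within each gene's region +/- flank, so the
    downstream position-based SNP-to-gene mapping recovers the assignment.
    """
    enriched = set(enriched_genes)
    unknown = enriched - set(regions["gene"])
    if unknown:
        raise ValueError(f"enriched genes without regions: {sorted(unknown)}")
    rng = np.random.default_rng(rng_seed)
    rows = []
    snp_i = 0
    for row in regions.itertuples(index=False):
        for _ in range(n_snps_per_gene):
            pos = int(rng.integers(row.start - flank, row.end + flank + 1))
            if row.gene in enriched:
                p = float(rng.uniform(0.0, effect_p))
            else:
                p = float(rng.uniform(0.0, 1.0))
            rows.append({"snp": f"rs{snp_i:07d}", "chrom": str(row.chrom),
                         "pos": pos, "pvalue": p})
            snp_i += 1
    return pd.DataFrame(rows)
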