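"""Benchmarking harness: leave-one-out cross-validation, random-seed degree-bias
diagnostics and GWAS-based external validation.

LOOCV removes one seed gene at a time, reruns the prioritizer with the
remaining seeds and records the rank the left-out gene receives; the median
of those rediscovery ranks is the headline performance number.  On
heterogeneous networks the association edge between the query disease and the
left-out gene is also removed for the fold, so no information about the
held-out association leaks into the run.  Random-seed trials rerun an
algorithm with uniformly drawn seed sets to expose seed-independent (degree)
bias.  GWAS validation maps SNPs to the top-ranked genes, applies
Benjamini-Hochberg FDR control across the pooled SNPs and calls a gene
validated when a significant share of its SNPs passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import HeteroNetwork, Network, RankTable, SeedSet
from .prioritizers import Prioritizer

logger = logging.getLogger(__name__)

__all__ = [
    "LOOCVResult",
    "RandomSeedResult",
    "GWASValidationResult",
    "loocv",
    "random_seed_experiment",
    "degree_rank_association",
    "read_gene_regions",
    "read_gwas_table",
    "map_snps_to_genes",
    "gwas_validate",
    "confirmed_gene_metrics",
]


@dataclass(frozen=True)
class LOOCVResult:
    """Per-seed left-out ranks ("na" = NaN), with median/mean over available folds."""

    algorithm: str
    ranks: pd.Series  # index: seed gene, value: rank or NaN
    params: dict = field(default_factory=dict)

    @property
    def median(self) -> float:
        return float(self.ranks.median()) if self.ranks.notna().any() else float("nan")

    @property
    def mean(self) -> float:
        return float(self.ranks.mean()) if self.ranks.notna().any() else float("nan")

    @property
    def n_na(self) -> int:
        return int(self.ranks.isna().sum())

    @property
    def all_folds_ok(self) -> bool:
        return self.n_na == 0

    def to_frame(self) -> pd.DataFrame:
        rows = self.ranks.map(lambda r: "na" if pd.isna(r) else r)
        out = pd.concat([rows, pd.Series({"Median": self.median, "Mean": self.mean})])
        return out.to_frame(name=self.algorithm)


def loocv(
    prioritizer: Prioritizer,
    net: Network | HeteroNetwork,
    seeds: SeedSet,
    disease: str | None = None,
    exclude_remaining: bool = True,
    fold_hook=None,
) -> LOOCVResult:
    """Leave-one-out rediscovery ranks for a prioritizer on a (hetero)network.

    For each seed gene g the algorithm runs with the other seeds; on a
    heterogeneous network with a query disease, the (disease, g) association
    edge is additionally removed for the fold (the input network is never
    mutated).  Remaining seeds are excluded from the candidate ranking by
    default.  ``fold_hook(gene, fold_net)`` is called per fold, mainly for
    testing the leakage contract.
    """
    if len(seeds) < 2:
        raise ValueError("LOOCV needs at least 2 seed genes")
    hetero = isinstance(net, HeteroNetwork)
    if not hetero or disease is None:
        prioritizer.fit(net)
    ranks: dict[str, float] = {}
    any_failed = False
    for gene in seeds.ids:
        fold_seeds = seeds.without(gene)
        fold_net = net
        try:
            if hetero and disease is not None:
                fold_net = net.without_association(gene, disease)
                prioritizer.fit(fold_net)
            if fold_hook is not None:
                fold_hook(gene, fold_net)
            exclude = fold_seeds.ids if exclude_remaining else None
            table = prioritizer.rank(fold_seeds, disease, exclude=exclude)
            r = table.ranks.get(gene, np.nan)
            ranks[gene] = float(r) if pd.notna(r) else np.nan
        except Exception:
            logger.exception("loocv fold for %s failed; marked na", gene)
            ranks[gene] = np.nan
            any_failed = True
    result = LOOCVResult(
        algorithm=prioritizer.name,
        ranks=pd.Series(ranks, dtype=float),
        params={"exclude_remaining": exclude_remaining, "disease": disease,
                "partial_failure": any_failed},
    )
    logger.info("loocv %s: median=%.1f mean=%.1f na=%d",
                prioritizer.name, result.median, result.mean, result.n_na)
    return result


@dataclass(frozen=True)
class RandomSeedResult:
    """Rank matrix (trial x node) and per-node medians from random-seed trials."""

    algorithm: str
    rank_matrix: pd.DataFrame  # rows: trials, columns: node ids
    seeds_per_trial: int
    rng_seed: int

    @property
    def n_trials(self) -> int:
        return len(self.rank_matrix)

    @property
    def median_ranks(self) -> pd.Series:
        return self.rank_matrix.median(axis=0)

    def rank_distribution(self, gene: str) -> pd.Series:
        return self.rank_matrix[gene]


def random_seed_experiment(
    prioritizer: Prioritizer,
    net: Network,
    n_trials: int = 1000,
    seeds_per_trial: int = 10,
    rng_seed: int = 0,
) -> RandomSeedResult:
    """Rerun a prioritizer with uniformly drawn seed sets; collect all node ranks.

    Used on the plain gene network, where degree has a direct biological
    reading.  Failed trials are skipped and logged.
    """
    if net.n <= seeds_per_trial:
        raise ValueError("network must have more nodes than seeds_per_trial")
    rng = np.random.default_rng(rng_seed)
    prioritizer.fit(net)
    nodes = list(net.nodes)
    rows = []
    for trial in range(n_trials):
        chosen = rng.choice(net.n, size=seeds_per_trial, replace=False)
        seeds = SeedSet(tuple(nodes[i] for i in chosen))
        try:
            table = prioritizer.rank(seeds, exclude=None)
        except Exception:
            logger.exception("random-seed trial %d failed; skipped", trial)
            continue
        rows.append(table.ranks.reindex(nodes))
    mat = pd.DataFrame(rows).reset_index(drop=True)
    return RandomSeedResult(
        algorithm=prioritizer.name,
        rank_matrix=mat,
        seeds_per_trial=seeds_per_trial,
        rng_seed=rng_seed,
    )


def degree_rank_association(result: RandomSeedResult, net: Network, n_bins: int = 10):
    """Spearman correlation of node degree with median random-seed rank, plus binned medians.

    A strongly negative correlation (high degree -> good rank) is the
    signature of degree bias in an algorithm.  Returns (rho, pvalue, table);
    rho is NaN when the ranks are constant.
    """
    med = result.median_ranks.reindex(list(net.nodes))
    deg = pd.Series(net.degree, index=list(net.nodes), dtype=float)
    if med.nunique() <= 1 or deg.nunique() <= 1:
        logger.warning("degree_rank_association: constant input, correlation undefined")
        rho, pval = float("nan"), float("nan")
    else:
        rho, pval = stats.spearmanr(deg, med)
    decile = pd.qcut(deg.rank(method="first"), q=n_bins, labels=False)
    table = pd.DataFrame({"degree": deg, "median_rank": med, "degree_bin": decile})
    binned = table.groupby("degree_bin").agg(
        degree_median=("degree", "median"), rank_median=("median_rank", "median"),
        n=("degree", "size"),
    )
    return float(rho), float(pval), binned


def read_gene_regions(path) -> pd.DataFrame:
    """Read gene regions as 1-based inclusive coordinates.

    ``*.bed`` files (chrom, start, end, name; 0-based half-open) are
    converted on read; anything else is a TSV ``gene chrom start end``
    already in 1-based inclusive coordinates.  ``#`` comments are skipped.
    """
    if str(path).endswith(".bed"):
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "start", "end", "gene"],
                         dtype={"chrom": str})
        df["start"] = df["start"] + 1  # 0-based half-open -> 1-based inclusive
    else:
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["gene", "chrom", "start", "end"],
                         dtype={"chrom": str})
    return df[["gene", "chrom", "start", "end"]]


def read_gwas_table(path) -> pd.DataFrame:
    """Read GWAS summary statistics: TSV ``snp chrom pos pvalue``; bad rows dropped."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["snp", "chrom", "pos", "pvalue"], dtype={"chrom": str})
    n_raw = len(df)
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["pvalue"] = pd.to_numeric(df["pvalue"], errors="coerce")
    df = df.dropna(subset=["snp", "chrom", "pos", "pvalue"])
    dropped = n_raw - len(df)
    if dropped:
        logger.warning("read_gwas_table: dropped %d malformed row(s)", dropped)
    return df.reset_index(drop=True)


def map_snps_to_genes(gwas: pd.DataFrame, regions: pd.DataFrame, flank: int = 1000) -> dict[str, pd.DataFrame]:
    """Assign SNPs to genes by position: same chromosome, within the region +/- flank.

    Coordinates are 1-based inclusive; a SNP may map to several overlapping
    genes.  Returns {gene: SNP sub-table}; genes with no SNPs are absent.
    """
    out: dict[str, pd.DataFrame] = {}
    by_chrom = {c: g for c, g in gwas.groupby("chrom")}
    for row in regions.itertuples(index=False):
        snps = by_chrom.get(str(row.chrom))
        if snps is None:
            continue
        lo, hi = row.start - flank, row.end + flank
        hit = snps[(snps["pos"] >= lo) & (snps["pos"] <= hi)]
        if len(hit):
            out[row.gene] = hit.reset_index(drop=True)
    return out


@dataclass(frozen=True)
class GWASValidationResult:
    """Per-gene SNP significance calls over the top-ranked genes (FDR-pooled)."""

    gene_table: pd.DataFrame  # gene, rank, n_snps, n_sig_snps, test_p, validated
    n_sig_snps: int
    n_total_snps: int
    fdr: float
    top_n: int
    fdr_method: str = "fdr_bh"

    @property
    def n_validated(self) -> int:
        return int(self.gene_table["validated"].sum())

    @property
    def n_genes_tested(self) -> int:
        return len(self.gene_table)

    @property
    def validated_genes(self) -> list[str]:
        t = self.gene_table
        return list(t.loc[t["validated"], "gene"])


def _gene_validated(indicators: np.ndarray, alpha: float) -> tuple[float, bool]:
    """One-sample location test of SNP pass/fail indicators against 0.

    Degenerate vectors are decided deterministically: all-zero -> not
    validated; constant all-one -> validated (a single passing SNP counts).
    """
    mean = indicators.mean()
    if mean == 0.0:
        return 1.0, False
    if len(indicators) == 1 or indicators.std(ddof=1) == 0.0:
        return 0.0, True  # the sole SNP passes, or every SNP passes
    t = stats.ttest_1samp(indicators, popmean=0.0)
    return float(t.pvalue), bool(t.pvalue < alpha)


def gwas_validate(
    ranks: RankTable,
    gwas: pd.DataFrame,
    regions: pd.DataFrame,
    top_n: int = 200,
    fdr: float = 0.05,
    flank: int = 1000,
    gene_alpha: float = 0.05,
) -> GWASValidationResult:
    """Validate the top-ranked genes against GWAS summary statistics.

    All SNPs mapping to the top ``top_n`` genes are pooled and BH-adjusted;
    a gene is validated when a one-sample test finds a significant share of
    its SNPs below the adjusted-p threshold.  Genes with no mapped SNPs are
    excluded from the denominator (logged).
    """
    if top_n > ranks.n_ranked:
        raise ValueError(f"top_n={top_n} exceeds ranked genes ({ranks.n_ranked})")
    top_genes = ranks.top(top_n)
    gene_snps = map_snps_to_genes(gwas, regions[regions["gene"].isin(top_genes)], flank=flank)
    n_no_snps = len(top_genes) - len(gene_snps)
    if n_no_snps:
        logger.info("gwas_validate: %d top gene(s) with no mapped SNPs excluded", n_no_snps)
    pooled = (
        pd.concat(gene_snps.values(), ignore_index=True)[["snp", "pvalue"]]
        .drop_duplicates(subset="snp")
        if gene_snps else pd.DataFrame(columns=["snp", "pvalue"])
    )
    if len(pooled):
        _, p_adj, _, _ = multipletests(pooled["pvalue"].to_numpy(), method="fdr_bh")
        adj = pd.Series(p_adj, index=pooled["snp"].to_numpy())
    else:
        adj = pd.Series(dtype=float)
    rows = []
    for gene in top_genes:
        if gene not in gene_snps:
            continue
        snps = gene_snps[gene]
        indicators = (adj.loc[snps["snp"]].to_numpy() < fdr).astype(float)
        test_p, ok = _gene_validated(indicators, gene_alpha)
        rows.append({
            "gene": gene, "rank": ranks.rank_of(gene), "n_snps": len(snps),
            "n_sig_snps": int(indicators.sum()), "test_p": test_p, "validated": ok,
        })
    table = pd.DataFrame(rows, columns=["gene", "rank", "n_snps", "n_sig_snps",
                                        "test_p", "validated"])
    return GWASValidationResult(
        gene_table=table,
        n_sig_snps=int((adj < fdr).sum()),
        n_total_snps=len(adj),
        fdr=fdr,
        top_n=top_n,
    )


def confirmed_gene_metrics(ranks: RankTable, confirmed, top_frac: float = 0.1):
    """Median rank of externally confirmed genes plus the hits within the top fraction.

    Returns (median_rank, hits, hit_list); confirmed genes absent from the
    ranking are excluded and logged.
    """
    confirmed = list(confirmed)
    if not confirmed:
        raise ValueError("empty confirmed-gene list")
    present = [g for g in confirmed if g in ranks.ranks.index and pd.notna(ranks.ranks.get(g))]
    absent = sorted(set(confirmed) - set(present))
    if absent:
        logger.info("confirmed_gene_metrics: %d gene(s) unranked, excluded: %s", len(absent), absent)
    if not present:
        return float("nan"), 0, []
    r = ranks.ranks.loc[present].sort_values()
    cutoff = top_frac * ranks.n_ranked
    hits = r[r <= cutoff]
    return float(r.median()), int(len(hits)), list(hits.index)
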