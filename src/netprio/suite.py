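"""Configured benchmark suite: run selected algorithms + evaluations, write reports.

The report bundle mirrors the benchmarking workflow's summary tables: a LOOCV
matrix (one column per algorithm, one row per seed gene plus Median/Mean
rows, "na" preserved for folds an algorithm never ranked) and a GWAS summary
(significant/total SNPs and genes, confirmed-gene median rank and hits within
the top 10%).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .evaluation import (
    confirmed_gene_metrics,
    gwas_validate,
    loocv,
    read_gene_regions,
    read_gwas_table,
)
from .manifest import write_manifest
from .network import load_edge_list, load_hetero_network, load_seed_list
from .prioritizers import ALGORITHMS, make_prioritizer
from .propagation import IDLPParams, RWRParams

logger = logging.getLogger(__name__)

__all__ = ["run_benchmark_suite", "load_config"]

_HETERO_ALGOS = {"rwrh", "n2vh", "idlp"}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _build_prioritizer(name: str, params: dict):
    params = dict(params or {})
    if name in ("rwr", "rwrh"):
        rp = RWRParams(restart=params.pop("restart", 0.5),
                       tolerance=params.pop("tolerance", 1e-8))
        return make_prioritizer(name, params=rp, **params)
    if name == "idlp":
        return make_prioritizer(name, params=IDLPParams(**params))
    if name in ("n2v", "n2vh"):
        from .embedding import WalkParams

        wp = WalkParams(
            n_walks=params.pop("n_walks", 20),
            l_walks=params.pop("l_walks", 80),
            p=params.pop("p", 1.0),
            q=params.pop("q", 1.0),
            rng_seed=params.pop("rng_seed", 0),
        )
        return make_prioritizer(name, walk_params=wp, **params)
    return make_prioritizer(name, **params)


def run_benchmark_suite(config: dict, out_dir) -> dict:
    """Execute the configured algorithms and evaluation blocks; write reports.

    Raises on configuration errors before any computation; per-algorithm
    failures inside a block are recorded and re-raised at the end so the
    process exits nonzero while still writing partial reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    algorithms = list(config.get("algorithms", []))
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise KeyError(f"unknown algorithm keys {unknown}; valid: {sorted(ALGORITHMS)}")
    needs_hetero = [a for a in algorithms if a in _HETERO_ALGOS]
    if needs_hetero and not config.get("gda"):
        raise ValueError(f"algorithms {needs_hetero} need a heterogeneous network; "
                         "config key 'gda' is missing")

    net = load_edge_list(config["network"], config.get("score_threshold"))
    hnet = None
    if config.get("gda"):
        hnet = load_hetero_network(net, config["gda"], config.get("dsim"),
                                   config.get("gda_threshold"), config.get("dsim_threshold"))
    seeds = load_seed_list(config["seeds"], net)
    disease = config.get("disease")
    algo_params = config.get("algorithm_params", {})

    results: dict = {"loocv": {}, "gwas": {}}
    failures: list[str] = []
    loocv_cols = []
    gwas_rows = []
    for name in algorithms:
        pr = _build_prioritizer(name, algo_params.get(name))
        target = hnet if pr.needs_hetero else net
        try:
            if config.get("loocv", True):
                res = loocv(pr, target, seeds, disease if pr.needs_hetero else None)
                results["loocv"][name] = res
                loocv_cols.append(res.to_frame())
                if res.params.get("partial_failure"):
                    failures.append(f"loocv:{name}")
            gwas_cfg = config.get("gwas")
            if gwas_cfg:
                pr.fit(target)
                if name == "diamond":
                    pr.force_full = True  # hits@10% needs a complete ranking
                table = pr.rank(seeds, disease if pr.needs_hetero else None,
                                exclude=seeds.ids)
                gwas = read_gwas_table(gwas_cfg["gwas"])
                regions = read_gene_regions(gwas_cfg["regions"])
                val = gwas_validate(table, gwas, regions,
                                    top_n=gwas_cfg.get("top_n", 200),
                                    fdr=gwas_cfg.get("fdr", 0.05))
                row = {
                    "algorithm": name,
                    "snp_sig_total": f"{val.n_sig_snps}/{val.n_total_snps}",
                    "gene_sig_total": f"{val.n_validated}/{val.n_genes_tested}",
                }
                confirmed = gwas_cfg.get("confirmed")
                if confirmed:
                    med, hits, hit_list = confirmed_gene_metrics(
                        table, confirmed, gwas_cfg.get("top_frac", 0.1))
                    row.update({"median_rank": med,
                                "hits_top10pct": f"{hits}/{len(confirmed)}",
                                "hits_list": ",".join(hit_list)})
                results["gwas"][name] = val
                gwas_rows.append(row)
        except Exception:
            logger.exception("benchmark block failed for algorithm %r", name)
            failures.append(name)
    if loocv_cols:
        loocv_table = pd.concat(loocv_cols, axis=1)
        loocv_table.to_csv(out_dir / "loocv_table.tsv", sep="\t")
        results["loocv_table"] = loocv_table
    if gwas_rows:
        gwas_table = pd.DataFrame(gwas_rows)
        gwas_table.to_csv(out_dir / "gwas_summary.tsv", sep="\t", index=False)
        results["gwas_table"] = gwas_table
    inputs = {k: config[k] for k in ("network", "gda", "dsim", "seeds") if config.get(k)}
    write_manifest(out_dir / "manifest.json", "benchmark-suite", config, inputs=inputs,
                   rng_seeds={"config_rng_seed": config.get("rng_seed", 0)})
    if failures:
        raise RuntimeError(f"benchmark blocks failed: {failures}")
    return results
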