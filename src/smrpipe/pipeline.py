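"""End-to-end driver and result summaries.

Stage order: read → MAF filter → harmonize → inverse-variance meta →
instrument selection → SMR per pair → Bonferroni.  The run log records
in/out counts for every stage so record conservation can be audited, and
the whole pipeline is a pure function of (input files, configuration).
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from . import io
from .exceptions import EmptyResultError
from .meta import InverseVarianceMeta
from .smr import SMR

logger = logging.getLogger(__name__)

__all__ = [
    "maf_filter", "run_pipeline", "PipelineResult", "aggregate_by_gene",
    "aggregate_by_snp", "manhattan_table", "shared_instrument_network",
    "format_run_log",
]


def maf_filter(records: pd.DataFrame, min_maf: float = 0.001):
    """Retain records with minor-allele frequency above ``min_maf``.

    MAF is min(eaf, 1−eaf).  Returns (retained records, exclusion count).
    The default threshold keeps variants with MAF > 0.1%.
    """
    maf = np.minimum(records["freq"], 1.0 - records["freq"])
    keep = maf > min_maf
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("maf_filter: excluded %d record(s) at MAF <= %g",
                    n_excluded, min_maf)
    return records[keep].reset_index(drop=True), n_excluded


class PipelineResult(NamedTuple):
    results: pd.DataFrame
    gene_summary: pd.DataFrame
    log: dict


def run_pipeline(gwas_paths, eqtl_path, *, min_maf: float = 0.001,
                 drop_ambiguous: bool = True, require_all_cohorts: bool = False,
                 instrument_p_threshold: float = 5e-8, mode: str = "per_pair",
                 statistic: str = "approx", alpha: float = 0.05) -> PipelineResult:
    """Run the full scan from summary files to Bonferroni-flagged results.

    Raises :class:`~smrpipe.exceptions.EmptyResultError` naming the first
    stage that leaves zero records.
    """
    log: dict = {}
    cohorts = [io.read_gwas(p) for p in gwas_paths]
    log["read.gwas_files"] = len(cohorts)
    log["read.gwas_records"] = int(sum(len(c) for c in cohorts))
    if log["read.gwas_records"] == 0:
        raise EmptyResultError("read")

    filtered = []
    n_maf_excluded = 0
    for cohort in cohorts:
        kept, n_excl = maf_filter(cohort, min_maf)
        filtered.append(kept)
        n_maf_excluded += n_excl
    log["maf_filter.records_excluded"] = n_maf_excluded
    log["maf_filter.records_out"] = int(sum(len(c) for c in filtered))
    if log["maf_filter.records_out"] == 0:
        raise EmptyResultError("maf_filter")

    meta = InverseVarianceMeta(drop_ambiguous=drop_ambiguous,
                               require_all_cohorts=require_all_cohorts)
    meta.fit(filtered)
    log.update(meta.log_)
    if len(meta.results_) == 0:
        raise EmptyResultError("meta_combine")

    eqtl = io.read_eqtl(eqtl_path)
    log["read.eqtl_records"] = int(len(eqtl))
    if len(eqtl) == 0:
        raise EmptyResultError("read_eqtl")

    smr = SMR(instrument_p_threshold=instrument_p_threshold, mode=mode,
              statistic=statistic, alpha=alpha)
    smr.fit(meta.results_, eqtl)
    log.update(smr.log_)
    if smr.log_["smr.instruments_selected"] == 0:
        raise EmptyResultError("select_instruments")
    if len(smr.results_) == 0:
        raise EmptyResultError("smr_test")

    gene_summary = aggregate_by_gene(smr.results_)
    return PipelineResult(smr.results_, gene_summary, log)


def aggregate_by_gene(results: pd.DataFrame) -> pd.DataFrame:
    """Per-gene summary: SNPs tested/significant, top SNP, min p, b_xy there."""
    if len(results) == 0:
        raise ValueError("results table is empty")
    rows = []
    for gene, block in results.groupby("gene", sort=True):
        top = block.loc[block["p_SMR"].idxmin()]
        rows.append({
            "gene": gene,
            "n_snps_tested": int(len(block)),
            "n_snps_significant": int(block["significant"].sum()),
            "top_snp": top["SNP"],
            "min_p": float(top["p_SMR"]),
            "b_xy_at_top": float(top["b_xy"]),
        })
    return pd.DataFrame(rows)


def aggregate_by_snp(results: pd.DataFrame) -> pd.DataFrame:
    """Per-SNP summary over significant results only.

    One row per SNP appearing in at least one significant test, with the
    count and sorted list of genes it regulates.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    sig = results[results["significant"]]
    rows = []
    for snp, block in sig.groupby("SNP", sort=True):
        genes = sorted(block["gene"])
        rows.append({"snp": snp, "n_genes_regulated": len(genes),
                     "genes": ",".join(genes)})
    return pd.DataFrame(rows, columns=["snp", "n_genes_regulated", "genes"])


def manhattan_table(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Plot-ready table: one row per test with −log10 p and the threshold line.

    The significance line is −log10(alpha/m) with m the number of tests.
    Positions are carried through when present, otherwise emitted missing.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    line = -np.log10(alpha / len(results))
    return pd.DataFrame({
        "snp": results["SNP"].to_numpy(),
        "chrom": results["chrom"].to_numpy() if "chrom" in results else pd.NA,
        "pos": results["pos"].to_numpy() if "pos" in results else pd.NA,
        "neg_log10_p": -np.log10(results["p_SMR"].to_numpy()),
        "threshold_line": line,
    })


def shared_instrument_network(results: pd.DataFrame) -> nx.Graph:
    """Gene co-association network from shared significant instruments.

    Nodes are genes with at least one significant test; an edge joins two
    genes with weight w when exactly w SNPs are significant instruments for
    both.  This is pipeline-derived plumbing, not an external interaction
    database.
    """
    sig = results[results["significant"]]
    graph = nx.Graph()
    graph.add_nodes_from(sorted(sig["gene"].unique()))
    for _, block in sig.groupby("SNP", sort=False):
        genes = sorted(block["gene"].unique())
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1:]:
                if graph.has_edge(g1, g2):
                    graph[g1][g2]["weight"] += 1
                else:
                    graph.add_edge(g1, g2, weight=1)
    return graph


def format_run_log(log: dict) -> str:
    """Render the run log as key=value lines."""
    return "\n".join(f"{key}={value}" for key, value in log.items())
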