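"""Fixed-effects inverse-variance meta-analysis of GWAS cohorts.

Each SNP's per-cohort effect β_i with standard error SE_i receives weight
w_i = 1/SE_i²; the combined effect is β = Σβ_i·w_i / Σw_i with
SE = sqrt(1/Σw_i) and Z = β/SE tested against the standard normal.

Before combining, cohorts are harmonized to a single effect-allele
orientation per SNP.  The canonical orientation is the alphabetically
first allele of the pair, which makes every output independent of cohort
order; records entering on the opposite orientation get β negated and the
effect-allele frequency complemented.  SNPs whose allele pairs disagree
across cohorts are excluded with a logged reason, as are strand-ambiguous
(A/T, C/G) SNPs when ``drop_ambiguous`` is set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import GWAS_COLUMNS

logger = logging.getLogger(__name__)

__all__ = ["harmonize", "meta_combine", "meta_z_p", "InverseVarianceMeta"]

_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


def harmonize(cohort_tables, drop_ambiguous: bool = True):
    """Align per-cohort GWAS records to one effect-allele orientation per SNP.

    Parameters
    ----------
    cohort_tables : sequence of DataFrame
        Validated GWAS tables (canonical columns), one per cohort.
    drop_ambiguous : bool
        Exclude strand-ambiguous A/T and C/G SNPs.

    Returns
    -------
    aligned : DataFrame
        Long table of all retained records with a ``cohort`` column; within
        each SNP all rows share one (a1, a2) orientation.
    exclusions : DataFrame
        Columns ``snp``, ``reason`` for every excluded record group.
    """
    if len(cohort_tables) < 1:
        raise ValueError("need at least one cohort")
    frames = []
    for c, table in enumerate(cohort_tables):
        frame = table[GWAS_COLUMNS].copy()
        frame["cohort"] = c
        frames.append(frame)
    long = pd.concat(frames, ignore_index=True)

    excl_records = []

    pair_set = long.apply(lambda r: frozenset((r["a1"], r["a2"])), axis=1)
    if drop_ambiguous:
        ambiguous = pair_set.isin(_AMBIGUOUS)
        for snp in long.loc[ambiguous, "snp"].unique():
            excl_records.append({"snp": snp, "reason": "strand-ambiguous alleles"})
        keep = ~long["snp"].isin(long.loc[ambiguous, "snp"].unique())
        long, pair_set = long[keep], pair_set[keep]

    # allele-pair consistency across cohorts
    n_pairs = pair_set.groupby(long["snp"]).nunique()
    mismatched = set(n_pairs.index[n_pairs > 1])
    for snp in sorted(mismatched):
        excl_records.append({"snp": snp, "reason": "allele mismatch"})
    long = long[~long["snp"].isin(mismatched)].copy()

    if len(long):
        # canonical orientation: alphabetically first allele carries the effect
        flip = long["a1"] > long["a2"]
        long.loc[flip, ["a1", "a2"]] = long.loc[flip, ["a2", "a1"]].to_numpy()
        long.loc[flip, "b"] = -long.loc[flip, "b"]
        long.loc[flip, "freq"] = 1.0 - long.loc[flip, "freq"]

    exclusions = pd.DataFrame(excl_records, columns=["snp", "reason"])
    if len(exclusions):
        logger.info("harmonize: excluded %d SNP(s): %s", len(exclusions),
                    exclusions["reason"].value_counts().to_dict())
    return long.reset_index(drop=True), exclusions


def meta_combine(aligned: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance combine harmonized records, one output row per SNP.

    Output columns: ``snp a1 a2 freq b se k n`` where ``b``/``se`` are the
    fixed-effects combined estimate, ``freq`` the N-weighted mean
    effect-allele frequency, ``k`` the cohort count and ``n`` the summed
    sample size.  Rows follow first appearance order of each SNP.
    """
    if len(aligned) == 0:
        raise ValueError("cannot combine an empty record group")
    df = aligned.copy()
    w = 1.0 / df["se"] ** 2
    df["_w"] = w
    df["_bw"] = df["b"] * w
    df["_fn"] = df["freq"] * df["n"]
    grouped = df.groupby("snp", sort=False)
    out = grouped.agg(
        a1=("a1", "first"), a2=("a2", "first"),
        _w=("_w", "sum"), _bw=("_bw", "sum"), _fn=("_fn", "sum"),
        n=("n", "sum"), k=("snp", "size"),
    ).reset_index()
    out["b"] = out["_bw"] / out["_w"]
    out["se"] = np.sqrt(1.0 / out["_w"])
    out["freq"] = out["_fn"] / out["n"]
    return out[["snp", "a1", "a2", "freq", "b", "se", "k", "n"]]


def meta_z_p(combined: pd.DataFrame) -> pd.DataFrame:
    """Attach Z = β/SE and the two-sided standard-normal p-value."""
    out = combined.copy()
    out["z"] = out["b"] / out["se"]
    out["p"] = np.maximum(2.0 * stats.norm.sf(np.abs(out["z"])),
                          np.finfo(float).tiny)
    return out


class InverseVarianceMeta(BaseEstimator):
    """Fixed-effects inverse-variance meta-analysis across GWAS cohorts.

    Parameters
    ----------
    drop_ambiguous : bool, default True
        Exclude strand-ambiguous (A/T, C/G) SNPs during harmonization.
    require_all_cohorts : bool, default False
        Keep only SNPs observed in every cohort; by default SNPs present in
        a subset of cohorts are retained with the smaller k.

    Attributes
    ----------
    results_ : DataFrame
        Per-SNP combined table with columns
        ``snp a1 a2 freq b se k n z p`` — itself a valid GWAS input for the
        SMR stage.
    exclusions_ : DataFrame
        Harmonization exclusions (``snp``, ``reason``).
    n_cohorts_ : int
    log_ : dict
        Stage in/out record counts.
    """

    def __init__(self, drop_ambiguous: bool = True, require_all_cohorts: bool = False):
        self.drop_ambiguous = drop_ambiguous
        self.require_all_cohorts = require_all_cohorts

    def fit(self, cohort_tables, y=None):
        cohort_tables = list(cohort_tables)
        if not cohort_tables:
            raise ValueError("need at least one cohort table")
        n_in = int(sum(len(t) for t in cohort_tables))
        aligned, exclusions = harmonize(cohort_tables,
                                        drop_ambiguous=self.drop_ambiguous)
        combined = meta_z_p(meta_combine(aligned)) if len(aligned) else \
            pd.DataFrame(columns=["snp", "a1", "a2", "freq", "b", "se",
                                  "k", "n", "z", "p"])
        n_dropped_subset = 0
        if self.require_all_cohorts and len(combined):
            full = combined["k"] == len(cohort_tables)
            n_dropped_subset = int((~full).sum())
            combined = combined[full].reset_index(drop=True)
        self.n_cohorts_ = len(cohort_tables)
        self.results_ = combined
        self.exclusions_ = exclusions
        self.log_ = {
            "meta.records_in": n_in,
            "meta.records_harmonized": int(len(aligned)),
            "meta.records_excluded": n_in - int(len(aligned)),
            "meta.snps_excluded": int(len(exclusions)),
            "meta.snps_dropped_subset": n_dropped_subset,
            "meta.snps_out": int(len(combined)),
        }
        return self
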