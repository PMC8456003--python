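"""Summary-data Mendelian randomization (SMR) with eQTL instruments.

Given a SNP z instrumenting gene expression x for trait y, the causal
effect of expression on trait is the Wald ratio b_xy = b_zy / b_zx.  When
the eQTL effect size is unavailable, b_zx is recovered from the eQTL
Z-score on the standardized-phenotype scale:

    se_zx = 1 / sqrt(2 f (1 − f) (n + z²)),    b_zx = z · se_zx,

with f the effect-allele frequency and n the eQTL sample size.  The
sampling variance of the ratio comes from the first-order Delta method
(GWAS and eQTL samples independent, so the cross covariance is 0), and the
test statistic T_SMR = b_xy² / var(b_xy) is referred to χ² with 1 df.
Because only the Z-scores have a known distribution, the operative form of
the statistic is

    T_SMR ≈ Z_zy² Z_zx² / (Z_zy² + Z_zx²),

which equals the Delta-method statistic exactly when both SEs are derived
from the same Z-scores.  Multiple testing across (gene, SNP) pairs is
controlled by Bonferroni at the family-wise rate alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "TestConfig", "bzx_from_z", "wald_ratio", "delta_variance",
    "t_smr_delta", "t_smr_approx", "smr_pvalue", "variance_from_r2",
    "select_instruments", "bonferroni", "SMR",
]


@dataclass
class TestConfig:
    """Testing policy for an SMR scan.

    alpha: family-wise error rate for Bonferroni.
    instrument_p_threshold: maximum eQTL p for a SNP to serve as instrument.
    mode: "per_pair" tests every qualifying (gene, SNP) pair;
          "top_per_gene" tests only each gene's smallest-p SNP.
    statistic: "approx" (Z-score form) or "delta" (Delta-method form).
    """

    alpha: float = 0.05
    instrument_p_threshold: float = 5e-8
    mode: str = "per_pair"
    statistic: str = "approx"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.instrument_p_threshold <= 1.0:
            raise ValueError("instrument_p_threshold must lie in (0, 1]")
        if self.mode not in ("per_pair", "top_per_gene"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.statistic not in ("approx", "delta"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


def bzx_from_z(z, f, n):
    """Estimate (b_zx, se_zx) from an eQTL Z-score on the standardized scale.

    se_zx = 1/sqrt(2f(1−f)(n+z²)); b_zx = z·se_zx.  Vectorized.
    """
    z = np.asarray(z, dtype=float)
    f = np.asarray(f, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("allele frequency f must lie strictly in (0, 1)")
    if np.any(n < 1):
        raise ValueError("sample size n must be >= 1")
    se_zx = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * (n + z**2))
    return z * se_zx, se_zx


def wald_ratio(b_zy, b_zx):
    """Wald-ratio causal estimate b_xy = b_zy / b_zx (b_zx must be nonzero)."""
    b_zx = np.asarray(b_zx, dtype=float)
    if np.any(b_zx == 0):
        raise ZeroDivisionError(
            "b_zx = 0: SNP is not an instrument; exclude it before the ratio"
        )
    return np.asarray(b_zy, dtype=float) / b_zx


def delta_variance(b_zy, se_zy, b_zx, se_zx, cov_zx_zy=0.0):
    """First-order Delta-method variance of the Wald ratio b_zy/b_zx.

    Computed in the expanded form

        var = se_zy²/b_zx² + b_zy²·se_zx²/b_zx⁴ − 2·b_zy·cov/b_zx³,

    algebraically identical to the factored ratio expansion but defined at
    b_zy = 0.  ``cov_zx_zy`` defaults to 0, the value for effects estimated
    in independent GWAS and eQTL samples.
    """
    b_zy = np.asarray(b_zy, dtype=float)
    se_zy = np.asarray(se_zy, dtype=float)
    b_zx = np.asarray(b_zx, dtype=float)
    se_zx = np.asarray(se_zx, dtype=float)
    if np.any(b_zx == 0):
        raise ZeroDivisionError("b_zx = 0 has no Delta-method variance")
    if np.any(se_zy < 0) or np.any(se_zx < 0):
        raise ValueError("standard errors must be non-negative")
    return (se_zy**2 / b_zx**2
            + b_zy**2 * se_zx**2 / b_zx**4
            - 2.0 * b_zy * np.asarray(cov_zx_zy, dtype=float) / b_zx**3)


def t_smr_delta(b_xy, var_bxy):
    """Delta-method test statistic T = b_xy² / var(b_xy)."""
    var_bxy = np.asarray(var_bxy, dtype=float)
    if np.any(var_bxy <= 0):
        raise ValueError("var_bxy must be > 0")
    return np.asarray(b_xy, dtype=float) ** 2 / var_bxy


def t_smr_approx(z_zy, z_zx):
    """Z-score form of the SMR statistic: T = Z_zy²·Z_zx² / (Z_zy² + Z_zx²).

    The degenerate case Z_zy = Z_zx = 0 returns 0 by convention (logged).
    """
    z_zy = np.asarray(z_zy, dtype=float)
    z_zx = np.asarray(z_zx, dtype=float)
    num = z_zy**2 * z_zx**2
    den = z_zy**2 + z_zx**2
    zero = den == 0
    if np.any(zero):
        logger.warning("t_smr_approx: both Z-scores zero; statistic set to 0")
    with np.errstate(invalid="ignore"):
        t = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    return t if t.ndim else float(t)


def smr_pvalue(t_smr):
    """Upper-tail χ²(1 df) probability of the SMR statistic."""
    t_smr = np.asarray(t_smr, dtype=float)
    if np.any(t_smr < 0):
        raise ValueError("t_smr must be >= 0")
    p = stats.chi2.sf(t_smr, df=1)
    return np.maximum(p, np.finfo(float).tiny)


def variance_from_r2(var_x, var_y, r2_xy, r2_zx, n):
    """Diagnostic variance of b_xy from explicit phenotype variances.

    var(b_xy) = var(y)·(1 − R²_xy) / (n · var(x) · R²_zx), where R²_xy is
    the trait variance explained by expression and R²_zx the expression
    variance explained by the SNP.  Requires individual-level variance
    components, so it is a diagnostic only — the pipeline's operative
    statistic comes from the summary-level forms above.
    """
    if var_x <= 0 or var_y <= 0 or n < 1 or not 0 < r2_zx <= 1 or not 0 <= r2_xy < 1:
        raise ValueError("invalid variance components")
    return var_y * (1.0 - r2_xy) / (n * var_x * r2_zx)


def select_instruments(eqtl: pd.DataFrame, config: TestConfig):
    """Choose (gene, SNP) test pairs from the eQTL table.

    "per_pair": every pair with eQTL p ≤ threshold.  "top_per_gene": each
    gene's smallest-p qualifying SNP, ties broken by larger |Z| then
    lexicographic SNP id.

    Returns (selected pairs as a DataFrame slice, list of untested genes).
    """
    qualifying = eqtl[eqtl["p"] <= config.instrument_p_threshold]
    if config.mode == "top_per_gene" and len(qualifying):
        ranked = qualifying.assign(_absz=qualifying["z"].abs()).sort_values(
            ["gene", "p", "_absz", "snp"], ascending=[True, True, False, True]
        )
        qualifying = ranked.groupby("gene", sort=False).head(1).drop(columns="_absz")
        qualifying = qualifying.sort_index()
    untested = sorted(set(eqtl["gene"]) - set(qualifying["gene"]))
    if untested:
        logger.info("select_instruments: %d gene(s) with no qualifying SNP",
                    len(untested))
    return qualifying.reset_index(drop=True), untested


def bonferroni(pvalues, alpha: float = 0.05):
    """Bonferroni family-wise control: significant ⇔ p ≤ alpha/m.

    Returns (boolean array, threshold).  ``m`` is the number of tests
    actually performed (the length of ``pvalues``).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bonferroni needs at least one p-value")
    threshold = alpha / p.size
    return p <= threshold, threshold


class SMR(BaseEstimator):
    """Summary-data Mendelian randomization scan over (gene, SNP) pairs.

    Parameters
    ----------
    instrument_p_threshold : float, default 5e-8
        Maximum eQTL p-value for a SNP to serve as instrument.
    mode : {"per_pair", "top_per_gene"}, default "per_pair"
        Test every qualifying pair, or only each gene's top eQTL.
    statistic : {"approx", "delta"}, default "approx"
        Z-score form or Delta-method form of T_SMR.
    alpha : float, default 0.05
        Family-wise error rate for the Bonferroni flag.

    Attributes
    ----------
    results_ : DataFrame
        One row per tested pair with columns
        ``gene SNP A1 b_zx se_zx b_zy se_zy b_xy se_xy T_SMR p_SMR significant``.
    bonferroni_threshold_ : float
    m_tests_ : int
    untested_genes_ : list of str
    exclusions_ : DataFrame
        (snp, reason) rows for pairs dropped while merging GWAS and eQTL.
    log_ : dict
        Record counts at each stage.
    """

    def __init__(self, instrument_p_threshold: float = 5e-8,
                 mode: str = "per_pair", statistic: str = "approx",
                 alpha: float = 0.05):
        self.instrument_p_threshold = instrument_p_threshold
        self.mode = mode
        self.statistic = statistic
        self.alpha = alpha

    def _config(self) -> TestConfig:
        return TestConfig(alpha=self.alpha,
                          instrument_p_threshold=self.instrument_p_threshold,
                          mode=self.mode, statistic=self.statistic)

    def fit(self, gwas: pd.DataFrame, eqtl: pd.DataFrame):
        """Run the scan.

        ``gwas``: per-SNP trait associations (canonical GWAS columns; the
        meta-analysis output qualifies).  ``eqtl``: eQTL table with ``z``
        populated.  eQTL records are re-oriented to the GWAS effect allele
        (Z and frequency flipped on swapped alleles); pairs whose allele
        sets disagree are excluded with a logged reason.
        """
        config = self._config()
        instruments, untested = select_instruments(eqtl, config)
        merged = instruments.merge(
            gwas[["snp", "a1", "a2", "freq", "b", "se"]],
            on="snp", how="inner", suffixes=("_eqtl", ""),
        )
        n_unmatched = len(instruments) - len(merged)

        # orient eQTL Z to the GWAS effect allele
        same = (merged["a1_eqtl"] == merged["a1"]) & (merged["a2_eqtl"] == merged["a2"])
        swapped = (merged["a1_eqtl"] == merged["a2"]) & (merged["a2_eqtl"] == merged["a1"])
        mismatch = ~(same | swapped)
        exclusions = pd.DataFrame(
            {"snp": merged.loc[mismatch, "snp"],
             "reason": "allele mismatch between GWAS and eQTL"},
            columns=["snp", "reason"],
        )
        if mismatch.any():
            logger.info("SMR: excluded %d pair(s) with GWAS/eQTL allele mismatch",
                        int(mismatch.sum()))
        merged = merged[~mismatch].copy()
        merged.loc[swapped[~mismatch], "z"] *= -1.0

        z_zx = merged["z"].to_numpy()
        f = merged["freq"].to_numpy()          # GWAS-side effect-allele frequency
        n_eqtl = merged["n"].to_numpy(dtype=float)
        b_zy = merged["b"].to_numpy()
        se_zy = merged["se"].to_numpy()

        b_zx, se_zx = bzx_from_z(z_zx, f, n_eqtl)
        nonzero = b_zx != 0
        if not np.all(nonzero):
            merged = merged[nonzero].copy()
            b_zx, se_zx = b_zx[nonzero], se_zx[nonzero]
            b_zy, se_zy, z_zx = b_zy[nonzero], se_zy[nonzero], z_zx[nonzero]
        b_xy = wald_ratio(b_zy, b_zx)
        var_bxy = delta_variance(b_zy, se_zy, b_zx, se_zx)
        if config.statistic == "approx":
            t = t_smr_approx(b_zy / se_zy, z_zx)
        else:
            t = t_smr_delta(b_xy, var_bxy)
        p = smr_pvalue(t)

        results = pd.DataFrame({
            "gene": merged["gene"].to_numpy(),
            "SNP": merged["snp"].to_numpy(),
            "A1": merged["a1"].to_numpy(),
            "b_zx": b_zx, "se_zx": se_zx,
            "b_zy": b_zy, "se_zy": se_zy,
            "b_xy": b_xy, "se_xy": np.sqrt(var_bxy),
            "T_SMR": np.atleast_1d(t), "p_SMR": np.atleast_1d(p),
        })
        if len(results):
            flags, threshold = bonferroni(results["p_SMR"], config.alpha)
            results["significant"] = flags
        else:
            results["significant"] = pd.Series(dtype=bool)
            threshold = config.alpha
        self.results_ = results
        self.bonferroni_threshold_ = float(threshold)
        self.m_tests_ = int(len(results))
        self.untested_genes_ = untested
        self.exclusions_ = exclusions.reset_index(drop=True)
        self.log_ = {
            "smr.eqtl_records": int(len(eqtl)),
            "smr.instruments_selected": int(len(instruments)),
            "smr.instruments_unmatched_in_gwas": int(n_unmatched),
            "smr.pairs_allele_mismatch": int(len(exclusions)),
            "smr.pairs_tested": int(len(results)),
            "smr.pairs_significant": int(results["significant"].sum()) if len(results) else 0,
            "smr.bonferroni_threshold": float(threshold),
            "smr.genes_untested": len(untested),
        }
        return self
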