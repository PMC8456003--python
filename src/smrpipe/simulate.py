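"""Simulation of GWAS and eQTL summary statistics with known causal structure.

The generative model is the structural chain SNP → expression → trait:
each SNP ``z`` is a cis-instrument for exactly one gene, expression
``x_g = Σ_j b_zx(j,g)·z_j + ε_x`` and trait ``y = Σ_g b_xy(g)·x_g + ε_y``,
with both phenotypes standardized to unit variance in expectation.  SNPs
are in linkage equilibrium, so the Wald-ratio assumptions hold exactly and
recovery tests have an unambiguous truth.

Two simulators are provided:

* :func:`simulate_individual_cohort` draws genotype dosages, expression and
  trait at the individual level — slow, and used as the oracle for the fast
  path;
* :func:`simulate_summary_stats` draws the summary statistics directly from
  their sampling distributions (eQTL ``Z ~ N(b_zx·sqrt(2f(1−f)·n), 1)``,
  GWAS ``β ~ N(b_zx·b_xy, SE²)`` with ``SE = 1/sqrt(2f(1−f)·n)``), which is
  what calibration and power studies at many replicates need.

All randomness flows from one config seed; per-cohort streams are derived
deterministically from (seed, cohort index).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io
from .exceptions import ConfigurationError, MonomorphicSnpError

__all__ = [
    "SimConfig",
    "simulate_truth",
    "simulate_individual_cohort",
    "summarize_association",
    "simulate_summary_stats",
    "write_fixture",
]

# unambiguous allele pairs only, so default harmonization drops nothing
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class SimConfig:
    """Parameters of the synthetic GWAS/eQTL study.

    Defaults mirror the two-cohort UK-scale GWAS plus blood-eQTL design the
    pipeline targets (cohort sizes 394,929 and 32,965; eQTL n=5,311) at a
    desk-scale gene panel: 50 genes × 20 cis-SNPs with 3 causal genes of
    effect 0.2 trait-SD per expression-SD.
    """

    n_genes: int = 50
    snps_per_gene: int = 20
    frac_causal_genes: float = 0.06
    b_xy_causal: float = 0.2
    b_zx_range: tuple[float, float] = (0.1, 0.5)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_gwas_cohorts: int = 2
    n_per_cohort: tuple[int, ...] = (394_929, 32_965)
    n_eqtl: int = 5_311
    seed: int = 42

    def __post_init__(self):
        if self.n_genes < 1 or self.snps_per_gene < 1:
            raise ConfigurationError("n_genes and snps_per_gene must be >= 1")
        if not 0.0 <= self.frac_causal_genes <= 1.0:
            raise ConfigurationError("frac_causal_genes must lie in [0, 1]")
        if self.n_gwas_cohorts < 1:
            raise ConfigurationError("n_gwas_cohorts must be >= 1")
        self.n_per_cohort = tuple(int(n) for n in self.n_per_cohort)
        if len(self.n_per_cohort) != self.n_gwas_cohorts:
            raise ConfigurationError(
                f"n_per_cohort has {len(self.n_per_cohort)} entries for "
                f"{self.n_gwas_cohorts} cohorts"
            )
        if any(n < 1 for n in self.n_per_cohort) or self.n_eqtl < 1:
            raise ConfigurationError("all sample sizes must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("maf_range must be an interval within (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("b_zx_range", "maf_range", "n_per_cohort"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("b_zx_range", "maf_range", "n_per_cohort"):
            d[key] = list(d[key])
        return d


def _truth_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 0])


def _cohort_rng(config: SimConfig, cohort_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1 + cohort_index])


def _eqtl_rng(config: SimConfig) -> np.random.Generator:
    return np.random.default_rng([config.seed, 999])


def simulate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw the ground-truth causal architecture for ``config``.

    Returns one row per SNP with columns ``gene``, ``snp``, ``b_zx``,
    ``b_xy``, ``maf``, ``is_causal`` plus allele columns ``a1``/``a2``.
    ``is_causal`` is True exactly when the gene's ``b_xy`` is nonzero.
    Deterministic in the config seed.
    """
    rng = _truth_rng(config)
    n_snps = config.n_genes * config.snps_per_gene
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    n_causal = int(round(config.frac_causal_genes * config.n_genes))
    causal_idx = rng.choice(config.n_genes, size=n_causal, replace=False)
    b_xy_gene = np.zeros(config.n_genes)
    b_xy_gene[causal_idx] = config.b_xy_causal

    lo, hi = config.b_zx_range
    b_zx = rng.uniform(lo, hi, size=n_snps) * rng.choice([-1.0, 1.0], size=n_snps)
    maf = rng.uniform(*config.maf_range, size=n_snps)
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=n_snps)

    gene_of_snp = np.repeat(np.arange(config.n_genes), config.snps_per_gene)
    return pd.DataFrame({
        "gene": [genes[g] for g in gene_of_snp],
        "snp": [f"rs{i + 1:06d}" for i in range(n_snps)],
        "a1": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "a2": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "b_zx": b_zx,
        "b_xy": b_xy_gene[gene_of_snp],
        "maf": maf,
        "is_causal": b_xy_gene[gene_of_snp] != 0.0,
    })


def simulate_individual_cohort(config: SimConfig, cohort_index: int):
    """Simulate one cohort at the individual level.

    Genotypes are dosages in {0,1,2} (two Bernoulli(maf) draws per SNP),
    expression and trait follow the structural model with noise scaled so
    each phenotype has unit variance in expectation.

    Returns
    -------
    (genotypes, expression, trait) : ndarray (n, n_snps), ndarray (n, n_genes), ndarray (n,)

    Raises
    ------
    ConfigurationError
        If a gene's genetic variance (or the trait's) reaches 1, leaving no
        room for residual noise.
    """
    if not 0 <= cohort_index < config.n_gwas_cohorts:
        raise ConfigurationError(
            f"cohort_index {cohort_index} out of range for "
            f"{config.n_gwas_cohorts} cohorts"
        )
    truth = simulate_truth(config)
    rng = _cohort_rng(config, cohort_index)
    n = config.n_per_cohort[cohort_index]
    maf = truth["maf"].to_numpy()
    b_zx = truth["b_zx"].to_numpy()
    gene_codes = pd.Categorical(truth["gene"], categories=truth["gene"].unique()).codes

    genotypes = (rng.random((n, len(maf))) < maf).astype(np.int8)
    genotypes = genotypes + (rng.random((n, len(maf))) < maf).astype(np.int8)

    # per-gene genetic variance of expression: Σ_j b_zx_j² · 2f(1−f)
    var_dose = 2.0 * maf * (1.0 - maf)
    genetic_var = np.bincount(gene_codes, weights=b_zx**2 * var_dose,
                              minlength=config.n_genes)
    resid_var = 1.0 - genetic_var
    if np.any(resid_var <= 0):
        bad = truth["gene"].unique()[np.argmax(resid_var <= 0)]
        raise ConfigurationError(
            f"gene {bad}: per-SNP effects imply genetic variance >= 1; "
            "residual expression variance would be non-positive"
        )
    effects = np.zeros((len(maf), config.n_genes))
    effects[np.arange(len(maf)), gene_codes] = b_zx
    expression = genotypes @ effects
    expression += rng.normal(0.0, np.sqrt(resid_var), size=(n, config.n_genes))

    b_xy_gene = truth.groupby("gene", sort=False)["b_xy"].first().to_numpy()
    trait_genetic_var = float(np.sum(b_xy_gene**2))
    if trait_genetic_var >= 1.0:
        raise ConfigurationError(
            "gene-level effects imply trait genetic variance >= 1; "
            "residual trait variance would be non-positive"
        )
    trait = expression @ b_xy_gene
    trait += rng.normal(0.0, np.sqrt(1.0 - trait_genetic_var), size=n)
    return genotypes, expression, trait


def summarize_association(genotype, phenotype):
    """Per-SNP association summary: OLS slope of phenotype on dosage.

    Returns ``(beta, se, pvalue, n)`` with the SE from the residual
    variance and a two-sided p-value from the t-distribution with n−2
    degrees of freedom.  An exact linear fit yields se=0 and p=0 (the
    degenerate case a caller should treat as flagged).
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("genotype and phenotype must be equal-length 1-D vectors")
    n = g.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    sxx = float(np.sum((g - g.mean()) ** 2))
    if sxx == 0.0:
        raise MonomorphicSnpError("genotype vector is constant (monomorphic SNP)")
    sxy = float(np.sum((g - g.mean()) * (y - y.mean())))
    beta = sxy / sxx
    resid = y - y.mean() - beta * (g - g.mean())
    rss = float(resid @ resid)
    se = float(np.sqrt(rss / (n - 2) / sxx))
    if se == 0.0:
        return beta, 0.0, 0.0, n
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return beta, se, max(p, float(np.finfo(float).tiny)), n


def simulate_summary_stats(config: SimConfig):
    """Fast path: draw summary statistics directly from their sampling laws.

    Returns
    -------
    gwas_cohorts : list of DataFrame
        One ``.ma``-schema table per cohort (columns :data:`smrpipe.io.GWAS_COLUMNS`).
    eqtl : DataFrame
        eQTL table (columns :data:`smrpipe.io.EQTL_COLUMNS`).
    truth : DataFrame
        Ground-truth table from :func:`simulate_truth`.
    """
    truth = simulate_truth(config)
    maf = truth["maf"].to_numpy()
    b_zx = truth["b_zx"].to_numpy()
    b_zy = b_zx * truth["b_xy"].to_numpy()
    het = 2.0 * maf * (1.0 - maf)
    tiny = float(np.finfo(float).tiny)

    gwas_cohorts = []
    for c, n_c in enumerate(config.n_per_cohort):
        rng = _cohort_rng(config, c)
        se = 1.0 / np.sqrt(het * n_c)
        beta = rng.normal(b_zy, se)
        p = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), tiny)
        gwas_cohorts.append(pd.DataFrame({
            "snp": truth["snp"], "a1": truth["a1"], "a2": truth["a2"],
            "freq": maf, "b": beta, "se": se, "p": p,
            "n": float(n_c),
        }))

    rng = _eqtl_rng(config)
    z = rng.normal(b_zx * np.sqrt(het * config.n_eqtl), 1.0)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), tiny)
    eqtl = pd.DataFrame({
        "gene": truth["gene"], "snp": truth["snp"],
        "a1": truth["a1"], "a2": truth["a2"],
        "freq": maf, "z": z, "p": p, "n": float(config.n_eqtl),
    })
    return gwas_cohorts, eqtl, truth


def write_fixture(config: SimConfig, out_dir) -> dict:
    """Write a complete fixture set (GWAS cohorts, eQTL, truth) to ``out_dir``.

    Returns a manifest dict with keys ``gwas`` (list of paths), ``eqtl``,
    ``truth``, ``config``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gwas_cohorts, eqtl, truth = simulate_summary_stats(config)
    manifest = {"gwas": [], "eqtl": None, "truth": None, "config": None}
    for c, table in enumerate(gwas_cohorts):
        path = out_dir / f"gwas_cohort{c + 1}.ma"
        io.write_gwas(table, path)
        manifest["gwas"].append(str(path))
    eqtl_path = out_dir / "eqtl.tsv"
    io.write_eqtl(eqtl, eqtl_path)
    manifest["eqtl"] = str(eqtl_path)

    truth_path = out_dir / "truth.tsv"
    out = truth[["gene", "snp", "b_zx", "b_xy", "maf", "is_causal"]].copy()
    out.columns = ["gene", "SNP", "b_zx", "b_xy", "maf", "is_causal"]
    out.to_csv(truth_path, sep="\t", index=False, float_format="%.12g")
    manifest["truth"] = str(truth_path)

    config_path = out_dir / "sim_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    manifest["config"] = str(config_path)
    return manifest
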