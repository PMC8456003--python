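import pandas as pd
import pytest

from smrpipe import SimConfig, simulate_summary_stats


def make_gwas_frame(rows):
    """Build a canonical GWAS table from (snp, a1, a2, freq, b, se, p, n) tuples."""
    return pd.DataFrame(rows, columns=["snp", "a1", "a2", "freq", "b", "se", "p", "n"])


def write_ma(path, rows):
    lines = ["SNP A1 A2 freq b se p N"]
    lines += [" ".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_eqtl_tsv(path, rows, with_z=True):
    header = ("gene\tSNP\tA1\tA2\tfreq\tZ\tp\tN" if with_z
              else "gene\tSNP\tA1\tA2\tfreq\tb\tse\tp\tN")
    lines = [header] + ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale causal architecture: 10 genes x 5 SNPs, 2 causal."""
    return SimConfig(n_genes=10, snps_per_gene=5, frac_causal_genes=0.2,
                     b_xy_causal=0.2, b_zx_range=(0.2, 0.5),
                     n_gwas_cohorts=2, n_per_cohort=(50_000, 20_000),
                     n_eqtl=5_000, seed=7)


@pytest.fixture(scope="session")
def small_summary(small_config):
    return simulate_summary_stats(small_config)
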