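import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from smrpipe import (SMR, bonferroni, bzx_from_z, delta_variance,
                     select_instruments, smr_pvalue, t_smr_approx,
                     t_smr_delta, variance_from_r2, wald_ratio)
from smrpipe import TestConfig as ScanConfig


class TestBzxFromZ:
    def test_null_z_gives_reference_se(self):
        b, se = bzx_from_z(0.0, 0.25, 2000)
        assert b == 0.0
        assert se == pytest.approx(1 / np.sqrt(2 * 0.25 * 0.75 * 2000))

    def test_hand_case(self):
        # z=5, f=0.5, n=1000: se = 1/sqrt(0.5*1025)
        b, se = bzx_from_z(5.0, 0.5, 1000)
        assert se == pytest.approx(0.0441726, abs=1e-7)
        assert b == pytest.approx(0.220863, abs=1e-6)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.5])
    def test_frequency_domain_error(self, f):
        with pytest.raises(ValueError):
            bzx_from_z(1.0, f, 1000)

    def test_monte_carlo_recovery(self):
        """Estimated b_zx is unbiased at b_zx=0.2, f=0.3, n=5000."""
        rng = np.random.default_rng(21)
        ncp = 0.2 * np.sqrt(2 * 0.3 * 0.7 * 5000)
        z = rng.normal(ncp, 1.0, size=2000)
        b, _ = bzx_from_z(z, 0.3, 5000)
        assert 0.19 <= b.mean() <= 0.21


class TestWaldRatio:
    def test_division(self):
        assert wald_ratio(0.05, 0.25) == pytest.approx(0.2)

    def test_null_numerator(self):
        assert wald_ratio(0.0, 0.25) == 0.0

    def test_allele_flip_invariance(self):
        assert wald_ratio(-0.05, -0.25) == wald_ratio(0.05, 0.25)

    def test_zero_instrument_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.05, 0.0)


class TestDeltaVariance:
    def test_hand_case(self):
        var = delta_variance(0.05, 0.01, 0.25, 0.02)
        assert var == pytest.approx(0.001856, abs=1e-12)

    def test_exact_instrument_limit(self):
        var = delta_variance(0.05, 0.01, 0.25, 0.0)
        assert var == pytest.approx(0.01**2 / 0.25**2, abs=1e-15)

    def test_defined_at_zero_numerator(self):
        var = delta_variance(0.0, 0.01, 0.25, 0.02)
        assert var == pytest.approx(0.01**2 / 0.25**2, abs=1e-15)

    def test_zero_instrument_rejected(self):
        with pytest.raises(ZeroDivisionError):
            delta_variance(0.05, 0.01, 0.0, 0.02)


class TestStatistics:
    def test_t_delta_hand_case(self):
        assert t_smr_delta(0.2, 0.001856) == pytest.approx(21.5517, abs=1e-3)

    def test_t_delta_even_in_sign(self):
        assert t_smr_delta(-0.2, 0.001856) == t_smr_delta(0.2, 0.001856)

    def test_t_delta_rejects_bad_variance(self):
        with pytest.raises(ValueError):
            t_smr_delta(0.2, 0.0)

    def test_t_approx_hand_case(self):
        assert t_smr_approx(2.0, 4.0) == pytest.approx(64 / 20)

    def test_t_approx_null_numerator(self):
        assert t_smr_approx(0.0, 3.0) == 0.0

    def test_t_approx_exact_instrument_limit(self):
        assert t_smr_approx(2.5, 1e6) == pytest.approx(2.5**2, abs=1e-6)

    def test_t_approx_double_zero_convention(self):
        assert t_smr_approx(0.0, 0.0) == 0.0

    def test_pvalue_boundaries_and_critical_value(self):
        assert smr_pvalue(0.0) == pytest.approx(1.0)
        assert smr_pvalue(3.841459) == pytest.approx(0.05, abs=1e-6)

    def test_pvalue_strictly_decreasing(self):
        grid = np.linspace(0, 30, 200)
        p = smr_pvalue(grid)
        assert np.all(np.diff(p) < 0)

    def test_variance_from_r2_diagnostic(self):
        # var(y)=1, R2_xy=0.1, var(x)=1, R2_zx=0.05, n=1000
        assert variance_from_r2(1.0, 1.0, 0.1, 0.05, 1000) == \
            pytest.approx(0.9 / 50)
        with pytest.raises(ValueError):
            variance_from_r2(1.0, 1.0, 0.1, 0.0, 1000)


def _eqtl_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "snp", "a1", "a2", "freq",
                                       "z", "p", "n"])


class TestSelectInstruments:
    def test_unit_threshold_selects_everything(self):
        eqtl = _eqtl_frame([("G1", "rs1", "A", "G", 0.3, 1.0, 0.3, 500),
                            ("G2", "rs2", "A", "G", 0.3, 2.0, 0.04, 500)])
        pairs, untested = select_instruments(
            eqtl, ScanConfig(instrument_p_threshold=1.0))
        assert len(pairs) == 2 and untested == []

    def test_top_per_gene_picks_smallest_p(self):
        eqtl = _eqtl_frame([("G1", "rs1", "A", "G", 0.3, 6.1, 1e-9, 500),
                            ("G1", "rs2", "A", "G", 0.3, 3.2, 1e-3, 500)])
        pairs, _ = select_instruments(
            eqtl, ScanConfig(instrument_p_threshold=5e-8,
                             mode="top_per_gene"))
        assert pairs["snp"].tolist() == ["rs1"]

    def test_per_pair_count_matches_filter_oracle(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, size=200)
        eqtl = _eqtl_frame([(f"G{i % 20}", f"rs{i}", "A", "G", 0.3,
                             stats.norm.isf(p[i] / 2), p[i], 500)
                            for i in range(200)])
        cfg = ScanConfig(instrument_p_threshold=0.1)
        pairs, untested = select_instruments(eqtl, cfg)
        assert len(pairs) == int((p <= 0.1).sum())
        brute_untested = {f"G{i % 20}" for i in range(200)} - \
            {f"G{i % 20}" for i in range(200) if p[i] <= 0.1}
        assert set(untested) == brute_untested

    def test_top_per_gene_tie_break_prefers_larger_z(self):
        eqtl = _eqtl_frame([("G1", "rs_b", "A", "G", 0.3, -5.0, 1e-4, 500),
                            ("G1", "rs_a", "A", "G", 0.3, 4.0, 1e-4, 500)])
        pairs, _ = select_instruments(
            eqtl, ScanConfig(instrument_p_threshold=1.0, mode="top_per_gene"))
        assert pairs["snp"].tolist() == ["rs_b"]


class TestBonferroni:
    def test_threshold_and_flags(self):
        p = np.full(100, 0.9)
        p[0], p[1] = 4e-4, 6e-4
        flags, threshold = bonferroni(p, alpha=0.05)
        assert threshold == pytest.approx(5e-4)
        assert flags[0] and not flags[1]

    def test_single_test_uses_alpha(self):
        flags, threshold = bonferroni([0.04], alpha=0.05)
        assert threshold == 0.05 and flags[0]

    def test_count_non_increasing_in_m(self):
        p = np.array([1e-4, 2e-3, 0.02, 0.4])
        counts = [bonferroni(np.r_[p, np.full(extra, 0.99)], 0.05)[0].sum()
                  for extra in (0, 10, 100, 1000)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([], 0.05)


class TestSmrEstimator:
    def test_sklearn_contract(self):
        est = SMR(alpha=0.01, mode="top_per_gene")
        params = est.get_params()
        assert params["alpha"] == 0.01
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_eqtl_alleles_reoriented_to_gwas(self, small_summary):
        gwas, eqtl, _ = small_summary
        flipped = eqtl.copy()
        flipped[["a1", "a2"]] = flipped[["a2", "a1"]].to_numpy()
        flipped["z"] = -flipped["z"]
        flipped["freq"] = 1 - flipped["freq"]
        a = SMR(instrument_p_threshold=1.0).fit(gwas[0], eqtl).results_
        b = SMR(instrument_p_threshold=1.0).fit(gwas[0], flipped).results_
        np.testing.assert_allclose(a["T_SMR"], b["T_SMR"], rtol=1e-12)
        np.testing.assert_allclose(a["b_xy"], b["b_xy"], rtol=1e-12)

    def test_allele_mismatch_pairs_excluded(self, small_summary):
        gwas, eqtl, _ = small_summary
        broken = eqtl.copy()
        broken.loc[0, ["a1", "a2"]] = ["C", "T"] \
            if gwas[0].loc[0, "a1"] not in ("C", "T") else ["A", "G"]
        est = SMR(instrument_p_threshold=1.0).fit(gwas[0], broken)
        assert est.log_["smr.pairs_allele_mismatch"] == 1
        assert broken.loc[0, "snp"] in set(est.exclusions_["snp"])

    def test_statistic_modes_agree_for_strong_instruments(self, small_summary):
        gwas, eqtl, _ = small_summary
        strong = eqtl[np.abs(eqtl["z"]) >= 10]
        approx = SMR(instrument_p_threshold=1.0, statistic="approx") \
            .fit(gwas[0], strong).results_
        delta = SMR(instrument_p_threshold=1.0, statistic="delta") \
            .fit(gwas[0], strong).results_
        np.testing.assert_allclose(approx["T_SMR"], delta["T_SMR"], rtol=0.05)

    def test_invariants_on_results(self, small_summary):
        gwas, eqtl, _ = small_summary
        res = SMR(instrument_p_threshold=1.0).fit(gwas[0], eqtl).results_
        assert (res["T_SMR"] >= 0).all()
        assert ((res["p_SMR"] > 0) & (res["p_SMR"] <= 1)).all()
        z_zy = res["b_zy"] / res["se_zy"]
        z_zx = res["b_zx"] / res["se_zx"]
        assert (res["T_SMR"] <= np.minimum(z_zy**2, z_zx**2) + 1e-9).all()
        sign = np.sign(res["b_zy"]) * np.sign(res["b_zx"])
        nonzero = res["b_xy"] != 0
        assert (np.sign(res.loc[nonzero, "b_xy"]) == sign[nonzero]).all()
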