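"""Per-SNP factor GWAS: expansion, estimation, calibration, power summary."""

import numpy as np
import pandas as pd
import pytest

from gsemkit import gwas, ldsc, sem, simulate as sm
from gsemkit._linalg import vech_pair_index
from tests.conftest import exact_estimate


def _snp_rows(labels, betas, se=0.01):
    return {lab: {"beta": b, "se": se} for lab, b in zip(labels, betas)}


class TestExpandWithSnp:
    def test_null_snp_gives_diagonal_block(self):
        est = exact_estimate(["a", "b"], [[0.2, 0.1], [0.1, 0.2]])
        s_full, v_full, labels = gwas.expand_with_snp(
            est, _snp_rows(["a", "b"], [0.0, 0.0]), maf=0.3)
        assert labels[-1] == gwas.SNP_LABEL
        np.testing.assert_allclose(s_full[:2, 2], 0.0)
        assert s_full[2, 2] == pytest.approx(2 * 0.3 * 0.7)

    def test_linearity_in_genotype_variance(self):
        est = exact_estimate(["a", "b"], [[0.2, 0.1], [0.1, 0.2]])
        rows = _snp_rows(["a", "b"], [0.02, -0.01])
        s1, _, _ = gwas.expand_with_snp(est, rows, maf=0.1)
        s2, _, _ = gwas.expand_with_snp(est, rows, maf=0.5)
        ratio = (2 * 0.5 * 0.5) / (2 * 0.1 * 0.9)
        np.testing.assert_allclose(s2[:2, 2], s1[:2, 2] * ratio)

    def test_matches_hand_computed_oracle(self):
        """Independent elementwise construction of the expanded (S, V)."""
        s = np.array([[0.25, 0.05], [0.05, 0.16]])
        intercepts = np.array([[1.0, 0.2], [0.2, 1.0]])
        est = exact_estimate(["a", "b"], s)
        est.intercepts = intercepts
        beta, se, maf = [0.03, -0.02], [0.011, 0.013], 0.25
        s_full, v_full, _ = gwas.expand_with_snp(
            est, {"a": {"beta": beta[0], "se": se[0]},
                  "b": {"beta": beta[1], "se": se[1]}}, maf)
        vx = 2 * maf * (1 - maf)
        expected_s = np.zeros((3, 3))
        expected_s[:2, :2] = s
        expected_s[2, 2] = vx
        expected_s[0, 2] = expected_s[2, 0] = beta[0] * vx
        expected_s[1, 2] = expected_s[2, 1] = beta[1] * vx
        np.testing.assert_allclose(s_full, expected_s, atol=1e-15)
        pair = vech_pair_index(3)
        for t in range(2):
            for u in range(2):
                assert v_full[pair[(t, 2)], pair[(u, 2)]] == pytest.approx(
                    vx ** 2 * se[t] * se[u] * intercepts[t, u])
        assert v_full[pair[(2, 2)], pair[(2, 2)]] == 0.0

    def test_missing_trait_errors(self):
        est = exact_estimate(["a", "b"], np.eye(2) * 0.2)
        with pytest.raises(KeyError, match="b"):
            gwas.expand_with_snp(est, _snp_rows(["a"], [0.0]), maf=0.3)


class TestSnpFactorEffect:
    def test_passthrough_identity(self):
        """A factor with one indicator at fixed unit loading and zero
        residual reproduces the indicator GWAS exactly."""
        est = exact_estimate(["a"], [[0.2]], v_scale=1e-6)
        spec = sem.parse_model("F =: a@1\na ~~ a@0",
                               identification="unit-loading")
        beta, se = 0.0123, 0.0045
        out = gwas.snp_factor_effect(
            spec, est, {"a": {"beta": beta, "se": se}}, maf=0.3, target="F")
        sd_f = np.sqrt(0.2)
        assert out["beta"] * sd_f == pytest.approx(beta, abs=1e-6)
        assert out["se"] * sd_f == pytest.approx(se, abs=1e-6)
        assert out["z"] == pytest.approx(beta / se, abs=1e-6)

    def test_null_snp_gives_zero_z(self):
        lam = np.array([0.6, 0.5, 0.4])
        s = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        est = exact_estimate(["a", "b", "c"], s)
        spec = sem.parse_model("F =: a, b, c")
        out = gwas.snp_factor_effect(
            spec, est, _snp_rows(["a", "b", "c"], [0.0, 0.0, 0.0]),
            maf=0.2, target="F")
        assert out["z"] == 0.0 and out["p"] == 1.0

    def test_conditional_agrees_with_full_refit(self):
        lam = np.array([0.6, 0.5, 0.4])
        s = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        est = exact_estimate(["a", "b", "c"], s, v_scale=1e-7)
        spec = sem.parse_model("F =: a@1, b, c",
                               identification="unit-loading")
        rows = _snp_rows(["a", "b", "c"], [0.012, 0.011, 0.008], se=0.005)
        cond = gwas.snp_factor_effect(spec, est, rows, maf=0.3, target="F")
        full = gwas.snp_factor_effect(spec, est, rows, maf=0.3, target="F",
                                      mode="full")
        assert cond["beta"] == pytest.approx(full["beta"], rel=1e-3)

    def test_allele_flip_invariance(self):
        lam = np.array([0.6, 0.5, 0.4])
        s = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        est = exact_estimate(["a", "b", "c"], s)
        spec = sem.parse_model("F =: a, b, c")
        betas = [0.02, 0.015, 0.01]
        plus = gwas.snp_factor_effect(spec, est, _snp_rows(list("abc"), betas),
                                      maf=0.3, target="F")
        minus = gwas.snp_factor_effect(
            spec, est, _snp_rows(list("abc"), [-b for b in betas]),
            maf=0.3, target="F")
        assert plus["beta"] == pytest.approx(-minus["beta"])
        assert abs(plus["z"]) == pytest.approx(abs(minus["z"]))


class TestRunFactorGwas:
    def test_deterministic(self, factor_panel):
        _, _, tables, _, est, spec, _ = factor_panel
        small = {k: v.head(500) for k, v in tables.items()}
        r1 = gwas.run_factor_gwas(small, est, spec, "F")
        r2 = gwas.run_factor_gwas(small, est, spec, "F")
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_snp_skipped_and_counted(self, factor_panel):
        _, _, tables, _, est, spec, _ = factor_panel
        small = {k: v.head(500).copy() for k, v in tables.items()}
        dropped_snp = small["t2"]["snp"].iloc[10]
        small["t2"] = small["t2"].drop(small["t2"].index[10])
        res = gwas.run_factor_gwas(small, est, spec, "F")
        assert dropped_snp not in set(res["snp"])
        assert res.attrs["n_skipped"] == 1

    def test_effect_recovery_slope(self, factor_panel):
        """Estimated SNP factor effects regress on the generating effects
        with slope near 1 (per standardized genotype and unit factor)."""
        _, _, tables, truth, est, spec, _ = factor_panel
        res = gwas.run_factor_gwas(tables, est, spec, "F")
        merged = res.merge(truth, on="snp")
        per_geno = merged["beta"] * np.sqrt(
            2 * merged["maf"] * (1 - merged["maf"]))
        x = merged["factor_effect_1"].to_numpy()
        slope = float(x @ per_geno) / float(x @ x)
        assert 0.9 <= slope <= 1.1

    def test_type_one_error_calibrated(self, factor_panel):
        """Null SNPs (no genetic signal) reject at the nominal 5% rate
        within binomial bounds."""
        cfg, _, _, _, est, spec, _ = factor_panel
        n_seeds, within = 10, 0
        for s in range(n_seeds):
            null_cfg = sm.SimulationConfig(
                m=2_000, labels=cfg.labels, n=cfg.n, seed=100 + s,
                sigma_g=np.zeros((4, 4)))
            null_ld = sm.simulate_ld_reference(null_cfg)
            null_tabs = sm.simulate_sumstats(null_cfg, null_ld)
            res = gwas.run_factor_gwas(null_tabs, est, spec, "F")
            rate = float((res["p"] < 0.05).mean())
            half_width = 1.96 * np.sqrt(0.05 * 0.95 / len(res))
            within += abs(rate - 0.05) <= half_width
        # each seed's rate sits in its binomial 95% band at the rate the
        # band implies (>= 8 of 10)
        assert within >= 8

    def test_empty_intersection_errors(self, factor_panel):
        _, _, tables, _, est, spec, _ = factor_panel
        broken = {k: v.head(100).copy() for k, v in tables.items()}
        broken["t1"]["snp"] = "zz_" + broken["t1"]["snp"]
        with pytest.raises(ValueError, match="no SNPs shared"):
            gwas.run_factor_gwas(broken, est, spec, "F")


class TestPowerSummaries:
    def test_expected_sample_size_exact_inversion(self):
        n = 50_000.0
        rng = np.random.default_rng(0)
        maf = rng.uniform(0.11, 0.39, 100)
        se = 1.0 / np.sqrt(n * 2 * maf * (1 - maf))
        res = pd.DataFrame({"maf": maf, "se": se, "z": 0.0})
        assert gwas.expected_sample_size(res) == pytest.approx(n, rel=1e-12)

    def test_maf_window_respected(self):
        res = pd.DataFrame({"maf": [0.05, 0.45], "se": [0.1, 0.1],
                            "z": [0.0, 0.0]})
        with pytest.raises(ValueError, match="MAF"):
            gwas.expected_sample_size(res)

    def test_z_invariant_to_joint_rescaling(self):
        """z (hence p) is scale-free; expected N requires the standardized
        factor scale and changes by 1/c^2 under a joint rescale by c."""
        rng = np.random.default_rng(1)
        maf = rng.uniform(0.11, 0.39, 50)
        se = 1.0 / np.sqrt(10_000 * 2 * maf * (1 - maf))
        beta = rng.normal(0, se)
        res = pd.DataFrame({"maf": maf, "beta": beta, "se": se,
                            "z": beta / se})
        scaled = res.assign(beta=res["beta"] * 3, se=res["se"] * 3)
        np.testing.assert_allclose(scaled["beta"] / scaled["se"], res["z"])
        assert gwas.expected_sample_size(scaled) == pytest.approx(
            gwas.expected_sample_size(res) / 9, rel=1e-9)

    def test_simulated_expected_n_within_envelope(self, factor_panel):
        """N-hat of the simulated factor GWAS lands within 10% of the
        information-sum prediction sum_t N_t lambda_t^2 and inside the
        (max_t N_t min lambda^2, sum_t N_t) envelope."""
        _, _, tables, _, est, spec, lam = factor_panel
        res = gwas.run_factor_gwas(tables, est, spec, "F")
        nhat = gwas.expected_sample_size(res)
        theory = float(np.sum(50_000.0 * lam ** 2))
        assert nhat == pytest.approx(theory, rel=0.10)
        assert 50_000.0 * lam.min() ** 2 < nhat < 4 * 50_000.0

    @pytest.mark.parametrize("z,expected", [
        ([1.0, 1.0, 1.0], 1.0),
        ([0.0, 2.0], 2.0),
    ])
    def test_mean_chisq(self, z, expected):
        res = pd.DataFrame({"z": z})
        assert gwas.mean_chisq(res) == pytest.approx(expected)

    def test_mean_chisq_null_calibration(self, factor_panel):
        cfg, _, _, _, est, spec, _ = factor_panel
        null_cfg = sm.SimulationConfig(m=5_000, labels=cfg.labels, n=cfg.n,
                                       seed=55, sigma_g=np.zeros((4, 4)))
        null_ld = sm.simulate_ld_reference(null_cfg)
        null_tabs = sm.simulate_sumstats(null_cfg, null_ld)
        res = gwas.run_factor_gwas(null_tabs, est, spec, "F")
        assert gwas.mean_chisq(res) == pytest.approx(1.0, abs=0.1)
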