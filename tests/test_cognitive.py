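"""Model builders: df bookkeeping, orthogonality, variance decomposition."""

import numpy as np
import pytest

from gsemkit import cognitive, ldsc, sem, simulate as sm
from tests.conftest import exact_estimate


@pytest.fixture
def battery():
    return cognitive.CognitiveBattery()


class TestBuilders:
    @pytest.mark.parametrize("builder,df", [
        (cognitive.build_cfa, 11),
        (cognitive.build_extended, 21),
        (cognitive.build_subtraction, 15),
    ])
    def test_df_bookkeeping(self, battery, demo_exact_estimate, builder, df):
        res = sem.fit_dwls(builder(battery), demo_exact_estimate)
        assert res.df == df
        assert res.converged

    def test_cfa_free_parameter_census(self, battery, demo_exact_estimate):
        compiled = sem.compile_model(cognitive.build_cfa(battery),
                                     demo_exact_estimate.labels)
        loadings = [l for l in compiled.free_labels if "=:" in l]
        assert len(loadings) == 8  # incl. the cross-loading indicator twice
        assert sum("~~" in l and l.split("~~")[0] != l.split("~~")[1]
                   for l in compiled.free_labels) == 3

    def test_missing_gc_indicator_errors(self):
        with pytest.raises(ValueError, match="Gc-indicator"):
            cognitive.CognitiveBattery(gc_indicators=["VocSyn"])

    def test_extended_dropping_language_gf_path_raises_df(self, battery,
                                                          demo_exact_estimate):
        spec = cognitive.build_extended(battery)
        dropped = sem.ModelSpec(
            statements=[s for s in spec.statements
                        if s.key() != ("loading", "Gf", "LANG")],
            latents=spec.latents, identification=spec.identification)
        res = sem.fit_dwls(dropped, demo_exact_estimate)
        assert res.df == 22

    def test_subtraction_recovers_generating_decomposition(
            self, battery, demo_exact_estimate):
        res = sem.fit_dwls(cognitive.build_subtraction(battery),
                           demo_exact_estimate)
        shares = cognitive.variance_decomposition(res, "EA")
        gen = {f: 100 * l ** 2 for f, l in zip(
            cognitive.SUBTRACTION_FACTORS, sm.DEMO_STD_LOADINGS["EA"])}
        for fac in cognitive.SUBTRACTION_FACTORS:
            assert shares[fac] == pytest.approx(gen[fac], abs=1e-3)
        assert sum(shares.values()) == pytest.approx(100.0, abs=1e-6)

    def test_builders_round_trip_through_serializer(self, battery):
        for builder in (cognitive.build_cfa, cognitive.build_extended,
                        cognitive.build_subtraction):
            spec = builder(battery)
            again = sem.parse_model(spec.to_text())
            assert {(s.key(), s.fixed, s.start) for s in again.statements} \
                == {(s.key(), s.fixed, s.start) for s in spec.statements}
            assert again.identification == spec.identification
            # per-factor loading order (which sets unit-loading anchors)
            # survives the round trip
            for fac in spec.factors():
                assert [s.rhs for s in again.statements
                        if s.kind == "loading" and s.lhs == fac] \
                    == [s.rhs for s in spec.statements
                        if s.kind == "loading" and s.lhs == fac]

    def test_gwas_mode_anchors_fixed(self, battery):
        spec = cognitive.build_subtraction(battery, gwas_mode=True)
        fixed = {s.key(): s.fixed for s in spec.statements
                 if s.fixed is not None and s.kind == "loading"}
        assert fixed == {("loading", "RTg", "RT"): 1.0,
                         ("loading", "Gf_u", "matrix"): 1.0,
                         ("loading", "Gc_u", "VocSyn"): 1.0,
                         ("loading", "NonCog", "EA"): 1.0}


class TestLanguageFactor:
    def test_df_bookkeeping(self):
        traits = ["word_reading", "nonword_reading", "phoneme_awareness",
                  "spelling"]
        lam = np.full(4, 0.95)
        s = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        est = exact_estimate(traits, s, v_scale=1e-6)
        res = sem.fit_dwls(cognitive.build_language_factor(traits), est)
        assert res.df == 2
        for t in traits:
            assert res[f"LANGg=:{t}"] == pytest.approx(0.95, abs=1e-3)

    def test_unit_loading_chi2_identical(self):
        traits = ["word_reading", "nonword_reading", "phoneme_awareness",
                  "spelling"]
        rng = np.random.default_rng(5)
        lam = np.array([0.95, 0.96, 0.94, 0.95])
        s = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        jitter = rng.normal(0, 0.005, s.shape)
        s = s + (jitter + jitter.T) / 2
        est = exact_estimate(traits, s, v_scale=1e-5)
        uv = sem.fit_dwls(cognitive.build_language_factor(traits), est)
        ul = sem.fit_dwls(cognitive.build_language_factor(traits,
                                                          gwas_mode=True), est)
        assert uv.chi2 == pytest.approx(ul.chi2, abs=1e-6)
        anchored = {s.key(): s.fixed for s in
                    cognitive.build_language_factor(traits, gwas_mode=True
                                                    ).statements}
        assert anchored[("loading", "LANGg", "nonword_reading")] == 1.0

    def test_wrong_trait_count_errors(self):
        with pytest.raises(ValueError, match="4 traits"):
            cognitive.build_language_factor(["a", "b", "c"])


class TestSubtractionContract:
    def test_factor_covariances_exactly_zero(self, battery, demo_exact_estimate):
        res = sem.fit_dwls(cognitive.build_subtraction(battery),
                           demo_exact_estimate)
        compiled = res.compiled
        full = compiled.implied_full(res.theta)
        idx = [compiled.var_names.index(f)
               for f in cognitive.SUBTRACTION_FACTORS]
        block = full[np.ix_(idx, idx)]
        off = block - np.diag(np.diag(block))
        assert np.abs(off).max() == 0.0

    def test_cholesky_equals_correlated_on_saturated_toy(self):
        """On a toy where both parameterizations are saturated, the
        correlated-factor and Cholesky fits imply the same covariance."""
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.4, (4, 4))
        s = a @ a.T + 0.5 * np.eye(4)
        est = exact_estimate(list("wxyz"), s, v_scale=1e-6)
        correlated = sem.parse_model(
            "F1 =: w\nF2 =: x\nF3 =: y\nF4 =: z\n"
            "w ~~ w@0\nx ~~ x@0\ny ~~ y@0\nz ~~ z@0\n"
            "F1 ~~ F2\nF1 ~~ F3\nF1 ~~ F4\nF2 ~~ F3\nF2 ~~ F4\nF3 ~~ F4")
        cholesky = sem.parse_model(
            "C1 =: w, x, y, z\nC2 =: x, y, z\nC3 =: y, z\nC4 =: z\n"
            "w ~~ w@0\nx ~~ x@0\ny ~~ y@0\nz ~~ z@0\n"
            "C1 ~~ C2@0\nC1 ~~ C3@0\nC1 ~~ C4@0\n"
            "C2 ~~ C3@0\nC2 ~~ C4@0\nC3 ~~ C4@0")
        r1 = sem.fit_dwls(correlated, est)
        r2 = sem.fit_dwls(cholesky, est)
        assert np.abs(r1.sigma - r2.sigma).max() < 1e-6
        np.testing.assert_allclose(r1.sigma, s, atol=1e-6)


class TestExternal:
    def test_adds_exactly_five_free_parameters(self, battery,
                                               demo_exact_estimate):
        base = cognitive.build_subtraction(battery)
        ext_labels = demo_exact_estimate.labels + ["DIS"]
        base_compiled = sem.compile_model(base, demo_exact_estimate.labels)
        ext = cognitive.build_external(battery, "DIS")
        ext_compiled = sem.compile_model(ext, ext_labels)
        assert ext_compiled.n_free == base_compiled.n_free + 5

    def test_recovery_of_external_correlations(self, battery):
        # generating external trait with the sign pattern seen for
        # psychotic disorders: worse RT/fluid, better crystallized/noncog
        r = np.array([-0.2, -0.2, 0.15, 0.1])
        h2_dis = 0.2
        labels = list(sm.DEMO_STD_LOADINGS)
        std = np.array([sm.DEMO_STD_LOADINGS[t] for t in labels])
        h2 = np.array([sm.DEMO_H2[t] for t in labels])
        g = std * np.sqrt(h2)[:, None]
        g = np.vstack([g, r * np.sqrt(h2_dis)])
        s = g @ g.T + np.diag(np.append(
            h2 * np.clip(1 - (std ** 2).sum(axis=1), 0, None),
            h2_dis * (1 - np.sum(r ** 2))))
        est = exact_estimate(labels + ["DIS"], s, v_scale=1e-8)
        res = sem.fit_dwls(cognitive.build_external(battery, "DIS"), est)
        std_sol = sem.standardize(res).set_index("parameter")
        for fac, truth in zip(cognitive.SUBTRACTION_FACTORS, r):
            assert std_sol.loc[f"DIS~~{fac}", "std_estimate"] \
                == pytest.approx(truth, abs=1e-3)

    def test_externals_leave_cognitive_parameters_unchanged(self, battery,
                                                            demo_exact_estimate):
        r1 = np.array([-0.2, -0.2, 0.15, 0.1])
        r2 = np.array([0.1, -0.05, 0.3, 0.2])
        labels = list(sm.DEMO_STD_LOADINGS)
        std = np.array([sm.DEMO_STD_LOADINGS[t] for t in labels])
        h2 = np.array([sm.DEMO_H2[t] for t in labels])
        g = std * np.sqrt(h2)[:, None]
        g = np.vstack([g, r1 * np.sqrt(0.2), r2 * np.sqrt(0.15)])
        uniq = np.concatenate([
            h2 * np.clip(1 - (std ** 2).sum(axis=1), 0, None),
            [0.2 * (1 - np.sum(r1 ** 2)), 0.15 * (1 - np.sum(r2 ** 2))]])
        s = g @ g.T + np.diag(uniq)
        est = exact_estimate(labels + ["D1", "D2"], s, v_scale=1e-8)
        fit1 = sem.fit_dwls(cognitive.build_external(battery, "D1"), est)
        fit2 = sem.fit_dwls(cognitive.build_external(battery, "D2"), est)
        shared = [l for l in fit1.labels if "D1" not in l and "D2" not in l]
        for lab in shared:
            assert fit1[lab] == pytest.approx(fit2[lab], abs=1e-6)

    def test_missing_external_trait(self, battery, demo_exact_estimate):
        spec = cognitive.build_external(battery, "GHOST")
        with pytest.raises(ValueError, match="GHOST"):
            sem.fit_dwls(spec, demo_exact_estimate)


class TestVarianceDecomposition:
    @pytest.mark.parametrize("loading,expected", [
        (0.75, 43.75),   # printed worked example: 1 - 0.75^2
        (1.0, 0.0),
        (0.0, 100.0),
    ])
    def test_combined_path(self, loading, expected):
        assert cognitive.noncog_share(loading) == pytest.approx(expected)

    def test_vector_of_paths(self):
        assert cognitive.noncog_share([0.3, 0.4]) == pytest.approx(75.0)

    def test_cfa_factor_correlation_recovery(self, battery, trivariate_panel=None):
        """Fitting the correlated model to a simulated battery recovers the
        generating factor correlations within two sandwich SEs."""
        cfg = sm.demo_config(m=20_000, seed=7)
        ld = sm.simulate_ld_reference(cfg)
        tables, _ = sm.simulate_factor_architecture(cfg, ld)
        est = ldsc.build_covariance(tables, ld, n_blocks=200)
        res = sem.fit_dwls(cognitive.build_cfa(battery), est)
        std = sem.standardize(res)
        # generating correlation of the RT and fluid streams
        gen = np.array([sm.DEMO_STD_LOADINGS[t] for t in sm.DEMO_STD_LOADINGS])
        # implied factor correlations of the generating Cholesky model
        # (fluid factor = mix of RT and unique-fluid components)
        lam_gf = np.array(sm.DEMO_STD_LOADINGS["matrix"])
        rt_gf_true = lam_gf[0] / np.linalg.norm(lam_gf)
        row = std.set_index("parameter")
        est_corr = row.loc["RTg~~Gf", "std_estimate"]
        se_corr = row.loc["RTg~~Gf", "std_se"]
        assert abs(est_corr - rt_gf_true) < max(2 * se_corr, 0.05)
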