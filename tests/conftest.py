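import numpy as np
import pandas as pd
import pytest

from gsemkit import simulate as sm
from gsemkit.ldsc import CovarianceEstimate


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """A tiny harmonized sumstats table with exact z = beta/se."""
    beta = np.array([0.01, -0.02, 0.005, 0.0])
    se = np.array([0.01, 0.01, 0.02, 0.01])
    return pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3", "rs4"],
        "chr": [1, 1, 2, 2], "bp": [1000, 2000, 1000, 2000],
        "a1": ["A", "C", "G", "T"], "a2": ["G", "T", "A", "C"],
        "freq": [0.3, 0.5, 0.2, 0.45],
        "beta": beta, "se": se, "z": beta / se,
        "p": [0.3, 0.05, 0.8, 1.0], "n": [10_000.0] * 4,
    })


@pytest.fixture
def panel(toy_table) -> pd.DataFrame:
    return pd.DataFrame({
        "snp": toy_table["snp"], "chr": toy_table["chr"], "bp": toy_table["bp"],
        "a1": toy_table["a1"], "a2": toy_table["a2"],
        "maf": np.minimum(toy_table["freq"], 1 - toy_table["freq"]),
    })


def exact_estimate(labels, s, v_scale=1e-8) -> CovarianceEstimate:
    """A CovarianceEstimate with exact S and a tiny diagonal V."""
    k = len(labels)
    q = k * (k + 1) // 2
    return CovarianceEstimate(labels=list(labels), s=np.asarray(s, float),
                              v=np.eye(q) * v_scale, intercepts=np.eye(k),
                              m=100_000, mean_chisq=np.ones(k))


@pytest.fixture(scope="session")
def demo_exact_estimate() -> CovarianceEstimate:
    """Noise-free S implied by the demo generating battery."""
    labels = list(sm.DEMO_STD_LOADINGS)
    std = np.array([sm.DEMO_STD_LOADINGS[t] for t in labels])
    h2 = np.array([sm.DEMO_H2[t] for t in labels])
    g = std * np.sqrt(h2)[:, None]
    s = g @ g.T + np.diag(h2 * np.clip(1 - (std ** 2).sum(axis=1), 0, None))
    return exact_estimate(labels, s)


@pytest.fixture(scope="session")
def factor_panel():
    """Single-factor architecture with four indicators and known truth,
    shared by the factor-GWAS tests."""
    from gsemkit import ldsc, sem
    lam = np.array([0.9, 0.85, 0.8, 0.75]) * np.sqrt(0.2)
    cfg = sm.SimulationConfig(m=20_000, labels=["t1", "t2", "t3", "t4"],
                              n=np.full(4, 50_000.0), seed=11,
                              loadings=lam.reshape(1, -1),
                              h2_factor=np.array([1.0]),
                              h2_unique=0.05 * np.ones(4))
    ld = sm.simulate_ld_reference(cfg)
    tables, truth = sm.simulate_factor_architecture(cfg, ld)
    est = ldsc.build_covariance(tables, ld, n_blocks=200)
    # the overlap-induced intercept matrix is known exactly here, as it is
    # (to high precision) in well-powered real analyses
    est.intercepts = cfg.intercept_matrix()
    spec = sem.parse_model("F =: t1@1, t2, t3, t4",
                           identification="unit-loading")
    return cfg, ld, tables, truth, est, spec, lam


@pytest.fixture(scope="session")
def trivariate_panel():
    """Simulated 3-trait panel at the standard recovery conditions
    (M = 50,000, N = 50,000, h2 = 0.2 each, rg = 0.5), shared across
    LDSC-recovery tests to avoid re-simulation."""
    s_true = np.array([[0.2, 0.1, 0.1], [0.1, 0.2, 0.1], [0.1, 0.1, 0.2]])
    cfg = sm.SimulationConfig(m=50_000, labels=["a", "b", "c"],
                              n=np.full(3, 50_000.0), seed=1, sigma_g=s_true)
    ld = sm.simulate_ld_reference(cfg)
    tables = sm.simulate_sumstats(cfg, ld)
    return cfg, ld, tables, s_true
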