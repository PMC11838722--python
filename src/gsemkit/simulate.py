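"""LDSC-consistent synthetic GWAS summary statistics with known truth.

The generator works directly on the z-statistic scale, which is the
sufficiency level that LD-score regression and summary-statistic SEM
consume. For SNP j with LD score l_j, the k-vector of trait z-statistics is
drawn from a multivariate normal with covariance

    C_j = A * l_j + B,
    A[t,u] = sqrt(N_t N_u) Sigma_g[t,u] / M,
    B[t,t] = 1,   B[t,u] = pheno_corr[t,u] * overlap[t,u] / sqrt(N_t N_u),

so the LDSC regression recovers Sigma_g and B is the intercept matrix
induced by sample overlap. Cross-SNP LD correlation of z is not simulated
(the LD structure enters only through l_j); dedicated block LD matrices are
generated separately for clumping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .loci import LdMatrix
from .sumstats import CohortDesign, effective_n

__all__ = ["SimulationConfig", "simulate_ld_reference", "simulate_ld_matrix",
           "simulate_sumstats", "simulate_factor_architecture",
           "simulate_case_control"]

_N_CHROM = 22
_BP_SPACING = 10_000


@dataclass
class SimulationConfig:
    """Generating parameters for a multi-trait summary-statistic panel.

    ``sigma_g`` may be given directly or derived from a factor structure:
    Sigma_g = sum_f h2_factor[f] * loadings[f] loadings[f]' + diag(h2_unique).
    Loadings are on the standardized trait scale, so a trait's total
    heritability is sum_f h2_factor[f] * loading[f,t]^2 + h2_unique[t].
    """

    m: int
    labels: list[str]
    n: np.ndarray
    seed: int
    sigma_g: np.ndarray | None = None
    loadings: np.ndarray | None = None
    h2_factor: np.ndarray | None = None
    h2_unique: np.ndarray | None = None
    overlap: np.ndarray | None = None
    pheno_corr: np.ndarray | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_shape: float = 2.0
    ld_scale: float = 40.0
    causal_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        self.n = np.asarray(self.n, dtype=float)
        k = len(self.labels)
        if self.n.shape != (k,):
            raise ValueError("one sample size per trait required")
        if self.loadings is not None:
            self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
            self.h2_factor = np.atleast_1d(np.asarray(
                1.0 if self.h2_factor is None else self.h2_factor, dtype=float))
            if self.h2_unique is None:
                self.h2_unique = np.zeros(k)
            self.h2_unique = np.asarray(self.h2_unique, dtype=float)
        if self.sigma_g is None:
            if self.loadings is None:
                raise ValueError("either sigma_g or loadings must be given")
            lam = self.loadings * np.sqrt(self.h2_factor)[:, None]
            self.sigma_g = lam.T @ lam + np.diag(self.h2_unique)
        self.sigma_g = np.asarray(self.sigma_g, dtype=float)
        if self.sigma_g.shape != (k, k):
            raise ValueError("sigma_g must be k x k")
        if np.linalg.eigvalsh((self.sigma_g + self.sigma_g.T) / 2).min() < -1e-8:
            raise ValueError("sigma_g must be positive semidefinite")
        if self.overlap is None:
            self.overlap = np.diag(self.n)
        self.overlap = np.asarray(self.overlap, dtype=float)
        if not np.allclose(self.overlap, self.overlap.T):
            raise ValueError("overlap matrix must be symmetric")
        if not np.allclose(np.diag(self.overlap), self.n):
            raise ValueError("overlap diagonal must equal the sample sizes")
        if self.pheno_corr is None:
            self.pheno_corr = np.eye(k)
        self.pheno_corr = np.asarray(self.pheno_corr, dtype=float)
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal fraction must lie in (0, 1]")

    @property
    def k(self) -> int:
        return len(self.labels)

    def intercept_matrix(self) -> np.ndarray:
        """The k x k LDSC intercept matrix implied by sample overlap."""
        b = self.pheno_corr * self.overlap / np.sqrt(np.outer(self.n, self.n))
        np.fill_diagonal(b, 1.0)
        return b

    def rng(self, stream: int) -> np.random.Generator:
        # independent streams keyed on (seed, stream) keep stages
        # reproducible even when run in different orders
        return np.random.default_rng([int(self.seed), int(stream)])


def _matrix_sqrt(mat: np.ndarray, name: str) -> np.ndarray:
    w, u = np.linalg.eigh((mat + mat.T) / 2)
    if w.min() < -1e-8:
        raise ValueError(f"{name} is not positive semidefinite "
                         f"(min eigenvalue {w.min():.3g}); per-SNP z covariance "
                         "C_j would be invalid — check the simulation config")
    return u * np.sqrt(np.clip(w, 0.0, None))


def simulate_ld_reference(config: SimulationConfig) -> pd.DataFrame:
    """LD-score table: snp, chr, bp, ld, maf; deterministic per seed.

    MAF ~ Uniform over ``maf_range``; LD score ~ 1 + Gamma(shape, scale).
    SNPs are spread evenly over 22 chromosomes at fixed spacing.
    """
    import warnings
    if config.m < 1000:
        warnings.warn("fewer than 1000 SNPs: LDSC estimates will be unstable")
    rng = config.rng(0)
    m = config.m
    per_chrom = int(np.ceil(m / _N_CHROM))
    chrom = np.repeat(np.arange(1, _N_CHROM + 1), per_chrom)[:m]
    bp = np.concatenate([
        np.arange(1, (chrom == c).sum() + 1) * _BP_SPACING
        for c in range(1, _N_CHROM + 1) if (chrom == c).any()])
    return pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(m)],
        "chr": chrom,
        "bp": bp,
        "ld": 1.0 + rng.gamma(config.ld_shape, config.ld_scale, size=m),
        "maf": rng.uniform(*config.maf_range, size=m),
    })


def simulate_ld_matrix(n_snps: int, seed: int, chrom: int = 1,
                       block_size_mean: float = 5.0,
                       bp_spacing: int = _BP_SPACING) -> LdMatrix:
    """A block-diagonal signed LD correlation matrix for clumping tests.

    Blocks have geometric sizes; within a block correlations follow an AR(1)
    profile with random decay and random per-SNP sign flips, which keeps the
    matrix positive semidefinite with unit diagonal.
    """
    rng = np.random.default_rng([int(seed), 7])
    r = np.zeros((n_snps, n_snps))
    start = 0
    while start < n_snps:
        size = min(1 + rng.geometric(1.0 / block_size_mean), n_snps - start)
        rho = rng.uniform(0.3, 0.95)
        signs = rng.choice([-1.0, 1.0], size=size)
        idx = np.arange(size)
        block = rho ** np.abs(idx[:, None] - idx[None, :])
        block = np.outer(signs, signs) * block
        r[start:start + size, start:start + size] = block
        start += size
    np.fill_diagonal(r, 1.0)
    return LdMatrix(
        snp_ids=[f"rs{i + 1}" for i in range(n_snps)],
        chrom=np.full(n_snps, chrom),
        pos=np.arange(1, n_snps + 1) * bp_spacing,
        r=r,
    )


def _tables_from_z(config: SimulationConfig, ld: pd.DataFrame,
                   z: np.ndarray, n: np.ndarray) -> dict[str, pd.DataFrame]:
    maf = ld["maf"].to_numpy()
    tables = {}
    for t, label in enumerate(config.labels):
        se = 1.0 / np.sqrt(n[t] * 2.0 * maf * (1.0 - maf))
        tab = pd.DataFrame({
            "snp": ld["snp"], "chr": ld["chr"], "bp": ld["bp"],
            "a1": "A", "a2": "G", "freq": maf,
            "beta": z[:, t] * se, "se": se, "z": z[:, t],
            "p": 2.0 * norm.sf(np.abs(z[:, t])), "n": n[t],
        })
        tables[label] = tab
    return tables


def _draw_noise(config: SimulationConfig, rng: np.random.Generator,
                m: int) -> np.ndarray:
    b_sqrt = _matrix_sqrt(config.intercept_matrix(), "intercept matrix B")
    return rng.standard_normal((m, config.k)) @ b_sqrt.T


def simulate_sumstats(config: SimulationConfig, ld: pd.DataFrame
                      ) -> dict[str, pd.DataFrame]:
    """Draw per-SNP z vectors from the LDSC model; return one table per trait.

    z_j = sqrt(l_j) * La e1 + Lb e2 with La La' = A and Lb Lb' = B, giving
    cov(z_j) = A l_j + B exactly.
    """
    rng = config.rng(1)
    a = np.sqrt(np.outer(config.n, config.n)) * config.sigma_g / config.m
    a_sqrt = _matrix_sqrt(a, "genetic covariance term A")
    z = (np.sqrt(ld["ld"].to_numpy())[:, None]
         * (rng.standard_normal((config.m, config.k)) @ a_sqrt.T)
         + _draw_noise(config, rng, config.m))
    return _tables_from_z(config, ld, z, config.n)


def simulate_factor_architecture(config: SimulationConfig, ld: pd.DataFrame
                                 ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-SNP factor effects propagated to traits, plus the truth table.

    For each causal SNP (fraction ``causal_fraction``), the marginal factor
    effect is drawn with variance l_j * h2_factor / (c * M) on the
    standardized scale, so the mean chi-square matches the LDSC expectation.
    Trait effects are loadings x factor effects plus trait-unique effects;
    z = sqrt(N_t) * effect + correlated noise.
    """
    if config.loadings is None:
        raise ValueError("factor architecture requires loadings")
    rng = config.rng(2)
    m, k = config.m, config.k
    ell = ld["ld"].to_numpy()
    c = config.causal_fraction
    causal = rng.random(m) < c
    n_fac = config.loadings.shape[0]

    gamma = np.zeros((m, n_fac))
    sd_fac = np.sqrt(ell[:, None] * config.h2_factor[None, :] / (c * m))
    gamma[causal] = rng.standard_normal((causal.sum(), n_fac)) * sd_fac[causal]

    unique = np.zeros((m, k))
    sd_uni = np.sqrt(ell[:, None] * config.h2_unique[None, :] / (c * m))
    unique[causal] = rng.standard_normal((causal.sum(), k)) * sd_uni[causal]

    effects = gamma @ config.loadings + unique
    z = np.sqrt(config.n)[None, :] * effects + _draw_noise(config, rng, m)
    truth = pd.DataFrame({"snp": ld["snp"], "causal": causal})
    for f in range(n_fac):
        truth[f"factor_effect_{f + 1}"] = gamma[:, f]
    return _tables_from_z(config, ld, z, config.n), truth


#: standardized genetic-scale loadings of the demo battery on the four
#: orthogonal generating factors (RT stream, unique fluid, unique
#: crystallized, noncognitive); rows sum-of-squares <= 1, remainder is
#: trait-unique genetic variance. RT and EA have no unique part, matching
#: the zero-residual constraints of the subtraction model.
DEMO_STD_LOADINGS: dict[str, tuple[float, float, float, float]] = {
    "RT":      (1.00, 0.00, 0.00, 0.00),
    "matrix":  (0.25, 0.80, 0.00, 0.00),
    "tower":   (0.25, 0.75, 0.00, 0.00),
    "TMTB":    (0.25, 0.70, 0.00, 0.00),
    "VNR":     (0.20, 0.60, 0.55, 0.00),
    "VocSyn":  (0.12, 0.40, 0.75, 0.00),
    "VocPic":  (0.12, 0.40, 0.70, 0.00),
    "LANG":    (0.10, 0.15, 0.65, 0.00),
    "EA":      (0.05, 0.35, 0.65, 0.67268120),
}

#: per-trait SNP heritabilities for the demo battery (loosely mirroring
#: published estimates for these phenotypes)
DEMO_H2: dict[str, float] = {
    "RT": 0.074, "matrix": 0.147, "tower": 0.120, "TMTB": 0.153,
    "VNR": 0.217, "VocSyn": 0.103, "VocPic": 0.208, "LANG": 0.250,
    "EA": 0.104,
}

#: demo per-trait GWAS sample sizes (desk-scale panel)
DEMO_N: dict[str, int] = {
    "RT": 10_000, "matrix": 5_000, "tower": 5_000, "TMTB": 5_000,
    "VNR": 8_000, "VocSyn": 8_000, "VocPic": 5_000, "LANG": 6_000,
    "EA": 20_000,
}


def demo_config(m: int = 20_000, seed: int = 1,
                external: dict | None = None) -> SimulationConfig:
    """Generating configuration for the bundled nine-trait battery.

    The genetic covariance follows the Cholesky subtraction structure with
    four orthogonal unit-variance factors; optionally one external trait is
    appended with prescribed genetic correlations to the factors, e.g.
    ``external={"label": "SCZ", "h2": 0.225, "n": 8000,
    "factor_corr": (-0.20, -0.25, 0.15, 0.12)}``.
    """
    labels = list(DEMO_STD_LOADINGS)
    std = np.array([DEMO_STD_LOADINGS[t] for t in labels])
    h2 = np.array([DEMO_H2[t] for t in labels])
    loadings = (std * np.sqrt(h2)[:, None]).T          # factors x traits
    h2_unique = h2 * np.clip(1.0 - (std ** 2).sum(axis=1), 0.0, None)
    n = np.array([DEMO_N[t] for t in labels], dtype=float)
    if external is not None:
        r = np.asarray(external["factor_corr"], dtype=float)
        h2_ext = float(external["h2"])
        labels = labels + [external["label"]]
        loadings = np.column_stack([loadings, r * np.sqrt(h2_ext)])
        h2_unique = np.append(h2_unique,
                              h2_ext * max(0.0, 1.0 - float(np.sum(r ** 2))))
        n = np.append(n, float(external["n"]))
    return SimulationConfig(m=m, labels=labels, n=n, seed=seed,
                            loadings=loadings,
                            h2_factor=np.ones(loadings.shape[0]),
                            h2_unique=h2_unique)


def simulate_case_control(config: SimulationConfig, ld: pd.DataFrame,
                          designs: list[CohortDesign], label: str | None = None
                          ) -> pd.DataFrame:
    """Case-control trait simulated on the effective-N scale.

    z statistics are generated exactly as for a continuous trait, with the
    sample size replaced by the summed per-cohort effective N; the table's
    ``n`` column carries that effective N.
    """
    neff = effective_n(designs)
    if config.k != 1:
        raise ValueError("case-control simulation expects a single-trait config")
    sub = SimulationConfig(m=config.m, labels=list(config.labels),
                           n=np.array([neff]), seed=config.seed,
                           sigma_g=config.sigma_g,
                           maf_range=config.maf_range,
                           ld_shape=config.ld_shape, ld_scale=config.ld_scale)
    table = simulate_sumstats(sub, ld)[sub.labels[0]]
    table.attrs["neff"] = neff
    return table
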