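"""Per-SNP multivariate GWAS of latent factors.

Two-stage summary-statistic approach: the structural model is fitted once
to the genome-wide (S, V); each SNP then expands the covariance structure
by one row and the SNP -> factor paths are estimated by weighted least
squares on the SNP-covariance moments, with sandwich standard errors that
propagate the full per-SNP sampling covariance (cross-trait terms through
the LDSC intercept matrix). By default the structural parameters are held
at their genome-wide estimates (conditional estimation); a full joint
per-SNP refit is available via ``mode="full"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._linalg import subset_vech_positions, vech_pair_index
from .ldsc import CovarianceEstimate
from .sem import FitResult, ModelSpec, fit_dwls

logger = logging.getLogger(__name__)

__all__ = ["expand_with_snp", "snp_factor_effect", "run_factor_gwas",
           "expected_sample_size", "mean_chisq"]

SNP_LABEL = "SNP"


def expand_with_snp(est: CovarianceEstimate, snp_rows: dict[str, dict],
                    maf: float) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Expand (S, V) with one harmonized SNP record per trait.

    The SNP (appended as the last variable) contributes variance
    2*maf*(1-maf); its covariance with trait t is beta_t * 2*maf*(1-maf).
    Sampling variances of those covariances scale the per-trait SEs by the
    same factor, and their cross-trait sampling covariances are
    approximated through the LDSC intercept matrix. The SNP variance is
    treated as known (zero sampling variance).
    """
    missing = [lab for lab in est.labels if lab not in snp_rows]
    if missing:
        raise KeyError(f"SNP record missing for traits: {missing}")
    k = est.k
    var_x = 2.0 * maf * (1.0 - maf)
    beta = np.array([float(snp_rows[lab]["beta"]) for lab in est.labels])
    se = np.array([float(snp_rows[lab]["se"]) for lab in est.labels])

    s_full = np.zeros((k + 1, k + 1))
    s_full[:k, :k] = est.s
    s_full[k, k] = var_x
    s_full[:k, k] = s_full[k, :k] = beta * var_x

    labels_full = list(est.labels) + [SNP_LABEL]
    q_full = (k + 1) * (k + 2) // 2
    v_full = np.zeros((q_full, q_full))
    old_pos = subset_vech_positions(labels_full, list(est.labels))
    v_full[np.ix_(old_pos, old_pos)] = est.v
    pair = vech_pair_index(k + 1)
    snp_cov = var_x ** 2 * np.outer(se, se) * est.intercepts
    for t in range(k):
        for u in range(k):
            v_full[pair[(t, k)], pair[(u, k)]] = snp_cov[t, u]
    return s_full, v_full, labels_full


@dataclass
class _ConditionalEngine:
    """Precomputed pieces of the conditional per-SNP estimator."""

    factor_names: list[str]
    trait_labels: list[str]
    t_mat: np.ndarray        # total factor -> indicator effects, k x nf
    intercepts: np.ndarray   # k x k LDSC intercept matrix
    factor_sd: np.ndarray    # model-implied factor SDs (standardization)

    def estimate(self, beta: np.ndarray, se: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        d_inv = 1.0 / se ** 2
        a = self.t_mat.T @ (d_inv[:, None] * self.t_mat)
        a_inv = np.linalg.pinv(a)
        b = a_inv @ (self.t_mat.T @ (d_inv * beta))
        # sandwich: full sampling covariance of the SNP moments
        v_snp = np.outer(se, se) * self.intercepts
        mid = self.t_mat.T @ (d_inv[:, None] * v_snp * d_inv[None, :]) @ self.t_mat
        cov_b = a_inv @ mid @ a_inv
        return b, np.sqrt(np.clip(np.diag(cov_b), 0.0, None))


def _build_engine(base_fit: FitResult, est: CovarianceEstimate
                  ) -> _ConditionalEngine:
    compiled = base_fit.compiled
    factors = [v for v in compiled.latent]
    if not factors:
        raise ValueError("model has no latent factors to associate the SNP with")
    b_tot = compiled.total_effects(base_fit.theta)
    obs_idx = np.arange(compiled.n_obs)
    fac_idx = np.array([compiled.var_names.index(f) for f in factors])
    t_mat = b_tot[np.ix_(obs_idx, fac_idx)]
    full = compiled.implied_full(base_fit.theta)
    factor_sd = np.sqrt(np.clip(np.diag(full)[fac_idx], 1e-300, None))
    trait_labels = compiled.observed
    lab_idx = [est.labels.index(lab) for lab in trait_labels]
    intercepts = est.intercepts[np.ix_(lab_idx, lab_idx)]
    return _ConditionalEngine(factor_names=factors, trait_labels=trait_labels,
                              t_mat=t_mat, intercepts=intercepts,
                              factor_sd=factor_sd)


def snp_factor_effect(spec: ModelSpec, est: CovarianceEstimate,
                      snp_rows: dict[str, dict], maf: float, target: str,
                      base_fit: FitResult | None = None,
                      mode: str = "conditional") -> dict:
    """SNP -> factor effect for one SNP, on the standardized factor scale.

    ``mode="conditional"`` (default) holds the structural parameters at the
    genome-wide fit and solves the SNP paths by weighted least squares on
    the SNP moments; ``mode="full"`` refits the whole expanded model by
    DWLS for this SNP.
    """
    if base_fit is None:
        base_fit = fit_dwls(spec, est, compute_fit=False)
    engine = _build_engine(base_fit, est)
    if target not in engine.factor_names:
        raise KeyError(f"target factor {target!r} not in model "
                       f"factors {engine.factor_names}")
    f_pos = engine.factor_names.index(target)

    if mode == "full":
        s_full, v_full, labels_full = expand_with_snp(est, snp_rows, maf)
        exp_spec = spec.with_identification(spec.identification)
        for fac in engine.factor_names:
            exp_spec.add("regression", fac, SNP_LABEL)
        exp_spec.add("covariance", SNP_LABEL, SNP_LABEL,
                     fixed=2.0 * maf * (1.0 - maf))
        exp_est = CovarianceEstimate(labels=labels_full, s=s_full, v=v_full,
                                     intercepts=np.eye(len(labels_full)),
                                     m=est.m, mean_chisq=np.zeros(len(labels_full)))
        fit = fit_dwls(exp_spec, exp_est, compute_fit=False)
        beta_f = fit[f"{target}<-{SNP_LABEL}"]
        se_f = fit.se_of(f"{target}<-{SNP_LABEL}")
        sd = engine.factor_sd[f_pos]
    else:
        beta = np.array([float(snp_rows[lab]["beta"])
                         for lab in engine.trait_labels])
        se = np.array([float(snp_rows[lab]["se"])
                       for lab in engine.trait_labels])
        b, b_se = engine.estimate(beta, se)
        beta_f, se_f = float(b[f_pos]), float(b_se[f_pos])
        sd = engine.factor_sd[f_pos]

    beta_std, se_std = beta_f / sd, se_f / sd
    z = beta_std / se_std if se_std > 0 else 0.0
    return {"factor": target, "beta": beta_std, "se": se_std, "z": z,
            "p": float(2.0 * norm.sf(abs(z)))}


def run_factor_gwas(tables: dict[str, pd.DataFrame], est: CovarianceEstimate,
                    spec: ModelSpec, target: str,
                    maf: pd.DataFrame | None = None) -> pd.DataFrame:
    """Factor GWAS over every SNP shared by all trait tables.

    ``maf`` optionally supplies reference-panel frequencies (columns snp,
    maf); otherwise the first table's ``freq`` column is used. The output
    is deterministic given the inputs; SNPs missing in any trait are
    skipped and counted in ``attrs['n_skipped']``.
    """
    labels = [lab for lab in est.labels if lab in tables]
    if set(labels) != set(est.labels):
        raise KeyError(f"tables missing for traits: "
                       f"{sorted(set(est.labels) - set(labels))}")
    base_fit = fit_dwls(spec, est, compute_fit=False)
    engine = _build_engine(base_fit, est)
    if target not in engine.factor_names:
        raise KeyError(f"target factor {target!r} not in model factors")
    f_pos = engine.factor_names.index(target)

    frame = None
    union = set()
    for lab in engine.trait_labels:
        tab = tables[lab]
        union |= set(tab["snp"])
        cols = tab[["snp", "beta", "se"] + (
            [c for c in ("chr", "bp", "a1", "a2", "freq") if c in tab.columns]
            if frame is None else [])].copy()
        cols = cols.rename(columns={"beta": f"beta_{lab}", "se": f"se_{lab}"})
        frame = cols if frame is None else frame.merge(cols, on="snp", how="inner")
    if frame.empty:
        raise ValueError("no SNPs shared across all trait tables")
    n_skipped = len(union) - len(frame)
    if maf is not None:
        frame = frame.drop(columns=[c for c in ("freq",) if c in frame.columns])
        frame = frame.merge(maf[["snp", "maf"]], on="snp", how="inner")
    else:
        frame = frame.rename(columns={"freq": "maf"})
        frame["maf"] = np.minimum(frame["maf"], 1.0 - frame["maf"])
    sort_cols = [c for c in ("chr", "bp", "snp") if c in frame.columns]
    frame = frame.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    betas = frame[[f"beta_{lab}" for lab in engine.trait_labels]].to_numpy(float)
    ses = frame[[f"se_{lab}" for lab in engine.trait_labels]].to_numpy(float)
    sd = engine.factor_sd[f_pos]
    out_beta = np.empty(len(frame))
    out_se = np.empty(len(frame))
    for i in range(len(frame)):
        b, b_se = engine.estimate(betas[i], ses[i])
        out_beta[i] = b[f_pos] / sd
        out_se[i] = b_se[f_pos] / sd
    z = np.divide(out_beta, out_se, out=np.zeros_like(out_beta),
                  where=out_se > 0)
    result = pd.DataFrame({
        "snp": frame["snp"],
        **{c: frame[c] for c in ("chr", "bp", "a1", "a2") if c in frame.columns},
        "maf": frame["maf"], "beta": out_beta, "se": out_se, "z": z,
        "p": 2.0 * norm.sf(np.abs(z)), "factor": target,
    })
    result.attrs["n_skipped"] = n_skipped
    if n_skipped:
        logger.info("factor GWAS: skipped %d SNPs missing in some trait", n_skipped)
    return result


def expected_sample_size(results: pd.DataFrame, maf_lo: float = 0.10,
                         maf_hi: float = 0.40) -> float:
    """Univariate-GWAS-equivalent sample size of a factor GWAS.

    N-hat is the mean over SNPs with MAF in [maf_lo, maf_hi] of
    1 / (2 maf (1 - maf) se^2). Valid only on the standardized factor
    scale (jointly rescaling beta and se changes N-hat by the inverse
    square of the factor).
    """
    window = results.loc[(results["maf"] >= maf_lo) & (results["maf"] <= maf_hi)]
    if window.empty:
        raise ValueError(f"no SNPs with MAF in [{maf_lo}, {maf_hi}]")
    maf = window["maf"].to_numpy(float)
    se = window["se"].to_numpy(float)
    return float(np.mean(1.0 / (2.0 * maf * (1.0 - maf) * se ** 2)))


def mean_chisq(results: pd.DataFrame) -> float:
    """Arithmetic mean of the squared factor z statistics."""
    if results.empty:
        raise ValueError("empty results")
    return float(np.mean(results["z"].to_numpy(float) ** 2))
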