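"""Multivariable LD-score regression with a block jackknife.

Estimates per-trait SNP heritability, cross-trait genetic covariance, the
intercept matrix (confounding on the diagonal, sample overlap off it), and
the joint sampling covariance V of the half-vectorized genetic covariance
matrix S. The univariate regression fits

    E[chi2_j] = a + (N h2 / M) * l_j

and the bivariate regression of z1*z2 fits

    E[z1 z2] = a12 + (sqrt(N1 N2) sigma_g12 / M) * l_j,

both by two-pass heteroskedasticity-weighted least squares. Standard errors
and V come from a delete-one block jackknife over contiguous genome-ordered
SNP blocks; all entries of S share the same blocks so V is internally
consistent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._linalg import nearest_psd, vech_indices

logger = logging.getLogger(__name__)

__all__ = ["LdscFit", "CovarianceEstimate", "read_ld_scores",
           "univariate_ldsc", "bivariate_ldsc", "build_covariance",
           "genetic_correlations"]

_MEAN_FLOOR = 0.05  # floor on the fitted mean inside the variance weights


@dataclass
class LdscFit:
    """One LD-score regression: physical-scale slope and intercept."""

    slope: float          # h2 (univariate) or sigma_g12 (bivariate)
    intercept: float
    slope_se: float
    intercept_se: float
    flagged: bool         # nonpositive univariate slope
    delete_one_slopes: np.ndarray
    delete_one_intercepts: np.ndarray


@dataclass
class CovarianceEstimate:
    """Genetic covariance matrix S with its sampling covariance V.

    V is q x q over vech(S) in lower-triangle column-major order, estimated
    from the joint block-jackknife pseudovalues. ``intercepts`` carries the
    univariate intercepts on the diagonal and cross-trait intercepts off it.
    """

    labels: list[str]
    s: np.ndarray
    v: np.ndarray
    intercepts: np.ndarray
    m: int
    mean_chisq: np.ndarray

    @property
    def k(self) -> int:
        return len(self.labels)

    def smoothed_s(self, eig_floor: float = 1e-8) -> np.ndarray:
        """S projected to positive semidefinite (for SEM consumption)."""
        smoothed, perturb = nearest_psd(self.s, eig_floor)
        if perturb > 0:
            logger.info("smoothed S to PSD; max |perturbation| = %.3g", perturb)
        return smoothed

    def to_json(self, path) -> None:
        payload = {"labels": self.labels, "S": self.s.tolist(),
                   "V": self.v.tolist(), "intercepts": self.intercepts.tolist(),
                   "M": self.m, "mean_chisq": self.mean_chisq.tolist()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CovarianceEstimate":
        with open(path) as fh:
            d = json.load(fh)
        return cls(labels=d["labels"], s=np.asarray(d["S"]),
                   v=np.asarray(d["V"]), intercepts=np.asarray(d["intercepts"]),
                   m=int(d["M"]), mean_chisq=np.asarray(d["mean_chisq"]))


def read_ld_scores(path, freq_path=None) -> pd.DataFrame:
    """Read an LD-score file (CHR, SNP, BP, L2 [, MAF via companion file])."""
    tab = pd.read_csv(path, sep=r"\s+")
    tab.columns = [c.lower() for c in tab.columns]
    tab = tab.rename(columns={"l2": "ld", "chrom": "chr", "pos": "bp"})
    for required in ("snp", "ld"):
        if required not in tab.columns:
            raise ValueError(f"LD-score file missing column: {required!r}")
    if freq_path is not None:
        frq = pd.read_csv(freq_path, sep=r"\s+")
        frq.columns = [c.lower() for c in frq.columns]
        tab = tab.merge(frq[["snp", "maf"]], on="snp", how="inner")
    return tab


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted LS of y on [1, x]; returns (intercept, slope)."""
    xtwx = np.array([[w.sum(), (w * x).sum()],
                     [(w * x).sum(), (w * x * x).sum()]])
    xtwy = np.array([(w * y).sum(), (w * x * y).sum()])
    return np.linalg.solve(xtwx, xtwy)


def _jackknife_wls(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                   block_ids: np.ndarray, n_blocks: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Delete-one-block WLS fits with fixed weights.

    Returns (theta_full, theta_delete) with theta = (intercept, slope) and
    theta_delete of shape (n_blocks, 2). Uses per-block sufficient
    statistics, so cost is O(len(x)).
    """
    ones = np.ones_like(x)
    feats = {
        "s0": w, "sx": w * x, "sxx": w * x * x,
        "sy": w * y, "sxy": w * x * y,
    }
    sums = {key: np.bincount(block_ids, weights=val, minlength=n_blocks)
            for key, val in feats.items()}
    tot = {key: val.sum() for key, val in sums.items()}

    def solve(s0, sx, sxx, sy, sxy):
        det = s0 * sxx - sx * sx
        a = (sxx * sy - sx * sxy) / det
        b = (s0 * sxy - sx * sy) / det
        return a, b

    a_full, b_full = solve(tot["s0"], tot["sx"], tot["sxx"], tot["sy"], tot["sxy"])
    a_del, b_del = solve(tot["s0"] - sums["s0"], tot["sx"] - sums["sx"],
                         tot["sxx"] - sums["sxx"], tot["sy"] - sums["sy"],
                         tot["sxy"] - sums["sxy"])
    del ones
    return np.array([a_full, b_full]), np.column_stack([a_del, b_del])


def _jackknife_se(delete_one: np.ndarray) -> np.ndarray:
    g = delete_one.shape[0]
    mean = delete_one.mean(axis=0)
    return np.sqrt((g - 1) / g * ((delete_one - mean) ** 2).sum(axis=0))


def _block_ids(m: int, n_blocks: int) -> np.ndarray:
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    ids = np.zeros(m, dtype=int)
    for b in range(n_blocks):
        ids[edges[b]:edges[b + 1]] = b
    return ids


def _check_size(m: int, n_blocks: int) -> None:
    if m < 10 * n_blocks:
        raise ValueError(
            f"too few SNPs for LDSC: {m} shared, need >= {10 * n_blocks} "
            f"for {n_blocks} jackknife blocks")


def _univariate_core(z: np.ndarray, ell: np.ndarray, n: np.ndarray, m_ref: int,
                     block_ids: np.ndarray, n_blocks: int) -> LdscFit:
    chi2 = z ** 2
    x = n * ell / m_ref
    w0 = 1.0 / np.maximum(ell, 1.0)
    a0, h0 = _wls(x, chi2, w0)
    mean_hat = np.maximum(a0 + h0 * x, _MEAN_FLOOR)
    w1 = 1.0 / (np.maximum(ell, 1.0) * mean_hat ** 2)
    (a, h2), delete = _jackknife_wls(x, chi2, w1, block_ids, n_blocks)
    se = _jackknife_se(delete)
    return LdscFit(slope=float(h2), intercept=float(a), slope_se=float(se[1]),
                   intercept_se=float(se[0]), flagged=bool(h2 <= 0),
                   delete_one_slopes=delete[:, 1],
                   delete_one_intercepts=delete[:, 0])


def _first_pass_mean(z: np.ndarray, ell: np.ndarray, n: np.ndarray,
                     m_ref: int) -> np.ndarray:
    x = n * ell / m_ref
    a0, h0 = _wls(x, z ** 2, 1.0 / np.maximum(ell, 1.0))
    return np.maximum(a0 + h0 * x, _MEAN_FLOOR)


def _bivariate_core(z1: np.ndarray, z2: np.ndarray, ell: np.ndarray,
                    n1: np.ndarray, n2: np.ndarray, m_ref: int,
                    block_ids: np.ndarray, n_blocks: int) -> LdscFit:
    # the variance term uses first-pass means throughout, so a trait paired
    # with itself reduces to the univariate regression exactly (weights
    # proportional by a factor of 2)
    y = z1 * z2
    x = np.sqrt(n1 * n2) * ell / m_ref
    w0 = 1.0 / np.maximum(ell, 1.0)
    a0, g0 = _wls(x, y, w0)
    mean1 = _first_pass_mean(z1, ell, n1, m_ref)
    mean2 = _first_pass_mean(z2, ell, n2, m_ref)
    var_y = mean1 * mean2 + np.maximum(a0 + g0 * x, _MEAN_FLOOR) ** 2 \
        if z1 is z2 or np.array_equal(z1, z2) else \
        mean1 * mean2 + (a0 + g0 * x) ** 2
    w1 = 1.0 / (np.maximum(ell, 1.0) * var_y)
    (a, g), delete = _jackknife_wls(x, y, w1, block_ids, n_blocks)
    se = _jackknife_se(delete)
    return LdscFit(slope=float(g), intercept=float(a), slope_se=float(se[1]),
                   intercept_se=float(se[0]), flagged=False,
                   delete_one_slopes=delete[:, 1],
                   delete_one_intercepts=delete[:, 0])


def _common_frame(tables: list[pd.DataFrame], ld: pd.DataFrame
                  ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Single genome-ordered SNP frame shared by all traits and the LD table."""
    frame = ld[["snp", "ld"] + [c for c in ("chr", "bp") if c in ld.columns]].copy()
    for i, tab in enumerate(tables):
        cols = tab[["snp", "z", "n"]].rename(columns={"z": f"z{i}", "n": f"n{i}"})
        frame = frame.merge(cols, on="snp", how="inner")
    if {"chr", "bp"} <= set(frame.columns):
        frame = frame.sort_values(["chr", "bp", "snp"], kind="mergesort")
    else:
        frame = frame.sort_values("snp", kind="mergesort")
    ell = frame["ld"].to_numpy(float)
    zs = [frame[f"z{i}"].to_numpy(float) for i in range(len(tables))]
    ns = [frame[f"n{i}"].to_numpy(float) for i in range(len(tables))]
    return frame["snp"].to_numpy(), ell, zs, ns


def univariate_ldsc(table: pd.DataFrame, ld: pd.DataFrame,
                    n_blocks: int = 200) -> LdscFit:
    """SNP heritability and intercept for one trait, with jackknife SEs."""
    _, ell, (z,), (n,) = _common_frame([table], ld)
    _check_size(len(ell), n_blocks)
    ids = _block_ids(len(ell), n_blocks)
    fit = _univariate_core(z, ell, n, len(ell), ids, n_blocks)
    if fit.flagged:
        logger.warning("univariate LDSC: nonpositive heritability slope (%.4g)",
                       fit.slope)
    return fit


def bivariate_ldsc(t1: pd.DataFrame, t2: pd.DataFrame, ld: pd.DataFrame,
                   n_blocks: int = 200) -> LdscFit:
    """Genetic covariance and cross-trait intercept for a pair of traits."""
    _, ell, (z1, z2), (n1, n2) = _common_frame([t1, t2], ld)
    _check_size(len(ell), n_blocks)
    ids = _block_ids(len(ell), n_blocks)
    m_ref = len(ell)
    return _bivariate_core(z1, z2, ell, n1, n2, m_ref, ids, n_blocks)


def build_covariance(tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
                     ld: pd.DataFrame, n_blocks: int = 200
                     ) -> CovarianceEstimate:
    """Assemble S, V and the intercept matrix from all pairwise regressions.

    All traits are restricted to one common SNP frame so that the jackknife
    blocks align across the q = k(k+1)/2 entries of vech(S), making V a
    coherent joint sampling covariance.
    """
    if isinstance(tables, dict):
        labels = list(tables)
        tabs = list(tables.values())
    else:
        labels = [t.attrs.get("label", f"trait{i + 1}") for i, t in enumerate(tables)]
        tabs = list(tables)
    k = len(tabs)
    if k < 2:
        raise ValueError("build_covariance requires at least 2 traits")
    _, ell, zs, ns = _common_frame(tabs, ld)
    m_ref = len(ell)
    _check_size(m_ref, n_blocks)
    ids = _block_ids(m_ref, n_blocks)

    uni = []
    for t in range(k):
        try:
            uni.append(_univariate_core(zs[t], ell, ns[t], m_ref, ids, n_blocks))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError(f"univariate LDSC failed for {labels[t]!r}: {exc}")

    s = np.zeros((k, k))
    intercepts = np.zeros((k, k))
    rows, cols = vech_indices(k)
    q = len(rows)
    delete_mat = np.zeros((n_blocks, q))
    for pos, (i, j) in enumerate(zip(rows, cols)):
        if i == j:
            fit = uni[i]
        else:
            try:
                fit = _bivariate_core(zs[i], zs[j], ell, ns[i], ns[j],
                                      m_ref, ids, n_blocks)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ValueError(
                    f"bivariate LDSC failed for pair ({labels[i]!r}, "
                    f"{labels[j]!r}): {exc}")
        s[i, j] = s[j, i] = fit.slope
        intercepts[i, j] = intercepts[j, i] = fit.intercept
        delete_mat[:, pos] = fit.delete_one_slopes

    g = n_blocks
    centered = delete_mat - delete_mat.mean(axis=0)
    v = (g - 1) / g * (centered.T @ centered)
    mean_chisq = np.array([float(np.mean(z ** 2)) for z in zs])
    return CovarianceEstimate(labels=labels, s=s, v=v, intercepts=intercepts,
                              m=m_ref, mean_chisq=mean_chisq)


def genetic_correlations(est: CovarianceEstimate
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Genetic correlation matrix r_ij = S_ij / sqrt(S_ii S_jj) with SEs.

    Standard errors come from the delta method applied to V; diagonal SEs
    are 0 by construction.
    """
    s, v = est.s, est.v
    diag = np.diag(s)
    bad = [lab for lab, d in zip(est.labels, diag) if d <= 0]
    if bad:
        raise ValueError(f"nonpositive heritability for traits: {bad}")
    denom = np.sqrt(np.outer(diag, diag))
    corr = s / denom
    k = est.k
    from ._linalg import vech_pair_index
    pair = vech_pair_index(k)
    ses = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            grad = np.zeros(v.shape[0])
            grad[pair[(i, j)]] = 1.0 / denom[i, j]
            grad[pair[(i, i)]] = -s[i, j] / (2.0 * diag[i] * denom[i, j])
            grad[pair[(j, j)]] = -s[i, j] / (2.0 * diag[j] * denom[i, j])
            ses[i, j] = ses[j, i] = float(np.sqrt(grad @ v @ grad))
    return corr, ses
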