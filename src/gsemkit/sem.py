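"""Structural-equation models on a genetic covariance matrix.

Models are written in a small text grammar, one statement per line:

    F =: a, b, c          loadings of factor F on indicators a, b, c
    y <- x                regression of y on x
    x ~~ y                covariance of x and y (variance when x == y)

A parameter token may carry ``@v`` (fixed at v) or ``*s`` (start value s);
the prefix form ``0@x`` is also accepted. A line ``!identification
unit-loading`` (or ``unit-variance``, the default) selects how factor scale
is set: fixing each factor variance to 1, or fixing its first loading to 1
and freeing the variance.

Fitting uses diagonally weighted least squares: with s = vech(S) and
model-implied sigma(theta),

    F(theta) = (s - sigma)' D^-1 (s - sigma),   D = diag(V),

minimized by quasi-Newton with analytic gradients. Parameter uncertainty
uses the full V through the sandwich estimator, and the model chi-square is
the residual quadratic form with the rank-df pseudo-inverse of the residual
sampling covariance.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._linalg import nearest_psd, subset_vech_positions, vech, vech_indices
from .ldsc import CovarianceEstimate

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "FitResult", "parse_model", "implied_covariance",
           "fit_dwls", "fit_statistics", "standardize", "chi2_pvalue"]


def chi2_pvalue(chi2: float, df: int) -> float:
    """Upper-tail p-value of the model chi-square statistic."""
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(chi2, df))

UNIT_VARIANCE = "unit-variance"
UNIT_LOADING = "unit-loading"

_TOKEN_RE = re.compile(
    r"^(?:(?P<prefix>[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?)@)?"
    r"(?P<name>[A-Za-z_][\w.\-]*)"
    r"(?:@(?P<fix>[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?))?"
    r"(?:\*(?P<start>[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?))?$")


class ModelSyntaxError(ValueError):
    pass


@dataclass
class Statement:
    kind: str                     # "loading" | "regression" | "covariance"
    lhs: str
    rhs: str
    fixed: float | None = None
    start: float | None = None

    def key(self) -> tuple:
        if self.kind == "covariance":
            return (self.kind, *sorted((self.lhs, self.rhs)))
        return (self.kind, self.lhs, self.rhs)


@dataclass
class ModelSpec:
    """A parsed structural-equation model."""

    statements: list[Statement]
    latents: list[str]
    identification: str = UNIT_VARIANCE

    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for st in self.statements:
            for v in (st.lhs, st.rhs):
                seen.setdefault(v, None)
        return list(seen)

    def factors(self) -> list[str]:
        out: dict[str, None] = {}
        for st in self.statements:
            if st.kind == "loading":
                out.setdefault(st.lhs, None)
        return list(out)

    def with_identification(self, mode: str) -> "ModelSpec":
        return ModelSpec(statements=[Statement(**vars(s)) for s in self.statements],
                         latents=list(self.latents), identification=mode)

    def add(self, kind: str, lhs: str, rhs: str, fixed: float | None = None,
            start: float | None = None) -> None:
        st = Statement(kind, lhs, rhs, fixed=fixed, start=start)
        if any(st.key() == other.key() for other in self.statements):
            raise ModelSyntaxError(f"parameter declared twice: {kind} {lhs}/{rhs}")
        self.statements.append(st)
        if kind == "loading" and lhs not in self.latents:
            self.latents.append(lhs)

    def to_text(self) -> str:
        """Serialize back to the grammar (round-trips through parse_model)."""
        lines = [f"!identification {self.identification}"]

        def tok(st: Statement) -> str:
            t = st.rhs
            if st.fixed is not None:
                t += f"@{st.fixed:g}"
            if st.start is not None:
                t += f"*{st.start:g}"
            return t

        by_factor: dict[str, list[Statement]] = {}
        for st in self.statements:
            if st.kind == "loading":
                by_factor.setdefault(st.lhs, []).append(st)
        for fac, sts in by_factor.items():
            lines.append(f"{fac} =: " + ", ".join(tok(s) for s in sts))
        for st in self.statements:
            if st.kind == "regression":
                lines.append(f"{st.lhs} <- " + tok(st))
            elif st.kind == "covariance":
                lines.append(f"{st.lhs} ~~ " + tok(st))
        return "\n".join(lines) + "\n"


def _parse_token(token: str, line_no: int) -> tuple[str, float | None, float | None]:
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ModelSyntaxError(f"line {line_no}: cannot parse token {token!r}")
    fixed = m.group("prefix") or m.group("fix")
    start = m.group("start")
    return (m.group("name"), float(fixed) if fixed is not None else None,
            float(start) if start is not None else None)


def parse_model(text: str, identification: str = UNIT_VARIANCE) -> ModelSpec:
    """Parse model text into a validated :class:`ModelSpec`."""
    spec = ModelSpec(statements=[], latents=[], identification=identification)
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("!identification"):
            mode = line.split(None, 1)[1].strip()
            if mode not in (UNIT_VARIANCE, UNIT_LOADING):
                raise ModelSyntaxError(f"line {line_no}: unknown identification {mode!r}")
            spec.identification = mode
            continue
        try:
            if "=:" in line:
                lhs, rhs = line.split("=:", 1)
                lhs = lhs.strip()
                if not re.fullmatch(r"[A-Za-z_][\w.\-]*", lhs):
                    raise ModelSyntaxError(f"line {line_no}: bad factor name {lhs!r}")
                items = [t for t in rhs.split(",") if t.strip()]
                if not items:
                    raise ModelSyntaxError(f"line {line_no}: empty loading list")
                for token in items:
                    name, fixed, start = _parse_token(token, line_no)
                    spec.add("loading", lhs, name, fixed=fixed, start=start)
            elif "~~" in line:
                lhs, rhs = (part.strip() for part in line.split("~~", 1))
                name, fixed, start = _parse_token(rhs, line_no)
                if not re.fullmatch(r"[A-Za-z_][\w.\-]*", lhs):
                    raise ModelSyntaxError(f"line {line_no}: bad variable {lhs!r}")
                spec.add("covariance", lhs, name, fixed=fixed, start=start)
            elif "<-" in line:
                lhs, rhs = (part.strip() for part in line.split("<-", 1))
                if not re.fullmatch(r"[A-Za-z_][\w.\-]*", lhs):
                    raise ModelSyntaxError(f"line {line_no}: bad variable {lhs!r}")
                for token in (t for t in rhs.split(",") if t.strip()):
                    name, fixed, start = _parse_token(token, line_no)
                    spec.add("regression", lhs, name, fixed=fixed, start=start)
            else:
                raise ModelSyntaxError(f"line {line_no}: unrecognized statement {line!r}")
        except ModelSyntaxError:
            raise
        except Exception as exc:
            raise ModelSyntaxError(f"line {line_no}: {exc}") from exc
    return spec


# ---------------------------------------------------------------------------
# compilation to RAM matrices

@dataclass
class _Param:
    matrix: str            # "A" (directed) or "S" (undirected)
    row: int
    col: int
    label: str
    free: bool
    value: float           # fixed value, or start value when free


@dataclass
class CompiledModel:
    """A ModelSpec bound to an observed-variable frame.

    RAM parameterization: directed paths in A (A[i, j] is the path j -> i),
    undirected (co)variances in S_mat; with B = (I - A)^-1 the implied
    covariance of all variables is B S_mat B' and the observed block is its
    leading n_obs x n_obs corner.
    """

    spec: ModelSpec
    observed: list[str]
    latent: list[str]
    params: list[_Param]

    def __post_init__(self) -> None:
        self.var_names = self.observed + self.latent
        self.n_obs = len(self.observed)
        self.n = len(self.var_names)
        self.free_idx = [i for i, p in enumerate(self.params) if p.free]
        self.n_free = len(self.free_idx)
        self.free_labels = [self.params[i].label for i in self.free_idx]

    def start_values(self) -> np.ndarray:
        return np.array([self.params[i].value for i in self.free_idx])

    def _matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = np.zeros((self.n, self.n))
        s = np.zeros((self.n, self.n))
        it = iter(theta)
        for p in self.params:
            val = next(it) if p.free else p.value
            if p.matrix == "A":
                a[p.row, p.col] = val
            else:
                s[p.row, p.col] = val
                s[p.col, p.row] = val
        return a, s

    def implied_full(self, theta: np.ndarray) -> np.ndarray:
        a, s = self._matrices(theta)
        b = np.linalg.inv(np.eye(self.n) - a)
        return b @ s @ b.T

    def implied(self, theta: np.ndarray) -> np.ndarray:
        full = self.implied_full(theta)
        return full[:self.n_obs, :self.n_obs]

    def sigma_vech(self, theta: np.ndarray) -> np.ndarray:
        return vech(self.implied(theta))

    def jacobian(self, theta: np.ndarray) -> np.ndarray:
        """Analytic d vech(Sigma) / d theta, shape (q, n_free)."""
        a, s = self._matrices(theta)
        b = np.linalg.inv(np.eye(self.n) - a)
        c = b @ s @ b.T
        rows, cols = vech_indices(self.n_obs)
        jac = np.zeros((len(rows), self.n_free))
        for out_col, pi in enumerate(self.free_idx):
            p = self.params[pi]
            if p.matrix == "A":
                # dSigma = B E_ij C + C E_ij' B'
                d_full = np.outer(b[:, p.row], c[p.col, :])
                d_full = d_full + d_full.T
            else:
                if p.row == p.col:
                    d_full = np.outer(b[:, p.row], b[:, p.row])
                else:
                    d_full = (np.outer(b[:, p.row], b[:, p.col])
                              + np.outer(b[:, p.col], b[:, p.row]))
            jac[:, out_col] = d_full[rows, cols]
        return jac

    def total_effects(self, theta: np.ndarray) -> np.ndarray:
        """Total directed effect of every variable on every variable (B)."""
        a, _ = self._matrices(theta)
        return np.linalg.inv(np.eye(self.n) - a)

    def residual_variance_estimates(self, theta: np.ndarray) -> dict[str, float]:
        _, s = self._matrices(theta)
        return {self.var_names[i]: float(s[i, i]) for i in range(self.n)}


def compile_model(spec: ModelSpec, observed_labels: list[str],
                  s_obs: np.ndarray | None = None) -> CompiledModel:
    """Bind a spec to an observed frame and assign parameter slots.

    Variables present in ``observed_labels`` are observed (ordered as
    there); all others are latent. Defaults: free residual variance per
    observed variable, factor scale per the identification mode, and no
    covariance unless declared.
    """
    model_vars = spec.variables()
    observed = [lab for lab in observed_labels if lab in set(model_vars)]
    latent = [v for v in model_vars if v not in set(observed)]
    undeclared = [v for v in latent if v not in spec.latents
                  and v not in spec.factors()]
    if undeclared:
        logger.debug("variables treated as latent (absent from S): %s", undeclared)
    var_index = {v: i for i, v in enumerate(observed + latent)}
    n_obs = len(observed)

    def s_diag(var: str, default: float = 1.0) -> float:
        if s_obs is None or var not in var_index or var_index[var] >= n_obs:
            return default
        return float(s_obs[var_index[var], var_index[var]])

    params: list[_Param] = []
    explicit_var: set[str] = set()
    fixed_loading_of: dict[str, bool] = {}
    first_loading_idx: dict[str, int] = {}

    # detect cycles among directed paths
    import collections
    edges = collections.defaultdict(set)
    for st in spec.statements:
        if st.kind == "loading":
            edges[st.lhs].add(st.rhs)     # factor -> indicator
        elif st.kind == "regression":
            edges[st.rhs].add(st.lhs)     # predictor -> outcome
    color: dict[str, int] = {}

    def dfs(node: str) -> None:
        color[node] = 1
        for nxt in edges.get(node, ()):  # pragma: no branch
            if color.get(nxt) == 1:
                raise ModelSyntaxError(f"cyclic directed paths involving {nxt!r}")
            if color.get(nxt, 0) == 0:
                dfs(nxt)
        color[node] = 2

    for node in list(edges):
        if color.get(node, 0) == 0:
            dfs(node)

    for st in spec.statements:
        if st.kind == "loading":
            row, col = var_index[st.rhs], var_index[st.lhs]
            label = f"{st.lhs}=:{st.rhs}"
            fixed_loading_of.setdefault(st.lhs, False)
            if st.lhs not in first_loading_idx:
                first_loading_idx[st.lhs] = len(params)
            if st.fixed is not None:
                params.append(_Param("A", row, col, label, False, st.fixed))
                fixed_loading_of[st.lhs] = True
            else:
                start = st.start if st.start is not None else 0.5 * np.sqrt(
                    max(s_diag(st.rhs), 1e-6))
                params.append(_Param("A", row, col, label, True, start))
        elif st.kind == "regression":
            row, col = var_index[st.lhs], var_index[st.rhs]
            label = f"{st.lhs}<-{st.rhs}"
            if st.fixed is not None:
                params.append(_Param("A", row, col, label, False, st.fixed))
            else:
                params.append(_Param("A", row, col, label, True,
                                     st.start if st.start is not None else 0.0))
        else:
            i, j = var_index[st.lhs], var_index[st.rhs]
            label = f"{st.lhs}~~{st.rhs}"
            if st.lhs == st.rhs:
                explicit_var.add(st.lhs)
            if st.fixed is not None:
                params.append(_Param("S", i, j, label, False, st.fixed))
            else:
                if st.start is not None:
                    start = st.start
                elif st.lhs == st.rhs:
                    start = 0.5 * s_diag(st.lhs)
                else:
                    start = 0.0
                params.append(_Param("S", i, j, label, True, start))

    # identification defaults for factor scale
    for fac in spec.factors():
        if fac in explicit_var:
            continue
        i = var_index[fac]
        if spec.identification == UNIT_VARIANCE:
            params.append(_Param("S", i, i, f"{fac}~~{fac}", False, 1.0))
        else:
            if not fixed_loading_of.get(fac, False):
                p0 = params[first_loading_idx[fac]]
                params[first_loading_idx[fac]] = _Param(
                    p0.matrix, p0.row, p0.col, p0.label, False, 1.0)
            params.append(_Param("S", i, i, f"{fac}~~{fac}", True,
                                 0.5 * max(s_diag(fac), 1.0)))
        explicit_var.add(fac)

    # free residual variance for every variable lacking one
    for v in observed + latent:
        if v in explicit_var or v in spec.factors():
            continue
        i = var_index[v]
        if i < n_obs:
            params.append(_Param("S", i, i, f"{v}~~{v}", True,
                                 0.5 * max(s_diag(v), 1e-6)))
        else:
            params.append(_Param("S", i, i, f"{v}~~{v}", False, 1.0))

    # every latent must reach an observed variable through directed paths;
    # a dangling latent is almost always a trait missing from S
    reaches: set[str] = set(observed)
    changed = True
    while changed:
        changed = False
        for src, dsts in edges.items():
            if src not in reaches and dsts & reaches:
                reaches.add(src)
                changed = True
    dangling = [v for v in latent if v not in reaches]
    if dangling:
        raise ValueError(
            f"variables {dangling} are not among the observed traits and "
            "have no directed path to one; missing from the covariance "
            "estimate?")

    return CompiledModel(spec=spec, observed=observed, latent=latent,
                         params=params)


def implied_covariance(spec: ModelSpec, theta: np.ndarray,
                       observed_labels: list[str]) -> np.ndarray:
    """Model-implied covariance over the observed variables (exactly symmetric)."""
    compiled = compile_model(spec, observed_labels)
    sigma = compiled.implied(np.asarray(theta, dtype=float))
    return (sigma + sigma.T) / 2.0


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    """DWLS estimates, sandwich SEs, fit statistics and diagnostics."""

    compiled: CompiledModel
    theta: np.ndarray
    se: np.ndarray
    cov_theta: np.ndarray
    sigma: np.ndarray           # implied covariance of observed block
    s_obs: np.ndarray
    v_obs: np.ndarray
    objective: float
    converged: bool
    n_iterations: int
    heywood: bool
    chi2: float = np.nan
    df: int = 0
    pvalue: float = np.nan
    cfi: float = np.nan
    srmr: float = np.nan

    @property
    def labels(self) -> list[str]:
        return self.compiled.free_labels

    def estimates(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.labels, "estimate": self.theta,
                             "se": self.se})

    def __getitem__(self, label: str) -> float:
        return float(self.theta[self.labels.index(label)])

    def se_of(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])


def _dwls_objective(compiled: CompiledModel, s_vec: np.ndarray,
                    w: np.ndarray):
    def fun(theta: np.ndarray) -> float:
        e = s_vec - compiled.sigma_vech(theta)
        return float(e @ (w * e))

    def grad(theta: np.ndarray) -> np.ndarray:
        e = s_vec - compiled.sigma_vech(theta)
        jac = compiled.jacobian(theta)
        return -2.0 * (jac.T @ (w * e))

    return fun, grad


def fit_dwls(spec: ModelSpec, est: CovarianceEstimate, n_restarts: int = 5,
             grad_tol: float = 1e-8, compute_fit: bool = True) -> FitResult:
    """Fit a model to (S, V) by diagonally weighted least squares.

    S is smoothed to positive semidefinite first (eigenvalue floor 1e-8)
    when needed. Optimization runs from the default starts plus jittered
    restarts; the best converged solution wins. Sandwich standard errors use
    the full sampling covariance V. Heywood cases (negative residual
    variances) are flagged, not fatal.
    """
    spec_vars = set(spec.variables())
    observed = [lab for lab in est.labels if lab in spec_vars]
    if not observed:
        raise ValueError("none of the model's variables appear in the "
                         "covariance estimate")
    pos = subset_vech_positions(est.labels, observed)
    s_full = est.smoothed_s()
    obs_idx = [est.labels.index(lab) for lab in observed]
    s_obs = s_full[np.ix_(obs_idx, obs_idx)]
    v_obs = est.v[np.ix_(pos, pos)]

    compiled = compile_model(spec, observed, s_obs=s_obs)
    q = len(pos)
    if compiled.n_free > q:
        raise ValueError(f"model not identified: {compiled.n_free} free "
                         f"parameters for {q} moments")
    s_vec = vech(s_obs)
    d = np.diag(v_obs).copy()
    floor = max(d.max(), 1e-300) * 1e-12
    w = 1.0 / np.maximum(d, floor)
    fun, grad = _dwls_objective(compiled, s_vec, w)

    theta0 = compiled.start_values()
    rng = np.random.default_rng(0)
    best = None
    n_iter_total = 0
    for attempt in range(max(1, n_restarts)):
        start = theta0 if attempt == 0 else theta0 + rng.normal(
            0.0, 0.1 * (np.abs(theta0) + 0.1))
        res = optimize.minimize(fun, start, jac=grad, method="L-BFGS-B",
                                options={"maxiter": 2000, "ftol": 1e-15,
                                         "gtol": grad_tol})
        n_iter_total += res.nit
        g_norm = float(np.max(np.abs(grad(res.x)))) if res.x.size else 0.0
        ok = bool(res.success) or g_norm <= max(grad_tol, 1e-6 * (1.0 + abs(res.fun)))
        if best is None or (ok and not best[2]) or \
                (ok == best[2] and res.fun < best[1]):
            best = (res.x, float(res.fun), ok)
    theta_hat, obj, converged = best
    if not converged:
        raise RuntimeError(f"DWLS did not converge after {n_restarts} restarts "
                           f"(best objective {obj:.6g})")

    jac = compiled.jacobian(theta_hat)
    bread = np.linalg.pinv(jac.T @ (w[:, None] * jac))
    meat = jac.T @ (w[:, None] * v_obs * w[None, :]) @ jac
    cov_theta = bread @ meat @ bread
    se = np.sqrt(np.clip(np.diag(cov_theta), 0.0, None))

    resid_vars = compiled.residual_variance_estimates(theta_hat)
    heywood = any(val < -1e-10 for name, val in resid_vars.items()
                  if name in compiled.observed)
    if heywood:
        logger.warning("Heywood case: negative residual variance estimated")

    sigma = compiled.implied(theta_hat)
    result = FitResult(compiled=compiled, theta=theta_hat, se=se,
                       cov_theta=cov_theta, sigma=(sigma + sigma.T) / 2.0,
                       s_obs=s_obs, v_obs=v_obs, objective=obj,
                       converged=converged, n_iterations=n_iter_total,
                       heywood=heywood)
    if compute_fit:
        fit_statistics(result, est)
    return result


def _independence_baseline(observed: list[str]) -> ModelSpec:
    spec = ModelSpec(statements=[], latents=[], identification=UNIT_VARIANCE)
    for v in observed:
        spec.add("covariance", v, v)
    return spec


def fit_statistics(result: FitResult, est: CovarianceEstimate,
                   baseline: ModelSpec | None = None
                   ) -> tuple[float, int, float, float, float]:
    """Chi-square, df, p, CFI and SRMR for a converged fit.

    The chi-square is e' pinv(cov(e)) e with e = s - sigma(theta_hat) and
    cov(e) = P V P' for the DWLS projection P, using a rank-df
    pseudo-inverse. CFI compares against the independence baseline fitted by
    the same machinery; SRMR is the RMS of correlation-scale residuals.
    """
    compiled = result.compiled
    q = result.v_obs.shape[0]
    df = q - compiled.n_free
    if df < 0:
        raise ValueError("negative degrees of freedom")
    s_vec = vech(result.s_obs)
    e = s_vec - vech(result.sigma)

    if df == 0:
        chi2, p = 0.0, 1.0
    else:
        d = np.diag(result.v_obs).copy()
        floor = max(d.max(), 1e-300) * 1e-12
        w = 1.0 / np.maximum(d, floor)
        jac = compiled.jacobian(result.theta)
        bread = np.linalg.pinv(jac.T @ (w[:, None] * jac))
        proj = np.eye(q) - jac @ bread @ (jac.T * w[None, :])
        cov_e = proj @ result.v_obs @ proj.T
        vals, vecs = np.linalg.eigh((cov_e + cov_e.T) / 2.0)
        order = np.argsort(vals)[::-1][:df]
        inv_vals = 1.0 / vals[order]
        chi2 = float(e @ (vecs[:, order] * inv_vals) @ (vecs[:, order].T @ e))
        chi2 = max(chi2, 0.0)
        p = chi2_pvalue(chi2, df)

    # SRMR on the correlation scale of the observed S
    sd = np.sqrt(np.clip(np.diag(result.s_obs), 1e-300, None))
    rows, cols = vech_indices(len(sd))
    std_resid = e / (sd[rows] * sd[cols])
    srmr = float(np.sqrt(np.mean(std_resid ** 2)))

    if df == 0:
        cfi = 1.0
    else:
        base_spec = baseline or _independence_baseline(compiled.observed)
        base = fit_dwls(base_spec, est, n_restarts=1, compute_fit=False)
        chi2_b, df_b = _chi2_only(base)
        num = max(chi2 - df, 0.0)
        denom = max(chi2_b - df_b, chi2 - df, 0.0)
        cfi = 1.0 if denom == 0.0 else 1.0 - num / denom

    result.chi2, result.df, result.pvalue = chi2, df, p
    result.cfi, result.srmr = cfi, srmr
    return chi2, df, p, cfi, srmr


def _chi2_only(result: FitResult) -> tuple[float, int]:
    """Residual chi-square of a fit without recursing into CFI."""
    compiled = result.compiled
    q = result.v_obs.shape[0]
    df = q - compiled.n_free
    if df <= 0:
        return 0.0, 0
    s_vec = vech(result.s_obs)
    e = s_vec - vech(result.sigma)
    d = np.diag(result.v_obs).copy()
    floor = max(d.max(), 1e-300) * 1e-12
    w = 1.0 / np.maximum(d, floor)
    jac = compiled.jacobian(result.theta)
    bread = np.linalg.pinv(jac.T @ (w[:, None] * jac))
    proj = np.eye(q) - jac @ bread @ (jac.T * w[None, :])
    cov_e = proj @ result.v_obs @ proj.T
    vals, vecs = np.linalg.eigh((cov_e + cov_e.T) / 2.0)
    order = np.argsort(vals)[::-1][:df]
    chi2 = float(e @ (vecs[:, order] * (1.0 / vals[order])) @ (vecs[:, order].T @ e))
    return max(chi2, 0.0), df


def _standardized_vector(compiled: CompiledModel, theta: np.ndarray) -> np.ndarray:
    a, s = compiled._matrices(theta)
    b = np.linalg.inv(np.eye(compiled.n) - a)
    full = b @ s @ b.T
    sd = np.sqrt(np.clip(np.diag(full), 1e-300, None))
    out = []
    it = iter(theta)
    for p in compiled.params:
        val = next(it) if p.free else p.value
        if p.matrix == "A":
            out.append(val * sd[p.col] / sd[p.row])
        else:
            out.append(val / (sd[p.row] * sd[p.col]))
    return np.asarray(out)


def standardize(result: FitResult) -> pd.DataFrame:
    """Standardized solution (all variances rescaled to 1) with 95% CIs.

    Standard errors come from the delta method: the numeric Jacobian of the
    standardized parameters with respect to theta, propagated through the
    sandwich covariance.
    """
    compiled = result.compiled
    theta = result.theta
    a, s = compiled._matrices(theta)
    b = np.linalg.inv(np.eye(compiled.n) - a)
    variances = np.diag(b @ s @ b.T)
    zero = [compiled.var_names[i] for i, v in enumerate(variances)
            if v <= 1e-12]
    if zero:
        raise ValueError(f"zero model-implied variance for: {zero}")

    std = _standardized_vector(compiled, theta)
    eps = 1e-6
    jac = np.zeros((len(std), compiled.n_free))
    for i in range(compiled.n_free):
        shift = np.zeros_like(theta)
        step = eps * max(1.0, abs(theta[i]))
        shift[i] = step
        jac[:, i] = (_standardized_vector(compiled, theta + shift)
                     - _standardized_vector(compiled, theta - shift)) / (2 * step)
    std_se = np.sqrt(np.clip(np.diag(jac @ result.cov_theta @ jac.T), 0.0, None))

    unstd = []
    it = iter(theta)
    for p in compiled.params:
        unstd.append(next(it) if p.free else p.value)
    return pd.DataFrame({
        "parameter": [p.label for p in compiled.params],
        "free": [p.free for p in compiled.params],
        "estimate": unstd,
        "std_estimate": std,
        "std_se": std_se,
        "ci_lower": std - 1.959963984540054 * std_se,
        "ci_upper": std + 1.959963984540054 * std_se,
    })
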