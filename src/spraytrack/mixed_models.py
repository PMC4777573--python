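"""Mixed-model engine: GLMMs (Laplace) and LMMs (REML) with random intercepts.

The engine covers exactly what the downstream analyses need:

* binomial (logit) and Poisson (log) generalized linear mixed models fitted by
  maximum likelihood with a Laplace approximation to the integrated
  likelihood (one quadrature point), with random intercepts for any number of
  grouping factors, crossed or nested;
* Gaussian linear mixed models fitted by REML;
* fixed-part or conditional predictions on new data.

Random effects are parameterised spherically (``b = sigma * u`` with
``u ~ N(0, I)``), so zero variances sit on the boundary of the optimisation
box rather than at infinity.  The fit is deterministic given data and the
fixed starting values (variances at 1, coefficients at the GLM estimate).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "ConvergenceError",
    "fit_glmm",
    "fit_lmm",
    "predict_response",
]

_FAMILIES = {"binomial", "poisson", "gaussian"}


class ConvergenceError(RuntimeError):
    """Raised when the outer optimisation fails to converge."""


@dataclass
class ModelSpec:
    """Declarative model description.

    ``fixed_terms`` holds main effects (column names) and pairwise
    interactions written ``"a:b"``.  ``random_intercepts`` holds grouping
    factors; a nested factor is written ``"outer/inner"`` (expanding to the
    outer factor plus the inner-within-outer combination) or directly as the
    combination ``"outer:inner"``.
    """

    family: str
    response: str
    fixed_terms: list[str] = field(default_factory=list)
    random_intercepts: list[str] = field(default_factory=list)
    trials: str | None = None
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and self.trials is None:
            raise ValueError("binomial models need a trials column")
        expanded: list[str] = []
        for g in self.random_intercepts:
            if "/" in g:
                outer, inner = (s.strip() for s in g.split("/", 1))
                expanded.extend([outer, f"{outer}:{inner}"])
            else:
                expanded.append(g)
        self.random_intercepts = expanded


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


@dataclass
class _DesignInfo:
    """Frozen encoding of the fixed-effect design (treatment contrasts)."""

    terms: list[str]
    categorical_levels: dict[str, list[str]]  # reference level first
    column_names: list[str]

    def _encode_variable(self, frame: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
        if name not in frame.columns:
            raise KeyError(f"variable {name!r} not in data")
        col = frame[name]
        if name in self.categorical_levels:
            levels = self.categorical_levels[name]
            values = col.astype(str).to_numpy()
            unknown = set(values) - set(levels)
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(unknown)} for {name!r}")
            cols = np.column_stack([(values == lv).astype(float) for lv in levels[1:]])
            names = [f"{name}[{lv}]" for lv in levels[1:]]
            return cols, names
        return col.to_numpy(dtype=float)[:, None], [name]

    def build(self, frame: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(frame), 1))]
        for term in self.terms:
            parts = term.split(":")
            mat, names = self._encode_variable(frame, parts[0])
            for part in parts[1:]:
                pmat, pnames = self._encode_variable(frame, part)
                mat = np.einsum("ij,ik->ijk", mat, pmat).reshape(len(frame), -1)
            blocks.append(mat)
        X = np.hstack(blocks)
        if X.shape[1] != len(self.column_names):
            raise ValueError("design width mismatch against fitted design")
        return X


def _is_categorical(col: pd.Series) -> bool:
    return (
        col.dtype == object
        or isinstance(col.dtype, pd.CategoricalDtype)
        or pd.api.types.is_bool_dtype(col)
        or pd.api.types.is_string_dtype(col)
    )


def _make_design_info(frame: pd.DataFrame, spec: ModelSpec) -> _DesignInfo:
    variables: list[str] = []
    for term in spec.fixed_terms:
        for part in term.split(":"):
            if part not in variables:
                variables.append(part)
    cat_levels: dict[str, list[str]] = {}
    for name in variables:
        if name not in frame.columns:
            raise KeyError(f"fixed-effect variable {name!r} not in data")
        if _is_categorical(frame[name]):
            levels = sorted(frame[name].astype(str).unique())
            ref = spec.reference_levels.get(name, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {name!r}")
            cat_levels[name] = [ref] + [lv for lv in levels if lv != ref]

    names = ["Intercept"]
    for term in spec.fixed_terms:
        parts = term.split(":")
        part_names: list[list[str]] = []
        for part in parts:
            if part in cat_levels:
                part_names.append([f"{part}[{lv}]" for lv in cat_levels[part][1:]])
            else:
                part_names.append([part])
        combos = part_names[0]
        for pn in part_names[1:]:
            combos = [f"{a}:{b}" for a in combos for b in pn]
        names.extend(combos)
    return _DesignInfo(terms=list(spec.fixed_terms), categorical_levels=cat_levels, column_names=names)


def _group_codes(frame: pd.DataFrame, factor: str) -> tuple[np.ndarray, list[str]]:
    if ":" in factor:
        parts = factor.split(":")
        for p in parts:
            if p not in frame.columns:
                raise KeyError(f"grouping variable {p!r} not in data")
        combined = frame[parts[0]].astype(str)
        for p in parts[1:]:
            combined = combined + ":" + frame[p].astype(str)
    else:
        if factor not in frame.columns:
            raise KeyError(f"grouping variable {factor!r} not in data")
        combined = frame[factor].astype(str)
    codes, levels = pd.factorize(combined, sort=True)
    return codes, list(levels)


def _z_matrix(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """A fitted mixed model: coefficient table, variance components, design."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index term; columns coef, se, z, p
    random_sd: dict[str, float]
    loglik: float
    converged: bool
    n_obs: int
    method: str  # "laplace-ml" or "reml"
    scale: float | None = None  # residual SD (gaussian only)
    vcov: np.ndarray | None = None  # fixed-effect covariance (Wald)
    design_info: _DesignInfo | None = None
    random_modes: dict[str, pd.Series] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.coefficients.loc[name, "coef"])

    def se(self, name: str) -> float:
        return float(self.coefficients.loc[name, "se"])

    @property
    def beta(self) -> np.ndarray:
        return self.coefficients["coef"].to_numpy()

    def summary(self) -> str:
        lines = [
            f"{self.spec.family} mixed model ({self.method}), "
            f"n = {self.n_obs}, logLik = {self.loglik:.3f}, "
            f"converged = {self.converged}",
            self.coefficients.to_string(float_format=lambda v: f"{v:.4f}"),
            "Random-effect SDs: "
            + ", ".join(f"{k} = {v:.4f}" for k, v in self.random_sd.items()),
        ]
        if self.scale is not None:
            lines.append(f"Residual SD: {self.scale:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "family": self.spec.family,
            "method": self.method,
            "n_obs": self.n_obs,
            "loglik": self.loglik,
            "converged": self.converged,
            "coefficients": {
                name: {
                    "coef": float(row["coef"]),
                    "se": float(row["se"]),
                    "z": float(row["z"]) if np.isfinite(row["z"]) else None,
                    "p": float(row["p"]) if np.isfinite(row["p"]) else None,
                }
                for name, row in self.coefficients.iterrows()
            },
            "random_sd": {k: float(v) for k, v in self.random_sd.items()},
            "residual_sd": float(self.scale) if self.scale is not None else None,
            "messages": list(self.messages),
        }


# ---------------------------------------------------------------------------
# GLMM (Laplace)
# ---------------------------------------------------------------------------


def _family_funcs(family: str):
    if family == "binomial":

        def mu_of(eta):
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))

        def loglik(y_count, m, mu):
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            from scipy.special import gammaln

            return float(
                np.sum(
                    y_count * np.log(mu)
                    + (m - y_count) * np.log1p(-mu)
                    + gammaln(m + 1)
                    - gammaln(y_count + 1)
                    - gammaln(m - y_count + 1)
                )
            )

        def weights(m, mu):
            return m * mu * (1 - mu)

        def resid(y_count, m, mu):
            return y_count - m * mu

        return mu_of, loglik, weights, resid

    if family == "poisson":

        def mu_of(eta):
            return np.exp(np.clip(eta, -35, 35))

        def loglik(y_count, m, mu):
            from scipy.special import gammaln

            mu = np.clip(mu, 1e-12, None)
            return float(np.sum(y_count * np.log(mu) - mu - gammaln(y_count + 1)))

        def weights(m, mu):
            return mu

        def resid(y_count, m, mu):
            return y_count - mu

        return mu_of, loglik, weights, resid

    raise ValueError(family)


def _pirls(
    family: str,
    y_count: np.ndarray,
    m: np.ndarray,
    fixed_eta: np.ndarray,
    Zs: np.ndarray,
    u0: np.ndarray,
    tol: float = 1e-11,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Penalised IRLS for the random-effect modes given fixed part and scale.

    Returns (u_mode, penalised_deviance, cho_factor_of(Zs'WZs+I), ok).
    """
    mu_of, loglik, weights, resid = _family_funcs(family)
    q = Zs.shape[1]
    u = u0.copy()

    def pdev(u):
        mu = mu_of(fixed_eta + Zs @ u)
        return -2.0 * loglik(y_count, m, mu) + float(u @ u), mu

    dev, mu = pdev(u)
    ok = False
    chol = None
    for _ in range(max_iter):
        W = weights(m, mu)
        H = Zs.T @ (Zs * W[:, None]) + np.eye(q)
        g = Zs.T @ resid(y_count, m, mu) - u
        chol = linalg.cho_factor(H, lower=True)
        step = linalg.cho_solve(chol, g)
        # step halving on the penalised deviance
        alpha = 1.0
        for _ in range(30):
            u_new = u + alpha * step
            dev_new, mu_new = pdev(u_new)
            if dev_new <= dev + 1e-12:
                break
            alpha /= 2.0
        improvement = dev - dev_new
        u, dev, mu = u_new, dev_new, mu_new
        if improvement < tol * (abs(dev) + 1.0):
            ok = True
            break
    if chol is None:  # q == 0 handled by caller
        raise RuntimeError("empty random-effect design")
    # refresh factor at the mode for the Laplace determinant
    W = weights(m, mu)
    H = Zs.T @ (Zs * W[:, None]) + np.eye(q)
    chol = linalg.cho_factor(H, lower=True)
    return u, dev, chol, ok


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    *,
    tol: float = 1e-8,
    max_outer_iter: int = 500,
) -> MixedModelFit:
    """Fit a binomial/Poisson GLMM by Laplace-approximated ML.

    Stage 1 profiles the fixed effects inside the penalised least-squares
    problem and optimises the random-effect SDs alone; stage 2 polishes
    (SDs, coefficients) jointly against the Laplace objective, mirroring the
    two-stage default of the reference mixed-model implementations.
    """
    if spec.family == "gaussian":
        raise ValueError("use fit_lmm for gaussian models")
    if not spec.random_intercepts:
        raise ValueError("no random intercepts declared; fit a plain GLM instead")
    data = data.reset_index(drop=True)

    info = _make_design_info(data, spec)
    X = info.build(data)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")

    y = data[spec.response].to_numpy(dtype=float)
    if spec.family == "binomial":
        m = data[spec.trials].to_numpy(dtype=float)
        if np.any((y < 0) | (y > m)):
            raise ValueError("binomial response outside [0, trials]")
    else:
        m = np.ones(n)
        if np.any(y < 0):
            raise ValueError("negative Poisson response")

    groups = []
    for factor in spec.random_intercepts:
        codes, levels = _group_codes(data, factor)
        groups.append((factor, codes, levels, _z_matrix(codes, len(levels))))
    Z = np.hstack([g[3] for g in groups])
    sizes = [len(g[2]) for g in groups]
    q = Z.shape[1]
    col_factor = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])

    mu_of, loglik_f, weights_f, resid_f = _family_funcs(spec.family)

    # deterministic start: GLM coefficients, unit random-effect SDs
    import statsmodels.api as sm

    glm_family = (
        sm.families.Binomial() if spec.family == "binomial" else sm.families.Poisson()
    )
    if spec.family == "binomial":
        endog = np.column_stack([y, m - y])
    else:
        endog = y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta_start = sm.GLM(endog, X, family=glm_family).fit().params

    state = {"u": np.zeros(q)}

    def scaled_Z(sig: np.ndarray) -> np.ndarray:
        return Z * sig[col_factor]

    def laplace_objective(sig: np.ndarray, beta: np.ndarray) -> float:
        Zs = scaled_Z(np.maximum(sig, 0.0))
        u, dev, chol, ok = _pirls(spec.family, y, m, X @ beta, Zs, state["u"])
        state["u"] = u
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        return dev + logdet

    n_sig = len(sizes)

    # ---- stage 1: optimise SDs with fixed effects profiled via joint PIRLS
    def profiled_objective(sig_vec: np.ndarray) -> float:
        sig = np.maximum(sig_vec, 0.0)
        Zs = scaled_Z(sig)
        A = np.hstack([X, Zs])  # profile beta jointly; penalty only on u block
        pen = np.concatenate([np.zeros(p), np.ones(q)])
        v = np.concatenate([beta_start, state["u"]])

        def pdev(v):
            mu = mu_of(A @ v)
            return -2.0 * loglik_f(y, m, mu) + float(v @ (pen * v)), mu

        dev, mu = pdev(v)
        for _ in range(200):
            W = weights_f(m, mu)
            H = A.T @ (A * W[:, None]) + np.diag(pen)
            g = A.T @ resid_f(y, m, mu) - pen * v
            try:
                chol = linalg.cho_factor(H, lower=True)
            except linalg.LinAlgError:
                return np.inf
            step = linalg.cho_solve(chol, g)
            alpha = 1.0
            for _ in range(30):
                v_new = v + alpha * step
                dev_new, mu_new = pdev(v_new)
                if dev_new <= dev + 1e-12:
                    break
                alpha /= 2.0
            improvement = dev - dev_new
            v, dev, mu = v_new, dev_new, mu_new
            if improvement < 1e-10 * (abs(dev) + 1.0):
                break
        W = weights_f(m, mu)
        Hu = Zs.T @ (Zs * W[:, None]) + np.eye(q)
        sign, logdet = np.linalg.slogdet(Hu)
        state["u"] = v[p:]
        state["beta_profiled"] = v[:p]
        return dev + logdet

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stage1 = optimize.minimize(
            profiled_objective,
            np.ones(n_sig),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
    sig1 = np.maximum(stage1.x, 0.0)
    beta1 = state.get("beta_profiled", beta_start)

    # ---- stage 2: joint quasi-Newton over (SDs, coefficients)
    def objective(params: np.ndarray) -> float:
        return laplace_objective(params[:n_sig], params[n_sig:])

    x0 = np.concatenate([sig1, beta1])
    bounds = [(0.0, None)] * n_sig + [(None, None)] * p
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": max_outer_iter},
        )
    converged = bool(res.success)
    if not converged:
        # L-BFGS-B can stop "abnormally" on boundary optima; a derivative-free
        # polish both verifies and (if needed) completes the convergence.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            polish = optimize.minimize(
                lambda x: objective(np.concatenate([np.maximum(x[:n_sig], 0), x[n_sig:]])),
                res.x,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
        if polish.fun <= res.fun + 1e-6:
            res = polish
            converged = bool(
                polish.success or abs(polish.fun - res.fun) < 1e-6
            )
    sig = np.maximum(res.x[:n_sig], 0.0)
    beta = res.x[n_sig:]

    # final inner solve at the optimum
    Zs = scaled_Z(sig)
    u, dev, chol, inner_ok = _pirls(spec.family, y, m, X @ beta, Zs, state["u"])
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
    loglik_value = -0.5 * (dev + logdet)

    # Wald covariance of beta conditional on the variance parameters:
    # invert the (beta, u) block information and keep the beta block.
    mu = mu_of(X @ beta + Zs @ u)
    W = weights_f(m, mu)
    Hbb = X.T @ (X * W[:, None])
    Hbu = X.T @ (Zs * W[:, None])
    Huu = Zs.T @ (Zs * W[:, None]) + np.eye(q)
    Huu_inv_Hub = linalg.cho_solve(linalg.cho_factor(Huu, lower=True), Hbu.T)
    vcov = np.linalg.inv(Hbb - Hbu @ Huu_inv_Hub)
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))

    messages: list[str] = []
    eta = X @ beta + Zs @ u
    if np.max(np.abs(eta)) > 25 or np.max(np.abs(beta)) > 25:
        messages.append(
            "possible separation: extreme linear predictor or coefficients"
        )
        warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)
    if not converged:
        messages.append(f"outer optimiser did not converge: {res.message}")
        warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)

    zval = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    coef_table = pd.DataFrame(
        {"coef": beta, "se": se, "z": zval, "p": pval}, index=info.column_names
    )

    random_sd = {g[0]: float(s) for g, s in zip(groups, sig)}
    random_modes = {}
    offset = 0
    for (factor, codes, levels, _), s in zip(groups, sig):
        random_modes[factor] = pd.Series(
            s * u[offset : offset + len(levels)], index=levels
        )
        offset += len(levels)

    return MixedModelFit(
        spec=spec,
        coefficients=coef_table,
        random_sd=random_sd,
        loglik=loglik_value,
        converged=converged and inner_ok,
        n_obs=n,
        method="laplace-ml",
        vcov=vcov,
        design_info=info,
        random_modes=random_modes,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# LMM (REML)
# ---------------------------------------------------------------------------


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, *, tol: float = 1e-10) -> MixedModelFit:
    """Fit a Gaussian LMM with random intercepts by REML.

    The variance ratios (random-effect SD over residual SD) are optimised on
    the profiled REML criterion; residual variance and coefficients have
    closed-form profiles.  Uses the Woodbury identity throughout, so cost is
    O(n q^2) for q total random-effect levels.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm is for gaussian models")
    if not spec.random_intercepts:
        raise ValueError("no random intercepts declared; fit OLS instead")
    data = data.reset_index(drop=True)

    info = _make_design_info(data, spec)
    X = info.build(data)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")
    y = data[spec.response].to_numpy(dtype=float)

    groups = []
    for factor in spec.random_intercepts:
        codes, levels = _group_codes(data, factor)
        groups.append((factor, codes, levels, _z_matrix(codes, len(levels))))
    Z = np.hstack([g[3] for g in groups])
    sizes = [len(g[2]) for g in groups]
    q = Z.shape[1]
    col_factor = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
    n_lam = len(sizes)

    def criterion_parts(lam: np.ndarray):
        """REML criterion pieces for relative SDs lam (>= 0)."""
        Zl = Z * lam[col_factor]
        A = Zl.T @ Zl + np.eye(q)  # inner matrix of Omega = I + Zl Zl'
        cholA = linalg.cho_factor(A, lower=True)
        logdet_omega = 2.0 * float(np.sum(np.log(np.diag(cholA[0]))))

        def omega_solve(B):
            return B - Zl @ linalg.cho_solve(cholA, Zl.T @ B)

        XtOiX = X.T @ omega_solve(X)
        XtOiy = X.T @ omega_solve(y)
        cholX = linalg.cho_factor(XtOiX, lower=True)
        beta = linalg.cho_solve(cholX, XtOiy)
        r = y - X @ beta
        quad = float(r @ omega_solve(r))
        logdet_X = 2.0 * float(np.sum(np.log(np.diag(cholX[0]))))
        sigma2 = quad / (n - p)
        crit = (
            (n - p) * np.log(2 * np.pi * sigma2)
            + logdet_omega
            + logdet_X
            + (n - p)
        )
        return crit, beta, sigma2, cholA, Zl, XtOiX

    def objective(lam_vec: np.ndarray) -> float:
        lam = np.maximum(lam_vec, 0.0)
        try:
            return criterion_parts(lam)[0]
        except linalg.LinAlgError:
            return np.inf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            objective,
            np.ones(n_lam),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": tol, "maxiter": 2000},
        )
    lam = np.maximum(res.x, 0.0)
    crit, beta, sigma2, cholA, Zl, XtOiX = criterion_parts(lam)
    sigma = float(np.sqrt(sigma2))
    reml_loglik = -0.5 * crit

    vcov = sigma2 * np.linalg.inv(XtOiX)
    se = np.sqrt(np.clip(np.diag(vcov), 0, None))
    tval = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    # no default p-values for LMM fixed effects (denominator df not defined)
    pval = np.full_like(tval, np.nan)
    coef_table = pd.DataFrame(
        {"coef": beta, "se": se, "z": tval, "p": pval}, index=info.column_names
    )

    # BLUPs on the response scale: b_hat = lam^2 * Z' Omega^{-1} r
    r = y - X @ beta
    omr = r - Zl @ linalg.cho_solve(cholA, Zl.T @ r)
    u_hat = Zl.T @ omr
    random_modes = {}
    offset = 0
    for (factor, codes, levels, _), l in zip(groups, lam):
        random_modes[factor] = pd.Series(
            l * u_hat[offset : offset + len(levels)], index=levels
        )
        offset += len(levels)

    messages: list[str] = []
    if not res.success:
        messages.append(f"REML optimiser did not converge: {res.message}")
        warnings.warn(messages[-1], RuntimeWarning, stacklevel=2)

    return MixedModelFit(
        spec=spec,
        coefficients=coef_table,
        random_sd={g[0]: float(sigma * l) for g, l in zip(groups, lam)},
        loglik=reml_loglik,
        converged=bool(res.success),
        n_obs=n,
        method="reml",
        scale=sigma,
        vcov=vcov,
        design_info=info,
        random_modes=random_modes,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _inverse_link(family: str, eta: np.ndarray) -> np.ndarray:
    if family == "binomial":
        return 1.0 / (1.0 + np.exp(-eta))
    if family == "poisson":
        return np.exp(eta)
    return eta


def predict_response(
    fit: MixedModelFit,
    newdata: pd.DataFrame,
    include_random: bool = False,
) -> np.ndarray:
    """Expected response for new records.

    With ``include_random=False`` (the default) only the fixed part of the
    linear predictor is used.  With ``include_random=True`` the conditional
    modes of every declared grouping factor are added; unknown levels raise.
    """
    if fit.design_info is None:
        raise ValueError("fit carries no design information")
    X = fit.design_info.build(newdata)
    eta = X @ fit.beta
    if include_random:
        for factor, modes in fit.random_modes.items():
            if ":" in factor:
                parts = factor.split(":")
                combined = newdata[parts[0]].astype(str)
                for pcol in parts[1:]:
                    combined = combined + ":" + newdata[pcol].astype(str)
            else:
                combined = newdata[factor].astype(str)
            unknown = set(combined) - set(modes.index)
            if unknown:
                raise ValueError(
                    f"unknown level(s) {sorted(unknown)} of grouping factor "
                    f"{factor!r} in newdata"
                )
            eta = eta + modes.reindex(combined).to_numpy()
    return _inverse_link(fit.spec.family, eta)
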