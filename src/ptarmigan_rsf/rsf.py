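"""Used–available mixed-effects logistic regression and the exponential RSF.

The selection model is a logistic GLMM contrasting used locations (y = 1)
with available locations (y = 0), with a random intercept per survey area
absorbing between-area density differences:

    logit P(y=1 | x, area j) = β'x + u_j,   u_j ~ N(0, σ_u²).

The marginal likelihood integrates u_j out; we maximize its Laplace
approximation (exact mode + curvature per area, quasi-Newton outer loop
with analytic gradients).  An adaptive Gauss–Hermite quadrature evaluator
of the same marginal likelihood is provided as an independent cross-check.

The fitted fixed effects define the exponential resource selection
function w(x) = exp(β₁x₁ + β₂x₂ + …), evaluated without the intercept or
the random effects, then max-scaled to (0, 1] and cut into 10 quantile
bins ranked from low (1) to high (10) relative probability of selection.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, roots_hermite
from scipy.stats import norm

from .covariates import REFERENCE_CLASS, StandardizationParams

_TL_OPTIONS = ("none", "linear", "quadratic")
_SLOPE_OPTIONS = ("none", "linear", "quadratic")
_ASPECT_OPTIONS = ("none", "categorical", "ns", "ns_ew")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure; vegetation type is always included."""

    timberline: str = "none"
    slope: str = "none"
    aspect: str = "none"

    def __post_init__(self) -> None:
        if self.timberline not in _TL_OPTIONS:
            raise ValueError(f"timberline option {self.timberline!r}")
        if self.slope not in _SLOPE_OPTIONS:
            raise ValueError(f"slope option {self.slope!r}")
        if self.aspect not in _ASPECT_OPTIONS:
            raise ValueError(f"aspect option {self.aspect!r}")

    def continuous_terms(self) -> list[str]:
        terms = []
        if self.timberline != "none":
            terms.append("timberline_dev")
        if self.timberline == "quadratic":
            terms.append("timberline_dev^2")
        if self.slope != "none":
            terms.append("slope")
        if self.slope == "quadratic":
            terms.append("slope^2")
        if self.aspect in ("ns", "ns_ew"):
            terms.append("n_aspect")
        if self.aspect == "ns_ew":
            terms.append("e_aspect")
        return terms

    def n_fixed_effects(self, n_veg_levels: int = 16) -> int:
        n = 1 + (n_veg_levels - 1) + len(self.continuous_terms())
        if self.aspect == "categorical":
            n += 4
        return n

    def n_parameters(self, n_veg_levels: int = 16) -> int:
        """K = fixed effects + 1 for the random-intercept variance."""
        return self.n_fixed_effects(n_veg_levels) + 1

    def label(self) -> str:
        parts = ["Vegetation type"]
        if self.timberline != "none":
            parts.append("Timberline")
        if self.timberline == "quadratic":
            parts.append("Timberline^2")
        if self.slope != "none":
            parts.append("Slope")
        if self.slope == "quadratic":
            parts.append("Slope^2")
        if self.aspect == "categorical":
            parts.append("Aspect Categorical")
        elif self.aspect == "ns":
            parts.append("Aspect North-South")
        elif self.aspect == "ns_ew":
            parts.extend(["Aspect North-South", "Aspect East-West"])
        return " + ".join(parts)


def candidate_set(
    timberline_options=("linear", "quadratic"),
    slope_options=("none", "linear", "quadratic"),
    aspect_options=("none", "categorical", "ns", "ns_ew"),
) -> list[ModelSpec]:
    """Candidate fixed-effect structures (default grid: 24 models).

    Vegetation type is in every model.  Empty option lists collapse to
    'none', so an empty grid yields the single vegetation-only model.
    """
    tl = tuple(timberline_options) or ("none",)
    sl = tuple(slope_options) or ("none",)
    asp = tuple(aspect_options) or ("none",)
    seen, out = set(), []
    for t, s, a in itertools.product(tl, sl, asp):
        spec = ModelSpec(timberline=t, slope=s, aspect=a)
        if spec in seen:
            warnings.warn(f"duplicate model spec collapsed: {spec.label()}")
            continue
        seen.add(spec)
        out.append(spec)
    return out


def build_design(
    records: pd.DataFrame, spec: ModelSpec, veg_levels=None
) -> tuple[np.ndarray | None, pd.DataFrame, np.ndarray]:
    """Design matrix for the logistic GLMM.

    Treatment coding with exposed alpine ridges as the vegetation
    reference and 'flat' as the aspect reference.  Columns: intercept,
    vegetation dummies, then continuous terms in spec order.  Returns
    (response or None, fixed-effects DataFrame, area labels).
    """
    veg = records["vegetation_class"]
    if veg_levels is None:
        present = list(pd.unique(veg))
        if REFERENCE_CLASS not in present:
            raise ValueError(
                f"reference vegetation level {REFERENCE_CLASS!r} absent from data"
            )
        veg_levels = [REFERENCE_CLASS] + sorted(
            set(present) - {REFERENCE_CLASS}
        )
    elif "response" in records:
        # fitting: a requested level with no data is inestimable
        missing = sorted(set(veg_levels) - set(veg))
        if missing:
            raise ValueError(f"vegetation level(s) absent from data: {missing}")
    unknown = sorted(set(veg) - set(veg_levels))
    if unknown:
        raise ValueError(f"records contain unmodelled vegetation level(s): {unknown}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(records))}
    for level in veg_levels[1:]:
        cols[f"veg[{level}]"] = (veg == level).to_numpy(dtype=float)

    std = {
        "timberline_dev": "timberline_dev_m_std",
        "slope": "slope_deg_std",
        "n_aspect": "n_aspect_std",
        "e_aspect": "e_aspect_std",
    }
    for term in spec.continuous_terms():
        base = term[:-2] if term.endswith("^2") else term
        col = std[base]
        if col not in records:
            raise ValueError(
                f"records lack standardized column {col!r}; standardize first"
            )
        v = records[col].to_numpy(dtype=float)
        cols[term] = v * v if term.endswith("^2") else v
    if spec.aspect == "categorical":
        for cat in ("north", "east", "south", "west"):
            cols[f"aspect[{cat}]"] = (
                records["aspect_category"] == cat
            ).to_numpy(dtype=float)

    X = pd.DataFrame(cols)
    y = records["response"].to_numpy(dtype=float) if "response" in records else None
    groups = records["area_id"].to_numpy() if "area_id" in records else None
    return y, X, groups


@dataclass
class RSFFit:
    """A fitted selection model."""

    spec: ModelSpec
    veg_levels: list[str]
    beta: pd.Series
    se: pd.Series
    sigma_u: float
    loglik: float
    aic: float
    K: int
    n_obs: int
    n_groups: int
    converged: bool
    std_params: StandardizationParams | None = None

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        z = norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {"lower": self.beta - z * self.se, "upper": self.beta + z * self.se}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": vars(self.spec) | {},
                "veg_levels": self.veg_levels,
                "beta": self.beta.to_dict(),
                "se": self.se.to_dict(),
                "sigma_u": self.sigma_u,
                "loglik": self.loglik,
                "aic": self.aic,
                "K": self.K,
                "n_obs": self.n_obs,
                "n_groups": self.n_groups,
                "converged": self.converged,
                "standardization": self.std_params.to_dict()
                if self.std_params
                else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "RSFFit":
        d = json.loads(text)
        std = d.get("standardization")
        return cls(
            spec=ModelSpec(**d["spec"]),
            veg_levels=list(d["veg_levels"]),
            beta=pd.Series(d["beta"]),
            se=pd.Series(d["se"]),
            sigma_u=d["sigma_u"],
            loglik=d["loglik"],
            aic=d["aic"],
            K=d["K"],
            n_obs=d["n_obs"],
            n_groups=d["n_groups"],
            converged=d["converged"],
            std_params=StandardizationParams.from_dict(std) if std else None,
        )


class _Laplace:
    """Laplace-approximated marginal log-likelihood and its gradient for a
    random-intercept logistic model, vectorized across groups."""

    def __init__(self, y, X, group_idx, n_groups):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.g = np.asarray(group_idx)
        self.J = n_groups
        self._u = np.zeros(n_groups)

    def _modes(self, beta, tau, tol=1e-11, max_iter=100):
        """Per-group posterior modes û_j by Newton; concave, warm-started."""
        t = 1.0 / tau**2
        u = self._u.copy()
        eta0 = self.X @ beta
        for _ in range(max_iter):
            p = _sigmoid(eta0 + u[self.g])
            s = np.bincount(self.g, weights=self.y - p, minlength=self.J) - t * u
            W = np.bincount(self.g, weights=p * (1 - p), minlength=self.J)
            D = W + t
            step = s / D
            u += step
            if np.max(np.abs(step)) < tol:
                break
        self._u = u
        return u

    def loglik_grad(self, theta):
        beta, rho = theta[:-1], theta[-1]
        tau = math.exp(rho)
        t = 1.0 / tau**2
        u = self._modes(beta, tau)
        eta = self.X @ beta + u[self.g]
        p = _sigmoid(eta)
        w = p * (1 - p)
        W = np.bincount(self.g, weights=w, minlength=self.J)
        D = W + t
        ll_rows = self.y * eta - np.logaddexp(0.0, eta)
        l = (
            float(ll_rows.sum())
            - 0.5 * t * float(u @ u)
            - self.J * math.log(tau)
            - 0.5 * float(np.log(D).sum())
        )
        # gradient wrt beta: envelope term + curvature correction
        resid = self.y - p
        g_beta = self.X.T @ resid
        wx = self.X * w[:, None]
        A = np.zeros((self.J, self.X.shape[1]))
        np.add.at(A, self.g, wx)  # a_j = sum_i w_i x_i
        k = w * (1 - 2 * p)
        B = np.zeros_like(A)
        np.add.at(B, self.g, self.X * k[:, None])  # b_j = sum_i w_i(1-2p_i) x_i
        V = np.bincount(self.g, weights=k, minlength=self.J)
        corr = (B - (V / D)[:, None] * A) / D[:, None]
        g_beta -= 0.5 * corr.sum(axis=0)
        # gradient wrt rho = log tau
        g_rho = float(np.sum(t * u**2 - 1.0 + t / D - t * u * V / D**2))
        return l, np.concatenate([g_beta, [g_rho]])


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def marginal_loglik_agq(beta, sigma_u, y, X, groups, n_nodes: int = 51) -> float:
    """Adaptive Gauss–Hermite evaluation of the marginal log-likelihood.

    Independent of the Laplace path: each group's integral over its random
    intercept is computed by quadrature centred at the posterior mode with
    curvature-matched scaling.  Intended as an oracle on small data.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    J = codes.max() + 1
    nodes, weights = roots_hermite(n_nodes)
    lap = _Laplace(y, X, codes, J)
    u_hat = lap._modes(np.asarray(beta, dtype=float), sigma_u)
    eta0 = X @ np.asarray(beta, dtype=float)
    t = 1.0 / sigma_u**2
    total = 0.0
    for j in range(J):
        rows = codes == j
        p_hat = _sigmoid(eta0[rows] + u_hat[j])
        D = np.sum(p_hat * (1 - p_hat)) + t
        scale = math.sqrt(2.0 / D)
        us = u_hat[j] + scale * nodes
        h = np.array(
            [
                float(
                    np.sum(
                        y[rows] * (eta0[rows] + u)
                        - np.logaddexp(0.0, eta0[rows] + u)
                    )
                )
                - 0.5 * t * u**2
                - 0.5 * math.log(2 * math.pi * sigma_u**2)
                for u in us
            ]
        )
        total += logsumexp(h + nodes**2 + np.log(weights)) + math.log(scale)
    return float(total)


def fit_mixed_logistic(
    y,
    X: pd.DataFrame,
    groups,
    std_params: StandardizationParams | None = None,
    spec: ModelSpec | None = None,
    veg_levels=None,
    gtol: float = 1e-8,
) -> RSFFit:
    """Maximum (Laplace-approximated marginal) likelihood fit.

    Outer optimization is L-BFGS-B over (β, log σ_u) with analytic
    gradients; inner per-area modes by Newton.  Standard errors come from
    the observed information (finite differences of the analytic
    gradient).  K counts fixed effects plus the variance parameter.
    """
    y = np.asarray(y, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    J = len(uniques)
    if J < 2:
        raise ValueError("need >=2 survey areas to estimate the random intercept")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")
    _warn_on_separation(y, X)

    lap = _Laplace(y, Xv, codes, J)

    # starting values: plain logistic via IRLS, modest random-effect SD
    beta0 = _plain_logistic_irls(y, Xv)
    theta0 = np.concatenate([beta0, [math.log(0.3)]])
    bounds = [(None, None)] * Xv.shape[1] + [(-8.0, 3.0)]

    def negll(theta):
        l, g = lap.loglik_grad(theta)
        return -l, -g

    res = optimize.minimize(
        negll,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "gtol": gtol, "ftol": 1e-13},
    )
    theta = res.x
    l_hat, g_hat = lap.loglik_grad(theta)
    at_bound = theta[-1] <= bounds[-1][0] + 1e-9
    grad_ok = np.max(np.abs(g_hat[:-1])) < 1e-4 and (
        at_bound or abs(g_hat[-1]) < 1e-4
    )
    converged = bool(res.success or grad_ok)
    if not converged:
        raise RuntimeError(
            f"GLMM did not converge: {res.message}; |grad|={np.abs(g_hat).max():.2e}"
        )

    H = _numeric_hessian(lambda th: lap.loglik_grad(th)[1], theta)
    cov = _safe_inverse(-H)
    se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))

    K = Xv.shape[1] + 1
    beta = pd.Series(theta[:-1], index=list(X.columns))
    return RSFFit(
        spec=spec if spec is not None else ModelSpec(),
        veg_levels=list(veg_levels) if veg_levels is not None else [],
        beta=beta,
        se=pd.Series(se, index=list(X.columns)),
        sigma_u=float(math.exp(theta[-1])),
        loglik=float(l_hat),
        aic=float(-2 * l_hat + 2 * K),
        K=K,
        n_obs=len(y),
        n_groups=J,
        converged=converged,
        std_params=std_params,
    )


def _plain_logistic_irls(y, X, max_iter=50, tol=1e-10):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = _sigmoid(X @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = X @ beta + (y - p) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _warn_on_separation(y, X: pd.DataFrame):
    for col in X.columns:
        v = X[col].to_numpy()
        if col == "intercept" or len(np.unique(v)) > 2:
            continue
        on = v != 0
        if on.any() and (y[on].min() == y[on].max()):
            warnings.warn(f"possible complete separation in term {col!r}")


def _numeric_hessian(grad_fn, theta, eps=1e-5):
    n = len(theta)
    H = np.zeros((n, n))
    for i in range(n):
        step = eps * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += step
        tm[i] -= step
        H[:, i] = (grad_fn(tp) - grad_fn(tm)) / (2 * step)
    return 0.5 * (H + H.T)


def _safe_inverse(A):
    try:
        return np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A)


def select_model(fits: list[RSFFit]) -> RSFFit:
    """ΔAIC-parsimony rule: among fits within 2 AIC units of the best,
    return the one with fewest parameters (ties → lower AIC)."""
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to select from")
    best_aic = min(f.aic for f in fits)
    equivalent = [f for f in fits if f.aic - best_aic < 2.0]
    return min(equivalent, key=lambda f: (f.K, f.aic))


def model_comparison_table(fits: list[RSFFit]) -> pd.DataFrame:
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2)
    w /= w.sum()
    tab = pd.DataFrame(
        {
            "model": [f.spec.label() for f in fits],
            "K": [f.K for f in fits],
            "AIC": aics,
            "dAIC": delta,
            "AIC_wt": w,
        }
    ).sort_values("AIC", ignore_index=True)
    return tab


def predict_rsf(fit: RSFFit, records: pd.DataFrame) -> np.ndarray:
    """Exponential RSF w(x) = exp(β'x) over the fixed effects, excluding
    the intercept and the random intercepts (prediction is marginal)."""
    rec = records.drop(columns=["response"], errors="ignore")
    _, X, _ = build_design(rec, fit.spec, veg_levels=fit.veg_levels or None)
    cols = [c for c in X.columns if c != "intercept"]
    beta = fit.beta.reindex(X.columns)
    if beta.isna().any():
        raise ValueError("fit is missing coefficients for design columns")
    eta = X[cols].to_numpy() @ beta[cols].to_numpy()
    return np.exp(eta)


def scale_rsf(values) -> np.ndarray:
    """Divide by the maximum so the output lies in (0, 1]."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("no finite RSF values to scale")
    return v / np.nanmax(v[finite])


@dataclass
class BinAssignment:
    """Quantile cut points (interior edges) and the 1..n_bins assignment."""

    edges: np.ndarray
    n_bins: int = 10

    def assign(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.searchsorted(self.edges, v, side="right") + 1


def quantile_bin(values, n_bins: int = 10) -> BinAssignment:
    """Interior quantile cut points at 1/n, …, (n−1)/n of the sample."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(np.unique(v)) < n_bins:
        warnings.warn("fewer distinct values than bins; bins will be degenerate")
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(v, qs)
    if len(np.unique(edges)) < len(edges):
        warnings.warn("tied quantile edges; some bins collapse")
    return BinAssignment(edges=edges, n_bins=n_bins)
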