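"""One-inflated beta mixed regression for Preference Coefficients.

The response y is a pairwise Preference Coefficient on (0, 1]: a mixture of
a point mass at exactly 1 (two fish with an identical preference ranking),
with probability nu, and a beta density on (0, 1) for everything else:

    f(y) = nu * 1{y = 1} + (1 - nu) * Beta(y; mu * phi, (1 - mu) * phi) * 1{0 < y < 1}

with logit(mu) = x'beta + u_{fish1} + v_{fish2}.  The two fish identities in
each comparison enter as two separate crossed random intercepts,
u ~ N(0, sigma_u^2) and v ~ N(0, sigma_v^2).

Because the random effects enter only the beta component's mean, the
likelihood factorises exactly: the ones contribute a Bernoulli likelihood in
nu alone, and the beta part is marginalised over (u, v) by a Laplace
approximation whose inner Hessian is solved in block form (both
random-effect blocks are diagonal, so only a Schur complement the size of
the fish2 level set is dense).

Exact zeros (perfectly opposite rankings) fall outside the stated support
0 < Y <= 1 and are mapped to eps = 1/(2 * n) before fitting; the count of
such mappings is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, expit, gammaln, logit, polygamma

logger = logging.getLogger(__name__)

MEAN_TERMS = ("cover", "species", "site", "year", "cover:species")

_VAR_OF = {"species": "fish_species", "site": "site", "year": "year"}


@dataclass(frozen=True)
class OibeModelSpec:
    """Model structure: fixed-effect terms per submodel plus random terms.

    ``mean_terms`` is a subset of {"cover", "species", "site", "year",
    "cover:species"}; precision (log link) and inflation (logit link) default
    to intercept-only.  ``inflation_terms=None`` fixes nu = 0 (a plain beta
    mixed model).  Categorical terms use reference-level (drop-first) coding.
    """

    mean_terms: tuple[str, ...] = ("cover", "species", "site", "year")
    precision_terms: tuple[str, ...] = ()
    inflation_terms: tuple[str, ...] | None = ()
    random_terms: tuple[str, ...] = ("fish1_id", "fish2_id")

    def drop(self, term: str) -> "OibeModelSpec":
        return replace(self, mean_terms=tuple(t for t in self.mean_terms if t != term))


class DesignInfo:
    """Fixed-effect design matrix builder frozen to training categories."""

    def __init__(self, data: pd.DataFrame, terms: Sequence[str]):
        self.terms = tuple(terms)
        self.levels: dict[str, list] = {}
        for term in self.terms:
            base = term.split(":")[-1] if ":" in term else term
            if base in _VAR_OF:
                var = _VAR_OF[base]
                self.levels[var] = sorted(pd.unique(data[var]).tolist())
        self.columns = ["(Intercept)"]
        for term in self.terms:
            self.columns.extend(self._term_columns(term))

    def _term_columns(self, term: str) -> list[str]:
        if term == "cover":
            return ["cover"]
        if term in _VAR_OF:
            var = _VAR_OF[term]
            return [f"{term}[{lev}]" for lev in self.levels[var][1:]]
        if term == "cover:species":
            return [f"cover:species[{lev}]" for lev in self.levels["fish_species"][1:]]
        raise ValueError(f"unknown model term {term!r}")

    def build(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        cols = [np.ones(n)]
        for term in self.terms:
            if term == "cover":
                cols.append(np.asarray(data["hard_coral_cover"], dtype=float))
            elif term in _VAR_OF:
                var = _VAR_OF[term]
                for lev in self.levels[var][1:]:
                    cols.append((data[var].to_numpy() == lev).astype(float))
            elif term == "cover:species":
                cover = np.asarray(data["hard_coral_cover"], dtype=float)
                for lev in self.levels["fish_species"][1:]:
                    cols.append(cover * (data["fish_species"].to_numpy() == lev))
        return np.column_stack(cols)


@dataclass
class OibeFit:
    """A fitted one-inflated beta mixed model."""

    spec: OibeModelSpec
    beta: dict[str, float]
    se: dict[str, float]
    ci: dict[str, tuple[float, float]]
    phi: float
    nu: float
    sigma_u: float
    sigma_v: float
    loglik: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    r2_generalized: float | None = None
    design: DesignInfo | None = None
    blup_u: dict[str, float] = field(default_factory=dict)
    blup_v: dict[str, float] = field(default_factory=dict)

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[c] for c in self.design.columns])


# ---------------------------------------------------------------------------
# beta log-density pieces (mean-precision parameterisation)


def _beta_parts(eta: np.ndarray, ystar: np.ndarray, log_y: np.ndarray,
                log_1my: np.ndarray, phi: float):
    """Log-density, eta-score and the two curvature weights per observation."""
    eta = np.clip(eta, -16.0, 16.0)
    mu = expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * log_y + (b - 1.0) * log_1my
    mustar = digamma(a) - digamma(b)
    m = mu * (1.0 - mu)
    s = phi * (ystar - mustar) * m
    w_fisher = phi**2 * (polygamma(1, a) + polygamma(1, b)) * m**2
    w_obs = w_fisher - phi * (ystar - mustar) * (1.0 - 2.0 * mu) * m
    return ll, s, w_fisher, w_obs


class OibeModel:
    """Likelihood machinery bound to one dataset and one model spec."""

    def __init__(self, data: pd.DataFrame, spec: OibeModelSpec, zero_eps: float | None = None):
        if len(data) < 1:
            raise ValueError("need at least one observation")
        self.spec = spec
        self.data = data.reset_index(drop=True)
        y = np.asarray(self.data["coefficient"], dtype=float)
        if np.any(y < 0) or np.any(y > 1):
            raise ValueError("responses must lie in [0, 1]")
        eps = zero_eps if zero_eps is not None else 1.0 / (2.0 * len(y))
        n_zero = int(np.sum(y == 0))
        if n_zero:
            logger.info("mapped %d exact-zero responses to eps=%.3g", n_zero, eps)
            y = np.where(y == 0, eps, y)
        self.y = y
        self.ones = y == 1.0
        self.n = len(y)
        self.design = DesignInfo(self.data, spec.mean_terms)
        self.X = self.design.build(self.data)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design matrix is rank deficient")
        self.p = self.X.shape[1]
        self.has_re = len(spec.random_terms) > 0
        sub = ~self.ones
        self.Xs = self.X[sub]
        ys = y[sub]
        self.log_y = np.log(ys)
        self.log_1my = np.log1p(-ys)
        self.ystar = self.log_y - self.log_1my
        if self.has_re:
            u_codes, self.u_levels = pd.factorize(self.data.loc[sub, spec.random_terms[0]])
            v_codes, self.v_levels = pd.factorize(self.data.loc[sub, spec.random_terms[1]])
            self.u_idx = u_codes
            self.v_idx = v_codes
            self.n_u = len(self.u_levels)
            self.n_v = len(self.v_levels)
        else:
            self.n_u = self.n_v = 0
        self._b_warm: np.ndarray | None = None
        # inflation submodel bookkeeping
        self.nu_fixed_zero = spec.inflation_terms is None
        self.n_ones = int(self.ones.sum())
        if self.nu_fixed_zero and self.n_ones:
            raise ValueError("data contain exact ones but inflation is fixed at zero")

    # -- inflation part ----------------------------------------------------

    def nu_mle(self) -> float:
        if self.nu_fixed_zero:
            return 0.0
        return self.n_ones / self.n

    def inflation_loglik(self, nu: float) -> float:
        if self.nu_fixed_zero:
            return 0.0
        n1, n0 = self.n_ones, self.n - self.n_ones
        ll = 0.0
        if n1:
            ll += n1 * np.log(nu)
        if n0:
            ll += n0 * np.log1p(-nu)
        return ll

    @property
    def n_inflation_params(self) -> int:
        return 0 if self.nu_fixed_zero else 1

    # -- beta part ---------------------------------------------------------

    def _inner_mode(self, offset: np.ndarray, phi: float, prec_u: float, prec_v: float):
        """Maximise the penalised beta loglik over the random-effect vector."""
        q = self.n_u + self.n_v
        b = self._b_warm.copy() if self._b_warm is not None and len(self._b_warm) == q \
            else np.zeros(q)

        def objective(bvec):
            eta = offset + bvec[self.u_idx] + bvec[self.n_u + self.v_idx]
            ll, s, wf, wo = _beta_parts(eta, self.ystar, self.log_y, self.log_1my, phi)
            pen = 0.5 * prec_u * np.sum(bvec[: self.n_u] ** 2) \
                + 0.5 * prec_v * np.sum(bvec[self.n_u:] ** 2)
            return ll.sum() - pen, s, wf, wo

        f, s, wf, wo = objective(b)
        converged = False
        for _ in range(60):
            g_u = np.bincount(self.u_idx, weights=s, minlength=self.n_u) - prec_u * b[: self.n_u]
            g_v = np.bincount(self.v_idx, weights=s, minlength=self.n_v) - prec_v * b[self.n_u:]
            gmax = max(np.abs(g_u).max(initial=0.0), np.abs(g_v).max(initial=0.0))
            if gmax < 1e-7 * max(1.0, abs(f)):
                converged = True
                break
            d_u = np.bincount(self.u_idx, weights=wf, minlength=self.n_u) + prec_u
            d_v = np.bincount(self.v_idx, weights=wf, minlength=self.n_v) + prec_v
            C = np.zeros((self.n_u, self.n_v))
            np.add.at(C, (self.u_idx, self.v_idx), wf)
            S = np.diag(d_v) - (C / d_u[:, None]).T @ C
            rhs_v = g_v - (C / d_u[:, None]).T @ g_u
            try:
                cf = cho_factor(S, lower=True)
                dv = cho_solve(cf, rhs_v)
            except np.linalg.LinAlgError:
                dv = np.linalg.solve(S + 1e-8 * np.eye(self.n_v), rhs_v)
            du = (g_u - C @ dv) / d_u
            step = np.concatenate([du, dv])
            t = 1.0
            for _ in range(30):
                f_new, s_new, wf_new, wo_new = objective(b + t * step)
                if f_new >= f - 1e-12:
                    break
                t *= 0.5
            b = b + t * step
            f, s, wf, wo = f_new, s_new, wf_new, wo_new
        self._b_warm = b.copy()
        return b, f, wf, wo

    def _logdet_H(self, w: np.ndarray, prec_u: float, prec_v: float) -> float:
        d_u = np.bincount(self.u_idx, weights=w, minlength=self.n_u) + prec_u
        d_v = np.bincount(self.v_idx, weights=w, minlength=self.n_v) + prec_v
        C = np.zeros((self.n_u, self.n_v))
        np.add.at(C, (self.u_idx, self.v_idx), w)
        S = np.diag(d_v) - (C / d_u[:, None]).T @ C
        cf = cho_factor(S, lower=True)
        return float(np.sum(np.log(d_u)) + 2.0 * np.sum(np.log(np.diag(cf[0]))))

    def beta_marginal_loglik(self, beta: np.ndarray, phi: float,
                             sigma_u: float, sigma_v: float) -> float:
        """Laplace-approximate marginal loglik of the beta component."""
        if self.Xs.shape[0] == 0:  # every response is an exact one
            return 0.0
        offset = self.Xs @ beta
        if not self.has_re or (sigma_u == 0 and sigma_v == 0):
            ll, *_ = _beta_parts(offset, self.ystar, self.log_y, self.log_1my, phi)
            return float(ll.sum())
        prec_u, prec_v = 1.0 / sigma_u**2, 1.0 / sigma_v**2
        b, f, wf, wo = self._inner_mode(offset, phi, prec_u, prec_v)
        q = self.n_u + self.n_v
        g = f - 0.5 * self.n_u * np.log(2 * np.pi * sigma_u**2) \
            - 0.5 * self.n_v * np.log(2 * np.pi * sigma_v**2)
        try:
            logdet = self._logdet_H(np.maximum(wo, 1e-10), prec_u, prec_v)
        except np.linalg.LinAlgError:
            logdet = self._logdet_H(wf, prec_u, prec_v)
        return float(g + 0.5 * q * np.log(2 * np.pi) - 0.5 * logdet)

    def loglik(self, beta: np.ndarray, phi: float, nu: float,
               sigma_u: float, sigma_v: float) -> float:
        """Total log-likelihood: inflation part plus marginal beta part."""
        ll_beta = self.beta_marginal_loglik(np.asarray(beta, dtype=float), phi,
                                            sigma_u, sigma_v)
        return float(self.inflation_loglik(nu) + ll_beta)

    # -- fitting -----------------------------------------------------------

    def _theta_loglik(self, theta: np.ndarray) -> float:
        beta = theta[: self.p]
        phi = np.exp(theta[self.p])
        if self.has_re:
            sigma_u = np.exp(theta[self.p + 1])
            sigma_v = np.exp(theta[self.p + 2])
        else:
            sigma_u = sigma_v = 0.0
        return self.beta_marginal_loglik(beta, phi, sigma_u, sigma_v)

    def _initial_theta(self) -> np.ndarray:
        ys = np.clip(self.y[~self.ones], 1e-4, 1 - 1e-4)
        z = logit(ys)
        beta0, *_ = np.linalg.lstsq(self.Xs, z, rcond=None)
        mu0 = expit(np.clip(self.Xs @ beta0, -16, 16))
        resid_var = max(np.var(ys - mu0), 1e-4)
        phi0 = np.clip(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0, 200.0)
        theta = np.concatenate([beta0, [np.log(phi0)]])
        if self.has_re:
            theta = np.concatenate([theta, [np.log(0.2), np.log(0.2)]])
        return theta

    def fit(self, init: np.ndarray | None = None, compute_se: bool = True,
            compute_r2: bool = True, gtol: float = 1e-6) -> OibeFit:
        if self.ones.all():
            raise ValueError("all responses are exactly 1; the beta component is empty")
        if self.n < 2:
            raise ValueError("need at least two observations to fit")
        theta0 = init if init is not None else self._initial_theta()
        bounds = [(None, None)] * self.p + [(np.log(1e-2), np.log(1e5))]
        if self.has_re:
            bounds += [(np.log(1e-4), np.log(10.0))] * 2

        def nll(theta):
            val = self._theta_loglik(theta)
            if not np.isfinite(val):
                return 1e12
            return -val

        # without random effects the objective is smooth and exact, so the
        # finite-difference step and gradient tolerance can be much tighter
        eps = 1e-5 if self.has_re else 1e-8
        res = optimize.minimize(
            nll, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "gtol": gtol if self.has_re else 1e-10, "eps": eps},
        )
        theta = res.x
        beta = theta[: self.p]
        phi = float(np.exp(theta[self.p]))
        sigma_u = float(np.exp(theta[self.p + 1])) if self.has_re else 0.0
        sigma_v = float(np.exp(theta[self.p + 2])) if self.has_re else 0.0
        nu = self.nu_mle()
        ll = self.inflation_loglik(nu) - res.fun
        n_params = len(theta) + self.n_inflation_params
        aic = -2.0 * ll + 2.0 * n_params

        se = {c: float("nan") for c in self.design.columns}
        ci = {c: (float("nan"), float("nan")) for c in self.design.columns}
        if compute_se:
            cov = self._theta_covariance(theta)
            if cov is not None:
                for k, c in enumerate(self.design.columns):
                    s = float(np.sqrt(max(cov[k, k], 0.0)))
                    se[c] = s
                    ci[c] = (float(beta[k] - 1.959964 * s), float(beta[k] + 1.959964 * s))

        blup_u, blup_v = {}, {}
        if self.has_re and self._b_warm is not None:
            b = self._b_warm
            blup_u = {str(l): float(x) for l, x in zip(self.u_levels, b[: self.n_u])}
            blup_v = {str(l): float(x) for l, x in zip(self.v_levels, b[self.n_u:])}

        fit = OibeFit(
            spec=self.spec,
            beta={c: float(v) for c, v in zip(self.design.columns, beta)},
            se=se,
            ci=ci,
            phi=phi,
            nu=float(nu),
            sigma_u=sigma_u,
            sigma_v=sigma_v,
            loglik=float(ll),
            aic=float(aic),
            n_obs=self.n,
            n_params=n_params,
            converged=bool(res.success),
            design=self.design,
            blup_u=blup_u,
            blup_v=blup_v,
        )
        if not res.success:
            logger.warning("OIBE fit did not converge: %s", res.message)
        if compute_r2 and self.spec.mean_terms:
            null_spec = replace(self.spec, mean_terms=())
            null_fit = OibeModel(self.data, null_spec).fit(
                compute_se=False, compute_r2=False
            )
            fit.r2_generalized = float(
                1.0 - np.exp(2.0 * (null_fit.loglik - fit.loglik) / self.n)
            )
        return fit

    def _theta_covariance(self, theta: np.ndarray) -> np.ndarray | None:
        """Inverse observed information of the outer parameters (numerical)."""
        k = len(theta)
        # step large enough that inner-solver noise (~1e-6 in the loglik)
        # does not swamp the quadratic signal
        h = 3e-3 * np.maximum(1.0, np.abs(theta))
        H = np.zeros((k, k))
        f0 = self._theta_loglik(theta)
        fp = np.zeros(k)
        fm = np.zeros(k)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            fp[i] = self._theta_loglik(theta + e)
            fm[i] = self._theta_loglik(theta - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for j in range(i + 1, k):
                e_i = np.zeros(k); e_i[i] = h[i]
                e_j = np.zeros(k); e_j[j] = h[j]
                fpp = self._theta_loglik(theta + e_i + e_j)
                fmm = self._theta_loglik(theta - e_i - e_j)
                H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                    2 * h[i] * h[j]
                )
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            logger.warning("observed information not invertible; SEs unavailable")
            return None


# ---------------------------------------------------------------------------
# public operations


def oibe_loglik(params: Mapping, data: pd.DataFrame, spec: OibeModelSpec) -> float:
    """Total log-likelihood at given parameters.

    ``params`` carries ``beta`` (vector aligned with the design columns,
    intercept first), ``phi``, ``nu``, ``sigma_u`` and ``sigma_v``.
    """
    model = OibeModel(data, spec)
    ll = model.loglik(
        np.asarray(params["beta"], dtype=float),
        float(params["phi"]),
        float(params.get("nu", 0.0)),
        float(params.get("sigma_u", 0.0)),
        float(params.get("sigma_v", 0.0)),
    )
    if not np.isfinite(ll):
        raise ValueError(f"non-finite log-likelihood at params {dict(params)!r}")
    return ll


def fit_oibe(
    data: pd.DataFrame,
    spec: OibeModelSpec,
    init: np.ndarray | None = None,
    compute_se: bool = True,
    compute_r2: bool = True,
) -> OibeFit:
    """Maximum-likelihood fit of the one-inflated beta mixed model."""
    return OibeModel(data, spec).fit(init=init, compute_se=compute_se, compute_r2=compute_r2)


def backward_aic_select(
    data: pd.DataFrame, full_spec: OibeModelSpec
) -> tuple[OibeFit, list[dict]]:
    """Backward elimination on the mean terms under the two-point AIC rule.

    At each stage the reduced model with the lowest AIC is adopted unless
    keeping the term improves AIC by at least 2 (the more complex model must
    earn its parameters); the trace records every comparison.
    """
    current_spec = full_spec
    current = fit_oibe(data, current_spec, compute_se=False, compute_r2=False)
    trace: list[dict] = []
    while current_spec.mean_terms:
        candidates = []
        for term in current_spec.mean_terms:
            reduced = current_spec.drop(term)
            fit_r = fit_oibe(data, reduced, compute_se=False, compute_r2=False)
            candidates.append((term, fit_r))
            trace.append(
                {
                    "kept_terms": current_spec.mean_terms,
                    "dropped": term,
                    "aic_with": current.aic,
                    "aic_without": fit_r.aic,
                    "delta_aic": fit_r.aic - current.aic,
                }
            )
        term, best = min(candidates, key=lambda c: c[1].aic)
        # keep the complex model only if it beats the reduction by >= 2
        if current.aic <= best.aic - 2.0:
            break
        current_spec = current_spec.drop(term)
        current = best
        trace.append({"action": "dropped", "term": term, "aic": best.aic})
    final = fit_oibe(data, current_spec)
    return final, trace


def compare_interaction(
    data: pd.DataFrame, base_spec: OibeModelSpec
) -> tuple[OibeModelSpec, float]:
    """Compare the base model against base + cover x species interaction.

    Returns the preferred spec and delta AIC (interaction minus base); the
    interaction is preferred only if it improves AIC by at least 2.
    """
    if "cover" not in base_spec.mean_terms or "species" not in base_spec.mean_terms:
        raise ValueError("base spec must contain cover and species")
    int_spec = replace(base_spec, mean_terms=base_spec.mean_terms + ("cover:species",))
    base_fit = fit_oibe(data, base_spec, compute_se=False, compute_r2=False)
    int_fit = fit_oibe(data, int_spec, compute_se=False, compute_r2=False)
    delta = int_fit.aic - base_fit.aic
    preferred = int_spec if int_fit.aic <= base_fit.aic - 2.0 else base_spec
    return preferred, float(delta)


def predict(
    fit: OibeFit,
    newdata: pd.DataFrame,
    include_inflation: bool = True,
    pair: tuple[str, str] | None = None,
) -> np.ndarray:
    """Predicted Preference Coefficient for new covariate rows.

    Population-level by default (random effects at zero); ``pair=(f1, f2)``
    conditions on one named fish pair's estimated intercepts.  With
    ``include_inflation`` the expected response nu + (1 - nu) * mu is
    returned, otherwise the beta-component mean mu.
    """
    X = fit.design.build(newdata)
    eta = X @ fit.beta_vector
    if pair is not None:
        eta = eta + fit.blup_u.get(pair[0], 0.0) + fit.blup_v.get(pair[1], 0.0)
    mu = expit(eta)
    if include_inflation:
        return fit.nu + (1.0 - fit.nu) * mu
    return mu


def jackknife_predictions(
    data: pd.DataFrame,
    spec: OibeModelSpec,
    cover_grid: np.ndarray | None = None,
    frac: float = 0.8,
    reps: int = 100,
    seed: int | np.random.Generator | None = None,
    grid_size: int = 25,
    wide_quantiles: bool = False,
    include_inflation: bool = True,
) -> dict[str, dict]:
    """Subsample-jackknife prediction bands per species over observed cover.

    Each replicate refits on a random 80% subset and predicts on a grid
    limited to each species' observed cover range; the band at each grid
    point is the 5th and 95th ordered replicate values (literally the 5th
    and 95th of 100, i.e. a ~90% band; ``wide_quantiles=True`` uses the
    2.5th/97.5th instead).  Failed replicate fits are skipped and logged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species = sorted(pd.unique(data["fish_species"]))
    full = fit_oibe(data, spec, compute_se=False, compute_r2=False)
    grids: dict[str, np.ndarray] = {}
    for sp in species:
        cov = data.loc[data["fish_species"] == sp, "hard_coral_cover"]
        grids[sp] = (
            cover_grid
            if cover_grid is not None
            else np.linspace(cov.min(), cov.max(), grid_size)
        )
    preds: dict[str, list[np.ndarray]] = {sp: [] for sp in species}
    m = int(np.floor(frac * len(data)))
    n_ok = 0
    for _ in range(reps):
        idx = rng.choice(len(data), size=m, replace=False)
        sub = data.iloc[idx]
        try:
            f = fit_oibe(sub, spec, compute_se=False, compute_r2=False)
        except Exception as exc:  # rank-deficient subsample etc.
            logger.warning("jackknife replicate skipped: %s", exc)
            continue
        n_ok += 1
        for sp in species:
            nd = _prediction_frame(data, sp, grids[sp])
            preds[sp].append(predict(f, nd, include_inflation=include_inflation))
    if n_ok < 0.8 * reps:
        logger.warning("only %d of %d jackknife replicates succeeded", n_ok, reps)
    lo_q, hi_q = (0.025, 0.975) if wide_quantiles else (0.05, 0.95)
    k_lo = max(0, int(np.ceil(lo_q * n_ok)) - 1)
    k_hi = max(0, int(np.ceil(hi_q * n_ok)) - 1)
    out = {}
    for sp in species:
        stack = np.sort(np.stack(preds[sp]), axis=0)
        nd = _prediction_frame(data, sp, grids[sp])
        out[sp] = {
            "cover": grids[sp],
            "fit": predict(full, nd, include_inflation=include_inflation),
            "lo": stack[k_lo],
            "hi": stack[k_hi],
            "n_replicates": n_ok,
        }
    return out


def oibe_density(y, mu: float, phi: float, nu: float = 0.0) -> np.ndarray:
    """One-inflated beta density: continuous part on (0,1), mass nu at y=1.

    Shares the likelihood's beta-density code path, so numerical
    integration of this function validates the model's normalisation.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    out = np.zeros_like(y)
    at_one = y == 1.0
    interior = (y > 0) & (y < 1)
    if interior.any():
        yi = y[interior]
        eta = np.full(yi.shape, logit(mu))
        ll, *_ = _beta_parts(eta, logit(yi), np.log(yi), np.log1p(-yi), phi)
        out[interior] = (1.0 - nu) * np.exp(ll)
    out[at_one] = nu
    return out


def _prediction_frame(data: pd.DataFrame, species: str, grid: np.ndarray) -> pd.DataFrame:
    """Covariate frame for prediction: reference site/year, given species."""
    ref = {}
    for var in ("site", "year"):
        if var in data.columns:
            ref[var] = sorted(pd.unique(data[var]))[0]
    return pd.DataFrame(
        {
            "hard_coral_cover": grid,
            "fish_species": species,
            **{k: [v] * len(grid) for k, v in ref.items()},
        }
    )
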