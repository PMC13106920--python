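"""Random-intercept GLMMs for peak significance and rhythmic regularity.

Two model families back the analysis:

* **Poisson, log link** — the peak-significance count model.  Response:
  number of ratios falling in each on/off bin per contribution; fixed
  factors bin, sex and their interaction; ``offset = log(bin width)``
  so the model estimates counts per unit ratio width; random intercept
  per individual.
* **Beta, logit link** — the regularity model.  Response: the
  width-weighted on/(on+off) proportion per contribution and category;
  fixed factors sex, age class and their interaction; precision
  parameter phi; random intercept per grouping unit.

Both are fitted by maximising the Laplace-approximated marginal
likelihood (adaptive Gauss-Hermite quadrature available via
``n_agq``): the scalar random intercept of each group is profiled out
with an inner Newton step, and the outer optimisation runs over the
fixed effects, log random-effect SD and (beta family) log precision.
With the random-effect SD pinned at zero the objective reduces exactly
to the ordinary GLM likelihood, which anchors the implementation
against standard Poisson regression.

Model comparison follows the usual chain: likelihood-ratio test of the
full model against the null (random intercept and offset only), then
estimated-marginal-mean pairwise contrasts with Tukey (studentized
range) adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "GlmmFit",
    "LRTResult",
    "fit_poisson_glmm",
    "fit_beta_glmm",
    "fit_glmm",
    "null_spec",
    "likelihood_ratio_test",
    "pairwise_contrasts",
    "check_zero_inflation",
    "detect_significant_categories",
]

POISSON_LOG = "POISSON_LOG"
BETA_LOGIT = "BETA_LOGIT"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description mapped onto a data frame's columns."""

    response: str
    factors: tuple[str, ...] = ()
    interaction: bool = True
    offset: str | None = None  # column holding log-scale offset values
    group: str = "individual_id"
    family: str = POISSON_LOG

    def formula(self) -> str:
        if not self.factors:
            rhs = "1"
        else:
            sep = " * " if self.interaction and len(self.factors) > 1 else " + "
            rhs = sep.join(f"C({f})" for f in self.factors)
        return f"{self.response} ~ {rhs}"


def null_spec(spec: ModelSpec) -> ModelSpec:
    """The nested null: same offset and grouping, no fixed factors."""
    return replace(spec, factors=(), interaction=False)


@dataclass
class GlmmFit:
    """A fitted random-intercept GLMM."""

    spec: ModelSpec
    beta: np.ndarray
    beta_names: list[str]
    cov_beta: np.ndarray
    sigma2_u: float
    phi: float | None
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    factor_levels: dict[str, list[str]]
    u_hat: np.ndarray
    message: str = ""
    degenerate_all_zero: bool = False
    # training arrays retained for diagnostics (zero-inflation check)
    _design_info: object = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _offset: np.ndarray = field(default=None, repr=False)
    _group_idx: np.ndarray = field(default=None, repr=False)

    @property
    def n_fixed(self) -> int:
        return len(self.beta)

    def se_beta(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_beta))

    def summary_frame(self) -> pd.DataFrame:
        se = self.se_beta()
        z = self.beta / se
        return pd.DataFrame(
            {
                "term": self.beta_names,
                "estimate": self.beta,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


# ---------------------------------------------------------------------------
# likelihood internals


def _poisson_ll_terms(y, eta):
    mu = np.exp(eta)
    return y * eta - mu - special.gammaln(y + 1), mu


def _beta_ll_terms(y, eta, phi):
    mu = special.expit(eta)
    ll = (
        special.gammaln(phi)
        - special.gammaln(mu * phi)
        - special.gammaln((1 - mu) * phi)
        + (mu * phi - 1) * np.log(y)
        + ((1 - mu) * phi - 1) * np.log1p(-y)
    )
    return ll, mu


def _inner_newton(beta, sigma2, phi, X, y, offset, gidx, n_groups, family, u0):
    """Maximise the penalised log-likelihood over the group intercepts.

    Vectorised scalar Newton across groups; returns (u_hat, ll_pen,
    neg_curvature) where neg_curvature = -d2/du2 of the penalised
    objective at u_hat (per group).
    """
    u = u0.copy()
    xb = X @ beta + offset
    ystar = None
    if family == BETA_LOGIT:
        ystar = np.log(y) - np.log1p(-y)
    for _ in range(100):
        eta = xb + u[gidx]
        if family == POISSON_LOG:
            mu = np.exp(np.clip(eta, -700, 30))
            score = np.bincount(gidx, y - mu, minlength=n_groups) - u / sigma2
            curv = np.bincount(gidx, mu, minlength=n_groups) + 1.0 / sigma2
        else:
            mu = special.expit(eta)
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            w = mu * (1 - mu)
            mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
            dldeta = phi * (ystar - mustar) * w
            score = np.bincount(gidx, dldeta, minlength=n_groups) - u / sigma2
            fisher = (phi**2) * (
                special.polygamma(1, mu * phi) + special.polygamma(1, (1 - mu) * phi)
            ) * w**2
            curv = np.bincount(gidx, fisher, minlength=n_groups) + 1.0 / sigma2
        step = score / curv
        np.clip(step, -4.0, 4.0, out=step)
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = xb + u[gidx]
    if family == POISSON_LOG:
        ll_terms, mu = _poisson_ll_terms(y, np.clip(eta, -700, 30))
        curv_data = np.bincount(gidx, mu, minlength=n_groups)
    else:
        mu = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
        ll_terms, _ = _beta_ll_terms(y, eta, phi)
        w = mu * (1 - mu)
        fisher = (phi**2) * (
            special.polygamma(1, mu * phi) + special.polygamma(1, (1 - mu) * phi)
        ) * w**2
        curv_data = np.bincount(gidx, fisher, minlength=n_groups)
    ll_group = np.bincount(gidx, ll_terms, minlength=n_groups)
    ll_pen = ll_group - u**2 / (2 * sigma2)
    return u, ll_pen, curv_data


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _marginal_loglik(
    beta, sigma, phi, X, y, offset, gidx, n_groups, family, u_state, n_agq=1
):
    """Laplace (or adaptive Gauss-Hermite) marginal log-likelihood."""
    if sigma <= 0:
        eta = X @ beta + offset
        if family == POISSON_LOG:
            ll, _ = _poisson_ll_terms(y, np.clip(eta, -700, 30))
        else:
            ll, _ = _beta_ll_terms(y, np.clip(eta, -40, 40), phi)
        return float(ll.sum()), np.zeros(n_groups)
    sigma2 = sigma * sigma
    u, ll_pen, curv_data = _inner_newton(
        beta, sigma2, phi, X, y, offset, gidx, n_groups, family, u_state
    )
    neg_curv = curv_data + 1.0 / sigma2
    if n_agq <= 1:
        ll = ll_pen - 0.5 * np.log1p(sigma2 * curv_data)
        return float(ll.sum()), u
    # adaptive GH centred at u_hat with scale 1/sqrt(neg_curv)
    if n_agq not in _GH_CACHE:
        _GH_CACHE[n_agq] = np.polynomial.hermite_e.hermegauss(n_agq)
    nodes, weights = _GH_CACHE[n_agq]
    scale = 1.0 / np.sqrt(neg_curv)
    xb = X @ beta + offset
    log_terms = np.empty((n_agq, n_groups))
    for j, (z, w) in enumerate(zip(nodes, weights)):
        uj = u + scale * z
        eta = xb + uj[gidx]
        if family == POISSON_LOG:
            terms, _ = _poisson_ll_terms(y, np.clip(eta, -700, 30))
        else:
            terms, _ = _beta_ll_terms(y, np.clip(eta, -40, 40), phi)
        gll = np.bincount(gidx, terms, minlength=n_groups)
        log_terms[j] = np.log(w) + gll - uj**2 / (2 * sigma2) + 0.5 * z * z
    ll = (
        special.logsumexp(log_terms, axis=0)
        + np.log(scale)
        - 0.5 * np.log(2 * np.pi * sigma2)
    )
    return float(ll.sum()), u


def _pack_bounds(p, family, fix_sigma):
    bounds = [(None, None)] * p
    if fix_sigma is None:
        bounds.append((np.log(1e-5), np.log(50.0)))  # log sigma
    if family == BETA_LOGIT:
        bounds.append((np.log(1e-3), np.log(1e5)))  # log phi
    return bounds


def fit_glmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    n_agq: int = 1,
    fix_sigma: float | None = None,
    maxiter: int = 500,
    tol: float = 1e-10,
) -> GlmmFit:
    """Fit a random-intercept GLMM by Laplace-approximated ML.

    ``n_agq > 1`` switches to adaptive Gauss-Hermite quadrature with
    that many nodes.  ``fix_sigma`` pins the random-effect SD (0 gives
    the ordinary GLM).  Non-convergence is reported in the fit's
    ``converged`` flag and ``message``, never silently.

    Fixed factors with a single observed level are dropped from the
    design (they are not estimable) and noted in ``message``.
    """
    data = data.reset_index(drop=True)
    y = np.asarray(data[spec.response], dtype=float)
    if spec.family == POISSON_LOG:
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("Poisson response must be nonnegative integers")
    elif spec.family == BETA_LOGIT:
        if np.any(y <= 0) or np.any(y >= 1):
            raise ValueError(
                "beta response must lie strictly in (0, 1); apply the "
                "boundary compression transform y' = (y(n-1)+0.5)/n first"
            )
    else:
        raise ValueError(f"unknown family {spec.family!r}")

    msg_parts = []
    factors = []
    factor_levels: dict[str, list[str]] = {}
    for f in spec.factors:
        levels = sorted(map(str, pd.unique(data[f].astype(str))))
        if len(levels) < 2:
            msg_parts.append(f"factor {f!r} has a single level and was dropped")
        else:
            factors.append(f)
            factor_levels[f] = levels
    eff_spec = replace(spec, factors=tuple(factors))

    ymat, X = patsy.dmatrices(eff_spec.formula(), data, return_type="dataframe")
    design_info = X.design_info
    beta_names = list(X.columns)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]

    offset = (
        np.asarray(data[spec.offset], dtype=float)
        if spec.offset is not None
        else np.zeros(len(y))
    )
    groups = data[spec.group].astype(str)
    group_labels, gidx = np.unique(groups, return_inverse=True)
    n_groups = len(group_labels)
    if n_groups == len(y) and fix_sigma is None:
        warnings.warn(
            f"grouping factor {spec.group!r} has one observation per level; "
            "the random-intercept variance is weakly identified (consider "
            "grouping at a higher level, e.g. the individual)",
            UserWarning,
            stacklevel=2,
        )

    if spec.family == POISSON_LOG and y.sum() == 0:
        # All-zero counts: the Poisson likelihood supremum (0) is on the
        # boundary lambda -> 0; report a flagged degenerate fit.
        return GlmmFit(
            spec=eff_spec,
            beta=np.zeros(p),
            beta_names=beta_names,
            cov_beta=np.full((p, p), np.inf),
            sigma2_u=0.0,
            phi=None,
            loglik=0.0,
            converged=True,
            n_obs=len(y),
            n_groups=n_groups,
            factor_levels=factor_levels,
            u_hat=np.zeros(n_groups),
            message="all counts are zero; degenerate fit",
            degenerate_all_zero=True,
            _design_info=design_info,
            _X=X,
            _y=y,
            _offset=offset,
            _group_idx=gidx,
        )

    # --- starting values ---------------------------------------------------
    if spec.family == POISSON_LOG:
        import statsmodels.api as sm

        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        beta0 = np.asarray(glm.params, dtype=float)
        extra0 = []
    else:
        ystar = np.log(y) - np.log1p(-y)
        beta0, *_ = np.linalg.lstsq(X, ystar - offset, rcond=None)
        mu0 = special.expit(X @ beta0 + offset)
        resid_var = float(np.var(y - mu0)) or 1e-3
        phi0 = max(float(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0), 2.0)
        extra0 = [np.log(phi0)]

    u_state = {"u": np.zeros(n_groups)}

    def unpack(theta):
        beta = theta[:p]
        i = p
        if fix_sigma is not None:
            sigma = float(fix_sigma)
        else:
            sigma = float(np.exp(theta[i]))
            i += 1
        phi = float(np.exp(theta[i])) if spec.family == BETA_LOGIT else None
        return beta, sigma, phi

    def negloglik(theta):
        beta, sigma, phi = unpack(theta)
        ll, u = _marginal_loglik(
            beta, sigma, phi, X, y, offset, gidx, n_groups, spec.family,
            u_state["u"], n_agq,
        )
        u_state["u"] = u
        if not np.isfinite(ll):
            return 1e12
        return -ll

    theta0 = np.concatenate(
        [beta0, [] if fix_sigma is not None else [np.log(0.3)], extra0]
    )
    bounds = _pack_bounds(p, spec.family, fix_sigma)
    res = optimize.minimize(
        negloglik,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": tol, "maxfun": 100000},
    )
    theta_hat = res.x
    beta_hat, sigma_hat, phi_hat = unpack(theta_hat)
    loglik = -negloglik(theta_hat)

    # --- covariance: central-difference Hessian of the neg log-likelihood --
    cov_beta = _beta_covariance(negloglik, theta_hat, p)

    converged = bool(res.success)
    if not converged:
        msg_parts.append(f"optimizer: {res.message}")
    message = "; ".join(msg_parts)

    return GlmmFit(
        spec=eff_spec,
        beta=beta_hat,
        beta_names=beta_names,
        cov_beta=cov_beta,
        sigma2_u=sigma_hat**2 if fix_sigma is None else float(fix_sigma) ** 2,
        phi=phi_hat,
        loglik=loglik,
        converged=converged,
        n_obs=len(y),
        n_groups=n_groups,
        factor_levels=factor_levels,
        u_hat=u_state["u"],
        message=message,
        _design_info=design_info,
        _X=X,
        _y=y,
        _offset=offset,
        _group_idx=gidx,
    )


def _beta_covariance(negloglik, theta, p, h=1e-4):
    """Fixed-effect covariance from a central-difference Hessian."""
    n = len(theta)
    H = np.zeros((n, n))
    f0 = negloglik(theta)
    steps = h * np.maximum(1.0, np.abs(theta))
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = steps[i]
        fpp = negloglik(theta + ei)
        fmm = negloglik(theta - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = steps[j]
            fpj = negloglik(theta + ei + ej)
            fmj = negloglik(theta - ei - ej)
            H[i, j] = H[j, i] = (
                fpj - negloglik(theta + ei - ej) - negloglik(theta - ei + ej) + fmj
            ) / (4 * steps[i] * steps[j])
    def _inv(mat):
        try:
            return np.linalg.inv(mat)
        except np.linalg.LinAlgError:
            return np.linalg.pinv(mat)

    cov_beta = _inv(H)[:p, :p]
    d = np.diag(cov_beta)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        cov_beta = _inv(H[:p, :p])
        d = np.diag(cov_beta).copy()
        # quasi-separated cells (counts ~ 0) leave the Hessian singular in
        # that direction; an infinite SE (p -> 1) is the honest report
        bad = ~np.isfinite(d) | (d <= 0)
        if np.any(bad):
            cov_beta = cov_beta.copy()
            for i in np.where(bad)[0]:
                cov_beta[i, :] = 0.0
                cov_beta[:, i] = 0.0
                cov_beta[i, i] = np.inf
    return cov_beta


def fit_poisson_glmm(
    data: pd.DataFrame, spec: ModelSpec | None = None, **kwargs
) -> GlmmFit:
    """Poisson count GLMM (log link) with offset and random intercept.

    Default spec: ``count ~ bin * sex + offset(log_width)`` with a
    random intercept per ``individual_id`` — the peak-significance
    model applied to the long bin-count table.
    """
    if spec is None:
        spec = ModelSpec(
            response="count",
            factors=("bin", "sex"),
            interaction=True,
            offset="log_width",
            group="individual_id",
            family=POISSON_LOG,
        )
    if spec.family != POISSON_LOG:
        raise ValueError("fit_poisson_glmm requires the Poisson family")
    return fit_glmm(data, spec, **kwargs)


def fit_beta_glmm(
    data: pd.DataFrame, spec: ModelSpec | None = None, **kwargs
) -> GlmmFit:
    """Beta GLMM (logit link, precision phi) with random intercept.

    Default spec: ``regularity ~ sex * age_class`` with a random
    intercept per ``contribution_id`` — the regularity model.
    """
    if spec is None:
        spec = ModelSpec(
            response="regularity",
            factors=("sex", "age_class"),
            interaction=True,
            offset=None,
            group="contribution_id",
            family=BETA_LOGIT,
        )
    if spec.family != BETA_LOGIT:
        raise ValueError("fit_beta_glmm requires the beta family")
    return fit_glmm(data, spec, **kwargs)


# ---------------------------------------------------------------------------
# model comparison and contrasts


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float


def likelihood_ratio_test(full: GlmmFit, null: GlmmFit) -> LRTResult:
    """2(l_full - l_null) against chi-square with df = extra fixed params."""
    if full.n_obs != null.n_obs:
        raise ValueError("full and null models were fitted to different row counts")
    if not set(null.beta_names) <= set(full.beta_names):
        raise ValueError("null model terms are not nested in the full model")
    df = full.n_fixed - null.n_fixed
    if df < 0:
        raise ValueError("null model has more fixed parameters than the full model")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(statistic=stat, df=df, p=p)


def _tukey_p(z: np.ndarray, k: int) -> np.ndarray:
    """Studentized-range adjustment for a family of k(k-1)/2 comparisons.

    Asymptotic (infinite-df) version, matching the normal-based Wald
    contrasts; with k = 2 it reduces to the two-sided normal p-value.
    """
    q = np.abs(z) * np.sqrt(2.0)
    with np.errstate(all="ignore"):
        p = stats.studentized_range.sf(q, k, np.inf)
    return np.clip(p, 0.0, 1.0)


def _wald_se(L: np.ndarray, cov: np.ndarray) -> float:
    """sqrt(L' cov L); infinite when the direction is not identified."""
    if np.any(np.isinf(np.diag(cov)[L != 0])):
        return np.inf
    v = float(L @ cov @ L)
    if not np.isfinite(v) or v < 0:
        return np.inf
    return float(np.sqrt(v))


def estimated_marginal_means(
    fit: GlmmFit, factors: Sequence[str]
) -> pd.DataFrame:
    """Link-scale EMMs for combinations of ``factors``.

    Predictions on the reference grid (the product of all fixed-factor
    levels, offset excluded, random effect at zero) are averaged with
    equal weights over the factors not listed.
    """
    all_factors = list(fit.spec.factors)
    for f in factors:
        if f not in all_factors:
            raise ValueError(f"factor {f!r} is not in the model ({all_factors})")
    levels = [fit.factor_levels[f] for f in all_factors]
    grid = pd.DataFrame(
        list(itertools.product(*levels)), columns=all_factors, dtype=str
    )
    (Xg,) = patsy.build_design_matrices(
        [fit._design_info], grid, return_type="dataframe"
    )
    Xg = np.asarray(Xg, dtype=float)
    keys = grid[list(factors)].apply(tuple, axis=1)
    rows = []
    for key in sorted(keys.unique()):
        mask = (keys == key).to_numpy()
        L = Xg[mask].mean(axis=0)
        est = float(L @ fit.beta)
        se = _wald_se(L, fit.cov_beta)
        rows.append({**dict(zip(factors, key)), "emm": est, "se": se, "_L": L})
    return pd.DataFrame(rows)


def pairwise_contrasts(
    fit: GlmmFit,
    factor: str,
    adjust: str = "tukey",
    by: str | None = None,
) -> pd.DataFrame:
    """All pairwise contrasts of ``factor``'s marginal means.

    With ``by`` set, contrasts are computed within each level of the
    companion factor and each within-``by`` family is adjusted
    separately (the per-sex comparisons of the peak model).  Estimates
    are on the link scale; p-values use the studentized-range (Tukey)
    method, or no adjustment with ``adjust="none"``.
    """
    if not fit.converged:
        raise ValueError("cannot compute contrasts from an unconverged fit")
    if adjust not in {"tukey", "none"}:
        raise ValueError(f"unknown adjustment {adjust!r}")
    emm_factors = [factor] if by is None else [by, factor]
    emms = estimated_marginal_means(fit, emm_factors)
    out = []
    groups = [(None, emms)] if by is None else list(emms.groupby(by, sort=True))
    for by_level, sub in groups:
        sub = sub.sort_values(factor).reset_index(drop=True)
        k = len(sub)
        for i, j in itertools.combinations(range(k), 2):
            L = sub["_L"][i] - sub["_L"][j]
            est = float(L @ fit.beta)
            se = _wald_se(L, fit.cov_beta)
            z = 0.0 if np.isinf(se) else (est / se if se > 0 else np.nan)
            row = {
                "contrast": f"{sub[factor][i]} - {sub[factor][j]}",
                "estimate": est,
                "se": se,
                "z": z,
            }
            if by is not None:
                row[by] = by_level
            row["_k"] = k
            out.append(row)
    table = pd.DataFrame(out)
    if adjust == "tukey":
        table["p_adj"] = [
            float(_tukey_p(np.array([z]), int(k))[0])
            for z, k in zip(table["z"], table["_k"])
        ]
    else:
        table["p_adj"] = 2 * stats.norm.sf(np.abs(table["z"]))
    return table.drop(columns=["_k"])


@dataclass(frozen=True)
class ZeroInflationResult:
    observed_zeros: int
    expected_zeros: float
    ratio: float
    inflated: bool


def check_zero_inflation(fit: GlmmFit, tol: float = 0.05) -> ZeroInflationResult:
    """Observed vs model-expected zero counts for a Poisson fit.

    Expected zeros are ``sum_i exp(-mu_i)`` with the conditional fitted
    means (random intercepts at their modes); the flag is raised when
    observed/expected exceeds ``1 + tol``.
    """
    if fit.spec.family != POISSON_LOG:
        raise ValueError("zero-inflation check applies to Poisson fits only")
    eta = fit._X @ fit.beta + fit._offset + fit.u_hat[fit._group_idx]
    mu = np.exp(eta)
    observed = int(np.sum(fit._y == 0))
    expected = float(np.sum(np.exp(-mu)))
    ratio = observed / expected if expected > 0 else (0.0 if observed == 0 else np.inf)
    if observed == 0:
        ratio = 0.0
    return ZeroInflationResult(
        observed_zeros=observed,
        expected_zeros=expected,
        ratio=ratio,
        inflated=ratio > 1 + tol,
    )


def detect_significant_categories(
    fits: Mapping[str, tuple[GlmmFit, GlmmFit]],
    alpha: float = 0.05,
    categories: Sequence[str] = ("R12", "R11", "R21"),
) -> pd.DataFrame:
    """Which rhythmic categories are significantly on-integer, per age class.

    ``fits`` maps age-class name to ``(full, null)`` Poisson fits of the
    bin-count model.  A category is significant for a sex when (a) the
    full model beats the null by LRT at ``alpha`` and (b) the within-sex
    Tukey-adjusted on-minus-off contrast for that category is positive
    with adjusted p < ``alpha``.
    """
    rows = []
    for age_class, (full, null) in fits.items():
        if full.degenerate_all_zero or null.degenerate_all_zero:
            lrt = LRTResult(0.0, max(full.n_fixed - null.n_fixed, 0), 1.0)
        else:
            lrt = likelihood_ratio_test(full, null)
        sexes = full.factor_levels.get("sex")
        by = "sex" if sexes else None
        if full.degenerate_all_zero:
            contrasts = None
        else:
            contrasts = pairwise_contrasts(full, "bin", adjust="tukey", by=by)
        sex_levels = sexes if sexes else [None]
        for sex in sex_levels:
            for cat in categories:
                significant = False
                est = p_adj = np.nan
                if contrasts is not None and lrt.p < alpha:
                    sub = contrasts
                    if by is not None:
                        sub = sub[sub["sex"] == sex]
                    name = f"off_{cat} - on_{cat}"
                    alt = f"on_{cat} - off_{cat}"
                    hit = sub[sub["contrast"].isin([name, alt])]
                    if len(hit) == 1:
                        r = hit.iloc[0]
                        est = r["estimate"] if r["contrast"] == alt else -r["estimate"]
                        p_adj = r["p_adj"]
                        significant = bool(est > 0 and p_adj < alpha)
                rows.append(
                    {
                        "age_class": age_class,
                        "sex": sex if sex is not None else "ALL",
                        "category": cat,
                        "on_minus_off": est,
                        "p_adj": p_adj,
                        "lrt_p": lrt.p,
                        "significant": significant,
                    }
                )
    return pd.DataFrame(rows)
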