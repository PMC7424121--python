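"""Mixed-model inference for 2AFC choices and reaction times, from scratch.

Two models, matching the standard analysis of morph-continuum experiments:

* a binomial GLMM with logit link for the choice data, with fixed effects
  for scaled morph percentage, familiarity condition (zero-sum contrasts)
  and their interaction, and crossed random intercepts for participant and
  continuum.  The marginal likelihood is approximated by the Laplace method:
  the inner step is penalized iteratively reweighted least squares (PIRLS)
  for the joint mode of fixed and random coefficients, the outer step is
  derivative-free optimization over the log standard deviations of the
  random intercepts.

* a Gaussian linear mixed model for log reaction times with the same fixed
  and random structure.  Here the marginal likelihood is exact and is
  evaluated from precomputed cross-products, so each outer evaluation costs
  O(q^3) in the number of random coefficients.

Term-wise Type-3 Wald chi-square tests and point-of-subjective-equality
(PSE) estimates with delta-method standard errors are derived from the
fitted coefficients and their asymptotic covariance.

Choices are aggregated to binomial counts per (participant, continuum,
condition, morph level) cell before fitting; this leaves the likelihood
unchanged and makes the PIRLS step operate on a few hundred rows instead of
thousands of Bernoulli trials.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .data_model import validate_trials

_LOG_SIGMA_BOUNDS = (-6.0, 2.5)
_PIRLS_TOL = 1e-10
_PIRLS_MAX_ITER = 200
_SEPARATION_BOUND = 25.0  # |beta| beyond this on scaled predictors flags separation


class SingularTermError(np.linalg.LinAlgError):
    """The covariance block of a model term is singular."""


@dataclasses.dataclass
class ModelSpec:
    """Fixed/random structure shared by the choice and RT models.

    Fixed effects: intercept, scaled morph percentage (continuous), condition
    (zero-sum contrasts) and the morph x condition interaction.  Random:
    crossed intercepts for the factors in ``random``.

    ``scaling="zscore_over_trials"`` centers and scales the morph percentage
    by its mean and standard deviation over trials; ``"center50_div40"`` uses
    (m - 50)/40.  Both are recorded on the fit so PSEs can be mapped back to
    morph-percent units.
    """

    response: str = "choice"  # "choice" | "log_rt"
    scaling: str = "zscore_over_trials"
    random: tuple[str, ...] = ("participant_id", "continuum_id")
    condition_levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.response not in ("choice", "log_rt"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.scaling not in ("zscore_over_trials", "center50_div40"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclasses.dataclass
class WaldTable:
    """Type-3 Wald chi-square tests, one row per model term."""

    terms: list[str]
    chi_square: dict[str, float]
    df: dict[str, int]
    p_value: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                term=self.terms,
                chi_square=[self.chi_square[t] for t in self.terms],
                df=[self.df[t] for t in self.terms],
                p_value=[self.p_value[t] for t in self.terms],
            )
        )


@dataclasses.dataclass
class PseEstimate:
    """Categorical boundary for one condition, in morph-percent units."""

    condition: str
    pse: float
    se: float
    reference: str | None = None
    shift: float | None = None
    shift_se: float | None = None


@dataclasses.dataclass
class MixedModelFit:
    beta: np.ndarray
    beta_names: list[str]
    vcov_beta: np.ndarray
    sigma: dict[str, float]  # random-intercept std devs by factor
    sigma_resid: float | None  # residual std dev (linear model only)
    loglik: float
    converged: bool
    n_obs: int
    n_groups: dict[str, int]
    term_slices: dict[str, slice]
    condition_levels: tuple[str, ...]
    scaling_center: float
    scaling_scale: float
    spec: ModelSpec
    diagnostics: dict = dataclasses.field(default_factory=dict)

    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "beta": dict(zip(self.beta_names, map(float, self.beta))),
            "se": dict(zip(self.beta_names, map(float, self.se_beta()))),
            "sigma": {k: float(v) for k, v in self.sigma.items()},
            "sigma_resid": None if self.sigma_resid is None else float(self.sigma_resid),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_groups": {k: int(v) for k, v in self.n_groups.items()},
            "condition_levels": list(self.condition_levels),
            "scaling": {"center": self.scaling_center, "scale": self.scaling_scale},
            "diagnostics": {
                k: v for k, v in self.diagnostics.items() if np.isscalar(v) or isinstance(v, (list, str, bool))
            },
        }


# ---------------------------------------------------------------------------
# design construction


def zero_sum_contrasts(n_levels: int) -> np.ndarray:
    """Effect coding: level j < K-1 gets indicator column j; the last level
    gets -1 in every column, so each contrast column sums to zero."""
    C = np.vstack([np.eye(n_levels - 1), -np.ones((1, n_levels - 1))])
    return C


@dataclasses.dataclass
class _Design:
    X: np.ndarray
    Z: np.ndarray
    u_slices: dict[str, slice]  # random factor -> columns of Z
    factor_levels: dict[str, list[str]]
    beta_names: list[str]
    term_slices: dict[str, slice]
    condition_levels: tuple[str, ...]
    center: float
    scale: float


def _build_design(
    df: pd.DataFrame, spec: ModelSpec, weights: np.ndarray | None = None
) -> _Design:
    morph = df["morph_pct"].to_numpy(float)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, float)
    if spec.scaling == "center50_div40":
        center, scale = 50.0, 40.0
    else:
        center = float(np.average(morph, weights=w))
        # ddof-1 sample sd over trials, as a plain scale() of the column
        n_tr = w.sum()
        var = float(np.average((morph - center) ** 2, weights=w)) * n_tr / (n_tr - 1.0)
        scale = float(np.sqrt(var))
    x = (morph - center) / scale

    levels = spec.condition_levels or tuple(sorted(df["condition"].unique()))
    missing = set(df["condition"].unique()) - set(levels)
    if missing:
        raise ValueError(f"conditions in data but not in spec: {sorted(missing)}")
    K = len(levels)
    cols = [np.ones(len(df)), x]
    names = ["intercept", "morph"]
    term_slices = {"intercept": slice(0, 1), "morph": slice(1, 2)}
    if K > 1:
        C = zero_sum_contrasts(K)
        idx = pd.Categorical(df["condition"], categories=list(levels)).codes
        cond_cols = C[idx]  # (n, K-1)
        cols.extend(cond_cols.T)
        names.extend(f"cond[{levels[j]}]" for j in range(K - 1))
        term_slices["condition"] = slice(2, 2 + K - 1)
        cols.extend((cond_cols * x[:, None]).T)
        names.extend(f"morph:cond[{levels[j]}]" for j in range(K - 1))
        term_slices["interaction"] = slice(2 + K - 1, 2 + 2 * (K - 1))
    X = np.column_stack(cols)

    z_blocks, u_slices, factor_levels = [], {}, {}
    start = 0
    for factor in spec.random:
        fl = sorted(df[factor].unique())
        codes = pd.Categorical(df[factor], categories=fl).codes
        Zf = np.zeros((len(df), len(fl)))
        Zf[np.arange(len(df)), codes] = 1.0
        z_blocks.append(Zf)
        u_slices[factor] = slice(start, start + len(fl))
        factor_levels[factor] = fl
        start += len(fl)
    Z = np.hstack(z_blocks) if z_blocks else np.zeros((len(df), 0))
    return _Design(
        X=X,
        Z=Z,
        u_slices=u_slices,
        factor_levels=factor_levels,
        beta_names=names,
        term_slices=term_slices,
        condition_levels=tuple(levels),
        center=center,
        scale=scale,
    )


def _aggregate_choices(df: pd.DataFrame) -> pd.DataFrame:
    out = (
        df.assign(_b=(df["response"] == "B").astype(int))
        .groupby(
            ["participant_id", "continuum_id", "condition", "morph_pct"], as_index=False
        )
        .agg(k=("_b", "sum"), n=("_b", "size"))
    )
    return out


# ---------------------------------------------------------------------------
# binomial GLMM with Laplace approximation


def _binom_const(k: np.ndarray, n: np.ndarray) -> float:
    return float(
        np.sum(special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1))
    )


def _pirls(
    A: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    pen: np.ndarray,
    coef0: np.ndarray,
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Penalized IRLS for the joint mode of (beta, u).

    ``A = [X Z]``; ``pen`` is the per-coefficient ridge precision (0 for the
    fixed effects, 1/sigma_f^2 for factor f's intercepts).  Returns the mode,
    the penalized log-likelihood at the mode, the IRLS weights, and a
    convergence flag.  Newton steps with step-halving.
    """

    def pen_ll(coef: np.ndarray) -> float:
        eta = A @ coef
        ll = float(np.sum(k * eta - n * np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(pen @ coef**2)

    coef = coef0.copy()
    ll = pen_ll(coef)
    converged = False
    for _ in range(_PIRLS_MAX_ITER):
        eta = A @ coef
        p = special.expit(eta)
        w = n * p * (1.0 - p)
        grad = A.T @ (k - n * p) - pen * coef
        H = (A * w[:, None]).T @ A
        H[np.diag_indices_from(H)] += pen + 1e-12
        try:
            step = linalg.cho_solve(linalg.cho_factor(H), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            new = coef + t * step
            ll_new = pen_ll(new)
            if ll_new >= ll - 1e-13:
                break
            t *= 0.5
        improved = ll_new - ll
        coef, ll = new, ll_new
        if abs(improved) < _PIRLS_TOL * (1.0 + abs(ll)):
            converged = True
            break
    eta = A @ coef
    p = special.expit(eta)
    return coef, ll, n * p * (1.0 - p), converged


def _irls_logistic(X: np.ndarray, k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Plain (unpenalized) logistic regression by IRLS; starting values."""
    coef, _, _, _ = _pirls(X, k, n, np.zeros(X.shape[1]), np.zeros(X.shape[1]))
    return coef


def _laplace_loglik(
    A: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    design: _Design,
    log_sigma: np.ndarray,
    coef0: np.ndarray,
    const: float,
) -> tuple[float, np.ndarray, np.ndarray, bool]:
    """Profiled Laplace marginal log-likelihood at the given log std devs."""
    p_fix = design.X.shape[1]
    q = design.Z.shape[1]
    pen = np.zeros(p_fix + q)
    half_logdet_prec = 0.0
    for j, factor in enumerate(design.u_slices):
        s = design.u_slices[factor]
        prec = np.exp(-2.0 * log_sigma[j])
        pen[p_fix + s.start : p_fix + s.stop] = prec
        half_logdet_prec += -(s.stop - s.start) * log_sigma[j]
    coef, pen_ll, w, ok = _pirls(A, k, n, pen, coef0)
    Zw = design.Z * w[:, None]
    Hu = Zw.T @ design.Z
    Hu[np.diag_indices_from(Hu)] += pen[p_fix:]
    sign, logdet_hu = np.linalg.slogdet(Hu) if q else (1.0, 0.0)
    ll = pen_ll + const + half_logdet_prec - 0.5 * logdet_hu
    return ll, coef, w, ok


def fit_binomial_glmm(trials: pd.DataFrame, spec: ModelSpec | None = None) -> MixedModelFit:
    """Fit the Laplace-approximated binomial GLMM to choice data.

    Trials are aggregated to binomial counts per design cell (likelihood
    preserved).  Outer optimization is Nelder-Mead over the log random-effect
    standard deviations, warm-starting the inner PIRLS at the previous mode.
    """
    spec = spec or ModelSpec(response="choice")
    if spec.response != "choice":
        raise ValueError("fit_binomial_glmm requires spec.response == 'choice'")
    df = validate_trials(trials)
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    agg = _aggregate_choices(df)
    k = agg["k"].to_numpy(float)
    n = agg["n"].to_numpy(float)
    design = _build_design(agg, spec, weights=n)
    A = np.hstack([design.X, design.Z])
    p_fix = design.X.shape[1]
    q = design.Z.shape[1]
    const = _binom_const(k, n)

    beta0 = _irls_logistic(design.X, k, n)
    state = {"coef": np.concatenate([beta0, np.zeros(q)])}

    n_factors = len(design.u_slices)
    if n_factors == 0:
        coef, pen_ll, w, ok = _pirls(A, k, n, np.zeros(p_fix), state["coef"])
        beta, loglik, converged = coef, pen_ll + const, ok
        theta = np.array([])
    else:

        def objective(log_sigma: np.ndarray) -> float:
            ll, coef, _, _ = _laplace_loglik(A, k, n, design, log_sigma, state["coef"], const)
            state["coef"] = coef
            return -ll

        x0 = np.full(n_factors, np.log(0.5))
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=[_LOG_SIGMA_BOUNDS] * n_factors,
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 600},
        )
        theta = res.x
        loglik, coef, w, inner_ok = _laplace_loglik(A, k, n, design, theta, state["coef"], const)
        beta = coef
        converged = bool(res.success and inner_ok)

    # covariance of beta: Schur complement of the joint Hessian at the mode
    Aw = A * w[:, None]
    H = Aw.T @ A
    for j, factor in enumerate(design.u_slices):
        s = design.u_slices[factor]
        H[p_fix + s.start : p_fix + s.stop, p_fix + s.start : p_fix + s.stop] += np.eye(
            s.stop - s.start
        ) * np.exp(-2.0 * theta[j])
    Hbb = H[:p_fix, :p_fix]
    if q:
        Hbu = H[:p_fix, p_fix:]
        Huu = H[p_fix:, p_fix:]
        schur = Hbb - Hbu @ np.linalg.solve(Huu, Hbu.T)
    else:
        schur = Hbb
    vcov = np.linalg.inv(schur)

    sigma = {
        factor: float(np.exp(theta[j])) for j, factor in enumerate(design.u_slices)
    }
    diagnostics = {}
    if np.any(np.abs(beta[:p_fix]) > _SEPARATION_BOUND):
        diagnostics["separation"] = True
        converged = False
    return MixedModelFit(
        beta=beta[:p_fix].copy(),
        beta_names=design.beta_names,
        vcov_beta=vcov,
        sigma=sigma,
        sigma_resid=None,
        loglik=float(loglik),
        converged=converged,
        n_obs=int(n.sum()),
        n_groups={f: len(l) for f, l in design.factor_levels.items()},
        term_slices=design.term_slices,
        condition_levels=design.condition_levels,
        scaling_center=design.center,
        scaling_scale=design.scale,
        spec=spec,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Gaussian linear mixed model (exact marginal ML)


def fit_linear_mixed(trials: pd.DataFrame, spec: ModelSpec | None = None) -> MixedModelFit:
    """Fit the Gaussian random-intercept model to log reaction times by
    maximum likelihood.

    The caller is expected to pass RT-filtered trials (see
    :func:`morphcp.data_model.filter_for_rt`).  Random factors with fewer
    than two levels are not identifiable and are dropped with a diagnostic,
    falling back to ordinary least squares when none remain.
    """
    spec = spec or ModelSpec(response="log_rt")
    if spec.response != "log_rt":
        raise ValueError("fit_linear_mixed requires spec.response == 'log_rt'")
    df = validate_trials(trials)
    if df.empty:
        raise ValueError("no trials to fit")
    y = np.log(df["rt_ms"].to_numpy(float))

    dropped = [f for f in spec.random if df[f].nunique() < 2]
    eff_spec = dataclasses.replace(
        spec, random=tuple(f for f in spec.random if f not in dropped)
    )
    design = _build_design(df, eff_spec)
    X, Z = design.X, design.Z
    n_obs, p_fix = X.shape
    q = Z.shape[1]
    factors = list(design.u_slices)

    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    if q:
        ZtZ, ZtX, Zty = Z.T @ Z, Z.T @ X, Z.T @ y

    def eval_ll(log_sig: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Returns (loglik, beta, vcov_beta) for (log sigma_f..., log sigma_e)."""
        sig_e2 = np.exp(2.0 * log_sig[-1])
        if q == 0:
            beta = np.linalg.solve(XtX, Xty)
            quad = (yty - 2 * beta @ Xty + beta @ XtX @ beta) / sig_e2
            ll = -0.5 * (n_obs * np.log(2 * np.pi * sig_e2) + quad)
            return ll, beta, sig_e2 * np.linalg.inv(XtX)
        gam_inv = np.zeros(q)
        log_gam_sum = 0.0
        for j, factor in enumerate(factors):
            s = design.u_slices[factor]
            gam = np.exp(2.0 * (log_sig[j] - log_sig[-1]))
            gam_inv[s] = 1.0 / gam
            log_gam_sum += (s.stop - s.start) * np.log(gam)
        Amat = ZtZ + np.diag(gam_inv)
        cf = linalg.cho_factor(Amat)
        AiZtX = linalg.cho_solve(cf, ZtX)
        AiZty = linalg.cho_solve(cf, Zty)
        S_xx = XtX - ZtX.T @ AiZtX
        S_xy = Xty - ZtX.T @ AiZty
        S_yy = yty - Zty @ AiZty
        beta = np.linalg.solve(S_xx, S_xy)
        quad = (S_yy - beta @ S_xy) / sig_e2
        logdetV = (
            n_obs * np.log(sig_e2)
            + 2.0 * np.sum(np.log(np.diag(cf[0])))
            + log_gam_sum
        )
        ll = -0.5 * (n_obs * np.log(2 * np.pi) + logdetV + quad)
        return ll, beta, sig_e2 * np.linalg.inv(S_xx)

    # OLS residual scale anchors the starting values
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    resid_sd = float(np.std(y - X @ beta_ols)) or 1e-3
    if q == 0:
        ll, beta, vcov = eval_ll(np.array([np.log(resid_sd)]))
        # profile sigma_e analytically for the pure OLS fallback
        rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
        sig_e = float(np.sqrt(rss / n_obs))
        ll, beta, vcov = eval_ll(np.array([np.log(sig_e)]))
        fit_sigma: dict[str, float] = {}
        converged = True
    else:
        x0 = np.concatenate(
            [np.full(len(factors), np.log(max(resid_sd * 0.5, 1e-4))), [np.log(resid_sd)]]
        )
        res = optimize.minimize(
            lambda ls: -eval_ll(ls)[0],
            x0,
            method="Nelder-Mead",
            bounds=[(-8.0, 3.0)] * (len(factors) + 1),
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000},
        )
        ll, beta, vcov = eval_ll(res.x)
        fit_sigma = {f: float(np.exp(res.x[j])) for j, f in enumerate(factors)}
        sig_e = float(np.exp(res.x[-1]))
        converged = bool(res.success)

    diagnostics = {}
    if dropped:
        diagnostics["dropped_random"] = dropped
    for f in dropped:
        fit_sigma[f] = float("nan")
    return MixedModelFit(
        beta=beta,
        beta_names=design.beta_names,
        vcov_beta=vcov,
        sigma=fit_sigma,
        sigma_resid=sig_e,
        loglik=float(ll),
        converged=converged,
        n_obs=n_obs,
        n_groups={f: len(l) for f, l in design.factor_levels.items()},
        term_slices=design.term_slices,
        condition_levels=design.condition_levels,
        scaling_center=design.center,
        scaling_scale=design.scale,
        spec=eff_spec,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Wald tests and PSE


def wald_type3(
    fit: MixedModelFit, terms: Sequence[str] = ("morph", "condition", "interaction")
) -> WaldTable:
    """Term-wise Type-3 Wald chi-square tests.

    For each term's coefficient block b with covariance block V the statistic
    is b' V^-1 b on df = block size.  With zero-sum contrasts this tests each
    effect adjusted for all others, the usual Type-3 semantics.
    """
    present = [t for t in terms if t in fit.term_slices]
    chi, dof, pval = {}, {}, {}
    for term in present:
        s = fit.term_slices[term]
        b = fit.beta[s]
        V = fit.vcov_beta[s, s]
        try:
            stat = float(b @ np.linalg.solve(V, b)) if b.size else 0.0
        except np.linalg.LinAlgError as err:
            raise SingularTermError(f"singular covariance block for term {term!r}") from err
        if b.size and np.linalg.cond(V) > 1e12:
            raise SingularTermError(f"singular covariance block for term {term!r}")
        chi[term] = max(stat, 0.0)
        dof[term] = int(b.size)
        pval[term] = float(stats.chi2.sf(chi[term], dof[term])) if b.size else 1.0
    return WaldTable(terms=present, chi_square=chi, df=dof, p_value=pval)


def _condition_row(fit: MixedModelFit, condition: str) -> np.ndarray:
    levels = fit.condition_levels
    if condition not in levels:
        raise ValueError(f"condition {condition!r} not in fit ({levels})")
    K = len(levels)
    if K == 1:
        return np.zeros(0)
    return zero_sum_contrasts(K)[levels.index(condition)]


def _pse_components(fit: MixedModelFit, condition: str) -> tuple[float, float, np.ndarray]:
    """(pse, variance-gradient row, full-beta gradient) for one condition."""
    row = _condition_row(fit, condition)
    beta = fit.beta
    sl = fit.term_slices
    a = beta[sl["intercept"]][0] + (row @ beta[sl["condition"]] if row.size else 0.0)
    s = beta[sl["morph"]][0] + (row @ beta[sl["interaction"]] if row.size else 0.0)
    if abs(s) < 1e-12:
        raise ZeroDivisionError(
            f"morph slope is zero for condition {condition!r}; PSE undefined"
        )
    grad = np.zeros(len(beta))
    grad[sl["intercept"]] = -1.0 / s
    grad[sl["morph"]] = a / s**2
    if row.size:
        grad[sl["condition"]] = row * (-1.0 / s)
        grad[sl["interaction"]] = row * (a / s**2)
    pse = fit.scaling_center + fit.scaling_scale * (-a / s)
    return pse, s, grad * fit.scaling_scale


def estimate_pse(
    fit: MixedModelFit, condition: str, reference: str | None = None
) -> PseEstimate:
    """Morph level at which the fitted P(Identity B) crosses 0.5 (random
    effects at zero), with a delta-method standard error; optionally also the
    boundary shift against a reference condition."""
    pse, _, grad = _pse_components(fit, condition)
    se = float(np.sqrt(grad @ fit.vcov_beta @ grad))
    est = PseEstimate(condition=condition, pse=float(pse), se=se)
    if reference is not None:
        pse_ref, _, grad_ref = _pse_components(fit, reference)
        d = grad - grad_ref
        est.reference = reference
        est.shift = float(pse - pse_ref)
        est.shift_se = float(np.sqrt(d @ fit.vcov_beta @ d))
    return est
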