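"""Liability-threshold G-BLUP for a binary trait with logistic residuals.

Model
-----
Each individual carries a latent liability

    l = mu + g + e,        g ~ N(0, G * sigma_a^2),   e ~ Logistic(0, s=1)

with G the genomic relationship matrix. The observed class is y = 1 iff
l > 0, so P(y_i = 1) = logistic(mu + g_i) and the narrow-sense heritability
on the liability scale is

    h2 = sigma_a^2 / (sigma_a^2 + pi^2/3)

(pi^2/3 ~ 3.29 is the variance of the standard logistic residual).

Fitting maximizes the Laplace-approximate marginal likelihood of the
Bernoulli-logit GLMM: an inner Newton solve for the joint mode of
(mu, g) given sigma_a^2, and an outer bounded scalar optimization of
sigma_a^2 on the log scale. Individuals without a phenotype carry no
Bernoulli record but stay in g through the joint prior, so their fitted
genetic value is the BLUP conditional mean G_21 G_11^{-1} g_train — this is
how cross-validation test sets are predicted.

The module also provides the equivalent marker-effect (ridge logistic,
RR-BLUP) parameterization, classification by the p > 0.5 rule, and the
boundary-corrected likelihood-ratio test of sigma_a^2 = 0.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import linalg, optimize, special, stats

from .grm import GRM

LOGISTIC_VARIANCE = math.pi**2 / 3.0  # residual variance, scale s = 1

__all__ = [
    "LOGISTIC_VARIANCE",
    "LiabilityFit",
    "ClassProbability",
    "LRTResult",
    "ConvergenceError",
    "heritability",
    "variance_from_h2",
    "fit_threshold_model",
    "classify",
    "likelihood_ratio_test",
    "fit_marker_effects_ridge",
    "laplace_marginal_loglik",
]


class ConvergenceError(RuntimeError):
    pass


def heritability(sigma_a2: float) -> float:
    """Liability-scale heritability sigma_a^2 / (sigma_a^2 + pi^2/3)."""
    if sigma_a2 < 0:
        raise ValueError("sigma_a2 must be non-negative")
    return sigma_a2 / (sigma_a2 + LOGISTIC_VARIANCE)


def variance_from_h2(h2: float) -> float:
    """Inverse map: the genetic variance that yields heritability ``h2``."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    return h2 / (1.0 - h2) * LOGISTIC_VARIANCE


@dataclasses.dataclass
class LiabilityFit:
    mu: float
    g: np.ndarray  # liability-scale genetic values, one per GRM sample
    sigma_a2: float
    h2: float
    h2_se: float | None
    deviance: float  # -2 * Laplace marginal log-likelihood
    null_deviance: float  # intercept-only Bernoulli model
    converged: bool
    fixed_h2: float | None
    sample_ids: list
    n_obs: int

    def summary(self) -> dict:
        return {
            "mu": self.mu,
            "sigma_a2": self.sigma_a2,
            "h2": self.h2,
            "h2_se": self.h2_se,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "converged": self.converged,
            "fixed_h2": self.fixed_h2,
            "n_obs": self.n_obs,
        }


@dataclasses.dataclass
class ClassProbability:
    sample_id: str
    p_high: float
    predicted_class: int  # 1 iff p_high > 0.5 (ties -> 0)


@dataclasses.dataclass
class LRTResult:
    statistic: float
    p_value: float  # 50:50 mixture of chi2_0 and chi2_1 (boundary null)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _penalized_loglik(y, obs, P, mu, g):
    eta = mu + g[obs]
    return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * g @ (P @ g))


def _inner_newton(y, obs, P, mu0=0.0, g0=None, tol=1e-8, max_iter=100):
    """Joint mode of (mu, g) for the penalized Bernoulli-logit objective.

    P is the prior precision of g (K^-1 / sigma_a^2); obs indexes the
    phenotyped entries of g.
    """
    n = P.shape[0]
    mu = float(mu0)
    g = np.zeros(n) if g0 is None else np.asarray(g0, dtype=float).copy()
    obs1 = obs + 1  # positions in the bordered (mu, g) system
    converged = False
    best_gnorm = np.inf
    stall = 0
    for _ in range(max_iter):
        eta = mu + g[obs]
        p = special.expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        r = y - p
        grad_g = -(P @ g)
        np.add.at(grad_g, obs, r)
        grad_mu = float(r.sum())
        gnorm = max(abs(grad_mu), float(np.abs(grad_g).max()))
        if gnorm < tol:
            converged = True
            break
        # An ill-conditioned K caps the reachable gradient norm; accept a
        # stalled iteration near the mode instead of spinning to max_iter.
        if gnorm >= 0.9 * best_gnorm:
            stall += 1
            if stall >= 5:
                converged = gnorm < 1e-5
                break
        else:
            stall = 0
        best_gnorm = min(best_gnorm, gnorm)
        H = np.zeros((n + 1, n + 1))
        H[1:, 1:] = P
        H[obs1, obs1] += w
        H[0, 0] = w.sum()
        H[0, obs1] = w
        H[obs1, 0] = w
        rhs = np.concatenate(([grad_mu], grad_g))
        try:
            cf = linalg.cho_factor(H, lower=True, check_finite=False)
            step = linalg.cho_solve(cf, rhs, check_finite=False)
        except linalg.LinAlgError:
            step = linalg.solve(H + 1e-10 * np.eye(n + 1), rhs, assume_a="sym")
        f0 = _penalized_loglik(y, obs, P, mu, g)
        t = 1.0
        for _ in range(40):
            mu_new = mu + t * step[0]
            g_new = g + t * step[1:]
            if _penalized_loglik(y, obs, P, mu_new, g_new) >= f0 - 1e-12:
                break
            t *= 0.5
        mu, g = mu_new, g_new
    return mu, g, converged


def _laplace_at_mode(y, obs, K, P, sigma_a2, mu, g):
    """Laplace-approximate marginal log-likelihood at the joint mode."""
    eta = mu + g[obs]
    p = special.expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    f = float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * g @ (P @ g))
    Koo = K[np.ix_(obs, obs)]
    sw = np.sqrt(w)
    M = np.eye(len(obs)) + sigma_a2 * (sw[:, None] * Koo * sw[None, :])
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise ConvergenceError("non-positive Laplace determinant")
    return f - 0.5 * logdet


def laplace_marginal_loglik(
    y_obs: np.ndarray,
    K: np.ndarray,
    sigma_a2: float,
    mu: float | None = None,
    obs: np.ndarray | None = None,
    inner_tol: float = 1e-8,
) -> float:
    """Laplace marginal log-likelihood at a given variance (and optionally mu).

    With ``mu=None`` the intercept is profiled out (maximized jointly with
    the random effects); with ``mu`` given, only the random-effect mode is
    found. Exposed for direct comparison against numerical integration of
    the marginal likelihood on tiny problems.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    n = K.shape[0]
    if obs is None:
        obs = np.arange(n)
    cf = linalg.cho_factor(K, lower=True)
    Kinv = linalg.cho_solve(cf, np.eye(n))
    P = Kinv / sigma_a2
    if mu is None:
        mu_hat, g_hat, _ = _inner_newton(y_obs, obs, P, tol=inner_tol)
    else:
        mu_hat = float(mu)
        g_hat = _mode_given_mu(y_obs, obs, P, mu_hat, tol=inner_tol)
    return _laplace_at_mode(y_obs, obs, K, P, sigma_a2, mu_hat, g_hat)


def _mode_given_mu(y, obs, P, mu, g0=None, tol=1e-8, max_iter=100):
    n = P.shape[0]
    g = np.zeros(n) if g0 is None else np.asarray(g0, dtype=float).copy()
    for _ in range(max_iter):
        eta = mu + g[obs]
        p = special.expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = -(P @ g)
        np.add.at(grad, obs, y - p)
        if np.abs(grad).max() < tol:
            break
        H = P.copy()
        H[obs, obs] += w
        cf = linalg.cho_factor(H, lower=True, check_finite=False)
        step = linalg.cho_solve(cf, grad, check_finite=False)
        f0 = _penalized_loglik(y, obs, P, mu, g)
        t = 1.0
        for _ in range(40):
            g_new = g + t * step
            if _penalized_loglik(y, obs, P, mu, g_new) >= f0 - 1e-12:
                break
            t *= 0.5
        g = g_new
    return g


def _bernoulli_deviance(y, mu):
    eta = np.full_like(y, mu)
    return float(-2.0 * (y @ eta - np.logaddexp(0.0, eta).sum()))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

SIGMA_BOUNDS = (1e-6, 1e4)


def fit_threshold_model(
    y: np.ndarray,
    grm: GRM,
    mode: str = "estimate",
    h2_fixed: float | None = None,
    *,
    ridge: float | str = "auto",
    inner_tol: float = 1e-8,
    outer_tol: float = 1e-6,
    compute_se: bool = False,
) -> LiabilityFit:
    """Fit the liability-threshold G-BLUP by Laplace maximum likelihood.

    Parameters
    ----------
    y:
        Phenotypes aligned with ``grm.sample_ids``; 0/1 with NaN for
        individuals to predict (they remain in ``g`` through the prior).
    grm:
        Relationship matrix covering every individual.
    mode:
        ``"estimate"`` — maximize over sigma_a^2 (bracket
        [1e-6, 1e4] on the log scale; hitting the upper bound flags
        quasi-separation and sets ``converged=False``);
        ``"fixed_h2"`` — set sigma_a^2 = h2/(1-h2) * pi^2/3 and estimate only
        (mu, g).
    ridge:
        Diagonal jitter added to G before inversion; ``"auto"`` uses
        1e-6 * mean(diag(G)). Pass 0.0 to invert G exactly.
    compute_se:
        Also compute a delta-method standard error for h2 from the numerical
        curvature of the profile log-likelihood (estimate mode only).
    """
    y = np.asarray(y, dtype=float)
    n = grm.n
    if y.shape != (n,):
        raise ValueError(f"y has shape {y.shape}, expected ({n},)")
    obs = np.flatnonzero(~np.isnan(y))
    y_obs = y[obs]
    classes = np.unique(y_obs)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("phenotypes must be 0/1 (NaN = unphenotyped)")
    if len(classes) < 2:
        raise ValueError("need at least one phenotyped sample of each class")

    if ridge == "auto":
        eps = max(1e-6 * float(np.mean(np.diag(grm.values))), 1e-12)
    else:
        eps = float(ridge)
    K = grm.values + eps * np.eye(n) if eps > 0 else grm.values
    cf = linalg.cho_factor(K, lower=True)
    Kinv = linalg.cho_solve(cf, np.eye(n))
    Kinv = 0.5 * (Kinv + Kinv.T)

    warm = {"mu": float(special.logit(y_obs.mean())), "g": np.zeros(n)}

    def profile(sigma_a2):
        P = Kinv / sigma_a2
        mu_hat, g_hat, ok = _inner_newton(
            y_obs, obs, P, mu0=warm["mu"], g0=warm["g"], tol=inner_tol
        )
        warm["mu"], warm["g"] = mu_hat, g_hat.copy()
        ll = _laplace_at_mode(y_obs, obs, K, P, sigma_a2, mu_hat, g_hat)
        return ll, mu_hat, g_hat, ok

    converged = True
    h2_se = None
    if mode == "fixed_h2":
        if h2_fixed is None or not 0.0 < h2_fixed < 1.0:
            raise ValueError("fixed_h2 mode requires h2_fixed in (0, 1)")
        sigma_a2 = variance_from_h2(h2_fixed)
        ll, mu_hat, g_hat, ok = profile(sigma_a2)
        converged = ok
    elif mode == "estimate":
        lo, hi = np.log(SIGMA_BOUNDS[0]), np.log(SIGMA_BOUNDS[1])
        res = optimize.minimize_scalar(
            lambda x: -profile(np.exp(x))[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": outer_tol, "maxiter": 100},
        )
        sigma_a2 = float(np.exp(res.x))
        ll, mu_hat, g_hat, ok = profile(sigma_a2)
        converged = bool(res.success) and ok
        if sigma_a2 > 0.99 * SIGMA_BOUNDS[1]:
            converged = False  # quasi-separation: variance ran to the bound
        if compute_se and converged:
            h2_se = _h2_se(profile, sigma_a2, ll)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    mu0 = float(special.logit(y_obs.mean()))
    null_dev = _bernoulli_deviance(y_obs, mu0)

    return LiabilityFit(
        mu=float(mu_hat),
        g=g_hat,
        sigma_a2=float(sigma_a2),
        h2=heritability(sigma_a2),
        h2_se=h2_se,
        deviance=-2.0 * ll,
        null_deviance=null_dev,
        converged=converged,
        fixed_h2=h2_fixed if mode == "fixed_h2" else None,
        sample_ids=list(grm.sample_ids),
        n_obs=len(obs),
    )


def _h2_se(profile, sigma_a2, ll0):
    """Delta-method SE of h2 from the profile-likelihood curvature."""
    h = max(1e-3 * sigma_a2, 1e-6)
    try:
        lp = profile(sigma_a2 + h)[0]
        lm = profile(max(sigma_a2 - h, 1e-9))[0]
    except (linalg.LinAlgError, ConvergenceError):
        return None
    d2 = (lp - 2.0 * ll0 + lm) / h**2
    if d2 >= 0:
        return None
    se_sigma = math.sqrt(-1.0 / d2)
    c = LOGISTIC_VARIANCE
    return c / (sigma_a2 + c) ** 2 * se_sigma


def classify(fit: LiabilityFit, sample_ids=None) -> list:
    """Class probabilities p = logistic(mu + g) and the p > 0.5 rule.

    Ties (p exactly 0.5) go to class 0, matching the "<= 0.5 is low" rule.
    """
    if sample_ids is None:
        sample_ids = fit.sample_ids
    index = {sid: i for i, sid in enumerate(fit.sample_ids)}
    out = []
    for sid in sample_ids:
        if sid not in index:
            raise KeyError(f"sample {sid!r} not in fit")
        p = float(special.expit(fit.mu + fit.g[index[sid]]))
        out.append(ClassProbability(sid, p, int(p > 0.5)))
    return out


def likelihood_ratio_test(fit: LiabilityFit, tol: float = 1e-3) -> LRTResult:
    """Full vs intercept-only model, boundary-corrected reference.

    Because sigma_a^2 = 0 sits on the boundary of the parameter space, the
    null distribution is the 50:50 mixture of a point mass at 0 and chi2_1;
    p = 0.5 * P(chi2_1 > statistic), which is 0.5 at statistic = 0.
    """
    if fit.fixed_h2 is not None:
        raise ValueError("LRT requires sigma_a2 to have been estimated")
    stat = fit.null_deviance - fit.deviance
    if stat < -tol:
        raise ConvergenceError(
            f"full model fits worse than null (statistic {stat:.3g}); "
            "optimization did not converge"
        )
    stat = max(stat, 0.0)
    p = float(0.5 * stats.chi2.sf(stat, df=1))
    return LRTResult(statistic=float(stat), p_value=p)


# ---------------------------------------------------------------------------
# RR-BLUP (marker-effect) parameterization
# ---------------------------------------------------------------------------

def fit_marker_effects_ridge(
    y: np.ndarray,
    Z: np.ndarray,
    sigma_b2: float,
    tol: float = 1e-10,
    max_iter: int = 200,
):
    """Penalized logistic regression on centered marker dosages.

    Maximizes sum_i [y_i eta_i - log(1+e^eta_i)] - ||b||^2 / (2 sigma_b2)
    with eta = mu + Z b. With sigma_b2 = sigma_a2 / denom and
    G = Z Z' / denom of full rank, the fitted genetic values Z b equal the
    G-BLUP mode — the RR-BLUP/G-BLUP equivalence.

    Returns ``(mu, b, g)`` with g = Z @ b.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    X = np.column_stack([np.ones(n), Z])
    pen = np.zeros(m + 1)
    pen[1:] = 1.0 / sigma_b2
    beta = np.zeros(m + 1)

    def obj(b):
        eta = X @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (pen * b * b).sum())

    for _ in range(max_iter):
        eta = X @ beta
        p = special.expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = X.T @ (y - p) - pen * beta
        if np.abs(grad).max() < tol:
            break
        H = (X * w[:, None]).T @ X + np.diag(pen)
        cf = linalg.cho_factor(H, lower=True, check_finite=False)
        step = linalg.cho_solve(cf, grad, check_finite=False)
        f0 = obj(beta)
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            if obj(cand) >= f0 - 1e-14:
                break
            t *= 0.5
        beta = cand
    mu = float(beta[0])
    b = beta[1:]
    return mu, b, Z @ b
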