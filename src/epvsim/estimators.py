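"""Maximum-likelihood and Firth-penalized logistic regression.

Both fitters use Fisher scoring (iteratively reweighted least squares)
from a zero start and judge convergence on the relative change in
deviance between successive iterations,

    |dev_new - dev_old| / (|dev_new| + 0.1) < tol,

the criterion used by R's ``glm``.  The maximum-likelihood fitter
deliberately uses plain scoring with no step control so that divergence
on separated data is observable — the separation detectors rely on it.
Firth's procedure maximizes the Jeffreys-penalized log-likelihood

    l*(beta) = l(beta) + 1/2 log det I(beta)

via the modified score U*_r = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ir,
where h_i are the hat-matrix leverages; its estimates are finite even on
separated data.  Standard errors come from the expected information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2, norm

__all__ = [
    "ConvergenceSpec",
    "CONVERGENCE_PRESETS",
    "FitResult",
    "ConfidenceInterval",
    "fit_ml",
    "fit_firth",
    "wald_ci",
    "profile_ci",
    "SingularDesignError",
    "InvalidOutcomeError",
    "UnboundedIntervalError",
]


class SingularDesignError(ValueError):
    """Intercept-augmented design matrix is rank deficient."""


class InvalidOutcomeError(ValueError):
    """Outcome vector contains a single class."""


class UnboundedIntervalError(RuntimeError):
    """No finite bracket found for a profile-likelihood endpoint."""


@dataclass(frozen=True)
class ConvergenceSpec:
    """Deviance tolerance and Fisher-scoring iteration cap."""

    tolerance: float = 1e-8
    max_iterations: int = 25

    def __post_init__(self):
        if self.tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("tolerance must be positive and max_iterations >= 1")


#: named presets: the glm default plus the three stricter/looser variants
#: used when comparing non-convergence as a separation proxy
CONVERGENCE_PRESETS: dict[str, ConvergenceSpec] = {
    "default": ConvergenceSpec(1e-8, 25),
    "typeI": ConvergenceSpec(1e-6, 25),
    "typeII": ConvergenceSpec(1e-10, 25),
    "typeIII": ConvergenceSpec(1e-10, 50),
}


@dataclass
class FitResult:
    method: str  # "ML" or "Firth"
    coefficients: np.ndarray  # (beta0, beta1..betaP)
    standard_errors: np.ndarray
    loglik: float  # penalized log-likelihood for Firth
    converged: bool
    n_iterations: int
    deviance_trace: np.ndarray  # deviance after each scoring iteration


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    kind: str  # "wald" or "profile"

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


# ---------------------------------------------------------------------------
# internals shared by both fitters


def _design(data) -> tuple[np.ndarray, np.ndarray]:
    """Validated intercept-augmented design and outcome."""
    X = np.asarray(data.X, dtype=float)
    y = np.asarray(data.y, dtype=float)
    Z = np.column_stack([np.ones(X.shape[0]), X])
    if len(np.unique(y)) < 2:
        raise InvalidOutcomeError("outcome has a single class")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise SingularDesignError("intercept-augmented design is rank deficient")
    return Z, y


def _loglik_eta(y: np.ndarray, eta: np.ndarray) -> float:
    # log pi_i for y=1 and log(1-pi_i) for y=0, without inf - inf:
    # l = -sum log(1 + exp((1-2y) eta))
    return float(-np.logaddexp(0.0, (1.0 - 2.0 * y) * eta).sum())


def _loglik(Z: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    if not np.all(np.isfinite(beta)):
        return -np.inf
    return _loglik_eta(y, Z @ beta)


def _info(Z: np.ndarray, pi: np.ndarray) -> np.ndarray:
    w = pi * (1.0 - pi)
    return (Z * w[:, None]).T @ Z


def _solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(A, b, rcond=None)[0]


def _se_from_info(info: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(info)
        d = np.diag(cov)
        # a non-positive diagonal means the information has collapsed
        return np.sqrt(np.where(d > 0, d, np.inf))
    except np.linalg.LinAlgError:
        return np.full(info.shape[0], np.inf)


def _penalized_loglik(Z: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    if not np.all(np.isfinite(beta)):
        return -np.inf
    pi = expit(Z @ beta)
    sign, logdet = np.linalg.slogdet(_info(Z, pi))
    if sign <= 0:
        return -np.inf
    return _loglik(Z, y, beta) + 0.5 * logdet


def _converged(dev_new: float, dev_old: float, tol: float) -> bool:
    if not (np.isfinite(dev_new) and np.isfinite(dev_old)):
        return False
    return abs(dev_new - dev_old) / (abs(dev_new) + 0.1) < tol


def _irls(Z: np.ndarray, y: np.ndarray, tol: float, max_iterations: int,
          enforce_tol: bool = True, record_path: bool = False):
    """Iteratively reweighted least squares for the logistic model.

    Initialization follows standard GLM software: the first working
    response is built from mu = (y + 1/2)/2 rather than from a
    coefficient vector, so iteration counts (and hence the behaviour of
    convergence-based separation diagnostics) are directly comparable
    with ``glm``-family implementations.  No step control is applied;
    on separated data the iterates diverge, which is exactly what the
    separation detectors monitor.  With ``enforce_tol=False`` the loop
    always runs ``max_iterations`` steps.

    Returns ``(beta, converged, n_iter, deviance_trace, path)`` where
    ``path`` (if requested) holds ``(beta, se)`` snapshots after every
    iteration.
    """
    n, p = Z.shape
    eps = np.finfo(float).eps
    mu = (y + 0.5) / 2.0
    eta = np.log(mu / (1.0 - mu))

    def deviance(mu_):
        return -2.0 * float(y @ np.log(mu_) + (1.0 - y) @ np.log1p(-mu_))

    dev_old = deviance(mu)
    beta = np.zeros(p)
    trace: list[float] = []
    path: list[tuple[np.ndarray, np.ndarray]] = []
    converged = False
    n_iter = 0
    for it in range(1, max_iterations + 1):
        w = mu * (1.0 - mu)
        # weighted least squares on the working response via QR, the way
        # glm-family software does it
        sw = np.sqrt(w)
        z = eta + (y - mu) / w
        beta_new = np.linalg.lstsq(sw[:, None] * Z, sw * z, rcond=None)[0]
        if not np.all(np.isfinite(beta_new)):
            n_iter = it
            break
        beta = beta_new
        eta = Z @ beta
        # fitted probabilities are clamped away from 0/1 exactly as in
        # standard GLM inverse-link code; keeps weights strictly positive
        mu = np.clip(expit(eta), eps, 1.0 - eps)
        dev_new = deviance(mu)
        trace.append(dev_new)
        n_iter = it
        if record_path:
            # SEs from the weights that produced this iterate — what a
            # GLM summary reports for a fit stopped at this iteration
            path.append((beta.copy(), _se_from_info((Z * w[:, None]).T @ Z)))
        if enforce_tol and _converged(dev_new, dev_old, tol):
            converged = True
            break
        dev_old = dev_new
    return beta, converged, n_iter, np.asarray(trace), path


def ml_scoring_path(data, n_iterations: int, tol: float | None = 1e-8):
    """Snapshots of ML fits capped at k = 1..n_iterations iterations.

    Returns ``(beta, se)`` after every iteration; the k-th element equals
    the final iterate of an ML fit with iteration cap k, which is what
    the tracing separation detector monitors.  With the default ``tol``
    the deviance criterion is active, as in GLM software, so once the fit
    converges at iteration j the path is constant for k >= j.  Pass
    ``tol=None`` to disable the tolerance and force exactly k scoring
    steps per refit.
    """
    Z, y = _design(data)
    enforce = tol is not None
    _, _, _, _, path = _irls(Z, y, tol=tol if enforce else np.inf,
                             max_iterations=n_iterations,
                             enforce_tol=enforce, record_path=True)
    while len(path) < n_iterations:  # converged early or weights collapsed
        path.append(path[-1])
    return path


def fit_ml(data, conv: ConvergenceSpec = CONVERGENCE_PRESETS["default"]) -> FitResult:
    """Fit by maximum likelihood with plain Fisher scoring (IRLS).

    The last iterate is returned whether or not the deviance criterion
    was met, so estimates on separated data reflect exactly what an
    unguarded IRLS implementation reports at the iteration cap.
    """
    Z, y = _design(data)
    beta, converged, n_iter, trace, _ = _irls(
        Z, y, conv.tolerance, conv.max_iterations
    )
    pi = expit(Z @ beta)
    return FitResult(
        method="ML",
        coefficients=beta,
        standard_errors=_se_from_info(_info(Z, pi)),
        loglik=_loglik(Z, y, beta),
        converged=converged,
        n_iterations=n_iter,
        deviance_trace=trace,
    )


def _firth_scoring(Z, y, beta0, conv, fixed: dict[int, float] | None = None,
                   max_halvings: int = 10):
    """Modified-score Fisher scoring with step-halving.

    ``fixed`` maps coefficient indices to pinned values, which yields the
    profile penalized likelihood when maximizing over the rest.  Because
    the modified score is the exact gradient of the penalized
    log-likelihood for the logistic model, the restricted update only
    uses the free block of score and information.
    """
    free = np.array([j for j in range(Z.shape[1]) if not fixed or j not in fixed])
    beta = beta0.copy()
    if fixed:
        for j, v in fixed.items():
            beta[j] = v
    pl_old = _penalized_loglik(Z, y, beta)
    dev_old = -2.0 * pl_old
    trace = []
    converged = False
    n_iter = 0
    for it in range(1, conv.max_iterations + 1):
        pi = expit(Z @ beta)
        w = pi * (1.0 - pi)
        info = _info(Z, pi)
        # hat-matrix leverages h_i = w_i * z_i' info^{-1} z_i
        h = w * np.einsum("ij,ji->i", Z, _solve(info, Z.T))
        ustar = Z.T @ (y - pi + h * (0.5 - pi))
        delta = np.zeros_like(beta)
        delta[free] = _solve(info[np.ix_(free, free)], ustar[free])
        step = 1.0
        pl_new = _penalized_loglik(Z, y, beta + delta)
        halvings = 0
        # nan-safe: any step not improving l* (including nan) is halved
        while not pl_new >= pl_old and halvings < max_halvings:
            step *= 0.5
            halvings += 1
            pl_new = _penalized_loglik(Z, y, beta + step * delta)
        beta = beta + step * delta
        dev_new = -2.0 * pl_new
        trace.append(dev_new)
        n_iter = it
        if _converged(dev_new, dev_old, conv.tolerance):
            converged = True
            break
        dev_old = dev_new
        pl_old = pl_new
    return beta, pl_new, converged, n_iter, np.asarray(trace)


def fit_firth(data, conv: ConvergenceSpec = CONVERGENCE_PRESETS["default"]) -> FitResult:
    """Fit by Firth's Jeffreys-penalized likelihood.

    Estimates are finite on every dataset with both outcome classes,
    including completely or quasi-completely separated ones.
    """
    Z, y = _design(data)
    beta, pl, converged, n_iter, trace = _firth_scoring(
        Z, y, np.zeros(Z.shape[1]), conv
    )
    pi = expit(Z @ beta)
    return FitResult(
        method="Firth",
        coefficients=beta,
        standard_errors=_se_from_info(_info(Z, pi)),
        loglik=pl,
        converged=converged,
        n_iterations=n_iter,
        deviance_trace=trace,
    )


def wald_ci(fit: FitResult, index: int = 1, level: float = 0.90) -> ConfidenceInterval:
    """Symmetric normal-theory interval: estimate +/- z * SE."""
    z = norm.ppf(0.5 * (1.0 + level))
    b = fit.coefficients[index]
    se = fit.standard_errors[index]
    return ConfidenceInterval(lower=b - z * se, upper=b + z * se, level=level, kind="wald")


def _profile_pl(Z, y, index, value, beta_start, conv) -> float:
    """Penalized log-likelihood profiled over all coefficients but one."""
    if Z.shape[1] == 1:
        beta = np.array([value])
        return _penalized_loglik(Z, y, beta)
    beta, pl, _, _, _ = _firth_scoring(Z, y, beta_start, conv, fixed={index: value})
    return pl


def profile_ci(data, fit: FitResult, index: int = 1, level: float = 0.90,
               xtol: float = 1e-6, max_range: float = 50.0) -> ConfidenceInterval:
    """Profile penalized-likelihood interval for one Firth coefficient.

    The endpoints solve 2 (l*(beta_hat) - l*_profile(b)) = chi^2_{1,level},
    found by bracketed root-finding expanding outward from the estimate.
    """
    if fit.method != "Firth":
        raise ValueError("profile_ci expects a Firth fit")
    Z, y = _design(data)
    conv = ConvergenceSpec(1e-10, 100)
    target = fit.loglik - 0.5 * chi2.ppf(level, df=1)
    bhat = float(fit.coefficients[index])
    se = float(fit.standard_errors[index])
    if not np.isfinite(se) or se <= 0:
        se = 1.0
    start = fit.coefficients.copy()

    def g(v: float) -> float:
        return _profile_pl(Z, y, index, v, start, conv) - target

    bounds = []
    for direction in (-1.0, 1.0):
        step = 1.0 * se
        lo_v = bhat
        found = None
        while True:
            at_edge = step >= max_range
            v = bhat + direction * (max_range if at_edge else step)
            if g(v) < 0.0:
                found = (v, lo_v) if direction < 0 else (lo_v, v)
                break
            if at_edge:
                break
            lo_v = v
            step *= 1.8
        if found is None:
            raise UnboundedIntervalError(
                f"no profile-CI bracket within +/-{max_range} of the estimate"
            )
        root = brentq(g, found[0], found[1], xtol=xtol)
        bounds.append(root)
    lower, upper = sorted(bounds)
    return ConfidenceInterval(lower=lower, upper=upper, level=level, kind="profile")
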