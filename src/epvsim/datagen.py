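"""Simulated data generation for logistic-regression sampling experiments.

Covariates are drawn from one of three laws (independent standard normal,
equicorrelated multivariate normal, independent Bernoulli(0.5)) and the
binary outcome from the logistic model

    logit P(Y=1 | x) = beta0 + beta' x.

Datasets are produced by *quota sampling*: covariate/outcome pairs are
drawn i.i.d. and the first ``n_events`` events and ``n_total - n_events``
non-events are retained, which fixes both the total sample size and the
number of events in every simulated dataset.  Under the logistic model
this conditioning only affects the intercept, so the slope coefficients
of the generating model remain the estimands.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "CovariateLaw",
    "TrueModel",
    "SamplingSpec",
    "Dataset",
    "sample_quota",
    "calibrate_intercept",
    "InvalidModelError",
    "SamplingStallError",
]

#: recognised covariate laws
NORMAL = "normal"
EQUICORR_NORMAL = "equicorr_normal"
BERNOULLI = "bernoulli"
CovariateLaw = str

_LAWS = (NORMAL, EQUICORR_NORMAL, BERNOULLI)

#: hard cap on raw draws per dataset, guards against degenerate models
MAX_RAW_DRAWS = 10**7

_DRAW_CHUNK = 512  # fixed chunk size keeps the RNG stream reproducible


class InvalidModelError(ValueError):
    """The generating model produces non-finite linear predictors."""


class SamplingStallError(RuntimeError):
    """Quota sampling exceeded the raw-draw safety cap."""


@dataclass(frozen=True)
class TrueModel:
    """Data-generating logistic model.

    Parameters
    ----------
    intercept
        beta0 on the logit scale.
    coefficients
        Slope coefficients beta1..betaP (log odds ratios).
    covariate_law
        One of ``"normal"`` (independent standard normal),
        ``"equicorr_normal"`` (multivariate normal, unit variances, all
        pairwise correlations equal to ``correlation``) or ``"bernoulli"``
        (independent Bernoulli(0.5)).
    correlation
        Common pairwise correlation rho, used only by the
        equicorrelated-normal law.
    """

    intercept: float
    coefficients: tuple[float, ...]
    covariate_law: CovariateLaw = NORMAL
    correlation: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        p = len(self.coefficients)
        if p < 1:
            raise InvalidModelError("at least one slope coefficient is required")
        if self.covariate_law not in _LAWS:
            raise InvalidModelError(f"unknown covariate law {self.covariate_law!r}")
        if not all(np.isfinite(self.coefficients)) or not np.isfinite(self.intercept):
            raise InvalidModelError("non-finite model parameters")
        if self.covariate_law == EQUICORR_NORMAL:
            # positive definiteness of the equicorrelation matrix
            if p > 1 and not (-1.0 / (p - 1) < self.correlation < 1.0):
                raise InvalidModelError("equicorrelation matrix is not positive definite")

    @property
    def p(self) -> int:
        return len(self.coefficients)

    @property
    def beta(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)


@dataclass(frozen=True)
class SamplingSpec:
    """Quota-sampling target: total size, event count and RNG seed."""

    n_total: int
    n_events: int
    seed: object  # int or numpy SeedSequence

    def __post_init__(self):
        if not (0 < self.n_events < self.n_total):
            raise ValueError("need 0 < n_events < n_total")


@dataclass
class Dataset:
    """Design matrix plus binary outcome with a known event count."""

    X: np.ndarray
    y: np.ndarray
    n_events: int = field(default=-1)
    #: raw (x, y) pairs consumed by quota sampling; -1 if not sampled
    n_raw_draws: int = field(default=-1, compare=False)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        observed = int(self.y.sum())
        if self.n_events < 0:
            self.n_events = observed
        elif self.n_events != observed:
            raise ValueError("n_events does not match sum(y)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=[f"x{j + 1}" for j in range(self.p)])
        df.insert(0, "y", self.y)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Dataset":
        if "y" not in df.columns:
            raise ValueError("dataset table needs a 'y' outcome column")
        xcols = [c for c in df.columns if c != "y"]
        return cls(X=df[xcols].to_numpy(dtype=float), y=df["y"].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        return cls.from_frame(pd.read_csv(path))


def _draw_covariates(model: TrueModel, size: int, rng: np.random.Generator) -> np.ndarray:
    p = model.p
    if model.covariate_law == NORMAL:
        return rng.standard_normal((size, p))
    if model.covariate_law == EQUICORR_NORMAL:
        rho = model.correlation
        z = rng.standard_normal((size, p))
        if rho == 0.0 or p == 1:
            return z
        if rho > 0.0:
            # equicorrelated MVN via one shared factor:
            # x_j = sqrt(rho) * g + sqrt(1-rho) * z_j  has corr(x_j, x_k) = rho
            g = rng.standard_normal((size, 1))
            return np.sqrt(rho) * g + np.sqrt(1.0 - rho) * z
        sigma = np.full((p, p), rho)
        np.fill_diagonal(sigma, 1.0)
        return z @ np.linalg.cholesky(sigma).T
    # Bernoulli(0.5)
    return (rng.random((size, p)) < 0.5).astype(float)


def sample_quota(model: TrueModel, spec: SamplingSpec) -> Dataset:
    """Draw a dataset with exactly ``spec.n_events`` events.

    Pairs (x, y) are simulated i.i.d. from the generating model and the
    first ``n_events`` pairs with y=1 plus the first
    ``n_total - n_events`` pairs with y=0 are retained, in draw order.
    The result is bit-reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_nonevents = spec.n_total - spec.n_events
    rows_x: list[np.ndarray] = []
    rows_y: list[int] = []
    got_events = 0
    got_nonevents = 0
    drawn = 0
    while got_events < spec.n_events or got_nonevents < n_nonevents:
        if drawn >= MAX_RAW_DRAWS:
            raise SamplingStallError(
                f"quota not filled after {MAX_RAW_DRAWS} raw draws "
                f"(events {got_events}/{spec.n_events})"
            )
        x = _draw_covariates(model, _DRAW_CHUNK, rng)
        eta = model.intercept + x @ model.beta
        if not np.all(np.isfinite(eta)):
            raise InvalidModelError("non-finite linear predictor")
        yy = (rng.random(_DRAW_CHUNK) < expit(eta)).astype(int)
        for i in range(_DRAW_CHUNK):
            drawn += 1
            if yy[i] == 1:
                if got_events < spec.n_events:
                    rows_x.append(x[i])
                    rows_y.append(1)
                    got_events += 1
            elif got_nonevents < n_nonevents:
                rows_x.append(x[i])
                rows_y.append(0)
                got_nonevents += 1
            if got_events >= spec.n_events and got_nonevents >= n_nonevents:
                break
    return Dataset(X=np.array(rows_x), y=np.array(rows_y), n_events=spec.n_events,
                   n_raw_draws=drawn)


def _prevalence(beta0: float, coefficients, covariate_law: CovariateLaw,
                correlation: float, gh: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Marginal event probability E[expit(beta0 + beta'X)] under the law."""
    beta = np.asarray(coefficients, dtype=float)
    p = beta.size
    if covariate_law == BERNOULLI:
        if p <= 20:
            total = 0.0
            for combo in itertools.product((0.0, 1.0), repeat=p):
                total += expit(beta0 + float(np.dot(beta, combo)))
            return total / 2**p
        rng = np.random.default_rng(0)
        x = (rng.random((200_000, p)) < 0.5).astype(float)
        return float(expit(beta0 + x @ beta).mean())
    # normal laws: beta'X ~ N(0, s^2) with s^2 = beta' Sigma beta
    if covariate_law == EQUICORR_NORMAL and p > 1:
        s2 = float(beta @ beta) * (1 - correlation) + correlation * float(beta.sum()) ** 2
    else:
        s2 = float(beta @ beta)
    s = np.sqrt(s2)
    if s == 0.0:
        return float(expit(beta0))
    if gh is None:
        gh = hermgauss(80)
    nodes, weights = gh
    # E[f(sZ)] with Z std normal = sum w_i f(s * sqrt(2) * t_i) / sqrt(pi)
    return float(weights @ expit(beta0 + s * np.sqrt(2.0) * nodes) / np.sqrt(np.pi))


def calibrate_intercept(coefficients, covariate_law: CovariateLaw,
                        target_prevalence: float, correlation: float = 0.0) -> float:
    """Solve for beta0 so the marginal event probability hits the target.

    For the normal laws the expectation reduces to a one-dimensional
    Gauss-Hermite quadrature (the linear predictor minus beta0 is normal);
    for Bernoulli covariates it is an exact enumeration over the 2^P
    support.  Root-finding is accurate to well below 1e-4 on the
    prevalence scale.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")
    gh = hermgauss(80)

    def f(b0: float) -> float:
        return _prevalence(b0, coefficients, covariate_law, correlation, gh) - target_prevalence

    return float(brentq(f, -40.0, 40.0, xtol=1e-10))
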