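"""Detection of complete and quasi-complete separation.

Four detectors are provided:

* ``detect_tracing`` — the re-estimation (tracing) diagnostic: refit by
  ML with iteration caps 1..30 and flag when the variance of
  first-iteration-scaled standard errors explodes.
* ``detect_threshold`` — flag when any slope estimate exceeds log(50) in
  magnitude.
* ``detect_nonconvergence`` — flag fits that did not meet the deviance
  tolerance within the iteration cap.
* ``detect_exact`` — an exact linear-programming oracle for the
  complete / quasi-complete / overlap taxonomy: a dataset is completely
  separated iff some direction b strictly separates events from
  non-events in the intercept-augmented design, quasi-completely
  separated iff separation holds with ties on at least one point, and
  overlapped (finite MLE exists) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .estimators import FitResult, ml_scoring_path

__all__ = [
    "TraceDiagnostics",
    "SeparationVerdict",
    "detect_tracing",
    "detect_threshold",
    "detect_nonconvergence",
    "detect_exact",
    "DetectorUnavailableError",
    "NONE",
    "QUASI_COMPLETE",
    "COMPLETE",
]

NONE = "none"
QUASI_COMPLETE = "quasi_complete"
COMPLETE = "complete"

_LP_EPS = 1e-9  # strictness threshold guarding against solver round-off

DEFAULT_THRESHOLD_CUTOFF = float(np.log(50.0))


class DetectorUnavailableError(RuntimeError):
    """The LP solver failed; the exact verdict is unknown."""


@dataclass
class TraceDiagnostics:
    """Standard-error paths over capped refits, one column per parameter."""

    se_paths: np.ndarray  # shape (n_refits, n_params)
    scaled_variances: np.ndarray  # per-parameter variance of SE_k / SE_1

    @property
    def n_refits(self) -> int:
        return self.se_paths.shape[0]


@dataclass
class SeparationVerdict:
    tracing: bool = False
    threshold: bool = False
    nonconvergence: bool = False
    exact: str = NONE
    flagged_parameters: frozenset = field(default_factory=frozenset)


def detect_tracing(data, n_refits: int = 30, cutoff: float = 20.0,
                   tol: float | None = 1e-8):
    """Flag separation from the divergence of ML standard errors.

    The model is refit with iteration caps k = 1..n_refits.  Each
    parameter's SE path is scaled by its value at k = 1; separation is
    declared when any parameter's sample variance of the scaled path
    exceeds ``cutoff``.  On overlapped data the SEs stabilize after a few
    iterations, so the scaled variance stays near zero; on separated data
    the SEs grow without bound.

    By default each capped refit also honours the usual deviance
    tolerance, exactly as a ``glm(..., maxit=k)`` refit would, so the SE
    path flattens once the fit converges; pass ``tol=None`` to force
    exactly k scoring iterations per refit instead.

    Returns ``(flagged, TraceDiagnostics)``.
    """
    path = ml_scoring_path(data, n_refits, tol=tol)
    se_paths = np.vstack([se for _, se in path])
    base = se_paths[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = se_paths / base
    # non-finite SEs mean the information matrix already collapsed:
    # the path has diverged, which the cutoff is meant to catch
    bad = ~np.all(np.isfinite(scaled), axis=0)
    variances = np.empty(se_paths.shape[1])
    variances[bad] = np.inf
    if (~bad).any():
        variances[~bad] = np.var(scaled[:, ~bad], axis=0, ddof=1)
    flagged_params = frozenset(int(j) for j in np.nonzero(variances > cutoff)[0])
    diag = TraceDiagnostics(se_paths=se_paths, scaled_variances=variances)
    return bool(flagged_params), diag


def detect_threshold(fit: FitResult, cutoff: float = DEFAULT_THRESHOLD_CUTOFF) -> bool:
    """Flag when any non-intercept coefficient exceeds the cutoff in magnitude."""
    return bool(np.any(np.abs(fit.coefficients[1:]) > cutoff))


def detect_nonconvergence(fit: FitResult) -> bool:
    """Flag fits whose deviance criterion was not met within the cap."""
    return not fit.converged


def _lp(c, A_ub, b_ub, bounds):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise DetectorUnavailableError(f"LP solver failed: {res.message}")
    return -res.fun  # linprog minimizes


def detect_exact(data) -> str:
    """Exact separation taxonomy via two linear programs.

    With s_i = 2 y_i - 1 and Z the intercept-augmented design, the data
    are completely separated iff max { t : s_i (Z_i b) >= t, |b|_inf <= 1 }
    is strictly positive.  Otherwise they are quasi-completely separated
    iff max { sum u_i : s_i (Z_i b) >= u_i, 0 <= u_i <= 1, |b|_inf <= 1 }
    is strictly positive (some points strictly classified, none
    misclassified).  If both optima are zero the classes overlap and a
    finite MLE exists.
    """
    X = np.asarray(data.X, dtype=float)
    y = np.asarray(data.y, dtype=float)
    n = X.shape[0]
    Z = np.column_stack([np.ones(n), X])
    s = 2.0 * y - 1.0
    SZ = s[:, None] * Z
    m = Z.shape[1]

    # LP-1: maximize t subject to s_i Z_i b - t >= 0, |b|_inf <= 1
    c1 = np.zeros(m + 1)
    c1[-1] = -1.0
    A1 = np.hstack([-SZ, np.ones((n, 1))])
    t_opt = _lp(c1, A1, np.zeros(n), [(-1, 1)] * m + [(None, None)])
    if t_opt > _LP_EPS:
        return COMPLETE

    # LP-2: maximize sum u_i subject to u_i - s_i Z_i b <= 0, 0 <= u_i <= 1
    c2 = np.concatenate([np.zeros(m), -np.ones(n)])
    A2 = np.hstack([-SZ, np.eye(n)])
    u_opt = _lp(c2, A2, np.zeros(n), [(-1, 1)] * m + [(0, 1)] * n)
    if u_opt > _LP_EPS:
        return QUASI_COMPLETE
    return NONE
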