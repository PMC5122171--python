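"""Factorial simulation studies of logistic regression at low EPV.

Six study designs are built in.  Part I varies events-per-variable (EPV),
true effect size, covariate count, outcome prevalence and covariate
correlation with continuous covariates, where separation is rare:

* ``Ia`` — EPV 15..150 (step 5) x odds ratio in {1/4, 1/2, 1, 2, 4},
  one standard-normal covariate, prevalence 1/2.
* ``Ib`` — same EPV grid x P in {2, 3, 4} x odds ratio in {2, 4} (all
  slopes equal), independent standard normal, prevalence 1/2.
* ``Ic`` — EPV 6..30 (step 2) x prevalence in {1/2, 1/3, 1/4, 1/5, 1/10},
  P = 2, odds ratio 2, uncorrelated.
* ``Id`` — EPV 6..30 (step 2) x correlation in {0.10, 0.15, 0.20, 0.25},
  P = 2, odds ratio 2, prevalence 1/4.

Part II probes separation detection and handling:

* ``IIa`` — EPV 6..30 (step 2) x beta1 in {log 1, log 2, log 4}, one
  Bernoulli(0.5) covariate, events:non-events 1:1.
* ``IIb`` — a single cell: EPV 4, one standard-normal covariate,
  beta1 = log 4, 4 events and 4 non-events per dataset; used to compare
  detectors and convergence criteria head to head.

Every replicate gets its own RNG stream derived from
(master seed, study, scenario index, replicate index), so results are
identical regardless of execution order or parallelism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import norm

from . import datagen
from .datagen import Dataset, SamplingSpec, TrueModel, calibrate_intercept, sample_quota
from .estimators import (
    CONVERGENCE_PRESETS,
    ConfidenceInterval,
    ConvergenceSpec,
    fit_firth,
    fit_ml,
    profile_ci,
    wald_ci,
)
from .metrics import ScenarioSummary, summarize
from .separation import detect_exact, detect_nonconvergence, detect_threshold, detect_tracing

__all__ = [
    "Scenario",
    "HandlingPolicy",
    "build_grid",
    "run_scenario",
    "run_study",
    "run_study_iib",
    "DegenerateScenarioError",
    "STUDY_IDS",
]

STUDY_IDS = ("Ia", "Ib", "Ic", "Id", "IIa", "IIb")
_STUDY_CODE = {sid: i + 1 for i, sid in enumerate(STUDY_IDS)}
_STUDY_CODE["custom"] = 0

#: detectors usable inside a handling policy (comma-join to OR them)
_DETECTORS = ("tracing", "threshold", "nonconvergence", "exact")


class DegenerateScenarioError(RuntimeError):
    """Every replicate of a scenario was flagged under a remove policy."""


@dataclass(frozen=True)
class Scenario:
    """One simulation cell: generating model, EPV, sizes, seed."""

    study_id: str
    epv: float
    p: int
    prevalence: float
    true_model: TrueModel
    n_reps: int = 10_000
    master_seed: int = 0
    scenario_index: int = 0

    @property
    def n_events(self) -> int:
        n_ev = self.epv * self.p
        if abs(n_ev - round(n_ev)) > 1e-9:
            raise ValueError("EPV x P must be an integer event count")
        return int(round(n_ev))

    @property
    def n_total(self) -> int:
        # nearest-integer rounding when 1/prevalence is not integral
        return int(round(self.n_events / self.prevalence))

    def replicate_seed(self, rep: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            entropy=self.master_seed,
            spawn_key=(_STUDY_CODE.get(self.study_id, 0), self.scenario_index, rep),
        )

    def sample(self, rep: int) -> Dataset:
        spec = SamplingSpec(self.n_total, self.n_events, self.replicate_seed(rep))
        return sample_quota(self.true_model, spec)


@dataclass(frozen=True)
class HandlingPolicy:
    """What to do with flagged datasets when summarizing ML results.

    tag
        ``remove`` (drop flagged replicates), ``keep_naive`` (use the
        software's last iterate regardless of flags) or ``replace_max``
        (substitute flagged primary estimates with the largest
        non-flagged estimate in the same scenario).
    detector
        Which flags to react to: one of tracing / threshold /
        nonconvergence / exact, or several joined by commas (OR).
    """

    tag: str = "remove"
    detector: str = "tracing,nonconvergence"
    use_absolute: bool = False  # replace_max on |estimate| for negative effects

    def __post_init__(self):
        if self.tag not in ("remove", "keep_naive", "replace_max"):
            raise ValueError(f"unknown handling tag {self.tag!r}")
        for d in self.detectors:
            if d not in _DETECTORS:
                raise ValueError(f"unknown detector {d!r}")

    @property
    def detectors(self) -> tuple[str, ...]:
        return tuple(d.strip() for d in self.detector.split(",") if d.strip())

    @property
    def label(self) -> str:
        return f"{self.tag}[{self.detector}]" if self.tag != "keep_naive" else "keep_naive"


DEFAULT_POLICIES = (
    HandlingPolicy("remove", "tracing,nonconvergence"),
    HandlingPolicy("keep_naive", "tracing"),
)


def _model(beta: tuple[float, ...], law: str, prevalence: float, rho: float = 0.0) -> TrueModel:
    b0 = calibrate_intercept(beta, law, prevalence, correlation=rho)
    return TrueModel(intercept=b0, coefficients=beta, covariate_law=law, correlation=rho)


def build_grid(study_id: str, n_reps: int = 10_000, master_seed: int = 0) -> list[Scenario]:
    """Full factor crossing for one of the built-in studies."""
    epv_coarse = tuple(range(15, 151, 5))
    epv_fine = tuple(range(6, 31, 2))
    cells: list[dict] = []
    if study_id == "Ia":
        for epv, or1 in itertools.product(epv_coarse, (0.25, 0.5, 1.0, 2.0, 4.0)):
            cells.append(dict(epv=epv, p=1, prevalence=0.5,
                              beta=(float(np.log(or1)),), law=datagen.NORMAL))
    elif study_id == "Ib":
        for epv, p, orj in itertools.product(epv_coarse, (2, 3, 4), (2.0, 4.0)):
            cells.append(dict(epv=epv, p=p, prevalence=0.5,
                              beta=(float(np.log(orj)),) * p, law=datagen.NORMAL))
    elif study_id == "Ic":
        for epv, prev in itertools.product(epv_fine, (1 / 2, 1 / 3, 1 / 4, 1 / 5, 1 / 10)):
            cells.append(dict(epv=epv, p=2, prevalence=prev,
                              beta=(float(np.log(2.0)),) * 2, law=datagen.NORMAL))
    elif study_id == "Id":
        for epv, rho in itertools.product(epv_fine, (0.10, 0.15, 0.20, 0.25)):
            cells.append(dict(epv=epv, p=2, prevalence=0.25,
                              beta=(float(np.log(2.0)),) * 2,
                              law=datagen.EQUICORR_NORMAL, rho=rho))
    elif study_id == "IIa":
        for epv, or1 in itertools.product(epv_fine, (1.0, 2.0, 4.0)):
            cells.append(dict(epv=epv, p=1, prevalence=0.5,
                              beta=(float(np.log(or1)),), law=datagen.BERNOULLI))
    elif study_id == "IIb":
        cells.append(dict(epv=4, p=1, prevalence=0.5,
                          beta=(float(np.log(4.0)),), law=datagen.NORMAL))
    else:
        raise ValueError(f"unknown study {study_id!r}")
    scenarios = []
    for idx, cell in enumerate(cells):
        model = _model(cell["beta"], cell["law"], cell["prevalence"], cell.get("rho", 0.0))
        scenarios.append(
            Scenario(
                study_id=study_id,
                epv=float(cell["epv"]),
                p=cell["p"],
                prevalence=cell["prevalence"],
                true_model=model,
                n_reps=n_reps,
                master_seed=master_seed,
                scenario_index=idx,
            )
        )
    return scenarios


def simulate_replicates(
    scenario: Scenario,
    conv: ConvergenceSpec = CONVERGENCE_PRESETS["default"],
    compute_profile_ci: bool = True,
    with_exact: bool = True,
    extra_conv: dict[str, ConvergenceSpec] | None = None,
) -> pd.DataFrame:
    """Per-replicate fits, intervals and separation verdicts.

    ``extra_conv`` maps labels to additional convergence specs; for each,
    an extra ML fit is recorded (estimate, SE, converged flag) so that
    non-convergence-based removal can be compared across criteria.
    """
    rows = []
    for rep in range(scenario.n_reps):
        data = scenario.sample(rep)
        if np.linalg.matrix_rank(np.column_stack([np.ones(data.n), data.X])) < data.p + 1:
            # constant covariate column (possible with Bernoulli draws at
            # tiny n): the slope is unidentifiable for both estimators —
            # recorded as degenerate and excluded by every policy
            row = {"rep": rep, "degenerate": True,
                   "ml_est": np.nan, "ml_se": np.nan, "ml_converged": False,
                   "wald_lower": np.nan, "wald_upper": np.nan,
                   "firth_est": np.nan, "firth_se": np.nan,
                   "tracing": True, "threshold": True, "nonconvergence": True}
            if compute_profile_ci:
                row["profile_lower"] = np.nan
                row["profile_upper"] = np.nan
            if with_exact:
                row["exact"] = "degenerate"
            if extra_conv:
                for label in extra_conv:
                    row[f"ml_est_{label}"] = np.nan
                    row[f"ml_se_{label}"] = np.nan
                    row[f"nonconvergence_{label}"] = True
            rows.append(row)
            continue
        mlfit = fit_ml(data, conv)
        ffit = fit_firth(data, conv)
        wci = wald_ci(mlfit, index=1, level=0.90)
        tracing_flag, _ = detect_tracing(data)
        row = {
            "rep": rep,
            "degenerate": False,
            "ml_est": mlfit.coefficients[1],
            "ml_se": mlfit.standard_errors[1],
            "ml_converged": mlfit.converged,
            "wald_lower": wci.lower,
            "wald_upper": wci.upper,
            "firth_est": ffit.coefficients[1],
            "firth_se": ffit.standard_errors[1],
            "tracing": tracing_flag,
            "threshold": detect_threshold(mlfit),
            "nonconvergence": detect_nonconvergence(mlfit),
        }
        if compute_profile_ci:
            # separated low-N datasets can put the upper endpoint far out in
            # the flat tail of the penalized profile; search a wide window
            pci = profile_ci(data, ffit, index=1, level=0.90, max_range=500.0)
            row["profile_lower"] = pci.lower
            row["profile_upper"] = pci.upper
        if with_exact:
            row["exact"] = detect_exact(data)
        if extra_conv:
            for label, spec in extra_conv.items():
                efit = fit_ml(data, spec)
                row[f"ml_est_{label}"] = efit.coefficients[1]
                row[f"ml_se_{label}"] = efit.standard_errors[1]
                row[f"nonconvergence_{label}"] = not efit.converged
        rows.append(row)
    return pd.DataFrame(rows)


def _flag_mask(reps: pd.DataFrame, policy: HandlingPolicy) -> np.ndarray:
    mask = np.zeros(len(reps), dtype=bool)
    for det in policy.detectors:
        if det == "exact":
            mask |= (reps["exact"] != "none").to_numpy()
        else:
            mask |= reps[det].to_numpy(dtype=bool)
    return mask


def _intervals(lower: np.ndarray, upper: np.ndarray, kind: str) -> list[ConfidenceInterval]:
    return [ConfidenceInterval(lo, up, 0.90, kind) for lo, up in zip(lower, upper)]


def summarize_policies(
    reps: pd.DataFrame,
    scenario: Scenario,
    policies=DEFAULT_POLICIES,
) -> list[ScenarioSummary]:
    """ML summaries per handling policy plus the all-data Firth summary."""
    true_b1 = scenario.true_model.coefficients[0]
    labels = dict(scenario_id=f"{scenario.study_id}:{scenario.scenario_index}", epv=scenario.epv)
    if "degenerate" in reps.columns:
        # unidentifiable datasets carry no estimate under either method
        reps = reps[~reps["degenerate"].astype(bool)].reset_index(drop=True)
    n_nonconv = int(reps["nonconvergence"].sum())
    out = []
    for policy in policies:
        flags = _flag_mask(reps, policy)
        est = reps["ml_est"].to_numpy(dtype=float)
        lo = reps["wald_lower"].to_numpy(dtype=float)
        up = reps["wald_upper"].to_numpy(dtype=float)
        if policy.tag == "remove":
            keep = ~flags
            if not keep.any():
                raise DegenerateScenarioError(
                    f"all replicates flagged in {labels['scenario_id']}"
                )
            est, lo, up = est[keep], lo[keep], up[keep]
        elif policy.tag == "replace_max":
            if (~flags).any():
                pool = est[~flags]
                repl = pool[np.abs(pool).argmax()] if policy.use_absolute else pool.max()
                est = est.copy()
                est[flags] = repl
        out.append(
            summarize(
                est,
                _intervals(lo, up, "wald"),
                true_b1,
                estimator="ML",
                handling=policy.label,
                n_separated=int(flags.sum()),
                n_nonconverged=n_nonconv,
                **labels,
            )
        )
    # Firth always uses every dataset
    if "profile_lower" in reps.columns:
        fints = _intervals(
            reps["profile_lower"].to_numpy(dtype=float),
            reps["profile_upper"].to_numpy(dtype=float),
            "profile",
        )
    else:
        fints = [ConfidenceInterval(np.nan, np.nan, 0.90, "profile")] * len(reps)
    out.append(
        summarize(
            reps["firth_est"].to_numpy(dtype=float),
            fints,
            true_b1,
            estimator="Firth",
            handling="all",
            n_separated=0,
            n_nonconverged=0,
            **labels,
        )
    )
    return out


def run_scenario(
    scenario: Scenario,
    conv: ConvergenceSpec = CONVERGENCE_PRESETS["default"],
    policies=DEFAULT_POLICIES,
    compute_profile_ci: bool = True,
    with_exact: bool = True,
    return_replicates: bool = False,
):
    """Simulate one scenario and summarize per estimator x policy."""
    reps = simulate_replicates(
        scenario, conv, compute_profile_ci=compute_profile_ci, with_exact=with_exact
    )
    summaries = summarize_policies(reps, scenario, policies)
    if return_replicates:
        return summaries, reps
    return summaries


def run_study(
    study_id: str,
    n_reps: int = 10_000,
    master_seed: int = 0,
    conv: ConvergenceSpec = CONVERGENCE_PRESETS["default"],
    policies=DEFAULT_POLICIES,
    compute_profile_ci: bool = True,
    with_exact: bool = True,
    n_jobs: int = 1,
    scenarios: list[Scenario] | None = None,
) -> pd.DataFrame:
    """Run every scenario of a study and return a tidy summary table."""
    if scenarios is None:
        scenarios = build_grid(study_id, n_reps=n_reps, master_seed=master_seed)

    def one(s):
        return run_scenario(
            s, conv, policies, compute_profile_ci=compute_profile_ci, with_exact=with_exact
        )

    if n_jobs == 1:
        per_scenario = [one(s) for s in scenarios]
    else:
        per_scenario = Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in scenarios)
    rows = []
    for s, summaries in zip(scenarios, per_scenario):
        for summ in summaries:
            d = summ.to_dict()
            d.update(
                study_id=s.study_id,
                scenario_index=s.scenario_index,
                p=s.p,
                prevalence=s.prevalence,
                n_total=s.n_total,
                n_events=s.n_events,
                true_beta1=s.true_model.coefficients[0],
                correlation=s.true_model.correlation,
            )
            rows.append(d)
    return pd.DataFrame(rows)


#: study IIb comparison columns: estimator, detector used for removal,
#: convergence spec for the ML fit
IIB_COLUMNS = (
    ("firth", None, "default"),
    ("ml", "tracing", "default"),
    ("ml", "threshold", "default"),
    ("ml", "nonconvergence", "default"),
    ("ml", "nonconvergence", "typeI"),
    ("ml", "nonconvergence", "typeII"),
    ("ml", "nonconvergence", "typeIII"),
)


def run_study_iib(
    n_reps: int = 10_000,
    master_seed: int = 0,
    compute_profile_ci: bool = True,
    with_exact: bool = False,
    return_replicates: bool = False,
):
    """Head-to-head comparison of separation detectors on the IIb cell.

    Returns a table with one column per approach (Firth on all data; ML
    with tracing, threshold or non-convergence removal, the latter under
    four convergence criteria) and rows: percent of datasets removed,
    bias, coverage and mean width of the 90% interval, and MSE.
    """
    scenario = build_grid("IIb", n_reps=n_reps, master_seed=master_seed)[0]
    extra = {k: v for k, v in CONVERGENCE_PRESETS.items() if k != "default"}
    reps = simulate_replicates(
        scenario,
        CONVERGENCE_PRESETS["default"],
        compute_profile_ci=compute_profile_ci,
        with_exact=with_exact,
        extra_conv=extra,
    )
    reps = reps[~reps["degenerate"].astype(bool)].reset_index(drop=True)
    true_b1 = scenario.true_model.coefficients[0]
    cols = {}
    for est, detector, conv_name in IIB_COLUMNS:
        if est == "firth":
            if compute_profile_ci:
                ints = _intervals(
                    reps["profile_lower"].to_numpy(), reps["profile_upper"].to_numpy(), "profile"
                )
            else:
                ints = [ConfidenceInterval(np.nan, np.nan, 0.90, "profile")] * len(reps)
            summ = summarize(reps["firth_est"].to_numpy(), ints, true_b1,
                             estimator="Firth", handling="all")
            removed_pct = 0.0
        else:
            suffix = "" if conv_name == "default" else f"_{conv_name}"
            est_col = reps[f"ml_est{suffix}"].to_numpy(dtype=float)
            se_col = reps[f"ml_se{suffix}"].to_numpy(dtype=float)
            if detector == "nonconvergence":
                flags = reps[f"nonconvergence{suffix}"].to_numpy(dtype=bool)
            else:
                flags = reps[detector].to_numpy(dtype=bool)
            keep = ~flags
            z = float(norm.ppf(0.5 * (1.0 + 0.90)))
            ints = _intervals(est_col[keep] - z * se_col[keep],
                              est_col[keep] + z * se_col[keep], "wald")
            summ = summarize(est_col[keep], ints, true_b1,
                             estimator="ML", handling=f"remove[{detector}:{conv_name}]",
                             n_separated=int(flags.sum()))
            removed_pct = 100.0 * float(flags.mean())
        name = est if est == "firth" else f"ml_{detector}_{conv_name}"
        cols[name] = {
            "removed_pct": removed_pct,
            "bias": summ.bias,
            "coverage": summ.coverage,
            "mean_width": summ.mean_ci_width,
            "mse": summ.mse,
        }
    table = pd.DataFrame(cols)
    if return_replicates:
        return table, reps
    return table
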