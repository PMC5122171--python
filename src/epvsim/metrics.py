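"""Accuracy summaries for collections of simulated fits.

For the primary coefficient beta1 with true value b, a set of estimates
{beta1_hat} and 90% confidence intervals yields

* bias            = mean(beta1_hat) - b
* relative bias   = bias / b                (undefined when b = 0)
* coverage        = fraction of intervals containing b
* mean CI width   = mean(upper - lower)
* MSE             = bias^2 + SD(beta1_hat)^2   (sample SD, n-1)
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .estimators import ConfidenceInterval

__all__ = ["ScenarioSummary", "summarize", "aggregate"]


@dataclass
class ScenarioSummary:
    bias: float
    relative_bias: float  # fraction; multiply by 100 for percent
    coverage: float
    mean_ci_width: float
    mse: float
    n_used: int
    n_separated: int = 0
    n_nonconverged: int = 0
    estimator: str = ""
    handling: str = ""
    scenario_id: str = ""
    epv: float = np.nan
    true_value: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(estimates: Sequence[float],
              intervals: Sequence[ConfidenceInterval],
              true_value: float,
              **labels) -> ScenarioSummary:
    """Compute the five accuracy quantities for one scenario cell.

    Extra keyword arguments (estimator, handling, n_separated, ...) are
    stored on the returned summary unchanged.
    """
    est = np.asarray(estimates, dtype=float)
    if len(est) != len(intervals):
        raise ValueError("estimates and intervals are not aligned")
    if len(est) < 2:
        raise ValueError("need at least two estimates to summarize")
    bias = float(est.mean() - true_value)
    rel = bias / true_value if true_value != 0.0 else np.nan
    cover = float(np.mean([ci.contains(true_value) for ci in intervals]))
    width = float(np.mean([ci.width for ci in intervals]))
    sd = float(est.std(ddof=1))
    mse = bias**2 + sd**2
    return ScenarioSummary(
        bias=bias,
        relative_bias=rel,
        coverage=cover,
        mean_ci_width=width,
        mse=mse,
        n_used=len(est),
        true_value=float(true_value),
        **labels,
    )


def aggregate(summaries: Iterable[ScenarioSummary],
              epv_band: Sequence[float] | None = None,
              nominal: float = 0.90,
              include_zero_effect_bias: bool = True) -> dict:
    """Banded averages and extrema over scenario summaries.

    Relative-bias statistics always exclude scenarios whose true
    coefficient is zero (relative bias is undefined there); the
    ``include_zero_effect_bias`` switch controls whether those scenarios
    enter the absolute-bias rows.
    """
    rows = [s for s in summaries]
    if epv_band is not None:
        band = set(float(e) for e in epv_band)
        rows = [s for s in rows if float(s.epv) in band]
    if not rows:
        raise ValueError("empty scenario band")
    bias_rows = rows if include_zero_effect_bias else [s for s in rows if s.true_value != 0.0]
    rel_rows = [s for s in rows if s.true_value != 0.0]

    def stats(values):
        v = np.asarray(values, dtype=float)
        return {"mean": float(v.mean()), "max": float(v.max()), "min": float(v.min())}

    out = {
        "n_scenarios": len(rows),
        "bias": stats([s.bias for s in bias_rows]),
        "coverage_pct": stats([100.0 * s.coverage for s in rows]),
        "mean_ci_width": stats([s.mean_ci_width for s in rows]),
        "mse": stats([s.mse for s in rows]),
        "pct_coverage_outside_nominal": 100.0
        * float(np.mean([abs(100.0 * s.coverage - 100.0 * nominal) > 1.0 for s in rows])),
        "separated_total_pct": 100.0
        * float(sum(s.n_separated for s in rows))
        / float(sum(s.n_separated + s.n_used for s in rows)),
    }
    if rel_rows:
        out["relative_bias_pct"] = stats([100.0 * s.relative_bias for s in rel_rows])
        out["pct_rel_bias_above_10"] = 100.0 * float(
            np.mean([100.0 * s.relative_bias > 10.0 for s in rel_rows])
        )
    return out


def summaries_to_frame(summaries: Iterable[ScenarioSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
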