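"""Canonical small datasets used across tests and examples."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datagen import Dataset, SamplingSpec, TrueModel, sample_quota

__all__ = ["make_fixtures", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "cells_5555",
    "cells_6446",
    "complete_sep",
    "quasi_sep",
    "overlap_2x2",
    "overlapped_200",
)


def _table_2x2(n11: int, n01: int, n10: int, n00: int) -> Dataset:
    """events at x=1, events at x=0, non-events at x=1, non-events at x=0."""
    x = np.concatenate([np.ones(n11), np.zeros(n01), np.ones(n10), np.zeros(n00)])
    y = np.concatenate([np.ones(n11 + n01, dtype=int), np.zeros(n10 + n00, dtype=int)])
    return Dataset(X=x[:, None], y=y)


def make_fixtures(seed: int = 0, out_dir=None) -> dict[str, Dataset]:
    """Build the canonical test datasets; optionally write them as CSV.

    * ``cells_5555`` — symmetric 2x2 table (5 per cell): both estimators
      give a zero slope.
    * ``cells_6446`` — 2x2 table with cells (6, 4, 4, 6): ML slope is
      log(2.25), Firth slope is the add-1/2 corrected log odds ratio.
    * ``complete_sep`` — x = (-2, -1, 1, 2), y = (0, 0, 1, 1).
    * ``quasi_sep`` — x = (0, 0, 1), y = (0, 1, 1).
    * ``overlap_2x2`` — both classes at both covariate levels.
    * ``overlapped_200`` — 200 quota-sampled rows, beta1 = log 2,
      standard-normal covariate, 100 events; comfortably overlapped.
    """
    fixtures = {
        "cells_5555": _table_2x2(5, 5, 5, 5),
        "cells_6446": _table_2x2(6, 4, 4, 6),
        "complete_sep": Dataset(X=np.array([[-2.0], [-1.0], [1.0], [2.0]]),
                                y=np.array([0, 0, 1, 1])),
        "quasi_sep": Dataset(X=np.array([[0.0], [0.0], [1.0]]), y=np.array([0, 1, 1])),
        "overlap_2x2": Dataset(X=np.array([[0.0], [1.0], [0.0], [1.0]]),
                               y=np.array([0, 0, 1, 1])),
        "overlapped_200": sample_quota(
            TrueModel(0.0, (float(np.log(2.0)),), "normal"),
            SamplingSpec(200, 100, np.random.SeedSequence(seed, spawn_key=(99,))),
        ),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, ds in fixtures.items():
            ds.to_csv(out / f"{name}.csv")
    return fixtures
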