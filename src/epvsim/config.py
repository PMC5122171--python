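"""Run configuration: serializable description of a simulation run."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .studies import DEFAULT_POLICIES, HandlingPolicy

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run.

    A copy of the resolved config is written into the output directory of
    every run, so any result file can be traced back to the exact grid,
    seed and policies that produced it.
    """

    study: str = "IIb"
    n_reps: int = 10_000
    master_seed: int = 0
    convergence: list[str] = field(default_factory=lambda: ["default"])
    policies: list[dict] = field(default_factory=lambda: [
        dataclasses.asdict(p) for p in DEFAULT_POLICIES
    ])
    output_dir: str = "results"
    keep_replicates: bool = False
    compute_profile_ci: bool = True
    with_exact: bool = False
    n_jobs: int = 1

    def handling_policies(self) -> list[HandlingPolicy]:
        return [HandlingPolicy(**p) for p in self.policies]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
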