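"""Declarative run configuration with explicit seeding.

A :class:`RunConfig` captures everything needed to reproduce a run: the
cohort simulation parameters, the encryption parameter request, output
paths, milestones, and one master seed.  The master seed fans out to
per-stage generators through ``numpy.random.SeedSequence`` spawning, so
every stage is independently reproducible and no stage ever seeds from
the wall clock.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortParams

__all__ = ["RunConfig", "stage_rngs", "STAGES"]

STAGES = ("simulate", "keygen", "encrypt", "exposure", "timing")


def stage_rngs(master_seed: int) -> dict[str, np.random.Generator]:
    """Per-stage generators spawned deterministically from one seed."""
    seqs = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(STAGES, seqs)}


@dataclass
class RunConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    security_bits: int = 128
    mult_depth: int = 1
    max_value: int = 1000
    seed: int = 0
    out_dir: str = "hecohort-out"
    milestones: list = field(default_factory=lambda: [10, "all"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cohort_raw = raw.pop("cohort", {})
        cohort_known = {f.name for f in fields(CohortParams)}
        bad = set(cohort_raw) - cohort_known
        if bad:
            raise ValueError(f"unknown cohort keys: {sorted(bad)}")
        return cls(cohort=CohortParams(**cohort_raw), **raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def out_path(self, name: str) -> Path:
        d = Path(self.out_dir)
        d.mkdir(parents=True, exist_ok=True)
        return d / name
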