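"""Experimental design: differentiation stages and their replicate samples.

A :class:`StageDesign` maps each RNA-seq sample to one differentiation
stage (e.g. ES, DE, OD5, OD7, OD10 — embryonic stem cells, definitive
endoderm, and organoids from day-5/7/10 spheroids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class StageDesign:
    """Ordered stages with per-stage replicate counts.

    Sample identifiers are derived as ``<stage>_r<replicate>`` and are
    guaranteed unique; every sample belongs to exactly one stage.
    """

    stages: tuple[str, ...]
    replicates: tuple[int, ...]
    sample_ids: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.stages) == 0:
            raise ValueError("design needs at least one stage")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage labels")
        if len(self.replicates) != len(self.stages):
            raise ValueError("one replicate count per stage required")
        if any(r < 1 for r in self.replicates):
            raise ValueError("replicate counts must be >= 1")
        ids = tuple(
            f"{stage}_r{i + 1}"
            for stage, reps in zip(self.stages, self.replicates)
            for i in range(reps)
        )
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return sum(self.replicates)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def stage_of(self) -> dict[str, str]:
        """Map sample id -> stage label."""
        out: dict[str, str] = {}
        for stage, reps in zip(self.stages, self.replicates):
            for i in range(reps):
                out[f"{stage}_r{i + 1}"] = stage
        return out

    def samples_of(self, stage: str) -> list[str]:
        if stage not in self.stages:
            raise KeyError(f"unknown stage {stage!r}")
        reps = self.replicates[self.stages.index(stage)]
        return [f"{stage}_r{i + 1}" for i in range(reps)]


def generate_design(stages: Sequence[str], replicates: Sequence[int] | int) -> StageDesign:
    """Build a :class:`StageDesign`.

    ``replicates`` may be a single integer (same count for every stage)
    or one count per stage.
    """
    stages = tuple(stages)
    if isinstance(replicates, int):
        reps = tuple([replicates] * len(stages))
    else:
        reps = tuple(int(r) for r in replicates)
    return StageDesign(stages=stages, replicates=reps)
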