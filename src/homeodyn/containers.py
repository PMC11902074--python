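"""Shared tabular containers: the sample design and the gene x sample count matrix.

These are the two objects every downstream stage consumes.  A
:class:`SampleDesign` binds sample names to (stage, replicate); a
:class:`CountMatrix` wraps an integer pandas DataFrame whose columns follow
that design, optionally carrying gene lengths for FPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_STAGES = ("0M", "5M", "12M", "EC", "BC")


@dataclass(frozen=True)
class SampleDesign:
    """Ordered stages and a fixed replicate count per stage.

    Sample identifiers are canonical ``<stage>_<rep>`` strings with
    1-based replicate numbers, e.g. ``EC_2``.
    """

    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates: int = 3

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("design needs at least 2 stages")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("duplicate stage names")
        if self.replicates < 2:
            raise ValueError("design needs at least 2 replicates per stage")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def sample_ids(self) -> list[str]:
        return [f"{s}_{r}" for s in self.stages for r in range(1, self.replicates + 1)]

    def samples_for_stage(self, stage: str) -> list[str]:
        if stage not in self.stages:
            raise KeyError(f"stage {stage!r} not in design {self.stages}")
        return [f"{stage}_{r}" for r in range(1, self.replicates + 1)]

    def stage_of(self, sample_id: str) -> str:
        stage, _, rep = sample_id.rpartition("_")
        if stage not in self.stages or not rep.isdigit():
            raise KeyError(f"sample {sample_id!r} does not match design")
        return stage

    @property
    def consecutive_comparisons(self) -> list[tuple[str, str]]:
        """(numerator, denominator) pairs for each consecutive stage step."""
        return [(self.stages[i + 1], self.stages[i]) for i in range(len(self.stages) - 1)]


@dataclass
class CountMatrix:
    """Integer counts (genes x samples) bound to a :class:`SampleDesign`.

    ``gene_lengths`` (bp, indexed like ``counts``) is optional and only
    required for FPKM.
    """

    counts: pd.DataFrame
    design: SampleDesign
    gene_lengths: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        expected = self.design.sample_ids
        missing = [s for s in expected if s not in self.counts.columns]
        if missing:
            raise ValueError(f"count matrix missing design samples: {missing}")
        extra = [c for c in self.counts.columns if c not in expected]
        if extra:
            raise ValueError(f"count matrix has columns not in design: {extra}")
        self.counts = self.counts.loc[:, expected]
        if not self.counts.index.is_unique:
            raise ValueError("duplicate gene ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def stage_columns(self, stage: str) -> pd.DataFrame:
        return self.counts[self.design.samples_for_stage(stage)]
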