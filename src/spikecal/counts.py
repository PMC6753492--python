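"""Dual-genome tagged count matrices.

A :class:`TaggedCounts` holds a genes x samples integer count matrix in
which every gene carries a genome-of-origin tag: ``"target"`` for the
experimental genome (e.g. mm10) or ``"spike"`` for the exogenous spike-in
genome (e.g. dm6 or hg19). Sample metadata records the condition, the assay
and, for assay samples, the name of the matched input-gDNA sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

TARGET = "target"
SPIKE = "spike"
_VALID_TAGS = frozenset({TARGET, SPIKE})


@dataclass
class TaggedCounts:
    """Gene x sample count matrix with a genome tag per gene.

    Parameters
    ----------
    counts
        Non-negative integer matrix, index = gene ids, columns = sample names.
    genome
        Series aligned to ``counts.index`` with values ``"target"`` or
        ``"spike"``.
    samples
        Optional per-sample metadata aligned to ``counts.columns``.
        Recognised columns: ``condition``, ``assay``, ``matched_input``.
    """

    counts: pd.DataFrame
    genome: pd.Series
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene ids in counts")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if not np.isfinite(vals).all():
            raise ValidationError("counts contain non-finite values")
        if (vals < 0).any():
            raise ValidationError("counts contain negative values")
        self.genome = pd.Series(self.genome)
        if not self.genome.index.equals(self.counts.index):
            self.genome = self.genome.reindex(self.counts.index)
        if self.genome.isna().any():
            raise ValidationError("every gene needs a genome tag")
        bad = set(self.genome.unique()) - _VALID_TAGS
        if bad:
            raise ValidationError(f"unknown genome tags: {sorted(bad)}")
        if len(self.samples) and not self.samples.index.equals(
            pd.Index(self.counts.columns)
        ):
            self.samples = self.samples.reindex(self.counts.columns)

    # -- views ------------------------------------------------------------

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def target_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.genome == TARGET]

    @property
    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.genome == SPIKE]

    def totals(self, tag: str) -> pd.Series:
        """Per-sample read totals for one genome tag."""
        if tag not in _VALID_TAGS:
            raise ValidationError(f"unknown genome tag {tag!r}")
        return self.counts.loc[self.genome == tag].sum(axis=0)

    def condition_of(self, sample: str) -> str:
        return str(self.samples.loc[sample, "condition"])

    def matched_input_of(self, sample: str) -> str:
        if "matched_input" not in self.samples.columns:
            raise ValidationError("sample metadata has no matched_input column")
        return str(self.samples.loc[sample, "matched_input"])
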