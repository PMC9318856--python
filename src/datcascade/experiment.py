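"""The count-matrix container every expression stage operates on."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import SchemaError, read_table, write_table

__all__ = ["CountExperiment"]


@dataclass
class CountExperiment:
    """A gene x sample matrix of non-negative integer read counts plus the
    sample sheet describing each column.

    counts
        DataFrame indexed by gene_id with one integer column per sample.
    samples
        DataFrame indexed by sample_id with columns ``pair``, ``condition``,
        ``replicate`` and ``batch``, aligned with the columns of ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise SchemaError(f"duplicate gene_id '{dup}' in count matrix")
        if list(self.counts.columns) != list(self.samples.index):
            raise SchemaError("count columns and sample sheet rows disagree")
        if "condition" not in self.samples.columns:
            raise SchemaError("sample sheet lacks a 'condition' column")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise SchemaError("negative counts are not allowed")
        if not np.allclose(values, np.round(values)):
            raise SchemaError("counts must be integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, mask: pd.Series) -> "CountExperiment":
        keep = self.samples.index[mask]
        return CountExperiment(self.counts[keep], self.samples.loc[keep])

    # -- disk round trip ---------------------------------------------------

    def write(self, counts_path: str | Path, samples_path: str | Path) -> None:
        counts_out = self.counts.reset_index()
        counts_out = counts_out.rename(columns={counts_out.columns[0]: "gene_id"})
        write_table(counts_out, counts_path)
        samples_out = self.samples.reset_index()
        samples_out = samples_out.rename(columns={samples_out.columns[0]: "sample_id"})
        write_table(samples_out, samples_path)

    @classmethod
    def read(cls, counts_path: str | Path, samples_path: str | Path) -> "CountExperiment":
        counts = read_table(counts_path)
        if "gene_id" not in counts.columns:
            raise SchemaError(f"{counts_path}: missing required column 'gene_id'")
        counts = counts.set_index("gene_id")
        samples = read_table(samples_path, schema="sample_sheet").set_index("sample_id")
        return cls(counts, samples)
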