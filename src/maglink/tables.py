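"""Samples-by-taxa abundance tables.

One container serves both uses in the pipeline: per-culture read
recruitment fractions and environmental relative-abundance time series
(rows labelled with ISO-8601 dates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

KINDS = ("raw-counts", "fractions")


@dataclass
class AbundanceTable:
    """Nonnegative samples x taxa matrix, either raw counts or
    per-sample fractions (rows summing to 1)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    kind: str = "raw-counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise InvalidParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa")
        if self.kind not in KINDS:
            raise InvalidParameterError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if (self.values < 0).any():
            raise InvalidParameterError("abundance values must be nonnegative")
        if self.kind == "fractions":
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
                raise InvalidParameterError(
                    f"fraction rows must sum to 1; sample {bad!r} sums to "
                    f"{sums[np.argmax(np.abs(sums - 1.0))]:.12g}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str) -> "AbundanceTable":
        return cls(sample_ids=[str(i) for i in df.index],
                   taxon_ids=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=float), kind=kind)

    def subset_taxa(self, taxa: list[str]) -> "AbundanceTable":
        """Column subset.  The result is typed raw-counts because a
        subset of a closed composition no longer sums to 1 per row."""
        df = self.to_frame()[list(taxa)]
        return AbundanceTable(sample_ids=list(self.sample_ids), taxon_ids=list(taxa),
                              values=df.to_numpy(), kind="raw-counts")

    def column(self, taxon: str) -> np.ndarray:
        return self.values[:, self.taxon_ids.index(taxon)]
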