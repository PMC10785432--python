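"""Region-by-sample count matrix container.

The matrix ``M`` holds nonnegative integer read counts with ``M[i, j]`` the
number of reads for sample ``i`` in region ``j``.  On disk the matrix is a TSV
with one row per region: first column the region identifier, header row the
sample identifiers (regions are usually far more numerous than samples, so the
file is tall rather than wide; in memory samples index rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix"]


@dataclass
class CountMatrix:
    """Integer read counts over genomic regions for a set of samples.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    region_ids : list of str
        Unique region identifiers, one per matrix column.
    counts : ndarray of shape (n_samples, n_regions)
        Nonnegative integer read counts.
    """

    sample_ids: list[str]
    region_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array (samples x regions)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise ValueError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.shape != (len(self.sample_ids), len(self.region_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.region_ids)} regions"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def row(self, sample_id: str) -> np.ndarray:
        """Counts for one sample across all regions."""
        try:
            i = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None
        return self.counts[i]

    def to_frame(self) -> pd.DataFrame:
        """Regions-as-rows DataFrame (the on-disk orientation)."""
        return pd.DataFrame(
            self.counts.T, index=pd.Index(self.region_ids, name="region_id"),
            columns=self.sample_ids,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(
            sample_ids=[str(c) for c in frame.columns],
            region_ids=[str(r) for r in frame.index],
            counts=frame.to_numpy().T,
        )

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)
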