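"""Core in-memory containers: the abundance table and the sample group map.

An :class:`AbundanceTable` is the universal exchange object of the pipeline:
taxonomy-labelled rows by sample columns of non-negative counts, backed by a
pandas DataFrame.  A :class:`GroupMap` assigns samples to an interest in-group
and an out-group based on one column of a per-sample metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["AbundanceTable", "GroupMap"]

#: Separator appended (with an ordinal) to disambiguate duplicate taxonomy
#: row ids produced by readers; stripped again by collapse_by_taxonomy.
DUP_SEP = "@@"


class ValidationError(ValueError):
    """Raised when a table, mapping or parameter violates its contract."""


@dataclass(frozen=True)
class AbundanceTable:
    """Taxonomy-labelled rows x sample columns of non-negative counts.

    Parameters
    ----------
    data
        DataFrame with taxonomy strings as the index and sample names as
        columns.  Values must be finite and non-negative; floats are allowed
        (real-world BIOM exports contain them and downstream binarization
        makes them harmless).
    provenance
        Identifier of the source file or generator, carried along for logs.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate row ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("counts contain non-finite values")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count {values[i, j]!r} at row {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )

    @property
    def row_ids(self) -> list[str]:
        return [str(r) for r in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def column_sums(self) -> pd.Series:
        """Per-sample total counts (sequencing depth after OTU assignment)."""
        return self.data.sum(axis=0)

    def with_data(self, data: pd.DataFrame) -> "AbundanceTable":
        return replace(self, data=data)


@dataclass(frozen=True)
class GroupMap:
    """Sample -> group assignment splitting samples into in- and out-group.

    ``metadata`` holds one row per sample (index = sample id) with group
    columns; ``group_column`` selects the column used for the split.  The
    in-group is every sample whose label equals ``interest``; the out-group is
    every sample whose label is in ``outgroup``, or every non-interest sample
    when ``outgroup`` is None ("rest").  Matching is exact and case-sensitive:
    silent case-folding would hide mapping errors.
    """

    metadata: pd.DataFrame
    group_column: str
    interest: str
    outgroup: frozenset[str] | None = None  # None means "rest"

    def __post_init__(self) -> None:
        if self.metadata.index.has_duplicates:
            dups = self.metadata.index[self.metadata.index.duplicated()]
            raise ValidationError(f"duplicate sample id in mapping: {dups[0]!r}")
        if self.group_column not in self.metadata.columns:
            raise ValidationError(
                f"group column {self.group_column!r} not found; available: "
                f"{list(self.metadata.columns)}"
            )
        if self.outgroup is not None and self.interest in self.outgroup:
            raise ValidationError(
                f"interest label {self.interest!r} cannot also be an out-group label"
            )
        if not self.in_samples:
            raise ValidationError(
                f"interest label {self.interest!r} matches zero samples in "
                f"column {self.group_column!r} (matching is case-sensitive)"
            )
        if not self.out_samples:
            raise ValidationError("out-group matches zero samples")

    @property
    def labels(self) -> pd.Series:
        return self.metadata[self.group_column]

    @property
    def in_samples(self) -> tuple[str, ...]:
        mask = self.labels == self.interest
        return tuple(str(s) for s in self.metadata.index[mask])

    @property
    def out_samples(self) -> tuple[str, ...]:
        if self.outgroup is None:
            mask = self.labels != self.interest
        else:
            mask = self.labels.isin(self.outgroup)
        return tuple(str(s) for s in self.metadata.index[mask])

    @property
    def n_in(self) -> int:
        return len(self.in_samples)

    @property
    def n_out(self) -> int:
        return len(self.out_samples)

    def restrict(self, sample_ids) -> "GroupMap":
        """Return a GroupMap limited to ``sample_ids`` (preserving order).

        Used after depth filtering removes samples from the table.
        """
        keep = [s for s in self.metadata.index if s in set(sample_ids)]
        return replace(self, metadata=self.metadata.loc[keep])
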