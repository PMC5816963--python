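"""Taxonomy canonicalization and table algebra.

Greengenes-style lineage strings ("k__Bacteria;p__Proteobacteria;...") are the
merge keys of the whole pipeline, so "identical taxonomy" must be well defined:
:func:`canonicalize_lineage` strips whitespace and normalizes single-underscore
rank prefixes ("p_") to the canonical double-underscore form ("p__").  On top
of that this module provides within-table collapse (rows with identical
taxonomy summed per sample), intersection merge across studies, sample depth
filtering, normalization (total-sum or seeded rarefaction), rank-level
summarization, and presence/absence binarization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .table import DUP_SEP, AbundanceTable, ValidationError

__all__ = [
    "Lineage",
    "PresenceMatrix",
    "canonicalize_lineage",
    "collapse_by_taxonomy",
    "merge_tables",
    "filter_low_depth_samples",
    "normalize",
    "collapse_at_rank",
    "binarize",
    "RANKS",
]

logger = logging.getLogger(__name__)

#: Rank order of a Greengenes lineage, kingdom through species.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s")

_PREFIX_RE = re.compile(r"^([A-Za-z])_{1,2}(.*)$")


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic ranks parsed from a Greengenes-style string.

    ``ranks`` is a tuple of (prefix, name) pairs; an unnamed rank keeps its
    prefix with an empty name (canonical form "p__").  ``raw`` preserves the
    original input string.
    """

    ranks: tuple[tuple[str, str], ...]
    raw: str

    @property
    def canonical(self) -> str:
        parts = []
        for prefix, name in self.ranks:
            parts.append(f"{prefix}__{name}" if prefix else name)
        return ";".join(parts)

    @property
    def named_ranks(self) -> int:
        return sum(1 for _, name in self.ranks if name)

    @property
    def terminal_name(self) -> str:
        """Deepest non-empty rank token, e.g. "g__Lysobacter"."""
        for prefix, name in reversed(self.ranks):
            if name:
                return f"{prefix}__{name}" if prefix else name
        prefix, name = self.ranks[0]
        return f"{prefix}__{name}" if prefix else name

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def canonicalize_lineage(raw: str) -> Lineage:
    """Parse a taxonomy string into its canonical rank sequence.

    Whitespace around separators is stripped and both "p_" and "p__" prefixes
    are accepted, normalizing to double underscore (the Greengenes
    convention).  Trailing empty ranks are preserved: "k__Bacteria;p__" and
    "k__Bacteria" are distinct canonical strings.  A token without a
    recognizable rank prefix is kept verbatim as a bare name.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValidationError("empty taxonomy string")
    ranks = []
    for token in raw.split(";"):
        token = token.strip()
        m = _PREFIX_RE.match(token)
        if m:
            ranks.append((m.group(1), m.group(2).strip()))
        else:
            ranks.append(("", token))
    return Lineage(ranks=tuple(ranks), raw=raw)


def strip_dup_suffix(row_id: str) -> str:
    """Remove the reader's internal duplicate-disambiguation suffix."""
    idx = row_id.find(DUP_SEP)
    return row_id if idx < 0 else row_id[:idx]


def _canonical_key(row_id: str) -> str:
    return canonicalize_lineage(strip_dup_suffix(row_id)).canonical


def collapse_by_taxonomy(table: AbundanceTable) -> AbundanceTable:
    """Sum rows with identical canonical taxonomy within each sample.

    One row per canonical taxonomy remains, ordered by first occurrence;
    per-sample column totals are unchanged.
    """
    keys = [_canonical_key(r) for r in table.row_ids]
    df = table.data.copy()
    df.index = pd.Index(keys, name=table.data.index.name)
    # sort=False keeps first-occurrence order
    collapsed = df.groupby(level=0, sort=False).sum()
    return table.with_data(collapsed)


def merge_tables(tables: list[AbundanceTable]) -> AbundanceTable:
    """Intersection-merge collapsed tables from separate studies.

    The merged row set is the intersection of canonical taxonomies (any
    taxonomy absent from one study is dropped); the sample set is the
    concatenation of all tables' samples, which must be disjoint.
    """
    if not tables:
        raise ValidationError("merge requires at least one table")
    seen: set[str] = set()
    for t in tables:
        overlap = seen.intersection(t.sample_ids)
        if overlap:
            raise ValidationError(
                f"duplicate sample id across tables: {sorted(overlap)[:5]}"
            )
        seen.update(t.sample_ids)
        if len(set(t.row_ids)) != t.n_rows:  # pragma: no cover - guarded upstream
            raise ValidationError("merge_tables requires collapsed tables")
    shared_set = set.intersection(*(set(t.row_ids) for t in tables))
    shared = [r for r in tables[0].row_ids if r in shared_set]
    if not shared:
        raise ValidationError("no shared taxonomies across input tables")
    merged = pd.concat([t.data.loc[shared] for t in tables], axis=1)
    prov = "+".join(filter(None, (t.provenance for t in tables)))
    return AbundanceTable(data=merged, provenance=prov)


def filter_low_depth_samples(table: AbundanceTable, min_depth: float) -> AbundanceTable:
    """Drop samples whose total count is below ``min_depth``.

    Mirrors the common practice of removing failed libraries before analysis;
    removals are logged with sample id and depth.
    """
    if min_depth < 0:
        raise ValidationError("min_depth must be >= 0")
    depths = table.column_sums()
    keep = depths[depths >= min_depth].index
    dropped = depths[depths < min_depth]
    for sample, depth in dropped.items():
        logger.info("dropping sample %s: depth %g < %g", sample, depth, min_depth)
    if len(keep) == 0:
        raise ValidationError(
            f"all {table.n_samples} samples removed by min_depth={min_depth}"
        )
    return table.with_data(table.data[keep])


def normalize(
    table: AbundanceTable,
    method: str = "none",
    depth: int | None = None,
    seed: int | None = None,
) -> AbundanceTable:
    """Apply the user-preferred normalization.

    ``none``
        identity.
    ``total_sum``
        each column divided by its total, so columns sum to 1 (relative
        abundance).
    ``rarefy``
        seeded subsampling without replacement to ``depth`` counts per
        sample; columns already below ``depth`` are dropped with a warning.

    Binarization at threshold 1 is scale-invariant, so for the core test
    itself ``none`` and ``total_sum`` are equivalent; rarefaction can flip
    low-count cells to zero and is provided for parity with standard 16S
    workflows.
    """
    if method == "none":
        return table
    if method == "total_sum":
        sums = table.column_sums()
        zero = sums[sums == 0]
        if len(zero):
            raise ValidationError(
                f"total_sum normalization undefined for all-zero sample {zero.index[0]!r}"
            )
        return table.with_data(table.data / sums)
    if method == "rarefy":
        if not depth or depth <= 0:
            raise ValidationError("rarefy requires a positive depth")
        return _rarefy(table, int(depth), seed)
    raise ValidationError(f"unknown normalization method {method!r}")


def _rarefy(table: AbundanceTable, depth: int, seed: int | None) -> AbundanceTable:
    """Subsample each column to exactly ``depth`` counts without replacement."""
    rng = np.random.default_rng(seed)
    sums = table.column_sums()
    keep = [s for s in table.data.columns if sums[s] >= depth]
    for s in table.data.columns:
        if sums[s] < depth:
            logger.warning(
                "rarefy: dropping sample %s (depth %g < %d)", s, sums[s], depth
            )
    if not keep:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    counts = np.rint(table.data[keep].to_numpy()).astype(np.int64)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    df = pd.DataFrame(out, index=table.data.index, columns=keep)
    return table.with_data(df)


def collapse_at_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Re-key rows to the lineage truncated at ``rank`` and sum within keys.

    ``rank`` is one of kingdom..species; collapsing at species on a
    species-resolved table is identical to :func:`collapse_by_taxonomy`.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r}; choose from {RANKS}")
    level = RANKS.index(rank) + 1
    keys = []
    for r in table.row_ids:
        lin = canonicalize_lineage(strip_dup_suffix(r))
        truncated = Lineage(ranks=lin.ranks[:level], raw=lin.raw)
        keys.append(truncated.canonical)
    df = table.data.copy()
    df.index = pd.Index(keys, name=table.data.index.name)
    return table.with_data(df.groupby(level=0, sort=False).sum())


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean presence/absence view of an abundance table.

    A taxon is present in a sample when its count is at least
    ``detection_threshold``; the default threshold of 1 reproduces the
    zero/nonzero rule for integer counts.
    """

    data: pd.DataFrame  # boolean
    detection_threshold: float = 1

    @property
    def row_ids(self) -> list[str]:
        return [str(r) for r in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]


def binarize(table: AbundanceTable, detection_threshold: float = 1) -> PresenceMatrix:
    """Convert counts to present/absent: present iff count >= threshold."""
    if detection_threshold <= 0:
        raise ValidationError("detection_threshold must be > 0")
    present = table.data >= detection_threshold
    return PresenceMatrix(data=present, detection_threshold=detection_threshold)
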