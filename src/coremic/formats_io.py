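"""Reading and writing the pipeline's file formats.

Supported inputs are BIOM v1 JSON tables (dense or sparse encoding, with the
taxonomic assignment of each observation under the "taxonomy" metadata key),
plain TSV abundance tables with a taxonomy column, and tab-delimited sample
mapping files.  Outputs are a results TSV, a BIOM v1 JSON writer for
round-tripping, and a mapping writer used by the synthetic-data generator.

BIOM v2 (HDF5) is deliberately unsupported to keep the tool dependency-light;
an HDF5 file is detected by its magic bytes and rejected with a clear message.
Readers never merge rows: duplicate taxonomies are preserved (disambiguated
with an internal ordinal suffix) so that the collapse step is observable.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .table import DUP_SEP, AbundanceTable, GroupMap, ValidationError
from .tableops import canonicalize_lineage

__all__ = [
    "read_biom_v1",
    "write_biom_v1",
    "read_tsv_table",
    "read_mapping",
    "write_mapping",
    "write_results_tsv",
]

_HDF5_MAGIC = b"\x89HDF\r\n\x1a\n"


def _dedupe_row_ids(row_ids: list[str]) -> list[str]:
    """Suffix repeated ids with an ordinal; collapse strips it later."""
    seen: dict[str, int] = {}
    out = []
    for rid in row_ids:
        k = seen.get(rid, 0)
        seen[rid] = k + 1
        out.append(rid if k == 0 else f"{rid}{DUP_SEP}{k}")
    return out


def read_biom_v1(path) -> AbundanceTable:
    """Read a BIOM v1 (JSON) table into an :class:`AbundanceTable`.

    Row ids are the canonicalized, semicolon-joined taxonomy strings from
    each observation's "taxonomy" metadata (given either as a list of rank
    strings or a single joined string).  Counts are preserved exactly; absent
    cells of a sparse encoding are zero.
    """
    path = Path(path)
    head = path.open("rb").read(8)
    if head == _HDF5_MAGIC:
        raise ValidationError(
            f"{path}: BIOM v2 (HDF5) is not supported; convert to BIOM v1 JSON"
        )
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(
            f"{path}: malformed JSON at line {e.lineno}, column {e.colno} "
            f"(byte offset {e.pos})"
        ) from e
    for key in ("rows", "columns", "data", "matrix_type"):
        if key not in doc:
            raise ValidationError(f"{path}: BIOM v1 document missing key {key!r}")

    row_ids = []
    for obs in doc["rows"]:
        md = obs.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax is None:
            raise ValidationError(
                f"{path}: observation {obs.get('id')!r} has no 'taxonomy' metadata"
            )
        raw = ";".join(str(t) for t in tax) if isinstance(tax, (list, tuple)) else str(tax)
        row_ids.append(canonicalize_lineage(raw).canonical)
    sample_ids = [str(c["id"]) for c in doc["columns"]]

    n_rows, n_cols = len(row_ids), len(sample_ids)
    counts = np.zeros((n_rows, n_cols))
    mtype = doc["matrix_type"]
    if mtype == "dense":
        data = np.asarray(doc["data"], dtype=float)
        if data.shape != (n_rows, n_cols):
            raise ValidationError(
                f"{path}: dense data shape {data.shape} != ({n_rows}, {n_cols})"
            )
        counts = data
    elif mtype == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    else:
        raise ValidationError(f"{path}: unknown matrix_type {mtype!r}")
    if counts.size and counts.min() < 0:
        raise ValidationError(f"{path}: negative count in data")

    df = pd.DataFrame(counts, index=_dedupe_row_ids(row_ids), columns=sample_ids)
    return AbundanceTable(data=df, provenance=path.name)


def write_biom_v1(table: AbundanceTable, path) -> None:
    """Write an :class:`AbundanceTable` as a sparse BIOM v1 JSON file."""
    path = Path(path)
    values = table.counts
    data = [
        [int(i), int(j), float(values[i, j]) if values[i, j] % 1 else int(values[i, j])]
        for i, j in zip(*np.nonzero(values))
    ]
    doc = {
        "id": table.provenance or "table",
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "coremic",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "float" if np.any(values % 1) else "int",
        "shape": [table.n_rows, table.n_samples],
        "rows": [
            {"id": f"OTU{i}", "metadata": {"taxonomy": rid.split(";")}}
            for i, rid in enumerate(table.row_ids)
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    path.write_text(json.dumps(doc))


def read_tsv_table(path, taxonomy_column: str = "taxonomy") -> AbundanceTable:
    """Read a tab-delimited abundance table with a taxonomy column."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as e:
        raise ValidationError(f"{path}: no data rows") from e
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    if taxonomy_column not in df.columns:
        raise ValidationError(
            f"{path}: taxonomy column {taxonomy_column!r} not found; "
            f"available: {list(df.columns)}"
        )
    sample_cols = [c for c in df.columns if c != taxonomy_column]
    if len(set(sample_cols)) != len(sample_cols):
        raise ValidationError(f"{path}: duplicate sample name in header")
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns")
    counts = np.empty((df.shape[0], len(sample_cols)))
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            try:
                counts[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric count {cell!r} at row {i + 1}, "
                    f"column {col!r}"
                ) from None
    if counts.size and counts.min() < 0:
        i, j = np.argwhere(counts < 0)[0]
        raise ValidationError(
            f"{path}: negative count at row {i + 1}, column {sample_cols[j]!r}"
        )
    row_ids = [canonicalize_lineage(t).canonical for t in df[taxonomy_column]]
    out = pd.DataFrame(counts, index=_dedupe_row_ids(row_ids), columns=sample_cols)
    return AbundanceTable(data=out, provenance=path.name)


def read_mapping(
    path, group_column: str, interest: str, outgroup="rest"
) -> GroupMap:
    """Read a tab-delimited sample mapping file into a :class:`GroupMap`.

    The first column holds sample ids; lines starting with "#" are ignored.
    ``outgroup`` is either the literal string "rest" (all non-interest
    samples) or a collection of group labels.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    # QIIME convention: the header may itself start with "#SampleID"; only
    # subsequent "#" lines are comments.
    header = next((ln for ln in lines if ln.strip()), None)
    if header is None:
        raise ValidationError(f"{path}: empty mapping file")
    body = [ln for ln in lines[lines.index(header) + 1 :]
            if ln.strip() and not ln.startswith("#")]
    df = pd.read_csv(
        io.StringIO("\n".join([header.lstrip("#")] + body)), sep="\t", dtype=str
    )
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: mapping needs a sample id and group column")
    df = df.set_index(df.columns[0])
    og = None if outgroup == "rest" else frozenset(outgroup)
    return GroupMap(metadata=df, group_column=group_column, interest=interest, outgroup=og)


def write_mapping(metadata: pd.DataFrame, path) -> None:
    """Write per-sample metadata (index = sample id) as a mapping TSV."""
    metadata.to_csv(Path(path), sep="\t", index_label="#SampleID")


RESULT_COLUMNS = [
    "taxonomy", "a", "b", "c", "d", "p_value", "q_value",
    "presence_in_pct", "presence_out_pct", "is_core",
]


def write_results_tsv(results, path) -> None:
    """Write per-taxon results, sorted by (q, p, taxonomy), as TSV."""
    rows = sorted(results, key=lambda r: (r.q_value, r.p_value, r.taxonomy.canonical))
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.taxonomy.canonical,
                        str(r.counts.a),
                        str(r.counts.b),
                        str(r.counts.c),
                        str(r.counts.d),
                        f"{r.p_value:.6g}",
                        f"{r.q_value:.6g}",
                        f"{r.presence_in_pct:.1f}",
                        f"{r.presence_out_pct:.1f}",
                        "true" if r.is_core else "false",
                    ]
                )
                + "\n"
            )
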