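"""Readers and writers for all tabular inputs and outputs.

Every file is plain tab-separated UTF-8 text; lines starting with ``#``
are comments and are skipped, with one exception: a leading
``#library_sizes`` directive line in a count table supplies explicit
mapped-fragment totals (which may exceed the column sums).

All floating-point output is serialized at 6 significant digits so that
repeated runs under a fixed configuration produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from hybridexpr.core import (
    AnalysisConfig,
    ConfigError,
    CountTable,
    FormatError,
    GeneMeta,
    MiRNATargetMap,
)

LIBRARY_SIZE_DIRECTIVE = "#library_sizes"


def _read_rows(path):
    """Yield (lineno, fields) for non-comment lines; capture directives."""
    directives = {}
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line.split("\t")
                if parts[0] == LIBRARY_SIZE_DIRECTIVE:
                    directives["library_sizes"] = parts[1:]
                continue
            rows.append((lineno, line.split("\t")))
    return rows, directives


def read_count_table(path, expected_samples=None) -> CountTable:
    """Read a gene x sample TSV of integer counts.

    The header row is ``gene_id`` followed by sample labels.  When
    ``expected_samples`` is given, every listed label must be present
    (extra columns are kept).  Gene order is preserved.
    """
    rows, directives = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty count table")
    _, header = rows[0]
    if header[0] != "gene_id":
        raise FormatError(f"{path}: first header column must be 'gene_id'")
    sample_labels = header[1:]
    if expected_samples is not None:
        for label in expected_samples:
            if label not in sample_labels:
                raise ConfigError(f"{path}: missing sample column {label!r}")
    gene_ids = []
    counts = []
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0])
        row = []
        for label, cell in zip(sample_labels, fields[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer count {cell!r} in column {label!r}"
                ) from None
            if value < 0:
                raise FormatError(
                    f"{path}:{lineno}: negative count {value} in column {label!r}"
                )
            row.append(value)
        counts.append(row)
    library_sizes = None
    if "library_sizes" in directives:
        cells = directives["library_sizes"]
        if len(cells) != len(sample_labels):
            raise FormatError(
                f"{path}: {LIBRARY_SIZE_DIRECTIVE} must list one total per sample"
            )
        library_sizes = np.array([int(c) for c in cells], dtype=np.int64)
    matrix = (
        np.array(counts, dtype=np.int64)
        if counts
        else np.zeros((0, len(sample_labels)), dtype=np.int64)
    )
    return CountTable(gene_ids, matrix, sample_labels, library_sizes)


def write_count_table(table: CountTable, path, explicit_library_sizes=False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if explicit_library_sizes or not np.array_equal(
            table.library_sizes, table.counts.sum(axis=0)
        ):
            fh.write(
                LIBRARY_SIZE_DIRECTIVE
                + "\t"
                + "\t".join(str(int(v)) for v in table.library_sizes)
                + "\n"
            )
        fh.write("gene_id\t" + "\t".join(table.sample_labels) + "\n")
        for gid, row in zip(table.gene_ids, table.counts):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_gene_meta(path) -> dict:
    """Read gene metadata TSV (gene_id, length_bp, go_terms) keyed by gene_id.

    ``go_terms`` is a semicolon-separated list and may be empty.
    """
    rows, _ = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty gene metadata table")
    _, header = rows[0]
    for col in ("gene_id", "length_bp", "go_terms"):
        if col not in header:
            raise FormatError(f"{path}: missing column {col!r}")
    idx = {col: header.index(col) for col in header}
    meta = {}
    for lineno, fields in rows[1:]:
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: too few fields")
        gid = fields[idx["gene_id"]]
        if gid in meta:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
        try:
            length = int(fields[idx["length_bp"]])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer length_bp") from None
        terms_cell = (
            fields[idx["go_terms"]] if idx["go_terms"] < len(fields) else ""
        ).strip()
        terms = frozenset(t for t in terms_cell.split(";") if t)
        meta[gid] = GeneMeta(gid, length, terms)
    return meta


def write_gene_meta(meta: Mapping[str, GeneMeta], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlength_bp\tgo_terms\n")
        for gid in meta:
            m = meta[gid]
            fh.write(f"{m.gene_id}\t{m.length_bp}\t{';'.join(sorted(m.go_terms))}\n")


def read_mirna_target_map(path) -> MiRNATargetMap:
    """Read a two-column TSV (mirna_id, gene_id) of target links."""
    rows, _ = _read_rows(path)
    if not rows:
        raise FormatError(f"{path}: empty target map")
    _, header = rows[0]
    if header[:2] != ["mirna_id", "gene_id"]:
        raise FormatError(f"{path}: header must be 'mirna_id<TAB>gene_id'")
    links = []
    for lineno, fields in rows[1:]:
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected two fields")
        links.append((fields[0], fields[1]))
    if len(links) != len(set(links)):
        raise FormatError(f"{path}: duplicate (mirna_id, gene_id) links")
    return MiRNATargetMap(frozenset(links))


def write_mirna_target_map(target_map: MiRNATargetMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tgene_id\n")
        for mirna_id, gene_id in target_map:
            fh.write(f"{mirna_id}\t{gene_id}\n")


def format_float(value) -> str:
    """6-significant-digit representation used for all output floats."""
    if value is None:
        return ""
    if isinstance(value, float) and math.isnan(value):
        return "nan"
    return format(float(value), ".6g")


def _format_cell(value) -> str:
    if isinstance(value, (float, np.floating)):
        return format_float(value)
    if isinstance(value, (np.integer,)):
        return str(int(value))
    if value is None:
        return ""
    return str(value)


def write_table(df: pd.DataFrame, path, sort_by=None) -> None:
    """Write a result DataFrame as deterministic TSV.

    Rows are sorted by ``sort_by`` (defaults to ``gene_id``/``mirna_id``
    when present), columns keep their DataFrame order, floats are
    emitted at 6 significant digits.
    """
    if sort_by is None:
        for candidate in ("gene_id", "mirna_id", "term_id", "statistic", "category"):
            if candidate in df.columns:
                sort_by = candidate
                break
    if sort_by is not None and len(df):
        df = df.sort_values(sort_by, kind="mergesort")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_cell(v) for v in row) + "\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    config: AnalysisConfig | None = None,
    input_paths: Iterable[str] = (),
) -> dict:
    """Write each named result table plus a JSON run manifest.

    Returns the manifest: config snapshot, seed, input digests, and per
    table row counts and file names.  Output is deterministic for fixed
    inputs and config.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "inputs": {
            os.path.basename(str(p)): file_digest(p) for p in sorted(map(str, input_paths))
        },
        "tables": {},
    }
    for name in sorted(tables):
        fname = f"{name}.tsv"
        path = os.path.join(out_dir, fname)
        write_table(tables[name], path)
        manifest["tables"][name] = {"file": fname, "rows": int(len(tables[name]))}
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
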