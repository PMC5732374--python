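"""Readers and writers for the package's plain-text formats.

Supported formats
-----------------
* plain genotype tables: one row per individual, delimiter auto-detected
  among tab/comma/whitespace, optional header row and leading ID column;
* PLINK ``.raw`` additive exports (read-only): whitespace table whose first
  six columns (FID IID PAT MAT SEX PHENOTYPE) are metadata;
* one-label-per-line population files;
* two-column partition TSVs (individual id, 1-based cluster);
* square N x N matrix TSVs with an ID header row and column, used for
  caching proximity and co-association matrices.

Missing genotypes are rejected, never imputed: a loud failure is safer
than silently fabricating data. Filter or impute upstream.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .datatypes import GenotypeMatrix, Partition, PopulationLabels
from .errors import FormatError, MissingGenotypeError, ValidationError

MISSING_TOKENS = frozenset({"NA", "N/A", "nan", "NaN", "", ".", "-9", "?"})
_PLINK_META_COLS = 6

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_labels",
    "write_labels",
    "read_partition",
    "write_partition",
    "read_square_matrix",
    "write_square_matrix",
]


def _split(line: str, delim: str | None) -> list[str]:
    return line.split(delim) if delim else line.split()


def _detect_delimiter(first_line: str) -> str | None:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # any whitespace


def _parse_genotype_token(tok: str, row: int, col: int) -> int:
    if tok in MISSING_TOKENS:
        raise MissingGenotypeError(
            f"missing-value token {tok!r} at row {row}, column {col}; "
            "missing genotypes are not supported — filter or impute markers "
            "before loading"
        )
    try:
        value = int(tok)
    except ValueError:
        raise ValidationError(
            f"genotype entry {tok!r} at row {row}, column {col} is not an integer"
        ) from None
    if value not in (0, 1, 2):
        raise ValidationError(
            f"genotype entry {tok!r} at row {row}, column {col} is not in {{0, 1, 2}}"
        )
    return value


def _looks_like_genotype(tok: str) -> bool:
    return tok in ("0", "1", "2") or tok in MISSING_TOKENS


def read_genotypes(path, dialect: str = "plain") -> GenotypeMatrix:
    """Read an additively coded genotype matrix.

    Parameters
    ----------
    path : path-like
    dialect : {"plain", "plink_raw"}
        ``plain``: delimited text, optionally with a header row and/or a
        leading ID column (both auto-detected). ``plink_raw``: PLINK
        ``--recode A`` output; IID becomes the individual id.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    if dialect == "plink_raw":
        return _read_plink_raw(path, lines)
    if dialect != "plain":
        raise ValidationError(f"unknown genotype dialect {dialect!r}")
    return _read_plain(path, lines)


def _read_plain(path: Path, lines: list[str]) -> GenotypeMatrix:
    delim = _detect_delimiter(lines[0])
    rows = [_split(ln, delim) for ln in lines]
    first = rows[0]

    # Header row: every non-leading cell fails to look like a genotype value.
    has_header = not any(_looks_like_genotype(t) for t in first[1:] or first[:1])
    data_rows = rows[1:] if has_header else rows
    if not data_rows:
        raise FormatError(f"{path}: no data rows")

    # Leading ID column: first cell of each data row is not a genotype token.
    has_id_col = all(not _looks_like_genotype(r[0]) for r in data_rows)

    marker_ids = None
    if has_header:
        marker_ids = first[1:] if has_id_col else first

    width = len(data_rows[0])
    matrix = np.empty((len(data_rows), width - (1 if has_id_col else 0)), dtype=np.int8)
    ids: list[str] | None = [] if has_id_col else None
    for i, row in enumerate(data_rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {i}: {len(row)} fields, expected {width}"
            )
        toks = row
        if has_id_col:
            ids.append(toks[0])  # type: ignore[union-attr]
            toks = toks[1:]
        for j, tok in enumerate(toks):
            matrix[i, j] = _parse_genotype_token(tok, i, j)
    return GenotypeMatrix(matrix, individual_ids=ids, marker_ids=marker_ids)


def _read_plink_raw(path: Path, lines: list[str]) -> GenotypeMatrix:
    header = lines[0].split()
    expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if header[:_PLINK_META_COLS] != expected:
        raise FormatError(
            f"{path}: not a PLINK .raw file (header starts {header[:6]})"
        )
    marker_ids = header[_PLINK_META_COLS:]
    n_markers = len(marker_ids)
    matrix = np.empty((len(lines) - 1, n_markers), dtype=np.int8)
    ids = []
    for i, ln in enumerate(lines[1:]):
        fields = ln.split()
        if len(fields) != _PLINK_META_COLS + n_markers:
            raise FormatError(
                f"{path}: ragged row {i}: {len(fields)} fields, "
                f"expected {_PLINK_META_COLS + n_markers}"
            )
        ids.append(fields[1])
        for j, tok in enumerate(fields[_PLINK_META_COLS:]):
            matrix[i, j] = _parse_genotype_token(tok, i, j)
    return GenotypeMatrix(matrix, individual_ids=ids, marker_ids=marker_ids)


def write_genotypes(path, g: GenotypeMatrix) -> None:
    """Write a genotype matrix as TSV with an ID column and marker header."""
    markers = g.marker_ids or [f"snp{j}" for j in range(g.n_markers)]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(markers) + "\n")
        for ind, row in zip(g.individual_ids, g.values):
            fh.write(ind + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_labels(path, n_expected: int | None = None) -> PopulationLabels:
    """Read one population label per line, in genotype row order."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if n_expected is not None and len(lines) != n_expected:
        raise ValidationError(
            f"{path}: {len(lines)} labels but {n_expected} individuals"
        )
    return PopulationLabels(np.array(lines))


def write_labels(path, labels: PopulationLabels) -> None:
    Path(path).write_text("\n".join(str(s) for s in labels.labels) + "\n")


def write_partition(path, p: Partition, ids: list[str]) -> None:
    """Write (individual id, 1-based cluster) rows as TSV."""
    if len(ids) != len(p):
        raise ValidationError(f"{len(ids)} ids for {len(p)} assignments")
    with open(path, "w") as fh:
        for ind, c in zip(ids, p.assignment):
            fh.write(f"{ind}\t{int(c)}\n")


def read_partition(path) -> tuple[Partition, list[str]]:
    ids, labels = [], []
    for i, ln in enumerate(Path(path).read_text().splitlines()):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}: row {i} has {len(fields)} fields, expected 2")
        ids.append(fields[0])
        labels.append(int(fields[1]))
    return Partition(np.array(labels)), ids


def write_square_matrix(path, m: np.ndarray, ids: list[str]) -> None:
    """Write an N x N matrix as TSV with the ID list as header row/column."""
    m = np.asarray(m)
    if m.shape != (len(ids), len(ids)):
        raise ValidationError(f"matrix shape {m.shape} does not match {len(ids)} ids")
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for ind, row in zip(ids, m):
            fh.write(ind + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_square_matrix(path) -> tuple[np.ndarray, list[str]]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    n = len(header)
    m = np.empty((n, n))
    row_ids = []
    if len(lines) - 1 != n:
        raise FormatError(f"{path}: {len(lines) - 1} rows for {n} header columns")
    for i, ln in enumerate(lines[1:]):
        fields = ln.split("\t")
        row_ids.append(fields[0])
        if len(fields) != n + 1:
            raise FormatError(f"{path}: ragged row {i}")
        m[i] = [float(v) for v in fields[1:]]
    if row_ids != header:
        raise FormatError(f"{path}: row ids do not match column ids")
    return m, row_ids
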