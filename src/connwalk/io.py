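"""Reading connectivity files and writing analysis reports.

Two plain-text input formats are supported: a dense ``n x n`` matrix
(CSV/TSV, optional single header row of node labels, blank cells read as 0)
and a 3-column weighted edge list (``node_a  node_b  weight``, undirected,
each pair listed once).  Reports are written as a JSON record of the global
measures plus a per-node TSV; node labels are 1-based in all files.
"""

from __future__ import annotations

import csv
import io
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, symmetrize as _symmetrize
from .global_measures import GlobalMeasures

__all__ = ["read_connectivity", "AnalysisReport", "write_report", "write_matrix", "matrix_to_csv"]

#: significant digits used in all written tables
PRECISION = 12


def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def _split(line: str, delim: str) -> list[str]:
    if delim == " ":
        return line.split()
    return [c.strip() for c in line.split(delim)]


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def _read_rows(path: str | os.PathLike) -> tuple[list[list[str]], list[str] | None]:
    """Split a file into data rows; returns (rows, labels-from-#labels-line)."""
    text = Path(path).read_text()
    labels = None
    lines = []
    for ln in text.splitlines():
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.startswith("#labels"):
            rest = stripped[len("#labels"):].lstrip(":, \t")
            labels = _split(rest, _sniff_delimiter(rest))
        elif not stripped.startswith("#"):
            lines.append(ln)
    if not lines:
        raise ValueError(f"{path}: empty input")
    delim = _sniff_delimiter(lines[0])
    return [_split(ln, delim) for ln in lines], labels


def _has_label_header(rows: list[list[str]]) -> bool:
    # a header row contains no numeric cell; a data row with a stray
    # non-numeric cell must be reported as an error, not eaten as labels
    return not any(_is_number(c) for c in rows[0] if c != "")


def _parse_matrix(
    rows: list[list[str]],
    path: str,
    clip_negative: bool,
    allow_asymmetric: bool,
    labels: list[str] | None = None,
) -> ConnectivityMatrix:
    if _has_label_header(rows):
        labels = [c for c in rows[0] if c != ""]
        rows = rows[1:]
    n = len(rows)
    width = len(rows[0])
    C = np.zeros((n, width))
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged input, row {i + 1} has {len(row)} cells, expected {width}"
            )
        for j, cell in enumerate(row):
            if cell == "":
                continue  # blank cell = no connection
            if not _is_number(cell):
                raise ValueError(f"{path}: non-numeric cell {cell!r} at row {i + 1}, column {j + 1}")
            C[i, j] = float(cell)
    if n != width:
        raise ValueError(f"{path}: matrix is {n} rows x {width} columns, must be square")
    if labels is not None and len(labels) != n:
        raise ValueError(f"{path}: header has {len(labels)} labels for {n} columns")
    neg = np.argwhere(C < 0)
    if neg.size and not clip_negative:
        i, j = neg[0]
        raise ValueError(
            f"{path}: negative weight {C[i, j]} at row {i + 1}, column {j + 1}; "
            "pass clip_negative to zero negative weights"
        )
    C = np.clip(C, 0.0, None)
    if allow_asymmetric:
        return _symmetrize(C, labels=labels)
    asym = np.argwhere(~np.isclose(C, C.T, rtol=0.0, atol=1e-12))
    if asym.size:
        i, j = asym[0]
        raise ValueError(
            f"{path}: asymmetric entry at row {i + 1}, column {j + 1} "
            f"({C[i, j]} vs {C[j, i]}); pass symmetrize to copy the upper triangle"
        )
    np.fill_diagonal(C, 0.0)
    return ConnectivityMatrix(C, labels=labels)


def _parse_edgelist(rows: list[list[str]], path: str, clip_negative: bool) -> ConnectivityMatrix:
    labels: list[str] = []
    index: dict[str, int] = {}
    triples: list[tuple[int, int, float]] = []
    seen: set[tuple[int, int]] = set()
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 3:
            raise ValueError(f"{path}: edge-list line {lineno} has {len(row)} columns, expected 3")
        a, b, w = row
        if not _is_number(w):
            raise ValueError(f"{path}: non-numeric weight {w!r} on line {lineno}")
        weight = float(w)
        if weight < 0:
            if not clip_negative:
                raise ValueError(
                    f"{path}: negative weight {weight} on line {lineno}; "
                    "pass clip_negative to zero negative weights"
                )
            weight = 0.0
        for node in (a, b):
            if node not in index:
                index[node] = len(labels)
                labels.append(node)
        i, j = index[a], index[b]
        if i == j:
            raise ValueError(f"{path}: self-loop {a!r} on line {lineno}")
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"{path}: duplicate edge {a!r}-{b!r} on line {lineno}")
        seen.add(key)
        triples.append((i, j, weight))
    n = len(labels)
    C = np.zeros((n, n))
    for i, j, w in triples:
        C[i, j] = C[j, i] = w
    return ConnectivityMatrix(C, labels=labels)


def read_connectivity(
    path: str | os.PathLike,
    format: str = "auto",
    symmetrize: bool = False,
    clip_negative: bool = False,
) -> ConnectivityMatrix:
    """Read a connectivity matrix from a dense-matrix or edge-list file.

    Parameters
    ----------
    path:
        CSV/TSV file.  Lines starting with ``#`` and blank lines are
        ignored.
    format:
        ``"matrix"``, ``"edgelist"`` or ``"auto"``.  Auto picks the
        edge-list reader when every row has exactly 3 columns and the
        table is not a 3 x 3 square; a 3 x 3 table is read as a matrix.
    symmetrize:
        Copy upper-triangle values below the diagonal and zero the
        diagonal instead of rejecting asymmetric input.
    clip_negative:
        Replace negative weights with 0 instead of rejecting them.
    """
    rows, file_labels = _read_rows(path)
    path = str(path)
    if format == "auto":
        all3 = all(len(r) == 3 for r in rows)
        n_data = len(rows) - (1 if _has_label_header(rows) else 0)
        format = "edgelist" if all3 and n_data != 3 else "matrix"
    if format == "matrix":
        return _parse_matrix(rows, path, clip_negative,
                             allow_asymmetric=symmetrize, labels=file_labels)
    if format == "edgelist":
        return _parse_edgelist(rows, path, clip_negative)
    raise ValueError(f"unknown format {format!r}; expected auto, matrix or edgelist")


def _fmt(x: float) -> str:
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    return f"{x:.{PRECISION}g}"


def matrix_to_csv(C: ConnectivityMatrix) -> str:
    """Dense CSV text for a matrix; node labels go on a ``#labels`` comment line."""
    buf = io.StringIO()
    buf.write("#labels," + ",".join(C.labels) + "\n")
    writer = csv.writer(buf)
    for row in C.C:
        writer.writerow([_fmt(v) for v in row])
    return buf.getvalue()


def write_matrix(C: ConnectivityMatrix, path: str | os.PathLike) -> None:
    """Write a dense CSV matrix file (see :func:`matrix_to_csv`)."""
    with _atomic_open(path) as fh:
        fh.write(matrix_to_csv(C))


class _atomic_open:
    """Write to a temp file and rename on success, so errors leave no partial output."""

    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, self.tmp = tempfile.mkstemp(dir=self.path.parent, suffix=".tmp")
        self.fh = os.fdopen(fd, "w", newline="")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            os.unlink(self.tmp)
        return False


@dataclass
class AnalysisReport:
    """Bundle of everything computed for one input network."""

    metadata: dict
    global_measures: GlobalMeasures
    node_table: pd.DataFrame
    fit_table: pd.DataFrame | None = None

    def summary(self) -> dict:
        """JSON-ready dict: metadata, global measures (bits), node extremes."""
        extremes = {}
        for col in self.node_table.columns:
            series = self.node_table[col].dropna()
            if series.empty:
                continue
            # all tied nodes are reported
            extremes[col] = {
                "max": {"value": float(series.max()),
                        "nodes": sorted(series.index[series == series.max()].tolist())},
                "min": {"value": float(series.min()),
                        "nodes": sorted(series.index[series == series.min()].tolist())},
            }
        out = {
            "metadata": self.metadata,
            "global_measures_bits": self.global_measures.as_dict(),
            "node_extremes": extremes,
        }
        if self.fit_table is not None:
            out["log_fits"] = self.fit_table.to_dict(orient="records")
        return out


def write_report(report: AnalysisReport, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the JSON summary and per-node TSV into ``out_dir``.

    Returns the paths written.  Raises ``ValueError`` on an empty node
    table (nothing was computed).
    """
    if report.node_table.empty:
        raise ValueError("empty per-node table: nothing to write")
    out_dir = Path(out_dir)
    paths = {"global": out_dir / "global.json", "nodes": out_dir / "nodes.tsv"}
    with _atomic_open(paths["global"]) as fh:
        json.dump(report.summary(), fh, indent=2)
        fh.write("\n")
    with _atomic_open(paths["nodes"]) as fh:
        cols = list(report.node_table.columns)
        fh.write("\t".join(["node_label"] + cols) + "\n")
        for label, row in report.node_table.iterrows():
            fh.write("\t".join([str(label)] + [_fmt(v) for v in row]) + "\n")
    if report.fit_table is not None:
        paths["fits"] = out_dir / "fits.tsv"
        with _atomic_open(paths["fits"]) as fh:
            report.fit_table.to_csv(fh, sep="\t", index=False, float_format=f"%.{PRECISION}g")
    return paths
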