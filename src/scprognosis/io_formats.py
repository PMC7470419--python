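"""Readers and writers for the matrices and tables the pipeline consumes.

Two on-disk layouts are supported for expression data: dense delimited text
(first row = cell/sample ids, first column = gene ids, comma or tab
auto-detected) and MatrixMarket triplets with ``genes.txt``/``barcodes.txt``
sidecar files. Clinical tables are delimited text with columns
``sample``, ``time``, ``event``. All matrices are held genes-in-rows
internally; readers transpose when told the file is samples-in-rows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class ValidationError(ValueError):
    """Invalid input data or parameters (CLI exit code 2)."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A genes x cells (or genes x samples) non-negative expression matrix.

    Expression units are treated as opaque non-negative reals; the pipeline
    makes no assumption about counts vs normalized values.

    Parameters
    ----------
    values
        ``(G, C)`` float array, non-negative, no missing entries.
    gene_ids
        Length-``G`` unique gene symbols.
    cell_ids
        Length-``C`` unique cell/sample identifiers.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        g, c = self.values.shape
        if g < 1 or c < 1:
            raise ValidationError("expression matrix must be at least 1 x 1")
        if len(self.gene_ids) != g or len(self.cell_ids) != c:
            raise ValidationError(
                f"id lengths ({len(self.gene_ids)}, {len(self.cell_ids)}) do not "
                f"match matrix shape {self.values.shape}"
            )
        if len(set(self.gene_ids)) != g:
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != c:
            raise ValidationError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains missing or non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("expression matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene)
        if idx.size == 0:
            raise ValidationError(f"gene {gene!r} not found in matrix")
        return int(idx[0])

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        rows = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(self.values[rows], np.asarray(list(genes)), self.cell_ids)

    def subset_cells(self, order) -> "ExpressionMatrix":
        order = np.asarray(order)
        return ExpressionMatrix(self.values[:, order], self.gene_ids, self.cell_ids[order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


# Accepted spellings for the binary event indicator. Unknown strings are an
# error, never silently dropped.
_EVENT_MAP = {
    "1": 1, "0": 0, "1.0": 1, "0.0": 0,
    "TRUE": 1, "FALSE": 0, "T": 1, "F": 0,
    "YES": 1, "NO": 0,
    "DEAD": 1, "ALIVE": 0,
    "DECEASED": 1, "LIVING": 0,
    "EVENT": 1, "CENSORED": 0,
}


@dataclass
class ClinicalTable:
    """Per-sample right-censored survival outcomes.

    ``time`` is positive follow-up time (days or months — declared by the
    cohort, opaque here); ``event`` is 1 when the event (death/relapse) was
    observed and 0 when the sample is right-censored.
    """

    sample_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    time_unit: str = "unspecified"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.sample_ids)
        if len(self.time) != n or len(self.event) != n:
            raise ValidationError("clinical columns have mismatched lengths")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in clinical table")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = self.sample_ids[~(np.isfinite(self.time) & (self.time > 0))]
            raise ValidationError(f"non-positive survival time for sample(s): {', '.join(bad[:5])}")
        ev = np.asarray([_coerce_event(e) for e in self.event], dtype=int)
        self.event = ev

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, order) -> "ClinicalTable":
        order = np.asarray(order)
        return ClinicalTable(self.sample_ids[order], self.time[order],
                             self.event[order], self.time_unit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event},
                            index=pd.Index(self.sample_ids, name="sample"))


def _coerce_event(value) -> int:
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    if isinstance(value, (int, np.integer)):
        if value in (0, 1):
            return int(value)
        raise ValidationError(f"event value {value!r} outside {{0, 1}}")
    if isinstance(value, (float, np.floating)):
        if value in (0.0, 1.0):
            return int(value)
        raise ValidationError(f"event value {value!r} outside {{0, 1}}")
    key = str(value).strip().upper()
    if key in _EVENT_MAP:
        return _EVENT_MAP[key]
    raise ValidationError(f"unrecognized event encoding {value!r}")


# ---------------------------------------------------------------------------
# Expression matrix I/O
# ---------------------------------------------------------------------------

def _detect_sep(path: str) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if line.count("\t") >= line.count(",") else ","
    raise ValidationError(f"empty file: {path}")


def read_expression(path: str, format: str = "dense",
                    samples_in_rows: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        Dense text file, or the ``.mtx`` file for ``format="mtx"`` (sidecars
        ``genes.txt`` and ``barcodes.txt`` are looked up next to it).
    format
        ``"dense"`` or ``"mtx"``.
    samples_in_rows
        Set when a dense file stores samples/cells as rows; the matrix is
        transposed to the internal genes-in-rows layout.
    """
    if format == "dense":
        df = pd.read_csv(path, sep=_detect_sep(path), index_col=0, comment="#")
        if samples_in_rows:
            df = df.T
        if df.isna().any().any():
            raise ValidationError(f"missing entries in {path}")
        return ExpressionMatrix(df.to_numpy(dtype=float),
                                df.index.astype(str).to_numpy(),
                                df.columns.astype(str).to_numpy())
    if format == "mtx":
        mat = scipy.io.mmread(path)
        base = os.path.dirname(os.path.abspath(path))
        genes = _read_names(os.path.join(base, "genes.txt"))
        cells = _read_names(os.path.join(base, "barcodes.txt"))
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise ValidationError(
                f"matrix shape {dense.shape} does not match sidecar names "
                f"({len(genes)} genes, {len(cells)} barcodes)")
        return ExpressionMatrix(dense, genes, cells)
    raise ValidationError(f"unknown expression format {format!r}")


def _read_names(path: str) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([line.strip() for line in fh if line.strip()], dtype=str)


def write_expression(mat: ExpressionMatrix, path: str, format: str = "dense") -> None:
    if format == "dense":
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        mat.to_frame().to_csv(path, sep=sep)
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(mat.values))
        base = os.path.dirname(os.path.abspath(path))
        np.savetxt(os.path.join(base, "genes.txt"), mat.gene_ids, fmt="%s")
        np.savetxt(os.path.join(base, "barcodes.txt"), mat.cell_ids, fmt="%s")
    else:
        raise ValidationError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# Clinical table I/O
# ---------------------------------------------------------------------------

def read_clinical(path: str) -> ClinicalTable:
    """Read a clinical table with columns sample, time, event."""
    df = pd.read_csv(path, sep=_detect_sep(path), comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing column(s): {sorted(missing)}")
    return ClinicalTable(df["sample"].astype(str).to_numpy(),
                         df["time"].to_numpy(),
                         df["event"].to_numpy())


def write_clinical(table: ClinicalTable, path: str) -> None:
    table.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene score table I/O
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["MAD", "SDE", "NET", "MAD_norm", "SDE_norm", "NET_norm", "W", "rank"]


def write_scores(table: pd.DataFrame, path: str, header_lines=()) -> None:
    """Write a gene score table (index = gene) as TSV.

    Columns not yet computed (e.g. normalized scores before integration) are
    written as empty fields.
    """
    out = table.reindex(columns=SCORE_COLUMNS)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index_label="gene")


def read_scores(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene", comment="#")
    if "rank" in df and df["rank"].notna().all():
        df["rank"] = df["rank"].astype(int)
    return df
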