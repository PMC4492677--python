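"""Tabular containers and TSV readers/writers.

Three plain-text formats are used throughout the package:

* expression TSV — first column ``gene``, remaining columns ``t<minutes>``
  (``t10``, ``t20``, ...), cells are log2 expression ratios of treated vs.
  control;
* connectivity TSV — edge list with columns ``tf``, ``gene`` and an optional
  ``sign`` column (kept for provenance, ignored by the model, which learns
  free-signed regulatory strengths);
* category TSV — two columns ``gene``, ``category`` mapping each gene to one
  functional category.

All files are UTF-8 with LF line endings.  Floats are written with ``%.17g``
so that a write/read round trip is exact in double precision.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

_TIME_COL_RE = re.compile(r"^t([0-9]+(?:\.[0-9]+)?)$")


@dataclass
class ExpressionMatrix:
    """Gene x time matrix of log2 expression ratios for one condition.

    ``time_points_min`` must be non-decreasing; repeated values represent
    replicate arrays for the same sampling time (averaged before model
    fitting).
    """

    gene_ids: list[str]
    time_points_min: list[float]
    values: np.ndarray  # shape (n_genes, n_times), log2 ratios
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            for g in self.gene_ids:
                if g in seen:
                    raise ValueError(f"duplicate gene id: {g!r}")
                seen.add(g)
        t = np.asarray(self.time_points_min, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) < 0):
            raise ValueError("time_points_min must be non-decreasing")
        if np.any(t <= 0):
            raise ValueError("time_points_min must be positive")
        if self.values.shape != (len(self.gene_ids), len(self.time_points_min)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.time_points_min)} times"
            )
        if np.isnan(self.values).any():
            raise ValueError("values must not contain missing entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_points_min)

    def to_frame(self) -> pd.DataFrame:
        cols = [_format_time_col(t) for t in self.time_points_min]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "gene", self.gene_ids)
        return df


@dataclass
class ConnectivityMatrix:
    """Binary gene x TF regulon-membership matrix (the model's X)."""

    gene_ids: list[str]
    tf_names: list[str]
    entries: np.ndarray  # shape (n_genes, n_tfs), values in {0, 1}

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("connectivity entries must be 0 or 1")
        self.entries = self.entries.astype(np.int8)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in connectivity")
        if len(set(self.tf_names)) != len(self.tf_names):
            raise ValueError("duplicate TF names in connectivity")
        if self.entries.shape != (len(self.gene_ids), len(self.tf_names)):
            raise ValueError("entries shape does not match gene/TF lists")
        col_sums = self.entries.sum(axis=0)
        if (col_sums < 1).any():
            empty = [t for t, s in zip(self.tf_names, col_sums) if s < 1]
            raise ValueError(f"TF(s) with no targets: {', '.join(empty)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_names)

    def targets_of(self, tf: str) -> list[str]:
        j = self.tf_names.index(tf)
        mask = self.entries[:, j] == 1
        return [g for g, m in zip(self.gene_ids, mask) if m]


@dataclass
class CategoryMap:
    """Mapping of gene id to a single functional category."""

    mapping: dict[str, str]
    #: genes that appeared under more than one category in the source file
    multi_category_genes: list[str] = field(default_factory=list)

    def __getitem__(self, gene: str) -> str:
        return self.mapping[gene]

    def get(self, gene: str, default: Optional[str] = None) -> Optional[str]:
        return self.mapping.get(gene, default)

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def _format_time_col(t: float) -> str:
    t = float(t)
    return f"t{t:g}"


def read_expression(path: str | Path, condition_label: str = "") -> ExpressionMatrix:
    """Read an expression TSV.

    Rows with any missing value are dropped (never imputed) and the count is
    logged.  Duplicate gene ids and non-numeric cells are errors.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "gene":
        raise ValueError(f"{path}: first column must be 'gene', got {header[:1]}")
    times = []
    for col in header[1:]:
        m = _TIME_COL_RE.match(col)
        if m is None:
            raise ValueError(f"{path}: malformed time column {col!r} (expected t<minutes>)")
        times.append(float(m.group(1)))
    # header parsed manually so replicate columns (repeated t<min>) survive
    df = pd.read_csv(path, sep="\t", header=None, skiprows=1, dtype=str)
    if df.shape[1] != len(header):
        raise ValueError(f"{path}: ragged rows (expected {len(header)} columns)")
    genes = df.iloc[:, 0].tolist()
    dupes = pd.Series(genes)[pd.Series(genes).duplicated()].unique()
    if len(dupes):
        raise ValueError(f"{path}: duplicate gene id: {dupes[0]!r}")
    raw = df.iloc[:, 1:]
    values = np.full(raw.shape, np.nan)
    for j in range(raw.shape[1]):
        col = raw.iloc[:, j]
        missing = col.isna() | (col.str.strip() == "")
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & ~missing
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {col.iloc[i]!r} at gene {genes[i]!r}, "
                f"column {header[j + 1]!r}"
            )
        values[:, j] = numeric.to_numpy()
    keep = ~np.isnan(values).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: %d gene(s) removed (missing values)", path.name, n_dropped)
    order = np.argsort(np.asarray(times), kind="stable")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(genes, keep) if k],
        time_points_min=[times[i] for i in order],
        values=values[keep][:, order],
        condition_label=condition_label or path.stem,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
                             lineterminator="\n")


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    """Read a TF->gene edge-list TSV into a binary gene x TF matrix.

    Duplicate edges collapse to a single entry with a logged warning.  A
    ``sign`` column, if present, is ignored (the model learns signs).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty connectivity file")
    for col in ("tf", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        bad = df[col].isna() | (df[col].str.strip() == "")
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: malformed line {lineno} (empty {col!r})")
    n_dup = int(df.duplicated(subset=["tf", "gene"]).sum())
    if n_dup:
        logger.warning("%s: %d duplicated edge(s) collapsed", path.name, n_dup)
        df = df.drop_duplicates(subset=["tf", "gene"])
    tf_names = sorted(df["tf"].unique())
    gene_ids = sorted(df["gene"].unique())
    gi = {g: i for i, g in enumerate(gene_ids)}
    tj = {t: j for j, t in enumerate(tf_names)}
    entries = np.zeros((len(gene_ids), len(tf_names)), dtype=np.int8)
    for tf, gene in zip(df["tf"], df["gene"]):
        entries[gi[gene], tj[tf]] = 1
    return ConnectivityMatrix(gene_ids=gene_ids, tf_names=tf_names, entries=entries)


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    rows = []
    for j, tf in enumerate(conn.tf_names):
        for i in np.flatnonzero(conn.entries[:, j]):
            rows.append((tf, conn.gene_ids[i]))
    pd.DataFrame(rows, columns=["tf", "gene"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def read_categories(path: str | Path) -> CategoryMap:
    """Read a gene -> functional-category TSV.

    A gene listed under several categories keeps the first one (the
    multiplicity is logged and recorded on the returned map).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty category file")
    for col in ("gene", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        bad = df[col].isna() | (df[col].str.strip() == "")
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: malformed line {lineno} (empty {col!r})")
    mapping: dict[str, str] = {}
    multi: list[str] = []
    for gene, cat in zip(df["gene"], df["category"]):
        if gene in mapping:
            if mapping[gene] != cat and gene not in multi:
                multi.append(gene)
            continue  # first listed category wins
        mapping[gene] = cat
    if multi:
        logger.warning("%s: %d gene(s) in multiple categories; first kept",
                       path.name, len(multi))
    return CategoryMap(mapping=mapping, multi_category_genes=multi)


def write_categories(categories: CategoryMap, path: str | Path) -> None:
    pd.DataFrame(sorted(categories.mapping.items()), columns=["gene", "category"]
                 ).to_csv(path, sep="\t", index=False, lineterminator="\n")
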