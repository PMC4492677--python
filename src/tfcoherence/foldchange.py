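"""Fold-change classification and category/genome summaries.

Expression ratios are stored internally on the log2 scale; the significance
rule works on the ratio scale: a gene is *up* at a time point when its fold
change is >= 2 and *down* when it is <= 0.5 (both thresholds inclusive),
otherwise *unchanged*.  Heat-map values use the natural logarithm of the
fold change, so downregulation is negative and a two-fold change is
``+/-ln 2``.

Fold-change tables are tidy :class:`pandas.DataFrame` objects with columns
``gene``, ``time_min``, ``fold_change`` (ratio scale), ``direction`` and
optionally ``category``.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .io import CategoryMap, ExpressionMatrix

logger = logging.getLogger(__name__)

UP_THRESHOLD = 2.0
DOWN_THRESHOLD = 0.5

FOLD_CHANGE_COLUMNS = ["gene", "time_min", "fold_change", "direction"]


def classify_direction(fold_change: np.ndarray) -> np.ndarray:
    """Vectorised up/down/unchanged call on ratio-scale fold changes."""
    fc = np.asarray(fold_change, dtype=float)
    out = np.full(fc.shape, "unchanged", dtype=object)
    out[fc >= UP_THRESHOLD] = "up"
    out[fc <= DOWN_THRESHOLD] = "down"
    return out


def classify_fold_changes(
    matrix: ExpressionMatrix,
    categories: Optional[CategoryMap] = None,
) -> pd.DataFrame:
    """Classify every (gene, time) cell of a log2 expression matrix.

    Returns a tidy table with one row per (gene, time); ``fold_change`` is
    the ratio-scale value ``2**log2_ratio``.  When a category map is given a
    ``category`` column is added (missing genes get ``NaN``).
    """
    n, t = matrix.values.shape
    fc = np.power(2.0, matrix.values).ravel()
    table = pd.DataFrame({
        "gene": np.repeat(matrix.gene_ids, t),
        "time_min": np.tile(matrix.time_points_min, n),
        "fold_change": fc,
        "direction": classify_direction(fc),
    })
    if categories is not None:
        table["category"] = table["gene"].map(categories.mapping)
    return table


def category_percentages(table: pd.DataFrame,
                         categories: Optional[CategoryMap] = None) -> pd.DataFrame:
    """Per-(category, time) percentage of genes up and down.

    Percentages are denominated on the number of categorised genes in the
    category, so ``pct_up + pct_down <= 100``.  Genes with no category are
    excluded (and counted in the log); a category with no genes left after
    exclusion simply has no row — it is reported as absent, never as 0%.
    """
    table = table.copy()
    if "category" not in table.columns:
        if categories is None:
            raise ValueError("table has no 'category' column and no CategoryMap given")
        table["category"] = table["gene"].map(categories.mapping)
    uncategorised = table["category"].isna()
    n_excluded = table.loc[uncategorised, "gene"].nunique()
    if n_excluded:
        logger.info("%d uncategorised gene(s) excluded from category summary",
                    n_excluded)
    table = table[~uncategorised]
    rows = []
    for (cat, t), grp in table.groupby(["category", "time_min"], sort=True):
        n = len(grp)
        rows.append((cat, t,
                     100.0 * (grp["direction"] == "up").sum() / n,
                     100.0 * (grp["direction"] == "down").sum() / n))
    return pd.DataFrame(rows, columns=["category", "time_min", "pct_up", "pct_down"])


def genome_fraction_altered(table: pd.DataFrame,
                            genome_size: int = 4598) -> pd.DataFrame:
    """Per-time percentage of the whole genome up- and downregulated.

    Percentages are denominated on ``genome_size`` (default 4,598 genes),
    not on the number of measured genes, so unmeasured genes count as
    unchanged.
    """
    n_genes = table["gene"].nunique()
    if genome_size < n_genes:
        raise ValueError(
            f"genome_size {genome_size} is smaller than the {n_genes} observed genes")
    times = sorted(table["time_min"].unique())
    rows = []
    for t in times:
        at_t = table[table["time_min"] == t]
        rows.append((t,
                     100.0 * (at_t["direction"] == "up").sum() / genome_size,
                     100.0 * (at_t["direction"] == "down").sum() / genome_size))
    if not rows:
        rows = []  # empty table -> empty summary
    return pd.DataFrame(rows, columns=["time_min", "pct_up", "pct_down"])


def heat_values(table: pd.DataFrame) -> pd.DataFrame:
    """Gene x time matrix of ln(fold change) for heat-map display.

    Unchanged genes land strictly inside (ln 0.5, ln 2); downregulated genes
    are negative.  Nonpositive fold changes are rejected.
    """
    fc = table["fold_change"].to_numpy(dtype=float)
    if (fc <= 0).any():
        bad = table.loc[fc <= 0, "gene"].iloc[0]
        raise ValueError(f"nonpositive fold change for gene {bad!r}")
    with_heat = table.assign(heat=np.log(fc))
    wide = with_heat.pivot(index="gene", columns="time_min", values="heat")
    wide = wide.reindex(index=table["gene"].unique(),
                        columns=sorted(table["time_min"].unique()))
    wide.columns.name = "time_min"
    return wide
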