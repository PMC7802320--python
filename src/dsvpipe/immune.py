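"""Deletion–immune-expression correlation screen.

Expression from the immune panel is min–max scaled per gene, then every
(deletion, gene) pair is scored with the point-biserial correlation — the
Pearson correlation between a 0/1 carrier indicator and a continuous
variable, computed via the group-means formula.  A deletion is called
immune-associated when some gene exceeds the |r| threshold (0.3 by
default), and per-deletion category enrichment over the six immune
functional categories is assessed with a hypergeometric upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression with functional categories."""

    values: pd.DataFrame            # index = gene ids, columns = sample ids
    categories: pd.Series           # per-gene category label
    normalized: bool = False
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.categories.index):
            raise ValueError("categories index must match gene index")


def minmax_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene min–max scaling to [0, 1]; constant genes map to 0 (flagged)."""
    v = expr.values
    if v.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    lo = v.min(axis=1)
    span = v.max(axis=1) - lo
    constant = span == 0
    if constant.any():
        logger.warning("%d constant gene(s) set to all-zero", int(constant.sum()))
    scaled = v.sub(lo, axis=0).div(span.where(~constant, 1.0), axis=0)
    scaled[constant] = 0.0
    return ExpressionMatrix(
        values=scaled,
        categories=expr.categories,
        normalized=True,
        constant_genes=list(v.index[constant]),
    )


def point_biserial(x, y) -> float:
    """Point-biserial correlation of a dichotomous x with a continuous y.

    r = (mean(y|x=1) - mean(y|x=0)) / s_y * sqrt(n1 n0 / n^2) with s_y the
    population (divide-by-n) standard deviation; algebraically identical to
    the Pearson correlation of y with 0/1-coded x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    vals = np.unique(x)
    if vals.size != 2:
        raise ValueError("x must take exactly two values")
    ones = x == vals.max()
    n1, n0 = int(ones.sum()), int((~ones).sum())
    n = n1 + n0
    s_y = y.std()  # population sd
    if s_y == 0:
        raise ValueError("y is constant; correlation undefined")
    return float((y[ones].mean() - y[~ones].mean()) / s_y * np.sqrt(n1 * n0 / n**2))


@dataclass
class CorrelationScreen:
    r: pd.DataFrame                  # DSV x gene point-biserial correlations
    selected_pairs: pd.DataFrame     # columns dsv_id, gene, r
    threshold: float
    use_abs: bool = True

    @property
    def immune_associated_dsvs(self) -> list[str]:
        return sorted(self.selected_pairs["dsv_id"].unique())


def correlation_screen(
    carriers, expr: ExpressionMatrix, threshold: float = 0.3, use_abs: bool = True
) -> CorrelationScreen:
    """All DSV x gene point-biserial correlations on the sample intersection.

    A pair is selected when |r| (or r, with ``use_abs=False``) exceeds
    ``threshold``; a DSV is immune-associated iff it has a selected pair.
    DSVs or genes constant on the intersection yield NaN and are never
    selected.
    """
    shared = [s for s in carriers.data.index if s in set(expr.values.columns)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} overlapping samples (need >= 10)")
    X = carriers.data.loc[shared].to_numpy(dtype=float)          # n x m
    Y = expr.values[shared].to_numpy(dtype=float).T              # n x g
    n = len(shared)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    xs = X.std(axis=0)
    ys = Y.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ Yc) / n / np.outer(xs, ys)
    r[~np.isfinite(r)] = np.nan
    rdf = pd.DataFrame(r, index=carriers.data.columns, columns=expr.values.index)
    score = rdf.abs() if use_abs else rdf
    pairs = score.stack()
    hits = pairs[pairs > threshold].index
    selected = pd.DataFrame(
        {
            "dsv_id": [d for d, _ in hits],
            "gene": [g for _, g in hits],
            "r": [rdf.loc[d, g] for d, g in hits],
        }
    )
    return CorrelationScreen(r=rdf, selected_pairs=selected, threshold=threshold, use_abs=use_abs)


def category_summary(screen: CorrelationScreen, categories: pd.Series) -> pd.DataFrame:
    """Per-DSV functional-category composition of its selected genes.

    For each (DSV, category): ratio = selected genes of that category /
    all selected genes of the DSV; enrichment p is the hypergeometric upper
    tail of drawing that many category genes from the panel given the DSV's
    selected-gene count; BH adjustment runs across all (DSV, category)
    cells.  DSVs with no selected genes are omitted.
    """
    if len(screen.selected_pairs) == 0:
        raise ValueError("empty screen: no selected pairs")
    panel_size = len(categories)
    cat_sizes = categories.value_counts()
    rows = []
    for dsv, grp in screen.selected_pairs.groupby("dsv_id"):
        genes = grp["gene"].unique()
        n_sel = len(genes)
        gene_cats = categories.loc[genes]
        for cat, k_cat in cat_sizes.items():
            k = int((gene_cats == cat).sum())
            p = stats.hypergeom.sf(k - 1, panel_size, int(k_cat), n_sel)
            rows.append(
                {
                    "dsv_id": dsv,
                    "category": cat,
                    "n_selected": n_sel,
                    "n_in_category": k,
                    "ratio": k / n_sel,
                    "p": float(p),
                }
            )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df
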