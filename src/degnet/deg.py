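"""Differential-expression core: count filtering, a stand-in DE test,
Benjamini-Hochberg adjustment, and DEG selection.

The differential test implemented here is a Welch two-sample t-test on
log2(counts-per-million + 1) with total-count library-size scaling.  It is
deliberately NOT DESeq2's negative-binomial Wald/LRT model: it exists so the
pipeline is self-contained on count matrices, and externally produced DEG
tables (e.g. real DESeq2 output) are accepted through the same table schema
(columns ``log2_fold_change``, ``p_raw``, ``p_adj``) wherever a DEG table is
consumed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "filter_low_counts",
    "differential_expression",
    "bh_adjust",
    "select_degs",
]

CASE = "case"
CONTROL = "control"


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts with case/control labels.

    ``counts`` is a genes-by-samples DataFrame; ``groups`` maps each sample
    id (the columns) to ``"case"`` or ``"control"``.
    """

    counts: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without a group label: {missing}")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control', got {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def filter_low_counts(m: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes whose total count across ALL samples is below ``min_total``.

    A gene with fewer than ``min_total`` reads summed over every sample is
    excluded; a total exactly equal to ``min_total`` is kept ("less than" is
    strict).  Row order is preserved and the operation is idempotent.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = m.counts.sum(axis=1) >= min_total
    return CountMatrix(m.counts.loc[keep], m.groups)


def _log_cpm(counts: pd.DataFrame, pseudocount: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    libsize = counts.sum(axis=0).astype(float)
    if (libsize == 0).any():
        empty = libsize.index[libsize == 0].tolist()
        raise ValueError(f"samples with zero total counts: {empty}")
    cpm = counts.div(libsize, axis=1) * 1e6
    return cpm, np.log2(cpm + pseudocount)


def differential_expression(m: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene case-vs-control test on library-size normalised counts.

    Welch's t-test on log2(CPM + pseudocount) per gene; the fold change is
    log2(mean case CPM + pseudocount) - log2(mean control CPM + pseudocount).
    Returns a DEG table indexed by gene id with columns ``log2_fold_change``,
    ``p_raw`` and ``p_adj`` (Benjamini-Hochberg).  Genes with undefined test
    statistics (e.g. zero variance in both groups) carry NaN p-values and are
    never selected downstream.
    """
    case_ids = m.samples_in_group(CASE)
    ctrl_ids = m.samples_in_group(CONTROL)
    if not case_ids or not ctrl_ids:
        raise ValueError("both a case and a control group are required")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("at least two samples per group are required for the test")

    cpm, logc = _log_cpm(m.counts, pseudocount)
    lfc = np.log2(cpm[case_ids].mean(axis=1) + pseudocount) - np.log2(
        cpm[ctrl_ids].mean(axis=1) + pseudocount
    )
    with warnings.catch_warnings():
        # zero-variance genes legitimately produce NaN statistics
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            logc[case_ids].to_numpy(), logc[ctrl_ids].to_numpy(),
            axis=1, equal_var=False,
        )
    p_raw = np.asarray(res.pvalue, dtype=float)
    p_adj = np.full_like(p_raw, np.nan)
    ok = ~np.isnan(p_raw)
    if ok.any():
        p_adj[ok] = bh_adjust(p_raw[ok])
    n_nan = int((~ok).sum())
    if n_nan:
        logger.warning("%d genes had undefined test statistics (NaN p)", n_nan)
    return pd.DataFrame(
        {"log2_fold_change": lfc.to_numpy(), "p_raw": p_raw, "p_adj": p_adj},
        index=pd.Index(m.counts.index, name="gene"),
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if arr.size == 0:
        return arr.copy()
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def select_degs(t: pd.DataFrame, regime: str, alpha: float = 0.05) -> frozenset[str]:
    """Select significant genes under the named threshold regime.

    ``regime="adjusted"`` selects genes with BH-adjusted p strictly below
    ``alpha`` (the human-data rule); ``regime="raw"`` uses the uncorrected p
    (the mouse-data rule).  NaN p-values are never selected.
    """
    cols = {"adjusted": "p_adj", "raw": "p_raw"}
    if regime not in cols:
        raise ValueError(f"regime must be 'adjusted' or 'raw', got {regime!r}")
    col = cols[regime]
    sel = t.index[t[col] < alpha]
    logger.info("select_degs regime=%s alpha=%g -> %d genes", regime, alpha, len(sel))
    return frozenset(sel)
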