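"""Dosage checks, adult-brain-silent DEG selection, developmental-stage
profile testing, prenatal-maximum selection, and NDD binomial enrichment.

Expression units follow the upstream resources: adult tissue expression in
TPM, developmental-stage expression in RPKM; both thresholds default to 1.5
and no cross-unit conversion is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DosageCheck",
    "BrainSilentSelection",
    "NddEnrichment",
    "dosage_check",
    "select_brain_silent_degs",
    "stage_profile_test",
    "select_prenatal_max",
    "ndd_binomial_enrichment",
]

PRENATAL = "prenatal"
BRAIN_CORTEX = "brain_cortex"


@dataclass(frozen=True)
class DosageCheck:
    """Per-tissue partition of deletion-region genes by expression."""

    expressed: dict[str, frozenset[str]]   # TPM strictly above threshold
    low: dict[str, frozenset[str]]
    missing: frozenset[str]                # region genes absent from the table
    threshold: float


@dataclass(frozen=True)
class BrainSilentSelection:
    selected: frozenset[str]
    missing: frozenset[str]   # DEGs with no expression record ("no data" tally)


@dataclass(frozen=True)
class NddEnrichment:
    overlap: int
    n_degs: int
    p0: float
    p_value: float


def dosage_check(
    region_genes: Iterable[str], expr: pd.DataFrame, threshold: float = 1.5
) -> DosageCheck:
    """Partition deletion-region genes into expressed vs low per tissue.

    ``expr`` is a genes x tissues TPM table.  A gene counts as expressed in
    a tissue when its TPM is strictly greater than ``threshold``; a TPM of
    exactly the threshold is low.  Region genes absent from the table are
    reported in ``missing`` rather than silently dropped.
    """
    region = set(region_genes)
    if not region:
        raise ValueError("region_genes must be non-empty")
    present = region & set(expr.index)
    missing = frozenset(region - present)
    if missing:
        logger.warning("dosage_check: %d region genes missing from expression table", len(missing))
    expressed: dict[str, frozenset[str]] = {}
    low: dict[str, frozenset[str]] = {}
    for tissue in expr.columns:
        vals = expr.loc[sorted(present), tissue]
        expressed[tissue] = frozenset(vals.index[vals > threshold])
        low[tissue] = frozenset(vals.index[~(vals > threshold)])
    return DosageCheck(expressed=expressed, low=low, missing=missing, threshold=threshold)


def select_brain_silent_degs(
    degs: Iterable[str],
    expr: pd.DataFrame,
    tissue: str = BRAIN_CORTEX,
    threshold: float = 1.5,
) -> BrainSilentSelection:
    """DEGs expressed below ``threshold`` TPM in the adult brain cortex.

    Strict inequality (< threshold).  DEGs without an expression record are
    excluded from the selection and returned in ``missing`` — they mirror
    the genes whose expression cannot be retrieved from the source atlas.
    """
    degs = set(degs)
    present = degs & set(expr.index)
    missing = frozenset(degs - present)
    if missing:
        logger.info("select_brain_silent_degs: %d DEGs without expression data", len(missing))
    vals = expr.loc[sorted(present), tissue]
    return BrainSilentSelection(
        selected=frozenset(vals.index[vals < threshold]),
        missing=missing,
    )


def stage_profile_test(genes: Iterable[str], m: pd.DataFrame) -> pd.DataFrame:
    """Tukey HSD over developmental stages for a gene group.

    One-way layout: genes are the observations, stages (the columns of
    ``m``) the groups.  Returns the square, symmetric matrix of Tukey
    honestly-significant-difference adjusted p-values (studentized range
    distribution) indexed by stage.  Genes missing from the matrix or with
    incomplete profiles are excluded with a warning.
    """
    genes = set(genes)
    present = sorted(genes & set(m.index))
    dropped = len(genes) - len(present)
    data = m.loc[present].dropna()
    if len(data) < len(present):
        dropped += len(present) - len(data)
    if dropped:
        logger.warning("stage_profile_test: %d genes without complete stage data excluded", dropped)
    if len(data) < 2:
        raise ValueError("at least two genes with complete stage data are required")
    if data.shape[1] < 2:
        raise ValueError("at least two stages are required")
    groups = [data[c].to_numpy(dtype=float) for c in data.columns]
    res = stats.tukey_hsd(*groups)
    return pd.DataFrame(res.pvalue, index=data.columns, columns=data.columns)


def select_prenatal_max(
    genes: Iterable[str],
    m: pd.DataFrame,
    prenatal_threshold: float = 1.5,
    prenatal_stage: str = PRENATAL,
) -> frozenset[str]:
    """Genes whose expression peaks prenatally above the RPKM threshold.

    Selected genes satisfy both: prenatal RPKM strictly above
    ``prenatal_threshold`` and prenatal value strictly greater than every
    other stage ("maximum in the prenatal stage" read as a strict maximum;
    ties with another stage are logged and excluded).  Genes with missing
    stage data are excluded and logged.
    """
    if prenatal_stage not in m.columns:
        raise ValueError(f"stage matrix has no '{prenatal_stage}' column")
    genes = set(genes)
    present = sorted(genes & set(m.index))
    if len(present) < len(genes):
        logger.info("select_prenatal_max: %d genes missing from stage matrix", len(genes) - len(present))
    data = m.loc[present].dropna()
    other = [c for c in data.columns if c != prenatal_stage]
    pre = data[prenatal_stage]
    rest_max = data[other].max(axis=1)
    above = pre > prenatal_threshold
    strict = pre > rest_max
    ties = above & ~strict & (pre == rest_max)
    if ties.any():
        logger.info("select_prenatal_max: %d genes tie their prenatal maximum; excluded",
                    int(ties.sum()))
    return frozenset(data.index[above & strict])


def ndd_binomial_enrichment(
    degs: Iterable[str], ndd_genes: Iterable[str], universe: Iterable[str]
) -> NddEnrichment:
    """One-sided binomial test for DEG enrichment in NDD genes.

    With k = |DEGs intersect NDD|, n = |DEGs| and baseline success
    probability p0 = |NDD|/|universe|, returns the exact upper-tail
    P(X >= k) for X ~ Binomial(n, p0).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    degs = set(degs)
    ndd = set(ndd_genes)
    if not degs <= universe:
        raise ValueError("degs must be a subset of the universe")
    if not ndd <= universe:
        raise ValueError("ndd_genes must be a subset of the universe")
    k = len(degs & ndd)
    n = len(degs)
    p0 = len(ndd) / len(universe)
    if n == 0:
        return NddEnrichment(overlap=0, n_degs=0, p0=p0, p_value=1.0)
    p = stats.binomtest(k, n, p0, alternative="greater").pvalue
    return NddEnrichment(overlap=k, n_degs=n, p0=p0, p_value=float(p))
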