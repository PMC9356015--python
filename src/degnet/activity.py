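"""Running-sum module activity: GSEA-style enrichment score with a
permutation z-statistic and activated/inactivated classification.

For a functional module f with N_f member genes inside a ranked list of N
genes, walking down the list accumulates +1/N_f at member genes and
-1/(N - N_f) elsewhere; the enrichment score ES_f is the maximum of that
running sum.  Because the sum returns to zero at the end of the list,
ES_f always lies in [0, 1].  The "activity" of a module scores the list
ranked by descending log2 fold change, the "inactivity" the ascending
ranking.  Each ES is standardised by the mean and standard deviation of
ES over random permutations of the gene order (z = (ES - mu)/sigma); a
module is activated when its activity z exceeds the threshold while its
inactivity z is negative, and symmetrically for inactivated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import substream
from .network import FunctionalModule

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "PermutationZ",
    "rank_genes",
    "enrichment_score",
    "permutation_z",
    "classify_module",
    "score_all_modules",
]

DOWNWARD = "downward"
UPWARD = "upward"

ACTIVATED = "activated"
INACTIVATED = "inactivated"
NEITHER = "neither"
DEGENERATE = "degenerate"


@dataclass(frozen=True)
class RankedList:
    """A fold-change-ordered gene list (the ranking substrate for ES)."""

    gene_ids: tuple[str, ...]
    ranking_values: tuple[float, ...]
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (DOWNWARD, UPWARD):
            raise ValueError(f"direction must be '{DOWNWARD}' or '{UPWARD}'")
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("ranked gene ids must be unique")
        if len(self.gene_ids) < 2:
            raise ValueError("a ranked list needs at least two genes")
        vals = np.asarray(self.ranking_values)
        diffs = np.diff(vals)
        ok = (diffs <= 0).all() if self.direction == DOWNWARD else (diffs >= 0).all()
        if not ok:
            raise ValueError("ranking_values are not ordered consistently with direction")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class PermutationZ:
    es: float
    mu: float
    sigma: float
    z: float
    n_perm: int
    degenerate: bool = False


def rank_genes(t: pd.DataFrame, direction: str) -> RankedList:
    """Rank the DEG table by log2 fold change.

    ``downward`` sorts descending (activity ranking), ``upward`` ascending
    (inactivity ranking); ties are broken by gene id, ascending, in both
    directions.  Genes with a missing fold change are excluded and logged.
    """
    if direction not in (DOWNWARD, UPWARD):
        raise ValueError(f"direction must be '{DOWNWARD}' or '{UPWARD}'")
    vals = t["log2_fold_change"]
    missing = vals.isna()
    if missing.any():
        logger.warning("rank_genes: %d genes without fold change excluded", int(missing.sum()))
        vals = vals[~missing]
    # sort ids ascending first, then a stable sort by value keeps that order on ties
    vals = vals.loc[sorted(vals.index)]
    ordered = vals.sort_values(ascending=(direction == UPWARD), kind="mergesort")
    return RankedList(
        gene_ids=tuple(str(g) for g in ordered.index),
        ranking_values=tuple(float(v) for v in ordered.to_numpy()),
        direction=direction,
    )


def _member_mask(ranked_ids: Sequence[str], module_genes: Iterable[str]) -> np.ndarray:
    members = set(module_genes)
    return np.fromiter((g in members for g in ranked_ids), dtype=bool, count=len(ranked_ids))


def enrichment_score(
    r: RankedList | Sequence[str], module_genes: Iterable[str]
) -> tuple[float, np.ndarray]:
    """Enrichment score and the full running-sum vector for one module.

    Module genes absent from the ranked list are dropped before computing
    N_f.  Raises if no module gene is in the list (N_f = 0) or if the module
    covers the whole list (N_f = N, where the decrement is undefined).
    Returns (ES, S) with S the length-N running sum; S[-1] is 0 up to
    floating-point roundoff and ES = max(S).
    """
    ids = r.gene_ids if isinstance(r, RankedList) else tuple(r)
    mask = _member_mask(ids, module_genes)
    n = mask.size
    nf = int(mask.sum())
    if nf == 0:
        raise ValueError("no module gene is present in the ranked list (N_f = 0)")
    if nf == n:
        raise ValueError("module covers the entire ranked list (N_f = N): ES undefined")
    # accumulate integer member counts, then divide: S_i = j_i/N_f - (i - j_i)/(N - N_f)
    # (exactly 0 at i=N and exactly 1 for a member prefix, no float drift)
    hits = np.cumsum(mask)
    steps = np.arange(1, n + 1)
    running = hits / nf - (steps - hits) / (n - nf)
    return float(running.max()), running


def _es_from_positions(positions: np.ndarray, n: int) -> np.ndarray:
    """ES for member positions only (vectorised over permutations).

    ``positions`` is an (n_perm, N_f) array of 0-based member positions.
    Between member positions the running sum only decreases and it ends at
    exactly zero, so its maximum is attained at a member position; at the
    j-th member (1-based), sitting at 0-based list position p, the running
    sum equals j/N_f - (p + 1 - j)/(N - N_f).
    """
    pos = np.sort(positions, axis=1)
    nf = pos.shape[1]
    j = np.arange(1, nf + 1, dtype=float)
    s = j / nf - (pos + 1 - j) / (n - nf)
    return s.max(axis=1)


def _sample_positions(rng: np.random.Generator, n: int, nf: int, n_perm: int) -> np.ndarray:
    """Uniform without-replacement member positions for each permutation.

    Rejection sampling on rows with duplicate draws; exact for any N_f <= N
    and fast when N_f << N (the regime of gene-set scoring).
    """
    if nf > n:
        raise ValueError("cannot place more members than list positions")
    if nf > n // 2:
        out = np.empty((n_perm, nf), dtype=np.int64)
        for i in range(n_perm):
            out[i] = rng.choice(n, size=nf, replace=False)
        return out
    def has_dup(rows: np.ndarray) -> np.ndarray:
        if nf == 1:
            return np.zeros(rows.shape[0], dtype=bool)
        return (np.diff(np.sort(rows, axis=1), axis=1) == 0).any(axis=1)

    pos = rng.integers(0, n, size=(n_perm, nf))
    bad = has_dup(pos)
    while bad.any():
        pos[bad] = rng.integers(0, n, size=(int(bad.sum()), nf))
        bad = has_dup(pos)
    return pos


def permutation_z(
    r: RankedList,
    module_genes: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> PermutationZ:
    """Standardise a module's ES against a permutation null.

    The null replicates randomly permute the gene order; since only member
    positions matter, each replicate equivalently draws N_f member positions
    uniformly without replacement.  mu and sigma are the mean and sample
    standard deviation (n-1 denominator) of the n_perm null scores; sigma=0
    flags the result degenerate (z undefined).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    es, _ = enrichment_score(r, module_genes)
    n = len(r)
    nf = int(_member_mask(r.gene_ids, module_genes).sum())
    if rng is None:
        rng = substream(seed, "permutation-z")
    positions = _sample_positions(rng, n, nf, n_perm)
    null = _es_from_positions(positions, n)
    mu = float(null.mean())
    sigma = float(null.std(ddof=1))
    if sigma == 0.0:
        return PermutationZ(es=es, mu=mu, sigma=sigma, z=float("nan"),
                            n_perm=n_perm, degenerate=True)
    return PermutationZ(es=es, mu=mu, sigma=sigma, z=(es - mu) / sigma, n_perm=n_perm)


def classify_module(z_act: float, z_inact: float, z_threshold: float = 2.0) -> str:
    """Activated / inactivated / neither from the two direction z-scores.

    Activated: activity z > threshold AND inactivity z < 0.  Inactivated:
    inactivity z > threshold AND activity z < 0.  The two conditions are
    mutually exclusive by sign.  Non-finite z flags the module degenerate.
    """
    if not (np.isfinite(z_act) and np.isfinite(z_inact)):
        return DEGENERATE
    if z_act > z_threshold and z_inact < 0:
        return ACTIVATED
    if z_inact > z_threshold and z_act < 0:
        return INACTIVATED
    return NEITHER


def score_all_modules(
    t: pd.DataFrame,
    modules: Sequence[FunctionalModule],
    n_perm: int = 1000,
    seed: int = 0,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Score every functional module in both directions and classify it.

    The entire DEG table (every expression-tested gene with a fold change)
    forms the ranked list; genes absent from the network still occupy list
    positions.  Each (module, direction) pair draws its null from its own
    named substream of ``seed``, so results are independent of module order
    and reproducible standalone.  Modules with no gene in the ranked list
    are skipped with a warning rather than aborting the batch.
    """
    down = rank_genes(t, DOWNWARD)
    up = rank_genes(t, UPWARD)
    ranked_genes = set(down.gene_ids)
    rows = []
    for module in modules:
        present = module.genes & ranked_genes
        if not present:
            logger.warning("score_all_modules: %s has no gene in the ranked list; skipped",
                           module.term_id)
            continue
        if len(present) == len(ranked_genes):
            logger.warning("score_all_modules: %s covers the entire list; degenerate",
                           module.term_id)
            rows.append({
                "term_id": module.term_id, "n_module_genes": len(present),
                "es_activity": np.nan, "mu_activity": np.nan, "sigma_activity": np.nan,
                "z_activity": np.nan, "es_inactivity": np.nan, "mu_inactivity": np.nan,
                "sigma_inactivity": np.nan, "z_inactivity": np.nan, "status": DEGENERATE,
            })
            continue
        act = permutation_z(down, present, n_perm=n_perm,
                            rng=substream(seed, "activity", module.term_id))
        inact = permutation_z(up, present, n_perm=n_perm,
                              rng=substream(seed, "inactivity", module.term_id))
        status = classify_module(act.z, inact.z, z_threshold=z_threshold)
        rows.append({
            "term_id": module.term_id,
            "n_module_genes": len(present),
            "es_activity": act.es, "mu_activity": act.mu,
            "sigma_activity": act.sigma, "z_activity": act.z,
            "es_inactivity": inact.es, "mu_inactivity": inact.mu,
            "sigma_inactivity": inact.sigma, "z_inactivity": inact.z,
            "status": status,
        })
    return pd.DataFrame(rows)
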