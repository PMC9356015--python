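"""Cross-species DEG set overlap with a Monte-Carlo permutation null.

The significance of a k-way DEG intersection is assessed against random
gene sets of the same sizes drawn uniformly from a fixed universe (default
20,000 genes, 100,000 samplings).  For two sets the null intersection is
exactly hypergeometric, which serves as the analytic cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import substream
from .deg import CountMatrix, CASE, CONTROL, differential_expression, filter_low_counts, select_degs

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapResult",
    "OverlapCounts",
    "map_orthologs",
    "overlap_sets",
    "permutation_overlap_p",
    "hypergeometric_overlap_p",
    "exclude_region_genes",
    "control_split_overlap",
]


@dataclass(frozen=True)
class OverlapResult:
    """Observed k-way intersection against its Monte-Carlo null."""

    set_sizes: tuple[int, ...]
    universe_size: int
    observed: int
    n_samplings: int
    count_ge: int   # null samplings with intersection >= observed
    p_empirical: float


@dataclass(frozen=True)
class OverlapCounts:
    kway: int
    pairwise: dict[tuple[int, int], int]


def map_orthologs(genes: Iterable[str], table: pd.DataFrame) -> frozenset[str]:
    """Map a gene set through a two-column (source, target) orthology table.

    Exact duplicate rows collapse to one pair.  Source ids mapping to more
    than one target are ambiguous and dropped, as are sources absent from
    the table; both cases are logged.
    """
    genes = set(genes)
    pairs = table.iloc[:, :2].drop_duplicates()
    counts = pairs.iloc[:, 0].value_counts()
    ambiguous = set(counts.index[counts > 1])
    mapping = dict(
        zip(pairs.iloc[:, 0], pairs.iloc[:, 1], strict=True)
    )
    dropped_ambiguous = genes & ambiguous
    dropped_missing = {g for g in genes - ambiguous if g not in mapping}
    if dropped_ambiguous:
        logger.warning("map_orthologs: %d ambiguous source ids dropped", len(dropped_ambiguous))
    if dropped_missing:
        logger.warning("map_orthologs: %d source ids absent from table dropped", len(dropped_missing))
    return frozenset(mapping[g] for g in genes - ambiguous - dropped_missing)


def overlap_sets(sets: Sequence[Iterable[str]]) -> OverlapCounts:
    """Exact full k-way and all pairwise intersection cardinalities."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("at least two sets are required")
    kway = len(set.intersection(*sets))
    pairwise = {(i, j): len(sets[i] & sets[j]) for i, j in combinations(range(len(sets)), 2)}
    return OverlapCounts(kway=kway, pairwise=pairwise)


def permutation_overlap_p(
    set_sizes: Sequence[int],
    observed: int,
    universe_size: int = 20_000,
    n_samplings: int = 100_000,
    seed: int = 0,
) -> OverlapResult:
    """Monte-Carlo p-value for a k-way overlap under random gene sets.

    Each sampling draws, for every set, an independent uniform subset of the
    given size from a universe of ``universe_size`` genes and records the
    size of the full intersection.  The draw is realised as a chain of
    hypergeometric variates (|A1|=s1; |A1 n A2| ~ Hypergeom(N, s1, s2); each
    further set thins the running intersection the same way), which has
    exactly the distribution of materialised uniform subsets while needing
    no per-gene bookkeeping.  The empirical p uses the add-one convention
    (count_ge + 1)/(n_samplings + 1) and therefore never reports zero.
    """
    sizes = tuple(int(s) for s in set_sizes)
    if not sizes:
        raise ValueError("at least one set size is required")
    if any(s < 0 or s > universe_size for s in sizes):
        raise ValueError("set sizes must lie in [0, universe_size]")
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if n_samplings < 1:
        raise ValueError("n_samplings must be >= 1")
    rng = substream(seed, "overlap-null")
    inter = np.full(n_samplings, sizes[0], dtype=np.int64)
    for s in sizes[1:]:
        inter = rng.hypergeometric(inter, universe_size - inter, s)
    count_ge = int((inter >= observed).sum())
    p = (count_ge + 1) / (n_samplings + 1)
    return OverlapResult(
        set_sizes=sizes,
        universe_size=int(universe_size),
        observed=int(observed),
        n_samplings=int(n_samplings),
        count_ge=count_ge,
        p_empirical=p,
    )


def hypergeometric_overlap_p(size_a: int, size_b: int, observed: int, universe_size: int) -> float:
    """Exact upper-tail P(X >= observed) for the two-set overlap null."""
    if size_a > universe_size or size_b > universe_size:
        raise ValueError("set sizes must not exceed the universe")
    if observed <= 0:
        return 1.0
    return float(stats.hypergeom.sf(observed - 1, universe_size, size_a, size_b))


def exclude_region_genes(s: Iterable[str], region: Iterable[str]) -> frozenset[str]:
    """Remove deletion-region genes from a gene set (set difference)."""
    return frozenset(s) - frozenset(region)


def control_split_overlap(
    controls: CountMatrix,
    other_deg_sets: Sequence[Iterable[str]],
    universe_size: int = 20_000,
    n_samplings: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
    min_total: int = 10,
) -> tuple[OverlapResult, frozenset[str]]:
    """Negative control: split the control samples in two and overlap their
    "DEGs" with the other species' DEG sets.

    The control columns are partitioned into two pseudo-groups by a seeded
    permutation, differential expression is run between the halves, genes
    with raw p < alpha are selected, and their overlap with the supplied
    sets is tested against the permutation null.  Any true signal absent,
    the resulting p should be unremarkable.
    """
    ids = list(controls.counts.columns)
    if len(ids) < 4:
        raise ValueError("at least four control samples are required to split")
    rng = substream(seed, "control-split")
    perm = [ids[i] for i in rng.permutation(len(ids))]
    half = len(perm) // 2
    first, second = perm[:half], perm[half:]
    groups = pd.Series(
        [CASE if s in set(first) else CONTROL for s in ids], index=ids
    )
    split = CountMatrix(controls.counts, groups)
    split = filter_low_counts(split, min_total=min_total)
    table = differential_expression(split)
    if table["p_raw"].isna().all():
        warnings.warn(
            "control split produced no defined test statistics "
            "(no within-split variation); returning an empty DEG set",
            stacklevel=2,
        )
        split_degs: frozenset[str] = frozenset()
    else:
        split_degs = select_degs(table, regime="raw", alpha=alpha)
    others = [set(s) for s in other_deg_sets]
    observed = len(set(split_degs).intersection(*others)) if others else len(split_degs)
    result = permutation_overlap_p(
        [len(split_degs), *[len(s) for s in others]],
        observed,
        universe_size=universe_size,
        n_samplings=n_samplings,
        seed=seed,
    )
    return result, split_degs
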