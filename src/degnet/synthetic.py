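"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a small
human-blood cohort (3 microdeletion cases vs 4 controls) and a mouse-cortex
cohort (10 vs 10) sharing part of their differential signal through a 1:1
orthology; halved-dosage deletion-region genes; a sparse protein-interaction
graph with planted, internally connected GO-coherent modules; GO annotations
with experimental and non-experimental evidence; and developmental-stage
profiles with planted prenatal-maximum genes that are silent in the adult
brain cortex.

Counts are negative-binomial with a per-gene log-normal mean and a shared
dispersion; planted differential genes have their case-group mean scaled by
2**(+-lfc_magnitude) and deletion genes by 0.5.  All outputs are byte-stable
functions of the configuration (including its seed): the truth plan and each
artefact are drawn from named substreams so regenerating any one artefact
never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._util import substream
from .deg import CASE, CONTROL, CountMatrix
from .network import EXPERIMENTAL_EVIDENCE_CODES

__all__ = [
    "STAGES",
    "SimConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "plan_truth",
    "generate_counts",
    "generate_ppi",
    "generate_go_annotations",
    "generate_stage_expression",
    "generate_tissue_expression",
    "generate_ndd_genes",
    "generate_orthology",
    "simulate_all",
    "write_bundle",
    "deletion_region_example",
]

STAGES = ("prenatal", "infant", "child", "adolescent", "adult")

HUMAN = "human"
MOUSE = "mouse"
MOUSE_DESIGN = (10, 10)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic universe.

    Defaults mirror the emulated study: a 20,000-gene universe (the overlap
    null universe), 3 cases vs 4 controls for the primary (human-like)
    dataset, 5% of genes carrying planted fold changes of |log2 FC| = 2,
    half of them shared with the second pseudo-species, and eight
    deletion-region genes at halved case dosage.
    """

    n_genes: int = 20_000
    n_case: int = 3
    n_control: int = 4
    nb_mean_log_mu: float = 5.0       # natural-log scale; mean count ~ e**5
    nb_sigma_log_mu: float = 1.0
    nb_dispersion: float = 0.05
    frac_de: float = 0.05
    lfc_magnitude: float = 2.0
    deletion_genes: tuple[str, ...] | None = None   # default: first 8 universe genes
    shared_fraction: float = 0.5
    ppi_n_edges: int = 50_000          # background edges beyond planted module edges
    module_sizes: tuple[int, ...] = (30, 30, 30, 30)
    module_extra_edges: int = 15
    n_background_terms: int = 50
    background_term_size: int = 15
    background_nonexperimental_fraction: float = 0.3
    n_stages: int = 5
    stage_names: tuple[str, ...] = STAGES
    n_prenatal_max: int = 40
    n_ndd_genes: int = 300
    ndd_de_fraction: float = 0.3   # fraction of the NDD list drawn from planted DEGs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for name in ("frac_de", "shared_fraction", "background_nonexperimental_fraction",
                     "ndd_de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        max_edges = self.n_genes * (self.n_genes - 1) // 2
        if not 0 <= self.ppi_n_edges <= max_edges:
            raise ValueError("ppi_n_edges exceeds the simple-graph maximum")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if len(self.stage_names) != self.n_stages:
            raise ValueError("stage_names length must equal n_stages")
        if self.stage_names[0] != "prenatal":
            raise ValueError("the first stage must be 'prenatal'")
        if self.deletion_genes is not None:
            if not set(self.deletion_genes) <= set(self.gene_ids):
                raise ValueError("deletion_genes must lie inside the gene universe")

    @cached_property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"G{i:05d}" for i in range(self.n_genes))

    @cached_property
    def mouse_gene_ids(self) -> tuple[str, ...]:
        return tuple(f"g{i:05d}" for i in range(self.n_genes))

    def region_genes(self) -> tuple[str, ...]:
        if self.deletion_genes is not None:
            return self.deletion_genes
        return self.gene_ids[: min(8, self.n_genes)]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth, all in the shared (human-style) id space."""

    true_deg_sets: Mapping[str, frozenset[str]]
    true_shared_set: frozenset[str]
    planted_activated_modules: frozenset[str]
    planted_inactivated_modules: frozenset[str]
    module_genes: Mapping[str, tuple[str, ...]]
    true_prenatal_max_genes: frozenset[str]
    effects: Mapping[str, pd.Series] = field(repr=False, compare=False)  # per-species planted log2 FC

    def __post_init__(self) -> None:
        for species, s in self.true_deg_sets.items():
            if not self.true_shared_set <= s:
                raise ValueError(f"shared set must be a subset of the {species} DEG set")
        seen: set[str] = set()
        for term, genes in self.module_genes.items():
            if seen & set(genes):
                raise ValueError(f"planted module {term} overlaps another planted module")
            seen |= set(genes)


@dataclass
class SyntheticBundle:
    config: SimConfig
    truth: SyntheticTruth
    counts: dict[str, CountMatrix]
    ppi: nx.Graph
    annotations: pd.DataFrame
    stage_expression: pd.DataFrame
    tissue_expression: pd.DataFrame
    orthology: pd.DataFrame
    ndd_genes: frozenset[str]


def plan_truth(config: SimConfig) -> SyntheticTruth:
    """Draw the planted-truth plan (which genes do what) for a configuration.

    The plan is shared by every generator: both species' count matrices, the
    PPI graph, the annotations and the stage profiles all read the same plan,
    so cross-artefact structure (shared DEGs, DEG-bearing modules,
    prenatal-maximum DEGs) is consistent by construction.
    """
    rng = substream(config.seed, "plan")
    genes = np.array(config.gene_ids)
    region = set(config.region_genes())

    n_de = int(round(config.frac_de * config.n_genes))
    eligible = np.array([g for g in genes if g not in region])

    # planted modules first: disjoint, drawn from the eligible pool,
    # alternating activated / inactivated direction
    module_genes: dict[str, tuple[str, ...]] = {}
    module_dir: dict[str, str] = {}
    pool = rng.permutation(eligible)
    offset = 0
    for i, size in enumerate(config.module_sizes):
        term = f"GO:91{i:05d}"
        module_genes[term] = tuple(sorted(pool[offset: offset + size]))
        module_dir[term] = "activated" if i % 2 == 0 else "inactivated"
        offset += size
    planted_module_members = [g for gs in module_genes.values() for g in gs]
    if len(planted_module_members) > n_de:
        raise ValueError("module_sizes exceed the planted DEG budget (frac_de * n_genes)")

    # human DE set = module members + random fill from the remaining pool
    fill = pool[offset: offset + (n_de - len(planted_module_members))]
    human_de = sorted(set(planted_module_members) | set(fill))

    # shared subset also differential in the mouse; mouse topped up with
    # genes differential only there
    n_shared = int(round(config.shared_fraction * n_de))
    shared = set(rng.choice(np.array(human_de), size=min(n_shared, len(human_de)), replace=False))
    remaining = np.array(sorted(set(eligible) - set(human_de)))
    n_mouse_only = n_de - len(shared)
    mouse_only = set(rng.choice(remaining, size=min(n_mouse_only, len(remaining)), replace=False))
    mouse_de = sorted(shared | mouse_only)

    # planted signs: module members follow their module's direction,
    # everything else is a coin flip; shared genes keep one sign in both species
    sign = pd.Series(rng.choice([-1.0, 1.0], size=config.n_genes), index=genes)
    for term, gs in module_genes.items():
        sign[list(gs)] = 1.0 if module_dir[term] == "activated" else -1.0

    def effect_series(de: list[str]) -> pd.Series:
        eff = pd.Series(0.0, index=genes)
        eff[de] = sign[de] * config.lfc_magnitude
        return eff

    # prenatal-maximum genes: half planted among human DEGs (outside modules,
    # so the module fold changes stay unconstrained), half among non-DE genes
    non_module_de = sorted(set(human_de) - set(planted_module_members))
    k = min(config.n_prenatal_max, len(non_module_de) + len(remaining))
    k_de = min(k // 2, len(non_module_de))
    pre_de = rng.choice(np.array(non_module_de), size=k_de, replace=False) if k_de else []
    pre_bg = rng.choice(remaining, size=k - k_de, replace=False) if k - k_de else []
    prenatal = frozenset(map(str, [*pre_de, *pre_bg]))

    return SyntheticTruth(
        true_deg_sets={HUMAN: frozenset(human_de), MOUSE: frozenset(mouse_de)},
        true_shared_set=frozenset(shared),
        planted_activated_modules=frozenset(t for t, d in module_dir.items() if d == "activated"),
        planted_inactivated_modules=frozenset(t for t, d in module_dir.items() if d == "inactivated"),
        module_genes=module_genes,
        true_prenatal_max_genes=prenatal,
        effects={HUMAN: effect_series(human_de), MOUSE: effect_series(mouse_de)},
    )


def generate_counts(
    config: SimConfig,
    species_label: str = HUMAN,
    truth: SyntheticTruth | None = None,
    n_case: int | None = None,
    n_control: int | None = None,
) -> tuple[CountMatrix, frozenset[str]]:
    """Negative-binomial count matrix for one pseudo-species.

    Returns the matrix and the planted DEG set in the matrix's own id space
    (mouse matrices carry mouse-style ids).  Case means are the control
    means times 2**(planted log2 FC), and times 0.5 for deletion-region
    genes (uncompensated haploinsufficiency).
    """
    if truth is None:
        truth = plan_truth(config)
    n_case = config.n_case if n_case is None else n_case
    n_control = config.n_control if n_control is None else n_control
    if n_case < 1 or n_control < 1:
        raise ValueError("sample counts must be positive")

    rng = substream(config.seed, "counts", species_label)
    genes = np.array(config.gene_ids)
    mu = np.exp(rng.normal(config.nb_mean_log_mu, config.nb_sigma_log_mu, config.n_genes))

    effects = truth.effects.get(species_label)
    if effects is None:
        effects = pd.Series(0.0, index=genes)
    multiplier = np.power(2.0, effects.to_numpy())
    region_mask = np.isin(genes, np.array(config.region_genes()))
    multiplier = np.where(region_mask, multiplier * 0.5, multiplier)

    r = 1.0 / config.nb_dispersion

    def draw(mean: np.ndarray, n_samples: int) -> np.ndarray:
        p = r / (r + mean)
        return rng.negative_binomial(r, p[:, None], size=(config.n_genes, n_samples))

    case = draw(mu * multiplier, n_case)
    ctrl = draw(mu, n_control)
    cols = [f"{species_label}_case_{i + 1}" for i in range(n_case)] + [
        f"{species_label}_control_{i + 1}" for i in range(n_control)
    ]
    row_ids = config.mouse_gene_ids if species_label == MOUSE else config.gene_ids
    counts = pd.DataFrame(
        np.hstack([case, ctrl]), index=pd.Index(row_ids, name="gene"), columns=cols
    )
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=cols)

    de_universe_ids = truth.true_deg_sets.get(species_label, frozenset())
    if species_label == MOUSE:
        to_mouse = dict(zip(config.gene_ids, config.mouse_gene_ids, strict=True))
        planted = frozenset(to_mouse[g] for g in de_universe_ids)
    else:
        planted = frozenset(de_universe_ids)
    return CountMatrix(counts, groups), planted


def generate_ppi(config: SimConfig, truth: SyntheticTruth | None = None) -> nx.Graph:
    """Sparse undirected PPI graph with internally connected planted modules.

    Each planted module receives a random spanning tree plus a few extra
    internal edges; the background is Erdos-Renyi by edge count
    (``ppi_n_edges`` edges drawn uniformly among all remaining pairs).
    """
    if truth is None:
        truth = plan_truth(config)
    rng = substream(config.seed, "ppi")
    genes = config.gene_ids
    g = nx.Graph()
    g.add_nodes_from(genes)
    index = {gene: i for i, gene in enumerate(genes)}

    for term in sorted(truth.module_genes):
        members = list(truth.module_genes[term])
        order = [members[i] for i in rng.permutation(len(members))]
        for i in range(1, len(order)):
            parent = order[int(rng.integers(0, i))]
            g.add_edge(order[i], parent)
        for _ in range(config.module_extra_edges):
            a, b = rng.choice(len(members), size=2, replace=False)
            g.add_edge(members[a], members[b])

    existing = {tuple(sorted((index[a], index[b]))) for a, b in g.edges}
    target = config.ppi_n_edges
    added = 0
    while added < target:
        batch = max(1024, 2 * (target - added))
        a = rng.integers(0, config.n_genes, size=batch)
        b = rng.integers(0, config.n_genes, size=batch)
        for x, y in zip(a, b, strict=True):
            if x == y:
                continue
            key = (int(x), int(y)) if x < y else (int(y), int(x))
            if key in existing:
                continue
            existing.add(key)
            g.add_edge(genes[key[0]], genes[key[1]])
            added += 1
            if added == target:
                break
    return g


def generate_go_annotations(config: SimConfig, truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """GAF-like annotation table (gene, term, evidence, aspect).

    Planted modules become GO BP terms annotating exactly their genes with
    experimental evidence.  Background terms annotate random gene sets; a
    configurable fraction of their rows carries the non-experimental IEA
    code to exercise the evidence filter.
    """
    if truth is None:
        truth = plan_truth(config)
    rng = substream(config.seed, "annotations")
    exp_codes = sorted(EXPERIMENTAL_EVIDENCE_CODES)
    rows: list[tuple[str, str, str, str]] = []
    for term in sorted(truth.module_genes):
        for gene in truth.module_genes[term]:
            rows.append((gene, term, exp_codes[int(rng.integers(0, len(exp_codes)))], "P"))
    genes = np.array(config.gene_ids)
    for i in range(config.n_background_terms):
        term = f"GO:80{i:05d}"
        members = rng.choice(genes, size=min(config.background_term_size, config.n_genes),
                             replace=False)
        for gene in members:
            if rng.random() < config.background_nonexperimental_fraction:
                code = "IEA"
            else:
                code = exp_codes[int(rng.integers(0, len(exp_codes)))]
            rows.append((str(gene), term, code, "P"))
    return pd.DataFrame(rows, columns=["gene", "term", "evidence", "aspect"])


def generate_stage_expression(config: SimConfig, truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """Gene x developmental-stage RPKM matrix with planted prenatal peaks.

    Planted prenatal-maximum genes strictly exceed both the 1.5 RPKM
    threshold and every postnatal stage in the prenatal column.  All other
    genes are constructed never to peak prenatally (their largest value is
    swapped into a postnatal stage), so the downstream prenatal-maximum rule
    recovers exactly the planted set.
    """
    if truth is None:
        truth = plan_truth(config)
    rng = substream(config.seed, "stages")
    n, k = config.n_genes, config.n_stages
    values = np.exp(rng.normal(0.5, 1.0, size=(n, k)))

    # background genes: move each row's maximum out of the prenatal column
    argmax = values.argmax(axis=1)
    swap = argmax == 0
    values[swap, 0], values[swap, -1] = values[swap, -1], values[swap, 0].copy()

    planted = sorted(truth.true_prenatal_max_genes)
    idx = {g: i for i, g in enumerate(config.gene_ids)}
    rows = np.array([idx[g] for g in planted], dtype=int)
    if rows.size:
        post = rng.uniform(0.0, 1.2, size=(rows.size, k - 1))
        pre = post.max(axis=1) + rng.uniform(0.6, 3.0, size=rows.size) + 1.5
        values[rows, 0] = pre
        values[rows, 1:] = post
    return pd.DataFrame(values, index=pd.Index(config.gene_ids, name="gene"),
                        columns=list(config.stage_names))


def generate_tissue_expression(config: SimConfig, truth: SyntheticTruth | None = None) -> pd.DataFrame:
    """Gene x tissue TPM table (adult brain cortex and blood).

    Planted prenatal-maximum genes are silenced in the adult cortex
    (TPM < 1.5) so the adult-silent filter admits them; other genes draw
    log-normal TPMs in both tissues.
    """
    if truth is None:
        truth = plan_truth(config)
    rng = substream(config.seed, "tissues")
    cortex = np.exp(rng.normal(1.0, 1.2, size=config.n_genes))
    blood = np.exp(rng.normal(1.0, 1.2, size=config.n_genes))
    expr = pd.DataFrame(
        {"brain_cortex": cortex, "blood": blood},
        index=pd.Index(config.gene_ids, name="gene"),
    )
    planted = sorted(truth.true_prenatal_max_genes)
    expr.loc[planted, "brain_cortex"] = rng.uniform(0.0, 1.4, size=len(planted))
    return expr


def generate_ndd_genes(config: SimConfig, truth: SyntheticTruth | None = None) -> frozenset[str]:
    """A curated-disease-gene stand-in list enriched in planted DEGs.

    ``ndd_de_fraction`` of the list is drawn from the planted human DEG set
    (so downstream binomial enrichment has signal to find); the remainder is
    drawn from the rest of the universe.
    """
    if truth is None:
        truth = plan_truth(config)
    rng = substream(config.seed, "ndd")
    de = np.array(sorted(truth.true_deg_sets[HUMAN]))
    rest = np.array(sorted(set(config.gene_ids) - set(de)))
    n_de = min(int(round(config.ndd_de_fraction * config.n_ndd_genes)), de.size)
    n_rest = min(config.n_ndd_genes - n_de, rest.size)
    chosen = [
        *(rng.choice(de, size=n_de, replace=False) if n_de else []),
        *(rng.choice(rest, size=n_rest, replace=False) if n_rest else []),
    ]
    return frozenset(map(str, chosen))


def generate_orthology(config: SimConfig) -> pd.DataFrame:
    """1:1 orthology pairs mapping mouse-style ids onto the shared universe."""
    return pd.DataFrame({
        "source": list(config.mouse_gene_ids),
        "target": list(config.gene_ids),
    })


def simulate_all(config: SimConfig) -> SyntheticBundle:
    """Generate every pipeline input for one configuration.

    The human-like dataset uses the configured design (default 3 vs 4); the
    mouse-like dataset uses a 10 vs 10 design mirroring the emulated cortex
    cohort.
    """
    truth = plan_truth(config)
    human, _ = generate_counts(config, HUMAN, truth)
    mouse, _ = generate_counts(config, MOUSE, truth,
                               n_case=MOUSE_DESIGN[0], n_control=MOUSE_DESIGN[1])
    return SyntheticBundle(
        config=config,
        truth=truth,
        counts={HUMAN: human, MOUSE: mouse},
        ppi=generate_ppi(config, truth),
        annotations=generate_go_annotations(config, truth),
        stage_expression=generate_stage_expression(config, truth),
        tissue_expression=generate_tissue_expression(config, truth),
        orthology=generate_orthology(config),
        ndd_genes=generate_ndd_genes(config, truth),
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write every artefact of a bundle to ``outdir`` as plain-text files.

    Emits per-species count TSVs, the PPI edge list, GAF-like annotations,
    stage and tissue expression TSVs, the orthology pairs, region/NDD-style
    gene sets derived from the truth, and the truth JSON.  Returns a map of
    artefact name to written path.
    """
    from pathlib import Path

    from . import io as dio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def note(key: str, p) -> None:
        paths[key] = str(p)

    for species, m in bundle.counts.items():
        p = out / f"counts_{species}.tsv"
        dio.write_counts_tsv(m, p)
        note(f"counts_{species}", p)
    dio.write_edge_list(bundle.ppi, out / "ppi_edges.tsv"); note("ppi", out / "ppi_edges.tsv")
    dio.write_annotations(bundle.annotations, out / "go_annotations.tsv")
    note("annotations", out / "go_annotations.tsv")
    dio.write_expression_tsv(bundle.stage_expression, out / "stage_expression.tsv")
    note("stage_expression", out / "stage_expression.tsv")
    dio.write_expression_tsv(bundle.tissue_expression, out / "tissue_expression.tsv")
    note("tissue_expression", out / "tissue_expression.tsv")
    dio.write_pairs_tsv(bundle.orthology, out / "orthology.tsv")
    note("orthology", out / "orthology.tsv")
    dio.write_gmt({"deletion_region": sorted(bundle.config.region_genes())},
                  out / "deletion_region.gmt")
    note("region_genes", out / "deletion_region.gmt")
    dio.write_gmt({"ndd": sorted(bundle.ndd_genes)}, out / "ndd_genes.gmt")
    note("ndd_genes", out / "ndd_genes.gmt")
    dio.write_truth_json(bundle.truth, out / "truth.json")
    note("truth", out / "truth.json")
    return paths


def deletion_region_example() -> tuple[tuple[str, ...], pd.DataFrame]:
    """Synthetic tissue-expression fixture for the eight 15q13.3 region genes.

    The TPM values are invented (synthetic stand-ins, not measurements)
    but reproduce the qualitative pattern of the locus: four genes (FAN1,
    MTMR10, KLF13, OTUD7A) expressed above 1.5 TPM in adult brain cortex,
    of which MTMR10 and KLF13 are also highly expressed in blood, while
    CHRNA7, TRPM1, ARHGAP11B and MIR211 are low in both tissues.
    """
    region = ("CHRNA7", "FAN1", "TRPM1", "KLF13", "OTUD7A", "MTMR10", "ARHGAP11B", "MIR211")
    expr = pd.DataFrame(
        {
            "brain_cortex": [0.3, 12.0, 0.1, 22.0, 5.1, 8.5, 0.6, 0.0],
            "blood": [0.1, 0.5, 0.05, 45.0, 0.8, 30.0, 0.2, 0.0],
        },
        index=pd.Index(region, name="gene"),
    )
    return region, expr
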