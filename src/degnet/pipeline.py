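"""End-to-end orchestration: DEG calling per dataset, cross-species
overlap, functional-module activity, dosage and developmental-stage
analyses, with a reproducible output bundle.

Every stage writes its table under the output directory, a machine-readable
``summary.json`` collects the headline numbers, and a run log records the
seed and every decision-bearing threshold.  Stages whose inputs are missing
are skipped with an explicit notice rather than failing the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as dio
from .activity import score_all_modules, ACTIVATED, INACTIVATED
from .deg import CountMatrix, differential_expression, filter_low_counts, select_degs
from .devstage import (
    dosage_check, ndd_binomial_enrichment, select_brain_silent_degs,
    select_prenatal_max, stage_profile_test,
)
from .network import build_deg_network, extract_functional_modules, filter_experimental_annotations
from .overlap import (
    control_split_overlap, exclude_region_genes, map_orthologs,
    overlap_sets, permutation_overlap_p,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds and sampling sizes for one pipeline run."""

    outdir: Path
    seed: int = 0
    primary: str = "human"
    counts: dict[str, Path] = field(default_factory=dict)       # dataset -> counts TSV
    deg_tables: dict[str, Path] = field(default_factory=dict)   # dataset -> precomputed DEG TSV
    deg_regime: dict[str, str] = field(default_factory=dict)    # dataset -> adjusted|raw
    orthology: dict[str, Path] = field(default_factory=dict)    # dataset -> pairs TSV into primary ids
    ppi: Path | None = None
    annotations: Path | None = None
    region_genes: Path | None = None        # GMT; first set = deletion-region genes
    ndd_genes: Path | None = None           # GMT; first set = NDD genes
    tissue_expression: Path | None = None
    stage_expression: Path | None = None
    alpha: float = 0.05
    low_count_min_total: int = 10
    tpm_threshold: float = 1.5
    rpkm_threshold: float = 1.5
    z_threshold: float = 2.0
    overlap_samplings: int = 100_000
    universe_size: int = 20_000
    n_perm: int = 1000

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        for attr in ("ppi", "annotations", "region_genes", "ndd_genes",
                     "tissue_expression", "stage_expression"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, Path(v))
        self.counts = {k: Path(v) for k, v in self.counts.items()}
        self.deg_tables = {k: Path(v) for k, v in self.deg_tables.items()}
        self.orthology = {k: Path(v) for k, v in self.orthology.items()}
        for t in (self.alpha, self.tpm_threshold, self.rpkm_threshold, self.z_threshold):
            if t <= 0:
                raise ValueError("thresholds must be positive")
        for name, regime in self.deg_regime.items():
            if regime not in ("adjusted", "raw"):
                raise ValueError(f"deg_regime[{name}] must be 'adjusted' or 'raw'")

    @classmethod
    def from_yaml(cls, path: Path | str, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update(overrides)
        return cls(**data)

    def referenced_paths(self) -> list[Path]:
        paths = [*self.counts.values(), *self.deg_tables.values(), *self.orthology.values()]
        for attr in ("ppi", "annotations", "region_genes", "ndd_genes",
                     "tissue_expression", "stage_expression"):
            v = getattr(self, attr)
            if v is not None:
                paths.append(v)
        return paths


def _first_gmt_set(path: Path) -> frozenset[str]:
    sets = dio.read_gmt(path)
    first = next(iter(sets))
    return frozenset(sets[first])


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage for which inputs are available; return the summary."""
    missing = [p for p in config.referenced_paths() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {[str(p) for p in missing]}")
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("degnet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    summary: dict[str, Any] = {"seed": config.seed, "skipped": []}
    cfg_dict = {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(config).items()}
    cfg_dict["counts"] = {k: str(v) for k, v in config.counts.items()}
    cfg_dict["deg_tables"] = {k: str(v) for k, v in config.deg_tables.items()}
    cfg_dict["orthology"] = {k: str(v) for k, v in config.orthology.items()}
    summary["config"] = cfg_dict
    logger.info("run_pipeline seed=%d universe=%d samplings=%d n_perm=%d",
                config.seed, config.universe_size, config.overlap_samplings, config.n_perm)

    try:
        # --- per-dataset differential expression -------------------------
        tables: dict[str, pd.DataFrame] = {}
        matrices: dict[str, CountMatrix] = {}
        for name, path in sorted(config.counts.items()):
            m = dio.read_counts_tsv(path)
            if not isinstance(m, CountMatrix):
                raise ValueError(f"{path}: could not infer case/control labels")
            m = filter_low_counts(m, min_total=config.low_count_min_total)
            matrices[name] = m
            tables[name] = differential_expression(m)
            dio.write_deg_table(tables[name], out / f"deg_{name}.tsv")
        for name, path in sorted(config.deg_tables.items()):
            tables[name] = dio.read_deg_table(path)

        deg_sets: dict[str, frozenset[str]] = {}
        for name, table in tables.items():
            regime = config.deg_regime.get(
                name, "adjusted" if name == config.primary else "raw")
            deg_sets[name] = select_degs(table, regime=regime, alpha=config.alpha)
            summary.setdefault("degs", {})[name] = {
                "regime": regime, "n": len(deg_sets[name]),
                "n_tested": int(len(table)),
            }

        primary = config.primary
        primary_table = tables.get(primary)
        primary_degs = deg_sets.get(primary, frozenset())

        # --- cross-species overlap ---------------------------------------
        others = sorted(n for n in deg_sets if n != primary)
        mapped: dict[str, frozenset[str]] = {}
        for name in others:
            s = deg_sets[name]
            if name in config.orthology:
                s = map_orthologs(s, dio.read_pairs_tsv(config.orthology[name]))
            mapped[name] = frozenset(s)
        if primary in deg_sets and mapped:
            all_sets = [primary_degs, *[mapped[n] for n in others]]
            counts = overlap_sets(all_sets)
            res = permutation_overlap_p(
                [len(s) for s in all_sets], counts.kway,
                universe_size=config.universe_size,
                n_samplings=config.overlap_samplings, seed=config.seed)
            shared = frozenset(set(primary_degs).intersection(*[set(m) for m in mapped.values()]))
            summary["overlap"] = {
                "datasets": [primary, *others],
                "set_sizes": list(res.set_sizes),
                "observed": res.observed,
                "p_empirical": res.p_empirical,
                "n_samplings": res.n_samplings,
                "universe_size": res.universe_size,
            }
            if config.region_genes is not None:
                region = _first_gmt_set(config.region_genes)
                outside = exclude_region_genes(shared, region)
                res_out = permutation_overlap_p(
                    [len(s) for s in all_sets], len(outside),
                    universe_size=config.universe_size,
                    n_samplings=config.overlap_samplings, seed=config.seed)
                summary["overlap"]["observed_outside_region"] = len(outside)
                summary["overlap"]["p_empirical_outside_region"] = res_out.p_empirical
            dio.write_gmt({"shared_degs": sorted(shared)}, out / "shared_degs.gmt")

            # negative control: split the primary controls in two
            if primary in matrices:
                ctrl_ids = matrices[primary].samples_in_group("control")
                if len(ctrl_ids) >= 4:
                    ctrl = CountMatrix(matrices[primary].counts[ctrl_ids],
                                       matrices[primary].groups[ctrl_ids])
                    split_res, split_set = control_split_overlap(
                        ctrl, [mapped[n] for n in others],
                        universe_size=config.universe_size,
                        n_samplings=config.overlap_samplings,
                        seed=config.seed, alpha=config.alpha,
                        min_total=config.low_count_min_total)
                    summary["control_split"] = {
                        "n_split_degs": len(split_set),
                        "observed": split_res.observed,
                        "p_empirical": split_res.p_empirical,
                    }
        elif primary in deg_sets:
            summary["skipped"].append("overlap: no secondary DEG set")

        # --- functional modules and activity ------------------------------
        if config.ppi is not None and config.annotations is not None and primary_table is not None:
            pin = dio.read_edge_list(config.ppi)
            ann = filter_experimental_annotations(dio.read_annotations(config.annotations))
            net = build_deg_network(primary_degs, pin)
            modules = extract_functional_modules(net, ann, primary_degs)
            scores = score_all_modules(primary_table, modules,
                                       n_perm=config.n_perm, seed=config.seed,
                                       z_threshold=config.z_threshold)
            scores.to_csv(out / "module_activity.tsv", sep="\t", index=False)
            by_term = {m.term_id: m for m in modules}
            for status, fname in ((ACTIVATED, "activated_modules.gmt"),
                                  (INACTIVATED, "inactivated_modules.gmt")):
                chosen = scores.loc[scores["status"] == status, "term_id"]
                dio.write_gmt({t: sorted(by_term[t].genes) for t in chosen}, out / fname)
            summary["modules"] = {
                "n_modules": int(len(scores)),
                "n_activated": int((scores["status"] == ACTIVATED).sum()),
                "n_inactivated": int((scores["status"] == INACTIVATED).sum()),
            }
        else:
            summary["skipped"].append("modules: PPI, annotations or primary DEG table missing")

        # --- dosage + developmental stages --------------------------------
        if config.tissue_expression is not None:
            tissue = dio.read_expression_tsv(config.tissue_expression)
            if config.region_genes is not None:
                region = _first_gmt_set(config.region_genes)
                dc = dosage_check(region, tissue, threshold=config.tpm_threshold)
                summary["dosage"] = {
                    t: {"expressed": sorted(dc.expressed[t]), "low": sorted(dc.low[t])}
                    for t in dc.expressed
                } | {"missing": sorted(dc.missing)}
            if primary_degs:
                silent = select_brain_silent_degs(primary_degs, tissue,
                                                  threshold=config.tpm_threshold)
                summary["brain_silent"] = {
                    "n_selected": len(silent.selected),
                    "n_no_data": len(silent.missing),
                }
                if config.stage_expression is not None:
                    stages = dio.read_expression_tsv(config.stage_expression)
                    if len(silent.selected) >= 2:
                        tukey = stage_profile_test(silent.selected, stages)
                        tukey.to_csv(out / "stage_tukey_pvalues.tsv", sep="\t")
                        summary["stage_test"] = {
                            "p_adult_vs_prenatal": float(tukey.loc["adult", "prenatal"])
                            if {"adult", "prenatal"} <= set(tukey.columns) else None,
                        }
                    prenatal = select_prenatal_max(silent.selected, stages,
                                                   prenatal_threshold=config.rpkm_threshold)
                    dio.write_gmt({"prenatal_max_degs": sorted(prenatal)},
                                  out / "prenatal_max_degs.gmt")
                    summary["prenatal_max"] = {"n_selected": len(prenatal)}
        else:
            summary["skipped"].append("devstage: tissue expression missing")

        # --- NDD enrichment ------------------------------------------------
        if config.ndd_genes is not None and primary_table is not None:
            universe = frozenset(primary_table.index)  # genes tested after the low-count filter
            ndd = _first_gmt_set(config.ndd_genes) & universe
            enr = ndd_binomial_enrichment(primary_degs & universe, ndd, universe)
            summary["ndd"] = {
                "overlap": enr.overlap, "n_degs": enr.n_degs,
                "p0": enr.p0, "p_value": enr.p_value,
                "universe": "genes tested for differential expression",
                "universe_size": len(universe),
            }
        elif config.ndd_genes is not None:
            summary["skipped"].append("ndd: primary DEG table missing")

        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
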