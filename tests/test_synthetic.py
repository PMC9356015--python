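import hashlib

import numpy as np
import pandas as pd
import pytest

from degnet.deg import differential_expression, filter_low_counts
from degnet.network import filter_experimental_annotations
from degnet.synthetic import (
    SimConfig, generate_counts, generate_go_annotations, generate_ppi,
    generate_stage_expression, generate_tissue_expression, plan_truth,
    simulate_all,
)


def checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()


class TestConfigValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frac_de=1.5)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(nb_dispersion=0.0)

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_case=0)

    def test_impossible_edge_count_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=10, ppi_n_edges=100)

    def test_deletion_genes_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_genes=100, deletion_genes=("NOPE",))


class TestTruthPlan:
    def test_shared_subset_invariant(self, bundle):
        truth = bundle.truth
        for s in truth.true_deg_sets.values():
            assert truth.true_shared_set <= s

    def test_planted_modules_disjoint_and_directed(self, bundle):
        truth = bundle.truth
        seen = set()
        for genes in truth.module_genes.values():
            assert not (seen & set(genes))
            seen |= set(genes)
        assert truth.planted_activated_modules | truth.planted_inactivated_modules == set(
            truth.module_genes)

    def test_module_genes_are_planted_human_degs(self, bundle):
        truth = bundle.truth
        for genes in truth.module_genes.values():
            assert set(genes) <= truth.true_deg_sets["human"]

    def test_shared_fraction_sizes(self, small_config, bundle):
        truth = bundle.truth
        n_de = round(small_config.frac_de * small_config.n_genes)
        assert len(truth.true_deg_sets["human"]) == n_de
        assert len(truth.true_deg_sets["mouse"]) == n_de
        assert len(truth.true_shared_set) == round(small_config.shared_fraction * n_de)


class TestCounts:
    def test_same_seed_identical_matrices(self, small_config):
        a, _ = generate_counts(small_config, "human")
        b, _ = generate_counts(small_config, "human")
        assert checksum(a.counts) == checksum(b.counts)

    def test_different_seed_differs(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a, _ = generate_counts(small_config, "human")
        b, _ = generate_counts(other, "human")
        assert checksum(a.counts) != checksum(b.counts)

    def test_deletion_gene_case_mean_is_halved(self):
        # planted 0.5x dosage: with a large case group the sample mean sits
        # within 3 standard errors of half the control mean
        cfg = SimConfig(n_genes=200, frac_de=0.0, module_sizes=(), n_prenatal_max=0,
                        ppi_n_edges=0, nb_sigma_log_mu=0.0, nb_mean_log_mu=np.log(100.0),
                        seed=9)
        m, _ = generate_counts(cfg, "human", n_case=50, n_control=50)
        region = cfg.region_genes()
        case_cols = m.samples_in_group("case")
        ctrl_cols = m.samples_in_group("control")
        for g in region:
            case = m.counts.loc[g, case_cols].to_numpy(dtype=float)
            ctrl_mean = m.counts.loc[g, ctrl_cols].mean()
            se = case.std(ddof=1) / np.sqrt(case.size)
            assert abs(case.mean() - 50.0) < 3 * max(se, 1.0)
            assert ctrl_mean == pytest.approx(100.0, rel=0.35)

    def test_no_signal_null_is_exchangeable(self):
        # frac_de=0 and no deletion effect in the tested rows: a stand-in DE
        # test sees uniform p-values (KS p > 0.01 at 5000 genes)
        from scipy import stats

        cfg = SimConfig(n_genes=5000, frac_de=0.0, module_sizes=(), n_prenatal_max=0,
                        ppi_n_edges=0, seed=21)
        m, _ = generate_counts(cfg, "human", n_case=10, n_control=10)
        keep = [g for g in m.gene_ids if g not in set(cfg.region_genes())]
        from degnet.deg import CountMatrix
        m = CountMatrix(m.counts.loc[keep], m.groups)
        t = differential_expression(filter_low_counts(m))
        assert stats.kstest(t["p_raw"].dropna(), "uniform").pvalue > 0.01

    def test_planted_truth_record_matches_plan(self, small_config, bundle):
        _, planted = generate_counts(small_config, "human", bundle.truth)
        assert planted == bundle.truth.true_deg_sets["human"]

    def test_mouse_matrix_uses_mouse_ids(self, small_config, bundle):
        m, planted = generate_counts(small_config, "mouse", bundle.truth,
                                     n_case=3, n_control=3)
        assert all(g.startswith("g") for g in m.gene_ids)
        assert all(g.startswith("g") for g in planted)

    def test_bad_sample_counts_rejected(self, small_config):
        with pytest.raises(ValueError):
            generate_counts(small_config, "human", n_case=0)


class TestPpi:
    def test_zero_edges_no_modules_empty(self):
        cfg = SimConfig(n_genes=50, ppi_n_edges=0, module_sizes=(), frac_de=0.0,
                        n_prenatal_max=0, seed=0)
        g = generate_ppi(cfg)
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 50

    def test_planted_module_connected(self, bundle):
        import networkx as nx
        for genes in bundle.truth.module_genes.values():
            assert nx.is_connected(bundle.ppi.subgraph(genes))

    def test_determinism(self, small_config):
        a = generate_ppi(small_config)
        b = generate_ppi(small_config)
        assert sorted(map(tuple, map(sorted, a.edges))) == sorted(map(tuple, map(sorted, b.edges)))


class TestAnnotations:
    def test_planted_terms_annotate_exactly_their_genes(self, bundle):
        ann = bundle.annotations
        for term, genes in bundle.truth.module_genes.items():
            rows = ann[ann["term"] == term]
            assert set(rows["gene"]) == set(genes)
            assert len(rows) == len(genes)
            assert rows["evidence"].isin(
                {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"}).all()
            assert (rows["aspect"] == "P").all()

    def test_fully_nonexperimental_background_filtered_away(self):
        cfg = SimConfig(n_genes=200, frac_de=0.2, module_sizes=(5, 5),
                        n_prenatal_max=0, ppi_n_edges=50,
                        background_nonexperimental_fraction=1.0,
                        n_background_terms=5, seed=2)
        ann = filter_experimental_annotations(generate_go_annotations(cfg))
        assert set(ann["term"]) == set(plan_truth(cfg).module_genes)

    def test_no_terms_no_rows(self):
        cfg = SimConfig(n_genes=50, frac_de=0.0, module_sizes=(), n_prenatal_max=0,
                        ppi_n_edges=0, n_background_terms=0, seed=0)
        assert generate_go_annotations(cfg).empty


class TestStageAndTissue:
    def test_planted_genes_peak_prenatally_above_threshold(self, bundle):
        m = bundle.stage_expression
        for g in bundle.truth.true_prenatal_max_genes:
            row = m.loc[g]
            assert row["prenatal"] > 1.5
            assert row["prenatal"] > row.drop("prenatal").max()

    def test_non_planted_genes_never_peak_prenatally(self, bundle):
        m = bundle.stage_expression.drop(index=sorted(bundle.truth.true_prenatal_max_genes))
        assert not (m["prenatal"] >= m.max(axis=1)).any()

    def test_planted_genes_silent_in_adult_cortex(self, bundle):
        t = bundle.tissue_expression
        vals = t.loc[sorted(bundle.truth.true_prenatal_max_genes), "brain_cortex"]
        assert (vals < 1.5).all()


class TestBundleDeterminism:
    def test_full_bundle_checksums_stable(self, small_config, bundle):
        again = simulate_all(small_config)
        assert checksum(bundle.counts["human"].counts) == checksum(again.counts["human"].counts)
        assert checksum(bundle.counts["mouse"].counts) == checksum(again.counts["mouse"].counts)
        assert checksum(bundle.stage_expression) == checksum(again.stage_expression)
        assert checksum(bundle.tissue_expression) == checksum(again.tissue_expression)
        assert checksum(bundle.annotations) == checksum(again.annotations)
        assert bundle.truth == again.truth
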