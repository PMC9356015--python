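from unittest import mock

import numpy as np
import pandas as pd
import pytest

from degnet.activity import (
    DEGENERATE, RankedList, _es_from_positions, classify_module,
    enrichment_score, permutation_z, rank_genes, score_all_modules,
)
from degnet.network import FunctionalModule


def naive_enrichment_score(ranked_ids, members):
    """Literal per-position evaluation: at step i, with j members seen so
    far, the running sum is j/N_f - (i - j)/(N - N_f)."""
    members = set(members)
    n = len(ranked_ids)
    nf = sum(1 for g in ranked_ids if g in members)
    hits, best, s = 0, -np.inf, np.nan
    for i, g in enumerate(ranked_ids, start=1):
        if g in members:
            hits += 1
        s = hits / nf - (i - hits) / (n - nf)
        best = max(best, s)
    return best, s


def table(values: dict) -> pd.DataFrame:
    return pd.DataFrame({"log2_fold_change": pd.Series(values),
                         "p_raw": 0.5, "p_adj": 0.5})


def module(term, genes):
    genes = sorted(genes)
    return FunctionalModule(term_id=term, genes=frozenset(genes),
                            edges=frozenset({(genes[0], genes[1])}),
                            deg_members=frozenset(genes))


class TestRankGenes:
    def test_downward(self):
        r = rank_genes(table({"a": 2.0, "b": -1.0, "c": 0.0}), "downward")
        assert r.gene_ids == ("a", "c", "b")

    def test_upward(self):
        r = rank_genes(table({"a": 2.0, "b": -1.0, "c": 0.0}), "upward")
        assert r.gene_ids == ("b", "c", "a")

    def test_ties_break_by_gene_id_ascending(self):
        r = rank_genes(table({"b": 1.0, "a": 1.0}), "downward")
        assert r.gene_ids == ("a", "b")
        r = rank_genes(table({"b": 1.0, "a": 1.0}), "upward")
        assert r.gene_ids == ("a", "b")

    def test_missing_fold_change_excluded(self):
        r = rank_genes(table({"a": 1.0, "b": np.nan, "c": 0.0}), "downward")
        assert "b" not in r.gene_ids


class TestEnrichmentScore:
    def test_hand_worked_running_sum(self):
        # N=5, members at ranks 1 and 3
        ids = ("m1", "x1", "m2", "x2", "x3")
        es, running = enrichment_score(ids, {"m1", "m2"})
        assert running == pytest.approx([0.5, 1 / 6, 2 / 3, 1 / 3, 0.0])
        assert es == pytest.approx(2 / 3)

    def test_prefix_members_give_exactly_one(self):
        ids = tuple(f"g{i}" for i in range(50))
        es, _ = enrichment_score(ids, set(ids[:7]))
        assert es == 1.0

    def test_running_sum_returns_to_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 500))
            nf = int(rng.integers(1, n))
            ids = tuple(f"g{i}" for i in range(n))
            members = set(rng.choice(n, size=nf, replace=False))
            es, running = enrichment_score(ids, {f"g{i}" for i in members})
            assert abs(running[-1]) < 1e-9
            assert 0.0 <= es <= 1.0 + 1e-12

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(3, 300))
            nf = int(rng.integers(1, n))
            ids = tuple(f"g{i}" for i in range(n))
            members = {f"g{i}" for i in rng.choice(n, size=nf, replace=False)}
            es, _ = enrichment_score(ids, members)
            expected, _ = naive_enrichment_score(ids, members)
            assert es == expected

    def test_positions_shortcut_equals_full_cumsum(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 200))
            nf = int(rng.integers(1, n))
            pos = np.sort(rng.choice(n, size=nf, replace=False))
            ids = tuple(f"g{i}" for i in range(n))
            members = {f"g{i}" for i in pos}
            es_full, _ = enrichment_score(ids, members)
            es_fast = _es_from_positions(pos[None, :], n)[0]
            assert es_fast == pytest.approx(es_full, abs=1e-12)

    def test_empty_and_full_membership_rejected(self):
        ids = ("a", "b", "c")
        with pytest.raises(ValueError):
            enrichment_score(ids, {"z"})
        with pytest.raises(ValueError):
            enrichment_score(ids, {"a", "b", "c"})

    def test_absent_members_dropped_before_nf(self):
        ids = ("a", "b", "c", "d")
        es_with_ghost, _ = enrichment_score(ids, {"a", "ghost"})
        es_plain, _ = enrichment_score(ids, {"a"})
        assert es_with_ghost == es_plain


class TestPermutationZ:
    @staticmethod
    def _ranked(n):
        return RankedList(
            gene_ids=tuple(f"g{i}" for i in range(n)),
            ranking_values=tuple(float(n - i) for i in range(n)),
            direction="downward",
        )

    def test_top_loaded_module_scores_high(self):
        r = self._ranked(1000)
        members = {f"g{i}" for i in range(10)}
        res = permutation_z(r, members, n_perm=1000, seed=0)
        assert res.es == pytest.approx(1.0)
        assert res.z > 2

    def test_same_seed_reproducible(self):
        r = self._ranked(200)
        members = {f"g{i}" for i in range(5, 15)}
        a = permutation_z(r, members, n_perm=500, seed=3)
        b = permutation_z(r, members, n_perm=500, seed=3)
        assert (a.mu, a.sigma, a.z) == (b.mu, b.sigma, b.z)

    def test_null_module_z_is_centred(self):
        # modules placed uniformly at random score like their own null
        r = self._ranked(300)
        rng = np.random.default_rng(4)
        zs = []
        for _ in range(200):
            members = {f"g{i}" for i in rng.choice(300, size=10, replace=False)}
            zs.append(permutation_z(r, members, n_perm=200,
                                    rng=np.random.default_rng(rng.integers(2**31))).z)
        assert abs(np.mean(zs)) < 0.2

    def test_null_sampling_equals_explicit_list_permutation(self):
        # shuffling the ranked list and re-scoring the module is the same
        # null as re-drawing the member positions; compare the two routes
        n, nf = 40, 6
        ids = tuple(f"g{i}" for i in range(n))
        members = {f"g{i}" for i in range(nf)}
        rng = np.random.default_rng(7)
        explicit = []
        for _ in range(4000):
            perm = rng.permutation(n)
            shuffled = tuple(ids[i] for i in perm)
            es, _ = enrichment_score(shuffled, members)
            explicit.append(es)
        r = self._ranked(n)
        res = permutation_z(r, members, n_perm=4000, seed=11)
        assert res.mu == pytest.approx(np.mean(explicit), abs=0.02)
        assert res.sigma == pytest.approx(np.std(explicit, ddof=1), abs=0.02)

    def test_zero_variance_null_flags_degenerate(self):
        r = self._ranked(20)
        fixed = np.tile(np.arange(5), (100, 1))
        with mock.patch("degnet.activity._sample_positions", return_value=fixed):
            res = permutation_z(r, {f"g{i}" for i in range(5)}, n_perm=100, seed=0)
        assert res.degenerate and np.isnan(res.z)


class TestClassifyModule:
    @pytest.mark.parametrize("z_act, z_inact, expected", [
        (2.5, -1.0, "activated"),
        (-0.3, 3.1, "inactivated"),
        (2.5, 0.5, "neither"),
        (0.5, 2.5, "neither"),
        (2.0, -1.0, "neither"),   # strictly greater than the threshold
        (-1.0, -1.0, "neither"),
    ])
    def test_rule(self, z_act, z_inact, expected):
        assert classify_module(z_act, z_inact) == expected

    def test_nan_is_degenerate(self):
        assert classify_module(float("nan"), 1.0) == DEGENERATE

    def test_mutual_exclusivity_is_structural(self):
        rng = np.random.default_rng(0)
        for z_act, z_inact in rng.normal(0, 3, size=(500, 2)):
            status = classify_module(z_act, z_inact)
            both = (z_act > 2 and z_inact < 0) and (z_inact > 2 and z_act < 0)
            assert not both
            assert status in {"activated", "inactivated", "neither"}


class TestScoreAllModules:
    def test_planted_shift_direction_recovered(self):
        rng = np.random.default_rng(0)
        n = 2000
        lfc = pd.Series(rng.normal(0, 1, n), index=[f"g{i:04d}" for i in range(n)])
        up = list(lfc.index[:20])
        down = list(lfc.index[20:40])
        lfc[up] += 2.0
        lfc[down] -= 2.0
        t = pd.DataFrame({"log2_fold_change": lfc, "p_raw": 0.5, "p_adj": 0.5})
        modules = [module("go:up", up), module("go:down", down)]
        scores = score_all_modules(t, modules, n_perm=500, seed=1)
        by_term = scores.set_index("term_id")["status"]
        assert by_term["go:up"] == "activated"
        assert by_term["go:down"] == "inactivated"

    def test_module_absent_from_list_skipped_not_fatal(self):
        t = table({"a": 1.0, "b": 0.0, "c": -1.0})
        modules = [module("go:ghost", ["x", "y"]), module("go:ok", ["a", "b"])]
        scores = score_all_modules(t, modules, n_perm=50, seed=0)
        assert list(scores["term_id"]) == ["go:ok"]

    def test_es_bounds_and_status_consistency(self, bundle):
        from degnet.network import (
            build_deg_network, extract_functional_modules,
            filter_experimental_annotations,
        )
        degs = bundle.truth.true_deg_sets["human"]
        net = build_deg_network(degs, bundle.ppi)
        ann = filter_experimental_annotations(bundle.annotations)
        mods = extract_functional_modules(net, ann, degs)
        lfc = bundle.truth.effects["human"]
        t = pd.DataFrame({"log2_fold_change": lfc + 0.01 * np.random.default_rng(0).normal(size=len(lfc)),
                          "p_raw": 0.5, "p_adj": 0.5})
        scores = score_all_modules(t, mods, n_perm=200, seed=2)
        assert ((scores["es_activity"] >= 0) & (scores["es_activity"] <= 1)).all()
        assert ((scores["es_inactivity"] >= 0) & (scores["es_inactivity"] <= 1)).all()
        for _, row in scores.iterrows():
            assert row["status"] == classify_module(row["z_activity"], row["z_inactivity"])
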