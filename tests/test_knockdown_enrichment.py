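"""DE thresholds, hypergeometric ORA, and the from-scratch GSEA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusionatlas.io_formats import GeneSetCollection
from fusionatlas.knockdown_enrichment import (
    differential_expression,
    enrichment_score,
    gsea,
    marker_panel_table,
    ora,
)
from fusionatlas.synthetic_data import SimulationConfig, simulate_knockdown

from helpers import es_oracle, ora_oracle


@pytest.fixture(scope="module")
def kd_sim():
    return simulate_knockdown(SimulationConfig(seed=42))


@pytest.fixture(scope="module")
def de_result(kd_sim):
    return differential_expression(kd_sim.counts, kd_sim.groups)


class TestDifferentialExpression:
    def test_identical_groups_make_no_calls(self, kd_sim):
        counts = kd_sim.counts[["CT1", "CT2", "CT3", "CT1", "CT2", "CT3"]].copy()
        counts.columns = ["a1", "a2", "a3", "b1", "b2", "b3"]
        groups = {"a1": "knockdown", "a2": "knockdown", "a3": "knockdown",
                  "b1": "control", "b2": "control", "b3": "control"}
        de, _ = differential_expression(counts, groups)
        assert np.allclose(de["log2_fold_change"], 0.0)
        assert (de["status"] == "ns").all()

    def test_planted_genes_recovered_at_paper_thresholds(self, kd_sim, de_result):
        de, _ = de_result
        called = set(de.loc[de["status"] != "ns", "gene"])
        planted = set(kd_sim.truth.de_genes)
        assert len(called & planted) / len(planted) >= 0.8

    def test_direction_matches_planted_sign(self, kd_sim, de_result):
        de, _ = de_result
        by_gene = de.set_index("gene")
        for gene, true_lfc in kd_sim.truth.de_genes.items():
            status = by_gene.at[gene, "status"]
            if status == "up":
                assert true_lfc > 0
            elif status == "down":
                assert true_lfc < 0

    def test_null_type_one_error_near_nominal(self):
        fracs = []
        for seed in range(25):
            kd = simulate_knockdown(SimulationConfig(seed=seed, lfc_de=0.0))
            de, _ = differential_expression(kd.counts, kd.groups)
            fracs.append(float((de["p_value"] < 0.05).mean()))
        pooled = float(np.mean(fracs))
        band = 1.96 * math.sqrt(0.05 * 0.95 / 2000)  # one experiment's resolution
        assert 0.05 - band <= pooled <= 0.05 + band

    def test_all_zero_genes_excluded_and_reported(self, kd_sim):
        counts = kd_sim.counts.copy()
        counts.iloc[0] = 0
        de, excluded = differential_expression(counts, kd_sim.groups)
        assert counts.index[0] in excluded
        assert counts.index[0] not in set(de["gene"])

    def test_input_contract_errors(self, kd_sim):
        with pytest.raises(ValueError, match="samples"):
            differential_expression(kd_sim.counts[["KD1", "CT1", "CT2"]],
                                    kd_sim.groups)
        bad = kd_sim.counts.astype(float).copy()
        bad.iloc[0, 0] = 1.5
        with pytest.raises(ValueError, match="integer"):
            differential_expression(bad, kd_sim.groups)

    def test_bh_fdr_is_monotone_in_p(self, de_result):
        de, _ = de_result
        s = de.sort_values("p_value")
        assert (np.diff(s["fdr"].values) >= -1e-12).all()


class TestOra:
    def test_worked_example_is_one_over_choose(self):
        # universe 20, one set of 5, DE list = exactly that set
        universe = [f"g{i}" for i in range(20)]
        sets = GeneSetCollection(sets={"S": universe[:5]})
        table = ora(universe[:5], universe, sets)
        assert table.at[0, "p_value"] == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_is_near_one(self):
        universe = [f"g{i}" for i in range(30)]
        sets = GeneSetCollection(sets={"S": universe[:5]})
        table = ora(universe[25:27], universe, sets)
        assert table.at[0, "p_value"] > 0.6

    def test_matches_exhaustive_oracle_for_small_universes(self):
        for M in (5, 8, 12):
            universe = [f"g{i}" for i in range(M)]
            for K, n in itertools.product(range(1, M), range(1, M)):
                sets = GeneSetCollection(sets={"S": universe[:K]})
                de = universe[M - n:]
                k = len(set(universe[:K]) & set(de))
                table = ora(de, universe, sets)
                assert table.at[0, "p_value"] == pytest.approx(
                    float(ora_oracle(M, K, n, k)), rel=1e-9
                ), (M, K, n, k)

    def test_disjoint_set_skipped_with_flag(self):
        universe = [f"g{i}" for i in range(10)]
        sets = GeneSetCollection(sets={"S": ["absent1", "absent2"]})
        table = ora(universe[:3], universe, sets)
        assert bool(table.at[0, "skipped"])

    def test_de_outside_universe_raises(self):
        with pytest.raises(ValueError, match="subset"):
            ora(["x"], ["a", "b"], GeneSetCollection(sets={"S": ["a"]}))


class TestGsea:
    def test_es_matches_exact_running_sum_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(60):
            n = int(rng.integers(4, 11))
            scores = np.sort(rng.integers(-5, 6, size=n))[::-1].astype(float)
            k = int(rng.integers(1, n))
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            for weight in (0, 1):
                expected = es_oracle(list(scores), list(mask), weight=weight)
                if expected is None:  # exact +/- magnitude tie: sign is a convention
                    continue
                es, _ = enrichment_score(scores, mask, weight=weight)
                assert es == pytest.approx(float(expected), abs=1e-12), (scores, mask, weight)

    def test_prefix_set_at_weight_zero_equals_ks_statistic(self):
        # set = top-k of the ranking: the running sum peaks at rank k with
        # value 1 - k-th miss fraction = 1 - 0 = k/k - 0... computed exactly
        n, k = 10, 3
        scores = np.arange(n, 0, -1, dtype=float)
        mask = np.zeros(n, dtype=bool)
        mask[:k] = True
        es, peak = enrichment_score(scores, mask, weight=0)
        assert es == pytest.approx(1.0)  # all hits before any miss
        assert peak == k - 1

    def test_planted_set_enriched_null_sets_not(self, kd_sim, de_result):
        de, _ = de_result
        ranking = de.set_index("gene")["log2_fold_change"]
        table = gsea(ranking, kd_sim.gene_sets, n_permutations=1000, seed=5)
        planted = table.set_index("set").loc["PLANTED_UP"]
        assert planted["es"] > 0 and planted["nes"] > 0
        assert planted["fdr"] < 0.05
        nulls = table[table["set"].str.startswith("NULL_")]
        assert (nulls["p_value"] > 0.05).mean() >= 0.8

    def test_null_set_p_values_uniform(self):
        kd = simulate_knockdown(SimulationConfig(seed=9, lfc_de=0.0, n_null_sets=100))
        de, _ = differential_expression(kd.counts, kd.groups)
        ranking = de.set_index("gene")["log2_fold_change"]
        table = gsea(ranking, kd.gene_sets, n_permutations=1000, seed=11)
        assert len(table) == 100
        assert stats.kstest(table["p_value"], "uniform").pvalue > 0.01

    def test_permutation_p_floor_and_determinism(self, kd_sim, de_result):
        de, _ = de_result
        ranking = de.set_index("gene")["log2_fold_change"]
        t1 = gsea(ranking, kd_sim.gene_sets, n_permutations=200, seed=3)
        t2 = gsea(ranking, kd_sim.gene_sets, n_permutations=200, seed=3)
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["p_value"] >= 1 / 201).all()

    def test_oversized_and_degenerate_sets_rejected(self):
        ranking = pd.Series(np.arange(10, 0, -1, dtype=float),
                            index=[f"g{i}" for i in range(10)])
        whole = GeneSetCollection(sets={"ALL": [f"g{i}" for i in range(10)]})
        with pytest.raises(ValueError, match="whole ranked list"):
            gsea(ranking, whole, n_permutations=10, min_size=1, max_size=500)
        mask = np.ones(10, dtype=bool)
        with pytest.raises(ValueError):
            enrichment_score(ranking.values, mask)

    def test_size_bounds_filter_sets(self, kd_sim, de_result):
        de, _ = de_result
        ranking = de.set_index("gene")["log2_fold_change"]
        table = gsea(ranking, kd_sim.gene_sets, n_permutations=50, min_size=500)
        assert table.empty


class TestMarkerPanels:
    def test_single_gene_panel_mean_is_that_gene(self, de_result):
        de, _ = de_result
        gene = de["gene"].iat[0]
        panels = GeneSetCollection(sets={"P": [gene]})
        table = marker_panel_table(de, panels)
        assert table.at[0, "mean_lfc"] == pytest.approx(
            de.set_index("gene").at[gene, "log2_fold_change"]
        )

    def test_empty_intersection_flagged(self, de_result):
        de, _ = de_result
        table = marker_panel_table(de, GeneSetCollection(sets={"P": ["NOPE"]}))
        assert bool(table.at[0, "empty"]) and math.isnan(table.at[0, "mean_lfc"])
        assert table.at[0, "missing_genes"] == "NOPE"

    def test_planted_up_panel_has_positive_mean(self, kd_sim, de_result):
        de, _ = de_result
        table = marker_panel_table(de, kd_sim.gene_sets).set_index("panel")
        assert table.at["PLANTED_UP", "mean_lfc"] > 1.0
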