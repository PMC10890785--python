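"""Expression metric, stage trend, and parent-chimera correlation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fusionatlas.fusion_quantify import (
    expression_heatmap_table,
    expression_metric,
    expression_records,
    parent_chimera_correlation,
    stage_trend,
)
from fusionatlas.io_formats import SampleLibrary, read_genome
from fusionatlas.fusion_classify import classify_all, filter_candidates
from fusionatlas.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_fusions,
    simulate_genome_annotation,
)

from helpers import spearman_oracle


class TestExpressionMetric:
    def test_ten_reads_at_ten_million_is_one(self):
        assert expression_metric(10, 10_000_000) == pytest.approx(1.0)

    def test_single_read_at_ten_million_is_zero(self):
        assert expression_metric(1, 10_000_000) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # 37 reads in a 52M library: log10(37 / 52e6 * 1e7) = log10(7.1153846)
        assert expression_metric(37, 52_000_000) == pytest.approx(
            math.log10(37 / 52e6 * 1e7), abs=1e-12
        )
        assert expression_metric(37, 52_000_000) == pytest.approx(0.8522, abs=1e-4)

    def test_zero_reads_is_undefined_not_zero(self):
        assert math.isnan(expression_metric(0, 1_000_000))

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            expression_metric(5, 0)

    @given(
        su=st.integers(min_value=1, max_value=10**6),
        total=st.integers(min_value=10**6, max_value=10**9),
        factor=st.integers(min_value=2, max_value=50),
    )
    @settings(max_examples=100, deadline=None)
    def test_joint_scaling_invariance(self, su, total, factor):
        assert expression_metric(su * factor, total * factor) == pytest.approx(
            expression_metric(su, total), rel=1e-12
        )

    def test_monotone_in_reads_and_depth(self):
        assert expression_metric(11, 10**7) > expression_metric(10, 10**7)
        assert expression_metric(10, 2 * 10**7) < expression_metric(10, 10**7)


def _series(tmp_path, **overrides):
    cfg = SimulationConfig(seed=overrides.pop("seed", 17), **overrides)
    sim = simulate_genome_annotation(cfg, tmp_path)
    genome = read_genome(sim.fasta_path)
    calls, truth = simulate_fusions(cfg, sim, genome)
    surv = filter_candidates(calls)
    classified = classify_all(surv, {m.gene: m for m in sim.models})
    samples = sorted({(c.sample_id, c.stage_day) for c in calls})
    libs = [SampleLibrary(s, 30_000_000, d) for s, d in samples]
    return cfg, calls, surv, classified, libs


class TestStageTrend:
    def test_noiseless_simulation_is_exactly_linear(self, tmp_path):
        cfg, _, _, classified, libs = _series(tmp_path, noise_sd=0.0)
        t = stage_trend(classified, libs, "intra")
        assert t.r_squared == pytest.approx(1.0, abs=1e-12)
        assert t.slope == pytest.approx(cfg.trend_slope, abs=1e-12)
        assert t.r_squared == pytest.approx(t.r * t.r, abs=1e-12)

    def test_inter_chromosomal_counts_flagged_constant(self, tmp_path):
        _, _, _, classified, libs = _series(tmp_path, noise_sd=0.0)
        t = stage_trend(classified, libs, "inter")
        assert t.flagged == "zero-variance counts"
        assert math.isnan(t.r)

    def test_planted_slope_with_noise_is_detected(self, tmp_path):
        _, _, _, classified, libs = _series(tmp_path, noise_sd=3.0, seed=23)
        t = stage_trend(classified, libs, "intra")
        assert t.p_value < 0.05
        assert t.slope > 0

    def test_permuted_stage_labels_give_uniform_p(self, tmp_path):
        _, _, _, classified, libs = _series(tmp_path, noise_sd=3.0, seed=29)
        rng = np.random.default_rng(0)
        days = [l.stage_day for l in libs]
        ps = []
        for _ in range(200):
            perm = rng.permutation(days)
            plibs = [
                SampleLibrary(l.sample_id, l.total_reads, int(d))
                for l, d in zip(libs, perm)
            ]
            t = stage_trend(classified, plibs, "intra")
            if not math.isnan(t.p_value):
                ps.append(t.p_value)
        assert len(ps) >= 190
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_fewer_than_three_stages_raises(self, tmp_path):
        _, _, _, classified, libs = _series(tmp_path)
        two_stage = [
            SampleLibrary(l.sample_id, l.total_reads, 0 if l.stage_day < 60 else 120)
            for l in libs
        ]
        with pytest.raises(ValueError, match="3 distinct stages"):
            stage_trend(classified, two_stage, "intra")


class TestParentChimeraCorrelation:
    def test_independent_simulation_usually_not_significant(self, tmp_path):
        rejections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg, calls, surv, _, _ = _series(tmp_path / str(seed), seed=seed)
            libs, parents, _ = simulate_expression(cfg, calls)
            expr = expression_records(surv, libs)
            _, pooled = parent_chimera_correlation(expr, parents, libs)
            if pooled.p_value <= 0.05:
                rejections += 1
        assert rejections <= 0.1 * n_seeds + 1

    def test_exact_monotone_parent_gives_rho_one(self):
        # one fusion seen in 8 libraries of equal depth; parent counts an
        # exact monotone function of the spanning reads
        libs = [SampleLibrary(f"s{i}", 10**7, 15 * i) for i in range(8)]
        su = [1, 2, 3, 5, 8, 13, 21, 34]
        expr = pd.DataFrame({
            "fusion_id": ["f"] * 8,
            "gene5": ["P5"] * 8,
            "gene3": ["P5"] * 8,
            "sample_id": [l.sample_id for l in libs],
            "stage_day": [l.stage_day for l in libs],
            "spanning_unique_reads": su,
            "metric": [expression_metric(s, 10**7) for s in su],
        })
        parents = pd.DataFrame({l.sample_id: [100 * s] for l, s in zip(libs, su)}, index=["P5"])
        _, pooled = parent_chimera_correlation(
            expr, parents, libs, parent_totals={l.sample_id: 10**7 for l in libs}
        )
        assert pooled.rho == pytest.approx(1.0)

    def test_too_few_pairs_raises(self):
        libs = [SampleLibrary(f"s{i}", 10**7, i) for i in range(3)]
        expr = pd.DataFrame({
            "fusion_id": ["f"] * 3, "gene5": ["P"] * 3, "gene3": ["Q"] * 3,
            "sample_id": [l.sample_id for l in libs], "stage_day": [0, 1, 2],
            "spanning_unique_reads": [1, 2, 3],
            "metric": [0.1, 0.2, 0.3],
        })
        parents = pd.DataFrame(
            {l.sample_id: [5] for l in libs}, index=["ZZZ"]  # parents absent
        )
        with pytest.raises(ValueError, match="paired observations"):
            parent_chimera_correlation(expr, parents, libs)

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 8), st.integers(0, 8)), min_size=3, max_size=6
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_spearman_matches_rank_oracle(self, data):
        x = [a for a, _ in data]
        y = [b for _, b in data]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        rho = stats.spearmanr(x, y).statistic
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestHeatmapTable:
    def test_single_fusion_all_stages(self, tmp_path):
        cfg, calls, surv, _, _ = _series(tmp_path)
        libs, _, _ = simulate_expression(cfg, calls)
        expr = expression_records(surv, libs)
        one = expr[expr["fusion_id"] == expr["fusion_id"].iat[0]]
        table = expression_heatmap_table(one)
        assert table.shape[0] == 1

    def test_absent_cells_stay_missing(self):
        expr = pd.DataFrame({
            "fusion_id": ["f", "f"], "gene5": ["A", "A"], "gene3": ["B", "B"],
            "sample_id": ["s1", "s2"], "stage_day": [0, 30],
            "spanning_unique_reads": [3, 0],
            "metric": [0.5, math.nan],
        })
        table = expression_heatmap_table(expr)
        assert table.at["f", 0] == pytest.approx(0.5)
        assert math.isnan(table.at["f", 30])

    def test_cell_totals_match_records(self, tmp_path):
        cfg, calls, surv, _, _ = _series(tmp_path)
        libs, _, _ = simulate_expression(cfg, calls)
        expr = expression_records(surv, libs)
        table = expression_heatmap_table(expr)
        # sum of all defined cells = sum over per-(fusion,stage) means
        expected = (
            expr.dropna(subset=["metric"])
            .groupby(["fusion_id", "stage_day"])["metric"].mean().sum()
        )
        assert np.nansum(table.values) == pytest.approx(expected)
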