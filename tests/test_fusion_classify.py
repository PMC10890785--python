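"""Filtering, breakpoint anatomy and junction-effect classification."""

import pytest

from fusionatlas.fusion_classify import (
    classify_all,
    classify_chromosomal,
    classify_effect,
    filter_candidates,
    locate_breakpoint,
    resolve_models,
    summarize_biotypes,
    summarize_classes,
)
from fusionatlas.io_formats import Breakpoint, FusionCall, TranscriptModel

from helpers import reflect_call, reflect_genome, reflect_model, translation_oracle


def _call(bp5="1:100:+", bp3="1:200:+", reads=1, gene5="A", gene3="B"):
    from fusionatlas.io_formats import parse_breakpoint

    return FusionCall(
        gene5=gene5, gene3=gene3,
        bp5=parse_breakpoint(bp5), bp3=parse_breakpoint(bp3),
        spanning_unique_reads=reads, sample_id="s",
    )


class TestFilter:
    def test_keeps_exactly_reads_ge_one_in_order(self):
        calls = [_call(reads=r) for r in (0, 1, 5, 0)]
        kept = filter_candidates(calls)
        assert [c.spanning_unique_reads for c in kept] == [1, 5]

    def test_all_zero_input_empties(self):
        assert filter_candidates([_call(reads=0)] * 3) == []

    def test_simulated_survivors_match_truth_recount(self, fusion_data):
        calls, _ = fusion_data
        expected = sum(1 for c in calls if c.spanning_unique_reads >= 1)
        assert len(filter_candidates(calls)) == expected


class TestChromosomalRelation:
    def test_ctcl_breakpoints_are_intra(self):
        call = _call("1:9871187:-", "1:9773394:-")
        assert classify_chromosomal(call) == "intra"

    def test_different_chromosomes_are_inter(self):
        assert classify_chromosomal(_call("chr1:5:+", "chr2:5:+")) == "inter"

    def test_agrees_with_simulated_truth(self, fusion_data):
        calls, truth = fusion_data
        got = [classify_chromosomal(c) for c in calls]
        assert got == truth.call_relations


PLUS_GENE = TranscriptModel(
    gene="TOY", transcript_id="TOY.t1", chrom="c1", strand="+",
    exons=((81, 140), (161, 220)), cds=((101, 140), (161, 180)),
)
# coordinate mirror of PLUS_GENE in a 300-bp chromosome (pos -> 301 - pos)
MINUS_GENE = TranscriptModel(
    gene="TOY", transcript_id="TOY.t1", chrom="c1", strand="-",
    exons=((161, 220), (81, 140)), cds=((161, 200), (121, 140)),
)


class TestLocateBreakpoint:
    def test_cds_breakpoint_counts_retained_bases(self):
        # CDS spans 101-140 and 161-180; bp at 130 retains bases 101..130
        region, l5 = locate_breakpoint(Breakpoint("c1", 130, "+"), PLUS_GENE, "five_prime")
        assert region == "cds" and l5 == 30

    def test_minus_strand_mirror_gives_same_count(self):
        region, l5 = locate_breakpoint(Breakpoint("c1", 301 - 130, "-"), MINUS_GENE, "five_prime")
        assert region == "cds" and l5 == 30

    def test_three_prime_count_is_exclusive(self):
        region, s3 = locate_breakpoint(Breakpoint("c1", 101, "+"), PLUS_GENE, "three_prime")
        assert region == "cds" and s3 == 0
        _, s3 = locate_breakpoint(Breakpoint("c1", 161, "+"), PLUS_GENE, "three_prime")
        assert s3 == 40

    def test_upstream_of_tss_is_intergenic(self):
        region, _ = locate_breakpoint(Breakpoint("c1", 50, "+"), PLUS_GENE, "five_prime")
        assert region == "intergenic"

    def test_regions_cover_utr_and_intron(self):
        assert locate_breakpoint(Breakpoint("c1", 90, "+"), PLUS_GENE, "five_prime")[0] == "five_prime_utr"
        assert locate_breakpoint(Breakpoint("c1", 150, "+"), PLUS_GENE, "five_prime")[0] == "intron"
        assert locate_breakpoint(Breakpoint("c1", 200, "+"), PLUS_GENE, "five_prime")[0] == "three_prime_utr"

    def test_wrong_chromosome_raises(self):
        with pytest.raises(ValueError, match="chromosome"):
            locate_breakpoint(Breakpoint("c2", 130, "+"), PLUS_GENE, "five_prime")


class TestClassifyEffect:
    def test_matches_planted_truth_exactly(self, fusion_data, classified):
        calls, truth = fusion_data
        surviving_truth = [
            t for c, t in zip(calls, truth.call_classes) if c.spanning_unique_reads >= 1
        ]
        assert [c.effect for c in classified] == surviving_truth

    def test_cds_cds_calls_match_translation_oracle(self, resolved, sim_genome, genome):
        from fusionatlas.synthetic_data import SimulationConfig, simulate_fusion_pool

        cfg = SimulationConfig(seed=55, class_mix={"In-frame": 0.5, "Out-of-frame": 0.5})
        pool = simulate_fusion_pool(cfg, sim_genome, genome, 100)
        calls = [
            FusionCall(gene5=e.gene5, gene3=e.gene3, bp5=e.bp5, bp3=e.bp3,
                       spanning_unique_reads=1, sample_id="s")
            for e in pool
        ]
        classified = classify_all(calls, resolved, genome)
        assert {c.effect for c in classified} == {"In-frame", "Out-of-frame"}
        for c in classified:
            expected = translation_oracle(
                c.call, resolved[c.call.gene5], resolved[c.call.gene3], sim_genome.fasta_path
            )
            assert (c.effect == "In-frame") == expected, c.call.fusion_id

    def test_one_base_shift_flips_frame_parity(self, classified, resolved, genome):
        shifted = 0
        for c in classified:
            if c.effect != "In-frame":
                continue
            m3 = resolved[c.call.gene3]
            bp3 = c.call.bp3
            # one exonic base further 3' in transcript order
            new_pos = bp3.pos + 1 if m3.strand == "+" else bp3.pos - 1
            if m3.region_of(new_pos) != "cds":
                continue
            call2 = FusionCall(
                gene5=c.call.gene5, gene3=c.call.gene3, bp5=c.call.bp5,
                bp3=Breakpoint(bp3.chrom, new_pos, bp3.strand),
                spanning_unique_reads=c.call.spanning_unique_reads,
                sample_id=c.call.sample_id,
            )
            effect, *_ = classify_effect(call2, resolved[c.call.gene5], m3, genome)
            assert effect == "Out-of-frame"
            shifted += 1
            if shifted >= 25:
                break
        assert shifted >= 10

    def test_in_frame_parity_invariant(self, classified):
        for c in classified:
            if c.effect == "In-frame":
                assert (c.retained_cds5 - c.skipped_cds3) % 3 == 0
            if c.effect == "Out-of-frame":
                assert (c.retained_cds5 - c.skipped_cds3) % 3 != 0

    def test_unresolvable_gene_is_unclassified(self, resolved, genome):
        call = _call(gene5="NOSUCH", gene3="NOSUCH2")
        effect, *_ = classify_effect(call, None, None, genome)
        assert effect == "unclassified"

    def test_totality_every_call_classified(self, classified):
        from fusionatlas.fusion_classify import EFFECT_CLASSES

        assert all(c.effect in EFFECT_CLASSES for c in classified)

    def test_strand_reflection_leaves_effects_unchanged(
        self, tmp_path, classified, resolved, sim_genome
    ):
        from fusionatlas.io_formats import read_genome

        lengths = reflect_genome(sim_genome.fasta_path, tmp_path / "reflected.fa")
        rgenome = read_genome(tmp_path / "reflected.fa")
        rmodels = {g: reflect_model(m, lengths) for g, m in resolved.items()}
        subset = classified[:150]
        rcalls = [reflect_call(c.call, lengths) for c in subset]
        reflected = classify_all(rcalls, rmodels, rgenome)
        assert [r.effect for r in reflected] == [c.effect for c in subset]


class TestBiotypesAndSummaries:
    def test_all_protein_coding_fixture_sums_to_one(self):
        pairs = summarize_biotypes(
            classify_all([_call("c1:130:+", "c1:200:+", gene5="TOY", gene3="TOY2")], {
                "TOY": PLUS_GENE,
                "TOY2": TranscriptModel(
                    gene="TOY2", transcript_id="TOY2.t1", chrom="c1", strand="+",
                    exons=((100, 300),), cds=((150, 250),),
                ),
            })
        )
        assert len(pairs) == 1
        assert pairs.iloc[0]["proportion"] == 1.0
        assert pairs.iloc[0][["biotype5", "biotype3"]].tolist() == [
            "protein_coding", "protein_coding"]

    def test_summaries_on_empty_input(self):
        assert summarize_classes([]).empty
        assert summarize_biotypes([]).empty

    def test_class_proportions_sum_to_one(self, classified):
        s = summarize_classes(classified)
        assert s["proportion"].sum() == pytest.approx(1.0)
        assert s["count"].sum() == len(classified)

    def test_biotypes_follow_truth(self, classified, fusion_data):
        _, truth = fusion_data
        for c in classified:
            assert c.biotype5 == truth.gene_biotypes[c.call.gene5]
            assert c.biotype3 == truth.gene_biotypes[c.call.gene3]


class TestModelResolution:
    def test_longest_cds_wins_then_lexicographic(self):
        short = TranscriptModel("G", "G.t2", "c", "+", ((1, 100),), ((10, 39),))
        long = TranscriptModel("G", "G.t9", "c", "+", ((1, 100),), ((10, 69),))
        tie = TranscriptModel("G", "G.t1", "c", "+", ((1, 100),), ((20, 79),))
        resolved = resolve_models([short, long, tie])
        assert resolved["G"].transcript_id == "G.t1"  # tie on length 60 -> smallest id
        resolved = resolve_models([short, long])
        assert resolved["G"].transcript_id == "G.t9"
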