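#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Emulates the study design: a toy genome + GTF whose introns carry canonical
GT..AG splice sites, fusion calls across eight developmental stages (days
0-120, 2-3 replicates each, 22 libraries) with a planted linear increase in
intra-chromosomal events, per-library depths and parental-gene counts, and
a two-group knockdown count matrix with planted DE genes and one enriched
gene set. Everything lands under results/data/.
"""

import sys
from pathlib import Path

import pandas as pd

from fusionatlas.io_formats import read_genome, write_counts, write_fusion_table, write_gmt, write_libraries
from fusionatlas.synthetic_data import (
    SimulationConfig,
    simulate_expression,
    simulate_fusions,
    simulate_genome_annotation,
    simulate_knockdown,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)

    sim = simulate_genome_annotation(cfg, OUT)
    genome = read_genome(sim.fasta_path)
    print(f"genome: {cfg.n_chromosomes} chromosomes x {cfg.chromosome_length} bp, "
          f"{len(sim.models)} genes "
          f"({sum(1 for m in sim.models if m.biotype == 'protein_coding')} protein-coding)")

    calls, truth = simulate_fusions(cfg, sim, genome)
    libs, parents, _ = simulate_expression(cfg, calls)
    write_fusion_table(calls, OUT / "fusions.tsv")
    write_libraries(libs, OUT / "libraries.tsv")
    write_counts(parents, OUT / "parent_counts.tsv")
    pd.DataFrame({
        "call_index": range(len(calls)),
        "true_class": truth.call_classes,
        "true_relation": truth.call_relations,
    }).to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)
    n_zero = sum(1 for c in calls if c.spanning_unique_reads == 0)
    print(f"fusion calls: {len(calls)} across {len(libs)} libraries "
          f"({n_zero} zero-read candidates for the filter to remove)")
    print(f"planted intra-chromosomal trend: {cfg.trend_intercept} + "
          f"{cfg.trend_slope}*day distinct fusions per library")

    kd = simulate_knockdown(cfg)
    write_counts(kd.counts, OUT / "kd_counts.tsv")
    pd.DataFrame({"sample_id": list(kd.groups), "group": list(kd.groups.values())}
                 ).to_csv(OUT / "kd_groups.tsv", sep="\t", index=False)
    write_gmt(kd.gene_sets, OUT / "gene_sets.gmt")
    pd.DataFrame({"gene": list(kd.truth.de_genes),
                  "true_lfc": list(kd.truth.de_genes.values())}
                 ).to_csv(OUT / "kd_ground_truth.tsv", sep="\t", index=False)
    print(f"knockdown: {kd.counts.shape[0]} genes x {kd.counts.shape[1]} samples, "
          f"{len(kd.truth.de_genes)} planted DE genes, "
          f"planted-enriched set: {kd.truth.enriched_sets}")
    print(f"wrote inputs -> {OUT}")


if __name__ == "__main__":
    main()
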