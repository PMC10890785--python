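# fusionatlas

Characterization of chimeric RNAs (gene fusions) in developmental bulk
RNA-seq, with the statistics machinery for a follow-up knockdown
experiment. The package is aimed at analysts who have per-sample fusion
calls in FusionCatcher's final-list format (or a compact equivalent) plus a
genome FASTA and a GTF annotation, and who want to go from raw calls to a
characterized fusion landscape: which junctions preserve reading frame,
which parental biotypes pair up, whether fusion burden trends with
developmental stage, whether chimera expression tracks parental expression,
and what sequence context surrounds the junctions.

Every analysis is exercisable end to end on synthetic data with planted
ground truth, generated by the package itself — no controlled-access data
are needed to validate the machinery.

## What it computes

**Candidate filter.** A fusion call is a positive candidate only if it has
at least one *spanning unique read* (a read uniquely aligned across the
junction).

**Junction effect by reading-frame arithmetic.** With transcript models
resolved per gene (longest CDS, ties to the smallest transcript id), let

- *L5* = number of CDS nucleotides of the 5' transcript at or upstream of
  the 5' breakpoint (transcription order), and
- *S3* = number of CDS nucleotides of the 3' transcript strictly upstream
  of the 3' breakpoint (the coding prefix the fusion skips).

A CDS x CDS junction is **In-frame** iff `L5 ≡ S3 (mod 3)`, else
**Out-of-frame**; other region pairs name their class directly
(`CDS(truncated)_UTR`, `UTR_UTR`, `intronic_CDS(truncated)`, ...). Each
call also gets its chromosomal relation (intra- vs inter-chromosomal) and
ordered parental biotype pair.

**Expression metric.** Per call and library,
`log10(spanning_unique_reads / total_reads x 10^7)` — the depth-normalized
spanning-read rate on a reads-per-ten-million log scale, undefined (absent,
not zero) at zero reads.

**Developmental trend.** Distinct fusions per library are counted by
relation, averaged over replicates within each stage, and Pearson-correlated
against day of differentiation (r, r², two-sided t-based p, least-squares
slope). Parent-vs-chimera association uses Spearman rank correlation of the
chimera metric against parental log expression (parental counts normalized
by their own library totals), per fusion and pooled.

**Junction motifs.** 20-bp windows (10 bp each side, gene-strand oriented)
around donor and acceptor breakpoints are summarized as position weight
matrices; a consensus report flags whether the canonical `GT` donor /
`AG` acceptor dinucleotides carry the maximal weights.

**Knockdown arm.** Per-gene Welch t-test on log2(CPM + 0.5) with DEG calls
at |log2 fold change| > 1 and raw p < 0.05 (BH FDR reported alongside);
exact hypergeometric over-representation of the up/down lists in gene sets;
and a from-scratch permutation GSEA (weighted Kolmogorov–Smirnov running
sum, gene-set-label permutation null, NES, empirical p, pooled-null FDR).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1 by default), writing tables under `results/`:

```
python analysis/01_simulate.py
python analysis/02_classify_fusions.py
python analysis/03_expression_trend.py
python analysis/04_junction_motifs.py
python analysis/05_knockdown_enrichment.py
```

`02_classify_fusions.py` prints:

```
candidate filter: kept 1040/1299 calls (spanning unique reads >= 1)

predicted-effect taxonomy (top 5):
  Out-of-frame                   248   23.8%
  UTR_UTR                        234   22.5%
  In-frame                       175   16.8%
  CDS(truncated)_UTR             140   13.5%
  CDS(truncated)_intronic         88    8.5%
protein-coding x protein-coding pairs: 70.9%
agreement with planted truth: 100.0%
```

— 259 zero-read candidates were removed by the filter, every surviving
call was assigned exactly one effect class, and the classifier reproduced
the generator's planted labels exactly. `03_expression_trend.py` then
reports the planted developmental trend and the independence of chimera
and parental expression:

```
intra-chromosomal trend: r^2 = 1.000, p = 0.00e+00, slope = 0.200 fusions/day
inter-chromosomal trend: zero-variance counts (stationary by design)
parent vs chimera (pooled Spearman): rho = 0.009, p = 0.692 over 2080 pairs -> not significant
```

(the noiseless default makes the intra-chromosomal counts exactly linear:
r² = 1 and the slope equals the planted 0.2 fusions/day), and
`04_junction_motifs.py` recovers the planted splice signal:

```
canonical GT at donor +1/+2: True; canonical AG at acceptor -2/-1: True
```

The same flows are available as a CLI (`fusionatlas atlas --seed 1 --out
run1`, `fusionatlas knockdown ...`, plus per-stage subcommands `simulate`,
`classify`, `quantify`, `trend`, `motif`, `de`, `ora`, `gsea`) and as
library calls (`fusionatlas.pipeline.run_atlas` / `run_knockdown`). Runs
at a fixed seed are byte-for-byte reproducible.

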