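# Methods

This note records the models, conventions and numerical choices behind
fusionatlas, and what the synthetic-data experiments do and do not show.

## Coordinates and breakpoints

All genomic coordinates are 1-based, fully closed, forward-strand numbered,
matching the `chrom:pos:strand` breakpoint strings of FusionCatcher output;
conversion to Python's half-open slices happens in exactly one place
(`GenomeStore.fetch`). A 5' breakpoint denotes the **last transcribed base**
of the 5' segment and a 3' breakpoint the **first transcribed base** of the
3' segment. This convention makes retained-length arithmetic closed-form
and puts exon-boundary junctions on the exon side: a breakpoint exactly on
an exon/intron boundary belongs to the exon.

Multiple transcripts per gene are resolved to the transcript with the
longest CDS, ties broken by the lexicographically smallest transcript id —
deterministic and close to "canonical transcript" behaviour.

## The frame rule

For a CDS x CDS junction, let L5 be the CDS nucleotides of the 5'
transcript at or 5' of the breakpoint (transcription order) and S3 the CDS
nucleotides of the 3' transcript strictly 5' of its breakpoint. Prefixing
L5 coding bases reproduces the codon phase at which the retained 3' CDS
begins, so the downstream frame is preserved iff `L5 ≡ S3 (mod 3)`. The
rule is validated against an independent translation oracle that builds the
fused CDS from the FASTA and translates it: In-frame iff the 3' gene's
annotated stop codon is reached in frame with no premature stop.

One edge case is deliberate: a junction codon that straddles the breakpoint
can itself encode a stop. The parity rule still reports In-frame; the
classifier flags such junctions separately (`junction_stop`) when a genome
is available, since whether they count as in-frame is a matter of
convention. The synthetic generator avoids planting them so that the parity
rule and the translation oracle agree exactly on simulated data.

Region vocabulary: exonic breakpoints in transcripts without a CDS
(lincRNA, pseudogene) are labelled `noncoding_exon` and contribute "UTR" to
the class name — they donate untranslated sequence to the chimera. The
implemented classes are the ten constructible region pairs plus
In-frame/Out-of-frame, `intergenic` and `unclassified`; non-coding partners
can never yield In-frame. Intron-involving classes are emitted with
explicit orientation (`CDS(truncated)_intronic` vs
`intronic_CDS(truncated)`) because the orientation is recoverable and
collapsing it would lose information.

## Expression and correlation

The chimera expression unit is `log10(su / total_reads x 10^7)` — spanning
unique reads per ten million sequenced reads, log-transformed. "log" is
implemented as base 10 (the convention of expression heat maps and sequence
logos); a `base` argument exposes e and 2. Zero spanning reads make the
metric undefined: the record is absent, never zero, so heat-map cells and
correlations are computed over defined observations only.

The stage trend counts **distinct** fusions per library (not total call
events), averages libraries within a stage — replicate numbers differ
between stages, and summing would bias the trend — and Pearson-correlates
stage means against day. The two-sided p uses the t transform
`t = r sqrt((n-2)/(1-r²))` with n−2 df; a permutation cross-check
(`stage_trend_permutation_p`) is available. Fewer than 3 stages is an
error; zero-variance counts yield a flagged NaN r rather than a fabricated
p-value.

Parent-vs-chimera association is Spearman over pairs of (chimera metric,
parental log expression), one pair per defined observation per parent.
Parental expression uses the same `log10(count/total x 10^7)` family but
with the **parental count matrix's own per-sample totals**: parental genes
are quantified by a separate alignment/counting track, and normalizing both
variables by one shared library total would correlate them through the
common denominator alone (we measured a spurious pooled rho of ~0.25 doing
so on independent simulations). The totals are overridable
(`parent_totals`) for designs where a shared denominator is intended.

## Junction windows and PWMs

Each junction side yields one 20-nt window in gene-strand orientation:
positions −10..−1 are retained context (donor windows end at the 5'
breakpoint; acceptor windows start at the 3' breakpoint at +1) and +1..+10
(resp. −10..−1) continue into the departed genomic context. Donor and
acceptor windows are kept separate by default — pooling them would make
GT/AG detection ill-posed, since the canonical dinucleotides sit at
different window positions. Minus-strand genes are reverse-complemented so
all windows read 5'→3' biologically.

The PWM uses pure per-column frequencies (pseudocount 0, seqLogo-style;
configurable); N bases are excluded from a column's denominator rather than
dropping the whole window. Windows that would overrun a chromosome end are
dropped with a warning and counted. The consensus report takes the
per-column argmax with alphabetical tie-breaking and an explicit tie flag,
and checks G/T maximal at +1/+2 (donor) and A/G at −2/−1 (acceptor).

## Knockdown statistics

Differential expression is a Welch t-test on log2(CPM + 0.5) with the fold
change computed from group-mean CPM (+0.5 damping), BH FDR reported, and
DEG status called at |log2FC| > 1 and **raw** p < 0.05 — the volcano-plot
convention; the FDR column lets users apply an adjusted cut instead. The
choice is deliberate: the claim of this package is the thresholding and the
downstream enrichment machinery, not a negative-binomial model competitor.
Known limitation: the Welch–Satterthwaite approximation is mildly
conservative at n = 5 per group (empirical size ≈ 0.044 at nominal 0.05 on
simulated counts); genes with all-zero counts are excluded and reported,
and all-zero-variance genes with equal means get p = 1.

ORA is the exact upper-tail hypergeometric probability of the observed
overlap, BH-corrected across sets; sets disjoint from the universe are
skipped with a flag.

GSEA is implemented from scratch: genes ranked by descending score (default
the DE log2 fold change; a signed −log10(p) ranking can be passed just as
well), hit increments proportional to |score|^weight (weight default 1)
normalized by the set total, miss decrements 1/(N−Nh), ES = the maximal
signed deviation. The null permutes **gene-set labels** (random same-size
sets from the ranked universe) rather than phenotypes, because the intended
designs have very few samples per group; this is a documented divergence
from the canonical phenotype permutation and makes the null a "random set
of this size" null. Null distributions are shared between sets of equal
size, so the pooled-null FDR is well populated even with few sets. NES
divides ES by the mean |null ES| of matching sign; the empirical p uses the
same-signed null tail with the +1 correction (floor 1/(n_perm+1)). If the
positive and negative running-sum extremes tie exactly in magnitude, the
reported sign follows the floating-point argmax — such ties have measure
zero for continuous scores.

All permutation machinery takes an explicit seed; fixed seed means
bit-identical results.

## The synthetic-data generator

The generator emulates the study design the analyses assume, at desk scale.
One root seed expands into named substreams (genome / fusions / expression
/ knockdown), so adding a generator never perturbs the others, and a fixed
seed yields byte-identical files.

**Genome and annotation** (defaults: 4 chromosomes x 90 kb, 40 genes, 3–6
exons each, biotypes 70% protein-coding / 20% lincRNA / 10% pseudogene):
every intron begins GT and ends AG on the gene strand (minimum intron 25 bp,
so 10-bp windows never cross a neighbouring feature); protein-coding
transcripts have UTR–CDS–UTR structure with the CDS a codon multiple
starting ATG, ending in a stop, with no internal stop.

**Fusions**: each event realizes a requested effect class by construction —
exon-boundary breakpoints wherever the class allows (planting the GT/AG
motif), intron-interior positions for intronic classes, with parity chosen
across exon-boundary combinations for In-/Out-of-frame. The class is drawn
from the configurable mix and held fixed while gene pairs are resampled, so
hard-to-place classes are not under-represented. Spanning reads are
geometric (P = 0.35, support 1, 2, ...) for detected events — fusion
evidence is empirically low-count — plus a 25% admixture of zero-read
candidate calls that the ≥1-read filter must remove.

**Stage series**: eight stages at days 0, 30, 45, 60, 75, 90, 105, 120 with
replicates (3,3,3,3,3,3,2,2) — 22 libraries. Per library, the number of
distinct detected intra-chromosomal fusions is
`round(20 + 0.2·day + N(0, noise_sd))` and the inter-chromosomal count is
stationary at 15. The paper-scale per-stage counts are not published, so
these are free parameters chosen once; the slope 0.2/day is integral on the
15-day stage grid, so the `noise_sd = 0` default is *exactly* linear
(r² = 1, slope recovered to machine precision) — the clean baseline the
calibration tests build on. Noise is Gaussian with an explicit sd knob
(rather than Poisson, whose variance would be tied to the mean), rounded
and clipped at zero.

**Expression**: library depths uniform in 20–60 M reads; parental counts
negative-binomial (mean 500, dispersion 0.2) independent of chimera
evidence by default. A coupling knob makes the parent count a monotone
function of the library's chimera spanning reads
(`mean x (1+su)^coupling`, optional lognormal noise) for power checks.

**Knockdown**: 2000 genes x 5+5 samples, negative-binomial (mean 100,
dispersion 0.1 — overdispersed on purpose, so the DE test faces realistic
counts), 100 planted DE genes (half up, half down, |log2FC| = 2), one
planted-enriched GMT set drawn from the up-shifted genes plus 10 null sets
of unshifted genes. The gene universe is synthetic (with annotation gene
names optionally leading) because the enrichment calibrations need far more
genes than the toy genome carries.

**What passing does not show.** The generator has no sequencing-error
model, no read-level simulation, no isoform mixtures, no GC or length
biases, uniform gene baseline expression in the knockdown arm, and gene
structures far smaller than human genes. Passing tests demonstrate that the
arithmetic, calibrations and plumbing are correct under the planted model —
not that real-data fusion calls are accurate (that is FusionCatcher's job,
upstream of this package) nor that effect sizes estimated on real data will
match.

## Problem sizes

The test suite and the acceptance script run the full study design but at
desk scale, chosen as the sizes at which every planted signal is
comfortably detectable: 100-fusion pools x 5 seeds for classifier/oracle
equivalence, ~1300-call stage series for filter/trend/motif checks, 100
seeds for the independence calibration, 2000-gene x 10-sample knockdown
matrices (25 null seeds for the type-I estimate, 100 null sets x 1000
permutations for GSEA calibration), and duplicate end-to-end runs for
byte-identity.
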