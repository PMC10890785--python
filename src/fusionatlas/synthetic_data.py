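"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* a toy genome and GTF in which every intron carries the canonical GT..AG
  donor/acceptor dinucleotides on the gene strand and every protein-coding
  CDS starts with ATG, ends with a stop, and contains no internal stop;
* fusion calls constructed to realize requested junction-effect classes,
  with breakpoints placed on exon boundaries where the class allows (so the
  splice-motif signal is planted) and spanning-read counts drawn from a
  shifted geometric distribution so the "at least one spanning unique read"
  filter is exercised;
* a developmental stage series (default days 0, 30, 45, 60, 75, 90, 105, 120
  with 2-3 replicates each, 22 libraries) in which the number of distinct
  intra-chromosomal fusions per stage follows a linear trend in day while
  the inter-chromosomal count is stationary;
* parental-gene counts independent of chimera evidence by default, with a
  coupling knob for power checks;
* a two-group knockdown experiment with negative-binomial counts, planted
  differentially expressed genes and one planted-enriched gene set among
  null sets.

Randomness: one root seed is expanded into named substreams
(:func:`component_rng`), so adding a generator does not perturb the others,
and a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    Breakpoint,
    FusionCall,
    GeneSetCollection,
    GenomeStore,
    SampleLibrary,
    TranscriptModel,
    reverse_complement,
    write_annotation,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedGenome",
    "component_rng",
    "simulate_genome_annotation",
    "simulate_fusion_pool",
    "simulate_fusions",
    "simulate_expression",
    "simulate_knockdown",
]

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]

#: Default junction-effect class mix, loosely shaped like the observed
#: taxonomy (In-frame a minority; UTR- and intron-involving classes common).
DEFAULT_CLASS_MIX = {
    "In-frame": 0.15,
    "Out-of-frame": 0.20,
    "CDS(truncated)_UTR": 0.15,
    "UTR_CDS(truncated)": 0.10,
    "UTR_UTR": 0.15,
    "CDS(truncated)_intronic": 0.10,
    "intronic_CDS(truncated)": 0.05,
    "intronic_intronic": 0.10,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators, with study-scale defaults."""

    seed: int = 0

    # genome / annotation
    n_chromosomes: int = 4
    chromosome_length: int = 90_000
    n_genes: int = 40
    exons_min: int = 3
    exons_max: int = 6
    biotype_proportions: dict[str, float] = field(
        default_factory=lambda: {"protein_coding": 0.7, "lincRNA": 0.2, "pseudogene": 0.1}
    )

    # fusion calls
    n_fusions: int = 100
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    stages: tuple[int, ...] = (0, 30, 45, 60, 75, 90, 105, 120)
    replicates: tuple[int, ...] = (3, 3, 3, 3, 3, 3, 2, 2)  # N = 22 libraries
    trend_intercept: float = 20.0
    trend_slope: float = 0.2          # distinct intra-chromosomal fusions per day
    inter_level: float = 15.0         # stationary inter-chromosomal count
    noise_sd: float = 0.0             # sd of Gaussian noise on per-library counts
    zero_read_fraction: float = 0.25  # extra zero-read candidates per library
    read_geom_p: float = 0.35         # geometric P for spanning-read counts

    # expression / parent-chimera coupling
    total_reads_range: tuple[int, int] = (20_000_000, 60_000_000)
    parent_mean: float = 500.0
    parent_dispersion: float = 0.2
    coupling: float = 0.0             # 0 = parents independent of chimera evidence
    parent_noise_sd: float = 0.0      # lognormal sd on coupled parent counts

    # knockdown experiment
    kd_n_genes: int = 2000
    n_genes_de: int = 100
    lfc_de: float = 2.0
    n_replicates: int = 5
    kd_mean: float = 100.0
    kd_dispersion: float = 0.1
    n_null_sets: int = 10
    set_size: int = 30

    def __post_init__(self) -> None:
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("biotype_proportions must sum to 1")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if len(self.replicates) != len(self.stages):
            raise ValueError("replicates must give one count per stage")


@dataclass
class GroundTruth:
    """Planted truth for the simulated records (the acceptance oracle)."""

    gene_biotypes: dict[str, str] = field(default_factory=dict)
    fusion_classes: dict[str, str] = field(default_factory=dict)    # fusion_id -> class
    fusion_relations: dict[str, str] = field(default_factory=dict)  # fusion_id -> intra/inter
    call_classes: list[str] = field(default_factory=list)           # one per emitted call
    call_relations: list[str] = field(default_factory=list)
    stage_intra_counts: dict[str, int] = field(default_factory=dict)  # sample -> detected intra
    stage_inter_counts: dict[str, int] = field(default_factory=dict)
    trend_slope: float | None = None
    trend_intercept: float | None = None
    coupling: float | None = None
    de_genes: dict[str, float] = field(default_factory=dict)        # gene -> true lfc
    enriched_sets: list[str] = field(default_factory=list)


# stable component keys (hash() is salted per process)
_COMPONENT_KEYS = {
    "genome": 1,
    "fusions": 2,
    "expression": 3,
    "knockdown": 4,
}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Independent substream for a named generator component."""
    key = _COMPONENT_KEYS[component]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


_rng = component_rng


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedGenome:
    fasta_path: Path
    gtf_path: Path
    models: list[TranscriptModel]
    truth: GroundTruth


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + sense codons + stop; ``length`` must be a multiple of 3, >= 9."""
    n_inner = length // 3 - 2
    inner = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_inner))
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + inner + stop


def _build_gene(
    rng: np.random.Generator,
    gene: str,
    chrom: str,
    offset: int,
    biotype: str,
    exons_min: int,
    exons_max: int,
) -> tuple[str, TranscriptModel]:
    """One gene body (sequence) plus its transcript model at ``offset``."""
    strand = "+" if rng.random() < 0.5 else "-"
    k = int(rng.integers(exons_min, exons_max + 1))
    exon_lengths = rng.integers(50, 121, size=k)
    total = int(exon_lengths.sum())

    if biotype == "protein_coding":
        u5 = int(rng.integers(15, 41))
        u3 = int(rng.integers(15, 41))
        cds_len = total - u5 - u3
        u3 += cds_len % 3          # make CDS a codon multiple
        cds_len = total - u5 - u3
        transcript = _random_seq(rng, u5) + _random_cds(rng, cds_len) + _random_seq(rng, u3)
        cds_range = (u5 + 1, u5 + cds_len)   # 1-based transcript coords
    else:
        transcript = _random_seq(rng, total)
        cds_range = None

    # introns: GT .. AG on the gene strand, minimum length 25
    intron_lengths = rng.integers(25, 61, size=k - 1)
    boundaries = np.cumsum(exon_lengths)  # transcript coords of exon ends

    # assemble the gene body in transcript orientation
    parts: list[str] = []
    pos = 0
    for i, b in enumerate(boundaries):
        parts.append(transcript[pos:b])
        pos = b
        if i < k - 1:
            ilen = int(intron_lengths[i])
            parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
    body = "".join(parts)
    body_len = len(body)

    # transcript-coordinate -> body-coordinate shift per exon
    exon_tx_ranges = [(int(boundaries[i] - exon_lengths[i] + 1), int(boundaries[i])) for i in range(k)]
    intron_before = np.concatenate([[0], np.cumsum(intron_lengths)])

    def body_pos(t: int, exon_idx: int) -> int:
        return t + int(intron_before[exon_idx])

    # genomic mapping: '+' strand writes the body as-is; '-' writes its
    # reverse complement, so transcript order runs against genomic order
    def genomic(b: int) -> int:
        return offset + b if strand == "+" else offset + body_len - b + 1

    exons_genomic: list[tuple[int, int]] = []
    cds_genomic: list[tuple[int, int]] = []
    for i, (ts, te) in enumerate(exon_tx_ranges):
        g1, g2 = genomic(body_pos(ts, i)), genomic(body_pos(te, i))
        exons_genomic.append((min(g1, g2), max(g1, g2)))
        if cds_range is not None:
            cs, ce = max(ts, cds_range[0]), min(te, cds_range[1])
            if cs <= ce:
                g1, g2 = genomic(body_pos(cs, i)), genomic(body_pos(ce, i))
                cds_genomic.append((min(g1, g2), max(g1, g2)))

    reverse = strand == "-"
    model = TranscriptModel(
        gene=gene,
        transcript_id=f"{gene}.t1",
        chrom=chrom,
        strand=strand,
        exons=tuple(sorted(exons_genomic, reverse=reverse)),
        cds=tuple(sorted(cds_genomic, reverse=reverse)),
        biotype=biotype,
    )
    seq = body if strand == "+" else reverse_complement(body)
    return seq, model


def simulate_genome_annotation(
    config: SimulationConfig, outdir: str | Path
) -> SimulatedGenome:
    """Write ``genome.fa`` and ``annotation.gtf`` under ``outdir``.

    Every intron starts with GT and ends with AG on the gene strand; every
    protein-coding CDS is a codon multiple beginning ATG, ending with a stop
    codon and free of internal stops.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed, "genome")

    biotypes = list(config.biotype_proportions)
    probs = np.array([config.biotype_proportions[b] for b in biotypes])

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sequences = {c: list(_random_seq(rng, config.chromosome_length)) for c in chroms}
    models: list[TranscriptModel] = []
    truth = GroundTruth()
    cursors = {c: 200 for c in chroms}

    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        gene = f"GENE{gi + 1:03d}"
        biotype = str(rng.choice(biotypes, p=probs))
        seq, model = _build_gene(
            rng, gene, chrom, cursors[chrom], biotype,
            config.exons_min, config.exons_max,
        )
        end = cursors[chrom] + len(seq)
        if end + 200 > config.chromosome_length:
            raise ValueError(
                f"chromosome_length {config.chromosome_length} too short to host "
                f"{config.n_genes} genes on {config.n_chromosomes} chromosomes"
            )
        sequences[chrom][cursors[chrom] : end] = list(seq)
        cursors[chrom] = end + int(rng.integers(150, 401))
        models.append(model)
        truth.gene_biotypes[gene] = biotype

    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            s = "".join(sequences[c])
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    gtf_path = outdir / "annotation.gtf"
    write_annotation(models, gtf_path)
    return SimulatedGenome(fasta_path=fasta_path, gtf_path=gtf_path, models=models, truth=truth)


# ---------------------------------------------------------------------------
# Fusion construction
# ---------------------------------------------------------------------------

def _donor_sites(model: TranscriptModel) -> list[tuple[int, str, int]]:
    """Exon-boundary donor candidates: (pos, region, L5) at each exon end
    followed by an intron (so the next gene-strand bases read GT)."""
    sites = []
    for s, e in model.exons[:-1]:
        pos = e if model.strand == "+" else s
        sites.append((pos, model.region_of(pos), model.cds_bases_upstream(pos, inclusive=True)))
    return sites


def _acceptor_sites(model: TranscriptModel) -> list[tuple[int, str, int]]:
    """Exon-boundary acceptor candidates: (pos, region, S3) at each exon start
    preceded by an intron (so the preceding gene-strand bases read AG)."""
    sites = []
    for s, e in model.exons[1:]:
        pos = s if model.strand == "+" else e
        sites.append((pos, model.region_of(pos), model.cds_bases_upstream(pos, inclusive=False)))
    return sites


def _region_positions(model: TranscriptModel, wanted: set[str]) -> list[int]:
    """All genomic positions within the model's exons whose region label is in
    ``wanted`` ('utr' matches any untranslated exonic label)."""
    out = []
    for s, e in model.exons:
        for pos in range(s, e + 1):
            r = model.region_of(pos)
            if r in wanted or ("utr" in wanted and r in (
                "five_prime_utr", "three_prime_utr", "noncoding_exon")):
                out.append(pos)
    return out


def _intron_positions(model: TranscriptModel) -> list[int]:
    spans = sorted([s for s, _ in model.exons]), sorted([e for _, e in model.exons])
    starts, ends = spans
    out = []
    for i in range(len(starts) - 1):
        out.extend(range(ends[i] + 1, starts[i + 1]))
    return out


_STOP_SET = set(_STOPS)


def _junction_stop(
    m5: TranscriptModel, pos5: int, l5: int, m3: TranscriptModel, pos3: int,
    genome: GenomeStore,
) -> bool:
    from .fusion_classify import _cds_head, _cds_tail

    phase = l5 % 3
    if phase == 0:
        return False
    return (_cds_tail(m5, pos5, phase, genome) + _cds_head(m3, pos3, 3 - phase, genome)) in _STOP_SET


def _pick_side(
    rng: np.random.Generator,
    model: TranscriptModel,
    kind: str,
    side: str,
) -> tuple[int, int] | None:
    """Choose a breakpoint realizing a region ``kind`` on one fusion side.

    ``kind`` in {'cds','utr5','utr3','intron'}; returns (pos, cds_upstream)
    or None if the model cannot realize it. Exon-boundary positions are
    preferred so the GT/AG junction motif is planted.
    """
    boundary = _donor_sites(model) if side == "five" else _acceptor_sites(model)
    inclusive = side == "five"
    if kind == "cds":
        cands = [(p, c) for p, r, c in boundary if r == "cds"]
        if cands:
            return cands[rng.integers(0, len(cands))]
        return None
    if kind == "intron":
        pool = _intron_positions(model)
        if not pool:
            return None
        pos = int(pool[rng.integers(0, len(pool))])
        return pos, model.cds_bases_upstream(pos, inclusive=inclusive)
    wanted = {"five_prime_utr", "noncoding_exon"} if kind == "utr5" else {
        "three_prime_utr", "noncoding_exon"}
    cands = [(p, c) for p, r, c in boundary if r in wanted]
    if cands:
        return cands[rng.integers(0, len(cands))]
    pool = _region_positions(model, wanted)
    if not pool:
        return None
    pos = int(pool[rng.integers(0, len(pool))])
    return pos, model.cds_bases_upstream(pos, inclusive=inclusive)


# per effect class: required (5' side kind, 3' side kind)
_CLASS_SIDES = {
    "CDS(truncated)_UTR": ("cds", "utr3"),
    "UTR_CDS(truncated)": ("utr5", "cds"),
    "UTR_UTR": ("utr5", "utr3"),
    "CDS(truncated)_intronic": ("cds", "intron"),
    "intronic_CDS(truncated)": ("intron", "cds"),
    "UTR_intronic": ("utr5", "intron"),
    "intronic_UTR": ("intron", "utr3"),
    "intronic_intronic": ("intron", "intron"),
}


def _realize_fusion(
    rng: np.random.Generator,
    m5: TranscriptModel,
    m3: TranscriptModel,
    effect: str,
    genome: GenomeStore,
) -> tuple[Breakpoint, Breakpoint] | None:
    """Breakpoints on (m5, m3) realizing ``effect``, or None if impossible."""
    if effect in ("In-frame", "Out-of-frame"):
        if m5.biotype != "protein_coding" or m3.biotype != "protein_coding":
            return None
        donors = [(p, c) for p, r, c in _donor_sites(m5) if r == "cds"]
        acceptors = [(p, c) for p, r, c in _acceptor_sites(m3) if r == "cds"]
        want_equal = effect == "In-frame"
        combos = [
            (dp, dc, ap, ac)
            for dp, dc in donors
            for ap, ac in acceptors
            if (dc % 3 == ac % 3) == want_equal
        ]
        rng.shuffle(combos)
        for dp, dc, ap, ac in combos:
            if want_equal and _junction_stop(m5, dp, dc, m3, ap, genome):
                continue  # keep parity rule and translation oracle in agreement
            return (
                Breakpoint(m5.chrom, dp, m5.strand),
                Breakpoint(m3.chrom, ap, m3.strand),
            )
        return None

    sides = _CLASS_SIDES.get(effect)
    if sides is None:
        raise ValueError(f"cannot realize effect class {effect!r}")
    five = _pick_side(rng, m5, sides[0], "five")
    three = _pick_side(rng, m3, sides[1], "three")
    if five is None or three is None:
        return None
    return (
        Breakpoint(m5.chrom, five[0], m5.strand),
        Breakpoint(m3.chrom, three[0], m3.strand),
    )


@dataclass(frozen=True)
class _FusionEvent:
    gene5: str
    gene3: str
    bp5: Breakpoint
    bp3: Breakpoint
    effect: str
    relation: str

    @property
    def fusion_id(self) -> str:
        return (
            f"{self.gene5}--{self.gene3}|{self.bp5.chrom}:{self.bp5.pos}:"
            f"{self.bp5.strand}|{self.bp3.chrom}:{self.bp3.pos}:{self.bp3.strand}"
        )


def simulate_fusion_pool(
    config: SimulationConfig,
    sim: SimulatedGenome,
    genome: GenomeStore,
    n: int,
    relation: str | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 200,
) -> list[_FusionEvent]:
    """``n`` distinct fusion events with classes drawn from ``class_mix``.

    ``relation`` restricts parental gene pairs to the same chromosome
    ('intra'), different chromosomes ('inter'), or any (None).
    """
    if rng is None:
        rng = _rng(config.seed, "fusions")
    models = {m.gene: m for m in sim.models}
    genes = list(models)
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])

    events: list[_FusionEvent] = []
    seen: set[str] = set()
    attempts = 0
    while len(events) < n:
        attempts += 1
        if attempts > max_retries * max(n, 1):
            raise RuntimeError(
                f"could not realize {n} fusions with relation={relation!r}; "
                f"class mix may be unrealizable on this annotation"
            )
        # keep the drawn class fixed while resampling gene pairs, so classes
        # that are hard to place do not end up under-represented in the pool
        effect = str(rng.choice(classes, p=probs))
        for _ in range(max_retries):
            g5, g3 = rng.choice(genes, size=2, replace=False)
            m5, m3 = models[g5], models[g3]
            rel = "intra" if m5.chrom == m3.chrom else "inter"
            if relation is not None and rel != relation:
                continue
            bps = _realize_fusion(rng, m5, m3, effect, genome)
            if bps is None:
                continue
            ev = _FusionEvent(g5, g3, bps[0], bps[1], effect, rel)
            if ev.fusion_id in seen:
                continue
            seen.add(ev.fusion_id)
            events.append(ev)
            break
    return events


def simulate_fusions(
    config: SimulationConfig, sim: SimulatedGenome, genome: GenomeStore
) -> tuple[list[FusionCall], GroundTruth]:
    """Per-library fusion-call records across the developmental stage series.

    Each library at day ``d`` detects ``round(intercept + slope*d [+ noise])``
    distinct intra-chromosomal fusions (spanning reads >= 1) and a stationary
    number of inter-chromosomal ones, plus a fraction of zero-read candidate
    calls that the >= 1 spanning-read filter must remove.
    """
    rng = _rng(config.seed, "fusions")
    max_intra = int(round(config.trend_intercept + config.trend_slope * max(config.stages))) + 15
    max_inter = int(round(config.inter_level)) + 15
    intra_pool = simulate_fusion_pool(config, sim, genome, max_intra, "intra", rng)
    inter_pool = simulate_fusion_pool(config, sim, genome, max_inter, "inter", rng)

    truth = GroundTruth(
        gene_biotypes=dict(sim.truth.gene_biotypes),
        trend_slope=config.trend_slope,
        trend_intercept=config.trend_intercept,
    )
    for ev in intra_pool + inter_pool:
        truth.fusion_classes[ev.fusion_id] = ev.effect
        truth.fusion_relations[ev.fusion_id] = ev.relation

    calls: list[FusionCall] = []
    for day, n_rep in zip(config.stages, config.replicates):
        for rep in range(1, n_rep + 1):
            sample = f"S{day:03d}R{rep}"
            noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            n_intra = max(0, int(round(config.trend_intercept + config.trend_slope * day + noise)))
            noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            n_inter = max(0, int(round(config.inter_level + noise)))
            n_intra = min(n_intra, len(intra_pool))
            n_inter = min(n_inter, len(inter_pool))

            chosen_i = rng.choice(len(intra_pool), size=n_intra, replace=False)
            chosen_j = rng.choice(len(inter_pool), size=n_inter, replace=False)
            detected = [intra_pool[i] for i in chosen_i] + [inter_pool[j] for j in chosen_j]
            truth.stage_intra_counts[sample] = n_intra
            truth.stage_inter_counts[sample] = n_inter

            # zero-read candidates, drawn from the pools minus this library's
            # detected events, to exercise the candidate filter
            n_zero = int(round(config.zero_read_fraction * (n_intra + n_inter)))
            detected_ids = {e.fusion_id for e in detected}
            spare = [e for e in intra_pool + inter_pool if e.fusion_id not in detected_ids]
            zeros = [spare[i] for i in rng.choice(len(spare), size=min(n_zero, len(spare)), replace=False)]

            for ev in detected:
                reads = int(rng.geometric(config.read_geom_p))  # >= 1
                calls.append(FusionCall(
                    gene5=ev.gene5, gene3=ev.gene3, bp5=ev.bp5, bp3=ev.bp3,
                    spanning_unique_reads=reads, sample_id=sample, stage_day=int(day),
                ))
                truth.call_classes.append(ev.effect)
                truth.call_relations.append(ev.relation)
            for ev in zeros:
                calls.append(FusionCall(
                    gene5=ev.gene5, gene3=ev.gene3, bp5=ev.bp5, bp3=ev.bp3,
                    spanning_unique_reads=0, sample_id=sample, stage_day=int(day),
                ))
                truth.call_classes.append(ev.effect)
                truth.call_relations.append(ev.relation)
    return calls, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig, calls: Sequence[FusionCall]
) -> tuple[list[SampleLibrary], pd.DataFrame, GroundTruth]:
    """Library sizes and parental-gene counts for the fusion-call samples.

    With ``coupling == 0`` (default) parental counts are negative-binomial
    draws independent of chimera evidence; with ``coupling > 0`` the parent
    count is a monotone function of the sample's chimera spanning reads
    (times lognormal noise of sd ``parent_noise_sd``), for power checks.
    """
    rng = _rng(config.seed, "expression")
    samples: dict[str, int] = {}
    for c in calls:
        if c.sample_id not in samples:
            samples[c.sample_id] = c.stage_day if c.stage_day is not None else 0
    lo, hi = config.total_reads_range
    libraries = [
        SampleLibrary(sample_id=s, total_reads=int(rng.integers(lo, hi + 1)), stage_day=d)
        for s, d in samples.items()
    ]

    genes = sorted({c.gene5 for c in calls} | {c.gene3 for c in calls})
    sample_ids = list(samples)

    # chimera evidence per (gene, sample): summed spanning reads of calls
    # having the gene as either parent
    su = pd.DataFrame(0, index=genes, columns=sample_ids, dtype=float)
    for c in calls:
        su.loc[c.gene5, c.sample_id] += c.spanning_unique_reads
        su.loc[c.gene3, c.sample_id] += c.spanning_unique_reads

    disp = config.parent_dispersion
    nb_n = 1.0 / disp
    if config.coupling == 0:
        p = nb_n / (nb_n + config.parent_mean)
        counts = rng.negative_binomial(nb_n, p, size=(len(genes), len(sample_ids)))
    else:
        base = config.parent_mean * (1.0 + su.values) ** config.coupling
        if config.parent_noise_sd > 0:
            base = base * np.exp(rng.normal(0.0, config.parent_noise_sd, size=base.shape))
        counts = np.round(base).astype(int)
    parent_counts = pd.DataFrame(counts, index=genes, columns=sample_ids)
    truth = GroundTruth(coupling=config.coupling)
    return libraries, parent_counts, truth


# ---------------------------------------------------------------------------
# Knockdown
# ---------------------------------------------------------------------------

@dataclass
class KnockdownSimulation:
    counts: pd.DataFrame                 # genes x samples, integer
    groups: dict[str, str]               # sample -> 'knockdown' | 'control'
    gene_sets: GeneSetCollection
    truth: GroundTruth


def simulate_knockdown(
    config: SimulationConfig,
    annotation: Sequence[TranscriptModel] | None = None,
) -> KnockdownSimulation:
    """Two-group negative-binomial counts with planted DE genes and sets.

    Half of the ``n_genes_de`` planted genes shift up by ``lfc_de`` in the
    knockdown group, half shift down. The GMT carries one planted-enriched
    set (a subset of the up-shifted genes) plus ``n_null_sets`` sets of
    random unshifted genes. Gene symbols come from ``annotation`` when given,
    padded with synthetic symbols up to ``kd_n_genes``.
    """
    if config.n_replicates < 3:
        raise ValueError("n_replicates must be >= 3 per group")
    rng = _rng(config.seed, "knockdown")

    genes: list[str] = []
    if annotation is not None:
        genes = sorted({m.gene for m in annotation})[: config.kd_n_genes]
    genes += [f"G{i:04d}" for i in range(len(genes), config.kd_n_genes)]

    lfc = np.zeros(len(genes))
    n_de = config.n_genes_de if config.lfc_de != 0 else 0  # lfc 0 plants nothing
    de_idx = rng.choice(len(genes), size=n_de, replace=False)
    half = n_de // 2
    lfc[de_idx[:half]] = config.lfc_de
    lfc[de_idx[half:]] = -config.lfc_de

    n = config.n_replicates
    kd_samples = [f"KD{i + 1}" for i in range(n)]
    ct_samples = [f"CT{i + 1}" for i in range(n)]
    nb_n = 1.0 / config.kd_dispersion

    def draw(mu: np.ndarray, n_samples: int) -> np.ndarray:
        p = nb_n / (nb_n + mu)
        return rng.negative_binomial(nb_n, p[:, None], size=(len(mu), n_samples))

    mu_ct = np.full(len(genes), config.kd_mean)
    mu_kd = mu_ct * (2.0 ** lfc)
    counts = np.hstack([draw(mu_kd, n), draw(mu_ct, n)])
    counts_df = pd.DataFrame(counts, index=genes, columns=kd_samples + ct_samples)
    groups = {s: "knockdown" for s in kd_samples} | {s: "control" for s in ct_samples}

    up_genes = [genes[i] for i in de_idx[:half]]
    null_universe = [g for i, g in enumerate(genes) if lfc[i] == 0.0]
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    if up_genes:
        planted = [up_genes[i] for i in rng.choice(len(up_genes), size=min(config.set_size, len(up_genes)), replace=False)]
        sets["PLANTED_UP"] = sorted(planted)
        desc["PLANTED_UP"] = "planted enriched set (up-shifted genes)"
    for k in range(config.n_null_sets):
        members = [null_universe[i] for i in rng.choice(len(null_universe), size=config.set_size, replace=False)]
        name = f"NULL_{k + 1:02d}"
        sets[name] = sorted(members)
        desc[name] = "random unshifted genes"

    truth = GroundTruth(
        de_genes={genes[i]: float(lfc[i]) for i in de_idx},
        enriched_sets=["PLANTED_UP"] if up_genes else [],
    )
    return KnockdownSimulation(
        counts=counts_df,
        groups=groups,
        gene_sets=GeneSetCollection(sets=sets, descriptions=desc),
        truth=truth,
    )
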