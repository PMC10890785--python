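"""Candidate filtering and junction-effect classification of fusion calls.

Each fusion call is assigned:

* a chromosomal relation — ``intra`` if both parental genes lie on the same
  chromosome, ``inter`` otherwise;
* a predicted junction effect (``In-frame``, ``Out-of-frame``,
  ``CDS(truncated)_UTR``, ``UTR_UTR``, ...), derived from where each
  breakpoint falls within its parental transcript model and, for CDS x CDS
  junctions, from reading-frame arithmetic;
* the ordered pair of parental gene biotypes.

The frame rule
--------------
Let ``L5`` be the number of CDS bases of the 5' transcript at or upstream
(in transcription order) of the 5' breakpoint, and ``S3`` the number of CDS
bases of the 3' transcript strictly upstream of the 3' breakpoint (the CDS
bases the fusion *skips*). Prefixing ``L5`` coding bases reproduces the codon
phase at which the retained 3' CDS begins, so the junction preserves the
downstream reading frame iff::

    L5 = S3  (mod 3)

A junction codon straddling the breakpoint can still encode a stop; such
junctions remain ``In-frame`` under the parity rule and are flagged in the
``junction_stop`` field when a genome is supplied.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import Breakpoint, FusionCall, GenomeStore, TranscriptModel

__all__ = [
    "EFFECT_CLASSES",
    "ClassifiedFusion",
    "filter_candidates",
    "classify_chromosomal",
    "locate_breakpoint",
    "classify_effect",
    "classify_biotypes",
    "classify_all",
    "summarize_classes",
    "resolve_models",
    "select_model",
]

#: The constructible effect classes, in reporting order.
EFFECT_CLASSES = (
    "In-frame",
    "Out-of-frame",
    "CDS(truncated)_UTR",
    "UTR_CDS(truncated)",
    "UTR_UTR",
    "CDS(truncated)_intronic",
    "intronic_CDS(truncated)",
    "UTR_intronic",
    "intronic_UTR",
    "intronic_intronic",
    "intergenic",
    "unclassified",
)

# Map of a transcript region to the token it contributes to a class name.
# Exonic positions in non-coding transcripts behave as UTR for naming: they
# contribute untranslated sequence to the chimera.
_REGION_TOKEN = {
    "five_prime_utr": "UTR",
    "three_prime_utr": "UTR",
    "noncoding_exon": "UTR",
    "cds": "CDS(truncated)",
    "intron": "intronic",
}


@dataclass(frozen=True)
class ClassifiedFusion:
    """A fusion call plus its chromosomal relation, effect and biotype pair."""

    call: FusionCall
    chrom_relation: str            # 'intra' | 'inter'
    effect: str                    # one of EFFECT_CLASSES
    biotype5: str
    biotype3: str
    retained_cds5: int             # L5, nt
    skipped_cds3: int              # S3, nt
    region5: str
    region3: str
    junction_stop: bool = False    # junction codon encodes a stop (In-frame only)


# ---------------------------------------------------------------------------
# Filtering and chromosomal relation
# ---------------------------------------------------------------------------

def filter_candidates(calls: Sequence[FusionCall]) -> list[FusionCall]:
    """Keep calls supported by at least one spanning unique read.

    This is the positive-candidate criterion of the screening procedure;
    input order is preserved.
    """
    return [c for c in calls if c.spanning_unique_reads >= 1]


def classify_chromosomal(call: FusionCall) -> str:
    """``intra`` if both breakpoints share a chromosome (case-insensitive)."""
    return "intra" if call.bp5.chrom.lower() == call.bp3.chrom.lower() else "inter"


# ---------------------------------------------------------------------------
# Model resolution
# ---------------------------------------------------------------------------

def resolve_models(models: Iterable[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One representative transcript per gene symbol.

    The transcript with the longest CDS wins; ties break to the
    lexicographically smallest transcript_id, so resolution is deterministic.
    """
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene)
        if cur is None or (m.cds_length, _neg(m.transcript_id)) > (
            cur.cds_length, _neg(cur.transcript_id)
        ):
            best[m.gene] = m
    return best


def _neg(tid: str) -> tuple[int, ...]:
    # invert lexicographic order so that "max" prefers the smallest id
    return tuple(-ord(c) for c in tid)


def select_model(
    models: Mapping[str, TranscriptModel], gene: str
) -> TranscriptModel | None:
    return models.get(gene)


# ---------------------------------------------------------------------------
# Breakpoint anatomy
# ---------------------------------------------------------------------------

def locate_breakpoint(
    bp: Breakpoint, model: TranscriptModel, side: str
) -> tuple[str, int]:
    """Region of a breakpoint within a transcript, plus L5 or S3.

    ``side='five_prime'`` returns ``(region, L5)`` with L5 the count of CDS
    bases at or 5' of the breakpoint in transcription order;
    ``side='three_prime'`` returns ``(region, S3)`` with S3 the count of CDS
    bases strictly 5' of the breakpoint (the coding prefix the fusion skips).

    A breakpoint outside the gene span is ``intergenic`` (with a zero count);
    a breakpoint on the wrong chromosome is an error.
    """
    if side not in ("five_prime", "three_prime"):
        raise ValueError(f"side must be 'five_prime' or 'three_prime', got {side!r}")
    if bp.chrom != model.chrom:
        raise ValueError(
            f"breakpoint chromosome {bp.chrom!r} does not match transcript "
            f"{model.transcript_id} on {model.chrom!r}"
        )
    region = model.region_of(bp.pos)
    count = model.cds_bases_upstream(bp.pos, inclusive=(side == "five_prime"))
    return region, count


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

def classify_effect(
    call: FusionCall,
    model5: TranscriptModel | None,
    model3: TranscriptModel | None,
    genome: GenomeStore | None = None,
) -> tuple[str, int, int, str, str, bool]:
    """Predicted junction effect for one fusion call.

    Returns ``(effect, L5, S3, region5, region3, junction_stop)``. The
    decision tree:

    1. either parental gene unresolvable -> ``unclassified``;
    2. either breakpoint outside its gene span -> ``intergenic``;
    3. both breakpoints in CDS of protein-coding transcripts ->
       ``In-frame`` iff ``L5 = S3 (mod 3)``, else ``Out-of-frame``;
    4. otherwise the region pair names the class, e.g. CDS x UTR ->
       ``CDS(truncated)_UTR``, intron x CDS -> ``intronic_CDS(truncated)``.

    Non-protein-coding partners have no CDS, hence can never yield
    ``In-frame``. When ``genome`` is given, In-frame junctions whose
    straddling codon encodes a stop are flagged (but stay In-frame under the
    parity rule).
    """
    if model5 is None or model3 is None:
        return "unclassified", 0, 0, "unresolved", "unresolved", False

    region5, l5 = locate_breakpoint(call.bp5, model5, "five_prime")
    region3, s3 = locate_breakpoint(call.bp3, model3, "three_prime")

    if region5 == "intergenic" or region3 == "intergenic":
        return "intergenic", l5, s3, region5, region3, False

    if region5 == "cds" and region3 == "cds":
        if (l5 - s3) % 3 == 0:
            stop = False
            if genome is not None:
                stop = _junction_codon_is_stop(call, model5, model3, l5, genome)
            return "In-frame", l5, s3, region5, region3, stop
        return "Out-of-frame", l5, s3, region5, region3, False

    effect = f"{_REGION_TOKEN[region5]}_{_REGION_TOKEN[region3]}"
    if effect == "CDS(truncated)_CDS(truncated)":  # unreachable, guarded above
        raise AssertionError("CDS x CDS must be handled by the frame rule")
    return effect, l5, s3, region5, region3, False


_STOPS = {"TAA", "TAG", "TGA"}


def _junction_codon_is_stop(
    call: FusionCall,
    model5: TranscriptModel,
    model3: TranscriptModel,
    l5: int,
    genome: GenomeStore,
) -> bool:
    """Whether the codon straddling an in-frame junction encodes a stop."""
    phase = l5 % 3
    if phase == 0:
        return False  # junction falls on a codon boundary; no straddling codon
    tail = _cds_tail(model5, call.bp5.pos, phase, genome)
    head = _cds_head(model3, call.bp3.pos, 3 - phase, genome)
    return (tail + head) in _STOPS


def _cds_tail(model: TranscriptModel, pos: int, n: int, genome: GenomeStore) -> str:
    """Last ``n`` CDS bases at or upstream of ``pos``, transcript orientation."""
    bases: list[str] = []
    for s, e in model.cds:
        if model.strand == "+":
            lo, hi = s, min(e, pos)
        else:
            lo, hi = max(s, pos), e
        if lo <= hi:
            bases.append(genome.fetch(model.chrom, lo, hi, model.strand))
    seq = "".join(bases)
    return seq[-n:]


def _cds_head(model: TranscriptModel, pos: int, n: int, genome: GenomeStore) -> str:
    """First ``n`` CDS bases at or downstream of ``pos``, transcript orientation."""
    bases: list[str] = []
    for s, e in model.cds:
        if model.strand == "+":
            lo, hi = max(s, pos), e
        else:
            lo, hi = s, min(e, pos)
        if lo <= hi:
            bases.append(genome.fetch(model.chrom, lo, hi, model.strand))
    seq = "".join(bases)
    return seq[:n]


def classify_biotypes(
    call: FusionCall,
    model5: TranscriptModel | None,
    model3: TranscriptModel | None,
) -> tuple[str, str]:
    """Ordered (5' biotype, 3' biotype) pair; unresolved genes -> 'unknown'."""
    b5 = model5.biotype if model5 is not None else "unknown"
    b3 = model3.biotype if model3 is not None else "unknown"
    return b5, b3


# ---------------------------------------------------------------------------
# Batch driver and summaries
# ---------------------------------------------------------------------------

def classify_all(
    calls: Sequence[FusionCall],
    models: Iterable[TranscriptModel] | Mapping[str, TranscriptModel],
    genome: GenomeStore | None = None,
) -> list[ClassifiedFusion]:
    """Classify every call: relation, effect, biotype pair, L5/S3."""
    if not isinstance(models, Mapping):
        models = resolve_models(models)
    out: list[ClassifiedFusion] = []
    for call in calls:
        m5, m3 = models.get(call.gene5), models.get(call.gene3)
        effect, l5, s3, r5, r3, stop = classify_effect(call, m5, m3, genome)
        b5, b3 = classify_biotypes(call, m5, m3)
        out.append(
            ClassifiedFusion(
                call=call,
                chrom_relation=classify_chromosomal(call),
                effect=effect,
                biotype5=b5,
                biotype3=b3,
                retained_cds5=l5,
                skipped_cds3=s3,
                region5=r5,
                region3=r3,
                junction_stop=stop,
            )
        )
    return out


def summarize_classes(classified: Sequence[ClassifiedFusion]) -> pd.DataFrame:
    """Per-effect-class counts and proportions (over observed classes)."""
    counts = Counter(c.effect for c in classified)
    total = sum(counts.values())
    rows = [
        {"effect": eff, "count": n, "proportion": n / total}
        for eff, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["effect", "count", "proportion"])


def summarize_biotypes(classified: Sequence[ClassifiedFusion]) -> pd.DataFrame:
    """Per biotype-pair counts and proportions (ordered 5' x 3' pairs)."""
    counts = Counter((c.biotype5, c.biotype3) for c in classified)
    total = sum(counts.values())
    rows = [
        {"biotype5": b5, "biotype3": b3, "count": n, "proportion": n / total}
        for (b5, b3), n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["biotype5", "biotype3", "count", "proportion"])


def classified_to_frame(classified: Sequence[ClassifiedFusion]) -> pd.DataFrame:
    """Tidy table of classified fusions (input columns + annotations)."""
    from .io_formats import format_breakpoint

    rows = [
        {
            "gene5": c.call.gene5,
            "gene3": c.call.gene3,
            "bp5": format_breakpoint(c.call.bp5),
            "bp3": format_breakpoint(c.call.bp3),
            "spanning_unique_reads": c.call.spanning_unique_reads,
            "sample_id": c.call.sample_id,
            "stage_day": c.call.stage_day,
            "chrom_relation": c.chrom_relation,
            "effect": c.effect,
            "biotype5": c.biotype5,
            "biotype3": c.biotype3,
            "L5": c.retained_cds5,
            "S3": c.skipped_cds3,
            "region5": c.region5,
            "region3": c.region3,
            "junction_stop": c.junction_stop,
        }
        for c in classified
    ]
    return pd.DataFrame(rows)
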