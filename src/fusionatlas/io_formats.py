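"""Readers and writers for the external formats the pipeline touches.

Formats: fusion-call tables (FusionCatcher final-list dialect and a compact
"minimal" dialect), genome FASTA (via pyfaidx, strand-aware retrieval), gene
annotation GTF, gene-set GMT, gene-level count matrices (TSV) and sample
library tables (TSV).

Coordinate convention: all genomic coordinates are 1-based, fully closed,
forward-strand numbering — the convention of the ``chrom:pos:strand``
breakpoint strings in FusionCatcher output. Any conversion to Python's
half-open 0-based slices happens exactly once, inside :class:`GenomeStore`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

log = logging.getLogger(__name__)

__all__ = [
    "Breakpoint",
    "FusionCall",
    "SampleLibrary",
    "GeneSetCollection",
    "TranscriptModel",
    "GenomeStore",
    "FormatError",
    "parse_breakpoint",
    "format_breakpoint",
    "read_fusion_table",
    "write_fusion_table",
    "read_genome",
    "read_annotation",
    "read_gmt",
    "write_gmt",
    "read_counts",
    "write_counts",
    "read_libraries",
    "write_libraries",
    "query_fusion",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Breakpoint:
    """One side of a fusion junction, as ``chrom:pos:strand``.

    ``pos`` is the 1-based forward-strand genomic coordinate of the last
    transcribed base of the 5' segment (for a 5' breakpoint) or the first
    transcribed base of the 3' segment (for a 3' breakpoint).
    """

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("breakpoint chromosome must be non-empty")
        if self.pos < 1:
            raise ValueError(f"breakpoint position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"breakpoint strand must be '+' or '-', got {self.strand!r}")


def parse_breakpoint(text: str) -> Breakpoint:
    """Parse a ``chrom:pos:strand`` string into a :class:`Breakpoint`."""
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise FormatError(f"breakpoint {text!r} is not of the form chrom:pos:strand")
    chrom, pos_s, strand = parts
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise FormatError(f"breakpoint {text!r} has non-integer position") from exc
    try:
        return Breakpoint(chrom=chrom, pos=pos, strand=strand)
    except ValueError as exc:
        raise FormatError(f"breakpoint {text!r}: {exc}") from exc


def format_breakpoint(bp: Breakpoint) -> str:
    return f"{bp.chrom}:{bp.pos}:{bp.strand}"


@dataclass(frozen=True)
class FusionCall:
    """One chimeric-RNA call: a 5' and a 3' parental gene with breakpoints.

    ``spanning_unique_reads`` — reads uniquely aligned across the junction —
    is the evidence unit the candidate filter operates on.
    """

    gene5: str
    gene3: str
    bp5: Breakpoint
    bp3: Breakpoint
    spanning_unique_reads: int
    sample_id: str = ""
    stage_day: int | None = None

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("fusion partner gene symbols must be non-empty")
        if self.spanning_unique_reads < 0:
            raise ValueError("spanning_unique_reads must be non-negative")

    @property
    def fusion_id(self) -> str:
        """Identity of the fusion isoform: partners plus both breakpoints."""
        return (
            f"{self.gene5}--{self.gene3}|"
            f"{format_breakpoint(self.bp5)}|{format_breakpoint(self.bp3)}"
        )


@dataclass(frozen=True)
class SampleLibrary:
    """Per-sample sequencing depth and developmental stage."""

    sample_id: str
    total_reads: int
    stage_day: int

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> member symbols."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are lists of 1-based closed genomic intervals in
    transcription order: ascending genomic coordinates on '+', descending on
    '-'. ``cds`` is a subset of the exonic space. Non-coding biotypes carry an
    empty ``cds``.
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    # -- basic geometry ------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds)

    # -- transcript-order arithmetic ----------------------------------------

    def _is_upstream_or_at(self, q: int, pos: int) -> bool:
        """True if genomic base q is at or 5' of pos in transcription order."""
        return q <= pos if self.strand == "+" else q >= pos

    def cds_bases_upstream(self, pos: int, inclusive: bool) -> int:
        """Count CDS bases at (if ``inclusive``) or strictly 5' of ``pos``.

        Works for any genomic position on the transcript's chromosome —
        including intronic and UTR positions — because on a single strand
        transcription order coincides with genomic order (or its reverse).
        """
        n = 0
        for s, e in self.cds:
            if self.strand == "+":
                if e <= pos:
                    n += e - s + 1
                elif s <= pos:
                    n += pos - s + 1
            else:
                if s >= pos:
                    n += e - s + 1
                elif e >= pos:
                    n += e - pos + 1
        if not inclusive and self.in_cds(pos):
            n -= 1
        return n

    def region_of(self, pos: int) -> str:
        """Region label of a genomic position relative to this transcript.

        One of ``five_prime_utr``, ``cds``, ``three_prime_utr``, ``intron``,
        ``intergenic``, or ``noncoding_exon`` (exonic position of a transcript
        with no CDS).
        """
        if not self.contains(pos):
            return "intergenic"
        if not self.in_exon(pos):
            return "intron"
        if not self.cds:
            return "noncoding_exon"
        if self.in_cds(pos):
            return "cds"
        # exonic, coding transcript, outside CDS: 5' or 3' UTR by position
        # relative to the CDS start in transcription order
        cds_start = self.cds[0][0] if self.strand == "+" else self.cds[0][1]
        if self._is_upstream_or_at(pos, cds_start) and pos != cds_start:
            return "five_prime_utr"
        return "three_prime_utr"

    def spliced_sequence(self, genome: "GenomeStore") -> str:
        """Mature transcript sequence, 5'→3' on the gene strand."""
        return "".join(
            genome.fetch(self.chrom, s, e, self.strand) for s, e in self.exons
        )


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class GenomeStore:
    """Random-access genome sequence with strand-aware retrieval.

    Queries use 1-based closed intervals; a '-' strand query returns the
    reverse complement. Out-of-range queries raise rather than clip.
    """

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def chromosomes(self) -> list[str]:
        return list(self._fasta.keys())

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._fasta:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start > end:
            raise ValueError(f"empty interval: start {start} > end {end}")
        if start < 1 or end > self.chrom_length(chrom):
            raise IndexError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {self.chrom_length(chrom)})"
            )
        seq = self._fasta[chrom][start - 1 : end].seq.upper()
        if strand == "-":
            return reverse_complement(seq)
        if strand != "+":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        return seq


def read_genome(path: str | Path) -> GenomeStore:
    """Open a FASTA file as a :class:`GenomeStore`."""
    return GenomeStore(path)


# ---------------------------------------------------------------------------
# Fusion tables
# ---------------------------------------------------------------------------

# FusionCatcher final-list column names, mapped to our field names.
_FC_COLUMNS = {
    "gene5": "Gene_1_symbol(5end_fusion_partner)",
    "gene3": "Gene_2_symbol(3end_fusion_partner)",
    "bp5": "Fusion_point_for_gene_1(5end_fusion_partner)",
    "bp3": "Fusion_point_for_gene_2(3end_fusion_partner)",
    "spanning_unique_reads": "Spanning_unique_reads",
}
_MINIMAL_COLUMNS = {
    "gene5": "gene5",
    "gene3": "gene3",
    "bp5": "bp5",
    "bp3": "bp3",
    "spanning_unique_reads": "spanning_unique_reads",
}


def read_fusion_table(
    path: str | Path,
    dialect: str = "minimal",
    sample_id: str | None = None,
) -> list[FusionCall]:
    """Read a fusion-call TSV in the ``fusioncatcher`` or ``minimal`` dialect.

    Columns are located by header name, so column order is immaterial. The
    minimal dialect additionally carries ``sample_id`` and optional
    ``stage_day`` columns; for the fusioncatcher dialect (whose final-list
    files are per-sample) the sample identity may be supplied via the
    ``sample_id`` argument or an optional ``Sample`` column.
    """
    if dialect not in ("fusioncatcher", "minimal"):
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = _FC_COLUMNS if dialect == "fusioncatcher" else _MINIMAL_COLUMNS

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field_name, col in colmap.items():
        if col not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {col!r} for dialect {dialect!r}"
            )

    calls: list[FusionCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        rowd = dict(zip(df.columns, row))
        try:
            bp5 = parse_breakpoint(rowd[colmap["bp5"]])
            bp3 = parse_breakpoint(rowd[colmap["bp3"]])
            reads = int(rowd[colmap["spanning_unique_reads"]])
            sid = rowd.get("sample_id") or rowd.get("Sample") or sample_id or ""
            stage_raw = rowd.get("stage_day", "")
            stage = int(stage_raw) if stage_raw not in ("", None) else None
            calls.append(
                FusionCall(
                    gene5=rowd[colmap["gene5"]],
                    gene3=rowd[colmap["gene3"]],
                    bp5=bp5,
                    bp3=bp3,
                    spanning_unique_reads=reads,
                    sample_id=sid,
                    stage_day=stage,
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
    return calls


def write_fusion_table(
    calls: Sequence[FusionCall], path: str | Path, dialect: str = "minimal"
) -> None:
    """Write fusion calls as TSV; inverse of :func:`read_fusion_table`."""
    if dialect == "minimal":
        rows = [
            {
                "gene5": c.gene5,
                "gene3": c.gene3,
                "bp5": format_breakpoint(c.bp5),
                "bp3": format_breakpoint(c.bp3),
                "spanning_unique_reads": c.spanning_unique_reads,
                "sample_id": c.sample_id,
                "stage_day": "" if c.stage_day is None else c.stage_day,
            }
            for c in calls
        ]
        cols = ["gene5", "gene3", "bp5", "bp3", "spanning_unique_reads",
                "sample_id", "stage_day"]
    elif dialect == "fusioncatcher":
        rows = [
            {
                _FC_COLUMNS["gene5"]: c.gene5,
                _FC_COLUMNS["gene3"]: c.gene3,
                _FC_COLUMNS["bp5"]: format_breakpoint(c.bp5),
                _FC_COLUMNS["bp3"]: format_breakpoint(c.bp3),
                _FC_COLUMNS["spanning_unique_reads"]: c.spanning_unique_reads,
                "Sample": c.sample_id,
            }
            for c in calls
        ]
        cols = list(_FC_COLUMNS.values()) + ["Sample"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def query_fusion(
    calls: Iterable[FusionCall], gene5: str, gene3: str
) -> list[FusionCall]:
    """All calls whose 5' partner is ``gene5`` and 3' partner is ``gene3``.

    Order-sensitive: the 5'/3' roles are part of the fusion's identity.
    """
    return [c for c in calls if c.gene5 == gene5 and c.gene3 == gene3]


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

_ATTR_QUOTED = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_EQ = re.compile(r"(\w+)=([^;]+)")


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    """Parse a GTF attribute column, tolerating `key "value";` and `key=value`."""
    attrs = dict(_ATTR_QUOTED.findall(text))
    if not attrs:
        attrs = {k: v.strip().strip('"') for k, v in _ATTR_EQ.findall(text)}
    return attrs


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Read a GTF into transcript models with exons in transcription order.

    Requires exon features (CDS optional); attributes ``gene_id``/``gene_name``,
    ``transcript_id`` and ``gene_biotype``. A missing ``gene_biotype`` defaults
    to ``protein_coding`` with a logged warning. A CDS interval not covered by
    the transcript's exons raises an annotation-consistency error.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}: line {lineno}: fewer than 9 GTF columns")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_gtf_attributes(attr_s)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}: line {lineno}: missing transcript_id")
            start, end = int(start_s), int(end_s)
            if tid not in meta:
                if "gene_biotype" not in attrs:
                    log.warning(
                        "%s: transcript %s lacks gene_biotype; defaulting to protein_coding",
                        path, tid,
                    )
                meta[tid] = {
                    "gene": attrs.get("gene_name", attrs.get("gene_id", tid)),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("gene_biotype", "protein_coding"),
                }
            target = exons if feature == "exon" else cds
            target.setdefault(tid, []).append((start, end))

    models: list[TranscriptModel] = []
    for tid, ex in exons.items():
        info = meta[tid]
        reverse = info["strand"] == "-"
        ex_sorted = sorted(ex, reverse=reverse)
        cds_sorted = sorted(cds.get(tid, []), reverse=reverse)
        for cs, ce in cds_sorted:
            if not any(s <= cs and ce <= e for s, e in ex_sorted):
                raise FormatError(
                    f"{path}: transcript {tid}: CDS {cs}-{ce} not covered by any exon"
                )
        models.append(
            TranscriptModel(
                gene=info["gene"],
                transcript_id=tid,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple(ex_sorted),
                cds=tuple(cds_sorted),
                biotype=info["biotype"],
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_annotation(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GTF (gene/transcript/exon/CDS features)."""
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.span[0], m.transcript_id)):
            attrs = (
                f'gene_id "{m.gene}"; gene_name "{m.gene}"; '
                f'transcript_id "{m.transcript_id}"; gene_biotype "{m.biotype}";'
            )
            lo, hi = m.span
            for feature, lohi in (("gene", (lo, hi)), ("transcript", (lo, hi))):
                fh.write(
                    f"{m.chrom}\tfusionatlas\t{feature}\t{lohi[0]}\t{lohi[1]}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for s, e in sorted(m.exons):
                fh.write(f"{m.chrom}\tfusionatlas\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in sorted(m.cds):
                fh.write(f"{m.chrom}\tfusionatlas\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t{attrs}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``"""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT set {parts[0]!r} is empty"
                )
            name, d, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: GMT set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            desc[name] = d
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            d = collection.descriptions.get(name, "")
            fh.write("\t".join([name, d, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Count matrices and library tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample count matrix (TSV, gene symbols as row index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene rows: {dupes[:5]}")
    if (df.values < 0).any():
        raise FormatError(f"{path}: negative counts present")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_libraries(path: str | Path) -> list[SampleLibrary]:
    """Read a sample-library TSV: sample_id, total_reads, stage_day."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "total_reads", "stage_day"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return [
        SampleLibrary(
            sample_id=str(r.sample_id),
            total_reads=int(r.total_reads),
            stage_day=int(r.stage_day),
        )
        for r in df.itertuples(index=False)
    ]


def write_libraries(libraries: Sequence[SampleLibrary], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": l.sample_id, "total_reads": l.total_reads, "stage_day": l.stage_day}
            for l in libraries
        ]
    ).to_csv(path, sep="\t", index=False)
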