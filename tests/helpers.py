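"""Independent oracles and fixture utilities for the test suite.

Everything here is deliberately written from first principles (Biopython for
sequence work, exact Fraction arithmetic for combinatorics) so it checks the
package's implementations without sharing their code paths.
"""

from __future__ import annotations

import math
from fractions import Fraction

from Bio.Seq import Seq

from fusionatlas.io_formats import Breakpoint, FusionCall, TranscriptModel

STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Translation oracle for CDS x CDS junctions
# ---------------------------------------------------------------------------

def _chrom_seq(fasta_path, chrom: str) -> str:
    seqs = {}
    name = None
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name:
                seqs[name].append(line)
    return "".join(seqs[chrom]).upper()


def _cds_sequence_until(model: TranscriptModel, pos: int, chrom_seq: str) -> str:
    """CDS bases of ``model`` at or 5' of ``pos`` (transcript order, 5'->3')."""
    parts = []
    for s, e in sorted(model.cds):  # genomic order
        piece = chrom_seq[s - 1 : e]
        parts.append((s, e, piece))
    if model.strand == "+":
        out = ""
        for s, e, p in parts:
            if e <= pos:
                out += p
            elif s <= pos:
                out += p[: pos - s + 1]
        return out
    out = ""
    for s, e, p in sorted(parts, reverse=True):
        if s >= pos:
            out += str(Seq(p).reverse_complement())
        elif e >= pos:
            out += str(Seq(p[pos - s :]).reverse_complement())
    return out


def _cds_sequence_from(model: TranscriptModel, pos: int, chrom_seq: str) -> str:
    """CDS bases of ``model`` at or 3' of ``pos`` (transcript order, 5'->3')."""
    parts = [(s, e, chrom_seq[s - 1 : e]) for s, e in sorted(model.cds)]
    if model.strand == "+":
        out = ""
        for s, e, p in parts:
            if s >= pos:
                out += p
            elif e >= pos:
                out += p[pos - s :]
        return out
    out = ""
    for s, e, p in sorted(parts, reverse=True):
        if e <= pos:
            out += str(Seq(p).reverse_complement())
        elif s <= pos:
            out += str(Seq(p[: pos - s + 1]).reverse_complement())
    return out


def translation_oracle(
    call: FusionCall,
    model5: TranscriptModel,
    model3: TranscriptModel,
    fasta_path,
) -> bool:
    """True iff the fused coding sequence reads through, in frame, to the 3'
    gene's annotated stop codon with no premature stop.

    Builds the chimeric CDS (5' coding prefix + retained 3' coding suffix)
    straight from the FASTA and translates it with Biopython.
    """
    seq5 = _chrom_seq(fasta_path, model5.chrom)
    seq3 = _chrom_seq(fasta_path, model3.chrom) if model3.chrom != model5.chrom else seq5
    prefix = _cds_sequence_until(model5, call.bp5.pos, seq5)
    suffix = _cds_sequence_from(model3, call.bp3.pos, seq3)
    fused = prefix + suffix
    if len(fused) % 3 != 0 or len(fused) == 0:
        return False
    protein = str(Seq(fused).translate())
    return protein.endswith("*") and protein.count("*") == 1


# ---------------------------------------------------------------------------
# Rank-based Spearman oracle
# ---------------------------------------------------------------------------

def spearman_oracle(x, y) -> float:
    """Spearman rho: average ranks plus the direct Pearson sum formula."""
    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


# ---------------------------------------------------------------------------
# GSEA running-sum oracle (exact rational arithmetic)
# ---------------------------------------------------------------------------

def es_oracle(scores, member, weight: int = 0) -> Fraction:
    """Enrichment score by direct running-sum enumeration with Fractions.

    ``scores`` sorted descending; ``member`` booleans. Integer weights only,
    so arithmetic stays exact.
    """
    n = len(scores)
    nh = sum(member)
    hit_weights = [
        Fraction(abs(Fraction(str(s))) ** weight) if m else Fraction(0)
        for s, m in zip(scores, member)
    ]
    total = sum(hit_weights)
    if total == 0:
        hit_weights = [Fraction(1) if m else Fraction(0) for m in member]
        total = Fraction(nh)
    best_pos = Fraction(0)
    best_neg = Fraction(0)
    p_hit = Fraction(0)
    p_miss = Fraction(0)
    for w, m in zip(hit_weights, member):
        p_hit += Fraction(w, total) if total else Fraction(0)
        if not m:
            p_miss += Fraction(1, n - nh)
        dev = p_hit - p_miss
        best_pos = max(best_pos, dev)
        best_neg = min(best_neg, dev)
    if best_pos > -best_neg:
        return best_pos
    if -best_neg > best_pos:
        return best_neg
    return None  # exact magnitude tie: the ES sign is convention-dependent


# ---------------------------------------------------------------------------
# Hypergeometric upper-tail oracle (exact)
# ---------------------------------------------------------------------------

def ora_oracle(M: int, K: int, n: int, k: int) -> Fraction:
    """P(overlap >= k) by exhaustive enumeration of the hypergeometric pmf."""
    total = math.comb(M, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, j) * math.comb(M - K, n - j), total)
    return acc


# ---------------------------------------------------------------------------
# Genome reflection (strand-symmetry fixture)
# ---------------------------------------------------------------------------

def reflect_genome(fasta_path, out_path) -> dict[str, int]:
    """Reverse-complement every chromosome; returns chromosome lengths."""
    lengths = {}
    chroms = []
    name = None
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                chroms.append((name, []))
            elif name:
                chroms[-1][1].append(line)
    with open(out_path, "w") as fh:
        for name, parts in chroms:
            seq = str(Seq("".join(parts)).reverse_complement()).upper()
            lengths[name] = len(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return lengths


def reflect_model(model: TranscriptModel, lengths: dict[str, int]) -> TranscriptModel:
    L = lengths[model.chrom]
    flip = lambda iv: (L - iv[1] + 1, L - iv[0] + 1)
    strand = "-" if model.strand == "+" else "+"
    reverse = strand == "-"
    return TranscriptModel(
        gene=model.gene,
        transcript_id=model.transcript_id,
        chrom=model.chrom,
        strand=strand,
        exons=tuple(sorted((flip(iv) for iv in model.exons), reverse=reverse)),
        cds=tuple(sorted((flip(iv) for iv in model.cds), reverse=reverse)),
        biotype=model.biotype,
    )


def reflect_call(call: FusionCall, lengths: dict[str, int]) -> FusionCall:
    def flip_bp(bp: Breakpoint) -> Breakpoint:
        L = lengths[bp.chrom]
        return Breakpoint(bp.chrom, L - bp.pos + 1, "-" if bp.strand == "+" else "+")

    return FusionCall(
        gene5=call.gene5,
        gene3=call.gene3,
        bp5=flip_bp(call.bp5),
        bp3=flip_bp(call.bp3),
        spanning_unique_reads=call.spanning_unique_reads,
        sample_id=call.sample_id,
        stage_day=call.stage_day,
    )
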