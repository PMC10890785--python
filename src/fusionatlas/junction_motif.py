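"""Sequence context of fusion junctions: 20-bp windows and nucleotide PWMs.

Each junction side yields a 20-nt window in gene-strand orientation: ten
bases of retained transcript context and ten bases of the departed genomic
context. Window positions are labelled -10..-1, +1..+10:

* donor window (5' breakpoint): position -1 is the last retained base, so
  +1/+2 read the first two bases past the junction — ``GT`` when the
  junction coincides with an exon/intron boundary;
* acceptor window (3' breakpoint): position +1 is the first retained base,
  so -2/-1 read the two bases immediately upstream — ``AG`` at an intron's
  3' end.

A position weight matrix over the windows then summarizes per-position
nucleotide frequencies; a consensus report checks whether the canonical
GT/AG donor-acceptor dinucleotides carry the maximal weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fusion_classify import ClassifiedFusion
from .io_formats import Breakpoint, GenomeStore

log = logging.getLogger(__name__)

__all__ = [
    "JunctionWindow",
    "PositionWeightMatrix",
    "ConsensusReport",
    "extract_junction_windows",
    "build_pwm",
    "consensus_report",
]

_ALPHABET = ("A", "C", "G", "T")
FLANK = 10  # bases on each side of the junction


@dataclass(frozen=True)
class JunctionWindow:
    fusion_id: str
    side: str        # 'donor' | 'acceptor'
    sequence: str    # 20 nt, uppercase, gene-strand oriented

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * FLANK:
            raise ValueError(f"junction window must be {2 * FLANK} nt")
        if self.side not in ("donor", "acceptor"):
            raise ValueError(f"side must be 'donor' or 'acceptor', got {self.side!r}")


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Per-position nucleotide probabilities over a fixed-width window."""

    weights: np.ndarray   # shape (4, width), rows A,C,G,T; columns sum to 1
    n_sequences: int

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [str(p) for p in range(-FLANK, 0)] + [f"+{p}" for p in range(1, FLANK + 1)]
        if self.width != 2 * FLANK:
            cols = [str(i) for i in range(self.width)]
        return pd.DataFrame(self.weights, index=list(_ALPHABET), columns=cols)


def _window_for(bp: Breakpoint, anchor: str, genome: GenomeStore) -> str | None:
    """20-mer around a breakpoint in gene-strand orientation.

    ``anchor='last'`` puts the breakpoint base at window position -1 (donor);
    ``anchor='first'`` puts it at +1 (acceptor). Returns None when the window
    would overrun the chromosome.
    """
    pos, strand = bp.pos, bp.strand
    if (anchor == "last") == (strand == "+"):
        start, end = pos - FLANK + 1, pos + FLANK
    else:
        start, end = pos - FLANK, pos + FLANK - 1
    if start < 1 or end > genome.chrom_length(bp.chrom):
        return None
    return genome.fetch(bp.chrom, start, end, strand)


def extract_junction_windows(
    classified: Sequence[ClassifiedFusion],
    genome: GenomeStore,
) -> tuple[list[JunctionWindow], int]:
    """Donor and acceptor windows for every classified fusion.

    Windows overrunning a chromosome end are dropped with a warning; the
    second return value counts the dropped windows.
    """
    windows: list[JunctionWindow] = []
    dropped = 0
    for c in classified:
        fid = c.call.fusion_id
        donor = _window_for(c.call.bp5, "last", genome)
        if donor is None:
            dropped += 1
            log.warning("donor window for %s overruns chromosome end; dropped", fid)
        else:
            windows.append(JunctionWindow(fid, "donor", donor))
        acceptor = _window_for(c.call.bp3, "first", genome)
        if acceptor is None:
            dropped += 1
            log.warning("acceptor window for %s overruns chromosome end; dropped", fid)
        else:
            windows.append(JunctionWindow(fid, "acceptor", acceptor))
    return windows, dropped


def build_pwm(
    windows: Sequence[JunctionWindow | str],
    pseudocount: float = 0.0,
) -> PositionWeightMatrix:
    """Position weight matrix of a set of equal-length windows.

    Column j weight of base b is ``(count + pseudocount) / (n_valid +
    4*pseudocount)`` where ``n_valid`` excludes N bases at that position
    (ambiguity bases are excluded per column, not per window).
    """
    seqs = [w.sequence if isinstance(w, JunctionWindow) else w.upper() for w in windows]
    if not seqs:
        raise ValueError("build_pwm needs at least one window")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("all windows must have equal length")

    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), width)
    counts = np.zeros((4, width))
    for i, b in enumerate(_ALPHABET):
        counts[i] = (arr == b.encode()).sum(axis=0)
    n_valid = counts.sum(axis=0)  # Ns contribute to no row
    denom = n_valid + 4.0 * pseudocount
    if np.any(denom == 0):
        raise ValueError("a column contains only ambiguity bases")
    weights = (counts + pseudocount) / denom
    return PositionWeightMatrix(weights=weights, n_sequences=len(seqs))


@dataclass(frozen=True)
class ConsensusReport:
    consensus: str                 # per-position argmax base
    ties: tuple[bool, ...]         # per-position tie flag
    donor_canonical: bool          # G,T maximal at +1,+2
    acceptor_canonical: bool       # A,G maximal at -2,-1


def consensus_report(pwm: PositionWeightMatrix) -> ConsensusReport:
    """Per-position consensus and canonical GT/AG splice-motif flags.

    Ties break alphabetically and are flagged. The donor flag asks whether G
    and T are the (untied) maxima at window positions +1 and +2; the acceptor
    flag asks the same for A and G at -2 and -1.
    """
    w = pwm.weights
    argmax = w.argmax(axis=0)  # first (alphabetical) index on ties
    maxval = w.max(axis=0)
    ties = tuple(bool((np.abs(w[:, j] - maxval[j]) < 1e-12).sum() > 1) for j in range(pwm.width))
    consensus = "".join(_ALPHABET[i] for i in argmax)

    donor_canonical = acceptor_canonical = False
    if pwm.width == 2 * FLANK:
        plus1, plus2 = FLANK, FLANK + 1
        minus2, minus1 = FLANK - 2, FLANK - 1
        donor_canonical = (
            consensus[plus1] == "G" and not ties[plus1]
            and consensus[plus2] == "T" and not ties[plus2]
        )
        acceptor_canonical = (
            consensus[minus2] == "A" and not ties[minus2]
            and consensus[minus1] == "G" and not ties[minus1]
        )
    return ConsensusReport(
        consensus=consensus,
        ties=ties,
        donor_canonical=donor_canonical,
        acceptor_canonical=acceptor_canonical,
    )
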