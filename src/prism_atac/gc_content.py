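"""GC-fraction annotation of peaks from an indexed genome FASTA.

GC content is the covariate used for background matching: sets of peaks
with different base composition carry different technical biases, so the
correction stage requires every peak's GC fraction.  GC is computed on the
peak interval exactly as given, case-insensitively, over determined bases
only — N and other IUPAC ambiguity codes are excluded from the denominator.
"""
from __future__ import annotations

import numpy as np
from pyfaidx import Fasta

from .exceptions import MissingChromosomeError
from .matrix_io import PeakTable

__all__ = ["compute_gc", "gc_fraction"]

_GC = frozenset("GC")
_ACGT = frozenset("ACGT")


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T), case-insensitive; NaN if no ACGT base."""
    seq = sequence.upper()
    acgt = sum(seq.count(b) for b in _ACGT)
    if acgt == 0:
        return float("nan")
    return sum(seq.count(b) for b in _GC) / acgt


def compute_gc(peaks: PeakTable, fasta_path) -> PeakTable:
    """Return a copy of ``peaks`` with the gc column filled from the FASTA.

    Peaks whose sequence contains no determined base keep gc = NaN; they are
    excluded from background-matching candidacy downstream rather than
    imputed.  A peak on a chromosome missing from the FASTA, or extending
    past its end, is a hard error listing the offending peaks.
    """
    genome = Fasta(str(fasta_path), rebuild=False)
    missing = [str(pid) for pid, chrom in zip(peaks.peak_id, peaks.chrom)
               if str(chrom) not in genome]
    if missing:
        raise MissingChromosomeError(
            f"peaks on chromosomes absent from FASTA: {missing[:10]}"
            + ("..." if len(missing) > 10 else ""))
    out_of_range = [str(pid) for pid, chrom, end in
                    zip(peaks.peak_id, peaks.chrom, peaks.end)
                    if int(end) > len(genome[str(chrom)])]
    if out_of_range:
        raise MissingChromosomeError(
            f"peaks extending past chromosome end: {out_of_range[:10]}")
    gc = np.empty(len(peaks))
    for i in range(len(peaks)):
        seq = genome[str(peaks.chrom[i])][int(peaks.start[i]):int(peaks.end[i])].seq
        gc[i] = gc_fraction(seq)
    return peaks.with_gc(gc)
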