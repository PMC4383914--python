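"""From raw 3'-end tags to strand-corrected cleavage events.

A raw read from the tag-sequencing protocol is
``linker + T^k + reverse-complement(3' fragment of the transcript)``: the
oligo-d(T) primer leaves a run of T's after the 5' template-switching linker,
and the remainder is the transcript's 3' end read back towards the body of
the gene.  Preprocessing therefore (1) requires and removes the linker,
(2) strips the T-run greedily until a non-T base, (3) discards anything
shorter than 25 nt, (4) maps the surviving fragment and keeps unique hits
only, and (5) converts each unique alignment into a cleavage event on the
*transcript* strand — which is the opposite of the alignment strand, with the
cleavage position at the alignment's 3'-most base in transcript orientation.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .io import Alignment, Genome, reverse_complement

__all__ = [
    "RawRead",
    "TrimmedRead",
    "CleavageEvent",
    "REJECT_NO_LINKER",
    "REJECT_TOO_SHORT",
    "MIN_TRIMMED_LENGTH",
    "read_fastq",
    "write_fastq",
    "trim_read",
    "trim_reads",
    "map_reads",
    "to_cleavage_event",
]

REJECT_NO_LINKER = "no_linker"
REJECT_TOO_SHORT = "too_short"

#: Trimmed fragments shorter than this are discarded.
MIN_TRIMMED_LENGTH = 25


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    quality: Optional[str] = None


@dataclass(frozen=True)
class TrimmedRead:
    """A read with linker and leading T-run removed."""

    read_id: str
    sequence: str
    n_t_removed: int


@dataclass(frozen=True)
class CleavageEvent:
    """One read's 3' end placed on the genome.

    ``pos`` is the 1-based genomic position of the 3'-most templated base of
    the transcript (the base immediately before the poly(A) tail); ``strand``
    is the transcript strand.
    """

    chrom: str
    strand: str
    pos: int
    read_id: Optional[str] = None
    sample: str = "pooled"


def read_fastq(path: str | os.PathLike) -> list[RawRead]:
    with open(path) as fh:
        return [
            RawRead(title.split()[0], seq.upper(), qual)
            for title, seq, qual in FastqGeneralIterator(fh)
        ]


def write_fastq(reads: Iterable[RawRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def trim_read(
    read: RawRead,
    linker: str,
    max_linker_mismatches: int = 0,
    min_length: int = MIN_TRIMMED_LENGTH,
) -> tuple[Optional[TrimmedRead], Optional[str]]:
    """Remove the linker prefix and the following T-run.

    Returns ``(TrimmedRead, None)`` on success or ``(None, reason)`` with
    reason ``no_linker`` (linker prefix not recognized within the mismatch
    budget) or ``too_short`` (fragment < `min_length` after trimming).
    """
    if not linker:
        raise ValueError("linker sequence must be non-empty")
    seq = read.sequence
    if not seq:
        raise ValueError(f"empty read {read.read_id}")
    if len(seq) < len(linker):
        return None, REJECT_NO_LINKER
    mismatches = sum(a != b for a, b in zip(linker, seq))
    if mismatches > max_linker_mismatches:
        return None, REJECT_NO_LINKER
    i = len(linker)
    j = i
    while j < len(seq) and seq[j] == "T":
        j += 1
    fragment = seq[j:]
    if len(fragment) < min_length:
        return None, REJECT_TOO_SHORT
    return TrimmedRead(read.read_id, fragment, j - i), None


def trim_reads(
    reads: Iterable[RawRead],
    linker: str,
    max_linker_mismatches: int = 0,
    min_length: int = MIN_TRIMMED_LENGTH,
) -> tuple[list[TrimmedRead], Counter]:
    """Trim a batch, returning kept reads and per-reason rejection counts."""
    kept: list[TrimmedRead] = []
    counts: Counter = Counter(n_raw=0)
    for read in reads:
        counts["n_raw"] += 1
        trimmed, reason = trim_read(read, linker, max_linker_mismatches, min_length)
        if trimmed is None:
            counts[reason] += 1
        else:
            kept.append(trimmed)
    return kept, counts


def _find_all(text: str, pattern: str) -> list[int]:
    hits, i = [], text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def map_reads(
    trimmed_reads: Iterable[TrimmedRead],
    genome: Genome,
    size_cap: int = 10_000_000,
) -> tuple[list[Alignment], Counter]:
    """Exact-match toy mapper: every occurrence of the read or its reverse
    complement, both strands, whole genome.

    A read is unique iff it occurs exactly once genome-wide; only unique
    alignments are returned.  Intended for the small synthetic genomes used
    in tests — genomes above `size_cap` are refused because the scan is
    linear per read.
    """
    total = sum(genome.lengths.values())
    if total > size_cap:
        raise ValueError(
            f"builtin mapper refused: genome size {total} exceeds cap {size_cap}"
        )
    cache: dict[str, list[tuple[str, int, int, str]]] = {}
    alignments: list[Alignment] = []
    counts: Counter = Counter(unmapped=0, multimapped=0, mapped_unique=0)
    for read in trimmed_reads:
        seq = read.sequence
        occs = cache.get(seq)
        if occs is None:
            occs = []
            rc = reverse_complement(seq)
            for chrom, text in genome.seqs.items():
                for i in _find_all(text, seq):
                    occs.append((chrom, i, i + len(seq), "+"))
                for i in _find_all(text, rc):
                    occs.append((chrom, i, i + len(seq), "-"))
            cache[seq] = occs
        if not occs:
            counts["unmapped"] += 1
        elif len(occs) > 1:
            counts["multimapped"] += 1
        else:
            chrom, start, end, strand = occs[0]
            counts["mapped_unique"] += 1
            alignments.append(Alignment(read.read_id, chrom, start, end, strand))
    return alignments, counts


def to_cleavage_event(alignment: Alignment, sample: str = "pooled") -> CleavageEvent:
    """Convert a unique alignment of a trimmed tag into a cleavage event.

    The trimmed read is the reverse complement of the transcript 3' end, so
    the transcript strand is the opposite of the alignment strand and the
    cleavage site is the read's 5' base: the alignment's rightmost base
    (1-based ``end``) for minus-strand alignments, the leftmost (``start+1``)
    for plus-strand alignments.
    """
    if not alignment.unique:
        raise ValueError(f"non-unique alignment for {alignment.read_id}")
    if alignment.strand == "-":
        return CleavageEvent(alignment.chrom, "+", alignment.end,
                             alignment.read_id, sample)
    return CleavageEvent(alignment.chrom, "-", alignment.start + 1,
                         alignment.read_id, sample)
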