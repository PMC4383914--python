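"""Readers, writers and coordinate conventions for the standard formats.

Every genomic interval handled inside the package is 0-based, half-open
``[start, end)`` on the plus strand of the reference.  Cleavage positions and
poly(A)-site reference points, which are user-facing, are 1-based single
positions and are rendered as ``pA:<pos>`` in output files.

Parsing of FASTA is delegated to Biopython, GTF/GFF3 to gffutils and SAM/BAM
to pysam; this module only fixes the conventions and the in-memory types.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pysam
from Bio import SeqIO

__all__ = [
    "Genome",
    "GeneModel",
    "Alignment",
    "AlignmentSet",
    "reverse_complement",
    "load_genome",
    "load_gene_models",
    "read_alignments",
    "write_alignments_sam",
    "write_polya_sites",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N, case preserved."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Genome:
    """A set of named chromosome sequences with strand-aware subsequence access."""

    seqs: Mapping[str, str]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.seqs

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.seqs.items()}

    def length(self, chrom: str) -> int:
        return len(self.seqs[chrom])

    def subseq(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on `chrom`; minus strand returns the
        reverse complement (5'->3' on the transcribed strand)."""
        if chrom not in self.seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self.seqs[chrom])
        if not (0 <= start < end <= n):
            raise ValueError(
                f"invalid interval [{start}, {end}) on {chrom} of length {n}"
            )
        if strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        s = self.seqs[chrom][start:end]
        return s if strand == "+" else reverse_complement(s)


def load_genome(fasta_path: str | os.PathLike) -> Genome:
    """Load a FASTA file into memory, uppercasing all sequences.

    Duplicate record names and files with no FASTA records are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return Genome(seqs)


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exons, optional CDS, and the derived 3'-end landmarks.

    ``tts`` is the 1-based genomic position of the 3'-most transcribed base
    (max exon end on '+', min exon start + 1 on '-').  The 3'-UTR is derived
    as the exonic sequence 3' of the CDS when a CDS is present.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        object.__setattr__(self, "exons", exons)
        if self.cds is not None:
            object.__setattr__(self, "cds", tuple(sorted(tuple(c) for c in self.cds)))

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tts(self) -> int:
        if self.strand == "+":
            return self.exons[-1][1]
        return self.exons[0][0] + 1

    def _exonic_3prime_of_cds(self) -> tuple[tuple[int, int], ...]:
        assert self.cds
        if self.strand == "+":
            hi = max(e for _, e in self.cds)
            return tuple((max(s, hi), e) for s, e in self.exons if e > hi)
        lo = min(s for s, _ in self.cds)
        return tuple((s, min(e, lo)) for s, e in self.exons if s < lo)

    def _exonic_5prime_of_cds(self) -> tuple[tuple[int, int], ...]:
        assert self.cds
        if self.strand == "+":
            lo = min(s for s, _ in self.cds)
            return tuple((s, min(e, lo)) for s, e in self.exons if s < lo)
        hi = max(e for _, e in self.cds)
        return tuple((max(s, hi), e) for s, e in self.exons if e > hi)

    @property
    def three_prime_utr(self) -> Optional[tuple[tuple[int, int], ...]]:
        """Intervals of the derived 3'-UTR, or None when no CDS is annotated."""
        if self.cds is None:
            return None
        return self._exonic_3prime_of_cds()

    @property
    def five_prime_utr(self) -> Optional[tuple[tuple[int, int], ...]]:
        if self.cds is None:
            return None
        return self._exonic_5prime_of_cds()


def _feature_ids(feat: gffutils.Feature) -> tuple[str, str | None]:
    """(transcript_id, gene_id) from GTF attributes or GFF3 Parent links."""
    attrs = feat.attributes
    if "transcript_id" in attrs:
        tid = attrs["transcript_id"][0]
    elif "Parent" in attrs:
        tid = attrs["Parent"][0]
    else:
        raise ValueError(f"feature without transcript_id/Parent: {feat}")
    gid = attrs["gene_id"][0] if "gene_id" in attrs else None
    return tid, gid


def load_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GTF or GFF3 file into one :class:`GeneModel` per transcript.

    Accepts GTF attribute keys (``gene_id``/``transcript_id``) and GFF3
    ``ID``/``Parent`` links.  A declared transcript with no exons, or exons
    with contradictory strands, is an error.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str, str | None]] = {}  # chrom, strand, gene
    declared: dict[str, str | None] = {}  # transcript features seen -> gene_id

    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype in ("transcript", "mrna"):
            gid = None
            if "gene_id" in feat.attributes:
                gid = feat.attributes["gene_id"][0]
            elif "Parent" in feat.attributes:
                gid = feat.attributes["Parent"][0]
            declared[feat.id] = gid
            continue
        if ftype not in ("exon", "cds"):
            continue
        tid, gid = _feature_ids(feat)
        interval = (feat.start - 1, feat.end)  # gffutils is 1-based inclusive
        meta = (feat.seqid, feat.strand, gid)
        if tid in tx_meta:
            chrom, strand, known_gid = tx_meta[tid]
            if chrom != feat.seqid:
                raise ValueError(f"transcript {tid} spans multiple chromosomes")
            if strand != feat.strand:
                raise ValueError(f"contradictory strands within transcript {tid}")
            if known_gid is None and gid is not None:
                tx_meta[tid] = (chrom, strand, gid)
        else:
            tx_meta[tid] = meta
        (tx_exons if ftype == "exon" else tx_cds).setdefault(tid, []).append(interval)

    for tid in declared:
        if tid not in tx_exons:
            raise ValueError(f"transcript {tid} has no exons")

    models = []
    for tid, (chrom, strand, gid) in tx_meta.items():
        if tid not in tx_exons:
            raise ValueError(f"transcript {tid} has no exons")
        if gid is None:
            gid = declared.get(tid) or tid
        cds = tuple(tx_cds[tid]) if tid in tx_cds else None
        models.append(
            GeneModel(
                gene_id=gid,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=tuple(tx_exons[tid]),
                cds=cds,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.span, m.transcript_id))
    return models


@dataclass(frozen=True)
class Alignment:
    """A mapped read as a 0-based half-open genomic interval."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    unique: bool = True

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty alignment interval for {self.read_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad alignment strand {self.strand!r}")


@dataclass
class AlignmentSet:
    """Alignments read from SAM/BAM plus counts of skipped records."""

    alignments: list[Alignment] = field(default_factory=list)
    n_unmapped: int = 0
    n_secondary: int = 0

    def __iter__(self):
        return iter(self.alignments)

    def __len__(self) -> int:
        return len(self.alignments)


def read_alignments(path: str | os.PathLike) -> AlignmentSet:
    """Read SAM/BAM into :class:`Alignment` records.

    Unmapped records are skipped and counted; secondary/supplementary records
    are skipped and counted (their primaries carry the multi-mapper flag); a
    primary record with an ``NH`` tag > 1 is kept but marked non-unique.
    """
    result = AlignmentSet()
    try:
        fh = pysam.AlignmentFile(str(path))
    except ValueError as exc:
        raise ValueError(f"cannot read alignments from {path}: {exc}") from exc
    with fh:
        for rec in fh:
            if rec.is_unmapped:
                result.n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                result.n_secondary += 1
                continue
            unique = not (rec.has_tag("NH") and rec.get_tag("NH") > 1)
            result.alignments.append(
                Alignment(
                    read_id=rec.query_name,
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    unique=unique,
                )
            )
    return result


def write_alignments_sam(
    alignments: Iterable[Alignment], genome: Genome, path: str | os.PathLike
) -> None:
    """Write alignments as SAM (text) against `genome`'s sequence dictionary."""
    chroms = list(genome.chroms)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": genome.length(c)} for c in chroms],
    }
    index = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = index[aln.chrom]
            rec.reference_start = aln.start
            rec.flag = 16 if aln.strand == "-" else 0
            length = aln.end - aln.start
            rec.cigartuples = [(0, length)]
            rec.query_sequence = genome.subseq(aln.chrom, aln.start, aln.end, "+")
            rec.mapping_quality = 255
            if not aln.unique:
                rec.set_tag("NH", 2)
            out.write(rec)


def _site_row(site, samples: Sequence[str]) -> dict:
    cluster = site.cluster
    lo, hi = cluster.span
    signals = ";".join(f"{s.hexamer}@{s.offset}" for s in site.signals) or "."
    ann = site.annotation
    row = {
        "chrom": cluster.chrom,
        "strand": cluster.strand,
        "ref_pos": site.reference_pos,
        "name": f"pA:{site.reference_pos}",
        "cluster_start": lo,
        "cluster_end": hi,
        "n_positions": len(cluster.counts),
        "total_reads": cluster.total,
        "pooled_rpm": site.pooled_rpm,
        "signals": signals,
        "category": ann.category if ann else ".",
        "gene_id": (ann.gene_id if ann and ann.gene_id else "."),
        "position_counts": ";".join(
            f"{p}:{c}" for p, c in sorted(cluster.counts.items())
        ),
    }
    for s in samples:
        row[f"rpm_{s}"] = site.rpm.get(s, 0.0)
    return row


def write_polya_sites(
    sites: Sequence,
    bed_path: str | os.PathLike,
    tsv_path: str | os.PathLike,
    samples: Sequence[str] | None = None,
) -> None:
    """Write called poly(A) sites as BED6 plus a full per-site TSV.

    BED intervals are the single reference position ``(ref-1, ref)``, named
    ``pA:<1-based ref>`` with the rounded pooled RPM as score, sorted by
    chromosome and coordinate.  The TSV carries cluster span, per-position
    counts, signals, annotation and per-sample RPM.
    """
    import pandas as pd

    if samples is None:
        seen: dict[str, None] = {}
        for site in sites:
            for s in site.rpm:
                seen.setdefault(s)
        samples = list(seen)
    ordered = sorted(sites, key=lambda s: (s.cluster.chrom, s.reference_pos))
    with open(bed_path, "w") as bed:
        for site in ordered:
            ref = site.reference_pos
            bed.write(
                f"{site.cluster.chrom}\t{ref - 1}\t{ref}\tpA:{ref}\t"
                f"{round(site.pooled_rpm)}\t{site.cluster.strand}\n"
            )
    columns = [
        "chrom", "strand", "ref_pos", "name", "cluster_start", "cluster_end",
        "n_positions", "total_reads", "pooled_rpm", "signals", "category",
        "gene_id", "position_counts",
    ] + [f"rpm_{s}" for s in samples]
    frame = pd.DataFrame([_site_row(s, samples) for s in ordered], columns=columns)
    frame.to_csv(tsv_path, sep="\t", index=False)
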