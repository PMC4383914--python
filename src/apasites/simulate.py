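"""Synthetic reference and 3'-end read generator with full ground truth.

The generator emulates the tag-library structure the pipeline expects: each
read is ``linker + T^k + reverse-complement(transcript 3' fragment)`` where
the fragment ends at a cleavage position jittered a few nucleotides around a
planted poly(A) site.  The reference is a random genome carrying planted
two-exon genes (1-4 poly(A) sites each in the last exon, an AATAAA signal
10-30 nt upstream of every site, TTS at the distal site) and planted
internal-priming traps: genomic A-tracts with reads ending immediately
upstream, which the internal-priming filter must remove.

Construction guarantees that matter for interpreting green tests:

* the base at every possible cleavage position is chosen so the greedy
  T-strip cannot eat into the fragment (no A immediately 5' of the tail in
  read orientation) — real data has no such guarantee, which is an inherent,
  documented bias of the trimming rule;
* the 20-nt windows downstream of every true site (for all jitter offsets)
  are redrawn until the internal-priming filter passes, so planted true
  sites are never artifact-flagged;
* fragments are rejected and resampled if they occur more than once in the
  genome, keeping the unique-mapper assumption testable.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import os
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, Genome, reverse_complement
from .preprocess import RawRead, write_fastq
from .sites import internal_priming_flag

__all__ = [
    "SimConfig",
    "GeneTruth",
    "TrapTruth",
    "SimTruth",
    "SimReference",
    "simulate_reference",
    "simulate_reads",
]

_BASES = np.array(list("ACGT"))

# gene geometry (nt): first exon, intron, coding part of the last exon,
# distance from the end of the CDS to the first poly(A) site, and the
# spacing between successive sites (> 24-nt cluster gap + jitter).
_EXON1 = 150
_INTRON = 80
_CDS_LAST = 100
_UTR_LEAD = 50
_SITE_SPACING = 80
_MARGIN = 200
_TRAP_OFFSET = 1150  # past the gene end: > 1 kb downstream extent + tolerance
_TRAP_LEN = 15
_STRIDE_SLACK = 2400


def _last_exon_len(k: int) -> int:
    return _CDS_LAST + _UTR_LEAD + (k - 1) * _SITE_SPACING


def _gene_span(k: int) -> int:
    return _EXON1 + _INTRON + _last_exon_len(k)


@dataclass(frozen=True)
class SimConfig:
    """The stated world of the simulation; defaults are the conditions the
    acceptance suite runs under (20 genes x 2 sites, 100 reads/site)."""

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 60_000
    n_genes: int = 20
    sites_per_gene: int = 2
    site_abundances: Optional[tuple[float, ...]] = None  # None = uniform
    reads_per_gene: int = 200
    jitter: dict[int, float] = field(
        default_factory=lambda: {0: 0.6, 1: 0.15, -1: 0.15, 2: 0.05, -2: 0.05}
    )
    tail_length_range: tuple[int, int] = (5, 20)
    linker: str = "AGCTGTCA"
    fragment_length_range: tuple[int, int] = (40, 80)
    n_traps: int = 5
    reads_per_trap: int = 20
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.sites_per_gene <= 4:
            raise ValueError("sites_per_gene must be in 1..4")
        if abs(sum(self.jitter.values()) - 1.0) > 1e-9:
            raise ValueError("jitter probabilities must sum to 1")
        ab = self.abundances
        if len(ab) != self.sites_per_gene or abs(sum(ab) - 1.0) > 1e-9:
            raise ValueError("site abundances must match sites_per_gene and sum to 1")
        lo, hi = self.fragment_length_range
        if lo < 25 or hi < lo:
            raise ValueError("fragment lengths must be >= 25 and ordered")
        if not self.linker or set(self.linker) - set("ACGT"):
            raise ValueError("linker must be a non-empty ACGT string")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")
        if self.n_traps > self.n_genes:
            raise ValueError("n_traps must not exceed n_genes")

    @property
    def abundances(self) -> tuple[float, ...]:
        if self.site_abundances is not None:
            return tuple(self.site_abundances)
        k = self.sites_per_gene
        return tuple(1.0 / k for _ in range(k))


@dataclass(frozen=True)
class GeneTruth:
    """Planted facts for one gene; sites are ordered proximal -> distal
    along the transcript (the distal site is the annotated TTS)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    sites: tuple[int, ...]  # 1-based cleavage positions
    abundances: tuple[float, ...]
    signal_offsets: tuple[int, ...]
    tts: int


@dataclass(frozen=True)
class TrapTruth:
    chrom: str
    cleavage_pos: int  # 1-based position immediately upstream of the tract
    tract_start: int  # 0-based start of the planted A-run
    tract_len: int


@dataclass
class SimTruth:
    genes: list[GeneTruth]
    traps: list[TrapTruth]

    @property
    def all_sites(self) -> list[tuple[str, str, int, str]]:
        """(chrom, strand, 1-based position, gene_id) for every true site."""
        return [
            (g.chrom, g.strand, pos, g.gene_id)
            for g in self.genes
            for pos in g.sites
        ]


@dataclass
class SimReference:
    genome: Genome
    models: list[GeneModel]
    truth: SimTruth
    config: SimConfig

    def fasta_text(self) -> str:
        out = []
        for chrom, seq in self.genome.seqs.items():
            out.append(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                out.append(seq[i : i + 80] + "\n")
        return "".join(out)

    def gtf_text(self) -> str:
        lines = []
        for m in self.models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            lo, hi = m.span
            for ftype, ivs in (
                ("gene", [(lo, hi)]),
                ("transcript", [(lo, hi)]),
                ("exon", list(m.exons)),
                ("CDS", list(m.cds or ())),
            ):
                for s, e in ivs:
                    lines.append(
                        f"{m.chrom}\tapasim\t{ftype}\t{s + 1}\t{e}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )
        return "".join(lines)

    def save(self, fasta_path: str | os.PathLike, gtf_path: str | os.PathLike) -> None:
        with open(fasta_path, "w") as fh:
            fh.write(self.fasta_text())
        with open(gtf_path, "w") as fh:
            fh.write(self.gtf_text())


def _plant(arr: np.ndarray, start: int, text: str) -> None:
    arr[start : start + len(text)] = list(text)


def _redraw(arr: np.ndarray, start: int, end: int, rng, exclude: str = "") -> None:
    alphabet = np.array([b for b in "ACGT" if b not in exclude])
    arr[start:end] = rng.choice(alphabet, size=end - start)


def _gene_layout(origin: int, strand: str, k: int) -> tuple[
    tuple[tuple[int, int], ...], tuple[tuple[int, int], ...], tuple[int, ...]
]:
    """(exons, cds, sites proximal->distal as 1-based) for a gene at origin."""
    e2 = _last_exon_len(k)
    if strand == "+":
        exon1 = (origin, origin + _EXON1)
        e2s = origin + _EXON1 + _INTRON
        exon2 = (e2s, e2s + e2)
        cds = ((origin + 20, origin + _EXON1), (e2s, e2s + _CDS_LAST))
        sites = tuple(e2s + _CDS_LAST + _UTR_LEAD + i * _SITE_SPACING
                      for i in range(k))
        return (exon1, exon2), cds, sites
    exon2 = (origin, origin + e2)
    e1s = origin + e2 + _INTRON
    exon1 = (e1s, e1s + _EXON1)
    cds = ((origin + e2 - _CDS_LAST, origin + e2), (e1s, e1s + _EXON1 - 20))
    sites = tuple(origin + 1 + (k - 1 - i) * _SITE_SPACING for i in range(k))
    return (exon2, exon1), cds, sites


def simulate_reference(config: SimConfig) -> SimReference:
    """Build the toy genome, gene models and ground truth for `config`."""
    rng = np.random.default_rng([config.seed, 0])
    k = config.sites_per_gene
    span = _gene_span(k)
    per_chrom = -(-config.n_genes // config.n_chroms)  # ceil
    usable = config.chrom_length - 2 * _MARGIN
    stride = usable // per_chrom if per_chrom else usable
    if stride < span + _STRIDE_SLACK:
        raise ValueError(
            f"config infeasible: {config.n_genes} genes of span {span} nt do "
            f"not fit in {config.n_chroms} x {config.chrom_length} nt"
        )
    arrays = {
        f"chr{c + 1}": rng.choice(_BASES, size=config.chrom_length)
        for c in range(config.n_chroms)
    }
    models: list[GeneModel] = []
    genes: list[GeneTruth] = []
    traps: list[TrapTruth] = []

    for g in range(config.n_genes):
        chrom = f"chr{g % config.n_chroms + 1}"
        arr = arrays[chrom]
        origin = _MARGIN + (g // config.n_chroms) * stride
        strand = "+" if g % 2 == 0 else "-"
        exons, cds, sites = _gene_layout(origin, strand, k)
        gene_id = f"g{g:03d}"
        model = GeneModel(gene_id, f"{gene_id}.t1", chrom, strand, exons, cds)
        models.append(model)

        offsets = []
        for pos in sites:
            o = int(rng.integers(10, 31))
            offsets.append(o)
            if strand == "+":
                _plant(arr, pos - o - 1, "AATAAA")
            else:
                _plant(arr, pos + o - 6, reverse_complement("AATAAA"))
        for pos in sites:
            # cleavage zone: the T-strip must stop at the fragment's 3' base
            _redraw(arr, pos - 3, pos + 2, rng,
                    exclude="A" if strand == "+" else "T")
        genes.append(
            GeneTruth(gene_id, model.transcript_id, chrom, strand, sites,
                      config.abundances, tuple(offsets), model.tts)
        )
        if g < config.n_traps:
            t0 = origin + span + _TRAP_OFFSET
            _plant(arr, t0, "A" * _TRAP_LEN)
            if arr[t0 - 1] == "A":
                _redraw(arr, t0 - 1, t0, rng, exclude="A")
            traps.append(TrapTruth(chrom, t0, t0, _TRAP_LEN))

    # Redraw downstream windows until no true site (at any jitter offset)
    # would be flagged as internal priming.
    for _ in range(100):
        genome = Genome({c: "".join(a) for c, a in arrays.items()})
        dirty = False
        for gene in genes:
            arr = arrays[gene.chrom]
            for pos in gene.sites:
                for delta in (-2, -1, 0, 1, 2):
                    if internal_priming_flag(genome, gene.chrom, gene.strand,
                                             pos + delta):
                        dirty = True
                        if gene.strand == "+":
                            _redraw(arr, pos + 2, pos + 22, rng)
                        else:
                            _redraw(arr, pos - 23, pos - 3, rng)
        if not dirty:
            break
    else:  # pragma: no cover - probabilistically unreachable
        raise RuntimeError("could not sanitize downstream windows")

    genome = Genome({c: "".join(a) for c, a in arrays.items()})
    return SimReference(genome, models, SimTruth(genes, traps), config)


def _count_occurrences(genome: Genome, fragment: str) -> int:
    rc = reverse_complement(fragment)
    n = 0
    for text in genome.seqs.values():
        for pat in (fragment, rc) if rc != fragment else (fragment,):
            i = text.find(pat)
            while i != -1:
                n += 1
                if n > 1:
                    return n
                i = text.find(pat, i + 1)
    return n


def _mutate(seq: str, rng, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != base]))
    return "".join(out)


def simulate_reads(
    reference: SimReference,
    sample: str = "sample1",
    abundances: Optional[Sequence[float]] = None,
    reads_per_gene: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[list[RawRead], pd.DataFrame]:
    """Generate one sample's reads plus a per-read truth table.

    `abundances` and `reads_per_gene` override the config (e.g. to model
    condition-specific site usage across samples); the random stream is
    derived from the config seed and the sample name, so distinct samples
    differ but reruns are identical.
    """
    config = reference.config
    if seed is None:
        seed = zlib.crc32(sample.encode()) % (2**31)
    rng = np.random.default_rng([config.seed, 1, seed])
    ab = tuple(abundances) if abundances is not None else config.abundances
    if len(ab) != config.sites_per_gene or abs(sum(ab) - 1.0) > 1e-9:
        raise ValueError("abundances must match sites_per_gene and sum to 1")
    n_per_gene = config.reads_per_gene if reads_per_gene is None else reads_per_gene
    genome = reference.genome
    frag_lo, frag_hi = config.fragment_length_range
    tail_lo, tail_hi = config.tail_length_range
    jitter_offsets = sorted(config.jitter)
    jitter_probs = [config.jitter[o] for o in jitter_offsets]

    unique_cache: dict[tuple[str, int, int, str], bool] = {}

    def fragment_at(chrom: str, strand: str, pos: int) -> tuple[str, int]:
        """Unique genomic fragment whose transcript 3' end is `pos`; returns
        (read-orientation fragment part, length).  Resamples the length if
        the fragment is not unique genome-wide."""
        for _ in range(30):
            length = int(rng.integers(frag_lo, frag_hi + 1))
            key = (chrom, strand, pos, length)
            if strand == "+":
                piece = genome.subseq(chrom, pos - length, pos, "+")
                readpart = reverse_complement(piece)
            else:
                piece = genome.subseq(chrom, pos - 1, pos - 1 + length, "+")
                readpart = piece
            ok = unique_cache.get((chrom, pos, length, strand))
            if ok is None:
                ok = _count_occurrences(genome, piece) == 1
                unique_cache[(chrom, pos, length, strand)] = ok
            if ok:
                return readpart, length
        raise RuntimeError(f"no unique fragment at {chrom}:{pos}")

    reads: list[RawRead] = []
    rows: list[dict] = []

    def emit(chrom, strand, true_pos, pos, origin, origin_id, jitter) -> None:
        readpart, length = fragment_at(chrom, strand, pos)
        tail = int(rng.integers(tail_lo, tail_hi + 1))
        seq = config.linker + "T" * tail + readpart
        seq = _mutate(seq, rng, config.error_rate)
        rid = f"{sample}_r{len(reads):06d}"
        reads.append(RawRead(rid, seq))
        rows.append({
            "read_id": rid, "sample": sample, "chrom": chrom, "strand": strand,
            "origin": origin, "origin_id": origin_id, "true_site": true_pos,
            "cleavage_pos": pos, "jitter": jitter, "fragment_len": length,
            "tail_len": tail,
        })

    for gene in reference.truth.genes:
        site_counts = rng.multinomial(n_per_gene, ab)
        for site_idx, n_reads in enumerate(site_counts):
            true_pos = gene.sites[site_idx]
            for _ in range(n_reads):
                delta = int(rng.choice(jitter_offsets, p=jitter_probs))
                emit(gene.chrom, gene.strand, true_pos, true_pos + delta,
                     "site", gene.gene_id, delta)

    for t_idx, trap in enumerate(reference.truth.traps):
        for _ in range(config.reads_per_trap):
            emit(trap.chrom, "+", trap.cleavage_pos, trap.cleavage_pos,
                 "trap", f"trap{t_idx:02d}", 0)

    truth = pd.DataFrame(rows)
    return reads, truth


def save_reads(
    reads: Sequence[RawRead],
    truth: pd.DataFrame,
    fastq_path: str | os.PathLike,
    truth_path: str | os.PathLike,
) -> None:
    write_fastq(reads, fastq_path)
    truth.to_csv(truth_path, sep="\t", index=False)
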