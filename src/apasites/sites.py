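"""Poly(A)-site calling: internal-priming filter, 24-nt clustering,
reference-point selection, normalized-read thresholding and poly(A)-signal
search.

The core model: true 3'-end tags mark cleavage positions scattered a few
nucleotides apart downstream of one poly(A) signal (cleavage heterogeneity).
Positions on the same chromosome strand within 24 nt of each other are
chained into one cluster; the most frequently used position is the cluster's
reference point, and clusters with at least a minimum number of normalized
reads (RPM, reads per million mapped) are reported as poly(A) sites.  Tags
whose downstream genomic context is A-rich are internal-priming artifacts
(the oligo-dT primer annealed to genomically encoded adenines rather than a
poly(A) tail) and are removed before clustering.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io import Genome
from .preprocess import CleavageEvent

__all__ = [
    "DEFAULT_SIGNAL_HEXAMERS",
    "CleavageCluster",
    "PolyASite",
    "Signal",
    "downstream_window",
    "internal_priming_flag",
    "filter_internal_priming",
    "cluster_events",
    "call_polya_sites",
    "find_signals",
]

#: Canonical AATAAA/ATTAAA plus the common single-base variants; overridable
#: wherever a signal set is accepted.
DEFAULT_SIGNAL_HEXAMERS: tuple[str, ...] = (
    "AATAAA", "ATTAAA", "AGTAAA", "TATAAA", "CATAAA", "GATAAA",
    "AATATA", "AATACA", "AATAGA", "ACTAAA", "AAGAAA", "AATGAA",
)

_A_RUN = "AAAAAAAA"
_GA_PATTERN = re.compile(r"GA{4,}GA{3,}G")


def downstream_window(
    genome: Genome, chrom: str, strand: str, pos: int, window: int = 20
) -> str:
    """Transcript-strand sequence of the `window` genomic positions
    immediately downstream of 1-based cleavage position `pos`.

    Truncated silently at the chromosome end; may be empty.
    """
    n = genome.length(chrom)
    if not 1 <= pos <= n:
        raise ValueError(f"position {pos} outside {chrom} (length {n})")
    if strand == "+":
        start, end = pos, min(pos + window, n)
    else:
        start, end = max(0, pos - 1 - window), pos - 1
    if start >= end:
        return ""
    return genome.subseq(chrom, start, end, strand)


def internal_priming_flag(
    genome: Genome,
    chrom: str,
    strand: str,
    pos: int,
    window: int = 20,
    max_a: int = 12,
) -> bool:
    """True iff the cleavage at `pos` looks internally primed.

    The downstream window (1..`window` nt past the cleavage site on the
    transcript strand) is flagged when it contains more than `max_a` A's,
    a run of eight A's, or the pattern ``G A{4,} G A{3,} G``.  N never
    counts as A and never matches a pattern.
    """
    w = downstream_window(genome, chrom, strand, pos, window)
    return (
        w.count("A") > max_a
        or _A_RUN in w
        or _GA_PATTERN.search(w) is not None
    )


def filter_internal_priming(
    events: Iterable[CleavageEvent],
    genome: Genome,
    window: int = 20,
    max_a: int = 12,
) -> tuple[list[CleavageEvent], list[CleavageEvent]]:
    """Split events into (retained, flagged-as-internal-priming)."""
    kept: list[CleavageEvent] = []
    flagged: list[CleavageEvent] = []
    for ev in events:
        if internal_priming_flag(genome, ev.chrom, ev.strand, ev.pos, window, max_a):
            flagged.append(ev)
        else:
            kept.append(ev)
    return kept, flagged


@dataclass
class CleavageCluster:
    """Heterogeneous cleavage positions chained within the 24-nt rule.

    ``counts`` pools all samples; ``sample_counts`` keeps the per-sample
    breakdown needed for normalized quantification.
    """

    chrom: str
    strand: str
    counts: dict[int, int]
    sample_counts: dict[str, dict[int, int]] = field(default_factory=dict)

    @property
    def positions(self) -> list[int]:
        return sorted(self.counts)

    @property
    def span(self) -> tuple[int, int]:
        pos = self.positions
        return pos[0], pos[-1]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def cluster_events(
    events: Iterable[CleavageEvent], max_gap: int = 24
) -> list[CleavageCluster]:
    """Single-linkage chaining of cleavage events on each (chrom, strand).

    Distinct positions are sorted; adjacent positions no more than `max_gap`
    nt apart join the same cluster, a larger gap starts a new one.  A chain
    may therefore span more than `max_gap` nt overall.  The result is
    deterministic and independent of input order.
    """
    pooled: dict[tuple[str, str], Counter] = defaultdict(Counter)
    by_sample: dict[tuple[str, str], dict[str, Counter]] = defaultdict(
        lambda: defaultdict(Counter)
    )
    for ev in events:
        key = (ev.chrom, ev.strand)
        pooled[key][ev.pos] += 1
        by_sample[key][ev.sample][ev.pos] += 1

    clusters: list[CleavageCluster] = []
    for key in sorted(pooled):
        chrom, strand = key
        counts = pooled[key]
        positions = sorted(counts)
        runs: list[list[int]] = [[positions[0]]]
        for prev, cur in zip(positions, positions[1:]):
            if cur - prev <= max_gap:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            members = set(run)
            sample_counts = {
                sample: {p: c for p, c in ctr.items() if p in members}
                for sample, ctr in by_sample[key].items()
            }
            sample_counts = {s: c for s, c in sample_counts.items() if c}
            clusters.append(
                CleavageCluster(
                    chrom=chrom,
                    strand=strand,
                    counts={p: counts[p] for p in run},
                    sample_counts=sample_counts,
                )
            )
    return clusters


@dataclass(frozen=True)
class Signal:
    """A poly(A)-signal hexamer `offset` nt upstream of the reference point
    (1-based; the hexamer occupies upstream offsets offset..offset-5)."""

    hexamer: str
    offset: int


@dataclass
class PolyASite:
    """A called poly(A) site: a cluster with its reference point, per-sample
    normalized usage, signals, and (once annotated) a genomic category."""

    cluster: CleavageCluster
    reference_pos: int
    rpm: dict[str, float]
    pooled_rpm: float
    signals: list[Signal] = field(default_factory=list)
    annotation: Optional[object] = None

    @property
    def chrom(self) -> str:
        return self.cluster.chrom

    @property
    def strand(self) -> str:
        return self.cluster.strand

    @property
    def name(self) -> str:
        return f"pA:{self.reference_pos}"

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.strand}:pA:{self.reference_pos}"


def _reference_position(cluster: CleavageCluster) -> int:
    best = max(cluster.counts.values())
    candidates = [p for p, c in cluster.counts.items() if c == best]
    # ties break towards the 3'-most position on the transcript strand
    return max(candidates) if cluster.strand == "+" else min(candidates)


def call_polya_sites(
    clusters: Iterable[CleavageCluster],
    mapped_totals: Mapping[str, int],
    min_pooled_rpm: float = 2.0,
) -> list[PolyASite]:
    """Normalize clusters to RPM and keep those above the site threshold.

    Per-sample RPM is ``raw reads x 1e6 / mapped total`` for that sample;
    the pooled RPM is the sum over samples, and clusters below
    `min_pooled_rpm` (default 2 normalized reads) are discarded.
    """
    for sample, total in mapped_totals.items():
        if total <= 0:
            raise ValueError(f"mapped total for sample {sample!r} must be > 0")
    sites: list[PolyASite] = []
    for cluster in clusters:
        rpm: dict[str, float] = {}
        for sample, counts in cluster.sample_counts.items():
            if sample not in mapped_totals:
                raise KeyError(f"no mapped total for sample {sample!r}")
            raw = sum(counts.values())
            rpm[sample] = raw * 1e6 / mapped_totals[sample]
        pooled = sum(rpm.values())
        if pooled < min_pooled_rpm:
            continue
        sites.append(
            PolyASite(
                cluster=cluster,
                reference_pos=_reference_position(cluster),
                rpm=rpm,
                pooled_rpm=pooled,
            )
        )
    return sites


def find_signals(
    genome: Genome,
    site: PolyASite | tuple[str, str, int],
    signal_set: Sequence[str] = DEFAULT_SIGNAL_HEXAMERS,
    window: int = 50,
) -> list[Signal]:
    """Scan the `window` nt upstream of the reference point (transcript
    strand, offsets -window..-1) for every occurrence of every signal
    hexamer lying fully within the window.

    The window is truncated at the chromosome start; the result may be
    empty — sites without any recognizable signal exist.
    """
    signal_set = tuple(signal_set)
    if not signal_set:
        raise ValueError("signal set must be non-empty")
    if any(len(h) != 6 for h in signal_set):
        raise ValueError("signal hexamers must have length 6")
    if isinstance(site, PolyASite):
        chrom, strand, ref = site.chrom, site.strand, site.reference_pos
    else:
        chrom, strand, ref = site
    n = genome.length(chrom)
    if strand == "+":
        length = min(window, ref - 1)
        w = genome.subseq(chrom, ref - 1 - length, ref - 1, "+") if length else ""
    else:
        length = min(window, n - ref)
        w = genome.subseq(chrom, ref, ref + length, "-") if length else ""
    members = set(signal_set)
    found = [
        Signal(w[i : i + 6], length - i)
        for i in range(len(w) - 5)
        if w[i : i + 6] in members
    ]
    found.sort(key=lambda s: (s.offset, s.hexamer))
    return found
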