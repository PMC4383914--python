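"""Annotation of called poly(A) sites against gene models, and usage
quantification: RPM matrices, gene expression, usage fractions and
cleavage-heterogeneity profiles.

Categories follow a most-specific-first precedence on the site's transcript
strand: a site at (or within a tolerance of) an annotated transcription
termination site is ``known_TTS``; otherwise membership in a derived 3'-UTR,
then the 1-kb region downstream of a TTS, then coding exon, intron and
5'-UTR; anything else is intergenic.  Gene expression is the sum of
normalized reads over all of a gene's 3' ends, and a site's usage fraction
is its share of that sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io import GeneModel
from .sites import PolyASite

__all__ = [
    "CATEGORIES",
    "SiteAnnotation",
    "UsageMatrix",
    "HeterogeneityProfile",
    "annotate_site",
    "annotate_sites",
    "normalize_counts",
    "build_usage_matrix",
    "gene_expression",
    "usage_fractions",
    "heterogeneity_profile",
]

#: Precedence order, most specific first; the last entry is the fallback.
CATEGORIES: tuple[str, ...] = (
    "known_TTS",
    "three_prime_utr",
    "downstream_1kb",
    "internal_exon",
    "intron",
    "five_prime_utr",
    "intergenic",
)

_RANK = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class SiteAnnotation:
    category: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in _RANK:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.gene_id is None) != (self.category == "intergenic"):
            raise ValueError("gene_id present iff category is not intergenic")


def _in_any(p0: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(s <= p0 < e for s, e in intervals)


def _model_category(
    model: GeneModel, ref: int, tts_tolerance: int, downstream_extent: int
) -> Optional[str]:
    """Best (most specific) category `model` offers for 1-based position
    `ref`, or None when the model says nothing about it."""
    p0 = ref - 1
    tts = model.tts
    if abs(ref - tts) <= tts_tolerance:
        return "known_TTS"
    utr3 = model.three_prime_utr
    if utr3 and _in_any(p0, utr3):
        return "three_prime_utr"
    if model.strand == "+":
        downstream = tts < ref <= tts + downstream_extent
    else:
        downstream = tts - downstream_extent <= ref < tts
    if downstream:
        return "downstream_1kb"
    lo, hi = model.span
    if not lo <= p0 < hi:
        return None
    if _in_any(p0, model.exons):
        utr5 = model.five_prime_utr
        if utr5 and _in_any(p0, utr5):
            return "five_prime_utr"
        return "internal_exon"
    return "intron"


def annotate_site(
    site: PolyASite | tuple[str, str, int],
    gene_models: Sequence[GeneModel],
    tts_tolerance: int = 24,
    downstream_extent: int = 1000,
) -> SiteAnnotation:
    """Assign one category and (unless intergenic) one gene to a site.

    Only same-chromosome, same-strand transcripts are considered (antisense
    sites fall through to intergenic).  Among transcripts offering the
    winning category, the gene with the nearest TTS is chosen, ties broken
    by lexicographic gene id, so the result does not depend on input order.
    """
    if isinstance(site, PolyASite):
        chrom, strand, ref = site.chrom, site.strand, site.reference_pos
    else:
        chrom, strand, ref = site
    best_rank = _RANK["intergenic"]
    candidates: list[tuple[int, int, str]] = []  # (rank, |ref - tts|, gene_id)
    for model in gene_models:
        if model.chrom != chrom or model.strand != strand:
            continue
        category = _model_category(model, ref, tts_tolerance, downstream_extent)
        if category is None:
            continue
        rank = _RANK[category]
        candidates.append((rank, abs(ref - model.tts), model.gene_id))
        best_rank = min(best_rank, rank)
    if best_rank == _RANK["intergenic"]:
        return SiteAnnotation("intergenic", None)
    _, _, gene_id = min(c for c in candidates if c[0] == best_rank)
    return SiteAnnotation(CATEGORIES[best_rank], gene_id)


def annotate_sites(
    sites: Iterable[PolyASite],
    gene_models: Sequence[GeneModel],
    tts_tolerance: int = 24,
    downstream_extent: int = 1000,
) -> None:
    """Annotate in place; every site receives exactly one category."""
    for site in sites:
        site.annotation = annotate_site(
            site, gene_models, tts_tolerance, downstream_extent
        )


def normalize_counts(raw_count: float, mapped_total: int) -> float:
    """Reads per million mapped reads: ``raw x 1e6 / mapped_total``."""
    if mapped_total <= 0:
        raise ValueError("mapped total must be > 0")
    return raw_count * 1e6 / mapped_total


@dataclass
class UsageMatrix:
    """Poly(A)-site x sample table of RPM with site->gene assignments."""

    rpm: pd.DataFrame  # index: site label, columns: samples
    mapped_totals: dict[str, int]
    site_gene: dict[str, Optional[str]]
    sites: dict[str, PolyASite]

    @property
    def samples(self) -> list[str]:
        return list(self.rpm.columns)

    def gene_sites(self, gene_id: str) -> list[str]:
        labels = [s for s, g in self.site_gene.items() if g == gene_id]
        if not labels:
            raise KeyError(f"no annotated sites for gene {gene_id!r}")
        return labels


def build_usage_matrix(
    sites: Sequence[PolyASite], samples: Sequence[str]
) -> UsageMatrix:
    """Assemble the RPM matrix; absent site/sample combinations are 0."""
    mapped_totals: dict[str, int] = {}
    rows = []
    site_gene: dict[str, Optional[str]] = {}
    index: dict[str, PolyASite] = {}
    for site in sites:
        for sample in site.rpm:
            if sample not in samples:
                raise KeyError(f"sample {sample!r} absent from manifest {samples}")
        rows.append({s: site.rpm.get(s, 0.0) for s in samples})
        label = site.label
        index[label] = site
        ann = site.annotation
        site_gene[label] = ann.gene_id if ann is not None else None
    frame = pd.DataFrame(rows, index=list(index), columns=list(samples), dtype=float)
    frame = frame.fillna(0.0)
    return UsageMatrix(frame, mapped_totals, site_gene, index)


def gene_expression(gene_id: str, matrix: UsageMatrix) -> pd.Series:
    """Per-sample expression: sum of RPM over the gene's poly(A) sites."""
    labels = matrix.gene_sites(gene_id)
    return matrix.rpm.loc[labels].sum(axis=0)


def usage_fractions(
    gene_id: str, matrix: UsageMatrix, sample: str
) -> Optional[pd.Series]:
    """Per-site fraction of the gene's expression in one sample.

    Returns None (usage undefined) when the gene has zero expression in
    that sample; otherwise the fractions sum to 1.
    """
    labels = matrix.gene_sites(gene_id)
    col = matrix.rpm.loc[labels, sample]
    total = col.sum()
    if total <= 0:
        return None
    return col / total


@dataclass(frozen=True)
class HeterogeneityProfile:
    """Relative usage of each heterogeneous cleavage position in a cluster."""

    frequencies: dict[int, float]
    reference_pos: int

    @property
    def reference_fraction(self) -> float:
        return self.frequencies[self.reference_pos]


def heterogeneity_profile(site: PolyASite) -> HeterogeneityProfile:
    """Per-position relative frequencies within the site's cluster.

    Frequencies sum to 1 and the reference position carries the maximum;
    scaled by the site's usage they recover the per-position normalized
    reads, whose sum is the usage of the poly(A) site.
    """
    counts = site.cluster.counts
    total = sum(counts.values())
    freqs = {p: c / total for p, c in counts.items()}
    return HeterogeneityProfile(freqs, site.reference_pos)
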