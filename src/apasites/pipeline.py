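"""End-to-end orchestration: trim -> map -> cleavage events -> internal
priming filter -> cluster -> call -> signal search -> annotate -> quantify.

Each stage is an ordinary function and can be run on its own; this module
wires them together for a multi-sample run, keeps the per-stage QC counters
needed to verify read conservation, and writes the standard output files
(site BED/TSV, usage matrix, gene expression, usage fractions,
heterogeneity profiles, QC log).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io as fio
from .preprocess import (
    CleavageEvent,
    map_reads,
    read_fastq,
    to_cleavage_event,
    trim_reads,
)
from .quantify import (
    UsageMatrix,
    annotate_sites,
    build_usage_matrix,
    gene_expression,
    heterogeneity_profile,
    usage_fractions,
)
from .sites import (
    DEFAULT_SIGNAL_HEXAMERS,
    PolyASite,
    call_polya_sites,
    cluster_events,
    filter_internal_priming,
    find_signals,
)

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline",
           "extract_sample_events"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying reason."""

    def __init__(self, stage: str, reason: str):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {reason}")


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run.

    `samples` maps sample name to a FASTQ (raw tags, mapped by the builtin
    exact mapper) or SAM/BAM (externally aligned trimmed tags) path.
    Threshold defaults are the method's: linker-anchored trimming with a
    25-nt minimum, a 20-nt/12-A internal-priming window, 24-nt clustering,
    2 normalized reads per site, a 50-nt signal window, 1-kb downstream
    annotation extent and a 24-nt TTS tolerance.
    """

    genome: str
    annotation: str
    samples: dict[str, str]
    out_dir: str
    linker: str = "AGCTGTCA"
    linker_mismatches: int = 0
    min_trimmed_length: int = 25
    ip_window: int = 20
    ip_max_a: int = 12
    max_gap: int = 24
    min_pooled_rpm: float = 2.0
    signal_window: int = 50
    signal_hexamers: tuple[str, ...] = DEFAULT_SIGNAL_HEXAMERS
    downstream_extent: int = 1000
    tts_tolerance: int = 24
    mapper_size_cap: int = 10_000_000

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("sample manifest must be non-empty")
        for name in ("min_trimmed_length", "ip_window", "max_gap",
                     "signal_window", "downstream_extent", "tts_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    sites: list[PolyASite]
    matrix: UsageMatrix
    qc: pd.DataFrame
    expression: pd.DataFrame
    fractions: pd.DataFrame
    heterogeneity: pd.DataFrame
    mapped_totals: dict[str, int]
    events: list[CleavageEvent] = field(default_factory=list)
    out_dir: Optional[str] = None


_FASTQ_SUFFIXES = {".fastq", ".fq"}
_ALIGNED_SUFFIXES = {".sam", ".bam"}


def extract_sample_events(
    path: str, sample: str, genome: fio.Genome, config: RunConfig
) -> tuple[list[CleavageEvent], dict[str, int]]:
    """Run one sample to strand-corrected cleavage events with QC counts.

    FASTQ input goes through trimming and the builtin exact mapper; SAM/BAM
    input is taken as already-trimmed alignments (unique primaries only).
    """
    suffix = Path(path).suffix.lower()
    counts = {k: 0 for k in ("n_raw", "no_linker", "too_short", "unmapped",
                             "multimapped", "n_secondary", "mapped_unique")}
    events: list[CleavageEvent] = []
    if suffix in _FASTQ_SUFFIXES:
        raw = read_fastq(path)
        trimmed, trim_counts = trim_reads(
            raw, config.linker, config.linker_mismatches, config.min_trimmed_length
        )
        counts.update({k: trim_counts.get(k, 0)
                       for k in ("n_raw", "no_linker", "too_short")})
        alignments, map_counts = map_reads(trimmed, genome, config.mapper_size_cap)
        counts.update({k: map_counts.get(k, 0)
                       for k in ("unmapped", "multimapped", "mapped_unique")})
        events = [to_cleavage_event(a, sample) for a in alignments]
    elif suffix in _ALIGNED_SUFFIXES:
        result = fio.read_alignments(path)
        counts["unmapped"] = result.n_unmapped
        counts["n_secondary"] = result.n_secondary
        for aln in result:
            if aln.chrom not in genome:
                raise ValueError(f"reference {aln.chrom!r} absent from genome")
            if not aln.unique:
                counts["multimapped"] += 1
                continue
            counts["mapped_unique"] += 1
            events.append(to_cleavage_event(aln, sample))
        counts["n_raw"] = (counts["unmapped"] + counts["n_secondary"]
                           + counts["multimapped"] + counts["mapped_unique"])
    else:
        raise ValueError(f"cannot tell FASTQ from SAM/BAM: {path!r}")
    return events, counts


def _quantify_tables(
    sites: Sequence[PolyASite], matrix: UsageMatrix
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    genes = sorted({g for g in matrix.site_gene.values() if g})
    expression = pd.DataFrame(
        {g: gene_expression(g, matrix) for g in genes}
    ).T
    expression.index.name = "gene_id"

    frac_rows = []
    for gene in genes:
        for sample in matrix.samples:
            fracs = usage_fractions(gene, matrix, sample)
            if fracs is None:
                continue
            for label, value in fracs.items():
                frac_rows.append({"gene_id": gene, "site": label,
                                  "sample": sample, "fraction": value})
    fractions = pd.DataFrame(
        frac_rows, columns=["gene_id", "site", "sample", "fraction"]
    )

    het_rows = []
    for site in sites:
        profile = heterogeneity_profile(site)
        for pos in sorted(profile.frequencies):
            het_rows.append({
                "site": site.label,
                "position": pos,
                "count": site.cluster.counts[pos],
                "frequency": profile.frequencies[pos],
                "is_reference": pos == site.reference_pos,
            })
    heterogeneity = pd.DataFrame(
        het_rows, columns=["site", "position", "count", "frequency",
                           "is_reference"]
    )
    return expression, fractions, heterogeneity


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline for every sample in the manifest.

    Writes sites.bed, sites.tsv, usage_matrix.tsv, gene_expression.tsv,
    usage_fractions.tsv, heterogeneity.tsv and qc.tsv under
    ``config.out_dir``.  A stage failure raises :class:`PipelineError`
    naming the stage.
    """
    try:
        genome = fio.load_genome(config.genome)
    except Exception as exc:
        raise PipelineError("load_genome", str(exc)) from exc
    try:
        models = fio.load_gene_models(config.annotation)
    except Exception as exc:
        raise PipelineError("load_gene_models", str(exc)) from exc

    all_events: list[CleavageEvent] = []
    mapped_totals: dict[str, int] = {}
    qc_rows: dict[str, dict[str, int]] = {}
    for sample, path in config.samples.items():
        try:
            events, counts = extract_sample_events(path, sample, genome, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"preprocess[{sample}]", str(exc)) from exc
        if counts["mapped_unique"] == 0:
            warnings.warn(
                f"sample {sample!r} produced no uniquely mapped reads",
                stacklevel=2,
            )
        else:
            mapped_totals[sample] = counts["mapped_unique"]
        all_events.extend(events)
        qc_rows[sample] = counts

    try:
        retained, flagged = filter_internal_priming(
            all_events, genome, config.ip_window, config.ip_max_a
        )
    except Exception as exc:
        raise PipelineError("internal_priming_filter", str(exc)) from exc
    for sample in qc_rows:
        qc_rows[sample]["ip_flagged"] = sum(
            1 for ev in flagged if ev.sample == sample
        )
        qc_rows[sample]["events_retained"] = sum(
            1 for ev in retained if ev.sample == sample
        )

    try:
        clusters = cluster_events(retained, config.max_gap)
        sites = call_polya_sites(clusters, mapped_totals, config.min_pooled_rpm)
        for site in sites:
            site.signals = find_signals(
                genome, site, config.signal_hexamers, config.signal_window
            )
    except Exception as exc:
        raise PipelineError("site_calling", str(exc)) from exc
    if not sites:
        warnings.warn("no poly(A) sites called", stacklevel=2)

    try:
        annotate_sites(sites, models, config.tts_tolerance,
                       config.downstream_extent)
        matrix = build_usage_matrix(sites, list(config.samples))
        matrix.mapped_totals = dict(mapped_totals)
        expression, fractions, heterogeneity = _quantify_tables(sites, matrix)
    except Exception as exc:
        raise PipelineError("annotate_quant", str(exc)) from exc

    qc = pd.DataFrame.from_dict(qc_rows, orient="index").fillna(0).astype(int)
    qc.index.name = "sample"

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        fio.write_polya_sites(sites, out_dir / "sites.bed",
                              out_dir / "sites.tsv", list(config.samples))
        matrix.rpm.rename_axis("site").to_csv(
            out_dir / "usage_matrix.tsv", sep="\t"
        )
        expression.to_csv(out_dir / "gene_expression.tsv", sep="\t")
        fractions.to_csv(out_dir / "usage_fractions.tsv", sep="\t", index=False)
        heterogeneity.to_csv(out_dir / "heterogeneity.tsv", sep="\t", index=False)
        qc.to_csv(out_dir / "qc.tsv", sep="\t")
    except OSError as exc:
        raise PipelineError("write_outputs", str(exc)) from exc

    return PipelineResult(
        sites=sites,
        matrix=matrix,
        qc=qc,
        expression=expression,
        fractions=fractions,
        heterogeneity=heterogeneity,
        mapped_totals=mapped_totals,
        events=retained,
        out_dir=str(out_dir),
    )
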