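# Methods

## The measurement model

A 3′-end tag library reads each polyadenylated transcript's last bases: the
sequenced read is `linker + T^k + revcomp(f)` where `f` is the transcript
fragment ending at the cleavage site and `T^k` comes from the oligo-d(T)
primer annealed to the poly(A) tail. Three facts drive the pipeline design:

* the read's 5′ fragment base (after linker and T-run) is the complement of
  the 3′-most templated base of the transcript, so a unique alignment pins
  the cleavage position exactly — on the strand *opposite* to the alignment;
* oligo-d(T) also primes on genomically encoded A-stretches, creating false
  cleavage events ("internal priming") recognizable from the downstream
  genomic sequence;
* cleavage downstream of one poly(A) signal is heterogeneous over a few
  nucleotides, so positions must be clustered before they are counted as
  sites, and the within-cluster distribution is itself biologically
  meaningful.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `linker`, `linker_mismatches` | required, 0 | linker must match the read prefix with ≤ this many substitutions; default is the strictest reading ("unrecognizable linker" ⇒ discard) |
| `min_trimmed_length` | 25 nt | fragments shorter than this after trimming are discarded |
| `ip_window`, `ip_max_a` | 20 nt, 12 | internal-priming test: > `ip_max_a` A's in the downstream window, or an `A×8` run, or `G A{4,} G A{3,} G` |
| `max_gap` | 24 nt | adjacent cleavage positions within this gap chain into one cluster |
| `min_pooled_rpm` | 2 | clusters below this many normalized reads (summed over samples) are not called as sites |
| `signal_window` | 50 nt | upstream scan range for signal hexamers (offsets 1–50; a hexamer must fit fully, so starts lie at 6–50) |
| `tts_tolerance` | 24 nt | a site within this distance of an annotated TTS is `known_TTS` (the clustering scale, reused) |
| `downstream_extent` | 1000 nt | past-TTS region annotated `downstream_1kb` |

RPM normalization divides a site's raw read count by the sample's total
*uniquely mapped* reads (×10⁶); this makes the per-sample conservation
identity exact: Σ site RPM = 10⁶ · (events in called sites) / mapped total.

## Design choices where the method description is open

* **Clustering is single-linkage**: "within 24 nt of each other" is applied
  to adjacent sorted positions, so a chain may span more than 24 nt overall.
  Between two clusters the minimum distance is therefore always > 24 nt.
* **Reference-point ties** (two positions with equal maximal count) break
  towards the 3′-most position on the transcript strand — deterministic and
  consistent with the distal-cleavage convention.
* **Internal priming is filtered per event, before clustering**, since the
  artifact is a property of a read's downstream context, not of a cluster.
  Truncated windows at chromosome ends are tested on the available bases,
  with the >12-A count kept absolute (conservative).
* **Annotation precedence** is most-specific-first: known_TTS > 3′-UTR >
  downstream-1kb > coding exon > intron > 5′-UTR > intergenic, evaluated
  against same-strand transcripts only; among genes offering the winning
  category the nearest TTS wins, ties by lexicographic gene id. The result
  is invariant under permutation of the annotation input.
* **T-stripping is greedy and unconditional**: a fragment whose genomic 3′
  base is an A loses it to the T-strip (read orientation). This is an
  inherent bias of the trimming rule, accepted and documented rather than
  patched; the simulator avoids planting such sites so that recovery tests
  measure the pipeline, not the bias.
* **The signal catalog** (AATAAA, ATTAAA, AGTAAA, TATAAA, CATAAA, GATAAA,
  AATATA, AATACA, AATAGA, ACTAAA, AAGAAA, AATGAA) is the standard hexamer
  set; it is a configurable argument everywhere because no single canonical
  list exists.
* **N bases** never count as A in the artifact filter and never match
  signal hexamers.

## What the simulator does and does not emulate

`simulate_reference` plants two-exon genes (CDS split across both exons,
1–4 poly(A) sites in the last exon 80 nt apart, TTS at the distal site,
AATAAA planted 10–30 nt upstream of every site) in a uniform-random genome,
plus intergenic 15-nt A-tracts as internal-priming traps (> 1 kb from any
TTS, so they annotate as intergenic). `simulate_reads` draws per-site read
counts from the configured abundances (default uniform; 200 reads/gene ⇒
100/site for two sites), jitters each cleavage by {0: 0.6, ±1: 0.15,
±2: 0.05}, and assembles reads with uniform tail lengths (5–20 nt) and
fragment lengths (40–80 nt). Everything is deterministic given the seed;
per-sample streams are derived from the sample name so conditions differ
reproducibly.

Constructed guarantees (and therefore limits on what a green test proves):
cleavage zones are planted so the T-strip never shifts an event; downstream
windows of true sites are redrawn until the artifact filter passes them;
fragments are resampled if they occur more than once in the genome. Real
data honours none of these. The simulator also omits sequencing-error
models beyond uniform substitution (default off), base qualities, PCR
duplicates, spliced 3′ fragments spanning introns, antisense transcription
and expression models richer than fixed per-site abundances. Green recovery
tests establish that the pipeline's logic is correct on its stated model,
not that it is robust to artifacts it was never shown. The engineered
poly(A) mutations some library protocols introduce are likewise off by
default; if emulated, a mutated tail base simply ends the T-strip early.

## Degenerate inputs and numerical notes

* Empty samples complete with a warning and contribute zero columns; a
  sample with zero uniquely mapped reads is excluded from the RPM
  denominator map rather than dividing by zero.
* Usage fractions for a gene with zero expression in a sample are reported
  as absent (None), not as NaN rows.
* The builtin mapper is an exact-match scanner intended for ≤10 Mb toy
  genomes and refuses larger inputs; real data should arrive as SAM/BAM
  from a proper aligner. A read equal to its own reverse complement counts
  as two placements and is dropped as ambiguous.
* All counters are integers; the only floating arithmetic is the ×10⁶/total
  normalization, so the conservation identity holds to ~1e-15 relative.

## Known limitations

Single-end reads only, one cleavage event per read; no statistical test for
APA switching between conditions (descriptive fractions and profiles only);
no de-novo signal discovery; no probabilistic internal-priming model; gene
assignment trusts the supplied models — transcripts are treated
independently, with no notion of a canonical transcript per gene.
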