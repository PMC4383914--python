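"""Call poly(A) sites from simulated tags, stage by stage.

Shows the core method: trimming, exact unique mapping, internal-priming
filtering, 24-nt clustering of heterogeneous cleavage positions, the
2-normalized-read site threshold, and the upstream signal search.
"""

from apasites.preprocess import map_reads, to_cleavage_event, trim_reads
from apasites.simulate import SimConfig, simulate_reads, simulate_reference
from apasites.sites import (
    call_polya_sites,
    cluster_events,
    filter_internal_priming,
    find_signals,
)

config = SimConfig(seed=7)
reference = simulate_reference(config)
reads, truth = simulate_reads(reference)

trimmed, trim_counts = trim_reads(reads, config.linker)
alignments, map_counts = map_reads(trimmed, reference.genome)
events = [to_cleavage_event(a) for a in alignments]
kept, flagged = filter_internal_priming(events, reference.genome)
clusters = cluster_events(kept)
sites = call_polya_sites(clusters, {"pooled": map_counts["mapped_unique"]})
for site in sites:
    site.signals = find_signals(reference.genome, site)

print(f"{trim_counts['n_raw']} raw reads -> "
      f"{map_counts['mapped_unique']} uniquely mapped -> "
      f"{len(flagged)} internal-priming events removed -> "
      f"{len(clusters)} clusters -> {len(sites)} poly(A) sites")

planted = {(c, s, p) for c, s, p, _ in reference.truth.all_sites}
exact = sum((s.chrom, s.strand, s.reference_pos) in planted for s in sites)
print(f"reference points matching a planted site exactly: {exact}/{len(sites)}")

site = sites[0]
print(f"example site {site.chrom}:{site.name} ({site.strand}): "
      f"cluster span {site.cluster.span}, {site.cluster.total} reads, "
      f"pooled {site.pooled_rpm:.1f} RPM")
print("  signals:", ", ".join(f"{s.hexamer} {s.offset} nt upstream"
                              for s in site.signals) or "none")

# The reference point of each cluster is its most-used cleavage position;
# RPM is reads per million uniquely mapped reads in the sample.
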