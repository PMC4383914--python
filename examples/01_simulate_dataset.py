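"""Build a synthetic 3'-end tag dataset with full ground truth.

Generates a toy genome with 20 planted two-site genes (AATAAA signals
10-30 nt upstream of each site), 5 genomic A-tracts acting as
internal-priming traps, and one sample of reads with cleavage-site jitter.
"""

import tempfile
from pathlib import Path

from apasites.simulate import SimConfig, save_reads, simulate_reads, simulate_reference

config = SimConfig(seed=42)
reference = simulate_reference(config)
reads, truth = simulate_reads(reference, sample="demo")

with tempfile.TemporaryDirectory() as out:
    out = Path(out)
    reference.save(out / "genome.fa", out / "genes.gtf")
    save_reads(reads, truth, out / "demo.fastq", out / "demo.truth.tsv")
    print("wrote", *(p.name for p in sorted(out.iterdir())))

genome_nt = sum(reference.genome.lengths.values())
print(f"genome: {len(reference.genome.chroms)} chromosome(s), {genome_nt} nt")
print(f"genes: {len(reference.truth.genes)} "
      f"({config.sites_per_gene} poly(A) sites each), "
      f"traps: {len(reference.truth.traps)}")
print(f"reads: {len(reads)} "
      f"({int((truth.origin == 'trap').sum())} from internal-priming traps)")
first = reference.truth.genes[0]
print(f"example gene {first.gene_id} ({first.strand} strand): "
      f"sites at {list(first.sites)}, AATAAA offsets {list(first.signal_offsets)}")

# Each read is linker + poly(T) + the reverse-complemented transcript 3' end;
# the truth table records which planted site (or trap) every read came from.
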