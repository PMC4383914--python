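"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: clustering is re-derived
by union-find over all position pairs, the internal-priming rule by direct
counting plus a regex, mapping by naive string scanning, and the TTS by
scanning every exon boundary.
"""

from __future__ import annotations

import re


def union_find_clusters(positions: list[int], max_gap: int = 24) -> set[frozenset]:
    """Single-linkage partition via union-find over all pairs within max_gap."""
    positions = sorted(set(positions))
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a in positions:
        for b in positions:
            if a < b and b - a <= max_gap:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    groups: dict[int, set[int]] = {}
    for p in positions:
        groups.setdefault(find(p), set()).add(p)
    return {frozenset(g) for g in groups.values()}


_GA = re.compile(r"GA{4,}GA{3,}G")


def internal_priming_oracle(window: str, max_a: int = 12) -> bool:
    """Letter-count + regex re-statement of the artifact rule."""
    n_a = sum(1 for b in window if b == "A")
    return n_a > max_a or "A" * 8 in window or bool(_GA.search(window))


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_occurrences(seqs: dict[str, str], read: str) -> set[tuple[str, int, str]]:
    """All (chrom, 0-based start, strand) placements of `read`, by scanning
    every window of every chromosome on both strands."""
    hits = set()
    rc = naive_revcomp(read)
    n = len(read)
    for chrom, text in seqs.items():
        for i in range(len(text) - n + 1):
            window = text[i : i + n]
            if window == read:
                hits.add((chrom, i, "+"))
            if window == rc:
                hits.add((chrom, i, "-"))
    return hits


def brute_force_tts(exons: list[tuple[int, int]], strand: str) -> int:
    """1-based 3'-most transcribed base over all exon boundaries."""
    boundaries = []
    for s, e in exons:
        boundaries.extend(range(s + 1, e + 1))  # all 1-based exonic positions
    return max(boundaries) if strand == "+" else min(boundaries)
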