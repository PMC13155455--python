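"""Nucleotide composition of IR arms and spacers versus genome background."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .ir_detection import InvertedRepeat, ir_footprint, ir_density_per_kb
from .intervals import total_bp


@dataclass
class KmerCounts:
    k: int
    counts: dict[str, int]
    total: int


def count_kmers(seqs, k: int) -> KmerCounts:
    """Overlapping k-mer counts over one or more sequences.

    Windows containing N are counted under their N-containing key; sequences
    shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(seqs, str):
        seqs = [seqs]
    counts: Counter[str] = Counter()
    total = 0
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
            total += 1
    return KmerCounts(k=k, counts=dict(counts), total=total)


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator; all-N raises."""
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def gc_enrichment_vs_background(arm_gc: float, genome_gc: float) -> float:
    """Ratio of arm GC fraction to genome-wide GC fraction."""
    if genome_gc <= 0:
        raise ValueError("genome GC content must be positive")
    return arm_gc / genome_gc


def length_spectra(irs) -> dict[str, pd.DataFrame]:
    """Arm-length %, spacer-length %, and (arm, spacer) count heatmap tables."""
    irs = list(irs)
    if not irs:
        empty = pd.DataFrame()
        return {"arm": empty, "spacer": empty, "heatmap": empty}
    n = len(irs)
    arm_counts = Counter(ir.arm_length for ir in irs)
    spacer_counts = Counter(ir.spacer_length for ir in irs)
    cell_counts = Counter((ir.arm_length, ir.spacer_length) for ir in irs)
    arm = pd.DataFrame(
        sorted((a, c, 100.0 * c / n) for a, c in arm_counts.items()),
        columns=["arm_length", "count", "percent"],
    )
    spacer = pd.DataFrame(
        sorted((s, c, 100.0 * c / n) for s, c in spacer_counts.items()),
        columns=["spacer_length", "count", "percent"],
    )
    heat = pd.DataFrame(
        sorted((a, s, c) for (a, s), c in cell_counts.items()),
        columns=["arm_length", "spacer_length", "count"],
    )
    return {"arm": arm, "spacer": spacer, "heatmap": heat}


def gc_stratified_density(
    irs: list[InvertedRepeat], genome_length: int, gc_threshold: float, use: str = "span"
) -> float:
    """Footprint density per kB using only IRs with arm GC >= threshold."""
    kept = [ir for ir in irs if ir.arm_gc >= gc_threshold]
    if not kept:
        return 0.0
    return ir_density_per_kb(total_bp(ir_footprint(kept, use=use)), genome_length)
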