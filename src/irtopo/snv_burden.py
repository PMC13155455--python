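"""Intraspecific SNV burden in IR arms and spacers.

Two null models for the number of SNV sites inside an IR segment: a
length-based expectation E(L, r) = L·r, where r is the genome-wide density of
distinct SNV sites, and a trinucleotide-adjusted expectation
E[X] = Σ_j c_j·p_j over the 32 canonical trinucleotide classes (lexicographic
minimum of a trinucleotide and its reverse complement), where c_j counts
segment positions in class j and p_j is the genome-wide per-class SNV site
frequency. Each site is a binary indicator — duplicate alleles at a position
count once, and allele frequency is ignored.

Terminator-proximal stratification partitions IRs by distance (<= 50 bp,
inclusive) from terminator intervals, and the regression-deviation ratio R
compares how far through-origin regressions of observed-vs-expected burden
deviate from the 45° identity line for spacers relative to arms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeSequence
from .ir_detection import InvertedRepeat, reverse_complement
from .intervals import Interval, gap_to, merge, subtract, total_bp

log = logging.getLogger(__name__)

_BASES = "ACGT"

CANONICAL_TRINUCS: tuple[str, ...] = tuple(
    sorted(
        {
            min(t, reverse_complement(t))
            for a in _BASES
            for b in _BASES
            for c in _BASES
            for t in [a + b + c]
        }
    )
)
assert len(CANONICAL_TRINUCS) == 32

_CLASS_INDEX = {t: i for i, t in enumerate(CANONICAL_TRINUCS)}

# base-5 encoded trinucleotide (A,C,G,T,N -> 0..4) -> class id, or -1 if any N
_CODE_OF = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE_OF[ord(_b)] = _i
_TRI_CLASS = np.full(125, -1, dtype=np.int64)
for _a in range(4):
    for _b in range(4):
        for _c in range(4):
            _t = _BASES[_a] + _BASES[_b] + _BASES[_c]
            _TRI_CLASS[_a * 25 + _b * 5 + _c] = _CLASS_INDEX[min(_t, reverse_complement(_t))]


def _as_genome_list(genomes) -> list[GenomeSequence]:
    if isinstance(genomes, GenomeSequence):
        return [genomes]
    return list(genomes)


def classify_positions(residues: str) -> np.ndarray:
    """Per-position canonical trinucleotide class id; -1 where the centered
    context is incomplete (sequence ends) or contains N."""
    n = len(residues)
    out = np.full(n, -1, dtype=np.int64)
    if n < 3:
        return out
    codes = _CODE_OF[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    tri = codes[:-2] * 25 + codes[1:-1] * 5 + codes[2:]
    out[1:-1] = _TRI_CLASS[np.clip(tri, 0, 124)]
    out[1:-1][(codes[:-2] > 3) | (codes[1:-1] > 3) | (codes[2:] > 3)] = -1
    return out


@dataclass
class TrinucleotideProfile:
    genome_occurrences: np.ndarray  # per class, positions with full N-free context
    snv_site_occurrences: np.ndarray  # per class, distinct SNV positions
    p: np.ndarray  # snv / genome occurrences; 0 (with warning) for empty classes

    @property
    def classes(self) -> tuple[str, ...]:
        return CANONICAL_TRINUCS


def distinct_snv_positions(snvs) -> set[tuple[str, int]]:
    return {(s.seq_id, s.pos) for s in snvs}


def genome_snv_density(snvs, genomes) -> float:
    """r: distinct SNV sites per genomic base pair (allele-frequency blind)."""
    genomes = _as_genome_list(genomes)
    total = sum(len(g.residues) for g in genomes)
    if total == 0:
        raise ValueError("empty genome")
    return len(distinct_snv_positions(snvs)) / total


def trinucleotide_profile(genomes, snvs) -> TrinucleotideProfile:
    """Genome-wide per-class SNV site frequencies p_j.

    SNV positions without a full N-free trinucleotide context are excluded
    from the numerator, mirroring their exclusion from the denominator.
    """
    genomes = _as_genome_list(genomes)
    class_of: dict[str, np.ndarray] = {g.seq_id: classify_positions(g.residues) for g in genomes}
    genome_occ = np.zeros(32, dtype=np.int64)
    for arr in class_of.values():
        cnt = np.bincount(arr[arr >= 0], minlength=32)
        genome_occ += cnt
    snv_occ = np.zeros(32, dtype=np.int64)
    n_skipped = 0
    for sid, pos in distinct_snv_positions(snvs):
        arr = class_of.get(sid)
        if arr is None or not (0 <= pos < len(arr)) or arr[pos] < 0:
            n_skipped += 1
            continue
        snv_occ[arr[pos]] += 1
    if n_skipped:
        log.info("trinucleotide_profile: %d SNV sites without full context skipped", n_skipped)
    p = np.zeros(32, dtype=float)
    nonzero = genome_occ > 0
    p[nonzero] = snv_occ[nonzero] / genome_occ[nonzero]
    if (~nonzero).any():
        log.warning(
            "trinucleotide_profile: %d classes absent from genome; p set to 0",
            int((~nonzero).sum()),
        )
    return TrinucleotideProfile(genome_occ, snv_occ, p)


def segment_class_counts(segments: dict[str, list[Interval]], genomes) -> np.ndarray:
    """c_j: per-class counts of (merged) segment positions with full context."""
    genomes = {g.seq_id: g for g in _as_genome_list(genomes)}
    c = np.zeros(32, dtype=np.int64)
    for sid, ivs in segments.items():
        g = genomes.get(sid)
        if g is None:
            continue
        arr = classify_positions(g.residues)
        for s, e in merge(ivs):
            part = arr[max(s, 0) : min(e, len(arr))]
            c += np.bincount(part[part >= 0], minlength=32)
    return c


def expected_burden_trinuc(
    segments: dict[str, list[Interval]], genomes, profile: TrinucleotideProfile
) -> float:
    """Trinucleotide-adjusted expected SNV count: E = Σ_j c_j p_j."""
    c = segment_class_counts(segments, genomes)
    return float(np.dot(c, profile.p))


@dataclass
class BurdenTable:
    segment: str  # "arms" | "spacers"
    L: int  # non-overlapping footprint bp
    observed: int
    expected_length: float  # L * r
    expected_trinuc: float  # sum c_j p_j
    r: float


def segment_footprints(
    irs: list[InvertedRepeat], precedence: str = "arms"
) -> tuple[dict[str, list[Interval]], dict[str, list[Interval]]]:
    """Merged arm and spacer footprints per seq_id.

    A base covered by an arm of one IR and the spacer of another is assigned
    to the segment named by ``precedence`` (default arms: pairing constrains
    the base).
    """
    arms: dict[str, list[Interval]] = {}
    spacers: dict[str, list[Interval]] = {}
    for ir in irs:
        arms.setdefault(ir.seq_id, []).extend([ir.left_arm, ir.right_arm])
        if ir.spacer_length:
            spacers.setdefault(ir.seq_id, []).append(ir.spacer)
    arms = {sid: merge(ivs) for sid, ivs in arms.items()}
    spacers = {sid: merge(ivs) for sid, ivs in spacers.items()}
    if precedence == "arms":
        spacers = {sid: subtract(ivs, arms.get(sid, [])) for sid, ivs in spacers.items()}
    elif precedence == "spacers":
        arms = {sid: subtract(ivs, spacers.get(sid, [])) for sid, ivs in arms.items()}
    else:
        raise ValueError(f"unknown precedence {precedence!r}")
    return arms, spacers


def _count_snvs_in(segments: dict[str, list[Interval]], snvs) -> int:
    n = 0
    for sid, pos in distinct_snv_positions(snvs):
        for s, e in segments.get(sid, []):
            if s <= pos < e:
                n += 1
                break
    return n


def burden_tables(
    irs: list[InvertedRepeat],
    snvs,
    genomes,
    profile: TrinucleotideProfile | None = None,
    precedence: str = "arms",
) -> dict[str, BurdenTable]:
    """Observed vs expected SNV burden for IR arms and spacers."""
    genomes = _as_genome_list(genomes)
    if profile is None:
        profile = trinucleotide_profile(genomes, snvs)
    r = genome_snv_density(snvs, genomes)
    arms, spacers = segment_footprints(irs, precedence=precedence)
    out = {}
    for name, segs in (("arms", arms), ("spacers", spacers)):
        L = sum(total_bp(ivs) for ivs in segs.values())
        out[name] = BurdenTable(
            segment=name,
            L=L,
            observed=_count_snvs_in(segs, snvs),
            expected_length=L * r,
            expected_trinuc=expected_burden_trinuc(segs, genomes, profile),
            r=r,
        )
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fisher_ir_enrichment(
    observed_in_ir: int, expected_in_ir: float, total_snvs: int
) -> tuple[float, float]:
    """Two-tailed Fisher's exact test of observed vs expected SNVs inside IRs.

    The expected count is rounded half away from zero to build the 2x2 table
    (in-IR / out-of-IR for observed vs expected). Zero-margin tables return
    (nan, nan).
    """
    exp_in = _round_half_away(expected_in_ir)
    table = np.array(
        [
            [observed_in_ir, total_snvs - observed_in_ir],
            [exp_in, total_snvs - exp_in],
        ]
    )
    if (table < 0).any():
        raise ValueError("counts exceed total_snvs")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.warning("fisher_ir_enrichment: zero-margin table; flagged")
        return float("nan"), float("nan")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def partition_by_terminator(
    irs: list[InvertedRepeat],
    terminators: dict[str, list[Interval]],
    distance: int = 50,
) -> tuple[list[InvertedRepeat], list[InvertedRepeat]]:
    """(near, far): near IRs lie within ``distance`` bp (inclusive) of a
    terminator interval on the same replicon; without terminators all are far."""
    near, far = [], []
    for ir in irs:
        terms = terminators.get(ir.seq_id, [])
        if terms and gap_to(terms, ir.start, ir.end) <= distance:
            near.append(ir)
        else:
            far.append(ir)
    return near, far


def terminator_partition_density(
    irs: list[InvertedRepeat],
    snvs,
    terminators: dict[str, list[Interval]],
    distance: int = 50,
    precedence: str = "arms",
) -> pd.DataFrame:
    """Per (segment, near/far, spacer-length stratum): footprint bp, observed
    SNV sites and SNV density (sites per bp). Stratum 'all' pools all spacers."""
    near, far = partition_by_terminator(irs, terminators, distance)
    rows = []
    for group, members in (("near", near), ("far", far)):
        strata: dict[object, list[InvertedRepeat]] = {"all": members}
        for ir in members:
            strata.setdefault(ir.spacer_length, []).append(ir)
        for stratum, sub in sorted(strata.items(), key=lambda kv: str(kv[0])):
            arms, spacers = segment_footprints(sub, precedence=precedence)
            for segment, segs in (("arms", arms), ("spacers", spacers)):
                bp = sum(total_bp(ivs) for ivs in segs.values())
                obs = _count_snvs_in(segs, snvs) if bp else 0
                rows.append(
                    dict(
                        segment=segment,
                        group=group,
                        spacer=stratum,
                        bp=bp,
                        observed=obs,
                        density=obs / bp if bp else float("nan"),
                    )
                )
    return pd.DataFrame(rows)


def _slope_through_origin(expected, observed) -> float:
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("expected values are all zero; slope undefined")
    return float(np.dot(x, y) / denom)


def regression_deviation_ratio(
    obs_arm, exp_arm, obs_spacer, exp_spacer, orientation: str = "spacer_over_arm"
) -> float:
    """R = |arctan(slope_num) − π/4| / |arctan(slope_den) − π/4|.

    Slopes are through-origin least squares of observed on expected across
    species. Default numerator is the spacer regression and denominator the
    arm regression (R > 1 means spacers deviate more from the identity line);
    orientation="arm_over_spacer" swaps them. A denominator slope of exactly 1
    raises (ratio undefined).
    """
    b_arm = _slope_through_origin(exp_arm, obs_arm)
    b_spacer = _slope_through_origin(exp_spacer, obs_spacer)
    if orientation == "spacer_over_arm":
        num, den = b_spacer, b_arm
    elif orientation == "arm_over_spacer":
        num, den = b_arm, b_spacer
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    dev_den = abs(math.atan(den) - math.pi / 4)
    if dev_den == 0:
        raise ZeroDivisionError("denominator regression coincides with the 45-degree line")
    return abs(math.atan(num) - math.pi / 4) / dev_den
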