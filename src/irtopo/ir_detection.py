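"""Detection of maximal perfect inverted repeats (IRs).

A perfect IR is ``left_arm + spacer + right_arm`` with
``reverse_complement(left_arm) == right_arm`` exactly. The detector reports,
for every center (left-arm end position, spacer length) with
``arm >= min_arm`` and ``spacer <= max_spacer``, the unique maximal arm —
maximal meaning the arms can be extended neither outward by one complementary
pair nor (for spacer >= 2) inward by trading two spacer bases for one extra
pair. ``N`` never base-pairs, so arms are N-free; spacers are unconstrained.

Defaults (min_arm=10, max_spacer=8) target arms long enough and loops short
enough to plausibly extrude hairpin/cruciform structures.

``brute_force_inverted_repeats`` is an independent reference enumerator
(slice extraction + Biopython reverse complement, binary search on the arm)
used as the oracle in tests and for synthetic-data truth tables; it shares no
code with the production scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeSequence
from .intervals import Interval, merge, total_bp

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_TRANS = str.maketrans("ACGTN", "TGCAN")

# byte-level complement lookup: comp_code[ord(base)] = ord(complement); N -> 0
# sentinel so that N never matches anything (not even another N).
_COMP_CODE = np.zeros(256, dtype=np.uint8)
for _b, _c in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _COMP_CODE[ord(_b)] = ord(_c)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; involution; N maps to N."""
    if not set(seq) <= _COMPLEMENT.keys():
        bad = sorted(set(seq) - _COMPLEMENT.keys())
        raise ValueError(f"non-ACGTN characters: {bad}")
    return seq.translate(_TRANS)[::-1]


@dataclass(frozen=True)
class DetectionParams:
    min_arm: int = 10
    max_spacer: int = 8

    def __post_init__(self) -> None:
        if self.min_arm < 1:
            raise ValueError("min_arm must be >= 1")
        if self.max_spacer < 0:
            raise ValueError("max_spacer must be >= 0")


DEFAULT_PARAMS = DetectionParams()


@dataclass(frozen=True)
class InvertedRepeat:
    """One detected IR; full span [start, end), end − start = 2·arm + spacer."""

    seq_id: str
    start: int
    end: int
    arm_length: int
    spacer_length: int
    left_arm_seq: str
    spacer_seq: str
    right_arm_seq: str

    @property
    def left_arm(self) -> Interval:
        return (self.start, self.start + self.arm_length)

    @property
    def spacer(self) -> Interval:
        return (self.start + self.arm_length, self.start + self.arm_length + self.spacer_length)

    @property
    def right_arm(self) -> Interval:
        return (self.end - self.arm_length, self.end)

    @property
    def arm_gc(self) -> float:
        arm = self.left_arm_seq
        return (arm.count("G") + arm.count("C")) / len(arm)


def _pair(a: str, b: str) -> bool:
    return a != "N" and _COMPLEMENT[a] == b


def detect_inverted_repeats(
    genome: GenomeSequence, params: DetectionParams = DEFAULT_PARAMS
) -> list[InvertedRepeat]:
    """All maximal perfect IRs in one replicon, sorted by (start, spacer_length).

    For each spacer length s, a vectorized scan finds seed centers where the
    innermost pair matches; arms are then extended outward per character.
    Deterministic; circular sequences are scanned as linear.
    """
    seq = genome.residues
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    comp = _COMP_CODE[arr]  # comp[i] == code that seq[i] pairs with (0 for N)
    out: list[InvertedRepeat] = []
    for s in range(params.max_spacer + 1):
        if n < 2 + s:
            continue
        # seed[j] true iff seq[j] pairs with seq[j+s+1]; center i = j + 1
        seed = (comp[: n - s - 1] == arr[s + 1 :]) & (comp[: n - s - 1] != 0)
        for j in np.flatnonzero(seed):
            i = int(j) + 1  # left arm ends at i (exclusive)
            # inward maximality: skip if the spacer's end bases pair
            if s >= 2 and _pair(seq[i], seq[i + s - 1]):
                continue
            a = 1
            while (
                i - a - 1 >= 0
                and i + s + a < n
                and comp[i - a - 1] == arr[i + s + a]
                and comp[i - a - 1] != 0
            ):
                a += 1
            if a < params.min_arm:
                continue
            start, end = i - a, i + s + a
            out.append(
                InvertedRepeat(
                    seq_id=genome.seq_id,
                    start=start,
                    end=end,
                    arm_length=a,
                    spacer_length=s,
                    left_arm_seq=seq[start : start + a],
                    spacer_seq=seq[i : i + s],
                    right_arm_seq=seq[end - a : end],
                )
            )
    out.sort(key=lambda ir: (ir.start, ir.spacer_length))
    return out


def brute_force_inverted_repeats(
    seq: str, min_arm: int = 10, max_spacer: int = 8, seq_id: str = "seq"
) -> list[InvertedRepeat]:
    """Reference enumerator over every (center, spacer) with maximality checks.

    At a fixed center, arm validity is downward-closed, so the maximal arm is
    found by binary search using slice reverse-complement comparison.
    Independent of the production detector's scan; O(n · spacer · log n).
    """
    from Bio.Seq import Seq

    n = len(seq)

    def arm_valid(i: int, s: int, a: int) -> bool:
        left = seq[i - a : i]
        right = seq[i + s : i + s + a]
        return "N" not in left and right == str(Seq(left).reverse_complement())

    hits = []
    for s in range(max_spacer + 1):
        for i in range(1, n - s):
            lo, hi = 0, min(i, n - (i + s))
            # quick reject: innermost pair
            if hi == 0 or not arm_valid(i, s, 1):
                continue
            lo = 1
            while lo < hi:
                mid = (lo + hi + 1) // 2
                if arm_valid(i, s, mid):
                    lo = mid
                else:
                    hi = mid - 1
            a = lo
            if a < min_arm:
                continue
            # inward maximality: spacer >= 2 and inner pair would extend the arm
            if s >= 2 and arm_valid(i + 1, s - 2, a + 1):
                continue
            start, end = i - a, i + s + a
            hits.append(
                InvertedRepeat(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    arm_length=a,
                    spacer_length=s,
                    left_arm_seq=seq[start : start + a],
                    spacer_seq=seq[i : i + s],
                    right_arm_seq=seq[end - a : end],
                )
            )
    hits.sort(key=lambda ir: (ir.start, ir.spacer_length))
    return hits


def validate_ir(ir: InvertedRepeat, genome: GenomeSequence) -> bool:
    """Re-extract the IR from the genome and check every invariant."""
    n = len(genome.residues)
    if not (0 <= ir.start < ir.end <= n):
        raise ValueError(f"IR coordinates [{ir.start},{ir.end}) outside genome of length {n}")
    if ir.end - ir.start != 2 * ir.arm_length + ir.spacer_length:
        return False
    seq = genome.residues
    left = seq[ir.start : ir.start + ir.arm_length]
    spacer = seq[ir.start + ir.arm_length : ir.end - ir.arm_length]
    right = seq[ir.end - ir.arm_length : ir.end]
    if (left, spacer, right) != (ir.left_arm_seq, ir.spacer_seq, ir.right_arm_seq):
        return False
    if "N" in left or "N" in right:
        return False
    return reverse_complement(left) == right


def ir_footprint(irs, use: str = "span") -> list[Interval]:
    """Union of IR intervals on one replicon.

    use="span" (default) covers arms + spacer; use="arms" covers arm bases only.
    """
    seq_ids = {ir.seq_id for ir in irs}
    if len(seq_ids) > 1:
        raise ValueError(f"mixed seq_ids in footprint: {sorted(seq_ids)}")
    if use == "span":
        ivs = [(ir.start, ir.end) for ir in irs]
    elif use == "arms":
        ivs = [iv for ir in irs for iv in (ir.left_arm, ir.right_arm)]
    else:
        raise ValueError(f"unknown footprint mode {use!r}")
    return merge(ivs)


def ir_density_per_kb(ir_bp: int, region_bp: int) -> float:
    """IR bp per kilobase: 1000 · ir_bp / region_bp."""
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    return 1000.0 * ir_bp / region_bp


def genome_ir_density(irs_by_seq: dict[str, list[InvertedRepeat]],
                      lengths: dict[str, int], use: str = "span") -> float:
    """Assembly-level density: footprint bp over all replicons per total kB."""
    fp = sum(total_bp(ir_footprint(irs, use=use)) for irs in irs_by_seq.values() if irs)
    return ir_density_per_kb(fp, sum(lengths.values()))
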