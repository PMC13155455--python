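"""Synthetic genomes with planted IRs, gene models, variants and terminators.

The generator emulates the statistical structure the pipeline assumes: random
background of controlled GC / dinucleotide composition, perfect IRs planted
with chosen arm/spacer lengths and arm GC either uniformly or at fixed
offsets from gene anchors, prokaryote-style gene models with optional UTRs,
terminator intervals downstream of gene ends, and SNV sites drawn per
position from per-trinucleotide-class rates with configurable multipliers
inside IR spacers/arms and near terminators.

Planted IRs are flanked by guard bases that break outward extension and their
spacers are screened against inward extension, so the planted arm is the
maximal arm. Truth tables are produced by running the brute-force reference
enumerator on the *final* genome, so accidental background IRs are part of
the truth rather than silently missed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneRecord, GenomeSequence, LineageRecord, SnvSite
from .intervals import Interval, merge
from .ir_detection import (
    DetectionParams,
    InvertedRepeat,
    brute_force_inverted_repeats,
    reverse_complement,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PlantedIR:
    arm_length: int
    spacer_length: int
    count: int = 1
    arm_gc: float = 0.5
    placement: str = "uniform"  # "uniform" | "TSS" | "TES"
    offset: int = 0  # window offset of the IR midpoint for anchored placement


@dataclass(frozen=True)
class GeneModel:
    n_genes: int = 0
    gene_length: int = 600
    intergenic_length: int = 400
    utr5_length: int = 0
    utr3_length: int = 0
    minus_strand_fraction: float = 0.5


@dataclass(frozen=True)
class SnvModel:
    """Per-position SNV site probabilities.

    ``base_rate`` applies to every class unless ``class_rates`` (length-32
    array over the canonical trinucleotide classes) is given. Multipliers
    rescale the rate inside IR spacer/arm footprints; the ``near_*`` variants
    apply to IRs within ``terminator_distance`` of a terminator and emulate
    the elevated spacer polymorphism / arm conservation seen at intrinsic
    terminators.
    """

    base_rate: float = 5e-3
    class_rates: tuple[float, ...] | None = None
    spacer_multiplier: float = 1.0
    arm_multiplier: float = 1.0
    near_spacer_multiplier: float = 3.0
    near_arm_multiplier: float = 0.5
    terminator_distance: int = 50


@dataclass(frozen=True)
class SimulationSpec:
    genome_length: int = 20_000
    gc: float = 0.5
    cpg_depletion: float = 0.0  # 0..1: first-order Markov CG-doublet deficit
    genes: GeneModel = field(default_factory=GeneModel)
    planted_irs: tuple[PlantedIR, ...] = ()
    terminator_offset: int | None = None  # terminator interval starts this far after TES
    terminator_length: int = 20
    snv: SnvModel = field(default_factory=SnvModel)
    assembly_id: str = "SYN_000001.1"
    species: str = "Synthia exempli"
    family: str = "Synthiaceae"
    phylum: str = "Synthota"
    kingdom: str = ""
    domain: str = "Bacteria"


@dataclass
class SimulatedGenome:
    spec: SimulationSpec
    genome: GenomeSequence
    genes: list[GeneRecord]
    planted: list[InvertedRepeat]  # exactly what was planted
    truth: list[InvertedRepeat]  # brute-force scan of the final genome
    terminators: dict[str, list[Interval]]
    lineage: LineageRecord


def random_class_rates(rng: np.random.Generator, low: float = 1e-3, high: float = 1e-2):
    """Per-class SNV rates drawn log-uniformly in [low, high] (32 values)."""
    return tuple(np.exp(rng.uniform(np.log(low), np.log(high), size=32)))


def _draw_background(rng: np.random.Generator, n: int, gc: float, cpg_depletion: float) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    if cpg_depletion <= 0:
        idx = rng.choice(4, size=n, p=p)
        return [_BASES[i] for i in idx]
    # first-order Markov: after C, the G probability is scaled down
    out = []
    prev = None
    for _ in range(n):
        row = p.copy()
        if prev == "C":
            row[2] *= 1 - cpg_depletion
            row /= row.sum()
        prev = _BASES[rng.choice(4, p=row)]
        out.append(prev)
    return out


def _draw_arm(rng: np.random.Generator, length: int, arm_gc: float) -> str:
    gcn = np.array([(1 - arm_gc) / 2, arm_gc / 2, arm_gc / 2, (1 - arm_gc) / 2])
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=gcn))


def _draw_spacer(rng: np.random.Generator, length: int) -> str:
    while True:
        sp = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if length < 2 or _COMP[sp[0]] != sp[-1]:
            return sp


def _build_genes(spec: SimulationSpec, rng: np.random.Generator) -> list[GeneRecord]:
    gm = spec.genes
    genes: list[GeneRecord] = []
    pos = gm.intergenic_length
    for k in range(gm.n_genes):
        start, end = pos, pos + gm.gene_length
        if end + gm.intergenic_length > spec.genome_length:
            raise ValueError(
                f"infeasible packing: {gm.n_genes} genes need at least "
                f"{gm.n_genes * (gm.gene_length + gm.intergenic_length) + gm.intergenic_length} bp"
            )
        strand = "-" if rng.random() < gm.minus_strand_fraction else "+"
        if gm.utr5_length or gm.utr3_length:
            if strand == "+":
                cds = [(start + gm.utr5_length, end - gm.utr3_length)]
            else:
                cds = [(start + gm.utr3_length, end - gm.utr5_length)]
        else:
            cds = [(start, end)]
        genes.append(
            GeneRecord(
                gene_id=f"gene{k:04d}",
                seq_id=spec.assembly_id,
                start=start,
                end=end,
                strand=strand,
                biotype="protein_coding",
                exons=[(start, end)],
                cds=cds,
            )
        )
        pos = end + gm.intergenic_length
    return genes


def _write_ir(
    residues: list[str],
    start: int,
    arm: str,
    spacer: str,
    seq_id: str,
) -> InvertedRepeat:
    right = reverse_complement(arm)
    word = arm + spacer + right
    end = start + len(word)
    residues[start:end] = list(word)
    # guard base: break outward extension (sequence ends block it for free)
    if start > 0 and end < len(residues) and _COMP.get(residues[start - 1], "?") == residues[end]:
        residues[start - 1] = next(b for b in _BASES if _COMP[b] != residues[end])
    return InvertedRepeat(
        seq_id=seq_id,
        start=start,
        end=end,
        arm_length=len(arm),
        spacer_length=len(spacer),
        left_arm_seq=arm,
        spacer_seq=spacer,
        right_arm_seq=right,
    )


def plant_ir_at_offset(
    residues: list[str],
    gene: GeneRecord,
    anchor: str,
    offset: int,
    arm_length: int,
    spacer_length: int,
    rng: np.random.Generator,
    arm_gc: float = 0.5,
    seq_id: str = "seq",
) -> InvertedRepeat:
    """Overwrite the genome so a maximal IR is centered ``offset`` window
    positions from the gene's anchor (strand-aware: negative = upstream)."""
    anchor_pos = gene.tss if anchor == "TSS" else gene.tes
    center = anchor_pos + offset if gene.strand == "+" else anchor_pos - offset
    span = 2 * arm_length + spacer_length
    start = center - span // 2
    if start - 1 < 0 or start + span + 1 > len(residues):
        raise ValueError("anchored IR placement falls outside the genome")
    arm = _draw_arm(rng, arm_length, arm_gc)
    spacer = _draw_spacer(rng, spacer_length)
    return _write_ir(residues, start, arm, spacer, seq_id)


def simulate_genome(spec: SimulationSpec, seed: int | np.random.Generator = 0) -> SimulatedGenome:
    """Deterministic (for a fixed seed) synthetic genome with truth tables."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues = _draw_background(rng, spec.genome_length, spec.gc, spec.cpg_depletion)
    genes = _build_genes(spec, rng)

    occupied: list[Interval] = []
    planted: list[InvertedRepeat] = []

    def reserve(start: int, end: int) -> bool:
        for s, e in occupied:
            if start - 1 < e and s < end + 1:
                return False
        occupied.append((start - 1, end + 1))
        return True

    # anchored placements are fixed in place, so they go first; uniform
    # placements then sample around them
    ordered = sorted(spec.planted_irs, key=lambda p: p.placement == "uniform")
    for p in ordered:
        span = 2 * p.arm_length + p.spacer_length
        if p.placement == "uniform":
            for _ in range(p.count):
                placed = False
                for _attempt in range(2000):
                    start = int(rng.integers(1, spec.genome_length - span - 1))
                    if reserve(start, start + span):
                        arm = _draw_arm(rng, p.arm_length, p.arm_gc)
                        spacer = _draw_spacer(rng, p.spacer_length)
                        planted.append(_write_ir(residues, start, arm, spacer, spec.assembly_id))
                        placed = True
                        break
                if not placed:
                    need = span + 2
                    raise ValueError(
                        f"infeasible packing: cannot place IR of span {span}; "
                        f"genome needs at least ~{need} more bp of free space"
                    )
        elif p.placement in ("TSS", "TES"):
            # anchored placement plants one IR per gene; count is ignored
            if not genes:
                raise ValueError("anchored IR placement requires a gene model")
            for g in genes:
                ir = plant_ir_at_offset(
                    residues, g, p.placement, p.offset, p.arm_length, p.spacer_length,
                    rng, p.arm_gc, seq_id=spec.assembly_id,
                )
                if not reserve(ir.start, ir.end):
                    raise ValueError("anchored IR placements overlap; reduce span or offset")
                planted.append(ir)
        else:
            raise ValueError(f"unknown placement {p.placement!r}")

    seq = "".join(residues)
    genome = GenomeSequence(spec.assembly_id, seq, "linear")

    params = DetectionParams()
    truth = brute_force_inverted_repeats(
        seq, min_arm=params.min_arm, max_spacer=params.max_spacer, seq_id=spec.assembly_id
    )

    terminators: dict[str, list[Interval]] = {}
    if spec.terminator_offset is not None:
        ivs = []
        for g in genes:
            if g.strand == "+":
                t0 = g.end + spec.terminator_offset
                ivs.append((t0, t0 + spec.terminator_length))
            else:
                t1 = g.start - spec.terminator_offset
                ivs.append((t1 - spec.terminator_length, t1))
        terminators[spec.assembly_id] = merge(
            (max(0, s), min(spec.genome_length, e)) for s, e in ivs
        )

    lineage = LineageRecord(
        assembly_id=spec.assembly_id,
        species=spec.species,
        family=spec.family,
        phylum=spec.phylum,
        kingdom=spec.kingdom,
        domain=spec.domain,
    )
    return SimulatedGenome(spec, genome, genes, planted, truth, terminators, lineage)


def simulate_snvs(
    sim: SimulatedGenome,
    irs: list[InvertedRepeat] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SnvSite]:
    """Bernoulli SNV sites per position under the spec's SnvModel.

    The per-position probability is the class rate (or base_rate) times the
    spacer/arm multiplier of any IR footprint covering the position, with the
    ``near_*`` multipliers for IRs within terminator_distance of a terminator.
    Probabilities are capped at 1 with a warning. Positions lacking a full
    trinucleotide context still mutate at base_rate (their context is simply
    unclassifiable); arm/spacer assignment follows arm precedence.
    """
    from .snv_burden import classify_positions, partition_by_terminator, segment_footprints

    model = sim.spec.snv
    seq = sim.genome.residues
    n = len(seq)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    classes = classify_positions(seq)
    if model.class_rates is not None:
        rates = np.asarray(model.class_rates, dtype=float)[np.clip(classes, 0, 31)]
        rates[classes < 0] = model.base_rate
    else:
        rates = np.full(n, model.base_rate)

    irs = sim.truth if irs is None else irs
    near, far = partition_by_terminator(
        irs, sim.terminators, distance=model.terminator_distance
    )
    mult = np.ones(n)
    for group, sp_m, arm_m in (
        (far, model.spacer_multiplier, model.arm_multiplier),
        (near, model.near_spacer_multiplier, model.near_arm_multiplier),
    ):
        if not group:
            continue
        arms, spacers = segment_footprints(group, precedence="arms")
        for s, e in spacers.get(sim.genome.seq_id, []):
            mult[s:e] *= sp_m
        for s, e in arms.get(sim.genome.seq_id, []):
            mult[s:e] *= arm_m
    prob = rates * mult
    if (prob > 1).any():
        log.warning("simulate_snvs: %d per-position probabilities capped at 1", int((prob > 1).sum()))
        prob = np.minimum(prob, 1.0)

    hits = np.flatnonzero(rng.random(n) < prob)
    sites = []
    for pos in hits:
        ref = seq[pos]
        if ref == "N":
            continue
        alts = [b for b in _BASES if b != ref]
        alt = alts[rng.integers(3)]
        sites.append(SnvSite(sim.genome.seq_id, int(pos), ref, alt, 60.0, 100.0))
    return sites


def write_simulation(sim: SimulatedGenome, outdir) -> dict[str, str]:
    """Emit FASTA, GFF3, truth-IR BED, terminator BED and lineage TSV."""
    import os

    from . import genome_io

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, f"{sim.spec.assembly_id}.fa"),
        "gff": os.path.join(outdir, f"{sim.spec.assembly_id}.gff3"),
        "truth_bed": os.path.join(outdir, f"{sim.spec.assembly_id}.truth_irs.bed"),
        "terminators": os.path.join(outdir, f"{sim.spec.assembly_id}.terminators.bed"),
        "lineage": os.path.join(outdir, f"{sim.spec.assembly_id}.lineage.tsv"),
    }
    genome_io.write_fasta([sim.genome], paths["fasta"])
    genome_io.write_gff3(sim.genes, paths["gff"])
    genome_io.write_ir_bed(sim.truth, paths["truth_bed"])
    genome_io.write_bed(
        [(sid, s, e, "terminator", ".", ".") for sid, ivs in sim.terminators.items() for s, e in ivs],
        paths["terminators"],
    )
    genome_io.write_lineage_tsv([sim.lineage], paths["lineage"])
    return paths
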