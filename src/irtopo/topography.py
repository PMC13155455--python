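"""IR topography: compartment densities and anchored positional profiles.

Functional compartments (genic, exonic, intronic, CDS, 5'/3' UTR, intergenic)
are merged, mutually-disjoint interval sets derived from gene annotations.
Positional profiles count IR footprint bp at every offset of a symmetric
window around an anchor (TSS, TES, or an externally supplied point of
termination), strand-oriented so negative offsets are always upstream, and
normalize by the window mean so a flat profile reads 1 everywhere. Domain-
level profiles average per-species enrichment vectors; confidence bands come
from a two-stage bootstrap resampling families then species within families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GeneRecord
from .intervals import Interval, complement, intersect, merge, subtract, total_bp

COMPARTMENT_LABELS = ("genome", "genic", "intergenic", "exonic", "intronic", "cds", "utr5", "utr3")


@dataclass
class CompartmentSet:
    label: str
    intervals: list[Interval]

    @property
    def total_bp(self) -> int:
        return total_bp(self.intervals)


@dataclass
class PositionalProfile:
    anchor: str  # "TSS" | "TES" | "POT"
    window: int
    raw_counts: np.ndarray  # IR bp per offset, length 2*window + 1
    n_anchors: int
    n_dropped: int = 0
    flagged: bool = False  # window mean == 0: enrichment undefined

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.window, self.window + 1)

    @property
    def enrichment(self) -> np.ndarray:
        m = self.raw_counts.mean()
        if m == 0:
            raise ZeroDivisionError("window mean is 0; enrichment undefined")
        return self.raw_counts / m


def derive_compartments(
    genes: list[GeneRecord], genome_length: int
) -> dict[str, CompartmentSet]:
    """Merged, disjoint compartment coordinates from gene records.

    UTRs are strand-aware: 5' UTR is the exonic portion 5' of the CDS start,
    3' UTR the exonic portion 3' of the CDS end; genes without CDS contribute
    no UTRs. Intergenic is the complement of genic; intronic is genic − exonic.
    """
    for g in genes:
        if g.end > genome_length:
            raise ValueError(f"gene {g.gene_id} extends past genome end ({g.end} > {genome_length})")
    genic = merge((g.start, g.end) for g in genes)
    exonic = merge(iv for g in genes for iv in g.exons)
    cds = merge(iv for g in genes for iv in g.cds)
    utr5_raw: list[Interval] = []
    utr3_raw: list[Interval] = []
    for g in genes:
        if not g.cds:
            continue
        cds_lo = min(s for s, _ in g.cds)
        cds_hi = max(e for _, e in g.cds)
        before = intersect(g.exons, [(g.start, cds_lo)])
        after = intersect(g.exons, [(cds_hi, g.end)])
        if g.strand == "+":
            utr5_raw += before
            utr3_raw += after
        else:
            utr5_raw += after
            utr3_raw += before
    sets = {
        "genome": [(0, genome_length)],
        "genic": genic,
        "intergenic": complement(genic, 0, genome_length),
        "exonic": exonic,
        "intronic": subtract(genic, exonic),
        "cds": cds,
        "utr5": merge(utr5_raw),
        "utr3": merge(utr3_raw),
    }
    return {label: CompartmentSet(label, ivs) for label, ivs in sets.items()}


def compartment_density(
    footprint: list[Interval], compartments: dict[str, CompartmentSet]
) -> dict[str, float]:
    """IR bp per kB per compartment; overlap bp attributed proportionally.

    Zero-length compartments get density NaN (flagged by value).
    """
    out = {}
    for label, comp in compartments.items():
        if comp.total_bp == 0:
            out[label] = float("nan")
            continue
        bp = total_bp(intersect(footprint, comp.intervals))
        out[label] = 1000.0 * bp / comp.total_bp
    return out


def _coverage_array(footprint: list[Interval], length: int) -> np.ndarray:
    cov = np.zeros(length, dtype=np.uint8)
    for s, e in footprint:
        cov[max(s, 0) : min(e, length)] = 1
    return cov


def _anchor_pos(gene: GeneRecord, anchor: str) -> int:
    if anchor == "TSS":
        return gene.tss
    if anchor == "TES":
        return gene.tes
    raise ValueError(f"unknown anchor {anchor!r}")


def positional_profile(
    footprints: dict[str, list[Interval]],
    genes: list[GeneRecord],
    anchor: str,
    lengths: dict[str, int],
    window: int = 500,
) -> PositionalProfile:
    """Summed IR bp per offset around each gene's anchor, strand-oriented.

    ``footprints`` maps seq_id to a merged IR footprint. Genes whose window
    would overrun a contig end are dropped (zero-padding would bias the
    window mean). Offset 0 is the anchor base; negative offsets are upstream
    of the gene regardless of strand.
    """
    w = window
    counts = np.zeros(2 * w + 1, dtype=np.int64)
    cov_cache = {
        sid: _coverage_array(fp, lengths[sid]) for sid, fp in footprints.items() if sid in lengths
    }
    n_used = n_dropped = 0
    for g in genes:
        length = lengths.get(g.seq_id)
        if length is None:
            n_dropped += 1
            continue
        pos = _anchor_pos(g, anchor)
        if pos - w < 0 or pos + w >= length:
            n_dropped += 1
            continue
        cov = cov_cache.get(g.seq_id)
        sl = cov[pos - w : pos + w + 1] if cov is not None else np.zeros(2 * w + 1, np.uint8)
        counts += sl[::-1] if g.strand == "-" else sl
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene with a full window inside the genome")
    flagged = counts.sum() == 0
    return PositionalProfile(anchor, w, counts, n_anchors=n_used, n_dropped=n_dropped, flagged=flagged)


def pot_profile(
    footprints: dict[str, list[Interval]],
    pot_coords: list[tuple[str, int, str]],
    lengths: dict[str, int],
    window: int = 100,
) -> PositionalProfile:
    """Profile around externally supplied points of termination.

    ``pot_coords`` are (seq_id, position, strand) triples, e.g. read from BED
    rows as (chrom, start, strand).
    """
    if not pot_coords:
        raise ValueError("empty POT coordinate set")
    w = window
    counts = np.zeros(2 * w + 1, dtype=np.int64)
    cov_cache = {
        sid: _coverage_array(fp, lengths[sid]) for sid, fp in footprints.items() if sid in lengths
    }
    n_used = n_dropped = 0
    for sid, pos, strand in pot_coords:
        length = lengths.get(sid)
        if length is None or pos - w < 0 or pos + w >= length:
            n_dropped += 1
            continue
        cov = cov_cache.get(sid)
        sl = cov[pos - w : pos + w + 1] if cov is not None else np.zeros(2 * w + 1, np.uint8)
        counts += sl[::-1] if strand == "-" else sl
        n_used += 1
    if n_used == 0:
        raise ValueError("no POT with a full window inside the genome")
    flagged = counts.sum() == 0
    return PositionalProfile("POT", w, counts, n_anchors=n_used, n_dropped=n_dropped, flagged=flagged)


def aggregate_profiles(enrichments) -> np.ndarray:
    """Per-offset arithmetic mean of per-species enrichment vectors."""
    mat = np.asarray(list(enrichments), dtype=float)
    if mat.size == 0:
        raise ValueError("no profiles to aggregate")
    return mat.mean(axis=0)


def bootstrap_ci(
    species_enrichments: dict[str, np.ndarray],
    species_family: dict[str, str],
    n_boot: int = 1000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage bootstrap bands for the aggregate profile.

    Each replicate resamples families with replacement (outer layer), then
    species within each drawn family with replacement (inner layer), and
    recomputes the aggregate mean profile; per-offset percentiles over the
    replicates form the band. With a single family the outer layer is
    degenerate and resampling falls back to species only.
    """
    import logging

    species = sorted(species_enrichments)
    fam_members: dict[str, list[str]] = {}
    for sp in species:
        fam_members.setdefault(species_family.get(sp, ""), []).append(sp)
    families = sorted(fam_members)
    rng = np.random.default_rng(seed)
    mat = np.stack([np.asarray(species_enrichments[sp], dtype=float) for sp in species])
    idx_of = {sp: i for i, sp in enumerate(species)}
    if len(families) == 1:
        logging.getLogger(__name__).warning(
            "bootstrap_ci: single family; falling back to species-only resampling"
        )
    reps = np.empty((n_boot, mat.shape[1]))
    for b in range(n_boot):
        rows: list[int] = []
        if len(families) == 1:
            rows = list(rng.integers(0, len(species), size=len(species)))
        else:
            drawn = rng.integers(0, len(families), size=len(families))
            for fi in drawn:
                members = fam_members[families[fi]]
                picks = rng.integers(0, len(members), size=len(members))
                rows += [idx_of[members[p]] for p in picks]
        reps[b] = mat[rows].mean(axis=0)
    lo = np.percentile(reps, ci[0], axis=0)
    hi = np.percentile(reps, ci[1], axis=0)
    return lo, hi
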