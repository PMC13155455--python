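"""Readers/writers for the standard formats the pipeline touches.

Everything is normalized into a single internal convention on ingest:
0-based half-open coordinates, uppercase residues over ``{A,C,G,T,N}``
(any other IUPAC code becomes ``N``, with a logged count). GFF3 (1-based
closed) and VCF (1-based) are converted at the boundary. All readers accept
gzip-compressed input.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO

from .intervals import Interval, merge

log = logging.getLogger(__name__)

_VALID = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenomeSequence:
    """One replicon: identifier, residues over {A,C,G,T,N}, topology flag."""

    seq_id: str
    residues: str
    topology: str = "linear"  # {"linear", "circular"}; recorded, detection is linear

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneRecord:
    """A gene with 0-based half-open coordinates and exon/CDS sub-structure."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    biotype: str = "protein_coding"  # or "non_coding"
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"gene {self.gene_id}: end <= start")
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand {self.strand!r}")
        self.exons = merge(self.exons)
        self.cds = merge(self.cds)

    @property
    def tss(self) -> int:
        """Position of the first transcribed/translated base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Position of the last transcribed/translated base (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class SnvSite:
    seq_id: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    mapping_quality: float
    phred_quality: float


@dataclass(frozen=True)
class LineageRecord:
    assembly_id: str
    species: str
    family: str = ""
    phylum: str = ""
    kingdom: str = ""
    domain: str = ""


def _open_text(path):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA


def sanitize_residues(raw: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN IUPAC codes to N; return (clean, n_substituted)."""
    up = raw.upper()
    n_sub = 0
    if not set(up) <= _VALID:
        cleaned = []
        for c in up:
            if c in _VALID:
                cleaned.append(c)
            else:
                cleaned.append("N")
                n_sub += 1
        up = "".join(cleaned)
    return up, n_sub


def read_fasta(path, topology: str = "linear") -> list[GenomeSequence]:
    records: list[GenomeSequence] = []
    n_sub_total = 0
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            residues, n_sub = sanitize_residues(str(rec.seq))
            n_sub_total += n_sub
            records.append(GenomeSequence(rec.id, residues, topology))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if n_sub_total:
        log.info("read_fasta(%s): mapped %d non-ACGTN residues to N", path, n_sub_total)
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[GeneRecord]:
    """Parse gene/mRNA/exon/CDS features into GeneRecords.

    GFF 1-based closed coordinates become 0-based half-open. Genes without
    explicit exon children (the prokaryotic annotation style) get a single
    exon spanning the gene. CDS intervals falling outside the exon union are
    kept and the union extended, with a warning.
    """
    genes: dict[str, GeneRecord] = {}
    gene_raw: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    pending: list[tuple[str, str, int, int]] = []  # (type, parent, start, end)

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            seq_id, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = parts[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"{path}: line {lineno}: end < start")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
            )
            fid = attrs.get("ID", f"{ftype}:{seq_id}:{start}")
            parent = attrs.get("Parent", "")
            if ftype == "gene":
                biotype = attrs.get("gene_biotype", attrs.get("biotype", "protein_coding"))
                biotype = "protein_coding" if biotype == "protein_coding" else "non_coding"
                gene_raw[fid] = dict(
                    gene_id=fid, seq_id=seq_id, start=start, end=end,
                    strand=strand if strand in "+-" else "+",
                    biotype=biotype, exons=[], cds=[],
                )
            elif ftype in ("mRNA", "transcript", "tRNA", "rRNA", "ncRNA"):
                mrna_parent[fid] = parent
            elif ftype in ("exon", "CDS"):
                pending.append((ftype, parent, start, end))

    n_skipped = 0
    for ftype, parent, start, end in pending:
        gid = parent if parent in gene_raw else mrna_parent.get(parent, "")
        if gid not in gene_raw:
            n_skipped += 1
            continue
        key = "exons" if ftype == "exon" else "cds"
        gene_raw[gid][key].append((start, end))
    if n_skipped:
        log.warning("read_gff3(%s): skipped %d features with unknown Parent", path, n_skipped)

    out: list[GeneRecord] = []
    for raw in gene_raw.values():
        if not raw["exons"]:
            # prokaryotic style: fill in a single exon spanning the gene
            raw["exons"] = [(raw["start"], raw["end"])]
        exon_union = merge(raw["exons"])
        for c in raw["cds"]:
            if not any(s <= c[0] and c[1] <= e for s, e in exon_union):
                log.warning(
                    "read_gff3(%s): CDS %s outside exon union of %s; exon union extended",
                    path, c, raw["gene_id"],
                )
                raw["exons"].append(c)
                exon_union = merge(raw["exons"])
        out.append(GeneRecord(**raw))
    genes_sorted = sorted(out, key=lambda g: (g.seq_id, g.start, g.end))
    return genes_sorted


def write_gff3(genes: Iterable[GeneRecord], path) -> None:
    """Write normalized GeneRecords back to GFF3 (re-reading is idempotent)."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.seq_id, g.start, g.end)):
            bt = g.biotype
            fh.write(
                f"{g.seq_id}\tirtopo\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};gene_biotype={bt}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.seq_id}\tirtopo\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"Parent={g.gene_id}\n"
                )
            for s, e in g.cds:
                fh.write(
                    f"{g.seq_id}\tirtopo\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# VCF


def read_vcf_filtered(path, min_mq: float = 50, min_qual: float = 60) -> list[SnvSite]:
    """High-quality biallelic SNVs: MQ >= min_mq and QUAL >= min_qual (inclusive).

    Multi-allelic records are split per alt before filtering; indel alts and
    records without an MQ annotation are dropped, with counts logged.
    """
    import pysam

    sites: list[SnvSite] = []
    n_indel = n_lowq = n_nomq = 0
    with pysam.VariantFile(os.fspath(path)) as vf:
        for rec in vf:
            qual = rec.qual
            mq = rec.info.get("MQ", None)
            if isinstance(mq, tuple):
                mq = mq[0] if mq else None
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                    n_indel += 1
                    continue
                if mq is None:
                    n_nomq += 1
                    continue
                if qual is None or mq < min_mq or qual < min_qual:
                    n_lowq += 1
                    continue
                sites.append(SnvSite(rec.chrom, rec.pos - 1, ref, alt, float(mq), float(qual)))
    log.info(
        "read_vcf_filtered(%s): kept %d sites; dropped %d indel/non-SNV, %d low-quality, %d missing-MQ",
        path, len(sites), n_indel, n_lowq, n_nomq,
    )
    return sites


def write_vcf(sites: Iterable[SnvSite], path, contigs: dict[str, int] | None = None) -> None:
    """Write SNV sites as a minimal VCF 4.2 file (MQ in INFO, QUAL column set)."""
    sites = sorted(sites, key=lambda s: (s.seq_id, s.pos))
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            fh.write(
                f"{s.seq_id}\t{s.pos + 1}\t.\t{s.ref_base}\t{s.alt_base}\t"
                f"{s.phred_quality:g}\t.\tMQ={s.mapping_quality:g}\n"
            )


# ---------------------------------------------------------------------------
# BED


def write_ir_bed(irs, path) -> None:
    """BED6: chrom start end IR:arm=<a>;spacer=<s> <arm_length> ."""
    with open(path, "wt") as fh:
        for ir in irs:
            fh.write(
                f"{ir.seq_id}\t{ir.start}\t{ir.end}\t"
                f"IR:arm={ir.arm_length};spacer={ir.spacer_length}\t{ir.arm_length}\t.\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str, str, str]]:
    """Read BED (3-6 columns) into (chrom, start, end, name, score, strand) tuples."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}: line {lineno}: end < start")
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return rows


def write_bed(rows: Iterable[tuple], path) -> None:
    with open(path, "wt") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# Lineage TSV


LINEAGE_COLUMNS = ("assembly_id", "species", "family", "phylum", "kingdom", "domain")


def read_lineage_tsv(path) -> list[LineageRecord]:
    """TSV with a header row naming (at least) assembly_id and species columns."""
    import csv

    out: list[LineageRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "assembly_id" not in reader.fieldnames:
            raise FormatError(f"{path}: missing header row with 'assembly_id' column")
        for row in reader:
            aid = (row.get("assembly_id") or "").strip()
            if not aid:
                continue
            if aid in seen:
                raise FormatError(f"{path}: duplicate assembly_id {aid!r}")
            seen.add(aid)
            out.append(
                LineageRecord(
                    assembly_id=aid,
                    species=(row.get("species") or "").strip(),
                    family=(row.get("family") or "").strip(),
                    phylum=(row.get("phylum") or "").strip(),
                    kingdom=(row.get("kingdom") or "").strip(),
                    domain=(row.get("domain") or "").strip(),
                )
            )
    return out


def write_lineage_tsv(records: Iterable[LineageRecord], path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(LINEAGE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join([r.assembly_id, r.species, r.family, r.phylum, r.kingdom, r.domain])
                + "\n"
            )
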