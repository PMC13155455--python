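"""End-to-end orchestration: detect → shuffle → detect-on-control → enrich →
topography → composition → burden, over one or many assemblies.

Every stage is a thin call into the library modules, so each is equally
usable standalone; the pipeline adds manifest handling, deterministic
per-assembly seeding, logging of counts, and tabular outputs. Re-running
with the same manifest and seed reproduces all tables.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome_io
from .composition import gc_content, length_spectra
from .dinucleotide_shuffle import ShuffleParams, shuffle_genome
from .enrichment_stats import PairedDensities, enrichment_fe, paired_test_with_bh
from .ir_detection import (
    DetectionParams,
    detect_inverted_repeats,
    genome_ir_density,
    ir_footprint,
)
from .intervals import merge
from .snv_burden import burden_tables, fisher_ir_enrichment, terminator_partition_density
from .topography import (
    aggregate_profiles,
    bootstrap_ci,
    compartment_density,
    derive_compartments,
    positional_profile,
)

log = logging.getLogger(__name__)


@dataclass
class AssemblyInputs:
    fasta: str
    gff: str | None = None
    vcf: str | None = None
    terminators: str | None = None


@dataclass
class RunManifest:
    assemblies: dict[str, AssemblyInputs]
    lineage: str | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    chunk_bp: int = 1000
    window: int = 500
    n_boot: int = 1000
    min_mq: float = 50
    min_qual: float = 60
    terminator_distance: int = 50
    group_by: str = "phylum"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunManifest":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        assemblies = {
            aid: AssemblyInputs(**paths) for aid, paths in raw.pop("assemblies").items()
        }
        det = DetectionParams(
            min_arm=raw.pop("min_arm", 10), max_spacer=raw.pop("max_spacer", 8)
        )
        return cls(assemblies=assemblies, detection=det, **raw)


def _assembly_stage(
    aid: str, inputs: AssemblyInputs, manifest: RunManifest, sub_seed: int
) -> dict:
    seqs = genome_io.read_fasta(inputs.fasta)
    lengths = {s.seq_id: len(s) for s in seqs}
    irs_by_seq = {s.seq_id: detect_inverted_repeats(s, manifest.detection) for s in seqs}
    irs = [ir for lst in irs_by_seq.values() for ir in lst]
    density = genome_ir_density(irs_by_seq, lengths)

    shuffled = [
        shuffle_genome(s, ShuffleParams(chunk_bp=manifest.chunk_bp, seed=sub_seed + i))
        for i, s in enumerate(seqs)
    ]
    ctrl_by_seq = {s.seq_id: detect_inverted_repeats(s, manifest.detection) for s in shuffled}
    ctrl_density = genome_ir_density(ctrl_by_seq, lengths)
    log.info("%s: %d IRs (density %.3f/kB), control %.3f/kB", aid, len(irs), density, ctrl_density)

    out = dict(
        assembly_id=aid,
        seqs=seqs,
        lengths=lengths,
        irs_by_seq=irs_by_seq,
        irs=irs,
        density=density,
        ctrl_density=ctrl_density,
        fe=enrichment_fe(density, ctrl_density),
        gc=gc_content("".join(s.residues for s in seqs)),
    )
    if inputs.gff:
        out["genes"] = genome_io.read_gff3(inputs.gff)
    if inputs.vcf:
        out["snvs"] = genome_io.read_vcf_filtered(
            inputs.vcf, min_mq=manifest.min_mq, min_qual=manifest.min_qual
        )
    if inputs.terminators:
        terms: dict[str, list] = {}
        for chrom, s, e, *_ in genome_io.read_bed(inputs.terminators):
            terms.setdefault(chrom, []).append((s, e))
        out["terminators"] = {sid: merge(ivs) for sid, ivs in terms.items()}
    return out


def run_pipeline(manifest: RunManifest, outdir: str) -> dict[str, pd.DataFrame]:
    """Run every applicable stage; write TSV tables plus a summary JSON."""
    os.makedirs(outdir, exist_ok=True)
    lineage = (
        {r.assembly_id: r for r in genome_io.read_lineage_tsv(manifest.lineage)}
        if manifest.lineage
        else {}
    )

    stages = []
    for i, (aid, inputs) in enumerate(sorted(manifest.assemblies.items())):
        stages.append(_assembly_stage(aid, inputs, manifest, manifest.seed * 100_003 + i))

    density_rows = []
    for st in stages:
        lin = lineage.get(st["assembly_id"])
        density_rows.append(
            dict(
                assembly_id=st["assembly_id"],
                species=lin.species if lin else st["assembly_id"],
                family=lin.family if lin else "",
                group=getattr(lin, manifest.group_by) if lin else "",
                n_irs=len(st["irs"]),
                density=st["density"],
                ctrl_density=st["ctrl_density"],
                fe=st["fe"],
                genome_gc=st["gc"],
            )
        )
    densities = pd.DataFrame(density_rows)

    # species level: mean over assemblies; rank level: paired tests per group
    species = (
        densities.groupby(["group", "species"], as_index=False)
        .agg(density=("density", "mean"), ctrl_density=("ctrl_density", "mean"))
    )
    groups = {}
    for gname, sub in species.groupby("group"):
        if len(sub) >= 2:
            groups[gname or "(ungrouped)"] = PairedDensities(
                list(sub["species"]), sub["density"].to_numpy(), sub["ctrl_density"].to_numpy()
            )
    enrich = paired_test_with_bh(groups) if groups else pd.DataFrame()

    # topography + composition per assembly
    comp_rows, profile_mats, spectra_frames = [], {}, []
    for st in stages:
        spect = length_spectra(st["irs"])
        if not spect["arm"].empty:
            arm_t = spect["arm"].assign(assembly_id=st["assembly_id"])
            spectra_frames.append(arm_t)
        if "genes" not in st:
            continue
        genome_len = sum(st["lengths"].values())
        genes = st["genes"]
        comps_all = {}
        for sid, length in st["lengths"].items():
            comps = derive_compartments([g for g in genes if g.seq_id == sid], length)
            fp = ir_footprint(st["irs_by_seq"][sid]) if st["irs_by_seq"][sid] else []
            dens = compartment_density(fp, comps)
            for label, d in dens.items():
                comps_all.setdefault(label, []).append(
                    (d, comps[label].total_bp)
                )
        for label, pairs in comps_all.items():
            tot = sum(bp for _, bp in pairs)
            val = (
                sum(d * bp for d, bp in pairs if bp) / tot if tot else float("nan")
            )
            comp_rows.append(
                dict(assembly_id=st["assembly_id"], compartment=label, density=val)
            )
        footprints = {
            sid: ir_footprint(lst) for sid, lst in st["irs_by_seq"].items() if lst
        }
        for anchor in ("TSS", "TES"):
            try:
                prof = positional_profile(
                    footprints, genes, anchor, st["lengths"], window=manifest.window
                )
                if not prof.flagged:
                    profile_mats.setdefault(anchor, {})[st["assembly_id"]] = prof.enrichment
            except ValueError:
                log.warning("%s: no usable %s windows", st["assembly_id"], anchor)

    compartments = pd.DataFrame(comp_rows)
    profiles = {}
    for anchor, mats in profile_mats.items():
        agg = aggregate_profiles(mats.values())
        fam = {
            aid: (lineage[aid].family if aid in lineage else "")
            for aid in mats
        }
        lo, hi = bootstrap_ci(mats, fam, n_boot=manifest.n_boot, seed=manifest.seed)
        profiles[anchor] = pd.DataFrame(
            dict(
                offset=np.arange(-manifest.window, manifest.window + 1),
                enrichment=agg,
                ci_low=lo,
                ci_high=hi,
            )
        )

    # SNV burden per assembly with a VCF
    burden_rows = []
    for st in stages:
        if "snvs" not in st:
            continue
        tables = burden_tables(st["irs"], st["snvs"], st["seqs"])
        total = len({(s.seq_id, s.pos) for s in st["snvs"]})
        obs_ir = tables["arms"].observed + tables["spacers"].observed
        exp_ir = tables["arms"].expected_trinuc + tables["spacers"].expected_trinuc
        odds, p = fisher_ir_enrichment(obs_ir, exp_ir, total) if total else (np.nan, np.nan)
        for t in tables.values():
            burden_rows.append(
                dict(
                    assembly_id=st["assembly_id"],
                    segment=t.segment,
                    L=t.L,
                    observed=t.observed,
                    expected_length=t.expected_length,
                    expected_trinuc=t.expected_trinuc,
                    r=t.r,
                    fisher_or=odds,
                    fisher_p=p,
                )
            )
        if "terminators" in st:
            tp = terminator_partition_density(
                st["irs"], st["snvs"], st["terminators"], distance=manifest.terminator_distance
            )
            tp.insert(0, "assembly_id", st["assembly_id"])
            tp.to_csv(
                os.path.join(outdir, f"terminator_partition.{st['assembly_id']}.tsv"),
                sep="\t",
                index=False,
            )
    burden = pd.DataFrame(burden_rows)

    out = dict(densities=densities, enrichment=enrich, compartments=compartments, burden=burden)
    for name, df in out.items():
        df.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
    for anchor, df in profiles.items():
        out[f"profile_{anchor.lower()}"] = df
        df.to_csv(os.path.join(outdir, f"profile_{anchor.lower()}.tsv"), sep="\t", index=False)
    if spectra_frames:
        out["arm_spectra"] = pd.concat(spectra_frames, ignore_index=True)
        out["arm_spectra"].to_csv(os.path.join(outdir, "arm_spectra.tsv"), sep="\t", index=False)

    summary = dict(
        n_assemblies=len(stages),
        seed=manifest.seed,
        params=dict(
            min_arm=manifest.detection.min_arm,
            max_spacer=manifest.detection.max_spacer,
            chunk_bp=manifest.chunk_bp,
            window=manifest.window,
            n_boot=manifest.n_boot,
            min_mq=manifest.min_mq,
            min_qual=manifest.min_qual,
            terminator_distance=manifest.terminator_distance,
        ),
        tables=sorted(out),
    )
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return out
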