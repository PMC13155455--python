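#!/usr/bin/env python
"""Build the synthetic study cohort.

Generates 12 assemblies (8 species, 4 families, 2 phyla) with planted IRs,
gene models, terminators downstream of gene ends, and intraspecific SNVs with
an elevated substitution rate in IR spacers near terminators. Raw sequence
data goes to scratch/sim/ (regenerated on demand); the pipeline manifest and
the cohort summary go with it.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import os
import sys

import yaml

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from irtopo import genome_io
from irtopo.synthetic_data import (
    GeneModel,
    PlantedIR,
    SimulationSpec,
    SnvModel,
    simulate_genome,
    simulate_snvs,
    write_simulation,
)

SEED = 20240322
OUTDIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "sim")


def cohort_specs():
    """12 assemblies; IR density varies by phylum so rank statistics have signal."""
    specs = []
    k = 0
    for phylum, fam_count, ir_count in (("Synthota", 2, 18), ("Placidota", 2, 6)):
        for fam in range(fam_count):
            for sp in range(2):
                for asm in range(1 + (k % 2 == 0)):  # 1-2 assemblies per species
                    specs.append(
                        SimulationSpec(
                            genome_length=22_000,
                            genes=GeneModel(n_genes=10, gene_length=600, intergenic_length=1200),
                            planted_irs=(
                                PlantedIR(12, 4, count=ir_count + k % 5),
                                PlantedIR(11, 8, placement="TES", offset=40),
                            ),
                            terminator_offset=30,
                            snv=SnvModel(base_rate=1.2e-2),
                            assembly_id=f"SYN_{k:03d}.1",
                            species=f"{phylum[:-3]}a specimen{fam}{sp}",
                            family=f"{phylum[:-3]}aceae{fam}",
                            phylum=phylum,
                            domain="Bacteria",
                        )
                    )
                    k += 1
    return specs[:12]


def main() -> None:
    os.makedirs(OUTDIR, exist_ok=True)
    specs = cohort_specs()
    assemblies, lineages = {}, []
    for i, spec in enumerate(specs):
        sim = simulate_genome(spec, seed=SEED + i)
        paths = write_simulation(sim, os.path.join(OUTDIR, spec.assembly_id))
        snvs = simulate_snvs(sim, seed=SEED + 1000 + i)
        vcf = os.path.join(OUTDIR, spec.assembly_id, "snvs.vcf")
        genome_io.write_vcf(snvs, vcf, contigs={sim.genome.seq_id: len(sim.genome)})
        assemblies[spec.assembly_id] = dict(
            fasta=os.path.abspath(paths["fasta"]),
            gff=os.path.abspath(paths["gff"]),
            vcf=os.path.abspath(vcf),
            terminators=os.path.abspath(paths["terminators"]),
        )
        lineages.append(sim.lineage)
        print(f"{spec.assembly_id}: {len(sim.truth)} truth IRs, {len(snvs)} SNV sites")
    lin_path = os.path.join(OUTDIR, "lineage.tsv")
    genome_io.write_lineage_tsv(lineages, lin_path)
    manifest = dict(assemblies=assemblies, lineage=os.path.abspath(lin_path), seed=SEED)
    with open(os.path.join(OUTDIR, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh)
    print(f"\ncohort of {len(specs)} assemblies written to {os.path.abspath(OUTDIR)}")


if __name__ == "__main__":
    main()
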