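"""Build a population-specific SNP panel from reference genotypes.

Simulates two reference populations, exports them as a VCF, then runs the
panel-construction path a user would run on real data: per-population MAFs
with a pooled minor-allele designation, specificity filtering (polymorphic
in exactly one population), a closed MAF window and seeded subsampling.
"""

import tempfile
from pathlib import Path

import numpy as np

from ancspec import (
    AdmixtureDesign,
    PopulationAssignment,
    SimConfig,
    compute_maf,
    select_specific_snps,
    simulate_genotypes,
    simulate_panel,
    tabulate_panel,
)
from ancspec.io import read_vcf, write_assignment, write_panel, write_vcf

workdir = Path(tempfile.mkdtemp())

# two reference populations, 2,000 candidate SNPs each, 100 diploids per pop
truth_panel = simulate_panel(
    SimConfig(populations=("EAS", "EUR"), m_per_pop=2000, seed=11)
)
design = AdmixtureDesign(
    ("EAS", "EUR"),
    np.repeat(np.eye(2), 100, axis=0),
    labels=("EAS",) * 100 + ("EUR",) * 100,
)
geno = simulate_genotypes(truth_panel, design, seed=12)
write_vcf(geno, truth_panel, workdir / "reference.vcf")

assignment = PopulationAssignment(tuple(geno.sample_ids), design.labels)
write_assignment(assignment, workdir / "reference.pop.tsv")

# the real-data path: VCF -> MAF table -> specific-SNP panel
geno_back = read_vcf(workdir / "reference.vcf")
mafs = compute_maf(geno_back, assignment)
panel = select_specific_snps(mafs, maf_window=(0.01, 0.05), panel_size=500, seed=13)
write_panel(panel, workdir / "panel.tsv")

print(f"candidate SNPs in VCF: {geno_back.n_snps}")
print(f"panel: {panel.M} SNPs, {panel.sizes} per population")
print(tabulate_panel(panel, pop_sizes=assignment.sizes()))
print(
    "\nEach panel SNP is polymorphic in exactly one reference population with\n"
    "an estimated MAF inside the closed window [0.01, 0.05]; the per-stratum\n"
    "counts show how the selected MAF spectrum is distributed."
)
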