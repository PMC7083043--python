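"""Non-redundant genotype matrix and diagnostic-site classification.

Three species, noiseless coverage: the matrix keeps exactly the sites where
every accession has clean evidence, then sites are classified as
within-species polymorphic, between-species fixed, or genome-unique.
"""

from snpdiag import (Replicon, SimulationConfig, build_matrix, call_accession,
                     emit_pileups, evolve_panel, fixed_snps, polymorphic_sites,
                     simulate_reference, unique_substitutions)

config = SimulationConfig(
    seed=7,
    species_tree="((M:0.02,N:0.02):0.01,C:0.03);",
    accessions_per_species={"M": 3, "N": 3, "C": 3},
    within_species_diversity={"M": 0.001, "N": 0.001, "C": 0.002},
    replicons=[Replicon("chr1", 20_000)],
    mean_depth=40.0, error_rate=0.0, dropout_rate=0.0, depth_dispersion=0.0,
)
truth = evolve_panel(simulate_reference(config), config)
pileups = emit_pileups(truth, config)
panel = config.panel()

statuses = {acc: call_accession(pileups[acc], acc)[1] for acc in panel.accessions}
matrix = build_matrix(statuses, panel)
print(f"non-redundant SNP matrix: {matrix.n_sites} sites x "
      f"{len(matrix.accessions)} accessions (no missing cells)")

for sp in ("M", "N", "C"):
    print(f"polymorphic within {sp}: {len(polymorphic_sites(matrix, panel, sp))} sites")

fixed_mn = fixed_snps(matrix, panel, "M", "N")
print(f"fixed SNPs between M and N: {len(fixed_mn)}  "
      "(monomorphic in each species, different alleles between them)")

for sp in ("M", "N", "C"):
    uniq = unique_substitutions(matrix, panel, sp)
    print(f"unique substitutions diagnostic for {sp}: {len(uniq)}")
# Fixed SNPs are the raw material for genome-diagnostic markers; unique
# substitutions separate one genome from every other species in the panel.
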