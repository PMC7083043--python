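"""Simulate a small multi-species selfing panel with known truth.

Two species diverge 0.05 substitutions/site from their common ancestor;
species A carries within-species diversity, species B is clonal.  Pileup
evidence gets Poisson-like coverage and per-read errors.
"""

from snpdiag import Replicon, SimulationConfig, emit_pileups, evolve_panel, simulate_reference

config = SimulationConfig(
    seed=42,
    species_tree="(A:0.05,B:0.05);",
    accessions_per_species={"A": 3, "B": 2},
    within_species_diversity={"A": 0.002, "B": 0.0},
    replicons=[Replicon("chr1", 10_000)],
    mean_depth=30.0, error_rate=0.005, dropout_rate=0.01,
)

reference = simulate_reference(config)
truth = evolve_panel(reference, config)
pileups = emit_pileups(truth, config)

print(f"reference: {len(reference['chr1'])} bp")
for acc in truth.accessions:
    i = truth.accessions.index(acc)
    divergent = (truth.true_alleles["chr1"][i] != reference["chr1"]).sum()
    print(f"{acc}: {len(pileups[acc])} pileup records, "
          f"{divergent} sites truly differ from the reference")
# Accessions of species A differ from the reference at ~jc_p(0.05)*10kb sites
# (plus a little within-species scatter); B accessions are identical clones.
exp = truth.per_species_expected_diversity
print(f"expected within-species pairwise difference rate: {exp}")
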