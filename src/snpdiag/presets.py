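"""Canonical panel configurations.

:func:`study_panel_config` builds the default simulated panel: twelve
diploid wheat-relative species (genome types A, Am, S, D, C, M, N, U and the
S-like Emarginata group) plus a single distant outgroup accession (the
barley analogue), with accession counts shaped like a real multi-archive
RNA-seq panel.  The nuclear topology places the Truncata-section S genome
basal within the ingroup, then the A+Am einkorn pair, then a split between
{U, (C, (M, N))} and {D + Emarginata S species}; the organellar tree moves
the D lineage out of its nuclear position, planting a cytonuclear
discordance of the kind reported for these species.

Branch lengths are expected substitutions per site.  Within-species
diversity is highest in the outcrossing S species and lowest in the
recently expanded U species; D carries three sublineages and Am two,
mirroring known intraspecific structure.
"""

from __future__ import annotations

from .simulate import Replicon, SimulationConfig

# ingroup topology (see module docstring); outgroup on a long branch
NUCLEAR_TREE = (
    "(barley:0.15,(speltoides:0.030,((urartu:0.022,monococcum:0.022):0.008,"
    "(((caudata:0.024,(comosa:0.020,uniaristata:0.020):0.006):0.004,"
    "umbellulata:0.026):0.004,"
    "(tauschii:0.022,(sharonensis:0.016,(longissima:0.015,"
    "(searsii:0.014,bicornis:0.014):0.004):0.004):0.008):0.006):0.006):0.005):0.04);"
)

# same species, D (tauschii) moved basal to the {U,C,M,N} + Emarginata clade
ORGANELLE_TREE = (
    "(barley:0.15,(speltoides:0.030,((urartu:0.022,monococcum:0.022):0.008,"
    "(tauschii:0.026,(((caudata:0.024,(comosa:0.020,uniaristata:0.020):0.006):0.004,"
    "umbellulata:0.026):0.004,"
    "(sharonensis:0.016,(longissima:0.015,"
    "(searsii:0.014,bicornis:0.014):0.004):0.004):0.010):0.004):0.006):0.005):0.04);"
)

ACCESSIONS = {
    "caudata": 9, "comosa": 3, "uniaristata": 3,
    "tauschii": 10, "umbellulata": 12,
    "speltoides": 4, "sharonensis": 3, "longissima": 6,
    "searsii": 3, "bicornis": 3,
    "urartu": 5, "monococcum": 10,
    "barley": 1,
}

GENOME_LABELS = {
    "caudata": "C", "comosa": "M", "uniaristata": "N",
    "tauschii": "D", "umbellulata": "U",
    "speltoides": "S", "sharonensis": "Ssh", "longissima": "Sl",
    "searsii": "Sse", "bicornis": "Sb",
    "urartu": "A", "monococcum": "Am",
    "barley": "H",
}

#: the Emarginata-section S-like species, grouped for unique-substitution calls
EMARGINATA_GROUP = ["sharonensis", "longissima", "searsii", "bicornis"]

DIVERSITY = {
    "speltoides": 0.004,   # outcrossing: highest diversity
    "caudata": 0.0025,
    "tauschii": 0.0015,
    "monococcum": 0.001,
    "umbellulata": 0.0004,  # star-like, recent expansion
    "comosa": 0.0008, "uniaristata": 0.0008,
    "sharonensis": 0.0008, "longissima": 0.0008,
    "searsii": 0.0008, "bicornis": 0.0008,
    "urartu": 0.0008,
    "barley": 0.0,
}

SUBLINEAGES = {
    "tauschii": (3, 0.003),    # three divergent sublineages
    "monococcum": (2, 0.002),  # two divergent groups
    "caudata": (2, 0.002),
}


def study_panel_config(
    seed: int = 0,
    nuclear_length: int = 50_000,
    organelle_length: int = 5_000,
) -> SimulationConfig:
    """The default study-shaped panel (72 accessions, 13 species)."""
    return SimulationConfig(
        seed=seed,
        species_tree=NUCLEAR_TREE,
        accessions_per_species=dict(ACCESSIONS),
        within_species_diversity=dict(DIVERSITY),
        sublineage_spec=dict(SUBLINEAGES),
        replicons=[
            Replicon("chr1", nuclear_length // 2, is_organelle=False),
            Replicon("chr2", nuclear_length - nuclear_length // 2, is_organelle=False),
            Replicon("chloroplast", organelle_length, is_organelle=True),
        ],
        organelle_tree=ORGANELLE_TREE,
        mean_depth=40.0,
        depth_dispersion=0.05,
        dropout_rate=0.01,
        error_rate=0.005,
        outgroup_alignable_fraction=0.7,
        outgroup_species="barley",
        deletion_rate=0.02,
    )


def study_panel(config=None, seed: int = 0):
    """Convenience: config → (config, panel, truth, pileups)."""
    from .simulate import emit_pileups, evolve_panel, simulate_reference

    if config is None:
        config = study_panel_config(seed=seed)
    ref = simulate_reference(config)
    truth = evolve_panel(ref, config)
    pileups = emit_pileups(truth, config)
    return config, config.panel(), truth, pileups
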