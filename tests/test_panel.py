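"""Genotype-matrix construction and polymorphic/fixed/unique classification."""

import numpy as np
import pandas as pd
import pytest

from snpdiag.calling import Status, call_accession
from snpdiag.errors import MissingInputError, UsageError
from snpdiag.panel import (GenotypeMatrix, SpeciesPanel, build_matrix,
                           fixed_snps, polymorphic_sites, unique_substitutions)
from snpdiag.simulate import emit_pileups, evolve_panel, simulate_reference

from oracles import fixed_oracle, matrix_oracle, polymorphic_oracle, unique_oracle

BASES = "ACGT"


def status_frame(rows):
    """rows: (replicon, pos, ref, status, allele_code)"""
    return pd.DataFrame(rows, columns=["replicon", "pos", "ref", "status", "allele"])


def two_acc_panel():
    return SpeciesPanel(["x", "y"], {"x": "spx", "y": "spy"})


class TestBuildMatrix:
    def test_low_depth_anywhere_excludes_the_site(self):
        statuses = {
            "x": status_frame([("chr1", 5, "A", int(Status.ALT_CALLED), 2)]),
            "y": status_frame([("chr1", 5, "A", int(Status.LOW_DEPTH), -1)]),
        }
        m = build_matrix(statuses, two_acc_panel())
        assert m.n_sites == 0

    def test_all_accessions_covered_site_retained_with_ref_fill(self):
        statuses = {
            "x": status_frame([("chr1", 5, "A", int(Status.ALT_CALLED), 2)]),
            "y": status_frame([("chr1", 5, "A", int(Status.REF_CONFIRMED), -1)]),
        }
        m = build_matrix(statuses, two_acc_panel())
        assert m.sites == [("chr1", 5, "A")]
        assert m.column("x")[0] == 2 and m.column("y")[0] == 0

    def test_missing_accession_table_raises(self):
        with pytest.raises(MissingInputError):
            build_matrix({"x": status_frame([])}, two_acc_panel())

    def test_shared_alt_site_is_retained_but_inert(self):
        """All accessions carrying the same alt stays in the matrix (variant
        vs reference) but is never polymorphic/fixed within the panel."""
        statuses = {
            "x": status_frame([("chr1", 9, "C", int(Status.ALT_CALLED), 3)]),
            "y": status_frame([("chr1", 9, "C", int(Status.ALT_CALLED), 3)]),
        }
        panel = two_acc_panel()
        m = build_matrix(statuses, panel)
        assert m.n_sites == 1
        assert polymorphic_sites(m, panel, "spx") == []  # singleton: warns, empty

    def test_noiseless_panel_recovers_truth_exactly(self, two_species_config):
        cfg = two_species_config
        ref = simulate_reference(cfg)
        truth = evolve_panel(ref, cfg)
        pileups = emit_pileups(truth, cfg)
        panel = cfg.panel()
        statuses = {a: call_accession(pileups[a], a)[1] for a in panel.accessions}
        m = build_matrix(statuses, panel)
        arr = truth.true_alleles["chr1"]
        variable = np.flatnonzero((arr != ref["chr1"]).any(axis=0))
        assert [s[1] for s in m.sites] == [int(p) + 1 for p in variable]
        for j, acc in enumerate(panel.accessions):
            i = truth.accessions.index(acc)
            assert np.array_equal(m.alleles[:, j], arr[i][variable])

    def test_noisy_panel_matches_brute_force_recomputation(self, rng):
        """Retained sites and cells equal the literal site-by-site oracle."""
        from snpdiag.simulate import Replicon, SimulationConfig

        cfg = SimulationConfig(
            seed=23, species_tree="(A:0.03,B:0.03);",
            accessions_per_species={"A": 2, "B": 2},
            within_species_diversity={"A": 0.002, "B": 0.001},
            replicons=[Replicon("chr1", 3000)],
            mean_depth=15.0, dropout_rate=0.05, error_rate=0.01,
        )
        truth = evolve_panel(simulate_reference(cfg), cfg)
        pileups = emit_pileups(truth, cfg)
        panel = cfg.panel()
        statuses = {a: call_accession(pileups[a], a)[1] for a in panel.accessions}
        m = build_matrix(statuses, panel)

        tables = {}
        for acc in panel.accessions:
            df = statuses[acc]
            tables[acc] = {
                (r, p): (Status(s).name, BASES[al] if al >= 0 else None, rf)
                for r, p, rf, s, al in df[
                    ["replicon", "pos", "ref", "status", "allele"]
                ].itertuples(index=False, name=None)
            }
        expected = matrix_oracle(tables, panel.accessions)
        assert {(s[0], s[1]) for s in m.sites} == set(expected)
        for i, site in enumerate(m.sites):
            for j, acc in enumerate(panel.accessions):
                assert BASES[m.alleles[i, j]] == expected[(site[0], site[1])][acc]


class TestClassification:
    def test_polymorphic_requires_two_alleles(self):
        panel = SpeciesPanel(["a1", "a2", "a3"], {k: "sp" for k in ("a1", "a2", "a3")})
        m = GenotypeMatrix([("chr1", 1, "A"), ("chr1", 2, "A")],
                           np.array([[3, 3, 1], [2, 2, 2]], dtype=np.uint8), ["a1", "a2", "a3"])
        sites = polymorphic_sites(m, panel, "sp")
        assert sites == [("chr1", 1, "A")]

    def test_fixed_snp_definition_and_symmetry(self):
        accs = ["a1", "a2", "b1", "b2"]
        panel = SpeciesPanel(accs, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        alleles = np.array([[3, 3, 1, 1],    # fixed T/C
                            [3, 1, 1, 1],    # A polymorphic
                            [2, 2, 2, 2]],   # invariant
                           dtype=np.uint8)
        m = GenotypeMatrix([("chr1", i + 1, "A") for i in range(3)], alleles, accs)
        fwd = fixed_snps(m, panel, "A", "B")
        rev = fixed_snps(m, panel, "B", "A")
        assert [r.site for r in fwd] == [("chr1", 1, "A")]
        assert fwd == rev
        assert fwd[0].alleles == {"A": "T", "B": "C"}
        with pytest.raises(UsageError):
            fixed_snps(m, panel, "A", "A")

    def test_unique_substitution_definition(self):
        accs = ["a1", "a2", "b1", "c1"]
        panel = SpeciesPanel(accs, {"a1": "A", "a2": "A", "b1": "B", "c1": "C"})
        alleles = np.array([[2, 2, 0, 0],    # A fixed G, others A -> unique to A
                            [2, 2, 0, 2]],   # C shares G -> not unique
                           dtype=np.uint8)
        m = GenotypeMatrix([("chr1", 1, "A"), ("chr1", 2, "A")], alleles, accs)
        recs = unique_substitutions(m, panel, "A")
        assert [(r.site[1], r.diagnostic_allele) for r in recs] == [(1, "G")]
        with pytest.raises(UsageError):
            unique_substitutions(m, panel, ["A", "B", "C"])

    def test_random_matrices_match_loop_oracles(self, rng):
        from conftest import random_matrix

        for trial in range(3):
            m, panel = random_matrix(rng, n_accessions=12, n_sites=400, n_species=4)
            by_acc = {a: [BASES[c] for c in m.column(a)] for a in m.accessions}
            species = panel.species_list
            for sp in species:
                got = {s[1] - 1 for s in polymorphic_sites(m, panel, sp)}
                assert got == set(polymorphic_oracle(by_acc, panel.accessions_of(sp)))
            for i, a in enumerate(species):
                for b in species[i + 1:]:
                    got = fixed_snps(m, panel, a, b)
                    exp = fixed_oracle(by_acc, panel.accessions_of(min(a, b)),
                                       panel.accessions_of(max(a, b)))
                    assert [(r.site[1] - 1, r.alleles[min(a, b)], r.alleles[max(a, b)])
                            for r in got] == exp
            for sp in species:
                others = [x for s2 in species if s2 != sp
                          for x in panel.accessions_of(s2)]
                got = unique_substitutions(m, panel, sp)
                exp = unique_oracle(by_acc, panel.accessions_of(sp), others)
                assert [(r.site[1] - 1, r.diagnostic_allele) for r in got] == exp

    def test_fixed_sites_are_polymorphic_in_neither_species(self, rng):
        from conftest import random_matrix

        m, panel = random_matrix(rng, n_accessions=10, n_sites=300, n_species=3)
        species = panel.species_list
        for i, a in enumerate(species):
            for b in species[i + 1:]:
                fixed = {r.site for r in fixed_snps(m, panel, a, b)}
                assert not fixed & set(polymorphic_sites(m, panel, a))
                assert not fixed & set(polymorphic_sites(m, panel, b))

    def test_biallelic_unique_sets_are_disjoint_across_groups(self, rng):
        from conftest import random_matrix

        m, panel = random_matrix(rng, n_accessions=9, n_sites=500, n_species=3)
        biallelic = {m.sites[i] for i in range(m.n_sites)
                     if len(np.unique(m.alleles[i])) == 2}
        owners: dict = {}
        for sp in panel.species_list:
            for r in unique_substitutions(m, panel, sp):
                if r.site in biallelic:
                    assert r.site not in owners, "two groups own one biallelic site"
                    owners[r.site] = sp

    def test_outgroup_excluded_from_unique_comparison(self):
        accs = ["a1", "b1", "o1"]
        panel = SpeciesPanel(accs, {"a1": "A", "b1": "B", "o1": "OUT"}, outgroup={"o1"})
        # outgroup shares A's allele; must not spoil uniqueness
        alleles = np.array([[2, 0, 2]], dtype=np.uint8)
        m = GenotypeMatrix([("chr1", 1, "A")], alleles, accs)
        recs = unique_substitutions(m, panel, "A")
        assert len(recs) == 1
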