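"""Synthetic multi-species accession panels with known truth.

The generator emulates the data structure of an RNA-seq-derived diploid
selfing panel: ~a dozen species diverged along a known species tree, a few
accessions per species hanging star-like off each species tip (optionally
partitioned into sublineages sharing an extra internal branch), one distant
outgroup with a reduced alignable fraction, a small unlinked organellar
replicon that may follow a discordant tree, and per-site pileup evidence
with Poisson / negative-binomial coverage, dropouts and per-read miscalls.

Sequence evolution is Jukes–Cantor: along a branch of length ``t`` expected
substitutions/site, each site changes with probability
``p = 3/4 * (1 - exp(-4t/3))`` to a uniformly chosen different base.  All
genotypes are homozygous by construction (selfing); heterozygous-looking
evidence can only arise from sequencing error.

Determinism: every random stage draws from generators spawned from the
config seed, so identical configs give bit-identical outputs regardless of
which stage runs first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd

from .calling import PILEUP_COLUMNS
from .errors import ConfigurationError, FormatError
from .panel import SpeciesPanel
from .util import BASES


@dataclass(frozen=True)
class Replicon:
    name: str
    length: int
    is_organelle: bool = False


@dataclass
class SimulationConfig:
    seed: int
    species_tree: str                       # newick, branch lengths in subst/site
    accessions_per_species: dict[str, int]
    within_species_diversity: dict[str, float] = field(default_factory=dict)
    sublineage_spec: dict[str, tuple[int, float]] | None = None
    replicons: list[Replicon] = field(default_factory=lambda: [Replicon("chr1", 10000)])
    organelle_tree: str | None = None
    mean_depth: float = 40.0
    depth_dispersion: float = 0.05
    dropout_rate: float = 0.01
    error_rate: float = 0.005
    outgroup_alignable_fraction: float = 1.0
    outgroup_species: str | None = None
    deletion_rate: float = 0.0              # deletions per unit branch length

    def validate(self) -> None:
        for name, p in [("dropout_rate", self.dropout_rate),
                        ("error_rate", self.error_rate),
                        ("outgroup_alignable_fraction", self.outgroup_alignable_fraction)]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ConfigurationError("depth_dispersion must be nonnegative")
        if self.deletion_rate < 0:
            raise ConfigurationError("deletion_rate must be nonnegative")
        for rep in self.replicons:
            if rep.length < 1:
                raise ConfigurationError(f"replicon {rep.name!r} length must be >= 1")
        for sp, t in self.within_species_diversity.items():
            if t < 0:
                raise ConfigurationError(f"negative terminal branch for {sp}")
        tree = parse_tree(self.species_tree)
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        if leaves != set(self.accessions_per_species):
            raise ConfigurationError(
                "accessions_per_species keys must exactly match species-tree leaves; "
                f"tree has {sorted(leaves)}, config has {sorted(self.accessions_per_species)}"
            )
        for sp, n in self.accessions_per_species.items():
            if n < 1:
                raise ConfigurationError(f"species {sp!r} needs >= 1 accession")
        if self.outgroup_species is not None and self.outgroup_species not in leaves:
            raise ConfigurationError(f"outgroup species {self.outgroup_species!r} not in tree")
        if self.organelle_tree is not None:
            ot = parse_tree(self.organelle_tree)
            oleaves = {lf.taxon.label for lf in ot.leaf_node_iter()}
            if oleaves != leaves:
                raise ConfigurationError("organelle tree must have the same leaf set")

    def accession_ids(self) -> list[str]:
        out = []
        for sp, n in self.accessions_per_species.items():
            out.extend(f"{sp}_{i+1:02d}" for i in range(n))
        return out

    def panel(self) -> SpeciesPanel:
        ids = self.accession_ids()
        species_of = {a: a.rsplit("_", 1)[0] for a in ids}
        outgroup = {a for a in ids if species_of[a] == self.outgroup_species}
        genome_of = {sp: sp for sp in self.accessions_per_species}
        return SpeciesPanel(ids, species_of, genome_of, outgroup)


@dataclass
class TruthSet:
    """Planted alleles plus the structures needed for recovery tests."""

    accessions: list[str]
    # replicon -> (length,) uint8 reference base codes
    reference: dict[str, np.ndarray]
    # replicon -> (n_accessions, length) uint8 base codes
    true_alleles: dict[str, np.ndarray]
    # replicon -> (n_accessions, length) bool, True where the lineage lost the site
    deletions: dict[str, np.ndarray]
    species_tree_used: dict[str, str]       # partition label -> newick
    per_species_expected_diversity: dict[str, float]
    config: SimulationConfig

    def allele(self, replicon: str, position: int, accession: str) -> str:
        i = self.accessions.index(accession)
        return BASES[self.true_alleles[replicon][i, position - 1]]


def parse_tree(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparseable newick: {exc}") from exc


def jc_p(t: float) -> float:
    """Jukes–Cantor probability that a site differs after branch length t."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _rngs(config: SimulationConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(3)
    return {k: np.random.default_rng(s)
            for k, s in zip(("reference", "evolve", "pileup"), children)}


def simulate_reference(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Uniform-random base codes per replicon, reproducible under the seed."""
    config.validate()
    rng = _rngs(config)["reference"]
    return {rep.name: rng.integers(0, 4, size=rep.length, dtype=np.uint8)
            for rep in config.replicons}


def _mutate(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """JC substitution of one sequence along a branch of length t."""
    if t == 0:
        return seq.copy()
    hit = rng.random(seq.shape[0]) < jc_p(t)
    out = seq.copy()
    # uniform among the three other bases: add 1..3 mod 4
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)) % 4
    return out


def _delete(dele: np.ndarray, t: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate == 0 or t == 0:
        return dele.copy()
    p = 1.0 - math.exp(-rate * t)
    return dele | (rng.random(dele.shape[0]) < p)


def _expected_diversity(config: SimulationConfig, species: str) -> float:
    """Expected pairwise differing fraction per site for a random pair."""
    n = config.accessions_per_species[species]
    if n < 2:
        return 0.0
    t = config.within_species_diversity.get(species, 0.0)
    sub = (config.sublineage_spec or {}).get(species)
    if not sub or sub[0] <= 1:
        return jc_p(2 * t)
    k, ts = sub
    groups = [len(range(i, n, k)) for i in range(k)]  # round-robin assignment
    same = sum(g * (g - 1) // 2 for g in groups)
    total = n * (n - 1) // 2
    return (same * jc_p(2 * t) + (total - same) * jc_p(2 * (t + ts))) / total


def evolve_panel(reference: dict[str, np.ndarray], config: SimulationConfig) -> TruthSet:
    """Evolve accession sequences from the reference along the configured trees.

    The reference sequence is placed at the root; each tree edge applies JC
    substitution (and optional site loss at ``deletion_rate`` per unit
    branch length, absorbing).  Species tips fan out into accessions via a
    star (or sublineage-partitioned) topology with the configured terminal
    branch lengths.  Organelle replicons follow ``organelle_tree`` when
    given, else the species tree.
    """
    config.validate()
    rng = _rngs(config)["evolve"]
    accessions = config.accession_ids()
    acc_index = {a: i for i, a in enumerate(accessions)}
    sub_spec = config.sublineage_spec or {}

    true_alleles: dict[str, np.ndarray] = {}
    deletions: dict[str, np.ndarray] = {}
    for rep in config.replicons:
        use_organelle = rep.is_organelle and config.organelle_tree is not None
        newick = config.organelle_tree if use_organelle else config.species_tree
        tree = parse_tree(newick)
        L = rep.length
        alleles = np.empty((len(accessions), L), dtype=np.uint8)
        dels = np.zeros((len(accessions), L), dtype=bool)

        root_seq = reference[rep.name]
        root_del = np.zeros(L, dtype=bool)

        def descend(node, seq, dele):
            for child in node.child_nodes():
                t = child.edge.length or 0.0
                cseq = _mutate(seq, t, rng)
                cdel = _delete(dele, t, config.deletion_rate, rng)
                if child.is_leaf():
                    _expand_species(child.taxon.label, cseq, cdel)
                else:
                    descend(child, cseq, cdel)

        def _expand_species(species, seq, dele):
            n = config.accessions_per_species[species]
            t_term = config.within_species_diversity.get(species, 0.0)
            sub = sub_spec.get(species)
            ids = [f"{species}_{i+1:02d}" for i in range(n)]
            if sub and sub[0] > 1 and n > 1:
                k, ts = sub
                anc = [(_mutate(seq, ts, rng), _delete(dele, ts, config.deletion_rate, rng))
                       for _ in range(k)]
                assign = [i % k for i in range(n)]  # round-robin
            else:
                anc = [(seq, dele)]
                assign = [0] * n
            for acc, g in zip(ids, assign):
                aseq = _mutate(anc[g][0], t_term, rng)
                adel = _delete(anc[g][1], t_term, config.deletion_rate, rng)
                alleles[acc_index[acc]] = aseq
                dels[acc_index[acc]] = adel

        descend(tree.seed_node, root_seq, root_del)
        true_alleles[rep.name] = alleles
        deletions[rep.name] = dels

    expected = {sp: _expected_diversity(config, sp)
                for sp, n in config.accessions_per_species.items() if n >= 2}
    trees_used = {"nuclear": config.species_tree,
                  "organelle": config.organelle_tree or config.species_tree}
    return TruthSet(accessions, reference, true_alleles, deletions,
                    trees_used, expected, config)


def emit_pileups(truth: TruthSet, config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Per-accession pileup-summary tables from the planted truth.

    Depth is Poisson(mean_depth) when ``depth_dispersion == 0``, otherwise
    negative binomial with variance ``mu * (1 + dispersion * mu)``.  A
    site×accession drops out (no record) with probability ``dropout_rate``;
    outgroup accessions additionally lose each site with probability
    ``1 - outgroup_alignable_fraction`` (unalignable in a distant taxon).
    Each read reports the true base with probability ``1 - error_rate``,
    else one of the three other bases uniformly.  Zero-depth sites emit no
    record.
    """
    config.validate()
    rng = _rngs(config)["pileup"]
    panel = config.panel()
    out: dict[str, pd.DataFrame] = {}
    for acc in truth.accessions:
        frames = []
        is_outgroup = acc in panel.outgroup
        for rep in config.replicons:
            L = rep.length
            i = truth.accessions.index(acc)
            alleles = truth.true_alleles[rep.name][i]
            deleted = truth.deletions[rep.name][i]

            if config.depth_dispersion == 0:
                depth = rng.poisson(config.mean_depth, size=L)
            else:
                nparam = 1.0 / config.depth_dispersion
                p = nparam / (nparam + config.mean_depth)
                depth = rng.negative_binomial(nparam, p, size=L)
            keep = rng.random(L) >= config.dropout_rate
            if is_outgroup:
                keep &= rng.random(L) < config.outgroup_alignable_fraction
            keep &= depth > 0
            idx = np.flatnonzero(keep)
            d = depth[idx].astype(np.int64)

            counts = np.zeros((len(idx), 4), dtype=np.int64)
            ndel = np.zeros(len(idx), dtype=np.int64)
            site_deleted = deleted[idx]
            ndel[site_deleted] = d[site_deleted]

            obs = np.flatnonzero(~site_deleted)
            if len(obs):
                errs = rng.binomial(d[obs], config.error_rate)
                true_b = alleles[idx][obs]
                counts[obs, true_b] = d[obs] - errs
                has_err = errs > 0
                if has_err.any():
                    spread = rng.multinomial(errs[has_err], [1 / 3] * 3)
                    rows = obs[has_err]
                    others = (true_b[has_err][:, None] + np.arange(1, 4)[None, :]) % 4
                    for k in range(3):
                        counts[rows, others[:, k]] += spread[:, k]

            ref_bases = np.array(list(BASES))[truth.reference[rep.name][idx]]
            df = pd.DataFrame({
                "replicon": rep.name,
                "pos": idx + 1,
                "ref": ref_bases,
                "nA": counts[:, 0], "nC": counts[:, 1],
                "nG": counts[:, 2], "nT": counts[:, 3],
                "nN": 0, "nDel": ndel, "nIns": 0,
            })
            frames.append(df)
        out[acc] = pd.concat(frames, ignore_index=True)[PILEUP_COLUMNS]
    return out
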