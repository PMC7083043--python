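"""End-to-end driver: simulation (or file input) → calling → genotype
matrices per partition → classification → diversity → NJ trees with
bootstrap → cytonuclear congruence → CAPS candidates.

Every stage writes deterministic text artifacts into the output directory;
the machine-readable ``run_log.json`` records the thresholds, seeds and
package versions actually applied.  Two runs with the same config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from . import __version__
from .calling import MIN_ALT_FRACTION, MIN_DEPTH, call_accession
from .caps import design_caps_markers, load_enzymes
from .errors import ConfigurationError, RootingError, StageError, UsageError
from .panel import (GenotypeMatrix, SpeciesPanel, build_matrix, fixed_snps,
                    polymorphic_sites, unique_substitutions)
from .phylo import (bootstrap_support, collapse_to_species, compare_trees,
                    diversity_summary, diversity_table, pairwise_differences,
                    root_at_outgroup)
from .simulate import SimulationConfig, emit_pileups, evolve_panel, simulate_reference


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``simulation`` is given (self-contained synthetic run) or the
    three input paths are; thresholds default to the published criteria
    (depth >= 10, allele fraction strictly > 0.95), bootstrap to 1000
    replicates.
    """

    simulation: SimulationConfig | None = None
    reference_path: str | None = None
    manifest_path: str | None = None
    pileup_dir: str | None = None
    partition_of: dict[str, str] | None = None   # replicon -> nuclear|organelle
    min_depth: int = MIN_DEPTH
    min_alt_fraction: float = MIN_ALT_FRACTION
    n_bootstrap: int = 1000
    seed: int = 0
    unique_targets: list = field(default_factory=list)   # species or groups; [] = all ingroup species
    caps_pair: tuple[str, str] | None = None
    caps_flank: int = 50
    caps_amplicon_size: int = 500
    caps_enzyme_table: str | None = None

    def validate(self) -> None:
        if self.simulation is None:
            missing = [n for n, v in [("reference_path", self.reference_path),
                                      ("manifest_path", self.manifest_path),
                                      ("pileup_dir", self.pileup_dir)] if v is None]
            if missing:
                raise ConfigurationError(
                    f"either 'simulation' or input paths required; missing {missing}")
        if self.min_depth < 1:
            raise ConfigurationError("min_depth must be >= 1")
        if not 0 < self.min_alt_fraction <= 1:
            raise ConfigurationError("min_alt_fraction must be in (0, 1]")
        if self.n_bootstrap < 1:
            raise ConfigurationError("n_bootstrap must be >= 1")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("inputs")
def _acquire_inputs(config: PipelineConfig, outdir: Path):
    if config.simulation is not None:
        sim = config.simulation
        reference = simulate_reference(sim)
        truth = evolve_panel(reference, sim)
        pileups = emit_pileups(truth, sim)
        panel = sim.panel()
        partition_of = {r.name: ("organelle" if r.is_organelle else "nuclear")
                        for r in sim.replicons}
        sio.write_fasta(outdir / "reference.fasta", reference)
        sio.write_manifest(outdir / "manifest.tsv", panel)
        pdir = outdir / "pileups"
        pdir.mkdir(exist_ok=True)
        for acc, df in pileups.items():
            sio.write_pileup_summary(pdir / f"{acc}.pileup.tsv", df)
        sio.write_truth_tsv(outdir / "truth_alleles.tsv", truth)
    else:
        reference = sio.read_fasta(config.reference_path)
        panel = sio.read_manifest(config.manifest_path)
        pdir = Path(config.pileup_dir)
        pileups = {a: sio.read_pileup_summary(pdir / f"{a}.pileup.tsv")
                   for a in panel.accessions}
        partition_of = config.partition_of or {r: "nuclear" for r in reference}
        truth = None
    return reference, panel, pileups, partition_of, truth


@_stage("calling")
def _call_all(config: PipelineConfig, panel, pileups, reference, outdir: Path):
    cdir = outdir / "calls"
    cdir.mkdir(exist_ok=True)
    contigs = {name: len(seq) for name, seq in reference.items()}
    statuses, summaries = {}, []
    for acc in panel.accessions:
        calls, status, summary = call_accession(
            pileups[acc], acc, config.min_depth, config.min_alt_fraction)
        statuses[acc] = status
        summaries.append(summary)
        sio.write_vcf_calls(cdir / f"{acc}.vcf", calls, contigs)
        status.to_csv(cdir / f"{acc}.status.tsv", sep="\t", index=False)
    pd.DataFrame(summaries).to_csv(outdir / "call_summaries.tsv", sep="\t", index=False)
    return statuses, summaries


@_stage("matrix")
def _build_matrices(statuses, panel, partition_of, reference, outdir: Path):
    contigs = {name: len(seq) for name, seq in reference.items()}
    matrices = {}
    for part in ("nuclear", "organelle"):
        reps = sorted(r for r, p in partition_of.items() if p == part)
        if not reps:
            continue
        sub = {acc: df[df["replicon"].isin(reps)] for acc, df in statuses.items()}
        m = build_matrix(sub, panel, partition_label=part, replicon_order=reps)
        matrices[part] = m
        sio.write_matrix_vcf(outdir / f"matrix.{part}.vcf", m,
                             {r: contigs[r] for r in reps})
        sio.write_matrix_tsv(outdir / f"matrix.{part}.tsv", m)
        sio.snp_density_table(m).to_csv(outdir / f"snp_density.{part}.tsv",
                                        sep="\t", index=False)
    return matrices


@_stage("classify")
def _classify(config: PipelineConfig, matrices, panel, outdir: Path):
    m = matrices.get("nuclear")
    results = {"polymorphic": {}, "fixed": {}, "unique": {}}
    if m is None or m.n_sites == 0:
        return results
    rows = []
    for sp in panel.ingroup_species:
        if len(panel.accessions_of(sp)) < 2:
            continue
        sites = polymorphic_sites(m, panel, sp)
        results["polymorphic"][sp] = sites
        rows.extend((sp, *s) for s in sites)
    pd.DataFrame(rows, columns=["species", "replicon", "pos", "ref"]).to_csv(
        outdir / "polymorphic_sites.tsv", sep="\t", index=False)

    ingroup = panel.ingroup_species
    frows = []
    for i, a in enumerate(ingroup):
        for b in ingroup[i + 1:]:
            recs = fixed_snps(m, panel, a, b)
            results["fixed"][tuple(sorted((a, b)))] = recs
            frows.extend((a, b, *r.site, r.alleles[min(a, b)], r.alleles[max(a, b)])
                         for r in recs)
    pd.DataFrame(frows, columns=["species_a", "species_b", "replicon", "pos",
                                 "ref", "allele_a", "allele_b"]).to_csv(
        outdir / "fixed_snps.tsv", sep="\t", index=False)

    targets = config.unique_targets or list(ingroup)
    urows = []
    for tgt in targets:
        recs = unique_substitutions(m, panel, tgt)
        key = tgt if isinstance(tgt, str) else "+".join(tgt)
        results["unique"][key] = recs
        urows.extend((key, *r.site, r.diagnostic_allele) for r in recs)
    udf = pd.DataFrame(urows, columns=["group", "replicon", "pos", "ref", "allele"])
    udf.to_csv(outdir / "unique_substitutions.tsv", sep="\t", index=False)
    sio.write_bed(outdir / "unique_substitutions.bed",
                  [(r, p, f) for _, r, p, f, _ in udf.itertuples(index=False, name=None)])
    return results


@_stage("diversity")
def _diversity(matrices, panel, outdir: Path):
    m = matrices.get("nuclear")
    if m is None or m.n_sites == 0:
        return None
    dist = pairwise_differences(m)
    sio.write_phylip_distances(outdir / "distances.nuclear.phylip", dist)
    dist.to_dataframe().to_csv(outdir / "distances.nuclear.tsv", sep="\t")
    summaries = diversity_summary(dist, panel)
    diversity_table(summaries).to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    pairs = [(s.species, v) for s in summaries for v in s.values]
    pd.DataFrame(pairs, columns=["species", "pairwise_differences"]).to_csv(
        outdir / "diversity_pairs.tsv", sep="\t", index=False)
    return summaries


@_stage("trees")
def _trees(config: PipelineConfig, matrices, panel, outdir: Path, log: dict):
    trees = {}
    for part, m in matrices.items():
        if m.n_sites == 0 or len(m.accessions) < 3:
            continue
        tree = bootstrap_support(m, n_replicates=config.n_bootstrap, seed=config.seed)
        trees[part] = tree
        out_tree = tree
        if panel.outgroup:
            try:
                out_tree = root_at_outgroup(tree, panel.outgroup)
            except RootingError as exc:
                log.setdefault("rooting_warnings", {})[part] = str(exc)
        sio.write_newick(outdir / f"tree.{part}.nwk", out_tree)
    return trees


@_stage("compare")
def _compare(trees, panel, outdir: Path):
    if "nuclear" not in trees or "organelle" not in trees:
        return None
    report = compare_trees(trees["nuclear"], trees["organelle"], panel)
    payload = {
        "rf_distance": report.rf_distance,
        "congruent": report.congruent,
        "splits_only_in_nuclear": [sorted(s) for s in report.splits_only_in_first],
        "splits_only_in_organelle": [sorted(s) for s in report.splits_only_in_second],
        "monophyly": {sp: {"nuclear": a, "organelle": b}
                      for sp, (a, b) in report.monophyly.items()},
        "misplaced_species": report.misplaced_species,
    }
    # species-level congruence (one leaf per species) abstracts away
    # within-species noise; only possible if every species is monophyletic
    try:
        sp_report = compare_trees(collapse_to_species(trees["nuclear"], panel),
                                  collapse_to_species(trees["organelle"], panel))
        payload["species_level"] = {
            "rf_distance": sp_report.rf_distance,
            "splits_only_in_nuclear": [sorted(s) for s in sp_report.splits_only_in_first],
            "splits_only_in_organelle": [sorted(s) for s in sp_report.splits_only_in_second],
        }
        report.species_level = sp_report
    except UsageError as exc:
        payload["species_level"] = {"error": str(exc)}
        report.species_level = None
    sio.write_json(outdir / "congruence.json", payload)
    return report


@_stage("caps")
def _caps(config: PipelineConfig, classify_results, reference, outdir: Path):
    if config.caps_pair is None:
        return []
    pair = tuple(sorted(config.caps_pair))
    recs = classify_results["fixed"].get(pair, [])
    enzymes = load_enzymes(config.caps_enzyme_table)
    candidates = design_caps_markers(recs, reference, enzymes,
                                     flank=config.caps_flank,
                                     amplicon_size=config.caps_amplicon_size)
    rows = []
    for c in candidates:
        rep, pos, ref = c.fixed_snp.site
        win = c.amplicon_window
        frag_txt = ";".join(f"{b}:{','.join(map(str, f))}" for b, f in c.fragments.items())
        rows.append((rep, pos, ref, c.enzyme.name, c.cut_in_species, c.cut_allele,
                     win[1], win[2], frag_txt))
    pd.DataFrame(rows, columns=["replicon", "pos", "ref", "enzyme", "cut_in_species",
                                "cut_allele", "window_start", "window_end",
                                "fragments"]).to_csv(
        outdir / "caps_candidates.tsv", sep="\t", index=False)
    sio.write_caps_gff3(outdir / "caps_candidates.gff3", candidates)
    return candidates


@dataclass
class RunReport:
    outdir: Path
    panel: SpeciesPanel
    matrices: dict[str, GenotypeMatrix]
    call_summaries: list[dict]
    classify: dict
    diversity: list | None
    trees: dict
    congruence: object | None
    caps_candidates: list
    log: dict


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Execute all stages and write the full artifact bundle into ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "min_depth": config.min_depth,
        "min_alt_fraction": config.min_alt_fraction,
        "n_bootstrap": config.n_bootstrap,
        "seed": config.seed,
        "simulated": config.simulation is not None,
    }
    if config.simulation is not None:
        log["simulation_seed"] = config.simulation.seed

    reference, panel, pileups, partition_of, truth = _acquire_inputs(config, outdir)
    statuses, summaries = _call_all(config, panel, pileups, reference, outdir)
    matrices = _build_matrices(statuses, panel, partition_of, reference, outdir)
    classify_results = _classify(config, matrices, panel, outdir)
    diversity = _diversity(matrices, panel, outdir)
    trees = _trees(config, matrices, panel, outdir, log)
    congruence = _compare(trees, panel, outdir)
    caps_candidates = _caps(config, classify_results, reference, outdir)

    log["n_sites_matrix"] = {p: m.n_sites for p, m in matrices.items()}
    log["n_caps_candidates"] = len(caps_candidates)
    sio.write_json(outdir / "run_log.json", log)
    return RunReport(outdir, panel, matrices, summaries, classify_results,
                     diversity, trees, congruence, caps_candidates, log)
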