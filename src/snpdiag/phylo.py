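"""Pairwise-difference distances, diversity summaries, neighbor-joining
trees with column bootstrap, outgroup rooting and tree congruence.

Distances are raw counts of differing genotype-matrix sites (Hamming over
matrix rows) by default, matching the semantics of "number of pairwise
nucleotide differences between accessions"; an optional Jukes–Cantor
correction is available but off by default.

Neighbor joining is the classic agglomerative algorithm: repeatedly
join the pair (i, j) minimising

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with branch lengths from the standard three-point formulas, negative
lengths clamped to zero, and ties broken lexicographically by the smallest
leaf label contained in each cluster — so results are reproducible and
invariant to input order.  NJ recovers the true topology exactly on
additive distance matrices.

Bootstrap support resamples matrix columns (sites) with replacement,
rebuilds the NJ tree per replicate, and annotates each internal edge of the
point-estimate tree with the percentage of replicates containing the same
leaf bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import DataError, RootingError, UsageError
from .panel import GenotypeMatrix, SpeciesPanel


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    normalized: bool = False    # True if per-site rates rather than counts

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataError("distance matrix shape does not match labels")

    def validate(self) -> None:
        v = self.values
        if np.isnan(v).any():
            raise DataError("NaN in distance matrix")
        if not np.allclose(v, v.T):
            raise DataError("distance matrix is not symmetric")
        if (np.diag(v) != 0).any() or (v < 0).any():
            raise DataError("distances must be nonnegative with zero diagonal")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def site_mismatch_tensor(matrix: GenotypeMatrix) -> np.ndarray:
    """(n_sites, n_acc, n_acc) boolean tensor of per-site disagreements."""
    a = matrix.alleles
    return a[:, :, None] != a[:, None, :]


def pairwise_differences(
    matrix: GenotypeMatrix,
    per_site: bool = False,
    jc_correction: bool = False,
) -> DistanceMatrix:
    """Count (or rate of) sites at which each accession pair differs."""
    if matrix.n_sites == 0:
        raise UsageError("empty genotype matrix")
    d = site_mismatch_tensor(matrix).sum(axis=0).astype(float)
    normalized = per_site or jc_correction
    if normalized:
        p = d / matrix.n_sites
        if jc_correction:
            arg = 1.0 - 4.0 * p / 3.0
            if (arg <= 0).any():
                raise DataError("pairwise difference too large for JC correction")
            p = -0.75 * np.log(arg)
        d = p
    return DistanceMatrix(list(matrix.accessions), d, normalized=normalized)


# ---------------------------------------------------------------------------
# diversity summaries

@dataclass
class SpeciesDiversity:
    species: str
    n_accessions: int
    values: list[float]          # all within-species pairwise differences
    median: float
    min: float
    max: float
    multimodal: bool             # large gap in the sorted values


def _gap_flag(values: list[float]) -> bool:
    """Evidence of discrete sublineages: one inter-value gap dominating the
    spread (largest consecutive gap > half the range)."""
    if len(values) < 3:
        return False
    v = sorted(values)
    rng = v[-1] - v[0]
    if rng == 0:
        return False
    gaps = np.diff(v)
    return bool(gaps.max() > 0.5 * rng)


def diversity_summary(dist: DistanceMatrix, panel: SpeciesPanel) -> list[SpeciesDiversity]:
    """Within-species pairwise-difference summaries, outgroup excluded.

    Species with fewer than two accessions in the matrix are skipped with a
    warning (their diversity is undefined).
    """
    import warnings

    out = []
    idx = {a: i for i, a in enumerate(dist.labels)}
    for sp in panel.ingroup_species:
        accs = [a for a in panel.accessions_of(sp) if a in idx]
        if len(accs) < 2:
            warnings.warn(f"species {sp!r} has < 2 accessions; skipped", stacklevel=2)
            continue
        vals = [float(dist.values[idx[a], idx[b]])
                for i, a in enumerate(accs) for b in accs[i + 1:]]
        out.append(SpeciesDiversity(
            sp, len(accs), vals,
            float(np.median(vals)), float(min(vals)), float(max(vals)),
            _gap_flag(vals),
        ))
    return out


def diversity_table(summaries: list[SpeciesDiversity]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.species, s.n_accessions, len(s.values), s.median, s.min, s.max, s.multimodal)
         for s in summaries],
        columns=["species", "n_accessions", "n_pairs", "median", "min", "max", "multimodal"],
    )


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Among all pairs minimising Q, the pair whose (sorted) representative
    labels — the lexicographically smallest leaf in each cluster — compare
    lowest is joined first.  Negative branch lengths are clamped to zero.
    Returns an unrooted dendropy tree (trifurcating seed node for n >= 3).
    """
    dist.validate()
    labels = list(dist.labels)
    n = len(labels)
    if n < 3:
        raise UsageError("neighbor joining needs >= 3 labels")

    tns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lb)) for lb in labels]
    reps = list(labels)                     # representative label per cluster
    d = dist.values.astype(float).copy()
    active = list(range(n))

    def join(i: int, j: int, li: float, lj: float) -> None:
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(0.0, li)
        nodes[j].edge.length = max(0.0, lj)
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-9 * max(1.0, abs(qmin))))
        best = min(
            ((a, b) for a, b in ties if a < b),
            key=lambda ab: tuple(sorted((reps[active[ab[0]]], reps[active[ab[1]]]))),
        )
        ai, aj = active[best[0]], active[best[1]]
        dij = d[ai, aj]
        li = 0.5 * dij + (r[best[0]] - r[best[1]]) / (2 * (m - 2))
        lj = dij - li
        # distances from the new node to all remaining clusters
        for k in active:
            if k in (ai, aj):
                continue
            d[ai, k] = d[k, ai] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        join(ai, aj, li, lj)
        active.remove(aj)

    a, b, c = active
    # three-point formulas for the final star
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    seed = dendropy.Node()
    for i, ln in zip((a, b, c), (la, lb, lc)):
        seed.add_child(nodes[i])
        nodes[i].edge.length = max(0.0, ln)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = seed
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap

def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial leaf bipartitions, canonicalised to the side *not*
    containing the lexicographically smallest leaf label."""
    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(
    matrix: GenotypeMatrix,
    n_replicates: int = 1000,
    seed: int | None = None,
    jc_correction: bool = False,
) -> dendropy.Tree:
    """Point-estimate NJ tree with column-bootstrap support percentages.

    Matrix columns (sites) are resampled with replacement ``n_replicates``
    times; each internal edge of the point tree is labelled with the
    percentage of replicate NJ trees containing the same bipartition.
    Support is stored on ``node.label`` (and ``node.support``).
    """
    if n_replicates < 1:
        raise UsageError("n_replicates must be >= 1")
    dist = pairwise_differences(matrix, jc_correction=jc_correction)
    tree = nj_tree(dist)
    all_leaves = leaf_labels(tree)
    anchor = min(all_leaves)

    S = matrix.n_sites
    n_acc = len(matrix.accessions)
    mism = site_mismatch_tensor(matrix).astype(np.uint8).reshape(S, n_acc * n_acc)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        take = rng.integers(0, S, size=S)
        w = np.bincount(take, minlength=S).astype(np.float64)
        dboot = (w @ mism).reshape(n_acc, n_acc)
        np.fill_diagonal(dboot, 0.0)
        rep_tree = nj_tree(DistanceMatrix(list(matrix.accessions), dboot))
        for bp in tree_bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1

    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if not (2 <= len(side) <= len(all_leaves) - 2):
            continue
        support = 100.0 * counts.get(side, 0) / n_replicates
        node.support = support
        node.label = f"{support:g}"
    return tree


# ---------------------------------------------------------------------------
# rooting and congruence

def root_at_outgroup(tree: dendropy.Tree, outgroup: set[str] | list[str]) -> dendropy.Tree:
    """Root on the edge separating the outgroup from the ingroup.

    The outgroup accession set must form one side of an edge of the
    unrooted tree (monophyly); otherwise a :class:`RootingError` lists the
    observed bipartitions for diagnosis.
    """
    og = set(outgroup)
    tree = tree.clone(depth=1)
    all_leaves = leaf_labels(tree)
    missing = og - all_leaves
    if missing:
        raise RootingError(f"outgroup leaves absent from tree: {sorted(missing)}")
    if og == all_leaves:
        raise RootingError("outgroup cannot cover every leaf")

    target = None
    if len(og) == 1:
        (lab,) = og
        target = next(lf for lf in tree.leaf_node_iter() if lf.taxon.label == lab)
    else:
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if side == og or side == all_leaves - og:
                target = node
                break
    if target is None:
        splits = sorted(tuple(sorted(bp)) for bp in tree_bipartitions(tree))
        raise RootingError(
            f"outgroup {sorted(og)} is not monophyletic; observed bipartitions: {splits}"
        )
    elen = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=elen / 2, length2=elen / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


@dataclass
class CongruenceReport:
    """Robinson–Foulds congruence between two trees on their shared leaves."""

    shared_leaves: list[str]
    rf_distance: int
    splits_only_in_first: list[frozenset[str]]
    splits_only_in_second: list[frozenset[str]]
    # species -> (monophyletic in tree1, monophyletic in tree2); multi-accession only
    monophyly: dict[str, tuple[bool, bool]] = field(default_factory=dict)
    # species whose removal alone reconciles the two trees (RF -> 0)
    misplaced_species: list[str] = field(default_factory=list)
    # optional nested report on species-collapsed trees (pipeline fills this)
    species_level: "CongruenceReport | None" = None

    @property
    def congruent(self) -> bool:
        return self.rf_distance == 0


def _restrict(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    t = tree.clone(depth=1)
    t.retain_taxa_with_labels(sorted(keep))
    return t


def _is_monophyletic(bips: set[frozenset[str]], group: frozenset[str],
                     all_leaves: frozenset[str]) -> bool:
    if len(group) <= 1 or len(all_leaves - group) <= 1:
        return True
    anchor = min(all_leaves)
    canon = group if anchor not in group else all_leaves - group
    return canon in bips


def compare_trees(
    tree1: dendropy.Tree,
    tree2: dendropy.Tree,
    panel: SpeciesPanel | None = None,
) -> CongruenceReport:
    """Robinson–Foulds distance, conflicting splits, per-species monophyly
    and single-species discordance diagnosis.

    Comparison is restricted to the shared leaf set.  When a ``panel`` is
    given, each multi-accession species is tested for monophyly in both
    trees, and every species whose removal (all its accessions) brings the
    RF distance to zero is flagged as *misplaced* — a moved lineage, the
    signature of cytonuclear discordance.
    """
    l1, l2 = leaf_labels(tree1), leaf_labels(tree2)
    shared = l1 & l2
    if not shared:
        raise UsageError("trees share no leaves")
    t1 = _restrict(tree1, shared) if shared != l1 else tree1
    t2 = _restrict(tree2, shared) if shared != l2 else tree2
    b1, b2 = tree_bipartitions(t1), tree_bipartitions(t2)
    only1 = sorted(b1 - b2, key=lambda s: (len(s), sorted(s)))
    only2 = sorted(b2 - b1, key=lambda s: (len(s), sorted(s)))
    report = CongruenceReport(sorted(shared), len(only1) + len(only2), only1, only2)

    if panel is not None:
        fs = frozenset(shared)
        for sp in panel.species_list:
            accs = frozenset(a for a in panel.accessions_of(sp) if a in shared)
            if len(accs) >= 2:
                report.monophyly[sp] = (
                    _is_monophyletic(b1, accs, fs),
                    _is_monophyletic(b2, accs, fs),
                )
        if report.rf_distance > 0:
            for sp in panel.species_list:
                accs = {a for a in panel.accessions_of(sp) if a in shared}
                rest = shared - accs
                if len(rest) < 4 or not accs:
                    continue
                r1, r2 = _restrict(t1, rest), _restrict(t2, rest)
                if tree_bipartitions(r1) == tree_bipartitions(r2):
                    report.misplaced_species.append(sp)
    return report


# ---------------------------------------------------------------------------
# species-level helpers

def collapse_to_species(tree: dendropy.Tree, panel: SpeciesPanel) -> dendropy.Tree:
    """Collapse an accession-level tree to one leaf per species.

    Requires every multi-accession species to be monophyletic on the tree;
    keeps the first accession of each species and renames it to the species
    id.  Raises :class:`UsageError` if a species is not monophyletic.
    """
    all_leaves = leaf_labels(tree)
    bips = tree_bipartitions(tree)
    keep = {}
    for sp in panel.species_list:
        accs = [a for a in panel.accessions_of(sp) if a in all_leaves]
        if not accs:
            continue
        if not _is_monophyletic(bips, frozenset(accs), frozenset(all_leaves)):
            raise UsageError(f"species {sp!r} is not monophyletic; cannot collapse")
        keep[accs[0]] = sp
    t = _restrict(tree, set(keep))
    # fresh Taxon objects: clone(depth=1) shares taxa with the source tree,
    # so renaming in place would corrupt the caller's tree
    tns = dendropy.TaxonNamespace()
    for lf in t.leaf_node_iter():
        lf.taxon = tns.new_taxon(keep[lf.taxon.label])
    t.taxon_namespace = tns
    return t


def induced_accession_bipartitions(
    species_tree: dendropy.Tree, panel: SpeciesPanel
) -> set[frozenset[str]]:
    """Map each nontrivial species-tree split to the accession-level split."""
    sp_bips = tree_bipartitions(species_tree)
    all_accs = frozenset(panel.accessions)
    anchor = min(all_accs)
    out = set()
    for bp in sp_bips:
        accs = frozenset(a for sp in bp for a in panel.accessions_of(sp))
        if anchor in accs:
            accs = all_accs - accs
        if 2 <= len(accs) <= len(all_accs) - 2:
            out.add(accs)
    return out


def jc_expected_difference(t: float) -> float:
    """Expected differing fraction of sites after total path length t (JC)."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
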