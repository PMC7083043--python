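"""Independent brute-force reference implementations used only by tests.

Each oracle restates the scientific rule in the most literal possible form
(loops, Fractions, exhaustive scans) with no code shared with the package.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

BASES = "ACGT"


# ---------------------------------------------------------------------------
# calling

def call_oracle(ref_base, nA, nC, nG, nT, nN, nDel, min_depth=10, frac=Fraction(95, 100)):
    """Literal re-statement: depth >= 10 and one allele alone strictly over
    95% of all reads spanning the site.  Returns (status, allele)."""
    counts = {"A": nA, "C": nC, "G": nG, "T": nT}
    depth = nA + nC + nG + nT + nN + nDel
    if depth < min_depth:
        return "LOW_DEPTH", None
    for base, c in counts.items():
        if Fraction(c, depth) > frac:
            if base == ref_base:
                return "REF_CONFIRMED", None
            return "ALT_CALLED", base
    if Fraction(nDel, depth) > frac:
        return "DEL_CALLED", None
    return "AMBIGUOUS", None


# ---------------------------------------------------------------------------
# matrix & classification

def matrix_oracle(status_tables, accessions):
    """Recompute retained sites and alleles by scanning dicts site by site.

    ``status_tables``: accession -> {(replicon, pos): (status, allele, ref)}.
    Returns {(replicon, pos): {accession: base}} for retained sites.
    """
    candidates = {}
    for acc in accessions:
        for key, (status, allele, ref) in status_tables[acc].items():
            if status == "ALT_CALLED":
                candidates[key] = ref
    out = {}
    for key, ref in candidates.items():
        row = {}
        ok = True
        for acc in accessions:
            st = status_tables[acc].get(key)
            if st is None or st[0] not in ("REF_CONFIRMED", "ALT_CALLED"):
                ok = False
                break
            row[acc] = st[1] if st[0] == "ALT_CALLED" else ref
        if ok:
            out[key] = row
    return out


def polymorphic_oracle(alleles_by_acc, accessions):
    """Double loop: any pair of accessions differing at a site."""
    n_sites = len(next(iter(alleles_by_acc.values())))
    hits = []
    for s in range(n_sites):
        poly = False
        for i, a in enumerate(accessions):
            for b in accessions[i + 1:]:
                if alleles_by_acc[a][s] != alleles_by_acc[b][s]:
                    poly = True
        if poly:
            hits.append(s)
    return hits


def fixed_oracle(alleles_by_acc, accs_a, accs_b):
    """Triple loop over sites x both species' accession sets."""
    n_sites = len(next(iter(alleles_by_acc.values())))
    hits = []
    for s in range(n_sites):
        va = {alleles_by_acc[a][s] for a in accs_a}
        vb = {alleles_by_acc[b][s] for b in accs_b}
        if len(va) == 1 and len(vb) == 1 and va != vb:
            hits.append((s, next(iter(va)), next(iter(vb))))
    return hits


def unique_oracle(alleles_by_acc, group_accs, other_accs):
    n_sites = len(next(iter(alleles_by_acc.values())))
    hits = []
    for s in range(n_sites):
        vg = {alleles_by_acc[a][s] for a in group_accs}
        if len(vg) != 1:
            continue
        allele = next(iter(vg))
        if all(alleles_by_acc[o][s] != allele for o in other_accs):
            hits.append((s, allele))
    return hits


# ---------------------------------------------------------------------------
# distances and trees

def pairwise_oracle(alleles_by_acc, accessions):
    n = len(accessions)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = sum(
                1 for x, y in zip(alleles_by_acc[accessions[i]],
                                  alleles_by_acc[accessions[j]]) if x != y
            )
    return d


def random_additive_matrix(n_leaves, rng):
    """Random binary tree with positive branch lengths -> leaf labels,
    path-distance matrix, and the set of nontrivial bipartitions."""
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    nodes = [(lbl, frozenset([lbl])) for lbl in labels]
    children: dict[int, list] = {}
    leafsets = {}
    idx = list(range(n_leaves))
    tree_nodes = {i: nodes[i] for i in idx}
    next_id = n_leaves
    edge_len = {}
    parent = {}
    while len(idx) > 1:
        i, j = sorted(rng.choice(len(idx), size=2, replace=False))
        a, b = idx[i], idx[j]
        children[next_id] = [a, b]
        parent[a] = parent[b] = next_id
        edge_len[a] = rng.uniform(0.1, 2.0)
        edge_len[b] = rng.uniform(0.1, 2.0)
        idx = [x for x in idx if x not in (a, b)] + [next_id]
        next_id += 1
    root = idx[0]

    def leaves_under(v):
        if v < n_leaves:
            return frozenset([labels[v]])
        return frozenset().union(*(leaves_under(c) for c in children[v]))

    # distances via root paths
    def depth_path(v):
        path = []
        while v in parent:
            path.append(v)
            v = parent[v]
        return path

    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            pi, pj = depth_path(i), depth_path(j)
            shared = set(pi) & set(pj)
            dist = sum(edge_len[v] for v in pi if v not in shared)
            dist += sum(edge_len[v] for v in pj if v not in shared)
            d[i, j] = d[j, i] = dist

    all_l = frozenset(labels)
    anchor = min(labels)
    bips = set()
    for v in children:
        side = leaves_under(v)
        if anchor in side:
            side = all_l - side
        if 2 <= len(side) <= n_leaves - 2:
            bips.add(side)
    return labels, d, bips


def newick_bipartitions_oracle(newick: str):
    """Nontrivial bipartitions by bracket matching on the newick string,
    independent of any tree library."""
    import re

    leaves = set(re.findall(r"[(,]([A-Za-z0-9_.+-]+)", newick))
    anchor = min(leaves)
    bips = set()
    stack = []
    token = ""
    groups = []
    for ch in newick:
        if ch == "(":
            stack.append(set())
        elif ch in ",);":
            if token:
                name = token.split(":")[0]
                if name and stack:
                    for s in stack:
                        s.add(name)
                token = ""
            if ch == ")":
                groups.append(frozenset(stack.pop()))
        else:
            token += ch
    for g in groups:
        side = g if anchor not in g else frozenset(leaves - g)
        if 2 <= len(side) <= len(leaves) - 2:
            bips.add(side)
    return bips


# ---------------------------------------------------------------------------
# CAPS

def iupac_match(pattern, text):
    table = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
             "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
             "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}
    return len(pattern) == len(text) and all(t in table[p] for p, t in zip(pattern, text))


def revcomp(s):
    return s.translate(str.maketrans("ACGTRYKMBVDHSWN", "TGCAYRMKVBHDSWN"))[::-1]


def caps_oracle(sequence, snp_pos0, allele_a, allele_b, enzymes):
    """Sliding-window scan: for each enzyme, does a recognition match
    overlapping the SNP exist in exactly one allele-substituted sequence?"""
    def has_overlap(seq, enz_site):
        L = len(enz_site)
        pats = {enz_site, revcomp(enz_site)}
        for start in range(max(0, snp_pos0 - L + 1), min(len(seq) - L, snp_pos0) + 1):
            window = seq[start:start + L]
            if any(iupac_match(p, window) for p in pats):
                return True
        return False

    seq_a = sequence[:snp_pos0] + allele_a + sequence[snp_pos0 + 1:]
    seq_b = sequence[:snp_pos0] + allele_b + sequence[snp_pos0 + 1:]
    hits = []
    for name, site in enzymes:
        ina, inb = has_overlap(seq_a, site), has_overlap(seq_b, site)
        if ina != inb:
            hits.append((name, "A" if ina else "B"))
    return hits
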