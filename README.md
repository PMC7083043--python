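# snpdiag

Comparative-genomics workbench for panels of selfing diploid species typed
by transcriptome-derived pileup evidence: homozygous SNP calling, a
missing-data-free cross-species genotype matrix, diagnostic-site
classification (polymorphic / fixed / genome-unique), pairwise-difference
diversity, neighbor-joining phylogenies with bootstrap for nuclear and
organellar partitions, cytonuclear-discordance detection, and conversion of
fixed SNPs into CAPS (cleaved amplified polymorphic sequence) restriction
markers.

The motivating setting is the diploid wheat-relative panels (genome types
A, A^m, S, D, C, M, N, U) where species are nearly completely homozygous
selfers, so a single-allele genotype per accession is the right model and
heterozygous-looking pileup evidence indicates sequencing error or RNA
editing rather than true heterozygosity. The package also ships a
synthetic-panel generator with known truth, so every analysis step can be
tested as a recovery problem.

## The rules at the core

**Calling.** An accession's site is scored from its pileup counts
(n_A, n_C, n_G, n_T, n_N, n_del). With depth d = ΣA..T + n_N + n_del, a
homozygous variant is called iff

    d ≥ 10   and   n_b / d > 0.95  for a single non-reference base b,

with the 95% comparison strict and evaluated in exact rational arithmetic
(19/20 fails). The same rule applied to the reference base yields
REF_CONFIRMED; everything else at d ≥ 10 is AMBIGUOUS and poisons the site.

**Matrix.** The non-redundant SNP set is the union of per-accession SNP
positions, retaining a site only when *every* accession is REF_CONFIRMED or
homozygous-ALT there — the resulting sites × accessions matrix has no
missing entries.

**Classification.** A site is *polymorphic* within a species if its
accessions carry ≥ 2 alleles; *fixed* between species X and Y if both are
monomorphic with different alleles; *unique* to a species (or group) if the
group is monomorphic for an allele absent from all other ingroup species.

**Distances and trees.** d(i,j) counts matrix sites where accessions i and
j differ (Hamming; optional Jukes–Cantor correction). Trees are classic
Saitou–Nei neighbor joining — iteratively join the pair minimising
Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k) — with lexicographic
tie-breaking, exact on additive matrices. Support comes from resampling
matrix columns with replacement (default 1000 replicates) and counting
recurrence of each bipartition. Congruence between nuclear and organelle
trees is reported as Robinson–Foulds distance, conflicting bipartitions,
per-species monophyly, and a leave-one-out diagnosis of moved lineages.

**CAPS design.** A fixed SNP becomes a marker candidate when a restriction
recognition site (IUPAC-aware, both strands) overlapping the SNP exists in
exactly one allele; candidates get a symmetric amplicon window and in-silico
digestion patterns per allele.

## A worked example

`examples/03_matrix_and_classification.py` simulates three species (3
accessions each, 20 kb, noiseless coverage) and prints:

```
non-redundant SNP matrix: 1809 sites x 9 accessions (no missing cells)
polymorphic within M: 59 sites
polymorphic within N: 64 sites
polymorphic within C: 133 sites
fixed SNPs between M and N: 794  (monomorphic in each species, different alleles between them)
unique substitutions diagnostic for M: 412
unique substitutions diagnostic for N: 408
unique substitutions diagnostic for C: 795
```

C was simulated with twice the within-species diversity of M and N (hence
more polymorphic sites) and sits on a longer branch (hence more unique
substitutions). `examples/06_caps_markers.py` then turns a fixed SNP inside
a GA[A/G]TTC context into an EcoRI CAPS marker:

```
EcoRI: cuts only the genomeM allele (A); amplicon chr1:9753-10252
  allele A: fragments [248, 252] (sum 500 bp)
  allele G: fragments [500] (sum 500 bp)
```

The other examples cover simulation (01), the calling thresholds (02),
bootstrap phylogenies with outgroup rooting (04), diversity summaries with
sublineage-gap detection (05), and the one-call full pipeline (07). A thin
CLI mirrors the stages: `snpdiag simulate | call | matrix | classify |
diversity | tree | compare | caps | run-all`.

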