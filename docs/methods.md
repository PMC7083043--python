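# Methods

This note documents the models, rules and numerical choices behind
`snpdiag`, in the order data flows through the package.

## Scope and assumptions

The workbench targets panels of *selfing diploid* species typed against a
single reference: genotypes are effectively homozygous, so each accession
carries one allele per site and any balanced mixed pileup is treated as
noise (sequencing error, misalignment, or RNA-editing artifacts on
organellar transcripts), never as heterozygosity. Nuclear and organellar
replicons run through the identical code path as separate partitions; the
organelle is unlinked and may follow a different topology, which is exactly
the signal the congruence stage is designed to expose. Maximum-likelihood
tree estimation is out of scope: neighbor joining is the single estimator,
chosen because it is deterministic, exact on additive inputs, and fast
enough to bootstrap thousands of times.

## Variant calling

A site×accession is scored from pileup counts. Definitions:

- depth `d = nA + nC + nG + nT + nN + nDel` — every read spanning the site,
  including ambiguous (N) and deletion-spanning reads. Using the full
  spanning depth in the denominator is the conservative choice: N and
  deletion reads count as evidence *against* a clean homozygous call.
- a base call requires `d ≥ min_depth` (default 10) and
  `n_b / d > min_alt_fraction` (default 0.95, **strict**) for a single base
  b. The threshold is held as an exact rational, so 19/20 = 95% never
  passes through float rounding. If b is the reference the status is
  REF_CONFIRMED, otherwise a homozygous SNP call.
- deletions are presence/absence events judged by the same rule applied to
  `nDel`; insertion observations ride on top of base-reporting reads, so
  insertion calls use `nIns / d` against the same denominator but do not
  determine the site status (an insertion can coexist with REF_CONFIRMED).
  Indel length and sequence are not modelled — downstream analysis only
  counts indels and excludes them from the matrix.
- everything else at sufficient depth is AMBIGUOUS. Because two alleles
  cannot both exceed 95% of one denominator, every call is homozygous by
  construction; a site where two alleles each exceed ~5% can never be
  called (the RNA-editing guard).
- multi-allelic evidence resolves the same way: a call requires one allele
  alone above the threshold, otherwise AMBIGUOUS.

Coordinates are 1-based inclusive everywhere (VCF convention); BED output
is the only 0-based half-open surface, converted in one documented helper.

## The non-redundant genotype matrix

Candidate sites are the union of homozygous SNP positions across
accessions. A candidate is retained iff **every** panel accession has
status REF_CONFIRMED or ALT_CALLED there; absence of a pileup record counts
as LOW_DEPTH and excludes the site. This is the strictest reading of
"unambiguous and covered in all accessions", applied symmetrically to the
reference-species accessions (their REF_CONFIRMED statuses supply their
alleles). Sites where all accessions share the same non-reference allele
are retained — they are variants against the reference — but are inert for
within-panel classification. Indel-called positions never enter the matrix.

Classification on the matrix: *polymorphic* (≥ 2 alleles within a species;
defined empty with a warning for singleton species), *fixed* (both species
monomorphic, alleles differ; symmetric in its arguments), *unique* (group
monomorphic, allele absent from every other ingroup species). Outgroup
accessions are excluded from classification and diversity; their only role
is rooting.

## Distances, diversity, trees

Distances are raw pairwise mismatch counts over matrix sites — the natural
axis for "number of pairwise nucleotide differences" — with optional
per-site normalisation and Jukes–Cantor correction (off by default; the
intended use applies no correction, and at within-species scales the
correction is negligible anyway).

Diversity summaries report, per multi-accession species, all within-species
pairwise values with median/min/max and a *multimodality flag*: the largest
gap between consecutive sorted values exceeding half the range. This is a
deliberately crude detector; it reliably flags discrete sublineages of the
kind planted by the simulator but is not a mixture test.

Neighbor joining follows Saitou–Nei exactly: join the pair minimising
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`, branch lengths
`l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2))`, distance update
`d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2`, final three clusters resolved by
the three-point formulas. Determinism: Q-ties are broken by the
lexicographically smallest pair of cluster representatives (the smallest
leaf label each cluster contains), so results are independent of input
order. Negative branch lengths are clamped to zero. Trees are unrooted
(trifurcating seed) until outgroup rooting, which requires the outgroup to
be monophyletic and splits its edge at the midpoint.

Bootstrap support resamples matrix columns with replacement, rebuilds the
NJ tree per replicate, and annotates each internal edge of the point tree
with the percentage of replicates containing the same bipartition. The
default 1000 replicates matches standard practice for these panels; a
precomputed per-site mismatch tensor makes each replicate a single matrix
product plus one NJ run.

Congruence between two trees (shared leaves only) reports the
Robinson–Foulds distance, the conflicting bipartitions on each side,
per-species monophyly, and *misplaced species*: any species whose removal
(all accessions) brings RF to zero. The leave-one-out diagnosis identifies
a single moved lineage exactly; with several moved lineages or residual
noise it reports none, by design — it is a certificate, not a heuristic
score. Species-level comparison (collapsing each monophyletic species to
one leaf) abstracts away within-species noise and is what the pipeline
reports alongside the accession-level numbers.

## CAPS marker design

An enzyme is diagnostic for a fixed SNP iff a recognition-site match
*overlapping the SNP position* exists in exactly one of the two
allele-substituted sequences. The overlap requirement is what guarantees
the digestion difference is caused by the diagnostic allele — a gained or
lost site elsewhere in the amplicon would segregate independently.
Matching is IUPAC-degenerate on both strands; palindromic recognition
sequences are searched once. In-silico digestion cuts at every match using
the top-strand cut offset and returns fragment lengths that always sum to
the sequence length. Amplicon selection takes a symmetric window (default
500 bp) around the SNP, trims at replicon edges, and discards candidates
whose two allele digests are identical within the window. The packaged
enzyme table holds twelve common 4–6-cutters (EcoRI, HindIII, BamHI, XbaI,
EcoRV, TaqI, MseI, AluI, HaeIII, RsaI, DdeI, HinfI); any table with the
same TSV columns can be substituted. Primer thermodynamics are out of
scope — window selection stands in for primer design.

## The synthetic panel generator

The generator produces the data structure the analysis assumes, not a
biological forward simulation:

- **Reference**: uniform random A/C/G/T per replicon.
- **Substitution model**: Jukes–Cantor only. Along a branch of length `t`
  (expected substitutions/site) each site mutates with probability
  `p = 3/4·(1 − e^{−4t/3})` to a uniform different base. The analysis
  never assumes more than JC, so a richer model would add parameters
  without adding test power.
- **Within-species structure**: accessions hang star-like off the species
  tip with a per-species terminal branch length; optional sublineages
  insert a shared internal branch (round-robin assignment of accessions to
  groups). This mirrors reported divergent-group patterns without a
  coalescent.
- **Deletions**: per-site, per-branch absorbing loss at a configurable
  rate per unit branch length; a deleted site emits pure
  deletion-observation pileups. Insertions are not simulated (the caller
  supports them; the matrix uses neither).
- **Coverage**: Poisson(mean_depth) when `depth_dispersion = 0`, else
  negative binomial with variance `μ(1 + αμ)`. A site×accession drops out
  (no record) with probability `dropout_rate`; outgroup accessions lose
  each site with probability `1 − outgroup_alignable_fraction`, emulating
  the reduced alignable fraction of a distant taxon.
- **Errors**: each read reports the true base with probability
  `1 − error_rate`, otherwise a uniform different base. All genotypes are
  homozygous (selfing); apparent heterozygosity arises only from error.
- **Determinism**: reference, evolution and pileup stages draw from
  generators spawned from the one config seed, so identical configs give
  bit-identical output regardless of call order.

The default study-shaped panel (`snpdiag.presets`) has 13 species — twelve
ingroup diploids plus one distant outgroup accession — with accession
counts (9, 3, 3, 10, 12, 4, 3, 6, 3, 3, 5, 10, 1) shaped like a real
multi-archive panel, nuclear topology with the Truncata-section S genome
basal in the ingroup, the A+A^m einkorn pair next, then
{U, (C, (M, N))} against {D + Emarginata S clade}, and an organelle tree
with the D lineage moved — a planted cytonuclear discordance. Terminal
diversities put the outcrossing S species highest (0.004 substitutions per
site of terminal branch) and the recently expanded U species lowest
(0.0004); D carries three sublineages, A^m and C two each. Noise defaults:
mean depth 40, dispersion 0.05, dropout 0.01, error 0.005, outgroup
alignable fraction 0.7. These are artifact choices — the emulated study
reports no generative model — chosen once to give realistic retention
(roughly a third of variable sites survive the all-accession rule on the
72-accession panel) and held fixed.

What the generator does **not** emulate: read-level artifacts (mapping
bias, spliced-alignment edge effects, base-quality structure),
recombination, gene flow, paralogy, and expression-dependent coverage.
Passing recovery tests therefore demonstrates correctness of the
*analysis logic* under the stated statistical structure, not robustness to
every failure mode of real RNA-seq.

## Problem sizes in the test-suite and acceptance script

Simulated problem sizes are chosen as the smallest that make each recovery
statement statistically sharp: 50–60 kb of nuclear sequence for exact
matrix/truth equality and species-tree recovery (thousands of retained
SNPs; internal branches ≥ 0.004 then carry ≥ 90% of 200-replicate
bootstrap support), 20 kb × 20 replicates for the diversity-ordering
study, 10 kb with 50 planted sites for CAPS recall, and 10⁴ randomized
sites for calling-oracle equivalence. The acceptance script runs the full
72-accession panel at 40 kb + 5 kb with 1000 bootstrap replicates.

## Known limitations

- The leave-one-out discordance certificate is silent when organelle
  signal is weak; the species-level conflicting-split list is then the
  informative output (short internal branches can add minor extra
  conflicts beyond a planted move, as seen in real chloroplast panels).
- NJ on non-additive (noisy) distances has no optimality guarantee; the
  bootstrap quantifies the resulting uncertainty.
- The pileup converter for classic `samtools mpileup` text handles the
  common token set (`. , ^ $ * +n/-n` runs) but not extended BAQ/overlap
  annotations.
- CAPS candidates are screened by recognition-site logic only; no
  primer-design or PCR-efficiency screening is attempted.
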