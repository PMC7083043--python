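"""Turning a fixed SNP into a CAPS marker.

A fixed SNP sits in a would-be EcoRI site (GA[A/G]TTC): the A allele
completes the recognition sequence, the G allele destroys it, so a PCR
amplicon spanning the SNP digests in one genome and stays intact in the
other — a gel-scorable genome-diagnostic marker.
"""

import numpy as np

from snpdiag import FixedSnpRecord, diagnostic_sites, load_enzymes, select_amplicon_window
from snpdiag.util import encode_seq

rng = np.random.default_rng(0)
codes = rng.integers(0, 4, size=20_000, dtype=np.uint8)
codes[9_999:10_005] = encode_seq("GAATTC")   # EcoRI site at positions 10000-10005
reference = {"chr1": codes}

fixed = FixedSnpRecord(
    site=("chr1", 10_002, "A"),                      # third base of the site
    species_pair=("genomeM", "genomeN"),
    allele_of=(("genomeM", "A"), ("genomeN", "G")),
)

enzymes = load_enzymes()
print(f"enzyme panel: {', '.join(e.name for e in enzymes)}")

for cand in diagnostic_sites(fixed, reference, enzymes, flank=30):
    final = select_amplicon_window(cand, reference, amplicon_size=500)
    if final is None:
        continue
    rep, start, end = final.amplicon_window
    print(f"\n{cand.enzyme.name}: cuts only the {cand.cut_in_species} allele "
          f"({cand.cut_allele}); amplicon {rep}:{start}-{end}")
    for allele, frags in final.fragments.items():
        print(f"  allele {allele}: fragments {list(frags)} (sum {sum(frags)} bp)")
# The two alleles give different fragment patterns on a gel; fragment
# lengths always add up to the amplicon length.
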