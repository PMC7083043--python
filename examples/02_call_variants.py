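"""Homozygous SNP calling and its exact thresholds.

A site is called only with read depth >= 10 and one allele strictly above
95% of the reads spanning the site — so 19 alt reads out of 20 (exactly
95%) is rejected, and heterozygous-looking evidence is never called.
"""

from snpdiag import PileupSite, call_site, classify_site_status

cases = [
    ("10/10 alt reads", PileupSite("chr1", 100, "C", (0, 0, 0, 10, 0))),
    ("19/20 alt reads (exactly 95%)", PileupSite("chr1", 101, "C", (0, 1, 0, 19, 0))),
    ("9/9 alt reads (depth below 10)", PileupSite("chr1", 102, "C", (0, 0, 0, 9, 0))),
    ("15 ref + 15 alt (het-like)", PileupSite("chr1", 103, "A", (15, 0, 15, 0, 0))),
    ("30/30 reference reads", PileupSite("chr1", 104, "A", (30, 0, 0, 0, 0))),
    ("20 deletion-spanning reads", PileupSite("chr1", 105, "A", (0, 0, 0, 0, 0), 20)),
]

for label, site in cases:
    call = call_site(site)
    status = classify_site_status(site)
    verdict = f"{call.alt_allele} ({call.variant_class})" if call else "no call"
    print(f"{label:36s} -> status {status.status.name:13s} call: {verdict}")
# Only unambiguous homozygous evidence produces calls; everything else is
# LOW_DEPTH (discarded) or AMBIGUOUS (blocks the site panel-wide).
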