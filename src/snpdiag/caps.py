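"""CAPS (cleaved amplified polymorphic sequence) marker design from fixed SNPs.

A fixed SNP becomes a CAPS marker when one of the two species' alleles
creates a restriction-enzyme recognition site that the other allele lacks:
a PCR amplicon spanning the SNP then digests differently between genomes
and the difference is scored on a gel.  Only recognition-site matches that
*overlap the SNP position* qualify — a gained or lost site elsewhere in the
window cannot be caused by the diagnostic allele, so the overlap rule
guarantees allele-specific digestion.

Recognition sequences may use IUPAC degeneracy codes; matching is performed
on both strands (palindromic sites are searched once).  The built-in panel
(``data/enzymes.tsv``) holds twelve common 4–6-cutters with their top/bottom
strand cut offsets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .panel import FixedSnpRecord
from .util import decode_seq, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: degenerate recognition sequence and cut offsets.

    ``cut_top`` is the number of bases 3' of the recognition-site start
    (top strand) after which the top strand is cut; ``cut_bottom`` is the
    analogous offset for the bottom strand measured on the top-strand
    coordinate.  EcoRI (G^AATTC) is ``cut_top=1, cut_bottom=5``.
    """

    name: str
    recognition: str
    cut_top: int
    cut_bottom: int

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise DataError(f"{self.name}: recognition sequence must be >= 4 bp")
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise DataError(f"{self.name}: invalid IUPAC letters {sorted(bad)}")
        if not (0 <= self.cut_top <= len(self.recognition)):
            raise DataError(f"{self.name}: cut_top outside recognition site")
        if not (0 <= self.cut_bottom <= len(self.recognition)):
            raise DataError(f"{self.name}: cut_bottom outside recognition site")

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition.upper()) == self.recognition.upper()


def load_enzymes(path=None) -> list[EnzymeSpec]:
    """Load an enzyme table TSV (columns: name, recognition, cut_top,
    cut_bottom); defaults to the packaged twelve-enzyme panel."""
    if path is None:
        src = resources.files("snpdiag.data").joinpath("enzymes.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [EnzymeSpec(r.name, r.recognition.upper(), int(r.cut_top), int(r.cut_bottom))
            for r in df.itertuples(index=False)]


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(
        c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in pattern.upper()
    ))


def find_recognition_sites(seq: str, enzyme: EnzymeSpec) -> list[tuple[int, str]]:
    """All (0-based start, strand) recognition matches in ``seq``.

    Both strands are searched (a bottom-strand site reported at its
    top-strand interval); overlapping matches are found with a lookahead.
    Palindromic enzymes yield each site once, on strand '+'.
    """
    seq = seq.upper()
    hits: list[tuple[int, str]] = []
    fwd = re.compile(f"(?=({_iupac_regex(enzyme.recognition).pattern}))")
    hits.extend((m.start(), "+") for m in fwd.finditer(seq))
    if not enzyme.is_palindromic:
        rc = re.compile(f"(?=({_iupac_regex(revcomp(enzyme.recognition)).pattern}))")
        hits.extend((m.start(), "-") for m in rc.finditer(seq))
    return sorted(hits)


def in_silico_digest(seq: str, enzyme: EnzymeSpec) -> list[int]:
    """Fragment lengths after complete digestion.

    Cuts at every recognition match (both strands); fragment boundaries
    follow the top-strand cut position.  Fragment lengths always sum to the
    input length.  Ambiguous (non-ACGT) bases in the input are rejected.
    """
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise DataError("in_silico_digest requires an unambiguous ACGT sequence")
    cuts = set()
    for start, strand in find_recognition_sites(seq, enzyme):
        off = enzyme.cut_top if strand == "+" else enzyme.site_length - enzyme.cut_bottom
        pos = start + off
        if 0 < pos < len(seq):
            cuts.add(pos)
    edges = [0, *sorted(cuts), len(seq)]
    return [b - a for a, b in zip(edges, edges[1:]) if b > a]


@dataclass(frozen=True)
class CapsCandidate:
    """A fixed SNP whose alleles digest differently with one enzyme."""

    fixed_snp: FixedSnpRecord
    enzyme: EnzymeSpec
    cut_in_species: str                 # species whose allele carries the site
    cut_allele: str
    amplicon_window: tuple[str, int, int] | None = None   # 1-based inclusive
    fragments_by_allele: tuple[tuple[str, tuple[int, ...]], ...] | None = None

    @property
    def fragments(self) -> dict[str, tuple[int, ...]]:
        return dict(self.fragments_by_allele or ())


def _window_seq(reference: dict[str, np.ndarray], replicon: str,
                start: int, end: int) -> str:
    """1-based inclusive slice of a reference replicon as a string."""
    codes = reference[replicon]
    return decode_seq(codes[start - 1:end])


def _substitute(seq: str, offset: int, base: str) -> str:
    return seq[:offset] + base + seq[offset + 1:]


def diagnostic_sites(
    fixed: FixedSnpRecord,
    reference: dict[str, np.ndarray],
    enzymes: list[EnzymeSpec],
    flank: int = 50,
) -> list[CapsCandidate]:
    """Enzymes whose recognition site overlapping the SNP exists in exactly
    one allele.

    For each enzyme, both allele-substituted local sequences (SNP ± flank,
    trimmed at replicon edges) are scanned on both strands; a candidate is
    reported iff at least one recognition match covering the SNP position
    exists in one allele and none in the other.
    """
    replicon, pos, _ref = fixed.site
    L = len(reference[replicon])
    if not 1 <= pos <= L:
        raise DataError(f"SNP position {pos} outside replicon {replicon!r}")
    max_site = max(e.site_length for e in enzymes)
    if flank < max_site:
        raise UsageError(f"flank must be >= longest recognition site ({max_site})")
    start = max(1, pos - flank)
    end = min(L, pos + flank)
    window = _window_seq(reference, replicon, start, end)
    snp_off = pos - start

    (sp_a, base_a), (sp_b, base_b) = fixed.allele_of
    seq_a = _substitute(window, snp_off, base_a)
    seq_b = _substitute(window, snp_off, base_b)

    out = []
    for enz in enzymes:
        def overlapping(seq):
            return any(s <= snp_off < s + enz.site_length
                       for s, _ in find_recognition_sites(seq, enz))
        in_a, in_b = overlapping(seq_a), overlapping(seq_b)
        if in_a != in_b:
            sp, allele = (sp_a, base_a) if in_a else (sp_b, base_b)
            out.append(CapsCandidate(fixed, enz, sp, allele))
    return out


def select_amplicon_window(
    candidate: CapsCandidate,
    reference: dict[str, np.ndarray],
    amplicon_size: int = 500,
) -> CapsCandidate | None:
    """Attach a symmetric amplicon window and per-allele digest predictions.

    The window is centred on the SNP (size ``amplicon_size``, trimmed at
    replicon edges).  Candidates whose two allele digests are identical
    within the window are discarded (returns ``None``), as are windows too
    short to contain two recognition sites.
    """
    replicon, pos, _ref = candidate.fixed_snp.site
    L = len(reference[replicon])
    half = amplicon_size // 2
    start = max(1, pos - (amplicon_size - half) + 1)
    end = min(L, pos + half)
    if end - start + 1 < 2 * candidate.enzyme.site_length:
        return None
    window = _window_seq(reference, replicon, start, end)
    off = pos - start

    frags = {}
    for _sp, base in candidate.fixed_snp.allele_of:
        frags[base] = tuple(in_silico_digest(_substitute(window, off, base),
                                             candidate.enzyme))
    vals = list(frags.values())
    if sorted(vals[0]) == sorted(vals[1]):
        return None
    return replace(
        candidate,
        amplicon_window=(replicon, start, end),
        fragments_by_allele=tuple((b, f) for b, f in frags.items()),
    )


def design_caps_markers(
    fixed_records: list[FixedSnpRecord],
    reference: dict[str, np.ndarray],
    enzymes: list[EnzymeSpec] | None = None,
    flank: int = 50,
    amplicon_size: int = 500,
) -> list[CapsCandidate]:
    """End-to-end CAPS design: diagnostic-site scan then window selection."""
    if enzymes is None:
        enzymes = load_enzymes()
    out = []
    for fx in fixed_records:
        for cand in diagnostic_sites(fx, reference, enzymes, flank=flank):
            final = select_amplicon_window(cand, reference, amplicon_size)
            if final is not None:
                out.append(final)
    return out
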