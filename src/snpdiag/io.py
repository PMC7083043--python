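"""Readers and writers for every on-disk surface of the workbench.

Conventions: internal and VCF coordinates are 1-based inclusive; BED is the
only 0-based half-open format and all conversions pass through
:func:`snpdiag.util.to_bed_interval`.  All writers are deterministic (no
timestamps), so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import PILEUP_COLUMNS, VariantCall
from .errors import FormatError
from .panel import GenotypeMatrix, SpeciesPanel
from .util import BASES, decode_seq, encode_seq, to_bed_interval


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path, reference: dict[str, np.ndarray | str]) -> None:
    records = []
    for name, seq in reference.items():
        s = seq if isinstance(seq, str) else decode_seq(seq)
        records.append(SeqRecord(Seq(s), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, np.ndarray]:
    return {rec.id: encode_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# panel manifest

MANIFEST_COLUMNS = ["accession_id", "species_id", "genome_label", "is_outgroup"]


def write_manifest(path, panel: SpeciesPanel) -> None:
    rows = [
        (a, panel.species_of[a],
         panel.genome_of.get(panel.species_of[a], panel.species_of[a]),
         int(a in panel.outgroup))
        for a in panel.accessions
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> SpeciesPanel:
    df = pd.read_csv(path, sep="\t", dtype={"is_outgroup": int})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns {sorted(missing)}", str(path))
    return SpeciesPanel(
        accessions=list(df["accession_id"]),
        species_of=dict(zip(df["accession_id"], df["species_id"])),
        genome_of=dict(zip(df["species_id"], df["genome_label"])),
        outgroup={a for a, o in zip(df["accession_id"], df["is_outgroup"]) if o},
    )


# ---------------------------------------------------------------------------
# pileup summary TSV

def write_pileup_summary(path, pileup: pd.DataFrame) -> None:
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pileup_summary(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse pileup summary: {exc}", str(path)) from exc
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"pileup summary missing columns {sorted(missing)}", str(path))
    counts = df[PILEUP_COLUMNS[3:]].to_numpy()
    bad = np.flatnonzero((counts < 0).any(axis=1))
    if len(bad):
        # +2: header line plus 1-based line numbering
        raise FormatError("negative read count", str(path), int(bad[0]) + 2)
    if (df["pos"] < 1).any():
        line = int(np.flatnonzero((df["pos"] < 1).to_numpy())[0]) + 2
        raise FormatError("position must be >= 1", str(path), line)
    return df


def pileup_from_samtools(path, reference: dict[str, np.ndarray]) -> pd.DataFrame:
    """Convert classic ``samtools mpileup`` text output to the summary table.

    Handles read-start (``^`` + mapping quality), read-end (``$``),
    indel length runs (``+n``/``-n`` followed by inserted/deleted bases),
    ``*`` deletion placeholders and ``.``/``,`` reference matches.  Base
    qualities are not used.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError("mpileup line has fewer than 5 fields", str(path), ln)
            rep, pos, ref = fields[0], int(fields[1]), fields[2].upper()
            bases = fields[4]
            counts = {b: 0 for b in "ACGTN"}
            ndel = nins = 0
            i = 0
            while i < len(bases):
                c = bases[i]
                if c == "^":
                    i += 2
                    continue
                if c in "$":
                    i += 1
                    continue
                if c in "+-":
                    j = i + 1
                    while j < len(bases) and bases[j].isdigit():
                        j += 1
                    n = int(bases[i + 1:j])
                    if c == "+":
                        nins += 1
                    i = j + n
                    continue
                if c in ".,":
                    counts[ref] += 1
                elif c == "*":
                    ndel += 1
                elif c.upper() in counts:
                    counts[c.upper()] += 1
                i += 1
            rows.append((rep, pos, ref, counts["A"], counts["C"], counts["G"],
                         counts["T"], counts["N"], ndel, nins))
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


# ---------------------------------------------------------------------------
# VCF

_VCF_FIXED_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Fraction of reads supporting the alternate allele">',
    '##ALT=<ID=DEL,Description="Deletion observed in pileup">',
    '##ALT=<ID=INS,Description="Insertion observed in pileup">',
]


def write_vcf_calls(path, calls: list[VariantCall],
                    contig_lengths: dict[str, int] | None = None) -> None:
    """Per-accession VCF of SNP and symbolic indel calls (INFO DP and AF)."""
    lines = list(_VCF_FIXED_HEADER)
    for name, length in (contig_lengths or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in calls:
        alt = c.alt_allele if c.variant_class == "SNP" else f"<{c.alt_allele}>"
        lines.append(
            f"{c.replicon}\t{c.position}\t.\t{c.ref_base}\t{alt}\t.\tPASS\t"
            f"DP={c.depth};AF={c.alt_fraction:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf_calls(path) -> list[VariantCall]:
    """Read a per-accession calls VCF (written by :func:`write_vcf_calls`)."""
    import pysam

    calls = []
    vf = pysam.VariantFile(str(path))
    for rec in vf:
        alt = rec.alts[0]
        symbolic = alt.startswith("<")
        calls.append(VariantCall(
            rec.chrom, rec.pos, rec.ref,
            alt.strip("<>"),
            int(rec.info["DP"]), float(rec.info["AF"]),
            "indel" if symbolic else "SNP",
        ))
    return calls


def write_matrix_vcf(path, matrix: GenotypeMatrix,
                     contig_lengths: dict[str, int] | None = None) -> None:
    """Multi-sample VCF with haploid GT fields; REF allele from the reference.

    Sites where every accession carries the same non-reference allele are
    still emitted (they are variants against the reference); the ALT column
    lists every non-reference allele observed in the panel.
    """
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">']
    for name, length in (contig_lengths or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.accessions))
    for i, (rep, pos, ref) in enumerate(matrix.sites):
        row = matrix.alleles[i]
        ref_code = BASES.index(ref)
        alts = sorted({int(c) for c in row if c != ref_code})
        allele_index = {ref_code: 0, **{c: k + 1 for k, c in enumerate(alts)}}
        alt_field = ",".join(BASES[c] for c in alts) if alts else "."
        gts = "\t".join(str(allele_index[int(c)]) for c in row)
        lines.append(f"{rep}\t{pos}\t.\t{ref}\t{alt_field}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_vcf(path, partition_label: str = "nuclear") -> GenotypeMatrix:
    """Read a haploid multi-sample VCF back into a genotype matrix (pysam)."""
    import pysam

    vf = pysam.VariantFile(str(path))
    accessions = list(vf.header.samples)
    sites = []
    rows = []
    for rec in vf:
        alleles = [rec.ref, *(rec.alts or ())]
        codes = []
        for acc in accessions:
            gt = rec.samples[acc]["GT"]
            idx = gt[0] if isinstance(gt, tuple) else gt
            if idx is None:
                raise FormatError("missing genotype in matrix VCF", str(path))
            codes.append(BASES.index(alleles[idx]))
        sites.append((rec.chrom, rec.pos, rec.ref))
        rows.append(codes)
    alleles_arr = (np.array(rows, dtype=np.uint8) if rows
                   else np.zeros((0, len(accessions)), np.uint8))
    return GenotypeMatrix(sites, alleles_arr, accessions, partition_label)


# ---------------------------------------------------------------------------
# matrix TSV

def write_matrix_tsv(path, matrix: GenotypeMatrix) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path, partition_label: str = "nuclear") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    accessions = [c for c in df.columns if c not in ("replicon", "pos", "ref")]
    sites = [(r, int(p), b) for r, p, b in
             df[["replicon", "pos", "ref"]].itertuples(index=False, name=None)]
    alleles = np.array([[BASES.index(b) for b in df[a]] for a in accessions],
                       dtype=np.uint8).T if len(df) else np.zeros((0, len(accessions)), np.uint8)
    return GenotypeMatrix(sites, alleles, accessions, partition_label)


# ---------------------------------------------------------------------------
# distance matrices

def write_phylip_distances(path, dist) -> None:
    """PHYLIP-style square distance matrix (full, space-separated)."""
    lines = [f"{len(dist.labels)}"]
    width = max(len(l) for l in dist.labels) + 2
    for lab, row in zip(dist.labels, dist.values):
        vals = " ".join(f"{v:.6f}" for v in row)
        lines.append(f"{lab:<{width}}{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trees

def write_newick(path, tree: dendropy.Tree) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True)


# ---------------------------------------------------------------------------
# BED / GFF3

def write_bed(path, sites, name_of=None) -> None:
    """Width-1 BED intervals (0-based half-open) from 1-based sites."""
    lines = []
    for site in sites:
        rep, pos = site[0], site[1]
        start, end = to_bed_interval(pos)
        name = name_of(site) if name_of else f"{rep}:{pos}"
        lines.append(f"{rep}\t{start}\t{end}\t{name}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_caps_gff3(path, candidates) -> None:
    lines = ["##gff-version 3"]
    for i, c in enumerate(candidates, start=1):
        rep, pos, _ = c.fixed_snp.site
        if c.amplicon_window:
            _, start, end = c.amplicon_window
        else:
            start = end = pos
        pair = "-".join(c.fixed_snp.species_pair)
        attrs = (f"ID=caps{i:05d};enzyme={c.enzyme.name};snp_pos={pos};"
                 f"species_pair={pair};cut_in={c.cut_in_species}")
        lines.append(f"{rep}\tsnpdiag\tPCR_product\t{start}\t{end}\t.\t+\t.\t{attrs}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# truth set / density / misc tables

def write_truth_tsv(path, truth) -> None:
    """Long-format planted alleles (replicon, pos, accession, base, deleted)."""
    frames = []
    for rep, arr in truth.true_alleles.items():
        dels = truth.deletions[rep]
        for i, acc in enumerate(truth.accessions):
            frames.append(pd.DataFrame({
                "replicon": rep,
                "pos": np.arange(1, arr.shape[1] + 1),
                "accession": acc,
                "allele": np.array(list(BASES))[arr[i]],
                "deleted": dels[i].astype(int),
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def snp_density_table(matrix: GenotypeMatrix, window: int = 1000) -> pd.DataFrame:
    """Per-replicon SNP counts in fixed windows (plotting-ready)."""
    rows = []
    df = pd.DataFrame(matrix.sites, columns=["replicon", "pos", "ref"])
    for rep, grp in df.groupby("replicon", sort=True):
        binned = ((grp["pos"] - 1) // window).value_counts().sort_index()
        for b, n in binned.items():
            rows.append((rep, int(b) * window + 1, (int(b) + 1) * window, int(n)))
    return pd.DataFrame(rows, columns=["replicon", "start", "end", "n_snps"])


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
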