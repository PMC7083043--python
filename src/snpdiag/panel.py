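"""Cross-accession SNP genotype matrices and diagnostic-site classification.

The central object is the *non-redundant* :class:`GenotypeMatrix`: the union
of per-accession homozygous SNP positions, filtered so that **every** panel
accession has unambiguous, sufficiently covered evidence at each retained
site (REF_CONFIRMED or a homozygous SNP call).  The result has no missing
cells, which is what makes the downstream distance and tree computations
well defined without imputation.

Classification on the matrix follows the standard comparative definitions:

polymorphic site (within species)
    >= 2 distinct alleles among the species' accessions.
fixed SNP (between two species)
    each species monomorphic, with different alleles — the raw material for
    genome-diagnostic markers.
unique substitution (species or species-group)
    the group is monomorphic and its allele occurs in no other non-outgroup
    species of the panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import Status
from .errors import DataError, MissingInputError, UsageError
from .util import BASES

Site = tuple[str, int, str]  # (replicon, 1-based position, ref base)


@dataclass
class SpeciesPanel:
    """Accession → species/genome manifest, with optional outgroup flags."""

    accessions: list[str]
    species_of: dict[str, str]
    genome_of: dict[str, str] = field(default_factory=dict)
    outgroup: set[str] = field(default_factory=set)

    def __post_init__(self):
        missing = [a for a in self.accessions if a not in self.species_of]
        if missing:
            raise DataError(f"accessions without species assignment: {missing}")
        self.outgroup = set(self.outgroup)

    @property
    def species_list(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.accessions:
            seen.setdefault(self.species_of[a], None)
        return list(seen)

    def accessions_of(self, species: str) -> list[str]:
        return [a for a in self.accessions if self.species_of[a] == species]

    @property
    def outgroup_species(self) -> set[str]:
        return {self.species_of[a] for a in self.outgroup}

    @property
    def ingroup_species(self) -> list[str]:
        og = self.outgroup_species
        return [s for s in self.species_list if s not in og]


@dataclass
class GenotypeMatrix:
    """Sites × accessions allele table with no missing entries.

    ``alleles`` holds base codes 0..3 with shape (n_sites, n_accessions);
    ``sites`` is aligned row-wise and strictly increasing within replicon.
    """

    sites: list[Site]
    alleles: np.ndarray
    accessions: list[str]
    partition_label: str = "nuclear"

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.shape != (len(self.sites), len(self.accessions)):
            raise DataError(
                f"allele table shape {self.alleles.shape} does not match "
                f"{len(self.sites)} sites x {len(self.accessions)} accessions"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def column(self, accession: str) -> np.ndarray:
        return self.alleles[:, self.accessions.index(accession)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.sites, columns=["replicon", "pos", "ref"])
        for j, acc in enumerate(self.accessions):
            df[acc] = [BASES[c] for c in self.alleles[:, j]]
        return df


@dataclass(frozen=True)
class FixedSnpRecord:
    site: Site
    species_pair: tuple[str, str]       # sorted, unordered semantics
    allele_of: tuple[tuple[str, str], ...]  # ((species, base), ...)

    @property
    def alleles(self) -> dict[str, str]:
        return dict(self.allele_of)


@dataclass(frozen=True)
class UniqueSnpRecord:
    site: Site
    group: tuple[str, ...]
    diagnostic_allele: str


RETAINED_STATUSES = (int(Status.REF_CONFIRMED), int(Status.ALT_CALLED))


def build_matrix(
    statuses_by_accession: dict[str, pd.DataFrame],
    panel: SpeciesPanel,
    partition_label: str = "nuclear",
    replicon_order: list[str] | None = None,
) -> GenotypeMatrix:
    """Assemble the non-redundant genotype matrix from per-accession statuses.

    Candidate sites are the union of homozygous SNP positions over all
    accessions; a candidate is retained iff every accession's status there
    is REF_CONFIRMED or ALT_CALLED (depth >= threshold, unambiguous, no
    indel evidence winning).  A site absent from an accession's table counts
    as LOW_DEPTH.  Indel-called positions never enter the matrix.
    """
    missing = [a for a in panel.accessions if a not in statuses_by_accession]
    if missing:
        raise MissingInputError(f"no status table for accession(s): {missing}")

    key_frames = []
    for acc in panel.accessions:
        df = statuses_by_accession[acc]
        alt = df[df["status"] == int(Status.ALT_CALLED)]
        key_frames.append(alt[["replicon", "pos", "ref"]])
    if key_frames:
        candidates = pd.concat(key_frames, ignore_index=True).drop_duplicates()
    else:
        candidates = pd.DataFrame(columns=["replicon", "pos", "ref"])
    if candidates.empty:
        return GenotypeMatrix([], np.zeros((0, len(panel.accessions)), np.uint8),
                              list(panel.accessions), partition_label)

    if replicon_order is not None:
        order = {r: i for i, r in enumerate(replicon_order)}
        candidates = candidates.assign(_r=candidates["replicon"].map(order))
        if candidates["_r"].isna().any():
            raise DataError("candidate site on replicon absent from replicon_order")
        candidates = candidates.sort_values(["_r", "pos"]).drop(columns="_r")
    else:
        candidates = candidates.sort_values(["replicon", "pos"])
    candidates = candidates.reset_index(drop=True)

    n_sites, n_acc = len(candidates), len(panel.accessions)
    ref_codes = np.array([BASES.index(b) for b in candidates["ref"]], dtype=np.uint8)
    alleles = np.tile(ref_codes[:, None], (1, n_acc))
    keep = np.ones(n_sites, dtype=bool)

    for j, acc in enumerate(panel.accessions):
        df = statuses_by_accession[acc]
        merged = candidates.merge(
            df[["replicon", "pos", "status", "allele"]],
            on=["replicon", "pos"], how="left",
        )
        status = merged["status"].fillna(int(Status.LOW_DEPTH)).to_numpy(dtype=np.int64)
        keep &= np.isin(status, RETAINED_STATUSES)
        is_alt = status == int(Status.ALT_CALLED)
        alleles[is_alt, j] = merged["allele"].to_numpy()[is_alt].astype(np.uint8)

    sites = [
        (str(r), int(p), str(b))
        for r, p, b in candidates[keep].itertuples(index=False, name=None)
    ]
    return GenotypeMatrix(sites, alleles[keep], list(panel.accessions), partition_label)


def _species_columns(matrix: GenotypeMatrix, panel: SpeciesPanel, species: str) -> np.ndarray:
    idx = [matrix.accessions.index(a) for a in panel.accessions_of(species)
           if a in matrix.accessions]
    if not idx:
        raise UsageError(f"species {species!r} has no accessions in the matrix")
    return matrix.alleles[:, idx]


def polymorphic_sites(matrix: GenotypeMatrix, panel: SpeciesPanel, species: str) -> list[Site]:
    """Sites with >= 2 distinct alleles among the species' accessions.

    A single-accession species cannot segregate; the result is defined
    empty and a warning is issued.
    """
    cols = _species_columns(matrix, panel, species)
    if cols.shape[1] < 2:
        warnings.warn(f"species {species!r} has a single accession; "
                      "polymorphic-site set is defined empty", stacklevel=2)
        return []
    poly = (cols != cols[:, [0]]).any(axis=1)
    return [matrix.sites[i] for i in np.flatnonzero(poly)]


def _monomorphic_allele(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (mask of monomorphic sites, the shared allele per site)."""
    mono = (cols == cols[:, [0]]).all(axis=1)
    return mono, cols[:, 0]


def fixed_snps(
    matrix: GenotypeMatrix, panel: SpeciesPanel, species_a: str, species_b: str
) -> list[FixedSnpRecord]:
    """Sites monomorphic within each species but different between them."""
    if species_a == species_b:
        raise UsageError("fixed_snps requires two distinct species")
    pair = tuple(sorted((species_a, species_b)))
    mono_a, al_a = _monomorphic_allele(_species_columns(matrix, panel, pair[0]))
    mono_b, al_b = _monomorphic_allele(_species_columns(matrix, panel, pair[1]))
    hit = mono_a & mono_b & (al_a != al_b)
    return [
        FixedSnpRecord(matrix.sites[i], pair,
                       ((pair[0], BASES[al_a[i]]), (pair[1], BASES[al_b[i]])))
        for i in np.flatnonzero(hit)
    ]


def unique_substitutions(
    matrix: GenotypeMatrix, panel: SpeciesPanel, group: str | list[str]
) -> list[UniqueSnpRecord]:
    """Sites where a species (or species-group) is monomorphic for an allele
    absent from every other non-outgroup panel species."""
    species_group = [group] if isinstance(group, str) else list(group)
    if not species_group:
        raise UsageError("empty species group")
    others = [s for s in panel.ingroup_species if s not in species_group]
    if not others:
        raise UsageError("group covers the entire (non-outgroup) panel; "
                         "no comparison set remains")
    grp_cols = np.hstack([_species_columns(matrix, panel, s) for s in species_group])
    other_cols = np.hstack([_species_columns(matrix, panel, s) for s in others])
    mono, allele = _monomorphic_allele(grp_cols)
    absent = (other_cols != allele[:, None]).all(axis=1)
    hit = mono & absent
    gtuple = tuple(species_group)
    return [
        UniqueSnpRecord(matrix.sites[i], gtuple, BASES[allele[i]])
        for i in np.flatnonzero(hit)
    ]
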