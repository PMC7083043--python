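"""Homozygous variant calling from per-site pileup evidence.

The caller re-implements the filtering criteria used for selfing diploid
panels: a site in one accession yields a call only when read depth is at
least ``min_depth`` (default 10) and a single allele accounts for strictly
more than ``min_alt_fraction`` (default 95%) of the reads covering it.
Because no two alleles can each exceed 95% of the same denominator, every
emitted call is homozygous by construction — heterozygous-looking evidence
(including RNA-editing-like mixed sites on organellar transcripts) lands in
the AMBIGUOUS bin and is discarded downstream.

Depth is counted as A+C+G+T+N plus deletion-spanning reads; the same
denominator is used for the >95% fraction.  Insertion observations ride on
top of a base call, so insertion evidence is tested against the same
denominator but does not determine the site status.

Fraction comparisons are exact: thresholds are held as rationals, so
19 alt reads out of 20 (exactly 95%) never passes a strict 95% cut.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError, OrderingError
from .util import BASES, as_fraction, exceeds_fraction

#: default depth threshold (reads covering the site)
MIN_DEPTH = 10
#: default allele-fraction threshold; strict inequality
MIN_ALT_FRACTION = 0.95

PILEUP_COLUMNS = ["replicon", "pos", "ref", "nA", "nC", "nG", "nT", "nN", "nDel", "nIns"]
COUNT_COLUMNS = PILEUP_COLUMNS[3:]


class Status(enum.IntEnum):
    """Per-site, per-accession evidence classification."""

    LOW_DEPTH = 0
    REF_CONFIRMED = 1
    ALT_CALLED = 2      # homozygous non-reference base
    DEL_CALLED = 3      # deletion allele passes the same thresholds
    AMBIGUOUS = 4       # depth ok but no allele > min_alt_fraction


@dataclass(frozen=True)
class PileupSite:
    """Base-count evidence at one reference position in one accession."""

    replicon: str
    position: int          # 1-based
    ref_base: str
    counts: tuple[int, int, int, int, int]  # A, C, G, T, N
    deletion_obs: int = 0
    insertion_obs: int = 0

    def __post_init__(self):
        if self.position < 1:
            raise DataError(f"position must be >= 1, got {self.position}")
        if self.ref_base not in BASES:
            raise DataError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        if len(self.counts) != 5 or any(c < 0 for c in self.counts):
            raise DataError(f"counts must be 5 nonnegative integers, got {self.counts}")
        if self.deletion_obs < 0 or self.insertion_obs < 0:
            raise DataError("indel observation counts must be nonnegative")

    @property
    def depth(self) -> int:
        """Reads spanning the site: A+C+G+T+N plus deletion observations."""
        return int(sum(self.counts)) + self.deletion_obs


@dataclass(frozen=True)
class VariantCall:
    replicon: str
    position: int
    ref_base: str
    alt_allele: str        # 'A'/'C'/'G'/'T' or symbolic 'DEL'/'INS'
    depth: int
    alt_fraction: float
    variant_class: str     # 'SNP' | 'indel'


@dataclass(frozen=True)
class SiteStatus:
    replicon: str
    position: int
    accession: str | None
    status: Status
    allele: str | None = None   # set when status is ALT_CALLED


def classify_counts(
    ref_codes: np.ndarray,
    base_counts: np.ndarray,
    n_counts: np.ndarray,
    del_counts: np.ndarray,
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised classification kernel.

    Parameters
    ----------
    ref_codes : (n,) uint8 reference base codes 0..3
    base_counts : (n, 4) observed A/C/G/T read counts
    n_counts, del_counts : (n,) N and deletion-spanning read counts

    Returns
    -------
    status : (n,) int8 array of :class:`Status` values
    allele : (n,) int8 array; called base code where status == ALT_CALLED,
        -1 elsewhere
    """
    base_counts = np.asarray(base_counts, dtype=np.int64)
    if base_counts.min(initial=0) < 0 or np.min(n_counts, initial=0) < 0 or np.min(del_counts, initial=0) < 0:
        raise DataError("negative read counts in pileup")
    frac = as_fraction(min_alt_fraction)
    depth = base_counts.sum(axis=1) + np.asarray(n_counts, np.int64) + np.asarray(del_counts, np.int64)

    n = len(depth)
    status = np.full(n, Status.AMBIGUOUS, dtype=np.int8)
    allele = np.full(n, -1, dtype=np.int8)

    low = depth < min_depth
    status[low] = Status.LOW_DEPTH

    # at most one allele can strictly exceed 95% of a shared denominator
    top = np.argmax(base_counts, axis=1).astype(np.int8)
    top_count = np.take_along_axis(base_counts, top[:, None].astype(np.int64), axis=1)[:, 0]
    base_wins = exceeds_fraction(top_count, depth, frac) & ~low

    is_ref = base_wins & (top == ref_codes)
    is_alt = base_wins & (top != ref_codes)
    status[is_ref] = Status.REF_CONFIRMED
    status[is_alt] = Status.ALT_CALLED
    allele[is_alt] = top[is_alt]

    del_wins = exceeds_fraction(np.asarray(del_counts, np.int64), depth, frac) & ~low
    status[del_wins] = Status.DEL_CALLED
    return status, allele


def classify_site_status(
    site: PileupSite,
    accession: str | None = None,
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> SiteStatus:
    """Classify a single pileup site (scalar wrapper over the kernel)."""
    from .util import BASE_TO_CODE

    status, allele = classify_counts(
        np.array([BASE_TO_CODE[site.ref_base]], dtype=np.uint8),
        np.array([site.counts[:4]], dtype=np.int64),
        np.array([site.counts[4]], dtype=np.int64),
        np.array([site.deletion_obs], dtype=np.int64),
        min_depth=min_depth,
        min_alt_fraction=min_alt_fraction,
    )
    code = Status(int(status[0]))
    return SiteStatus(
        site.replicon,
        site.position,
        accession,
        code,
        BASES[allele[0]] if code == Status.ALT_CALLED else None,
    )


def call_site(
    site: PileupSite,
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> VariantCall | None:
    """Return the homozygous SNP or indel call at one site, or ``None``.

    A SNP is called iff depth >= ``min_depth`` and one non-reference base
    alone accounts for strictly more than ``min_alt_fraction`` of depth.
    Deletions are called under the same rule applied to deletion-spanning
    reads; insertion evidence is tested against the same denominator and,
    uniquely, may accompany a confirmed reference base.
    """
    st = classify_site_status(site, None, min_depth, min_alt_fraction)
    depth = site.depth
    if st.status == Status.ALT_CALLED:
        alt_n = site.counts[BASES.index(st.allele)]
        return VariantCall(site.replicon, site.position, site.ref_base,
                           st.allele, depth, alt_n / depth, "SNP")
    if st.status == Status.DEL_CALLED:
        return VariantCall(site.replicon, site.position, site.ref_base,
                           "DEL", depth, site.deletion_obs / depth, "indel")
    if depth >= min_depth and exceeds_fraction(site.insertion_obs, depth, as_fraction(min_alt_fraction)):
        return VariantCall(site.replicon, site.position, site.ref_base,
                           "INS", depth, site.insertion_obs / depth, "indel")
    return None


def classify_pileup_frame(
    pileup: pd.DataFrame,
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> pd.DataFrame:
    """Classify every row of a pileup-summary table.

    Returns a copy of ``pileup[['replicon','pos','ref']]`` with integer
    ``status`` (:class:`Status`) and ``allele`` (base code or -1) columns,
    plus an ``ins_call`` boolean column for insertion evidence.
    """
    from .util import BASE_TO_CODE

    ref_codes = pileup["ref"].map(BASE_TO_CODE).to_numpy(dtype=np.uint8)
    base_counts = pileup[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int64)
    n_counts = pileup["nN"].to_numpy(dtype=np.int64)
    del_counts = pileup["nDel"].to_numpy(dtype=np.int64)
    status, allele = classify_counts(ref_codes, base_counts, n_counts, del_counts,
                                     min_depth, min_alt_fraction)
    depth = base_counts.sum(axis=1) + n_counts + del_counts
    ins = (depth >= min_depth) & exceeds_fraction(
        pileup["nIns"].to_numpy(dtype=np.int64), depth, as_fraction(min_alt_fraction)
    )
    out = pileup[["replicon", "pos", "ref"]].copy()
    out["status"] = status
    out["allele"] = allele
    out["depth"] = depth
    out["ins_call"] = ins
    return out


def _check_sorted(pileup: pd.DataFrame) -> None:
    grp = pileup.groupby("replicon", sort=False)["pos"]
    if not grp.apply(lambda s: s.is_monotonic_increasing).all():
        raise OrderingError("pileup records must be sorted by (replicon, position)")
    # a replicon must not reappear after another replicon started
    reps = pileup["replicon"].to_numpy()
    if len(reps):
        change = reps[1:] != reps[:-1]
        if len(pd.unique(reps)) != 1 + int(change.sum()):
            raise OrderingError("pileup records must be grouped by replicon")


def call_accession(
    pileup: pd.DataFrame,
    accession: str,
    min_depth: int = MIN_DEPTH,
    min_alt_fraction: float = MIN_ALT_FRACTION,
) -> tuple[list[VariantCall], pd.DataFrame, dict]:
    """One-pass calling over an accession's sorted pileup-summary table.

    Returns the variant calls, the per-site status table (as produced by
    :func:`classify_pileup_frame`) and a summary dict with SNP/indel and
    status counts.
    """
    if not set(PILEUP_COLUMNS).issubset(pileup.columns):
        raise DataError(f"pileup table must have columns {PILEUP_COLUMNS}")
    _check_sorted(pileup)
    statuses = classify_pileup_frame(pileup, min_depth, min_alt_fraction)

    calls: list[VariantCall] = []
    alt_rows = np.flatnonzero(statuses["status"].to_numpy() == Status.ALT_CALLED)
    del_rows = np.flatnonzero(statuses["status"].to_numpy() == Status.DEL_CALLED)
    ins_rows = np.flatnonzero(statuses["ins_call"].to_numpy())
    depth = statuses["depth"].to_numpy()
    for i in alt_rows:
        row = pileup.iloc[i]
        alt = BASES[statuses["allele"].iat[i]]
        calls.append(VariantCall(row["replicon"], int(row["pos"]), row["ref"],
                                 alt, int(depth[i]), row[f"n{alt}"] / depth[i], "SNP"))
    for i in del_rows:
        row = pileup.iloc[i]
        calls.append(VariantCall(row["replicon"], int(row["pos"]), row["ref"],
                                 "DEL", int(depth[i]), row["nDel"] / depth[i], "indel"))
    for i in ins_rows:
        row = pileup.iloc[i]
        calls.append(VariantCall(row["replicon"], int(row["pos"]), row["ref"],
                                 "INS", int(depth[i]), row["nIns"] / depth[i], "indel"))
    calls.sort(key=lambda c: (c.replicon, c.position, c.alt_allele))

    counts = statuses["status"].value_counts()
    summary = {
        "accession": accession,
        "n_sites": int(len(pileup)),
        "n_snps": int(len(alt_rows)),
        "n_indels": int(len(del_rows) + len(ins_rows)),
        "n_ref_confirmed": int(counts.get(int(Status.REF_CONFIRMED), 0)),
        "n_ambiguous": int(counts.get(int(Status.AMBIGUOUS), 0)),
        "n_low_depth": int(counts.get(int(Status.LOW_DEPTH), 0)),
    }
    return calls, statuses, summary


def pileup_from_records(records: Iterable[PileupSite]) -> pd.DataFrame:
    """Build a pileup-summary table from :class:`PileupSite` records."""
    rows = [
        (s.replicon, s.position, s.ref_base, *s.counts, s.deletion_obs, s.insertion_obs)
        for s in records
    ]
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)
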