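"""Pairwise p-distances and per-region intra/interspecific summaries.

The barcode-gap analysis behind every species diagnosis: for a target
species and a marker region (ITS2 by convention, LSU as backup) we report
the maximum intraspecific p-distance over all pairs of member reads and the
minimum interspecific p-distance to related species, and whether the former
stays below the latter (the barcode gap).

p-distance = (# comparable sites with non-compatible symbols) / (# comparable
sites). By default, sites with a gap or an 'n' in either sequence are
excluded from numerator and denominator; IUPAC-compatible symbol pairs
count as matches. An alternative gaps-as-difference policy is exposed since
published per-taxon numbers may reflect either convention when reads differ
by repeat-length polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import AnnotatedAlignment, AlignmentError, SequenceRecord, encode

_N = ord("n")


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class DistancePolicy:
    """How sites enter the p-distance.

    gap_handling: 'exclude' drops sites with '-' in either sequence from
        numerator and denominator; 'difference' counts a gap opposite a base
        as a difference (gap-gap sites are always dropped).
    n_handling: 'exclude' drops sites with 'n' in either sequence.
    min_overlap: minimum comparable sites for a defined distance.
    """

    gap_handling: str = "exclude"
    n_handling: str = "exclude"
    min_overlap: int = 50

    def __post_init__(self) -> None:
        if self.gap_handling not in ("exclude", "difference"):
            raise DistanceError(f"unknown gap_handling {self.gap_handling!r}")
        if self.n_handling not in ("exclude", "include"):
            raise DistanceError(f"unknown n_handling {self.n_handling!r}")
        if self.min_overlap < 1:
            raise DistanceError("min_overlap must be >= 1")


@dataclass(frozen=True)
class DistanceReport:
    """Per-taxon, per-region barcode-gap summary (fractions, not percent)."""

    taxon: str
    region: str
    max_intra: float | None
    min_inter: float | None
    nearest_other: str | None
    n_pairs_intra: int
    n_pairs_inter: int
    single_member: bool = False

    @property
    def barcode_gap(self) -> bool | None:
        if self.max_intra is None or self.min_inter is None:
            return None
        return self.min_inter > self.max_intra

    def as_row(self) -> dict:
        pct = lambda x: None if x is None else round(100.0 * x, 1)
        return {
            "taxon": self.taxon,
            "region": self.region,
            "max_intra_pct": pct(self.max_intra),
            "min_inter_pct": pct(self.min_inter),
            "nearest_other": self.nearest_other,
            "barcode_gap": self.barcode_gap,
            "n_pairs_intra": self.n_pairs_intra,
            "n_pairs_inter": self.n_pairs_inter,
            "single_member": self.single_member,
        }


def _pair_distance(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    char_a: np.ndarray,
    char_b: np.ndarray,
    policy: DistancePolicy,
) -> float | None:
    gap_a = mask_a == 0
    gap_b = mask_b == 0
    keep = np.ones(mask_a.shape, dtype=bool)
    if policy.n_handling == "exclude":
        keep &= (char_a != _N) & (char_b != _N)
    if policy.gap_handling == "exclude":
        keep &= ~gap_a & ~gap_b
        diff = keep & ((mask_a & mask_b) == 0)
    else:  # gaps as difference; gap-gap sites dropped
        keep &= ~(gap_a & gap_b)
        diff = keep & ((mask_a & mask_b) == 0)
    n_comp = int(keep.sum())
    if n_comp < policy.min_overlap:
        return None
    return float(diff.sum()) / n_comp


def p_distance(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    columns: tuple[int, int] | None = None,
    policy: DistancePolicy = DistancePolicy(),
) -> float | None:
    """p-distance between two aligned sequences over a half-open column
    interval (whole alignment if None). Returns None when fewer than
    ``policy.min_overlap`` comparable sites remain."""
    sa = a.aligned if isinstance(a, SequenceRecord) else a.lower()
    sb = b.aligned if isinstance(b, SequenceRecord) else b.lower()
    if len(sa) != len(sb):
        raise DistanceError("sequences have unequal aligned length")
    lo, hi = columns if columns is not None else (0, len(sa))
    if hi <= lo:
        raise DistanceError("empty region")
    if not (0 <= lo and hi <= len(sa)):
        raise DistanceError("interval outside alignment width")
    ma, mb = encode(sa[lo:hi]), encode(sb[lo:hi])
    ca = np.frombuffer(sa[lo:hi].encode(), dtype=np.uint8)
    cb = np.frombuffer(sb[lo:hi].encode(), dtype=np.uint8)
    return _pair_distance(ma, mb, ca, cb, policy)


def _indices_distance(
    aln: AnnotatedAlignment, i: int, j: int, lo: int, hi: int, policy: DistancePolicy
) -> float | None:
    masks, chars = aln.masks, aln.chars
    return _pair_distance(
        masks[i, lo:hi], masks[j, lo:hi], chars[i, lo:hi], chars[j, lo:hi], policy
    )


def max_intraspecific(
    aln: AnnotatedAlignment,
    taxon: str,
    region: str,
    policy: DistancePolicy = DistancePolicy(),
    rank: str = "species",
) -> DistanceReport:
    """Maximum pairwise p-distance among the taxon's member reads.

    A single-member taxon reports 0.0 with ``single_member=True``.
    """
    lo, hi = aln.region_map.interval(region)
    members = aln.members(taxon, rank)
    if not members:
        raise DistanceError(f"empty taxon {taxon!r}")
    if len(members) == 1:
        return DistanceReport(taxon, region, 0.0, None, None, 0, 0, single_member=True)
    best: float | None = None
    n_pairs = 0
    for x in range(len(members)):
        for y in range(x + 1, len(members)):
            d = _indices_distance(aln, members[x], members[y], lo, hi, policy)
            if d is None:
                continue
            n_pairs += 1
            if best is None or d > best:
                best = d
    if best is None:
        raise DistanceError(f"insufficient coverage for {taxon!r} in {region}")
    return DistanceReport(taxon, region, best, None, None, n_pairs, 0)


def min_interspecific(
    aln: AnnotatedAlignment,
    taxon: str,
    region: str,
    policy: DistancePolicy = DistancePolicy(),
    rank: str = "species",
    contrast_rank: str | None = "genus",
) -> DistanceReport:
    """Minimum p-distance from any member read to any related non-member.

    "Related" defaults to non-members of the same genus when the target has
    a genus annotation and congeners exist; otherwise all non-members.
    """
    lo, hi = aln.region_map.interval(region)
    members = aln.members(taxon, rank)
    if not members:
        raise DistanceError(f"empty taxon {taxon!r}")
    others = []
    if contrast_rank is not None:
        others = aln.non_members(taxon, rank, contrast_rank=contrast_rank)
    if not others:
        others = aln.non_members(taxon, rank)
    if not others:
        raise DistanceError(f"no contrast set for {taxon!r}")
    best: float | None = None
    nearest: str | None = None
    n_pairs = 0
    for i in members:
        for j in others:
            d = _indices_distance(aln, i, j, lo, hi, policy)
            if d is None:
                continue
            n_pairs += 1
            if best is None or d < best:
                best = d
                nearest = aln.records[j].taxon(rank) or aln.records[j].id
    if best is None:
        raise DistanceError(f"insufficient coverage for contrast of {taxon!r} in {region}")
    return DistanceReport(taxon, region, None, best, nearest, 0, n_pairs)


def distance_report(
    aln: AnnotatedAlignment,
    taxon: str,
    region: str,
    policy: DistancePolicy = DistancePolicy(),
    rank: str = "species",
    contrast_rank: str | None = "genus",
) -> DistanceReport:
    """Combined barcode-gap report for one taxon and region."""
    intra = max_intraspecific(aln, taxon, region, policy, rank)
    inter = min_interspecific(aln, taxon, region, policy, rank, contrast_rank)
    return DistanceReport(
        taxon,
        region,
        intra.max_intra,
        inter.min_inter,
        inter.nearest_other,
        intra.n_pairs_intra,
        inter.n_pairs_inter,
        single_member=intra.single_member,
    )


def pairwise_distance_matrix(
    aln: AnnotatedAlignment,
    region: str | None = None,
    policy: DistancePolicy = DistancePolicy(),
    indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Symmetric p-distance matrix over the given records (NaN = undefined)."""
    if indices is None:
        indices = [i for i, r in enumerate(aln.records) if "reference" not in r.roles]
    lo, hi = aln.region_map.interval(region) if region else (0, aln.width)
    n = len(indices)
    mat = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            d = _indices_distance(aln, indices[x], indices[y], lo, hi, policy)
            mat[x, y] = mat[y, x] = np.nan if d is None else d
    ids = [aln.records[i].id for i in indices]
    return mat, ids
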