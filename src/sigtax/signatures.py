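"""Diagnostic nucleotide signature mining and verification.

A diagnostic signature is a short (typically 20 nt), possibly
IUPAC-degenerate motif at fixed alignment columns that separates a target
taxon from every related taxon within a stated mismatch budget. The motif
is the per-column union (IUPAC consensus) of the target members; the
allowed-mismatch count m is derived so that every non-target sequence
exceeds it: if the nearest non-target shows d_min mismatches to the motif,
m = d_min - 1 ("no/one/two mismatches allowed" in a printed diagnosis).

When no single motif covers a heterogeneous target, a disjunctive signature
("motif1 OR motif2") partitions the members into subgroups with one motif
each; a sequence counts as the target if it is within m of any alternative.

The search is exhaustive over gap-free target windows and fully
deterministic: ties are broken by (separation d_min descending, ambiguity
ascending, region priority, leftmost column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import (
    IUPAC_MASK,
    AlignmentError,
    AnnotatedAlignment,
    SequenceRecord,
    encode,
)

_MASK_TO_CODE_ARR = np.zeros(16, dtype="<U1")
for _code, _mask in IUPAC_MASK.items():
    if _mask:
        _MASK_TO_CODE_ARR[_mask] = _code
_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.int64)

#: Region search order: ITS2 is the preferred barcode fragment, then LSU.
DEFAULT_REGION_PRIORITY: tuple[str, ...] = ("ITS2", "LSU", "5.8S", "SSU")


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureSearchParams:
    min_len: int = 20
    max_len: int = 20
    max_ambiguous: int = 2
    region_priority: tuple[str, ...] = DEFAULT_REGION_PRIORITY
    max_alternatives: int = 3
    top_k: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise SignatureError("need 1 <= min_len <= max_len")
        if self.max_ambiguous < 0 or self.max_alternatives < 1:
            raise SignatureError("bad search parameters")


@dataclass(frozen=True)
class Signature:
    """A (possibly disjunctive) diagnostic signature for one taxon."""

    target: str
    region: str
    alternatives: tuple[str, ...]
    columns: tuple[tuple[int, int], ...]  # half-open, one interval per alternative
    allowed_mismatches: int
    ambiguity_count: int
    margin: int

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise SignatureError("signature needs at least one motif")
        if len(self.alternatives) != len(self.columns):
            raise SignatureError("one column interval per alternative required")

    @property
    def motif(self) -> str:
        """The printed motif string ('OR'-joined for disjunctions)."""
        return " OR ".join(self.alternatives)


@dataclass(frozen=True)
class VerificationReport:
    all_targets_match: bool
    min_nontarget_mismatches: int
    offending_ids: tuple[str, ...] = ()

    def is_valid(self, allowed_mismatches: int) -> bool:
        return self.all_targets_match and self.min_nontarget_mismatches > allowed_mismatches


def _target_and_contrast(
    aln: AnnotatedAlignment,
    target: str,
    rank: str | None,
    contrast_rank: str | None,
) -> tuple[list[int], list[int]]:
    members = aln.members(target, rank)
    if not members:
        raise SignatureError(f"empty taxon {target!r}")
    others = aln.non_members(target, rank, contrast_rank=contrast_rank)
    return members, others


def window_consensus(
    aln: AnnotatedAlignment,
    target: str,
    columns: tuple[int, int],
    rank: str | None = None,
) -> str | None:
    """Per-column IUPAC union of the target members over a half-open window.

    Undefined (None) when any target member has a gap in the window:
    printed signatures are contiguous barcodes, so gapped windows are
    excluded rather than padded.
    """
    lo, hi = columns
    if not (0 <= lo < hi <= aln.width):
        raise AlignmentError("interval outside alignment width")
    members = aln.members(target, rank)
    if not members:
        raise SignatureError(f"empty taxon {target!r}")
    sub = aln.masks[members, lo:hi]
    if (sub == 0).any():
        return None
    union = np.bitwise_or.reduce(sub, axis=0)
    return "".join(_MASK_TO_CODE_ARR[union])


def motif_ambiguity(motif: str) -> int:
    """Number of degenerate (multi-base) symbols in a motif."""
    return int((_POPCOUNT[encode(motif)] > 1).sum())


def mismatch_count(
    motif: str,
    seq: SequenceRecord | str,
    columns: tuple[int, int],
) -> int:
    """Columns where the motif symbol and the sequence symbol share no base.

    A gap in the sequence always counts as a mismatch.
    """
    lo, hi = columns
    s = seq.aligned if isinstance(seq, SequenceRecord) else seq.lower()
    window = s[lo:hi]
    if len(motif) != len(window):
        raise SignatureError("window shape: motif length != interval length")
    return int(((encode(motif) & encode(window)) == 0).sum())


def allowed_mismatches(
    motif: str,
    aln: AnnotatedAlignment,
    target: str,
    columns: tuple[int, int],
    rank: str | None = None,
    contrast_rank: str | None = None,
) -> tuple[int, VerificationReport]:
    """Derive the mismatch budget m = d_min - 1 from the nearest non-target.

    The signature is valid iff d_min >= 1 (some separation exists).
    """
    members, others = _target_and_contrast(aln, target, rank, contrast_rank)
    if not others:
        raise SignatureError(f"no contrast set for {target!r}")
    lo, hi = columns
    counts = [mismatch_count(motif, aln.records[j], (lo, hi)) for j in others]
    d_min = min(counts)
    m = max(d_min - 1, 0)
    offenders = tuple(aln.records[j].id for j, c in zip(others, counts) if c == d_min)
    report = VerificationReport(
        all_targets_match=all(
            mismatch_count(motif, aln.records[i], (lo, hi)) <= m for i in members
        ),
        min_nontarget_mismatches=d_min,
        offending_ids=offenders if d_min == 0 else (),
    )
    return m, report


def _sliding_sum(x: np.ndarray, length: int) -> np.ndarray:
    """Sum over every length-window along the last axis."""
    c = np.cumsum(x, axis=-1, dtype=np.int64)
    pad = np.zeros(c.shape[:-1] + (1,), dtype=np.int64)
    c = np.concatenate([pad, c], axis=-1)
    return c[..., length:] - c[..., :-length]


def find_signatures(
    aln: AnnotatedAlignment,
    target: str,
    params: SignatureSearchParams = SignatureSearchParams(),
    rank: str | None = None,
    contrast_rank: str | None = None,
) -> list[Signature]:
    """Exhaustively rank single-motif signatures for a target taxon.

    Every gap-free target window of each length in [min_len, max_len] within
    each region of ``params.region_priority`` is scored; windows whose
    consensus carries more than ``max_ambiguous`` degenerate symbols or
    which fail to separate from some non-target (d_min = 0) are dropped.
    Ranking: d_min descending, ambiguity ascending, region priority,
    leftmost column. Returns at most ``top_k`` signatures.
    """
    members, others = _target_and_contrast(aln, target, rank, contrast_rank)
    masks = aln.masks
    tgt = masks[members, :]
    union = np.bitwise_or.reduce(tgt, axis=0)
    gap_any = (tgt == 0).any(axis=0).astype(np.int64)
    ambiguous = (_POPCOUNT[union] > 1).astype(np.int64)

    candidates: list[tuple[tuple, Signature]] = []
    region_names = set(aln.region_map.names)
    for r_idx, region in enumerate(params.region_priority):
        if region not in region_names:
            continue
        lo, hi = aln.region_map.interval(region)
        for length in range(params.min_len, params.max_len + 1):
            if hi - lo < length:
                continue
            starts = np.arange(lo, hi - length + 1)
            ok = _sliding_sum(gap_any[lo:hi], length) == 0
            amb = _sliding_sum(ambiguous[lo:hi], length)
            ok &= amb <= params.max_ambiguous
            if others:
                nt = masks[others, lo:hi]
                mm = ((nt & union[lo:hi]) == 0).astype(np.int64)
                d_min = _sliding_sum(mm, length).min(axis=0)
            else:
                d_min = np.full(starts.shape, np.iinfo(np.int64).max)
            ok &= d_min >= 1
            for w in np.nonzero(ok)[0]:
                c0 = int(starts[w])
                motif = "".join(_MASK_TO_CODE_ARR[union[c0 : c0 + length]])
                dm = int(d_min[w])
                sig = Signature(
                    target=target,
                    region=region,
                    alternatives=(motif,),
                    columns=((c0, c0 + length),),
                    allowed_mismatches=max(dm - 1, 0),
                    ambiguity_count=int(amb[w]),
                    margin=dm - max(dm - 1, 0),
                )
                candidates.append(((-dm, int(amb[w]), r_idx, c0, length), sig))
    candidates.sort(key=lambda t: t[0])
    return [sig for _, sig in candidates[: params.top_k]]


def find_disjunctive_signature(
    aln: AnnotatedAlignment,
    target: str,
    params: SignatureSearchParams = SignatureSearchParams(),
    rank: str | None = None,
    contrast_rank: str | None = None,
) -> Signature | None:
    """Search for an 'OR'-of-motifs signature when no single motif separates.

    Target members are partitioned by complete-linkage clustering of their
    window-restricted mismatch distances into at most ``max_alternatives``
    groups, one consensus motif per group. A window qualifies when every
    non-target exceeds m mismatches against ALL alternatives (every target
    member is within m of its own group's motif by construction). Windows
    are scanned greedily in the single-motif rank order; with a single
    internally uniform target this degenerates to the find_signatures
    result.
    """
    members, others = _target_and_contrast(aln, target, rank, contrast_rank)
    if not others:
        raise SignatureError(f"no contrast set for {target!r}")
    masks = aln.masks
    tgt = masks[members, :]
    gap_any = (tgt == 0).any(axis=0).astype(np.int64)

    best: tuple[tuple, Signature] | None = None
    region_names = set(aln.region_map.names)
    for r_idx, region in enumerate(params.region_priority):
        if region not in region_names:
            continue
        lo, hi = aln.region_map.interval(region)
        for length in range(params.min_len, params.max_len + 1):
            if hi - lo < length:
                continue
            ok = _sliding_sum(gap_any[lo:hi], length) == 0
            for w in np.nonzero(ok)[0]:
                c0 = lo + int(w)
                window = (c0, c0 + length)
                cand = _best_partition_at_window(
                    aln, target, members, others, window, params
                )
                if cand is None:
                    continue
                key = (-cand.margin - cand.allowed_mismatches,  # == -d_min
                       cand.ambiguity_count, r_idx, c0, len(cand.alternatives))
                if best is None or key < best[0]:
                    best = (key, cand)
    return best[1] if best else None


def _best_partition_at_window(
    aln: AnnotatedAlignment,
    target: str,
    members: list[int],
    others: list[int],
    window: tuple[int, int],
    params: SignatureSearchParams,
) -> Signature | None:
    lo, hi = window
    length = hi - lo
    sub = aln.masks[members, lo:hi]
    # pairwise mismatch distances among members, restricted to the window
    n = len(members)
    if n > 1:
        dm = np.zeros((n, n))
        for x in range(n):
            incompat = (sub & sub[x]) == 0
            dm[x] = incompat.sum(axis=1)
        link = linkage(squareform(dm, checks=False), method="complete")
    nt = aln.masks[others, lo:hi]
    best: Signature | None = None
    for k in range(1, min(params.max_alternatives, n) + 1):
        groups = (
            fcluster(link, t=k, criterion="maxclust") if n > 1 else np.ones(1, dtype=int)
        )
        if len(set(groups)) != k:
            continue
        motifs, amb_total = [], 0
        feasible = True
        for g in sorted(set(groups)):
            gm = np.bitwise_or.reduce(sub[groups == g], axis=0)
            amb = int((_POPCOUNT[gm] > 1).sum())
            if amb > params.max_ambiguous:
                feasible = False
                break
            motifs.append("".join(_MASK_TO_CODE_ARR[gm]))
            amb_total += amb
        if not feasible:
            continue
        # each non-target's best (lowest) mismatch count over the alternatives
        per_alt = np.stack(
            [((nt & encode(m)) == 0).sum(axis=1) for m in motifs]
        )
        d_min = int(per_alt.min())
        if d_min < 1:
            continue
        m = d_min - 1
        sig = Signature(
            target=target,
            region=_region_of(aln, lo),
            alternatives=tuple(motifs),
            columns=tuple((lo, hi) for _ in motifs),
            allowed_mismatches=m,
            ambiguity_count=amb_total,
            margin=d_min - m,
        )
        if best is None or d_min > best.allowed_mismatches + best.margin:
            best = sig
        break  # smallest feasible k wins; larger k only adds alternatives
    return best


def _region_of(aln: AnnotatedAlignment, column: int) -> str:
    for name, s, e in aln.region_map.regions:
        if s <= column < e:
            return name
    return "unassigned"


def verify_signature(
    aln: AnnotatedAlignment,
    sig: Signature,
    rank: str | None = None,
    contrast_rank: str | None = None,
) -> VerificationReport:
    """Recompute the membership test for a signature against an alignment.

    A target sequence must lie within m mismatches of at least one
    alternative; every non-target must exceed m against all alternatives.
    Idempotent: verifying the output of the search reproduces its margin.
    """
    members, others = _target_and_contrast(aln, sig.target, rank, contrast_rank)
    m = sig.allowed_mismatches
    offenders: list[str] = []
    all_match = True
    for i in members:
        best = min(
            mismatch_count(alt, aln.records[i], cols)
            for alt, cols in zip(sig.alternatives, sig.columns)
        )
        if best > m:
            all_match = False
            offenders.append(aln.records[i].id)
    min_nt = np.iinfo(np.int64).max
    for j in others:
        best = min(
            mismatch_count(alt, aln.records[j], cols)
            for alt, cols in zip(sig.alternatives, sig.columns)
        )
        if best <= m:
            offenders.append(aln.records[j].id)
        min_nt = min(min_nt, best)
    return VerificationReport(
        all_targets_match=all_match,
        min_nontarget_mismatches=int(min_nt),
        offending_ids=tuple(offenders),
    )
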