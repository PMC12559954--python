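"""Core data model: IUPAC symbol algebra, annotated alignments, and readers.

The alignment is the substrate of every downstream stage: signature mining,
barcode-gap distances, coordinate mapping, and richness clustering all
operate on an :class:`AnnotatedAlignment`, which couples equal-length
IUPAC-coded sequences with a per-sequence taxonomic lineage, role flags
(legitype / nucleotype-derived / reference), and a map of rRNA-operon
regions (SSU, ITS1, 5.8S, ITS2, LSU) to alignment-column intervals.

Symbols are canonicalised to lower case; the alphabet is DNA ('t', not 'u')
because diagnostic signatures are conventionally printed as DNA even though
the markers are rRNA genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

#: Taxonomic ranks, highest to lowest, used in every lineage mapping.
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

#: Recognised role flags for a sequence record.
ROLES: frozenset[str] = frozenset({"legitype", "nucleotype-derived", "reference"})

#: rRNA-operon region names, 5' to 3'.
REGION_NAMES: tuple[str, ...] = ("SSU", "ITS1", "5.8S", "ITS2", "LSU")

# IUPAC nucleotide codes -> set of unambiguous bases. The gap '-' expands
# to the empty set and is therefore compatible with nothing.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "a": frozenset("a"),
    "c": frozenset("c"),
    "g": frozenset("g"),
    "t": frozenset("t"),
    "r": frozenset("ag"),
    "y": frozenset("ct"),
    "s": frozenset("cg"),
    "w": frozenset("at"),
    "k": frozenset("gt"),
    "m": frozenset("ac"),
    "b": frozenset("cgt"),
    "d": frozenset("agt"),
    "h": frozenset("act"),
    "v": frozenset("acg"),
    "n": frozenset("acgt"),
    "-": frozenset(),
}

_BASE_BIT = {"a": 1, "c": 2, "g": 4, "t": 8}

#: IUPAC code -> 4-bit base mask (a=1, c=2, g=4, t=8); gap is 0.
IUPAC_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_EXPANSION.items()
}

_MASK_TO_CODE = {mask: code for code, mask in IUPAC_MASK.items() if mask}

# ASCII lookup tables for vectorised encoding.
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _ENCODE_LUT[ord(_c)] = _m
    _ENCODE_LUT[ord(_c.upper())] = _m


class AlignmentError(ValueError):
    """Raised for malformed alignments, taxonomy tables, or region maps."""


def canonicalize(seq: str) -> str:
    """Lower-case a sequence and normalise '?'->'n', '.'->'-' (with a warning)."""
    s = seq.lower()
    if "?" in s or "." in s:
        warnings.warn("normalising '?' to 'n' and '.' to '-'", stacklevel=2)
        s = s.replace("?", "n").replace(".", "-")
    return s


def validate_symbols(seq: str, where: str = "") -> None:
    bad = set(seq) - set(IUPAC_EXPANSION)
    if bad:
        raise AlignmentError(
            f"non-IUPAC character {sorted(bad)!r}" + (f" in {where}" if where else "")
        )


def symbols_compatible(a: str, b: str) -> bool:
    """True iff the IUPAC expansions of *a* and *b* intersect.

    Any comparison involving the gap symbol '-' is False: a gap matches
    nothing, not even another gap.
    """
    return bool(IUPAC_MASK[a.lower()] & IUPAC_MASK[b.lower()])


def union_symbol(bases: Iterable[str]) -> str:
    """The unique IUPAC code whose expansion equals the union of *bases*.

    *bases* must be a non-empty collection of unambiguous bases {a,c,g,t}.
    """
    mask = 0
    n = 0
    for b in bases:
        bit = _BASE_BIT.get(b.lower())
        if bit is None:
            raise AlignmentError(f"not an unambiguous base: {b!r}")
        mask |= bit
        n += 1
    if n == 0 or mask == 0:
        raise AlignmentError("no consensus: empty base set")
    return _MASK_TO_CODE[mask]


def encode(seq: str) -> np.ndarray:
    """Encode a canonical IUPAC string as a uint8 array of base masks."""
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        validate_symbols(seq)  # raises with the offending characters
    return arr


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its lineage and role flags."""

    id: str
    aligned: str
    lineage: Mapping[str, str] = field(default_factory=dict)
    roles: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "aligned", canonicalize(self.aligned))
        validate_symbols(self.aligned, where=self.id)
        unknown_roles = set(self.roles) - ROLES
        if unknown_roles:
            raise AlignmentError(f"unknown roles {sorted(unknown_roles)} for {self.id}")
        unknown_ranks = set(self.lineage) - set(RANKS)
        if unknown_ranks:
            raise AlignmentError(f"unknown ranks {sorted(unknown_ranks)} for {self.id}")

    def taxon(self, rank: str) -> str | None:
        """The record's taxon name at *rank*, or None if unannotated."""
        name = self.lineage.get(rank, "")
        return name or None


@dataclass(frozen=True)
class RegionMap:
    """Ordered, non-overlapping rRNA-region intervals on alignment columns.

    Input intervals are 1-based inclusive (the convention of printed region
    tables); internally they are stored half-open 0-based.
    """

    regions: tuple[tuple[str, int, int], ...]  # (name, start0, end0) half-open

    @classmethod
    def from_inclusive(cls, rows: Iterable[tuple[str, int, int]]) -> "RegionMap":
        out = []
        for name, start1, end1 in rows:
            if name not in REGION_NAMES:
                raise AlignmentError(f"unknown region name {name!r}")
            if not (1 <= start1 <= end1):
                raise AlignmentError(f"bad interval for {name}: {start1}-{end1}")
            out.append((name, start1 - 1, end1))
        for (na, _, ea), (nb, sb, _) in zip(out, out[1:]):
            if sb < ea:
                raise AlignmentError(f"regions {na} and {nb} overlap or are out of order")
        return cls(tuple(out))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.regions)

    def interval(self, name: str) -> tuple[int, int]:
        """Half-open 0-based column interval of region *name*."""
        for rname, s, e in self.regions:
            if rname == name:
                return s, e
        raise AlignmentError(f"region {name!r} not in map")

    def check_width(self, width: int) -> None:
        if self.regions and self.regions[-1][2] > width:
            raise AlignmentError("region map extends beyond alignment width")


@dataclass
class AnnotatedAlignment:
    """Equal-length IUPAC records + taxonomy + region map."""

    records: list[SequenceRecord]
    region_map: RegionMap
    _masks: np.ndarray | None = field(default=None, repr=False, compare=False)
    _chars: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        widths = {len(r.aligned) for r in self.records}
        if len(widths) != 1:
            raise AlignmentError("unequal lengths among aligned records")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids")
        self.region_map.check_width(self.width)

    @property
    def width(self) -> int:
        return len(self.records[0].aligned)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def record(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise AlignmentError(f"unknown sequence id {seq_id!r}")

    def index_of(self, seq_id: str) -> int:
        for i, r in enumerate(self.records):
            if r.id == seq_id:
                return i
        raise AlignmentError(f"unknown sequence id {seq_id!r}")

    @property
    def masks(self) -> np.ndarray:
        """(n_records, width) uint8 matrix of IUPAC base masks (gap = 0)."""
        if self._masks is None:
            self._masks = np.vstack([encode(r.aligned) for r in self.records])
        return self._masks

    @property
    def chars(self) -> np.ndarray:
        """(n_records, width) uint8 matrix of ASCII codes of canonical symbols."""
        if self._chars is None:
            self._chars = np.vstack(
                [np.frombuffer(r.aligned.encode("ascii"), dtype=np.uint8) for r in self.records]
            )
        return self._chars

    def members(self, taxon: str, rank: str | None = None, *,
                include_reference: bool = False) -> list[int]:
        """Indices of records assigned to *taxon* (searched over all ranks,
        or at *rank* only). Reference records are excluded unless requested."""
        hits = []
        for i, r in enumerate(self.records):
            if not include_reference and "reference" in r.roles:
                continue
            if rank is not None:
                if r.taxon(rank) == taxon:
                    hits.append(i)
            elif taxon in (r.lineage.get(k, "") for k in RANKS):
                hits.append(i)
        return hits

    def non_members(self, taxon: str, rank: str | None = None, *,
                    contrast_rank: str | None = None,
                    include_reference: bool = False) -> list[int]:
        """Indices of records NOT assigned to *taxon*.

        With *contrast_rank*, restrict to non-members that share the target's
        taxon at that higher rank (the "closely related species" universe).
        """
        member = set(self.members(taxon, rank, include_reference=True))
        scope: set[str] | None = None
        if contrast_rank is not None:
            scope = {
                t for i in member
                if (t := self.records[i].taxon(contrast_rank)) is not None
            }
        hits = []
        for i, r in enumerate(self.records):
            if i in member:
                continue
            if not include_reference and "reference" in r.roles:
                continue
            if scope is not None and r.taxon(contrast_rank) not in scope:
                continue
            hits.append(i)
        return hits


def _read_table(path: str | Path) -> list[list[str]]:
    """Read a TSV tolerant of CRLF and '#' comment lines."""
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\r")
        if not line or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def read_taxonomy(path: str | Path) -> dict[str, tuple[dict[str, str], frozenset[str]]]:
    """Read the taxonomy TSV: id, phylum..species, roles (';'-separated).

    Empty cells above species are allowed (incertae sedis). A header row
    starting with 'id' is skipped.
    """
    out: dict[str, tuple[dict[str, str], frozenset[str]]] = {}
    for row in _read_table(path):
        if row[0].lower() == "id":
            continue
        if len(row) < len(RANKS) + 1:
            row = row + [""] * (len(RANKS) + 1 - len(row))
        seq_id = row[0]
        lineage = {rank: row[i + 1].strip() for i, rank in enumerate(RANKS) if row[i + 1].strip()}
        roles = frozenset(
            r.strip() for r in (row[len(RANKS) + 1] if len(row) > len(RANKS) + 1 else "").split(";")
            if r.strip()
        )
        out[seq_id] = (lineage, roles)
    return out


def read_region_map(path: str | Path) -> RegionMap:
    """Read the region-map TSV: name, start, end (1-based inclusive columns)."""
    rows = []
    for row in _read_table(path):
        if row[0].lower() in ("region", "name"):
            continue
        if len(row) < 3:
            raise AlignmentError(f"region row too short: {row}")
        rows.append((row[0], int(row[1]), int(row[2])))
    return RegionMap.from_inclusive(rows)


def read_alignment_fasta(
    path: str | Path,
    taxonomy: str | Path,
    regions: str | Path,
) -> AnnotatedAlignment:
    """Read an aligned FASTA plus taxonomy and region-map TSVs.

    Every FASTA id must be present in the taxonomy table; records must be
    equal length; symbols outside the IUPAC alphabet are rejected.
    """
    tax = read_taxonomy(taxonomy)
    region_map = read_region_map(regions)
    records = []
    widths = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in tax:
            raise AlignmentError(f"unlabelled sequence {rec.id!r}: id missing from taxonomy")
        lineage, roles = tax[rec.id]
        seq = str(rec.seq)
        widths.add(len(seq))
        records.append(SequenceRecord(rec.id, seq, lineage, roles))
    if len(widths) > 1:
        raise AlignmentError("unequal lengths among aligned records")
    return AnnotatedAlignment(records, region_map)


def write_alignment_fasta(aln: AnnotatedAlignment, path: str | Path, width: int = 80) -> None:
    """Write the alignment as wrapped FASTA (canonical lower case)."""
    with open(path, "w") as fh:
        for r in aln.records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.aligned), width):
                fh.write(r.aligned[i : i + width] + "\n")


def write_taxonomy(aln: AnnotatedAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(RANKS) + "\troles\n")
        for r in aln.records:
            cells = [r.lineage.get(rank, "") for rank in RANKS]
            fh.write(r.id + "\t" + "\t".join(cells) + "\t" + ";".join(sorted(r.roles)) + "\n")


def write_region_map(region_map: RegionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tstart\tend\n")
        for name, s0, e0 in region_map.regions:
            fh.write(f"{name}\t{s0 + 1}\t{e0}\n")
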