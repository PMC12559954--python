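"""Diagnosis rendering and new-taxon tallies.

Two jobs live here. First, a :class:`TaxonLedger` of newly proposed taxa
(the packaged fixture transcribes the study's summary table of new species
plus the family names from the formal descriptions) supports per-rank counts
of distinct newly proposed names — deduplicated across rows, with
previously described names and new combinations excluded — and the count of
distinct highest-rank novel lineages.

Second, :func:`render_diagnosis` assembles the formulaic molecular Diagnosis
paragraph: diagnostic signatures with dual coordinates and a number-word
mismatch budget ("no/one/two/three mismatch(es) allowed"), intra- and
interspecific percentages at one decimal, and the monophyly clause listing
the covered sequence ids. Rendering is deterministic and round-trips
through :func:`parse_diagnosis`.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .alignment import RANKS

_RANK_COLS = {rank: (rank, f"{rank}_status") for rank in RANKS}

_M_WORDS = {0: "no mismatch", 1: "one mismatch", 2: "two mismatches", 3: "three mismatches"}
_WORDS_M = {v: k for k, v in _M_WORDS.items()}


class LedgerError(ValueError):
    pass


@dataclass
class TaxonLedger:
    """Ranked taxon table with per-rank novelty flags."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        for rank in RANKS:
            name_col, status_col = _RANK_COLS[rank]
            if name_col not in self.rows.columns or status_col not in self.rows.columns:
                raise LedgerError(f"ledger missing columns for rank {rank!r}")
            if self.rows[name_col].isna().any() or (self.rows[name_col] == "").any():
                raise LedgerError(f"ledger has empty {rank} names")
        bad = set(self.rows["species_status"]) - {"new", "combination"}
        if bad:
            raise LedgerError(f"unknown species_status values {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.rows)


def load_table1() -> TaxonLedger:
    """Load the packaged new-taxon fixture, verifying its checksum."""
    data = resources.files("sigtax.data")
    raw = (data / "table1.tsv").read_bytes()
    expected = (data / "table1.sha256").read_text().strip()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise LedgerError("table1.tsv checksum mismatch: fixture corrupted")
    return read_ledger_bytes(raw)


def read_ledger(path: str | Path) -> TaxonLedger:
    return read_ledger_bytes(Path(path).read_bytes())


def read_ledger_bytes(raw: bytes) -> TaxonLedger:
    import io

    df = pd.read_csv(io.BytesIO(raw), sep="\t", comment="#", dtype=str).fillna("")
    return TaxonLedger(df)


def count_new_taxa(ledger: TaxonLedger, rank: str) -> int:
    """Distinct taxon names at *rank* flagged "new".

    Names shared across rows count once; previously described names are
    excluded; at species rank, new combinations are not new species.
    """
    if rank not in RANKS:
        raise LedgerError(f"bad rank {rank!r}")
    name_col, status_col = _RANK_COLS[rank]
    mask = ledger.rows[status_col] == "new"
    return int(ledger.rows.loc[mask, name_col].nunique())


def new_taxon_counts(ledger: TaxonLedger) -> dict[str, int]:
    """Per-rank distinct new-taxon counts for the whole ledger."""
    return {rank: count_new_taxa(ledger, rank) for rank in RANKS}


def distinct_highest_rank_lineages(ledger: TaxonLedger) -> int:
    """Distinct taxa over each row's highest newly proposed rank.

    A row whose highest novelty is a new class contributes that class; two
    rows sharing it contribute one lineage. Rows with no new rank at all are
    excluded with a warning.
    """
    lineages: set[tuple[str, str]] = set()
    for _, row in ledger.rows.iterrows():
        for rank in RANKS:  # highest rank first
            name_col, status_col = _RANK_COLS[rank]
            if row[status_col] == "new":
                lineages.add((rank, row[name_col]))
                break
        else:
            warnings.warn(f"row {row['species']!r} has no newly proposed rank")
    return len(lineages)


# ---------------------------------------------------------------------------
# Diagnosis rendering

@dataclass(frozen=True)
class SignatureLine:
    region: str
    positions: str  # dual-coordinate description, e.g. "119–133 in type species"
    motif: str      # possibly "... OR ..."
    allowed_mismatches: int


@dataclass(frozen=True)
class DiagnosisRecord:
    taxon: str
    parent: str
    signatures: tuple[SignatureLine, ...]
    intra: tuple[tuple[str, float], ...] = ()  # (region, fraction)
    inter: tuple[tuple[str, float], ...] = ()
    no_gap_regions: tuple[str, ...] = ()
    covered_ids: tuple[str, ...] = ()


def _m_phrase(m: int) -> str:
    if m in _M_WORDS:
        return f"{_M_WORDS[m]} allowed"
    warnings.warn(f"mismatch budget {m} exceeds the conventional wording range")
    return f"{m} mismatches allowed"


def _pct(x: float) -> str:
    return f"{100.0 * x:.1f}%"


def _join(parts: list[str]) -> str:
    if len(parts) <= 1:
        return "".join(parts)
    if len(parts) == 2:
        return " and ".join(parts)
    return ", ".join(parts[:-1]) + ", and " + parts[-1]


def render_diagnosis(record: DiagnosisRecord) -> str:
    """Render the molecular Diagnosis paragraph in the conventional format."""
    sig_parts = [
        f"{s.region} (positions {s.positions} {s.motif}; {_m_phrase(s.allowed_mismatches)})"
        for s in record.signatures
    ]
    plural = "signatures" if len(record.signatures) != 1 else "signature"
    out = (
        f"Distinguishable from other fungi based on diagnostic nucleotide "
        f"{plural} in {_join(sig_parts)}."
    )
    if record.intra:
        intra_parts = [f"up to {_pct(v)} in {r}" for r, v in record.intra]
        out += f" Intraspecific variation {_join(intra_parts)}."
    if record.inter:
        inter_parts = [f"at least {_pct(v)} in {r}" for r, v in record.inter]
        out += f" Interspecific distance {_join(inter_parts)}."
        for region in record.no_gap_regions:
            out += f" There is no clear barcode gap in {region}."
    if record.covered_ids:
        out += (
            f" Forms a monophyletic, least inclusive clade in {record.parent}, "
            f"covering sequences {_join(list(record.covered_ids))}."
        )
    return out


_SIG_RE = re.compile(
    r"(?P<region>[A-Za-z0-9.]+)\s"
    r"\(positions (?P<positions>.+?) (?P<motif>[acgtryswkmbdhvn-]+(?: OR [acgtryswkmbdhvn-]+)*); "
    r"(?P<m>no mismatch|one mismatch|two mismatches|three mismatches|\d+ mismatches) allowed\)"
)
_REGION_PAT = r"[A-Za-z0-9]+(?:\.[A-Za-z0-9]+)*"
_INTRA_RE = re.compile(rf"up to (?P<pct>[\d.]+)% in (?P<region>{_REGION_PAT})")
_INTER_RE = re.compile(rf"at least (?P<pct>[\d.]+)% in (?P<region>{_REGION_PAT})")
_NOGAP_RE = re.compile(rf"no clear barcode gap in (?P<region>{_REGION_PAT})")
_CLADE_RE = re.compile(
    r"Forms a monophyletic, least inclusive clade in (?P<parent>[^,]+), "
    r"covering sequences (?P<ids>.+?)\."
)


def parse_diagnosis(text: str, taxon: str = "") -> DiagnosisRecord:
    """Recover the structured fields from a rendered Diagnosis paragraph."""
    sigs = []
    for m in _SIG_RE.finditer(text):
        phrase = m.group("m")
        budget = _WORDS_M.get(phrase, None)
        if budget is None:
            budget = int(phrase.split()[0])
        sigs.append(
            SignatureLine(
                region=m.group("region"),
                positions=m.group("positions"),
                motif=m.group("motif"),
                allowed_mismatches=budget,
            )
        )
    intra = tuple(
        (m.group("region"), round(float(m.group("pct")) / 100.0, 6))
        for m in _INTRA_RE.finditer(text)
    )
    inter = tuple(
        (m.group("region"), round(float(m.group("pct")) / 100.0, 6))
        for m in _INTER_RE.finditer(text)
    )
    no_gap = tuple(m.group("region") for m in _NOGAP_RE.finditer(text))
    clade = _CLADE_RE.search(text)
    parent, ids = "", ()
    if clade:
        parent = clade.group("parent").strip()
        raw = clade.group("ids")
        ids = tuple(
            t.strip() for t in raw.replace(", and ", ", ").replace(" and ", ", ").split(",")
            if t.strip()
        )
    return DiagnosisRecord(
        taxon=taxon,
        parent=parent,
        signatures=tuple(sigs),
        intra=intra,
        inter=inter,
        no_gap_regions=no_gap,
        covered_ids=ids,
    )
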