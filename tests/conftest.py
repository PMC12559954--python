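"""Shared fixtures and independent pure-python oracles.

The oracles deliberately avoid the package's numpy/bitmask machinery: they
re-derive IUPAC compatibility from the expansion table with sets and plain
loops, so tests compare two genuinely different routes to each quantity.
"""

from __future__ import annotations

import random

import pytest

from sigtax.alignment import AnnotatedAlignment, RegionMap, SequenceRecord

# independent IUPAC expansion table (typed in, not imported)
ORACLE_EXPANSION = {
    "a": {"a"}, "c": {"c"}, "g": {"g"}, "t": {"t"},
    "r": {"a", "g"}, "y": {"c", "t"}, "s": {"c", "g"}, "w": {"a", "t"},
    "k": {"g", "t"}, "m": {"a", "c"}, "b": {"c", "g", "t"},
    "d": {"a", "g", "t"}, "h": {"a", "c", "t"}, "v": {"a", "c", "g"},
    "n": {"a", "c", "g", "t"}, "-": set(),
}

IUPAC_CODES = [c for c in ORACLE_EXPANSION if c != "-"]


def oracle_compatible(x: str, y: str) -> bool:
    return bool(ORACLE_EXPANSION[x] & ORACLE_EXPANSION[y])


def oracle_p_distance(a: str, b: str, min_overlap: int = 1) -> float | None:
    """Naive per-site loop: exclude sites with '-' or 'n' in either sequence;
    count non-compatible symbol pairs among the rest."""
    comparable = 0
    diffs = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-" or x == "n" or y == "n":
            continue
        comparable += 1
        if not oracle_compatible(x, y):
            diffs += 1
    if comparable < min_overlap:
        return None
    return diffs / comparable


def oracle_mismatch_count(motif: str, window: str) -> int:
    return sum(not oracle_compatible(m, s) for m, s in zip(motif, window))


def oracle_union(symbols: str) -> str:
    """Consensus code of a column from the expansion table."""
    bases = set()
    for s in symbols:
        bases |= ORACLE_EXPANSION[s]
    for code, exp in ORACLE_EXPANSION.items():
        if exp == bases:
            return code
    raise AssertionError("no IUPAC code for base set")


def make_alignment(
    seqs: dict[str, str],
    species: dict[str, str] | None = None,
    regions: list[tuple[str, int, int]] | None = None,
    roles: dict[str, set[str]] | None = None,
) -> AnnotatedAlignment:
    """Build a toy AnnotatedAlignment; the whole width is ITS2 by default."""
    width = len(next(iter(seqs.values())))
    if regions is None:
        regions = [("ITS2", 1, width)]
    records = []
    for sid, seq in seqs.items():
        sp = (species or {}).get(sid, sid.rsplit("_", 1)[0])
        records.append(
            SequenceRecord(
                sid, seq,
                lineage={"genus": sp.split()[0] if " " in sp else "Genus", "species": sp},
                roles=frozenset((roles or {}).get(sid, set())),
            )
        )
    return AnnotatedAlignment(records, RegionMap.from_inclusive(regions))


def random_toy_alignment(
    rng: random.Random,
    n_species: int = 3,
    reads_per_species: int = 2,
    width: int = 60,
    gap_rate: float = 0.03,
    ambig_rate: float = 0.03,
) -> AnnotatedAlignment:
    """Random small alignment with species structure, gaps, and ambiguity."""
    bases = "acgt"
    seqs: dict[str, str] = {}
    species: dict[str, str] = {}
    for s in range(n_species):
        anc = [rng.choice(bases) for _ in range(width)]
        for r in range(reads_per_species):
            read = list(anc)
            for i in range(width):
                u = rng.random()
                if u < gap_rate:
                    read[i] = "-"
                elif u < gap_rate + ambig_rate:
                    read[i] = rng.choice("rymwskn")
                elif u < gap_rate + ambig_rate + 0.02:
                    read[i] = rng.choice(bases)
            sid = f"sp{s}_r{r}"
            seqs[sid] = "".join(read)
            species[sid] = f"Species {s}"
    return make_alignment(seqs, species)


@pytest.fixture
def toy_aln() -> AnnotatedAlignment:
    return make_alignment(
        {
            "A_r1": "acgtacgtacgtacgtacgt",
            "A_r2": "acgtacgtacgtacgtacgt",
            "B_r1": "acgtacttacgtacgaacgt",
            "C_r1": "ttgaacgaatgtcagaaact",
        },
        species={"A_r1": "Taxon A", "A_r2": "Taxon A", "B_r1": "Taxon B", "C_r1": "Taxon C"},
    )
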