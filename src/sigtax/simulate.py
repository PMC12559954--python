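"""Synthetic rRNA-operon taxon sets with known truth.

The study's own reads live in sequence archives and are not redistributable,
so every downstream stage is exercised on generated alignments with a fully
known ground truth: a set of species whose ancestors are diverged from a
common root by at least ``d_inter`` per region (so a barcode gap exists by
construction), reads per species within ``d_intra_max`` of each other,
optional IUPAC ambiguity recoding, species-level indels realized as shared
gap columns, homopolymer/microsatellite length noise, and planted diagnostic
signatures that are guaranteed to separate their target from every other
species by at least a configured mismatch margin.

Substitutions follow a Jukes-Cantor-style uniform model: a mutated site
takes one of the three other bases uniformly. Divergence control is by
construction plus rejection: species ancestors are resampled until all
pairwise per-region p-distances reach ``d_inter + d_intra_max`` (so that
read-level interspecific distances still reach ``d_inter`` after
intraspecific noise), and read substitution counts are capped at
``d_intra_max * L / 2`` per region so intraspecific pairs cannot exceed
``d_intra_max``.

Determinism: a fixed seed gives a bit-identical alignment. Per-species
randomness comes from substreams seeded by (seed, species index), so adding
a species does not reshuffle the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import AnnotatedAlignment, RegionMap, SequenceRecord

_BASES = np.array(list("acgt"))
# 2-base degenerate code for each unordered pair of bases
_PAIR_CODE = {
    frozenset("ag"): "r", frozenset("ct"): "y", frozenset("cg"): "s",
    frozenset("at"): "w", frozenset("gt"): "k", frozenset("ac"): "m",
}

DEFAULT_REGION_LENGTHS: dict[str, int] = {
    "SSU": 1700, "ITS1": 250, "5.8S": 160, "ITS2": 300, "LSU": 1400,
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSpec:
    """A diagnostic signature to plant: window of ``length`` in ``region`` of
    ``target`` (species name or index), separated from every other species
    by at least ``margin`` mismatches."""

    target: int | str
    region: str = "ITS2"
    length: int = 20
    margin: int = 2

    def __post_init__(self) -> None:
        if self.length < 8:
            raise SimulationError("planted motif length must be >= 8")
        if self.margin < 1:
            raise SimulationError("planted margin must be >= 1")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_species: int = 6
    reads_per_species: tuple[int, int] = (3, 6)
    region_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LENGTHS)
    )
    d_inter: float = 0.10
    d_intra_max: float = 0.02
    ambiguity_rate: float = 0.005
    indel_rate: float = 0.0
    repeat_noise: bool = False
    planted: tuple[PlantedSpec, ...] = ()
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.d_intra_max < self.d_inter <= 1):
            raise SimulationError("need 0 <= d_intra_max < d_inter <= 1")
        for name, rate in (
            ("ambiguity_rate", self.ambiguity_rate),
            ("indel_rate", self.indel_rate),
        ):
            if not (0 <= rate <= 1):
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.n_species < 1 or self.reads_per_species[0] < 1:
            raise SimulationError("need at least one species and one read")
        if self.reads_per_species[0] > self.reads_per_species[1]:
            raise SimulationError("reads_per_species range inverted")


@dataclass(frozen=True)
class PlantedTruth:
    target: str
    region: str
    columns: tuple[int, int]  # half-open alignment columns
    motif: str
    margin: int


@dataclass
class SimulationTruth:
    species: list[str]
    read_ids: dict[str, list[str]]
    tree_newick: str
    planted: list[PlantedTruth]
    realized_max_intra: dict[tuple[str, str], float | None]
    realized_min_inter: dict[str, float | None]


def mutate_sequence(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``p_sub``; a
    mutated site takes one of the three other bases uniformly."""
    if not (0 <= p_sub <= 1):
        raise SimulationError("p_sub must be in [0, 1]")
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < p_sub
    n = int(hit.sum())
    if n:
        # shift by 1-3 in base order: always a different base, uniform
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return "".join(arr)


def _mutate_k_sites(seq: np.ndarray, k: int, forbidden: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly k sites chosen outside ``forbidden`` (bool mask)."""
    out = seq.copy()
    allowed = np.nonzero(~forbidden)[0]
    if k == 0 or allowed.size == 0:
        return out
    sites = rng.choice(allowed, size=min(k, allowed.size), replace=False)
    idx = np.searchsorted(_BASES, out[sites])
    out[sites] = _BASES[(idx + rng.integers(1, 4, size=sites.size)) % 4]
    return out


def _hamming_frac(a: np.ndarray, b: np.ndarray) -> float:
    return float((a != b).mean())


def _species_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _plant_repeats(root: np.ndarray, regions: dict[str, tuple[int, int]],
                   rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Write homopolymer (>=6 nt) and dinucleotide (>=4 unit) loci into the
    root within ITS1/ITS2; returns (start, unit_len, n_units) loci."""
    loci = []
    for region in ("ITS1", "ITS2"):
        if region not in regions:
            continue
        lo, hi = regions[region]
        span = hi - lo
        if span < 60:
            continue
        # one homopolymer and one dinucleotide repeat per ITS region
        h_start = lo + int(rng.integers(5, span // 2 - 10))
        h_len = int(rng.integers(6, 9))
        root[h_start : h_start + h_len] = rng.choice(_BASES)
        loci.append((h_start, 1, h_len))
        d_start = lo + int(rng.integers(span // 2, span - 15))
        d_units = int(rng.integers(4, 6))
        unit = rng.choice(_BASES, size=2)
        for u in range(d_units):
            root[d_start + 2 * u : d_start + 2 * u + 2] = unit
        loci.append((d_start, 2, d_units))
    return loci


def simulate_taxon_set(config: SyntheticConfig) -> tuple[AnnotatedAlignment, SimulationTruth]:
    """Generate an annotated alignment plus its ground truth.

    Deterministic for a fixed config; raises "cannot achieve divergence"
    when the requested interspecific distance is infeasible.
    """
    if config.d_inter + config.d_intra_max > 0.70:
        raise SimulationError("cannot achieve divergence: d_inter too large")
    region_items = [(n, l) for n, l in config.region_lengths.items() if l > 0]
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, length in region_items:
        offsets[name] = (pos, pos + length)
        pos += length
    width = pos
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    root = master.choice(_BASES, size=width)

    repeat_loci: list[tuple[int, int, int]] = []
    if config.repeat_noise:
        repeat_loci = _plant_repeats(root, offsets, master)

    species = [f"Simulella sp{i + 1:02d}" for i in range(config.n_species)]

    # resolve planted targets and reserve their windows before noise
    planted_resolved: list[tuple[int, PlantedSpec, tuple[int, int]]] = []
    protected = np.zeros(width, dtype=bool)
    for spec in config.planted:
        t_idx = spec.target if isinstance(spec.target, int) else species.index(spec.target)
        if spec.region not in offsets:
            raise SimulationError(f"planted region {spec.region!r} has zero length")
        lo, hi = offsets[spec.region]
        if hi - lo < spec.length:
            raise SimulationError("planted motif longer than its region")
        start = lo + int(master.integers(0, hi - lo - spec.length + 1))
        planted_resolved.append((t_idx, spec, (start, start + spec.length)))
        protected[start : start + spec.length] = True

    # species ancestors: rejection-sample until every pair reaches
    # d_inter + d_intra_max in every region (so read pairs reach d_inter)
    target_div = config.d_inter + config.d_intra_max
    p_anc = min(0.75, max(target_div * 0.9, 1.5 * target_div - 0.5 * target_div**2))
    ancestors: list[np.ndarray] = []
    for i in range(config.n_species):
        rng_i = _species_rng(config.seed, i + 1)
        for attempt in range(config.max_attempts):
            cand = np.array(list(mutate_sequence("".join(root), p_anc, rng_i)))
            ok = all(
                _hamming_frac(cand[lo:hi], prev[lo:hi]) >= target_div
                for prev in ancestors
                for lo, hi in offsets.values()
            )
            if ok:
                ancestors.append(cand)
                break
        else:
            raise SimulationError("cannot achieve divergence between species ancestors")

    # plant signatures: fresh random motif in the target; other species are
    # pushed to >= margin mismatches within the window if not already there
    planted_truth: list[PlantedTruth] = []
    for t_idx, spec, (lo, hi) in planted_resolved:
        motif = master.choice(_BASES, size=hi - lo)
        ancestors[t_idx][lo:hi] = motif
        for j, anc in enumerate(ancestors):
            if j == t_idx:
                continue
            window = anc[lo:hi]
            matching = np.nonzero(window == motif)[0]
            deficit = spec.margin - int((window != motif).sum())
            if deficit > 0:
                sites = master.choice(matching, size=deficit, replace=False)
                idx = np.searchsorted(_BASES, window[sites])
                window[sites] = _BASES[(idx + master.integers(1, 4, size=deficit)) % 4]
                anc[lo:hi] = window
        planted_truth.append(
            PlantedTruth(species[t_idx], spec.region, (lo, hi), "".join(motif), spec.margin)
        )

    # species-level indels: shared gap columns for the species' reads;
    # 'insertion' events gap every species EXCEPT the chosen one
    species_gap = np.zeros((config.n_species, width), dtype=bool)
    if config.indel_rate > 0:
        n_events = master.binomial(width, config.indel_rate)
        for _ in range(n_events):
            site = int(master.integers(0, width - 3))
            length = int(master.integers(1, 4))
            sp = int(master.integers(0, config.n_species))
            span = slice(site, site + length)
            if protected[span].any():
                continue
            if master.random() < 0.5:
                species_gap[sp, span] = True
            else:
                species_gap[:, span] = True
                species_gap[sp, span] = False

    # reads per species: substitution counts capped so that pairwise
    # intraspecific distances cannot exceed d_intra_max
    records: list[SequenceRecord] = []
    read_ids: dict[str, list[str]] = {}
    lineage_base = {
        "phylum": "Simulomycota", "class": "Simulomycetes",
        "order": "Simulales", "family": "Simulaceae", "genus": "Simulella",
    }
    for i, sp_name in enumerate(species):
        rng_i = _species_rng(config.seed, 10_000 + i)
        n_reads = int(rng_i.integers(config.reads_per_species[0],
                                     config.reads_per_species[1] + 1))
        ids = []
        for r in range(n_reads):
            read = ancestors[i].copy()
            for name, (lo, hi) in offsets.items():
                cap = int(np.floor(config.d_intra_max * (hi - lo) / 2.0))
                k = min(int(rng_i.binomial(hi - lo, config.d_intra_max / 2.0)), cap)
                read[lo:hi] = _mutate_k_sites(read[lo:hi], k, protected[lo:hi], rng_i)
            # IUPAC ambiguity recoding: base -> 2-base degenerate code
            if config.ambiguity_rate > 0:
                hit = (rng_i.random(width) < config.ambiguity_rate) & ~protected
                for site in np.nonzero(hit)[0]:
                    other = _BASES[(np.searchsorted(_BASES, read[site])
                                    + rng_i.integers(1, 4)) % 4]
                    read[site] = _PAIR_CODE[frozenset((str(read[site]), str(other)))]
            # repeat-length noise: drop 1-3 units at annotated loci (gaps)
            gaps = species_gap[i].copy()
            if config.repeat_noise:
                for start, unit, units in repeat_loci:
                    if protected[start : start + unit * units].any():
                        continue
                    if rng_i.random() < 0.5:
                        drop = int(rng_i.integers(1, min(3, units - 1) + 1))
                        gaps[start : start + unit * drop] = True
            seq = read.copy()
            seq[gaps] = "-"
            rid = f"sp{i + 1:02d}_r{r + 1}"
            roles = frozenset({"legitype"}) if r == 0 else frozenset()
            records.append(
                SequenceRecord(
                    rid, "".join(seq),
                    lineage={**lineage_base, "species": sp_name},
                    roles=roles,
                )
            )
            ids.append(rid)
        read_ids[sp_name] = ids

    region_map = RegionMap.from_inclusive(
        [(name, lo + 1, hi) for name, (lo, hi) in offsets.items()]
    )
    aln = AnnotatedAlignment(records, region_map)

    # post-hoc realized distance summaries (gap-exclude policy)
    from .distances import DistancePolicy, max_intraspecific, min_interspecific

    policy = DistancePolicy(min_overlap=10)
    realized_intra: dict[tuple[str, str], float | None] = {}
    realized_inter: dict[str, float | None] = {}
    for name in offsets:
        best_inter: float | None = None
        for sp_name in species:
            intra = max_intraspecific(aln, sp_name, name, policy)
            realized_intra[(sp_name, name)] = intra.max_intra
            if config.n_species > 1:
                inter = min_interspecific(aln, sp_name, name, policy)
                if inter.min_inter is not None and (
                    best_inter is None or inter.min_inter < best_inter
                ):
                    best_inter = inter.min_inter
        realized_inter[name] = best_inter

    newick = "(" + ",".join(f"{sp.replace(' ', '_')}:{p_anc:.4f}" for sp in species) + ");"
    truth = SimulationTruth(
        species=species,
        read_ids=read_ids,
        tree_newick=newick,
        planted=planted_truth,
        realized_max_intra=realized_intra,
        realized_min_inter=realized_inter,
    )
    return aln, truth
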