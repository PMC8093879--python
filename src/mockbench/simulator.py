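"""ANI-stratified in silico mock community construction.

A mock community is built in stages:

1. the number of member species is drawn from a normal distribution
   (medium complexity: 100 ± 25 species; high: 500 ± 100), rounded and
   truncated at 1;
2. species are sampled uniformly from the candidate pool of the requested
   ANI bin — "identical" (reference genomes themselves, 100% ANI), "high"
   ([99, 99.75]% ANI to the closest same-species reference genome),
   "moderate" ([97, 99)) or "low" ([95, 97)) — with one strain per species
   or 2–10 strains drawn uniformly and capped by availability;
3. strain relative abundances are drawn from a log-normal distribution
   (mean 1, sd 2 on the log scale) and normalized;
4. the paired-read budget N = floor(depth / (2 * read_length)) is split
   across strains as n_i = N * a_i * s_i / sum_j a_j * s_j (abundance times
   genome size), converted to integers by largest-remainder rounding so the
   budget is conserved exactly;
5. error-free 2 x 150 bp read pairs with insert length ~ Normal(200, 25)
   are sampled uniformly across each genome.

Ground truth is emitted under two conventions: the fraction of reads
belonging to each species, and the fraction of cells (reads normalized by
genome size), because classifiers differ in which quantity they estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

from .errors import InfeasibleError, ValidationError
from .reference_db import AniTable, ReferenceDatabase

#: ANI interval (in percent) of each bin; closures follow the study design:
#: high is closed on both ends, moderate and low are half-open.
ANI_BINS: dict[str, tuple[float, float]] = {
    "identical": (100.0, 100.0),
    "high": (99.0, 99.75),
    "moderate": (97.0, 99.0),
    "low": (95.0, 97.0),
}

#: (mu, sigma) of the species-count distribution for the named presets.
DIVERSITY_PRESETS: dict[str, tuple[float, float]] = {
    "medium": (100.0, 25.0),
    "high": (500.0, 100.0),
}

DEFAULT_DEPTH_BASES = 2_100_000_000  # 2.1 Gb
DEFAULT_READ_LENGTH = 150
DEFAULT_INSERT_MEAN = 200.0
DEFAULT_INSERT_SD = 25.0

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MockCommunitySpec:
    """All parameters of one community simulation."""

    ani_bin: str = "identical"
    diversity_mu: float = 100.0
    diversity_sigma: float = 25.0
    strain_mode: str = "single"  # "single" | "multiple"
    total_depth_bases: int = DEFAULT_DEPTH_BASES
    read_length: int = DEFAULT_READ_LENGTH
    insert_mean: float = DEFAULT_INSERT_MEAN
    insert_sd: float = DEFAULT_INSERT_SD
    abundance_log_mean: float = 1.0
    abundance_log_sd: float = 2.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ani_bin not in ANI_BINS:
            raise ValidationError(
                f"unknown ANI bin {self.ani_bin!r}; expected one of {sorted(ANI_BINS)}"
            )
        if self.strain_mode not in ("single", "multiple"):
            raise ValidationError(
                f"strain_mode must be 'single' or 'multiple', got {self.strain_mode!r}"
            )
        if self.diversity_mu <= 0:
            raise ValidationError("diversity_mu must be > 0")
        if self.read_length < 1:
            raise ValidationError("read_length must be >= 1")
        if self.insert_mean < 2 * self.read_length:
            import warnings

            warnings.warn(
                f"insert_mean ({self.insert_mean}) < 2*read_length "
                f"({2 * self.read_length}): mates will overlap",
                stacklevel=2,
            )

    @property
    def total_pairs(self) -> int:
        """Paired-read budget N = floor(depth / (2 * read_length))."""
        return int(self.total_depth_bases // (2 * self.read_length))


@dataclass
class CommunityMember:
    """One genome in a realized community."""

    assembly_id: str
    species_id: str
    relative_abundance: float  # a_i, strain-level, sums to 1 over community
    genome_size: int  # s_i in bases
    n_pairs: int = 0  # n_i, allocated paired reads


@dataclass(frozen=True)
class GroundTruthProfile:
    """Per-species ground truth under both abundance conventions.

    ``read_fraction`` is the proportion of read pairs from each species
    (proportional to a_i * s_i); ``cell_fraction`` is the proportion of
    cells, i.e. reads normalized by genome size (proportional to a_i).
    Both are simplex vectors.
    """

    read_fraction: dict[str, float]
    cell_fraction: dict[str, float]
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReadPair:
    """One simulated pair with full provenance."""

    read_id: str
    mate1: str
    mate2: str
    assembly_id: str
    contig_id: str
    start: int  # 0-based leftmost position of the fragment
    fragment_length: int


@dataclass
class MockCommunity:
    """A realized community: members, ground truth, and (optionally) reads."""

    spec: MockCommunitySpec
    members: list[CommunityMember]
    truth: GroundTruthProfile
    reads: list[ReadPair] | None = None
    output_files: dict[str, str] = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len({m.species_id for m in self.members})


def assign_ani_bin(
    candidate_id: str,
    ani: AniTable,
    reference: ReferenceDatabase,
    species_id: str | None = None,
) -> tuple[str | None, str]:
    """Assign a candidate genome to an ANI bin, or to none.

    Reference genomes themselves are "identical". Otherwise the candidate's
    maximum ANI to (same-species, when ``species_id`` is given) reference
    genomes decides: [99, 99.75] → high, [97, 99) → moderate, [95, 97) → low.
    Below 95% or strictly between 99.75 and 100 the candidate is unbinned.
    Returns (bin_or_None, reason).
    """
    ref_ids = reference.assembly_ids
    if candidate_id in ref_ids:
        return "identical", "reference genome"
    if species_id is not None:
        pool = {r.assembly_id for r in reference.representatives.get(species_id, [])}
    else:
        pool = ref_ids
    values = [
        v for other, v in ani.partners(candidate_id).items() if other in pool
    ]
    if not values:
        return None, "no recorded ANI to any reference genome"
    top = max(values)
    if 99.0 <= top <= 99.75:
        return "high", f"max ANI {top:g}"
    if 97.0 <= top < 99.0:
        return "moderate", f"max ANI {top:g}"
    if 95.0 <= top < 97.0:
        return "low", f"max ANI {top:g}"
    if top < 95.0:
        return None, f"max ANI {top:g} below the 95% species boundary"
    return None, (
        f"max ANI {top:g} above the high bin but not a reference genome"
    )


def draw_species_count(
    mu: float, sigma: float, rng: np.random.Generator
) -> int:
    """One species count: Normal(mu, sigma) rounded, redrawn until >= 1."""
    if mu <= 0:
        raise ValidationError("mu must be > 0")
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    while True:
        n = int(np.rint(rng.normal(mu, sigma)))
        if n >= 1:
            return n


def sample_members(
    bin_pool: Mapping[str, Sequence[str]],
    n_species: int,
    strain_mode: str,
    rng: np.random.Generator,
) -> list[tuple[str, list[str]]]:
    """Sample community composition from a bin's candidate pool.

    Species are drawn uniformly without replacement. In "single" mode each
    species contributes one genome; in "multiple" mode a target strain count
    is drawn uniformly from {2..10} and capped by how many genomes the
    species actually has (never below 1).
    """
    species_ids = sorted(s for s, genomes in bin_pool.items() if genomes)
    if n_species > len(species_ids):
        raise InfeasibleError(
            f"requested {n_species} species but the pool holds only "
            f"{len(species_ids)} (short by {n_species - len(species_ids)})"
        )
    chosen = rng.choice(species_ids, size=n_species, replace=False)
    out: list[tuple[str, list[str]]] = []
    for sp in chosen:
        genomes = sorted(bin_pool[sp])
        if strain_mode == "single":
            k = 1
        elif strain_mode == "multiple":
            target = int(rng.integers(2, 11))
            k = max(1, min(target, len(genomes)))
        else:
            raise ValidationError(f"unknown strain_mode {strain_mode!r}")
        picked = rng.choice(genomes, size=k, replace=False)
        out.append((str(sp), [str(g) for g in picked]))
    return out


def draw_abundances(
    n_members: int,
    log_mean: float,
    log_sd: float,
    rng: np.random.Generator,
    normalize: bool = True,
) -> np.ndarray:
    """Log-normal relative abundances.

    Raw draws are exp(Normal(log_mean, log_sd)); with ``normalize=True``
    (the default) the vector is scaled to sum to 1. ``normalize=False``
    returns the raw draws, useful for checking the distribution itself.
    """
    if n_members < 1:
        raise ValidationError("n_members must be >= 1")
    raw = np.exp(rng.normal(log_mean, log_sd, size=n_members))
    if not normalize:
        return raw
    return raw / raw.sum()


def allocate_reads(
    members: Sequence[CommunityMember], total_pairs: int
) -> list[CommunityMember]:
    """Split the paired-read budget as n_i = N * a_i s_i / sum_j a_j s_j.

    Real-valued shares are converted to integers by largest-remainder
    rounding so that the allocations sum to N exactly. Members are modified
    in place and returned.
    """
    if total_pairs < 0:
        raise ValidationError("total_pairs must be >= 0")
    weights = np.array(
        [m.relative_abundance * m.genome_size for m in members], dtype=float
    )
    if np.any(weights <= 0):
        raise ValidationError("all abundances and genome sizes must be > 0")
    exact = total_pairs * weights / weights.sum()
    floors = np.floor(exact).astype(np.int64)
    shortfall = int(total_pairs - floors.sum())
    if shortfall:
        # one extra pair to the largest fractional remainders; index
        # tie-break keeps the result order-stable
        order = np.lexsort((np.arange(len(members)), -(exact - floors)))
        floors[order[:shortfall]] += 1
    for m, n in zip(members, floors):
        m.n_pairs = int(n)
    return list(members)


def _phred_line(length: int) -> str:
    return "I" * length  # constant Q40; classifiers under test ignore quality


def simulate_read_pairs(
    contigs: Sequence[tuple[str, str]],
    n_pairs: int,
    rng: np.random.Generator,
    assembly_id: str = "genome",
    read_length: int = DEFAULT_READ_LENGTH,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    error_rate: float = 0.0,
) -> Iterator[ReadPair]:
    """Sample error-free paired-end reads uniformly across a genome.

    For each pair a fragment length is drawn from Normal(insert_mean,
    insert_sd), rounded and clamped to at least ``read_length``; a contig is
    chosen with probability proportional to its length and a start position
    uniformly such that the fragment fits (draws that do not fit anywhere
    on the chosen contig are redrawn). Mate 1 is the leading
    ``read_length`` bases of the fragment; mate 2 the reverse complement of
    its trailing ``read_length`` bases. Read IDs encode assembly, contig,
    start and fragment length so every read can be traced to its origin.

    With ``error_rate`` > 0, each base is substituted independently with
    that probability (uniform choice among the other three bases).
    """
    usable = [(cid, seq.upper()) for cid, seq in contigs if len(seq) >= read_length]
    if not usable:
        raise ValidationError(
            f"{assembly_id}: no contig is at least read_length "
            f"({read_length}) bases long"
        )
    lengths = np.array([len(seq) for _, seq in usable], dtype=float)
    probs = lengths / lengths.sum()
    bases = np.frombuffer(b"ACGT", dtype="S1")

    for i in range(n_pairs):
        for _attempt in range(1000):
            ci = int(rng.choice(len(usable), p=probs))
            cid, seq = usable[ci]
            frag = max(read_length, int(np.rint(rng.normal(insert_mean, insert_sd))))
            if frag <= len(seq):
                break
        else:
            raise ValidationError(
                f"{assembly_id}: could not place a fragment after 1000 draws"
            )
        start = int(rng.integers(0, len(seq) - frag + 1))
        fragment = seq[start : start + frag]
        mate1 = fragment[:read_length]
        mate2 = reverse_complement(fragment[-read_length:])
        if error_rate > 0:
            mate1 = _add_errors(mate1, error_rate, rng, bases)
            mate2 = _add_errors(mate2, error_rate, rng, bases)
        read_id = f"{assembly_id}|{cid}|{start}|{frag}|{i}"
        yield ReadPair(read_id, mate1, mate2, assembly_id, cid, start, frag)


def _add_errors(
    seq: str, rate: float, rng: np.random.Generator, bases: np.ndarray
) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        choices = bases[bases != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def build_ground_truth(
    members: Sequence[CommunityMember], metadata: dict | None = None
) -> GroundTruthProfile:
    """Aggregate member abundances into per-species dual-convention truth.

    read_fraction(species) is proportional to sum of a_i * s_i over the
    species' strains (the expected share of the read budget);
    cell_fraction(species) is proportional to sum of a_i. Both are
    renormalized to sum to 1 exactly. The integer read allocations n_i
    differ from read_fraction * N by less than one pair per member.
    """
    read_w: dict[str, float] = {}
    cell_w: dict[str, float] = {}
    for m in members:
        read_w[m.species_id] = (
            read_w.get(m.species_id, 0.0)
            + m.relative_abundance * m.genome_size
        )
        cell_w[m.species_id] = cell_w.get(m.species_id, 0.0) + m.relative_abundance
    read_total = sum(read_w.values())
    cell_total = sum(cell_w.values())
    return GroundTruthProfile(
        read_fraction={s: w / read_total for s, w in read_w.items()},
        cell_fraction={s: w / cell_total for s, w in cell_w.items()},
        metadata=dict(metadata or {}),
    )


GenomeLoader = Callable[[str], Sequence[tuple[str, str]]]


def _resolve_loader(
    genomes: Mapping[str, Sequence[tuple[str, str]]] | GenomeLoader,
) -> GenomeLoader:
    if callable(genomes):
        return genomes
    return lambda aid: genomes[aid]


def simulate_community(
    spec: MockCommunitySpec,
    bin_pool: Mapping[str, Sequence[str]],
    genomes: Mapping[str, Sequence[tuple[str, str]]] | GenomeLoader,
    collect_reads: bool = True,
    read_sink=None,
) -> MockCommunity:
    """Run the full simulation pipeline for one community.

    ``bin_pool`` maps species → candidate assembly ids for the requested ANI
    bin; ``genomes`` maps (or loads) assembly id → contig list. Reads are
    collected in memory unless a ``read_sink`` callable is given (called
    with each :class:`ReadPair`; used for streaming to FASTQ).

    Deterministic given ``spec.seed``: the composition draw and each
    genome's read stream use independent substreams spawned from the master
    seed, so per-genome reads do not depend on how many reads other genomes
    received.
    """
    loader = _resolve_loader(genomes)
    root = np.random.SeedSequence(spec.seed)
    comp_ss, reads_root = root.spawn(2)
    rng = np.random.default_rng(comp_ss)

    n_species = draw_species_count(spec.diversity_mu, spec.diversity_sigma, rng)
    composition = sample_members(bin_pool, n_species, spec.strain_mode, rng)

    members: list[CommunityMember] = []
    for species, assembly_ids in composition:
        for aid in assembly_ids:
            contigs = loader(aid)
            size = sum(len(seq) for _, seq in contigs)
            members.append(CommunityMember(aid, species, 0.0, size))
    abundances = draw_abundances(
        len(members), spec.abundance_log_mean, spec.abundance_log_sd, rng
    )
    for m, a in zip(members, abundances):
        m.relative_abundance = float(a)

    allocate_reads(members, spec.total_pairs)

    truth = build_ground_truth(
        members,
        metadata={
            "ani_bin": spec.ani_bin,
            "seed": spec.seed,
            "n_species": n_species,
            "strain_mode": spec.strain_mode,
        },
    )

    reads: list[ReadPair] | None = [] if collect_reads else None
    genome_streams = reads_root.spawn(len(members))
    for m, ss in zip(members, genome_streams):
        grng = np.random.default_rng(ss)
        for pair in simulate_read_pairs(
            loader(m.assembly_id),
            m.n_pairs,
            grng,
            assembly_id=m.assembly_id,
            read_length=spec.read_length,
            insert_mean=spec.insert_mean,
            insert_sd=spec.insert_sd,
            error_rate=spec.error_rate,
        ):
            if reads is not None:
                reads.append(pair)
            if read_sink is not None:
                read_sink(pair)

    return MockCommunity(spec=spec, members=members, truth=truth, reads=reads)
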