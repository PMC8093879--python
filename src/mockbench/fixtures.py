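"""Synthetic test data with controlled statistical structure.

Everything the other modules consume — genome FASTAs, assembly metadata
tables, pairwise ANI tables, candidate pools per ANI bin, and perturbed
predicted profiles — can be generated here from a seed, so the toolkit is
fully testable without downloading a single real genome.

Strain divergence is modelled by substitutions only (no indels): mutating
exactly round((1 - ANI/100) * L) positions of an L-base genome yields a
sequence whose identity to the original is the target ANI *exactly*, which
makes bin membership controllable and the fixture ANI table deterministic.
This is a deliberate departure from realistic evolutionary models (GTR,
indels, rearrangements), which would require an aligner to recover ANI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .reference_db import AniTable, AssemblyRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic benchmark fixture.

    ``candidate_anis`` are the target identities (percent) of the extra
    non-reference strains generated per species; the defaults place one
    candidate inside each of the high / moderate / low ANI bins.
    """

    n_species: int = 3
    genomes_per_species: int = 2  # reference-quality strains per species
    genome_length: int = 25_000  # must clear the N50 > 20 kb filter
    gc_fraction: float = 0.5
    candidate_anis: tuple[float, ...] = (99.4, 98.0, 96.0)
    reference_strain_ani: float = 97.5  # divergence between reference strains
    n_fp: int = 2
    n_fn: int = 1
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 50:
            raise ValidationError("genome_length must be >= 50")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValidationError("gc_fraction must be in (0, 1)")
        for ani in self.candidate_anis + (self.reference_strain_ani,):
            if not 80.0 <= ani <= 100.0:
                raise ValidationError(f"target ANI {ani} outside [80, 100]")


def random_genome(
    length: int,
    gc: float,
    n_contigs: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """I.i.d.-base genome at the stated GC content, split into near-equal
    contigs. Fails if any contig would be shorter than 50 bases."""
    if length < n_contigs * 50:
        raise ValidationError(
            f"cannot split {length} bases into {n_contigs} contigs of >= 50 bases"
        )
    at, gcp = (1.0 - gc) / 2.0, gc / 2.0
    seq = rng.choice(_BASES, size=length, p=[at, gcp, gcp, at])
    base, extra = divmod(length, n_contigs)
    contigs = []
    offset = 0
    for i in range(n_contigs):
        clen = base + (1 if i < extra else 0)
        contigs.append(
            (f"contig_{i + 1}", seq[offset : offset + clen].tobytes().decode())
        )
        offset += clen
    return contigs


def mutate_to_ani(
    sequence: str, target_ani: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Substitute exactly round((1 - ANI/100) * L) positions, each to a
    different base, and return (mutant, realized identity percent).

    Under this substitution-only model the realized identity equals the
    target up to the rounding of the substitution count.
    """
    if not 80.0 <= target_ani <= 100.0:
        raise ValidationError("target_ani must be in [80, 100]")
    length = len(sequence)
    n_sub = int(round((1.0 - target_ani / 100.0) * length))
    if n_sub == 0:
        return sequence, 100.0
    positions = rng.choice(length, size=n_sub, replace=False)
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    for pos in positions:
        alternatives = _BASES[_BASES != arr[pos]]
        arr[pos] = alternatives[rng.integers(len(alternatives))]
    mutant = arr.tobytes().decode()
    realized = 100.0 * (length - n_sub) / length
    return mutant, realized


def sequence_identity(a: str, b: str) -> float:
    """Exact percent identity of two equal-length (substitution-only) sequences."""
    if len(a) != len(b):
        raise ValidationError("sequences must have equal length")
    xa = np.frombuffer(a.encode(), dtype="S1")
    xb = np.frombuffer(b.encode(), dtype="S1")
    return 100.0 * float(np.mean(xa == xb))


@dataclass
class BenchmarkFixture:
    """In-memory synthetic inputs for database curation and simulation."""

    spec: FixtureSpec
    records: list[AssemblyRecord]
    ani: AniTable
    sequences: dict[str, list[tuple[str, str]]]  # assembly_id → contigs
    #: bin → species → candidate assembly ids
    pools: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def _clean_record(
    assembly_id: str,
    species_index: int,
    genome_length: int,
    is_isolate: bool = True,
) -> AssemblyRecord:
    """Metadata row that passes every quality filter (when an isolate)."""
    return AssemblyRecord(
        assembly_id=assembly_id,
        completeness=99.5,
        contamination=0.2,
        n_contigs=1,
        n50=genome_length,
        n_ambiguous=0,
        is_complete=False,
        is_isolate=is_isolate,
        genome_length=genome_length,
        ncbi_species=f"Species {species_index}",
        gtdb_species=f"s__Species_{species_index}",
        sequence_path=None,
    )


def make_benchmark_fixture(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> BenchmarkFixture:
    """Generate a complete toy benchmark input set.

    Per species: ``genomes_per_species`` reference-quality strains (mutually
    divergent so dereplication keeps them all) plus one candidate strain per
    entry of ``candidate_anis``, mutated from the first reference strain so
    its maximum ANI to the reference set hits the target. The ANI table
    records the exact realized identity of every intraspecific pair.
    Byte-stable given the seed; optionally written to ``out_dir`` as
    metadata.tsv, ani.tsv and genomes/*.fasta.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    records: list[AssemblyRecord] = []
    ani = AniTable()
    sequences: dict[str, list[tuple[str, str]]] = {}
    pools: dict[str, dict[str, list[str]]] = {
        "identical": {}, "high": {}, "moderate": {}, "low": {}
    }

    for k in range(1, spec.n_species + 1):
        species = f"s__Species_{k}"
        base = random_genome(spec.genome_length, spec.gc_fraction, 1, rng)
        base_seq = base[0][1]

        strain_seqs: dict[str, str] = {}
        for j in range(spec.genomes_per_species):
            aid = f"SP{k}_ref{j + 1}"
            if j == 0:
                seq = base_seq
            else:
                seq, _ = mutate_to_ani(base_seq, spec.reference_strain_ani, rng)
            strain_seqs[aid] = seq
            sequences[aid] = [("contig_1", seq)]
            records.append(_clean_record(aid, k, spec.genome_length))
        pools["identical"][species] = list(strain_seqs)

        candidates: dict[str, str] = {}
        for target in spec.candidate_anis:
            aid = f"SP{k}_cand{target:g}"
            seq, _ = mutate_to_ani(base_seq, target, rng)
            candidates[aid] = seq
            sequences[aid] = [("contig_1", seq)]
            # candidates emulate MAG-derived strains: they fail the isolate
            # requirement so curation never promotes them to representatives,
            # keeping their ANI-to-reference bin assignment under control
            records.append(
                _clean_record(aid, k, spec.genome_length, is_isolate=False)
            )
            bin_name = _bin_of(target)
            if bin_name:
                pools[bin_name].setdefault(species, []).append(aid)

        everything = {**strain_seqs, **candidates}
        ids = sorted(everything)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                ani.add(a, b, sequence_identity(everything[a], everything[b]))

    fixture = BenchmarkFixture(
        spec=spec, records=records, ani=ani, sequences=sequences, pools=pools
    )
    if out_dir is not None:
        _write_fixture(fixture, Path(out_dir))
    return fixture


def _bin_of(ani_value: float) -> str | None:
    if 99.0 <= ani_value <= 99.75:
        return "high"
    if 97.0 <= ani_value < 99.0:
        return "moderate"
    if 95.0 <= ani_value < 97.0:
        return "low"
    return None


def _write_fixture(fixture: BenchmarkFixture, out_dir: Path) -> None:
    from . import io as mbio

    out_dir.mkdir(parents=True, exist_ok=True)
    genome_dir = out_dir / "genomes"
    genome_dir.mkdir(exist_ok=True)
    records_with_paths = []
    for r in fixture.records:
        fasta = genome_dir / f"{r.assembly_id}.fasta"
        mbio.write_fasta(fixture.sequences[r.assembly_id], fasta)
        records_with_paths.append(
            AssemblyRecord(
                **{**r.__dict__, "sequence_path": str(fasta)}
            )
        )
    fixture.records = records_with_paths
    mbio.write_metadata(fixture.records, out_dir / "metadata.tsv")
    mbio.write_ani(fixture.ani, out_dir / "ani.tsv")
    fixture.paths = {
        "metadata": out_dir / "metadata.tsv",
        "ani": out_dir / "ani.tsv",
        "genomes": genome_dir,
    }


def perturb_profile(
    truth: dict[str, float],
    n_fp: int,
    n_fn: int,
    noise_sd: float,
    rng: np.random.Generator,
    fp_abundance: float = 0.5,
) -> dict[str, float]:
    """Build a synthetic "classifier prediction" from a truth profile.

    Removes ``n_fn`` random truth species, multiplies the survivors by
    exp(Normal(0, noise_sd)), adds ``n_fp`` novel species at a low abundance
    (``fp_abundance``, same unit as the truth), and renormalizes to the
    truth's total. With (0, 0, 0) the prediction equals the truth exactly.
    """
    if n_fn > len(truth):
        raise ValidationError(
            f"cannot remove {n_fn} species from a {len(truth)}-species truth"
        )
    if n_fp == 0 and n_fn == 0 and noise_sd == 0:
        return dict(truth)
    total = sum(truth.values())
    species = sorted(truth)
    dropped = set(
        rng.choice(species, size=n_fn, replace=False)
    ) if n_fn else set()
    pred = {
        sp: truth[sp] * float(np.exp(rng.normal(0.0, noise_sd)))
        for sp in species
        if sp not in dropped
    }
    for i in range(1, n_fp + 1):
        pred[f"planted_fp_{i}"] = fp_abundance
    scale = total / sum(pred.values())
    return {sp: a * scale for sp, a in pred.items()}
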