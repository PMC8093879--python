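"""Curation of a standardized reference genome database.

Assemblies are screened on isolate status and CheckM-style quality metadata,
restricted to species labels that map 1-to-1 between the GTDB and NCBI
taxonomies, scored with an assembly-quality statistic

    Q = completeness - 5*contamination - 0.05*n_contigs - 0.00005*n_ambiguous
        (+100 if the assembly is annotated as a complete genome)

and then, per species, up to ``max_per_species`` representatives are kept
greedily in descending Q, subject to every kept pair being < ``derep_ani``
percent identical (dereplication of near-clonal strains).

Quality metadata is consumed from a table, not computed: completeness and
contamination come from tools like CheckM, and ANI values from FastANI or
Mash, which sit outside this toolkit.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import MissingFieldError, NoSurvivingGenomesError, ValidationError

DEFAULT_MAX_PER_SPECIES = 5
DEFAULT_DEREP_ANI = 99.0

#: fields assembly_quality / passes_quality_filters cannot work without
_QC_FIELDS = (
    "completeness",
    "contamination",
    "n_contigs",
    "n50",
    "n_ambiguous",
    "is_complete",
    "is_isolate",
)


@dataclass(frozen=True)
class AssemblyRecord:
    """One genome assembly with QC metadata and dual taxonomy labels.

    Parameters mirror the metadata table columns. ``completeness`` and
    ``contamination`` are CheckM-style percentages; ``is_complete`` is the
    NCBI assembly-level "Complete Genome" flag; ``ncbi_species`` and
    ``gtdb_species`` may be None for genomes lacking a species assignment
    in that taxonomy.
    """

    assembly_id: str
    completeness: float
    contamination: float
    n_contigs: int
    n50: int
    n_ambiguous: int
    is_complete: bool
    is_isolate: bool
    genome_length: int
    ncbi_species: str | None = None
    gtdb_species: str | None = None
    sequence_path: str | None = None

    def __post_init__(self) -> None:
        def _num(x):
            return x is not None and not (isinstance(x, float) and math.isnan(x))

        if _num(self.completeness) and not (0.0 <= self.completeness <= 100.0):
            raise ValidationError(
                f"{self.assembly_id}: completeness must be in [0, 100], "
                f"got {self.completeness}"
            )
        if _num(self.contamination) and self.contamination < 0:
            raise ValidationError(
                f"{self.assembly_id}: contamination must be >= 0, "
                f"got {self.contamination}"
            )
        if _num(self.n50) and self.n50 > self.genome_length:
            raise ValidationError(
                f"{self.assembly_id}: N50 ({self.n50}) exceeds genome length "
                f"({self.genome_length})"
            )
        if _num(self.n_ambiguous) and self.n_ambiguous > self.genome_length:
            raise ValidationError(
                f"{self.assembly_id}: ambiguous-base count exceeds genome length"
            )

    def require_qc_fields(self) -> None:
        """Raise :class:`MissingFieldError` naming the first absent QC field."""
        for name in _QC_FIELDS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise MissingFieldError(
                    f"{self.assembly_id}: required QC field '{name}' is missing"
                )


class AniTable:
    """Symmetric sparse table of pairwise ANI percentages.

    Missing pairs are allowed (sketch-based estimators omit distant pairs and
    the source study computed ANI only within species); lookups on a missing
    pair return None.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._ani: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), value in pairs.items():
                self.add(a, b, value)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, value: float) -> None:
        if not (0.0 <= value <= 100.0):
            raise ValidationError(f"ANI({a},{b}) = {value} outside [0, 100]")
        if a == b and value != 100.0:
            raise ValidationError(f"self-ANI of {a} must be 100, got {value}")
        key = self._key(a, b)
        existing = self._ani.get(key)
        if existing is not None and not math.isclose(existing, value, abs_tol=1e-9):
            raise ValidationError(
                f"asymmetric ANI entries for ({a}, {b}): {existing} vs {value}"
            )
        self._ani[key] = float(value)

    def get(self, a: str, b: str) -> float | None:
        if a == b:
            return 100.0
        return self._ani.get(self._key(a, b))

    def partners(self, a: str) -> dict[str, float]:
        """All recorded partners of ``a`` (excluding ``a`` itself)."""
        out: dict[str, float] = {}
        for (x, y), value in self._ani.items():
            if x == a and y != a:
                out[y] = value
            elif y == a and x != a:
                out[x] = value
        return out

    def __len__(self) -> int:
        return len(self._ani)

    def items(self):
        return self._ani.items()


@dataclass(frozen=True)
class Decision:
    """One curation decision: a genome was kept or rejected, and why."""

    assembly_id: str
    kept: bool
    reason: str
    species: str | None = None


@dataclass
class ReferenceDatabase:
    """Species → ordered representative assemblies, plus the decision log."""

    representatives: dict[str, list[AssemblyRecord]]
    decisions: list[Decision] = field(default_factory=list)
    derep_ani: float = DEFAULT_DEREP_ANI
    max_per_species: int = DEFAULT_MAX_PER_SPECIES

    @property
    def species(self) -> list[str]:
        return sorted(self.representatives)

    @property
    def assembly_ids(self) -> set[str]:
        return {
            r.assembly_id for reps in self.representatives.values() for r in reps
        }

    def n_genomes(self) -> int:
        return sum(len(v) for v in self.representatives.values())


def assembly_quality(record: AssemblyRecord) -> float:
    """Assembly-quality score Q.

    Q = completeness - 5*contamination - 0.05*n_contigs - 0.00005*n_ambiguous,
    plus an additional 100 if the assembly is annotated as a complete genome.
    """
    record.require_qc_fields()
    q = (
        record.completeness
        - 5.0 * record.contamination
        - 0.05 * record.n_contigs
        - 0.00005 * record.n_ambiguous
    )
    if record.is_complete:
        q += 100.0
    return q


def passes_quality_filters(record: AssemblyRecord) -> tuple[bool, str | None]:
    """Screen one assembly; returns (passed, reject_reason).

    All inequalities are strict: isolate genomes with completeness > 90%,
    contamination < 5%, < 500 contigs, N50 > 20 kb and < 10,000 ambiguous
    bases pass.
    """
    record.require_qc_fields()
    if not record.is_isolate:
        return False, "not an isolate genome"
    if not record.completeness > 90.0:
        return False, f"completeness {record.completeness} not > 90"
    if not record.contamination < 5.0:
        return False, f"contamination {record.contamination} not < 5"
    if not record.n_contigs < 500:
        return False, f"contig count {record.n_contigs} not < 500"
    if not record.n50 > 20_000:
        return False, f"N50 {record.n50} not > 20000"
    if not record.n_ambiguous < 10_000:
        return False, f"ambiguous bases {record.n_ambiguous} not < 10000"
    return True, None


def taxonomy_bijection_filter(
    records: Sequence[AssemblyRecord],
) -> list[AssemblyRecord]:
    """Keep records whose species labels form a 1-to-1 GTDB↔NCBI mapping.

    A GTDB species label associated with two distinct NCBI labels across the
    input (or vice versa) disqualifies every record carrying it; records
    missing either label are rejected outright.
    """
    gtdb_to_ncbi: dict[str, set[str]] = defaultdict(set)
    ncbi_to_gtdb: dict[str, set[str]] = defaultdict(set)
    for r in records:
        if r.gtdb_species and r.ncbi_species:
            gtdb_to_ncbi[r.gtdb_species].add(r.ncbi_species)
            ncbi_to_gtdb[r.ncbi_species].add(r.gtdb_species)
    kept = []
    for r in records:
        if not r.gtdb_species or not r.ncbi_species:
            continue
        if (
            len(gtdb_to_ncbi[r.gtdb_species]) == 1
            and len(ncbi_to_gtdb[r.ncbi_species]) == 1
        ):
            kept.append(r)
    return kept


def select_representatives(
    species_records: Sequence[AssemblyRecord],
    ani: AniTable,
    max_per_species: int = DEFAULT_MAX_PER_SPECIES,
    derep_ani: float = DEFAULT_DEREP_ANI,
    *,
    return_log: bool = False,
):
    """Greedy representative selection for one species.

    Candidates are swept in descending assembly quality (ties broken by
    lexicographic assembly_id for reproducibility); a candidate is kept only
    if its ANI to every already-kept genome is below ``derep_ani``. Missing
    ANI pairs pass the test. Selection stops at ``max_per_species``.

    Returns the kept list in selection order; with ``return_log=True`` also
    returns a list of (record, reject_reason) for candidates not kept.
    """
    ranked = sorted(
        species_records, key=lambda r: (-assembly_quality(r), r.assembly_id)
    )
    kept: list[AssemblyRecord] = []
    rejected: list[tuple[AssemblyRecord, str]] = []
    for candidate in ranked:
        if len(kept) >= max_per_species:
            rejected.append(
                (candidate, f"species already has {max_per_species} representatives")
            )
            continue
        clash = None
        for chosen in kept:
            value = ani.get(candidate.assembly_id, chosen.assembly_id)
            if value is not None and value >= derep_ani:
                clash = (chosen.assembly_id, value)
                break
        if clash is None:
            kept.append(candidate)
        else:
            rejected.append(
                (
                    candidate,
                    f"ANI {clash[1]:g} to kept genome {clash[0]} "
                    f">= {derep_ani:g}% dereplication cutoff",
                )
            )
    if return_log:
        return kept, rejected
    return kept


def build_reference_db(
    records: Iterable[AssemblyRecord],
    ani: AniTable,
    max_per_species: int = DEFAULT_MAX_PER_SPECIES,
    derep_ani: float = DEFAULT_DEREP_ANI,
) -> ReferenceDatabase:
    """Full curation pipeline: quality filters → taxonomy bijection →
    per-species representative selection.

    Species are keyed by GTDB label. Every input genome receives exactly one
    entry in the decision log. Raises :class:`NoSurvivingGenomesError` if
    nothing survives.
    """
    records = list(records)
    decisions: list[Decision] = []

    qc_pass: list[AssemblyRecord] = []
    for r in records:
        ok, reason = passes_quality_filters(r)
        if ok:
            qc_pass.append(r)
        else:
            decisions.append(
                Decision(r.assembly_id, False, f"quality filter: {reason}",
                         r.gtdb_species)
            )

    bijective = taxonomy_bijection_filter(qc_pass)
    bijective_ids = {r.assembly_id for r in bijective}
    for r in qc_pass:
        if r.assembly_id not in bijective_ids:
            decisions.append(
                Decision(
                    r.assembly_id,
                    False,
                    "taxonomy: species labels do not form a 1-to-1 "
                    "GTDB/NCBI mapping",
                    r.gtdb_species,
                )
            )

    by_species: dict[str, list[AssemblyRecord]] = defaultdict(list)
    for r in bijective:
        by_species[r.gtdb_species].append(r)

    representatives: dict[str, list[AssemblyRecord]] = {}
    for species in sorted(by_species):
        kept, rejects = select_representatives(
            by_species[species], ani, max_per_species, derep_ani, return_log=True
        )
        if kept:
            representatives[species] = kept
        for rank, r in enumerate(kept, start=1):
            decisions.append(
                Decision(r.assembly_id, True, f"representative rank {rank}", species)
            )
        for r, reason in rejects:
            decisions.append(Decision(r.assembly_id, False, reason, species))

    if not representatives:
        raise NoSurvivingGenomesError(
            "no surviving genomes: every input assembly was rejected during curation"
        )
    return ReferenceDatabase(
        representatives=representatives,
        decisions=decisions,
        derep_ani=derep_ani,
        max_per_species=max_per_species,
    )
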