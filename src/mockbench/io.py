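"""Readers and writers for the toolkit's file dialects.

FASTA/FASTQ handling is delegated to Biopython's SeqIO (gzip detected by a
``.gz`` extension); tabular dialects (assembly metadata, ANI tables,
abundance profiles, truth/manifest outputs) go through pandas. Percent is
the canonical abundance unit in every output file; fractions are accepted
on input. All writers prepend a comment header carrying the toolkit
version and, when available, the resolved-configuration hash, so outputs
are traceable to the run that produced them.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import ValidationError
from .evaluation import AbundanceProfile
from .reference_db import AniTable, AssemblyRecord
from .simulator import GroundTruthProfile, MockCommunity, ReadPair

METADATA_COLUMNS = [
    "assembly_id", "completeness", "contamination", "n_contigs", "n50",
    "n_ambiguous", "is_complete", "is_isolate", "ncbi_species",
    "gtdb_species", "genome_length", "fasta_path",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- sequences

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file into (id, sequence) tuples."""
    with _open_text(path) as handle:
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(handle, "fasta")]
    if not records:
        warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
    return records


def write_fasta(contigs: Sequence[tuple[str, str]], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in contigs
    ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def write_fastq_pairs(
    pairs: Iterable[ReadPair],
    path_r1: str | Path,
    path_r2: str | Path,
    quality_char: str = "I",
) -> int:
    """Write mates to a FASTQ file pair (gzip by extension); constant base
    quality, since the classifiers under benchmark ignore it. Returns the
    number of pairs written."""
    n = 0
    with _open_text(path_r1, "wt") as r1, _open_text(path_r2, "wt") as r2:
        for pair in pairs:
            q1 = quality_char * len(pair.mate1)
            q2 = quality_char * len(pair.mate2)
            r1.write(f"@{pair.read_id}/1\n{pair.mate1}\n+\n{q1}\n")
            r2.write(f"@{pair.read_id}/2\n{pair.mate2}\n+\n{q2}\n")
            n += 1
    return n


# ------------------------------------------------------------------- tables

def _header_lines(extra: dict | None = None) -> str:
    parts = [f"# mockbench v{__version__}"]
    for key, value in (extra or {}).items():
        parts.append(f"# {key}: {value}")
    return "\n".join(parts) + "\n"


def read_metadata(path: str | Path) -> list[AssemblyRecord]:
    """Read the assembly metadata TSV into typed records."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing metadata columns {missing}")
    if df["assembly_id"].duplicated().any():
        dupes = df.loc[df["assembly_id"].duplicated(), "assembly_id"].tolist()
        raise ValidationError(f"{path}: duplicate assembly ids {dupes}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AssemblyRecord(
                assembly_id=str(row.assembly_id),
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                n_contigs=int(row.n_contigs),
                n50=int(row.n50),
                n_ambiguous=int(row.n_ambiguous),
                is_complete=_parse_bool(row.is_complete),
                is_isolate=_parse_bool(row.is_isolate),
                genome_length=int(row.genome_length),
                ncbi_species=_opt_str(row.ncbi_species),
                gtdb_species=_opt_str(row.gtdb_species),
                sequence_path=_opt_str(row.fasta_path),
            )
        )
    return records


def write_metadata(records: Sequence[AssemblyRecord], path: str | Path) -> None:
    rows = [
        {
            "assembly_id": r.assembly_id,
            "completeness": r.completeness,
            "contamination": r.contamination,
            "n_contigs": r.n_contigs,
            "n50": r.n50,
            "n_ambiguous": r.n_ambiguous,
            "is_complete": r.is_complete,
            "is_isolate": r.is_isolate,
            "ncbi_species": r.ncbi_species or "",
            "gtdb_species": r.gtdb_species or "",
            "genome_length": r.genome_length,
            "fasta_path": r.sequence_path or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "t", "yes", "1"):
        return True
    if text in ("false", "f", "no", "0"):
        return False
    raise ValidationError(f"cannot parse boolean value {value!r}")


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def read_ani(path: str | Path) -> AniTable:
    """Read a pairwise ANI TSV (query_id, target_id, ani).

    Symmetric duplicates must agree; a conflicting (b, a) entry raises.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["query_id", "target_id", "ani"]
    if not all(c in df.columns for c in required):
        raise ValidationError(f"{path}: expected columns {required}")
    table = AniTable()
    for row in df.itertuples(index=False):
        table.add(str(row.query_id), str(row.target_id), float(row.ani))
    return table


def write_ani(table: AniTable, path: str | Path) -> None:
    rows = [
        {"query_id": a, "target_id": b, "ani": value}
        for (a, b), value in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["query_id", "target_id", "ani"]).to_csv(
        path, sep="\t", index=False
    )


def read_profile(
    path: str | Path, unit: str = "percent", role: str = "prediction"
) -> AbundanceProfile:
    """Read a two-column species/abundance TSV into a percent-unit profile.

    Lines starting with '#' are ignored; an optional header line is
    detected by a non-numeric second column. Duplicate species and negative
    abundances raise.
    """
    pairs: list[tuple[str, float]] = []
    saw_header = False
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            try:
                value = float(parts[1])
            except ValueError:
                if not pairs and not saw_header:
                    saw_header = True
                    continue  # header line
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric abundance {parts[1]!r}"
                ) from None
            pairs.append((parts[0], value))
    profile = AbundanceProfile.from_pairs(
        pairs, unit=unit, role=role, source=str(path)
    )
    return profile.as_percent()


def write_profile(
    profile: AbundanceProfile, path: str | Path, extra_header: dict | None = None
) -> None:
    p = profile.as_percent()
    with open(path, "w") as handle:
        handle.write(_header_lines(extra_header))
        handle.write("species_id\tabundance_percent\n")
        for sp, a in sorted(p.items()):
            handle.write(f"{sp}\t{a:.10g}\n")


def write_truth(
    truth: GroundTruthProfile, path: str | Path, extra_header: dict | None = None
) -> None:
    """Write the dual-convention ground truth (percent units)."""
    header = dict(extra_header or {})
    header.update({k: v for k, v in truth.metadata.items()})
    with open(path, "w") as handle:
        handle.write(_header_lines(header))
        handle.write("species_id\tread_fraction_percent\tcell_fraction_percent\n")
        for sp in sorted(truth.read_fraction):
            handle.write(
                f"{sp}\t{100.0 * truth.read_fraction[sp]:.10g}"
                f"\t{100.0 * truth.cell_fraction[sp]:.10g}\n"
            )


def read_truth(
    path: str | Path, convention: str = "reads"
) -> AbundanceProfile:
    """Load one convention ("reads" or "cells") of a truth TSV as a profile."""
    if convention not in ("reads", "cells"):
        raise ValidationError("convention must be 'reads' or 'cells'")
    df = pd.read_csv(path, sep="\t", comment="#")
    column = (
        "read_fraction_percent" if convention == "reads"
        else "cell_fraction_percent"
    )
    if column not in df.columns:
        raise ValidationError(f"{path}: missing column {column}")
    return AbundanceProfile.from_pairs(
        [(str(r.species_id), float(getattr(r, column)))
         for r in df.itertuples(index=False)],
        unit="percent",
        role="truth-reads" if convention == "reads" else "truth-cells",
        source=str(path),
    )


def write_manifest(
    community: MockCommunity, path: str | Path
) -> None:
    rows = [
        {
            "assembly_id": m.assembly_id,
            "species_id": m.species_id,
            "relative_abundance": m.relative_abundance,
            "genome_size": m.genome_size,
            "n_pairs": m.n_pairs,
        }
        for m in community.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_translation(path: str | Path) -> dict[str, str]:
    """Two-column label translation table (from_label, to_label)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["from_label", "to_label"])
    return {str(r.from_label): str(r.to_label) for r in df.itertuples(index=False)}


# -------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Fully resolved parameters of one CLI run, echoed alongside results."""

    command: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    out_dir: str | None = None
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        doc = {
            "mockbench_version": __version__,
            "command": self.command,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "parameters": self.parameters,
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        text = self.to_yaml()
        with open(path, "w") as handle:
            handle.write(text)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            doc = yaml.safe_load(handle) or {}
        return cls(
            command=doc.get("command", ""),
            parameters=doc.get("parameters", {}) or {},
            seed=doc.get("seed"),
            out_dir=doc.get("out_dir"),
            log_level=doc.get("log_level", "INFO"),
        )
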