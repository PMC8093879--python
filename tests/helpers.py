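"""Shared builders for tests."""

from mockbench import AssemblyRecord


def make_record(
    assembly_id="g1",
    completeness=95.0,
    contamination=1.0,
    n_contigs=100,
    n50=50_000,
    n_ambiguous=500,
    is_complete=False,
    is_isolate=True,
    genome_length=5_000_000,
    ncbi_species="Alpha",
    gtdb_species="s__Alpha",
    sequence_path=None,
):
    return AssemblyRecord(
        assembly_id=assembly_id,
        completeness=completeness,
        contamination=contamination,
        n_contigs=n_contigs,
        n50=n50,
        n_ambiguous=n_ambiguous,
        is_complete=is_complete,
        is_isolate=is_isolate,
        genome_length=genome_length,
        ncbi_species=ncbi_species,
        gtdb_species=gtdb_species,
        sequence_path=sequence_path,
    )
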