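# Methods

## Scope and model

`mockbench` implements the benchmarking side of classifier evaluation: it
curates the reference database the classifiers are measured against,
generates mock metagenomes whose composition is known exactly, and scores
predicted species profiles. It does not run any classifier, compute
completeness/contamination (CheckM's job), estimate ANI (FastANI/Mash), or
assign taxonomy (GTDB-Tk); those tools' *outputs* are the toolkit's inputs,
consumed as plain TSV tables.

## Reference database curation

Candidate assemblies are screened with strict inequalities — isolate
status, completeness > 90%, contamination < 5%, < 500 contigs,
N50 > 20,000 bases, < 10,000 ambiguous bases — and restricted to species
whose GTDB and NCBI labels form a 1-to-1 mapping across the input set (a
label on either side associated with two labels on the other disqualifies
every record carrying it, since the conflict makes all of their species
assignments suspect). Representatives are then chosen per species by a
greedy sweep in descending assembly quality
Q = completeness − 5·contamination − 0.05·contigs − 0.00005·ambiguous
(+100 for complete genomes); a candidate is kept only if its ANI to every
already-kept genome is below 99%, and selection stops at five.

Numerical choices:

- **Ties in Q** break lexicographically on assembly id, making the kept
  set independent of input order (a property test permutes the input).
- **Missing ANI pairs pass** the dereplication test. ANI is typically
  computed only within species, and sketch-based estimators drop distant
  pairs; treating absence as "not near-identical" is the only reading that
  does not discard data arbitrarily. The interaction with the five-genome
  cap is therefore permissive: an unmeasured pair can co-occur among the
  representatives.
- Every input genome gets exactly one decision-log entry (kept with rank,
  or rejected with the first failing rule), so curation is auditable and
  the log partitions the input.

## Mock community simulation

Candidate genomes are stratified by their maximum ANI to same-species
reference genomes: identical (the reference genomes themselves, 100%),
high [99, 99.75], moderate [97, 99), low [95, 97). Values below 95% fall
outside the operational prokaryotic species boundary and are unbinned, as
are values strictly between 99.75 and 100 (too close to the reference to
represent novel-strain difficulty, but not in the database).

The generator's defaults are the study conditions, not tuning knobs:
medium species diversity Normal(100, 25), high Normal(500, 100) (rounded,
redrawn until ≥ 1 — redrawing rather than clipping preserves approximate
normality); single-strain or 2–10 strains per species (target drawn
uniformly on {2..10}, capped by availability); strain abundances
log-normal with log-mean 1 and log-sd 2; total depth 2.1 Gb of 2 × 150 bp
pairs (N = 7,000,000 pairs at defaults); insert length Normal(200, 25) bp.
The phrase "log-normal with mean 1 and sd 2" is read as parameters of the
underlying normal on the log scale, the convention of the community-
modelling literature this distribution comes from; the acceptance script
verifies the draws on that scale.

Read pairs are error-free by default (no error model is part of the study
conditions; a uniform substitution rate is available as an option).
Fragments are wholly contained in a single contig, with the contig chosen
proportional to length and the start uniform — no circular wraparound.
Fragment lengths are rounded, clamped to at least the read length, and
redrawn if they do not fit the chosen contig. With the default geometry
the mates of a 200 bp fragment overlap; the spec-level warning makes that
explicit rather than silently truncating. FASTQ qualities are a constant
Q40 symbol, since the classifiers under benchmark ignore them. Read ids
encode assembly, contig, start and fragment length, so every read is
traceable and a provenance round-trip test re-extracts both mates exactly.

**Read budget.** nᵢ = N·aᵢsᵢ/Σaⱼsⱼ is converted to integers by
largest-remainder rounding, so Σnᵢ = N exactly for every community — depth
is conserved, not approximated.

**Dual-convention ground truth.** Read fractions are computed from the
exact expected weights aᵢsᵢ (not the integer nᵢ), and cell fractions from
aᵢ. This makes the two conventions consistent to machine precision —
dividing read fractions by the abundance-weighted mean strain genome size
and renormalizing recovers cell fractions — which is the invariant
downstream evaluation relies on. The realized integer counts nᵢ/N differ
from the read fractions by less than one pair per community member, and a
test asserts that bound.

**Seeding.** One master seed per community; the composition draw and each
genome's read stream use independent substreams spawned from it, so
per-genome reads are reproducible regardless of how other genomes'
allocations change and simulation could be parallelized without changing
output.

## Profile evaluation

All abundances are handled in percent (fractions accepted on input).
Evaluation filters the truth at 0.01% — the benchmark's convention for the
undetectable long tail — and keeps species *at* the threshold ("remove
below" semantics). Filtered profiles are **not renormalized**, so FP and
FN abundance mass stay on the original community scale.

Empty-denominator conventions: P = 1 for an empty prediction when the
truth is also empty, else 0; R = 1 for an empty truth; F1 = 0 when
P = R = 0; the FDR of an empty prediction is 0. These make the zero-FP
case well defined: a prediction with no false positives has detection
limit 0% at any target FDR, meaning no filtering is needed.

Both threshold sweeps (detection limit and optimized F1) use candidates
{0} ∪ {distinct predicted abundances} with "keep ≥ t" semantics, so a
species sitting exactly at the limit counts as detected. Sweeping only
observed abundances is equivalent to sweeping every midpoint between
consecutive abundances — the kept set only changes at observed values —
and a property test checks both procedures against that brute-force
oracle on ≤ 20-species profiles. The detection limit is returned as the
lowest surviving abundance; when even the top prediction is a false
positive the target is unachievable and the sentinel `None` is returned.
Aggregation reports the mean or median over achievable samples and counts
unachievable ones separately rather than folding a sentinel value into
the statistic. Ties in the F1 sweep go to the lowest threshold (filter as
little as possible).

Species matching is by exact identifier; an optional two-column
translation table can reconcile label namespaces (e.g. NCBI ↔ GTDB)
before comparison, with unmatched predicted labels counted as false
positives.

## Synthetic fixtures

The fixture generator emulates the *structure* of the benchmark inputs,
not real genomes: i.i.d. bases at a target GC, strains derived by
substituting exactly round((1 − ANI/100)·L) positions so realized identity
equals the target, and an ANI table storing those realized identities
directly. Candidate (non-reference) strains are written as non-isolates so
curation never promotes them into the database, mirroring how novel
strains sit outside a frozen reference release. Consequently, passing
tests demonstrate correctness of the bookkeeping and the statistics on
sequences with no repeat structure, no indels, no rearrangements and no
compositional bias; they say nothing about any classifier's accuracy on
real genomes — which is the point: the toolkit measures classifiers, the
fixtures measure the toolkit.

Perturbed predictions plant a known number of false positives and false
negatives and multiplicative log-normal abundance noise, giving exact
expected confusion counts for end-to-end tests.

## Problem sizes

Tests and the acceptance script run on fixture genomes of 1–100 kb, up to
~20 species, and 10³–10⁴ read pairs per community, with distribution-
recovery checks at 10³ draws (species counts), 10⁴ pairs (insert length)
and 10⁵ draws (abundances), each asserted within three standard errors.
These sizes exercise every code path; production-scale runs (2.1 Gb
depth, hundreds of species) use identical code with a larger budget, and
read output streams to gzipped FASTQ rather than memory.

## Known limitations

- No sequencing-error, quality, or GC-bias model beyond the optional
  uniform substitution rate.
- ANI handling is table-driven; the toolkit never aligns genomes, so
  fixture "ANI" is exact identity under a substitution-only model.
- Bacterial/archaeal framing throughout; no eukaryote or virus support.
- Detection-limit aggregation across samples assumes comparable target
  FDR grids; mixed grids aggregate only where they overlap.
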