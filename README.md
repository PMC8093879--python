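# mockbench

A benchmarking toolkit for metagenomic taxonomic classifiers. Shotgun
metagenomics estimates which microbial species are in a sample and at what
relative abundance, but every classifier (k-mer, marker-gene, protein- or
genome-alignment based) makes different trade-offs between false positives
and missed species, and its accuracy depends strongly on how similar the
sample's strains are to the genomes in its reference database. `mockbench`
provides the three ingredients needed to measure that, end to end and
without any external downloads:

1. **Reference database curation** (`mockbench.reference_db`) — screen
   isolate assemblies on CheckM-style quality metadata (completeness > 90%,
   contamination < 5%, < 500 contigs, N50 > 20 kb, < 10,000 ambiguous
   bases), keep only species whose GTDB and NCBI labels map 1-to-1, rank by
   the assembly-quality score

   ```
   Q = completeness − 5·contamination − 0.05·(no. contigs) − 0.00005·(no. ambiguous bases)
       (+100 if annotated as a complete genome)
   ```

   and select up to five representatives per species, greedily in
   descending Q, subject to every kept pair having ANI < 99% (strain
   dereplication).

2. **Mock community simulation** (`mockbench.simulator`) — build *in
   silico* communities stratified by ANI similarity to the reference
   database (identical 100%, high [99, 99.75]%, moderate [97, 99)%, low
   [95, 97)%). Species counts are drawn from Normal(μ, σ) (medium: 100 ± 25;
   high: 500 ± 100), with one strain per species or 2–10 random strains.
   Strain abundances aᵢ follow a log-normal distribution (log-mean 1,
   log-sd 2); the paired-read budget N = ⌊depth / (2·read length)⌋ is split
   as

   ```
   nᵢ = N · aᵢ sᵢ / Σⱼ aⱼ sⱼ        (sᵢ = genome size)
   ```

   with largest-remainder rounding so Σnᵢ = N exactly. Error-free
   2 × 150 bp read pairs with insert length ~ Normal(200, 25) bp are
   sampled uniformly across each genome, and the ground truth is emitted
   under two conventions — read fractions (∝ aᵢsᵢ) and cell fractions
   (∝ aᵢ, i.e. reads normalized by genome size) — because classifiers
   differ in which quantity they report.

3. **Profile evaluation** (`mockbench.evaluation`) — precision
   P = TP/(TP+FP), recall R = TP/(TP+FN), F1 = 2PR/(P+R) on species sets
   (after removing truth species below 0.01% abundance); L1 distance
   Σ|T−E| (0% identical, 200% disjoint); mean relative percent error
   100·|T−E|/T over truth species; FP/FN abundance mass; the best
   single-threshold ("optimized") F1; and the **detection limit**: the
   lowest reported abundance at which filtering the profile achieves a
   target false discovery rate FDR = FP/(TP+FP).

A fourth module (`mockbench.fixtures`) generates synthetic genomes and
strains at exact target ANI (substitution-only divergence, so identity is
controlled to the base), plus perturbed "classifier predictions" with
planted false positives/negatives — everything needed to exercise the
other modules at desk scale.

## Worked example

```bash
mockbench fixtures --preset mock-toy --seed 5 --out fx
mockbench build-db --metadata fx/metadata.tsv --ani fx/ani.tsv --out db
# -> "kept 24 genomes across 8 species"
mockbench simulate --db db --ani fx/ani.tsv --bin high --diversity 4:0 \
    --strains single --depth 120000 --seed 17 --out sim
# -> "replicate 1: 4 species, 4 genomes, 400 read pairs"
mockbench evaluate --truth sim/rep01/truth.tsv --pred pred.tsv \
    --convention reads --out eval
```

With a prediction degraded from the truth by dropping the rarest species
and adding one false positive at 0.6% abundance, `evaluate` prints:

```json
{
  "precision": 0.75, "recall": 0.75, "f1": 0.75,
  "l1_distance": 0.626, "mean_relative_error": 25.0,
  "fp_abundance_mass": 0.6, "fn_abundance_mass": 0.026,
  "tp": 3, "fp": 1, "fn": 1,
  "detection_limit_fdr_0.05": 14.56
}
```

Read it as: of the 4 predicted species 3 are real (P = 0.75) and one of
the 4 true species was missed (R = 0.75); the profiles differ by 0.63
percentage points of abundance in total; the false positive carries 0.6%
of the predicted community; and because the false positive sits at 0.6%
abundance, the profile must be filtered at 14.56% (the lowest true
abundance above it) before the FDR reaches 5% — a single confident FP is
expensive.

Every command writes a `run_config.yaml` echoing its fully resolved
parameters and seed, and all outputs carry the toolkit version, so any
result can be regenerated exactly.

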