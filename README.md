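# sptax

Lower-bound taxa counting in metagenomic data from **specific-peptide (SP)
markers** — short, deterministic amino-acid words whose exact occurrence marks
membership in a single-copy enzyme family (EC 6.1.1.x aminoacyl-tRNA
synthetases). Because each marked gene occurs once per genome, the minimal
number of mutually incompatible marker-bearing sequences is a lower bound on
the number of taxa in the sample.

## How it works

1. **Translate & search** — reads/contigs are translated in all six frames
   (`translate_search.six_frame_translate`) and scanned for exact marker
   occurrences from a look-up table (`find_sp_hits`); the Met-to-stop segment
   around a hit can be extracted as a putative protein
   (`extract_putative_protein`).
2. **Group & anchor** — sequences sharing one marker are anchored at its
   offset, putting them all in a single coordinate system (`group_by_sp`).
3. **Count** — two anchored sequences are *consistent* when they agree over
   their anchored overlap; consistent sequences may be fused, inconsistent
   ones must come from different taxa. The minimal number of mutually
   inconsistent fused strings equals the chromatic number of the
   inconsistency graph. `taxa_count.count_taxa_heuristic` computes it
   greedily (with a DSATUR-colouring cross-check); `chromatic_number_exact`
   is an exact oracle for small instances.
4. **Distance analysis** — `distance_count` sweeps a minimal anchored-Hamming
   distance *d* over the fused strings (strain vs species separation) and
   runs subsampling depth analyses.
5. **Calibration** — `calibration` estimates read-length acuity (probability
   of inequality over sliding windows), injects substitution errors to
   validate that the *d* ≥ 2 count of noisy data tracks the *d* ≥ 1 count of
   clean data, evaluates marker specificity on annotated genomes
   (TP/FP/EFP), and profiles mismatches against reference proteins.
6. **Synthetic data** — `synthetic` generates ground-truthed taxa proteins
   with a planted marker, amino-acid or nucleotide reads, and annotated toy
   genomes, so the whole pipeline is testable offline.

A 14-read worked example (marker `FYALPQAPQ`) ships in `sptax.datasets`.

## CLI

```sh
sptax --help
sptax --seed 1 simulate --k 5 --read-length 30 --coverage 6 --nucleotide --outdir sim/
sptax search --reads sim/reads.fasta --sp-table sim/sp_table.tsv --out hits.tsv
sptax count --group sim/reads_anchored.tsv --sp FYALPQAPQ --out count.tsv
sptax dcount --group sim/reads_anchored.tsv --sp FYALPQAPQ --dmax 10 \
      --subsample 10,20 --trials 20 --out dcount.tsv
sptax pine --proteins proteins.fasta --levels family,genus --out pine.tsv
sptax specificity --genome genome.fasta --annotation ann.bed \
      --sp-table sp.tsv --out specificity.tsv
sptax match --queries reads.fasta --reference refs.fasta --sp FYALPQAPQ \
      --kmax 10 --out match.tsv
```

Global options: `--seed`, `--log-level`, `--min-sp-length` (default 9) and
`--config FILE` (a `key=value` file preloading subcommand options).

Formats: FASTA/FASTQ sequences; two-column TSV marker tables
(`peptide<TAB>EC`, `#` comments); GFF3 or 4-column BED genic/intergenic
annotations; anchored-sequence TSVs (`id<TAB>sequence<TAB>anchor`). All
internal coordinates are 0-based half-open.

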