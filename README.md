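# mpratile

A toolkit for dense-tiling massively parallel reporter assays (MPRAs) that
locate RNA localization elements in 3' UTRs. It covers the full computational
arc of such an assay and is exercisable entirely on synthetic data:

| module               | role |
| -------------------- | ---- |
| `mpratile.design`    | meta-UTR construction from transcript annotation, gene filters (UTR length, conserved polyA sites), dense oligo tiling (260 nt / 4 nt step by default, 260-nt flank extension, PCR handles), control oligos |
| `mpratile.simulate`  | synthetic UTRs with planted A/G-rich elements, soma/neurite negative-binomial count matrices with replicate structure, error-bearing paired-end FASTQ (97/91-nt geometry, per-base mutation 0.002 / deletion 0.0001, 8-nt UMIs) — all with full truth records |
| `mpratile.quantify`  | adapter trimming, read-pair to oligo assignment (builtin seed-and-extend assigner with default/high effort modes; optional external bowtie2 backend via SAM), unique-UMI counting |
| `mpratile.enrich`    | median-of-ratios normalization, NB Wald test of neurite vs soma abundance with trend-shrunk dispersions and BH FDR, cross-dataset Z-score ranking, delta-delta-Ct utility |
| `mpratile.windows`   | "oligo union" calling (the x / y / x+2y gap-bridging traversal), intersection intervals, peak oligos, neighbor-similarity shuffle QC, sliding profiles |
| `mpratile.features`  | nucleotide composition, maximal A/G-content 100-nt windows (inclusive 75% threshold classification), kmer enrichment, optional RNAfold-backed structure profiles with a regex G-quadruplex fallback |

## CLI

The `mpratile` entry point exposes one subcommand per stage:

```bash
mpratile design --gtf anno.gtf --fasta genome.fa --polya-bed conserved.bed \
    --oligo-len 260 --step 4 --flank 260 --max-utr 10000 --out-prefix pool

mpratile simulate utrs   --n-genes 20 --seed 1 --element simgene0001:400:600:2.0 \
    --out-prefix sim
mpratile simulate counts --manifest pool.manifest.tsv --elements sim.elements.json \
    --seed 1 --out-prefix sim
mpratile simulate reads  --manifest pool.manifest.tsv --n-reads 100000 --seed 1 \
    --out-prefix sim

mpratile quantify --sample-sheet samples.tsv --pool pool.manifest.tsv \
    --effort high --aligner builtin --out-prefix quant

mpratile enrich --counts quant.counts.tsv --samples quant.samples.tsv \
    --min-count 20 --out enrichment.tsv

mpratile windows --enrichment enrichment.tsv --manifest pool.manifest.tsv \
    --fdr 0.01 --smooth 8 --out-prefix windows

mpratile features --fasta utrs.fa --classes classes.tsv \
    --ag-window 100 --ag-threshold 0.75 --kmer 6 --out-prefix feats
```

The quantify sample sheet is a TSV with columns
`sample  compartment  replicate  r1  r2` (compartment is `soma` or `neurite`).

## Notes on the builtin read assigner

Oligos in a dense tiling differ from their neighbors by only a few
nucleotides at each end, which is the hard case for read assignment. The
builtin assigner samples exact 20-mers at fixed read offsets (plus small
positional shifts so seeds downstream of a template deletion still hit),
ranks candidate oligos by seed votes, and extends with ungapped mismatch
counting. The `high` effort mode raises the candidate-extension budget
(15 → 150) and enables a banded gapped fallback that rescues reads carrying
deletions; `default` leaves those reads unassigned, which reproduces the
characteristic accuracy gap between default and raised search effort. Score
ties are left unassigned rather than guessed.
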