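# txsearch

BLASTX-style translated homology search of short DNA reads against a protein
database, accelerated algorithmically by database subsequence clustering with
triangle-inequality seed pruning.

Pipeline: six-frame translation of each read → seed search of every query
window against a clustered index of length-10 database windows → similarity
filtering (full distances only for cluster representatives; members screened
by the triangle-inequality lower bound `|D(q,r) − d(r,m)|`) → X-dropoff
ungapped extension → chain filtering → X-dropoff gapped extension (affine
gaps, linear-memory score pass + exact traceback) → Karlin–Altschul E-values
and bit scores → BLAST outfmt-6-style tabular output.

The database is indexed into chunks that are searched sequentially (with
optional background prefetch) and merged with E-values computed against the
whole database, so chunking, worker count, batch budget and prefetch never
change the output.

## CLI

Build an index, then search:

```sh
txsearch db --in proteins.fasta --out mydb
txsearch aln --query reads.fastq --db mydb --out hits.tsv
```

`txsearch db` options: `--chunk-bytes` (default 1 GiB), `--cluster-threshold`
(reduced-alphabet Hamming radius for clustering, default 1; negative disables
clustering), `--subseq-len` (window length, default 10), `--key-len` (hash-key
prefix, default 5).

`txsearch aln` options: `--threads`, `--evalue` (default 10), `--max-targets`
(default 25), `--filter-threshold` (similarity-filter radius, default 2),
`--xdrop-ungapped` / `--xdrop-gapped` (default 20 / 38), `--min-ungapped-score`
(default 20), `--batch-budget`, `--no-prefetch`, `--log`.

Scoring defaults: BLOSUM62, gap open 11 / extend 1, gapped Karlin–Altschul
constants λ = 0.267, K = 0.041 (no effective-length correction — a documented
divergence from NCBI BLAST E-values).

Output columns: `qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore`; query coordinates are 1-based nucleotide
positions on the read (reverse-frame hits have qstart > qend), subject
coordinates 1-based amino-acid positions.

## Library layout

| module | role |
|---|---|
| `txsearch.seq_codec` | residue codes, reduced 12-group alphabet, delimiter-concatenated sequence store |
| `txsearch.translate` | six-frame translation into stop-free query segments |
| `txsearch.db_index` | window extraction, greedy clustering, B_e/B_r/B_m lookup tables, chunking, serialization |
| `txsearch.seeding_filter` | seed lookup + triangle-inequality similarity filter |
| `txsearch.extend_ungapped` | scoring parameters, X-dropoff ungapped extension |
| `txsearch.chain_filter` | near-diagonal / contained-segment thinning |
| `txsearch.extend_gapped` | X-dropoff gapped extension, score-only pass + exact traceback |
| `txsearch.stats_evalue` | E-values, bit scores, ranking/thresholding |
| `txsearch.scheduler` | two-phase batched execution over chunks, prefetch, determinism contracts |
| `txsearch.io_cli` | FASTA/FASTQ readers, tabular writer, CLI |
| `txsearch.testkit` | read simulator, Smith–Waterman reference, brute-force oracles |

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the seven acceptance criteria (oracle
agreement ≥ 0.90 on the seeded synthetic benchmark, filter soundness,
clustering benefit, gapped X-dropoff convergence, chunk equivalence,
determinism matrix, traceback consistency).

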