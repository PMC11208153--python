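# ancestry-scan

Windowed competitive-mapping introgression scanner for plant genomes, with
diagnostic-kmer centromere calling, telomere detection, hierarchical
composition profiling, interval-overlap permutation testing, and
presence/absence pattern counting — plus a synthetic-genome simulator so the
whole pipeline is testable end-to-end with planted truth.

## What it does

Given a *recipient* reference, a *donor* reference, and one or more query
(cultivar) genomes, the scanner:

1. fragments genomes into overlapping fixed-length windows (default 10 kb
   windows, 7.5 kb overlap) and aligns them with a builtin minimizer-anchored
   ungapped aligner (or imports minimap2 PAF);
2. filters hits (best hit per window, identity ≥ 0.98/0.99, coverage ≥ 0.75)
   and prunes to collinear neighbourhoods (block of 5 within a window of 10);
3. masks low-divergence regions (200 kb intervals where >50% of 10 kb windows
   map at >98% identity between recipient and donor);
4. competitively classifies each query window against the concatenated
   recipient+donor reference (labels: recipient / donor / ambiguous /
   masked / unmapped);
5. calls candidate blocks of ≥10 consecutive donor windows, smooths with
   49-overlapping 50-window %donor intervals (≥70% introgressed, 30–70%
   ambiguous), and emits final introgressed/ambiguous blocks;
6. optionally projects block coordinates through a synteny anchor map.

Chromosome features: diagnostic 25-mers from known centromeric regions
(≥25 copies inside, zero outside), 250 kb/50 kb density scan with a ≥2.04%
coverage rule (or calibrated from per-chromosome peaks), telomere motif
counting, and hierarchical exon > Ty3 > other-repeat > intron > other
composition in 5 Mb/1 Mb sliding windows.

## CLI

```sh
ancestry-scan simulate   --config sim.json --out-dir fixtures/
ancestry-scan map        --query q.fa --target t.fa --window 10000 --overlap 7500 --out hits.paf
ancestry-scan introgress --query cultivar.fa --recipient ref.fa --donor donor.fa --out-prefix out
ancestry-scan centromeres --genome g.fa --seed-regions cen.bed --out cen_calls.bed
ancestry-scan telomeres  --genome g.fa --out telo.tsv
ancestry-scan composition --genome g.fa --exons e.bed --ty3 t.bed --repeats r.bed --introns i.bed --out comp.tsv
ancestry-scan overlap-test --a blocks.bed --b prior.bed --genome g.fa --n-perm 100000 --seed 42 --out result.json
ancestry-scan pav        --matrix pav.tsv --out patterns.tsv
ancestry-scan validate   --genome g.fa --bed x.bed --paf y.paf
```

`introgress` writes `out.windows.bed` (per-window labels), `out.seed_blocks.bed`,
`out.blocks.bed` (introgressed/ambiguous), `out.blocks.projected.bed` and a
JSON run report.

All coordinates are 0-based half-open (BED convention). The builtin aligner
is designed for desk-scale synthetic genomes; for real assemblies feed
minimap2 PAF via `--import-paf` / `--query-hits`.

## Layout

```
src/ancestry_scan/
  genome_io.py       FASTA/BED/PAF I/O, interval algebra, coordinate types
  window_mapper.py   windowing, builtin aligner, hit filters, collinearity pruning
  scan.py            low-divergence mask, competitive classification, block calling,
                     synteny projection, end-to-end pipeline
  chrom_features.py  diagnostic-kmer centromeres, telomeres, composition profiles
  stats.py           permutation overlap test, PAV patterns, summary arithmetic
  synthetic_data.py  recipient/donor/cultivar simulator with truth sets
  cli.py             click command group
```
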