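# linkdecon

Reference-free deconvolution of linked-read barcodes.

Linked-read technologies (10x Chromium, TELL-Seq, LoopSeq, stLFR) sequence
long DNA fragments (50–200 kb) with short reads that all carry the same
*barcode*. Barcodes are reused: a typical experiment has millions of fragments
but far fewer barcodes, so each *read cloud* (the reads sharing one barcode)
mixes several unrelated fragments. `linkdecon` splits each cloud back into
per-fragment groups — *enhanced barcodes* `BX:Z:<barcode>-<group>` — using
only the sequencing data, no reference genome.

## How it works

Genomes are sequenced at coverage *c* ≫ 1, so every fragment overlaps many
fragments carrying *other* barcodes. Two reads from the same fragment overlap
largely the same set of foreign fragments; two reads from different fragments
of the same cloud almost never do. Quantitatively, with fragment length *L*,
covered fragment fraction *p*, *n* fragments per barcode and *N*<sub>tot</sub>
barcodes, two same-fragment reads at distance *l* share on average

> p₁ = (L − l)/L · (c/p − 1)

overlapping fragments, while two far-apart reads of one cloud share

> p₂ = (c/p)² (n − 1) / (n·N_tot − c/p).

In realistic regimes (N<sub>tot</sub> ≥ 10⁶, c/p ≤ 10³) p₁ ≫ p₂, and that
contrast is the clustering signal. The pipeline:

1. **Sparse k-mer index** — canonical 20-mers whose lexicographic rank
   fraction falls below *d* = 1/8 are indexed; the fraction escalates per
   window of *w* = 50 bases so every *w*-stretch of every read holds an
   indexed k-mer. Two reads sharing ≥ 3 indexed k-mers are *similar* — no
   alignment is ever computed. K-mers occurring ≥ 2× the average multiplicity
   (repeats) are de-indexed.
2. **Read graph per barcode** — each anchor read links to the barcodes of its
   similar reads; collapsing this bipartite structure weights each anchor
   read pair by the number of barcodes they both overlap.
3. **Chinese-whispers clustering** — randomized weighted label propagation
   cuts the graph into an unknown number of groups; reads connected to
   nothing get group `0` ("not deconvolved").

The package also ships the linked-read simulator used for validation (uniform
fragments, pseudo-diploid genomes, ground truth), entropy-based evaluation
metrics, the p₁/p₂ theory model, and barcode-aware taxonomic rank promotion
for metagenomic classifications.

## Worked example

Simulate a pseudo-diploid dataset (200 kb random genome, 1% haplotype
divergence, 7–13 kb fragments, 50× coverage, 15% fragment coverage by 150 bp
pairs at 1% error, 4 fragments per barcode), deconvolve it, and score the
result against the ground truth:

```bash
linkdecon --verbose simulate --random-genome 200000 --divergence 0.01 \
    --frag-min 7000 --frag-max 13000 --seed 1 --out-prefix sim
linkdecon --verbose deconvolve --r1 sim_R1.fastq.gz --r2 sim_R2.fastq.gz \
    --seed 1 --out-prefix enh
linkdecon evaluate --r1 enh_R1.fastq.gz --r2 enh_R2.fastq.gz \
    --truth sim.truth.tsv --report report.tsv
```

Output (about a minute on one core):

```
INFO simulated 65198 read pairs over 13283 fragments
INFO read 65198 pairs, 3267 clouds, 0 unbarcoded
INFO index: 718052 k-mers kept, 4 pruned, mean occurrence 5.58
INFO deconvolved fraction (group >= 1): 0.9999
over_mean      0.0479403
over_median    0
under_mean     0.378003
under_median   0
n_reference_clouds      13279
n_deconvolved_clouds    7408
raw_under_median        1.37138
```

Reading the numbers: 99.99% of read pairs received a group ≥ 1. The
*over-deconvolution entropy* of a true fragment measures how much its reads
were scattered across output groups (0 = kept together); the
*under-deconvolution entropy* of an output group measures how many true
fragments it mixes (0 = pure). Raw barcodes hold ~4 fragments each, hence the
raw median ln 4 ≈ 1.37; after deconvolution the median drops to 0. The mean
under-entropy stays above zero because at this deliberately small genome size
same-barcode fragments frequently overlap the same locus (directly or through
the homologous haplotype) and are then genuinely inseparable — see
`docs/methods.md` for the scaling analysis. The enhanced FASTQ carries the
group in the barcode tag, e.g. `@sim0_0 BX:Z:TAGTGTATGACGAACC-1`.

The theory model is available directly:

```bash
$ linkdecon theory --L 100000 --l 0 --c 50 --p 0.15 --n 4 --ntot 1000000
p1      332.333
p2      0.0833403
p1/p2   3987.67
```

Other subcommands: `linkdecon promote` lifts taxonomic read assignments
(Kraken2-style TSV + a taxonomy table) to lower ranks supported by cloud
mates, and every subcommand writes a JSON manifest (parameters, seed, input
checksums) for exact reproduction.

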