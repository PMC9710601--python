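# Methods

## The deconvolution model

A linked-read experiment tags every short read with the barcode of its long
fragment of origin, and reuses each barcode for *n* fragments on average
(*n* ≈ 4 in 10x data). Deconvolution asks: within one barcode's read cloud,
which reads came from the same fragment? `linkdecon` answers without a
reference genome by exploiting sequencing redundancy. Fragments are drawn at
fragment coverage c/p (read coverage *c*, fraction *p* of each fragment under
reads), so every read overlaps reads from ~c/p foreign fragments. Reads of one
fragment overlap largely the *same* foreign barcodes; reads of different
fragments in the same cloud share foreign barcodes only by collision. The
expected numbers of shared overlapping fragments are

    p1(l) = (L - l)/L * (c/p - 1)          (same fragment, distance l)
    p2    = (c/p)^2 (n - 1) / (n N_tot - c/p)   (far-away fragments)

each multiplied by P², where P is the probability that a read of a common
overlapping fragment actually overlaps a given read. P has no closed form
here; it cancels from every p1/p2 ratio, so the model exposes it as a
parameter defaulting to 1 and all qualitative conclusions are P-free. With
N_tot ≥ 10⁶ barcodes and c/p ≤ 10³, p1 ≫ p2. The implementation evaluates the
two formulas as printed, without second-order corrections (the c/p
fragment-to-barcode identification is itself an approximation).

## Sparse k-mer indexing

Similarity search never aligns. Each read pair contributes the canonical
20-mers (lexicographic minimum of forward and reverse complement) of both
mates to one indexed set — pooling mates means one indexable mate suffices —
and two pairs sharing ≥ `min_shared` = 3 distinct indexed k-mers are
*similar*. Indexing all k-mers is wasteful; a k-mer is indexed at level *m*
when its canonical rank fraction (base-4 value / 4^k) is below m·d, with
d = 1/8 by default.

Rank selection alone can leave long stretches — GC-biased or low-complexity
regions — without any indexed k-mer, so the level escalates locally: for
every sliding window of w − k + 1 consecutive k-mer starts (w = 50 bases),
the smallest level that makes the window non-empty is found, and a k-mer is
selected iff its own level is within the largest such level over the windows
covering it. Two properties follow, both tested by brute force:

* every w-stretch containing an N-free k-mer holds an indexed k-mer;
* the *minimum-rank* canonical k-mer of every window is always selected.
  Because canonical ranks are position-independent, two reads sharing w bases
  of sequence select the shared window's minimum-rank k-mer on both sides,
  whatever their relative offsets — the window guarantee that makes sparse
  indexing safe for overlap detection.

A design note: escalation evaluated on *non-overlapping* fixed windows would
be cheaper but breaks the guarantee — the k-mer selected for a fixed window
can fall outside the part shared with the other read, and escalation levels
become offset-dependent. The sliding formulation is what the guarantee
requires; it is vectorised (sliding-window minima/maxima over integer rank
levels) and indexes ~130 k reads in ~10 s.

K-mers containing N are never selected. The level is capped at ceil(1/d),
where the indexed fraction reaches 1.

### Repeat de-indexing

Repeated sequence makes hub k-mers that link reads from unrelated loci.
After indexing, k-mers occurring at least `repeat_factor` = 2 times the
average multiplicity are de-indexed (removed from the dictionary and from
every pair's set); the average is frozen at its pre-pruning value. Which
average matters: with 1% sequencing error, singleton error k-mers dominate
the list of *distinct* k-mers (~83% of k-mer types on the scaled protocol,
pulling the per-k-mer mean down to ~5.6 while genuine genomic k-mers occur
79–90×), so thresholding at twice the per-k-mer mean would de-index
essentially the whole genome. The reference average is therefore the
*occurrence-weighted* mean — the expected multiplicity of a k-mer instance,
Σocc²/Σocc (~54 on the same data) — which sits on the coverage scale and
makes the threshold read "more than twice the typical multiplicity", pruning
only true repeat hubs. Both statistics are stored; `IndexParams.repeat_mean`
switches to the plain per-k-mer mean for datasets without singleton noise.

## Graph construction and clustering

Each barcode (*anchor*) is processed independently. Every anchor pair links
to the set of barcodes of its similar reads; the anchor's own barcode is
excluded (it adds a constant, fragment-indiscriminate +1 — exposed as
`include_self_barcode`). Collapsing gives a weighted graph on the anchor
pairs: edge weight = number of shared linked barcodes, edges absent at weight
0. Similarity counts distinct k-mer types, after pruning, at pair granularity.
For whole-dataset runs the similar sets are computed once as a sparse
pair×k-mer incidence product (`scipy.sparse`), which is exactly equivalent to
the per-pair dictionary walk (asserted in tests) and ~100× faster.

Chinese whispers then clusters each graph: every node starts as its own
cluster; nodes are visited in a fresh seeded-random order each pass and adopt
the label with the largest incident weight sum among neighbours (ties
uniform-random; a node's own label does not vote); iteration stops on a
change-free pass or after `max_iter` = 100 passes (oscillation is possible
but rare). The method is parameter-free in the number of clusters, and unlike
threshold-plus-connected-components it tolerates residual false links.
Clusters are renumbered 1..G per cloud by first appearance in input order;
pairs with no edges get group 0. Each cloud's RNG is seeded from
blake2b(global seed, barcode), so results are independent of cloud processing
order and of the `workers` thread count — runs are bit-reproducible.

## The simulator

`simulator` emulates the uniform-fragment protocol used for validation:
fragments of 70–130 kb (uniform length, uniform start, chromosome chosen by
length) are drawn until fragment count = ceil(c·G / (p·mean fragment
length)); within each fragment, read-pair start positions are uniform and
15% of the fragment length is emitted as 150 bp pairs (fixed 300 bp insert,
mate2 reverse-complemented) with 1% i.i.d. substitution error; barcodes
number fragments/4 and are assigned uniformly at random. A *pseudo-diploid*
genome — each sequence plus a copy with i.i.d. 1% substitutions, named
`*_hap2` — emulates a diploid sample. Ground truth (pair → fragment, with
fragment coordinates and per-pair start positions) is returned alongside the
reads.

Deliberate simplifications: no overlap enforcement between pairs, no indels,
no barcode sequencing errors, no PCR duplicates, no empirical 10x biases,
constant quality strings (the algorithm never reads qualities), fragments
clipped at chromosome ends kept and flagged (preserving start uniformity; at
genome sizes within ~10 fragment lengths this visibly depresses realized
coverage). Passing tests on this generator show the algorithm recovers
planted fragment structure under the stated noise model; they do not certify
behaviour under real library artefacts (chimeras, coverage waves,
barcode-collision hotspots).

## Evaluation metrics

With reference clouds = true fragments, two natural-log entropies are
computed per cloud: the *over-deconvolution* entropy of a reference cloud
(distribution of its reads over output groups; an even two-way split gives
ln 2 ≈ 0.693) and the *under-deconvolution* entropy of an output group
(distribution over reference clouds). Raw barcodes are scored by treating
each barcode as one output cloud; group-0 reads are excluded unless
requested. One value per cloud, unweighted by cloud size; histograms use
0.1-wide bins. The natural log is pinned by the even-split value: a two-way
split reads 0.7 in base e, 1.0 in base 2, 0.3 in base 10.

## Scaled study conditions and what they can show

Full-protocol datasets (Gb scale, N_tot ≥ 10⁶) don't fit in a test suite, so
validation runs a scaled protocol: 200 kb random genome, pseudo-diploid at 1%
divergence, fragments 7–13 kb, all other parameters as in the full protocol.
On this instance >99.9% of read pairs in multi-fragment clouds receive a
group, and the median under-deconvolution entropy drops from ln 4 to 0.

Scaling down distorts two regime quantities, and the distortion is visible in
the entropy tails rather than the medians:

* **Fragment collisions.** Two same-barcode fragments overlap the same locus
  with probability ≈ (L1+L2)/G per pair — ~10% at G = 200 kb against ~2–4% at
  full scale — and the two haplotypes share a coordinate system for this
  purpose, since 99%-identical homologous reads interlink. With ~6 fragment
  pairs per cloud, ~22% of output groups contain genuinely co-located
  fragments that no reference-free sequence method could separate; they
  dominate the nonzero tail of the under-entropy distribution.
* **Far-fragment contrast.** N_tot scales with the genome, so at 200 kb
  p1/p2 ≈ 13 instead of >10³; occasional well-separated fragments merge
  (~8% of groups). The empirical same-versus-far shared-barcode comparison
  is therefore run at a fragment size giving N_tot ≈ 6,700, where the model
  predicts a ~17× gap, and measures ≥ 10×.

The planted-partition recovery test preserves instead the two quantities that
control clustering at full scale: ~25 read pairs per fragment (full protocol:
50) via per-fragment coverage 0.75 at 8–12 kb fragments, and p2 ≈ 0 via one
barcode per background fragment; planted clouds merge 2–4 fragments pairwise
separated by more than one fragment length. Chinese whispers recovers the
fragments at mean adjusted Rand index 0.97–0.99 over 20 seeds. At naive
scalings (3–6 pairs per fragment) the intra-fragment graph is too sparse and
the clusterer splits fragment ends — the same over-deconvolution mode the
full-scale method exhibits as a minor tail.

## Taxonomic rank promotion

All reads of one fragment come from one organism, so cloud mates can vouch
for each other after classification. For read r with taxon t, let D be the
cloud-mates' taxa strictly below t. If D is conflict-free — every element is
an ancestor-or-self of the deepest one, i.e. all on one root-to-leaf chain —
r is promoted to that deepest taxon (or to the LCA of D with
`target="lca"`); any divergence in D blocks promotion. Unassigned reads are
promoted against all mates' taxa by default (`promote_unassigned=False`
disables). Promotion is monotone (never above the original rank). Splitting
a conflicted cloud can unlock promotions — the deconvolution benefit — but
splitting can also *remove* a promotion by separating a read from its only
informative mate, so no blanket monotonicity in cloud refinement holds, or is
claimed. Inputs are Kraken2-style two-column assignments and a
`nodes.dmp`-like (taxon, parent, rank) table.

## Numerical and degenerate-input choices

* Ranks are exact: base-4 k-mer codes are integers < 2^40 and 4^k is a power
  of two, so rank fractions are exact in float64.
* Sequences shorter than k index nothing; clouds of one pair get group 0 (no
  edges are possible), which depresses the deconvolved fraction when clouds
  are tiny — single-fragment clouds are excluded from the headline rate.
* Pairing of R1/R2 is positional; mismatched record counts and truncated
  FASTQ records are fatal with the record number named.
* Empty reference or output clouds are errors in the entropy routines;
  entropies are clamped to +0.0.
* All randomness flows from one integer seed: the simulator uses a single
  PCG64 stream; clustering derives one stream per cloud by hashing
  (seed, barcode).
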