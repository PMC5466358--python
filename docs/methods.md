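# Methods

## The circular template model

A circRNA candidate is an interval `[start, end)` on a chromosome (0-based
half-open, BED convention throughout; GTF input is converted on read). Its
transcript is modelled as the concatenation of the annotated exons of the
host transcript intersected with that interval, read 5'→3' on the transcript
strand (reverse-complemented as a whole for `-` circles). The annotated
transcript is chosen as the one on the same chromosome whose exons maximally
overlap the interval; when none overlaps, the whole genomic interval is used
as a single exon. The spliced sequence of length `L` is joined head to tail:
the back-splice junction sits between template positions `L-1` and `0`.

Junction identity for matching is the tuple `(chrom, start, end)`. Strand is
carried everywhere but excluded from identity by default, because several
callers report strand unreliably; `strict_strand=True` adds it back.

## Fragment geometry and junction support

Sequenced fragments are placed with an integer start offset drawn uniformly
on `{0, …, L-1}` and read off the circle, wrapping modulo `L` whenever the
fragment is longer than the spliced length (rolling circle). Mate 1 is the
first `read_len` bases of the fragment; mate 2 is the reverse complement of
the last `read_len` bases (FR orientation). A mate *spans the junction* iff
its interval on the unrolled template contains a multiple of `L` strictly
inside it — equivalently `floor((a + read_len − 1)/L) > floor(a/L)` for a
mate starting at unrolled offset `a`. A read pair *supports* the circle iff
at least one mate spans, and is counted **once** per pair in the truth (the
convention of roughly half the published callers; `convert_pair_counting`
produces the twice-per-pair convention by adding one count for every pair
whose two mates both span, which geometry forces whenever `L < read_len`).

Two sampling modes are provided, because a realistic positive dataset is
described by both a total read-pair yield and a per-circle junction-support
range that uniform coverage alone cannot jointly pin down:

- **coverage mode** — pairs per circle = `round(coverage · L / (2 · read_len))`,
  uniform starts; circles whose realized support falls outside
  `[min_support, max_support]` (default [2, 24], the range used for the
  simulated positive benchmark) are re-drawn in target-support mode with a
  target sampled uniformly from that range, so within-range geometry is
  undistorted;
- **target-support mode** — fragment starts are rejection-sampled
  conditioned on junction crossing until exactly the requested number of
  supporting pairs exists (here `support = total`).

Insert size is `round(Normal(insert_mean, insert_sd))`, truncated below at
`read_len`; `insert_sd = 0` (the positive-set default) gives a fixed
350 bp fragment. Defaults: `read_len` 101 bp, `insert_mean` 350 bp,
matching the paired-end library geometry of the benchmark datasets.

## Error model

Each base is substituted independently with probability ε (default 0.01 for
circle reads), uniformly among the three alternative bases; `N` is never
mutated. Qualities are the constant Phred character `round(−10·log10 ε)`
(Phred 20 at 1%), Phred 40 at ε = 0. This deliberately replaces a trained
sequencer-specific error profile: the evaluation needs error-bearing reads
with known marginal rate, not instrument realism, and a uniform rate is the
model the binomial test oracle can verify exactly.

The background simulator emits `round(fold_coverage · len / (2 · read_len))`
pairs per mRNA longer than the mean insert (shorter transcripts are skipped
with a warning), uniform fragment placement without wrapping, insert
350 ± 10 bp. Its default error rate is derived from a quality-shift
parameter: shifting an assumed Phred-30 baseline down by 13 gives
ε_bg = 10^(−(30−13)/10) ≈ 0.02, modelling poor-quality libraries. A
geometric-length (1–3 bp) indel model is available and off by default.
Background reads contain no back-splice junction signal by construction, so
truth-positive counts on background-only data are zero.

Every stochastic operation takes a NumPy `Generator` seeded from the
configuration (default seed 20160830); identical configurations produce
byte-identical FASTQ and truth files.

## Evaluation metrics

`confusion()` filters predictions at `support ≥ min_support` (default 2,
the filter applied throughout the benchmark analyses), matches junctions
exactly by default (`tolerance` in bp is available for real-tool outputs
whose breakpoints wobble), and reports S = TP/|truth|, P = TP/#detected and
F1 = 2PS/(P+S). Metrics are kept at full precision internally and rounded
only at report time (two decimals for percentages and F1). Deltas between
two datasets are differences of the *rounded* operands, matching how such
drops are conventionally printed.

The PR curve sweeps the integer support threshold from 1 to the maximum
observed support. AUC is the trapezoidal integral of precision over recall
after sorting by recall; the left edge is closed by carrying the precision
of the lowest-recall point down to recall 0, so a perfect predictor's AUC
equals its recall at threshold 1, and AUC never exceeds that recall. There
is no extrapolation beyond the maximum observed recall.

Undefined quantities are reported as absent rather than 0: precision with
no detections, sensitivity with empty truth.

## Cross-method analyses

- **Overlap**: for candidate sets already support-filtered,
  `C(i,j) = |set_i ∩ set_j|` by junction identity and
  `P(i,j) = C(i,j)/N_i`, so `P(i,j)·N_i = P(j,i)·N_j = C(i,j)`; methods
  with `N_i = 0` get an absent row.
- **RNase R enrichment**: the classification domain is candidates with
  support ≥ 2 in the *untreated* sample (treated-only candidates are out of
  the domain, consistent with using the untreated sample as denominator).
  Counts are normalized per million sequenced read pairs — the constant
  cancels in the ratio, which is the classified quantity: depleted (< 1),
  not depleted (≥ 1, ties count as not reduced), enriched (≥ 5-fold).
  Top-N summaries rank by the untreated normalized count, descending, ties
  broken by genomic coordinate for determinism.
- **Read-level sensitivity**: over candidates detected by every method,
  excluding circles whose spliced length is below the insert size (for
  those, the once-vs-twice counting conventions diverge and confound the
  comparison), the matrix of `log2(support + 1)` is clustered by
  average-linkage (UPGMA) on Euclidean row distances via
  `scipy.cluster.hierarchy`; the dendrogram is exported as newick with
  merge heights.
- **Validated recovery**: counts of externally validated junctions matched
  at support ≥ 1 (GE1) and ≥ 2 (GE2).

## The fixture generator

`make_fixture` emulates a genome + catalogue download at desk scale: random
uniform-composition chromosomes, genes with 2–6 exons (exon lengths 80–300
bp, log-uniform intron lengths so both sub-kilobase and multi-kilobase
circles arise), circles drawn as exon-bounded sub-intervals of transcripts
with genomic spans in 51 bp – 50 kb, and spliced mRNAs for the background
simulator. It is fully deterministic under its seed and self-validating
(every emitted circle is re-checked as exon-bounded and within the span
range).

What it does **not** emulate — and hence what passing tests do not show
about real data: realistic base composition, repeats and homologous regions
(a major false-positive source for real callers), intronic/intergenic
circle biogenesis, transcript-abundance skew, RNase R biochemistry
(pseudo-treated samples are generated by jittering supports), and genomic
spans up to the hundreds of kilobases seen in real catalogues (the
simulator itself has no span ceiling; only the fixture does).

## Problem sizes and numerical checks

Tests and the acceptance script run at fixture scale: 10–50 circles on
120–500 kb genomes, coverage 4–100×, giving hundreds to tens of thousands
of read pairs per check — sizes chosen so each statistical comparison has
the power its oracle needs (3σ binomial bands on ≥ 10³–10⁶ trials) while a
full run stays in seconds. Geometric accounting is checked against
exhaustive enumeration of all integer fragment offsets; read placement
against a string search over the rotated template; clustering against a
hand-computed three-row UPGMA example; determinism by byte comparison of
re-runs.

## Known limitations

- The simulator draws circles independently and uniformly; no abundance
  model links circle expression to host-gene expression.
- Duplicate rows in prediction tables are merged by summing support — the
  conservative reading when tool output dialects are unknown; tools that
  list per-read rows would need pre-aggregation.
- PCR duplicates, strand-specific protocols and quality-score training are
  out of scope; the error model is uniform by design.
- With matching tolerance > 0 a prediction may sit within tolerance of two
  truth junctions; it is counted once, and TP is capped by the number of
  distinct truth junctions recovered.
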