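# Methods

## Fragment-length extraction

Fragment lengths are read from coordinate-sorted, indexed, deduplicated
paired-end BAM files. Mates are matched by query name in a single pass;
each pair is counted once, at the absolute template length reported by the
aligner. A pair is rejected when (in this order, so each rejection
increments exactly one counter): either mate has mapping quality below
`min_mapq` (default 30); either mate's CIGAR contains soft or hard clips;
either mate's alignment interval overlaps an excluded region (BED, 0-based
half-open) by at least one base; or the length falls outside
[`min_length`, `max_length`] = [30, 700] bp. The filters are deliberately
conservative: clipped or low-MAPQ alignments make the inferred template
length unreliable, and excluded regions harbour systematic mapping
artefacts. Retained counts plus per-filter rejections always equal the
number of observed pairs, and the counters are reported.

Adapter-merged single-end records (from upstream read-merging tools) can be
counted by their query length behind an explicit flag
(`allow_merged_single_end`), off by default.

At a somatic variant locus (1-based, VCF convention; conversion to 0-based
BAM coordinates happens in a single helper), fragments physically covering
the position are split by the base they carry: alternate allele → mutated
histogram, reference allele → wild-type. Pairs showing a deletion or a
third allele, or whose two mates disagree, enter neither histogram and are
counted; this keeps the mutated histogram a clean estimate of the
tumor-derived length distribution.

## Histogram matrices

Per-sample histograms on a common contiguous grid stack into a
`samples x lengths` count matrix. Rows are scaled to sum to one before
factorization; all-zero rows are fatal by default and may be dropped with a
warning where they are expected (empty genome bins). Matrices round-trip
exactly through a TSV dialect (`label` column + integer-length columns,
floats written at 17 significant digits and re-read with round-trip
parsing).

Subsampling a histogram to `n` fragments is a multivariate hypergeometric
draw on its counts: drawing reads without replacement from the sequenced
pool and re-tallying lengths is exactly this distribution, given the
histogram. Draws are reproducible from a seed.

## KL-NMF

The normalized matrix `V` is approximated as `W H` by minimizing the
generalized Kullback–Leibler divergence with the standard multiplicative
updates

```
H ← H ⊙ (Wᵀ(V ⊘ WH)) ⊘ (Wᵀ1)
W ← W ⊙ ((V ⊘ WH) Hᵀ) ⊘ (1Hᵀ)
```

Numerical choices:

- **Initialization**: entries uniform on (0, 1] scaled by `mean(V)/k`. The
  scale only sets the starting loss; the updates are scale-covariant.
- **Floor**: `eps = 1e-12` is added inside the divisions to avoid 0/0.
  With it, the per-iteration loss decrease holds to ~1e-10 relative, which
  is what the monotonicity property test asserts.
- **Convergence**: stop when the relative loss improvement over one
  iteration falls below `tol = 1e-6`, or at `max_iter = 2000`.
- **Restarts**: 20 independent random initializations by default; the fit
  with the lowest final loss is kept. Per-restart streams are spawned from
  one master `SeedSequence`, so restart *r* is identical whether 5 or 50
  restarts are requested — adding restarts can only improve the selected
  loss.
- **Rescaling**: each signature (H row) is scaled to sum to one with the
  inverse scale absorbed into the matching W column, then each weight
  vector (W row) is normalized. The row-normalized reconstruction is
  invariant, and weights read as source proportions.

Weights for new samples are inferred by running only the W update against
fixed signatures. A caveat of multiplicative updates: components whose true
weight is exactly 0 decay only at O(1/iteration), so boundary weights reach
~1e-5 precision at 2·10⁴ iterations rather than machine precision; interior
mixtures converge fast and accurately.

The tumor component is identified as the signature with the lowest mean
fragment length, reflecting the left shift of ctDNA; exact ties break to
the lowest index with a warning. For k > 2, callers may instead match
components to reference signatures by cosine similarity.

Signature stability is measured by refitting on random sample subsets and
taking each signature's maximum cosine similarity to the full-data
signatures; generalization by repeated half-splits, fitting on one half,
projecting the other, and correlating the tumor weight with an external
ctDNA estimate in both halves.

## ctDNA burden from driver variants

Per sample, the driver VAF is the maximum observed VAF, or the median of
all VAFs within an absolute window of ±0.02 of the maximum (damping
single-variant noise; the window is read as ±2 percentage points, not
relative 2%). Purity is `2·VAF` for a heterozygous variant without LOH and
`2/(1/VAF + 1)` under LOH; values above 1 (e.g. VAF > 0.5 without an LOH
annotation) are clipped to 1 with a warning rather than reinterpreted. The
ctDNA fraction adjusts purity for tumor ploidy `t` (normal ploidy fixed at
2): `p·t / (p·t + (1−p)·2)`.

The DELFI ratio is the count of 100–150 bp fragments over 151–220 bp
fragments, both bounds inclusive; an empty denominator yields NaN (not an
exception) because sparse genomic bins are routine, and downstream
correlations are pairwise-complete.

## Genome bins

Chromosomes (autosomes by default) are tiled with fixed-size bins (250 kb
default; terminal bins shorter). Each fragment is assigned to the single
bin containing its midpoint — symmetric, and immune to double counting at
bin edges. Per-bin histograms are summed across healthy controls; bins
whose mean fragment count across controls falls outside
median ± 2·IQR (quartiles by linear interpolation, type 7 — stated because
the window depends on it; bounds inclusive) are excluded as likely
mappability artefacts. Bin-wise NMF on the aggregated, normalized matrix
yields chromatin-state length signatures; per-sample per-bin weights under
fixed signatures (bin-wise or sample-wise trained) become classifier
features, with bins under 100 fragments yielding missing values instead of
noisy weights. An external per-bin signal (e.g. ATAC-seq accessibility) can
be rank-correlated against the features.

## Classification

A linear SVM (fixed cost C = 1, no inner tuning) on per-sample features
under stratified 10-fold cross-validation repeated 50 times. Per training
fold: missing features are imputed with training-fold means, features are
standardized (mean 0, sd 1 with the n−1 denominator; zero-variance features
dropped), and held-out samples are scored with the decision function using
the training fold's statistics — no information crosses the fold boundary.
One AUC per repeat is computed from the pooled out-of-fold decision scores
(stabler than averaging per-fold AUCs with small folds); AUC uses the
Mann–Whitney formulation with ties counted ½. Stratified folds are used
throughout because unbalanced cohorts make unstratified folds degenerate.

## Synthetic cohorts

The generator emulates the qualitative anatomy of cfDNA length
distributions: a Gaussian mono-nucleosome mode, a di-nucleosome Gaussian
one nucleosomal repeat (+167 bp) away carrying a `dinucleosome_weight`
fraction of the main peak's mass, and a comb of narrow Gaussian teeth every
`periodicity` bp (default 10.4 bp, the helical repeat; configurable to
10.0) below the mode, with amplitude a fraction of the main peak height
decaying away from it. Defaults: background mode 166 bp (sd 22), mild comb
(amplitude 0.02), di-nucleosome mass 0.12 → mean 183.5 bp; tumor mode
145 bp (sd 18), strong comb (0.25), enlarged di-nucleosome mass 0.25 →
mean 172.4 bp. Per-sample histograms are multinomial draws of `depth`
fragments from `(1−w)·background + w·tumor`, with tumor weights `w` uniform
on [0, 0.9] by default — spanning the ctDNA burdens of a metastatic cohort
while guaranteeing no pure-tumor sample, which is the harder, realistic
regime for deconvolution. The binned generator mixes an "open" (152 bp
mode) and a "closed" (168 bp mode) state per bin with known openness,
providing both the bin-wise NMF recovery check and a stand-in
accessibility signal for rank-correlation tests.

What the generator does *not* emulate: GC and mappability biases,
batch/protocol differences in the length spectrum (e.g. extraction-kit
effects on the di-nucleosome peak), sub-nucleosomal and Jagged-end
artefacts, copy-number-driven regional coverage changes, or any sequence
content. Passing recovery tests on these cohorts therefore demonstrates
correctness of the estimator under the mixture model, not robustness to
real-data confounders.

## Problem sizes

The shipped experiments use 50-sample cohorts (10⁶ fragments/sample for
the deep-recovery and hold-out checks; 1000 fragments/sample across 20
replicate cohorts for the low-depth check), 500 bins at 10⁵ fragments for
the bin-wise check, and n = 200 for classifier sanity — sizes at which
every quantity is stable across seeds while the full suite runs in a few
minutes on one CPU.

## Known limitations

- Identifiability: NMF recovers signatures up to the geometry of the
  mixture; with no near-pure tumor samples the recovered tumor signature is
  an extreme ray that can be slightly sharper than the true source
  distribution. Weights remain near-affine in the truth (hence the high
  correlations) but are not calibrated ctDNA fractions.
- k is a hyperparameter set in advance; no automatic model selection is
  provided.
- The tumor-by-lowest-mean-length rule can misidentify components in
  cohorts whose dominant non-tumor variation also shortens fragments;
  reference-signature matching is the fallback.
- No GC/mappability correction in the bin-wise pipeline beyond the
  median ± 2·IQR coverage screen.
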