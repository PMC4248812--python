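# Methods

## The bootstrap DE test

The unit of resampling is the read — for paired-end data, the fragment:
both mates share one ID and are drawn as a unit, so pairing information
survives resampling. A bootstrap sample draws N read IDs with replacement,
uniformly, from the N reads of the original sample; a read drawn m times
contributes all of its alignments m times. Sample size is therefore
conserved exactly, while the alignment count varies with the ambiguity of
the selected reads. Each bootstrap sample gets its own seed
(`base_seed + index`) so any individual sample can be regenerated.

Given M per-gene FPKM estimates per condition (replicate folders are
concatenated first and then treated as one condition), fold-change
estimates a_i/b_j are formed by one of two pairings:

* **matching** — a single uniformly random permutation, shared across all
  genes, pairs the estimates one-to-one (N = M). Sharing one permutation
  preserves the cross-gene correlation structure of the bootstrap samples;
  per-gene permutations would destroy it without changing any per-gene
  marginal.
* **all** — every ordered pair (N = M_A × M_B). This is the default
  (M = 20), since it extracts far more comparisons from few EM runs and
  tolerates unequal bootstrap counts across conditions.

Zero denominators follow two conventions chosen for monotonicity and
conservatism: a/0 := +inf (a > 0), which supports every finite fold
threshold in the over direction, and 0/0 := 1, which supports none — a gene
absent from both conditions must not generate a DE call.

Support comparisons are inclusive (≥ f, ≤ 1/f, ≥ b) throughout. With
continuous FPKMs the boundary cases have measure zero; inclusiveness
matters only for constructed ties and makes the degenerate cases
predictable. If both directions pass at f = 1 the larger support wins and
an exact tie is reported non-DE.

The support threshold can be calibrated from a binomial null: under the
null each of the N estimates is assumed equally likely to fall on either
side of f, so b = x_min/N with x_min the smallest x whose exact binomial
tail P(X ≥ x) drops to α (no normal approximation; for tiny N the tail
never reaches α within 0..N and b > 1 is returned — no gene is callable).
The test emits no per-gene p-value and applies no multiple-testing
correction; its output is the support itself plus the minimum fold change
still supported at b, computed as the ⌈bN⌉-th largest ratio (reciprocal
order statistic for the under direction, more extreme direction reported).

### Calibration caveat (known limitation)

The binomial model treats the N indicators as independent. That is exact
for matching pairing with independent estimates, and a unit test verifies
the null DE-call rate stays near α there. For all-pairs the M² indicators
form a Mann–Whitney-type rank statistic whose null standard deviation at
M = 20 (≈ 0.09) is several times the binomial's (≈ 0.025 at N = 400), so
the same threshold is strongly anticonservative at f = 1. A second,
independent inflation affects both pairings on real pipeline data: the
bootstrap captures only within-sample resampling variance, so the sampling
noise between the two original samples shifts all of a gene's comparisons
jointly. The acceptance script measures both null rates; at practical fold
thresholds (f ≥ 1.5) the gap between conditions must exceed the combined
noise and the behaviour is far tamer, which is why the defaults pair
f = 2 with α = 0.05.

## The EM quantifier

A deliberately simplified isoform-aware quantifier resolves multi-mapped
reads. Reads are collapsed into equivalence classes by their alignment
signature; the E-step assigns each class fractionally among its transcripts
in proportion to θ_t/ℓ̃_t × weight, and the M-step re-estimates θ from the
assigned mass. At the fixed point θ_t is the fraction of reads from
transcript t and FPKM_t = 10⁹ · (assigned reads)_t / (ℓ̃_t · total reads).
Gene FPKM is the sum over the gene's isoforms.

* Effective length ℓ̃ = max(1, L − mean read length + 1), the standard
  single-end convention (mean fragment length for paired-end).
* Initialization is uniform; fractional assignment makes tie-breaking a
  non-issue.
* Defaults tol = 1e-8 (maximum relative change in θ) and max_iter = 1000:
  small enough that bootstrap-to-bootstrap variation dominates numerical
  error. Transcripts whose abundance has fallen below 1e-12 are excluded
  from the convergence criterion — their mass decays geometrically and
  never stabilizes in relative terms, while being orders of magnitude below
  anything FPKM-visible. Hitting max_iter returns the estimate with
  `converged=False` and a warning.
* Alignment weights default to 1; quality- and insert-size-based weighting
  is out of scope, but the weight enters the E-step so richer models can
  plug in.

Read mass is conserved exactly at every iteration (each class distributes
precisely its count), and the observed-data log-likelihood is
non-decreasing; both are asserted in tests, and the fixed point is checked
against a brute-force grid search of the likelihood on small instances.

## Fisher's exact test baseline

Row 1 of the 2×2 table holds the estimated reads per kilobase of gene
length in each condition (FPKM × total reads / 10⁶, rounded to integers —
the test needs counts and the convention is stated rather than implicit);
row 2 holds the normalization counts: total mapped reads, the
housekeeping gene's (POLR2A) reads per kilobase, or the reads per kilobase
of the aggregated ERCC spike-in FPKM. The two-sided p-value sums the
hypergeometric probabilities of all fixed-margin tables no more likely than
the observed one; the pmf is evaluated through log-gamma and renormalized
over its support, keeping entries up to ~10⁸ overflow-safe. Two-sided was
chosen because the DE question is symmetric. BH at 5% FDR adjusts across
genes, and a DE call additionally requires the row-1 fold change to meet
the threshold f in the claimed direction (the gate keeps Fisher calls
comparable with the bootstrap test's f).

## qPCR ground truth

CT values above 35 are clamped to 35 (the detection ceiling). Delta CT per
replicate is the condition's mean reference (POLR2A) CT minus the gene's
CT, and normalized expression is 2^ΔCT. Genes undetected in any replicate
are dropped, as are genes whose four normalized values in either condition
have coefficient of variation above 25% — the "25% standard deviation"
filter is interpreted as CV of the normalized expression values (SD of a
set of expression values is only meaningful relative to their mean;
configurable). The t-test is Student's unpaired two-tailed on the delta-CT
(log2) scale, since that is the scale the measurements live on
(Welch available); p-values are BH-adjusted at 5% FDR and a gene is truly
DE when the fold change of mean normalized expression exceeds the
threshold and the adjusted p < 0.05. Degenerate zero-variance inputs give
p = 0 when the means separate and p = 1 when they coincide.

Evaluation uses the 3×3 confusion matrix of predicted {over, non-DE,
under} against truth {TOE, TND, TUE}; sensitivity and PPV count correctly
directed DE calls only, accuracy adds the true non-DE diagonal, and the
F-score is the harmonic mean of sensitivity and PPV. Undefined ratios
(empty denominators, e.g. a quintile with no true-DE genes) are reported
as NaN, not zero. Quintiles sort evaluated genes by average expression
(stable tie-break on gene ID) into five near-equal bins; their matrices
sum to the global matrix by construction, which a test asserts. Genes
present in the truth but absent from a prediction table count as predicted
non-DE: the caller made no positive claim.

## The simulator

`synthdata` emulates what the test actually consumes: a transcriptome of
`num_genes` genes with 1–3 isoforms (lengths uniform 500–3000 nt),
per-transcript baseline expression that is lognormal (σ = 0.5) around a
mean of 1, paralog pairs that induce multi-mapping (a read carries a
second alignment to its transcript's partner with probability
`multimap_rate`, default 0.2), and two conditions in which designated
genes are scaled by their fold change. Read counts are multinomial with
expectation coverage × ℓ̃/1000 × expression; coverage defaults to 50
reads/kb. Reads are generated directly as alignment records — sequence
content never enters any in-scope computation — with optional GTF/SAM
emission that round-trips through the standard parsers. qPCR tables place
the reference gene at CT 20 in both conditions, gene baselines at CT
22–30, DE shifts of 2 CT (4-fold) and Gaussian CT noise (default 0.25,
which keeps expression CV under the 25% filter).

What the simulator does **not** model — GC and positional bias, sequencing
error, alignment error, genuinely continuous isoform-switching, biological
replicate variance beyond resampling — bounds what passing tests show:
they validate the statistical machinery under its own assumptions, not
performance on real libraries.

## Problem sizes

The default verification runs use 200-gene transcriptomes (~350
transcripts, 25–50 reads/kb, 20–90 k reads), M = 20 bootstrap samples per
condition, 10⁴ resamples for the uniformity check, exhaustive Fisher
enumeration for grand totals ≤ 60 (≤ 40 in the acceptance script) and the
full binomial-calculator sweep n ≤ 1000 — sizes at which every check is
exact or has negligible Monte-Carlo error while the whole suite stays
desk-scale.
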