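# Methods

This note documents the models, parameter choices and numerical
conventions behind `codonadapt`, and what the synthetic data generator
does and does not emulate.

## tRNA quantification

**Isodecoder collapsing.** tRNA genes whose mature sequences are identical
after appending the post-transcriptionally added 3′ CCA cannot be
distinguished by sequencing reads; they are collapsed into isodecoder
groups named `Aa-ANT-i`, with an `-X` suffix when more than one gene
encodes the group. Identical sequences annotated with different anticodons
or amino acids are treated as an annotation error and rejected outright
rather than silently merged. Collapsing is idempotent and conserves the
total gene count across groups.

**TMM normalization.** Between-sample scaling follows the trimmed mean of
M-values: for each sample against a reference, per-feature log-ratios
(M) and average log-abundances (A) are computed over features observed in
both samples, doubly trimmed (30% on M ranks, 5% on A ranks — the
canonical defaults, configurable), and combined in an inverse-variance
weighted mean using the delta-method variance `(N−y)/(Ny)` of a log
proportion. The reference sample is the one whose 75th-percentile count
fraction is closest to the panel mean. Factors are rescaled to geometric
mean 1, and normalized values are `count / (library size × factor)` put
back on a count-like scale by the geometric-mean library size, so a pure
depth change in any one sample cancels exactly. The implementation is
cross-checked in the test suite against an independently coded
transcription of the estimator and against edgeR's `calcNormFactors`
(agreement < 1e-6).

**Isoacceptor abundance** is the arithmetic mean of the condition-mean
normalized values over the member isodecoders of each anticodon group
(a `sum` mode exists but is off by default; the mean is the quantity the
downstream tAI weights are defined on). Gene copy numbers of
indistinguishable duplicates are *not* used as weights. Mitochondrial
tRNAs are carried through tables with a `genome` flag but excluded from
all isoacceptor/tAI/SDR computation, which concerns cytosolic translation
only.

**Differential expression.** Two-condition flagging uses
log2FC = log2(mean A / mean B) on normalized values and a t-test on
log2(value + 0.5) with Benjamini–Hochberg correction, flagging features
with |log2FC| ≥ 0.5 and q ≤ 0.1. This is a deliberately simple stand-in
for count-model-based testing of real tRNA-seq data and is tagged
`method=welch_bh_standin` in every output so its q-values are never
mistaken for those of a count-aware Bayesian method. Because a
3-replicate design leaves 2–4 residual degrees of freedom per feature,
per-feature variances are shrunk toward the panel-wide median with 4
prior degrees of freedom before testing (empirical-Bayes moderation; on
the log scale, count data with a shared coefficient of variation are
near-homoscedastic across features, which is what justifies pooling).
Moderation is what makes the test usable at n = 3: without it,
sensitivity on the default synthetic panel drops from 100% to ~80% at an
unchanged ~0% false-flag rate. `prior_df=0` restores plain Welch.
A condition mean of zero yields an infinite log2FC sentinel rather than
an error.

## Codon-level metrics

**Codon counting and frequencies.** A CDS must have length divisible by
3 and no internal stop; a single trailing stop codon is accepted and
excluded from the codon count L, so all metrics are defined over sense
codons only. Ambiguous bases reject the record by default (a permissive
mode drops the affected codons). Relative frequencies are `n_c / L`; the
within-family normalization divides each codon's count by its synonymous
family total, producing a 59-dimensional vector (61 sense codons minus
the single-codon families Met and Trp). Families absent from a CDS give
all-zero blocks rather than missing values, so every gene occupies the
same 59-dimensional space for PCA.

**CSC.** Per codon, the Pearson correlation across genes between relative
frequency and half-life. Half-lives enter untransformed by default (a
log option exists; with lognormal half-life noise the log scale is
arguably more linear, but the correlation sign and ranking — which is
what the optimality classification uses — are insensitive to the choice
on the synthetic data). Codons with zero frequency variance get an
undefined (NaN) CSC, reported as missing, and classify as `undefined`.
Class boundaries are optimal CSC ≥ 0.01, non-optimal CSC ≤ −0.01
(boundary inclusive on both sides), neutral in between.

**Wobble rules and tAI.** The decoding-rule table ships as an editable
TSV of (codon, anticodon, s) with the canonical eukaryotic selective
constraints: Watson–Crick 0, G:U 0.41, I:C 0.28, I:A 0.9999, U:G 0.68.
ATG is Watson–Crick-only (the U-wobble anticodon reads the Ile codon
ATA), and the prokaryote-specific lysidine rule is omitted. Raw weights
are `w_c = Σ_j (1 − s_cj) · abundance_j` over the rule table; anticodons
missing from the abundance table contribute zero (logged). Weights are
normalized within each synonymous family by the family maximum, so each
family's best codon has tAI exactly 1.0 and tAI is invariant to uniform
rescaling of the tRNA pool. An all-zero family is an error. Individual
zero-weight codons propagate as tAI 0 under the default strict policy
(and make `tai_gene` fail loudly, naming the codon); the lenient policy
substitutes the geometric mean of the family's nonzero weights, the
conventional imputation in the tAI literature. `tAI_gene` is the
geometric mean over all L codons (Met and Trp included — they carry real
weights), computed in the log domain.

**CAI.** Sharp–Li: codon counts pooled over the reference set; within
each family `w_c = count_c / max count`; codons unobserved in the
reference get a 0.5 pseudo-count floor before dividing so no weight is
zero. The gene score is the geometric mean of `w` over the CDS excluding
Met, Trp and stops (single-codon families carry no information about
synonymous choice). When no explicit reference list is supplied, the
pipeline uses the top 5% of genes by mean expression as the
highly-expressed reference.

**SDR.** Demand is `d_c = Σ_g expr_g · f_{c,g}`, rescaled to sum to 1
across codons by default so SDR magnitudes are comparable between
conditions with different total expression (a raw mode exists; the
monotonicity tests use it because rescaling couples codons).
`SDR_c = tAI_c / d_c`; the gene-level SDR is the geometric mean over the
CDS, and `ΔSDR` is the second condition minus the first
(post-transition minus progenitor). A used codon with zero demand is an
error rather than an infinity.

**Comparisons and selections.** The stabilizing (CSC > 0) vs
destabilizing (CSC < 0) codon groups are compared on tAI with pooled-SD
Cohen's d (sign = stabilizing − destabilizing) and Welch's t. The
between-condition tAI report keeps codons with |ΔtAI| ≥ 0.2. Gene
selections use summed relative frequency over a codon set (≥ 2% default
threshold) or top/bottom-fraction ranking (10% default) with stable
sorting and lexicographic gene-id tie-breaking, so selections are
deterministic; a tie spanning the cut emits a warning.

## Codon-usage clustering

PCA runs on the genes × 59 normalized matrix, mean-centered but not
variance-scaled by default (the coordinates already share a scale;
scaling is a flag, and constant columns are dropped with a warning when
it is on), via full SVD with a deterministic sign convention (each
component's largest-magnitude loading is positive). k-means uses
k-means++ with 25 restarts, tolerance 1e-6, 300 iterations, and a fixed
seed, giving bit-identical results across runs. The cluster number is
chosen by an explicit elbow rule: the k maximizing the discrete second
difference of **log** inertia. The log scale makes the rule scale-free;
the absolute-inertia version is biased toward small k whenever early
splits of well-separated clusters remove large absolute variance (on
5 well-separated planted clusters it reliably chose k = 3, the log
version recovers k = 5 in ≥ 18/20 seeds). A manual k override is
available. The CAI–ΔSDR association is a plain Pearson correlation with
a least-squares line; zero variance in either variable is an error.

## Synthetic data

The generators emulate the statistical structure of a
progenitor-vs-neuron study at its published scale, and their defaults
*are* the study conditions used in tests:

- **tRNA panel** — 44 cytosolic anticodon groups covering all 61 sense
  codons (one G34 anticodon per pyrimidine-ending codon box, U34 for
  sense A-ending codons, C34 for sense G-ending codons, with one
  redundant C34 anticodon dropped to reach 44), 84 isodecoders assigned
  round-robin, plus 2 flagged mitochondrial tRNAs; lognormal baseline
  abundances (log10 SD 1.1, spanning ≥ 4 orders of magnitude); 10
  differentially expressed isodecoders at |log2FC| = 1 with alternating
  direction; 3 replicates per condition as negative-binomial counts at
  CV 10% with lognormal per-sample depth factors (SD 0.25) so TMM has
  real work to do.
- **CDS library** — 2,000 genes, lognormal lengths around 350 codons
  (min 80), every gene starting with ATG; amino-acid composition fixed
  to a typical eukaryotic profile and *shared across clusters*, so the 5
  planted clusters differ only in synonymous choice: within each family
  a cluster puts probability 0.7 on its preferred codon (preferences
  drawn once by a fixed internal RNG and constant across datasets).
- **Half-lives** — `exp(β0 + β1·f_opt + ε)` with `f_opt` the summed
  relative frequency over the planted optimal codon set, β0 = ln 30
  (≈ 30 time units, minutes for a fly mRNA), β1 = 1.5, ε ~ N(0, 0.3²).
  This log-linear form is the simplest monotone model consistent with a
  correlation-based stabilization coefficient.
- **Expression** — lognormal (ln-mean ln 50, SD 1), shared baseline per
  gene, with an optional per-cluster condition boost. The default full
  dataset boosts cluster 0 (also the CAI reference cluster) 4× in the
  second condition, raising demand for its codons there and planting a
  negative CAI–ΔSDR association.

In the assembled dataset the per-condition optimal codon sets are the
family-maximal tAI codons of the *true* (noise-free) tRNA pools, so
mRNA-decay signal and tRNA supply agree, as the optimality model assumes.

What the generator does **not** emulate: alignment and multi-mapping
artifacts, tRNA modification-induced misincorporation, charged vs
uncharged tRNA fractions, batch structure, secondary-structure or
UTR-mediated decay, and anticodon buffering. Passing recovery tests
therefore show that the estimators recover the planted statistical
structure at realistic scale and noise — not that real tRNA-seq biases
are overcome.

## Determinism and numerics

Every random stage takes a seed; the pipeline fans one top-level seed
out to sub-stages via a seed sequence. Geometric means are computed in
the log domain (product and log forms agree to 1e-10 in tests). TSV
outputs use tab delimiters, UTF-8, '.' decimals, `%.10g` floats,
'#'-prefixed metadata headers, and sorted row order, making reruns
byte-identical; the run manifest records a SHA-256 hash of the config.
Problem sizes used in the recovery tests (20 seeds; 2,000 genes for CSC
and correlation recovery, 750 for cluster-number recovery) were chosen
to estimate the recovery rates stably at desk scale.

## Known limitations

- The DE stand-in is not a count model; its q-values are calibrated on
  the log-normal-ish synthetic data, not on real overdispersed,
  zero-inflated tRNA-seq counts.
- The wobble constraint values are the literature's canonical eukaryotic
  constants, not organism-fitted; absolute tAI values (and counts of
  tAI = 1.0 codons) depend on them.
- CSC assumes a linear frequency–half-life relationship per codon;
  strongly nonlinear decay kinetics would be attenuated.
- SDR uses whatever expression unit is supplied as demand weights;
  results are invariant to its overall scale but not to unit
  nonlinearity.
- Alternative genetic codes and selenocysteine recoding are out of scope;
  SeC tRNAs in abundance tables simply contribute to no sense codon.
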