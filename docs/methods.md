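# Methods

## Problem setting

Microarray platforms carry short oligo probes (25–60 nt) grouped into
probesets. A probe that happens to lie inside an endogenous retroelement
(RE) measures transcription of that element — provided it sits entirely
within the element, in the right orientation, and is not confounded by a
neighboring gene. `retroprobe` formalizes that decision chain and the
statistics applied downstream of it.

## Probe localization

Probes are mapped by exhaustive ungapped full-length comparison against
every offset of every chromosome, on both strands (implemented as a numpy
sliding-window identity count). A placement qualifies when the number of
identical bases is at least `ceil(min_identity * plen)` with
`min_identity = 0.95`; the identity denominator is fixed to the probe
length, and genomic N never matches. `numhits` counts qualifying placements
genome-wide; the reported hit maximizes the identity count, ties broken on
lowest (chromosome, start, strand).

This deliberately replaces a seed-and-extend short-sequence aligner. At
≥ 95% identity on oligos of this length, gapped alignments that would pass
the threshold are edge cases, and the exhaustive contract is exactly
testable: the test suite and acceptance script compare it against an
independent all-offset scanner written in plain Python, and the 24/25 vs
23/25 mismatch boundary is tested exhaustively over all mismatch positions
and position pairs. Probes containing N are rejected at input; hits shorter
than the full probe are not counted.

## RE classification and context

A probe reports RE expression iff its best placement is strictly contained
in a single repeat-masked interval (adjacent fragments of one element are
not merged) and the strand relationship matches the platform chemistry:

| chemistry | hybridizes | RE-reporting probe is |
|---|---|---|
| antisense cRNA (3' arrays) | antisense cRNA | sense to the element (probe strand == repeat strand) |
| sense cDNA (WT arrays) | sense cDNA | antisense to the element (strands differ) |

Chemistry is an explicit input (manifest pragma or CLI flag), never inferred
from a platform name. Nearest genes chromosomally 5' (greatest end ≤ probe
start) and 3' (least start ≥ probe end) are computed over protein-coding
genes only, irrespective of gene strand; the intergenic distance is the
smaller flanking gap, 0 when the probe overlaps a gene. Probes with
`numhits > 1` keep their annotation row but all fields requiring a specific
genomic context are omitted. LTR repeats are assigned retroviral classes
I (ERV1), II (ERVK) and III (ERVL, including MaLRs); non-LTR classes get NA.

Intragenic position histograms use the probe midpoint as a fraction of gene
length measured 5'→3' of the gene (gene bounds, not transcript bounds),
clamped to [0, 1] so near-genic probes within 1 kb land in the terminal bins.

## Enhanced filtering

Retained are rows with (i) `numhits == 1`; (ii) intergenic distance
strictly > 1000 bases from the nearest protein-coding gene; (iii) probeset
RE fraction strictly > 0.75, computed against **all** probes of the probeset
in the manifest, including probes that failed to map. Both thresholds are
strict: 1000 bases and 3-of-4 probesets are rejected, 1001 bases and 9-of-11
pass. The uniqueness requirement applies per probe (not to the whole
probeset). Coverage accounting reports, per top-level class (LTR/LINE/SINE),
retained-probe counts and the percentage of distinct repeat instances
carrying at least one retained probe.

## Expression statistics

**Background correction** assumes observed intensity = signal ~
Exponential(α) + noise ~ Normal(μ, σ²), per array. Parameters are estimated
ad hoc (μ as the kernel-density mode, σ from the half-normal spread of the
sub-mode tail, α from the mean excess above the mode) and the output is the
posterior expected signal, computed through the log-Mills ratio for
stability. The transform is strictly positive and monotone within an array.
The contract is tested by simulation from the model (corrected values
recover the true signal better than raw ones); for a constant signal plus
noise, any distribution-based estimator attributes the whole distribution
to background, so the test asserts the achievable property instead: the
noise offset is removed and the spread contracted. A zero-variance array is
a hard error (skip the step instead).

**Quantile normalization** replaces each array's order statistics by the
across-array mean of order statistics; ties receive the mean of the
quantile values they span. The operation is idempotent and rank-preserving.

**One-step Tukey biweight** (c = 5, ε = 10⁻⁴): u = (x − M)/(c·S + ε) with
M the median and S the unscaled MAD; weights (1 − u²)² for |u| < 1, else
exactly 0; the summary is the weighted mean. A single value returns itself;
when S = 0 the ε keeps the scale positive so values at the median carry
weight 1. Probeset summaries apply this per probeset per sample.

**ANOVA selection** fits, per probe, a fixed-effects linear model with the
eliminated (blocking) factors entered before the factor of interest and
tests the factor by the extra sum of squares (sequential/type-I), vectorized
across probes via a shared QR decomposition; results are cross-checked
against statsmodels `anova_lm` in the tests. p-values are uncorrected by
default (raw-p thresholds such as p < 0.01/0.001 are the intended usage); a
Benjamini–Hochberg option exists. A factor aliased with the blocking factors
is a hard error. The null calibration test uses 1000 independent probes,
3 tissues × 3 replicates; the power simulation plants tissue means spaced
4 residual-SD apart — chosen by closed-form noncentral-F power analysis
(power 0.9988 at α = 0.01) so that near-certain retention is a property of
the design, not of sampling luck.

**Concordance testing**: for each probeset with exactly one RE-reporting
probe and ≥ 2 other probes, the RE probe's values are compared with the
biweight summary of the remaining probes by Welch t tests per factor level
with ≥ 2 replicates, Holm–Bonferroni-corrected within the probeset;
"concordant" means every corrected p > 0.05.

**Nearest-gene regression**: one point per (RE probe, sample of the selected
tissue) pairing the probe value with the biweight summary of the nearer of
its 5'/3' flanking genes (tie → 5'); points whose gene is absent from the
summaries are omitted and counted; least-squares fits (slope, r, r², p) are
reported per repeat class and pooled.

**Hierarchical clustering** uses average linkage on Pearson correlation
distance (1 − r) — the linkage/metric are a documented choice, configurable
in principle; constant vectors get distance 1 to everything with a warning;
inputs are sorted by identifier first so leaf order is deterministic.

## Synthetic fixtures

The generator emulates the pipeline's real inputs at toy scale: 2
chromosomes × 70 kb of uniform random sequence with 46 planted repeats
(ERV1/ERVK/ERVL-MaLR/L1/B2 families) and 12 genes (10 protein-coding, 2
lincRNA). Inter-feature gaps of 1100–1500 bases keep intergenic repeats
strictly > 1 kb from coding genes; four "near-gene" repeats are attached
150–450 bases downstream of a gene; one element sequence is planted at three
loci to create `numhits = 3` probes. The platform (103 probes) engineers
probeset compositions straddling every filter boundary: 9/11 and 4/4 RE
probesets (retained), 8/11 and exactly-3/4 (fraction fails), multi-copy,
near-gene, wrong-orientation, boundary-overhang, genic, unmappable and
2-mismatch probes, plus 4-probe probesets per coding gene for the
nearest-gene analysis. Each probe carries a truth label (category,
expected-RE, expected-retained), so end-to-end precision and recall are
exactly 1.0 when the pipeline is correct, in both chemistry modes.

The expression matrix (12 samples = 3 tissues × 2 experiments × 2
replicates) plants probeset baselines N(8, 1), a +2 log2 heart effect on the
regulated probesets (one of them inverted on its lone RE probe, for the
discordance test), experiment offsets N(0, 0.3), per-gene latent components
shared with the RE probes nearest those genes at fraction 0.3, one +4
outlier probe, and N(0, 0.25) measurement noise. The standalone
shared-variance generator standardizes the gene component and
orthogonalizes the noise against it per pair, so the planted fraction is
the empirical shared variance, not merely its expectation; recovery within
±0.05 at 500 points then tests the estimator rather than Monte-Carlo drift.

What the fixtures do **not** emulate: sequence divergence within repeat
families, cross-hybridization physics, spatial array artifacts, non-Gaussian
intensity noise, and realistic repeat density. Passing tests therefore
demonstrate correctness of the decision rules and statistics, not
performance on real genomes, where fragmented RepeatMasker records,
assembly gaps and diverged elements add ambiguity the toy genomes lack.

## Numerical and design choices

- All internal coordinates are 0-based half-open; conversion happens only at
  the I/O boundary (.out and GTF are 1-based inclusive, BED half-open; the
  annotation CSV is written 1-based inclusive).
- Mapper score = identity count (no affine penalties); deterministic
  tie-break; identical (chromosome, start, strand) placements count once.
- The probeset RE fraction uses the manifest denominator; empty context
  fields are accepted quoted or unquoted on read.
- Single seed → three spawned substreams (genome, platform, expression), so
  extending one plan leaves the others' outputs unchanged.
- Problem sizes in the test suite (20 × 5 kb oracle genomes, 1000-probe
  calibrations, 500-point regressions) were chosen as the smallest sizes at
  which the binomial/regression tolerances are meaningful.

## Known limitations

- Ungapped matching can miss a placement that a gapped aligner would report
  (a single indel shifts every downstream base); at the 95% threshold on
  25-mers this requires contrived sequences but is possible.
- Fragmented repeat records are not merged before the containment test; a
  probe spanning two abutting fragments of one element is not classified.
- The background-correction parameter estimator is a mode-based heuristic;
  arrays whose intensity distribution is far from the convolution model get
  a monotone but poorly calibrated correction.
- Whether "within 1 kb" is measured to gene bounds or transcript bounds is
  ambiguous in general; gene bounds are used throughout.
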