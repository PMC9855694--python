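# Methods

## Study design and containers

The pipeline assumes a three-segment developmental series (S1, S2, S3 along
the body axis) with three biological replicates per segment, profiled for
three RNA classes (mRNA, lncRNA, miRNA). `SegmentDesign` carries the
sample-to-segment assignment; `ExpressionMatrix` is a genes × samples table
of nonnegative counts tagged with its RNA class. All thresholds below are
configuration fields of `PipelineConfig`; the defaults are the study's
stated cutoffs.

## Synthetic data generator

`generate_counts` draws counts from a negative binomial parameterized by
mean and dispersion, Var(X) = μ + αμ². The NB is the standard count model
for bulk RNA-seq replicates; no distribution is prescribed by the study
design itself, so this is the generator's own modelling choice. Defaults:
baseline mean 100 (a moderately expressed gene), dispersion α = 0.05
(tight biological replicates), fold step f = 4 per segment for planted
trends.

Planted signal:

- growth_up genes have segment means (m, mf, mf²), growth_down the
  reverse; formation_up (m, mf, m) and formation_down (m, m/f, m).
- each planted ceRNA triplet makes its mRNA and lncRNA growth_up and its
  miRNA growth_down, or all flipped, with the orientation drawn per
  triplet — miRNA repression implies opposite trends.
- per-sample library-size factors are drawn log-uniform in [0.7, 1.4] and
  multiply every gene's mean in that sample, so size-factor estimation is
  exercised nontrivially.

Gene-level draws use sub-seeds derived deterministically from the dataset
seed and the gene's index, so output is byte-identical under a fixed seed
and independent of iteration order.

`generate_sequences` emits 22-nt miRNAs (RNA alphabet) and 200–1000-nt
transcripts (DNA alphabet). Each planted triplet's mRNA and lncRNA receive
one exact full-length reverse complement of the miRNA at a random position.
A full-length site is planted (rather than a bare seed match) because the
default aligner threshold of 140 is deliberately close to the perfect-site
score of 145; a seed-only site (score 70) is not a detection target. The
planted site necessarily contains the exact seed-region complement.
Non-target transcripts are uniform random sequences; incidental seed-level
matches can occur but full-length complements are vanishingly improbable.
`dinucleotide_shuffle` (random Eulerian walk on the dinucleotide
multigraph) provides matched negative controls.

What the generator does **not** emulate: pooling of individuals within a
replicate, GC/length biases, transcript-structure effects (sites are
uniform over the transcript), correlated co-expression modules beyond the
planted triplets, and any upstream read-level process. Passing tests
therefore demonstrate correctness of the pipeline's logic under its own
statistical assumptions, not performance on real sequencing data.

## Normalization and differential expression

Size factors are median-of-ratios: genes with all-positive counts define a
per-gene geometric-mean reference; a sample's factor is the median of its
ratios to that reference. If no gene is positive everywhere the caller is
told to prefilter rather than silently proceeding.

`de_test` is a self-contained NB Wald test (agreement with any external DE
package is not a goal; the decision threshold, raw p < 0.05, is). Per gene:

- normalized group means μ̂_A, μ̂_B over the contrast samples;
- dispersion α̂ = max(0, (s² − μ̄)/μ̄²) by the classical method of moments
  (biased second moment, i.e. the plain second central moment) on the
  normalized counts of both groups pooled, floored at 10⁻⁸. Pooling across
  groups uses 6 observations instead of 3 and inflates the dispersion
  exactly when the group means differ, which acts as a built-in penalty;
  the biased moment was chosen because the ddof=1 variant makes the test
  measurably conservative at the 0.05 tail with n = 3 + 3 while the
  classical estimator keeps the null rejection rate at its nominal level.
- log₂FC = log₂((μ̂_B + c₀)/(μ̂_A + c₀)) with pseudocount c₀ = 0.5;
  delta-method SE from Var(μ̂) = (μ̂ + α̂μ̂²)/n; two-sided p from the Wald
  statistic against the standard normal.

With three replicates per group the null distribution of p is only
approximately uniform in its body (the dispersion estimate is noisy and
the reference is normal rather than t-like); the rejection *tail* at 0.05
is calibrated, which is what the p < 0.05 decision uses. No
multiple-testing adjustment gates the DE call, matching the raw threshold;
a BH-adjusted column is always emitted. All-zero genes are reported with
p = 1 rather than dropped so enrichment universes stay stable.

`relative_quantification` implements 2^−ΔΔCT for qPCR validation tables.

## Pattern classification

Per-segment means of size-factor-normalized counts are computed for the
union of genes DE in at least one of the three contrasts. A profile
(m₁, m₂, m₃) is labeled by thresholding consecutive differences at
ε = rel_tol · max(m₁, m₂, m₃, abs_floor) with rel_tol = 0.05 and
abs_floor = 1 normalized count: both differences above +ε → growth_up,
both below −ε → growth_down, an S2 peak → formation_up, an S2 dip →
formation_down, otherwise other. The tolerance is relative so labels are
scale-free; the absolute floor deliberately breaks scale invariance below
one normalized count so that noise-level profiles near zero are not
classified on meaningless differences. Direct rule-based classification is
used instead of profile-clustering software: with three time points the
twelve interpretable profile groups reduce exactly to these four rules
plus "other".

## Target prediction

`align_score` aligns the miRNA (5′→3′) against the reverse of a transcript
window with Gotoh affine-gap local alignment, scoring complementarity:
Watson–Crick +5, G:U wobble +2, mismatch −3, gap open −9, gap extend −4,
substitution scores at miRNA positions 2–8 doubled. These constants echo
the conventions of classical miRNA target scanners and are exposed in
`AlignParams`; the default site threshold is 140 (perfect 22-mer site:
145). `predict_targets` reports non-overlapping sites greedily by
descending score (ties to the leftmost start) and by default requires
contiguous, gap-free pairing (wobble allowed) at seed positions 2–7.
Thermodynamic (duplex free-energy) filtering is intentionally out of
scope; the expression-correlation gate downstream provides the
specificity that an energy filter would add.

Implementation: scanning anchors on exact occurrences of the ≤ 2⁶
wobble-expanded seed-complement hexamers, scores generously margined
windows around each anchor with a batched numpy DP kernel, and runs the
full traceback DP only on transcripts that can reach the threshold. The
batch kernel and the plain DP implement the identical recurrence and are
cross-checked in the tests; with `require_seed=False` every transcript is
scanned with the plain DP. Coordinates are 0-based half-open on the sense
strand; only the sense strand is scanned.

## ceRNA network

Spearman correlation is computed as the Pearson correlation of
average-rank vectors; two-sided p from t = ρ√((n−2)/(1−ρ²)) with n−2
degrees of freedom (n = 9 here; the t approximation is the common default
at this size). An exact permutation p (full enumeration, n ≤ 9) is
available via `spearman(..., method="exact")`. Constant vectors are
undefined and excluded. Correlations run on size-factor-normalized counts:
Spearman is invariant to monotone transforms within a gene's vector but
per-sample scaling mixes samples, so normalization matters and is fixed
here.

Candidate miRNA–mRNA and miRNA–lncRNA pairs are the predicted target
pairs; mRNA–lncRNA candidates are pairs sharing at least one common
targeting miRNA. Filters: ρ ≤ −0.7, p < 0.05 for miRNA edges; ρ ≥ +0.7,
p < 0.05 for mRNA–lncRNA. No multiple-testing correction is applied to
edge p-values (the thresholds are used as stated). The network is built
from growth-associated gene sets by default (`network_gene_sets:
formation` switches). Triplets require all three edges; components are
labeled from their mRNAs' regulation directions; hubs are all
maximal-degree nodes of a component ("hub" has no stronger standard
definition at this scale).

For enrichment, a miRNA's correlation-defined target set contains mRNAs
with at least one predicted site and |ρ| ≥ 0.7, p < 0.05 — the sign is
configurable (`mirna_target_corr_mode`: positive / negative / absolute,
default absolute) because a positive-correlation definition coexists in
the literature with the repression-motivated negative one; an lncRNA's set
contains all mRNAs with ρ ≥ 0.7, p < 0.05, with no targeting requirement.
A supplied protein-interaction table is filtered at combined score
strictly greater than 0.4 and restricted to network genes.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k | N, K, n); enrichment is flagged at raw p < 0.05 with BH-adjusted
values reported. The default universe is all genes of the RNA class under
test present in the experiment (not a whole-genome universe), overridable
by the caller. Annotation is a generic GMT input; database retrieval and
term content are outside the package.

## Numerical and design notes

- Determinism: every stochastic component takes an explicit seed; pipeline
  reruns are byte-identical. No stage depends on filesystem order or wall
  clock; outputs are canonically sorted.
- Degenerate inputs: degenerate contrasts, missing segments, duplicate
  ids, negative counts, out-of-range scores and empty queries all raise
  `ValueError` naming the offending field; pipeline stages wrap errors
  with the stage name.
- Problem sizes: the packaged demo and the acceptance script simulate 150
  mRNAs, 50 lncRNAs, 25 miRNAs with 20 planted triplets, and the
  statistical checks use 500–2000 genes per condition — sizes at which the
  Monte-Carlo properties of interest (calibration, power, recovery rates)
  are stable while the full pipeline runs in seconds.
- Known limitations: the DE test has no shrinkage, covariates or batch
  terms; pattern classification ignores within-segment variance; the
  aligner has no free-energy term; Spearman at n = 9 has limited
  resolution (the t approximation is coarse in the extreme tail); and all
  validation rests on synthetic data whose generative assumptions are
  stated above.
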