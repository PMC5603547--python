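# Methods

## Scope and data model

The package implements the downstream, count-level half of a lncRNA/mRNA
bulk RNA-seq study: everything from a gene × sample integer count matrix to
differential expression, co-expression networks, pathway enrichment and the
lncRNA–pathway projection. Upstream steps (read trimming, de novo assembly,
read mapping, quantification, homology annotation) are out of scope; their
products enter as inputs — a counts TSV, a sample sheet, a transcript table
and GMT gene sets. The in-memory containers are pandas DataFrames (counts,
expression, result tables) and networkx graphs (both networks).

## QC summaries

`summarize_mapping` aggregates per-sample raw/clean/mapped read counts.
Percentages are rounded half-up to one decimal, the convention of published
summary tables; the mean mapping ratio is the unweighted mean of the
rounded per-sample ratios (not the pooled Σmapped/Σclean, which weights
large libraries and differs by ~0.3 points on the bundled table).
`assembly_stats` computes N50 as the largest length L such that contigs of
at least L cover half the total assembly length, via the descending
cumulative sum; the median uses the midpoint convention for even n. No
NG50 (reference-length) variant is offered.

## Preprocessing

*CPM filter.* A gene is kept when CPM ≥ `min_cpm` (default 1) in at least
`min_samples` samples. `min_samples` defaults to 4, the per-cell replicate
number of the reference design; library sizes are always the pre-filtering
column sums.

*Normalization.* Median-of-ratios size factors: the reference set is the
genes with positive counts in every sample; s_j is the median over that set
of count_gj divided by the gene's across-sample geometric mean. Factors are
defined up to a common scale (identical columns give s = 1; a single-sample
matrix gives s = 1). The normalized matrix feeds only the correlation
stage; the exact test consumes raw counts and equalizes libraries itself.

*Replicate screening.* Distances are 1 − Pearson r between log₂(CPM+1)
profiles (pseudocount configurable), embedded by classical (Torgerson) MDS
in two dimensions. A sample is flagged when its Euclidean distance to its
own group's centroid exceeds median + k·MAD (k = 3) of all within-group
centroid distances, at most `n_flag_max` (default 2) samples, largest
first. The flagging rule is this package's own choice — the outcome it
emulates (a small number of aberrant replicates removed before DE) is
standard, but no published criterion was available to adopt. Groups of
size 1 are exempt and reported.

## Negative-binomial exact test

Counts are scaled to the geometric-mean library size and rounded
("pseudo-counts" on equal libraries), then summed within each group. Under
H0 the group sums are NB with means proportional to group sizes and
dispersion φ/n_group (a sum of n iid NB(μ, φ) variables is NB(nμ, φ/n)).
Conditioning on t = y_A + y_B, the two-sided p-value sums the probabilities
of every partition (a, t−a) whose null probability is at most that of the
observed partition (relative tie tolerance 1e-8), normalized over all
partitions. t = 0 is defined as p = 1. At φ = 0 the conditional law is
exactly Binomial(t, n_A/(n_A+n_B)), which the tests exploit as an oracle.
The library-size equalization by scaling + rounding is a documented
approximation to edgeR's quantile adjustment; the guarantees asserted are
calibration (type-I error 3–7% at nominal 5%) and power, not value-for-
value equality with edgeR.

The common dispersion is a trimmed (20% each tail) mean over genes of the
per-gene method-of-moments value max(0, (v − m)/m²), with v the pooled
within-group variance and m the mean of the group means on equalized
counts, over genes with m > 0. Pooling within groups keeps planted or real
DE from inflating the estimate. The estimator runs ~0.15 low at φ = 0.2
with 4+4 replicates (max(0,·) truncation and trimming of a right-skewed
distribution); it stays within the ±0.05 band the recovery tests require
and errs conservative for the exact test. Tagwise/trended shrinkage is
deliberately out of scope.

Fold changes are log₂((y_B/n_B + c)/(y_A/n_A + c)) with prior count
c = 0.125 (configurable); the reference group is the lexicographically
first label (CTRL before E2) unless overridden. Calls: `up` iff q < α and
log2FC > log₂(fc_min); `down` symmetric; α = 0.05, fc_min = 2. Each time
point is an independent two-group contrast. BH adjustment is the step-up
q_(i) = min_{j≥i} p_(j)·m/j, implemented directly and cross-checked against
statsmodels in the tests.

## lncRNA classification

Six-frame ORF scan (ATG to first in-frame stop, stop excluded, N matches
nothing); lncRNA iff length ≥ 200 nt and longest ORF < 100 aa and (when
enabled) no protein-database hit; mRNA iff ORF ≥ 100 aa or a hit; otherwise
ambiguous. The 200 nt floor is the standard lncRNA definition; 100 aa is a
widespread coding-potential heuristic. Machine-learned coding-potential
scores are out of scope; an externally computed hit table can be supplied
as a boolean column.

## Co-expression network

Pearson r between every DE lncRNA and DE mRNA over the samples of the
analyzed time point (after outlier removal; pooling both time points is an
option). Significance is the two-sided t-test on n−2 df — the conventional
choice where no test is otherwise specified — with |r| = 1 mapped to p = 0;
BH is applied over all lnc × mRNA pairs as one family. Edges require
q < 0.05 and r ≥ 0.99; the default is positive-only ("co-expression"), with
an absolute-value mode behind a flag. Pairs with a zero-variance profile
are untestable and counted, not tested. Only nodes incident to an edge are
reported as network members. Hubs: nodes ranked by degree, ties broken
lexicographically; top_k (k = 20) by default, top_fraction (ceil(f·n))
as the principled alternative.

## Enrichment and projection

Upper-tail hypergeometric p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n), inclusive
of the observed overlap, BH across tested sets. The universe defaults to
the expressed (CPM-filtered) genes of the matching biotype, not the whole
annotation — enrichment should be judged against what could have been
detected. Rich factor = k·N/(K·n), the observed over expected overlap. The
projection links a lncRNA to a pathway when ≥ min_support (default 1) of
its co-expressed mRNA neighbors are pathway members, restricted by default
to significantly enriched pathways; each edge stores its supporting mRNAs,
and a per-pathway regulatory-lncRNA count table is emitted.

## Synthetic data generator

Counts for gene g, sample j are NB with mean
s_j · μ_g · 2^(x_j β_g) · exp(λ f_{m,j}): log-normal baselines μ_g
(meanlog 3.5, sdlog 1 → median ≈ 33 counts, a realistic bulk depth at desk
scale), library factors s_j ~ U(0.7, 1.3) so normalization is non-trivial,
NB dispersion φ = 0.2 (typical bulk RNA-seq; φ = 0 degenerates to
Poisson). The design is two groups × two times × 4 replicates. 10% of
genes per biotype carry a treatment effect with |log2FC| ~ U(1, 3), active
only at 24 h by default — emulating a transient response in which the
later time point is essentially null. Co-expression modules are disjoint
sets of 10 lncRNAs + 15 mRNAs sharing a per-sample standard-normal latent
factor scaled by λ = 3 on the log scale; a multiplicative shared factor
produces tunable pairwise Pearson correlation without specifying a full
covariance matrix, and at λ = 3 the factor dominates NB noise enough for
r ≥ 0.99 edges to appear at n = 8. Module members are drawn from the
planted DE genes when available so modules survive DE-based selection.
Pathways are 20 sets of 30 mRNAs; the first 5 draw half their members from
planted DE mRNAs and are recorded as the enriched truth. One seed drives
everything through per-component substreams; identical configs are
bit-identical.

What the generator does **not** emulate: gene-length and GC biases,
tagwise dispersion variation, batch effects, correlated library-size and
composition effects, zero inflation, and any sequence content. Passing
recovery tests therefore demonstrates the pipeline's statistical
correctness under its own model assumptions, not performance on real
libraries.

## Numerical choices

Partition probabilities are computed in log space and normalized after
subtracting the maximum; ties in the minimum-likelihood comparison use a
1e-8 relative tolerance. Rounding of printed percentages is half-up via
decimal arithmetic (binary-float round-half-even would differ on exact
.x5 ratios). Correlations clip to [−1, 1] against float drift. Degenerate
inputs are defined, not errors, where a convention exists (t = 0 → p = 1;
k = 0 overlap → p = 1; single-sample size factor = 1); everything else
(empty matrices, zero library sizes, impossible module demands) raises
ValueError early.

## Problem sizes

Defaults (2,500 genes × 16 samples) keep a full pipeline run under ~2 s
and the entire validation suite — including the 2,000-gene null
calibration, the 50,000-pair null network and the recovery experiments —
in the tens of seconds, while leaving every statistical property testable
(overdispersion needs ≥ 1,000 genes; the type-I band needs ~2,000 tests).

## Known limitations

- The exact test approximates edgeR's library equalization; do not expect
  identical p-values to edgeR on the same matrix (ranks agree closely).
- The common-dispersion estimator is mildly biased low at small n; with
  strong tagwise dispersion variation the exact test can be anti-
  conservative for high-dispersion genes.
- The MDS flagging rule is a reasonable default, not an inference
  procedure; inspect `outliers.json` before trusting exclusions.
- r ≥ 0.99 with n ≤ 8 samples rides the heavy right tail of the sample
  correlation distribution; edge recall of true modules is draw-dependent
  (precision is the stable quantity, and is what the tests guarantee).
- Hypergeometric enrichment treats genes as exchangeable: no length or
  expression-level bias correction, no GO-graph-aware conditional testing.
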