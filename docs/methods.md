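# Methods

`locuscn` measures integer copy number (CN) at complex, highly copy-variable
loci — multicopy gene families embedded in segmental duplications such as
*CCL3L1* or the beta-defensin cluster — from high-throughput sequencing read
depth. This note documents the model, the parameters that matter, the
synthetic-cohort generator used for testing, and the numerical choices made
where the design was genuinely open.

## The read-depth model

At a locus with per-diploid-genome copy number `c`, the expected number of
reads starting in a window of width `w` is proportional to `c/2` times the
sample's mean coverage, times a window-specific mappability factor. Inside
segmental duplications most reads map with MAPQ 0 (several equally good
alignments) and a substantial fraction is lost to or reassigned among
paralogs, so raw per-sample depth *underestimates* CN — cohort-wide, the
median observed depth in such a region sits well below the diploid
expectation. The pipeline therefore never interprets one sample's depth in
isolation; every quantity is a ratio against the cohort.

### Stage 1 — windows, counts, ratios, standardization

The 1–2 Mb analysis region around the target gene is tiled with fixed
windows (`w` = 500 bp for a ~2 kb gene, 1000 bp for larger targets; windows
larger than the gene are refused because breakpoints near or inside the gene
would become undetectable). Reads are counted by leftmost aligned position;
unmapped, secondary and duplicate reads are excluded; `min_mapq` defaults to
0 because filtering MAPQ-0 reads at these loci deletes the signal.

Counts are normalized in two steps:

1. `p[s,j] = c[s,j] / N[s]` (within-sample proportions, removing coverage),
   then `r[s,j] = p[s,j] / median_s p[s,j]` (observed read-count ratio,
   removing shared window effects — including mappability depression, which
   multiplies every sample equally and cancels). Windows with a zero
   cross-sample reference are masked and excluded downstream.
2. `x[s,j] = (r[s,j] − median_j r[s,·]) / (1.4826 · MAD_j r[s,·])`. The
   robust location/scale are taken over the full region; because most of the
   region is CN-invariant they approximate the sample's diploid baseline, so
   `x` behaves as a per-window z-score. A zero MAD falls back to the sample
   standard deviation; a perfectly flat profile standardizes to zero.

### Stage 2 — segmentation

Each sample's standardized profile is segmented by circular binary
segmentation: the arc maximizing the arc-vs-complement t statistic is split
out if its within-segment permutation p-value is below `alpha`, recursively.
Defaults `alpha = 0.01`, `n_perm = 1000`, `min_width = 2` follow common CBS
practice. The permutation stream derives from an explicit seed, so
segmentation is reproducible bit for bit; permutation testing stops early
once the p-value provably cannot fall below `alpha` (a pure cost
optimization — decisions are unchanged). Zero-variance splits with distinct
means score +infinity; ties break toward the smallest arc indices,
deterministically. Masked windows are removed before segmentation and
absorbed into the enclosing segment's span afterwards.

### Stage 3 — region discovery

The union of all samples' breakpoints partitions the region into
sub-regions; within one sample each sub-region is covered by exactly one
segment, so its per-sample value is that segment's mean with no re-averaging
error. Cross-sample SDs (and a percentile ladder at 1/5/25/50/75/95/99 —
a symmetric set chosen for visual profiling) localize CN-variable blocks:
maximal runs of sub-regions with SD ≥ 0.5 (default threshold), with low-SD
gaps shorter than `max_bridge_bp` (default five window widths) bridged.
Bridging makes reproducible the otherwise-visual step of merging adjacent
high-SD blocks across a shallow dip. The discovered region is advisory:
scoring uses the user-supplied gene interval unless explicitly switched.

### Stage 4 — gene segmentation scores

A sample's segmentation score (SS) over the gene is extracted with merge and
boundary rules. Segments overlapping the gene are clipped to it (weights are
clipped bp lengths) and classified by the merge threshold τ (default 0.35):
gain (mean ≥ τ), loss (mean ≤ −τ), neutral otherwise.

1. One covering segment → its mean.
2. No segment whose sign opposes the dominant class → length-weighted
   average over all of them (same-sign near-zero segments merge freely).
3. Exactly one opposite-sign segment, at a gene boundary, with clipped
   length below half a window: its z-score (mean standardized ratio over its
   windows) arbitrates — matching sign: average over the *other* segments;
   otherwise zero.
4. Anything else → score 0, the population average at the locus.

Discordance is deliberately sign-based rather than τ-class-based: a small
negative-mean boundary segment against a gain majority is treated as
discordant (and rescued or zeroed via its z-score), not averaged in. τ
serves to identify the dominant class. With no unique majority (equal gain
and loss counts among non-neutral segments, or several discordant segments)
the score is zero — only the single-boundary case is arbitrated.

In the pooled multi-population run a stricter rule applies: any split of the
gene yields score zero, structurally — even a cosmetic split into segments
with equal means — because a split relative to the pooled average signals
that the sample straddles distinct CN regions.

### Stage 5 — cross-population adjustment

Scores are computed once within each major population (SSP) and once from
the pooled run (SSP_P). Within each population, ordinary least squares of
SSP_P on SSP is fitted and the fitted values are the final scores: they
inherit the pooled scale (comparable across populations) while retaining the
within-population segmentation's precision. Samples whose pooled score was
zeroed still enter the fit (no exclusion rule is imposed; with a single
population the stage is skipped and final = SSP; a zero-variance SSP falls
back to unadjusted SSP_P with a logged notice).

### Stage 6 — mixture clustering and CN assignment

Final scores fall into roughly equally spaced clusters, one per integer CN.
A reference population with clear clusters (user-named, or `auto` via the
best silhouette of per-population EM fits) is fitted by EM (multi-start
k-means++ initialization, best likelihood kept; likelihood verified
non-decreasing every iteration; a component collapsing onto fewer than two
points triggers a fresh start, while a well-populated point-mass component
has its scale clamped at `1e-6` of the data range). BIC (`−2·loglik +
(3K−1)·ln n`) selects the reference's component count.

Because final scores are affine in CN, the reference's component means sit
on an integer-spaced grid. The grid is recovered by least squares: each
component mean receives an integer grid index (cumulative adjacent-gap
counts, each gap rounded to its nearest whole number of spacings — a split
cluster contributes a zero step, a skipped group a double step), components
sharing an index are collapsed to their mixing-weight-weighted mean (exact
for a genuine split), and the slope and intercept of mean on index give the
inter-group spacing `d` and the grid position of the lowest reference
group. This is markedly more robust than averaging adjacent distances,
which a single split cluster biases downward twice over (it inserts a small
spurious gap *and* shrinks the neighbouring genuine gaps). The procedure
assumes the reference population's CN classes are contiguous (no empty
group between occupied ones), which is what makes a population a suitable
reference in the first place.

The cohort's group count K can be chosen three ways: explicitly (prior
knowledge of the locus); by the distance rule `K = round(range / d)` on the
outlier-free score range (the default, since it follows the method's own
scale logic); or by BIC. BIC is accurate when clusters are approximately
Gaussian but tends to overfit near-degenerate clusters, which is why it is
not the default.

Scores above a user-set `outlier_bound` are excluded from K selection and
fitting and are pinned to the largest CN group with probability 1.

The full cohort is then fitted by a Gibbs sampler for a univariate Gaussian
mixture with ordered means:

- `μ_k ~ Normal(anchor + (k−1)·d, s₀²)` truncated to the order constraint,
  with `d` the (cleaned) reference distance or a user-supplied prior
  distance, and `s₀²` the mean reference within-group variance (weakly
  informative; configurable).
- `σ_k² ~ InverseGamma(3, 2·σ̄²_ref)` — shape 3 keeps the prior variance
  finite while matching its mean to the reference within-group variance.
- `π ~ Dirichlet(1, …, 1)`.

The anchor is the fitted grid position of the reference's lowest group. If
the pooled cohort extends below the reference (the reference population may
simply lack the lowest CN class), the anchor is shifted down by whole
multiples of `d`. The decision is deliberately simple and conservative:
scores more than half a spacing below the anchor are candidate members of a
missing group; they count as one when there are at least max(3, 1% of n)
of them *and* their median sits at least 0.7 spacings below the anchor. A
genuine missing group always clears that bar (its center lies a whole
spacing down, give or take grid-fit error), while the sub-cut tail of the
anchor group itself — even of the zero-copy group, which is intrinsically
the widest since its gene ratio is exactly zero and its score is set
purely by each sample's normalization — does not. The asymmetry of the
threshold is intentional: a missed shift miscalls only the few
bottom-cluster samples, whereas a spurious shift moves every call in the
cohort by one. A bottom "cluster" of one or two samples is read as a tail
or outlier, not a group; for cohorts where that reading is wrong, supply
an explicit K with a matching `cn_of_first_group`, or an outlier bound.

The schedule is 100 adaptation iterations (discarded), 1000 burn-in, 20000
sampling iterations, with parameter estimates and per-sample assignment
frequencies taken from the last 20% (4000 draws). Ordering holds in every
retained draw by construction. CN calls are the argmax assignment (ties
toward the lower group), and `CN = group + cn_of_first_group`, where the
base CN is the caller's prior knowledge of the locus (0 for a
deletion-capable locus, 2 when the observed ratio range rules out
deletions). The largest group is an open class ("≥CN") since outliers are
folded into it.

Convergence of each mean chain is assessed with the Heidelberger–Welch
stationarity and half-width tests: the standardized cumulative-sum
(Brownian-bridge) Cramér–von Mises statistic against its asymptotic null
distribution, discarding leading 10% chunks until it passes or half the
chain is gone, then requiring `z_{1−α/2}·SE/|mean| ≤ eps` (defaults α =
0.05, eps = 0.1). The spectral density at frequency zero comes from an AR
fit (Yule–Walker, AIC order selection); a chain that is an exact linear
function of iteration has a degenerate spectrum, reported as 0, which
forces rejection. A constant chain passes both parts by convention; a
non-constant chain with exactly zero mean fails the half-width test, since
relative precision of a zero mean is unattainable.

## The synthetic cohort generator

Counts are simulated directly at the window level — the pipeline consumes
only window counts, so read-level simulation would add cost without test
power. Per sample, `λ = coverage · w / read_length` reads per window at
CN 2; inside the CN-variable block the expectation scales with CN/2 and the
whole block (not just the gene) is multiplied by a mappability factor,
mirroring the observation that the entire gene-containing region is
depressed. Counts are Poisson, or gamma-mixed Poisson (negative binomial,
`var = μ(1 + od·μ)`) when overdispersion is requested.

Defaults are the study conditions the package is tested under: three
populations of 100 samples whose CN 0–6 distributions follow published
1000 Genomes *CCL3L1* copy-number frequencies for the European, South Asian
and admixed American groupings; coverage drawn uniformly from 2.8–40.6×
(the range of low-coverage cohort sequencing; the end-to-end experiments
fix 20×); block mappability 0.8, with 0.7 as the stress regime; a 100 kb
region with 1 kb windows, a 20-window variable block and a 10-window gene.
These sizes keep a full three-population run (600 sample-profiles of CBS
plus a 21,100-iteration Gibbs fit) around a minute on one core while
preserving the geometry that matters: the block is a small fraction of the
region (so robust per-sample baselines hold) and the gene is several
windows long (so boundary rules and length-weighted averaging are
exercised).

What the simulator does *not* model: GC-content bias, paired-end insert
structure, reference errors, CN breakpoints that move between samples, and
sequence-level read mapping. Passing tests therefore demonstrate the
statistical machinery — normalization, segmentation, scoring, adjustment,
clustering — under the read-depth model's own assumptions, not robustness
to every artifact of real alignments.

## Numerical choices and degenerate inputs

- Segmentation ties break to the smallest `(i, j)`; constant vectors return
  one segment; vectors shorter than `2·min_width` return a flagged single
  segment rather than raising.
- EM convergence: absolute log-likelihood change below 1e-8 or 500
  iterations; k-means++ seeding; 8 starts.
- Gibbs truncated-normal draws use inverse-CDF sampling with a numerical
  floor: when the admissible interval's probability mass underflows, the
  draw pins to the nearest admissible value.
- All randomness flows from one root seed through named substreams
  (segmentation permutations per sample, EM, Gibbs), so a rerun with the
  same seed is byte-identical, including serialized outputs (fixed float
  format `%.8g`).
- The run manifest records package and library versions, the full
  configuration, selected K, reference population, outlier count, and
  per-chain convergence flags.

## Known limitations

- CN calls are only as good as the cluster structure of final scores; at
  high CN the relative Poisson noise grows and adjacent clusters blur, so
  residual errors concentrate at adjacent high CN values (the end-to-end
  experiments show exactly this pattern).
- The distance rule for K can undercount by one when clusters are extremely
  tight (the empirical range is then ≈ (K−1)·d̄ rather than ≈ K·d̄); when the
  true group count is known, passing K explicitly is preferred.
- `cn_of_first_group` is prior knowledge, not inferred: if the cohort's
  lowest cluster is not the assumed base CN, all calls shift together.
- The regression adjustment assumes an approximately affine relation
  between single-population and pooled scores within each population.
- A reference population must populate each of its CN classes with several
  samples: a class of one or two samples cannot be resolved as its own EM
  component (the fit restarts when a component owns fewer than two points),
  model selection then merges groups, and the inferred inter-group spacing
  degrades. Small cohorts at loci with rare extreme CN classes should
  supply K and the prior distance explicitly.
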