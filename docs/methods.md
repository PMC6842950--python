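# Methods

## Scope and model

`snownet` analyses two-period (early spring ES / late spring LS) snow
microbiome campaigns in which three kinds of measurements coexist:
ion-chromatography chemistry (organic acids, major ions, pH, with
per-analyte detection limits), 16S OTU count time series, and
read-level functional annotations plus resistance-database hits from
metagenomes (MG) and metatranscriptomes (MT).  The scientific question
is whether rising organic-acid concentrations coincide with a shift
from cooperation-dominated to competition-dominated community
structure, read out through (a) co-variance network topology and (b)
cooperation/competition marker genes.

## Chemistry

Left-censored values are imputed as LOD/2, the standard single-value
rule for trace chemistry; censoring is stored as a mask plus a LOD
table, never as a sentinel value, so imputation is an explicit,
testable operation.  Concentrations are natural-log transformed (the
choice of base only rescales axes; pH is excluded because it is
already logarithmic).  PCA standardizes columns to unit variance by
default (`scale=True`): the analytes span several orders of magnitude
in ppb and an unscaled covariance PCA would be a one-ion plot.  The
ES/LS difference is tested with a distance-based pseudo-F permutation
test (one-way PERMANOVA): Euclidean distance on the standardized log
matrix for chemistry, Bray-Curtis on CSS-normalized counts for the
community table.  All permutation p-values use the add-one rule
`(1 + #exceedances) / (1 + n_perm)`, so the attainable floor is
`1/(n_perm+1)` and p = 0 is impossible.

Chemistry-community coupling uses the RV coefficient of co-inertia
analysis, `trace(Cxy Cyx) / sqrt(trace(Cxx^2) trace(Cyy^2))` on
column-centred tables, with significance from random row permutations
of one table and co-inertia axes from the SVD of the cross-covariance.
RV is invariant to positive rescaling of either table and lies in
[0, 1] by Cauchy-Schwarz.

## Community

CSS normalization divides each sample by the sum of its nonzero
counts not exceeding the sample's q-th nonzero-count quantile
(default q = 0.5, lower-quantile convention, scale constant 1000).
The full adaptive-percentile search of the original CSS method is out
of scope: downstream LSA is rank-based, so the normalization variant
is second-order, and the chosen convention is pinned by a regression
test (counts (1,2,3,4) at q = 0.5 give scaling factor 3).

The core community of a period is the set of OTUs with a nonzero
count in at least `min_samples` of that period's samples.  Presence is
raw count > 0 — membership is deliberately independent of
normalization.  The boundary is inclusive (exactly 50% prevalence is
retained); `min_samples` defaults to half the period's sample count
rounded up but is always an explicit, recorded parameter, since a
fixed absolute cutoff and a fixed percentage disagree whenever the two
periods have different sample counts.

## Local similarity analysis

Each OTU series is rank-transformed to normal scores
(`Phi^-1(rank/(n+1))`, average ranks for ties — zero-heavy OTU vectors
tie often, so the convention matters and is documented).  The local
similarity of two z-vectors is the best nonnegative-reset running sum
of elementwise products over alignments whose offset never exceeds
the delay bound D, divided by n; the negative score uses negated
products, and the larger of the two sets the sign.  With D = 0 this is
a one-dimensional max-reset recursion; the general-D dynamic program
exists for oracle testing, while the headline pipeline uses D = 0.
Sample spacing is ignored: collection order is the time axis.

Significance is by permutation of one series (n_perm default 1000),
two-sided on the unsigned score, rather than the asymptotic
approximation used by fast LSA implementations — at n = 16-36 the
permutation null is exact in distribution and the edge filter is the
same p < 0.05 either way.  No multiple-testing correction is applied
to edges by default, matching the raw-p filtering convention of
co-occurrence network studies; a BH flag exists for sensitivity
analyses.  The per-pair permutation stream is keyed on the unordered
OTU-name pair (CRC32 of the sorted names mixed with the master seed),
which makes the all-pairs result invariant to column order and to
argument swapping.

## Networks

Nodes are OTUs participating in at least one significant pair; edges
carry sign and |score| as weight.  Sign is ignored for topology
metrics (negative edges count as edges), with a positive-only flag
for sensitivity.  Metrics: average degree 2E/N; density E/C(N,2);
global transitivity (3 x triangles / connected triples); modularity Q
of the partition found by deterministic greedy agglomerative
maximization (nodes pre-sorted so ties break lexicographically —
determinism is preferred over marginal Q gains); vertex connectivity
(0 for disconnected graphs); closeness in the Wasserman-Faust
within-component convention (each node's `(n_c-1)/sum d` scaled by
`(n_c-1)/(n-1)`, singletons scoring 0), which handles disconnected
networks without infinities; and unnormalized edge betweenness
averaged over edges.  An empty network reports undefined markers
(`None`), not zeros.

The positive-interaction ratio `E+ / C(n_core, 2)` divides the
positive edge count by the number of pairs the core community could
form.  This is the size standardization that makes a 59-OTU and a
29-OTU network comparable: 59 positive edges over C(59,2) = 1711
possible pairs gives 0.034, while 10 over C(29,2) = 406 gives 0.025.

## Markers

Plasmid (cooperation) markers: GO:0005727 membership OR a
case-insensitive "plasmid" substring in the protein name.  Antibiotic
(competition) markers: GO:0017000 membership OR an exact
(case-insensitive, whitespace-normalized) match against a curated
protein-name list; near-miss names are intentionally not matched.  GO
matching is by exact id — no ontology-graph descendant expansion.
The bundled list (`data/synthetic_antibiotic_protein_names.txt`) is a
synthetic stand-in assembled from widely reported resistance protein
names; real analyses should substitute a project-specific curation.

Resistance-database hits are kept when e-value < 1e-10 AND z-score >
50 AND identity > 60% (strict inequalities; the z-score is treated as
an opaque alignment-quality column and applied as given), then reduced
to one hit per read: highest z-score, then lowest e-value, then
lexicographically first gene name.  The tie-break order is pinned for
determinism.

Counts are normalized by total retained (post-eukaryote-removal)
reads per sample.  Differential abundance between periods is a
permutation test on the difference of group means of normalized
abundance, two-sided, with features observed in fewer than two samples
dropped first; log2 fold changes (LS over ES) use a pseudocount of
half the smallest nonzero value in the table; BH-adjusted p-values are
reported alongside, but calls are made on the raw p at alpha = 0.05.
This deliberately replaces a negative-binomial exact test with a
self-contained permutation test that keeps the same decision rule —
the substitution is recorded in every output header.  The ARGD-versus-
chemistry association is Spearman's rho (Pearson on average ranks)
with a two-sided permutation p.

## Synthetic data

The generator plants known structure under the study's design:

- **OTU series** (20 ES + 16 LS samples, default 300 OTUs): each
  planted pair shares a unit-variance AR(1) driver (phi = 0.8, smooth
  enough to create the local runs LSA looks for); members load on it
  with weight `driver_strength` (opposite signs for negative pairs)
  plus `noise_sd * sqrt(1 - driver_strength^2)` Gaussian noise, so at
  noise_sd = 1 the planted latent correlation equals driver_strength.
  Non-planted OTUs are independent white noise.  Latent series plus
  N(0, 1.5^2) static offsets pass through a softmax to composition and
  multinomial sampling at Poisson(10,000) depth.
- **Chemistry**: six organic acids rise linearly (weights split a
  total ramp of 55 ppb per collection step, chosen so season totals
  run from a few ppb to ~2000 ppb, two orders of magnitude); lactate
  declines; inorganic ions decline or stay flat; values below the
  per-analyte LOD are censored.
- **Markers** (8 ES + 12 LS samples, 60 features): gamma-Poisson
  (negative binomial) counts, lognormal per-sample size factors,
  six enriched features alternating direction with a 2^4 mean ratio.
- **ARGD hits**: hit rate rises with collection order and LS samples
  draw from a 12-gene pool versus 4 for ES; ~30% of hits violate
  exactly one filter threshold, and some reads carry several passing
  hits, exercising both the filter and best-hit resolution.

One master seed derives per-table child streams (SeedSequence with a
fixed per-table tag), so any single table is reproducible without
generating the others.

What the generator does *not* emulate: phylogenetic correlation among
OTUs, overdispersion beyond the softmax-multinomial, irregular
sampling gaps, chemistry-community coupling (the OTU drivers are
independent of the acid ramp, which is why the synthetic co-inertia RV
is small), and read-level sequence error.  Passing recovery tests
therefore demonstrate that the statistical machinery detects the
structure it claims to detect at realistic sample sizes — not that
real snow data will be as clean.

## Calibration and test margins

Planted-pair recovery is scored on the full 36-sample season (the
planted drivers span the season; within-period sub-series halve the
information).  Over 20 seeds at n_otus = 50 with 5 positive and 2
negative planted pairs, the pipeline recovers a median of 5/5 positive
pairs (minimum 4), and the false-positive rate among the ~1200
non-planted pairs sits near the nominal 5% of the raw p < 0.05 edge
filter (median 0.055); the test margins are median recovery >= 4/5 and
median FPR <= 0.10.  An absolute false-positive *count* near zero is
not achievable under raw-p filtering at this scale — that would
require FDR control, which the pipeline's decision rule deliberately
omits.  Null calibration checks hold P(p <= 0.05) within Monte-Carlo
error of 0.05 for the LSA, group-difference, differential-abundance
and Spearman permutation tests.

With strongly planted marker enrichments, null features still show
elevated detection rates (the worked example calls 15 of 60 features
with 6 planted): closure under total-count normalization propagates a
large planted shift into every other feature's relative abundance.
This is a property of relative-abundance differential testing
generally, not of the permutation substitution.

## Problem sizes and numerical choices

Tests and examples run at 50-60 OTUs, 200-1000 permutations, and
20-36 time points — large enough for the asymptotics they check,
small enough for routine re-runs; production settings (10,000
permutations, hundreds of OTUs) are plain configuration.  Score
comparisons in permutation tails use a 1e-12 tolerance so exact ties
count as exceedances (conservative).  Degenerate inputs fail loudly:
constant series (rank transform), all-zero samples (CSS), censored
cells without a LOD, mismatched sample sets (co-inertia), one-group
label vectors.
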