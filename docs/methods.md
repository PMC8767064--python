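# Methods

## The comparison system

The package decomposes compartment differences in a two-genotype seed
design. The wild type's endosperm halves (upper EnU, bottom EnB) exchange
nutrients and signals freely, so their difference reflects position only.
In the notched-belly mutant the notch isolates the bottom half, which
additionally receives the embryo's full influence. Writing cell means of
median-scaled intensities as `m(genotype, tissue)` per feature and stage:

* position effect: `m(WT, EnB)` vs `m(WT, EnU)`;
* compound effect: `m(NB, EnB)` vs `m(NB, EnU)` (position + embryo);
* embryo effect: `R = [m(NB,EnB)/m(NB,EnU)] / [m(WT,EnB)/m(WT,EnU)]`.

The defining identity is *position cancellation*: any multiplicative
change applied equally to the bottom half of both genotypes leaves R
unchanged (exactly, to floating-point precision — this is asserted by a
test). Swapping the genotype labels maps R to 1/R, so the up/down classes
swap only approximately under the default thresholds (0.95, 1.05), which
are not reciprocal (1/0.95 ≈ 1.0526); this near-symmetry is documented,
not assumed.

R aggregates replicates by the arithmetic mean; a geometric-mean option
exists behind a keyword for users who prefer a log-symmetric aggregate.
A cell with no detected replicate or a non-positive aggregate yields class
`undefined`, never a silent drop.

## Statistical tests

**Welch's t-test** (two-sided, Satterthwaite degrees of freedom) is used
for feature-wise two-group comparisons, including the NB_EnB-vs-WT_EnB
significance overlay reported next to each embryo-effect call and the DEG
test. Zero-variance degenerate inputs follow the limiting convention:
p = 1 for equal means, p = 0 (flagged by an infinite statistic) otherwise.
At n = 6 per group the test is mildly conservative — its true level is
≈ 0.046 at nominal 0.05 (measured by simulation at one million draws) —
which the test suite asserts as the correct behaviour rather than exact
nominal calibration.

**Duncan's multiple range test** sorts the group means and compares each
span of p consecutive ordered means against the critical range
`q*(p, df, alpha_p) * sqrt(MSE / n_h)`, with Duncan's protection level
`alpha_p = 1 - (1 - alpha)^(p-1)`, the pooled within-group mean square
MSE, and the harmonic mean group size `n_h` for unbalanced groups. The
no-crossing rule is enforced: pairs inside a non-significant wider span
are never declared significant. Per-pair p-values invert the protection
formula (`p = 1 - (1 - p_span)^(1/(p-1))`). Studentized-range quantiles
come from `scipy.stats.studentized_range` and are cached per
(span, df, alpha); for spans of two the exact identity `q = sqrt(2)·|t|`
routes through the t distribution, which is both faster and accurate to
machine precision. Ties in ordered means break by group index.

**Position and compound calls run Duncan on the two cells being
compared**, which for two groups coincides with a pooled-variance t-test
at alpha. An alternative — one joint Duncan over all four endosperm cells
with a shared error term — was evaluated and rejected: under a global
null the no-crossing protection deflates the rejection rate of a specific
pair to ≈ 0.036 at nominal 0.05 (20,000-feature simulation), i.e. the
call would no longer operate at its stated level. The two-cell contrast
calibrates at 0.048–0.050 under the generator's log-normal noise.

**Embryo-effect classification follows R alone** with inclusive
boundaries (down iff R ≤ 0.95, up iff R ≥ 1.05). The Welch overlay is
reported alongside (BH-adjusted across features within each stage) and is
what a rendered call table would colour by, but it does not gate the
class. Consequently the two error characteristics of the system are
evaluated separately:

* *directional sensitivity* — the fraction of truly affected
  feature × stage cells (true multiplier ≥ 1.5 or ≤ 1/1.5) whose class
  points the right way; ≈ 1.00 under default conditions;
* *false confident calls* — the fraction of unaffected cells that are
  both marked (outside the 0.95–1.05 band) and significant after BH;
  ≈ 0.001 under default conditions.

The unconditioned marked rate on null features is necessarily high
(≈ 0.8): a ±5% band is narrow relative to the sampling noise of a ratio
of four 6-replicate means at σ = 0.25, and this is an inherent property
of the printed rule, not of the implementation.

**Hypergeometric enrichment** uses the upper tail P(X ≥ k) with the
clustered feature set as the universe; pathway members are intersected
with the universe first. The `significant` flag follows raw p < 0.05;
a BH-adjusted column is reported for modern practice.

**Multiple-testing correction** is Benjamini–Hochberg throughout
(`statsmodels.stats.multitest`), recorded in column names as `p_adj`.

## Preprocessing

Median scaling divides each feature's detected values by their median
(idempotent; median of every scaled feature is 1). A non-detected value
is missing, not zero; imputation (per-feature minimum observed, or half
of it) is explicit and drops features with no observations rather than
inventing them. Z-scored profiles are design-cell means standardized per
feature with the sample standard deviation (ddof = 1). Genes count as
expressed at max FPKM ≥ 1 (inclusive); DEGs need |log2 ratio| ≥ 1 of
group means (pseudo-count 0.01 on both means to avoid infinities) at
BH-adjusted p ≤ 0.001.

## PCA and the distance trajectory

PCA is computed by SVD of the log-transformed, centered, unit-variance
scaled (autoscaled) sample × feature table; component signs are fixed by
making the largest-magnitude loading positive. The endosperm trajectory
takes, per genotype and stage, the Euclidean distance between the EnU and
EnB replicate centroids in the first k components. Patterns use strict
inequalities (largest-smallest-recovering = V-type; strictly decreasing =
monotone decline; ties = other).

The default is **k = 3**. The stage-wise accumulation profiles dominate
the first two components of an autoscaled endosperm PCA, while the
EnU-vs-EnB separation axis — carried by the ~20% of features with planted
positional/embryo effects — appears at the third component. At k = 2 the
genotype patterns are recovered in only ~20% of generator seeds; at k = 3
and k = 4 in 30/30 tested seeds. A 2-D projection is what one would plot,
but a 3-D distance is what reproduces the trajectory reliably, and k is
configurable throughout.

## Coexpression modules

K-means (Lloyd, k-means++ seeding, best of 10 restarts, fixed random
state) clusters Z-scored profiles into k = 6 modules. Euclidean distance
on Z-scored rows is monotone in correlation distance, so the default is
equivalent to clustering by Pearson similarity; a `correlation` option
re-standardizes rows explicitly. Modules are renamed DP1..DPk by
descending stage-specificity (margin of the top stage-mean Z over the
runner-up) then size, making the numbering deterministic. A module is
labelled with its dominant stage when that margin exceeds δ = 0.5 Z
units, else "broad".

## The synthetic study

The generator reproduces the study design: 2 genotypes × 3 tissues
(E, EnU, EnB) × 3 stages (10/20/30 DAF), six metabolome and three
transcriptome replicates, a 634-metabolite catalog split 484 shared /
109 embryo-only / 41 endosperm-only with the nine-class composition per
compartment, and FPKM-scale expression for (by default) 2,000 genes.

Intensities are multiplicative log-normal:
`b_f · exp(A·m(module_f, s)) · pi(f,s)^[t=EnB] · eps(f,s)^[g=NB, t=EnB] · exp(σz)`.

* Baselines `b_f` are log-uniform over 10³–10⁵ (arbitrary units).
* Module profiles are six Z-score archetypes over stages (three
  single-stage peaks, three two-stage "broad" patterns) with amplitude
  A = 0.8 natural-log units — strong but realistic stage structure that
  an autoscaled PCA and K-means can resolve.
* Noise is σ = 0.25 on the natural-log scale (≈ 25% CV), a typical
  untargeted-platform replicate spread.
* Position effects hit a fraction 0.2 of endosperm-present features with
  multipliers log-uniform in [1.5, 3] (half up, half reciprocal down),
  attenuated over stages by weights (1.0, 0.65, 0.3) — the halves of the
  wild-type grain converge as filling completes.
* Embryo effects hit an independent fraction 0.2 with the same
  multiplier law, applied only to NB_EnB, with stage weights
  (1.0, 0.2, 0.8): strongest at 10 DAF when the embryo grows fastest,
  nearly gone at 20 DAF (embryo dormancy), partly recovered at 30 DAF.
  These weights are what makes the default run produce the V-type
  NB trajectory against the WT's monotone decline.
* Embryo-only features are simply not detected in endosperm samples and
  vice versa; compound classes are assigned deterministically from the
  seed and do not influence the generative means.
* The transcriptome plants 10% of genes below the expressed threshold
  (baseline FPKM 0.05) and gives 10% of expressed genes a
  |log2| ∈ [1, 2] effect in NB_EnB at 10 DAF — "transporter" genes up,
  "synthesis" genes down.

Everything is deterministic given (config, seed); ground-truth tables
record per feature × stage the true multipliers, module and presence.

What the generator does **not** emulate: instrument drift and batch
structure, correlated features within pathways, missingness that depends
on intensity, count noise in RNA-seq, or contamination from the outer
grain layers shared across subsamples (configurable off by default in
the real study's caveats, not modelled here). Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to every artefact of real data.

## Problem sizes and numerical choices

Simulated checks use the default study size (634 × 108) except the null
calibration of the position call, which uses 10,000 shared features for
a tight binomial standard error, and the trajectory stability check,
which repeats the default study over 20 seeds. Studentized-range
quantiles are cached; decomposition over all features and stages is
vectorised (NaN-aware means/variances), so a full 10,000-feature
decomposition takes well under a second. Output tables are sorted
(feature, then stage) and floats rendered at 8 significant digits so
reruns are byte-identical.

## Known limitations

* Duncan's test is comparison-wise calibrated but, like the original
  procedure, does not control the family-wise error rate; the package
  reports BH-adjusted Welch p-values alongside for users who need FDR
  control across features.
* The ±5% ratio band yields many marked-but-insignificant calls at
  realistic noise; interpret `embryo_class` together with the Welch
  overlay.
* The DP numbering is deterministic for this package's rule but not
  comparable across datasets with different stage structures.
* With fewer than two replicates in a compared cell the Duncan-based
  calls are impossible; such cells are flagged at design validation.
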