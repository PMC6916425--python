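# Methods

This note documents the statistical models behind `microgliaseq`, the
defaults and why, the synthetic data the tests run on, and what the
package deliberately does not do.

## Normalization and transformation

Size factors are median-of-ratios: for gene g let `geomean_g` be its
geometric mean count across samples; sample j's factor is the median over
"usable" genes (positive count in every sample, i.e. `geomean_g > 0`) of
`counts[g,j] / geomean_g`.  Zero-geomean genes cannot influence the
factors.  The median uses the midpoint convention on even counts of usable
genes, for determinism.  Factors are **not** rescaled to unit geometric
mean afterwards: the definition is applied as stated, and any global
rescaling cancels wherever factors enter as ratios.  A consequence worth
knowing: scaling a subset of columns by c changes *every* factor (through
the geometric mean), not just the scaled columns' — only factor *ratios*
are equivariant.

The log transform is `log2(count/sf + pseudocount)` with pseudocount 1 by
default.  This keeps the role of a regularized log transform — a
variance-tamed log scale for correlation, PCA and replicate means — with a
fully explicit formula.  It is *not* the shrinkage-based rlog estimator:
low-count genes are compressed toward `log2(pseudocount)` rather than
toward a fitted prior mean.  PCA treats samples as observations and genes
as centered features; whether to run it on all genes or only DE genes is
exposed as a choice to the caller (default: all genes).

## Differential expression

Counts follow a negative binomial with `Var = μ + αμ²`.  For a contrast
A vs B:

* **Dispersion.**  Per gene, a method-of-moments estimate
  `α̂ = max(0, (s² − μ̄)/μ̄²)` on normalized counts, with the variance
  pooled within groups (so true group differences do not inflate it) and
  μ̄ the mean over the contrast samples.  Gene-wise estimates at n = 3 per
  group are very noisy, so they are shrunk toward a mean-dispersion trend
  `α_tr(μ) = a₀ + a₁/μ`, fitted by non-negative least squares of α̂ on
  `[1, 1/μ̄]`, with weight 0.5 each (`shrink_weight`, exposed); the result
  is floored at 1e-8.  The trend form captures the usual excess dispersion
  at low means; NNLS keeps both coefficients non-negative so the trend is
  a valid dispersion everywhere.
* **Group means.**  The per-group abundance q (normalized scale) maximizes
  the NB likelihood with the dispersion plugged in and size factors as
  offsets, by a damped Newton iteration in log q (an all-zero group gives
  q = 0).
* **Effect and test.**  `log2fc = log2((q_A + c)/(q_B + c))` with
  stabilizer c = 0.5 normalized counts, so empty groups remain finite.
  The standard error comes from the observed Fisher information of q at
  the optimum via the delta method (falling back to the expected
  information when the observed curvature degenerates numerically); the
  Wald statistic `log2fc/se` is referred to the standard normal.
  Benjamini–Hochberg runs over all genes with nonzero counts in the
  contrast; all-zero genes are excluded from testing and from the BH
  family.  Selection keeps `q ≤ 0.05` and `|log2fc| ≥ 1` (both
  inclusive); both thresholds are parameters.

Deliberately omitted relative to full-featured DE packages: outlier
refitting (Cook's distance), independent filtering, and shrinkage of the
fold change itself — selection uses the raw MLE log2 fold change.  The
consequence, visible in the calibration suite, is a mildly anti-
conservative test at n = 3 (null rejection ≈ 0.06 at the 5% level,
realized false-discovery proportion ≈ 0.09–0.10 at BH 0.05 with the fold
filter): the plug-in dispersion ignores its own estimation uncertainty,
and the normal reference has no small-sample correction.  Designs are
limited to single-factor group comparisons.

## Temporal expression groups

Each of the three timepoint contrasts (3v5, 3v7, 5v7; always oriented
earlier-over-later) contributes a sign per gene: +1 significantly higher
at the earlier timepoint, −1 at the later, 0 not selected.  The six
groups are defined by a priority-ordered decision table — conjunctive
patterns first:

| order | group | rule | reading |
|---|---|---|---|
| 1 | G2 | s37 = +1 and s57 = +1 | high at 3 and 5, low at 7 |
| 2 | G6 | s35 = +1 and s57 = −1 | high at 3 and 7, low at 5 |
| 3 | G4 | s35 = −1 and s37 = −1 | low at 3, high at 5 and 7 |
| 4 | G1 | s35 = +1 or s37 = +1 | high at 3 |
| 5 | G3 | s35 = −1 or s57 = +1 | peak at 5 |
| 6 | G5 | s37 = −1 or s57 = −1 | high at 7 |

The first match wins; genes selected in no contrast are unassigned, so
the labels partition the input.  This table is a declared convention:
verbal group definitions and a Venn diagram admit several formalizations,
and this one both matches the verbal readings and guarantees a partition.
Transitivity-violating triples (3 > 5 and 5 > 7 yet 7 > 3 — possible only
through inconsistent test calls) fall through the table by default; a
strict mode routes them to unassigned with a warning instead.

## Cross-species comparison

Ortholog pairing supports three policies for 1:many and many:many
relations: `one_to_one_only` (drop every multi-mapped gene; conservative),
`max_mean` (default — per multi-mapped gene keep the partner with the
highest mean expression; deterministic, identifier-ordered tie-break) and
`sum` (aggregate counts within connected ortholog components; count-scale
input only).  The policy used is recorded in the output metadata, because
the choice is not neutral.

Because normalization rescales samples relative to one another, each
cross-dataset analysis renormalizes from scratch: the two count matrices,
restricted to the shared ortholog rows, are concatenated column-wise and
size factors recomputed on the combined matrix before the log transform.
Correlations are Pearson r of log-scale replicate means over ortholog
pairs (log scale, because means of variance-tamed log expression are what
the correlation should summarize; the linear scale would be dominated by
a handful of very high expressors).

Whether two correlations to a shared reference differ is tested with the
Hotelling–Williams t:

    |R|  = 1 − r12² − r13² − r23² + 2·r12·r13·r23
    r̄    = (r12 + r13)/2
    t    = (r12 − r13) · sqrt( (n−1)(1+r23) /
             ( 2·((n−1)/(n−3))·|R| + r̄²·(1−r23)³ ) ),   df = n − 3

two-sided by default (one-sided available).  `|R| ≤ 0` — an exactly
singular correlation matrix, e.g. when the reference *is* one of the
query profiles — is a hard error rather than a degenerate statistic.
Treating gene pairs as independent observations overstates n when genes
are co-regulated; the calibration suite shows the nominal level holds
under independent sampling, which is the test's own assumption.

## Overlap and category enrichment

The overlap of two gene lists (sizes K and n) in a universe of N genes is
scored by the upper hypergeometric tail `P(X ≥ k)`, summed in log space;
fold enrichment is `k·N/(K·n)`; the shared percentage is `100·k/n`.  Only
enrichment is tested, never depletion.  The universe defaults to the
ortholog pairs detected (nonzero in at least one sample) in *both*
datasets — the only universe both lists can inhabit — and is always an
explicit, overridable argument, because fold enrichments are meaningless
without stating N.  Category enrichment applies the same test per
annotation term and reports only terms holding at least `min_size`
(default 10) query genes — a reporting filter, applied before BH across
the tested terms.  This is a fixed-list test; it does not reproduce
threshold-free ranked-list enrichment methods, and no ontology-graph
propagation is performed.

## qPCR quantification

Comparative Ct with amplification efficiency fixed at 2 (the classic
assumption; standard-curve efficiency correction is out of scope).
Technical duplicates are averaged on the Ct scale before any delta is
taken.  Each biological replicate is calibrated against the same-index
replicate of the calibrator group — each independent experiment carries
its own calibrator — which makes the calibrator group's fold exactly 1
with SD 0 by construction; the alternative (calibrating against the
calibrator group's mean ΔCt) leaves the calibrator's arithmetic mean fold
above 1 and was rejected for that reason.

## Synthetic data

The generators emulate the structure the pipeline assumes: gene × sample
NB counts for 3/5/7 dpf plus a brain-cell reference at 3 replicates each,
uneven depths, and a mean-dispersion trend.

Defaults and rationale (all in `SimConfig`):

* `n_genes = 2000` — enough for stable BH behaviour and trend fitting at
  interactive runtimes.
* baseline means log-normal, ln-mean 4 and ln-sd 2 — median ≈ 55 counts,
  range from single digits to tens of thousands, the usual bulk spread.
* dispersion trend `a₀ = 0.05`, `a₁ = 1` — moderate biological
  overdispersion with low-count excess; calibration runs override it with
  a flat α as stated per run.
* library-size factors log-uniform in [0.5, 2] — realistic depth
  variation that actually exercises normalization.
* planted |log2FC| uniform in [1, 3] (or a fixed value) — at least the
  two-fold change the selection filter targets.
* one global seed drives a single generator stream, so identical
  configurations reproduce bit-identical datasets.

The temporal generator plants pure exemplars of the six groups via
canonical per-group offsets (G1: high at 3; G2: high at 3 and 5; G3: peak
at 5; G4: low at 3; G5: high at 7; G6: dip at 5).  The dual-species
generator adds a second species with microglia/brain groups, an ortholog
map (80% 1:1, 10% 1:2, 10% unmapped by default), ortholog baselines that
covary across species (log-normal noise, ln-sd 1 — giving cross-species
mean-expression correlations around 0.8–0.9, in the range seen between
real microglia datasets), and a planted signature elevated in microglia
of both species for a configurable conserved fraction.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: batch and protocol effects between datasets,
library-preparation biases (gene length, GC), correlated gene modules
(genes are independent given their means, so the Williams test's
independence assumption is exactly true here and only approximately true
in reality), outlier samples, and annotation errors in real ortholog
maps.

## Numerical choices

* Hypergeometric tails are summed in log space (log-gamma binomials +
  log-sum-exp), exact to enumeration over the full N ≤ 30 lattice.
* BH is the step-up `q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1, stable
  under ties and permutations.
* The NB Newton solver iterates in log q with steps clipped to ±2 and an
  uphill fallback where curvature degenerates; all-zero groups shortcut
  to q = 0.
* Dispersions are clipped to [1e-8, 100]; size factors must be strictly
  positive; a matrix with no gene detected in every sample is a hard
  error advising filtering rather than a silent fallback.
* Problem sizes in the validation suite (2,000 genes, 20 seeds for DE
  calibration; 5,000 replicates for the Williams level; 50 seeds for the
  null-overlap uniformity) were chosen so Monte-Carlo error is a few
  times smaller than the tolerance each check asserts.

## Known limitations

Single-factor designs only; no multi-species (> 2) joint models; no
batch-effect correction — cross-dataset comparisons inherit whatever
protocol differences the inputs carry; the fixed-list enrichment is not a
substitute for ranked-list methods when no natural cutoff exists; and the
pseudocount transform under-shrinks low-count variance relative to a
fitted-prior regularized log, which mildly inflates low-expression noise
in PCA and correlations.
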