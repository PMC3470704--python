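# Methods

`heterochron` detects *transcriptional heterochrony*: a difference between
two groups of individuals in the timing — onset or rate — of age-related
gene-expression change. This note documents the statistical procedure, its
assumptions, the tunable parameters, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## The detection cascade

Each gene is carried through four stages; every stage uses raw p-values at
a per-stage threshold `alpha` (default 0.05, no multiple-testing
correction). This is an intentional reproduction of the classical
screening protocol for this problem; a Benjamini–Hochberg switch
(`correction="fdr_bh"`) is available for users who prefer FDR control.

**1. Age effect.** Expression is regressed on age with ordinary least
squares polynomials of degree 0–3; the degree is chosen by the adjusted-r²
criterion, with ties (within 1e-10) broken toward the lower degree. The
selected model is tested against the intercept-only model with

    F = ((RSS0 − RSS1)/d) / (RSS1/(n − d − 1)),

where d is the selected degree; degree-0 selection yields p = 1 by
definition. Ages are centered before fitting for numerical conditioning,
and coefficients are reported in the centered basis. Note that adjusted-r²
selection is deliberately liberal: with a true degree-k signal it selects
degree k+1 roughly a third of the time (it is equivalent to accepting an
extra term whenever its F statistic exceeds ≈1). This barely changes the
fitted curve inside the observed age range, but it is why fitted curves
are never extrapolated anywhere in the package. The adaptive selection
also makes the stage-1 F-test mildly anticonservative (measured null
rejection ≈0.07 at alpha 0.05); the downstream heterochrony significance
does not inherit this because its null simulation runs the identical
adaptive pipeline.

**2. Between-group divergence (ANCOVA).** One pooled curve for all
samples is compared with independent per-group curves. The degree is
chosen once on the pooled data (capped so each group can support it) so
the models nest and the F-test is valid:

    F = ((RSS_pooled − RSS_full)/(d+1)) / (RSS_full/(n − 2(d+1))).

Measured null rejection is ≈0.04–0.05 at alpha 0.05.

**3. Co-direction.** The two groups' fitted curves, evaluated on a
100-point grid spanning the overlap of their observed age ranges, must
correlate significantly positively (one-sided Pearson test). This filters
out genes whose divergence reflects opposite trends, which no time shift
can explain. Curves rather than raw values are correlated because samples
are unpaired across groups. Flat (degree-0) curves leave r undefined; such
genes are reported as not passing, with the reason.

**4. Heterochrony (DTW shift test).** Described next. A gene is called
significantly heterochronic only if both alignment directions reject at
`alpha` and their shift estimates agree in sign.

## The dynamic-time-warping shift test

The heterochrony statistic is built from a concrete, fully reproducible
alignment algorithm:

* Both groups' fitted curves are evaluated on an `n_grid`-point grid
  (default 50) spanning the overlap of the observed age ranges, then
  **jointly standardized** — one mean and SD across the two curves
  together. Joint standardization preserves the relative level of the two
  curves. This is essential: for monotone, co-directional trajectories an
  onset shift *is* a level offset (a group that reaches older-age
  expression levels early sits above or below its counterpart at every
  age), so removing per-curve levels would delete the very signal being
  tested. The flip side, documented here deliberately, is that a constant
  offset of non-heterochronic origin between monotone curves is
  indistinguishable from an onset shift — a limitation shared by any
  method that reads level differences as timing differences.
* Alignment is dynamic time warping with squared-difference local cost,
  step set {(1,0), (0,1), (1,1)}, and **relaxed end matching**: the path
  may start at (i,0) or (0,j) and end at (n−1,j) or (i,n−1) within
  `slack` grid points of the corners. Tie-breaks are deterministic
  (diagonal step preferred, then advancing the query index; the corner
  end cell preferred on equal cost). The implementation is verified
  against exhaustive path enumeration on small grids.
* From the optimal path, a per-query-grid-point shift is computed as the
  matched reference age minus the query age (averaged per query point);
  the test statistic is the mean shift over query points, in years.
  Positive shift always means group A accelerated, in both alignment
  directions.
* Significance is a **parametric bootstrap**: under the null both groups
  share the pooled adjusted-r²-selected curve, so `n_null` replicate
  datasets are drawn by adding Gaussian noise (pooled residual SD) to
  that curve at the real samples' ages and group sizes, and the entire
  fit → grid → align → shift pipeline is rerun per replicate. The
  p-value uses the add-one estimator p = (1 + #{|null| ≥ |obs|})/(n_null
  + 1), so p > 0 always. A label-permutation null (`null_mode=
  "permutation"`) is available; the parametric default preserves the age
  design exactly, which matters at ~20 samples per group. Both
  directions' p-values are computed from one shared set of replicates.

### Slack and the range of detectable shifts

`slack` bounds how far the curves may slide past each other, so it caps
the detectable shift at roughly `slack × grid step` years. The screening
default (5 points ≈ 7 y on a 50-point grid over a 65-y overlap) targets
modest shifts; recovery studies of 10–20-y planted shifts use the maximum
admissible slack `n_grid/4` (12 points), and that is what the acceptance
runs use. Setting slack below the true shift truncates the path at the
grid edges and biases the recovered mean shift toward zero.

### The nonlinear-least-squares alternative

As a cross-check on the alignment-based estimate, `nls_shift_estimate`
finds the δ minimizing the mean squared difference between one group's
*observed* values and the other group's fitted curve evaluated at
(age + δ), over δ ∈ [−span/2, span/2]. Two numerical choices matter:

* only query samples whose shifted age falls inside the reference group's
  observed range enter the objective (at least half must) — fitted
  polynomials are never extrapolated, which otherwise produces
  heavy-tailed estimates whenever the adjusted-r² criterion overfits;
* by default the estimate is symmetrized (average of the A-onto-fit(B)
  and negated B-onto-fit(A) estimates), mirroring the bidirectional
  alignment rule; `symmetric=False` gives the one-directional variant.

A coarse 201-point scan precedes bounded 1-D minimization to avoid local
minima of the fitted polynomial. On planted 10-y shifts at signal-to-noise
4 the symmetric estimator's median is within ~0.5 y of truth and its
correlation with the DTW mean shift exceeds 0.9.

## Downstream analyses

* **Cohen's d** with the pooled-variance denominator; undefined (NaN with
  a warning) at zero pooled SD.
* **Corrected effect size**: the residual of per-gene d on the per-gene
  expression–age Pearson correlation (OLS across genes, intercept
  included). By construction residuals are exactly orthogonal to the age
  correlation, isolating the case/control effect from shared aging
  signal. Gene-group comparisons of corrected effects use the two-sided
  Wilcoxon rank-sum test (exact for small samples without ties, normal
  approximation with tie correction otherwise, per scipy's policy);
  two-sided is the conservative default since directionality is usually
  the question under test, not an assumption.
* **Variance F-test**: within-group dispersions are compared on residuals
  around each group's own fitted age curve (raw variances would conflate
  trajectory divergence with dispersion), F = s²_A/s²_B with
  (n_A−d_A−1, n_B−d_B−1) df; both one-sided p-values are reported. At
  n = 20 per group the analytic power against a fourfold variance ratio
  is 0.85–0.89 depending on the residual df.
* **Gene clustering**: agglomerative, average linkage on correlation
  distance (1 − r), over either concatenated per-group fitted curves or
  per-point shift profiles; k is a user parameter (presets 6 and 4 in the
  example configurations echo common choices for trajectory clustering).
* **Sample bootstrap clustering**: hierarchical clustering of samples with
  gene resampling; the pairwise co-assignment frequency at the 2-cluster
  cut defines the consensus partition and its stability score (mean
  agreement between co-assignment frequencies and the consensus). When
  ages are supplied, genes are first residualized on their pooled fitted
  age curves. This detrending is the package's deliberate choice for
  subpopulation detection: on age-series data the dominant axis of raw
  expression correlation is age itself, so raw-space clustering splits
  samples into young versus old; only in deviation-from-trend space does
  an accelerated subpopulation become the leading structure. (Verified
  directly on synthetic data: raw clustering yields a stable but
  age-defined split; detrended clustering recovers the planted subgroup
  exactly.)
* **Gene-set overlap**: upper-tail hypergeometric p-value (exact, matches
  enumeration) and the 2×2 odds ratio with Haldane–Anscombe 0.5
  correction when a cell is zero.

## The synthetic-data generator

The generator emulates the structure of a two-group brain expression
age-series: `n_genes` ≈ 10–15k genes, ~20 samples per group, ages uniform
on 20–99 y (or a supplied list). A configurable fraction of genes is
age-related (polynomial trajectories of degree 1–3, coefficients drawn in
a scaled-age basis); of those a fraction diverges between groups; of
those a fraction is heterochronic, as either

* **onset-shift**: group A follows f(age + δ), group B follows f(age); or
* **rate-scale**: group A follows f(age_min + k·(age − age_min)) with k
  chosen so the planted shift equals δ at the age-span midpoint — curves
  coincide at the youngest age and diverge with age.

δ is signed (positive = A accelerated) with P(positive) =
`direction_bias`. Non-heterochronic divergent genes receive a constant
offset of half the signal amplitude with random sign; non-age-related
genes are flat. Noise is additive i.i.d. Gaussian per observation
(log-scale microarray residuals are approximately Gaussian, and the
variance F-tests assume it). Optionally a gene subset has its group-A
noise variance inflated, and a fraction of group-A samples forms a
shifted subpopulation — in that case the planted acceleration applies
*only* to the subpopulation members, the remaining group-A samples
following the group-B curve.

Free parameters the underlying study design does not pin down were fixed
once at values a practitioner would call realistic for log2 microarray
data and are not study estimates: `signal_amplitude` 1.0 (defined as the
SD of the noiseless trajectory over the age span, so amplitude/noise is a
genuine signal-to-noise ratio), `noise_sd` 0.25 (SNR 4), baseline
expression ~ N(7, 1), divergence offset 0.5·amplitude. Default planted
fractions (40% age-related, 38% of those divergent, 27% of those
heterochronic, 98% direction bias, shifts uniform on 5–20 y) mirror the
proportions reported for this class of data.

What the generator does **not** emulate: probe-level artifacts, batch
effects, array-specific intensity distributions, correlated noise across
genes, non-Gaussian heavy tails, or realistic gene–gene co-expression
structure. Passing the recovery tests therefore demonstrates correctness
of the inference machinery under the stated model, not robustness to
every failure mode of real microarray data.

## Problem sizes used by the verification runs

The packaged verification runs (test suite and `scripts/acceptance.py`)
use: 1000 null genes with 200 null replicates per gene and direction for
calibration; 200 planted-shift genes (δ = 10 y, SNR 4, linear onset-shift
archetype — the cleanest realization of a pure timing shift) for recovery
and estimator agreement; 300 genes, 200 bootstrap resamples for
subpopulation recovery; exhaustive enumeration up to universe 25 for the
overlap test and up to 6 grid points for the alignment oracle. These
sizes give stable binomial precision (±1–2 percentage points on the
calibration rates) while keeping a full verification run in minutes on a
single core.

## Known limitations

* A constant level offset between monotone co-directional curves is read
  as an onset shift (see above) — timing and level are confounded in
  exactly the way the underlying biology confounds them.
* "Earlier onset" versus "faster rate" is not classified gene-by-gene;
  the per-point shift profile (monotone-increasing for rate scaling,
  flat for onset shifts) is reported and can be clustered, but single-gene
  power to distinguish the two modes is poor at ~20 samples per group.
* The cascade's raw-p thresholds reproduce the classical protocol; users
  screening large platforms should enable the FDR switch.
* The parametric null assumes Gaussian residuals around the pooled curve;
  the permutation null relaxes this at some cost in power with small,
  unbalanced age designs.
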