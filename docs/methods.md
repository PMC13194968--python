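# Methods

## Data model and fixtures

The unit of analysis is a per-sample table of total concentrations
(mg kg⁻¹ dry soil) for eight metal(loid)s: As, Pb, Zn, Fe, Cd, Cu, Cr, Ni.
Tables are validated on construction: unique sample identifiers, fully
populated numeric metal columns, and strictly positive concentrations (the
log- and ratio-based indices are undefined otherwise).  CSV I/O is plain
comma-separated UTF-8 with a `sample_id` first column and full-precision
floats, so read/write round-trips bit-for-bit.

The packaged fixture (`data/study_summary.csv`, `data/backgrounds.csv`)
carries the published per-metal descriptive statistics of a 20-sample
smelter-site survey and the two background sets: average shale (ASV — Fe
47,200; Zn 95; Cr 90; Ni 68; Cu 45; Pb 20; As 13; Cd 0.3 mg kg⁻¹) and upper
continental crust (UCC).  ASV is the sole background for index computation;
UCC is kept for context ratios only.

Descriptive statistics use the n−1 standard deviation and the bias-adjusted
sample skewness and excess-kurtosis estimators.  The published table does not
state which estimator it used, so skewness/kurtosis are never treated as
reproducibility targets; min/max/mean/SD and CV = 100·SD/mean are.

## Synthetic site generator

`generate_site` draws `conc_i = (background + amplitude·e^{−d_i/λ})·e^{ε_i}`
with `ε_i ~ N(0, σ²)`, `d_i` the distance from a point source.  Noise is
multiplicative lognormal rather than additive Gaussian: it guarantees
positivity and reproduces the strong right skew and leptokurtosis
characteristic of smelter-impacted surveys (observed skewness up to 4.5,
CV up to 215%).  Defaults: 20 samples on a regular grid one decay length
apart, per-metal backgrounds at the published minima, amplitudes at the
published range, σ = 0.4.  With σ = 0 concentration is exactly non-increasing
in distance; the analytic expectation `(bg + amp·e^{−d/λ})·e^{σ²/2}` is used
as a Monte Carlo oracle in tests.

`moment_match` converts summary statistics into a concrete n-sample dataset:
the observed extremes are pinned, interior points are drawn from a
right-skewed beta shape and compressed one-sidedly toward the feasible
interior mean, so per-metal min, max and mean are exact (≈1e-16 relative).
Higher moments are deliberately not matched — simultaneously matching SD and
skewness at n = 20 is over-constrained, and the ratio-based indices only need
the extremes and the mean (CF is linear in concentration, Igeo monotone).
Infeasible targets (mean outside the interior-feasible interval) raise.

## Pollution indices

EF, Igeo, CF, PLI as defined in the README, with Fe as the conservative
reference element for EF.  The 1.5 factor in Igeo absorbs lithogenic
variability.  PLI is computed as `exp(mean(log CF))` for numerical stability.
Class schemes (Müller's seven Igeo classes, five EF groups, four CF groups,
four PLI groups, HI and TCR bands) live in `data/class_schemes.yaml` so
alternative published break-points can be swapped in without code changes.
Intervals are left-closed: a value exactly on a boundary belongs to the upper
class.  Indices are reported at two decimals; full precision is kept
internally.

## Deterministic risk model

Doses follow the USEPA residential-soil equations (see README).  Two fixed
receptors: child (IngR 200 mg d⁻¹, InhR 7.6 m³ d⁻¹, BW 15 kg, ED 6 y, SA
2800 cm², AF 0.2 mg cm⁻² d⁻¹) and adult (IngR 100, InhR 20, BW 70, ED 24,
SA 5700, AF 0.07); EF 350 d y⁻¹ and PEF 1.36×10⁹ m³ kg⁻¹ for both.
Averaging time is ED×365 days for non-carcinogenic endpoints and a 70-year
lifetime (25,550 days) for carcinogenic ones; the same dose equations are
used for both, only AT changes, and the two call paths are kept distinct so a
test can assert the dilution direction.

The toxicity registry ships IRIS/RSL-convention defaults with provenance
strings: inhalation RfDs converted from RfCs with 20 m³/70 kg where an RfC
exists, route-extrapolated otherwise; dermal values via RAGS Part E
(RfD·GIABS, CSF/GIABS); dermal absorption 0.03 for As and 0.001 elsewhere.
Chromium is treated as Cr(VI) (conservative).  Zn, Cu and Fe have no accepted
slope factor and appear only in non-carcinogenic outputs — they are excluded
from TCR tables with an explicit flag, never silently zeroed.  Cd and Ni have
no IRIS oral slope factor; the registry carries the literature values widely
used in soil risk assessment (6.1 and 0.91), provenance-tagged and
overridable.  Every value can be replaced via a YAML config; the defaults are
a documented convention, not site-specific calibration.

Useful structural facts, asserted as tests: every dose and risk is linear in
concentration; the child/adult HI ratio is constant across metals (the
exposure factors factor out); ingestion dominates inhalation for all metals
under the default registries.

## Monte Carlo simulation

`run_simulation` evaluates a deterministic risk closure over n = 10,000 joint
draws and reports mean, SD, P5/P50/P95 (linear interpolation of order
statistics) and exceedance probabilities against HI = 1 and TCR = 10⁻⁴.
Distributions are point, normal, lognormal, triangular or uniform with
optional truncation by inverse-CDF restriction; every parameter gets an
independent substream derived from the master seed, so runs are bit-for-bit
reproducible and results are invariant to evaluation order.  The model
closures reuse the deterministic dose code path, so with all-point inputs the
Monte Carlo percentiles equal the deterministic result exactly — a bridging
test between the two modules.

Default input distributions (the genuinely open design choice in this stage):

* **concentration** — truncated normal around the site mean with the standard
  error of the mean (SD/√n), truncated at the observed min/max.  The chronic
  exposure concentration is a site-wide average, so what is propagated is the
  sampling uncertainty of that mean, not raw spatial variability;
* **soil ingestion rate** — triangular (0.25×, 1×, 2×) around the point
  value.  Soil-ingestion estimates are the most uncertain exposure factor in
  the literature, with central estimates spanning roughly a factor of four;
* **InhR, SA, AF** — triangular ±30%;
* **body weight** — truncated normal, SD = BW/6, truncated to [BW/2, 2BW];
* **EF, ED, PEF** — fixed (chronic-scenario constants).

Under these defaults the variance budget of the hazard index is dominated by
ingestion rate (total-order Sobol index ≈ 0.70 for child-Cr), body weight
second (≈ 0.26), concentration minor (≈ 0.06) — except for metals with
extreme spatial CV such as As (CV 215%), where the concentration term
overtakes the exposure factors.

The convergence diagnostic evaluates the tracked statistics at checkpoints
(5k, 10k, 15k) along a single stream — the estimate an analyst would have
stopped with after n iterations — and reports the relative drift against the
largest checkpoint, flagging anything above 2%.  Statistics within 10⁻¹⁰ of
each other at the output's own scale count as converged (floating-point dust
on degenerate inputs).  For the default child-Cr HI model the 10k-vs-15k
drift is well under 1%.

## Sobol sensitivity analysis

No sensitivity-analysis library is bundled with the scientific stack used
here, so the Saltelli design and the estimators are implemented in
`soilrisk.sobol` on top of `scipy.stats.qmc.Sobol` (scrambled).  The design
is `[A; B; AB_i…; BA_i…]` — N·(2D+2) evaluations with second-order blocks,
N·(D+2) without.  Estimators: Saltelli-2010 for S1, Jansen for ST (both
chosen for low estimator variance), and the standard cross-block formula for
S2.  Outputs are centered before estimation, making the indices exactly
invariant under affine rescaling of the output.  Negative estimates are
reported as-is — clipping would hide non-convergence.  95% confidence
half-widths come from 100 bootstrap resamples of the base-sample index.
Base N defaults to 1024 (a power of two; other sizes warn).  The Ishigami
function with its closed-form variance decomposition is the test oracle;
at N = 1024 the S1 estimates land within ~0.01 of the analytic values.

`rank_parameters` applies the >0.1 total-order cut-off for critical
parameters.

## Multivariate source apportionment

`zscore` standardizes columns (n−1 SD), refusing constant columns.
`ward_cluster` clusters the **metals** on their standardized, transposed
per-sample profiles with Ward linkage and Euclidean distance — squared
Euclidean distance between z-scored columns is 2(n−1)(1−r), so this is
correlation-driven clustering.  Merge heights follow the standard
√(2·ΔESS) convention and are verified against an independent brute-force
greedy ESS-minimizing implementation in the tests.  The default cut is at the
largest fusion-height increase, overridable by k.  Dendrograms export to
Newick with branch lengths equal to height differences.

`pca_varimax` eigendecomposes the correlation matrix, retains components with
eigenvalue > 1 (Kaiser), scales eigenvectors by √eigenvalue into loadings and
applies the classic varimax rotation; communalities are preserved to 1e-10.
Each loading column is sign-flipped so its largest-magnitude entry is
positive.  Loadings are read with the usual thresholds (>0.5 strong, 0.3–0.5
moderate).  With 20 samples and 8 variables the loadings are noisy — the code
warns when samples ≤ variables — so PCA output is indicative of sources, not
a definitive apportionment.

## Problem sizes and reproducibility

Default problem sizes: 20-sample site; 10,000 Monte Carlo iterations
(5k/10k/15k for convergence); Saltelli base N = 1024 (14,336 evaluations for
the 6-parameter HI model); dendrograms over 8 metals.  Every stochastic stage
takes an explicit seed; the pipeline derives per-stage substreams from one
master seed and echoes its full configuration (with hash) into the output
directory.

## Known limitations

* The exposure and toxicity defaults are literature conventions, not
  site-measured values; absolute Monte Carlo risk magnitudes shift with them.
  Orderings (child > adult, ingestion-dominant, IngR > BW in the variance
  budget) are robust to moderate changes and are what the tests assert.
* The moment-matched dataset reproduces extremes and means only; statistics
  that depend on the full sample (per-sample PLI distribution, EF spread,
  PCA loadings) vary with the interior draw and are not reproduction targets.
* The synthetic generator emulates an isotropic single-source plume with
  independent per-metal noise; real sites have correlated multi-metal noise,
  anisotropic transport and multiple sources, so passing tests demonstrate
  correctness of the computations, not realism of any particular field site.
* No spatial interpolation (20 points cannot support variogram modelling),
  no food-chain or water pathways, and no receptor-model (PMF/isotope)
  source confirmation.
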