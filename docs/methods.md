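# Methods

## Scope and data model

`macrodiv` analyses species-level variation in mitochondrial barcode
diversity. Its inputs are (i) one aligned FASTA per species (equal-length
A/C/G/T records; IUPAC ambiguity codes and gaps are treated as missing),
(ii) a species table of traits (body size in mm, vision and maternal care
as 0/1) and latitudinal range in degrees, (iii) a per-sequence locality
table (species_id, lat, lon in decimal degrees), and (iv) a family-level
Newick tree with branch lengths. Species enter the analysis only with at
least three sequences.

## Nucleotide diversity

π is the per-site average number of pairwise differences: the sum of
differing sites over all unordered sequence pairs, divided by the number of
pairs and by the number of sites compared. Under **complete deletion**
(default) every alignment column containing a non-ACGT character is removed
before any statistic is computed; under **pairwise deletion** each pair is
compared over its own unambiguous sites and π is the mean per-pair
p-distance. Both conventions are in routine use for barcode data, so both
are provided and the choice is logged in the pipeline config. S counts columns with ≥ 2 unambiguous states; PIS counts columns
with ≥ 2 states each carried by ≥ 2 sequences. Implementation note: a
duplicate of an existing sequence can never raise S but can raise PIS (a
singleton state becomes doubly represented); this is a property of the
definitions, not an artefact.

## Predictors and response transform

Mean latitude is **signed** by default (southern hemisphere negative),
since the hemispheric contrast is part of the scientific question; an
absolute-latitude switch exists. Mean geographic distance averages
haversine distances (sphere radius 6371.0088 km) over all unordered pairs
of *sequence records*, so duplicated localities contribute zero-distance
pairs; averaging over unique localities is available via config. The
latitudinal range is an input column, not derived from occurrence
databases. Continuous covariates are z-scored (constants stored for
back-transformation); binary covariates stay 0/1 with "no" as reference.
Exact zeros in π are replaced by the shrinkage value (y·(n−1)+0.5)/n
evaluated at y = 0, i.e. 0.5/n (mode `sv_zeros`); the full transform
(`sv_all`) and a plain epsilon replacement are alternatives.

## Beta regression

The likelihood is the mean/precision parameterisation of the beta
distribution with a logit link for μ and a log link for φ (positivity; the
standard choice of the reference software). Fitting is damped Newton ascent
on the analytic gradient and Hessian, with Levenberg-style spectrum shifts
when the observed information is indefinite far from the optimum, falling
back to L-BFGS-B with three deterministically jittered restarts; a fit is
declared converged when the score sup-norm is ≤ 1e-6. Standard errors come
from the inverse observed information. The implementation agrees with an
independent generic-optimizer ML implementation to < 1e-4 in all
coefficients across random datasets (asserted in the test suite, which uses
that second implementation only as an oracle).

The family random intercept enters the mean submodel only. Its marginal
likelihood uses a Laplace approximation: per-family conditional modes are
independent one-dimensional concave problems solved by damped Newton
(warm-started between outer iterations), and the outer optimization runs
L-BFGS-B over (β, γ, log σ) with log σ bounded in [log 1e-6, log 10].
Variance estimates below (1e-3)² are flagged as boundary fits. AIC counts
the variance as one parameter.

Known numerical property: the ML dispersion estimate in beta regression is
biased upward in small samples, which surfaces as a small positive bias
(~0.07 at n = 128) in the **precision intercept**; slope coefficients and
the mean submodel are unbiased to within Monte-Carlo error. Bias-corrected
estimators are deliberately out of scope, so this property is documented
rather than patched, and the acceptance test asserts it stays modest.

Model selection fits {fixed}, {fixed+precision}, {fixed+RE},
{fixed+precision+RE} and ranks by AIC; non-convergent candidates are
reported but excluded from the winner. Pseudo-R² is the squared Pearson
correlation between logit(y) and the fitted mean linear predictor. VIFs are
1/(1−R²) from OLS of each predictor on the others (intercept included).
Bootstrap intervals are case (row) resampling with percentile 95% bounds;
replicates that fail to converge are excluded and counted (a warning fires
above 10%; at n = 128 the observed failure rate is zero, while very small
studies can produce degenerate resamples whose precision slope diverges —
those are excluded, not silently truncated). Replicate fits warm-start at
the full-data estimate. Effect curves vary one predictor across its
observed range with the others at their sample means (binary covariates at
their sample proportion), with delta-method or bootstrap-percentile bands.

## Spatial filtering

Species are reduced to the arithmetic centroid of their sequence
localities. The relative neighbourhood graph connects two centroids unless
a third is strictly closer to both (great-circle distances); exact
duplicate centroids are jittered by ~1e-6 degrees with a warning. Moran's I
follows the convention of the standard tree/stats implementation: the
binary symmetric matrix is row-normalised and the variance uses the
randomization (kurtosis-corrected) formula; the plain normal-theory
variance is available via `assumption="normality"`. (The implementation is
matched to that reference to 1e-12 on a frozen fixture.)

MEMs are eigenvectors of the doubly-centred weight matrix
(I − 11ᵀ/n) W (I − 11ᵀ/n) with |eigenvalue| > 1e-10, named MEM1.. in
descending eigenvalue order. On a chain graph the leading eigenvector is
the coarsest wave (exactly one sign change); it is not strictly monotone —
that property belongs to the Laplacian convention, which this package does
not use. When MEMs enter a regression they are rescaled to unit standard
deviation so their coefficients are comparable with the z-scored
covariates. Forward selection adds, at each step, the candidate whose
inclusion (via a caller-supplied refit) most reduces |I − E[I]| of the
residuals, stopping when the residual Moran p-value reaches α (default
0.05), when no candidate improves, or at a configurable cap (default 8).
All eigenvectors are candidates by default (negative-eigenvalue fine-scale
patterns included), with a positive-only option.

## Phylogenetic signal

Pagel's λ multiplies the off-diagonal entries of the Brownian covariance
built from shared root-to-tip path lengths. The mean and scale of the
multivariate normal are profiled analytically; λ is maximised by bounded
scalar search on [0, λ_max], where λ_max is the largest value keeping the
covariance positive definite (found by bisection, ≥ 1 for ultrametric
trees), and the endpoints {0, 1, λ_max} are checked explicitly so the
optimum never falls below those grid points. The p-value is a plain
likelihood-ratio χ²(1) against λ = 0 (the convention of the reference
implementation; a boundary-halved variant is available and the choice is
recorded). Species residuals attach to the family-level tree by family
means (default) or by expanding each family tip into a star polytomy with
branch ε = 1e-6 — neither mapping is canonical for species-level residuals
on a family-level tree, so both are provided and the choice is logged.

## Sensitivity analysis

For each species, m sequences are drawn with replacement (m = 2..10, 100
replicates each) and π recomputed; the replicate variance per (species, m)
is the plot data behind the minimum-sequence cutoff. The cutoff rerun keeps
species with n ≥ 4 (configurable) and refits the fixed+precision model with
the response set to the **median** resampled π per species; replicates use
each species' own n by default (drawing a fixed m is the documented
alternative — both conventions are defensible). The cutoff
itself stays a config choice; the module emits the variance-vs-m table
rather than auto-selecting.

## Synthetic studies

The generator emulates a realistic global centipede COI study: 128 species
in 13
non-empty families; sequences per species log-normally distributed around
~10 and clipped to [3, 68]; alignment lengths uniform on [465, 840] bp;
body sizes log-uniform on [8.5, 250] mm; maternal care prevalence 83/128
and vision 98/128; localities from 8 Gaussian clusters with latitudes
clipped to [−47°, 61°]; and generating coefficients of realistic magnitude
for mitochondrial diversity (mean submodel −3.061, −0.220, 0.212, −0.009, −0.248,
0.234, 0.437; precision 3.417, 0.228; spatial effects 0.199 on MEM13 and
−0.185 on MEM40 of the generated coordinate basis, rescaled to unit SD).
Alignments evolve on a star genealogy under Jukes–Cantor with branch length
t = −(3/8)·log(1 − 4π/3), so the expected pairwise difference equals the
target π exactly (targets at or above the 0.75 saturation bound are
rejected); the calibration is validated by Monte-Carlo in the tests. The
drawn beta response is the target π of each species' alignment, making the
full chain (alignment → π̂ → regression) coherent. All randomness flows
from one root seed through named substreams (table, tree, response,
alignments), recorded in the study manifest; a fixed config reproduces the
on-disk study byte-for-byte.

What the generator does **not** emulate: coalescent genealogies,
rate variation, selection, recombination, indels, geocoding error,
phylogenetically autocorrelated traits (unless a family effect is switched
on), or the uneven GenBank sampling of real archives. Passing tests
therefore demonstrate correctness of the estimators and the inference
chain under the stated generating model, not robustness to those
real-data features.

## Simulation design choices in the tests

The recovery/coverage study runs 200 response draws at n = 128 on one fixed
covariate table (conditional-on-design simulation) with B = 300 bootstrap
replicates. The model-selection power study generates data with a
precision slope of 0.5: an a-priori power calculation shows the default
generator value (0.228, z ≈ 1.9) gives an AIC detection probability of only
≈ 0.68 at n = 128 — too weak for a structure-recovery experiment — whereas
0.5 (noncentrality ≈ 17) makes the comparison well posed; the default
generator keeps 0.228 for study emulation. The spatial-filtering study
plants a unit-variance MEM3 signal with noise SD 0.3 over 60 centroids.
Problem sizes throughout (200/100-replicate studies, 30-tip trees, 1000
random alignments) are chosen to keep each experiment's Monte-Carlo error
well inside the asserted margins.

## Pipeline and reproducibility

`run_pipeline` executes nine stages in order (sequence statistics →
predictors → model selection → Moran test → MEM selection and refit →
diagnostics → bootstrap → phylogenetic signal → sensitivity rerun), writes
every artefact as plain text (CSV/JSON/Newick) and records a manifest with
the config hash, seed, package version and completed stages; a stage
failure aborts with the stage name, leaving earlier outputs on disk. MEM
selection refits use the fixed+precision structure (the final reported
model), regardless of whether the random-effect variant won the AIC step.
Residuals for the spatial and phylogenetic diagnostics are standardized
weighted residuals on the link scale by default (`residual_type` switches
to raw response residuals). Reports are regenerated deterministically from
stored outputs.

## Known limitations

* Mitochondrial π from a single locus; no nuclear comparison.
* The family random intercept uses a Laplace approximation; very small
  families make the variance estimate noisy, and the approximation error is
  not propagated into the fixed-effect standard errors.
* Forward MEM selection is greedy; the R spatial-ecology ecosystem offers
  several alternative selection criteria — the selection trace is exposed
  so results can be compared against any of them.
* Bootstrap intervals are percentile-based; no BCa correction.
* The RN graph is O(n³) and intended for the ~10²-species scale.
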