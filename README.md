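# macrodiv

Comparative macrogenetics of mitochondrial barcode diversity: what drives
the variation in intra-specific genetic diversity across species?

`macrodiv` estimates per-species nucleotide diversity (π) from aligned COI
sequence sets and models its variation across species with a
variable-precision beta regression, accounting for residual spatial
autocorrelation with Moran eigenvector maps, testing residual phylogenetic
signal with Pagel's λ, and probing the influence of per-species sample size
by resampling. It is aimed at researchers running species-level
("macrogenetic") comparative analyses of barcode diversity — for example
across a clade such as centipedes (Chilopoda), whose species differ in body
size, vision, maternal care and geographic distribution.

## The model

For each species *i* with diversity response `y_i ∈ (0, 1)`:

    y_i ~ Beta(μ_i φ_i, (1 − μ_i) φ_i)
    logit(μ_i) = x_iᵀ β          (traits, biogeography, optional MEMs)
    log(φ_i)   = z_iᵀ γ          (precision grows with number of sequences)

* **π estimation** — average per-site pairwise difference over an aligned
  sequence set; segregating sites (S) and parsimony-informative sites (PIS)
  are reported alongside. Gaps/ambiguities are handled by complete (default)
  or pairwise deletion.
* **Predictors** — body size, vision, maternal care, signed mean latitude
  of the sequenced localities, latitudinal range, and mean pairwise
  great-circle (haversine) distance among sequence localities; continuous
  covariates are z-scored. Exact zeros in the response are moved inside the
  unit interval with the standard shrinkage replacement (0 → 0.5/n).
* **Model selection** — four candidate structures (± precision submodel,
  ± Gaussian family random intercept via a Laplace approximation) compared
  by AIC.
* **Spatial filtering** — Moran's I of model residuals over a relative
  neighbourhood graph of species centroids (binary weights, row-normalised,
  randomization variance); Moran eigenvector maps (MEM) of the
  doubly-centred weight matrix are forward-selected until residual
  autocorrelation is non-significant.
* **Phylogenetic signal** — Pagel's λ of residuals on a family-level tree
  (species residuals averaged per family tip), with a likelihood-ratio test
  against λ = 0.
* **Sensitivity** — π is resampled with replacement at sample sizes 2–10
  (100 replicates) and the regression rerun on species with ≥ 4 sequences
  using median resampled diversity as the response.

A synthetic-data generator (`macrodiv.simulate`) produces complete studies
with known ground truth — alignments on a star genealogy under Jukes–Cantor
calibrated so the expected pairwise difference equals the target π, traits,
clustered coordinates, a family tree and a beta response — so that every
stage is testable without downloads.

## Worked example

```python
from macrodiv import SyntheticConfig, simulate_study, analyze, PipelineConfig

study = simulate_study(SyntheticConfig(seed=11))       # 128 species, 13 families
cfg = PipelineConfig(seed=11, bootstrap_B=200, sensitivity_reps=30)
result = analyze(study.species, study.alignments, study.coords, study.tree, cfg)
print(result.winner)
print(result.final_fit.summary())
```

prints the AIC winner `fixed+precision` and a coefficient table
(abridged):

```
Beta regression (logit mean link, log precision link)
  N = 128   log-likelihood = 228.5000   AIC = -438.9999
  pseudo R-squared = 0.3192   converged = True

Mean submodel
                              estimate       SE        z        p  boot 2.5% boot 97.5%
  mean:intercept               -3.2413   0.1690  -19.179   0.0000    -3.6022    -2.9553
  mean:mean_latitude           -0.2438   0.0642   -3.800   0.0001    -0.3884    -0.0817
  mean:body_size               -0.2711   0.0639   -4.243   0.0000    -0.4036    -0.1239
  mean:maternal_care            0.5190   0.1378    3.766   0.0002     0.2644     0.7875
Precision submodel
  precision:intercept           3.2109   0.1295   24.801   0.0000     3.0171     3.5946
  precision:n_sequences         0.3053   0.1380    2.213   0.0269     0.0564     0.7058
```

Diversity declines with body size and latitude, rises with maternal care,
and species sampled with more sequences are estimated more precisely
(positive precision slope) — the generating parameters used by the
simulator are recovered within their standard errors.

A command-line interface mirrors the library:
`macrodiv simulate|diversity|predictors|fit|spatial|phylosig|sensitivity|run-all|report`.

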