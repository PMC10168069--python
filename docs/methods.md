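# Methods

This note documents the models, conventions, and numerical choices behind
`funcstruct`, in the spirit of a package vignette: what each stage computes,
which defaults matter, what the synthetic generator does and does not emulate,
and where the design was genuinely open.

## 1. Traits

Seven continuous traits are handled. Three are derived per leaf from raw
measurements; four pass through:

| trait | definition | unit | default |
|-------|------------|------|---------|
| LT | leaf (or young succulent stem) thickness | mm | measured |
| PH | plant height | mm | measured |
| LS | leaf shape = length / width | — | derived |
| LA | leaf area | mm² | measured |
| LP | leaf perimeter | mm | measured |
| SLA | specific leaf area = area / dry mass | mm²·mg⁻¹ | derived |
| LDMC | dry matter content = dry mass / water-saturated mass | mg·mg⁻¹ | derived |

Records with non-positive dry mass, saturated mass, or width — or a dry mass
exceeding the saturated mass — cannot yield the ratios and are rejected with a
logged reason. Rehydration and drying are lab protocol, not computation; the
pipeline starts from measured masses. Stem-succulent taxa contribute shoot
measurements in the same fields (stem thickness as LT), with no special-casing.

**Aggregation.** Leaf values are averaged to species × plot means; the species
level is the *unweighted* mean of a species' plot means, so a species abundant
in many plots does not dominate its own trait value. The species × plot table
is retained for descriptive output, but all distance/SES machinery uses one
value per species — the randomization null reshuffles abundances, so trait
values must be a fixed species property.

**Pruning.** Pairs with |Pearson r| > 0.70 are reduced iteratively: the pair
member with the larger mean absolute correlation to all remaining traits is
dropped (constant columns first, since their correlation is undefined). On
leaf data the typical victim is LP, which tracks LA almost deterministically.

**Standardization.** Columns are centered and scaled to mean 0, SD 1 with the
*sample* SD (n−1), the convention of R's `scale`. The pool is the full species
set across all regions (global), matching a single pooled null-model species
pool; constant columns are a hard error naming the trait. Standardizing is
idempotent and rank-preserving; single-trait Gower distances are identical on
raw and z-scored values because the range normalization absorbs any affine
transform (property-tested).

## 2. Functional structure metrics

**Gower distance.** For one trait, `d(i,j) = |t_i − t_j| / range`; multi-trait
distances are the unweighted mean of per-trait distances. The range is taken
over the *global* species pool, not per plot, so distances are comparable
across plots and null replicates. A zero range is an error naming the trait.

**MPD.** Default is presence-only: the mean of `d(i,j)` over all unordered
pairs of distinct species present in the plot, `Σ_{i≠j} d_ij / (n(n−1))`.
The abundance-weighted variant (relative-abundance-product weights over
distinct pairs) is available but off by default, matching the default of the
standard null-model software for this metric. MPD is undefined for n < 2 and
is signalled, never silently zero.

**CWM.** `Σ_i p_i t_i` with relative covers `p_i = a_i / Σ a_i`. Covers are
normalized inside the metric, not at read time; this is the only
scale-invariant reading (plot cover sums are arbitrary in cover data), and a
raw-sum mode is deliberately not offered.

## 3. Null models and SES

Three randomization algorithms, all operating on the abundance matrix only —
trait values stay fixed to species:

* **independent swap** — repeated attempted swaps: two plots and two species
  are drawn; if their 2×2 submatrix has exactly two positive cells on a
  diagonal (a checkerboard), the positive values are exchanged across columns
  within their rows. Preserves every plot's richness, every species' occurrence
  frequency, each plot's total cover, and the multiset of positive values —
  exactly, in every replicate. Default effort is `max(1000, 10 × positive
  cells)` attempts per replicate; each replicate restarts from the observed
  matrix (independent replicates rather than one thinned chain). A matrix with
  no checkerboard (e.g., all cells positive) is returned unchanged with a
  warning.
* **frequency** — each species' abundance vector permuted across plots
  (preserves species frequencies, destroys plot richness).
* **richness** — each plot's abundance vector permuted across species
  (preserves plot richness, destroys species frequencies).

Replicate *r* draws from `default_rng([seed, r])`, so ensembles are bitwise
reproducible and parallelizable, and the first *k* replicates do not depend on
the ensemble size.

**Plot filter.** Only plots with more than two species (richness ≥ 3 by
default) enter the SES analysis; species never observed in retained plots are
dropped so the nulls draw on the realized pool.

**SES.** `(Obs − mean_null) / SD_null` with the sample-SD convention and the
observed value *not* included in the null distribution. One ensemble serves
both metrics and all traits. SES is recorded as missing — with a reason code,
never silently dropped — when the observed metric is undefined or the null SD
is zero; null SDs below `1e-10 × max(1, |mean_null|)` are treated as zero
because SDs at float-epsilon scale are summation-order noise, not variation
(a permuted plot containing the whole pool is the canonical case). Quantile
ranks/p-values from the null are deliberately not computed; downstream
analysis works on SES magnitudes.

Calibration: under neutral assembly scored with the richness-preserving null,
the observed community is an exact draw from the null distribution, so
per-plot SES has mean 0 and variance ≈ 1 (a t-like statistic with n_rep − 1
degrees of freedom). This is verified end-to-end in the acceptance tests.

## 4. Soil predictors and gradient models

**Screening** (three stages, full audit trail retained):

1. iterative correlation pruning at |r| > 0.70, as for traits;
2. PCA on the standardized survivors; variables are scored by their maximum
   absolute loading on the first two components, and those below the median
   score (configurable quantile) are cut, with the retained count capped at 6
   and floored at 2. The verbal rule this operationalizes — keep the variables
   that carry the two dominant soil axes — is not uniquely algorithmic; the
   quantile rule is one defensible choice and every cut is logged;
3. VIF pruning: the highest-VIF variable is dropped until all VIF < 5
   (threshold configurable; 5 is the common rule-of-thumb).

Soil variables are natural-log transformed before screening and modelling
(pH excepted — it is already a log-scale quantity). Non-positive values are a
hard error identifying plot and variable; no hidden +ε offset.

**Mixed models.** `SES ~ predictors + (1 | site)`, fitted by maximum
likelihood (not REML, because the compared nested models differ in fixed
effects; REML variances are reported for the full model only). Each predictor
is judged by a likelihood ratio test against the model without it (χ², 1 df).
Default inference mode is single-predictor (one model per soil variable,
matching per-gradient panel regressions); the joint multi-predictor mode is
also emitted.

Numerical care: a single optimizer routinely under-maximizes the reduced
model near the zero-variance boundary, which *inflates* LRT statistics. The
fitter therefore keeps the best log-likelihood across four optimizers plus the
OLS solution (the exact boundary optimum with zero site variance), and flags
convergence honestly. With this, the LRT's type-I rate over 200 simulated
null designs (16 sites × 3 plots) is 7.5%, matching R lme4's `anova()` on the
identical data to the last rejection. A constant response short-circuits to
zero coefficients and LRT 0. Sites with a single observation are allowed.

## 5. Synthetic data generator

The generator emulates a multi-site salt-marsh survey: 16 sites × 3 plots and
a 60-species pool by default.

* **Traits**: correlated latent normals mapped to field scales (lognormal;
  LDMC through a logistic onto (0,1)). The latent correlation matrix encodes
  leaf-economics structure — LA–LP 0.92 on the latent scale (≈0.85 after
  lognormal attenuation, so the perimeter trait is the one the pruning stage
  removes), SLA–LDMC −0.6, SLA–LT −0.5 (succulent leaves are thick with low
  dry matter content). Eigenvalues are clipped if a hand-specified matrix is
  not quite PSD.
* **Soil**: correlated normals at site level (SD 1.0) plus plot level
  (SD 0.3) on the log scale, exponentiated — a Gaussian-copula-style
  construction. The correlation matrix contains a collinear salinity block
  (Na–EC 0.9, Na–Mg 0.7, Na–K 0.6) and a fertility pair (N–OM 0.7), emulating
  the multicollinearity that motivates the predictor screen. pH is generated
  on its own (linear) scale around 7.8. Cover values are lognormal with
  median 5%, giving a mean positive cover ≈ 8.2%, the magnitude typical of
  cover surveys in open halophytic vegetation.
* **Assembly**: per-plot richness uniform on [4, 12]; species drawn without
  replacement — *neutral*: uniformly; *filtering*: with Gaussian niche weights
  `exp(−(z_s − μ_p)² · s² / 2)` where `z_s` is the species' latent value of the
  coupled trait, the plot optimum `μ_p` is `slope ×` the standardized log of
  the coupled soil variable, and `s` is `filtering_strength` (0 reduces
  exactly to neutral; the default coupling is LT ← Na with slope 1 and
  strength 2, i.e. niche width σ = 0.5 latent SD); *divergence*: greedy
  sequential draws weighted by (minimum mean latent distance to the already
  chosen)^strength — a transparent caricature of limiting similarity, not a
  determinantal process.

What the generator does **not** emulate: spatial autocorrelation within and
between sites, zonation (ordered belts along the gradient), species'
abundance–occupancy structure, cover sums constrained to ≤ 100%, measurement
error in traits, or missing data. A green calibration/power test therefore
establishes that the statistical chain is correct under a well-specified
assembly world, not that the pipeline is robust to every field pathology.

Fixture truth values (the `tiny` preset's expected MPD/CWM) come from an
independent brute-force script (`scripts/tiny_truth.py`), never from the
pipeline code.

## 6. Data handling conventions

* A species absent from a plot is abundance 0; cover data carry no
  "not recorded" distinction.
* Identifiers are opaque strings, matched exactly and case-sensitively.
* Duplicate (plot, species) records in long layout are an error, never summed.
* Writers emit CSV with a `# funcstruct v… seed=…` header comment; readers
  skip `#` lines.
* Mean cover is reported under both plausible averaging units (per positive
  record and per plot) because the field convention is ambiguous.

## 7. Known limitations

* The swap algorithm's attempted-swap effort is a heuristic; extremely dense
  or nearly-degenerate matrices may mix slowly, and the package warns when no
  swap fired. A formal mixing diagnostic is out of scope.
* LRT p-values rely on the χ²(1) asymptotics; with ~16 sites and a predictor
  that varies mostly between sites the realized type-I rate is ~7% rather
  than 5%. Small-sample corrections (Kenward–Roger/Satterthwaite) are not
  implemented.
* Only MPD and CWM are provided — no Rao's Q, FRic/FEve/FDiv, dendrogram FD,
  or phylogenetic distances — and no model averaging, spatial error
  structures, or random slopes in the gradient models.
* Categorical traits (life form, photosynthetic pathway, salt-tolerance
  classes) are out of scope; the Gower machinery here is for continuous
  traits.
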