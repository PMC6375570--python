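# Methods

## The scientific problem

Telomere length (TL) is already expressed in the zygote: each chromosome end
carries the telomere of the parental gamete that contributed it.  Parent-
offspring resemblance in TL therefore mixes two mechanisms — a classical
additive-genetic effect (genes that regulate telomere maintenance) and a
direct carry-over of the parental gamete's TL state, an epigenetic
inheritance of the phenotype itself.  Because sperm are produced throughout
life while oocytes are not, the carry-over route predicts that offspring TL
tracks the *father's* age (and his own TL trajectory) at conception.

Separating the two mechanisms needs longitudinal data: the same fathers
sampled across years, so that between-father differences (confounded with
genetics and selective disappearance) can be split from within-father change
(which cannot be genetic).  This package implements that inference chain for
longitudinal parent-offspring breeding tables, plus the gel densitometry
step that produces TL values in the first place.

## Within-subject centering

For a parental covariate `x` (age in years, or TL), each parent's rows are
decomposed as `x = mean_x + delta_x`, where `mean_x` is the parent's mean
over their *distinct breeding years* (each year counted once regardless of
brood size) and `delta_x` the row's deviation.  In a mixed model the
`mean_x` coefficient is the cross-sectional, between-parent effect and the
`delta_x` coefficient the longitudinal, within-parent effect.  Parents
sampled in a single year get `delta = 0`: they inform the between- but not
the within-effect and are retained.

Whether the per-parent mean should weight years or rows is ambiguous when
broods differ in size; year-level weighting is the default and row-level
weighting is available (`level="row"`), which makes the ambiguity testable.

## The mixed model

All models are Gaussian linear mixed models estimated by REML with

* crossed random intercepts (parent ID, gel ID, analysis year),
* nesting written as a composite factor (`father_id:nest_id`), and
* independent random slopes (zero intercept-slope correlation): the slope
  contribution is reported as a separate variance share, and the correlated
  variant is fragile at the small slope variances seen here.

The covariance is parameterised as `V = sigma2_e (I + sum_k gamma_k Z_k
Z_k')`; the fixed effects and residual variance are profiled out and the
profiled REML criterion is minimised over `log gamma_k` by L-BFGS-B with an
analytic gradient, two starts (variance ratios 1.0 and 0.05) to avoid
boundary traps, and convergence tolerance 1e-10 on the relative criterion.
Ratios at the lower bound are reported as variance 0 with a boundary flag.
Degrees of freedom are Satterthwaite, computed from the finite-difference
Hessian of the unprofiled REML criterion on the variance scale; components
whose contribution to response variance is below 1e-4 of the residual are
held at zero there, since the one-sided boundary would otherwise make the
Hessian singular.  If the Hessian still fails, the residual df `n - p` is
used and flagged.  The engine was verified against lme4/lmerTest
(coefficients, SEs, variance components, REML log-likelihood and df agree
to at least 4 significant figures on study-scale data) and against closed
forms (OLS; the balanced one-way ANOVA estimator `(MSB - MSW)/m`; a
brute-force profile search on tiny instances).  For a balanced one-way
design the Satterthwaite df of a group-level covariate is `k - 2` (with
intercept) and of the intercept alone `k - 1`; both are reproduced exactly.

## The preset battery

* **Parental age** (father/mother): `offspring_tl_bp ~ offspring_age_d +
  mean_age + delta_age`, random `parent/nest + gel`, random slope
  `delta_age | parent`.
* **Cross-foster**: covariates recoded to the *caring* father's age and the
  genetic-minus-foster age difference, which sum row-wise to the genetic
  father's age.  A conception-age effect loads both coefficients equally; a
  pure post-laying care effect loads only the caring-age term, leaving the
  age-difference near zero.  (A sometimes-quoted alternative expectation —
  equal magnitude, opposite sign — belongs to a different parameterisation
  and does not apply to this one; the simulated care-only scenario confirms
  the near-zero pattern.)  Random effects: genetic father/nest + gel +
  analysis year.
* **Parental TL** (father/mother): centred parental TL replaces the age
  terms.  Parental TL covariates enter in kb, so printed coefficients are
  bp-per-kb (divide by 1000 for the unit-free bp/bp slope).  Rows with
  missing parental TL are dropped listwise for these models only.  The
  same-year parental TL value in the table is used as "TL at conception";
  no interpolation to the laying date is attempted.

Derived statistics: the variance in offspring TL explained by a fixed term
is `Var((x - x_bar) beta_hat)` across rows; the **epigenetic fraction** is
`Var(delta path) / (Var(mean path) + Var(delta path))`, unit-free and
scale-invariant.  Random-effect percentages divide each component's
contribution (variance, times the mean squared covariate for slopes) by the
total of fixed + random + residual variance; `R^2` is conditional (all
modelled variance over total).  These conventions are stated because the
percentage denominators are not uniquely defined in the literature.
**Heritability** is the sum of the two single-parent offspring-on-parent
mean-TL slopes — a deliberately simple estimator with no shared-environment
correction; treat it as tentative.  The **partner attenuation** prediction
`r_mate_age x b_partner` says how much of a spurious own-age slope the
other parent's effect induces through age-assortative pairing.

## The synthetic-data generator

The generator emulates the study system: ~25 nest-box pairs followed for 12
seasons (~300 nests, ~700 sampled chicks of ~130-200 fathers), chicks
blood-sampled at 2-4 days, ~10% of nests cross-fostered by pairwise clutch
swaps within a season.  Offspring TL is built from an explicit generative
model (module docstring of `teloherit.simulate`) with defaults:

| parameter | default | meaning |
|---|---|---|
| `mu_tl0` | 7500 bp | mean adult TL at recruitment |
| `sd_tl0_genetic` | 550 bp | between-individual (additive) SD |
| `adult_attrition` | -87 bp/yr | within-adult TL change |
| `beta_paternal_age` | -56 bp/yr | within-father conception-age effect |
| `beta_offspring_age` | -32 bp/day | nestling sampling-age effect |
| `slope_father_mean` / `slope_mother_mean` | 0.26 / 0.46 | parent-offspring mean-TL slopes (bp/bp) |
| `carry_over` | 0 | fraction of the father's within-TL deviation transmitted |
| `beta_care_age` | 0 | post-laying care-age effect (exists to test the cross-foster logic) |
| `sd_nest`, `sd_gel`, `sd_resid` | 250, 300, 350 bp | noise layers |
| `adult_mortality`, `divorce_prob` | 0.35, 0.05 /yr | demography |

`carry_over` and `beta_paternal_age` are two generative routes to the same
within-father offspring-TL decline (`beta + carry_over x attrition`): a
direct conception-age effect versus transmission of the father's own
attrited gamete TL.  Cross-sectional data cannot distinguish them; the
default uses the direct route at the observed -56 bp/yr, and the switch is
exercised in tests.

Demographic choices worth knowing:

* **Age-assortative pairing.**  Founding pairs and all re-pairing match
  partners by age rank with Gaussian jitter (SD 0.7 yr).  With realistic
  turnover (annual mortality 0.35, breeder ages 1-13, mean ~3.5), purely
  random re-pairing caps the mate-age correlation near 0.1-0.69; assortative
  pairing reproduces the strong observed correlation (~0.75-0.77), which is
  the confound the centred analysis must untangle.  In reality most new
  pairs are two young recruits, so assortativity is the realistic choice.
  The correlation is monotone in pair-bond persistence in the random
  re-pairing regime (large jitter), which is how that property is tested.
* **Sampled brood size** is uniform on {2, 3} (mean 2.5), matching the
  ~2.4 sampled chicks per nest and ~700 offspring per ~300 nests of the
  study design.
* Chicks are spread over gels of 25 lanes at random; parental TL enters the
  table as latent truth plus year-to-year fluctuation (SD 100 bp), not as a
  gel measurement.
* Non-positive TL draws are redrawn; >1% redraws triggers a warning since
  it signals implausible parameters.
* True ages are used throughout; the field practice of assigning unringed
  adults a minimum age of 2 is *not* simulated (left-censoring is a noted
  possible extension).

What passing recovery tests show — and what they do not: the generator's
noise layers are Gaussian and its demography stationary, so unbiased
recovery here demonstrates the estimator chain is correct under the assumed
model; it cannot rule out biases from real-data features the generator
omits (selective disappearance correlated with TL, age-measurement
censoring, non-Gaussian measurement error, gel batch drift).

## TRF densitometry

Mean TL is computed from a 1-D lane intensity profile: calibration is a
monotone piecewise-cubic interpolant of log10(size) on migration distance
(exact at every ladder band, linear log-size extrapolation beyond, flagged);
the analysis window takes background as the lowest signal on the
short-fragment side of the smear peak, and the long-fragment limit where the
signal first drops below `Y = background + 0.10 (peak - background)`; mean
TL is the background-corrected intensity-weighted mean fragment size inside
the window (negative corrected intensities clipped to 0).  Raw corrected
intensity is used as the weight because the non-denaturing overhang probe
binds once per fragment, making intensity proportional to molar count; no
intensity/size correction is applied, and this choice is flagged rather
than asserted.  The synthetic-lane forward model maps sampled TLs through
the inverse calibration, bins, blurs, and adds a flat baseline plus a
gel-front signal rise; the front rise is what gives profiles their interior
background minimum just below the smear, as on real gels.  Recovery of a
known Normal(7200, 500^2) bp distribution is accurate to ~1%; the residual
error comes from log-scale binning/blur curvature and the window's
asymmetric truncation.

## Problem sizes and numerical choices

Replicate studies use the study-scale default (n ~ 700-760 offspring);
the packaged recovery study runs 100 replicates (single optimizer start per
replicate — replication already guards against the rare boundary trap) and
checks |bias| < 2 Monte-Carlo SE plus nominal 95% Wald coverage.  The
acceptance script summarises 40 replicates.  Large-n spot checks of the
generator use ~300 pairs (~9000 offspring).  Ties in the window rule resolve
to the first (long-side) crossing and the global short-side minimum;
degenerate inputs (flat profiles, rank-deficient fixed designs, fostered
rows with missing foster ages) raise informative errors rather than
returning numbers.

## Known limitations

* The heritability estimator ignores shared environment and assortative
  mating; the slope-sum equals narrow-sense heritability only under the
  usual parent-offspring regression assumptions.
* The epigenetic fraction is a *minimum* for the epigenetic contribution:
  between-father TL variance itself contains an epigenetic component, and
  sperm TL heterogeneity within ejaculates is unobserved.
* No generalized (non-Gaussian) models, no correlated random slopes, no
  pedigree/animal-model BLUP, no 2-D gel image segmentation.
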