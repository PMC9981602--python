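# Methods

## The experimental design being emulated

One exposure unit is a single host egg transferred to an artificial seed
of one of three flour qualities (90, 95, 100 % flour by dry mass) and,
at a scheduled age between 5 and 60 d after oviposition, exposed to a
mated female parasitoid for 24 h.  The reference design crosses 54
replicates × 56 daily ages × 3 qualities (9072 units).  Each host is
exposed exactly once; the outcome is binary (parasitized or not), and
the host's developmental stage at attack (L1–L4 instars, pupa, adult) is
observed — via molted head-capsule counts — only when it was parasitized,
because paralysis freezes development at the attack.

## Synthetic-data generator

The generator's defaults are the study conditions; they are not tuned
per analysis.

**Host development.**  A host crosses stage boundaries L1→L2 … P→A at
baseline ages (8, 12, 16, 21, 28) d on 100 % seeds, consistent with
~28 d egg-to-adult at full quality.  Poorer seeds stretch the whole
schedule multiplicatively: ×1.014 on 95 % seeds (1.4 % slower) and a
further ×1.22 on 90 % seeds (development approaching 60 d at the tail of
the noise distribution).  Each individual carries one lognormal factor
(sd 0.08 on the log scale) applied to all its boundaries — the simplest
positive-skew noise that can never reorder stages.  Dry biomass follows
a saturating curve toward a quality-scaled asymptote (3.0 mg at 100 %;
15 % smaller at 95 %, a further 46 % smaller at 90 %), frozen at
pupation.  Adults leave the seed 3 d after eclosion; an emerged host
records `host_emerged` and cannot be attacked.  Per-day host mortality
defaults to 0 for every quality (the source material notes higher
mortality on poor seeds but quantifies none; the rate is configurable).

**Parasitism.**  Attack success per 24-h exposure depends on stage:
{L1: 0.001, L2: 0.05, L3: 0.35, L4: 0.55, P: 0.35, A: 0.08},
quality-independent by default — efficacy rises through larval
development, peaks at L4, and is rare on L1 and on pre-emergence adults.
Superparasitism (≥ 2 eggs) occurs with probability 0.01 and flags the
host's parasitoid for exclusion from life-history analyses.
`ParasitismParams.with_log_hazard_ratio(stage, quality, lhr)` configures
a treatment effect on the grouped-time proportional-hazards scale:
p′ = 1 − (1 − p)^exp(lhr), i.e. the continuous hazard over the exposure
window is scaled by e^lhr.

**Parasitoid traits.**  Sex is Bernoulli in a logistic of host age
(even sex ratio near 22 d, females allocated to older/larger hosts);
female development takes 1 d longer than the 13 d male mean (gamma
noise, shape 80); hind tibia length ramps with host age and plateaus at
25 d with a +0.05 mm female offset and 0.04 mm noise; log emergence
mass is a per-sex linear function of log tibia.  Parasitized L1 hosts
never yield an adult parasitoid.

**Reproducibility.**  All draws for a dataset come from one seeded
generator in a fixed vectorized order over the design grid, so a config
plus seed reproduces every table byte for byte.

**What the generator does not emulate** — parasitoid behaviour and host
choice, egg-transfer/rearing details, within-host parasitoid
competition, and any fit of its parameters to the archived laboratory
data.  Passing tests therefore establish that the *analysis machinery*
is correct and calibrated under a known generative model, not that the
generator reproduces the real system's effect sizes.

## Stage distributions and imputation

`estimate_stage_distribution` turns reference development records into
relative stage frequencies per (quality, age) cell; rows sum to one
within 1e-12 and empty cells are simply absent.  The table conditions on
hosts still present (alive and inside the seed) at each age, matching
which exposure records reach the analysis — dead and emerged hosts are
excluded before imputation.  Imputation samples a stage for each
unparasitized host by inverse CDF on the fixed stage ordering (identical
seeds give identical assignments across platforms) and never touches an
observed stage or any other field.  A missing cell is a loud error
naming the (quality, age); an optional nearest-age fallback borrows the
closest age with data within the same quality, ties resolved to the
younger age.

## Per-stage Cox hazards

Each host contributes one row: time = age at exposure, event =
parasitized, right-censored at its age otherwise.  This treats the
cross-section of single 24-h exposures as survival data — the reading
supported by the survival-object formulation — rather than modelling the
exposure window explicitly.  Within each stage (L1 excluded), `Y ~ Q`
with treatment coding against the 100 % reference.

Ages are integers, so ties dominate; the Efron correction is the
default (matching the R survival machinery's default), Breslow is a
flag.  Because the single covariate is a 3-level factor and times take
at most 56 values, the partial likelihood is computed exactly from
per-(age, treatment) at-risk and event counts; Newton–Raphson with step
halving stops when the gradient's ∞-norm falls below 1e-8 (≤ 25
iterations), and |λ| > 10 or a group with no events flags a monotone
likelihood (non-converged, sign preserved).  The count path is verified
in tests against a per-subject brute-force implementation, a grid-search
maximizer and lifelines.

Two properties of this estimator matter for interpretation:

* **Development delay alone moves λ.**  If a treatment delays
  development, its hosts occupy any given stage at older ages; even with
  identical per-exposure attack probabilities this shifts the
  within-stage risk-set composition and produces λ < 0 for the delayed
  treatment.  The negative 90-vs-100 coefficients in the examples are
  exactly this effect, and the same mechanism operates in the original
  analysis design.
* **Heavy ties attenuate λ.**  With per-day attack probabilities as
  large as 0.55, the Efron-corrected estimate is substantially closer to
  zero than the grouped-time log hazard ratio that generated the data,
  and marginal-table imputation of censored hosts' stages dilutes it
  further: the parameter-recovery simulation (25 runs at n ≈ 5000)
  measures mean bootstrapped coefficients around −0.4 to −0.5 for a
  configured −0.7.  The estimator is consistent for a tie-attenuated
  functional, not for the generative log hazard ratio.

## Resampling inference

The "bootstrap" is over imputation randomness only — data rows are never
resampled: replicate b re-imputes every unparasitized host's stage and
refits all stage models; the observed effect `lambda_obs` is the mean of
the B replicate coefficients.  The null takes the treatment-agnostic
reading literally: permute quality labels across individuals (group
sizes preserved), then redraw *every* individual's stage — parasitized
included — from the cell of its permuted label and age, and refit.  A
pooled with-replacement label-resampling variant is available
(`null_scheme="pooled"`); neither is asserted to be the original
analysis's exact scheme.  p = max(2·min(r, 1−r), 1/B), where r is the
half-tie-counted fraction of null values below `lambda_obs`; Bonferroni
across the stage × contrast table; a single-imputation Wald p is
reported as a cross-check column only.

Because observed (parasitized) stages are kept in the bootstrap but
redrawn in the null, the null spread exceeds the observed-effect spread
in event-rich stages and falls short of it in the sparse adult stage;
under the exchangeable generator the pooled type-I error at nominal 0.05
measures slightly below 0.05 (0.047 over the 400 simulated
experiments of the calibration test).  This is a property of
the published scheme itself, kept deliberately.

Reference profile: B = 100 000.  Tests and the shipped CI profile use
B = 200, where the Monte-Carlo sd of a percentile p near 0.05 is about
0.015 and the smallest attainable p is 1/200.

## GLM / GAM model suite

Parametric fits are IRLS (statsmodels) with treatment coding; reference
levels are quality 100 %, stage L1 (L2 where L1 is excluded), sex male.
quasibinomial = binomial fit + Pearson ĉ; its candidate ranking uses
qAIC = −2ℓ/ĉ + 2(k+1) with ĉ taken from the most complex candidate,
k counting coefficients plus one for ĉ.  For GAMs k is the total
effective degrees of freedom (trace of the influence matrix).

Smooths are cubic B-splines on quantile-spaced knots (k = 10 basis
functions by default) with a second-order difference penalty — a
deliberately simple 1-D stand-in for thin-plate regression splines, so
criteria values are not expected to match mgcv's.  A `s(A, by=Q)` term
gets one basis block per level, zeroed off-level, sharing knots and one
smoothing parameter; each block carries a sum-to-zero constraint
(null-space reparameterization) so factor main effects stay
identifiable.  Smoothing parameters minimize GCV = n·D/(n − edf)² over a
log-spaced grid (coordinate descent across terms, penalties
trace-normalized); the penalty's null space is the constant + linear
coefficient sequences, so the infinite-penalty limit is a line (edf → 2
with an intercept).  Difference-of-smooths comparisons are taken on the
linear-predictor scale between prediction rows differing only in the
by-level — including the level's parametric offset — with pointwise 95 %
bands from the penalized ("Bayesian") coefficient covariance and a
Bonferroni z-multiplier across level pairs.

The shipped suite mirrors a stage- and age-structured regression table:
efficacy (quasibinomial `~ Q + S`; binomial `~ Q + s(A, by=Q)`), adult
production, emergence mass `~ T * G` (T = log hind tibia length, G =
sex), tibia and development time by stage and age, sex ratio, and host
biomass.  Host biomass is modelled as raw dry biomass with the
Gamma/inverse family: a Gamma response must be positive, which log
biomass of small larvae is not, so the log-response variant printed in
some summaries is not usable as stated.  Superparasitized hosts' wasps
are excluded from all life-history analyses (counts reported); efficacy
analyses keep every host.

## Pipeline, profiles and problem sizes

`run_full_analysis` chains generate → validate → impute → hazards +
resampling → model suite, writing delimited text plus a manifest with
the config hash, seed, version and per-stage replicate failure counts;
identical config and seed give byte-identical outputs.  The `default`
profile is the reference design (54 replicates, B = 100 000); the
`test` profile used throughout CI runs 10 replicates and B = 200 with a
7-point smoothing grid.  Simulation-based test scales — 400 experiments
at ~2000 hosts for calibration, 25 runs at ~5000 hosts for parameter
recovery, 50 runs for selection consistency — were chosen as the
smallest sizes at which the Monte-Carlo error of each checked quantity
is well below its assertion tolerance.

## Known limitations

* The cross-sectional Cox construction conflates development-rate
  effects with risk effects within stages (see above); λ is
  interpretable as "daily within-stage risk" only jointly with the
  stage-occupancy structure.
* The percentile test is mildly conservative for event-rich stages and
  anti-conservative for the sparse adult stage under the literal
  all-individuals stage-redraw null.
* Smoothing-parameter selection is a grid GCV, not REML; edf and AIC
  for GAMs are therefore approximations to the mgcv quantities.
* The generator draws each host independently; it does not model
  within-replicate correlation or day effects.
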