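# Methods

## Model

Plasma concentrations are strictly positive and mildly right-skewed, so each
response is modelled as gamma with an additive-scale mean. To keep effects
additive (directly interpretable as "mg/d of intake → mmol/l of plasma
change") while respecting the positivity of the gamma parameters, the
response is shifted: `y + c ~ Gamma(alpha, alpha/(mu + c))`, giving
`E[y] = mu` for any shift `c` large enough that `mu + c > 0` everywhere. The
shape is sampled on the log scale. The default shift is `2 × max |observed
concentration|`; note that under a shift the gamma is approximately
homoscedastic with sd `(mu+c)/sqrt(alpha)`, so the shape that corresponds to
a given noise level grows like `(mu+c)²` — the prior on `log alpha` is
therefore centred at the moment-matched value `log((ybar+c)²/var(y))` per
response (scale 2.0) rather than at a fixed constant. The pooled variance
overstates the observation noise (it includes real effect structure), so
this prior anchors from below and leaves room upward.

Effects form a nested two-level hierarchy: general effects `beta` (p
predictors × M responses), treatment-level deviations `g_l` for the three
dialysis modalities, and personal deviations `b_k` within treatment. The
deviations have covariance `Sigma = T C T'` with `T` diagonal sds and `C` a
full (p·M × p·M) correlation matrix — diagonal blocks correlate effects
within a response, off-diagonal blocks across responses, which is what makes
the seemingly-unrelated regressions joint. `C` is parameterized through its
Cholesky factor via canonical partial correlations (`tanh`-transformed
unconstrained values), under an LKJ(2) prior. In this parameterization the
LKJ density plus transform Jacobian separates per entry with coefficient
`(d-k)/2 + eta - 1` on `log(1 - tanh²y)` (k the 0-based column), which makes
prior evaluation and its gradient trivial and numerically stable at extreme
values (computed as `2 log sech`).

Model variants: `two_level` (full), `single_level` (no treatment layer; the
personal deviations are centred directly on the general effects), and
`separate_univariate` (block-diagonal correlations only, i.e. every response
has an independent effect covariance — the ablation of the multivariate
coupling).

## Estimation

Posterior sampling uses a No-U-Turn sampler written for this package
(recursive doubling with a slice variable, dual-averaging step-size
adaptation targeting 0.8 acceptance, diagonal mass matrix estimated from a
central warmup window, divergence detection at energy error 1000), driven by
analytic gradients of the full joint density: the gamma likelihood terms,
the non-centred hierarchy (`g = T L z`), and a vectorized backward pass
through the correlation-Cholesky transform. Gradients are verified against
finite differences in the test suite. Chains are seeded independently via
`SeedSequence`; given a fixed `SamplerConfig` the fit is bit-reproducible.

Default sampler settings are 4 chains × 3000 draws with 1000 warmup.
Replicated studies in the test suite and the acceptance script use reduced
settings (1–2 chains, 200–350 warmup, 250–400 draws, tree depth capped at
6, target acceptance 0.7) — chosen as the smallest runs whose ESS and R-hat
still support the quantities being read off (posterior means and 90%
intervals), which is what keeps full replication studies tractable on one
CPU.

### Predictor scaling, QR, and why predictors are *not* centred

Intakes span four orders of magnitude (micrograms to millilitres per day),
so predictors are scaled by their sample sd (binary covariates left as 0/1)
before a thin-QR reparameterization of the general-effect block:
`X = Q* R*` with `Q* = Q sqrt(n-1)`, `R* = R/sqrt(n-1)`, `beta = R*^-1
beta*`. Predictions are invariant to this reparameterization; coefficients
are reported per raw unit.

Columns are deliberately **not** centred. With coefficients that vary by
patient and only one shared intercept per response, centring changes the
model class: the patient-level contribution becomes `coef_k · (x - center)`,
which differs from the additive model by a patient-specific constant
`coef_k · center` that the model has no intercept to absorb. Empirically
this biased every per-patient slope (several standard errors off truth on
strongly identified synthetic data) while appearing to fit. Scale-only
standardization preserves the model class exactly; the QR still removes the
between-predictor correlation that motivates decorrelation.

An explicit per-response intercept is included by default (`intercept=False`
disables it). The shift constant is not an intercept: it reparameterizes
the gamma, while the intercept moves the mean.

### Priors

Auto-scaled by the response sample sd (the convention rstanarm uses), so one
set of multipliers serves responses living on mmol/l and g/l scales alike:
`beta* ~ N(0, 5 sd_m)`, intercept `~ N(ybar_m, 10 sd_m)`, effect sds
`~ half-N(sd_m)`, correlation Cholesky `~ LKJ(2)`, `log alpha` as above.

### Missing responses

Missing concentration cells are masked out of the likelihood during
fitting; afterwards they can be imputed with their posterior-mean predicted
concentration (personal level), flagged `"imputed"` in the table. Rows with
every response missing are left untouched — there is nothing within the row
to condition on.

## Personal graphs and recommendation

A patient's generative graph combines: intake Normals (sample mean, sample
sd with n−1; sd floored at 5% of the mean for single observations or
degenerate pairs — the graph needs positive uncertainty to simulate);
draw-aligned personal-level effect samples `beta + g_l + b_k`; the gamma
response nodes; and the patient's normal ranges (P-K 3.4–4.7 mmol/l and
fP-Pi 1.13–1.78 mmol/l for everyone; P-Alb 36–48 g/l to age 39, 36–45 for
40–69, 34–45 from 70). Intake Normals are truncated at zero when sampled.

The recommendation algorithm uses point estimates — by default the means of
the intake and effect distributions, or tail quantiles (`l_x`, `l_beta`) for
sensitivity analysis. It computes the baseline concentration `mu_q0` with
the queried nutrients' contributions removed, widens the sampling limits to
include the baseline when it starts outside the normal range (only the
sampling limits: the confidence of a proposal is always evaluated against
the original clinical ranges, so unreachable targets are honestly reported
as failures), draws proposals uniformly over the query box subject to the
point-estimate mean constraints, scores each proposal by the minimum across
responses of the gamma probability mass inside the range, and keeps those
above the confidence level. Constrained proposals are drawn by exact
rejection sampling from the box — for the one- or two-nutrient queries in
scope this is an exact sampler of the truncated uniform, and it is checked
against an exhaustive grid evaluation in the tests. The accepted cloud is
summarized by per-nutrient 2.5%/97.5% quantiles. Maximum per-response and
overall confidences are tracked and reported even when no proposal reaches
the threshold.

One printed step of the source algorithm assigns the upper sampling limit
with a `min`; the accompanying text requires the baseline to replace the
upper limit only when it exceeds it. This implementation follows the text
(`u_m = max(mu_q0, y_hi)`); a `min` there would make the limits degenerate
whenever the baseline sits inside the range.

## Evaluation

NRMSE normalizes the RMSE of predicted concentrations by the
patient-response mean observed concentration, then averages over responses
within patient and over patients. In-sample predictions use posterior means
at the observed intakes. Patient-level k-fold cross-validation (folds
stratified by treatment so no fold empties a modality — the treatment
effect would be unidentifiable) refits on the retained patients and
predicts held-out patients' personal deviations as `b = T_b L_b z` with `z`
the mode of the standard-normal prior times the patient's gamma likelihood,
all other parameters fixed at posterior means (L-BFGS with analytic
gradient; a draw-based conditional-mean option exists for comparison — the
two coincide in the Gaussian limit).

## Synthetic cohorts

The generator reproduces the structure the model assumes — and only that:
patients nested in treatment groups, patient-constant binary covariates,
per-patient latent intake means jittered across occasions, effects drawn
from `N(0, T C T')` at both levels, shifted-gamma responses. Defaults mirror
the study layout (K=37 in groups 21/9/7, n=2 occasions, 22 predictors with
Table-style units and ranges, M=3 responses) with effect magnitudes anchored
so a one-sd intake change moves a response by ~10%/sqrt(p) of its baseline,
deviation sds at 30% of that anchor, identity effect correlations (an
LKJ-style random correlation helper exists for correlated scenarios), and
gamma shape 50 per response (CV ≈ 14%). What it does **not** emulate:
realistic nutrient co-consumption correlations, food-record measurement
error, seasonal or visit effects, or informative missingness. Passing tests
therefore certify the inference machinery under the model's own
assumptions, not the model's adequacy for real dietary data.

Study-specific desk-scale choices in the tests: parameter recovery uses
K=12, n_obs=4, p=5, M=3 cohorts; the variant-ordering studies use cohorts
with pronounced treatment-level structure (`sigma_frac_g=0.5`,
`sigma_frac_b=0.2`) or strong cross-response effect correlation (0.8), the
regimes in which the corresponding model components matter; the held-out
prediction study uses large personal variation (`sigma_frac_b=0.7`) and a
high gamma shape (2500, CV 2%), matching the near-noiseless concentration
predictions the final fitted model exhibits, so that personal deviations
are the dominant signal to recover.

## Numerical choices and edge cases

- Rank-deficient designs raise naming the collinear column pair (detected by
  a near-zero `R` diagonal).
- `mu + c <= 0` at a proposal is rejected with `-inf` density (sampler) or
  resampled with a counted rejection (graph simulation), and raised with a
  "larger shift" hint in the generator.
- Correlation transforms are evaluated in log-space (`2 log sech`) and
  remain finite at extreme unconstrained values.
- The averaged Cholesky factor used in out-of-sample prediction is
  row-renormalized to keep unit-norm rows after posterior averaging.
- Quantile conventions: 90% credible intervals are 5%/95% posterior
  quantiles; recommendation windows are 2.5%/97.5% quantiles of the
  accepted samples.

## Known limitations

- Full correlation matrices at the treatment level are informed by only
  L=3 group draws; their posterior is prior-dominated at this design size.
- The NUTS implementation uses slice (not multinomial) trajectory sampling
  and a simple three-phase warmup; it is adequate for the model sizes here
  but less efficient than mature samplers on pathological geometries.
- Recommendation queries beyond two nutrients would need a smarter
  constrained sampler than rejection from the box.
- Out-of-sample deviation prediction uses a posterior-mean plug-in for
  `T_b L_b`; full uncertainty propagation would integrate over them.
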