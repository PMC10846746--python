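# renalrec

Personalized phosphorus and potassium intake recommendation for dialysis
patients, built on a hierarchical Bayesian multivariate model of nutrient
effects on plasma concentrations.

## The problem

Patients with end-stage renal disease on dialysis must keep plasma potassium
(P-K), fasting plasma phosphate (fP-Pi) and plasma albumin (P-Alb) inside
clinical target ranges, largely by adjusting their diet. Reactions to
nutrients differ between dialysis modalities (hospital hemodialysis, home
hemodialysis, peritoneal dialysis) and between individual patients, so a
single population-level dietary guideline fits nobody particularly well.
`renalrec` estimates nutrient effects at three nested levels — general,
dialysis-treatment, and personal — and inverts the fitted model to answer,
per patient: *which phosphorus and potassium intakes keep all plasma
concentrations inside this patient's normal ranges with at least, say, 90%
confidence?*

## The model

Each concentration m = 1..M is a gamma regression with an additive-scale
mean (a seemingly-unrelated-regressions system: no cross-equation terms, but
effects are correlated across responses through their hierarchical prior):

```
y_kmi + c ~ Gamma(alpha_m, alpha_m / (mu_kmi + c))
mu_kmi    = a_m + x_ki · (beta_·m + g_l(k),·m + b_k,·m)

g_l ~ N(0, T_g C_g T_g'),    b_k ~ N(0, T_b C_b T_b')
```

where `beta` are general effects, `g_l` treatment-level deviations, `b_k`
personal deviations within treatment, `T` diagonal matrices of effect
standard deviations, and `C` full (p·M × p·M) correlation matrices whose
diagonal blocks correlate effects within one response and whose off-diagonal
blocks correlate them across responses. The shift `c` keeps the gamma
support positive while the effects stay on the interpretable additive scale.
The general effects are estimated through a thin-QR reparameterization
(`X = Q* R*`, `beta = R*^-1 beta*`) after scaling predictors by their sample
sd. Sampling uses the package's own No-U-Turn sampler with analytic
gradients; arviz supplies ESS / R-hat diagnostics.

From a fitted posterior, each patient gets a generative graphical model:
intake nodes `X_kj ~ N(mean, sd²)` estimated from their food records, effect
nodes carrying draw-aligned personal-level posterior samples, and gamma
response nodes with the patient's (age-dependent) normal ranges. The
recommendation inverts this graph by multivariate acceptance sampling:
propose queried intakes uniformly (potassium up to 5800 mg/d, phosphorus up
to 2550 mg/d — population-maximum intakes), keep proposals whose predicted
concentration distributions put at least the required probability mass
inside **all** normal ranges, and report per-nutrient 2.5%/97.5% quantiles
of the accepted cloud as the recommended intake window.

The study's raw patient data are not deposited, so the package ships a
synthetic-cohort generator with exactly the structure the model assumes
(37 patients in groups of 21/9/7, two observations each, 22 predictors,
3 responses by default); all evaluation runs on such cohorts.

## Worked example

```python
import numpy as np
from renalrec import (toy_config, generate_cohort, ModelSpec, SamplerConfig,
                      fit, build_graph, NormalRanges, RecommendationQuery,
                      recommend)

cfg = toy_config(K=9, L=3, sizes=(4, 3, 2), n_obs=3, p=3, M=3, alpha=400.0,
                 seed=5, beta_seed=17)
data, truth = generate_cohort(cfg)
post = fit(data, ModelSpec(),
           SamplerConfig(chains=2, draws=500, warmup=500, seed=42,
                         max_treedepth=7))
print(post.diagnostics[["ess", "rhat"]].mean().round(3))

graph = build_graph(post, data, patient=0, ranges=NormalRanges.for_age(55))
query = RecommendationQuery(queried=["x0", "x1"],
                            proposal_bounds={"x0": (0.0, 12.0),
                                             "x1": (0.0, 12.0)},
                            S=4000, conf_level=0.8, seed=1)
res = recommend(graph, query)
print(res.succeeded, np.round(res.q_min, 2), np.round(res.q_max, 2),
      round(res.p_max, 3))
```

Output:

```
ess     83.788
rhat     1.026
dtype: float64
True [5.08 3.69] [6.72 4.34] 0.86
```

The first block says the chains mixed acceptably at these short desk-scale
settings (mean R-hat ≈ 1.03; production settings are 4 chains x 3000
draws). The second line reads: a recommendation was found
(`succeeded=True`); holding the rest of the diet at its current estimate,
nutrient `x0` may range over 5.1–6.7 units/d and `x1` over 3.7–4.3 units/d
while keeping every simulated concentration inside its target range with
>= 80% confidence; the best proposal reached confidence 0.86. On real
units these would be mg/d windows for potassium and phosphorus — the
analogue of a personalized dietary prescription. Patients whose targets
are unreachable by adjusting these two nutrients alone get
`succeeded=False` together with the per-response maximum confidences
(`p_m_max`), which name the concentration blocking the recommendation.

A command-line interface mirrors the library
(`renalrec simulate | fit | graphs | recommend | crossval | compare | run`).

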