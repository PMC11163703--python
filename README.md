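# movetypes

Person-oriented analysis of 24-hour movement behaviours in children and
adolescents: who are the *Workers*, *Drones* and *Queens* of the school-aged
day, and how is membership in these typologies associated with adiposity?

A day is a 4-part composition **x** = (MVPA, LPA, SB, sleep) of minutes
summing to 1440: moderate-to-vigorous physical activity, light physical
activity, sedentary behaviour and sleep carry only relative information, so
they are analysed on the simplex rather than in raw minutes.  `movetypes`
implements the full pipeline for this analysis:

1. **Accelerometry** — classify 5-s ENMO epochs (milli-g) with the cutpoints
   SB < 36 mg, LPA 36–200 mg, MVPA ≥ 201 mg (sleep from the sleep window),
   aggregate midnight-to-midnight days, apply wear-time validity rules
   (≥ 16 h/day; ≥ 3 school + ≥ 1 weekend valid days; wear in every 15-min
   period of the 24-h cycle) and average valid days per subject.
2. **Compositional coordinates** — express each composition in orthonormal
   isometric log-ratio (ilr) coordinates
   z_j = √((D−j)/(D−j+1)) · ln(x_j / g(x_{j+1..D})), mapping the simplex to
   R³; all bases are mutual rotations, so likelihood results are
   basis-invariant.
3. **Outlier screening** — robust Mahalanobis distances from a minimum
   covariance determinant fit, flagged beyond √χ²₃(0.975).
4. **Latent profile analysis** — a K-class Gaussian mixture on ilr
   coordinates with class means μ_k and one shared within-class covariance
   Σ, fitted by multi-start EM; model choice by BIC/AIC, relative entropy,
   the Lo–Mendell–Rubin / parametric-bootstrap likelihood-ratio test, and a
   minimum class share of 10%.
5. **Bias-adjusted distal outcomes (BCH)** — regression of ln(FM%), ln(FMI),
   ln(VAT) and the BMI z-score on typology membership with covariate
   adjustment, weighting an expanded subject-by-class dataset by
   w_i = p_i D⁻¹ (D the classification-error matrix) so that imperfect
   classification does not attenuate the estimates; subject-clustered
   sandwich standard errors.
6. **Missing data** — Little's MCAR test and chained-equation multiple
   imputation (predictive mean matching for continuous covariates, Bayesian
   logistic draws for binary ones; m = 5, 11 sweeps), pooled by Rubin's
   rules.
7. **Synthetic cohorts** — a generator whose presets reproduce the study
   conditions (children n = 374, two typologies mixed 80/20; adolescents
   n = 317, three typologies mixed 41/48/11; published component
   compositions, log-scale outcome effects and covariate margins), used by
   the tests and for end-to-end reproduction without any data download.

## Worked example

Simulate a children cohort and run the whole pipeline:

```sh
movetypes simulate --group children --seed 11 --out subjects.csv
movetypes run subjects.csv --group children --seed 11 --k-max 3 --out results
# -> selected 2 typologies: Workers, Queens
```

`results/report.json` then contains, among other tables (this exact run):

```text
profiles:  Workers share 0.83  (MVPA 64.3, LPA 312.6, SB 543.3, sleep 519.9 min/day)
           Queens  share 0.17  (MVPA 37.0, LPA 273.9, SB 594.7, sleep 534.5 min/day)
distal:    Queens vs Workers   ln FM%  B = 0.29  ->  1.33x higher FM%   (p < 0.001)
                               ln FMI  B = 0.53  ->  1.71x higher FMI   (p < 0.001)
                               ln VAT  B = 0.47  ->  1.60x higher VAT   (p < 0.001)
missingness: Little's MCAR p = 0.18 (deletion was MCAR by construction)
```

Read: the two-class solution splits the cohort into a large active typology
and a smaller inactive one; the inactive *Queens* carry substantially higher
total and central adiposity than *Workers* after covariate adjustment, with
multiplicative effects obtained by exponentiating the log-scale coefficients.
Estimates vary across simulated cohorts with ordinary sampling noise around
the generating values (Queens effects 0.32/0.36/0.51 on the log scale).

Each stage is equally usable as a library; see `movetypes.composition`,
`movetypes.lpa`, `movetypes.distal`, `movetypes.imputation`,
`movetypes.synthetic`, `movetypes.pipeline`.

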