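# icscore

Interval-coded integer score charts for clinical risk prediction.

Clinicians rarely use a logistic regression or an SVM at the bedside; they
use points systems: answer a handful of yes/no questions, add up small
integers, look the total up in a risk table. `icscore` learns such charts
directly from labelled patient data. Each covariate's effect is a step
function over automatically selected intervals; the fitted real-valued
effects are normalised and rounded into integer points, and a monotone link
maps the total score to an event probability. The audience is biostatisticians
and clinical-epidemiology researchers building decision-support
questionnaires from tabular cohort data.

## The model

For patient $i$ with covariates $x_{i}$, the classifier is additive over
variables $p$ and intervals $j$:

$$f(x_i) = \sum_{p}\sum_{j} w_{p,j}\, I\!\left(x_{ip} \in [\theta_{p,j}, \theta_{p,j+1})\right) + b,$$

with label $y_i \in \{-1,+1\}$ (event / no event). Training minimises the
hinge loss with a total-variation (fused-lasso) penalty on each variable's
interval coefficients,

$$\min_{w,b}\;\; \sum_i \max\bigl(0,\,1-y_i f(x_i)\bigr) \;+\; \gamma \sum_{p,j} u_{p,j}\,\lvert w_{p,j+1}-w_{p,j}\rvert ,$$

which fuses neighbouring intervals (the model chooses how many intervals
survive and where their boundaries lie) and removes variables entirely when
a whole block fuses to the reference level. The factors
$u_{p,j} = 1/(\lvert w_{p,j+1}-w_{p,j}\rvert + \varepsilon_c)$ are
re-estimated and the problem re-solved until the coefficients stabilise
(iteratively reweighted $\ell_1$), sharpening small spurious intervals away.
With unit factors the problem is an exact linear program; the default
pipeline adds a small quadratic term $\tfrac{r}{2}\lVert w\rVert^2$ solved
by an operator-splitting method, which makes the solution unique and the
coefficients graded rather than margin-quantised (see `docs/methods.md`).

Anchored fitted weights are divided by the smallest non-zero magnitude and
rounded to the nearest integer — the chart. A monotone (isotonic, optionally
kernel-smoothed) link fitted to the (score, outcome) pairs gives the
score-to-risk table. Trade-off $\gamma$ is chosen by stratified 10-fold
cross-validated AUC; $\varepsilon_c$ by "comparable performance, fewest
intervals" under 5-fold CV. Evaluation reports AUC with a bias-corrected
percentile bootstrap CI, Nagelkerke $R^2$, grouped calibration with the
predicted/observed ratio, and sensitivity / specificity / LR± / diagnostic
odds ratio at a sensitivity-constrained cutoff.

## Worked example

The package ships a published 10-variable adnexal-mass chart (age, lesion
diameter, solid/lesion ratio, papillations, papillation blood flow, wall
irregularity, acoustic shadows, color score, ascites, pouch-of-Douglas
fluid) together with its 16-row risk table and an example patient:

```python
from icscore import adnexal_fixture, score_patient
from icscore.presentation import render_questionnaire

chart, risk_table, patient, _, _ = adnexal_fixture()
print(score_patient(patient, chart))   # 27
print(risk_table.lookup(27))           # 0.96
print(render_questionnaire(chart, risk_table, format="text"))
```

The 56-year-old patient with a 133 mm lesion, solid/lesion ratio 0.74, more
than three papillations with blood flow, an irregular wall, color score 3
and 18 mm of free fluid collects 1+4+7+4+3+3+3+2 = 27 points, which the risk
table translates into a 0.96 probability of malignancy. The questionnaire
rendering begins:

```
Question                                               Points
Is age between 40 (included) and 60 years?              1
Is age 60 years or more (included)?                     3
Is lesion_diameter between 40 (included) and 75 mm?     1
Is lesion_diameter between 75 (included) and 95 mm?     3
...
Is acoustic_shadows present?                           -5
```

Fitting on your own data from the shell:

```sh
icscore simulate --n 2000 --seed 7 --out cohort.csv          # or any CSV
icscore fit --data cohort.csv --config variables.json \
            --out model.json --seed 7 --audit selection.csv
icscore render --model model.json --format text --bars chart.svg
icscore predict --model model.json --data newpatients.csv
icscore evaluate --model model.json --data cohort.csv --config variables.json
```

`variables.json` declares the outcome column and each covariate's kind
(continuous / categorical / binary); `model.json` bundles the chart, the
risk table, the link knots and fit metadata, and round-trips exactly.

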