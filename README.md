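# mnrm

Joint measurement of substantive traits and **response styles** from
Likert-type items with the multidimensional nominal response model (MNRM),
using fixed, user-chosen scoring functions.

Respondents differ not only in the constructs a questionnaire is meant to
measure but also in how they use the response scale: extreme responding
(ERS, a preference for the endpoint categories), midpoint responding (MRS),
and similar content-irrelevant tendencies. The traditional remedy — counting
endpoint or midpoint selections into a sum score — confounds style with
content: people who are genuinely very low or very high on the trait also
produce many endpoint responses. This package implements a model-based
alternative in which styles and traits are separate latent dimensions of one
item response model, plus the machinery to compare model-based scores with
the traditional sum-score composites.

## The model

For an item with categories $k = 0, \dots, K-1$ and latent traits
$\mathbf{x} = (x_1, \dots, x_D)$,

$$T(k \mid \mathbf{x}) = \frac{\exp\left(\sum_d a_d s_{kd} x_d + c_k\right)}
  {\sum_m \exp\left(\sum_d a_d s_{md} x_d + c_m\right)}$$

where $a_d$ is the item's slope on dimension $d$, $c_k$ a category intercept
($c_0 = 0$), and $s_{kd}$ a fixed **scoring function** value assigning
category $k$ its weight on dimension $d$ — e.g. $[0\,1\,2\,3\,4\,5\,6]$ for
an ordinal trait (the generalized-partial-credit convention),
$[1\,0\,0\,0\,0\,0\,1]$ for ERS, $[0\,0\,0\,1\,0\,0\,0]$ for MRS. The same
vectors that define recoded sum scores define the model, which is what makes
the two approaches directly comparable. Latent traits are standardized
multivariate normal with correlation matrix $R$.

The package provides:

- category response functions, pairwise logits, and parameterization
  conversions (overall-slope vs category-slope form, reference-category
  changes, affine rescalings of scoring functions);
- sum-score composites $v_d = \sum_j s_{j y_j d}$ by category recoding;
- Bock–Aitkin EM marginal-maximum-likelihood estimation of slopes,
  intercepts, and latent correlations over a rectangular quadrature grid,
  with AIC/BIC and likelihood-ratio comparisons;
- response-pattern EAP scores with posterior SDs;
- sum-score-to-EAP **translation tables** via a polytomous Lord–Wingersky
  recursion over collapsed (recoded) response functions, marginalizing
  nuisance dimensions by quadrature;
- a seeded simulator for style studies, and a score-comparison report.

## Worked example

Three 7-category quality-of-life items load on QOL (codes 0..6) and ERS
(endpoint indicator), latent correlation −0.18. Build the model, run the
summed-score recursion for ERS on a tiny 3 × 3 grid, and tabulate the
sum-score-to-EAP translation:

```python
import mnrm

wx = mnrm.worked_example()          # items, scoring functions, 3x3 grid
table = mnrm.translation_table(wx.model, wx.scoring, "ERS", wx.grid)
print(table.to_frame().round(3))
```

```
   v_ERS      p    EAP     SD
0    0.0  0.558 -0.340  0.776
1    1.0  0.292  0.081  0.577
2    2.0  0.106  0.829  0.989
3    3.0  0.045  1.742  0.671
```

A person endorsing no endpoints (`v_ERS = 0`, marginal probability 0.558)
gets an ERS score of −0.34 latent SD units; endorsing an endpoint on all
three items (probability 0.045) scores 1.74. `mnrm.score_by_sum(table, 2)`
then scores any person by lookup. The same fixtures drive
`mnrm worked-example` on the command line, which recomputes every
intermediate table (collapsed response functions, recursion steps,
marginalized kernels) and diffs them against stored references.

A full analysis runs through the CLI:

```sh
mnrm simulate --design design.json --seed 1 --out sim     # synthetic study
mnrm fit   --data sim_data.csv --config config.yaml --out fit
mnrm score --data sim_data.csv --params fit_parameters.csv \
           --config config.yaml --method pattern --out scores.csv
mnrm table --data sim_data.csv --params fit_parameters.csv \
           --config config.yaml --dimension ERS --out tables
mnrm compare --data sim_data.csv --params fit_parameters.csv \
           --config config.yaml --out report
```

where `config.yaml` names the dimensions:

```yaml
n_categories: 7
dimensions:
  - label: QOL
    scoring: trait
  - label: ERS
    scoring: ers
    role: style
```

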