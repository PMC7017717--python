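# Methods

## Model

The multidimensional nominal response model (MNRM) treats each item
response as a multinomial logit in the latent traits. For item $j$ with
categories $k = 0..K_j-1$,

$$T_j(k \mid \mathbf{x}) \propto \exp\Big(\sum_{d=1}^{D} a_{jd}\, s_{jkd}\, x_d + c_{jk}\Big),$$

with overall slopes $a_{jd}$, category intercepts $c_{jk}$ (anchor category
intercept fixed at 0), and *fixed* scoring-function codes $s_{jkd}$ chosen
by the analyst. The scoring functions carry the substantive meaning of each
dimension: ordinal codes $0..K-1$ for a trait make that dimension a
generalized-partial-credit-style trait; an endpoint indicator makes it
extreme response style; a midpoint indicator, midpoint response style.
Pairwise log-odds between categories $k$ and $k'$ are linear in each trait
with slope $a_d (s_{kd} - s_{k'd})$ exactly, which gives the model its
logistic-regression reading and implies *style neutrality*: a style
dimension whose codes agree for two categories (two non-endpoints, or the
two endpoints) contributes nothing to the choice between them.

Assumptions: responses are conditionally independent across items given
$\mathbf{x}$; traits are multivariate normal with means 0, variances 1, and
correlation matrix $R$ (scale fixing); scoring functions are known and
fixed, not estimated. Identification additionally requires, per item, that
the columns of $[\mathbf{1}\,|\,\mathbf{s}_1 \cdots \mathbf{s}_D]$ be
linearly independent — checked with a relative singular-value tolerance of
1e−8 — otherwise one dimension's codes are an affine combination of the
others (e.g. a non-endpoint indicator next to an endpoint indicator) and
slopes are not separable.

Equivalent parameterizations are supported rather than canonicalized:
category-slope (nominal) form $\tilde a_{kd} = a_d s_{kd}$, affine
rescalings of the codes with compensating slope changes (the $\pm 1$
endpoint coding halves the ERS slope), and first- vs last-category
referencing. Probabilities are invariant under all of these; tests assert
the invariance at 1e−12.

## Estimation

Bock–Aitkin EM-MML over a fixed rectangular quadrature grid. Weights are
the multivariate normal density with correlation $R$ at the nodes,
normalized; the nodes never move, so likelihoods are comparable across
iterations even as $R$ is updated.

- **E-step.** Per-person posterior node weights
  $\propto W(\mathbf{x}) \prod_j T_j(y_{ij} \mid \mathbf{x})$, accumulated
  into expected person counts per node and expected category counts
  $r_{jk}(\mathbf{x})$. Missing responses contribute a factor of 1.
- **M-step, items.** Each item's expected complete-data multinomial
  log-likelihood is maximized by Newton–Raphson with analytic gradient and
  Hessian in $(a_j, c_{j,1..K-1})$, with step-halving on any decrease.
  With the equal-slopes constraint (the sum-score-equivalent partial-credit
  setting) a joint Newton step over the shared slopes and all intercepts is
  used instead.
- **M-step, correlations.** $R$ is updated by directly maximizing the
  expected prior log-weight $\sum_{\mathbf{x}} \bar n(\mathbf{x}) \log
  W_R(\mathbf{x})$ over the off-diagonal entries (bounded scalar search for
  $D=2$, Nelder–Mead with a positive-definiteness barrier for $D \ge 3$),
  keeping the current $R$ unless a candidate strictly improves. A moment
  estimator from posterior cross-moments is *not* used because, with
  variances constrained to 1, it does not maximize this objective and can
  break the EM ascent property; the direct maximization keeps the marginal
  log-likelihood nondecreasing to numerical precision, which the tests
  assert on every fit.

Defaults: 21 nodes per dimension on $[-5, 5]$ for $D \le 2$, 15 for
$D \ge 3$ (estimation); convergence when successive log-likelihoods change
by less than 1e−5, at most 500 cycles; starting slopes 1.0 on the first
(substantive) dimension and 0.5 on style dimensions, starting intercepts
from smoothed log observed category proportions, starting $R = I$.
Scoring-time grids default to 49 nodes on $[-6, 6]$. The coarser estimation
grid is a deliberate accuracy/cost trade-off; a grid-refinement test checks
that doubling the node count moves the deviance by less than 0.5% on a
synthetic fit. Non-convergence sets a flag on the fit summary rather than
raising. Slope sign flips relative to the starting orientation (factor
reflection) are logged as warnings. Free-parameter counts are
$\sum_j (D + K_j - 1)$ plus $D(D-1)/2$ when $R$ is estimated; AIC
$= -2LL + 2\,np$, BIC $= -2LL + np \ln N$. Item-parameter standard errors
are not computed; score standard errors are.

## Scoring

**Pattern EAPs** are posterior means over the grid,
$\mathrm{EAP}_d = \sum_{\mathbf{x}} x_d L(\mathbf{y}\mid\mathbf{x})
W(\mathbf{x}) / \sum_{\mathbf{x}} L(\mathbf{y}\mid\mathbf{x})
W(\mathbf{x})$, with SDs from the posterior second moment. An all-missing
pattern returns the prior mean and SD, flagged.

**Sum-score EAPs** need the likelihood $L_d(v \mid \eta, \boldsymbol\xi)$
of each attainable sum score on the target dimension $\eta$ at every node.
Item categories are first collapsed by their recoded value,
$T_{jd}(m \mid \cdot) = \sum_{k: s_{jkd} = m} T_j(k \mid \cdot)$, then a
polytomous Lord–Wingersky recursion convolves items one at a time:
$L_j(v) = \sum_m T_{jd}(m) L_{j-1}(v - m)$. The recursion keys on exact
attainable sums via dictionary accumulation (merged at 1e−9), so arbitrary
real-valued codes work, not only integer offsets; distinct recoded values
are reported in ascending order. Multiplying by $W(\mathbf{x})$ and summing
over the nuisance nodes $\boldsymbol\xi$ gives the marginal kernel in
$\eta$, whose totals and weighted node moments are the table columns
$p(v)$, $E(\eta \mid v)$, and $V(\eta \mid v)$ (second-moment formula, no
resampling). Rows with $p(v) = 0$ are reported unattainable, never divided
by zero. When dimensions carry different scoring functions, one translation
run is performed per target dimension; the model itself never changes
between runs. An exhaustive-enumeration oracle (all $K^n$ patterns grouped
by sum score) verifies the recursion to 1e−12 on three-item models.
Reports round to 3 decimals; storage is full precision.

## Synthetic data

The generator draws traits from $N(\mathbf{0}, R)$ (Cholesky, seeded) and
responses from the categorical law $T(\cdot \mid \mathbf{x}_i)$. Default
design: $N = 1000$ persons, 20 seven-category items, one trait plus ERS,
$R = I$. Item parameters mimic the magnitudes seen in quality-of-life
style analyses: trait slopes uniform on $[0.3, 1.0]$ per unit code, style
slopes uniform on $[0.5, 1.5]$, and intercepts following a unimodal
profile peaking a little past the middle category (sine-shaped, maximum
$\approx 3$) with additive $N(0, 0.3^2)$ noise. Sub-streams for items,
traits, and responses are spawned deterministically from the design seed.

What the generator does *not* emulate: item content (no item-by-trait
interactions beyond the slopes), acquiescence or other styles unless
configured, person misfit, local dependence, or non-normal trait
distributions. Passing recovery tests therefore show that the estimator
recovers the generating process under the model's own assumptions — not
that real questionnaire data satisfy those assumptions.

Recovery conditions used by the tests: one seeded replicate with $N=2000$,
20 items, trait + ERS, $\rho = -0.18$, fit on the default 21-node grid
(slope RMSE < 0.15, latent-correlation error < 0.05, observed ≈ 0.07 and
0.026). The problem sizes keep a full suite run under a minute while
leaving the assertions far from their margins.

## Numerical choices and edge cases

- Softmax with max-subtraction throughout; no overflow for logits up to
  ~700.
- Missing responses are first-class: NaN in the response matrix, skipped in
  likelihoods, propagated (never zero-filled) in recoding, counted and
  flagged in sum scores; no imputation or proration anywhere.
- Grid weights must sum to 1 within 1e−12 by construction; translation
  probabilities sum to 1 within quadrature error (asserted at 1e−6).
- Parameter CSVs round-trip bit-exactly (`repr` of Python floats);
  human-readable rounding is presentation-only.
- The worked-example fixtures store item parameters to two decimals, the
  precision at which they are published; quantities derived from them are
  reproducible to about ±0.005 in probabilities, and regression tests
  assert agreement with the stored reference tables at 0.01 (2-dp tables)
  and 0.0025 (3-dp tables).

## Known limitations

- Fixed rectangular quadrature scales exponentially in $D$; the intended
  range is $D \le 3$ (trait + two styles). No adaptive quadrature or
  stochastic approximation.
- No item-parameter standard errors, no limited-information fit statistics,
  no multiple-group or bi-factor structures, no multiprocess/unfolding
  response mechanisms.
- The correlation update assumes the latent scale is fully fixed by unit
  variances; models identified some other way are out of scope.
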