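# Methods

## Model and estimation

`kinergm` fits exponential-family random graph models restricted to
dyad-independent terms. Under that restriction the likelihood factorises
over the $N = \binom{n}{2}$ unordered dyads, each an independent Bernoulli
trial with logistic link:

$$\log\frac{p_{ij}}{1-p_{ij}} = \theta_0 + \sum_k \theta_k z_{ijk} + \sum_\ell \lambda_\ell w_{ij\ell}.$$

Dyads are enumerated $(i, j)$ with $i < j$ in node-table
(first-appearance) order, which fixes the design-matrix layout. Non-edges
are observations with response 0, never missing data: a pair absent from
the IBD input is treated as $e_{ij} = 0$, and isolated nodes stay in the
dyad set. Thresholding is boundary-inclusive ($e_{ij} \ge c$).

Term families and their column counts over an attribute with $L$ levels:
`nodematch` (1), `nodematch_diff` ($L$), `nodemix` ($\binom{L}{2} + L - 1$,
one unordered level-pair cell being absorbed as the reference). The
default reference cell is the lexicographically smallest pair, overridable
(e.g. Adult F/Adult M for a joint sex/age attribute). Composite attributes
are formed explicitly with `NodeTable.with_combined`, never implicitly.
The nodematch column equals the sum of the attribute's nodematch_diff
columns, and the diff model is nested in the mix model; both facts are
enforced by tests.

Estimation is iteratively reweighted least squares (Newton-Raphson) with
step halving, converging when the score sup-norm drops below 1e-8, capped
at 100 iterations. Standard errors come from the inverse observed
information; Wald p-values are two-sided normal and deliberately
uncorrected for multiple testing (the summary table reports raw p, as is
conventional for these models — interpret marginal significances
accordingly). Coefficients diverging past |15| are flagged as separated
(the finite MLE does not exist for a cell observed as all-edges or
all-non-edges); their SE is infinite and p undefined, other coefficients
are still reported. Rank-deficient designs are rejected with the collinear
columns named, via a QR factorisation with a max(m,k)·eps·max|R_jj|
tolerance.

When many dyads share a covariate pattern the fitter can operate on
grouped binomial sufficient statistics (`group_design` + `fit_grouped`);
this is algebraically the same likelihood (no binomial coefficient, so the
log-likelihood equals the dyad-level one) and is what the simulation
experiments use internally. A test pins the grouped and dyad-level routes
to each other at 1e-10, and both to an independent GLM implementation.

## Effect sizes

The headline effect size is the fold-increase in connection probability
over the baseline cell, $\mathrm{logistic}(\theta_0 + \theta) /
\mathrm{logistic}(\theta_0)$, evaluated at the fitted intercept; the odds
ratio $e^\theta$ is also emitted. The probability fold is capped at
$1/\mathrm{logistic}(\theta_0)$, which matters when choosing generating
parameters for sparse, strongly clustered synthetic data (see the cohort
fixture below). As $\theta_0 \to -\infty$ the two scales coincide. At
$\theta_0 = -4$ the closed form gives 1.4085 at $\theta = 0.35$, 1.3415
at $\theta = 0.30$ and 1.2775 at $\theta = 0.25$ (the last reads as 1.27
or 1.28 depending on whether it is truncated or rounded to two decimals).

## Model selection

Candidates are fitted on the same dyad set and compared by BIC
($-2\ell + k\ln N$), with AIC and AICc also computed. $N$ is the dyad
count: each dyad is one observation, and dyads vastly outnumber parameters
even for modest networks, which is also why AICc is indistinguishable from
AIC here. Ties (within 1e-9) break toward smaller $k$, then candidate
order. A p-value baseline strategy is provided for comparison: backward
elimination from the largest candidate, repeatedly dropping the term block
whose smallest coefficient p-value is largest while it exceeds 0.05. The
exact elimination details are a design choice of this package; block
significance is judged by the block's best coefficient so that a mixing
term earns its keep if any cell is significant.

## Simulation machinery

`generate_attributes` allocates levels by deterministic floor quotas with
the remainder (at most one node per level) assigned by a seeded draw
weighted by fractional parts, then shuffles per attribute; exact
proportions therefore give exact counts, and distinct attributes are
uncorrelated by construction. `simulate_network` draws every dyad
independently. `expected_edges` evaluates $\sum_{i<j} p_{ij}$ exactly by
grouping nodes into joint attribute classes (cost scales with the number
of attribute patterns, not $n^2$), and `nodes_for_expected_edges` inverts
it by doubling-plus-bisection; expected edges are counted over unordered
dyads throughout.

The power and confusion experiments draw each replicate as one binomial
count per dyad covariate pattern rather than one Bernoulli per dyad. These
are the sufficient statistics of the fit, so the distribution of every
statistic computed from a replicate is exactly the same as under per-dyad
simulation; a consistency test compares the per-dyad simulator's mean edge
count against the closed-form expectation.

Randomness: every experiment takes one integer seed; replicate $r$ of
component $c$ uses `SeedSequence(seed, spawn_key=(c, r))`, so any single
replicate is reproducible in isolation.

### Confusion experiment

The default family spans the three homophily classes over a binary "sex"
and a three-level "site" attribute: M1 intercept-only, M2 +sexmatch, M3
+sitematch, M4 +differential sitematch, M5 +sitemix, M6 sexmatch+diff, M7
sexmatch+mix, at $n = 300$ and $\theta_0 = -4$. Single-parameter effects
default to 0.75. Multi-parameter truths are deliberately heterogeneous —
diff site (0.4, 0.8, 1.2); mix cells (A,B)=0.8, (A,C)=0.0, (B,B)=1.0,
(B,C)=0.3, (C,C)=1.4 relative to the within-A reference — because equal
within-level coefficients would make the differential model observationally
identical to simple homophily (and mixing to differential), so no
selection procedure could tell them apart; identifiability of each truth
within the family is a precondition of a meaningful confusion matrix. All
truths and the family itself are overridable.

With BIC's $\ln N \approx 10.7$ penalty per parameter, the probability
that a nested one-parameter extension beats a true smaller model is about
$P(\chi^2_1 > 10.7) \approx 0.001$ per replicate, so perfect diagonal
accuracy is the expected outcome at desk-scale replication but is not
mathematically guaranteed.

### Power and minimum detectable effects

Empirical power at $(\theta_0, \theta_1)$ is the fraction of replicates in
which the refitted match coefficient's Wald p-value is ≤ α (default 0.05).
The fitted model is the data-generating model — the coefficient is tested
directly, without a preceding selection step. Degenerate replicates (empty
or complete graphs) count as non-rejections and are reported separately
(conservative). Default 100 replicates per grid point; the calibration
checks in the acceptance suite use 200–1000.

The minimum-detectable-effect search sizes the network by inverting the
intercept-only expected edge count (at $\theta_0 = -4$, 500 expected edges
needs $n = 237$ and 10,000 needs $n = 1055$), then bisects over $\theta_1$
on a 0.01-resolution grid in $(0, 3]$ for the smallest value reaching the
target power, converting it to a probability fold at the baseline.
Monte-Carlo noise at the power boundary can perturb the bisection by a
grid step; the replicate counts used keep this within the tolerances
asserted.

## Synthetic cohort fixture

`make_avar_fixture` builds a reproducible 237-individual cohort across
four sites (HNJ, KFJ, KUP, RK; proportions 0.17/0.13/0.11/0.59), two
periods, sex and age classes (joint `sex_age` mixing attribute with
reference Adult F/Adult M), three burial orientations, and two grave-good
flags. The generating model combines strong differential site homophily
(folds 549/857/691/185), period homophily (5.16/9.17), sex/age mixing in
which adult-male pairs are strongly over-connected (6.62) and adult-female
pairs under-connected (0.26), an orientation match (2.86), and a
two-sided rare-item mixing effect (0.64/2.56), at baseline log-odds −9 —
chosen so the largest fold stays below the $1/\mathrm{logistic}(\theta_0)$
cap while the network stays sparse. The common-item ("buckle") flag is
generated but excluded from the model, providing a deliberately null
variable. The generating coefficient vector is returned so recovery can
be asserted; a test confirms each component is recovered within 3
Monte-Carlo SEs over 50 draws.

What the fixture does *not* emulate: real IBD networks violate dyad
independence (relatives of relatives tend to be related), IBD calling has
length-dependent false-negative rates, and attribute values can be missing
or uncertain. Passing tests on the fixture therefore validate the
estimator and selection machinery under the model's own assumptions, not
robustness to transitivity or measurement error in empirical data.
`simulate_pair_table` additionally emits continuous total-cM records
(related dyads at cutoff·(0.6 + Exp(1)), 1% background below 0.7·cutoff)
so that cutoff-sensitivity sweeps prune edges smoothly around the
threshold.

## Clustering and centrality

Louvain modularity clustering (resolution 1.0, seeded tie-breaking)
runs by default on the cM-weighted network; degree and betweenness
centrality are computed on the unweighted graph, betweenness
unnormalised, with a weighted variant (distance = 1/weight) behind a
flag. Both delegate to networkx.

## Problem sizes and defaults

The shipped experiments use the designs above at $n = 300$ (confusion,
power), $n = 237$ (500-edge MDE and cohort fixture) and $n = 1055$
(10,000-edge MDE), with 20–1000 replicates depending on the tightness of
the assertion; all counts are arguments. Calibration of the IBD cutoff
$c$ to a relatedness degree is out of scope — the two-block 12/16 cM
default encodes the convention for "approximately seventh-degree or
closer" but no calibration procedure is provided. Dyad-dependent ERGM
terms (triangles, degree terms) and MCMC maximum likelihood are
deliberately unsupported.
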