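# kinergm

Dyad-independent exponential-family random graph models (ERGMs) for
kinship networks built from genomic identity-by-descent (IBD) sharing.

Archaeogenetic studies increasingly reconstruct networks of biological
relatedness across cemeteries and regions: individuals are nodes, and an
edge records "sufficient" shared IBD (e.g. at least two segments ≥ 12 cM
and one ≥ 16 cM, roughly seventh-degree kin or closer). The scientific
question is rarely the network itself but *what drives its topology* — do
burial site, time period, sex, age class, or grave goods predict who is
related to whom, and by how much? `kinergm` answers this with network
regression: detection of significant drivers, quantified effect sizes, and
a simulation toolkit that tells you in advance whether your network is
large enough to detect the effects you care about.

## The model

Threshold a pairwise connectedness measure $e_{ij}$ (total cM, or segment
counts) at a cutoff $c$ to get an undirected simple graph with adjacency
$Y_{ij} = \mathbf{1}(e_{ij} \ge c)$. Each of the $\binom{n}{2}$ dyads is
then modelled as an independent Bernoulli trial with

$$\log\frac{p_{ij}}{1-p_{ij}} = \theta_0 + \sum_{k=1}^K \theta_k z_{ijk} + \sum_{\ell=1}^L \lambda_\ell w_{ij\ell},$$

where the $z_{ijk}$ are homophily/mixing indicators built from node
attributes — simple homophily (`nodematch`, one parameter), differential
homophily (`nodematch_diff`, one per level), attribute mixing (`nodemix`,
one per unordered level pair minus a reference cell) — and $w_{ij\ell}$
are optional dyad covariates. Restricting to dyad-independent terms keeps
the model a Bernoulli regression: fast, non-degenerate, and suitable for
sparse relatedness networks.

Candidate models are compared by BIC (penalty $k\ln N$ with $N$ the dyad
count), and effect sizes are reported as the fold-increase in connection
probability over the baseline cell,
$\mathrm{logistic}(\theta_0+\theta)/\mathrm{logistic}(\theta_0)$.
Simulation utilities quantify model-selection accuracy (confusion
matrices), the empirical power of coefficient tests, and the minimum
detectable fold as a function of expected network size.

## Worked example

```python
import kinergm as kg

# A reproducible synthetic 4-site, 237-individual cohort with known truth
nodes, spec, theta, net = kg.make_avar_fixture(seed=1)
res = kg.fit_model(kg.build_design(net, spec))
print(kg.format_table(kg.summary_table(res).head(8)))
```

```
variable            level   fold p_value type  significant
    site              HNJ 502.41  <1e-04 Diff         True
    site              KFJ 680.07  <1e-04 Diff         True
    site              KUP 737.60  <1e-04 Diff         True
    site               RK 172.61  <1e-04 Diff         True
  period            Early   4.80  <1e-04 Diff         True
  period      Middle/Late   9.24  <1e-04 Diff         True
 sex_age    AdultF/AdultF   0.30  <1e-04  Mix         True
 sex_age AdultF/SubadultF   0.96   0.775  Mix        False
```

Each row is one coefficient of the best-fitting model: two individuals
from site KFJ are ~680 times more likely to share an edge than the
baseline dyad, adult-female pairs are *less* related than adult
female/male pairs (fold 0.30 < 1, consistent with patrilocality and female
exogamy), and the adult-female/subadult-female cell is indistinguishable
from baseline. The generating folds of the fixture (549/857/691/185 for
the four sites, 6.62 for adult-male pairs, …) sit within simulation error
of these estimates.

Power analysis for a planned study:

```python
curve = kg.empirical_power([0.0, 0.25, 0.35], n=300, reps=200, seed=1)
for t, f, p in zip(curve.theta_grid, curve.fold, curve.power):
    print(f"theta1={t:.2f}  fold={f:.2f}  power={p:.3f}")
```

```
theta1=0.00  fold=1.00  power=0.045
theta1=0.25  fold=1.28  power=0.970
theta1=0.35  fold=1.41  power=1.000
```

At zero effect the rejection rate equals the 5% significance level; a
1.41-fold effect on a 300-node network is detected essentially always.

A command-line interface covers the same pipeline
(`kinergm build-net / fit / select / simulate / power / mde / confusion /
sensitivity / stats / fixture`), e.g.

```sh
kinergm build-net --pairs pairs.csv --nodes nodes.csv \
    --rule two-block:12,2,16,1 --out net.graphml
kinergm select --net net.graphml --family default7 --criterion bic --out sel.csv
```

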