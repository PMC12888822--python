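# Methods

## The problem

Multiplex immunofluorescence (mIF) panels count, for each tissue core, the
total number of cells in the tumor compartment and the number positive for
each marker combination defining an immune phenotype (T-cell, cytotoxic
T-cell, T-reg, ...). Relating these abundances to clinical covariates is
complicated by three features of the data: counts are over-dispersed
relative to binomial sampling, rare phenotypes are zero-inflated, and the
phenotypes are biologically nested along a differentiation pathway, so their
abundances are strongly dependent. `btime` models all phenotypes jointly,
with the dependence structure supplied by the differentiation tree, so that
inference for rare phenotypes can borrow strength from common ones.

## The hierarchical beta-binomial model

For cell type `i` in core `k` of subject `j` with covariates `X_j`:

```
Y_ijk ~ Binomial(N_jk, p_ij)
p_ij  ~ Beta(gamma_i * pi_ij, gamma_i * (1 - pi_ij))
logit(pi_ij) = beta0_i + sum_v beta_vi X_vj + S_ij
S_ij  ~ Normal(0, sigma_Si^2)
```

`gamma_i > 0` controls cell-type-specific over-dispersion (the implied
intra-class correlation is `1/(gamma_i + 1)`), and the subject random effect
`S_ij` is shared by all of a subject's cores. The random effect exists to
absorb within-subject correlation across repeated cores; by default
(`subject_effects="auto"`) it is included exactly when some subject
contributes more than one core. With one core per subject — the
simulation-study setting — `S` is unidentifiable against the beta-binomial
dispersion: the two variance components trade off freely, which inflates
slope credible intervals by roughly 15% and slows hyperparameter mixing
while leaving the likelihood unchanged, so the effect is dropped there.
Both behaviors can be forced with `subject_effects=True/False`. The latent `p` is integrated
out analytically by default, giving a beta-binomial likelihood per core;
`latent_p=True` samples it explicitly per (cell type, subject). The two
parameterizations coincide exactly when each subject contributes one core
(the simulation-study setting); with repeated cores the marginalized form
treats cores as conditionally independent given `S` while the latent form
shares one `p` per subject — both are supported, and equivalence on
one-core-per-subject data is covered by a test.

The coefficient vectors over the `m` cell types carry multivariate normal
priors `beta0 ~ MVN(0, T0)` and `beta_v ~ MVN(0, T1v)` whose covariance
encodes the tree:

* **unstructured** — `T ~ InvWishart(m + 2, I)`: no biological structure
  imposed, estimated freely (conjugate Gibbs update);
* **exponential decay** — `T = Sigma Delta Sigma` with
  `Delta_st = exp(-d_st / zeta)`, `d_st` the pathway distance between cell
  types, `zeta ~ Gamma(2, 1)` shared between `T0` and the slope
  covariances, and per-cell-type scales `sigma_m^2 ~ InvGamma(2, 1)` kept
  separate for intercepts and slopes;
* **tree** — `T_st` equals the root distance of the lowest common ancestor
  (LCA) of cell types `s` and `t`, ancestors taken inclusively; no free
  parameters;
* **scaled tree** — the LCA matrix times `lambda ~ Gamma(2, 1)`, one scalar
  per coefficient vector (intercepts and each slope get their own scale,
  the natural reading when one structural matrix must serve both);
* **multi-level tree** — `T = sum_l omega_l B^(l)` with `B^(l)[s, t] = 1`
  iff some node at pathway level `l` is an ancestor-or-self of both cell
  types, `omega_l ~ Gamma(2, 1)` per level and coefficient vector.

Tree-based structures support a **block** variant that zeroes covariance
between cell types on different branches (pairs whose only common ancestor
is the tree's root node). Matrices are symmetric PSD by construction; any
matrix whose smallest eigenvalue falls below `1e-8` (possible after block
masking) is repaired with diagonal jitter and a warning, never by
reordering cell types.

Remaining priors: `gamma_i ~ Gamma(0.01, 0.01)`,
`sigma_Si ~ half-Student-t(3, 0, 2.5)`. The screening families use
Student-t(3, 0, 2.5) intercepts, Normal(0, 5^2) slopes, Gamma(0.01, 0.01)
dispersions and Beta(1, 1) zero-inflation weights — portable equivalents of
the weakly informative defaults common in Bayesian regression software.
All are overridable through `MultiCellModelSpec`.

Continuous covariates are standardized (mean 0, SD 1) before fitting, with
the scaling recorded; binary covariates are coded 0/1. Cores with fewer
than 10 total tumor-compartment cells are excluded on load (configurable),
since they carry essentially no abundance information. No multiplicity
adjustment is applied across cell types: the joint prior is the only
sharing mechanism, and each cell type is reported with its own 95% CI.

## Posterior computation

Sampling uses an adaptive Metropolis-within-Gibbs scheme written directly
in numpy/scipy:

* coefficients: per-coordinate random-walk updates against the MVN prior
  (cached Cholesky factors of the current `T`);
* dispersions `gamma_i` and random-effect SDs: element-wise log-scale
  random walks, vectorized across cell types;
* random effects: simultaneous element-wise proposals for all
  (cell type, subject) pairs — valid because they are conditionally
  independent given the rest — with per-subject likelihood reductions;
* structure parameters: log-scale random walks (`zeta`, `lambda`,
  `omega`), conjugate inverse-Wishart draws for the unstructured case;
* two extra moves that break the posterior's known ridges: a joint
  `(log gamma_i, log sigma_Si)` step (with one core per subject the two
  dispersion sources trade off almost deterministically) and an
  ancillarity rescaling `(S_i, sigma_Si) -> (c S_i, c sigma_Si)` whose
  acceptance ratio carries the Jacobian `c^{n_subjects}` — the classic
  remedy for the funnel between a scale and its effects.

Proposal scales adapt by Robbins–Monro during a dedicated adaptation phase
(targets 0.44 element-wise, 0.234 for blocks) and are frozen afterwards,
keeping the retained chains Markovian. Chains are seeded independently
from the user seed; runs are bit-reproducible.

Convergence is monitored with the potential scale reduction factor
`sqrt(R_hat) = sqrt((((J-1)/J) W + B/J) / W)` computed per parameter from
4 chains by default (threshold 1.1), with the stricter split-chain variant
reported alongside. A fit whose worst parameter exceeds the threshold is
flagged, not discarded; the study runner excludes flagged fits from
aggregate tallies and reports their count. In short-schedule runs the flag
is usually driven by the dispersion hyperparameters (`sigma_S`, `gamma`) of
the rarest cell types, whose posteriors are intrinsically diffuse; the
slope chains that drive the reported intervals mix substantially faster.

Model comparison uses PSIS-LOO (generalized-Pareto smoothing of the upper
importance-weight tail, tail size `min(0.2 S, 3 sqrt(S))`, truncation at
the raw maximum) with WAIC as a cross-check; the pointwise unit is one
core-level count for a given cell type, so single-cell and joint models
are compared per cell type on identical observation sets. Pareto-k values
above 0.7 are recorded as warnings.

## The synthetic-data generator

The simulator emulates a two-group mIF experiment: `n_samples = 50`
samples split evenly between groups (`X = 0/1`), `m = 4` cell types
counted out of 500 cells, baseline mean proportions
(0.25, 0.10, 0.01, 0.005) spanning common to very rare, and a common
intra-class correlation `rho = 0.05` converted to Beta shapes by
`kappa = 1/rho - 1`, `alpha = mu kappa`, `beta = (1-mu) kappa`.
Cross-cell-type dependence comes from a Gaussian copula: latent
`Z ~ N(0, R_cop)` mapped through the normal CDF and the inverse Beta CDF,
with `R_cop = (1-s) I + s R_target` after projecting the target
correlation to the nearest PD correlation matrix (Higham alternating
projections, tolerance 1e-10). The default target correlation couples the
four cell types at 0.5–0.85; the default shrinkage is `s = 1` (full
target).

Group effects are local: a configured fraction of each group's samples
(0%, 20% or 60%; 20% of 25 is exactly 5 samples, 60% exactly 15) has all
four cell-type means shifted multiplicatively by +25% (affected `X = 1`)
or −25% (affected `X = 0`), selected uniformly without replacement. Shapes
are recomputed from the perturbed means with `kappa` fixed. Replicate
seeds derive deterministically from the master seed via a counter scheme
and are recorded in the output metadata.

The four simulated cell types are related by a four-level chain
M1 → M2 → M3 → M4 with unit edge distances and root distance 1 — the
natural pathway for strictly nested, strictly rarer sub-populations; the
distances, like all tree inputs, are user-assignable.

What the generator does *not* emulate: spatial structure within cores,
repeated cores per subject (each simulated sample is one subject's single
core), cell-type totals differing across markers, and explicit
zero-inflation (rare types produce abundant zeros through the BB tail
alone). Tests passing on these data therefore demonstrate calibration and
power of the estimators under the stated generative model, not robustness
to imaging artifacts or within-subject correlation misspecification — the
latter is exercised separately by fixtures with repeated cores.

## Study conditions and problem sizes

The full reference experiment is 100 replicates per perturbation level
with 4 chains of 40 000 iterations (10k adaptation, 10k burn-in, 20k
retained). The package's default simulation schedule is 4 chains ×
(1k adaptation, 1k burn-in, 2k retained), which the convergence
diagnostics support for these data sizes, and the bundled experiment
scripts run 20–25 replicates per level; both replicate count and schedule
are plain configuration (`ChainSchedule`, `ExperimentGrid`) with the full
schedule one line away. A heavy cohort preset
(4 × 202k iterations: 2k adaptation, 100k burn-in, 100k retained) is
provided for real-data analyses.

Tie-breaking in the highest-ELPD / narrowest-CI tallies favors the simpler
model (single-cell < unstructured < exponential decay < tree < scaled tree
< multi-level tree); ties are logged.

## Known limitations

* The sampler is random-walk based; for much larger panels (m >> 10) or
  many covariates a gradient-based sampler would mix faster.
* The exponential-decay kernel is assumed PD on the supplied tree metric;
  a tiny diagonal jitter guards extreme hyperparameter proposals.
* Zero-inflated likelihoods are available for single-cell-type screening
  but not in the joint model (a constant zero-inflation weight per cell
  type would be the natural extension).
* ELPD comparisons condition on the fitted latent structure; no
  moment-matching correction is applied when Pareto-k diagnostics exceed
  0.7 (they are reported instead).
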