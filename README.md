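# btime

Bayesian multi-cell-type beta-binomial models for tumor immune
microenvironment (TIME) cell-abundance data.

Multiplex immunofluorescence (mIF) experiments report, for each tissue
core, the total number of tumor-compartment cells and the number positive
for each marker combination defining an immune phenotype (e.g. CD3 →
T-cell, CD3+CD8+ → cytotoxic T-cell, CD3+CD8+CD69+ → recently activated
cytotoxic T-cell). Analysts want to know how these abundances relate to
clinical covariates — stage, age at diagnosis, treatment variables — but
the counts are over-dispersed, rare phenotypes are mostly zeros, subjects
contribute repeated cores, and the phenotypes are nested sub-populations
of one another. `btime` addresses all four at once with a joint Bayesian
hierarchical model, and is aimed at biostatisticians analyzing mIF / tissue
microarray panels.

## The model

For cell type $i$ in core $k$ of subject $j$:

$$Y_{ijk} \sim \mathrm{Bin}(N_{jk},\, p_{ij}), \qquad
p_{ij} \sim \mathrm{Beta}\!\big(\gamma_i \pi_{ij},\, \gamma_i (1-\pi_{ij})\big),$$

$$\mathrm{logit}(\pi_{ij}) = \beta_{0i} + \beta_{1i} X_j + S_{ij},
\qquad S_{ij} \sim N(0, \sigma_{S,i}^2),$$

with cell-type coefficient vectors tied together by multivariate normal
priors $\beta_0 \sim \mathrm{MVN}(v_0, T_0)$,
$\beta_1 \sim \mathrm{MVN}(v_1, T_1)$. Five constructions of $(T_0, T_1)$
are provided, from agnostic to fully pathway-informed:

| structure | covariance |
|---|---|
| `unstructured` | $T \sim \mathrm{InvWishart}(m+2, I)$ |
| `expdecay` | $T = \Sigma\,\Delta\,\Sigma$, $\ \Delta_{st} = e^{-d_{st}/\zeta}$ over pathway distances |
| `tree` | $T_{st} = $ root distance of the lowest common ancestor of $s, t$ |
| `scaled_tree` | $\lambda \cdot$ the LCA matrix, $\lambda \sim \Gamma(2,1)$ |
| `multilevel_tree` | $\sum_l \omega_l B^{(l)}$, per-level co-ancestry indicators |

Tree-based structures have a `block` variant forcing zero covariance
between cell types on different branches. An effect is *captured* when
the equal-tailed 95% credible interval for $\beta_{1i}$ excludes zero.
The package also ships the single-cell-type comparator, eight screening
count families (binomial, Poisson, beta-binomial, negative binomial and
their zero-inflated versions) ranked by PSIS-LOO ELPD, a Gaussian-copula
simulator for correlated beta-binomial counts, and Gelman–Rubin PSRF
convergence reporting. See `docs/methods.md` for priors, sampler design
and numerical details.

## Worked example

Simulate one replicate of the two-group experiment (50 samples, four cell
types of 500 cells each, 60% of each group locally perturbed by ±25%) and
fit the joint model with the scaled-tree prior:

```python
import btime
from btime.models import CountDataset, ChainSchedule, fit_multicell, MultiCellModelSpec
from btime.celltree import CovarianceStructure, simulation_tree

cfg = btime.SimConfig(perturb_fraction=0.6, seed=11)
data = btime.generate_dataset(cfg)
cd = CountDataset.from_frame(data.to_frame(),
                             cell_types=["M1", "M2", "M3", "M4"],
                             covariates=["group"])
spec = MultiCellModelSpec(structure=CovarianceStructure("scaled_tree"),
                          tree=simulation_tree())
fit = fit_multicell(spec, cd, schedule=ChainSchedule(4, 1000, 1000, 2000), seed=1)
print(fit.summary().to_string(index=False))
```

```
covariate cell_type     mean   median     lower    upper    width  significant     psrf
    group        M1 0.463798 0.464168  0.157567 0.753678 0.596111         True 1.009456
    group        M2 0.550700 0.556155  0.165806 0.913060 0.747253         True 1.006102
    group        M3 0.174003 0.182962 -0.494399 0.827230 1.321628        False 1.001592
    group        M4 0.008664 0.023568 -0.867301 0.855220 1.722520        False 1.004043
```

The group effect is detected for the two common cell types (M1, baseline
proportion 0.25; M2, 0.10): their 95% credible intervals exclude zero. For
the rare cell types (M3 at 1%, M4 at 0.5%) the intervals are wide and
include zero — at these abundances a ±25% shift in 60% of samples is
essentially undetectable with 25 samples per group, matching the behavior
of the reference experiment. The `psrf` column is the per-slope
Gelman–Rubin statistic (all well below the 1.1 threshold).

The same workflow is available from the shell:

```bash
btime simulate --reps 1 --perturb-fraction 0.6 --seed 11 --out sims/
btime fit --counts sims/replicate_000.csv --model scaled_tree \
      --covariate group --seed 1 --out summary.csv
btime study --grid grid.yaml --seed 1 --cache cache/ --out results/
```

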