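# fluxfoci

Integrated statistical analysis of radiation-induced metabolic shutdown and
DNA double-strand-break repair kinetics, built for biostatisticians and
radiation biologists who need the full chain — extracellular-flux
parameterization, multilevel Bayesian effect models, a hierarchical
binomial–beta model of gamma-H2A.X focus clearance, repair-kinetics distance
clustering, and linear models coupling repair to metabolism — as tested,
seeded, reusable code. Because the underlying study deposited no raw
microscopy or flux exports, the package ships first-class synthetic-data
generators that emulate the study's data structure and drive every test.

## The models

**Stress tests.** Per-well OCR/ECAR traces with injection phases yield basal
respiration, ATP production, proton leak, maximal respiration and spare
capacity (Mito Stress Test) and glycolysis, glycolytic capacity and
non-glycolytic acidification (Glycolysis Stress Test), RFU-normalized per
well; treatment effects are log2 fold changes of group means against matched
unirradiated controls.

**Metabolic effects.** Log parameters follow a multilevel normal model,
y = mu + a_cell + b_replicate(cell) + eps, with weakly informative priors;
cell-line deflections are summarized by posterior medians, 50%/95% highest
density intervals, and P⁻ = Pr(deflection < 0).

**Focus-count dynamics.** For nucleus i with A_i unit areas (0.1·Pixel² each)
at time t in replicate r:

    k_i ~ Binomial(A_i, p_{r,t}),   p_{r,t} ~ Beta(mean p_t, variance v_t),
    v_t ~ chi-square(k_t) truncated to the valid (unimodal) range,
    p_t ~ Uniform(0,1),  k_t ~ chi-square(2)

fitted per cell line by ensemble MCMC, checked by posterior predictive checks
and compared against pooled alternatives with PSIS-LOO. The five posterior
medians q = (p_0, p_0.5, p_2, p_6, p_24) form a repair vector; pairwise
Euclidean distances d_ij = ‖q_i − q_j‖ are hierarchically clustered, and
residual damage is the 24 h focus density as a percentage of the 0.5 h value.

**Coupling.** Focus probabilities interpolated to the metabolic grid
(0, 1, 6, 24 h) are regressed on log-metabolic parameters (Bayesian +
least-squares) per cell line; slope signs are called by HDI exclusion of zero.

Full model documentation: [docs/methods.md](docs/methods.md).

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from fluxfoci import (FociSimConfig, SamplerSettings, simulate_foci_dataset,
                      fit_foci_model, expected_foci)

cfg = FociSimConfig(p_curves={"A549like": (0.002, 0.030, 0.015, 0.005, 0.002)},
                    seed=7)
records = simulate_foci_dataset(cfg)          # 3 replicates x 80 nuclei x 5 times
post = fit_foci_model(records, SamplerSettings(chains=2, steps=1500, seed=13))
print(expected_foci(post, area_units=400).round(2))
```

prints

```
   time_h  median  cri95_lo  cri95_hi
0     0.0    0.69      0.32      1.36
1     0.5   12.92     11.16     14.86
2     2.0    8.04      5.15     13.36
3     6.0    1.81      1.25      2.54
4    24.0    0.95      0.70      1.26
```

the expected gamma-H2A.X focus count for a median-sized nucleus (400 unit
areas) with its 95% credible interval: ~0.7 foci of background damage, a peak
of ~13 foci 30 min after 3 Gy, and clearance back toward baseline by 24 h —
the truth used by the generator (400 × p_t = 0.8, 12, 6, 2, 0.8) lies inside
every interval.

The same analysis end-to-end, from a shell:

```sh
fluxfoci run-all --outdir demo_out --seed 1
```

writes the simulated tables, per-well parameters, fold changes, GLM effect
summaries, foci posteriors with PPC and LOO reports, the clustered distance
matrix and heatmap, residual damage, the coupling panel, and a seed-stamped
`report.md`. Each stage is also available as its own subcommand
(`simulate`, `flux-params`, `fold-change`, `glm`, `foci-fit`, `ppc`, `loo`,
`distances`, `coupling`, `schema`).

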