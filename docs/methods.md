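# Methods

`fluxfoci` reimplements, as a tested pipeline on synthetic data, an integrated
statistical analysis of how ionizing radiation (a single 3 Gy dose) transiently
shuts down cellular energy metabolism and how that couples to the clearance of
DNA double-strand breaks, measured as gamma-H2A.X foci. This note documents the
models, the choices made where the design was open, and what the synthetic data
do and do not establish.

## Stress-test parameterization (`flux_metrics`)

Extracellular-flux plates record oxygen consumption rate (OCR, pmol O2/min) and
extracellular acidification rate (ECAR, mpH/min) over measurement cycles
separated by inhibitor injections. Parameters follow the standard kit
definitions (Mito Stress Test: last basal cycle, minimum oligomycin cycle,
maximum FCCP cycle, minimum rotenone/antimycin-A cycle; Glycolysis Stress Test:
last glucose-free baseline cycle, maximum glucose and oligomycin cycles).
Vendor software versions differ on last-cycle vs phase-mean referencing, so
`cycle_stat="mean"` switches every selector to the per-phase mean. Parameters
are normalized per well by Hoechst fluorescence (RFU) as a cell-number proxy.
Group contrasts are log2 of the ratio of group means (not the mean of per-well
ratios), matching a presentation of mean values over n = 8-16 wells. Negative
derived parameters are retained and logged, never clipped; a fold change
against a non-positive group mean is an error rather than a NaN.

## Multilevel GLM of log-metabolic parameters (`metabolic_glm`)

Log-transformed parameters are modeled with normal distributions at all
levels: an overall mean, cell-line deflections, and replicate deflections
nested inside cell line (plus additive time deflections in the time-course
variant). Priors are weakly informative: Normal(mean(y), 10 sd(y)) on the
grand mean and HalfNormal(2.5 sd(y)) on every group-level and residual scale
(`prior_scale` configurable). Deflections are reported relative to the grand
mean by sum-to-zero adjustment at summary time, summarized by the posterior
median, 50%/95% highest-density intervals, and P-minus, the posterior
probability of a negative deflection. If no cell line has two replicates the
nested level is dropped with a logged notice. Model fit is checked by
posterior predictive checks on the overall mean, sd and per-cell-line means.

The HDI is computed by a sliding window over sorted draws (narrowest window
holding ceil(mass n) draws, ties toward the lower bound), which assumes a
unimodal marginal; `mass = 1` degenerates to the min-max range.

## Hierarchical model of focus-count dynamics (`foci_dynamics`)

Counts of gamma-H2A.X foci per nucleus are treated as binomial: the nuclear
area is divided into unit areas of 0.1 Pixel^2 — a unit small enough that the
per-unit focus probability lies safely inside (0, 1) — and the count k_i of a
nucleus with A_i unit areas is Binomial(A_i, p_{r,t}) for its replicate r and
time t. Replicate probabilities follow a beta with time-dependent mean p_t
(the replicate-overarching focus probability) and variance v_t; v_t is given
a chi-square(k_t) model truncated to the admissible range, with chi-square(2)
priors on the top-level positive parameters and Uniform(0,1) on p_t. Each
cell line is fitted separately; t = 0 (unirradiated baseline) is a time level
of the same model, giving the five-point repair vector at t = 0, 0.5, 2, 6,
24 h.

Two numerical decisions deserve emphasis:

* **Unimodal truncation.** The admissible variance range is capped at
  v_t < p_t(1-p_t) m/(1+m), m = min(p_t, 1-p_t), the largest variance for
  which both beta shape parameters exceed 1. Without this cap the
  mean/variance beta admits U-shaped densities whose value diverges as a
  replicate probability approaches 0; a single replicate with near-zero
  counts then drags the posterior into that regime and the *mean* p_t becomes
  unidentified (a converged reference run on all-zero data gave a p_t
  posterior median of ~0.09 under the uncapped model, versus ~1e-5 with the
  cap). U-shaped replicate distributions would also contradict the unit-area
  construction, which exists precisely to keep probabilities interior.
  A variant with a free chi-square(2) scale on the variance
  (`variance_model="scaled_chi2"`) is retained for comparison but documented
  as unidentified near boundary data.
* **Continuous k_t.** The degrees of freedom are treated as a continuous
  positive parameter, time-specific by default (`kt_shared=True` shares one
  k across times).

Sampling is ensemble MCMC (emcee) with differential-evolution and snooker
moves in unconstrained coordinates (logit for probabilities and the variance
fraction, log for scales), two independent ensembles, and data-informed
initialization at empirical densities clipped to [1e-6, 1-1e-6] with
per-walker jitter. The stretch move was rejected after showing persistent
between-ensemble disagreement on this posterior. Rank-normalized R-hat is
computed per p_t across ensembles; R-hat > 1.05 sets a validity flag that is
carried into every downstream summary rather than failing silently.

Model checking: posterior predictive checks on per-time mean counts,
variance/mean ratios and the maximum count; simulation-based calibration of
p_t (uniformity of rank statistics under prior-drawn data); and predictive
comparison against a replicate-pooled beta-binomial and a fully pooled
binomial by PSIS-LOO (pointwise conditional log-likelihoods retained at up to
2000 thinned draws; a preference is declared only when |elpd difference| >
2 se, and >10% of Pareto-k diagnostics above 0.7 raises a warning).

## Repair comparison (`repair_compare`)

Each cell line's repair vector q collects the five posterior medians of p_t.
Pairwise Euclidean distances d_ij = ||q_i - q_j|| are computed once per pair
(exact symmetry) and clustered agglomeratively for the heatmap; the linkage
criterion is not dictated by the analysis, so average linkage is the default
with single/complete/ward configurable (ward on precomputed distances is
heuristic). Distances use point summaries to match the single-heatmap
presentation; propagating posterior uncertainty through the distance is a
possible extension, deliberately off by default. Residual damage is
100 x (mean focus density at 24 h)/(mean density at 0.5 h) per cell line and
replicate, where density is foci_count/area_units per nucleus.

## Coupling of repair to metabolism (`coupling_linmod`)

Focus probabilities are interpolated from the repair grid to the metabolic
grid (0, 1, 6, 24 h); the 1 h value interpolates linearly in time between
0.5 h and 2 h (weight 1/3), the minimal assumption for an unspecified
interpolant (log-time interpolation is available). For each cell line and
metabolic parameter a Bayesian simple linear regression of focus probability
(response) on the log-metabolic parameter (predictor) is fitted on the four
paired points with weakly informative priors (Normal(0, 10 sd(y)/sd(x)) on
the slope), alongside the ordinary least-squares line used for plotting.
Four points cannot support strong inference, so the slope-sign report relies
on whether the 95% HDI excludes zero, not on point estimates.

## Synthetic data (`synthdata`)

The generators emulate the study's data structure, not its raw data (the
paper's microscopy and flux exports are not deposited):

* **Foci tables**: 3 biological replicates x 80 nuclei per time at t = 0,
  0.5, 2, 6, 24 h; per-(cell line, replicate, time) probabilities drawn from
  a beta with concentration phi = 2000 around the true curve, giving
  replicate CVs of focus density of roughly 10-50% over the realistic range
  p in [0.002, 0.03] — the replicate variability a microscopist would call
  typical. Much smaller concentrations make the generative beta itself
  U-shaped at low p (entire replicates with zero foci), which is not a
  credible experiment. Nuclear areas are discretized log-normal (median 400
  unit areas, log-sd 0.35); the real area distribution is not reported, so
  these are configurable placeholders.
* **Flux plates**: 3 cycles per injection phase, 12 wells per condition split
  over 2 experiments with a small batch factor (CV 5%), multiplicative
  log-normal measurement noise (CV 8%) and log-normal RFU. Irradiation acts
  multiplicatively on the whole trace with separate schedules for the
  mitochondrial arm (shutdown to 0.40 of control at 1 h, recovery to 0.70 at
  6 h and 0.85 at 24 h — incomplete) and the glycolytic arm (0.50 at 1 h,
  essentially complete recovery by 6 h), reproducing the qualitative
  shutdown/recovery pattern.
* **Coupled study**: a shared latent recovery trajectory (the mitochondrial
  response schedule) drives both arms so that the true relation between focus
  probability and log basal respiration is exactly linear with a configured
  slope; the 0.5 h and 2 h points are placed on the local linear-in-time
  segment through the 1 h value so that interpolation back to the metabolic
  grid is exact. True curves, slopes and intercepts are recorded in a
  metadata sidecar for recovery tests.

Randomness is split per (cell line, replicate, time) or per (condition, well)
with numpy seed sequences, so enlarging a study never perturbs existing
draws.

What passing tests show — and do not. Parameter recovery, LOO discrimination
and coupling recovery on these generators demonstrate that the estimators are
correctly implemented and calibrated *under the assumed data-generating
structure*. Real microscopy adds segmentation errors, focus-merging at early
times, cell-cycle heterogeneity and area-dependent detection efficiency;
real flux plates add edge effects, injection artifacts and drifting baselines.
None of these are emulated, so passing tests certify the statistics, not
robustness to those artifacts.

## Problem sizes and determinism

Default sampler sizes (2 ensembles; 1500 steps for the foci model, 800-1000
for the GLM, 2000+ for the 3-parameter coupling model; walkers about twice
the parameter count) were chosen as the smallest runs that hold
rank-normalized R-hat near 1.01 on study-scale data; a single foci-model fit
takes a few seconds on one CPU, and the full demo pipeline runs in under a
minute. All randomness — generators, samplers, posterior-predictive draws —
derives from explicit seeds, and the end-to-end pipeline is byte-reproducible
for a fixed configuration and seed.

## Known limitations

* The foci model's marginal posterior for p_t depends on the unimodality
  restriction near boundary data; fully boundary-dominated data (every
  replicate zero) identify p_t only up to "small".
* Ensemble R-hat pools walkers within an ensemble, which can understate
  within-ensemble autocorrelation; two independent ensembles and the
  reported ESS mitigate but do not eliminate this.
* The coupling analysis inherits the four-point design of the study; its
  posteriors are prior-sensitive by construction and only slope signs are
  reported as findings.
* Classical ANOVA/t-test analyses and image-derived focus counting are out
  of scope; foci counts are consumed as tabular input.
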