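# Methods

## Model

For repeated measures y₁…y_T (daily mean escape latencies, seconds) the
full autoregressive latent trajectory (ALT) model is

    y_it = I_i + λ_t S_i + ρ_t y_{i,t−1} + ε_it,        t ≥ 2
    I_i  = μ_I + Σ_k γ_I,k x_ik + ζ_I,i
    S_i  = μ_S + Σ_k γ_S,k x_ik + ζ_S,i

with intercept loadings fixed at 1, slope loadings λ_t fixed at
0, 1, …, T−1 (linear growth in days), free per-wave error variances
e_t = var(ε_it), and freely covarying factor disturbances
di = var(ζ_I), ds = var(ζ_S).  Binary covariates x_k (0/1) are
exogenous observed variables with free means, variances and (by
default) mutual covariances.  Setting all ρ_t = 0 gives the latent
growth (LGM) sub-model; dropping the factors gives the AR sub-model.

**First-wave variants.**  How y₁ enters the chain is a genuine
specification choice in the ALT literature and is exposed explicitly:

* **V1** (default): y₁ loads on both factors and receives no AR path;
* **V2** ("predetermined"): y₁ is exogenous with its own mean and
  variance; the factors load on y₂…y_T with slope loadings re-indexed
  0…T−2.  Optional covariances link y₁ to the factor disturbances and
  to the covariates (`first_wave_covariances`); switching them off
  leaves y₁ feeding the chain only through its AR path;
* **V3**: V1 with the wave-1 error variance fixed at 0.

Further toggles: a single shared AR coefficient (`ar_equal`), covariate
covariances on/off, and free per-wave outcome intercepts
(`free_wave_intercepts`; combined with free factor means this
over-parameterizes the mean structure — the means are then fitted
exactly and the χ² reflects covariance structure only, which mirrors
the df accounting of point-and-click SEM software).

## Estimation

Models are fitted to sample moments (covariance with the n−1
denominator, means, n) by minimizing the ML discrepancy; χ² =
(n−1)·F_min.  Implementation details:

* **Parameterization.**  Path-matrix form Σ = F(I−A)⁻¹Ψ(I−A)⁻ᵀFᵀ,
  μ = F(I−A)⁻¹m; free entries are labeled, shared labels impose
  equality.  Variances are optimized as log-variances so Σ stays
  positive definite along the search path; a non-PD proposal returns a
  large penalty (never a silent NaN).
* **Optimizer.**  L-BFGS with the analytic gradient of F_ML
  (∂F/∂Ψ = Bᵀ Ḡ B etc., with Ḡ the observed-block embedding of
  Σ⁻¹(Σ−S−ddᵀ)Σ⁻¹), followed by up to three damped Newton polish steps
  using a central-difference Hessian of the gradient.  Fitting a model
  to its own implied moments recovers the generating parameters to
  ~1e−8.  Everything is deterministic: identical inputs give
  bit-identical parameter tables.
* **Convergence** is declared when the gradient on the *optimized*
  scale (log for variances) falls below 1e−5; a variance estimate at
  the zero boundary therefore counts as a converged boundary solution,
  with a warning that its standard error is unreliable.
* **Starts.**  Sample variances for observed-variable variances (half
  for endogenous waves), latent means from a least-squares fit of the
  observed means on the fixed loadings (for linear growth: the day-1
  mean and the OLS slope of means over days), zeros for paths and
  covariances.
* **Inference.**  SEs from the inverse numerically-differentiated
  Hessian of ((n−1)/2)·F at the optimum (central differences of the
  analytic gradient, relative step 1e−5); CR = estimate/SE with
  two-sided normal p.  A singular information matrix (boundary or
  under-identification) yields missing SEs plus a warning.
* **Fit indices.**  The independence baseline (free variances and
  means) has the closed-form χ²_b = −(n−1)·ln|R|, df_b = p(p−1)/2.
  CFI and TLI use the standard truncations; RMSEA =
  √(max(χ²−df,0)/(df(n−1))) with a 90% CI from inverting the
  noncentral χ² at 5%/95% and PCLOSE at the RMSEA = 0.05 reference.
  With df = 0 the RMSEA is reported as undefined.
* **R².**  For every endogenous variable (growth factors included),
  1 − disturbance/implied variance.  The "learning-growth explained
  variance" reported for integrated fits is the slope factor's squared
  multiple correlation — the share of between-animal growth-rate
  variance attributable to the covariates.

## The embedded moment fixture

The published 13-variable table (day_1…day_9, sex, age, stress,
genotype; n = 183) is embedded with its covariances (diagonal and
above), correlations (below the diagonal, kept for consistency checks)
and means.  Two corrections, both documented in the fixture docstring
and verifiable from the printed numbers alone:

* the SD row's "9696" entries under the binary covariates are
  typesetting garbage; binary SDs follow from the variances;
* the age and stress *data columns* are transposed relative to their
  labels: only the swapped pairing makes the binary variances equal
  p(1−p) of the printed percentages, and only it reproduces the
  published per-factor significance pattern.  `as_printed=True`
  returns the uncorrected layout.

**Integrated-model variant search.**  The published integrated fit line
reports its accounting as 45 — with 104 distinct sample moments that is
the parameter count (df = 59), the only reading consistent with the
printed p and RMSEA.  `integrated_variant_search` fits the whole
variant space (first wave × equal-AR × covariate covariances ×
first-wave covariances × free intercepts; 32 specifications, ~10 s),
filters to the published parameter count and uses the published
chi-square as a tie-break anchor to identify the specification behind
the published line.  The selected model — predetermined first wave,
uncorrelated y₁, per-lag AR, free covariate covariances — reproduces
the published χ², CFI, TLI, RMSEA and explained variance within
rounding-level tolerances.  The single-factor models instead match the
published critical ratios with a V1 first wave and a single shared AR
coefficient; both choices are recorded in the search/table output
rather than hidden.

## Mixed-design ANOVA

Between-subject factors are binary, full-factorial with all
interactions, effect-coded (deviation coding); sums of squares are
Type III via the coefficient-hypothesis form SS = β̂ᵀ[L(XᵀX)⁻¹Lᵀ]⁻¹β̂,
so unbalanced cells are supported.  Between-subject tests use √T-scaled
subject means; within-subject tests use orthonormal (Helmert) day
contrasts, with error SSCP pooled within cells.  Partial η² =
SS_effect/(SS_effect+SS_error).  Sphericity: Mauchly's
W = |C'ΣC| / (tr(C'ΣC)/q)^q with the Bartlett χ² approximation on
q(q+1)/2 − 1 df; ε_GG from the contrast-covariance eigenvalues; ε_HF
by the GLM convention using the total N and the between-design rank,

    ε_HF = (N·q·ε_GG − 2) / (q·n_e − q²·ε_GG),   n_e = N − rank,

capped at 1 (uncapped value retained).  Corrected p-values evaluate F
on ε-scaled df; corrected df are displayed to 1 decimal.  When only a
total covariance matrix is available, within-cell sphericity
diagnostics are *approximated* by partialling the binary covariates out
of the day block and flagged as such — the honest best that moment-only
input permits.

## Simulator

`simulate_alt` draws trajectories from the same generative recursion
the builders specify, with a fixed draw order (cells in lexicographic
covariate order, latent draws before wave errors, waves ascending), so
a seed fully determines the dataset.  Covariate cells are exactly
balanced.  Because simulator and SEM engine are independent
implementations of one model, large-sample agreement between sample
moments and `implied_moments` is the package's central oracle (checked
at n = 100 000 within 2%).

Simulated latencies are **not** truncated at the 0/60 s task limits by
default, keeping the moments exactly model-implied; a truncation flag
exists for realism demonstrations and breaks moment-matching by
construction.  The generator is Gaussian and linear: it emulates the
factorial design, the mean decline, the variance scale and the lag-1
dependence of real escape-latency data, but not floor/ceiling
censoring, skewed daily distributions, trial-level (3/day) structure or
dropout.  Passing tests therefore certify the estimator under the
model's own assumptions, not robustness to those violations.

`table1_like_config()` is a documented configuration in the published
descriptive regime (implied day means declining ≈43 → 24 s, monotone;
day variances ≈150–230 s²; four balanced covariates).  Its constants
are round numbers chosen once to land in that regime; with a positive
AR coefficient a near-uniform mean decline forces a small ρ (0.05),
since the wave-2 mean picks up ρ·m₁.

`recovery_experiment` refits the generating model across replicates and
reports per-parameter bias, RMSE, 95% CI coverage and CR rejection
rates; replicates that fail the gradient criterion are excluded and
counted, and the report is flagged invalid above 20% failures.
Balanced-design covariate moments are recovered exactly by construction
and get no coverage entry.  Default experiment sizes (200 replicates at
n = 2000; 50 replicates in the quick suite) keep a full run in minutes
on one CPU.

## Known limitations

* Complete-case analysis only; no FIML or other missing-data handling.
* No robust (Satorra–Bentler) corrections, WLS/ADF, Bayesian
  estimation, multi-group models or latent interactions.
* Nonlinear growth is available only through user-supplied slope
  loadings.
* Product-coded interactions require raw data; they cannot be derived
  from a main-effects moment matrix, and the fixture therefore cannot
  reproduce the published interaction-model coefficients.
* The ANOVA module's moment-only sphericity path is approximate (see
  above); exact values require per-subject data.
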