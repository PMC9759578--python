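# Methods

## The model

`funcontrol` treats multi-region BOLD activity as a discrete linear
time-invariant system

```
x(t+1) = A x(t) + B u(t)
```

where `x` is the vector of region signals, `A` is a connectome coupling
matrix, `u` is an exogenous input and `B` selects where the input
enters.  Two node-level controllability metrics summarize how inputs
propagate through the network:

- **Average controllability** of region *i* is the trace of the
  infinite-horizon controllability Gramian for the single-input system
  `B = e_i`,

  ```
  trace(W_i),   W_i = Σ_{t≥0} A^t e_i e_i' (A')^t ,
  ```

  computed by solving the discrete Lyapunov equation
  `M = A' M A + I` once per connectome; `trace(W_i) = M_ii`, so one
  solve yields every region.  Values are ≥ 1 (the t = 0 term alone
  contributes 1) and grow as region *i*'s input echoes through the
  system.

- **Modal controllability** of region *i* is
  `φ_i = Σ_j (1 − λ_j²) v_ij²` over the eigenmodes `(λ_j, v_j)` of the
  symmetric `A`.  It weights a region's loadings on fast-decaying
  (hard-to-reach) modes; `φ_i ∈ (1 − ρ(A)², 1]` for a stable system.

Network-level values are unweighted means of the node values within
each functional network label.  An "unassigned" label is aggregated
like any other but excluded from group modeling.

Here `A` is a *functional* connectome: the signed partial-correlation
matrix of the cleaned BOLD timeseries, estimated by the graphical LASSO
(L1-penalized Gaussian maximum likelihood, penalty λ = 0.1 on
off-diagonal precision entries, applied to the sample correlation so the
penalty is scale-free), then converted edge-wise via
`w_ij = −ω_ij / √(ω_ii ω_jj)`.  Negative edges are retained.  Because a
partial-correlation matrix is not itself a stable system matrix, it is
rescaled as `A = W / (1 + σ_max(W))` before the control computations;
for symmetric `W` this guarantees spectral radius < 1.  The scheme and
factor are recorded in every `ControlSystem`.

## Preprocessing chain

Each run passes through, in this fixed order:

1. **Framewise displacement** — Power convention: sum of absolute
   backward differences of the six rigid-body parameters, rotations
   converted to arc length at a 50 mm radius; FD(0) = 0.
2. **Respiration notch** — the motion parameters are band-stop filtered
   at 0.31–0.41 Hz before the FD used for censoring is computed.  At
   TR = 2 s this band lies above the 0.25 Hz Nyquist frequency;
   respiration nevertheless appears in the sampled traces at its
   aliased image, so the band is mapped through
   `f ↦ |f − fs·round(f/fs)|` (0.31–0.41 Hz → 0.09–0.19 Hz) before a
   second-order zero-phase Butterworth band-stop is designed.  The
   mapped band is part of the run log.
3. **Censoring** — frames with notch-FD > 0.2 mm are removed, then any
   surviving segment shorter than 5 contiguous frames.
4. **Spectral interpolation** — censored frames are replaced by a
   least-squares spectral fit so the temporal filters see no gaps: the
   retained frames are jointly regressed on sine/cosine pairs over an
   oversampled frequency grid (minimum-norm least squares, singular
   values below 1e−6 of the largest discarded) and the fitted spectrum
   is evaluated at the censored frames.  The grid ceiling is half the
   Nyquist frequency: the reconstruction only needs to support the
   0.009–0.08 Hz band-pass that follows, and a dictionary extending to
   Nyquist behaves like a white-noise prior that interpolates nothing.
   A per-frequency (periodogram-style) fit was rejected because it
   systematically attenuates the reconstruction inside gaps.
   Interpolated values exist solely to stabilize filtering; the frames
   are re-censored before any covariance is computed.
5. **Band-pass** — 0.009–0.08 Hz, second-order Butterworth, zero phase
   (`filtfilt`), applied identically to the data and to every confound
   column.
6. **Nuisance regression** — 36 regressors: six motion parameters plus
   global, white-matter and CSF signals, each with backward-difference
   derivative, square, and squared derivative.  Ordinary least squares
   fit on retained frames only; the fitted model is evaluated at every
   frame so residuals exist everywhere, and collinear columns are
   dropped by pivoted QR with their labels recorded.
7. **Quality control** — a run is excluded when mean notch-FD exceeds
   0.5 mm or fewer than 50 good frames survive; a (session, context) is
   excluded when its included runs hold fewer than 150 good frames.
8. **Finalize** — per run linear detrend and z-scoring on retained
   frames, then concatenation across runs within a context.  Only
   retained frames enter the correlation that feeds the graphical
   LASSO.

## Estimation details

- Graphical LASSO: scikit-learn's coordinate descent (`tol = 1e-4`,
  `enet_tol = 1e-8`, diagonal unpenalized).  Every estimate is verified
  against the Karush–Kuhn–Tucker conditions (`kkt_residual`), which are
  solver-independent; on well-conditioned input residuals sit around
  1e−5.  The accepted residual ceiling (`kkt_tol`, default 1e−2) is
  deliberately looser than that: the only matrices that approach it are
  the near-singular correlations of heavily censored sessions, whose
  statistical uncertainty dwarfs the optimization slack.  When a run
  barely clears the 50-good-frame floor, the 38 regression dimensions
  can leave the residual series exactly rank-deficient and correlations
  at ±1, which breaks coordinate descent outright; the package then
  falls back to an ADMM splitting solver (warm-started from the partial
  coordinate-descent solution when one exists) whose Θ-update is a
  closed-form eigendecomposition and therefore defined for any
  symmetric input; it stops once its soft-thresholded iterate passes
  the KKT check at 1e−4.  λ = 0 is computed directly as the inverse
  sample correlation and requires more frames than regions.
- Mixed models: `statsmodels` `MixedLM`, REML, a random intercept per
  participant.  The outcome is standardized and covariates centered
  inside the fit for optimizer conditioning (contrast estimates and
  p-values are invariant; coefficients are transformed back).  p-values
  are two-sided t-statistics on the fixed-effect coefficients with
  containment degrees of freedom: participants minus fixed effects,
  since the reported group contrasts vary between participants and
  row-based df would overstate the information carried by repeated
  sessions.
  A singular or non-converged fit falls back to OLS and is flagged
  `ols_fallback` in the results table; flagged and failed cells are
  recorded, never dropped.
- Descriptive statistics: the two-sample t-test from summary statistics
  defaults to the pooled (Student) form, with Welch available by flag;
  the chi-squared test of independence is Pearson's without continuity
  correction.

## Group analysis

Two model sets per (metric, context, network) cell:

- **group_comparison** — TD sessions (both coded placebo) with the
  clinical group's placebo and MPH sessions; a three-level condition
  factor with TD as reference yields the clinical-placebo-vs-TD and
  clinical-MPH-vs-TD contrasts.
- **within_adhd** — clinical rows only, binary MPH indicator.

Covariates: age (years), biological sex, and mean raw FD — computed per
session × context over all frames before notch filtering, censoring or
cleaning.  With the full 13-network atlas and three scan contexts the
enumeration is 2 sets × 2 metrics × 3 contexts × 13 networks = 156
cells; no multiple-comparisons correction is applied, matching the
exploratory design.

Before modeling, clinical participants are filtered per scan context to
*acute behavioral responders*: mean raw FD strictly lower on MPH than
on placebo in that context (ties count as non-response; a missing
condition excludes the subject for that context).  TD participants are
always included.

## Synthetic cohorts

The generator (`funcontrol.synth`) emulates a placebo-controlled
crossover design: a clinical group scanned on drug and on placebo in
counterbalanced order, and a TD group scanned twice unmedicated; at
full scale each session has rest (2 × 150 volumes), go/no-go (2 × 195)
and rewarded go/no-go (4 × 185) contexts at TR = 2 s.

- **Dynamics**: per-subject VAR(1) with a symmetric, block-structured
  coupling matrix (within-network weight 0.25, between 0.04, entrywise
  jitter 0.01 before rescaling) rescaled to spectral radius 0.6;
  innovations are independent unit Gaussians, matching the
  linear-Gaussian assumptions of partial-correlation estimation.
- **Group/drug effect**: every within-network edge of the designated
  effect networks gains +`group_effect_size` (default 0.06, roughly
  doubling the scaled within-network weight — a deliberately strong,
  clearly recoverable construction) in the clinical placebo session;
  on MPH the increment is scaled by `1 − drug_recovery_fraction`
  (default 1, i.e. full normalization, so the MPH session's coupling
  equals the subject's unaffected baseline exactly).  Increments that
  would push the spectral radius to 0.98 are refused.
- **Motion**: white parameter jitter (0.01 mm) plus two spike
  processes.  Frequent small spikes (rate 0.15/volume, exponential
  magnitudes capped at 0.18 mm, i.e. below the censoring threshold)
  model restlessness; their scale depends on the (group, condition)
  cell — clinical-placebo 0.10 mm > TD 0.07 > clinical-MPH 0.05 — and
  is what the raw-FD responder rule and the motion covariate read.
  Rare large spikes (rate 0.01/volume, 0.25 mm + exponential) model the
  abrupt movements censoring removes; their scale is cell-independent
  so the censored-frame budget stays comparable across cells.  This
  separation is deliberate: when censoring differs systematically by
  cell, the retained-frame count mediates an estimator bias in the
  connectome that masquerades as a group effect.  Each subject carries
  a lognormal motion multiplier (σ = 0.5) constant across sessions, so
  in-scanner motion varies within cells and the FD covariate is
  identifiable.
- **Confounds**: linear-plus-cosine drift, AR(1) global/white-matter/
  CSF signals with per-ROI loadings, and a rank-one motion artifact
  (positive per-ROI loadings × spike magnitude) injected at spike
  frames — the contamination the cleaning chain must remove.

What the generator does *not* emulate: hemodynamic convolution, task
event structure, scanner physics, spatially correlated noise, or
non-Gaussian BOLD marginals.  Passing recovery tests therefore show
that the pipeline recovers effects expressed as VAR coupling changes
under realistic motion and nuisance contamination — not that it would
detect any particular physiological effect in real data.

## Simulation study sizes

The seeded acceptance study uses desk-scale cohorts of 40 ROIs over 4
networks with 20 subjects per group.  Effect recovery runs 20 replicate
cohorts at the rewarded go/no-go context (4 × 185 volumes, the design's
largest frame budget); the type-I-error study runs 200 replicate null
cohorts (`group_effect_size = 0`) at the rest context (2 × 150).  The
recovery check asks for the constructed pattern — higher average
and lower modal controllability of the effect network in the
clinical-placebo cell — in ≥ 80% of replicates with the drug cell
statistically indistinguishable from TD in most replicates, and the
null rejection rate inside the binomial 95% band around 0.05.

## Known limitations

- The stabilization `W/(1 + σ_max)` compresses all connectomes toward
  the origin by a subject-specific factor; controllability contrasts
  are therefore relative statements about network structure, not
  absolute energies.
- Retained-frame counts still vary across subjects; the mean-FD
  covariate absorbs this only approximately, which is a property of the
  modeled design rather than of this implementation.
- The mixed models use a single random intercept; no random slopes or
  session-level variance components are modeled.
- Degrees of freedom for the mixed-model t-tests are residual-based;
  Satterthwaite or Kenward–Roger approximations are not implemented.
- The ADMM fallback is slower than coordinate descent (hundreds of
  eigendecompositions) and is only engaged when the primary solver
  fails its optimality check.
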