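# funcontrol

Functional controllability of brain networks: a tested pipeline from
multi-run BOLD ROI timeseries to mixed-effects group contrasts, with a
first-class synthetic-cohort generator so every stage is verifiable
without any imaging download.

## The problem

Stimulant medication (methylphenidate, MPH) changes how the brains of
children with ADHD coordinate activity, but static functional
connectivity gives an incomplete picture of *dynamics*.  Network
control theory treats the brain as a discrete linear system

```
x(t+1) = A x(t) + B u(t)
```

with `A` a connectome and `u` exogenous input, and asks how strongly
input to one region moves the whole system.  Two node metrics capture
complementary aspects:

- **average controllability** `trace(W_i)`, the trace of the
  infinite-horizon controllability Gramian
  `W_i = Σ_t A^t e_i e_i' (A')^t` (solved via the discrete Lyapunov
  equation) — how reactive the system is to input at region *i*;
- **modal controllability** `φ_i = Σ_j (1 − λ_j²) v_ij²` — how well
  input at region *i* excites the fast-decaying, hard-to-reach modes.

`funcontrol` applies these metrics to *functional* connectomes:
signed, sparse partial-correlation networks estimated per
(subject, session, scan context) by graphical LASSO (λ = 0.1), after a
motion-aware cleaning chain (notch-filtered framewise displacement,
censoring at 0.2 mm with 5-frame segments, spectral interpolation,
0.009–0.08 Hz band-pass, 36-parameter nuisance regression, run- and
task-level QC).  Network-level means are then contrasted between
groups and drug conditions with linear mixed models (random intercept
per participant; age, sex and mean raw FD as covariates), after
filtering the clinical group per context to *acute behavioral
responders* (raw FD lower on drug than on placebo).

It is aimed at researchers who want a reproducible, end-to-end tested
reference implementation of this analysis, or a simulation bench for
its statistical behavior.

## Worked example

Simulate a crossover cohort (20 subjects per group, 40 ROIs in 4
networks, a coupling effect injected into the somatomotor-dorsal
network with full drug recovery) and fit the contrasts for the effect
network:

```python
from funcontrol import cli_io

results = cli_io.replicate_contrasts(7, effect=True)
print(results[["model_set", "metric", "contrast", "estimate", "se", "p"]])
```

```
       model_set  metric           contrast  estimate       se        p
group_comparison average adhd_placebo_vs_td  0.010654 0.002414 0.000103
group_comparison average     adhd_mph_vs_td -0.002930 0.002468 0.243733
group_comparison   modal adhd_placebo_vs_td -0.008734 0.001962 0.000092
group_comparison   modal     adhd_mph_vs_td  0.002299 0.002006 0.259942
     within_adhd average     mph_vs_placebo -0.014204 0.002921 0.000251
     within_adhd   modal     mph_vs_placebo  0.011492 0.002372 0.000259
```

The pipeline recovers the constructed pattern: on placebo the clinical
group shows *higher* average and *lower* modal controllability of the
effect network than the comparison group (rows 1 and 3, p ≈ 1e-4); on
drug the difference vanishes (rows 2 and 4, n.s.), and the
within-group drug effect mirrors it (last two rows).  Estimates are in
controllability units (dimensionless; average ≥ 1, modal ∈ (0, 1]).

The same analysis is available as a shell pipeline writing plain-text
TSVs with provenance headers:

```bash
funcontrol run --out results/demo --seed 7 --n-per-group 5
funcontrol report --data results/demo
```

Stage subcommands (`simulate`, `preprocess`, `connectome`, `control`,
`models`, `report`) re-run any part from the on-disk TSVs.

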