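# stepfinder

Automated, assumption-light detection of discrete steps in noisy
single-molecule time traces — FRET trajectories, optical/magnetic-tweezers
records, nanopore currents, photobleaching intensities, or any other signal
that dwells at constant levels and jumps between them.

Given a one-column (signal) or two-column (time, signal) text trace,
`stepfinder` returns the step locations, plateau levels, step sizes and dwell
times, with optional bootstrap 95% confidence intervals, without requiring
prior knowledge of the step size, step count, or noise model.

## Method

A trace of N₀ samples is modelled as a piecewise-constant signal plus noise.
Fitting proceeds top-down and greedily: starting from a single plateau, the
breakpoint that maximally reduces the summed squared residuals is inserted at
each iteration.  For a candidate split of a plateau into a left part (N_L
samples, mean A_L) and right part (N_R, A_R), the reduction is

    gain = Δ² / (1/N_L + 1/N_R),   Δ = A_R − A_L,

computed for every interior position from running prefix sums, so a full fit
costs O(N₀) per sweep instead of O(N₀²).

The number of steps is selected with a *counter fit*: within every plateau of
the current fit the next-best split position is located, the existing
breakpoints are discarded, and a deliberately mis-placed fit is built on those
interleaved positions.  The step spectrum ("S-curve")

    S(n) = σ²_counter(n) / σ²_fit(n)

peaks sharply where the fit captures genuine steps — at the optimum,
S_max ≈ 1 + P with P = Δ²/4σ_R² — and stays near 1 for step-free signals
(white noise, drift).  The fit is truncated at the S-curve's global maximum.

Because a single round resolves only the dominant step scale, the fit is
subtracted and a second round is run on the residual (*dual-pass*).  Each
round is accepted only if its S-curve clears an acceptance threshold,
S_max ≥ 1 + τ; accepted rounds' breakpoints are merged and plateau levels are
recomputed on the original data.  Per-step 95% confidence intervals come from
resampling the two plateaus adjacent to each step and re-locating the optimal
split in every replicate.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

```python
import stepfinder as sf

# a kinesin-like record: 10 steps of 8 a.u., 30-sample dwells, noise SD 2
trace, truth = sf.gen_motor(n_steps=10, step_size=8.0, plateau_length=30,
                            noise_sd=2.0, seed=42)
result = sf.autostepfinder(trace, sf.Config(n_bootstrap=1000, seed=42))

r1_fit, r1_curve = result.round1
print(f"round 1: S_max = {r1_curve.s_max:.2f} at n = {r1_curve.n_at_s_max}, "
      f"accepted rounds = {result.accepted_rounds}")
print(f"steps found: {result.fit.n_steps} (true: {truth.n_steps})")
cols = ["step_index", "step_size", "dwell_after_samples",
        "ci95_size_low", "ci95_size_high"]
print(result.step_table[cols].head(4).round(2).to_string(index=False))
```

prints

```
round 1: S_max = 4.54 at n = 10, accepted rounds = 1
steps found: 10 (true: 10)
 step_index  step_size  dwell_after_samples  ci95_size_low  ci95_size_high
         30       8.19                   30           7.39            9.01
         60       7.57                   30           6.84            8.28
         90       7.66                   30           6.83            8.41
        120       8.52                   30           7.48            9.48
```

The S-curve peaks at n = 10 iterations — the true step count — with
S_max ≈ 4.5, close to the predicted 1 + P = 5 for Δ = 8 and σ_R = 2.  All ten
8-a.u. steps are recovered at their exact 30-sample spacing, each with a
bootstrap interval of about ±0.8 a.u. that contains the true size.  The
second fitting round found no further step scale and was rejected, so
`accepted_rounds = 1`.

## Command line

```
stepfinder fit trace.txt --bootstrap 1000 --out results/   # one file
stepfinder fit data_dir/ --pattern "*.txt"                 # batch mode
stepfinder simulate staircase --repeats 100 --sd 1.0 --out sim.txt
stepfinder benchmark staircase --sd 1.0 --repeats 100
```

`fit` writes, per trace: `<name>_fits.csv` (time, data, fit per sample),
`<name>_properties.csv` (the step table with CI columns),
`<name>_scurve_round<k>.csv`, and a JSON run manifest.

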