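# Methods

This note documents the models, conventions and numerical choices behind
`pergss`: what each stage computes, which parameters matter, what the
synthetic cohorts do and do not emulate, and where the design was
genuinely open.

## Signal model and spectral conventions

A steady-state PERG sweep is modeled as

```
v(t) = A·sin(2πf·t + φ) + (a + b·t) + ε(t) [+ artifact spike]
```

with `f` the reversal rate (the response's fundamental: one cycle per
reversal), `A` the peak amplitude in μV, `φ = −2πf·t_r/1000` the phase of
a response delayed by `t_r` ms, an affine baseline drift, and white noise
`ε`. Harmonics are not modeled: the analysis reads only the fundamental
DFT bin, so a single sinusoid is the minimal sufficient structure.

Sweeps are 960 ms, so the analysis frequencies are *bin aligned*:
12.5 Hz × 0.96 s = bin 12, 18.75 Hz × 0.96 s = bin 18. Rectangular
(unwindowed) analysis is therefore leak-free at the analysis bin, and no
taper is applied. Amplitudes use the peak convention `A_k = 2|X_k|/N` so
that a sinusoid of peak amplitude A μV reads A μV. The reported phase is
the sine-convention phase itself (DFT argument + π/2, wrapped to (−π, π]);
this single convention is what makes the generator → analysis round trip
exact, and all other modules treat phase as opaque.

The default sampling rate is 500 Hz (480 samples per sweep): an integer
sample count, Nyquist well above the 40 Hz band of interest. Recording
hardware rates vary and are not part of the protocol definition; any rate
giving an integer number of samples works.

## Preprocessing

Order: artifact rejection → stimulus-synchronized averaging → low-pass →
detrend.

* **Artifact rejection** discards a sweep iff its maximum absolute voltage
  exceeds 120 μV. The criterion is deliberately the simplest reading of a
  voltage threshold; a peak-to-peak variant is available
  (`criterion="peak_to_peak"`). Fewer than 100 surviving sweeps triggers a
  data-quality warning, not an error, so small fixtures remain usable.
* **Low-pass filtering** is an ideal DFT-domain mask: components strictly
  above 40 Hz are zeroed. A brick-wall mask is reproducible bit-for-bit,
  idempotent, and cannot distort the analysis bins (12.5/18.75 Hz ≪
  40 Hz), which an IIR/FIR realization of unspecified order could.
* **Detrending** removes the affine drift `a + b·t`. The default
  ("protect") estimates the line *jointly* with a sine/cosine pair at the
  trace's analysis frequency and subtracts only the line. Rationale: over
  a finite window a sinusoid is not orthogonal to `t`, so a plain
  least-squares line soaks up part of the response and biases the
  fundamental bin by up to ~0.4% at bin 12; the joint fit decomposes an
  affine-plus-fundamental mixture exactly, leaving the response untouched
  while still annihilating any pure affine input. Plain OLS detrending is
  kept as `method="ols"` (its output has exactly zero mean and zero LS
  slope, at the cost of the small bin bias).
* **Stage order**: filtering and detrending do not commute sample-wise
  when drift is present — brick-wall filtering a ramp rings (Gibbs), and
  the subtracted line reintroduces out-of-band content. At the analysis
  bin the two orders agree to ~1e-3 μV even under a strong 3 μV/s drift,
  and exactly when drift is absent. The default is filter → detrend;
  `detrend_first=True` swaps them.

## Noise estimate, correction and SNR

The noise estimate is the mean amplitude of the two bins directly adjacent
to the analysis bin (k−1, k+1) — off-response frequencies that carry only
background noise because the sweep holds whole response cycles. The
default correction subtracts it linearly, floored at zero
(`max(0, A − N̂)`); a power-domain variant
(`sqrt(max(0, A² − N̂²))`) is provided because magnitude-domain and
power-domain subtraction are both in use in steady-state evoked-response
practice, and the choice is recorded in the pipeline's run log. SNR is
`A/N̂` with `inf` documented for noiseless fixtures. Per-response
statistical significance criteria (coherence-style tests) are not
implemented; inference happens at the group level.

## Response times

Phase determines latency only modulo the stimulus period (80 ms at
12.5 rps, 53.33 ms at 18.75 rps). The ambiguity is resolved per condition:
the reported time is the unique value `t₀ + k·period` inside
`[window_lo, window_lo + period)`. The default lower bound of 30 ms
brackets plausible steady-state PERG latencies for both rates (observed
group means span roughly 41–57 ms, all inside [30, 83.3) at both
periods). Cross-condition continuity chains (unwrapping against
neighbouring check sizes) are out of scope; per-condition windowing is
total and deterministic.

## Synthetic cohorts

`generate_cohort_table` draws, per subject/eye/condition,

```
amplitude = max(ε, μ_gc + u_s + c_sc + e_se)
```

with `μ_gc` the group × condition mean, `u_s ~ N(0, σ_subj²)` a subject
effect shared across all conditions (the within-subject correlation knob),
`c_sc` per-cell noise shared between eyes, and `e_se` eye jitter; response
times likewise. The configured per-cell SD is interpreted as the *total*
between-subject SD of the eye-averaged measure, so the cell noise SD is
derived as `sqrt(max(0, sd² − σ_subj² − σ_eye²/2))` and generated cohorts
reproduce the reference tables' SDs as printed. Defaults:
σ_subj = 0.3 μV / 1.5 ms, σ_eye = 0.2 μV / 0.5 ms — a moderate shared
component (~40% of amplitude variance) chosen once as a realistic degree
of within-subject correlation; it is exposed on `CohortDesign`.
Amplitudes are floored at ε = 0.01 μV (they are magnitudes).

Default mean/SD tables are the reference group summaries
(`pergss.reference`): 12 subjects per group, four check sizes × two rates,
amplitudes ~1.6–2.9 μV, times ~41–57 ms. `null_design()` gives both groups
the control model; `uniform_deficit_design(0.2)` scales patient amplitude
means by 0.8 with control SDs everywhere.

Sweep-level defaults: white noise 20 μV per sample (≈2 μV per sample
after averaging 100 sweeps, i.e. bin-level noise ≈0.13 μV and SNR ≈15 for
a 2 μV response), drift intercept/slope SDs 5 μV and 5 μV/s, artifacts as
single-sample spikes of ±200 μV at a uniform position (shape is irrelevant
to a max-|v| rule; 200 > 120 makes every injected artifact rejectable).
No sweep-level noise magnitudes are published for this protocol; these
values were chosen once for testability, not fidelity.

What the generator does **not** emulate: harmonic structure, 50/60 Hz
mains interference (the 40 Hz filter's stated purpose), non-stationary
noise, blink/eye-movement physiology, refraction errors, or any
correlation between amplitude deficit and symptom severity. Passing tests
therefore certify the *analysis chain* — not that real recordings satisfy
the generator's assumptions.

## Split-plot ANOVA

The mixed ANOVA is computed from its sums-of-squares decomposition (the
package authors this; established implementations serve only as test
cross-checks). For one between factor (group) and two within factors
(check size, frequency), observations decompose into the between-subject
stratum (group; subjects-within-groups error) and three within strata,
each pairing an effect and its group interaction with the matching
effect × subject-within-group error. SS are exactly additive; degenerate
inputs (all responses equal) report F = 0, p = 1.

Greenhouse–Geisser ε per within effect is computed from the pooled
*within-group* covariance of orthonormal-contrast scores
(ε = tr(M)²/(r·ΣM²), M = CΣC′, clamped to [1/r, 1]) and applied
multiplicatively to both dfs of that stratum's tests; 2-level effects have
ε = 1 identically. Group-centering (rather than grand-centering) matches
the classical split-plot treatment; during development the full table —
SS, F, p and ε — was verified to print precision against an independent
Type III sum-to-zero implementation, and those values are frozen as a
regression test.

**EMM post-hoc contrasts.** In this balanced design the estimated marginal
mean contrast per condition equals the difference of raw group cell means.
The SE pools all four error strata into a single variance
(`SE = sqrt(2·MS_pooled/n)`, `MS_pooled = ΣSS_err/Σdf_err`), which is why
one SE serves the whole table; p-values are two-sided t on the pooled df
(176 for the full design). Marginal-means software reaches the same SE
with a smaller containment df (113); the pooled-df choice is slightly
anti-conservative at these sizes and is recorded in the run log. Hedges g
is signed control − patient, so positive values mean patient reduction.

**Wilcoxon tests** delegate to scipy with the exact null when samples are
≤25 and tie-free, otherwise the tie-corrected normal approximation; the
method used is reported. All-zero paired differences return p = 1 with a
warning. One-sided alternatives are used only where directional hypotheses
exist (patients lower; higher rate lower); otherwise two-sided.

**Holm** is the classical step-down with adjusted p-values (running max of
`(m−i+1)·p_(i)`, capped at 1); flags are exactly `adjusted ≤ α`.

**Check-size ratio**: `A(0.8°)/A(16°)` per subject and frequency; the
denominator is floored at 0.05 μV and flagged when the floor engages.
Relative reduction is `100·(m_ctrl − m_pat)/m_ctrl` percent.

## Problem sizes and tolerances

Test and acceptance runs use scaled-down problem sizes chosen as the
smallest that exercise each property: pipeline demos use 2–6 subjects per
group and 3–20 sweeps per block; Monte-Carlo suites use 200 cohorts for
calibration/recovery and 100 for the ratio ordering, all at the full
n = 12 per group and with seeds fixed. Noiseless round trips are asserted
at 1e-9 μV / 1e-6 ms (measured ~1e-14); SS additivity at 1e-8 relative;
sphericity and projection identities at 1e-9; the OLS detrend bin bias at
≤0.5% (its analytic worst case at bin 12 is ~0.4%).

## Known limitations

* Unequal group sizes and incomplete designs are rejected rather than
  handled (no imputation, no unbalanced EMMs).
* The ANOVA supports one between and at most two within factors.
* No vendor file formats; archives are the package's own TSV+JSON layout.
* The ratio's denominator floor makes extinguished 16° responses produce
  large but finite ratios; downstream rank-based tests are insensitive to
  this, parametric ones less so.
* Phase unwrapping is per condition; pathologically long latencies beyond
  `window_lo + period` alias back into the window.
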