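# Methods

This note documents the models and procedures implemented in `nirquant`,
the defaults and numerical choices, what the synthetic data generator does
and does not emulate, and the known limitations.

## The calibration problem

Given absorbance spectra `X` (`n` samples × `p` wavelength channels,
1000–2500 nm) and reference concentrations `y` (g kg⁻¹) for one analyte,
build a linear calibration `ŷ = ȳ + (x − x̄)·β` that predicts unseen
samples, and report it with the field's standard metrics. The pipeline
reproduces the canonical NIR workflow: pretreat → screen outliers →
partition → (optionally) select wavelengths → fit PLS → evaluate.

## Spectral pretreatments

All operators act per spectrum (row) and are composable.

- **Moving-average smoothing**: `x_k ← (1/H)·Σ_{i=−w..w} h_i·x_{k+i}`
  with uniform weights `h_i = 1` by default and `H = Σ h_i`. Default
  half-width `w = 7` channels. At the edges the window shrinks
  symmetrically rather than padding, so no data are fabricated and the
  output keeps its shape.
- **Gap derivatives**: first `x′_k = (x_{k+g} − x_{k−g})/g`, second
  `x″_k = (x_{k+g} − 2x_k + x_{k−g})/g²`, default gap `g = 5` channels.
  The first-derivative divisor is `g`; the conventional central-difference
  divisor `2g` is available via `conventional=True` but is not the
  default — the two differ only by a constant factor, which PLS absorbs.
  Channels within `g` of either edge are trimmed, along with their
  wavelengths, so downstream channel indices stay aligned.
- **MSC**: each spectrum is regressed on a reference spectrum
  (`x ≈ m_i·x_ref + b_i`, ordinary least squares with intercept) and
  corrected to `(x − b_i)/m_i`. The reference is the column mean of the
  *calibration* partition, frozen at fit time — prediction spectra are
  never corrected against their own mean, which would leak information
  across the split.
- **SNV**: `(x − mean(x)) / sd(x)` with the `m − 1` denominator.

`d1_sg` / `d2_sg` denote smoothing followed by the gap derivative, the
standard composition when a smoothed-derivative pretreatment is reported
without parameters. Window and gap defaults are explicit package choices;
they are exposed in `PretreatmentSpec`.

## Outlier screening

Mahalanobis distance in a `k = 5` dimensional PCA score space of the
centred spectra (the full-channel covariance is singular whenever
`p ≫ n`), with covariance estimated from the scores. Samples with
distance above `mean + 3·sd` are flagged. Both `k` and the sd multiplier
are configurable; screening is analyte-agnostic (spectra only), with an
optional hook to append a standardized concentration column for joint
screening.

## Kennard–Stone partitioning

Canonical max–min selection in spectral Euclidean space: seed with the
most distant pair, then repeatedly add the candidate maximizing its
minimum distance to the selected set. Ties break to the lowest sample
index, making the partition deterministic and permutation-stable. The
default calibration size is `round(0.8·n)`, reproducing 96/24 from 120
samples and 94/23 from 117.

A note on range coverage: max–min selection favours boundary samples, so
the calibration set *tends* to cover the prediction set's concentration
range — measured at ~85% per analyte over 50 seeded runs on
composition-dominated spectra (the same rate as on a raw 3-D uniform
cloud), but only ~60% (the random-split rate) when spectral variance is
dominated by scatter and baseline nuisance uncorrelated with the analytes.
Coverage is a tendency of the algorithm, not a guarantee.

## PLS1 regression

Mean-centred NIPALS PLS1, no variance scaling — the dominant convention
in NIR chemometrics. One pass of the iteratively deflating algorithm
yields the regression-coefficient path `β(A)` for every component count
`A = 1..A_max` (via the incremental rotation
`r_a = w_a − Σ_{j<a}(p_jᵀw_a)·r_j`, `β_A = Σ_{a≤A} q_a·r_a`), so
cross-validation refits each training fold once rather than once per
component count. At `A = rank(X_centred)` the coefficients coincide with
the least-squares pseudoinverse solution; the test suite asserts this
against explicit normal-equation solves and against an independent NIPALS
implementation.

**Cross-validation.** RMSECV(A) = √(Σ held-out squared errors / n), with
leave-one-out folds by default and deterministic round-robin k-fold as a
faster option. The optimal `A` is the smallest count whose RMSECV ties
the curve minimum within numerical noise (`min + 1e−8·max` of the curve)
— preferring parsimony and immune to float-level dust among exact ties.
Folds whose training response is constant predict that constant.
`A_max` defaults to 18 and is configurable. If the signal deflates to
zero before `A_max` components, the coefficient path freezes at the last
valid component rather than dividing by zero.

## Wavelength selection

**UVE.** The spectra are augmented with `p` uniform-noise channels of
amplitude `1e−10·max|X|` — small enough not to perturb the fit, nonzero
so the noise-channel coefficients are defined. PLS is refit across CV
folds (leave-one-out by default) collecting `β` per fold; each channel's
stability is `h_i = mean(β_i)/std(β_i)` over folds, and real channels are
kept iff `|h_i|` exceeds the maximum `|h|` of the noise block (a quantile
of the noise block is available as an option). Because `h` is a ratio,
it — and hence the threshold — is *invariant to the noise amplitude*; the
amplitude has no vanishing-threshold limit. Channels with zero coefficient
spread across folds get `±∞` stability with a warning. The component
count is supplied by the caller (the pipeline passes the full-spectrum
CV-optimal count).

**CARS.** `N = 100` Monte-Carlo runs (configurable). Per run `i`:

1. draw `mc_fraction = 0.8` of the calibration samples without
   replacement;
2. fit PLS on the surviving channel subset, with the component count
   re-optimized by an inner 5-fold RMSECV on the Monte-Carlo subsample —
   fitting at the maximal allowed count instead produces overfit, spiky
   coefficient vectors and premature subset collapse;
3. normalize weights `w_j = |β_j|/Σ|β_j|`;
4. *forced removal* (EDF): keep the `⌈r_i·p⌉` heaviest channels, where
   `r_i = a·e^{−k·i}` with `a = (p/2)^{1/(N−1)}`, `k = ln(p/2)/(N−1)` —
   boundary conditions giving the full budget at run 1 and a budget of
   exactly 2 at run `N`;
5. *adaptive reweighted sampling* (ARS): draw that many channels with
   replacement with probability ∝ `w_j`; the distinct draws survive.
   Eliminated channels never re-enter;
6. score the surviving subset by cross-validated RMSECV on the full
   calibration set (leave-one-out by default, k-fold configurable), with
   the component count re-optimized up to `A_max`.

The subset with minimal RMSECV wins (earliest run on ties). Because ARS
keeps only distinct weighted draws, subsets can shrink faster than the
EDF budget; if the subset would fall below 2 channels the algorithm stops
early at the last valid run with a warning, which is common once the
informative channels have been isolated.

## Evaluation

RMSE uses the `n` divisor. Calibration R² centres the total sum of
squares on the measured mean (classical). Prediction-set R² centres it on
the *predicted* mean by default — matching a reporting convention found in
NIR papers — with the classical convention available; the two coincide
when predicted and measured means agree. RPD = sd(reference values,
`m − 1` denominator) / RMSEP, labelled exceptional (> 2), general
(1.4–2) or poor (< 1.4). The comparison table reports, per analyte and
model, PCs, variable count, R²_C, RMSECV, RMSEC, R²_P, RMSEP, RPD and the
CARS-vs-full percent RMSEP reduction `100·(RMSEP_full −
RMSEP_CARS)/RMSEP_full`; metrics render at 4 significant figures.

## Synthetic data generator

Forward model per sample:

```
spectrum_i = m_i · (Σ_c conc_{i,c} · pure_c + baseline_i) + b_i + ε_i
```

- `pure_c`: sums of Gaussian bands on the wavelength axis. The default
  component set is three analytes — total saponins (0.79–5.79 g kg⁻¹),
  mannitol (1.57–5.91), naringenin (0.0038–0.0369), bands near the strong
  1500/1940/2150/2310 nm absorption features — plus a *bulk matrix*
  component, nearly constant at ~900 g kg⁻¹ with broad bands (~1 AU
  total). The matrix term is essential realism: real powder spectra share
  a dominant common shape (cellulose, water), which is precisely why MSC
  and SNV work — without it, per-spectrum normalization divides out
  composition signal and scatter correction degrades rather than helps.
  Band heights scale with mass fraction, so analytes perturb spectra by
  ~0.01 AU against a ~1 AU background.
- Concentrations: uniform, independent across components.
- Baseline: random quadratic in wavelength, amplitude 0.1 AU — the smooth
  drift that derivative pretreatments remove.
- Scatter: per-sample affine, `m_i = exp(N(0, 0.10))` and
  `b_i ~ N(0, 0.02)` — exactly the model MSC inverts, so scatter-correction
  correctness is analytically checkable (SNV/MSC recover the scatter-free
  shape to machine precision on noise-free data).
- Noise: white Gaussian, sd 0.0005 AU (64-scan FT-NIR class).
- Answer key: pure spectra, scatter parameters, and per component the
  informative channel set (channels where the pure spectrum exceeds 1% of
  its band maximum).

Everything is drawn from one seeded generator; identical config + seed is
bit-identical.

**What the generator does not emulate** — and therefore what passing
tests do and do not show. The model is exactly linear and low-rank with
homoscedastic noise: no wavelength-dependent scatter, no band shifts or
nonlinear detector response, no correlated instrument drift, no
concentration correlations between analytes. On such data a full-spectrum
PLS model with a handful of components is already near-optimal, so
wavelength selection *cannot systematically reduce prediction error*: in
repeated runs CARS ties the full-spectrum model within a few percent
(sometimes better, sometimes worse), rather than reproducing the clear
CARS > full > UVE ordering reported on real instrument data, where the
discarded channels carry structured nonidealities. What the synthetic
tests do establish: every operator implements its formula exactly, the
workflow is leak-free and deterministic, scatter correction wins the
pretreatment sweep whenever multiplicative scatter dominates, and both
selectors recover planted informative channels with recall ≥ 0.9 at
SNR 100 while CARS's best subset cross-validates at least as well as the
full spectrum.

## Numerical choices and degenerate inputs

- Validation errors name the offending field or sample.
- SNV and MSC raise on constant rows/references (undefined scale);
  MSC raises if a fitted slope is exactly 0.
- Mahalanobis screening raises when the requested score dimension exceeds
  the spectral rank, advising a smaller `k`.
- KS and CARS tie-breaks are index-based (deterministic); CARS forced
  removal sorts weights with a stable sort.
- The pipeline derives per-analyte, per-algorithm seeds from the single
  experiment seed via a seeded generator, so adding an analyte does not
  shift another's draws.
- Problem sizes in the shipped tests and the acceptance script: the full
  study scale (120 × 1557, three analytes, CARS N = 100) with 5-fold CV
  inside the pipeline sweeps, and reduced constructions (n = 60,
  p = 40–50) for selection-recovery statistics over 20 replicates.

## Limitations

- PLS1 only (one response at a time); no PLS2, kernel PLS, or uncertainty
  intervals on coefficients.
- True least-squares Savitzky–Golay polynomial filters are not
  implemented; "smoothing" is the weighted moving average defined above.
- Only linear-in-nm wavelength axes; no cm⁻¹ grid support.
- The UVE variable counts and Table-style metric values of any specific
  real-data study are not reproducible without that study's spectra; the
  package reproduces the *procedures* and their internal arithmetic
  identities, not instrument-specific numbers.
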