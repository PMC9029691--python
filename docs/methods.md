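# Methods

This note records the statistical models the package implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## 1. The calibration problem

A near-infrared reflectance spectrum of a mosquito's head/thorax is a vector
of absorbances A(λ) = log10(1/R) on a nanometre grid, typically
350–2500 nm. Cuticular composition changes with adult age, so the spectrum
carries an age signal; it also carries per-scan nuisance variation
(pathlength/scatter, baseline drift) and a noisy visible region below
700 nm. The calibration task is to learn a map from spectrum to
chronological age (days post-eclosion) from cohorts of known-age,
lab-reared females, and to quantify how well that map transfers to new
samples.

## 2. Preprocessing

Order: band/range selection → multiplicative scatter correction →
Savitzky–Golay first derivative. The order is configurable; the default
puts MSC before the derivative because multiplicative scatter is physically
defined on absorbance, not on its derivative.

**Band selection** keeps wavelengths λ with range_low ≤ λ ≤ range_high and,
if band regions are given, λ inside some band. All endpoints are inclusive;
selection is a pure subset that never reorders the grid.

**MSC.** Each spectrum x is regressed on a reference spectrum r (ordinary
least squares over wavelengths): x ≈ a + b·r, and replaced by (x − a)/b.
The reference is the **calibration-set mean only**, stored in the model and
reused for test and field spectra — re-estimating it from prediction-time
data would leak information and make predictions depend on the batch
composition. MSC exactly undoes any affine distortion of the reference and
is idempotent up to floating error. A spectrum whose fitted slope is
numerically zero (|b| < 1e−12) cannot be corrected and is dropped with a
warning.

**Savitzky–Golay derivative.** Local least-squares polynomial fit (default
order 2) over an odd window (default 31 points, the conventional "SG1"
setting for this application), differentiated once and scaled by the grid
spacing. Edge points — (window−1)/2 per segment end — are dropped, not
padded: padding would fabricate spectral values. Because band selection can
leave a grid with gaps (e.g. 500–985 plus 1015–2400 nm), the filter is
applied per maximal uniformly-spaced segment; each segment must be at least
one window long, and a genuinely irregular grid is rejected. On a single
contiguous range the output has p_selected − (window − 1) points. Setting
the derivative order to 0 disables the stage entirely.

## 3. PLS1 by NIPALS

With centred calibration spectra X (n × p′) and centred ages y, factors
a = 1…A are extracted as

    w_a ∝ Xᵀy (unit norm),  t_a = X w_a,
    p_a = Xᵀt_a / t_aᵀt_a,  q_a = yᵀt_a / t_aᵀt_a,
    X ← X − t_a p_aᵀ,       y ← y − q_a t_a,

giving coefficients b = W(PᵀW)⁻¹q and intercept ȳ − x̄ᵀb. Score vectors are
mutually orthogonal, and with A = rank(X) the fit coincides with
least squares — both properties are tested, the latter against a
pseudoinverse oracle and against scikit-learn's implementation (used only
as a cross-check, never as the implementation). If a deflated weight
vector has zero norm the recursion stops early with a warning.

**Factor selection.** The number of factors is the smallest A whose 10-fold
cross-validated RMSEP is within 2% of the minimum over 1…A_max
(A_max = 15 by default). The parsimony band exists because CV curves for
these data are typically flat past the elbow, and the flat region's
minimum is sampling noise. One NIPALS fit per fold at A_max yields the
predictions for every smaller A as a by-product of the sequential score
path, which keeps selection at k·1 fits rather than k·A_max.

**Split.** Calibration/test is a uniform random 80/20 split
(floor(0.8·n) calibration), seeded and recorded. The published analyses
this mirrors used "arbitrarily selected" splits of roughly that ratio.

## 4. Validation metrics

- **R², slope, intercept**: OLS of predicted on known age, on the
  calibration subset (test-subset values are also computed and stored, since
  summary tables in this literature do not always say which is printed).
  CIs are t-based at 95%. A slope below 1 with intercept above 0 — the usual
  finding — means young mosquitoes are over-aged and old ones under-aged.
- **SEP**: SD of test-set residuals (predicted − known) about their mean,
  n−1 denominator; the bias-corrected chemometrics convention. RMSEP is
  stored alongside for transparency.
- **RPD** = SD(test known ages)/SEP, with classes: < 1.5 inadequate,
  1.5–2.0 usable for high/low screening, ≥ 2.0 coarse quantitative
  prediction.
- **Vector status**: predicted ages round to the nearest whole day and bin
  as 0–5 (non-vector, younger than the extrinsic incubation period), 6–14
  (unlikely vector), 15+ (potential vector). Rounding reconciles the "<5 d"
  and "0–5 d" phrasings that co-exist in this literature.

## 5. The SCP1 spline age model

*SCP1* transcript abundance declines predictably with adult age, so its
qPCR ΔCt (Ct(*SCP1*) − Ct(*RPS17*)) rises. The model is OLS of ln(age) on
the 3-knot restricted cubic spline of ΔCt in Harrell's truncated-power
form:

    C(x) = [(x−k1)₊³ − (x−k2)₊³(k3−k1)/(k3−k2) + (x−k3)₊³(k2−k1)/(k3−k2)] / (k3−k1)²

which has two continuous derivatives everywhere and is linear outside
[k1, k3]. Knots sit at the empirical 0.10/0.50/0.90 quantiles of the
training ΔCt — the standard default for three knots. The natural log is
used for "log age"; the base only rescales coefficients. Age predictions
are exp(linear predictor) and are **never clamped**: a ΔCt outside the
training range triggers an extrapolation warning but still returns a
value, because implausible predictions (parous females scored under 5
days) are a finding, not a bug to hide.

## 6. Concordance statistics

- **Parity comparison**: Kruskal–Wallis rank ANOVA (tie-corrected,
  chi-squared reference with k−1 df) across parity-by-model groups of NIRS
  age predictions, followed by Dunn's post hoc z tests,
  z_ij = (R̄_i − R̄_j)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)],
  Bonferroni-adjusted by default (the choice is configurable; the source
  analyses do not state one). The degenerate all-identical case returns
  H = 0, p = 1 with a warning rather than an error.
- **SCP1 regression**: OLS of NIRS age (response) on SCP1 age (predictor),
  matching the axis convention of the scatterplots this reproduces. Points
  with externally Studentized residuals |t| > 2 are removed in **one pass**
  and the model refit once — "removing … we used simple linear regression
  again" describes a single refit, not iteration to convergence. External
  (leave-one-out variance) Studentization is the default; internal is
  available. With threshold ∞ the result equals plain OLS.
- **Letter display**: slopes share a letter iff their 95% CIs overlap.
  Maximal groups of mutually overlapping intervals are found by the
  interval-graph sweep (every maximal clique shares the point max(lo)),
  and the construction is verified pairwise before returning.

## 7. The synthetic-data generator

No public spectra exist for this problem, so the generator produces data
with the *statistical* structure the analysis assumes:

- **Clean signal**: polynomial baseline over normalised wavelength plus
  Gaussian absorption bands at overtone-like positions (1200, 1450, 1720,
  1940, 2100, 2310 nm), with amplitudes amp(age) = base + gain·(1 −
  exp(−age/τ)), τ = 6–14 days. The saturation makes old ages intrinsically
  hard to separate — reproducing the universal finding that the oldest
  mosquitoes are scored too young.
- **Measurement model**: measured = m·A + c + tilt·(λ−mid)/span + ε, with
  lognormal multiplicative scatter m (sd 0.08 on the log scale), additive
  offset c (sd 0.02), a random spectral tilt, and heteroscedastic noise
  (sd 0.0015, plus sd 0.02 below 700 nm to mimic the noisy visible region).
- **Biological variability**: each mosquito's spectra reflect a
  *physiological* age, age·exp(N(0, cv)) with cv = 0.30 by default; the
  nominal age stays in the metadata. This multiplicative form was chosen
  because published prediction errors grow with the design's age span
  (SEP ≈ 4.6 d on a 1–27 d design vs ≈ 2.6–3.2 d on 1–18 d designs), which
  no constant additive jitter can reproduce. It is the main dial limiting
  attainable R²/RPD, and the default puts the four simulated treatment
  runs in the published qualitative regime (test R² ≈ 0.7–0.85, SEP ≈
  2–4.5 d, RPD ≈ 1.9–2.7).
- **ΔCt**: intercept + slope·(1 − exp(−age/τ)) + noise, slope > 0 enforced
  (expression falls, ΔCt rises); defaults −2 + 6·(1 − e^(−age/12)),
  noise sd 0.5 for field assays.
- **Field populations**: ages geometric on {1, 2, …} from constant daily
  survival (default 0.85), truncated at 30 d; a female is truly parous when
  her age exceeds the first-gonotrophic-cycle threshold (3 d plus N(0,1)
  jitter); the observed parity flips with probability 0.05 (skein-reading
  error); ΔCt is attached only to parous individuals, as nulliparous
  females are not normally assayed. At daily survival 0.55 the true
  parous/nulliparous mean age gap is ≈ 3.5 days, the condition used in the
  field-comparison checks.

What the generator does **not** emulate: real cuticular optics (no
radiative-transfer model), instrument drift between sessions, genetic or
environmental differences between rearing colonies, and seasonality. A
pipeline that passes the simulated checks is therefore validated for its
*statistical* machinery — preprocessing algebra, factor selection,
metric definitions, rank tests — not certified to reach any particular
accuracy on real field populations. One emergent caveat: because the
lognormal physiological-age jitter is right-skewed and the PLS map is
nonlinear in it, NIRS-predicted parity gaps on simulated populations
exceed the true age gap (≈ 5.5 predicted vs ≈ 3 true days in the
acceptance run); direction and significance, not magnitude, are the
tested claims.

## 8. Problem sizes and numerical choices

The simulated studies use n = 600 for the 1–27 day design and 40 per
tested day for the other three (360–520 samples), n = 500 field
populations, 300-sample SCP1 fits and 200-replicate coverage simulations —
sizes at which every statistic of interest is stable while a full run of
the test suite and the acceptance script stays in the tens of seconds.

Other numerical choices: grid uniformity tolerance 1e−6 (relative) per
segment; MSC slope guard 1e−12; NIPALS early-stop when ‖Xᵀy‖ falls below
1e−12 of scale; CSVs written at 17 significant digits and read with
round-trip float parsing so write→read is bit-exact; all randomness flows
from named integer seeds through `numpy.random.default_rng`, and every
saved artifact records its seed (and a settings hash in workflow reports).

## 9. Known limitations

- Commercial chemometrics packages do not disclose their internals (exact
  factor-selection rule, SG polynomial order, MSC/SG order), so published
  calibrations built with them cannot be replicated setting-for-setting;
  here every such choice is explicit configuration, with the defaults above.
- The SCP1 model's published coefficients and training data are not
  printed anywhere; only the fitting *procedure* is reproducible, so SCP1
  concordance is evaluated against self-generated data.
- Single-response PLS only; no per-sample prediction intervals; no
  neural-network calibrations.
- The compact letter display is exact for intervals (interval graphs are
  perfect); it does not generalise to arbitrary significance matrices.
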