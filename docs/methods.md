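# Methods

## Coordinate frame and timeline

All positions are 2-D (x = anterior–posterior axis, y = transverse axis) in
micrometres. Cytokinesis onset defines time 0, so analysed timestamps are
non-positive; event annotations (pseudo-cleavage, pronuclear meeting PM,
mitotic entry ME, cytokinesis onset) are strictly ordered. Every tracked
coordinate is corrected, per frame, by the centroid of the eggshell contour
(shoelace area-weighted centroid), which removes rigid stage drift such as
that caused by the air flow of a temperature controller. Drift correction
deliberately does not require simple polygons — a slightly self-touching
noisy contour still has a well-defined shoelace centroid — whereas geometry
measurements (below) reject self-intersecting contours.

## Feature estimators

**Migration and elongation speeds** are absolute OLS slopes of x against
time over declared windows (recording start → PM for the female pronucleus;
ME → 0 for each spindle pole). OLS was chosen over frame-to-frame
differencing for noise robustness; a window must contain ≥4 frames.

**Centration–rotation** is fitted with x = A·|t|ⁿ/(Kⁿ+|t|ⁿ) + cte by
bounded nonlinear least squares (K > 0, 0.5 ≤ n ≤ 20) on the PM → ME window.
Initialisation: cte₀ = mean of the last 10% of samples, A₀ = mean of the
first 10% minus cte₀, K₀ = |t| of the sample nearest half-saturation, with a
multi-start over n₀ ∈ {2, 1, 4, 8}; the lowest-cost start wins. The fitted
curve passes through A/2 + cte at |t| = K by construction. The analytic
velocity dx/dt = −A·n·Kⁿ·|t|ⁿ⁻¹/(Kⁿ+|t|ⁿ)² (d|t|/dt = −1 for t < 0) is
maximised on a 2001-point grid over the fitted window. Near-constant input
returns the degenerate flat fit (A = 0) rather than an optimiser failure.

**Oscillations.** The dominant angular frequency ω is the largest non-DC
magnitude of the DFT of the mean-removed posterior-pole y signal (≥64
uniformly sampled points required; a signal whose peak does not exceed 3× the
median non-DC magnitude raises "no oscillation detected"). A linear drift
term is then removed, estimated by OLS *jointly* with the dominant sinusoid
(design {1, t, sin ωt, cos ωt}): this leaves a pure in-bin oscillation
untouched while removing a drift ramp whose periodic discontinuity would
otherwise ring inside the pass band. A hard frequency-domain mask keeps
components in [0.5, 3]×(ω/2π) — low-pass to denoise, high-pass against
residual drift; masking cannot change the dominant bin (asserted). Amplitude
is half the maximum peak-to-trough distance of the filtered signal (primary
definition; the maximum absolute deviation is also reported). Duration is
the span where the analytic-signal envelope exceeds 25% (configurable) of
its maximum — a deterministic stand-in for visual inspection of the
oscillation profile.

**Geometry.** Areas use the shoelace formula (via shapely, which also
rejects self-intersecting polygons); length and width are the extents along
the two principal axes of the contour vertex cloud, making all geometry
metrics invariant to rigid motion. Division asymmetry is
100·area(AB)/(area(AB)+area(P1)) with daughter contours sampled at
t ≈ 0.25·t_PM *after* cytokinesis onset (the sampling epoch is configurable).

Per-feature failures are recorded as missing values with reason strings,
never silently dropped.

## Thermal-response screen

Within the thermal range, a feature is temperature-dependent iff its
two-sided Pearson p-value is below family_alpha/M (Bonferroni; M defaults to
the feature-family size, 35 in the reference screen, giving 0.05/35 ≈
0.0014). Constant features are reported with r = 0; features with fewer than
3 within-range observations are untestable.

The within-range model is the constant y = mean for temperature-independent
features; for dependent features both y = y₀ + αT and y = y₀·exp(αT) are
fitted (exponential in log space — deterministic and convex — requiring all
y > 0; a flag switches to nonlinear fitting) and the smaller data-space RSS
wins, ties to linear.

Beyond each limit, the data subset is the within-range observations plus the
observations beyond the tested side only; the edge temperature belongs to
both subsets (the deviation term vanishes there, so its inclusion is inert).
Model 1 is the within-range form refit to this subset; model 2 adds
β·(T − edge), active only beyond the tested limit, with all parameters refit
jointly (both models must see the same data for the F-test to be valid). For
constant/linear/Arrhenius forms both fits are exact linear least squares;
for the exponential form model 2 starts at the model-1 optimum with β = 0 so
its loss cannot exceed model 1's. Then
F = ((RSS₁−RSS₂)/(p₂−p₁))/(RSS₂/(n−p₂)) with a p-value from the
F(p₂−p₁, n−p₂) distribution; "changed" means p below the same
Bonferroni-corrected threshold. Under the null this p-value is exactly
uniform (verified by a 2000-replicate calibration test), and the test's
power is monotone in |β|.

**Respiration** is tested on the log O₂-flow scale with the within-range
form fixed to the Arrhenius shape — linear in 1/T[K] — plus the per-°C
deviation hinge. A model linear in Celsius would not be exact for
exponential-in-1/T data and would produce spurious nonzero F on noise-free
input.

**Arrhenius kinetics** are fitted as log duration vs 1/T[K] (Kelvin offset
273.15) on within-range data; in the convention duration = A·exp(−E/(k_B·T)),
durations that shorten with warming give negative E (the rate 1/duration has
activation energy −E). r² is the log-space explained variance; re-evaluating
a fixed fit with beyond-range points included quantifies departures as a
drop in r².

**Thermal limits** are the edges of the widest contiguous run of tested
temperatures with hatching fraction above the criterion (default 0.90). Ties
break toward the run containing 20 °C, then toward the warmer run; an
all-viable table warns "unbounded range", a single qualifying temperature
returns degenerate limits with a warning, and none raises an error. The
limits are by definition tested temperatures, so their resolution equals the
spacing of the temperature ladder.

## RNAi feeding-time model

t(T_c) = A/exp(α·T_c/(1+T_c/T₀)) with T₀ = 273 K (kept at 273, not 273.15,
matching the published constant). Since α·T_c/(1+T_c/T₀) = α·T₀²·(1/T₀ − 1/T)
with T = T₀ + T_c, this is an Arrhenius law with effective activation energy
α·k_B·T₀² (≈0.64 eV for α = 0.1 — close to the cell-cycle value, as expected
for a developmental-rate law). Fits are least
squares of log duration against g(T_c) = T_c/(1+T_c/T₀): `fit_alpha` frees
both slope and intercept (≥3 distinct points), `fit_prefactor` fixes the
slope and reduces to exp(mean(log d + α·g)). Fitting the published
embryogenesis durations gives α = 0.092, i.e. 0.1 at one decimal; with
α = 0.1 and the published feeding durations the extrapolated feeding times
at 12/16/20/24 °C are 94.2/65.6/46.1/32.8 h. The published rounded values
(90/65/44/31 h) are not exactly consistent with any single least-squares
prefactor; the agreement is within 10% and the discrepancy is documented
rather than resolved. Predicted durations are strictly decreasing in
temperature for any α > 0.

## Synthetic-data generators

The generators are forward models matched one-to-one to the estimators, so
noiseless output recovers truth parameters to numerical tolerance (≤10⁻³
relative) — the backbone round-trip of the test suite.

* **Recordings**: female pronucleus advances at the stated speed until PM;
  the spindle mid-position follows the sigmoid during PM → ME and is held at
  its ME value afterwards (centration–rotation is complete by mitotic
  entry), while the poles separate linearly at the elongation speeds; the
  posterior pole's transverse position is
  amplitude·exp(damping·t)·sin(2πft) + drift·t during mitosis; the eggshell
  is an ellipse polygon. A seeded random-walk stage drift is added to every
  coordinate and removed again by centroid correction. Tracked-point noise
  is i.i.d. Gaussian per frame (the noise structure of real tracking is
  unknown; i.i.d. is the configurable default). Contour noise is smoothed
  along the outline with a circular 5-tap binomial kernel rescaled to
  preserve the marginal sd: segmentation error is spatially correlated, and
  white vertex noise would occasionally produce self-intersecting polygons.
  An oscillation frequency at or above Nyquist (1/(2·frame interval)) is
  rejected.
* **Feature tables** draw kind-model(T) + β_lower·(T−lower)·1[T≤lower] +
  β_upper·(T−upper)·1[T≥upper] + N(0, σ) per cell — the generative twin of
  the screen's nested models.
* **Viability** is a plateau (0.98) inside the species' thermal range with
  logistic shoulders crossing 50% at 2 °C outside each limit (scale 0.5 °C),
  so the fraction is ≥0.93 at the limits and <0.9 one degree outside —
  consistent with a 1 °C test ladder; `noise=True` draws hatched counts
  binomially. Species presets encode limits 12/25 °C (*C. elegans*) and
  14/27 °C (*C. briggsae*) and a mean relative AB size of 57.4%.
* **Respiration**: log flow = log A − E/(k_B·T[K]) inside the range, plus a
  per-°C log-deviation beyond each edge, plus Gaussian noise.
* **Temperature presets** (`preset_recording_params`) scale cell-cycle pace
  by Arrhenius kinetics (E = 0.65 eV referenced to 20 °C, t_PM = 1080 s at
  20 °C), scale sigmoid half-time, migration speed and oscillation frequency
  with the pace, and apply the temperature-size trend (−6 µm²/°C within
  range, extra shrinkage below the lower limit) and beyond-upper-limit
  elongation of the aspect ratio.

What the generators do **not** emulate: pixel-level images, segmentation
error structure of real DIC data, embryo-to-embryo correlation of features,
non-Gaussian outliers, or any RNAi mechanism (RNAi conditions would be
represented as altered preset parameters). Passing tests therefore
demonstrate correctness of the estimators and the statistics under the
stated generative assumptions, not robustness to every property of real
recordings.

## Problem sizes and numerical choices

The simulated screen uses 7 temperatures × 3 embryos with 1 s frames
(recordings of ~600–3500 frames depending on temperature), a 1 °C viability
ladder with 200 embryos per temperature, and 20 respiration temperatures —
sizes at which every stage is exact or converges well and the full pipeline
runs in seconds. The F-test calibration suite uses 2000 null replicates;
estimator-bias checks use 200 noisy replicates at 0.2 µm tracking noise.
Exponential fits default to log space; Kelvin conversions use 273.15 (except
the feeding model's published T₀ = 273). The nested-model routine clamps
RSS₂ at RSS₁ within a 10⁻⁹ relative tolerance and treats a larger violation
as an optimiser failure; p-values are clamped into (0, 1].

## Known limitations

* The oscillation **amplitude** estimator (max peak-to-trough/2 of the
  filtered signal) is an extreme-value statistic: under measurement noise
  its expectation exceeds the true amplitude by roughly the expected maximum
  of the in-band noise at the ~n_peaks peak locations (≈1.9·σ_band for 25
  peaks). Both this bias and its standard error scale linearly with the
  noise sd, so the bias is a structural property of the definition, not of
  any noise level; the dominant-bin spectral magnitude is an unbiased
  alternative but is not the primary reported quantity. The frequency
  estimate is quantised to the FFT bin width (1/window duration).
* Within-range observations at exactly the limit temperatures enter both
  side tests (their deviation term is zero, so they only tighten the
  within-range part).
* The screen treats observations as independent (no embryo-level random
  effects) and corrects multiplicity by Bonferroni only.
* Limit detection reports tested temperatures only; it does not interpolate
  between ladder rungs.
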