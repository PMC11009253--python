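# Methods

## The measurement this package models

An excised inside-out patch sits at the tip of a glass pipette with a
membrane-targeted fluorophore in the bilayer. Pressure steps applied to the
pipette curve the membrane; movies of the fluorescent arc give the radius of
curvature *r* per step, and the Young–Laplace relation `T = |ΔP|·r/2` converts
the applied pressure into membrane tension. Peak currents per step, normalized
to the patch maximum (*I*/*I*max), plotted against tension and fitted with a
two-state Boltzmann `1/(1+exp((T50−T)/k))` give the channel's midpoint tension
and slope factor; in the tension domain these imply the in-plane area
expansion `ΔA = kB·T_abs/k` and intrinsic gating energy `ΔG = (T50/k)·kB·T_abs`
of the open-closed transition. Ultrasound stimulation is handled by the same
machinery in the acoustic-power domain, with hydrophone calibration
(Pa per volt) and intensity `I = (p_peak·0.707)²/Z·(1/100²)` W/cm², Z =
1.48×10⁶ kg·m⁻²·s⁻¹ (water). The 0.707 peak-to-RMS literal is kept as printed
in the field's convention rather than 1/√2 so numbers match published
arithmetic exactly.

## Synthetic experiments: what is emulated

No public raw recordings exist for this kind of experiment, so the generator
is a first-class module with explicit ground truth. Its defaults are the study
conditions all recovery statements refer to:

| parameter | default | rationale |
|---|---|---|
| T50, slope | 4.4, 1.7 mN/m | published TRAAK-like global fit; fixtures double as documentation |
| channels × i_single | 300 × 1.5 pA | "hundreds of channels" at ~1–2 pA single-channel current |
| basal (resting) tension | 0.5 mN/m | low end of literature estimates (0.5–4 mN/m); patches are pulled for low basal tension |
| current noise | 5 % of max current | calibrated realistic level |
| arc image noise | 20 % of arc peak intensity | calibrated realistic level |
| pressure protocol | −10, −20, −35, −50, −75, −110 mmHg × 0.5 s | spans below-midpoint to a saturating response, as the QC rule requires of analyzable patches |
| pipette radius, compliance | 1.5 µm, 20 mmHg | gives tensions ≈3–13 mN/m over the protocol |
| pixel scale, frame rate | 0.05 µm/px, 120 Hz | typical high-NA water-immersion imaging |
| cohort jitter | radius ±15 %, compliance ±30 %, basal SD 0.25 mN/m | between-patch variability enters through geometry and basal tension, not through gating parameters |

Patch mechanics are not modeled physically. The forward radius model
`r(ΔP) = r_pipette·(1 + c/|ΔP|)`, capped at `50·r_pipette` for the flat
resting patch, is a fixture chosen because it reproduces the qualitative
behavior (flat at rest, radius shrinking toward the pipette radius with
pressure) and makes tension strictly increasing in |ΔP|; it makes no
mechanical claim. Noise is additive Gaussian for both current and image
(simplest model sufficient for recovery tests); Poisson shot noise is
available behind `noise_model="poisson"`. Rendered frames anchor the arc at
the pipette aperture with a Gaussian cross-section (σ = 1.2 px) and a dim
pipette-wall silhouette. Every random draw flows from explicit seeds; cohorts
split one root `SeedSequence` into per-patch streams.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: patch creep up the pipette wall, adhesion to glass,
non-spherical-cap geometry, focus drift and photobleaching, leak and seal
currents, kinetics of activation/deactivation, and any acoustic-field physics
(ultrasound is modeled as acting through tension only).

By default cohorts render only the per-step analysis frames
(`image_mode="peak"`); `image_mode="full"` renders complete movies at the
camera frame rate on a common time base with the sweep, which the pipeline
tests exercise at short protocols. Monte-Carlo statements use 100 seeded
replicates of 12-patch × 6-step cohorts, a problem size chosen to keep each
replicate at a fraction of a second while leaving Monte-Carlo error on cohort
means an order of magnitude below the tolerances quoted.

## Analysis choices

**Detection.** One point per ROI row: the maximum-intensity column, leftmost
on ties (deterministic, order-independent). Optional sub-pixel refinement
(default on) interpolates a parabola through the log-intensities of the
maximum and its neighbors — exact for a Gaussian cross-section — so noise-free
round trips are limited by the fit, not by pixel quantization. Optional
1st–99th percentile contrast enhancement applies to the working copy only.

**Continuity filters.** The three filters are this package's concrete
definitions with stated defaults: `max_jump` (threshold 5 px against the last
retained point), `median_residual` (drop |radial residual| > 3× median about a
provisional circle; the provisional circle is a Huber-loss geometric refit of
the closed-form seed so gross outliers cannot capture it), and
`ransac_circle` (500 seeded three-point samples, 2 px consensus tolerance,
largest consensus set wins). Residual-threshold filters are inherently blind
to outlier sets that themselves define a plausible circle; RANSAC is the
default in the pipeline.

**Circle fits.** The exact three-point construction uses the standard
determinant intermediates (A, B, C, D) with
`radius = sqrt((B²+C²−4AD)/4A²)`; collinear input (A = 0) is a degenerate
geometry error. The many-point fit minimizes the algebraic (Kåsa) objective in
closed form after centering; the pipeline default adds a geometric
(orthogonal-distance) refinement because the Kåsa estimate is biased low on
shallow noisy arcs — exactly the large-radius, low-pressure frames. Fits with
radius above 25 µm are flagged flat-patch (the Laplace relation degenerates
for flat membranes) and tensions below 0.36 mN/m are flagged below the
reliably measurable range.

**Frame–time matching.** `floor(t × frame_rate)`, clamped; a time equal to the
stack duration maps to the last frame. Rounding direction is a convention this
package fixes explicitly.

**Peaks and normalization.** The per-step peak is the extremum of the
boxcar-smoothed (25 ms default) trace after subtracting the median of the
100 ms pre-step baseline; polarity is auto-detected, ties resolve to the
earliest time. Normalized responses are ratios of *absolute recorded* peak
currents (resting current plus step deviation), matching the *I*/*I*max
definition; exactly one point attains 1. Fold activation floors the basal
magnitude at one single-channel current (1.5 pA default) to avoid division
blow-up.

**QC.** A patch is excluded when basal activity exceeds 0.25 of *I*max or when
the responses at the two largest stimuli differ by more than 0.10 of *I*max
(no saturating response). Verdicts always carry their reasons, and excluded
patches remain listed in the report.

**Boltzmann fitting.** Amplitude is fixed at 1 because data are normalized to
*I*max (a free-amplitude variant exists behind a flag for sensitivity
analysis); no basal-offset term is fitted — the two-state form already has a
nonzero floor at T = 0, and an offset would be unidentifiable under the basal
QC cap. Fits use bounded least squares (slope > 0) with multi-start
initialization: midpoint at the median stimulus, slope at a quarter of the
span, plus 8 seeded jittered restarts; tolerances 1e−12. 95 % CIs come from
the Jacobian covariance with Student-t critical values; R² = 1 − SSres/SStot.
A fit is flagged non-identifiable when the midpoint CI exceeds the sampled
stimulus span or the midpoint falls outside it (e.g. all points on one side).
`global` mode pools all patches' points; `per_patch` fits each patch and
reports mean ± SEM-based CI.

**Energetics.** kB = 1.380649×10⁻²³ J/K, temperature default 298.15 K
(recordings at 25 °C), configurable. ΔG is anchored in kB·T_abs units; the
joule value is derived from them (`ΔG_J = ΔG_kBT · kB · T_abs` — an identity
the tests check to 1e−12). Energetics are refused for fits whose stimulus
domain is not tension: nothing thermodynamic follows from a pressure- or
acoustic-power-domain midpoint.

## Known systematic effects, by design

- **Resting tension is not added back.** Measured tension is stimulus-induced
  only, so recovered midpoints sit below the generator's true T50 by roughly
  the mean basal tension (≈0.5 mN/m at defaults) — the same unavoidable offset
  real excised-patch measurements carry. The slope factor, and therefore ΔA,
  is unaffected. Recovery tests quote tolerances wide enough to contain this
  documented offset; noise-free round-trip tests set basal tension to zero.
- **Normalization floor.** Dividing by the largest *recorded* response (not
  the true asymptote) shifts midpoints down by `k·ln(1/P(T_max))`; with the
  default saturating protocol this is ≲0.03 mN/m.
- **Peak-of-noise bias.** Taking an extremum over a noisy plateau inflates
  peaks by a few tenths of a percent of *I*max after 25 ms smoothing; it is
  common-mode across steps and largely cancels in normalization.

## Limitations

Tension is computed assuming uniform tension over a spherical-cap patch; no
correction for pipette-wall adhesion or patch creep. The pipeline reports the
acoustic intensity at the waveform's peak pressure and labels it as such
(burst-average conventions differ). Group-comparison statistics are out of
scope; the exported tidy tables (per-step CSV, JSON fit report) are structured
so any statistics package can run them.
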