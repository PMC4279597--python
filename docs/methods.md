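# Methods

This note documents the models, parameter choices and numerical
decisions behind `hemovar`, and what the synthetic-data validation does
and does not establish about real recordings.

## Tachogram and waveform model

The pulse-interval generator is additive and open-loop:

    PI(t) = PI₀ + A_LF·sin(2π f_LF t) + A_HF·sin(2π f_HF t) + ε,   ε ~ N(0, σ²)

with beats placed by integrate-and-fire, t(k+1) = t(k) + PI(t(k)).
Defaults describe a conscious adult rat: PI₀ = 150 ms (400 bpm),
f_LF = 0.4 Hz (Mayer-wave band), f_HF = 1.5 Hz (respiratory band),
all amplitudes in ms. The constraint A_LF + A_HF + 3σ < PI₀ keeps
intervals positive. A sinusoid of amplitude A contributes variance
A²/2, which is the ground truth every spectral test is written
against. The model is deliberately not a closed-loop baroreflex: no
respiratory–cardiac coupling beyond additive sinusoids, no ectopy.

Waveform rendering gives each beat a raised-cosine systolic upstroke
(DAP → SAP) and an exponential diastolic decay that reaches DAP exactly
when the next upstroke begins. The upstroke duration is *fixed* at
`upstroke_fraction` (default 0.25) of the median interval rather than a
fraction of each beat's own interval: with per-beat fractions, the
peak-to-peak spacing would differ from the injected PI by up to the
upstroke fraction times the beat-to-beat PI change (~1 ms under
modulation), which would mask detector timing errors. With the fixed
upstroke, peak-to-peak spacing equals the injected PI up to sampling
quantization, so the detector round trip can be held to one sample
period (0.5 ms at 2 kHz).

## Beat detection

Detection is prominence-thresholded peak picking (`scipy.signal.
find_peaks`) with a refractory period. Defaults: prominence 20 mmHg,
minimum inter-beat interval 80 ms (= 750 bpm ceiling, safely above any
rat HR). DAP is the minimum between consecutive systolic peaks and MAP
the time average of the pressure over the same interval — MAP is
measured from the signal, not approximated as DAP + PP/3. PI is
peak-to-peak: systolic peaks are sharper landmarks than diastolic feet
in both synthetic and real pulses. These are engineering choices; no
claim is made that they reconstruct any particular acquisition
system's criteria. Artifact and ectopic-beat editing are out of scope.

## Variability analysis

Per animal, three contiguous non-overlapping 5-min segments are taken
from the start of the beat series (placement configurable). Per
segment:

- **Time domain**: sample variance (n−1 denominator) of the beat
  values and its square root. SD and VAR are averaged across segments
  *separately*, so reported SD ≠ √(reported VAR) in general.
- **Frequency domain**: cubic-spline interpolation (not-a-knot, so
  cubic trends are reproduced exactly) of value-vs-time onto a 250 Hz
  grid, zero-phase FIR decimation to 10 Hz, linear detrend, and a
  rectangular-window FFT periodogram.

The 10 Hz working rate is a design choice: the interpolation rate is
conventionally 250 Hz, and decimation by 25 gives a 5 Hz Nyquist that
comfortably contains the 4 Hz HF ceiling. Decimation uses explicit
`firwin` + `filtfilt` stages (factors ≤ 10) rather than
`scipy.signal.decimate`, whose FIR path zero-pads and visibly droops
the segment edges; `filtfilt`'s odd extension keeps a constant series
constant to ~1e-6.

**Normalization.** The one-sided PSD satisfies Σ PSD·Δf = mean square
of the (detrended, hence zero-mean) input — Parseval exact to machine
precision with the rectangular window. A Hann option exists with the
Σw² power correction. Band powers are rectangle-rule bin sums over
half-open intervals [lo, hi): half-open means the 0.75 Hz edge bin is
counted once, bin summation makes LF + HF + out-of-band = total
exactly, and the full-range total equals the variance exactly. A
trapezoidal rule cannot deliver either identity on half-open bands,
which is why bin summation was chosen. The upper edge closes at
Nyquist so the full-range integral is complete.

Two band presets are provided because both conventions appear in
practice: `methods` (LF 0.20–0.75, HF 0.75–4.0 Hz) and `table2`
(HF and total power capped at 3 Hz). No single-segment Welch
averaging or windowing is applied by default — one periodogram per
5-min segment, then averaging across the three segments.

## KITT

First-order kinetics are assumed: the "linear phase of decline" is
read as log-linear, since KITT = 0.693/t₁/₂ presupposes exponential
disappearance. The default fit window is 4–16 min, excluding the
baseline sample taken before insulin acts. On noiseless exponentials
the estimator is exact for any k > 0 and invariant to rescaling all
glucose values. A raw-glucose linear fit is available
(`log_fit=False`) because the convention is ambiguous in parts of the
literature; it reports the average fractional decline and understates
k on a convex curve (≈3.2 vs 4.0 %/min on a k = 0.04 exponential), so
the log fit is the default and the mode is recorded in the result.
Non-declining fits (slope ≥ 0 within 1e-12) return KITT = 0 with a
flag rather than a negative rate.

## Caloric intake

kcal/day = chow·2.89 + fluid·(conc/1000)·4.0. On the group-level mean
consumptions bundled in `hemovar.datasets` this gives 73.62 (fructose
group), 33.24 and 48.55 kcal/day versus the reported 73.7, 33.3,
48.7 — the ≤ 0.15 kcal gaps are consistent with the inputs being
printed to 1 decimal.

## Statistics

- **Levene** uses mean centering (the original test, not
  Brown–Forsythe). When every group has zero spread of absolute
  deviations the statistic is 0/0; it is reported as W = 0, p = 1 if
  the between-group term is also zero, and W = ∞, p = 0 otherwise
  (matching the limit and scipy's behavior).
- **ANOVA** accepts raw groups or (mean, SEM, n) summaries; the raw
  path reduces to the summary path through the exact algebraic
  identity SS_within = Σ(nᵢ−1)sdᵢ², so the two agree to machine
  precision and published tables can be re-analyzed without raw data.
- **Studentized range.** The quantile is computed from first
  principles: P(range of r normals ≤ w) by 160-node Gauss–Legendre
  quadrature of r·∫φ(z)[Φ(z)−Φ(z−w)]^{r−1}dz over z ∈ [−8.5, 8.5],
  mixed over the χ scale density by adaptive quadrature, inverted with
  Brent's method (xtol 1e-6). Against published α = 0.05 critical
  tables and `scipy.stats.studentized_range` the error is < 5e-4,
  well inside the 1e-3 contract. Results are cached per (p, r, df).
- **SNK** sorts the k means, tests each pair spanning r ordered means
  at q = |Δ|/√(MS_within/n), and enforces the stepwise containment
  rule: any pair inside a non-significant wider range is declared
  non-significant without regard to its own q. Unequal n falls back to
  the harmonic mean with a warning; the intended design is balanced
  (n = 8). Simulation shows the family-wise type-I error on
  three-group null cohorts is ≈ 0.04–0.05 at α = 0.05.
- Significance is fixed at P ≤ 0.05 by default, configurable. No
  multiple-testing correction is applied across variables, matching
  the analysis convention being reproduced.

## Cohort generator

Cohort values are drawn from a multivariate normal with the requested
marginal means/SDs and pairwise correlations (the correlation matrix
is checked for positive semi-definiteness; SVD factorization allows
degenerate SD = 0 marginals). Normality is this package's assumption —
summary tables reported as mean ± SEM carry no distributional
information — and SD is reconstructed as SEM·√n.

## The simulated study and its limits

`example_study_config()` builds a three-group study (H, HO, FHO; n = 8)
from the bundled reference summaries: between-animal parameter SD =
SEM·√8, PI/SAP modulation amplitudes √(2·band power), and beat-domain
white noise supplying the remaining total variance. What this
calibration reproduces, and what it does not:

- Group means of SAP/DAP/MAP/HR, KITT, intake and the assay variables
  track their targets, and the systolic-pressure SNK marker pattern
  (FHO vs both, HO vs H not significant) is reproduced.
- The published DAP and MAP "vs HO" markers are **not** reproducible
  from summary statistics: re-running SNK on the printed DAP row
  (121±7, 144±5, 153±2; n = 8) gives q(FHO vs HO) ≈ 1.8 against a
  critical value of 2.94. A simulator parameterized by those same
  summaries therefore cannot reproduce that marker except by sampling
  accident; the original finding evidently rests on within-animal
  structure the summaries do not encode.
- Because the white noise that supplies the missing total variance is
  spectrally flat, its in-band share inflates recovered LF/HF above
  the injected narrowband components (e.g. PI LF ≈ 12 vs 3.2 ms² in
  the H group). The generator matches means and total variance, not
  the full spectral shape, of real recordings. Band-power *recovery*
  is therefore validated on noiseless and low-noise injections, where
  the analytic truth A²/2 is exact.
- Real arterial recordings contain movement artifacts, ectopic beats,
  catheter damping and non-stationarity; none are emulated. Passing
  round-trip tests demonstrates correctness of the computational
  chain, not robustness to those phenomena.

The default simulated recording is 960 s (three 5-min segments plus
margin) rather than the full 30 min; the segment count and length are
the analysis-relevant quantities and are configurable. The pipeline's
default `beats` mode synthesizes the beat series directly — the
downstream analysis path is identical — while `waveform` mode renders
2 kHz pressure waveforms and runs the detector; in that mode pulse
amplitudes are constant within an animal (DAP fixed, MAP = DAP + PP/3
in beats mode is likewise a synthetic-composition shortcut), so
pressure-variability indices are near zero by construction.

## Determinism

Every stochastic component takes an explicit seed; the pipeline
derives per-animal seeds from the study seed via `SeedSequence`
spawning, so reports are byte-identical across re-runs and the config
hash + seed recorded in the provenance block fully determine the
output.
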