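# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `varvesst`. Everything quantitative stated here is
computed by the test suite or the examples; nothing is quoted from external
results.

## Proxy model and calibration

The unsaturation index U37K' = C37:2/(C37:2 + C37:3) is formed from pooled
intensities, never averaged per spot: the pooled ratio equals the
intensity-weighted mean of per-spot ratios, which suppresses the shot-level
noise by roughly n^−1/2 and is well defined even when single spots have a
vanishing C37:3 signal. MSI-scale values are multiplied by the measured
MSI→GC transfer factor (default 1.194, SD 0.021 carried as metadata).
GC-equivalent values above 1 are flagged but not clamped — clamping would
bias every pooled statistic built on them.

Calibration is linear both ways: `SST = (u − intercept)/slope` with slope
0.033 U37K' per °C and intercept 0.044. A Bayesian spline calibration would
shift absolute SSTs (its confidence interval at warm values is of order
±3–4 °C) but is deliberately out of scope; the linear form is also the one
used to convert proxy-scale variability to °C, so all variability results
are internally consistent.

## Quality control and pooling

Spots are kept when both alkenones are detected (intensity > 0) with S/N ≥ 3
each. Yearly (and 5-yearly) bins are half-open on the age axis with
boundary spots assigned to the younger bin; bins with fewer than 10
qualifying spots are missing. Both thresholds are configuration values.

## The synthetic world

The generator states one scenario and keeps it fixed:

| parameter | default | meaning |
|---|---|---|
| age span | 11.9 → 11.2 kyr b2k | 700 annual varves |
| sedimentation | 1.4 → 0.5 mm/yr at 11.673 | varve thickness per era |
| thickness jitter | 5 % lognormal SD | year-to-year varve variability |
| mean SST | 23.8 °C | constant across the transition |
| seasonality | 0.8 → 1.8 °C step at 11.64 | non-upwelling − upwelling |
| cycles | 120 yr / 0.3 °C, 42 yr / 0.2 °C | sinusoidal anomalies |
| 2–8-yr band SD | 0.15 / 0.35 °C at 11.66 | AR(1) (φ = 0.5), scaled per era |
| raster | 100 µm over 50 × 4 mm | 20,000 spots per slice |
| detection | p = 0.7 per spot | both-compound detection |
| spot noise | SD 0.0741 on the ratio | additive Gaussian, clamped to [0,1] |
| abundance | 1.5× in the dark season | lognormal totals, σ(log) = 0.4 |

Dark (non-upwelling, warm) laminae occupy the upper half of each varve with
greyscale N(median − 20, 5); light laminae N(median + 20, 5). Elemental
means vary linearly with greyscale between 40 and 100 (Si rising toward
light, Fe/Ti/Ca toward dark, SD 15): a compositional continuum, because
with flat per-lamina levels the "bin of highest abundance" is a tie decided
by sampling noise. The thickness jitter exists because perfectly constant
0.5-mm varves place the lamina boundary knife-edge on the 100-µm raster
rows — an aliasing artefact no real varved record exhibits.

Per-spot S/N is reported as 0.02 × per-compound intensity. Together with
the S/N ≥ 3 rule this censors a small fraction of weak-C37:3 spots,
preferentially in the lower-abundance season, producing a mild cold bias
(≈ 0.1 °C) in pooled SST and a comparable positive offset in the season
difference. This is deliberate realism: thresholded detection is a property
of real MSI data, and the recovery tolerances absorb it.

What a green recovery test does establish: the pipeline's pooling, season
split, calibration, ramp fit and noise correction are mutually consistent
and recover known parameters at realistic noise levels. What it does not
establish: robustness to calibration-model error (simulator and
reconstruction share the calibration by design), bioturbation or lamination
regimes other than the stated couplet pattern, matrix effects, or real
instrument drift.

## Season threshold search

Candidates are integer ΔGS cuts, strictly lighter than every Ca/Ti/Fe
abundance-peak bin and strictly darker than the Si peak bin (bin width 5
for the elemental profile; peaks are taken over bins holding at least
max(25, 1 %) of the spots, because sparse tail bins have unstable means).
For each candidate the two sides are pooled to single SSTs; the candidate
maximising SST(dark) − SST(light) wins subject to each side holding ≥ 25 %
of spots, relaxed once to 15 %; RSS ties break toward the smallest
|threshold|. The search is exact (exhaustive) and is tested against an
independent enumeration.

Because the threshold maximises the very difference later reported, a
*selection bias* of order the slice-level estimation noise (≈ 0.1–0.2 °C at
default spot counts) inflates the seasonality when the true difference is
small. The package documents rather than corrects it — the paper-style
procedure is reproduced as stated — and the zero-seasonality test bounds
it explicitly.

## Ramp fitting

The ramp (constant → linear → constant on the b2k axis) is fitted by
exhaustive search of breakpoint pairs on the observed time grid with the
two levels solved analytically per pair; negative seasonality values are
excluded first. Ties in RSS (relative tolerance 1e−10) break toward the
shortest ramp. The constrained mode restricts the start to 11.725–11.8 and
the end to 11.6–11.675 kyr b2k. The season-mean difference d converts to a
sinusoid-equivalent peak-to-peak annual amplitude as (π/2)·d (half-cycle
means of a sinusoid of half-amplitude a differ by 4a/π).

## Variability analysis

Interior missing years are linearly interpolated (counted and reported);
leading/trailing gaps are an error, as is a missing fraction above 20 %.
The series is detrended by least squares, band-passed with a zero-phase
4th-order Butterworth (periods 2–8 yr; with annual data the short edge is
the Nyquist period, so the filter degenerates to a high-pass at 1/8 yr⁻¹),
and summarised as SDs of non-overlapping 25-yr blocks.

The analytical precision of a pooled value is 0.0741·n^−0.558 (MSI scale);
per block, the mean over member years (rescaled by the GC factor) is
subtracted from the observed SD and the remainder floored at 0 and divided
by the calibration slope. Subtracting SDs — the stated procedure — is
conservative: since obs = √(signal² + noise²), obs − noise < signal, and at
default spot counts the recovered band SD runs ≈ 35 % low. The
`domain="variance"` option subtracts in quadrature and recovers the true
era SDs within ≈ 10 %; the recovery test uses it, the pipeline default does
not.

The red-noise spectrum uses two half-overlapping, Hanning-tapered,
mean-removed segments, zero-padded ×2 (frequency oversampling), averaged;
the AR(1) coefficient comes from the full-series lag-1 autocorrelation
(clipped to [0, 0.99]) and the background is the theoretical AR(1) spectrum
scaled to the same mean power. The 95 % false-alarm level uses the
Welch-equivalent degrees of freedom for Hanning at 50 % overlap,
ν = 36K²/(19K−1) ≈ 3.89 for K = 2; on white noise the measured exceedance
is ≈ 4.9 %. Lomb–Scargle machinery is unnecessary because the series is
regular after gap interpolation. The Morlet wavelet (ω₀ = 6) uses dyadic
scales with dj = 0.25, s₀ = 2 dt, Fourier-domain convolution on a
zero-padded copy, a cone of influence from the √2·s e-folding time, and a
χ²₂ significance level against the variance-scaled AR(1) spectrum.

The two-group tests are Welch's unequal-variance t-test (the variability
change) and the two-sided Mann–Whitney rank test (seasonality groups);
degenerate zero-variance t-tests are flagged with a NaN p-value.

## Modern climatology

Each year's 12 monthly values are split into two complementary blocks of
3–9 *consecutive* calendar months, circularly (a warm season may wrap
December→January — the physically sensible reading); the split maximising
the absolute block-mean difference defines that year's seasonality and warm
season. The implementation is the exhaustive enumeration; a second,
independent enumeration guards it in the tests. NetCDF input is supported
via xarray when a backend is available; plain CSV (year, m1..m12) is the
primary, tested path.

## Numerical choices and degenerate inputs

- Ages are kyr b2k throughout (larger = older); series are stored
  oldest-first (ages strictly decreasing along rows).
- No extrapolation anywhere: age queries outside the control points,
  leading/trailing gaps, and empty ramp-constraint windows all raise.
- U37K' of a zero-total bin is an error, not NaN-by-division; missing bins
  are flagged before the ratio is formed.
- Gaussian smoothing (15-point, σ = window/6) renormalises weights around
  missing values; a window longer than the series is an error.
- Tilt correction interpolates each lamina surface linearly in x (edge
  values held), referenced to the lamina's mean tie-point depth, and
  applies the nearest surface above each spot (nearest overall if none
  above). Registration of MSI to X-ray imagery beyond tie points (the
  teaching-point transform) is out of scope and undocumented upstream; the
  tie-point mechanism is the only depth correction exposed.

## Known limitations

- Absolute SSTs inherit the linear calibration; only differences and
  variability are calibration-robust here.
- The SD-domain noise correction is conservative by construction (above).
- The threshold search's selection bias is documented, not corrected.
- The era-wise scaling of the AR(1) anomaly changes its amplitude at the
  era boundary discontinuously; the 2–8-yr band SD per era is exact by
  construction, but the transition year itself is not specially modelled.
- Acceptance-style checks run the null-variability case on a 260-yr record
  (10 seeds) rather than 700 yr, purely for runtime; the statistic is
  length-insensitive.
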