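"""Interannual variability of the annual proxy series.

Gap interpolation and detrending, a red-noise (AR(1)-background) spectrum,
continuous Morlet wavelet, a 2-8-yr zero-phase band-pass, 25-yr windowed
standard deviations and their correction for the analytical precision of the
pooled estimator.

The analytical precision of a pooled MSI U37K' value follows an empirical
power law in the number of pooled spots,

    sd(n) = 0.0741 * n**(-0.558)        (MSI proxy scale)

so thinner varves (fewer spots per year) carry more measurement noise. The
mean analytical variability of the years inside each 25-yr block is
subtracted from the observed block SD of the band-passed proxy signal and the
remainder converted to deg C through the calibration slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .annual import CalibrationConfig
from .errors import ConfigError, NoSignificantPeakError, ValidationError

MIN_SERIES_LEN = 64


@dataclass(frozen=True)
class NoiseModel:
    """Power-law precision of the pooled estimator: coeff * n**exponent."""

    coeff: float = 0.0741
    exponent: float = -0.558
    r_squared: float = 0.838  # fit quality of the source experiment, metadata

    def __post_init__(self) -> None:
        if self.coeff <= 0:
            raise ConfigError("noise coefficient must be > 0")
        if self.exponent >= 0:
            raise ConfigError("noise exponent must be < 0")


@dataclass
class PreparedSeries:
    """Regular annual anomaly series, oldest-first on the b2k axis."""

    ages_kyr: np.ndarray
    anomaly: np.ndarray
    n_interpolated: int
    n_spots: np.ndarray | None = None


@dataclass
class SpectrumResult:
    frequency: np.ndarray          # cycles per year, <= 0.5 (2-yr Nyquist period)
    power: np.ndarray
    background: np.ndarray         # scaled theoretical AR(1) spectrum
    false_alarm: np.ndarray        # 95% level from the chi-square of the background
    ar1_phi: float
    dof: float

    @property
    def period(self) -> np.ndarray:
        return 1.0 / self.frequency


@dataclass
class WaveletResult:
    period: np.ndarray             # yr, one per scale
    scale: np.ndarray
    time: np.ndarray               # sample index * dt
    power: np.ndarray              # (n_scales, n_times)
    coi_period: np.ndarray         # per time: largest trustworthy period
    significance: np.ndarray       # 95% level per scale vs AR(1) red noise
    signif_mask: np.ndarray        # power > significance


# ---------------------------------------------------------------------------
# Series preparation
# ---------------------------------------------------------------------------

def prepare_series(series: pd.DataFrame, value_col: str = "u37_gc",
                   max_missing_frac: float = 0.2) -> PreparedSeries:
    """Fill interior gaps linearly, remove the linear trend.

    ``series`` is an annual table (as from ``reconstruct_annual``) ordered by
    age; missing interior years are linearly interpolated between their
    nearest non-missing neighbours and counted. Leading or trailing missing
    runs cannot be filled without extrapolation and raise, as does a missing
    fraction above ``max_missing_frac``.
    """
    df = series.sort_values("age_kyr_b2k", ascending=False, ignore_index=True)
    vals = df[value_col].to_numpy(float)
    missing = ~np.isfinite(vals)
    if "missing" in df.columns:
        missing |= df["missing"].to_numpy(bool)
    n = len(vals)
    if n == 0:
        raise ValidationError("empty series")
    if missing[0] or missing[-1]:
        raise ValidationError("leading/trailing missing years cannot be interpolated")
    frac = missing.mean()
    if frac > max_missing_frac:
        raise ValidationError(
            f"missing fraction {frac:.2f} exceeds limit {max_missing_frac}")
    idx = np.arange(n, dtype=float)
    filled = vals.copy()
    if missing.any():
        filled[missing] = np.interp(idx[missing], idx[~missing], vals[~missing])
    # least-squares linear detrend
    coef = np.polyfit(idx, filled, 1)
    anomaly = filled - np.polyval(coef, idx)
    n_spots = None
    if "n_spots" in df.columns:
        n_spots = df["n_spots"].to_numpy(float).copy()
        if missing.any():
            n_spots[missing] = np.interp(idx[missing], idx[~missing], n_spots[~missing])
        n_spots = np.maximum(np.round(n_spots), 1).astype(int)
    return PreparedSeries(df["age_kyr_b2k"].to_numpy(float), anomaly,
                          int(missing.sum()), n_spots)


# ---------------------------------------------------------------------------
# Red-noise spectrum
# ---------------------------------------------------------------------------

def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = np.sum(x * x)
    if denom == 0:
        return 0.0
    return float(np.sum(x[:-1] * x[1:]) / denom)


def _ar1_spectrum(freq: np.ndarray, phi: float, dt: float = 1.0) -> np.ndarray:
    """Theoretical (unnormalised) AR(1) power spectral density shape."""
    return (1.0 - phi ** 2) / (1.0 - 2.0 * phi * np.cos(2.0 * np.pi * freq * dt) + phi ** 2)


def redfit_spectrum(x: np.ndarray, dt: float = 1.0, oversample: int = 2,
                    segments: int = 2, alpha: float = 0.95) -> SpectrumResult:
    """Welch-segmented, Hanning-tapered spectrum against an AR(1) background.

    The series is split into ``segments`` half-overlapping segments, each
    demeaned, Hanning-tapered and zero-padded by the frequency oversampling
    factor; segment periodograms are averaged. The AR(1) lag-1 coefficient is
    estimated from the full series and the theoretical AR(1) spectrum, scaled
    to the same mean power, provides the red-noise background; the false-alarm
    level is its scaled chi-square ``alpha`` quantile with Welch-equivalent
    degrees of freedom (Hanning, 50% overlap: 36 K^2 / (19 K - 1)).
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < MIN_SERIES_LEN:
        raise ValidationError(f"series length {n} < {MIN_SERIES_LEN}")
    if segments < 1 or oversample < 1:
        raise ConfigError("segments and oversample must be >= 1")
    x = x - x.mean()
    seg_len = int(np.floor(2 * n / (segments + 1)))
    starts = np.linspace(0, n - seg_len, segments).round().astype(int)
    nfft = int(seg_len * oversample)
    taper = np.hanning(seg_len)
    norm = dt / (np.sum(taper ** 2))
    psd = np.zeros(nfft // 2 + 1)
    for s in starts:
        seg = x[s:s + seg_len]
        seg = (seg - seg.mean()) * taper
        spec = np.fft.rfft(seg, n=nfft)
        psd += (np.abs(spec) ** 2) * norm
    psd /= segments
    freq = np.fft.rfftfreq(nfft, d=dt)
    keep = freq > 0
    freq, psd = freq[keep], psd[keep]

    phi = float(np.clip(_lag1_autocorr(x), 0.0, 0.99))
    gshape = _ar1_spectrum(freq, phi, dt)
    background = gshape * (psd.mean() / gshape.mean())
    dof = 36.0 * segments ** 2 / (19.0 * segments - 1.0) if segments > 1 else 2.0
    false_alarm = background * stats.chi2.ppf(alpha, dof) / dof
    return SpectrumResult(freq, psd, background, false_alarm, phi, dof)


def significant_peak_period(spec: SpectrumResult,
                            period_band: tuple[float, float]) -> float:
    """Period of the highest significant spectral peak inside a period band."""
    lo, hi = min(period_band), max(period_band)
    period = spec.period
    sel = (period >= lo) & (period <= hi) & (spec.power > spec.false_alarm)
    if not sel.any():
        raise NoSignificantPeakError(
            f"no peak above the false-alarm level in {lo}-{hi} yr")
    idx = np.flatnonzero(sel)
    best = idx[np.argmax(spec.power[idx])]
    return float(period[best])


# ---------------------------------------------------------------------------
# Morlet wavelet (continuous transform, Torrence & Compo conventions)
# ---------------------------------------------------------------------------

def morlet_wavelet(x: np.ndarray, dt: float = 1.0, dj: float = 0.25,
                   s0: float | None = None, omega0: float = 6.0,
                   alpha: float = 0.95) -> WaveletResult:
    """Continuous Morlet wavelet power with red-noise significance and COI.

    Scales form a dyadic-plus-suboctave set ``s0 * 2**(j*dj)``; the transform
    is computed in the Fourier domain on a zero-padded copy of the demeaned
    series. The cone of influence follows the Morlet e-folding time sqrt(2)*s.
    Significance is the chi-square(2) 95% level of the variance-scaled AR(1)
    spectrum evaluated at each scale's equivalent Fourier period.
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < MIN_SERIES_LEN:
        raise ValidationError(f"series length {n} < {MIN_SERIES_LEN}")
    if s0 is None:
        s0 = 2.0 * dt
    variance = float(np.var(x))
    xd = x - x.mean()
    npad = int(2 ** np.ceil(np.log2(n)))
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    fx = np.fft.fft(xd, n=npad)

    jmax = int(np.floor(np.log2(n * dt / s0) / dj))
    scale = s0 * 2.0 ** (dj * np.arange(jmax + 1))
    fourier_factor = (4.0 * np.pi) / (omega0 + np.sqrt(2.0 + omega0 ** 2))
    period = fourier_factor * scale

    power = np.empty((len(scale), n))
    pos = omega > 0
    for i, s in enumerate(scale):
        psi_hat = np.zeros(npad)
        psi_hat[pos] = (np.pi ** -0.25) * np.sqrt(2.0 * np.pi * s / dt) * np.exp(
            -0.5 * (s * omega[pos] - omega0) ** 2)
        w = np.fft.ifft(fx * psi_hat)
        power[i] = np.abs(w[:n]) ** 2

    dist = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    dist[dist == 0] = 1e-8
    coi_period = fourier_factor / np.sqrt(2.0) * dt * dist

    phi = float(np.clip(_lag1_autocorr(xd), 0.0, 0.99))
    freq_eq = 1.0 / period
    bg = _ar1_spectrum(freq_eq, phi, dt)
    # normalised AR(1) spectrum has unit mean power; scale by series variance
    signif = variance * bg * stats.chi2.ppf(alpha, 2) / 2.0
    mask = power > signif[:, None]
    return WaveletResult(period, scale, np.arange(n) * dt, power, coi_period,
                         signif, mask)


def global_wavelet_spectrum(result: WaveletResult) -> np.ndarray:
    """Time-averaged wavelet power per scale."""
    return result.power.mean(axis=1)


# ---------------------------------------------------------------------------
# Band-pass and windowed variability
# ---------------------------------------------------------------------------

def bandpass_filter(x: np.ndarray, period_lo: float = 2.0, period_hi: float = 8.0,
                    dt: float = 1.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass for periods in [period_lo, period_hi].

    On annually binned data the Nyquist period is 2 yr, so ``period_lo`` below
    2*dt is rejected. When the short-period edge coincides with Nyquist the
    filter degenerates to a high-pass at 1/period_hi (the grid itself removes
    everything faster than Nyquist).
    """
    if period_lo < 2.0 * dt - 1e-12:
        raise ValidationError(
            "period_lo below the 2-sample Nyquist period is not resolvable")
    if period_hi <= period_lo:
        raise ValidationError("period_hi must exceed period_lo")
    x = np.asarray(x, float)
    nyq = 0.5 / dt
    lo_norm = (1.0 / period_hi) / nyq
    hi_norm = (1.0 / period_lo) / nyq
    if hi_norm >= 1.0 - 1e-9:
        sos = signal.butter(order, lo_norm, btype="highpass", output="sos")
    else:
        sos = signal.butter(order, [lo_norm, hi_norm], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, x)


def windowed_variability(filtered: np.ndarray, ages_kyr: np.ndarray | None = None,
                         window: int = 25) -> pd.DataFrame:
    """SD of consecutive non-overlapping blocks of ``window`` samples.

    A partial trailing block is dropped. Returns one row per block with the
    member index range, the mid age (if ages are supplied) and the sample SD.
    """
    x = np.asarray(filtered, float)
    if window < 2:
        raise ValidationError("window must cover at least 2 samples")
    n_blocks = len(x) // window
    rows = []
    for b in range(n_blocks):
        i0, i1 = b * window, (b + 1) * window
        rows.append({
            "i0": i0, "i1": i1,
            "age_mid": float(np.mean(ages_kyr[i0:i1])) if ages_kyr is not None else np.nan,
            "sd": float(np.std(x[i0:i1], ddof=1)),
            "n_years": window,
        })
    return pd.DataFrame(rows)


def analytical_variability(n_spots, model: NoiseModel = NoiseModel()):
    """Predicted SD of a pooled U37K' value from ``n_spots`` spots (MSI scale)."""
    n = np.asarray(n_spots, float)
    if np.any(n < 1):
        raise ValidationError("n_spots must be >= 1")
    out = model.coeff * n ** model.exponent
    return float(out) if np.isscalar(n_spots) else out


def correct_variability(blocks: pd.DataFrame, n_spots_per_year: np.ndarray,
                        model: NoiseModel = NoiseModel(),
                        calib: CalibrationConfig = CalibrationConfig(),
                        domain: str = "sd") -> pd.DataFrame:
    """Subtract predicted analytical noise from observed block variability.

    ``blocks`` comes from :func:`windowed_variability` computed on the
    GC-equivalent proxy scale; ``n_spots_per_year`` aligns with the series the
    blocks were cut from. Per block, the mean analytical variability of its
    member years (power law evaluated per year, rescaled by ``gc_factor`` to
    the GC scale) is subtracted from the observed SD (``domain='sd'``, the
    default) or in quadrature (``domain='variance'``); the result is floored
    at zero and converted to deg C by dividing by the calibration slope.
    """
    if domain not in ("sd", "variance"):
        raise ConfigError("domain must be 'sd' or 'variance'")
    n_spots_per_year = np.asarray(n_spots_per_year, float)
    if not len(n_spots_per_year):
        raise ValidationError("n_spots_per_year is required for the correction")
    out = blocks.copy()
    ana_mean = np.empty(len(blocks))
    for k, row in enumerate(blocks.itertuples()):
        ns = n_spots_per_year[int(row.i0):int(row.i1)]
        if len(ns) == 0 or np.any(~np.isfinite(ns)):
            raise ValidationError("missing spot counts for a variability block")
        ana_mean[k] = float(np.mean(model.coeff * ns ** model.exponent)) * calib.gc_factor
    obs = blocks["sd"].to_numpy(float)
    if domain == "sd":
        corrected = np.maximum(obs - ana_mean, 0.0)
    else:
        corrected = np.sqrt(np.maximum(obs ** 2 - ana_mean ** 2, 0.0))
    out["analytical_sd"] = ana_mean
    out["raw_sd_c"] = obs / calib.slope
    out["corrected_sd_c"] = corrected / calib.slope
    return out


def compare_groups(values_a, values_b, test: str = "t"):
    """Two-sided two-group comparison: Welch t-test or Mann-Whitney rank test.

    Returns ``(statistic, p_value)``. A degenerate t-test (both groups
    constant and identical) is flagged with a NaN p-value.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if test == "t":
        if np.std(a) == 0 and np.std(b) == 0:
            import warnings
            warnings.warn("degenerate t-test: both groups have zero variance",
                          stacklevel=2)
            return 0.0, float("nan")
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValidationError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
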