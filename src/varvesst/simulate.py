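"""Forward model of a varved-sediment MSI dataset with known truth.

The generator states a world resembling the Cariaco Basin across the Younger
Dryas-Holocene transition: a 100-um laser raster over 5-cm thin-section
slices (500 x 40 = 20,000 spots per slice), annual laminae couplets whose
thickness follows the sedimentation rate (1.4 mm/yr in the YD dropping to
0.5 mm/yr in the Holocene at 11.673 kyr b2k), a dark non-upwelling lamina
(Fe/Ti/Ca-rich, warm season) and a light upwelling lamina (Si-rich, cool
season) per varve, an annual-mean SST held at 23.8 deg C with centennial
(120-yr) and multidecadal (42-yr) sinusoidal anomalies and an AR(1)
interannual component whose 2-8-yr band SD is set per era, and a true
season-mean SST difference stepping 0.8 -> 1.8 deg C at 11.64 kyr b2k.

Per detected spot the observed C37:2 fraction is the true proxy value plus
additive Gaussian noise with SD equal to the single-spot coefficient of the
pooled-precision power law (0.0741), clamped to [0, 1]; pooling n spots of
equal intensity then yields close to n**-0.5 scaling, compatible with the
fitted exponent -0.558 within the documented tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import SliceInfo, SpotTable
from .variability import bandpass_filter

KYR = 1e-3


@dataclass
class ScenarioConfig:
    """Parameters of the stated synthetic world (defaults = study regime)."""

    age_start: float = 11.9            # kyr b2k, oldest (record bottom)
    age_end: float = 11.2              # kyr b2k, youngest (record top)
    transition_age: float = 11.673     # sedimentation-rate change, kyr b2k
    sed_rate_old: float = 1.4          # mm/yr before (older than) transition
    sed_rate_young: float = 0.5        # mm/yr after
    mean_sst: float = 23.8             # deg C

    # true seasonality: non-upwelling minus upwelling season SST, deg C
    seasonality_step_age: float = 11.64
    seasonality_before: float = 0.8
    seasonality_after: float = 1.8
    seasonality_fn: Callable[[np.ndarray], np.ndarray] | None = None

    # annual-mean anomaly components
    cycles: Sequence[tuple[float, float]] = ((120.0, 0.3), (42.0, 0.2))  # (period yr, amp degC)
    interannual_sd_old: float = 0.15   # 2-8-yr band SD, deg C, older era
    interannual_sd_young: float = 0.35
    interannual_change_age: float = 11.66
    ar1_phi: float = 0.5
    white_sd: float = 0.0

    # observation model
    noise_coeff: float = 0.0741        # per-spot proxy noise SD (ratio units)
    noise_exp: float = -0.558          # pooled-precision exponent (metadata here)
    gc_factor: float = 1.194
    calib_slope: float = 0.033
    calib_intercept: float = 0.044
    season_abundance_ratio: float = 1.5  # mean alkenone intensity non-upw / upw
    detect_prob: float = 0.7
    intensity_median: float = 1000.0
    intensity_logsd: float = 0.4
    sn_per_intensity: float = 0.02     # S/N reported as intensity * this

    # geometry
    spot_pitch_um: float = 100.0
    slice_len_mm: float = 50.0
    slice_width_mm: float = 4.0
    base_depth_cm: float = 480.0       # composite depth of the record top
    dark_fraction: float = 0.5         # fraction of varve thickness that is dark
    thickness_jitter_sd: float = 0.05  # relative lognormal SD of varve thickness

    # lamina appearance
    gs_median: float = 128.0
    gs_dark_offset: float = -20.0
    gs_light_offset: float = 20.0
    gs_sd: float = 5.0
    background_gs: float = 5.0
    elem_high: float = 100.0
    elem_low: float = 40.0
    elem_sd: float = 15.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.sed_rate_old <= 0 or self.sed_rate_young <= 0:
            raise ConfigError("sedimentation rates must be > 0")
        if not (0.0 <= self.detect_prob <= 1.0):
            raise ConfigError("detect_prob must lie in [0, 1]")
        if self.calib_slope <= 0:
            raise ConfigError("calib_slope must be > 0")
        if self.age_start <= self.age_end:
            raise ConfigError("age_start must exceed age_end (b2k decreases toward present)")
        if any(p <= 0 for p, _ in self.cycles):
            raise ConfigError("cycle periods must be > 0")
        if min(self.interannual_sd_old, self.interannual_sd_young, self.white_sd) < 0:
            raise ConfigError("noise SDs must be >= 0")
        if not (0.0 < self.dark_fraction < 1.0):
            raise ConfigError("dark_fraction must lie in (0, 1)")

    # -- stated-world helpers ----------------------------------------------

    def seasonality_at(self, age_kyr) -> np.ndarray:
        """True season-mean SST difference at given ages (step by default)."""
        age = np.asarray(age_kyr, float)
        if self.seasonality_fn is not None:
            return np.asarray(self.seasonality_fn(age), float)
        return np.where(age > self.seasonality_step_age,
                        self.seasonality_before, self.seasonality_after)

    def sed_rate_at(self, age_kyr) -> np.ndarray:
        age = np.asarray(age_kyr, float)
        return np.where(age > self.transition_age, self.sed_rate_old,
                        self.sed_rate_young)


@dataclass
class TruthRecord:
    """Per-year ground truth: ages, SSTs, varve geometry, anomaly parts."""

    df: pd.DataFrame                   # youngest-first (depth order from record top)
    config: ScenarioConfig

    @property
    def n_years(self) -> int:
        return len(self.df)

    @property
    def total_depth_mm(self) -> float:
        return float(self.df["varve_bot_mm"].iloc[-1])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def simulate_truth(config: ScenarioConfig, seed: int | None = None) -> TruthRecord:
    """Generate the per-year true SST decomposition and varve geometry.

    Annual mean = mean_sst + sinusoidal cycles + AR(1) interannual anomaly
    (scaled so its 2-8-yr band SD matches the era's target) + white noise.
    Seasonal truths sit at +/- seasonality/2 around the annual mean. Varve
    thickness is 1/sedimentation-rate at the varve's age; depths accumulate
    from the record top (youngest year at depth 0).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_years = int(round((config.age_start - config.age_end) / KYR))
    if n_years < 1:
        raise ConfigError("age span must cover at least one year")
    # youngest-first ages at year midpoints
    age = config.age_end + KYR * (np.arange(n_years) + 0.5)

    # year-to-year varve-thickness variability (lognormal, unit mean); at
    # exactly constant thickness the lamina boundary can alias with the
    # raster rows, which no real varved record does
    if config.thickness_jitter_sd > 0:
        sd = config.thickness_jitter_sd
        jitter = rng.lognormal(-0.5 * np.log(1 + sd ** 2),
                               np.sqrt(np.log(1 + sd ** 2)), n_years)
    else:
        jitter = np.ones(n_years)

    cyclic = np.zeros(n_years)
    years_abs = age / KYR  # age in years; sinusoid phase fixed at zero
    for period, amp in config.cycles:
        cyclic += amp * np.sin(2.0 * np.pi * years_abs / period)

    # AR(1) anomaly generated chronologically (oldest -> youngest), then
    # band-scaled per era so the 2-8-yr band SD hits its target
    ar1 = np.zeros(n_years)
    if config.interannual_sd_old > 0 or config.interannual_sd_young > 0:
        innov = rng.standard_normal(n_years)
        chron = np.empty(n_years)
        chron[0] = innov[0] / np.sqrt(1 - config.ar1_phi ** 2)
        for t in range(1, n_years):
            chron[t] = config.ar1_phi * chron[t - 1] + innov[t]
        raw = chron[::-1]  # back to youngest-first
        band = bandpass_filter(raw, 2.0, 8.0) if n_years >= MIN_FILTER_LEN else raw
        old = age > config.interannual_change_age
        for era_mask, target in ((old, config.interannual_sd_old),
                                 (~old, config.interannual_sd_young)):
            if not era_mask.any():
                continue
            band_sd = float(np.std(band[era_mask]))
            ar1[era_mask] = raw[era_mask] * (target / band_sd if band_sd > 0 else 0.0)

    white = config.white_sd * rng.standard_normal(n_years) if config.white_sd > 0 \
        else np.zeros(n_years)

    sst_annual = config.mean_sst + cyclic + ar1 + white
    seas = config.seasonality_at(age)
    thick = config.sed_rate_at(age) * jitter
    bot = np.cumsum(thick)
    top = bot - thick
    df = pd.DataFrame({
        "age_kyr_b2k": age,
        "sst_annual": sst_annual,
        "sst_nonupw": sst_annual + seas / 2.0,
        "sst_upw": sst_annual - seas / 2.0,
        "seasonality": seas,
        "varve_top_mm": top,
        "varve_bot_mm": bot,
        "lamina_boundary_mm": top + config.dark_fraction * thick,
        "anom_cyclic": cyclic,
        "anom_ar1": ar1,
        "anom_white": white,
    })
    return TruthRecord(df, config)


MIN_FILTER_LEN = 40  # sosfiltfilt padding needs some room; below this, skip band scaling


def simulate_dataset(truth: TruthRecord, config: ScenarioConfig | None = None,
                     seed: int | None = None) -> SpotTable:
    """Raster the truth into a spot table (the synthetic MSI measurement).

    Spots sit on a regular grid at ``spot_pitch_um`` over ``slice_len_mm`` x
    ``slice_width_mm`` slices stacked downcore; each spot inherits the varve
    and lamina containing its depth. Greyscale and elemental intensities are
    drawn from the lamina-type distributions; alkenone intensities of
    detected spots encode the season's true SST through the inverse
    calibration plus per-spot ratio noise. Spots below the record bottom
    (last partial slice) are black background. Identical config + seed give a
    byte-identical table.
    """
    cfg = truth.config if config is None else config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    pitch_mm = cfg.spot_pitch_um / 1000.0
    n_rows = int(round(cfg.slice_len_mm / pitch_mm))
    n_cols = int(round(cfg.slice_width_mm / pitch_mm))
    if n_rows < 1 or n_cols < 1:
        raise ConfigError("slice geometry admits no spots")
    total_depth = truth.total_depth_mm
    if cfg.slice_len_mm > 0 and total_depth < truth.df["varve_bot_mm"].iloc[0]:
        raise ConfigError("record shorter than one varve")
    n_slices = int(np.ceil(total_depth / cfg.slice_len_mm))
    n_per_slice = n_rows * n_cols
    n_spots = n_slices * n_per_slice

    slice_idx = np.repeat(np.arange(n_slices), n_per_slice)
    row = np.tile(np.repeat(np.arange(n_rows), n_cols), n_slices)
    col = np.tile(np.arange(n_cols), n_rows * n_slices)
    depth_mm = (row + 0.5) * pitch_mm
    x_um = (col + 0.5) * cfg.spot_pitch_um
    depth_total = slice_idx * cfg.slice_len_mm + depth_mm

    bot = truth.df["varve_bot_mm"].to_numpy()
    varve = np.searchsorted(bot, depth_total, side="right")
    in_record = varve < len(bot)
    varve_c = np.clip(varve, 0, len(bot) - 1)
    boundary = truth.df["lamina_boundary_mm"].to_numpy()[varve_c]
    dark = in_record & (depth_total < boundary)
    light = in_record & ~dark

    gs = np.full(n_spots, cfg.background_gs)
    gs[dark] = rng.normal(cfg.gs_median + cfg.gs_dark_offset, cfg.gs_sd, dark.sum())
    gs[light] = rng.normal(cfg.gs_median + cfg.gs_light_offset, cfg.gs_sd, light.sum())
    gs = np.clip(gs, 0.0, 255.0)

    # elemental intensity varies continuously with greyscale (colour is
    # itself compositional): Si grows toward light, Fe/Ti/Ca toward dark
    gs_lo = cfg.gs_median + cfg.gs_dark_offset
    gs_hi = cfg.gs_median + cfg.gs_light_offset
    w_light = np.clip((gs - gs_lo) / (gs_hi - gs_lo), 0.0, 1.0)

    def elem(high_in_dark: bool) -> np.ndarray:
        w = 1.0 - w_light if high_in_dark else w_light
        mean = cfg.elem_low + w * (cfg.elem_high - cfg.elem_low)
        vals = rng.normal(mean, cfg.elem_sd)
        vals[~in_record] = 0.0
        return np.clip(vals, 0.0, None)

    ca, fe, ti = elem(True), elem(True), elem(True)
    si = elem(False)

    detected = in_record & (rng.random(n_spots) < cfg.detect_prob)
    sst_season = np.where(dark, truth.df["sst_nonupw"].to_numpy()[varve_c],
                          truth.df["sst_upw"].to_numpy()[varve_c])
    u_true = (cfg.calib_slope * sst_season + cfg.calib_intercept) / cfg.gc_factor
    ratio = np.clip(u_true + rng.normal(0.0, cfg.noise_coeff, n_spots), 0.0, 1.0) \
        if cfg.noise_coeff > 0 else np.clip(u_true, 0.0, 1.0)
    total = rng.lognormal(np.log(cfg.intensity_median), cfg.intensity_logsd, n_spots)
    total = np.where(dark, total * cfg.season_abundance_ratio, total)
    i372 = np.where(detected, total * ratio, 0.0)
    i373 = np.where(detected, total * (1.0 - ratio), 0.0)
    sn372 = i372 * cfg.sn_per_intensity
    sn373 = i373 * cfg.sn_per_intensity

    df = pd.DataFrame({
        "spot_id": np.arange(n_spots),
        "slice_id": np.char.add("S", np.char.zfill(slice_idx.astype(str), 3)),
        "x_um": x_um,
        "y_um": depth_mm * 1000.0,
        "depth_mm": depth_mm,
        "gs": gs,
        "ca": ca, "fe": fe, "ti": ti, "si": si,
        "i372": i372, "i373": i373,
        "sn372": sn372, "sn373": sn373,
    })
    slices = {
        f"S{k:03d}": SliceInfo(cfg.base_depth_cm + k * cfg.slice_len_mm / 10.0,
                               cfg.slice_len_mm, cfg.slice_width_mm)
        for k in range(n_slices)
    }
    return SpotTable(df, slices, validate=False)


def age_depth_model_from_truth(truth: TruthRecord):
    """Exact piecewise-linear age-depth control points implied by the truth.

    Control points are placed at the record top, the sedimentation-rate
    transition and the record bottom; because the rate is constant within
    each era this interpolates every varve boundary exactly.
    """
    from .io import AgeDepthModel

    cfg = truth.config
    df = truth.df
    top_cm = cfg.base_depth_cm
    bottom_cm = cfg.base_depth_cm + truth.total_depth_mm / 10.0
    depths = [top_cm]
    ages = [cfg.age_end]
    old = df["age_kyr_b2k"].to_numpy() > cfg.transition_age
    if old.any() and (~old).any():
        # boundary between the youngest old-era varve and the record above it
        d_trans = float(df.loc[old, "varve_top_mm"].min()) / 10.0 + cfg.base_depth_cm
        depths.append(d_trans)
        ages.append(cfg.transition_age)
    depths.append(bottom_cm)
    ages.append(cfg.age_start)
    return AgeDepthModel(np.asarray(depths), np.asarray(ages))
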