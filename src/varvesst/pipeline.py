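"""End-to-end orchestration: simulate -> reconstruct -> seasonality -> variability.

`run_full_pipeline` drives every stage from a single :class:`RunConfig` and a
single seed, either on a simulated dataset (in which case a truth-vs-recovered
comparison is attached) or on a spot table plus age model read from disk.
Outputs are plain CSV/JSON with provenance headers (config hash, seed,
package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annual, seasonality, simulate, variability
from .annual import CalibrationConfig
from .errors import ValidationError
from .io import AgeDepthModel, SpotTable, compute_delta_gs, depth_to_age
from .simulate import ScenarioConfig, age_depth_model_from_truth, simulate_dataset, simulate_truth
from .variability import NoiseModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs: inputs, constants, QC rules, analysis ages."""

    scenario: ScenarioConfig | None = None        # simulate when given
    spot_table_path: str | None = None            # otherwise read these
    age_model_path: str | None = None
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    sn_min: float = 3.0
    min_spots: int = 10
    background_gs_max: float = 30.0
    transition_midpoint: float = 11.673           # kyr b2k, reflectance-based
    window_halfwidth_yr: float = 200.0
    variability_split: float = 11.66              # kyr b2k
    seasonality_bin_years: float = 5.0
    ramp_start_window: tuple[float, float] = (11.725, 11.8)
    ramp_end_window: tuple[float, float] = (11.6, 11.675)
    smooth_window: int = 15
    seed: int = 0

    def validate(self) -> None:
        if self.scenario is None:
            if self.spot_table_path is None:
                raise ValidationError("spot_table_path is required when not simulating")
            if self.age_model_path is None:
                raise ValidationError("age_model_path is required when not simulating")

    def content_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if callable(obj):
                return getattr(obj, "__name__", "callable")
            return obj
        blob = json.dumps(enc(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of every stage's output for one run."""

    config: RunConfig
    truth: simulate.TruthRecord | None
    spots: SpotTable
    annual_series: pd.DataFrame
    window_stats: pd.DataFrame
    thresholds: dict
    seasonal_series: pd.DataFrame
    ramp_unconstrained: seasonality.RampFitResult
    ramp_constrained: seasonality.RampFitResult | None
    seasonality_test: tuple
    variability_blocks: pd.DataFrame
    variability_test: tuple
    spectrum: variability.SpectrumResult
    recovery: dict | None


def run_full_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute all stages; fully reproducible under a fixed config + seed."""
    config.validate()
    stage = "input"
    try:
        truth = None
        if config.scenario is not None:
            stage = "simulate"
            truth = simulate_truth(config.scenario, seed=config.seed)
            spots = simulate_dataset(truth, seed=config.seed + 1)
            model = age_depth_model_from_truth(truth)
            age_min, age_max = config.scenario.age_end, config.scenario.age_start
        else:
            stage = "read"
            spots = SpotTable.read(config.spot_table_path)
            model = AgeDepthModel.from_csv(config.age_model_path)
            age_min = age_max = None

        stage = "greyscale"
        spots = compute_delta_gs(spots, config.background_gs_max)

        stage = "reconstruct"
        nonbg = ~spots.df["background"].to_numpy(bool)
        depths = spots.composite_depth_cm
        ages = np.full(len(spots.df), np.nan)
        ages[nonbg] = depth_to_age(model, depths[nonbg])
        keep_tbl = SpotTable(spots.df[nonbg], spots.slices, validate=False)
        annual_series = annual.reconstruct_annual(
            keep_tbl, ages[nonbg], calib=config.calibration,
            min_spots=config.min_spots, sn_min=config.sn_min,
            age_min=age_min, age_max=age_max)
        sm = annual.smooth_gaussian(
            np.where(annual_series["missing"], np.nan, annual_series["sst_c"]),
            window=min(config.smooth_window,
                       len(annual_series) - (1 - len(annual_series) % 2)))
        annual_series = annual_series.assign(sst_smooth=sm)
        mid, hw = config.transition_midpoint, config.window_halfwidth_yr * 1e-3
        wstats = annual.window_stats(
            annual_series, [(mid, mid + hw), (mid - hw, mid)])

        stage = "seasonality"
        thresholds = seasonality.find_season_thresholds_by_slice(
            spots, calib=config.calibration, sn_min=config.sn_min)
        seasonal = seasonality.seasonal_sst_series(
            spots, thresholds, ages, calib=config.calibration,
            bin_years=config.seasonality_bin_years, min_spots=config.min_spots,
            sn_min=config.sn_min, age_min=age_min, age_max=age_max)
        ok = ~seasonal["missing"]
        ramp_u = seasonality.fit_ramp(
            seasonal.loc[ok, "age_kyr_b2k"], seasonal.loc[ok, "seasonality_c"],
            exclude_negative=True)
        ramp_c = None
        ages_ok = seasonal.loc[ok, "age_kyr_b2k"]
        if (ages_ok.max() >= config.ramp_start_window[0]
                and ages_ok.min() <= config.ramp_end_window[1]):
            try:
                ramp_c = seasonality.fit_ramp(
                    ages_ok, seasonal.loc[ok, "seasonality_c"],
                    constrain_start=config.ramp_start_window,
                    constrain_end=config.ramp_end_window, exclude_negative=True)
            except ValidationError:
                ramp_c = None
        split_mid = ramp_u.midpoint
        grp_old = seasonal.loc[ok & (seasonal["age_kyr_b2k"] > split_mid), "seasonality_c"]
        grp_new = seasonal.loc[ok & (seasonal["age_kyr_b2k"] <= split_mid), "seasonality_c"]
        seas_test = variability.compare_groups(grp_old, grp_new, test="mann_whitney") \
            if len(grp_old) >= 2 and len(grp_new) >= 2 else (np.nan, np.nan)

        stage = "variability"
        prepared = variability.prepare_series(annual_series, value_col="u37_gc")
        filtered = variability.bandpass_filter(prepared.anomaly, 2.0, 8.0)
        blocks = variability.windowed_variability(filtered, prepared.ages_kyr, 25)
        blocks = variability.correct_variability(
            blocks, prepared.n_spots, model=config.noise, calib=config.calibration)
        old = blocks["age_mid"] > config.variability_split
        var_test = variability.compare_groups(
            blocks.loc[old, "corrected_sd_c"], blocks.loc[~old, "corrected_sd_c"],
            test="t") if old.sum() >= 2 and (~old).sum() >= 2 else (np.nan, np.nan)
        spectrum = variability.redfit_spectrum(prepared.anomaly)

        stage = "report"
        recovery = None
        if truth is not None:
            sc = truth.config
            tr = truth.df
            rec = annual_series.assign(age_key=annual_series["age_kyr_b2k"].round(6))
            tru = tr[["age_kyr_b2k", "sst_annual"]].assign(
                age_key=tr["age_kyr_b2k"].round(6))
            joined = rec.merge(tru[["age_key", "sst_annual"]], on="age_key", how="left")
            resid = (joined.loc[~joined["missing"], "sst_c"]
                     - joined.loc[~joined["missing"], "sst_annual"]).dropna()
            recovery = {
                "true_mean_sst": sc.mean_sst,
                "recovered_window_means": wstats["mean"].tolist(),
                "true_level_before": float(sc.seasonality_at(np.array([sc.age_start]))[0]),
                "true_level_after": float(sc.seasonality_at(np.array([sc.age_end]))[0]),
                "true_step_age": sc.seasonality_step_age,
                "fitted_level_before": ramp_u.level_before,
                "fitted_level_after": ramp_u.level_after,
                "fitted_midpoint": ramp_u.midpoint,
                "annual_rmse": float(np.sqrt(np.nanmean(resid ** 2))) if len(resid) else np.nan,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(config, truth, spots, annual_series, wstats,
                            thresholds, seasonal, ramp_u, ramp_c, seas_test,
                            blocks, var_test, spectrum, recovery)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def _provenance(config: RunConfig) -> str:
    return (f"# varvesst {__version__} | seed {config.seed} | "
            f"config {config.content_hash()}\n")


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Write annual/seasonal/variability tables and fit JSONs with provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(result.config)

    def write_csv(df: pd.DataFrame, name: str) -> None:
        with open(outdir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    write_csv(result.annual_series, "annual_series.csv")
    write_csv(result.seasonal_series, "seasonal_series.csv")
    write_csv(result.variability_blocks, "variability_blocks.csv")
    write_csv(result.window_stats, "window_stats.csv")
    if result.truth is not None:
        write_csv(result.truth.df, "truth.csv")

    def ramp_dict(r):
        return None if r is None else {
            "t_start": r.t_start, "t_end": r.t_end, "midpoint": r.midpoint,
            "level_before": r.level_before, "level_after": r.level_after,
            "rms": r.rms, "constrained": r.constrained}

    report = {
        "provenance": header.strip("# \n"),
        "thresholds": {k: dataclasses.asdict(v) for k, v in result.thresholds.items()},
        "ramp_unconstrained": ramp_dict(result.ramp_unconstrained),
        "ramp_constrained": ramp_dict(result.ramp_constrained),
        "seasonality_mann_whitney": list(result.seasonality_test),
        "variability_t_test": list(result.variability_test),
        "recovery": result.recovery,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
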