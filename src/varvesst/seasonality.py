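"""Season deconvolution from sediment colour and the seasonality ramp.

Varve couplets split the year into a dark non-upwelling lamina (Fe/Ti/Ca
rich, warm) and a light upwelling lamina (Si rich, cool). A per-slice
greyscale-anomaly threshold assigns every alkenone-bearing spot to a season:
the threshold is the integer dGS cut that maximises pooled SST(below) minus
pooled SST(above), constrained to lie lighter than the Ca/Ti/Fe abundance
maxima, darker than the Si maximum, and to leave at least 25% of spots on
each side (15% as a fallback). Season-wise pooling at 5-yr resolution gives
seasonal SST records whose difference is the SST seasonality; its change
over the record is summarised by a constant-ramp-constant least-squares fit
and the season-mean difference can be converted to the peak-to-peak annual
amplitude of an equivalent sinusoid, amplitude = (pi/2) * difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annual
from .annual import CalibrationConfig
from .errors import NoThresholdError, ValidationError
from .io import SpotTable

ELEMENTS = ["ca", "fe", "ti", "si"]


@dataclass
class ElementalProfile:
    """Mean elemental intensity per dGS bin (default bin width 5 GS units)."""

    bin_edges: np.ndarray                  # len n_bins + 1, contiguous
    means: dict                            # element -> array of per-bin means
    counts: np.ndarray                     # spots per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def argmax_center(self, element: str, min_bin_count: int | None = None) -> float:
        """Centre of the bin where the element's mean intensity peaks.

        Sparse tail bins carry unstable means, so bins holding fewer than
        ``min_bin_count`` spots (default: max(25, 1% of spots), echoing the
        25-analyses floor used for binned displays) are excluded from the
        argmax; if no bin reaches the floor all non-empty bins compete.
        """
        if min_bin_count is None:
            min_bin_count = max(25, int(0.01 * self.counts.sum()))
        eligible = self.counts >= min_bin_count
        if not eligible.any():
            eligible = self.counts > 0
        means = np.where(eligible, self.means[element], -np.inf)
        return float(self.bin_centers[int(np.argmax(means))])


@dataclass
class SeasonThreshold:
    """Chosen dGS season split and its diagnostics for one slice/window."""

    window_id: str
    threshold: float
    frac_dark: float                       # fraction classified non-upwelling (below)
    frac_light: float
    sst_dark: float
    sst_light: float
    argmax_centers: dict
    fallback_used: bool


@dataclass
class RampFitResult:
    """Constant-linear-constant fit on the b2k axis (t_start older)."""

    t_start: float
    t_end: float
    level_before: float                    # level for t >= t_start (older side)
    level_after: float
    rss: float
    rms: float
    constrained: bool

    @property
    def midpoint(self) -> float:
        return (self.t_start + self.t_end) / 2.0


# ---------------------------------------------------------------------------
# Elemental profile
# ---------------------------------------------------------------------------

def elemental_gs_profile(table: SpotTable, bin_size: float = 5.0,
                         df: pd.DataFrame | None = None) -> ElementalProfile:
    """Bin non-background spots by dGS and average each element per bin.

    Bin edges are aligned to multiples of ``bin_size`` and cover the observed
    dGS range contiguously. Requires :func:`varvesst.io.compute_delta_gs` to
    have run.
    """
    data = table.nonbackground() if df is None else df
    if "delta_gs" not in data.columns or data["delta_gs"].isna().all():
        raise ValidationError("delta_gs not computed; run compute_delta_gs first")
    dgs = data["delta_gs"].to_numpy(float)
    lo = np.floor(dgs.min() / bin_size) * bin_size
    hi = np.ceil(dgs.max() / bin_size) * bin_size
    if hi <= lo:
        hi = lo + bin_size
    edges = np.arange(lo, hi + bin_size / 2, bin_size)
    idx = np.clip(np.digitize(dgs, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    means = {}
    with np.errstate(invalid="ignore"):
        for el in ELEMENTS:
            sums = np.bincount(idx, weights=data[el].to_numpy(float),
                               minlength=len(edges) - 1)
            means[el] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ElementalProfile(edges, means, counts)


# ---------------------------------------------------------------------------
# Threshold search
# ---------------------------------------------------------------------------

def find_season_threshold(table: SpotTable,
                          profile: ElementalProfile | None = None,
                          calib: CalibrationConfig = CalibrationConfig(),
                          min_fraction: float = 0.25,
                          fallback_fraction: float = 0.15,
                          window_id: str = "",
                          sn_min: float = 3.0) -> SeasonThreshold:
    """Exhaustive search for the dGS cut separating the two seasons.

    Alkenone-bearing spots (QC as in the annual reconstruction) are split at
    every candidate integer threshold into 'below' (darker, non-upwelling)
    and 'above' (lighter, upwelling); both sides are pooled to a single SST
    and the candidate maximising SST(below) - SST(above) wins, subject to:
    (1) the threshold is lighter than the dGS bins where Ca, Ti and Fe peak,
    (2) darker than the bin where Si peaks, and (3) each side holds at least
    ``min_fraction`` of the spots, relaxed to ``fallback_fraction`` only when
    (1)+(2) make (3) infeasible. Ties break toward the smallest |threshold|.
    """
    if profile is None:
        profile = elemental_gs_profile(table)
    qc = annual.qc_filter_spots(table, sn_min=sn_min)
    df = qc.nonbackground()
    if df.empty or df["delta_gs"].isna().all():
        raise NoThresholdError(f"window {window_id!r}: no usable alkenone spots")
    dgs = df["delta_gs"].to_numpy(float)
    i372 = df["i372"].to_numpy(float)
    i373 = df["i373"].to_numpy(float)

    argmax_centers = {el: profile.argmax_center(el) for el in ELEMENTS}
    lo_bound = max(argmax_centers["ca"], argmax_centers["ti"], argmax_centers["fe"])
    hi_bound = argmax_centers["si"]
    # candidate integer thresholds, bin size 1, strictly between the elemental maxima
    cand = np.arange(np.floor(lo_bound) + 1, np.ceil(hi_bound), 1.0)
    cand = cand[(cand > lo_bound) & (cand < hi_bound)]
    if cand.size == 0:
        raise NoThresholdError(
            f"window {window_id!r}: elemental constraints leave no candidate threshold")

    order = np.argsort(dgs, kind="stable")
    dgs_s = dgs[order]
    c372 = np.concatenate([[0.0], np.cumsum(i372[order])])
    c373 = np.concatenate([[0.0], np.cumsum(i373[order])])
    n = len(dgs_s)
    k = np.searchsorted(dgs_s, cand, side="left")  # spots with dgs < t are 'below'

    b372, b373 = c372[k], c373[k]
    a372, a373 = c372[n] - b372, c373[n] - b373
    with np.errstate(invalid="ignore", divide="ignore"):
        u_b = b372 / (b372 + b373)
        u_a = a372 / (a372 + a373)
    sst_b = (calib.gc_factor * u_b - calib.intercept) / calib.slope
    sst_a = (calib.gc_factor * u_a - calib.intercept) / calib.slope
    diff = sst_b - sst_a
    frac_b = k / n
    frac_a = 1.0 - frac_b
    valid = np.isfinite(diff)

    def pick(limit: float):
        ok = valid & (frac_b >= limit) & (frac_a >= limit)
        if not ok.any():
            return None
        idx = np.flatnonzero(ok)
        best_diff = diff[idx].max()
        ties = idx[np.isclose(diff[idx], best_diff, rtol=0, atol=1e-12)]
        return int(ties[np.argmin(np.abs(cand[ties]))])

    fallback_used = False
    best = pick(min_fraction)
    if best is None:
        best = pick(fallback_fraction)
        fallback_used = True
    if best is None:
        raise NoThresholdError(
            f"window {window_id!r}: no threshold satisfies the spot-fraction limits")
    return SeasonThreshold(window_id, float(cand[best]), float(frac_b[best]),
                           float(frac_a[best]), float(sst_b[best]),
                           float(sst_a[best]), argmax_centers, fallback_used)


def find_season_thresholds_by_slice(table: SpotTable, **kwargs) -> dict:
    """Per-slice threshold search (the default treatment); returns id -> result."""
    out = {}
    for sid in sorted(table.slices):
        sub = SpotTable(table.df[table.df["slice_id"] == sid], table.slices,
                        validate=False)
        if not len(sub):
            continue
        out[sid] = find_season_threshold(sub, window_id=sid, **kwargs)
    return out


# ---------------------------------------------------------------------------
# Seasonal series
# ---------------------------------------------------------------------------

def seasonal_sst_series(table: SpotTable, thresholds, ages: np.ndarray,
                        calib: CalibrationConfig = CalibrationConfig(),
                        bin_years: float = 5.0, min_spots: int = 10,
                        sn_min: float = 3.0, age_min: float | None = None,
                        age_max: float | None = None) -> pd.DataFrame:
    """Season-split pooled SST at ``bin_years`` resolution and its difference.

    ``thresholds`` is either a single :class:`SeasonThreshold` (whole-record
    split) or a mapping slice_id -> threshold. Spots darker than their
    window's threshold are the non-upwelling season. Per bin and season,
    intensities are pooled exactly as in the annual reconstruction; bins
    where either season has fewer than ``min_spots`` spots have that value
    (and the seasonality) missing.
    """
    qc = annual.qc_filter_spots(table, sn_min=sn_min)
    mask_src = table.df
    keep = (
        (mask_src["sn372"].to_numpy(float) >= sn_min)
        & (mask_src["sn373"].to_numpy(float) >= sn_min)
        & (mask_src["i372"].to_numpy(float) > 0)
        & (mask_src["i373"].to_numpy(float) > 0)
    )
    if "background" in mask_src.columns:
        keep &= ~mask_src["background"].to_numpy(bool)
    ages = np.asarray(ages, float)[keep]

    df = qc.df
    if isinstance(thresholds, SeasonThreshold):
        thr = np.full(len(df), thresholds.threshold)
    else:
        thr = df["slice_id"].map({sid: t.threshold for sid, t in thresholds.items()})
        if thr.isna().any():
            raise ValidationError("spots belong to a slice without a season threshold")
        thr = thr.to_numpy(float)
    dark = df["delta_gs"].to_numpy(float) < thr

    out = None
    for name, sel in (("nonupw", dark), ("upw", ~dark)):
        sub = SpotTable(df[sel], table.slices, validate=False)
        pooled = annual.pool_by_age(sub, ages[sel], bin_years=bin_years,
                                    min_spots=min_spots, age_min=age_min,
                                    age_max=age_max)
        ok = ~pooled["missing"].to_numpy(bool)
        sst = np.full(len(pooled), np.nan)
        if ok.any():
            u = annual.compute_uk37(pooled.loc[ok, "i372_sum"].to_numpy(),
                                    pooled.loc[ok, "i373_sum"].to_numpy())
            sst[ok] = (calib.gc_factor * u - calib.intercept) / calib.slope
        cols = pd.DataFrame({
            "age_kyr_b2k": pooled["age_kyr_b2k"],
            f"sst_{name}": sst,
            f"n_{name}": pooled["n_spots"],
            f"missing_{name}": pooled["missing"],
        })
        out = cols if out is None else out.merge(cols, on="age_kyr_b2k", how="outer")
    out = out.sort_values("age_kyr_b2k", ascending=False, ignore_index=True)
    out["seasonality_c"] = out["sst_nonupw"] - out["sst_upw"]
    out["missing"] = out["missing_nonupw"].fillna(True).astype(bool) \
        | out["missing_upw"].fillna(True).astype(bool)
    return out


# ---------------------------------------------------------------------------
# Ramp fitting
# ---------------------------------------------------------------------------

def _ramp_weights(t: np.ndarray, ts: float, te: float) -> np.ndarray:
    """Weight of the 'before' level at each time (b2k axis, ts >= te)."""
    if ts == te:
        return (t >= ts).astype(float)
    return np.clip((t - te) / (ts - te), 0.0, 1.0)


def fit_ramp(t: np.ndarray, y: np.ndarray,
             constrain_start: tuple[float, float] | None = None,
             constrain_end: tuple[float, float] | None = None,
             exclude_negative: bool = True) -> RampFitResult:
    """Least-squares constant-linear-constant ('ramp') fit on the b2k axis.

    The model is ``level_before`` for t >= t_start (older), ``level_after``
    for t <= t_end, linear in between; breakpoints are searched exhaustively
    over pairs of observed time-grid points (t_start >= t_end) with the two
    levels estimated analytically per pair. Negative-valued points are
    dropped first when ``exclude_negative``. RSS ties break toward the
    shortest ramp duration. Constraint intervals (lo, hi) restrict the
    respective breakpoint; an interval holding no grid point raises.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    ok = np.isfinite(t) & np.isfinite(y)
    if exclude_negative:
        ok &= y >= 0
    t, y = t[ok], y[ok]
    if len(t) < 6:
        raise ValidationError("ramp fit needs at least 6 points")
    grid = np.unique(t)

    def restrict(grid, interval, name):
        if interval is None:
            return grid
        lo, hi = min(interval), max(interval)
        sub = grid[(grid >= lo) & (grid <= hi)]
        if sub.size == 0:
            raise ValidationError(f"no grid points inside the {name} constraint window")
        return sub

    starts = restrict(grid, constrain_start, "start")
    ends = restrict(grid, constrain_end, "end")
    constrained = constrain_start is not None or constrain_end is not None

    best = None
    for ts in starts:
        for te in ends[ends <= ts]:
            w = _ramp_weights(t, ts, te)
            # 2-parameter least squares: y ~ L1*w + L2*(1-w)
            a11 = np.dot(w, w)
            a22 = np.dot(1 - w, 1 - w)
            a12 = np.dot(w, 1 - w)
            b1 = np.dot(w, y)
            b2 = np.dot(1 - w, y)
            det = a11 * a22 - a12 * a12
            if det <= 1e-15:
                # degenerate (all weights equal): single-level fit
                l1 = l2 = y.mean()
            else:
                l1 = (a22 * b1 - a12 * b2) / det
                l2 = (a11 * b2 - a12 * b1) / det
            resid = y - (l1 * w + l2 * (1 - w))
            rss = float(np.dot(resid, resid))
            dur = ts - te
            if best is None:
                best = (rss, dur, ts, te, l1, l2)
                continue
            tol = 1e-10 * (1.0 + best[0])
            if rss < best[0] - tol or (rss <= best[0] + tol and dur < best[1]):
                best = (rss, dur, ts, te, l1, l2)
    rss, dur, ts, te, l1, l2 = best
    return RampFitResult(float(ts), float(te), float(l1), float(l2), rss,
                         float(np.sqrt(rss / len(t))), constrained)


def amplitude_from_seasonality(d: float) -> float:
    """Peak-to-peak annual amplitude of a sinusoid with half-cycle mean gap d.

    A sinusoid of half-amplitude a has half-cycle means +/- 2a/pi, so the
    season-mean difference is 4a/pi and the peak-to-peak amplitude 2a equals
    (pi/2) * d.
    """
    if d < 0:
        raise ValidationError("season-mean difference must be >= 0")
    return float(np.pi / 2.0 * d)
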