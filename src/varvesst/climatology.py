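"""Modern SST seasonality from monthly climatologies.

The palaeo record resolves two seasons per year, so the comparable modern
statistic splits the twelve monthly SST values of each year into two
complementary blocks of consecutive calendar months (each at least three
months long, wrap across December allowed) and takes the largest absolute
difference between the block means. Averaged over years this gives the
modern two-season SST seasonality (about 1.6 degC at the Cariaco grid cell
for 1980-2020).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MONTH_LABELS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


def monthly_seasonality(values, min_block: int = 3):
    """Optimal two-block split of one year of monthly SST.

    ``values`` are the twelve monthly means (deg C). All splits of the
    calendar year into two complementary circular blocks of consecutive
    months, each of length ``min_block`` to ``12 - min_block``, are
    enumerated; the split with the largest absolute mean difference wins.

    Returns ``(seasonality, warm_months)`` where ``warm_months`` is the
    1-based month tuple of the warmer block in deposition order.
    """
    x = np.asarray(values, float)
    if x.shape != (12,):
        raise ValidationError("exactly 12 monthly values are required")
    if not np.all(np.isfinite(x)):
        raise ValidationError("monthly values must be finite (no missing months)")
    best = None
    for start in range(12):
        for length in range(min_block, 12 - min_block + 1):
            block = [(start + k) % 12 for k in range(length)]
            other = [m for m in range(12) if m not in block]
            diff = abs(x[block].mean() - x[other].mean())
            if best is None or diff > best[0] + 1e-12:
                warm = block if x[block].mean() >= x[other].mean() else None
                best = (diff, start, length, warm)
    diff, start, length, warm = best
    if warm is None:  # warmer side is the complement; express it as its own block
        comp_start = (start + length) % 12
        warm = [(comp_start + k) % 12 for k in range(12 - length)]
    return float(diff), tuple(m + 1 for m in warm)


def multi_year_seasonality(monthly: pd.DataFrame, min_block: int = 3):
    """Per-year optimal splits, their mean and the modal warm-season label.

    ``monthly`` must hold a ``year`` column and twelve monthly columns
    (``m1``..``m12``). Returns ``(mean_seasonality, modal_warm_months,
    per_year_table)``.
    """
    cols = [f"m{k}" for k in range(1, 13)]
    for c in ["year"] + cols:
        if c not in monthly.columns:
            raise FormatError(f"{c} missing")
    rows = []
    for rec in monthly.itertuples():
        vals = [getattr(rec, c) for c in cols]
        s, warm = monthly_seasonality(vals, min_block)
        rows.append({"year": int(rec.year), "seasonality_c": s,
                     "warm_months": warm,
                     "warm_label": "-".join(MONTH_LABELS[m - 1] for m in warm)})
    table = pd.DataFrame(rows)
    tally = table["warm_months"].value_counts()
    modal = tally.index[0]
    return float(table["seasonality_c"].mean()), tuple(modal), table


def load_monthly_csv(path: str | Path) -> pd.DataFrame:
    """Read a plain (year, m1..m12) CSV of monthly SST."""
    df = pd.read_csv(path)
    for c in ["year"] + [f"m{k}" for k in range(1, 13)]:
        if c not in df.columns:
            raise FormatError(f"{c} missing")
    return df


def load_monthly_netcdf(path: str | Path, lat: float = 10.5, lon: float = -65.0,
                        start_year: int = 1980, end_year: int = 2020,
                        var: str = "sst") -> pd.DataFrame:
    """Extract a (year, m1..m12) table from a gridded monthly SST NetCDF file.

    Uses the nearest grid cell to (lat, lon). Requires an xarray backend able
    to open the file; HadISST-style files are the intended input.
    """
    import xarray as xr

    ds = xr.open_dataset(path)
    da = ds[var]
    lat_name = "latitude" if "latitude" in da.dims else "lat"
    lon_name = "longitude" if "longitude" in da.dims else "lon"
    cell = da.sel({lat_name: lat, lon_name: lon}, method="nearest")
    frame = cell.to_dataframe().reset_index()
    time = pd.to_datetime(frame["time"])
    frame["year"] = time.dt.year
    frame["month"] = time.dt.month
    frame = frame[(frame["year"] >= start_year) & (frame["year"] <= end_year)]
    pivot = frame.pivot_table(index="year", columns="month", values=var)
    pivot = pivot.dropna()
    out = pd.DataFrame({"year": pivot.index.to_numpy()})
    for k in range(1, 13):
        out[f"m{k}"] = pivot[k].to_numpy()
    return out
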