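"""Spot tables, lamina tilt correction, age-depth models and greyscale normalisation.

The atomic input of the pipeline is a *spot table*: one row per laser spot of a
mass-spectrometry-imaging (MSI) run on a varved-sediment thin section, carrying
position on the slice, depth below the slice top, sediment greyscale, micro-XRF
elemental intensities (Ca, Fe, Ti, Si) and the intensities and signal-to-noise
of the two alkenones (C37:2, C37:3) entering the U37K' palaeothermometer.

Depths are measured in mm from the top of each 5-cm slice at spot centres;
composite depth below seafloor adds the slice offset. Greyscale is 8-bit
(0 = black, 255 = white); light laminae (upwelling season) sit above the slice
median, dark laminae (non-upwelling season) below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical column order of a spot table on disk (tab-separated).
SPOT_COLUMNS = [
    "spot_id", "slice_id", "x_um", "y_um", "depth_mm", "gs",
    "ca", "fe", "ti", "si", "i372", "i373", "sn372", "sn373",
]

#: Columns filled by processing steps; optional on disk.
EXTRA_COLUMNS = ["delta_gs", "background"]

_INTENSITY_COLUMNS = ["ca", "fe", "ti", "si", "i372", "i373", "sn372", "sn373"]
_SLICE_TAG = "# slice"


@dataclass(frozen=True)
class SliceInfo:
    """Metadata of one thin-section slice.

    Parameters
    ----------
    offset_cm_bsf
        Composite depth of the slice top, cm below seafloor.
    length_mm
        Downcore extent of the slice (default slices are 5 cm = 50 mm).
    width_mm
        Lateral extent of the rastered area.
    """

    offset_cm_bsf: float
    length_mm: float
    width_mm: float


class SpotTable:
    """Per-laser-spot records of one or more slices plus slice metadata.

    The record collection is held as a :class:`pandas.DataFrame` with the
    columns in :data:`SPOT_COLUMNS` (plus ``delta_gs``/``background`` once
    greyscale normalisation has run). All spots must reference a declared
    slice and sit inside it.
    """

    def __init__(self, df: pd.DataFrame, slices: Mapping[str, SliceInfo],
                 validate: bool = True):
        missing = [c for c in SPOT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{missing[0]} missing")
        extras = [c for c in EXTRA_COLUMNS if c in df.columns]
        self.df = df[SPOT_COLUMNS + extras].reset_index(drop=True)
        self.slices = dict(slices)
        if validate:
            self._validate()

    # -- container basics ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "SpotTable":
        return SpotTable(self.df.copy(), dict(self.slices), validate=False)

    def _validate(self) -> None:
        df = self.df
        unknown = set(df["slice_id"].unique()) - set(self.slices)
        if unknown:
            raise ValidationError(f"records reference undeclared slice(s): {sorted(unknown)}")
        gs = df["gs"].to_numpy(float)
        if np.any(gs < 0) or np.any(gs > 255):
            bad = df.loc[(gs < 0) | (gs > 255), "spot_id"].iloc[0]
            raise ValidationError(f"greyscale outside [0, 255] at spot_id={bad}")
        for col in _INTENSITY_COLUMNS:
            vals = df[col].to_numpy(float)
            if np.any(vals < 0):
                bad = df.loc[vals < 0, "spot_id"].iloc[0]
                raise ValidationError(f"negative intensity in column {col} at spot_id={bad}")
        for sid, info in self.slices.items():
            d = df.loc[df["slice_id"] == sid, "depth_mm"].to_numpy(float)
            if d.size and (d.min() < -1e-9 or d.max() > info.length_mm + 1e-9):
                raise ValidationError(
                    f"depth outside [0, {info.length_mm}] mm in slice {sid}")

    # -- derived quantities -------------------------------------------------

    @property
    def composite_depth_cm(self) -> np.ndarray:
        """Depth below seafloor of every spot, cm (slice offset + in-slice depth)."""
        offsets = self.df["slice_id"].map(
            {sid: info.offset_cm_bsf for sid, info in self.slices.items()})
        return offsets.to_numpy(float) + self.df["depth_mm"].to_numpy(float) / 10.0

    def nonbackground(self) -> pd.DataFrame:
        """Records not flagged as black background (requires compute_delta_gs)."""
        if "background" not in self.df.columns:
            return self.df
        return self.df[~self.df["background"].astype(bool)]

    # -- I/O ----------------------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write the table as tab-separated text with slice-metadata header lines."""
        path = Path(path)
        with open(path, "w") as fh:
            for sid in sorted(self.slices):
                info = self.slices[sid]
                fh.write(f"{_SLICE_TAG}\t{sid}\t{info.offset_cm_bsf}\t"
                         f"{info.length_mm}\t{info.width_mm}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SpotTable":
        """Read a table written by :meth:`write`; read∘write is the identity."""
        path = Path(path)
        slices: dict[str, SliceInfo] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                parts = line.rstrip("\n").split("\t")
                if parts[0] != "# slice" or len(parts) != 5:
                    raise FormatError(f"unrecognised header line: {line.strip()!r}")
                slices[parts[1]] = SliceInfo(float(parts[2]), float(parts[3]),
                                             float(parts[4]))
        df = pd.read_csv(path, sep="\t", comment="#")
        for col in SPOT_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"{col} missing")
        if "background" in df.columns:
            df["background"] = df["background"].astype(bool)
        return cls(df, slices)


def io_spot_table(path: str | Path, direction: str = "read",
                  table: SpotTable | None = None) -> SpotTable:
    """Read or write a spot table at ``path``.

    Functional wrapper around :meth:`SpotTable.read` / :meth:`SpotTable.write`
    so the operation has a single entry point. Returns the table either way.
    """
    if direction == "read":
        return SpotTable.read(path)
    if direction == "write":
        if table is None:
            raise ValidationError("direction='write' requires a table")
        table.write(path)
        return table
    raise ValidationError(f"direction must be 'read' or 'write', got {direction!r}")


# ---------------------------------------------------------------------------
# Lamina tilt correction
# ---------------------------------------------------------------------------

@dataclass
class LaminaTiePoints:
    """Tie points tracing one lamina surface across the slice width.

    At least four points per lamina are required; ``points`` is an (n, 2)
    array of (x_um, depth_mm) with strictly increasing x.
    """

    lamina_id: str
    points: np.ndarray
    slice_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError(f"lamina {self.lamina_id}: points must be (n, 2)")
        if len(self.points) < 4:
            raise ValidationError(
                f"lamina {self.lamina_id}: a minimum of four tie points per lamina is required")
        x = self.points[:, 0]
        if np.any(np.diff(x) <= 0):
            raise ValidationError(f"lamina {self.lamina_id}: x must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def depth(self) -> np.ndarray:
        return self.points[:, 1]


def correct_tilt(table: SpotTable,
                 tiepoints: Sequence[LaminaTiePoints]) -> SpotTable:
    """Remove lateral tilt of laminae from spot depths.

    Each lamina surface is modelled as piecewise-linear in x through its tie
    points; the surface's offset at a spot's x (relative to the lamina's mean
    tie-point depth) is subtracted from the spot depth, using the nearest
    lamina surface above the spot (the nearest surface overall if none lies
    above). Tie points of a corrected lamina become iso-depth.
    """
    if not tiepoints:
        return table.copy()
    out = table.copy()
    by_slice: dict[str | None, list[LaminaTiePoints]] = {}
    for tp in tiepoints:
        by_slice.setdefault(tp.slice_id, []).append(tp)
    if None in by_slice:
        if len(table.slices) != 1:
            raise ValidationError(
                "tie points without slice_id require a single-slice table")
        only = next(iter(table.slices))
        by_slice[only] = by_slice.get(only, []) + by_slice.pop(None)

    depth = out.df["depth_mm"].to_numpy(float).copy()
    for sid, tps in by_slice.items():
        mask = (out.df["slice_id"] == sid).to_numpy()
        if not mask.any():
            continue
        x = out.df.loc[mask, "x_um"].to_numpy(float)
        d = depth[mask]
        surfs = np.vstack([np.interp(x, tp.x, tp.depth) for tp in tps])
        refs = np.array([tp.depth.mean() for tp in tps])
        offsets = surfs - refs[:, None]
        above = surfs <= d[None, :] + 1e-9
        surf_above = np.where(above, surfs, -np.inf)
        choice = np.argmax(surf_above, axis=0)
        none_above = ~above.any(axis=0)
        if none_above.any():
            nearest = np.argmin(np.abs(surfs - d[None, :]), axis=0)
            choice[none_above] = nearest[none_above]
        d_corr = d - offsets[choice, np.arange(len(d))]
        depth[mask] = d_corr
    out.df["depth_mm"] = depth
    # correction may nudge spots marginally past slice ends; do not re-validate range
    return SpotTable(out.df, out.slices, validate=False)


# ---------------------------------------------------------------------------
# Age-depth model
# ---------------------------------------------------------------------------

@dataclass
class AgeDepthModel:
    """Monotone control points mapping composite depth (cm bsf) to age (kyr b2k).

    Ages are interpolated piecewise-linearly between control points; queries
    outside the control range raise (no extrapolation).
    """

    depths_cm: np.ndarray
    ages_kyr: np.ndarray

    def __post_init__(self) -> None:
        self.depths_cm = np.asarray(self.depths_cm, float)
        self.ages_kyr = np.asarray(self.ages_kyr, float)
        if self.depths_cm.size < 2:
            raise ValidationError("age-depth model needs at least 2 control points")
        if self.depths_cm.size != self.ages_kyr.size:
            raise ValidationError("depth and age arrays differ in length")
        if np.any(np.diff(self.depths_cm) <= 0):
            raise ValidationError("control depths must be strictly increasing")
        if np.any(np.diff(self.ages_kyr) <= 0):
            raise ValidationError("control ages must increase with depth (older = deeper)")

    def age_at(self, depth_cm_bsf):
        depth = np.asarray(depth_cm_bsf, float)
        lo, hi = self.depths_cm[0], self.depths_cm[-1]
        if np.any(depth < lo - 1e-12) or np.any(depth > hi + 1e-12):
            raise ValidationError(
                f"depth outside control range [{lo}, {hi}] cm; no extrapolation")
        age = np.interp(depth, self.depths_cm, self.ages_kyr)
        return float(age) if np.isscalar(depth_cm_bsf) else age

    @classmethod
    def from_csv(cls, path: str | Path) -> "AgeDepthModel":
        df = pd.read_csv(path)
        for col in ("depth_cm_bsf", "age_kyr_b2k"):
            if col not in df.columns:
                raise FormatError(f"{col} missing")
        return cls(df["depth_cm_bsf"].to_numpy(), df["age_kyr_b2k"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"depth_cm_bsf": self.depths_cm,
                      "age_kyr_b2k": self.ages_kyr}).to_csv(path, index=False)


def depth_to_age(model: AgeDepthModel, depth_cm_bsf):
    """Age (kyr b2k) at composite depth(s), by linear interpolation."""
    return model.age_at(depth_cm_bsf)


# ---------------------------------------------------------------------------
# Greyscale normalisation
# ---------------------------------------------------------------------------

def compute_delta_gs(table: SpotTable, background_gs_max: float = 30.0) -> SpotTable:
    """Flag black background and compute per-slice greyscale anomalies.

    Spots with ``gs <= background_gs_max`` are flagged ``background`` and are
    excluded from all downstream statistics. ``delta_gs`` is the spot
    greyscale minus the median greyscale of the non-background spots of the
    same slice, so that per slice ``median(delta_gs | not background) == 0``.
    """
    out = table.copy()
    gs = out.df["gs"].to_numpy(float)
    background = gs <= background_gs_max
    delta = np.full(len(out.df), np.nan)
    for sid in out.slices:
        in_slice = (out.df["slice_id"] == sid).to_numpy()
        keep = in_slice & ~background
        if in_slice.any() and not keep.any():
            raise ValidationError(f"slice {sid} has zero non-background spots")
        if keep.any():
            med = np.median(gs[keep])
            delta[keep] = gs[keep] - med
    out.df["delta_gs"] = delta
    out.df["background"] = background
    return SpotTable(out.df, out.slices, validate=False)
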