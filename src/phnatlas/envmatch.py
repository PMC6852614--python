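"""Attach gridded climatology values to sampling stations.

Stations are matched to the nearest non-missing grid node by planar
Euclidean distance in (latitude, longitude) degrees with longitude wrapped
at +/-180 (mirroring a kd-tree nearest-neighbour search on degree
coordinates), then to the nearest depth level at that horizontal position.
A match is accepted only inside a per-axis tolerance box; otherwise the
station's value is missing. Two presets reproduce the standard policies:

* ``woa``    -- 1 degree latitude/longitude, 5 m depth, annual fields;
* ``pisces`` -- 0.3 degree, 5 m depth, monthly fields (the sample's month
  restricts the candidate nodes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from phnatlas.io import SampleTable, ValidationError

__all__ = [
    "ClimatologyGrid",
    "MatchPolicy",
    "PRESETS",
    "read_climatology",
    "write_climatology",
    "match_stations",
    "derive_ratios",
]


@dataclass
class ClimatologyGrid:
    """Long-format gridded field: columns lat, lon, depth, [month], value.

    Missing cells are NaN values; they are skipped during matching so the
    next-nearest non-missing node wins.
    """

    table: pd.DataFrame
    variable: str = "value"
    units: str = ""

    def __post_init__(self) -> None:
        t = self.table
        required = {"lat", "lon", "depth", "value"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"climatology missing columns: {sorted(missing)}")
        if len(t) == 0:
            raise ValidationError("empty climatology grid")
        key_cols = ["lat", "lon", "depth"] + (["month"] if self.monthly else [])
        if t.duplicated(subset=key_cols).any():
            raise ValidationError("duplicate grid nodes")
        if self.monthly:
            m = t["month"]
            if ((m < 1) | (m > 12)).any():
                raise ValidationError("month outside 1..12")
        self.table = t.reset_index(drop=True)

    @property
    def monthly(self) -> bool:
        return "month" in self.table.columns


@dataclass(frozen=True)
class MatchPolicy:
    """Per-axis acceptance box for station-to-grid matching."""

    lat_tol: float
    lon_tol: float
    depth_tol: float
    temporal: str = "annual"  # or "monthly"

    def __post_init__(self) -> None:
        if min(self.lat_tol, self.lon_tol, self.depth_tol) <= 0:
            raise ValidationError("tolerances must be > 0")
        if self.temporal not in ("annual", "monthly"):
            raise ValidationError("temporal must be 'annual' or 'monthly'")


PRESETS: dict[str, MatchPolicy] = {
    "woa": MatchPolicy(lat_tol=1.0, lon_tol=1.0, depth_tol=5.0, temporal="annual"),
    "pisces": MatchPolicy(lat_tol=0.3, lon_tol=0.3, depth_tol=5.0, temporal="monthly"),
}


def read_climatology(
    path: str | Path, variable: str = "value", units: str = ""
) -> ClimatologyGrid:
    t = pd.read_csv(path, sep="\t")
    return ClimatologyGrid(t, variable=variable, units=units)


def write_climatology(grid: ClimatologyGrid, path: str | Path) -> None:
    grid.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _wrap_lon(delta: np.ndarray) -> np.ndarray:
    """Signed longitude difference wrapped to (-180, 180]."""
    return (delta + 180.0) % 360.0 - 180.0


def match_stations(
    samples: SampleTable,
    grid: ClimatologyGrid,
    policy: MatchPolicy,
) -> pd.DataFrame:
    """Nearest-neighbour climatology value per sample.

    Returns a frame indexed by sample_id with columns ``value`` (NaN when
    no node falls inside the tolerance box), ``grid_lat``, ``grid_lon``,
    ``grid_depth``. Deterministic: nearest-node ties are broken by lowest
    (lat, lon, depth) lexicographic order.
    """
    if policy.temporal == "monthly":
        if not grid.monthly:
            raise ValidationError("monthly policy requires a monthly grid")
        if "month" not in samples.table.columns:
            raise ValidationError("monthly policy requires sample months")

    nodes_all = grid.table.dropna(subset=["value"])
    if len(nodes_all) == 0:
        raise ValidationError("climatology grid has no non-missing cells")

    out = []
    for row in samples.table.itertuples(index=False):
        rec = {
            "sample_id": row.sample_id,
            "value": np.nan,
            "grid_lat": np.nan,
            "grid_lon": np.nan,
            "grid_depth": np.nan,
        }
        lat, lon, depth = row.latitude, row.longitude, row.depth
        if not (np.isfinite(lat) and np.isfinite(lon)):
            warnings.warn(f"sample {row.sample_id}: missing coordinates", stacklevel=2)
            out.append(rec)
            continue
        nodes = nodes_all
        if policy.temporal == "monthly":
            month = getattr(row, "month", np.nan)
            if pd.isna(month):
                warnings.warn(f"sample {row.sample_id}: missing month", stacklevel=2)
                out.append(rec)
                continue
            nodes = nodes_all[nodes_all["month"] == int(month)]
            if len(nodes) == 0:
                out.append(rec)
                continue

        dlat = nodes["lat"].to_numpy(float) - lat
        dlon = _wrap_lon(nodes["lon"].to_numpy(float) - lon)
        d2 = dlat * dlat + dlon * dlon
        at_min = np.flatnonzero(d2 == d2.min())
        cand = nodes.iloc[at_min]
        ddepth = np.abs(cand["depth"].to_numpy(float) - depth)
        order = np.lexsort(
            (
                cand["depth"].to_numpy(float),
                cand["lon"].to_numpy(float),
                cand["lat"].to_numpy(float),
                ddepth,
            )
        )
        best = cand.iloc[order[0]]
        if (
            abs(best["lat"] - lat) <= policy.lat_tol
            and abs(_wrap_lon(np.array([best["lon"] - lon]))[0]) <= policy.lon_tol
            and abs(best["depth"] - depth) <= policy.depth_tol
        ):
            rec.update(
                value=float(best["value"]),
                grid_lat=float(best["lat"]),
                grid_lon=float(best["lon"]),
                grid_depth=float(best["depth"]),
            )
        out.append(rec)
    return pd.DataFrame(out).set_index("sample_id")


def derive_ratios(
    covariates: pd.DataFrame, pairs: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Add ratio covariates like Fe:Pi or N:P.

    ``pairs`` lists (numerator, denominator) column names; a ratio is
    missing wherever either operand is missing or the denominator is 0.
    """
    if pairs is None:
        pairs = [("Fe", "Pi"), ("N", "Pi")]
    out = covariates.copy()
    for num, den in pairs:
        if num not in out.columns or den not in out.columns:
            continue
        denom = out[den].to_numpy(float)
        numer = out[num].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = numer / denom
        ratio[~np.isfinite(ratio)] = np.nan
        ratio[denom == 0] = np.nan
        out[f"{num}:{den}"] = ratio
    return out
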