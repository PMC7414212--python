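"""Readers, writers and run configuration.

Station temperature records and event/metric tables travel as CSV;
gridded SST travels as NetCDF (via xarray, scipy backend); run
configuration is a YAML file.  Station-file dialects (column names,
delimiter, rows to skip) are declared in configuration rather than
sniffed, so a run is reproducible from its config alone.

Dates are serialized ISO-8601 and temperatures at 0.001 °C precision;
event categories are written both as roman numerals and integers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .mhw_core import (
    Climatology,
    GridCell,
    GridSeries,
    MHWEvent,
    TemperatureSeries,
    infer_cadence,
)
from .exceedance_metrics import AnnualMetricSeries

__all__ = [
    "TableDialect",
    "RunConfig",
    "read_temperature_table",
    "write_temperature_table",
    "read_sst_grid",
    "write_sst_grid",
    "grid_to_dataset",
    "write_event_table",
    "read_event_table",
    "write_annual_metrics",
    "read_annual_metrics",
    "load_config",
]

logger = logging.getLogger("mhwkelp")

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV"}
ROMAN_INV = {v: k for k, v in ROMAN.items()}

# physically plausible range for coastal sea temperature, °C
TEMP_MIN, TEMP_MAX = -3.0, 40.0


@dataclass(frozen=True)
class TableDialect:
    """Declared layout of a station CSV."""

    date_col: str = "date"
    temp_col: str = "temperature"
    delimiter: str = ","
    skiprows: int = 0
    date_format: str | None = None


@dataclass
class RunConfig:
    """Fully resolved configuration of a pipeline run."""

    input_path: str | None = None
    baseline_start: str = "1971-01-01"
    baseline_end: str = "1999-12-31"
    window_half_width: int = 5
    smoothing_width: int = 31
    mask_winter: bool = True
    mask_start: str = "01-01"
    mask_end: str = "04-01"
    threshold: float | None = None
    stage_tolerances: list = field(default_factory=list)
    tau: float = 0.90
    ar1_correction: bool = False
    output_dir: str = "."
    seed: int = 0
    dialect: TableDialect = field(default_factory=TableDialect)

    def log_resolved(self) -> None:
        logger.info("resolved run configuration: %s", self)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    dialect = TableDialect(**raw.pop("dialect", {}))
    return RunConfig(dialect=dialect, **raw)


# --------------------------------------------------------------------------
# Station CSV
# --------------------------------------------------------------------------


def read_temperature_table(
    path,
    dialect: TableDialect = TableDialect(),
    site_id: str | None = None,
    depth_m: float = 1.0,
) -> TemperatureSeries:
    """Parse a station CSV into a TemperatureSeries.

    Duplicate dates and unparseable dates are hard errors naming the
    offending lines; values outside the physical range (-3, 40) °C are
    set missing with a warning.  Cadence is inferred from the median
    date spacing."""
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.delimiter, skiprows=dialect.skiprows)
    for col in (dialect.date_col, dialect.temp_col):
        if col not in df.columns:
            raise ValueError(f"{path}: column {col!r} not found (have {list(df.columns)})")
    dates = pd.to_datetime(
        df[dialect.date_col], format=dialect.date_format, errors="coerce"
    )
    bad = dates.isna()
    if bad.any():
        lines = [str(i + 2 + dialect.skiprows) for i in df.index[bad][:5]]
        raise ValueError(
            f"{path}: unparseable dates at line(s) {', '.join(lines)}"
        )
    dup = dates.duplicated()
    if dup.any():
        first = dates[dup].iloc[0]
        raise ValueError(f"{path}: duplicated date {first.date()}")
    values = pd.to_numeric(df[dialect.temp_col], errors="coerce").to_numpy(float)
    implausible = np.isfinite(values) & ((values < TEMP_MIN) | (values > TEMP_MAX))
    if implausible.any():
        warnings.warn(
            f"{path.name}: {int(implausible.sum())} value(s) outside "
            f"({TEMP_MIN}, {TEMP_MAX}) °C set to missing",
            stacklevel=2,
        )
        values = np.where(implausible, np.nan, values)
    order = np.argsort(dates.to_numpy())
    return TemperatureSeries.from_arrays(
        dates.to_numpy()[order],
        values[order],
        site_id=site_id or path.stem,
        depth_m=depth_m,
    )


def write_temperature_table(
    series: TemperatureSeries, path, dialect: TableDialect = TableDialect()
) -> None:
    df = pd.DataFrame(
        {
            dialect.date_col: series.dates.strftime("%Y-%m-%d"),
            dialect.temp_col: [
                "" if not np.isfinite(v) else f"{v:.3f}" for v in series.values
            ],
        }
    )
    df.to_csv(path, sep=dialect.delimiter, index=False)


# --------------------------------------------------------------------------
# Gridded SST (NetCDF via xarray/scipy backend)
# --------------------------------------------------------------------------


def read_sst_grid(path, coastline_km: Mapping[str, float] | None = None) -> GridSeries:
    """Read a NetCDF SST cube (dims time, lat, lon; variable 'sst') into a
    GridSeries.  Coastline lengths per cell come from a side table mapping
    cell id ('lat_lon' at 2 decimals) to km; cells absent from the table
    get 0 km.  Cells with no finite data are excluded."""
    ds = xr.open_dataset(path, engine="scipy")
    for coord in ("time", "lat", "lon"):
        if coord not in ds.coords and coord not in ds.dims:
            raise ValueError(f"{path}: missing coordinate variable {coord!r}")
    if "sst" not in ds:
        raise ValueError(f"{path}: missing temperature variable 'sst'")
    coastline_km = coastline_km or {}
    cells: list[GridCell] = []
    times = pd.DatetimeIndex(ds["time"].values)
    for lat in np.atleast_1d(ds["lat"].values):
        for lon in np.atleast_1d(ds["lon"].values):
            vals = ds["sst"].sel(lat=lat, lon=lon).values.astype(float)
            cell_id = f"{float(lat):.2f}_{float(lon):.2f}"
            if not np.isfinite(vals).any():
                logger.warning("cell %s has no finite data; excluded", cell_id)
                continue
            series = TemperatureSeries.from_arrays(
                times, vals, site_id=cell_id, depth_m=0.0
            )
            cells.append(
                GridCell(
                    cell_id=cell_id,
                    coastline_km=float(coastline_km.get(cell_id, 0.0)),
                    series=series,
                )
            )
    ds.close()
    return GridSeries(cells=cells)


def grid_to_dataset(grid: GridSeries) -> xr.Dataset:
    """Assemble a GridSeries (cells on a lat/lon lattice sharing one date
    axis) back into an xarray Dataset."""
    lats = sorted({float(c.cell_id.split("_")[0]) for c in grid.cells})
    lons = sorted({float(c.cell_id.split("_")[1]) for c in grid.cells})
    times = grid.cells[0].series.dates
    cube = np.full((len(times), len(lats), len(lons)), np.nan)
    for c in grid.cells:
        la, lo = (float(x) for x in c.cell_id.split("_"))
        cube[:, lats.index(la), lons.index(lo)] = c.series.values
    return xr.Dataset(
        {"sst": (("time", "lat", "lon"), cube)},
        coords={"time": times, "lat": lats, "lon": lons},
    )


def write_sst_grid(grid: GridSeries, path) -> None:
    grid_to_dataset(grid).to_netcdf(path, engine="scipy")


# --------------------------------------------------------------------------
# Event and metric tables
# --------------------------------------------------------------------------

_EVENT_COLS = [
    "start_date",
    "end_date",
    "peak_date",
    "duration_days",
    "max_intensity",
    "mean_intensity",
    "cumulative_intensity",
    "max_temperature",
    "category",
    "category_roman",
]


def write_event_table(events: Sequence[MHWEvent], path) -> None:
    """One CSV row per event; intensities at 0.001 precision, category as
    both integer and roman numeral.  Header-only file for no events."""
    rows = []
    for ev in events:
        rows.append(
            {
                "start_date": ev.start_date.strftime("%Y-%m-%d"),
                "end_date": ev.end_date.strftime("%Y-%m-%d"),
                "peak_date": ev.peak_date.strftime("%Y-%m-%d"),
                "duration_days": ev.duration_days,
                "max_intensity": f"{ev.max_intensity:.3f}",
                "mean_intensity": f"{ev.mean_intensity:.3f}",
                "cumulative_intensity": f"{ev.cumulative_intensity:.3f}",
                "max_temperature": f"{ev.max_temperature:.3f}",
                "category": "" if ev.category is None else ev.category,
                "category_roman": "" if ev.category is None else ROMAN[ev.category],
            }
        )
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, index=False)


def read_event_table(path) -> list[MHWEvent]:
    df = pd.read_csv(path)
    events: list[MHWEvent] = []
    for _, row in df.iterrows():
        cat = row["category"]
        events.append(
            MHWEvent(
                start_date=pd.Timestamp(row["start_date"]),
                end_date=pd.Timestamp(row["end_date"]),
                peak_date=pd.Timestamp(row["peak_date"]),
                duration_days=int(row["duration_days"]),
                max_intensity=float(row["max_intensity"]),
                mean_intensity=float(row["mean_intensity"]),
                cumulative_intensity=float(row["cumulative_intensity"]),
                max_temperature=float(row["max_temperature"]),
                category=None if pd.isna(cat) else int(cat),
            )
        )
    return events


def write_annual_metrics(metric: AnnualMetricSeries, path) -> None:
    df = metric.to_frame()
    df.attrs["units"] = metric.units
    df.to_csv(path, index=False, float_format="%.3f")


def read_annual_metrics(path, units: str = "") -> AnnualMetricSeries:
    df = pd.read_csv(path)
    name = [c for c in df.columns if c != "year"][0]
    return AnnualMetricSeries(
        df["year"].to_numpy(), df[name].to_numpy(float), name, units
    )
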