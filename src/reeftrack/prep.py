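"""Quality control and regularization of localized trajectories.

Downstream analyses assume a gap-free 1-minute daytime track. This module
computes sunrise/sunset windows (NOAA solar geometry, or explicit override),
applies the data-quality rule that every full daytime hour of an accepted
day must contain at least 30 position fixes, groups accepted dates into
contiguous runs, and linearly interpolates the daytime fixes of each
accepted day onto the 1-min grid.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440
SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class DayWindow:
    """Sunrise/sunset for one date, as minutes since local midnight."""

    date: dt.date | int
    sunrise_min: float
    sunset_min: float

    def __post_init__(self) -> None:
        if not self.sunrise_min < self.sunset_min:
            raise ValueError("sunrise must precede sunset")

    @property
    def length_min(self) -> float:
        return self.sunset_min - self.sunrise_min


def solar_day_window(
    date: dt.date,
    latitude: float,
    longitude: float,
    utc_offset_hours: float = 0.0,
    override: tuple[float, float] | None = None,
) -> DayWindow:
    """Sunrise/sunset for a date and site via the NOAA solar equations.

    Uses the standard -0.833 deg sun altitude (refraction plus solar disc).
    ``override`` returns explicit (sunrise_min, sunset_min) verbatim. Raises
    for polar day/night where the sun never crosses the horizon.
    """
    if override is not None:
        return DayWindow(date, float(override[0]), float(override[1]))
    if not (-90 <= latitude <= 90 and -180 <= longitude <= 180):
        raise ValueError("invalid coordinates")

    day_of_year = date.timetuple().tm_yday
    # fractional year, radians (NOAA approximation at mid-day)
    gamma = 2.0 * np.pi / 365.0 * (day_of_year - 1 + (12 - 12) / 24)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    lat = np.deg2rad(latitude)
    zenith = np.deg2rad(90.833)
    cos_ha = np.cos(zenith) / (np.cos(lat) * np.cos(decl)) - np.tan(lat) * np.tan(decl)
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError("sun does not cross the horizon on this date (polar day/night)")
    ha = np.rad2deg(np.arccos(cos_ha))  # degrees
    sunrise_utc = 720.0 - 4.0 * (longitude + ha) - eqtime  # minutes
    sunset_utc = 720.0 - 4.0 * (longitude - ha) - eqtime
    off = utc_offset_hours * 60.0
    return DayWindow(date, sunrise_utc + off, sunset_utc + off)


def _full_day_hours(window: DayWindow) -> list[int]:
    """Clock hours lying entirely inside the daytime window."""
    first = int(np.ceil(window.sunrise_min / 60.0))
    last = int(np.floor(window.sunset_min / 60.0))
    return list(range(first, last))


def select_qc_days(
    fixes: pd.DataFrame,
    day_windows: dict[int, DayWindow],
    min_per_hour: int = 30,
    daytime_only: bool = True,
) -> list[list[int]]:
    """Accept days whose every full (daytime) hour has >= min_per_hour fixes.

    ``fixes`` needs a `time_s` column (seconds since local midnight of day
    0); ``day_windows`` maps day index to its window. Returns the maximal
    runs of contiguous accepted day indices, earliest first.
    """
    if fixes.empty:
        return []
    t = np.sort(fixes["time_s"].to_numpy(dtype=float))
    day_idx = (t // SECONDS_PER_DAY).astype(int)
    hour_of_day = ((t % SECONDS_PER_DAY) // 3600.0).astype(int)
    accepted = []
    for day, window in sorted(day_windows.items()):
        hours = _full_day_hours(window) if daytime_only else list(range(24))
        if not hours:
            continue
        counts = {
            h: int(np.sum((day_idx == day) & (hour_of_day == h))) for h in hours
        }
        if all(counts[h] >= min_per_hour for h in hours):
            accepted.append(day)
    runs: list[list[int]] = []
    for day in accepted:
        if runs and day == runs[-1][-1] + 1:
            runs[-1].append(day)
        else:
            runs.append([day])
    return runs


def contiguous_days(runs: list[list[int]], min_run: int = 1) -> list[int]:
    """Flatten accepted runs, keeping only runs of at least ``min_run`` days."""
    return [d for r in runs if len(r) >= min_run for d in r]


@dataclass
class RegularTrajectory:
    """1-min interpolated daytime track of one fish on one day."""

    fish_id: str
    day: int
    times_min: np.ndarray  # minutes since local midnight of the day
    xy: np.ndarray  # (n, 2) m
    flags: np.ndarray  # "observed" | "interpolated" | "extrapolated"

    def __post_init__(self) -> None:
        if not np.allclose(np.diff(self.times_min), 1.0):
            raise ValueError("trajectory must be on an exact 1-min grid")
        if np.any(~np.isfinite(self.xy)):
            raise ValueError("trajectory contains missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": self.fish_id,
                "day": self.day,
                "t_min": self.times_min,
                "x_m": self.xy[:, 0],
                "y_m": self.xy[:, 1],
                "interp_flag": self.flags,
            }
        )


def interpolate_to_minutes(
    fixes: pd.DataFrame,
    window: DayWindow,
    day: int = 0,
    fish_id: str = "F1",
    observed_tol_min: float = 0.5,
    aggregate_bin_s: float = 60.0,
) -> RegularTrajectory | None:
    """Linearly interpolate one day's fixes onto the 1-min sunrise-sunset grid.

    Raw fixes are first aggregated into robust (median) positions per
    ``aggregate_bin_s`` time bin — with several transmissions per minute the
    median suppresses both timing noise and the occasional badly localized
    fix (set 0 to disable). x and y are then interpolated independently;
    grid points outside the observed span take the nearest endpoint value
    and are flagged "extrapolated"; grid points within ``observed_tol_min``
    of a fix are flagged "observed". Returns None (with a warning upstream)
    when fewer than two daytime fixes exist.
    """
    t = fixes["time_s"].to_numpy(dtype=float) / 60.0 - day * MINUTES_PER_DAY
    m = (t >= window.sunrise_min) & (t <= window.sunset_min)
    if int(m.sum()) < 2:
        return None
    t = t[m]
    x = fixes["x_m"].to_numpy(dtype=float)[m]
    y = fixes["y_m"].to_numpy(dtype=float)[m]
    order = np.argsort(t)
    t, x, y = t[order], x[order], y[order]
    if aggregate_bin_s > 0:
        bins = np.floor(t * 60.0 / aggregate_bin_s).astype(int)
        df = pd.DataFrame({"b": bins, "t": t, "x": x, "y": y})
        agg = df.groupby("b", sort=True).median()
        if len(agg) >= 2:
            t = agg["t"].to_numpy()
            x = agg["x"].to_numpy()
            y = agg["y"].to_numpy()

    n = int(np.floor(window.length_min)) + 1
    grid = window.sunrise_min + np.arange(n, dtype=float)
    gx = np.interp(grid, t, x)
    gy = np.interp(grid, t, y)
    flags = np.full(n, "interpolated", dtype=object)
    flags[(grid < t[0]) | (grid > t[-1])] = "extrapolated"
    near = np.min(np.abs(grid[:, None] - t[None, :]), axis=1) if len(t) < 20000 else None
    if near is None:  # memory-lean path for dense fixes
        idx = np.searchsorted(t, grid)
        idx = np.clip(idx, 1, len(t) - 1)
        near = np.minimum(np.abs(grid - t[idx - 1]), np.abs(grid - t[idx]))
    flags[near <= observed_tol_min] = "observed"
    return RegularTrajectory(fish_id, day, grid, np.column_stack([gx, gy]), flags)
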