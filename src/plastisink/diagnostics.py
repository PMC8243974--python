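"""Sinking diagnostics from particle trajectories.

Two quantities summarize each trajectory:

* the sinking timescale ``T_s`` — days from release until the stored net
  vertical velocity (settling plus vertical advection) first points
  strictly downward; particles whose velocity never turns downward within
  the horizon carry a no-sink sentinel (NaN);
* the first sinking depth ``Z_s`` — the depth reached when, after sinking
  begins, the net vertical velocity first stops pointing downward; if the
  particle is still sinking at the end of the horizon its final depth is
  recorded.  The trajectory after ``Z_s`` is not used.

"Downward" is tested on the snapshot-resolution stored velocity with a
strict tolerance (1e-12 m s⁻¹) so that the exact zero recorded while
surface-clamped never counts as sinking.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DomainError
from .params import SECONDS_PER_DAY

__all__ = [
    "DOWN_TOL",
    "sinking_timescale",
    "first_sinking_depth",
    "compute_diagnostics",
    "seasonal_average",
    "summarize",
    "maps_dataset",
]

DOWN_TOL = 1e-12  # m/s; net_w < -DOWN_TOL counts as downward


def sinking_timescale(net_w, times, tol=DOWN_TOL):
    """Days until the net vertical velocity first points downward, or NaN.

    ``net_w`` is positive up (m s⁻¹) per stored snapshot, ``times`` the
    snapshot times in seconds since release.
    """
    net_w = np.asarray(net_w, dtype=float)
    times = np.asarray(times, dtype=float)
    if net_w.size == 0:
        raise DomainError("empty trajectory")
    down = net_w < -tol
    if not down.any():
        return float("nan")
    return float(times[int(np.argmax(down))] / SECONDS_PER_DAY)


def first_sinking_depth(net_w, depth, times, tol=DOWN_TOL):
    """First sinking depth and the days from release to reach it.

    Follows the trajectory from the onset of sinking; ``Z_s`` is the depth
    at the first snapshot where the velocity is no longer downward, or the
    final depth if sinking persists through the horizon.
    """
    net_w = np.asarray(net_w, dtype=float)
    depth = np.asarray(depth, dtype=float)
    times = np.asarray(times, dtype=float)
    if net_w.size == 0:
        raise DomainError("empty trajectory")
    down = net_w < -tol
    if not down.any():
        raise DomainError("first_sinking_depth called on a no-sink trajectory")
    i0 = int(np.argmax(down))
    stalled = ~down[i0:]
    if stalled.any():
        j = i0 + int(np.argmax(stalled))
    else:
        j = net_w.size - 1
    return float(depth[j]), float(times[j] / SECONDS_PER_DAY)


def compute_diagnostics(traj: xr.Dataset) -> pd.DataFrame:
    """Per-particle sinking diagnostics from a trajectory dataset.

    Columns: particle, release_lon, release_lat, radius, density, ts_days
    (NaN = no sinking within the horizon), zs_m, time_to_zs_days, no_sink.
    """
    times = np.asarray(traj["time"], dtype=float)
    net_w = np.asarray(traj["net_w"], dtype=float)
    depth = np.asarray(traj["z"], dtype=float)
    n = net_w.shape[0]
    ts = np.full(n, np.nan)
    zs = np.full(n, np.nan)
    tzs = np.full(n, np.nan)
    for i in range(n):
        t = sinking_timescale(net_w[i], times)
        if np.isfinite(t):
            ts[i] = t
            zs[i], tzs[i] = first_sinking_depth(net_w[i], depth[i], times)
    return pd.DataFrame(
        {
            "particle": np.asarray(traj["traj"]),
            "release_lon": np.asarray(traj["release_lon"], dtype=float),
            "release_lat": np.asarray(traj["release_lat"], dtype=float),
            "radius": np.asarray(traj["radius"], dtype=float),
            "density": np.asarray(traj["density"], dtype=float),
            "ts_days": ts,
            "zs_m": zs,
            "time_to_zs_days": tzs,
            "no_sink": ~np.isfinite(ts),
        }
    )


def seasonal_average(season_frames: dict) -> pd.DataFrame:
    """Average T_s over seasons, per release location and particle class.

    Each value of ``season_frames`` is a diagnostics frame from one
    seasonal run; all runs must share the release grid and particle
    classes.  The mean is taken over the seasons in which the particle
    sinks; a location with no sinking season keeps the no-sink sentinel.
    A pure function of the set of frames — relabeling seasons does not
    change the result.
    """
    keys = ["release_lon", "release_lat", "radius", "density"]
    frames = list(season_frames.values())
    ref = frames[0][keys].reset_index(drop=True)
    for f in frames[1:]:
        if len(f) != len(ref) or not np.allclose(
            f[keys].reset_index(drop=True).to_numpy(), ref.to_numpy()
        ):
            raise DomainError("seasonal runs do not share a release grid")
    stacked = np.stack([f["ts_days"].to_numpy() for f in frames])  # (season, n)
    finite = np.isfinite(stacked)
    counts = finite.sum(axis=0)
    sums = np.where(finite, stacked, 0.0).sum(axis=0)
    mean_ts = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = ref.copy()
    out["ts_days"] = mean_ts
    out["n_sinking_seasons"] = np.isfinite(stacked).sum(axis=0)
    out["no_sink"] = out["n_sinking_seasons"] == 0
    return out


def summarize(diag: pd.DataFrame, by=None) -> pd.DataFrame:
    """Summary table of T_s: median/mean/std over sinking particles only,
    plus the no-sink fraction, optionally grouped (e.g. by radius/density).
    """
    if len(diag) == 0:
        raise DomainError("empty diagnostics set")

    def _one(group: pd.DataFrame) -> pd.Series:
        ts = group["ts_days"].to_numpy()
        sinking = ts[np.isfinite(ts)]
        return pd.Series(
            {
                "n_particles": len(group),
                "fraction_no_sink": float(np.mean(~np.isfinite(ts))),
                "ts_median_days": float(np.median(sinking)) if sinking.size else np.nan,
                "ts_mean_days": float(np.mean(sinking)) if sinking.size else np.nan,
                "ts_std_days": float(np.std(sinking, ddof=0)) if sinking.size else np.nan,
            }
        )

    if by:
        grouped = diag.groupby(list(by))
        out = grouped.apply(_one, include_groups=False).reset_index()
    else:
        out = _one(diag).to_frame().T
    return out


def maps_dataset(diag: pd.DataFrame) -> xr.Dataset:
    """Release-grid map layers (mean T_s, mean Z_s, no-sink mask).

    One layer set per (radius, density) class, on the lattice of release
    positions; cells with no released particle are NaN.
    """
    lons = np.sort(diag["release_lon"].unique())
    lats = np.sort(diag["release_lat"].unique())
    classes = sorted(set(zip(diag["radius"], diag["density"])))
    shape = (len(classes), lats.size, lons.size)
    ts = np.full(shape, np.nan)
    zs = np.full(shape, np.nan)
    nos = np.full(shape, np.nan)
    ilon = {v: i for i, v in enumerate(lons)}
    ilat = {v: i for i, v in enumerate(lats)}
    for k, (r, rho) in enumerate(classes):
        sub = diag[(diag["radius"] == r) & (diag["density"] == rho)]
        for _, row in sub.iterrows():
            i, j = ilat[row["release_lat"]], ilon[row["release_lon"]]
            ts[k, i, j] = row["ts_days"]
            zs[k, i, j] = row["zs_m"]
            nos[k, i, j] = float(row["no_sink"])
    return xr.Dataset(
        {
            "ts_days": (("pclass", "lat", "lon"), ts),
            "zs_m": (("pclass", "lat", "lon"), zs),
            "no_sink": (("pclass", "lat", "lon"), nos),
        },
        coords={
            "lat": lats,
            "lon": lons,
            "radius": ("pclass", [c[0] for c in classes]),
            "density": ("pclass", [c[1] for c in classes]),
        },
        attrs={"ts_statistic": "per-release-location T_s, sinking particles only"},
    )
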