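"""Offline hydrodynamics: velocities, hydrography and diffusivities from
files (or in-memory series) instead of the hydrodynamic solver.

Snapshots are interpolated linearly in time to the model's own stepping.
Spatially uniform velocity *profiles* (e.g. from ADCP monitoring data:
speed and direction per layer) can be broadcast onto the face normals of
the mesh, giving a divergence-free uniform flow per layer.  A wind-speed
dependent vertical diffusivity (power law plus background) supports the
farm-scale use case where the water column mixes with the wind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import Mesh3D


class OfflineError(ValueError):
    pass


@dataclass
class OfflineFieldSeries:
    """Time-stamped snapshots of named fields (u, eta, temp, salt, Kv, ...)."""

    times: np.ndarray                       # (T,), seconds, strictly increasing
    fields: dict = field(default_factory=dict)   # name -> (T, ...) arrays

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise OfflineError("offline time axis must be strictly increasing")
        for name, arr in self.fields.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != len(self.times):
                raise OfflineError(
                    f"field {name!r} has {arr.shape[0]} snapshots, "
                    f"expected {len(self.times)}")
            self.fields[name] = arr

    def coverage(self):
        return float(self.times[0]), float(self.times[-1])


def fields_at(series: OfflineFieldSeries, t: float) -> dict:
    """Linear temporal interpolation; exact at snapshot times.

    Raises :class:`OfflineError` outside the covered window (no
    extrapolation).
    """
    t0, t1 = series.coverage()
    if t < t0 - 1e-9 or t > t1 + 1e-9:
        raise OfflineError(f"time {t} outside offline coverage [{t0}, {t1}]")
    times = series.times
    j = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0,
                    len(times) - 2))
    w = (t - times[j]) / (times[j + 1] - times[j])
    w = min(max(w, 0.0), 1.0)
    return {name: (1.0 - w) * arr[j] + w * arr[j + 1]
            for name, arr in series.fields.items()}


def broadcast_profile(speed, direction_deg, mesh: Mesh3D) -> np.ndarray:
    """Broadcast a per-layer (speed, direction) profile to face-normal u.

    Direction follows the oceanographic "toward" convention, degrees
    clockwise from north: vx = speed sin(dir), vy = speed cos(dir).  The
    resulting flow is uniform per layer, hence divergence-free.
    """
    K = mesh.n_layers
    speed = np.broadcast_to(np.asarray(speed, dtype=float), (K,))
    direction = np.broadcast_to(np.asarray(direction_deg, dtype=float), (K,))
    rad = np.radians(direction)
    vx = speed * np.sin(rad)
    vy = speed * np.cos(rad)
    n = mesh.mesh2d.face_normal
    u = n[:, 0:1] * vx[None, :] + n[:, 1:2] * vy[None, :]
    u[~mesh.face_layer_wet] = 0.0
    return u


def wind_vertical_diffusivity(wind_speed, *, a: float = 1e-4, b: float = 1.0,
                              K_background: float = 1e-5):
    """Vertical diffusivity K_v = a * wind^b + K_background (m^2/s)."""
    W = np.asarray(wind_speed, dtype=float)
    if np.any(W < 0):
        raise OfflineError("wind speed must be >= 0")
    return a * W**b + K_background


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def save_offline(series: OfflineFieldSeries, path) -> None:
    """Write an offline series as NetCDF (this package's state layout)."""
    import xarray as xr

    data = {}
    for name, arr in series.fields.items():
        dims = ("time",) + tuple(f"{name}_d{i}" for i in range(arr.ndim - 1))
        data[name] = (dims, arr)
    ds = xr.Dataset(data, coords={"time": series.times})
    ds.to_netcdf(path, engine="scipy")


def load_offline(path) -> OfflineFieldSeries:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        times = ds["time"].values.astype(float)
        fields = {name: ds[name].values.copy() for name in ds.data_vars}
    return OfflineFieldSeries(times=times, fields=fields)


def read_adcp_profiles(path_or_buf, n_layers: int) -> OfflineFieldSeries:
    """Read ADCP-style text: columns time, layer, speed, direction.

    Time is seconds (decimal) or ISO 8601; layers are 0-based indices.
    Returns a series with fields 'speed' and 'direction' of shape (T, K).
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python",
                     comment="#",
                     names=["time", "layer", "speed", "direction"],
                     header=None, skipinitialspace=True)
    if df["time"].dtype == object:
        t = pd.to_datetime(df["time"])
        df["time"] = (t - t.iloc[0]).dt.total_seconds()
    times = np.sort(df["time"].unique())
    K = n_layers
    speed = np.zeros((len(times), K))
    direction = np.zeros((len(times), K))
    for i, tv in enumerate(times):
        sub = df[df["time"] == tv]
        speed[i, sub["layer"].astype(int)] = sub["speed"].to_numpy()
        direction[i, sub["layer"].astype(int)] = sub["direction"].to_numpy()
    return OfflineFieldSeries(times=times,
                              fields={"speed": speed, "direction": direction})


def divergence_report(u: np.ndarray, mesh: Mesh3D) -> np.ndarray:
    """Per-cell net volume imbalance (m^3/s) of an offline velocity field."""
    from .transport import horizontal_divergence

    flux = u * mesh.mesh2d.face_length[:, None] * mesh.face_layer_thickness
    return horizontal_divergence(flux, mesh).sum(axis=1)
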