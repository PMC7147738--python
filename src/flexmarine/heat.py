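"""Surface heat budget and in-water absorption.

Two modes are supported:

* ``fick`` — Newtonian conduction Q = k (T_air - T_surface), all heat into
  the surface layer;
* ``flux`` — bulk formulas: clear-sky shortwave from solar geometry reduced
  by cloud cover and surface reflectivity, Berliand-type net longwave,
  and wind-speed-proportional sensible and latent fluxes.

In-water absorption follows a reflect-and-redistribute bookkeeping that
closes the budget exactly: fluxes decay exponentially with an e-folding
length equal to the penetration depth (~ the Secchi depth).  Shortwave that
reaches the bottom is reflected and absorbed exponentially on the way up;
whatever survives to the surface is spread uniformly (per volume) over the
column.  Shortwave that reaches the penetration depth before the bottom is
deposited in the layer containing that depth.  The non-solar sum follows
the same downward rule, with the bottom remainder spread uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STEFAN_BOLTZMANN = 5.670374419e-8
RHO_AIR = 1.225          # kg/m^3
CP_AIR = 1005.0          # J/(kg K)
LATENT_VAPOR = 2.5e6     # J/kg
P_ATM_HPA = 1013.25


@dataclass
class MeteoForcing:
    """Meteorological forcing; entries are scalars or callables of time."""

    wind_speed: object = 0.0      # m/s
    air_temp: object = 10.0       # deg C
    cloud_cover: object = 0.0     # 0..1
    rel_humidity: object = None   # 0..1 (alternative to dew_point)
    dew_point: object = None      # deg C

    def at(self, t):
        def ev(v):
            return v(t) if callable(v) else v
        m = MeteoForcing(wind_speed=ev(self.wind_speed),
                         air_temp=ev(self.air_temp),
                         cloud_cover=ev(self.cloud_cover),
                         rel_humidity=ev(self.rel_humidity),
                         dew_point=ev(self.dew_point))
        c = np.asarray(m.cloud_cover, dtype=float)
        if np.any((c < 0) | (c > 1)):
            raise ValueError("cloud cover must lie in [0, 1]")
        if m.rel_humidity is not None:
            rh = np.asarray(m.rel_humidity, dtype=float)
            if np.any((rh < 0) | (rh > 1)):
                raise ValueError("relative humidity must lie in [0, 1]")
        return m


@dataclass
class HeatParams:
    mode: str = "flux"                       # flux | fick
    solar_constant: float = 1361.0           # W/m^2
    latitude: float = 55.0                   # deg
    penetration_depth: float = 5.0           # m (~ Secchi depth)
    shortwave_surface_reflectivity: float = 0.06
    bottom_reflectivity: float = 1.0
    conduction_coefficient: float = 0.0      # W/(m^2 K), fick mode
    rho_cp: float = 4.09e6                   # J/(m^3 K)
    atmos_transmission: float = 0.7
    cloud_attenuation: float = 0.62          # Reed-type linear factor
    emissivity: float = 0.985
    C_sensible: float = 1.1e-3
    C_latent: float = 1.3e-3

    def __post_init__(self):
        for r in (self.shortwave_surface_reflectivity,
                  self.bottom_reflectivity):
            if not 0.0 <= r <= 1.0:
                raise ValueError("reflectivities must lie in [0, 1]")
        if self.penetration_depth <= 0:
            raise ValueError("penetration depth must be positive")


# ---------------------------------------------------------------------------
# humidity helpers (Magnus formula)
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(T):
    """Magnus saturation vapor pressure over water, hPa, T in deg C."""
    T = np.asarray(T, dtype=float)
    return 6.112 * np.exp(17.62 * T / (243.12 + T))


def vapor_pressure(meteo: MeteoForcing):
    """Air vapor pressure (hPa) from RH or dew point."""
    if meteo.rel_humidity is not None:
        return np.asarray(meteo.rel_humidity) * saturation_vapor_pressure(
            meteo.air_temp)
    if meteo.dew_point is not None:
        return saturation_vapor_pressure(meteo.dew_point)
    raise ValueError("meteo needs rel_humidity or dew_point")


def dew_point_from_rh(air_temp, rel_humidity):
    """Invert the Magnus formula."""
    e = np.asarray(rel_humidity) * saturation_vapor_pressure(air_temp)
    x = np.log(e / 6.112)
    return 243.12 * x / (17.62 - x)


def _specific_humidity(e_hpa):
    return 0.622 * e_hpa / (P_ATM_HPA - 0.378 * e_hpa)


# ---------------------------------------------------------------------------
# solar geometry and surface fluxes
# ---------------------------------------------------------------------------

def solar_declination(day_of_year):
    """Solar declination (radians), Cooper's formula."""
    return np.radians(23.45) * np.sin(2 * np.pi * (284 + day_of_year) / 365.0)


def solar_elevation(latitude, day_of_year, time_of_day):
    """Sine of the solar elevation angle; time_of_day in hours (solar time)."""
    phi = np.radians(latitude)
    dec = solar_declination(day_of_year)
    hour_angle = np.radians(15.0 * (np.asarray(time_of_day, float) - 12.0))
    return (np.sin(phi) * np.sin(dec)
            + np.cos(phi) * np.cos(dec) * np.cos(hour_angle))


def clear_sky_shortwave(latitude, day_of_year, time_of_day, *,
                        solar_constant: float = 1361.0,
                        transmission: float = 0.7):
    """Clear-sky shortwave at the surface (W/m^2) from solar geometry.

    Q = S0 * cosZ * tau^(1/cosZ): direct-beam atmospheric attenuation with
    air-mass path length 1/cosZ; zero below the horizon.
    """
    if np.any(np.abs(np.asarray(latitude)) > 90):
        raise ValueError("latitude must lie in [-90, 90]")
    cosz = solar_elevation(latitude, day_of_year, time_of_day)
    cosz = np.asarray(cosz, dtype=float)
    q = np.zeros_like(cosz)
    up = cosz > 0
    q[up] = solar_constant * cosz[up] * transmission ** (1.0 / cosz[up])
    if q.ndim == 0:
        return float(q)
    return q


def surface_flux_bulk(meteo: MeteoForcing, water_surface_temp,
                      params: HeatParams | None = None, *,
                      day_of_year=None, time_of_day=None) -> dict:
    """Bulk surface heat fluxes (W/m^2, positive into the water).

    Returns Q_sw_incident (cloud-reduced, before surface reflection), Q_lw
    (Berliand net longwave), Q_sensible and Q_latent (both proportional to
    wind speed).  Shortwave is included only when day_of_year/time_of_day
    are given.
    """
    params = params or HeatParams()
    Tw = np.asarray(water_surface_temp, dtype=float)
    Ta = np.asarray(meteo.air_temp, dtype=float)
    W = np.asarray(meteo.wind_speed, dtype=float)
    C = np.asarray(meteo.cloud_cover, dtype=float)
    e_air = vapor_pressure(meteo)

    q_sens = RHO_AIR * CP_AIR * params.C_sensible * W * (Ta - Tw)
    q_lat = RHO_AIR * LATENT_VAPOR * params.C_latent * W * (
        _specific_humidity(e_air) - _specific_humidity(
            saturation_vapor_pressure(Tw)))

    TaK = Ta + 273.15
    lw_loss = (params.emissivity * STEFAN_BOLTZMANN * TaK**4
               * (0.39 - 0.05 * np.sqrt(np.clip(e_air, 0.0, None)))
               * (1.0 - 0.68 * C**2)
               + 4.0 * params.emissivity * STEFAN_BOLTZMANN * TaK**3
               * (Tw - Ta))
    q_lw = -lw_loss

    if day_of_year is not None and time_of_day is not None:
        q_clear = clear_sky_shortwave(
            params.latitude, day_of_year, time_of_day,
            solar_constant=params.solar_constant,
            transmission=params.atmos_transmission)
        q_sw = q_clear * np.clip(1.0 - params.cloud_attenuation * C, 0.0, 1.0)
    else:
        q_sw = np.zeros_like(Tw)

    return {"Q_sw_incident": q_sw, "Q_lw": q_lw,
            "Q_sensible": q_sens, "Q_latent": q_lat}


def fick_surface_conduction(meteo: MeteoForcing, surface_temp,
                            conduction_coefficient: float):
    """Fick/Newtonian conduction Q = k (T_air - T_surface), W/m^2."""
    Ta = np.asarray(meteo.air_temp, dtype=float)
    return conduction_coefficient * (Ta - np.asarray(surface_temp, float))


# ---------------------------------------------------------------------------
# in-water absorption (budget-closing bookkeeping)
# ---------------------------------------------------------------------------

def _exponential_path(Q, thicknesses, lam):
    """Absorb Q along a column with extinction lam.

    Returns (per-layer absorption, remainder leaving the far end);
    thicknesses are ordered along the direction of travel.
    """
    h = np.asarray(thicknesses, dtype=float)
    decay = np.exp(-lam * np.concatenate([[0.0], np.cumsum(h)]))
    absorbed = Q * (decay[:-1] - decay[1:])
    return absorbed, Q * decay[-1]


def absorb_shortwave_profile(Q_sw_net, column_thicknesses,
                             penetration_depth: float,
                             bottom_reflectivity: float = 1.0) -> np.ndarray:
    """Per-layer shortwave heating (W/m^2); sums exactly to Q_sw_net.

    Exponential absorption downward with e-folding = penetration depth; the
    flux reaching the bottom is reflected (bottom_reflectivity) and absorbed
    exponentially on the way up — the non-reflected part heats the bottom
    layer; whatever survives to the surface is distributed uniformly per
    volume over the column.
    """
    h = np.asarray(column_thicknesses, dtype=float)
    h = h[h > 0]
    n = len(h)
    if n == 0:
        return np.zeros(0)
    lam = 1.0 / penetration_depth
    heat, R = _exponential_path(Q_sw_net, h, lam)
    refl = bottom_reflectivity * R
    heat[n - 1] += R - refl
    up, R2 = _exponential_path(refl, h[::-1], lam)
    heat += up[::-1]
    heat += R2 * h / float(h.sum())     # uniform per volume
    return heat


def absorb_surface_fluxes(Q_nonsolar, column_thicknesses,
                          penetration_depth: float) -> np.ndarray:
    """Per-layer heating from the non-solar flux sum; budget closes exactly.

    Exponential decay downward with e-folding = penetration depth; the
    remainder reaching the bottom (significant only when the water is
    shallower than the penetration depth) is reflected and distributed
    uniformly per volume over the column.
    """
    h = np.asarray(column_thicknesses, dtype=float)
    h = h[h > 0]
    if len(h) == 0:
        return np.zeros(0)
    lam = 1.0 / penetration_depth
    heat, R = _exponential_path(Q_nonsolar, h, lam)
    heat += R * h / float(h.sum())
    return heat


def column_heating(mesh, Q_sw_net, Q_nonsolar, params: HeatParams):
    """Per-cell heating (W/m^2 of layer) over the whole mesh.

    Q_sw_net and Q_nonsolar are per-polygon scalars or arrays.
    """
    P, K = mesh.n_polygons, mesh.n_layers
    Qs = np.broadcast_to(np.asarray(Q_sw_net, float), (P,))
    Qn = np.broadcast_to(np.asarray(Q_nonsolar, float), (P,))
    out = np.zeros((P, K))
    for p in range(P):
        kb = mesh.bottom_layer[p]
        th = mesh.cell_thickness[p, :kb + 1]
        out[p, :kb + 1] = (
            absorb_shortwave_profile(Qs[p], th, params.penetration_depth,
                                     params.bottom_reflectivity)
            + absorb_surface_fluxes(Qn[p], th, params.penetration_depth))
    return out


def heating_to_temperature_tendency(heating, mesh, params: HeatParams):
    """Convert per-layer heating (W/m^2) to dT/dt (K/s)."""
    h = np.where(mesh.cell_thickness > 0, mesh.cell_thickness, np.inf)
    return np.asarray(heating) / (params.rho_cp * h)


def shortwave_light_profile(Q_sw_net, mesh, params: HeatParams):
    """Downwelling shortwave at layer centers (W/m^2) — the `light`
    environment field for the equation solver."""
    P, K = mesh.n_polygons, mesh.n_layers
    Qs = np.broadcast_to(np.asarray(Q_sw_net, float), (P,))
    z = mesh.layering.z_center
    lam = 1.0 / params.penetration_depth
    light = Qs[:, None] * np.exp(-lam * z[None, :])
    light[~mesh.cell_active] = 0.0
    return light
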