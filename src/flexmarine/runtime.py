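"""Simulation driver: module composition, time stepping, outputs, fixtures.

Within each time step the enabled modules run in a fixed, documented order:

1. forcings are interpolated to the current time;
2. the hydrodynamic provider advances (full solver, offline fields, or
   none) and yields the continuity-consistent face volume fluxes;
3. the surface heat budget heats the columns (and provides `light`);
4. advected tracers are transported (explicit or vertically semi-implicit);
5. the user equation systems react, settle, resuspend and exchange;
6. the ABM advances on its sub-step multiple;
7. outputs and budget diagnostics are recorded.

This operator-splitting order is part of the package contract.  The driver
is single-threaded and, given a seed, bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import abm as abmmod
from . import equations as eqmod
from . import heat as heatmod
from . import offline as offmod
from . import transport as trmod
from .config import SimulationSetup, load_setup
from .hydro import (EOS, HydroForcing, HydroParams, HydroState, bottom_stress,
                    cell_volumes, step_hydro)
from .mesh import Mesh3D, OPEN, generate_fixture_mesh, write_mesh_text

RHO_AIR = 1.225
CD_WIND = 1.3e-3


@dataclass
class RunLog:
    """Per-interval diagnostics and provenance."""

    times: list = field(default_factory=list)
    volume: list = field(default_factory=list)
    tracer_mass: dict = field(default_factory=dict)
    clipped_mass: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    config_hash: str = ""
    seed: int = 0
    version: str = ""

    def record(self, t, vol, masses):
        self.times.append(t)
        self.volume.append(vol)
        for k, v in masses.items():
            self.tracer_mass.setdefault(k, []).append(v)


@dataclass
class RunResult:
    setup: SimulationSetup
    times: np.ndarray
    eta: np.ndarray | None               # (T, P)
    fields: dict                         # name -> (T, P, K)
    benthic: eqmod.BenthicStack | None
    section_fluxes: dict                 # name -> (T,)
    population: abmmod.AgentPopulation | None
    connectivity: abmmod.ConnectivityMatrix | None
    hydro_state: HydroState | None
    log: RunLog


def _resolve(v, t):
    return v(t) if callable(v) else v


def _open_boundary_maps(setup: SimulationSetup, t):
    """(eta_bc per polygon, u_bc per face, tracer boundary values)."""
    mesh = setup.mesh
    m2 = mesh.mesh2d
    open_faces = np.where(m2.face_kind == OPEN)[0]
    eta_bc, u_bc = None, None
    if setup.boundary_eta is not None and open_faces.size:
        val = _resolve(setup.boundary_eta, t)
        eta_bc = {int(m2.face_left[f]): val for f in open_faces}
    if setup.boundary_u is not None and open_faces.size:
        vx = _resolve(setup.boundary_u[0], t)
        vy = _resolve(setup.boundary_u[1], t)
        u_bc = {int(f): vx * m2.face_normal[f, 0] + vy * m2.face_normal[f, 1]
                for f in open_faces}
    tr_bc = {name: _resolve(v, t)
             for name, v in setup.boundary_tracers.items()}
    return eta_bc, u_bc, tr_bc


def _source_arrays(setup: SimulationSetup, t):
    mesh = setup.mesh
    Q = np.zeros(mesh.n_polygons)
    loads: dict = {}
    for s in setup.sources:
        w = trmod.SourceSpec(polygon=s.polygon,
                             distribution=s.distribution).cell_weights(
            mesh, s.polygon)
        Q[s.polygon] += _resolve(s.flux, t)
        for name, rate in s.loads.items():
            arr = loads.setdefault(
                name, np.zeros((mesh.n_polygons, mesh.n_layers)))
            arr[s.polygon] += _resolve(rate, t) * w
    return Q, loads


def run(setup: SimulationSetup, outdir=None) -> RunResult:
    """Execute a simulation setup and return in-memory results.

    If ``outdir`` is given, fields, section fluxes and trajectories are also
    written there (NetCDF / delimited text).
    """
    mesh = setup.mesh
    P, K = mesh.n_polygons, mesh.n_layers
    dt = setup.dt
    system = setup.system or eqmod.EquationSystem()
    system.validate()

    log = RunLog(config_hash=setup.config_hash, seed=setup.seed,
                 version=__import__("flexmarine").__version__)

    # initial fields
    fields = {}
    for name in system.pelagic_names():
        init = system.variables[name].initial
        fields[name] = np.full((P, K), float(init))
        fields[name][~mesh.cell_active] = 0.0
    benthic = (eqmod.BenthicStack.zeros(system, P, setup.benthic_layers)
               if system.benthic_names() else None)
    temp = np.full((P, K), float(setup.initial_temp))
    salt = np.full((P, K), float(setup.initial_salt))

    hstate = None
    if setup.hydro_enabled:
        hstate = HydroState.rest(mesh, temp=setup.initial_temp,
                                 salt=setup.initial_salt,
                                 eos=setup.hydro_params.eos)
        tilt = getattr(setup, "initial_eta_tilt", None)
        if tilt:
            x = mesh.mesh2d.voronoi_points[:, 0]
            hstate.eta = tilt * 2.0 * (x - x.mean()) / np.ptp(x)

    series = None
    if setup.offline_enabled:
        series = offmod.load_offline(setup.base_dir / setup.offline_file)

    pop = None
    if setup.abm and setup.abm.n + sum(r[2] for r in setup.abm.releases):
        pop = _release_population(setup, mesh)

    adv_names = [n for n in system.pelagic_names()
                 if system.variables[n].advected]
    scheme = (trmod.advect_diffuse_semi_implicit
              if setup.transport_scheme == "semi_implicit"
              else trmod.advect_diffuse_explicit)

    rec_times, rec_eta, rec_fields = [], [], {n: [] for n in
                                             setup.output.fields}
    sec_flux = {name: [] for name in setup.sections}
    out_every = (int(round(setup.output.interval / dt))
                 if setup.output.interval else 0)

    env_xy = mesh.mesh2d.voronoi_points
    env_base = {
        "x": np.broadcast_to(env_xy[:, 0][:, None], (P, K)),
        "y": np.broadcast_to(env_xy[:, 1][:, None], (P, K)),
        "z": np.broadcast_to(mesh.layering.z_center[None, :], (P, K)),
        "depth": np.broadcast_to(mesh.bathymetry[:, None], (P, K)),
    }

    n_steps = setup.n_steps
    flux = np.zeros((mesh.n_faces, K))
    vol_old = cell_volumes(mesh, hstate.eta if hstate else None)

    for i in range(n_steps):
        t = setup.t_start + i * dt
        eta_bc, u_bc, tr_bc = _open_boundary_maps(setup, t)
        Q, load_arrays = _source_arrays(setup, t)
        meteo_t = setup.meteo.at(t) if setup.meteo else None

        Kv = setup.Kv
        if isinstance(Kv, tuple) and Kv[0] == "wind":
            wind = meteo_t.wind_speed if meteo_t else 0.0
            Kv = float(offmod.wind_vertical_diffusivity(
                wind, a=Kv[1], b=Kv[2], K_background=Kv[3]))

        # --- hydrodynamic provider
        if hstate is not None:
            wind_tau = (0.0, 0.0)
            if meteo_t is not None:
                w = float(np.asarray(meteo_t.wind_speed))
                wind_tau = (RHO_AIR * CD_WIND * w * abs(w), 0.0)
            forc = HydroForcing(wind_stress=wind_tau, eta_open=eta_bc,
                                u_open=u_bc, sources=Q if Q.any() else None)
            hstate.temp, hstate.salt = temp, salt
            hstate = step_hydro(hstate, mesh, setup.hydro_params, forc,
                                transport_ts=False)
            flux = hstate.last_flux
            vol_new = cell_volumes(mesh, hstate.eta)
        elif series is not None:
            snap = offmod.fields_at(series, t)
            if "u" in snap:
                u = snap["u"]
            elif "speed" in snap:
                u = offmod.broadcast_profile(snap["speed"],
                                             snap.get("direction", 0.0), mesh)
            else:
                u = np.zeros((mesh.n_faces, K))
            flux = (u * mesh.mesh2d.face_length[:, None]
                    * mesh.face_layer_thickness)
            if "Kv" in snap:
                Kv = float(np.asarray(snap["Kv"]).ravel()[0])
            vol_new = vol_old
        else:
            vol_new = vol_old

        # --- surface heat budget
        light = np.zeros((P, K))
        if setup.heat_enabled and meteo_t is not None:
            hp = setup.heat_params
            Tsurf = temp[:, 0]
            if hp.mode == "fick":
                qn = heatmod.fick_surface_conduction(
                    meteo_t, Tsurf, hp.conduction_coefficient)
                heating = np.zeros((P, K))
                heating[:, 0] = qn
            else:
                day = (t / 86400.0) % 365.0 + 1.0
                hour = (t / 3600.0) % 24.0
                fx = heatmod.surface_flux_bulk(meteo_t, Tsurf, hp,
                                               day_of_year=day,
                                               time_of_day=hour)
                q_sw_net = fx["Q_sw_incident"] * (
                    1.0 - hp.shortwave_surface_reflectivity)
                q_non = fx["Q_lw"] + fx["Q_sensible"] + fx["Q_latent"]
                heating = heatmod.column_heating(mesh, q_sw_net, q_non, hp)
                light = heatmod.shortwave_light_profile(q_sw_net, mesh, hp)
            temp = temp + dt * heatmod.heating_to_temperature_tendency(
                heating, mesh, hp)

        # --- tracer transport
        if adv_names or setup.hydro_enabled:
            kwargs = dict(vol_old=vol_old, vol_new=vol_new,
                          Kh=setup.Kh, Kv=Kv if np.isscalar(Kv) else 0.0)
            if setup.hydro_enabled:
                # T/S default to clamped initial values on open boundaries
                temp = scheme(temp, flux, mesh, dt,
                              boundary_values=tr_bc.get(
                                  "temp", setup.initial_temp), **kwargs)
                salt = scheme(salt, flux, mesh, dt,
                              boundary_values=tr_bc.get(
                                  "salt", setup.initial_salt), **kwargs)
            for name in adv_names:
                fields[name] = scheme(
                    fields[name], flux, mesh, dt,
                    boundary_values=tr_bc.get(name),
                    sources=load_arrays.get(name), **kwargs)
            for name, arr in load_arrays.items():
                if name not in adv_names and name in fields:
                    act = vol_new > 0
                    fields[name][act] += dt * arr[act] / vol_new[act]

        # --- equation systems
        if system.variables:
            env = dict(env_base)
            env.update({"temp": temp, "salt": salt, "light": light,
                        "time": t})
            tau = (bottom_stress(hstate, mesh, setup.hydro_params)
                   if hstate is not None else np.zeros(P))
            env["bottom_stress"] = np.broadcast_to(tau[:, None], (P, K))
            if system.equations:
                fields = eqmod.evaluate_timestep(system, fields, env, dt,
                                                 stiffness_warning=False)
            fields = eqmod.apply_settling(system, fields, mesh, dt,
                                          benthic=benthic, environment=env)
            if benthic is not None:
                fields = eqmod.resuspend(system, fields, benthic, tau, dt,
                                         mesh)
                fields = eqmod.interface_exchange(system, fields, benthic,
                                                  mesh, dt)
            for name in fields:
                if system.variables[name].nonnegative:
                    fields[name], err = trmod.clip_negative(fields[name],
                                                            mesh, vol_new)
                    log.clipped_mass[name] = (
                        log.clipped_mass.get(name, 0.0) + err)

        # --- ABM
        if pop is not None and (i + 1) % setup.abm.substep == 0:
            u_now = (hstate.u if hstate is not None
                     else flux / np.where(
                         mesh.face_layer_thickness > 0,
                         mesh.mesh2d.face_length[:, None]
                         * mesh.face_layer_thickness, np.inf))
            abmmod.step_agents(
                pop, mesh, u_now, setup.abm.substep * dt,
                diffusivity=setup.abm.diffusivity,
                diffusivity_v=setup.abm.diffusivity_v,
                boundary_mode=setup.abm.boundary,
                scheme=setup.abm.scheme)

        vol_old = vol_new

        # --- outputs
        if out_every and (i + 1) % out_every == 0:
            tt = t + dt
            rec_times.append(tt)
            if hstate is not None:
                rec_eta.append(hstate.eta.copy())
            for name in rec_fields:
                if name == "eta" and hstate is not None:
                    continue
                src = (fields.get(name) if name in fields
                       else {"temp": temp, "salt": salt}.get(name))
                if src is not None:
                    rec_fields[name].append(src.copy())
            for name, sec in setup.sections.items():
                sec_flux[name].append(trmod.section_flux(sec, flux, mesh))
            masses = {n: trmod.total_mass(fields[n], mesh, vol_new)
                      for n in fields}
            log.record(tt, float(vol_new.sum()), masses)

    connectivity = None
    if pop is not None and setup.abm.region_polygons:
        region_of_poly = np.full(P, -1, dtype=int)
        for region, polys in setup.abm.region_polygons.items():
            region_of_poly[polys] = region
        connectivity = abmmod.downstream_connectivity(
            pop, region_of_poly, regions=sorted(
                setup.abm.region_polygons))

    result = RunResult(
        setup=setup, times=np.asarray(rec_times),
        eta=np.asarray(rec_eta) if rec_eta else None,
        fields={n: np.asarray(v) for n, v in rec_fields.items() if v},
        benthic=benthic,
        section_fluxes={n: np.asarray(v) for n, v in sec_flux.items()},
        population=pop, connectivity=connectivity, hydro_state=hstate,
        log=log)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def run_file(xml_path, outdir=None) -> RunResult:
    return run(load_setup(xml_path), outdir=outdir)


def _release_population(setup: SimulationSetup, mesh: Mesh3D):
    rng = np.random.default_rng(setup.seed)
    positions, regions, zs = [], [], []
    for region, polys, n, z in setup.abm.releases:
        for _ in range(n):
            p = int(rng.choice(polys))
            positions.append(mesh.mesh2d.voronoi_points[p])
            regions.append(region)
            zs.append(z)
    if not positions:
        return None
    return abmmod.AgentPopulation.release(
        mesh, np.asarray(positions), z=np.asarray(zs),
        regions=np.asarray(regions), seed=setup.seed,
        substep_multiple=setup.abm.substep, traits=setup.abm.traits)


# ---------------------------------------------------------------------------
# output writing and state checkpoints
# ---------------------------------------------------------------------------

def write_outputs(result: RunResult, outdir) -> None:
    import pandas as pd
    import xarray as xr

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = {}
    if result.eta is not None and len(result.eta):
        data["eta"] = (("time", "poly"), result.eta)
    for name, arr in result.fields.items():
        data[name] = (("time", "poly", "layer"), arr)
    if data:
        xr.Dataset(data, coords={"time": result.times}).to_netcdf(
            outdir / "fields.nc", engine="scipy")
    for name, fl in result.section_fluxes.items():
        if len(fl):
            pd.DataFrame({"time": result.times, "flux_m3s": fl}).to_csv(
                outdir / f"section_{name}.csv", index=False)
    if result.connectivity is not None:
        np.savetxt(outdir / "connectivity.csv",
                   result.connectivity.matrix, delimiter=",",
                   header=",".join(map(str, result.connectivity.regions))
                   + ",lost", comments="")
    if result.population is not None:
        pop = result.population
        pd.DataFrame({"x": pop.x, "y": pop.y, "z": pop.z,
                      "active": pop.active.astype(int),
                      "region": pop.release_region}).to_csv(
            outdir / "agents.csv", index=False)


def save_state(state: HydroState, path) -> None:
    """Checkpoint a hydro state as NetCDF (doubles round-trip exactly)."""
    import xarray as xr

    xr.Dataset(
        {"u": (("face", "layer"), state.u),
         "eta": ("poly", state.eta),
         "temp": (("poly", "layer"), state.temp),
         "salt": (("poly", "layer"), state.salt)},
        attrs={"time": state.time}).to_netcdf(path, engine="scipy")


def load_state(path) -> HydroState:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        st = HydroState(u=ds["u"].values.copy(), eta=ds["eta"].values.copy(),
                        temp=ds["temp"].values.copy(),
                        salt=ds["salt"].values.copy(),
                        time=float(ds.attrs.get("time", 0.0)))
    st.rho = EOS()(st.temp, st.salt)
    return st


# ---------------------------------------------------------------------------
# fixture recipes
# ---------------------------------------------------------------------------

RECIPES = ("box_npzd", "seiche", "channel", "gyre_abm", "farm_depletion",
           "sediment_plume")


def generate_fixtures(recipe: str, outdir) -> Path:
    """Write a complete runnable setup directory for a named recipe.

    Each recipe runs in well under a minute on one CPU and exercises a
    different module combination.
    Returns the path of the setup XML file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fn = {
        "box_npzd": _fixture_box_npzd,
        "seiche": _fixture_seiche,
        "channel": _fixture_channel,
        "gyre_abm": _fixture_gyre_abm,
        "farm_depletion": _fixture_farm_depletion,
        "sediment_plume": _fixture_sediment_plume,
    }.get(recipe)
    if fn is None:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {RECIPES}")
    return fn(outdir)


def _write(outdir: Path, xml: str) -> Path:
    p = outdir / "setup.xml"
    p.write_text(xml.strip() + "\n")
    return p


def _fixture_box_npzd(outdir: Path) -> Path:
    day = 86400.0
    return _write(outdir, f"""
<flexmarine name="box_npzd">
  <mesh><fixture kind="rect" nx="1" ny="1" dx="100" depth="10"/>
        <layers>0,10</layers></mesh>
  <time start="0" stop="{100 * day}" dt="{0.01 * day}"/>
  <constants>
    <constant name="mu" value="{1.0 / day}"/>
    <constant name="kN" value="0.3"/>
    <constant name="m" value="{0.05 / day}"/>
  </constants>
  <pelagicvariables>
    <variable name="N" initial="1.0" nonnegative="true"/>
    <variable name="Phy" initial="0.01" nonnegative="true"/>
  </pelagicvariables>
  <auxiliaries><aux name="uptake">mu*Phy*N/(N+kN)</aux></auxiliaries>
  <equations>
    <equation variable="N">-uptake + m*Phy</equation>
    <equation variable="Phy">uptake - m*Phy</equation>
  </equations>
  <output interval="{day}" fields="N,Phy"/>
</flexmarine>""")


def _fixture_seiche(outdir: Path) -> Path:
    return _write(outdir, """
<flexmarine name="seiche">
  <mesh><fixture kind="rect" nx="50" ny="1" dx="100" depth="10"/>
        <layers>0,10</layers></mesh>
  <time start="0" stop="3200" dt="4"/>
  <hydro theta="0.5" tilt="0.01"/>
  <sections>
    <section name="mid"><point x="2480" y="-10"/>
                        <point x="2520" y="110"/></section>
  </sections>
  <output interval="4" fields="eta"/>
</flexmarine>""")


def _fixture_channel(outdir: Path) -> Path:
    return _write(outdir, """
<flexmarine name="channel">
  <mesh><fixture kind="rect" nx="30" ny="4" dx="100" depth="10"
                 open="west,east"/>
        <layers>0,10</layers></mesh>
  <time start="0" stop="36000" dt="60"/>
  <hydro theta="0.5"/>
  <transport scheme="explicit"/>
  <pelagicvariables>
    <variable name="C" initial="0.0" advected="true" nonnegative="true"/>
  </pelagicvariables>
  <boundary>
    <u vx="0.1" vy="0"/>
    <tracer name="C" value="1.0"/>
  </boundary>
  <output interval="600" fields="C,eta"/>
</flexmarine>""")


def _fixture_gyre_abm(outdir: Path) -> Path:
    mesh = generate_fixture_mesh("rect", nx=21, ny=21, dx=100.0, depth=10.0)
    u = _solid_body_u(mesh, omega=2e-3)
    offmod.save_offline(offmod.OfflineFieldSeries(
        times=np.array([0.0, 1e6]),
        fields={"u": np.stack([u, u])}), outdir / "gyre.nc")
    # three concentric regions by radius from the domain center
    vp = mesh.mesh2d.voronoi_points
    r = np.hypot(vp[:, 0] - vp[:, 0].mean(), vp[:, 1] - vp[:, 1].mean())
    bands = [np.where(r < 300)[0], np.where((r >= 300) & (r < 700))[0],
             np.where(r >= 700)[0]]
    rel = "\n".join(
        f'    <release region="{k}" n="200" z="5" polygons='
        f'"{",".join(map(str, band))}"/>' for k, band in enumerate(bands))
    return _write(outdir, f"""
<flexmarine name="gyre_abm">
  <mesh><fixture kind="rect" nx="21" ny="21" dx="100" depth="10"/>
        <layers>0,10</layers></mesh>
  <time start="0" stop="7200" dt="60" seed="7"/>
  <offline file="gyre.nc"/>
  <abm substep="1" diffusivity="0.5" boundary="solid">
{rel}
  </abm>
  <output interval="720" agents="true"/>
</flexmarine>""")


def _fixture_farm_depletion(outdir: Path) -> Path:
    # rectangle 1500 x 1050 m, 50 m cells, farm block (250 x 200 m) in the
    # middle with rope loops at 0-3 m depth; food tracer enters at the open
    # boundaries with an offline uniform current and is filtered in the farm
    K = 5
    mesh = generate_fixture_mesh(
        "rect", nx=30, ny=21, dx=50.0, depth=5.0,
        layer_interfaces=np.linspace(0, 5, K + 1),
        open_edges=("west", "east"))
    u = offmod.broadcast_profile(np.full(K, 0.05), np.full(K, 90.0), mesh)
    offmod.save_offline(offmod.OfflineFieldSeries(
        times=np.array([0.0, 1e7]),
        fields={"u": np.stack([u, u])}), outdir / "current.nc")
    day = 86400.0
    return _write(outdir, f"""
<flexmarine name="farm_depletion">
  <mesh><fixture kind="rect" nx="30" ny="21" dx="50" depth="5"
                 open="west,east"/>
        <layers>0,1,2,3,4,5</layers></mesh>
  <time start="0" stop="{0.5 * day}" dt="120"/>
  <offline file="current.nc"/>
  <transport scheme="explicit" kh="0.5"/>
  <constants><constant name="r_filter" value="{20.0 / day}"/></constants>
  <pelagicvariables>
    <variable name="food" initial="1.0" advected="true"
              nonnegative="true"/>
  </pelagicvariables>
  <auxiliaries>
    <aux name="in_farm">step(x-625)*step(875-x)*step(y-425)*step(625-y)</aux>
  </auxiliaries>
  <equations>
    <equation variable="food">-r_filter*in_farm*step(3-z)*food</equation>
  </equations>
  <boundary>
    <tracer name="food" value="1.0"/>
  </boundary>
  <output interval="{0.1 * day}" fields="food"/>
</flexmarine>""")


def _fixture_sediment_plume(outdir: Path) -> Path:
    # point release of two grain-size fractions in a uniform current;
    # Stokes fall velocities for 66 and 9 micron grains
    mesh = generate_fixture_mesh(
        "rect", nx=41, ny=5, dx=100.0, depth=20.0,
        layer_interfaces=np.linspace(0, 20, 5), open_edges=("west", "east"))
    u = offmod.broadcast_profile(0.05, 90.0, mesh)
    offmod.save_offline(offmod.OfflineFieldSeries(
        times=np.array([0.0, 1e7]),
        fields={"u": np.stack([u, u])}), outdir / "current.nc")
    return _write(outdir, """
<flexmarine name="sediment_plume">
  <mesh><fixture kind="rect" nx="41" ny="5" dx="100" depth="20"
                 open="west,east"/>
        <layers>0,5,10,15,20</layers></mesh>
  <time start="0" stop="86400" dt="120"/>
  <offline file="current.nc"/>
  <pelagicvariables>
    <variable name="sed_coarse" initial="0" advected="true"
              nonnegative="true" settling="3.9e-3"
              settle_target="dep_coarse"/>
    <variable name="sed_fine" initial="0" advected="true"
              nonnegative="true" settling="7.3e-5"
              settle_target="dep_fine"/>
  </pelagicvariables>
  <benthicvariables>
    <variable name="dep_coarse"/>
    <variable name="dep_fine"/>
  </benthicvariables>
  <boundary>
    <tracer name="sed_coarse" value="0"/>
    <tracer name="sed_fine" value="0"/>
  </boundary>
  <sources>
    <source polygon="92" flux="0" distribution="surface">
      <load name="sed_coarse" rate="1.0"/>
      <load name="sed_fine" rate="1.0"/>
    </source>
  </sources>
  <output interval="7200" fields="sed_coarse,sed_fine"/>
</flexmarine>""")


def _solid_body_u(mesh: Mesh3D, omega: float) -> np.ndarray:
    """Face-normal velocities of solid-body rotation about the mesh center."""
    m2 = mesh.mesh2d
    c = m2.voronoi_points.mean(axis=0)
    fc = m2.face_center - c
    v = omega * np.stack([-fc[:, 1], fc[:, 0]], axis=1)
    u = np.sum(v * m2.face_normal, axis=1)[:, None] * np.ones(
        (1, mesh.n_layers))
    u[~mesh.face_layer_wet] = 0.0
    u[m2.face_right < 0] = 0.0
    return u
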