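"""XML setup files: parsing, validation and the SimulationSetup contract.

A complete model — mesh, simulation period, module selection, constants,
variables, equations, forcings and output requests — is declared in one
XML file and run without programming.  Validation is aggregated: all
configuration errors are reported at once, not just the first.

Schema sketch (all blocks optional except <mesh> and <time>)::

    <flexmarine name="demo">
      <mesh>
        <fixture kind="rect" nx="50" ny="1" dx="100" depth="10"
                 open="west,east"/>
        <!-- or <file path="mesh.txt"/> (bathymetry column included) -->
        <layers>0, 5, 10</layers>
      </mesh>
      <time start="0" stop="3600" dt="5" seed="1"/>
      <hydro theta="0.5" f="1e-4" nu_h="0" nu_v="0" c_smag="0"
             c_bottom="0"/>
      <offline file="fields.nc"/>
      <heat mode="fick" conduction="50" penetration_depth="5"
            latitude="55"/>
      <meteo wind_speed="5" air_temp="10" cloud_cover="0.5"
             rel_humidity="0.8"/>
      <transport scheme="explicit" kh="0" kv="0"/>
      <constants> <constant name="r" value="0.1"/> </constants>
      <pelagicvariables>
        <variable name="P" initial="0.01" advected="true"
                  nonnegative="true"/>
      </pelagicvariables>
      <benthicvariables> ... </benthicvariables>
      <auxiliaries> <aux name="uptake">r*P</aux> </auxiliaries>
      <equations> <equation variable="P">r*P*(1-P/K)</equation> </equations>
      <boundary>
        <eta value="0"/> <u vx="0.1" vy="0"/>
        <tracer name="P" value="1.0"/>  <!-- or file="series.txt" -->
      </boundary>
      <sources>
        <source polygon="12" flux="1.0" distribution="surface">
          <load name="P" rate="2.0"/>
        </source>
      </sources>
      <abm n="1000" substep="1" diffusivity="0" boundary="solid">
        <release region="1" polygons="0,1,2" n="500" z="1.0"/>
      </abm>
      <sections>
        <section name="mid"> <point x="2500" y="-10"/>
                             <point x="2500" y="110"/> </section>
      </sections>
      <output interval="60" fields="eta,P" agents="false"/>
    </flexmarine>

Time-series forcing files are delimited text with two columns (time,
value); time is seconds or ISO 8601.
"""

from __future__ import annotations

import hashlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import equations as eqmod
from . import mesh as meshmod
from .heat import HeatParams, MeteoForcing
from .hydro import HydroParams, EOS


class SetupError(ValueError):
    """Aggregated configuration errors."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("configuration errors:\n  - "
                         + "\n  - ".join(self.errors))


def read_series(path) -> "TimeSeries":
    """Read a (time, value) delimited text series; time in seconds or ISO."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     header=None, names=["time", "value"],
                     skipinitialspace=True)
    if df["time"].dtype == object:
        t = pd.to_datetime(df["time"])
        df["time"] = (t - t.iloc[0]).dt.total_seconds()
    return TimeSeries(df["time"].to_numpy(float), df["value"].to_numpy(float))


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray

    def __call__(self, t):
        return float(np.interp(t, self.times, self.values))


@dataclass
class SourceConfig:
    polygon: int
    flux: object = 0.0                   # m^3/s, value or TimeSeries
    loads: dict = field(default_factory=dict)
    distribution: str = "surface"


@dataclass
class AbmConfig:
    n: int = 0
    substep: int = 1
    diffusivity: object = 0.0
    diffusivity_v: float = 0.0
    boundary: str = "solid"              # solid | sink
    scheme: str = "rk2"
    releases: list = field(default_factory=list)   # (region, polygons, n, z)
    region_polygons: dict = field(default_factory=dict)
    traits: dict = field(default_factory=dict)


@dataclass
class OutputConfig:
    interval: float = 0.0
    fields: list = field(default_factory=list)
    agents: bool = False
    path: str = "output"


@dataclass
class SimulationSetup:
    name: str
    mesh: meshmod.Mesh3D
    t_start: float
    t_stop: float
    dt: float
    seed: int = 0
    hydro_enabled: bool = False
    offline_enabled: bool = False
    hydro_params: HydroParams | None = None
    initial_eta_tilt: float | None = None
    offline_file: str | None = None
    heat_enabled: bool = False
    heat_params: HeatParams | None = None
    meteo: MeteoForcing | None = None
    transport_scheme: str = "explicit"
    Kh: float = 0.0
    Kv: object = 0.0
    system: eqmod.EquationSystem | None = None
    benthic_layers: int = 1
    boundary_eta: object = None
    boundary_u: tuple | None = None      # (vx, vy) values or TimeSeries
    boundary_tracers: dict = field(default_factory=dict)
    initial_temp: float = 10.0
    initial_salt: float = 35.0
    sources: list = field(default_factory=list)
    abm: AbmConfig | None = None
    sections: dict = field(default_factory=dict)
    output: OutputConfig = field(default_factory=OutputConfig)
    config_hash: str = ""
    base_dir: Path = Path(".")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_stop - self.t_start) / self.dt))


def _get(elem, name, default=None, cast=float):
    v = elem.get(name)
    if v is None:
        return default
    return cast(v)


def _bool(elem, name, default=False):
    v = elem.get(name)
    if v is None:
        return default
    return str(v).strip().lower() in ("1", "true", "yes", "on")


def _value_or_series(elem, attr, base: Path, errors, what):
    if elem.get("file"):
        p = base / elem.get("file")
        if not p.exists():
            errors.append(f"{what}: forcing file {p} not found")
            return 0.0
        return read_series(p)
    return _get(elem, attr, 0.0)


def load_setup(xml_path) -> SimulationSetup:
    """Parse and fully validate a setup file; raises SetupError with the
    complete list of problems found."""
    xml_path = Path(xml_path)
    text = xml_path.read_text()
    root = ET.fromstring(text)
    base = xml_path.parent
    errors: list = []

    # --- mesh
    mesh3d = None
    mnode = root.find("mesh")
    if mnode is None:
        errors.append("missing <mesh> block")
    else:
        layers_el = mnode.find("layers")
        layers = (np.array([float(v) for v in layers_el.text.replace(
            ",", " ").split()]) if layers_el is not None else None)
        fx = mnode.find("fixture")
        mf = mnode.find("file")
        try:
            if fx is not None:
                open_edges = tuple(e.strip() for e in
                                   (fx.get("open") or "").split(",")
                                   if e.strip())
                mesh3d = meshmod.generate_fixture_mesh(
                    fx.get("kind", "rect"),
                    nx=_get(fx, "nx", 10, int), ny=_get(fx, "ny", 10, int),
                    dx=_get(fx, "dx", 100.0), depth=_get(fx, "depth", 10.0),
                    rings=_get(fx, "rings", 2, int),
                    layer_interfaces=layers, open_edges=open_edges)
            elif mf is not None:
                p = base / mf.get("path")
                if not p.exists():
                    errors.append(f"mesh file {p} not found")
                else:
                    nodes, polys, mark, bathy = meshmod.read_mesh_text(
                        p, with_bathymetry=True)
                    if layers is None:
                        errors.append("<layers> required with a mesh file")
                    else:
                        mesh3d = meshmod.build_mesh(
                            nodes, polys, mark, bathy,
                            meshmod.Layering(layers))
            else:
                errors.append("<mesh> needs a <fixture> or <file> child")
        except meshmod.MeshError as e:
            errors.append(f"mesh: {e}")

    # --- time
    tnode = root.find("time")
    if tnode is None:
        errors.append("missing <time> block")
        t0, t1, dt, seed = 0.0, 0.0, 1.0, 0
    else:
        t0 = _get(tnode, "start", 0.0)
        t1 = _get(tnode, "stop", 0.0)
        dt = _get(tnode, "dt", 0.0)
        seed = _get(tnode, "seed", 0, int)
        if dt <= 0:
            errors.append("time step dt must be positive")
        if t1 <= t0:
            errors.append("stop time must exceed start time")

    # --- hydrodynamic providers (alternatives)
    hnode = root.find("hydro")
    onode = root.find("offline")
    if hnode is not None and onode is not None:
        errors.append("hydro and offline are alternative hydrodynamic "
                      "providers; enable at most one")
    hydro_params = None
    if hnode is not None:
        try:
            hydro_params = HydroParams(
                dt=dt if dt > 0 else 1.0,      # dt error reported above
                theta=_get(hnode, "theta", 0.5),
                f=_get(hnode, "f", 0.0),
                nu_laminar_h=_get(hnode, "nu_h", 0.0),
                nu_laminar_v=_get(hnode, "nu_v", 0.0),
                C_smag=_get(hnode, "c_smag", 0.0),
                C_bottom=_get(hnode, "c_bottom", 0.0),
                eos=EOS(mode=hnode.get("eos", "linear")))
        except ValueError as e:
            errors.append(f"hydro: {e}")
    offline_file = onode.get("file") if onode is not None else None
    if onode is not None and offline_file is None:
        errors.append("<offline> needs a file attribute")
    if offline_file and not (base / offline_file).exists():
        errors.append(f"offline file {base / offline_file} not found")

    # --- heat
    heat_node = root.find("heat")
    heat_params, meteo = None, None
    if heat_node is not None:
        try:
            heat_params = HeatParams(
                mode=heat_node.get("mode", "flux"),
                latitude=_get(heat_node, "latitude", 55.0),
                penetration_depth=_get(heat_node, "penetration_depth", 5.0),
                conduction_coefficient=_get(heat_node, "conduction", 0.0),
                shortwave_surface_reflectivity=_get(
                    heat_node, "albedo", 0.06),
                bottom_reflectivity=_get(heat_node, "bottom_reflectivity",
                                         1.0))
        except ValueError as e:
            errors.append(f"heat: {e}")
        mnode2 = root.find("meteo")
        if mnode2 is None:
            errors.append("<heat> requires a <meteo> block")
        else:
            meteo = MeteoForcing(
                wind_speed=_value_or_series(mnode2, "wind_speed", base,
                                            errors, "meteo wind"),
                air_temp=_value_or_series(mnode2, "air_temp", base,
                                          errors, "meteo air_temp"),
                cloud_cover=_get(mnode2, "cloud_cover", 0.0),
                rel_humidity=_get(mnode2, "rel_humidity", None),
                dew_point=_get(mnode2, "dew_point", None))

    # --- transport
    trnode = root.find("transport")
    scheme, Kh, Kv = "explicit", 0.0, 0.0
    if trnode is not None:
        scheme = trnode.get("scheme", "explicit")
        if scheme not in ("explicit", "semi_implicit"):
            errors.append(f"unknown transport scheme {scheme!r}")
        Kh = _get(trnode, "kh", 0.0)
        Kv = _get(trnode, "kv", 0.0)
        if trnode.get("kv_wind_a"):   # wind-dependent vertical diffusivity
            Kv = ("wind", float(trnode.get("kv_wind_a")),
                  _get(trnode, "kv_wind_b", 1.0),
                  _get(trnode, "kv_background", 1e-5))

    # --- equation system
    system = None
    try:
        system = eqmod.parse_equation_system(root)
    except (eqmod.EquationError, eqmod.DSLSyntaxError) as e:
        errors.append(f"equations: {e}")

    # --- boundaries
    bnode = root.find("boundary")
    boundary_eta, boundary_u = None, None
    boundary_tracers: dict = {}
    if bnode is not None:
        enode = bnode.find("eta")
        if enode is not None:
            boundary_eta = _value_or_series(enode, "value", base, errors,
                                            "boundary eta")
        unode = bnode.find("u")
        if unode is not None:
            boundary_u = (_value_or_series(unode, "vx", base, errors,
                                           "boundary u"),
                          _get(unode, "vy", 0.0))
        for tn in bnode.iter("tracer"):
            boundary_tracers[tn.get("name")] = _value_or_series(
                tn, "value", base, errors, f"boundary {tn.get('name')}")

    has_open = (mesh3d is not None
                and np.any(mesh3d.mesh2d.face_kind == meshmod.OPEN))
    if has_open and system is not None:
        for name in system.pelagic_names():
            spec = system.variables[name]
            if spec.advected and name not in boundary_tracers:
                errors.append(
                    f"advected variable {name!r} needs boundary values "
                    "(open boundaries exist)")

    # --- sources
    sources = []
    snode = root.find("sources")
    if snode is not None:
        for s in snode.iter("source"):
            loads = {ld.get("name"): _get(ld, "rate", 0.0)
                     for ld in s.iter("load")}
            sources.append(SourceConfig(
                polygon=_get(s, "polygon", 0, int),
                flux=_value_or_series(s, "flux", base, errors, "source"),
                loads=loads,
                distribution=s.get("distribution", "surface")))
            if system is not None:
                for ld in loads:
                    if ld not in system.variables:
                        errors.append(f"source load targets undeclared "
                                      f"variable {ld!r}")

    # --- abm
    abm_cfg = None
    anode = root.find("abm")
    if anode is not None:
        abm_cfg = AbmConfig(
            n=_get(anode, "n", 0, int),
            substep=_get(anode, "substep", 1, int),
            diffusivity=_get(anode, "diffusivity", 0.0),
            diffusivity_v=_get(anode, "diffusivity_v", 0.0),
            boundary=anode.get("boundary", "solid"),
            scheme=anode.get("scheme", "rk2"))
        if abm_cfg.boundary not in ("solid", "sink"):
            errors.append(f"unknown abm boundary mode {abm_cfg.boundary!r}")
        if abm_cfg.substep < 1:
            errors.append("abm substep must be >= 1")
        for r in anode.iter("release"):
            polys = [int(v) for v in r.get("polygons", "").replace(
                ",", " ").split()]
            region = _get(r, "region", 0, int)
            abm_cfg.releases.append((region, polys, _get(r, "n", 0, int),
                                     _get(r, "z", 0.0)))
            abm_cfg.region_polygons[region] = polys
        for tr in anode.iter("trait"):
            abm_cfg.traits[tr.get("name")] = _get(tr, "initial", 0.0)

    # --- sections
    sections: dict = {}
    secnode = root.find("sections")
    if secnode is not None and mesh3d is not None:
        for s in secnode.iter("section"):
            pts = [(float(p.get("x")), float(p.get("y")))
                   for p in s.iter("point")]
            try:
                sections[s.get("name")] = meshmod.define_section(
                    mesh3d, pts, name=s.get("name"))
            except meshmod.MeshError as e:
                errors.append(f"section {s.get('name')!r}: {e}")

    # --- output
    out = OutputConfig()
    outnode = root.find("output")
    if outnode is not None:
        out = OutputConfig(
            interval=_get(outnode, "interval", 0.0),
            fields=[f.strip() for f in (outnode.get("fields") or "").split(
                ",") if f.strip()],
            agents=_bool(outnode, "agents"),
            path=outnode.get("path", "output"))
        if out.interval and dt > 0:
            ratio = out.interval / dt
            if abs(ratio - round(ratio)) > 1e-9:
                errors.append("output interval must be a multiple of dt")

    if errors:
        raise SetupError(errors)

    return SimulationSetup(
        name=root.get("name", xml_path.stem), mesh=mesh3d,
        t_start=t0, t_stop=t1, dt=dt, seed=seed,
        hydro_enabled=hnode is not None, offline_enabled=onode is not None,
        hydro_params=hydro_params,
        initial_eta_tilt=(_get(hnode, "tilt", None)
                          if hnode is not None else None),
        offline_file=offline_file,
        heat_enabled=heat_node is not None, heat_params=heat_params,
        meteo=meteo, transport_scheme=scheme, Kh=Kh, Kv=Kv,
        system=system, boundary_eta=boundary_eta, boundary_u=boundary_u,
        boundary_tracers=boundary_tracers,
        initial_temp=_get(root.find("initial") if root.find("initial")
                          is not None else root, "temp", 10.0),
        initial_salt=_get(root.find("initial") if root.find("initial")
                          is not None else root, "salt", 35.0),
        sources=sources, abm=abm_cfg, sections=sections, output=out,
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
        base_dir=base)
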