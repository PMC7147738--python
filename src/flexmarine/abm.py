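"""Lagrangian agent-based module.

Agents carry user-named trait variables solved with the same expression
engine as the pelagic equations, are advected with velocities interpolated
to their positions (barycentric interpolation on the triangulated Voronoi
points — linear fields are reproduced exactly), and diffuse by a uniform
directional random walk.  The ABM sub-step can be any multiple of the
global time step.

Boundary rules: an agent that ends a sub-step outside the wet domain is
returned to the Voronoi point of its last wet element at unchanged depth
(clipped to the local water depth); open boundaries can instead act as
sinks that deactivate crossing agents.

Each agent owns a counter-based random stream derived from (seed, agent id)
so that changing the sub-stepping or agent count does not reorder draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .equations import EquationSystem, Expression, evaluate_timestep
from .mesh import Mesh3D, OPEN
from . import hydro


class AbmError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# point location
# ---------------------------------------------------------------------------

class Locator:
    """Point-in-polygon queries backed by a shapely STRtree.

    Boundary ties go to the lowest polygon id.
    """

    def __init__(self, mesh: Mesh3D):
        import shapely

        m2 = mesh.mesh2d
        self._polys = [shapely.Polygon(m2.nodes[p]) for p in m2.polygons]
        self._tree = shapely.STRtree(self._polys)
        self._shapely = shapely
        self.mesh = mesh

    def locate(self, x, y) -> np.ndarray:
        """Polygon id for each (x, y); -1 for points outside the mesh."""
        sh = self._shapely
        pts = sh.points(np.column_stack([np.atleast_1d(x).astype(float),
                                         np.atleast_1d(y).astype(float)]))
        out = np.full(len(pts), -1, dtype=int)
        qi, pi = self._tree.query(pts, predicate="intersects")
        # lowest polygon id wins on shared edges/vertices
        for q, p in zip(qi, pi):
            if out[q] < 0 or p < out[q]:
                out[q] = p
        return out


def locate_element(mesh: Mesh3D, x, y):
    """One-shot point location (builds/caches a Locator on the mesh)."""
    loc = getattr(mesh, "_locator", None)
    if loc is None:
        loc = Locator(mesh)
        mesh._locator = loc
    ids = loc.locate(x, y)
    if np.isscalar(x):
        return int(ids[0])
    return ids


# ---------------------------------------------------------------------------
# velocity interpolation
# ---------------------------------------------------------------------------

class VelocityInterpolator:
    """Area-based (barycentric) interpolation of cell-centered velocities.

    Cell-centered velocity vectors are reconstructed from the face-normal
    components, triangulated on the Voronoi points, and interpolated with
    barycentric (area-coordinate) weights; outside the triangulation hull
    the containing cell's value is used.  Uniform fields are reproduced
    exactly; at a Voronoi point the weights collapse onto that cell.
    Vertical interpolation is linear between layer centers.
    """

    def __init__(self, mesh: Mesh3D):
        self.mesh = mesh
        self.geom = hydro.geometry(mesh)
        pts = mesh.mesh2d.voronoi_points
        self.tri = None
        if len(pts) >= 3:
            try:
                self.tri = Delaunay(pts)
            except Exception:        # collinear cell centers (1D chains)
                self.tri = None

    def cell_velocities(self, u: np.ndarray) -> np.ndarray:
        return self.geom.cell_vectors(u)          # (P, K, 2)

    def horizontal_weights(self, x, y, cell_ids):
        """(indices, weights) arrays of shape (n, 3)."""
        n = len(x)
        idx = np.zeros((n, 3), dtype=int)
        w = np.zeros((n, 3))
        if self.tri is not None:
            q = np.column_stack([x, y])
            s = self.tri.find_simplex(q)
            inside = s >= 0
            if inside.any():
                T = self.tri.transform[s[inside]]
                b = np.einsum("nij,nj->ni", T[:, :2, :],
                              q[inside] - T[:, 2, :])
                bary = np.concatenate([b, 1.0 - b.sum(axis=1, keepdims=True)],
                                      axis=1)
                idx[inside] = self.tri.simplices[s[inside]]
                w[inside] = bary
            out = ~inside
        else:
            out = np.ones(n, dtype=bool)
        if out.any():
            idx[out, 0] = np.clip(cell_ids[out], 0, None)
            w[out, 0] = 1.0
        return idx, w

    def __call__(self, u, x, y, z, cell_ids=None, w_interface=None):
        """Interpolate to positions; returns (vx, vy, vz) arrays."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        z = np.atleast_1d(np.asarray(z, float))
        if cell_ids is None:
            cell_ids = locate_element(self.mesh, x, y)
        if np.any(cell_ids < 0):
            raise AbmError("velocity requested outside the wet domain")
        V = self.cell_velocities(u)               # (P, K, 2)
        K = self.mesh.n_layers
        zc = self.mesh.layering.z_center
        k = np.clip(np.searchsorted(zc, z) - 1, 0, K - 2) if K > 1 else \
            np.zeros(len(z), dtype=int)
        if K > 1:
            frac = np.clip((z - zc[k]) / (zc[k + 1] - zc[k]), 0.0, 1.0)
        else:
            frac = np.zeros(len(z))
            k = np.zeros(len(z), dtype=int)
        idx, w = self.horizontal_weights(x, y, cell_ids)
        Vk = np.einsum("ni,nij->nj", w, V[idx, k[:, None], :])
        if K > 1:
            Vk1 = np.einsum("ni,nij->nj", w, V[idx, np.minimum(
                k[:, None] + 1, K - 1), :])
            Vh = Vk * (1 - frac)[:, None] + Vk1 * frac[:, None]
        else:
            Vh = Vk
        vz = np.zeros(len(x))
        if w_interface is not None and K > 1:
            wv = w_interface / self.mesh.mesh2d.areas[:, None]  # (P, K-1) m/s
            kk = np.clip(k, 0, K - 2)
            vz = wv[cell_ids, kk]
        return Vh[:, 0], Vh[:, 1], vz


def interpolate_velocity(mesh: Mesh3D, u, position, w_interface=None):
    """Interpolate the face-normal field u to one (x, y, z) position."""
    interp = getattr(mesh, "_vel_interp", None)
    if interp is None:
        interp = VelocityInterpolator(mesh)
        mesh._vel_interp = interp
    x, y, z = position
    vx, vy, vz = interp(u, [x], [y], [z], w_interface=w_interface)
    return float(vx[0]), float(vy[0]), float(vz[0])


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

@dataclass
class AgentPopulation:
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    active: np.ndarray
    release_region: np.ndarray
    traits: dict = field(default_factory=dict)
    seed: int = 0
    abm_substep_multiple: int = 1
    cell: np.ndarray = None              # current polygon of each agent
    _rngs: list = None

    def __post_init__(self):
        if self._rngs is None:
            self._rngs = [
                np.random.default_rng(
                    np.random.SeedSequence(entropy=self.seed,
                                           spawn_key=(int(i),)))
                for i in range(len(self.x))]

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @classmethod
    def release(cls, mesh: Mesh3D, positions, *, z=0.0, regions=None,
                seed: int = 0, substep_multiple: int = 1,
                traits: dict | None = None) -> "AgentPopulation":
        positions = np.asarray(positions, dtype=float)
        n = len(positions)
        z = np.broadcast_to(np.asarray(z, float), (n,)).copy()
        cell = locate_element(mesh, positions[:, 0], positions[:, 1])
        if np.any(cell < 0):
            raise AbmError("release position outside the mesh")
        reg = (np.broadcast_to(np.asarray(regions, int), (n,)).copy()
               if regions is not None else np.zeros(n, dtype=int))
        tr = {k: np.broadcast_to(np.asarray(v, float), (n,)).copy()
              for k, v in (traits or {}).items()}
        return cls(x=positions[:, 0].copy(), y=positions[:, 1].copy(), z=z,
                   active=np.ones(n, dtype=bool), release_region=reg,
                   traits=tr, seed=seed,
                   abm_substep_multiple=substep_multiple, cell=cell)


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def _segment_crosses_open_face(mesh: Mesh3D, p_old, p_new, poly: int) -> bool:
    from .mesh import _segments_cross

    m2 = mesh.mesh2d
    faces, _ = m2.polygon_faces[poly]
    for f in faces:
        if m2.face_kind[f] == OPEN:
            a = m2.nodes[m2.face_nodes[f, 0]]
            b = m2.nodes[m2.face_nodes[f, 1]]
            if _segments_cross(p_old, p_new, a, b):
                return True
    return False


def handle_boundary(pop: AgentPopulation, i: int, mesh: Mesh3D,
                    old_xy, new_xy, mode: str = "solid") -> None:
    """Apply the boundary rule to agent i whose end point left the domain."""
    if mode == "sink" and _segment_crosses_open_face(mesh, old_xy, new_xy,
                                                     int(pop.cell[i])):
        pop.active[i] = False
        return
    p = int(pop.cell[i])
    vp = mesh.mesh2d.voronoi_points[p]
    pop.x[i], pop.y[i] = vp
    pop.z[i] = min(pop.z[i], mesh.bathymetry[p])


def step_agents(pop: AgentPopulation, mesh: Mesh3D, u: np.ndarray,
                dt_abm: float, *, system: EquationSystem | None = None,
                environment: dict | None = None, diffusivity=0.0,
                diffusivity_v: float = 0.0, boundary_mode: str = "solid",
                scheme: str = "rk2",
                deactivate: Expression | None = None) -> AgentPopulation:
    """Advance all active agents one ABM step (in place; returns pop).

    Per step: trait equations (forward Euler via the shared DSL engine),
    RK2-midpoint (or Euler) advection, uniform-direction random walk with
    horizontal step sqrt(4 D dt) and vertical step sqrt(2 Dv dt), then
    boundary handling and the optional deactivation criterion.
    """
    interp = getattr(mesh, "_vel_interp", None)
    if interp is None:
        interp = VelocityInterpolator(mesh)
        mesh._vel_interp = interp

    act = np.where(pop.active)[0]
    if act.size == 0:
        return pop

    if system is not None and system.equations:
        env = dict(environment or {})
        env.setdefault("time", 0.0)
        env["x"], env["y"], env["z"] = pop.x[act], pop.y[act], pop.z[act]
        sub = {k: v[act] for k, v in pop.traits.items()}
        newt = evaluate_timestep(system, sub, env, dt_abm,
                                 stiffness_warning=False)
        for k in pop.traits:
            pop.traits[k][act] = newt[k]

    x0, y0, z0 = pop.x[act].copy(), pop.y[act].copy(), pop.z[act].copy()
    cells = pop.cell[act]
    vx, vy, vz = interp(u, x0, y0, z0, cell_ids=cells)
    if scheme == "rk2":
        xm = x0 + 0.5 * dt_abm * vx
        ym = y0 + 0.5 * dt_abm * vy
        zm = z0 + 0.5 * dt_abm * vz
        cm = locate_element(mesh, xm, ym)
        ok = cm >= 0
        # fall back to the Euler velocity where the midpoint left the domain
        if ok.any():
            zm_cl = np.clip(zm[ok], 0.0, mesh.bathymetry[cm[ok]])
            vx2, vy2, vz2 = interp(u, xm[ok], ym[ok], zm_cl,
                                   cell_ids=cm[ok])
            vx = vx.copy(); vy = vy.copy(); vz = vz.copy()
            vx[ok], vy[ok], vz[ok] = vx2, vy2, vz2
    elif scheme != "euler":
        raise ValueError(f"unknown advection scheme {scheme!r}")

    xn = x0 + dt_abm * vx
    yn = y0 + dt_abm * vy
    zn = z0 + dt_abm * vz

    # uniform directional random walk
    if callable(diffusivity):
        D = np.asarray(diffusivity(pop, act), dtype=float)
    elif isinstance(diffusivity, Expression):
        env = dict(environment or {})
        env.update({k: v[act] for k, v in pop.traits.items()})
        env["x"], env["y"], env["z"] = x0, y0, z0
        D = np.broadcast_to(np.asarray(diffusivity(env), float),
                            (act.size,))
    else:
        D = np.broadcast_to(float(diffusivity), (act.size,))
    if np.any(D > 0) or diffusivity_v > 0:
        ell = np.sqrt(4.0 * D * dt_abm)
        ellv = np.sqrt(2.0 * diffusivity_v * dt_abm)
        for j, i in enumerate(act):
            rng = pop._rngs[i]
            draws = rng.random(2)
            ang = 2.0 * np.pi * draws[0]
            xn[j] += ell[j] * np.cos(ang)
            yn[j] += ell[j] * np.sin(ang)
            if ellv > 0:
                zn[j] += ellv if draws[1] < 0.5 else -ellv

    new_cell = locate_element(mesh, xn, yn)
    for j, i in enumerate(act):
        if new_cell[j] < 0:
            handle_boundary(pop, i, mesh, (x0[j], y0[j]), (xn[j], yn[j]),
                            mode=boundary_mode)
        else:
            pop.x[i], pop.y[i] = xn[j], yn[j]
            pop.cell[i] = new_cell[j]
            # reflect the vertical walk at surface and bottom
            d = mesh.bathymetry[new_cell[j]]
            zz = zn[j]
            if zz < 0:
                zz = -zz
            if zz > d:
                zz = max(2 * d - zz, 0.0)
            pop.z[i] = min(max(zz, 0.0), d)
        if not np.isfinite(pop.x[i]) or not np.isfinite(pop.y[i]):
            raise AbmError(f"non-finite position for agent {i}")

    if deactivate is not None:
        env = dict(environment or {})
        env.update({k: v for k, v in pop.traits.items()})
        env["x"], env["y"], env["z"] = pop.x, pop.y, pop.z
        crit = np.asarray(deactivate(env), dtype=float)
        pop.active &= ~((crit != 0) & pop.active)
    return pop


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    regions: list                     # region labels, index order
    matrix: np.ndarray                # (R, R+1); last column = lost
    counts: np.ndarray

    @property
    def lost(self) -> np.ndarray:
        return self.matrix[:, -1]

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)


def downstream_connectivity(pop: AgentPopulation, region_of_polygon,
                            regions=None) -> ConnectivityMatrix:
    """Census agents into a downstream-connectivity probability matrix.

    P[i, j] = fraction of agents released in region i that are censused in
    region j; the extra last column collects agents lost to open-boundary
    sinks or ending outside any region.  Rows over regions + lost sum to 1.
    """
    region_of_polygon = np.asarray(region_of_polygon, dtype=int)
    if regions is None:
        regions = sorted(set(pop.release_region.tolist()))
    regions = list(regions)
    rindex = {r: k for k, r in enumerate(regions)}
    R = len(regions)
    counts = np.zeros((R, R + 1))
    released = np.zeros(R)
    for i in range(pop.n):
        src = rindex.get(int(pop.release_region[i]))
        if src is None:
            continue
        released[src] += 1
        if not pop.active[i]:
            counts[src, R] += 1
            continue
        dst_region = region_of_polygon[int(pop.cell[i])]
        dst = rindex.get(int(dst_region))
        counts[src, dst if dst is not None else R] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = counts / released[:, None]
    empty = released == 0
    if empty.any():
        warnings.warn(f"regions with zero releases: "
                      f"{[regions[k] for k in np.where(empty)[0]]}",
                      UserWarning, stacklevel=2)
        matrix[empty] = np.nan
    return ConnectivityMatrix(regions=regions, matrix=matrix, counts=counts)
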