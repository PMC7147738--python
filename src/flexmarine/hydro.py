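"""Hydrostatic semi-implicit free-surface hydrodynamics on the C-grid.

The solver follows the classic semi-implicit finite difference / finite
volume approach for orthogonal unstructured meshes: face-normal velocities
are advanced with an explicit Adams-Bashforth-2 tendency (momentum advection,
horizontal and vertical diffusion, Coriolis, baroclinic pressure gradient,
wind and bottom drag), while the free-surface gradient and the divergence in
the continuity equation are treated with a theta-weighted implicit scheme.
Eliminating the new velocities from the continuity equation yields a
symmetric positive-definite system for the new surface elevation, solved
with a Jacobi-preconditioned conjugate gradient.

theta = 0 is fully explicit, theta = 1 fully implicit; theta = 0.5 gives the
second-order (least-damped) scheme.  The free surface is linearized: layer
thicknesses in fluxes are the undisturbed ones, but the surface-layer volume
carries the elevation so that discrete volume accounting is exact.

Open boundaries are clamped: elevation and/or normal velocity are prescribed
on open cells / faces.  The non-hydrostatic corrector is not implemented
(the ``nonhydrostatic`` flag is reserved in the configuration schema).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh3D, OPEN, SOLID

GRAVITY = 9.81


class HydroError(RuntimeError):
    pass


class CFLWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# equation of state
# ---------------------------------------------------------------------------

@dataclass
class EOS:
    """Equation of state rho(T, S) at surface pressure.

    mode='linear' (default): rho = rho0 * (1 - alpha_T (T - T0) + beta_S (S - S0)).
    mode='unesco': the EOS-80 one-atmosphere polynomial.
    """

    mode: str = "linear"
    rho0: float = 1025.0
    alpha_T: float = 2.0e-4   # 1/K
    beta_S: float = 7.6e-4    # 1/PSU
    T0: float = 10.0
    S0: float = 35.0

    def __call__(self, T, S):
        T = np.asarray(T, dtype=float)
        S = np.asarray(S, dtype=float)
        if self.mode == "linear":
            return self.rho0 * (1.0 - self.alpha_T * (T - self.T0)
                                + self.beta_S * (S - self.S0))
        if self.mode == "unesco":
            return _unesco_rho(T, S)
        raise ValueError(f"unknown EOS mode {self.mode!r}")


def _unesco_rho(T, S):
    """EOS-80 density of seawater at one atmosphere (kg/m^3)."""
    rw = (999.842594 + 6.793952e-2 * T - 9.095290e-3 * T**2
          + 1.001685e-4 * T**3 - 1.120083e-6 * T**4 + 6.536332e-9 * T**5)
    A = (0.824493 - 4.0899e-3 * T + 7.6438e-5 * T**2
         - 8.2467e-7 * T**3 + 5.3875e-9 * T**4)
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    return rw + A * S + B * S**1.5 + C * S**2


# ---------------------------------------------------------------------------
# parameters, state, forcing
# ---------------------------------------------------------------------------

@dataclass
class HydroParams:
    dt: float
    theta: float = 0.5
    g: float = GRAVITY
    f: float | np.ndarray = 0.0          # Coriolis parameter, 1/s
    rho0: float = 1025.0
    nu_laminar_h: float = 0.0            # m^2/s
    nu_laminar_v: float = 0.0
    C_smag: float = 0.0
    C_bottom: float = 0.0                # quadratic bottom drag coefficient
    pcg_tol: float = 1e-12
    pcg_maxiter: int = 2000
    eos: EOS = field(default_factory=EOS)
    advect_momentum: bool = True
    eta_limit: float = 100.0             # sanity bound on |eta|, m

    def __post_init__(self):
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.C_smag < 0:
            raise ValueError("C_smag must be >= 0")


def coriolis_from_latitude(lat_deg) -> np.ndarray:
    """f = 2 Omega sin(latitude)."""
    return 2.0 * 7.292115e-5 * np.sin(np.radians(np.asarray(lat_deg, float)))


@dataclass
class HydroState:
    u: np.ndarray                 # (F, K) face-normal velocity
    eta: np.ndarray               # (P,)
    temp: np.ndarray              # (P, K)
    salt: np.ndarray              # (P, K)
    rho: np.ndarray = None        # (P, K)
    nu_h: np.ndarray = None       # (P, K) total horizontal eddy viscosity
    prev_tendency: np.ndarray = None
    time: float = 0.0

    @classmethod
    def rest(cls, mesh: Mesh3D, temp: float = 10.0, salt: float = 35.0,
             eos: EOS | None = None) -> "HydroState":
        P, K, F = mesh.n_polygons, mesh.n_layers, mesh.n_faces
        t = np.full((P, K), float(temp))
        s = np.full((P, K), float(salt))
        eos = eos or EOS()
        return cls(u=np.zeros((F, K)), eta=np.zeros(P), temp=t, salt=s,
                   rho=eos(t, s), nu_h=np.zeros((P, K)))


@dataclass
class HydroForcing:
    """Time-resolvable forcings; entries may be constants or callables of t."""

    wind_stress: object = (0.0, 0.0)     # (tau_x, tau_y) N/m^2
    eta_open: dict | None = None         # polygon id -> eta value
    u_open: dict | None = None           # face id -> normal velocity
    sources: object = None               # (P,) volume fluxes m^3/s


def _eval(v, t):
    return v(t) if callable(v) else v


# ---------------------------------------------------------------------------
# geometry cache: velocity reconstruction and gradients
# ---------------------------------------------------------------------------

class HydroGeometry:
    """Precomputed incidence tables for vector reconstruction and gradients."""

    def __init__(self, mesh: Mesh3D):
        m2 = mesh.mesh2d
        P, F = m2.n_polygons, m2.n_faces
        inc_poly, inc_face = [], []
        for p, (faces, _) in enumerate(m2.polygon_faces):
            inc_poly.extend([p] * len(faces))
            inc_face.extend(faces.tolist())
        self.inc_poly = np.array(inc_poly, dtype=int)
        self.inc_face = np.array(inc_face, dtype=int)

        # signed incidence matrix: (R @ face_field)[p] = sum_f s_pf field_f
        signs = np.concatenate([s for _, s in m2.polygon_faces])
        self.R = sp.csr_matrix((signs, (self.inc_poly, self.inc_face)),
                               shape=(P, F))
        self.Rabs = sp.csr_matrix((np.abs(signs),
                                   (self.inc_poly, self.inc_face)),
                                  shape=(P, F))

        L = m2.face_length[self.inc_face]
        n = m2.face_normal[self.inc_face]
        M = np.zeros((P, 2, 2))
        np.add.at(M, self.inc_poly,
                  L[:, None, None] * n[:, :, None] * n[:, None, :])
        self.Minv = np.linalg.pinv(M)
        self.recon_w = L[:, None] * n      # weight of u_f in the rhs vector

        # least-squares gradient over Voronoi-point neighbours
        pair_p, pair_nb = [], []
        for p in range(P):
            for nb in m2.neighbors(p):
                pair_p.append(p)
                pair_nb.append(int(nb))
        self.pair_p = np.array(pair_p, dtype=int)
        self.pair_nb = np.array(pair_nb, dtype=int)
        dX = m2.voronoi_points[self.pair_nb] - m2.voronoi_points[self.pair_p]
        self.pair_w = np.zeros((len(pair_p), 2))
        for p in range(P):
            sel = np.where(self.pair_p == p)[0]
            if sel.size:
                self.pair_w[sel] = np.linalg.pinv(dX[sel]).T
        self.mesh = mesh

    def cell_vectors(self, u: np.ndarray) -> np.ndarray:
        """Reconstruct cell-centered velocity vectors from face-normal u.

        Least squares over the cell's faces; exact for any uniform field.
        Returns (P, K, 2).
        """
        F, K = u.shape
        b = np.zeros((self.Minv.shape[0], K, 2))
        np.add.at(b, self.inc_poly,
                  self.recon_w[:, None, :] * u[self.inc_face][:, :, None])
        return np.einsum("pij,pkj->pki", self.Minv, b)

    def cell_gradient(self, a: np.ndarray) -> np.ndarray:
        """Least-squares horizontal gradient of a per-(cell, layer) scalar.

        Returns (P, K, 2) = (d/dx, d/dy).
        """
        P, K = a.shape
        g = np.zeros((P, K, 2))
        diff = a[self.pair_nb] - a[self.pair_p]      # (pairs, K)
        np.add.at(g, self.pair_p, diff[:, :, None] * self.pair_w[:, None, :])
        return g


def geometry(mesh: Mesh3D) -> HydroGeometry:
    geom = getattr(mesh, "_hydro_geom", None)
    if geom is None:
        geom = HydroGeometry(mesh)
        mesh._hydro_geom = geom
    return geom


# ---------------------------------------------------------------------------
# viscosity
# ---------------------------------------------------------------------------

def smagorinsky_viscosity(state: HydroState, mesh: Mesh3D,
                          C_smag: float) -> np.ndarray:
    """Dynamic eddy viscosity nu = (C_s sqrt(A))^2 |S| from velocity shear.

    |S| = sqrt(2 S_ij S_ij) with S the symmetric part of the reconstructed
    cell-velocity gradient; zero for any uniform flow.
    """
    if C_smag == 0.0:
        return np.zeros((mesh.n_polygons, mesh.n_layers))
    geom = geometry(mesh)
    V = geom.cell_vectors(state.u)               # (P,K,2)
    gx = geom.cell_gradient(V[:, :, 0])          # (P,K,2) grads of Vx
    gy = geom.cell_gradient(V[:, :, 1])
    Sxx = gx[:, :, 0]
    Syy = gy[:, :, 1]
    Sxy = 0.5 * (gx[:, :, 1] + gy[:, :, 0])
    Smag = np.sqrt(2.0 * (Sxx**2 + Syy**2 + 2.0 * Sxy**2))
    L2 = mesh.mesh2d.areas[:, None]
    return (C_smag**2) * L2 * Smag


# ---------------------------------------------------------------------------
# momentum tendency
# ---------------------------------------------------------------------------

def _face_mean(cell_field, mesh):
    """Average a per-(cell, layer, ...) field to faces (one-sided on hull)."""
    m2 = mesh.mesh2d
    fl, fr = m2.face_left, m2.face_right
    left = cell_field[fl]
    right = np.where((fr >= 0).reshape((-1,) + (1,) * (cell_field.ndim - 1)),
                     cell_field[np.clip(fr, 0, None)], left)
    return 0.5 * (left + right)


def momentum_tendency(state: HydroState, mesh: Mesh3D, params: HydroParams,
                      wind_stress=(0.0, 0.0), *, combine_ab2: bool = True):
    """Explicit momentum tendency on faces (m/s^2), AB2-combined.

    Contributions: upwind momentum advection, horizontal + vertical
    diffusion, Coriolis, baroclinic pressure gradient, wind stress on the
    surface layer and quadratic bottom drag on the deepest wet layer.  The
    barotropic surface gradient is *not* included here; it belongs to the
    theta-weighted free-surface solve.

    Returns ``(tend_ab2, tend_raw)``; the raw tendency must be stored as
    ``state.prev_tendency`` for the next step (first step: forward Euler).
    """
    m2 = mesh.mesh2d
    geom = geometry(mesh)
    F, K = state.u.shape
    fl, fr = m2.face_left, m2.face_right
    interior = fr >= 0
    wet = mesh.face_layer_wet
    u = state.u

    cmax = float(np.max(np.abs(u) * params.dt / m2.face_distance[:, None]))
    if cmax > 1.0:
        warnings.warn(f"advective Courant number {cmax:.2f} exceeds 1",
                      CFLWarning, stacklevel=2)

    V = geom.cell_vectors(u)                     # (P,K,2)
    tend = np.zeros((F, K))

    vol = np.maximum(mesh.cell_volume, 1e-300)

    # --- upwind momentum advection (cell-vector form, projected to faces)
    if params.advect_momentum:
        flux = u * m2.face_length[:, None] * mesh.face_layer_thickness  # (F,K)
        Vl, Vr = V[fl], V[np.clip(fr, 0, None)]
        upwind = np.where((flux > 0)[:, :, None], Vl,
                          np.where((flux < 0)[:, :, None], Vr,
                                   0.5 * (Vl + Vr)))
        upwind = np.where(interior[:, None, None], upwind, Vl)
        div = geom.R @ flux
        adv = np.stack([geom.R @ (flux * upwind[:, :, 0]),
                        geom.R @ (flux * upwind[:, :, 1])], axis=2)
        adv = -(adv - V * div[:, :, None]) / vol[:, :, None]
        tend += np.einsum("fki,fi->fk", _face_mean(adv, mesh), m2.face_normal)

    # --- horizontal diffusion of momentum (two-point flux on the dual)
    nu_cell = state.nu_h if state.nu_h is not None else np.zeros_like(vol)
    nu_tot = nu_cell + params.nu_laminar_h
    if np.any(nu_tot > 0):
        nu_face = _face_mean(nu_tot, mesh)
        dV = np.where(interior[:, None, None],
                      V[np.clip(fr, 0, None)] - V[fl], 0.0)
        coef = (nu_face * m2.face_length[:, None] * mesh.face_layer_thickness
                / m2.face_distance[:, None])
        fluxV = coef[:, :, None] * dV
        lap = np.stack([geom.R @ fluxV[:, :, 0],
                        geom.R @ fluxV[:, :, 1]], axis=2)
        lap /= vol[:, :, None]
        tend += np.einsum("fki,fi->fk", _face_mean(lap, mesh), m2.face_normal)

    # --- vertical diffusion of momentum, directly on face columns
    if params.nu_laminar_v > 0 and K > 1:
        dzc = np.diff(mesh.layering.z_center)            # (K-1,)
        h = np.maximum(mesh.face_layer_thickness, 1e-300)
        du = u[:, :-1] - u[:, 1:]                        # (F, K-1)
        both_wet = wet[:, :-1] & wet[:, 1:]
        iflux = np.where(both_wet, params.nu_laminar_v * du / dzc[None, :], 0.0)
        tend[:, :-1] -= iflux / h[:, :-1]
        tend[:, 1:] += iflux / h[:, 1:]

    # --- Coriolis
    f_face = _face_mean(np.broadcast_to(
        np.asarray(params.f, float).reshape(-1),
        (mesh.n_polygons,)).copy(), mesh)
    if np.any(f_face != 0.0):
        Vf = _face_mean(V, mesh)                         # (F,K,2)
        acc = np.stack([f_face[:, None] * Vf[:, :, 1],
                        -f_face[:, None] * Vf[:, :, 0]], axis=2)
        tend += np.einsum("fki,fi->fk", acc, m2.face_normal)

    # --- baroclinic pressure gradient
    if state.rho is not None:
        drho = state.rho - params.rho0
        hthick = mesh.cell_thickness
        above = np.cumsum(drho * hthick, axis=1) - drho * hthick
        p_baro = params.g * (above + 0.5 * drho * hthick)     # at layer centers
        dp = np.where(interior[:, None],
                      p_baro[np.clip(fr, 0, None)] - p_baro[fl], 0.0)
        tend -= dp / (params.rho0 * m2.face_distance[:, None])

    # --- wind stress on the surface layer
    taux, tauy = wind_stress
    if np.any(np.asarray(taux) != 0) or np.any(np.asarray(tauy) != 0):
        tau_n = (np.broadcast_to(taux, (F,)) * m2.face_normal[:, 0]
                 + np.broadcast_to(tauy, (F,)) * m2.face_normal[:, 1])
        h0 = np.maximum(mesh.face_layer_thickness[:, 0], 1e-300)
        tend[:, 0] += tau_n / (params.rho0 * h0)

    # --- quadratic bottom drag on the deepest wet face layer
    if params.C_bottom > 0:
        kb = wet.sum(axis=1) - 1
        has = kb >= 0
        idx = np.arange(F)
        Vf = _face_mean(V, mesh)
        speed = np.hypot(Vf[:, :, 0], Vf[:, :, 1])
        hb = np.maximum(mesh.face_layer_thickness[idx[has], kb[has]], 1e-300)
        tend[idx[has], kb[has]] -= (params.C_bottom
                                    * speed[idx[has], kb[has]]
                                    * u[idx[has], kb[has]] / hb)

    tend[~wet] = 0.0

    if combine_ab2 and state.prev_tendency is not None:
        tend_ab2 = 1.5 * tend - 0.5 * state.prev_tendency
    else:
        tend_ab2 = tend
    return tend_ab2, tend


# ---------------------------------------------------------------------------
# free-surface solve
# ---------------------------------------------------------------------------

def solve_free_surface(state: HydroState, mesh: Mesh3D, params: HydroParams,
                       tendency: np.ndarray, *, eta_bc: dict | None = None,
                       u_bc: dict | None = None, sources=None):
    """Theta-weighted implicit free-surface solve.

    Parameters
    ----------
    tendency : explicit (AB2) momentum tendency, surface gradient excluded.
    eta_bc : {polygon: eta} clamped elevations on open cells.
    u_bc : {face: u} prescribed normal velocities on open faces (scalar or
        per-layer array).
    sources : (P,) volume sources, m^3/s.

    Returns ``(eta_new, u_new, flux_theta)`` where ``flux_theta`` is the
    continuity-consistent face volume flux (m^3/s per face and layer) to be
    used by the tracer transport so that a uniform tracer stays uniform.
    """
    m2 = mesh.mesh2d
    g, th, dt = params.g, params.theta, params.dt
    F, K = state.u.shape
    fl, fr = m2.face_left, m2.face_right
    interior = fr >= 0
    wet = mesh.face_layer_wet
    areas = m2.areas

    eta_bc = eta_bc or {}
    u_bc = u_bc or {}

    prescribed = np.zeros(F, dtype=bool)
    u_presc = np.zeros((F, K))
    for f, val in u_bc.items():
        prescribed[f] = True
        u_presc[f] = np.broadcast_to(np.asarray(val, float), (K,))
        u_presc[f][~wet[f]] = 0.0
    solid = (~interior) & ~prescribed

    # predictor velocity: explicit tendency + (1-theta) old surface gradient
    deta_old = np.where(interior, state.eta[np.clip(fr, 0, None)]
                        - state.eta[fl], 0.0)
    grad_old = g * deta_old / m2.face_distance
    u_star = state.u + dt * tendency - dt * (1 - th) * grad_old[:, None]
    u_star[~wet] = 0.0
    u_star[solid] = 0.0
    u_star[prescribed] = u_presc[prescribed]

    # conveyance sum_k h L of each face and theta-coupling coefficient
    HL = mesh.face_layer_thickness.sum(axis=1) * m2.face_length
    couple = interior & ~prescribed & (HL > 0)
    coef = np.zeros(F)
    coef[couple] = g * th**2 * dt**2 * HL[couple] / m2.face_distance[couple]

    Q = np.zeros(mesh.n_polygons)
    if sources is not None:
        Q += np.asarray(sources, float)

    # divergence of the predictor fluxes
    geom = geometry(mesh)
    flux_star = (m2.face_length[:, None] * mesh.face_layer_thickness
                 * (th * u_star + (1 - th) * state.u))
    flux_star[~wet] = 0.0
    div_star = np.asarray((geom.R @ flux_star).sum(axis=1)).ravel()

    rhs = areas * state.eta - dt * div_star + dt * Q

    clamped = np.zeros(mesh.n_polygons, dtype=bool)
    eta_cl = np.zeros(mesh.n_polygons)
    for p, val in eta_bc.items():
        clamped[p] = True
        eta_cl[p] = float(val)

    free = np.where(~clamped)[0]
    remap = -np.ones(mesh.n_polygons, dtype=int)
    remap[free] = np.arange(len(free))

    diag = areas.copy()
    rows, cols, vals = [], [], []
    cfaces = np.where(couple)[0]
    for f in cfaces:
        i, j = fl[f], fr[f]
        diag[i] += coef[f]
        diag[j] += coef[f]
        if clamped[i] and clamped[j]:
            continue
        if clamped[j]:
            rhs[i] += coef[f] * eta_cl[j]
        elif clamped[i]:
            rhs[j] += coef[f] * eta_cl[i]
        else:
            rows += [remap[i], remap[j]]
            cols += [remap[j], remap[i]]
            vals += [-coef[f], -coef[f]]
    rows += list(remap[free])
    cols += list(remap[free])
    vals += list(diag[free])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(free), len(free)))

    b = rhs[free]
    if len(free):
        Minv = sp.diags(1.0 / A.diagonal())
        x0 = state.eta[free]
        x, info = spla.cg(A, b, x0=x0, rtol=params.pcg_tol, atol=0.0,
                          maxiter=params.pcg_maxiter, M=Minv)
        if info != 0:
            res = np.linalg.norm(A @ x - b)
            raise HydroError(
                f"free-surface PCG did not converge (info={info}, "
                f"residual {res:.3e})")
    else:
        x = np.empty(0)

    eta_new = eta_cl.copy()
    eta_new[free] = x

    # corrector: new velocities from the theta-weighted surface gradient
    deta_new = np.where(interior, eta_new[np.clip(fr, 0, None)]
                        - eta_new[fl], 0.0)
    u_new = u_star - dt * th * g * (deta_new / m2.face_distance)[:, None]
    u_new[~wet] = 0.0
    u_new[solid] = 0.0
    u_new[prescribed] = u_presc[prescribed]

    # continuity-consistent fluxes and exact discrete volume update
    flux_theta = (m2.face_length[:, None] * mesh.face_layer_thickness
                  * (th * u_new + (1 - th) * state.u))
    flux_theta[~wet] = 0.0
    div = np.asarray((geom.R @ flux_theta).sum(axis=1)).ravel()
    eta_cons = state.eta - dt * (div - Q) / areas
    eta_new = np.where(clamped, eta_new, eta_cons)

    if np.any(np.abs(eta_new) > params.eta_limit):
        p = int(np.argmax(np.abs(eta_new)))
        raise HydroError(f"eta sanity limit exceeded at polygon {p}: "
                         f"{eta_new[p]:.3g} m")
    return eta_new, u_new, flux_theta


# ---------------------------------------------------------------------------
# full step
# ---------------------------------------------------------------------------

def step_hydro(state: HydroState, mesh: Mesh3D, params: HydroParams,
               forcings: HydroForcing | None = None, *,
               transport_ts: bool = False, Kh: float = 0.0, Kv: float = 0.0):
    """Advance the hydrodynamic state one time step.

    Order: viscosity update -> AB2 tendency -> free-surface solve ->
    optional T/S advection-diffusion -> EOS update.  Returns the new state;
    ``state`` itself is not modified.  The continuity-consistent face fluxes
    of the step are stored on the returned state as ``last_flux`` for use by
    the transport of other tracers.
    """
    forcings = forcings or HydroForcing()
    t = state.time
    wind = _eval(forcings.wind_stress, t)
    eta_bc = _eval(forcings.eta_open, t)
    u_bc = _eval(forcings.u_open, t)
    src = _eval(forcings.sources, t)

    nu_h = smagorinsky_viscosity(state, mesh, params.C_smag)
    work = HydroState(u=state.u, eta=state.eta, temp=state.temp,
                      salt=state.salt, rho=state.rho, nu_h=nu_h,
                      prev_tendency=state.prev_tendency, time=t)
    tend_ab2, tend_raw = momentum_tendency(work, mesh, params, wind)
    eta_new, u_new, flux = solve_free_surface(work, mesh, params, tend_ab2,
                                              eta_bc=eta_bc, u_bc=u_bc,
                                              sources=src)

    temp, salt = state.temp, state.salt
    if transport_ts:
        from . import transport as tr
        vol_old = cell_volumes(mesh, state.eta)
        vol_new = cell_volumes(mesh, eta_new)
        bval_t = getattr(forcings, "temp_open", None)
        bval_s = getattr(forcings, "salt_open", None)
        temp = tr.advect_diffuse_explicit(
            temp, flux, mesh, params.dt, vol_old=vol_old, vol_new=vol_new,
            Kh=Kh, Kv=Kv, boundary_values=_eval(bval_t, t))
        salt = tr.advect_diffuse_explicit(
            salt, flux, mesh, params.dt, vol_old=vol_old, vol_new=vol_new,
            Kh=Kh, Kv=Kv, boundary_values=_eval(bval_s, t))

    rho = params.eos(temp, salt)
    for name, arr in (("u", u_new), ("eta", eta_new)):
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise HydroError(f"NaN/Inf in {name} at index {tuple(bad)}, "
                             f"t={t + params.dt:.6g} s")

    new = HydroState(u=u_new, eta=eta_new, temp=temp, salt=salt, rho=rho,
                     nu_h=nu_h, prev_tendency=tend_raw, time=t + params.dt)
    new.last_flux = flux
    return new


def cell_volumes(mesh: Mesh3D, eta=None) -> np.ndarray:
    """Cell volumes; the surface-layer volume carries the free surface."""
    vol = mesh.cell_volume.copy()
    if eta is not None:
        vol[:, 0] += mesh.mesh2d.areas * np.asarray(eta, float)
    return vol


def total_energy(state: HydroState, mesh: Mesh3D,
                 params: HydroParams) -> float:
    """Potential + kinetic energy (J) of the resolved state."""
    m2 = mesh.mesh2d
    pe = 0.5 * params.rho0 * params.g * float(np.sum(m2.areas * state.eta**2))
    V = geometry(mesh).cell_vectors(state.u)
    ke = 0.5 * params.rho0 * float(
        np.sum(mesh.cell_volume * (V[:, :, 0]**2 + V[:, :, 1]**2)))
    return pe + ke


def bottom_stress(state: HydroState, mesh: Mesh3D,
                  params: HydroParams) -> np.ndarray:
    """Quadratic-drag bottom stress tau = rho0 C_b |u_b|^2 per polygon (Pa)."""
    V = geometry(mesh).cell_vectors(state.u)
    P = mesh.n_polygons
    kb = mesh.bottom_layer
    vb = V[np.arange(P), kb]
    return params.rho0 * params.C_bottom * (vb[:, 0]**2 + vb[:, 1]**2)
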