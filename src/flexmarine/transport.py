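"""Advection-diffusion of pelagic scalar fields on the mesh.

Horizontal advection is first-order upwind in flux form, built on the same
face volume fluxes (m^3/s) that the free-surface solver uses for continuity,
so a spatially uniform tracer stays exactly uniform and total mass changes
only through boundary fluxes and sources.  Two schemes are provided:

* explicit — upwind horizontal and vertical advection plus centered
  diffusion, restricted by the Courant condition in both directions;
* vertically semi-implicit — horizontal terms explicit, vertical advection
  (upwind) and diffusion solved fully implicitly per column, removing the
  vertical time-step restriction (settling-like velocities, thin layers).

Open boundaries are clamped: an inflow face uses the prescribed boundary
concentration in its upwind flux, an outflow face the interior value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .mesh import Mesh3D, OPEN, Section


class TransportError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass
class TracerField:
    """A named pelagic scalar with its boundary values and diffusivities."""

    name: str
    concentration: np.ndarray            # (P, K)
    boundary_values: object = None       # scalar | {face: value} | callable(t)
    diffusivity_h: float = 0.0           # m^2/s
    diffusivity_v: float = 0.0
    nonnegative: bool = False
    clip_mass_error: float = 0.0         # cumulative clipped mass (units)


@dataclass
class SourceSpec:
    """A volume/tracer source anywhere in the mesh, optionally moving."""

    polygon: object                      # int | callable t -> (x, y)
    volume_flux: object = 0.0            # m^3/s, scalar or callable(t)
    loads: dict = field(default_factory=dict)   # tracer -> units/s
    distribution: str = "surface"        # surface | bottom | uniform

    def cell_weights(self, mesh: Mesh3D, p: int) -> np.ndarray:
        """Vertical distribution weights over the active layers of column p."""
        K = mesh.n_layers
        w = np.zeros(K)
        kb = mesh.bottom_layer[p]
        if self.distribution == "surface":
            w[0] = 1.0
        elif self.distribution == "bottom":
            w[kb] = 1.0
        elif self.distribution == "uniform":
            vol = mesh.cell_volume[p, :kb + 1]
            w[:kb + 1] = vol / vol.sum()
        else:
            raise ConfigurationError(
                f"unknown source distribution {self.distribution!r}")
        return w


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def vertical_flux(flux: np.ndarray, mesh: Mesh3D) -> np.ndarray:
    """Diagnose upward volume flux through interior layer interfaces.

    Integrates the layer-wise continuity equation from the bottom; any
    residual divergence is absorbed by the free surface.  Returns a
    (P, K-1) array; column j is the interface between layers j and j+1,
    positive upward.
    """
    P, K = mesh.n_polygons, mesh.n_layers
    hdiv = horizontal_divergence(flux, mesh)
    if K == 1:
        return np.zeros((P, 0))
    W = -np.cumsum(hdiv[:, ::-1], axis=1)[:, ::-1][:, 1:]
    return W


def horizontal_divergence(flux: np.ndarray, mesh: Mesh3D) -> np.ndarray:
    """Signed net outflow (m^3/s) per cell and layer."""
    from .hydro import geometry

    return np.asarray(geometry(mesh).R @ flux)


def apply_open_boundary(c: np.ndarray, flux: np.ndarray, mesh: Mesh3D,
                        boundary_values=None) -> np.ndarray:
    """Upwind face concentrations with clamped open-boundary values.

    Interior faces take the upstream cell value (arithmetic mean at exactly
    zero flux); boundary faces with inflow take the prescribed boundary
    concentration, outflow faces the interior value.  Raises
    :class:`ConfigurationError` if an open face carries inflow but no
    boundary value is given.
    """
    m2 = mesh.mesh2d
    fl = m2.face_left
    fr = np.clip(m2.face_right, 0, None)
    interior = m2.face_right >= 0
    cl, cr = c[fl], c[fr]
    cup = np.where(flux > 0, cl, np.where(flux < 0, cr, 0.5 * (cl + cr)))
    # boundary faces: inflow means flux directed into the owner, i.e. < 0
    bfaces = np.where(~interior)[0]
    for f in bfaces:
        inflow = flux[f] < 0
        if not inflow.any():
            cup[f] = c[fl[f]]
            continue
        bv = _boundary_value_for_face(boundary_values, f)
        if bv is None:
            if m2.face_kind[f] == OPEN:
                raise ConfigurationError(
                    f"open face {f} has inflow but no boundary value")
            bv = 0.0
        cup[f] = np.where(inflow, bv, c[fl[f]])
    return cup


def _boundary_value_for_face(boundary_values, f):
    if boundary_values is None:
        return None
    if isinstance(boundary_values, dict):
        return boundary_values.get(f)
    if np.isscalar(boundary_values):
        return float(boundary_values)
    return np.asarray(boundary_values)[f]


def check_courant(flux: np.ndarray, mesh: Mesh3D, dt: float,
                  vol: np.ndarray | None = None, W: np.ndarray | None = None,
                  raise_error: bool = True) -> float:
    """Maximum cell Courant number sum(outflow) * dt / V (horiz + vert)."""
    from .hydro import geometry

    vol = mesh.cell_volume if vol is None else vol
    P, K = mesh.n_polygons, mesh.n_layers
    geom = geometry(mesh)
    # positive part of s*flux = (s*flux + |flux|)/2 since |s| = 1
    out = 0.5 * (np.asarray(geom.R @ flux) + np.asarray(
        geom.Rabs @ np.abs(flux)))
    if W is not None and W.size:
        out[:, 1:] += np.clip(W, 0.0, None)       # upward loss of layer k+1
        out[:, :-1] += np.clip(-W, 0.0, None)     # downward loss of layer k
    active = mesh.cell_active & (vol > 0)
    cou = np.zeros((P, K))
    cou[active] = out[active] * dt / vol[active]
    cmax = float(cou.max()) if cou.size else 0.0
    if raise_error and cmax > 1.0 + 1e-9:
        raise TransportError(
            f"transport Courant number {cmax:.3f} > 1; "
            f"reduce dt to <= {dt / cmax:.4g} s")
    return cmax


# ---------------------------------------------------------------------------
# explicit scheme
# ---------------------------------------------------------------------------

def advect_diffuse_explicit(c, flux, mesh: Mesh3D, dt, *, vol_old=None,
                            vol_new=None, Kh: float = 0.0, Kv: float = 0.0,
                            boundary_values=None, sources=None,
                            check_cfl: bool = True) -> np.ndarray:
    """One explicit upwind advection + centered diffusion step.

    Parameters
    ----------
    c : (P, K) concentration.
    flux : (F, K) signed face volume flux, m^3/s (positive along the stored
        face normal, i.e. left -> right).
    vol_old, vol_new : cell volumes before/after the step (default: the
        static mesh volumes; pass free-surface-consistent volumes when
        coupled to hydrodynamics).
    sources : (P, K) tracer load, units/s.
    """
    c = np.asarray(c, dtype=float)
    vol_old = mesh.cell_volume if vol_old is None else vol_old
    vol_new = vol_old if vol_new is None else vol_new
    W = vertical_flux(flux, mesh)
    if check_cfl:
        check_courant(flux, mesh, dt, vol=vol_old, W=W)

    from .hydro import geometry

    m2 = mesh.mesh2d
    P, K = c.shape
    geom = geometry(mesh)
    cup = apply_open_boundary(c, flux, mesh, boundary_values)
    mass = vol_old * c - dt * np.asarray(geom.R @ (flux * cup))

    if K > 1 and W.size:
        cw = np.where(W > 0, c[:, 1:], c[:, :-1])      # upwind on interfaces
        wflux = W * cw
        mass[:, :-1] += dt * wflux
        mass[:, 1:] -= dt * wflux

    if Kh > 0:
        interior = m2.face_right >= 0
        coef = np.zeros_like(flux)
        coef[interior] = (Kh * m2.face_length[interior, None]
                          * mesh.face_layer_thickness[interior]
                          / m2.face_distance[interior, None])
        dC = np.where(interior[:, None],
                      c[np.clip(m2.face_right, 0, None)] - c[m2.face_left],
                      0.0)
        # owner (sign +1) gains where the neighbour is richer
        mass += dt * np.asarray(geom.R @ (coef * dC))

    if Kv > 0 and K > 1:
        dzc = np.diff(mesh.layering.z_center)
        both = mesh.cell_active[:, :-1] & mesh.cell_active[:, 1:]
        dflux = np.where(both, (m2.areas[:, None] * Kv / dzc[None, :])
                         * (c[:, 1:] - c[:, :-1]), 0.0)
        mass[:, :-1] += dt * dflux
        mass[:, 1:] -= dt * dflux

    if sources is not None:
        mass += dt * np.asarray(sources, dtype=float)

    out = np.zeros_like(c)
    active = vol_new > 0
    out[active] = mass[active] / vol_new[active]
    out[~mesh.cell_active] = 0.0
    return out


# ---------------------------------------------------------------------------
# vertically semi-implicit scheme
# ---------------------------------------------------------------------------

def advect_diffuse_semi_implicit(c, flux, mesh: Mesh3D, dt, *, vol_old=None,
                                 vol_new=None, Kh: float = 0.0,
                                 Kv: float = 0.0, boundary_values=None,
                                 sources=None,
                                 check_cfl: bool = True) -> np.ndarray:
    """Horizontal terms explicit, vertical advection/diffusion fully implicit.

    The vertical operator is an M-matrix (upwind advection + diffusion), so
    the column solve is unconditionally stable and creates no new extrema.
    """
    c = np.asarray(c, dtype=float)
    vol_old = mesh.cell_volume if vol_old is None else vol_old
    vol_new = vol_old if vol_new is None else vol_new
    if check_cfl:
        check_courant(flux, mesh, dt, vol=vol_old, W=None)

    from .hydro import geometry

    m2 = mesh.mesh2d
    P, K = c.shape
    geom = geometry(mesh)
    cup = apply_open_boundary(c, flux, mesh, boundary_values)
    mass = vol_old * c - dt * np.asarray(geom.R @ (flux * cup))
    if Kh > 0:
        interior = m2.face_right >= 0
        coef = np.zeros_like(flux)
        coef[interior] = (Kh * m2.face_length[interior, None]
                          * mesh.face_layer_thickness[interior]
                          / m2.face_distance[interior, None])
        dC = np.where(interior[:, None],
                      c[np.clip(m2.face_right, 0, None)] - c[m2.face_left], 0.0)
        mass += dt * np.asarray(geom.R @ (coef * dC))
    if sources is not None:
        mass += dt * np.asarray(sources, dtype=float)

    if K == 1:
        out = np.zeros_like(c)
        act = vol_new[:, 0] > 0
        out[act, 0] = mass[act, 0] / vol_new[act, 0]
        return out

    W = vertical_flux(flux, mesh)
    dzc = np.diff(mesh.layering.z_center)
    out = np.zeros_like(c)
    A2 = m2.areas
    for p in range(P):
        kb = mesh.bottom_layer[p]
        n = kb + 1
        if n <= 0 or vol_new[p, 0] <= 0:
            continue
        diag = vol_new[p, :n].copy()
        sub = np.zeros(n)    # coefficient of c_{k-1} in row k
        sup = np.zeros(n)    # coefficient of c_{k+1} in row k
        for j in range(n - 1):        # interface between layers j and j+1
            w = W[p, j]
            D = A2[p] * Kv / dzc[j] if Kv > 0 else 0.0
            # layer j gains W*cup(j); layer j+1 loses it
            if w > 0:
                sup[j] += -dt * w
                diag[j + 1] += dt * w
            else:
                diag[j] += -dt * w
                sub[j + 1] += dt * w
            sup[j] += -dt * D
            diag[j] += dt * D
            sub[j + 1] += -dt * D
            diag[j + 1] += dt * D
        ab = np.zeros((3, n))
        ab[0, 1:] = sup[:-1]
        ab[1] = diag
        ab[2, :-1] = sub[1:]
        out[p, :n] = solve_banded((1, 1), ab, mass[p, :n])
    out[~mesh.cell_active] = 0.0
    return out


# ---------------------------------------------------------------------------
# diagnostics and bookkeeping
# ---------------------------------------------------------------------------

def section_flux(section: Section, flux: np.ndarray, mesh: Mesh3D,
                 field=None, boundary_values=None) -> float:
    """Signed volume (m^3/s) or tracer (units/s) flux through a section."""
    if field is None:
        return float(np.sum(section.signs[:, None] * flux[section.faces]))
    cup = apply_open_boundary(np.asarray(field, float), flux, mesh,
                              boundary_values)
    return float(np.sum(section.signs[:, None]
                        * (flux * cup)[section.faces]))


def total_mass(c, mesh: Mesh3D, vol=None) -> float:
    vol = mesh.cell_volume if vol is None else vol
    return float(np.sum(np.asarray(c) * vol))


def clip_negative(c: np.ndarray, mesh: Mesh3D, vol=None):
    """Clip negative concentrations to zero; return (clipped, mass added)."""
    vol = mesh.cell_volume if vol is None else vol
    neg = c < 0
    err = float(-np.sum(c[neg] * vol[neg]))
    if err:
        c = np.where(neg, 0.0, c)
    return c, err
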