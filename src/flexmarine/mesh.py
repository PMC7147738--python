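"""Orthogonal unstructured 2D mesh, its Voronoi dual, z-layering and sections.

The horizontal substrate of every module is a tessellation of convex polygons
in which each polygon owns a *Voronoi point*: the segments joining Voronoi
points of adjacent polygons are perpendicular to the shared faces.  Scalars
live at the Voronoi points (finite volume), normal velocities at the face
midpoints (finite difference) — the classic C-grid staggering.  The vertical
is discretized with fixed-depth z-layers; the bottom cell is clipped to the
local bathymetry (partial bottom cell), so the wet volume of a column equals
``area * depth`` exactly.

Depth is positive downward; layer index 0 is the surface layer.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

#: boundary-mark codes for nodes and faces
INTERIOR = 0
SOLID = 1
OPEN = 2

_EARTH_RADIUS = 6_371_000.0


class MeshError(ValueError):
    """Raised for invalid mesh geometry or topology."""


# ---------------------------------------------------------------------------
# basic geometry helpers
# ---------------------------------------------------------------------------

def polygon_area(pts: np.ndarray) -> float:
    """Signed shoelace area of a polygon given as an (n, 2) vertex array."""
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def circumcenter(pts: np.ndarray) -> np.ndarray:
    """Least-squares circumcenter of a set of vertices.

    For a cyclic polygon (triangle, rectangle, regular hexagon, ...) this is
    the exact circumcenter; for a nearly-cyclic polygon it is the point whose
    distances to the vertices are as equal as possible in the least-squares
    sense.  Orthogonal tessellations place the Voronoi point there.
    """
    p0 = pts[0]
    d = pts[1:] - p0
    # |p - p_i|^2 = |p - p_0|^2  ->  d . p = 0.5 (|p_i|^2 - |p_0|^2)
    rhs = 0.5 * (np.sum(pts[1:] ** 2, axis=1) - np.sum(p0**2))
    sol, *_ = np.linalg.lstsq(d, rhs, rcond=None)
    return sol


def point_in_polygon(pts: np.ndarray, p) -> bool:
    """Even-odd point-in-polygon test (boundary counts as inside)."""
    x, y = p
    inside = False
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xi:
                inside = not inside
    return inside


def local_projection(lon, lat, lon0: float, lat0: float):
    """Project lon/lat (degrees) to local Cartesian meters around a center.

    Equirectangular projection — adequate for the domain sizes (tens to a few
    hundred km) the framework targets.  Meshes are stored projected.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = np.radians(lon - lon0) * _EARTH_RADIUS * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * _EARTH_RADIUS
    return x, y


# ---------------------------------------------------------------------------
# Mesh2D
# ---------------------------------------------------------------------------

@dataclass
class OrthogonalityReport:
    max_deviation_deg: float
    offending_faces: np.ndarray      # face indices beyond tolerance
    deviations_deg: np.ndarray       # per interior face
    interior_faces: np.ndarray       # face indices the deviations refer to

    @property
    def ok(self) -> bool:
        return self.offending_faces.size == 0


@dataclass
class Mesh2D:
    """2D orthogonal polygon mesh with its Voronoi dual and face table."""

    nodes: np.ndarray                # (N, 2)
    polygons: list                   # list of int arrays, CCW node indices
    boundary_mark: np.ndarray        # (N,) node marks {INTERIOR, SOLID, OPEN}
    voronoi_points: np.ndarray = field(default=None)  # (P, 2)
    areas: np.ndarray = field(default=None)           # (P,)
    # face table ------------------------------------------------------------
    face_nodes: np.ndarray = field(default=None)      # (F, 2)
    face_left: np.ndarray = field(default=None)       # (F,) owner polygon
    face_right: np.ndarray = field(default=None)      # (F,) neighbour or -1
    face_length: np.ndarray = field(default=None)     # (F,)
    face_center: np.ndarray = field(default=None)     # (F, 2)
    face_normal: np.ndarray = field(default=None)     # (F, 2) unit, left->right
    face_distance: np.ndarray = field(default=None)   # (F,) dual-edge length
    face_kind: np.ndarray = field(default=None)       # (F,) {INTERIOR,SOLID,OPEN}
    polygon_faces: list = field(default=None)         # per poly: (faces, signs)
    voronoi_outside: np.ndarray = field(default=None)  # polys w/ VP outside

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_polygons(self) -> int:
        return len(self.polygons)

    @property
    def n_faces(self) -> int:
        return len(self.face_nodes)

    def neighbors(self, p: int) -> np.ndarray:
        faces, _ = self.polygon_faces[p]
        other = np.where(self.face_left[faces] == p,
                         self.face_right[faces], self.face_left[faces])
        return other[other >= 0]


def build_mesh2d(nodes, polygons, boundary_mark=None, *,
                 orthogonality_tol_deg: float = 0.5,
                 check: bool = True) -> Mesh2D:
    """Assemble the dual geometry and face table of an orthogonal mesh.

    Parameters
    ----------
    nodes : (N, 2) array of x, y coordinates in meters.
    polygons : sequence of node-index sequences, counter-clockwise.
    boundary_mark : (N,) int node marks; defaults to SOLID on hull nodes.
    orthogonality_tol_deg : maximum allowed deviation of the dual edge from
        the face normal before ``check`` raises.
    """
    nodes = np.asarray(nodes, dtype=float)
    polygons = [np.asarray(p, dtype=int) for p in polygons]
    if len(polygons) == 0:
        raise MeshError("mesh needs at least one polygon")
    for i, p in enumerate(polygons):
        if len(p) < 3 or len(np.unique(p)) != len(p):
            raise MeshError(f"polygon {i} must have >= 3 distinct nodes")

    areas = np.array([polygon_area(nodes[p]) for p in polygons])
    bad = np.where(areas <= 0)[0]
    if bad.size:
        raise MeshError(
            f"polygon {bad[0]} has non-positive area {areas[bad[0]]:.3g} "
            "(vertices must be counter-clockwise and non-degenerate)")

    vor = np.array([circumcenter(nodes[p]) for p in polygons])
    vor_outside = np.array(
        [i for i, p in enumerate(polygons)
         if not point_in_polygon(nodes[p], vor[i])], dtype=int)

    # face table: each undirected edge appears in one or two polygons
    edge_map: dict = {}
    for ip, poly in enumerate(polygons):
        for k in range(len(poly)):
            a, b = int(poly[k]), int(poly[(k + 1) % len(poly)])
            key = (a, b) if a < b else (b, a)
            edge_map.setdefault(key, []).append(ip)

    n_f = len(edge_map)
    face_nodes = np.empty((n_f, 2), dtype=int)
    face_left = np.empty(n_f, dtype=int)
    face_right = np.empty(n_f, dtype=int)
    for i, (key, polys) in enumerate(sorted(edge_map.items())):
        if len(polys) > 2:
            raise MeshError(f"edge {key} shared by more than two polygons")
        face_nodes[i] = key
        face_left[i] = min(polys)
        face_right[i] = max(polys) if len(polys) == 2 else -1

    a_xy = nodes[face_nodes[:, 0]]
    b_xy = nodes[face_nodes[:, 1]]
    edge_vec = b_xy - a_xy
    face_length = np.hypot(edge_vec[:, 0], edge_vec[:, 1])
    if np.any(face_length <= 0):
        raise MeshError("zero-length face encountered")
    face_center = 0.5 * (a_xy + b_xy)

    # unit normal, oriented from the left (owner) towards the right polygon;
    # for boundary faces, outward from the owner
    normal = np.stack([edge_vec[:, 1], -edge_vec[:, 0]], axis=1)
    normal /= face_length[:, None]
    interior = face_right >= 0
    to_right = np.where(interior[:, None],
                        vor[np.clip(face_right, 0, None)] - vor[face_left],
                        face_center - vor[face_left])
    flip = np.sum(normal * to_right, axis=1) < 0
    normal[flip] *= -1.0

    face_distance = np.hypot(to_right[:, 0], to_right[:, 1])
    if np.any(face_distance <= 0):
        j = int(np.argmin(face_distance))
        raise MeshError(f"degenerate dual edge at face {j} "
                        f"(distance {face_distance[j]:.3g} m)")

    if boundary_mark is None:
        boundary_mark = np.zeros(len(nodes), dtype=int)
        bnodes = np.unique(face_nodes[~interior].ravel())
        boundary_mark[bnodes] = SOLID
    else:
        boundary_mark = np.asarray(boundary_mark, dtype=int)

    face_kind = np.full(n_f, INTERIOR, dtype=int)
    bmask = ~interior
    both_open = ((boundary_mark[face_nodes[:, 0]] == OPEN)
                 & (boundary_mark[face_nodes[:, 1]] == OPEN))
    face_kind[bmask & both_open] = OPEN
    face_kind[bmask & ~both_open] = SOLID

    # per-polygon face lists with outward signs
    polygon_faces = []
    per_poly = [[] for _ in polygons]
    for i in range(n_f):
        per_poly[face_left[i]].append((i, +1))
        if face_right[i] >= 0:
            per_poly[face_right[i]].append((i, -1))
    for lst in per_poly:
        faces = np.array([f for f, _ in lst], dtype=int)
        signs = np.array([s for _, s in lst], dtype=float)
        polygon_faces.append((faces, signs))

    mesh = Mesh2D(nodes=nodes, polygons=polygons, boundary_mark=boundary_mark,
                  voronoi_points=vor, areas=areas, face_nodes=face_nodes,
                  face_left=face_left, face_right=face_right,
                  face_length=face_length, face_center=face_center,
                  face_normal=normal, face_distance=face_distance,
                  face_kind=face_kind, polygon_faces=polygon_faces,
                  voronoi_outside=vor_outside)

    if check and mesh.n_faces:
        report = check_orthogonality(mesh, orthogonality_tol_deg)
        if not report.ok:
            worst = report.interior_faces[int(np.argmax(report.deviations_deg))]
            raise MeshError(
                "mesh is not orthogonal: worst face "
                f"{worst} (nodes {tuple(face_nodes[worst])}) deviates "
                f"{report.max_deviation_deg:.4f} deg "
                f"(> {orthogonality_tol_deg} deg)")
    return mesh


def check_orthogonality(mesh: Mesh2D, tol_deg: float = 0.5) -> OrthogonalityReport:
    """Angle between each interior face and its dual edge, as 90 deg deviation."""
    interior = np.where(mesh.face_right >= 0)[0]
    if interior.size == 0:
        return OrthogonalityReport(0.0, np.empty(0, int), np.empty(0), interior)
    e = (mesh.nodes[mesh.face_nodes[interior, 1]]
         - mesh.nodes[mesh.face_nodes[interior, 0]])
    d = (mesh.voronoi_points[mesh.face_right[interior]]
         - mesh.voronoi_points[mesh.face_left[interior]])
    cosang = np.abs(np.sum(e * d, axis=1)
                    / (np.hypot(*e.T) * np.hypot(*d.T)))
    dev = np.degrees(np.arcsin(np.clip(cosang, 0.0, 1.0)))
    offending = interior[dev > tol_deg]
    return OrthogonalityReport(float(dev.max()), offending, dev, interior)


# ---------------------------------------------------------------------------
# vertical layering and Mesh3D
# ---------------------------------------------------------------------------

@dataclass
class Layering:
    """Fixed z-layer interfaces, 0 at the undisturbed surface, positive down."""

    interface_depths: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.interface_depths, dtype=float)
        if z[0] != 0.0:
            raise MeshError("first layer interface must be at depth 0")
        if np.any(np.diff(z) <= 0):
            raise MeshError("layer interfaces must be strictly increasing")
        self.interface_depths = z

    @property
    def n_layers(self) -> int:
        return len(self.interface_depths) - 1

    @property
    def thickness(self) -> np.ndarray:
        return np.diff(self.interface_depths)

    @property
    def z_top(self) -> np.ndarray:
        return self.interface_depths[:-1]

    @property
    def z_bottom(self) -> np.ndarray:
        return self.interface_depths[1:]

    @property
    def z_center(self) -> np.ndarray:
        return 0.5 * (self.z_top + self.z_bottom)


@dataclass
class Mesh3D:
    """3D computational mesh: 2D polygons x z-layers with wet masks."""

    mesh2d: Mesh2D
    layering: Layering
    bathymetry: np.ndarray           # (P,) positive-down depth
    cell_thickness: np.ndarray = None   # (P, K) clipped local thickness
    cell_active: np.ndarray = None      # (P, K) bool
    cell_volume: np.ndarray = None      # (P, K)
    bottom_layer: np.ndarray = None     # (P,)
    face_layer_thickness: np.ndarray = None  # (F, K)
    face_layer_wet: np.ndarray = None        # (F, K) bool

    @property
    def n_polygons(self):
        return self.mesh2d.n_polygons

    @property
    def n_layers(self):
        return self.layering.n_layers

    @property
    def n_faces(self):
        return self.mesh2d.n_faces

    @property
    def n_active_cells(self) -> int:
        return int(self.cell_active.sum())

    def total_volume(self) -> float:
        return float(self.cell_volume.sum())


def build_mesh(nodes, polygons, boundary_mark, bathymetry, layering, *,
               orthogonality_tol_deg: float = 0.5, check: bool = True) -> Mesh3D:
    """Build a full 3D mesh from node/connectivity tables and a bathymetry."""
    m2 = (nodes if isinstance(nodes, Mesh2D)
          else build_mesh2d(nodes, polygons, boundary_mark,
                            orthogonality_tol_deg=orthogonality_tol_deg,
                            check=check))
    if not isinstance(layering, Layering):
        layering = Layering(np.asarray(layering, dtype=float))
    bathy = np.broadcast_to(np.asarray(bathymetry, dtype=float),
                            (m2.n_polygons,)).copy()
    if np.any(bathy <= 0):
        raise MeshError("bathymetry must be positive (depth in m, down)")

    z_top = layering.z_top[None, :]
    z_bot = layering.z_bottom[None, :]
    h = np.clip(np.minimum(bathy[:, None], z_bot) - z_top, 0.0, None)
    active = bathy[:, None] > z_top
    h[~active] = 0.0
    vol = h * m2.areas[:, None]
    bottom_layer = active.sum(axis=1) - 1

    fl = m2.face_left
    fr = m2.face_right
    h_l = h[fl]
    h_r = np.where(fr[:, None] >= 0, h[np.clip(fr, 0, None)], h_l)
    fh = np.minimum(h_l, h_r)
    fwet = fh > 0

    return Mesh3D(mesh2d=m2, layering=layering, bathymetry=bathy,
                  cell_thickness=h, cell_active=active, cell_volume=vol,
                  bottom_layer=bottom_layer, face_layer_thickness=fh,
                  face_layer_wet=fwet)


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

@dataclass
class Section:
    """Signed chain of interior faces; positive crossing = right of travel."""

    name: str
    faces: np.ndarray   # face indices
    signs: np.ndarray   # +-1 relative to the stored face normal


def _segments_cross(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def define_section(mesh, polyline, name: str = "section") -> Section:
    """Build a section from a polyline crossing interior faces.

    The sign convention is the divergence-theorem one: flux is positive when
    directed to the *right* of the direction of travel along the polyline, so
    a counter-clockwise closed polyline around a cell measures outflow.
    A face crossed twice in opposite directions cancels out of the section.
    """
    m2 = mesh.mesh2d if isinstance(mesh, Mesh3D) else mesh
    polyline = np.asarray(polyline, dtype=float)
    counts: dict = {}
    interior = np.where(m2.face_right >= 0)[0]
    for s in range(len(polyline) - 1):
        p1, p2 = polyline[s], polyline[s + 1]
        d = p2 - p1
        right = np.array([d[1], -d[0]])
        for f in interior:
            a = m2.nodes[m2.face_nodes[f, 0]]
            b = m2.nodes[m2.face_nodes[f, 1]]
            if _segments_cross(p1, p2, a, b):
                sgn = 1.0 if float(np.dot(m2.face_normal[f], right)) > 0 else -1.0
                counts[f] = counts.get(f, 0.0) + sgn
    faces = np.array([f for f, c in sorted(counts.items()) if c != 0], dtype=int)
    signs = np.array([counts[f] / abs(counts[f]) for f in faces])
    if faces.size == 0:
        raise MeshError("polyline does not cross any interior face")
    return Section(name=name, faces=faces, signs=signs)


# ---------------------------------------------------------------------------
# fixture meshes
# ---------------------------------------------------------------------------

def _rect_mesh2d(nx, ny, dx, open_edges=()):
    xs = np.arange(nx + 1) * dx
    ys = np.arange(ny + 1) * dx
    nodes = np.array([(x, ys[j]) for j in range(ny + 1) for x in xs],
                     dtype=float)
    nid = lambda i, j: j * (nx + 1) + i
    polys = [np.array([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
             for j in range(ny) for i in range(nx)]
    mark = np.zeros(len(nodes), dtype=int)
    for i in range(nx + 1):
        mark[nid(i, 0)] = SOLID
        mark[nid(i, ny)] = SOLID
    for j in range(ny + 1):
        mark[nid(0, j)] = SOLID
        mark[nid(nx, j)] = SOLID
    edge_nodes = {
        "west": [nid(0, j) for j in range(ny + 1)],
        "east": [nid(nx, j) for j in range(ny + 1)],
        "south": [nid(i, 0) for i in range(nx + 1)],
        "north": [nid(i, ny) for i in range(nx + 1)],
    }
    for e in open_edges:
        mark[edge_nodes[e]] = OPEN
    return nodes, polys, mark


def _hex_mesh2d(rings, dx):
    """Regular-hexagon tessellation with `rings` rings around a center cell."""
    R = dx / np.sqrt(3.0)           # hexagon circumradius for center spacing dx
    centers = []
    for q in range(-rings, rings + 1):
        for r in range(max(-rings, -q - rings), min(rings, -q + rings) + 1):
            cx = dx * (q + r / 2.0)
            cy = dx * (np.sqrt(3.0) / 2.0) * r
            centers.append((cx, cy))
    centers = np.array(centers)
    node_map: dict = {}
    nodes = []
    polys = []
    ang = np.radians(30 + 60 * np.arange(6))
    for cx, cy in centers:
        idx = []
        for a in ang:
            px, py = cx + R * np.cos(a), cy + R * np.sin(a)
            key = (round(px, 9), round(py, 9))     # merge shared nodes
            if key not in node_map:
                node_map[key] = len(nodes)
                nodes.append((px, py))
            idx.append(node_map[key])
        polys.append(np.array(idx))
    return np.array(nodes, dtype=float), polys, None


def hex_polygon_count(rings: int) -> int:
    return 1 + 3 * rings * (rings + 1)


def generate_fixture_mesh(kind: str, nx: int = 10, ny: int = 10,
                          dx: float = 100.0, depth=10.0,
                          layer_interfaces=None, open_edges=(),
                          rings: int = 2) -> Mesh3D:
    """Orthogonal-by-construction synthetic meshes for tests and demos.

    kind='rect': nx x ny square cells of side dx; kind='hex': `rings` rings of
    regular hexagons (7 polygons for rings=1... following hexagonal numbers).
    `depth` is a constant or a callable depth_fn(xc, yc) evaluated at the
    Voronoi points.  A single-cell rect mesh is the 0D model substrate.
    """
    if kind == "rect":
        nodes, polys, mark = _rect_mesh2d(nx, ny, dx, open_edges)
    elif kind == "hex":
        nodes, polys, mark = _hex_mesh2d(rings, dx)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    m2 = build_mesh2d(nodes, polys, mark)
    if callable(depth):
        bathy = np.array([depth(x, y) for x, y in m2.voronoi_points])
    else:
        bathy = np.full(m2.n_polygons, float(depth))
    if layer_interfaces is None:
        layer_interfaces = np.array([0.0, float(np.max(bathy))])
    return build_mesh(m2, None, None, bathy, Layering(np.asarray(layer_interfaces,
                                                                 dtype=float)))


# ---------------------------------------------------------------------------
# mesh text / NetCDF I/O
# ---------------------------------------------------------------------------

def write_mesh_text(mesh: Mesh2D, path_or_buf, bathymetry=None) -> None:
    """Write the delimited mesh format: node table then connectivity table."""
    buf = io.StringIO()
    buf.write(f"NODES {mesh.n_nodes}\n")
    for i, (x, y) in enumerate(mesh.nodes):
        buf.write(f"{i} {x:.17g} {y:.17g} {mesh.boundary_mark[i]}\n")
    buf.write(f"POLYGONS {mesh.n_polygons}"
              f"{' bathymetry' if bathymetry is not None else ''}\n")
    for i, p in enumerate(mesh.polygons):
        d = f" {bathymetry[i]:.17g}" if bathymetry is not None else ""
        buf.write(f"{i}{d} " + " ".join(str(int(n)) for n in p) + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_mesh_text(path_or_buf, with_bathymetry: bool | None = None):
    """Read the delimited mesh format written by :func:`write_mesh_text`.

    ``with_bathymetry=None`` auto-detects from the POLYGONS header.
    """
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not lines[0].startswith("NODES"):
        raise MeshError("mesh file must start with a NODES header")
    n = int(lines[0].split()[1])
    nodes = np.empty((n, 2))
    mark = np.empty(n, dtype=int)
    for ln in lines[1:1 + n]:
        i, x, y, m = ln.split()
        nodes[int(i)] = (float(x), float(y))
        mark[int(i)] = int(m)
    if not lines[1 + n].startswith("POLYGONS"):
        raise MeshError("missing POLYGONS header")
    header = lines[1 + n].split()
    np_ = int(header[1])
    has_bathy = len(header) > 2 and header[2] == "bathymetry"
    if with_bathymetry is None:
        with_bathymetry = has_bathy
    polys = [None] * np_
    bathy = np.empty(np_) if has_bathy else None
    for ln in lines[2 + n:2 + n + np_]:
        parts = ln.split()
        i = int(parts[0])
        if has_bathy:
            bathy[i] = float(parts[1])
            polys[i] = np.array([int(v) for v in parts[2:]])
        else:
            polys[i] = np.array([int(v) for v in parts[1:]])
    if with_bathymetry:
        if bathy is None:
            raise MeshError("mesh file carries no bathymetry column")
        return nodes, polys, mark, bathy
    return nodes, polys, mark


def mesh_to_dataset(mesh3d: Mesh3D):
    """UGRID-flavoured xarray Dataset view of the mesh (NetCDF variant)."""
    import xarray as xr

    m2 = mesh3d.mesh2d
    maxn = max(len(p) for p in m2.polygons)
    conn = np.full((m2.n_polygons, maxn), -1, dtype=np.int32)
    for i, p in enumerate(m2.polygons):
        conn[i, :len(p)] = p
    return xr.Dataset(
        {
            "node_x": ("node", m2.nodes[:, 0]),
            "node_y": ("node", m2.nodes[:, 1]),
            "node_mark": ("node", m2.boundary_mark.astype(np.int32)),
            "face_node_connectivity": (("poly", "vertex"), conn),
            "bathymetry": ("poly", mesh3d.bathymetry),
            "layer_interfaces": ("interface", mesh3d.layering.interface_depths),
        },
        attrs={"cf_role": "mesh_topology", "conventions": "UGRID-like"},
    )


def mesh_from_dataset(ds) -> Mesh3D:
    conn = ds["face_node_connectivity"].values
    polys = [row[row >= 0] for row in conn]
    nodes = np.stack([ds["node_x"].values, ds["node_y"].values], axis=1)
    return build_mesh(nodes, polys, ds["node_mark"].values,
                      ds["bathymetry"].values,
                      Layering(ds["layer_interfaces"].values))
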