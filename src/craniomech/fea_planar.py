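"""2D linear-elastic plane-strain finite elements for biting skull models.

The domain is the lateral-view skull outline minus its fenestrae (cranial
openings), meshed with 3-node constant-strain triangles (CST).  Plane
strain is assumed — mediolateral strain negligible, no thickness parameter
needed — with the constitutive matrix

    D = E / ((1+nu)(1-2nu)) * [[1-nu, nu, 0], [nu, 1-nu, 0], [0, 0, (1-2nu)/2]]

in a consistent mm–N–MPa unit system; strains are reported in microstrain
(με = strain × 1e6).

Per-model loads are scaled with model area so that comparisons between
skulls of different sizes happen at a constant stress state:
``F_new = F_ref * sqrt(area_new / area_ref)``, the reference force being
applied to the smallest model.

Summaries follow comparative-FEA practice: the mesh-weighted arithmetic
mean (MWAM) of an equivalent strain scalar, and the intervals method (the
percent of model area falling in successive equal-width strain bands, the
last band open-ended).  The equivalent scalar is a von Mises-type strain
computed from the plane-strain tensor; signed principal strains are kept
for tensile/compressive maps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import cho_factor, cho_solve, LinAlgError


class SingularSystemError(RuntimeError):
    """The constrained stiffness matrix is singular or not positive definite."""


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def polygon_area(poly: np.ndarray) -> float:
    """Unsigned shoelace area of a polygon given as an (n, 2) vertex ring."""
    p = np.asarray(poly, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0


def _signed_tri_areas(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    a = nodes[triangles[:, 0]]
    b = nodes[triangles[:, 1]]
    c = nodes[triangles[:, 2]]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                  - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))


@dataclass
class PlanarMesh:
    """Triangulated solid skull domain (holes unmeshed).

    Triangles are stored counter-clockwise; clockwise input triples are
    reoriented on construction.  ``fenestra_polygons`` maps hole labels to
    their boundary rings (mm); ``outline_area`` is the area of the outer
    outline (solid + holes) when known.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    region_labels: np.ndarray | None = None
    fenestra_polygons: dict[str, np.ndarray] = field(default_factory=dict)
    outline_area: float | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        signed = _signed_tri_areas(self.nodes, self.triangles)
        flip = signed < 0
        if np.any(flip):
            t = self.triangles.copy()
            t[flip] = t[flip][:, [0, 2, 1]]
            self.triangles = t
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels, dtype=object)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def element_areas(self) -> np.ndarray:
        return _signed_tri_areas(self.nodes, self.triangles)

    @property
    def solid_area(self) -> float:
        return float(self.element_areas.sum())

    @property
    def fenestra_areas(self) -> dict[str, float]:
        return {k: polygon_area(v) for k, v in self.fenestra_polygons.items()}

    def validate(self, area_rtol: float = 1e-3) -> None:
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("non-finite node coordinates")
        areas = self.element_areas
        if np.any(areas <= 1e-12):
            raise ValueError(f"{int((areas <= 1e-12).sum())} degenerate triangles")
        if self.outline_area is not None:
            holes = sum(self.fenestra_areas.values())
            expected_solid = self.outline_area - holes
            if abs(self.solid_area - expected_solid) > area_rtol * self.outline_area:
                raise ValueError(
                    f"summed element areas {self.solid_area:.6g} differ from the "
                    f"solid polygon area {expected_solid:.6g} by more than "
                    f"{area_rtol:.1%} of the outline"
                )

    def nearest_node(self, point) -> int:
        d = np.linalg.norm(self.nodes - np.asarray(point, dtype=float), axis=1)
        return int(np.argmin(d))


@dataclass
class Material:
    """Isotropic linear elasticity: Young's modulus (MPa), Poisson ratio."""

    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")


@dataclass
class LoadCase:
    """Point constraints and nodal loads.

    ``constraints`` is a list of (node index, set of fixed directions from
    {"x", "y"}); ``loads`` a list of (node index, (fx, fy) in N).
    ``muscle_groups`` optionally records how the loads were generated.
    """

    constraints: list[tuple[int, frozenset]]
    loads: list[tuple[int, np.ndarray]]
    muscle_groups: dict | None = None

    def fixed_dofs(self) -> np.ndarray:
        dofs = []
        for node, dirs in self.constraints:
            for d in dirs:
                if d not in ("x", "y"):
                    raise ValueError(f"unknown constraint direction {d!r}")
                dofs.append(2 * node + (0 if d == "x" else 1))
        return np.unique(np.asarray(dofs, dtype=int))

    def force_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros(2 * n_nodes)
        for node, vec in self.loads:
            f[2 * node] += vec[0]
            f[2 * node + 1] += vec[1]
        return f


# ---------------------------------------------------------------------------
# Force scaling
# ---------------------------------------------------------------------------

def scale_force(f_ref: float, area_ref: float, area_new: float) -> float:
    """Constant-stress load scaling: ``f_ref * sqrt(area_new / area_ref)``."""
    if area_ref <= 0 or area_new <= 0:
        raise ValueError("areas must be positive")
    return float(f_ref) * float(np.sqrt(area_new / area_ref))


# ---------------------------------------------------------------------------
# Assembly and solve
# ---------------------------------------------------------------------------

def plane_strain_matrix(material: Material) -> np.ndarray:
    e, nu = material.young_modulus, material.poisson_ratio
    c = e / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return c * np.array([[1.0 - nu, nu, 0.0],
                         [nu, 1.0 - nu, 0.0],
                         [0.0, 0.0, (1.0 - 2.0 * nu) / 2.0]])


def _b_matrices(mesh: PlanarMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element strain-displacement matrices B (M, 3, 6) and areas (M,)."""
    tri = mesh.triangles
    p = mesh.nodes[tri]  # (M, 3, 2)
    areas = _signed_tri_areas(mesh.nodes, tri)
    x, y = p[..., 0], p[..., 1]
    # b_i = y_j - y_k ; c_i = x_k - x_j  (cyclic)
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    m = len(tri)
    B = np.zeros((m, 3, 6))
    B[:, 0, 0::2] = b
    B[:, 1, 1::2] = c
    B[:, 2, 0::2] = c
    B[:, 2, 1::2] = b
    B /= (2.0 * areas)[:, None, None]
    return B, areas


def assemble_stiffness(mesh: PlanarMesh, material: Material) -> sp.csr_matrix:
    """Global CST stiffness matrix (2N x 2N, unit thickness)."""
    D = plane_strain_matrix(material)
    B, areas = _b_matrices(mesh)
    ke = np.einsum("mji,jk,mkl->mil", B, D, B) * areas[:, None, None]
    tri = mesh.triangles
    dof = np.empty((len(tri), 6), dtype=int)
    dof[:, 0::2] = 2 * tri
    dof[:, 1::2] = 2 * tri + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    k = sp.coo_matrix((ke.ravel(), (rows, cols)),
                      shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes))
    return k.tocsr()


def _diagnose_rigid_mode(mesh: PlanarMesh, kff: sp.spmatrix,
                         free: np.ndarray) -> str:
    """Name the rigid-body mode with the smallest strain energy, if any."""
    centre = mesh.nodes.mean(axis=0)
    n = mesh.n_nodes
    candidates = {}
    for name, disp in (
        ("translation-x", np.column_stack([np.ones(n), np.zeros(n)])),
        ("translation-y", np.column_stack([np.zeros(n), np.ones(n)])),
        ("rotation", np.column_stack([-(mesh.nodes[:, 1] - centre[1]),
                                      mesh.nodes[:, 0] - centre[0]])),
    ):
        v = disp.ravel()[free]
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        v = v / norm
        candidates[name] = float(v @ (kff @ v))
    if not candidates:
        return "none identifiable"
    scale = abs(kff.diagonal()).max()
    name, energy = min(candidates.items(), key=lambda kv: kv[1])
    if energy < 1e-8 * scale:
        return name
    return "none identifiable"


def assemble_and_solve(mesh: PlanarMesh, material: Material,
                       case: LoadCase) -> np.ndarray:
    """Solve K u = f under the load case; returns (N, 2) displacements (mm).

    Constrained degrees of freedom are fixed at zero.  The reduced system
    must be symmetric positive definite; anything else raises
    :class:`SingularSystemError` naming the free rigid mode when one can be
    identified (no silent regularisation).
    """
    mesh.validate()
    k = assemble_stiffness(mesh, material)
    f = case.force_vector(mesh.n_nodes)
    fixed = case.fixed_dofs()
    if len(fixed) < 3:
        raise SingularSystemError(
            f"only {len(fixed)} constrained DOFs; at least 3 are needed to "
            "suppress rigid-body motion")
    ndof = 2 * mesh.n_nodes
    free = np.setdiff1d(np.arange(ndof), fixed, assume_unique=True)
    kff = k[free][:, free]
    ff = f[free]
    mode = _diagnose_rigid_mode(mesh, kff, free)
    if mode != "none identifiable":
        raise SingularSystemError(
            "reduced stiffness not positive definite; unconstrained rigid "
            f"mode: {mode}")
    u = np.zeros(ndof)
    if len(free) <= 3000:
        try:
            factor = cho_factor(kff.toarray(), lower=True)
        except LinAlgError:
            mode = _diagnose_rigid_mode(mesh, kff, free)
            raise SingularSystemError(
                "reduced stiffness not positive definite; unconstrained rigid "
                f"mode: {mode}") from None
        u[free] = cho_solve(factor, ff)
    else:
        lu = spla.splu(kff.tocsc(), diag_pivot_thresh=0.0,
                       options={"SymmetricMode": True})
        if np.any(lu.U.diagonal() <= 0):
            mode = _diagnose_rigid_mode(mesh, kff, free)
            raise SingularSystemError(
                "reduced stiffness not positive definite; unconstrained rigid "
                f"mode: {mode}")
        u[free] = lu.solve(ff)
    return u.reshape(-1, 2)


def reaction_forces(mesh: PlanarMesh, material: Material, case: LoadCase,
                    displacements: np.ndarray) -> np.ndarray:
    """Nodal reactions R = K u - f (N); nonzero only at constrained nodes."""
    k = assemble_stiffness(mesh, material)
    f = case.force_vector(mesh.n_nodes)
    r = k @ displacements.ravel() - f
    return r.reshape(-1, 2)


# ---------------------------------------------------------------------------
# Strains
# ---------------------------------------------------------------------------

@dataclass
class ElementStrains:
    """Per-element constant strains: tensor (εxx, εyy, γxy), principal
    strains (ε1 ≥ ε2), signed field for tensile/compressive maps, and the
    non-negative von Mises-type equivalent strain."""

    tensors: np.ndarray            # (M, 3)
    principal: np.ndarray          # (M, 2)
    signed_principal: np.ndarray   # (M,)
    equivalent: np.ndarray         # (M,), dimensionless

    @property
    def equivalent_micro(self) -> np.ndarray:
        return self.equivalent * 1e6

    @property
    def principal_micro(self) -> np.ndarray:
        return self.principal * 1e6


def element_strains(displacements: np.ndarray, mesh: PlanarMesh,
                    material: Material | None = None) -> ElementStrains:
    """Constant strain per triangle from the CST shape-function gradients."""
    u = np.asarray(displacements, dtype=float)
    if u.shape != (mesh.n_nodes, 2):
        raise ValueError(
            f"displacements shape {u.shape} does not match mesh ({mesh.n_nodes}, 2)")
    B, _ = _b_matrices(mesh)
    ue = u[mesh.triangles].reshape(len(mesh.triangles), 6)
    tensors = np.einsum("mij,mj->mi", B, ue)  # (εxx, εyy, γxy)
    exx, eyy, gxy = tensors[:, 0], tensors[:, 1], tensors[:, 2]
    mean = 0.5 * (exx + eyy)
    radius = np.sqrt((0.5 * (exx - eyy)) ** 2 + (0.5 * gxy) ** 2)
    e1, e2 = mean + radius, mean - radius
    principal = np.column_stack([e1, e2])
    signed = np.where(np.abs(e1) >= np.abs(e2), e1, e2)
    # von Mises equivalent strain under plane strain (εzz = 0):
    # deviatoric e = ε − tr(ε)/3 · I, ε_eq = sqrt(2/3 · e:e)
    tr3 = (exx + eyy) / 3.0
    dxx, dyy, dzz, dxy = exx - tr3, eyy - tr3, -tr3, 0.5 * gxy
    equivalent = np.sqrt((2.0 / 3.0)
                         * (dxx ** 2 + dyy ** 2 + dzz ** 2 + 2.0 * dxy ** 2))
    return ElementStrains(tensors=tensors, principal=principal,
                          signed_principal=signed, equivalent=equivalent)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def mwam(equivalent_strain, areas) -> float:
    """Mesh-weighted arithmetic mean: Σ(ε_i A_i) / Σ A_i."""
    e = np.asarray(equivalent_strain, dtype=float)
    a = np.asarray(areas, dtype=float)
    if len(e) == 0:
        raise ValueError("empty strain field")
    if len(e) != len(a):
        raise ValueError("strain and area lengths differ")
    if np.any(a <= 0):
        raise ValueError("element areas must be positive")
    return float(np.sum(e * a) / np.sum(a))


def intervals_method(equivalent_strain, areas, n_intervals: int = 4,
                     upper_bound: float | None = None) -> np.ndarray:
    """Percent of total area in each of ``n_intervals`` equal-width strain bands.

    Bands are half-open [0, u/n), …; the final band [(n-1)u/n, ∞) captures
    everything at or above the last edge.  Percentages sum to 100.
    """
    if upper_bound is None or upper_bound <= 0:
        raise ValueError("upper_bound must be positive")
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    e = np.asarray(equivalent_strain, dtype=float)
    a = np.asarray(areas, dtype=float)
    if len(e) != len(a) or len(e) == 0:
        raise ValueError("strain and area arrays must be equal-length and non-empty")
    edges = np.linspace(0.0, upper_bound, n_intervals + 1)[1:-1]
    idx = np.digitize(e, edges, right=False)
    weights = np.bincount(idx, weights=a, minlength=n_intervals)
    return 100.0 * weights / a.sum()


def fenestra_ratio(mesh: PlanarMesh) -> float:
    """Total fenestra area divided by the meshed solid area."""
    holes = sum(mesh.fenestra_areas.values())
    solid = mesh.solid_area
    if solid <= 0:
        raise ValueError("mesh has no solid area")
    if mesh.outline_area is not None and holes >= mesh.outline_area:
        raise ValueError("hole area is not smaller than the outline area")
    return holes / solid


def fenestra_ratios(mesh: PlanarMesh) -> dict[str, float]:
    """Per-fenestra area / solid area (for orbit, antorbital, etc. analyses)."""
    solid = mesh.solid_area
    if solid <= 0:
        raise ValueError("mesh has no solid area")
    return {k: v / solid for k, v in mesh.fenestra_areas.items()}


@dataclass
class FEAResult:
    """Solved bite model: displacement and strain fields with summaries."""

    nodal_displacements: np.ndarray   # (N, 2) mm
    strains: ElementStrains
    reactions: np.ndarray             # (N, 2) N
    mwam_strain: float                # με
    intervals: np.ndarray | None      # percent area per interval
    fenestra_ratio: float
    applied_force: float              # sum of applied load magnitudes, N
    applied_load_sum: np.ndarray | None = None  # vector sum of loads, N

    def validate(self) -> None:
        residual = self.reactions.sum(axis=0)
        if self.applied_load_sum is not None:
            residual = residual + self.applied_load_sum
        if np.abs(residual).max() > 1e-6:
            raise ValueError(f"global equilibrium violated: residual {residual}")
        if self.intervals is not None:
            if abs(self.intervals.sum() - 100.0) > 1e-6:
                raise ValueError("interval percentages do not sum to 100")
        if self.mwam_strain < 0:
            raise ValueError("MWAM strain must be non-negative")


def solve_case(mesh: PlanarMesh, material: Material, case: LoadCase,
               n_intervals: int = 4,
               upper_bound_micro: float | None = None) -> FEAResult:
    """Solve, differentiate, and summarise one bite model."""
    u = assemble_and_solve(mesh, material, case)
    strains = element_strains(u, mesh, material)
    # reactions: reuse assembled K via reaction_forces (assembly is cheap here)
    reactions = reaction_forces(mesh, material, case, u)
    # zero out roundoff at genuinely free dofs for a clean equilibrium report
    areas = mesh.element_areas
    mw = mwam(strains.equivalent_micro, areas)
    intervals = None
    if upper_bound_micro is not None:
        intervals = intervals_method(strains.equivalent_micro, areas,
                                     n_intervals, upper_bound_micro)
    ratio = fenestra_ratio(mesh) if mesh.fenestra_polygons else 0.0
    vectors = [np.asarray(v, dtype=float) for _, v in case.loads]
    total_force = float(sum(np.linalg.norm(v) for v in vectors))
    load_sum = np.sum(vectors, axis=0) if vectors else np.zeros(2)
    return FEAResult(nodal_displacements=u, strains=strains,
                     reactions=reactions, mwam_strain=mw, intervals=intervals,
                     fenestra_ratio=ratio, applied_force=total_force,
                     applied_load_sum=load_sum)


# ---------------------------------------------------------------------------
# Structured meshes and edge loads
# ---------------------------------------------------------------------------

def rectangle_mesh(width: float, height: float, nx: int, ny: int,
                   origin=(0.0, 0.0)) -> PlanarMesh:
    """Structured triangulation of a rectangle (each cell split in two)."""
    ox, oy = origin
    xs = np.linspace(ox, ox + width, nx + 1)
    ys = np.linspace(oy, oy + height, ny + 1)
    xv, yv = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([xv.ravel(), yv.ravel()])
    tris = []
    for j in range(ny):
        for i in range(nx):
            n0 = j * (nx + 1) + i
            n1 = n0 + 1
            n2 = n0 + (nx + 1)
            n3 = n2 + 1
            tris.append([n0, n1, n3])
            tris.append([n0, n3, n2])
    return PlanarMesh(nodes=nodes, triangles=np.asarray(tris, dtype=int),
                      region_labels=np.array(["domain"] * len(tris), dtype=object),
                      outline_area=width * height)


def nodes_on_line(mesh: PlanarMesh, axis: str, value: float,
                  tol: float = 1e-9) -> np.ndarray:
    """Indices of nodes lying on the line x=value (axis="x") or y=value."""
    col = 0 if axis == "x" else 1
    return np.flatnonzero(np.abs(mesh.nodes[:, col] - value) <= tol)


def edge_traction_loads(mesh: PlanarMesh, node_ids, total_force,
                        lumping: str = "tributary") -> list[tuple[int, np.ndarray]]:
    """Convert a uniform traction resultant on an edge chain to nodal loads.

    ``node_ids`` are the nodes along one straight or polyline edge (any
    order; they are sorted along the chain).  "tributary" lumping weights
    each node by half the length of its adjacent segments, which reproduces
    a uniform traction exactly for CST meshes; "equal" divides the
    resultant evenly.
    """
    node_ids = np.asarray(node_ids, dtype=int)
    if len(node_ids) < 2:
        raise ValueError("an edge chain needs at least 2 nodes")
    pts = mesh.nodes[node_ids]
    direction = pts - pts.mean(axis=0)
    # sort along the dominant direction of the chain
    _, _, vt = np.linalg.svd(direction, full_matrices=False)
    order = np.argsort(direction @ vt[0])
    node_ids = node_ids[order]
    pts = pts[order]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if lumping == "tributary":
        w = np.zeros(len(node_ids))
        w[:-1] += seg / 2.0
        w[1:] += seg / 2.0
        w /= w.sum()
    elif lumping == "equal":
        w = np.full(len(node_ids), 1.0 / len(node_ids))
    else:
        raise ValueError(f"unknown lumping {lumping!r}")
    total = np.asarray(total_force, dtype=float)
    return [(int(n), total * wi) for n, wi in zip(node_ids, w)]


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

def write_mesh_csv(mesh: PlanarMesh, nodes_path, elements_path) -> None:
    with open(nodes_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x_mm", "y_mm"])
        for i, (x, y) in enumerate(mesh.nodes):
            w.writerow([i, f"{x:.12g}", f"{y:.12g}"])
    with open(elements_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "n1", "n2", "n3", "region"])
        labels = (mesh.region_labels if mesh.region_labels is not None
                  else ["domain"] * len(mesh.triangles))
        for i, ((a, b, c), lab) in enumerate(zip(mesh.triangles, labels)):
            w.writerow([i, a, b, c, lab])


def read_mesh_csv(nodes_path, elements_path) -> PlanarMesh:
    nodes = []
    with open(nodes_path, newline="") as fh:
        for row in csv.DictReader(fh):
            nodes.append((float(row["x_mm"]), float(row["y_mm"])))
    tris, labels = [], []
    with open(elements_path, newline="") as fh:
        for row in csv.DictReader(fh):
            tris.append((int(row["n1"]), int(row["n2"]), int(row["n3"])))
            labels.append(row.get("region", "domain"))
    return PlanarMesh(nodes=np.asarray(nodes, dtype=float),
                      triangles=np.asarray(tris, dtype=int),
                      region_labels=np.asarray(labels, dtype=object))


def read_gmsh2(path) -> PlanarMesh:
    """Minimal ASCII Gmsh v2 reader: 2D nodes and 3-node triangles only."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    def section(name):
        try:
            start = lines.index(f"${name}") + 1
            end = lines.index(f"$End{name}")
        except ValueError:
            raise ValueError(f"missing ${name} section in {path}") from None
        return lines[start:end]
    node_lines = section("Nodes")
    n_nodes = int(node_lines[0])
    id_map: dict[int, int] = {}
    nodes = np.zeros((n_nodes, 2))
    for k, ln in enumerate(node_lines[1:1 + n_nodes]):
        parts = ln.split()
        id_map[int(parts[0])] = k
        nodes[k] = (float(parts[1]), float(parts[2]))
    elem_lines = section("Elements")
    n_elem = int(elem_lines[0])
    tris, labels = [], []
    for ln in elem_lines[1:1 + n_elem]:
        parts = ln.split()
        etype = int(parts[1])
        if etype != 2:  # only 3-node triangles
            continue
        ntags = int(parts[2])
        tags = parts[3:3 + ntags]
        conn = [id_map[int(p)] for p in parts[3 + ntags:6 + ntags]]
        tris.append(conn)
        labels.append(tags[0] if tags else "domain")
    if not tris:
        raise ValueError(f"no 3-node triangles in {path}")
    return PlanarMesh(nodes=nodes, triangles=np.asarray(tris, dtype=int),
                      region_labels=np.asarray(labels, dtype=object))
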