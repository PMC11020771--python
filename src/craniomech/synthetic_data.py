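"""Synthetic skull studies with known ground truth.

Generates everything the analysis stages consume — landmark datasets,
meshed skull domains with fenestra holes, jaw lever points, a calibrated
tree, and per-taxon deformation-mode weights evolved under Brownian
motion — from one seed, so each pipeline stage can be verified against the
quantities that generated the data.

The template is a stylised theropod-like lateral skull outline (snout
tapering anteriorly, tall cranium posteriorly) carrying four fenestrae
(naris, antorbital fenestra, orbit, lateral temporal fenestra), jaw lever
points, and muscle attachment regions.  Shape variation is injected
through four linearly independent deformation modes mirroring the dominant
axes of dromaeosaurid-like skull variation: snout elongation, snout
depth, fenestra size, and quadrate inclination.  Mode weights are the
ground truth a shape PCA should recover.

Coordinates: x increases anteriorly, y dorsally, units mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .fea_planar import PlanarMesh, polygon_area
from .lever_mechanics import LeverSet
from .phylo_pcm import CalibratedTree, simulate_bm
from .shape_data import (DatasetVariantSpec, LandmarkConfiguration,
                         ShapeDataset, preset_variant, validate_variant)

MODE_IDS = ("snout_elongation", "snout_depth", "fenestra_size",
            "quadrate_inclination")

#: BM rate (variance per unit tree depth) per deformation mode.  Snout
#: elongation dominates, as in the empirical shape axes this emulates.
DEFAULT_MODE_RATES = {
    "snout_elongation": 0.2,
    "snout_depth": 0.05,
    "fenestra_size": 0.05,
    "quadrate_inclination": 0.02,
}

_REF_LENGTH = 200.0  # mm; template is defined at this skull length

# outline vertices at reference scale: ventral chain (posterior->tip) then
# dorsal chain (tip->posterior); counter-clockwise overall
_OUTLINE = np.array([
    (0.0, 0.0), (30.0, -2.0), (70.0, 0.0), (120.0, 2.0), (160.0, 4.0),
    (195.0, 5.0), (200.0, 6.0),                       # 6: snout tip
    (190.0, 14.0), (160.0, 22.0), (120.0, 30.0), (90.0, 42.0),
    (60.0, 52.0), (30.0, 56.0), (10.0, 50.0), (0.0, 30.0),
])
_TIP_INDEX = 6

_FENESTRAE = {  # label: (cx, cy, rx, ry, n_vertices)
    "naris": (178.0, 11.0, 7.0, 3.0, 12),
    "antorbital": (135.0, 14.0, 16.0, 8.0, 18),
    "orbit": (85.0, 25.0, 16.0, 12.0, 20),
    "lateral_temporal": (38.0, 26.0, 9.0, 12.0, 14),
}
_FENESTRA_ORDER = ("orbit", "antorbital", "lateral_temporal", "naris")

_LEVER_POINTS = {
    "jaw_joint": (2.0, 0.0),
    "temporal_insertion": (50.0, -16.0),
    "quadrate_insertion": (88.0, -18.0),
    "anterior_bite_point": (200.0, 6.0),
    "posterior_bite_point": (140.0, 3.0),
}

_ATTACHMENTS = {  # group: (anchor x, y, radius); force aims at the insertion
    "temporal": (55.0, 48.0, 14.0),
    "quadrate": (14.0, 18.0, 9.0),
}


def _ellipse_ring(cx, cy, rx, ry, n=20) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


@dataclass
class SkullTemplate:
    """Reference geometry plus the landmarking design it must satisfy."""

    outline: np.ndarray
    fenestrae: dict[str, np.ndarray]
    lever_points: dict[str, np.ndarray]
    attachments: dict[str, tuple[np.ndarray, float]]
    variant: DatasetVariantSpec
    skull_length_mm: float

    def validate(self) -> None:
        poly = Polygon(self.outline)
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("template outline is self-intersecting")
        for label, ring in self.fenestrae.items():
            hole = Polygon(ring)
            if not hole.is_valid:
                raise ValueError(f"fenestra {label!r} ring is invalid")
            if not poly.contains(hole):
                raise ValueError(f"fenestra {label!r} is not strictly inside the outline")
        validate_variant(self.variant)


@dataclass
class DeformedSkull:
    """Template geometry after mode deformation and digitisation noise."""

    outline: np.ndarray
    fenestrae: dict[str, np.ndarray]
    lever_points: dict[str, np.ndarray]
    attachments: dict[str, tuple[np.ndarray, float]]
    mode_weights: dict[str, float] = field(default_factory=dict)

    @property
    def skull_length_mm(self) -> float:
        return float(np.ptp(self.outline[:, 0]))

    def lever_set(self, taxon_id: str) -> LeverSet:
        lp = self.lever_points
        return LeverSet(
            taxon_id=taxon_id,
            jaw_joint=tuple(lp["jaw_joint"]),
            temporal_insertion=tuple(lp["temporal_insertion"]),
            quadrate_insertion=tuple(lp["quadrate_insertion"]),
            anterior_bite_point=tuple(lp["anterior_bite_point"]),
            posterior_bite_point=tuple(lp["posterior_bite_point"]),
        )


def make_template(variant="a", skull_length_mm: float = 200.0,
                  fenestra_fraction: float | None = None) -> SkullTemplate:
    """Build the reference skull template for a dataset variant.

    ``fenestra_fraction`` rescales the fenestrae about their centres so
    the total hole area equals that fraction of the *solid* area
    (holes / (outline − holes)); 0 removes them.
    """
    if isinstance(variant, str):
        variant = preset_variant(variant)
    validate_variant(variant)
    s = skull_length_mm / _REF_LENGTH
    outline = _OUTLINE * s
    fenestrae = {label: _ellipse_ring(cx, cy, rx, ry, n) * s
                 for label, (cx, cy, rx, ry, n) in _FENESTRAE.items()}
    if fenestra_fraction is not None:
        if fenestra_fraction < 0:
            raise ValueError("fenestra_fraction must be >= 0")
        if fenestra_fraction == 0:
            fenestrae = {}
        else:
            total = polygon_area(outline)
            holes = sum(polygon_area(r) for r in fenestrae.values())
            target_holes = fenestra_fraction * total / (1.0 + fenestra_fraction)
            factor = np.sqrt(target_holes / holes)
            fenestrae = {
                label: (ring - ring.mean(axis=0)) * factor + ring.mean(axis=0)
                for label, ring in fenestrae.items()
            }
    tpl = SkullTemplate(
        outline=outline,
        fenestrae=fenestrae,
        lever_points={k: np.asarray(v) * s for k, v in _LEVER_POINTS.items()},
        attachments={k: (np.asarray(v[:2]) * s, v[2] * s)
                     for k, v in _ATTACHMENTS.items()},
        variant=variant,
        skull_length_mm=skull_length_mm,
    )
    tpl.validate()
    n_anchors = len(_anchor_pool(tpl.outline, tpl.fenestrae, tpl.lever_points))
    if variant.n_traditional > n_anchors:
        raise ValueError(
            f"{variant.n_traditional} traditional landmarks requested but the "
            f"template provides only {n_anchors} anatomical anchors")
    n_sources = len(_curve_sources(tpl.outline, tpl.fenestrae))
    if variant.n_curves > n_sources:
        raise ValueError(
            f"{variant.n_curves} curves requested but the template outline and "
            f"fenestrae provide only {n_sources} curve segments")
    return tpl


# ---------------------------------------------------------------------------
# Deformation modes
# ---------------------------------------------------------------------------

def _mode_displacement(mode: str, pts: np.ndarray, s: float) -> np.ndarray:
    """Per-unit-weight displacement field of one mode at the given points."""
    x, y = pts[:, 0] / s, pts[:, 1] / s  # reference-scale coordinates
    u = np.zeros_like(pts)
    if mode == "snout_elongation":
        r = np.clip((x - 100.0) / 100.0, 0.0, None)
        u[:, 0] = 30.0 * r
    elif mode == "snout_depth":
        r = np.clip((x - 90.0) / 110.0, 0.0, None)
        u[:, 1] = 0.6 * (y - 6.0) * r
    elif mode == "quadrate_inclination":
        r = np.clip((60.0 - x) / 60.0, 0.0, None)
        u[:, 0] = 0.3 * y * r
    elif mode == "fenestra_size":
        pass  # handled at ring level (radial scaling about each fenestra)
    else:
        raise ValueError(f"unknown deformation mode {mode!r}")
    return u * s


def _deform_points(pts: np.ndarray, weights: dict[str, float], s: float) -> np.ndarray:
    out = pts.astype(float).copy()
    for mode, w in weights.items():
        if w != 0.0 and mode != "fenestra_size":
            out = out + w * _mode_displacement(mode, pts, s)
    return out


def deform_geometry(template: SkullTemplate,
                    weights: dict[str, float]) -> DeformedSkull:
    """Apply weighted deformation modes to every template vertex."""
    for mode in weights:
        if mode not in MODE_IDS:
            raise ValueError(f"unknown deformation mode {mode!r}")
    s = template.skull_length_mm / _REF_LENGTH
    outline = _deform_points(template.outline, weights, s)
    fen = {}
    w_fen = weights.get("fenestra_size", 0.0)
    for label, ring in template.fenestrae.items():
        r = _deform_points(ring, weights, s)
        if w_fen != 0.0:
            centre = r.mean(axis=0)
            r = centre + (1.0 + 0.15 * w_fen) * (r - centre)
        fen[label] = r
    levers = {k: _deform_points(v[None, :], weights, s)[0]
              for k, v in template.lever_points.items()}
    attachments = {k: (_deform_points(c[None, :], weights, s)[0], rad)
                   for k, (c, rad) in template.attachments.items()}
    geom = DeformedSkull(outline=outline, fenestrae=fen, lever_points=levers,
                         attachments=attachments,
                         mode_weights={k: float(v) for k, v in weights.items()})
    _check_simple(geom, weights)
    return geom


def _check_simple(geom: DeformedSkull, weights: dict[str, float]) -> None:
    poly = Polygon(geom.outline)
    ok = poly.is_valid and poly.is_simple
    if ok:
        for ring in geom.fenestrae.values():
            hole = Polygon(ring)
            if not (hole.is_valid and poly.contains(hole)):
                ok = False
                break
    if not ok:
        worst = max(weights, key=lambda m: abs(weights.get(m, 0.0)), default="?")
        raise ValueError(
            f"deformation produced self-intersecting or escaping geometry "
            f"(largest weight: {worst}={weights.get(worst, 0.0):.3g})")


# ---------------------------------------------------------------------------
# Landmark sampling
# ---------------------------------------------------------------------------

def _point_on_polyline(pts: np.ndarray, t: float, closed: bool) -> np.ndarray:
    p = np.vstack([pts, pts[0]]) if closed else pts
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = t * cum[-1]
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, len(seg) - 1)
    frac = (target - cum[i]) / seg[i] if seg[i] > 0 else 0.0
    return p[i] + frac * (p[i + 1] - p[i])


def _anchor_pool(outline, fenestrae, lever_points) -> list[np.ndarray]:
    """Ordered pool of traditional-landmark positions (anatomical anchors)."""
    pool = [
        outline[_TIP_INDEX],        # snout tip
        lever_points["jaw_joint"],
        outline[14],                # posterior-dorsal corner
        outline[12],                # dorsal apex region
        outline[0],                 # posterior-ventral corner
        outline[2],                 # mid-ventral
        outline[13],                # quadrate head region
        outline[9],                 # mid-dorsal
    ]
    for label in _FENESTRA_ORDER:
        if label not in fenestrae:
            continue
        ring = fenestrae[label]
        pool.append(ring[np.argmax(ring[:, 0])])  # anterior-most
        pool.append(ring[np.argmin(ring[:, 0])])  # posterior-most
        pool.append(ring[np.argmax(ring[:, 1])])  # dorsal-most
        pool.append(ring[np.argmin(ring[:, 1])])  # ventral-most
    # remaining outline vertices keep fenestra-free templates usable
    pool.extend(outline[i] for i in (11, 10, 8, 7, 5, 4, 3, 1))
    return [np.asarray(p, dtype=float) for p in pool]


def _curve_sources(outline, fenestrae):
    """Ordered (points, closed, t0, t1) curve segments for semilandmarks."""
    ventral = outline[:_TIP_INDEX + 1]
    dorsal = outline[_TIP_INDEX:]
    sources = [
        (dorsal, False, 0.0, 0.5), (dorsal, False, 0.5, 1.0),
        (ventral, False, 0.0, 0.5), (ventral, False, 0.5, 1.0),
    ]
    for label in _FENESTRA_ORDER:
        if label in fenestrae:
            sources.append((fenestrae[label], True, 0.0, 1.0))
    for label in _FENESTRA_ORDER:
        if label in fenestrae:
            ring = fenestrae[label]
            for q in range(4):
                sources.append((ring, True, q / 4.0, (q + 1) / 4.0))
    for chain in (dorsal, ventral):
        for q in range(3):
            sources.append((chain, False, q / 3.0, (q + 1) / 3.0))
    return sources


def sample_landmarks(geometry: DeformedSkull, variant: DatasetVariantSpec,
                     specimen_id: str, taxon_id: str | None = None,
                     ) -> LandmarkConfiguration:
    """Sample a landmark configuration conforming to a variant design."""
    total = validate_variant(variant)
    pool = _anchor_pool(geometry.outline, geometry.fenestrae,
                        geometry.lever_points)
    if variant.n_traditional > len(pool):
        raise ValueError("variant requests more traditional landmarks than "
                         "the template provides")
    pts = [pool[i] for i in range(variant.n_traditional)]
    sources = _curve_sources(geometry.outline, geometry.fenestrae)
    if variant.n_curves > len(sources):
        raise ValueError("variant requests more curves than the template provides")
    for c in range(variant.n_curves):
        ring, closed, t0, t1 = sources[c]
        for i in range(variant.points_per_curve):
            t = t0 + (t1 - t0) * (i + 0.5) / variant.points_per_curve
            pts.append(_point_on_polyline(ring, t, closed))
    kinds, curves = variant.kind_arrays()
    cfg = LandmarkConfiguration(
        specimen_id=specimen_id, taxon_id=taxon_id or specimen_id,
        points=np.asarray(pts), landmark_kinds=kinds, curve_memberships=curves,
        scale_mm_per_unit=1.0, provenance="synthetic",
    )
    assert cfg.n_points == total
    cfg.validate()
    return cfg


def deform_template(template: SkullTemplate, weights: dict[str, float],
                    noise_sd: float = 0.0, seed: int | None = None,
                    specimen_id: str = "synthetic",
                    ) -> tuple[LandmarkConfiguration, DeformedSkull]:
    """Deform the template, add digitisation noise, and sample landmarks.

    Noise is isotropic Gaussian on every geometry vertex (outline, fenestra
    rings, lever points) before landmark sampling, so landmarks, levers and
    the meshed domain stay mutually consistent.  Deterministic under seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not all(np.isfinite(list(weights.values()))):
        raise ValueError("mode weights must be finite")
    geom = deform_geometry(template, weights)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        base = geom
        # digitisation noise must not break ring topology; redraw a bounded
        # number of times (still deterministic under the seed) if it does
        for attempt in range(10):
            noisy = DeformedSkull(
                outline=base.outline + rng.normal(0, noise_sd, base.outline.shape),
                fenestrae={k: v + rng.normal(0, noise_sd, v.shape)
                           for k, v in base.fenestrae.items()},
                lever_points={k: v + rng.normal(0, noise_sd, 2)
                              for k, v in base.lever_points.items()},
                attachments=base.attachments,
                mode_weights=base.mode_weights,
            )
            try:
                _check_simple(noisy, weights)
            except ValueError:
                if attempt == 9:
                    raise
                continue
            geom = noisy
            break
    cfg = sample_landmarks(geom, template.variant, specimen_id)
    return cfg, geom


def skull_length(obj) -> float:
    """Horizontal extent (max x − min x) of a geometry or configuration."""
    if isinstance(obj, DeformedSkull):
        return obj.skull_length_mm
    if isinstance(obj, LandmarkConfiguration):
        return float(np.ptp(obj.points[:, 0]))
    pts = np.asarray(obj, dtype=float)
    return float(np.ptp(pts[:, 0]))


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

def _densify_ring(ring: np.ndarray, spacing: float, closed: bool = True) -> np.ndarray:
    p = np.vstack([ring, ring[0]]) if closed else ring
    out = []
    for a, b in zip(p[:-1], p[1:]):
        length = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(length / spacing)))
        for i in range(n):
            out.append(a + (b - a) * i / n)
    if not closed:
        out.append(p[-1])
    return np.asarray(out)


def _tri_min_angles(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    angles = np.zeros((len(tris), 3))
    for i in range(3):
        a = p[:, i] - p[:, (i + 1) % 3]
        b = p[:, i] - p[:, (i + 2) % 3]
        # angle at vertex (i+? ) — compute at each corner
        u = p[:, (i + 1) % 3] - p[:, i]
        v = p[:, (i + 2) % 3] - p[:, i]
        cosang = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        angles[:, i] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angles.min(axis=1)


def mesh_skull(geometry, target_edge_mm: float = 6.0,
               min_angle_deg: float = 20.0, smooth_iters: int = 4,
               max_retries: int = 3) -> PlanarMesh:
    """Triangulate the solid skull domain (outline minus fenestrae).

    Boundary rings are densified to the target edge length, interior nodes
    are laid on a staggered triangular grid with a clearance band along
    boundaries, Laplacian smoothing improves element quality, and a
    Delaunay triangulation filtered by solid-region containment yields the
    mesh.  The edge spacing is refined automatically (up to
    ``max_retries`` times) if area coverage or the minimum-angle quality
    target is missed; persistent failure raises with a refinement hint.
    """
    if isinstance(geometry, DeformedSkull):
        outline, holes = geometry.outline, geometry.fenestrae
    elif isinstance(geometry, SkullTemplate):
        outline, holes = geometry.outline, geometry.fenestrae
    else:
        outline, holes = geometry  # (outline, {label: ring})
    poly = Polygon(outline, list(holes.values()))
    if not poly.is_valid:
        raise ValueError("invalid solid polygon (self-intersection or hole overlap)")
    target_area = poly.area

    # element size conforms to the finest boundary feature: a hole ring
    # whose vertices are closer than the target edge forces a finer mesh
    def _mean_edge(ring):
        r = np.asarray(ring)
        return float(np.mean(np.linalg.norm(np.diff(
            np.vstack([r, r[:1]]), axis=0), axis=1)))

    spacing = float(target_edge_mm)
    for ring in holes.values():
        spacing = min(spacing, _mean_edge(ring))
    # ... and to the narrowest solid band between boundary rings, floored at
    # a fraction of the requested edge so a single tight band cannot force
    # an extremely fine mesh on the first attempt (retries refine further)
    ring_geoms = [Polygon(outline).exterior] + [Polygon(r) for r in holes.values()]
    gap_cap = spacing
    for i in range(len(ring_geoms)):
        for j in range(i + 1, len(ring_geoms)):
            gap = ring_geoms[i].distance(ring_geoms[j])
            if gap > 0:
                gap_cap = min(gap_cap, 0.9 * gap)
    spacing = max(min(spacing, gap_cap), float(target_edge_mm) / 6.0)

    def _thin_chain(dense, min_d):
        # merge boundary points crowded by noise-induced kinks
        keep = [dense[0]]
        for q in dense[1:]:
            if np.linalg.norm(q - keep[-1]) >= min_d:
                keep.append(q)
        if len(keep) > 2 and np.linalg.norm(keep[0] - keep[-1]) < min_d:
            keep.pop()
        return np.asarray(keep)
    last_reason = ""
    for _ in range(max_retries + 1):
        rings = [np.asarray(outline)] + [np.asarray(r) for r in holes.values()]
        dense_rings = [_thin_chain(_densify_ring(r, spacing), 0.45 * spacing)
                       for r in rings]
        boundary = np.vstack(dense_rings)

        # offset layer: a staggered ring of points one layer inside each
        # boundary, so near-boundary triangles are well shaped
        offset_pts = []
        inset = 0.8 * spacing
        for dense in dense_rings:
            shifted = 0.5 * (dense + np.roll(dense, -1, axis=0))
            tangent = np.roll(dense, -1, axis=0) - dense
            norm = np.linalg.norm(tangent, axis=1, keepdims=True)
            tangent = tangent / np.where(norm > 0, norm, 1.0)
            normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
            for sign in (1.0, -1.0):
                cand = shifted + sign * inset * normal
                inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
                cand = cand[inside]
                if len(cand):
                    d = shapely.distance(shapely.points(cand), poly.boundary)
                    offset_pts.append(cand[d >= 0.55 * inset])
        offset = np.vstack(offset_pts) if offset_pts else np.empty((0, 2))

        minx, miny, maxx, maxy = poly.bounds
        dy = spacing * np.sqrt(3.0) / 2.0
        rows = []
        j = 0
        y = miny + dy
        while y < maxy:
            xoff = (spacing / 2.0) if (j % 2) else 0.0
            xs = np.arange(minx + spacing / 2.0 + xoff, maxx, spacing)
            rows.append(np.column_stack([xs, np.full_like(xs, y)]))
            y += dy
            j += 1
        grid = np.vstack(rows) if rows else np.empty((0, 2))
        if len(grid):
            inside = shapely.contains_xy(poly, grid[:, 0], grid[:, 1])
            grid = grid[inside]
        if len(grid):
            d = shapely.distance(shapely.points(grid), poly.boundary)
            grid = grid[d >= 1.3 * spacing]

        # thin non-boundary points that crowd earlier-kept points
        from scipy.spatial import cKDTree
        kept: list[np.ndarray] = [boundary]
        for cand in (offset, grid):
            if len(cand) == 0:
                continue
            existing = np.vstack(kept)
            tree_kd = cKDTree(existing)
            d, _ = tree_kd.query(cand)
            cand = cand[d >= 0.55 * spacing]
            # greedy self-thinning
            keep_mask = np.ones(len(cand), dtype=bool)
            if len(cand):
                ct = cKDTree(cand)
                pairs = ct.query_pairs(0.55 * spacing, output_type="ndarray")
                for a, b in pairs:
                    if keep_mask[a] and keep_mask[b]:
                        keep_mask[b] = False
            kept.append(cand[keep_mask])
        interior = np.vstack(kept[1:]) if len(kept) > 1 else np.empty((0, 2))

        n_boundary = len(boundary)
        pts = np.vstack([boundary, interior])

        for _ in range(smooth_iters):
            if len(interior) == 0:
                break
            tri = Delaunay(pts)
            neighbour_sum = np.zeros_like(pts)
            neighbour_cnt = np.zeros(len(pts))
            simp = tri.simplices
            for a in range(3):
                for b in range(3):
                    if a != b:
                        np.add.at(neighbour_sum, simp[:, a], pts[simp[:, b]])
                        np.add.at(neighbour_cnt, simp[:, a], 1)
            moved = pts.copy()
            idx = np.arange(n_boundary, len(pts))
            moved[idx] = neighbour_sum[idx] / neighbour_cnt[idx, None]
            ok = shapely.contains_xy(poly, moved[idx, 0], moved[idx, 1])
            dist = shapely.distance(shapely.points(moved[idx]), poly.boundary)
            ok &= dist >= 0.4 * spacing
            pts[idx[ok]] = moved[idx[ok]]

        tri = Delaunay(pts)
        cent = pts[tri.simplices].mean(axis=1)
        keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        # drop zero-area slivers from collinear boundary runs
        p0, p1, p2 = (pts[tri.simplices[:, i]] for i in range(3))
        tri_area = 0.5 * np.abs((p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
                                - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1]))
        keep &= tri_area > 1e-6 * spacing ** 2
        tris = tri.simplices[keep]
        used = np.unique(tris)
        remap = -np.ones(len(pts), dtype=int)
        remap[used] = np.arange(len(used))
        mesh = PlanarMesh(
            nodes=pts[used], triangles=remap[tris],
            region_labels=np.array(["skull"] * len(tris), dtype=object),
            fenestra_polygons={k: np.asarray(v) for k, v in holes.items()},
            outline_area=polygon_area(np.asarray(outline)),
        )
        area_err = abs(mesh.solid_area - target_area) / target_area
        min_angle = _tri_min_angles(mesh.nodes, mesh.triangles).min()
        if area_err <= 1e-3 and min_angle >= min_angle_deg:
            mesh.validate()
            return mesh
        last_reason = (f"area error {area_err:.2%}, min angle {min_angle:.1f} deg "
                       f"at spacing {spacing:.3g} mm")
        spacing /= 1.5
    raise ValueError(
        f"could not reach mesh quality (min angle >= {min_angle_deg} deg, area "
        f"within 0.1%) at target_edge {target_edge_mm} mm; try a smaller "
        f"target edge ({last_reason})")


# ---------------------------------------------------------------------------
# Trees and full studies
# ---------------------------------------------------------------------------

def pure_birth_tree(n_taxa: int, seed: int | None = None) -> CalibratedTree:
    """Pure-birth (Yule) tree, ultrametric, rescaled to unit root-to-tip depth.

    Lineages split after exponential waiting times (unit rate per lineage);
    after the n-th lineage appears one further waiting time extends all
    tips to the present, so no terminal branch has zero length.
    """
    import dendropy

    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    birth_time: dict = {}
    children = [dendropy.Node(), dendropy.Node()]
    for c in children:
        root.add_child(c)
        birth_time[c] = 0.0
    active = list(children)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        parent.edge.length = t - birth_time[parent]
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            birth_time[child] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length = t - birth_time[node]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label=f"t{i + 1}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    ct = CalibratedTree(tree=tree)
    ct.validate()
    return ct


@dataclass
class SyntheticStudy:
    """A complete synthetic study: data for every pipeline stage plus truth."""

    dataset: ShapeDataset
    geometries: dict[str, DeformedSkull]
    meshes: dict[str, PlanarMesh]
    levers: dict[str, LeverSet]
    tree: CalibratedTree
    true_mode_weights: "object"  # pandas DataFrame, taxa x modes
    seed: int

    @property
    def taxa(self) -> list[str]:
        return [c.taxon_id for c in self.dataset.configurations]

    def validate(self) -> None:
        self.dataset.validate(require_pca=True)
        taxa = set(self.taxa)
        if set(self.levers) != taxa or set(self.geometries) != taxa:
            raise ValueError("taxon sets differ between study components")
        if self.meshes and set(self.meshes) != taxa:
            raise ValueError("mesh taxon set differs from the dataset")
        if set(self.tree.tip_labels) != taxa:
            raise ValueError("tree tips differ from the dataset taxa")
        for m in self.meshes.values():
            m.validate()
        for lv in self.levers.values():
            lv.validate()


def generate_study(n_taxa: int = 8, tree_seed: int | None = None,
                   mode_rates: dict[str, float] | None = None,
                   noise_sd: float = 0.5, seed: int = 0, variant="a",
                   skull_length_mm: float = 200.0,
                   fenestra_fraction: float | None = None,
                   with_meshes: bool = True,
                   target_edge_mm: float = 8.0) -> SyntheticStudy:
    """Generate a full synthetic study, reproducible from (parameters, seed)."""
    import pandas as pd

    if n_taxa < 4:
        raise ValueError("a study needs at least 4 taxa")
    rates = dict(DEFAULT_MODE_RATES)
    if mode_rates:
        unknown = set(mode_rates) - set(MODE_IDS)
        if unknown:
            raise ValueError(f"unknown deformation modes: {sorted(unknown)}")
        rates.update(mode_rates)
    rng = np.random.default_rng(seed)
    if tree_seed is None:
        tree_seed = int(rng.integers(2 ** 31 - 1))
    tree = pure_birth_tree(n_taxa, seed=tree_seed)

    cols = {}
    for mode in MODE_IDS:
        rate = rates.get(mode, 0.0)
        child = int(rng.integers(2 ** 31 - 1))
        if rate > 0:
            cols[mode] = simulate_bm(tree, rate=rate, n_traits=1,
                                     seed=child).iloc[:, 0]
        else:
            cols[mode] = pd.Series(0.0, index=tree.tip_labels)
    weights = pd.DataFrame(cols)

    template = make_template(variant=variant, skull_length_mm=skull_length_mm,
                             fenestra_fraction=fenestra_fraction)
    configs, geometries, meshes, levers = [], {}, {}, {}
    for taxon in tree.tip_labels:
        child = int(rng.integers(2 ** 31 - 1))
        cfg, geom = deform_template(template, weights.loc[taxon].to_dict(),
                                    noise_sd=noise_sd, seed=child,
                                    specimen_id=taxon)
        cfg.taxon_id = taxon
        configs.append(cfg)
        geometries[taxon] = geom
        levers[taxon] = geom.lever_set(taxon)
        if with_meshes:
            meshes[taxon] = mesh_skull(geom, target_edge_mm=target_edge_mm)
    dataset = ShapeDataset(variant=template.variant, configurations=configs)
    study = SyntheticStudy(dataset=dataset, geometries=geometries,
                           meshes=meshes, levers=levers, tree=tree,
                           true_mode_weights=weights, seed=seed)
    study.validate()
    return study
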