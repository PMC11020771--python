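"""Two-dimensional landmark data: TPS I/O, dataset variants, subsetting.

Landmark configurations hold the lateral-view skull landmarks of one
specimen in millimetres.  Each point is either a *traditional* (discrete,
homologous) landmark or a *semilandmark* sampled along a curve; curve
membership is recorded per point.  Raw digitised coordinates are converted
to millimetres by the per-record scale factor at read time (the tpsDig
convention: scale multiplies raw coordinates).

A :class:`DatasetVariantSpec` describes one of the nested analysis designs
used when fragmentary material forces a trade-off between landmark count
and taxon coverage; the four built-in presets (``a``–``d``) carry 52, 76,
206 and 230 landmarks respectively.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

TRADITIONAL = "traditional"
SEMILANDMARK = "semilandmark"

#: variant_id -> (n_traditional, n_curves, points_per_curve)
PRESET_VARIANTS = {
    "a": (10, 6, 7),
    "b": (13, 9, 7),
    "c": (19, 17, 11),
    "d": (21, 19, 11),
}


class TPSParseError(ValueError):
    """Raised when a TPS file cannot be parsed; the message names the line."""


@dataclass
class LandmarkConfiguration:
    """One specimen's labelled 2D landmark set, in mm.

    ``curve_memberships`` is ``-1`` for traditional landmarks and a
    non-negative curve index for semilandmarks; semilandmarks of one curve
    must be contiguous and ordered.
    """

    specimen_id: str
    taxon_id: str
    points: np.ndarray
    landmark_kinds: np.ndarray | None = None
    curve_memberships: np.ndarray | None = None
    scale_mm_per_unit: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        n = len(self.points)
        if self.landmark_kinds is None:
            self.landmark_kinds = np.array([TRADITIONAL] * n, dtype=object)
        else:
            self.landmark_kinds = np.asarray(self.landmark_kinds, dtype=object)
        if self.curve_memberships is None:
            self.curve_memberships = np.full(n, -1, dtype=int)
        else:
            self.curve_memberships = np.asarray(self.curve_memberships, dtype=int)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        if not (self.scale_mm_per_unit > 0):
            raise ValueError(f"{self.specimen_id}: scale must be positive")
        n = self.n_points
        if len(self.landmark_kinds) != n or len(self.curve_memberships) != n:
            raise ValueError(f"{self.specimen_id}: per-point arrays disagree in length")
        for i in range(n):
            is_semi = self.landmark_kinds[i] == SEMILANDMARK
            if is_semi != (self.curve_memberships[i] >= 0):
                raise ValueError(
                    f"{self.specimen_id}: point {i} kind/curve flags inconsistent"
                )
        for c in np.unique(self.curve_memberships):
            if c < 0:
                continue
            idx = np.flatnonzero(self.curve_memberships == c)
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ValueError(
                    f"{self.specimen_id}: semilandmarks of curve {c} not contiguous"
                )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0), scale: float = 1.0,
                    reflect: bool = False) -> "LandmarkConfiguration":
        """Return a copy with a similarity transform applied to the points.

        ``reflect=True`` mirrors about the y axis (x → −x) before the
        rotation — the explicit switch for standardising left/right-facing
        specimens; nothing downstream ever reflects implicitly.
        """
        pts = self.points * float(scale)
        if reflect:
            pts = pts * np.array([-1.0, 1.0])
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        pts = pts + np.asarray(translation, dtype=float)
        return replace(self, points=pts)


@dataclass
class DatasetVariantSpec:
    """A nested landmarking design: traditional landmarks plus semilandmark curves."""

    variant_id: str
    n_traditional: int
    n_curves: int
    points_per_curve: int
    taxa: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n_traditional + self.n_curves * self.points_per_curve

    def kind_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-point kind flags and curve indices implied by this design.

        Traditional landmarks come first, followed by the curves in order.
        """
        kinds = [TRADITIONAL] * self.n_traditional
        curves = [-1] * self.n_traditional
        for c in range(self.n_curves):
            kinds.extend([SEMILANDMARK] * self.points_per_curve)
            curves.extend([c] * self.points_per_curve)
        return np.array(kinds, dtype=object), np.array(curves, dtype=int)


def preset_variant(variant_id: str, taxa: list[str] | None = None) -> DatasetVariantSpec:
    """Build one of the four built-in dataset variants (``a``–``d``)."""
    try:
        nt, nc, ppc = PRESET_VARIANTS[variant_id]
    except KeyError:
        raise ValueError(f"unknown preset variant {variant_id!r}") from None
    return DatasetVariantSpec(variant_id, nt, nc, ppc, taxa or [])


def validate_variant(spec: DatasetVariantSpec) -> int:
    """Validate a variant design and return its total landmark count."""
    if spec.n_traditional < 0 or spec.n_curves < 0 or spec.points_per_curve < 0:
        raise ValueError("landmark counts must be non-negative")
    total = spec.total
    if total < 3:
        raise ValueError(f"variant {spec.variant_id!r}: total {total} < 3, shape undefined")
    if spec.variant_id in PRESET_VARIANTS:
        nt, nc, ppc = PRESET_VARIANTS[spec.variant_id]
        preset_total = nt + nc * ppc
        if total != preset_total:
            raise ValueError(
                f"variant {spec.variant_id!r}: computed total {total} contradicts "
                f"preset total {preset_total}"
            )
    return total


@dataclass
class ShapeDataset:
    """A variant design together with the configurations conforming to it."""

    variant: DatasetVariantSpec
    configurations: list[LandmarkConfiguration]

    def validate(self, require_pca: bool = False) -> None:
        total = validate_variant(self.variant)
        for cfg in self.configurations:
            cfg.validate()
            if cfg.n_points != total:
                raise ValueError(
                    f"{cfg.specimen_id}: {cfg.n_points} points, variant "
                    f"{self.variant.variant_id!r} declares {total}"
                )
        if require_pca and len(self.configurations) < 3:
            raise ValueError("PCA-bearing analyses need at least 3 configurations")

    @property
    def taxa(self) -> list[str]:
        return [c.taxon_id for c in self.configurations]

    def points_array(self) -> np.ndarray:
        """Stack configurations into an (n_specimens, k, 2) array."""
        return np.stack([c.points for c in self.configurations])


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

def _is_coordinate_line(s: str) -> bool:
    parts = s.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a TPS file into landmark configurations (coordinates in mm).

    Accepts ``LM=`` count headers with optional ``IMAGE=``, ``ID=`` and
    ``SCALE=`` lines; raw coordinates are multiplied by the scale factor.
    A record without a scale line falls back to scale 1 with a warning.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"{path}: line {i + 1}: expected 'LM=' header, got {line!r}")
        try:
            count = int(line.split("=", 1)[1])
        except ValueError:
            raise TPSParseError(
                f"{path}: line {i + 1}: malformed landmark count {line!r}"
            ) from None
        header_line = i + 1
        i += 1
        coords: list[tuple[float, float]] = []
        while i < n_lines and len(coords) < count:
            s = lines[i].strip()
            if not s:
                i += 1
                continue
            if not _is_coordinate_line(s):
                break
            x, y = s.split()
            coords.append((float(x), float(y)))
            i += 1
        if len(coords) != count:
            raise TPSParseError(
                f"{path}: record starting line {header_line}: declared LM={count} "
                f"but found {len(coords)} coordinate lines"
            )
        image = None
        record_id = None
        scale = None
        while i < n_lines:
            s = lines[i].strip()
            if not s:
                i += 1
                continue
            upper = s.upper()
            if upper.startswith("LM="):
                break
            if _is_coordinate_line(s):
                raise TPSParseError(
                    f"{path}: record starting line {header_line}: more coordinate "
                    f"lines than declared (LM={count})"
                )
            if upper.startswith("IMAGE="):
                image = s.split("=", 1)[1].strip()
            elif upper.startswith("ID="):
                record_id = s.split("=", 1)[1].strip()
            elif upper.startswith("SCALE="):
                try:
                    scale = float(s.split("=", 1)[1])
                except ValueError:
                    raise TPSParseError(
                        f"{path}: line {i + 1}: malformed SCALE line {s!r}"
                    ) from None
            else:
                logger.debug("ignoring TPS keyword line %r", s)
            i += 1
        if scale is None:
            logger.warning(
                "TPS record %s lacks a SCALE line; assuming scale 1 (coordinates "
                "already in mm)", record_id or image or len(configs) + 1,
            )
            scale = 1.0
        sid = record_id or image or f"specimen_{len(configs) + 1}"
        pts = np.asarray(coords, dtype=float) * scale
        configs.append(
            LandmarkConfiguration(
                specimen_id=sid,
                taxon_id=sid,
                points=pts,
                scale_mm_per_unit=scale,
                provenance=image or "",
            )
        )
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    """Write configurations as TPS records; round-trips with :func:`read_tps`."""
    if not configs:
        raise ValueError("cannot write an empty list of configurations")
    for cfg in configs:
        cfg.validate()
    with open(path, "w") as fh:
        for cfg in configs:
            raw = cfg.points / cfg.scale_mm_per_unit
            fh.write(f"LM={cfg.n_points}\n")
            for x, y in raw:
                fh.write(f"{x:.17g} {y:.17g}\n")
            if cfg.provenance:
                fh.write(f"IMAGE={cfg.provenance}\n")
            fh.write(f"ID={cfg.specimen_id}\n")
            fh.write(f"SCALE={cfg.scale_mm_per_unit:.17g}\n")


# ---------------------------------------------------------------------------
# Subsetting and CSV export
# ---------------------------------------------------------------------------

def subset_to_variant(dataset: ShapeDataset, target: DatasetVariantSpec,
                      mapping) -> ShapeDataset:
    """Reduce every configuration to the mapped point indices.

    ``mapping`` lists, for each target point, its index in the source
    variant.  Kinds are carried over and curve indices renumbered in order
    of first appearance.
    """
    mapping = np.asarray(mapping, dtype=int)
    target_total = validate_variant(target)
    if len(mapping) != target_total:
        raise ValueError(
            f"mapping length {len(mapping)} != target variant total {target_total}"
        )
    source_total = validate_variant(dataset.variant)
    if np.any(mapping < 0) or np.any(mapping >= source_total):
        raise ValueError("mapping contains out-of-range point indices")

    new_configs = []
    for cfg in dataset.configurations:
        kinds = cfg.landmark_kinds[mapping]
        curves = cfg.curve_memberships[mapping]
        renumber: dict[int, int] = {}
        new_curves = np.full(len(curves), -1, dtype=int)
        for j, c in enumerate(curves):
            if c >= 0:
                new_curves[j] = renumber.setdefault(int(c), len(renumber))
        new_configs.append(
            replace(cfg, points=cfg.points[mapping], landmark_kinds=kinds,
                    curve_memberships=new_curves)
        )
    return ShapeDataset(variant=target, configurations=new_configs)


def export_csv(configs: list[LandmarkConfiguration], path) -> None:
    """Write a long-format CSV of configurations."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["specimen_id", "taxon_id", "point_index", "kind", "curve",
                    "x_mm", "y_mm"])
        for cfg in configs:
            for i, (x, y) in enumerate(cfg.points):
                w.writerow([cfg.specimen_id, cfg.taxon_id, i,
                            cfg.landmark_kinds[i], int(cfg.curve_memberships[i]),
                            f"{x:.12g}", f"{y:.12g}"])
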