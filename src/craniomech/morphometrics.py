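"""Generalized Procrustes superimposition, shape PCA, size and outlier tests.

The two workhorses are scikit-learn style transformers:

* :class:`GeneralizedProcrustes` — iterative superimposition removing
  translation, scale and rotation (reflections excluded, det(R)=+1) from a
  stack of landmark configurations, yielding unit-centroid-size shape
  coordinates and a consensus.  The aligned set is put into a canonical
  orientation derived from the consensus itself so output is reproducible
  regardless of how the inputs were oriented.
* :class:`ShapePCA` — principal components of the aligned coordinates about
  the consensus (covariance PCA via SVD) with a deterministic sign
  convention.  An optional orthogonal tangent-space projection is exposed
  but off by default, which is standard practice when shape variation is
  small.

Semilandmarks are treated as fixed points: no sliding is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .shape_data import LandmarkConfiguration, ShapeDataset


class ConvergenceError(RuntimeError):
    """GPA failed to converge; carries the last consensus displacement."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# Centroid size
# ---------------------------------------------------------------------------

def _as_points(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.points
    pts = np.asarray(config, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) point array")
    return pts


def centroid_size(config) -> float:
    """Square root of summed squared distances of the points from their centroid."""
    pts = _as_points(config)
    if len(pts) < 2:
        raise ValueError("centroid size needs at least 2 points")
    centred = pts - pts.mean(axis=0)
    size = float(np.sqrt((centred ** 2).sum()))
    if size <= 1e-300:
        raise ValueError("all points coincident: centroid size is zero")
    return size


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||source @ R - target||_F.

    Both inputs must already be centred.
    """
    m = source.T @ target
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _canonical_rotation(consensus: np.ndarray) -> np.ndarray:
    """Rotation putting the consensus into a reproducible orientation.

    Aligns the consensus' principal axes with the coordinate axes and fixes
    the residual two-fold ambiguity by making the largest-magnitude first-
    axis coordinate positive.
    """
    _, _, vt = np.linalg.svd(consensus, full_matrices=False)
    v = vt.T
    if np.linalg.det(v) < 0:
        v = v @ np.diag([1.0, -1.0])
    rotated = consensus @ v
    i = np.argmax(np.abs(rotated[:, 0]))
    if rotated[i, 0] < 0:
        v = v @ np.diag([-1.0, -1.0])  # rotation by pi, not a reflection
    return v


@dataclass
class AlignedShapeSet:
    """Procrustes-aligned coordinates plus consensus and original sizes."""

    aligned_points: np.ndarray  # (n, k, 2), unit centroid size each
    consensus: np.ndarray       # (k, 2), arithmetic mean of aligned
    centroid_sizes: np.ndarray  # (n,), mm
    iterations_used: int
    specimen_ids: list[str] | None = None
    taxon_ids: list[str] | None = None

    def validate(self) -> None:
        for i, pts in enumerate(self.aligned_points):
            c = pts.mean(axis=0)
            if np.abs(c).max() > 1e-9:
                raise ValueError(f"aligned configuration {i} not centred")
            if abs(np.sqrt((pts ** 2).sum()) - 1.0) > 1e-9:
                raise ValueError(f"aligned configuration {i} not unit size")
        if np.abs(self.aligned_points.mean(axis=0) - self.consensus).max() > 1e-9:
            raise ValueError("consensus is not the mean of the aligned set")


class GeneralizedProcrustes(TransformerMixin, BaseEstimator):
    """Iterative generalized Procrustes superimposition (rotation only).

    Parameters
    ----------
    tol : float
        Convergence threshold on the Frobenius displacement of the
        consensus between iterations.
    max_iter : int
        Iteration cap; exceeding it raises :class:`ConvergenceError`.

    Attributes
    ----------
    consensus_ : (k, 2) array, mean of the aligned configurations.
    aligned_ : (n, k, 2) array of unit-size shape coordinates.
    centroid_sizes_ : (n,) original sizes in mm.
    n_iter_ : iterations used.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _stack(X) -> np.ndarray:
        if isinstance(X, ShapeDataset):
            X = X.points_array()
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("expected (n_specimens, k, 2) landmark stack")
        return arr

    def fit(self, X, y=None):
        arr = self._stack(X)
        n = arr.shape[0]
        if n < 2:
            raise ValueError("GPA needs at least 2 configurations")
        sizes = np.array([centroid_size(a) for a in arr])
        z = (arr - arr.mean(axis=1, keepdims=True)) / sizes[:, None, None]

        consensus = z.mean(axis=0)
        consensus = consensus - consensus.mean(axis=0)
        consensus /= np.sqrt((consensus ** 2).sum())

        delta = np.inf
        aligned = z
        for it in range(1, self.max_iter + 1):
            aligned = np.stack([zi @ _optimal_rotation(zi, consensus) for zi in z])
            new_consensus = aligned.mean(axis=0)
            new_consensus = new_consensus - new_consensus.mean(axis=0)
            new_consensus /= np.sqrt((new_consensus ** 2).sum())
            delta = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
            consensus = new_consensus
            if delta < self.tol:
                break
        else:
            raise ConvergenceError(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last consensus displacement {delta:.3e})", delta)

        aligned = np.stack([zi @ _optimal_rotation(zi, consensus) for zi in z])
        rot = _canonical_rotation(aligned.mean(axis=0))
        aligned = aligned @ rot
        self.aligned_ = aligned
        self.consensus_ = aligned.mean(axis=0)
        self.centroid_sizes_ = sizes
        self.n_iter_ = it
        return self

    def transform(self, X) -> np.ndarray:
        """Align configurations to the fitted consensus."""
        arr = self._stack(X)
        out = []
        for a in arr:
            size = centroid_size(a)
            zi = (a - a.mean(axis=0)) / size
            out.append(zi @ _optimal_rotation(zi, self.consensus_))
        return np.stack(out)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).aligned_


def gpa(dataset, tol: float = 1e-8, max_iter: int = 100) -> AlignedShapeSet:
    """Run GPA on a :class:`ShapeDataset` (or landmark stack)."""
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter).fit(dataset)
    specimen_ids = taxon_ids = None
    if isinstance(dataset, ShapeDataset):
        specimen_ids = [c.specimen_id for c in dataset.configurations]
        taxon_ids = [c.taxon_id for c in dataset.configurations]
    return AlignedShapeSet(
        aligned_points=est.aligned_,
        consensus=est.consensus_,
        centroid_sizes=est.centroid_sizes_,
        iterations_used=est.n_iter_,
        specimen_ids=specimen_ids,
        taxon_ids=taxon_ids,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two centred unit-size shapes."""
    r = _optimal_rotation(a, b)
    return float(np.sqrt(((a @ r - b) ** 2).sum()))


# ---------------------------------------------------------------------------
# Shape PCA
# ---------------------------------------------------------------------------

@dataclass
class ShapePCAResult:
    scores: np.ndarray             # (n, r)
    loadings: np.ndarray           # (r, 2k), orthonormal rows
    variance_fraction: np.ndarray  # (r,)
    eigenvalues: np.ndarray        # (r,)


class ShapePCA(TransformerMixin, BaseEstimator):
    """PCA of Procrustes-aligned coordinates about the consensus.

    Components are computed from the centred (unstandardised) flattened
    coordinates via SVD.  Sign convention: the largest-magnitude loading
    entry of each component is positive.  ``tangent_project=True`` applies
    an orthogonal projection onto the tangent space at the mean shape
    before the decomposition.
    """

    def __init__(self, tangent_project: bool = False):
        self.tangent_project = tangent_project

    @staticmethod
    def _flatten(X) -> np.ndarray:
        if isinstance(X, AlignedShapeSet):
            X = X.aligned_points
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 3:
            arr = arr.reshape(arr.shape[0], -1)
        return arr

    def fit(self, X, y=None):
        flat = self._flatten(X)
        n = flat.shape[0]
        if n < 3:
            raise ValueError("shape PCA needs at least 3 specimens")
        self.mean_ = flat.mean(axis=0)
        centred = flat - self.mean_
        if self.tangent_project:
            m = self.mean_ / np.linalg.norm(self.mean_)
            centred = centred - np.outer(centred @ m, m)
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        r = min(n - 1, flat.shape[1])
        u, s, vt = u[:, :r], s[:r], vt[:r]
        # deterministic sign: largest-magnitude loading entry positive
        for j in range(r):
            i = np.argmax(np.abs(vt[j]))
            if vt[j, i] < 0:
                vt[j] = -vt[j]
                u[:, j] = -u[:, j]
        eigenvalues = s ** 2 / (n - 1)
        total = eigenvalues.sum()
        self.components_ = vt
        self.eigenvalues_ = eigenvalues
        self.explained_variance_ratio_ = (
            eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
        )
        self.scores_ = u * s
        return self

    def transform(self, X) -> np.ndarray:
        flat = self._flatten(X)
        return (flat - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_


def pca_shapes(aligned, tangent_project: bool = False) -> ShapePCAResult:
    """PCA of an aligned shape set; see :class:`ShapePCA`."""
    est = ShapePCA(tangent_project=tangent_project).fit(aligned)
    return ShapePCAResult(
        scores=est.scores_,
        loadings=est.components_,
        variance_fraction=est.explained_variance_ratio_,
        eigenvalues=est.eigenvalues_,
    )


# ---------------------------------------------------------------------------
# Outlier tests and allometry
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    variable_id: str
    lower_fence: float
    upper_fence: float
    outliers: list[tuple[str, float, str]]  # (specimen_id, value, side)


def boxplot_outliers(values, variable_id: str = "",
                     quartile_method: str = "linear") -> OutlierReport:
    """Tukey boxplot outlier test: flag values beyond Q1-1.5*IQR / Q3+1.5*IQR.

    ``values`` maps specimen labels to numbers (dict / pandas Series); a
    bare sequence gets positional labels.  Quartiles use linear
    interpolation between order statistics by default ("type 7").
    """
    if hasattr(values, "index") and hasattr(values, "to_numpy"):  # pandas
        labels = [str(k) for k in values.index]
        vals = values.to_numpy(dtype=float)
    elif isinstance(values, dict):
        labels = [str(k) for k in values.keys()]
        vals = np.asarray(list(values.values()), dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
        labels = [str(i) for i in range(len(vals))]
    if len(vals) < 4:
        raise ValueError("outlier test needs at least 4 values (quartiles unstable)")
    q1, q3 = np.quantile(vals, [0.25, 0.75], method=quartile_method)
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    outliers = []
    for label, v in zip(labels, vals):
        if v < lower:
            outliers.append((label, float(v), "lower"))
        elif v > upper:
            outliers.append((label, float(v), "upper"))
    return OutlierReport(variable_id, float(lower), float(upper), outliers)


@dataclass
class AllometryFit:
    slope: float
    intercept: float
    p_value: float
    adj_r2: float


def regress_allometry(response, predictor) -> AllometryFit:
    """Ordinary least squares of response on predictor with a slope t-test."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(y) != len(x):
        raise ValueError("response and predictor lengths differ")
    n = len(y)
    if n < 3:
        raise ValueError("regression needs at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero predictor variance")
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return AllometryFit(float(res.slope), float(res.intercept),
                        float(res.pvalue), float(adj))
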