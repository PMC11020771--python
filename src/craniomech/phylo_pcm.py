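"""Phylogenetic signal and regression under Brownian motion.

Traits evolving by Brownian motion (BM) on a time-calibrated tree have a
multivariate normal distribution among tips with covariance proportional
to shared root-to-ancestor path lengths.  That covariance matrix C drives
everything here:

* Blomberg's K — the ratio of observed to BM-expected (MSE0/MSE), where
  MSE0 is the mean squared deviation of tip values from the phylogenetic
  (GLS) mean and MSE the phylogenetically corrected error variance.  K has
  expectation 1 under BM; K > 1 means close relatives are more similar
  than BM predicts.  Significance by permuting tip values.
* K_mult — the multivariate generalisation for trait matrices (e.g. whole
  shape data); identical machinery applied to row vectors, reducing
  exactly to Blomberg's K for one variable.
* PGLS — generalized least squares regression with residual covariance C,
  with a t-test on the slope and a pseudo adjusted R² computed in the
  phylogenetically whitened space.

Trees come and go as Newick via dendropy; polytomies are allowed and
zero-length branches are flagged but tolerated.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)


@dataclass
class CalibratedTree:
    """A rooted tree with branch lengths in time units."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def validate(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        n_zero = 0
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:
                continue  # root edge
            if edge.length is None:
                raise ValueError(
                    f"edge above {edge.head_node} has no branch length")
            if edge.length < 0 or not np.isfinite(edge.length):
                raise ValueError(f"invalid branch length {edge.length}")
            if edge.length == 0:
                n_zero += 1
        if n_zero:
            logger.warning("tree contains %d zero-length branches", n_zero)

    def depths(self) -> pd.Series:
        """Root-to-tip path lengths."""
        self.tree.calc_node_root_distances(
            return_leaf_distances_only=False)
        return pd.Series({leaf.taxon.label: leaf.root_distance
                          for leaf in self.tree.leaf_node_iter()})


def _parse_newick(source: str, is_path: bool) -> CalibratedTree:
    try:
        if is_path:
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    ct = CalibratedTree(tree=tree)
    ct.validate()
    return ct


def read_newick(path) -> CalibratedTree:
    return _parse_newick(str(path), is_path=True)


def tree_from_string(newick: str) -> CalibratedTree:
    return _parse_newick(newick, is_path=False)


def write_newick(tree: CalibratedTree, path) -> None:
    s = tree.tree.as_string(schema="newick", suppress_rooting=True,
                            real_value_format_specifier=".17g")
    with open(path, "w") as fh:
        fh.write(s)


# ---------------------------------------------------------------------------
# Brownian-motion covariance
# ---------------------------------------------------------------------------

def bm_covariance(tree: CalibratedTree) -> pd.DataFrame:
    """Tip × tip BM covariance: shared root-to-MRCA path length.

    ``C[i, j]`` is the depth of the most recent common ancestor of tips i
    and j; the diagonal holds root-to-tip depths.  Symmetric PSD.
    """
    depths = tree.depths()
    labels = tree.tip_labels
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.tree.taxon_namespace}
    n = len(labels)
    c = np.zeros((n, n))
    for i, li in enumerate(labels):
        c[i, i] = depths[li]
        for j in range(i + 1, n):
            lj = labels[j]
            d = pdm.patristic_distance(taxa[li], taxa[lj])
            c[i, j] = c[j, i] = 0.5 * (depths[li] + depths[lj] - d)
    return pd.DataFrame(c, index=labels, columns=labels)


def _aligned_matrix(c: pd.DataFrame, data) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align trait data to the covariance row order; returns (C, Y, labels)."""
    labels = list(c.index)
    if isinstance(data, pd.Series):
        data = data.to_frame()
    if isinstance(data, dict):
        data = pd.Series(data).to_frame()
    if isinstance(data, pd.DataFrame):
        missing = [l for l in labels if l not in data.index]
        if missing:
            raise ValueError(f"trait data missing tips: {missing}")
        y = data.loc[labels].to_numpy(dtype=float)
    else:
        y = np.asarray(data, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if len(y) != len(labels):
            raise ValueError("unlabelled trait data length does not match tree")
    return c.to_numpy(), y, labels


# ---------------------------------------------------------------------------
# Phylogenetic signal
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None


def _k_statistic(cinv: np.ndarray, expected_ratio: float, y: np.ndarray,
                 ones_ciy_denom: float, one: np.ndarray) -> float:
    n = len(y)
    a = (one @ cinv @ y) / ones_ciy_denom  # GLS mean, one row per trait
    r = y - a
    mse0 = float(np.sum(r * r)) / (n - 1)
    mse = float(np.sum(r * (cinv @ r))) / (n - 1)
    if mse <= 0:
        raise ValueError("degenerate phylogenetic error variance")
    return (mse0 / mse) / expected_ratio


def _signal(tree: CalibratedTree, data, n_perm: int, seed) -> SignalResult:
    c = bm_covariance(tree)
    cm, y, _ = _aligned_matrix(c, data)
    n = len(y)
    if np.allclose(y.var(axis=0), 0):
        raise ValueError("constant trait: phylogenetic signal undefined")
    cinv = np.linalg.inv(cm)
    one = np.ones(n)
    denom = float(one @ cinv @ one)
    expected_ratio = (np.trace(cm) - n / denom) / (n - 1)
    observed = _k_statistic(cinv, expected_ratio, y, denom, one)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = _k_statistic(cinv, expected_ratio, y[perm], denom, one)
        if stat >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return SignalResult(statistic=float(observed), p_value=float(p),
                        n_permutations=n_perm, seed=seed)


def blomberg_k(tree: CalibratedTree, trait, n_perm: int = 999,
               seed: int | None = None) -> SignalResult:
    """Blomberg's K for one trait, with a tip-shuffling permutation test."""
    if isinstance(trait, pd.DataFrame):
        if trait.shape[1] != 1:
            raise ValueError("blomberg_k takes a single variable")
        trait = trait.iloc[:, 0]
    return _signal(tree, trait, n_perm, seed)


def kmult(tree: CalibratedTree, traits, n_perm: int = 999,
          seed: int | None = None) -> SignalResult:
    """Multivariate K for a tip × variable matrix; equals Blomberg's K for
    one variable."""
    return _signal(tree, traits, n_perm, seed)


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    slope: float
    intercept: float
    slope_p: float
    pseudo_r2_adj: float
    n: int


class PGLSRegression(RegressorMixin, BaseEstimator):
    """Generalized least squares regression with a BM residual covariance.

    Parameters
    ----------
    covariance : (n, n) array or DataFrame, or None
        Residual covariance among observations, in row order of the data
        passed to :meth:`fit`.  ``None`` means the identity (ordinary
        least squares).

    Attributes
    ----------
    coef_, intercept_ : GLS estimates.
    slope_pvalues_ : two-sided t-test p-value per predictor.
    pseudo_r2_adj_ : 1 − (RSS/TSS_GLS)·(n−1)/(n−p−1) in whitened space.
    """

    def __init__(self, covariance=None):
        self.covariance = covariance

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        yv = np.asarray(y, dtype=float).ravel()
        n, p = x.shape
        if n != len(yv):
            raise ValueError("X and y lengths differ")
        if n < p + 2:
            raise ValueError("too few observations for residual degrees of freedom")
        if self.covariance is None:
            cm = np.eye(n)
        else:
            cm = np.asarray(self.covariance, dtype=float)
            if cm.shape != (n, n):
                raise ValueError("covariance shape does not match data")
        try:
            l = np.linalg.cholesky(cm)
        except np.linalg.LinAlgError:
            raise ValueError("covariance matrix is singular or not PSD") from None
        design = np.column_stack([np.ones(n), x])
        wx = np.linalg.solve(l, design)
        wy = np.linalg.solve(l, yv)
        xtx = wx.T @ wx
        if np.linalg.matrix_rank(xtx) < p + 1:
            raise ValueError("singular design matrix")
        beta = np.linalg.solve(xtx, wx.T @ wy)
        resid = wy - wx @ beta
        rss = float(resid @ resid)
        dof = n - (p + 1)
        sigma2 = rss / dof
        cov_beta = sigma2 * np.linalg.inv(xtx)
        se = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
        # GLS mean of y for the whitened total sum of squares
        wone = np.linalg.solve(l, np.ones(n))
        a = float(wone @ wy) / float(wone @ wone)
        tss = float(np.sum((wy - a * wone) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.slope_pvalues_ = pvals[1:]
        self.pseudo_r2_adj_ = float(1.0 - (rss / tss) * (n - 1) / dof) if tss > 0 else np.nan
        self.r2_ = r2
        self.n_ = n
        self._chol = l
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        return self.intercept_ + x @ self.coef_


def pgls(tree: CalibratedTree, response, predictor) -> PGLSFit:
    """PGLS of one response on one predictor under the tree's BM covariance."""
    c = bm_covariance(tree)
    _, y, labels = _aligned_matrix(c, response)
    _, x, _ = _aligned_matrix(c, predictor)
    n = len(labels)
    if n < 4:
        raise ValueError("PGLS needs at least 4 tips")
    est = PGLSRegression(covariance=c.to_numpy()).fit(x[:, 0], y[:, 0])
    return PGLSFit(slope=float(est.coef_[0]), intercept=est.intercept_,
                   slope_p=float(est.slope_pvalues_[0]),
                   pseudo_r2_adj=est.pseudo_r2_adj_, n=n)


# ---------------------------------------------------------------------------
# Brownian-motion simulation
# ---------------------------------------------------------------------------

def simulate_bm(tree: CalibratedTree, rate: float = 1.0, n_traits: int = 1,
                seed: int | None = None, root_state: float = 0.0) -> pd.DataFrame:
    """Simulate traits under BM on the tree: tip draws ~ N(root, rate·C)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    c = bm_covariance(tree)
    cm = c.to_numpy()
    # tolerate ultrametric roundoff with a relative symmetric eigen floor
    try:
        l = np.linalg.cholesky(cm)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cm)
        w = np.clip(w, 0.0, None)
        l = v @ np.diag(np.sqrt(w))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(cm), n_traits))
    y = root_state + np.sqrt(rate) * (l @ z)
    return pd.DataFrame(y, index=c.index,
                        columns=[f"trait_{i + 1}" for i in range(n_traits)])
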