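"""Genome-wide ancestry principal components and prevalence surfaces.

PCs are computed Eigenstrat-style: variants below a minor-allele-frequency
floor are dropped, missing dosages are mean-imputed, and each variant column
is standardised as ``(g - 2p̂) / sqrt(p̂(1-p̂))`` with the shrunk frequency
estimate ``p̂ = (1 + Σg) / (2 + 2n)``.  Scores are the unit-norm left
singular vectors of the standardised matrix (the eigenvectors of the
individual × individual covariance), which is the scale on which ancestry
PCs typically enter regressions; eigenvalues are the squared singular
values.  Sign is fixed by making each component's largest-magnitude variant
loading positive.

The prevalence surface over (PC1, PC2) is a Nadaraya–Watson smooth with a
radial Gaussian kernel: at grid point ``x`` individual ``j`` receives weight
``φ(k·d(x,j)/d_max)`` where ``φ`` is the standard normal density, ``d`` the
Euclidean distance in PC space, ``d_max`` the maximum pairwise distance
among individuals, and ``k`` a unitless smoothing value (default 15).  The
smoothed value is the weighted mean of the binary outcome, hence a
prevalence in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .data import GenotypeData
from .errors import DegenerateInputError, InvalidArgumentError

DEFAULT_SMOOTHING_K = 15.0


@dataclass
class AncestryPCs:
    """Top-K ancestry principal components.

    ``scores`` has zero-mean, unit-sum-of-squares columns; ``eigenvalues``
    are non-increasing; ``variant_loadings`` (variants kept after filtering ×
    K) are the right singular vectors.
    """

    samples: list[str]
    scores: np.ndarray
    eigenvalues: np.ndarray
    variant_ids: list[str]
    variant_loadings: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"individual_id": self.samples, **cols})


def standardize_genotypes(
    genotypes: GenotypeData, maf_min: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Filter, impute and standardise the dosage matrix.

    Returns the standardised ``(n, m_kept)`` matrix and the indices of kept
    variants.  Raises :class:`DegenerateInputError` if no variant passes the
    frequency filter.
    """
    dos = genotypes.dosages
    n = dos.shape[0]
    maf = genotypes.minor_allele_frequencies()
    keep = np.flatnonzero(np.isfinite(maf) & (maf >= maf_min))
    if keep.size == 0:
        raise DegenerateInputError(
            "no polymorphic variants left after the MAF filter"
        )
    sub = dos[:, keep].copy()
    col_mean = np.nanmean(sub, axis=0)
    nan_r, nan_c = np.where(np.isnan(sub))
    sub[nan_r, nan_c] = col_mean[nan_c]
    # centre at the empirical mean dosage (scores exactly zero-mean) and
    # scale by the shrunk frequency estimate, as smartpca does
    p_hat = (1.0 + sub.sum(axis=0)) / (2.0 + 2.0 * n)
    x = (sub - sub.mean(axis=0)) / np.sqrt(p_hat * (1.0 - p_hat))
    return x, keep


def compute_pcs(
    genotypes: GenotypeData,
    n_components: int = 10,
    maf_min: float = 0.01,
) -> AncestryPCs:
    """Top ``n_components`` ancestry PCs of the standardised genotype matrix."""
    if genotypes.n_samples < 2:
        raise InvalidArgumentError("need at least two individuals")
    x, keep = standardize_genotypes(genotypes, maf_min)
    if keep.size < n_components:
        raise DegenerateInputError(
            f"only {keep.size} informative variants for {n_components} components"
        )
    k = min(n_components, min(x.shape) - 1 if min(x.shape) > 1 else 1)
    if min(x.shape) <= 500 or k >= min(x.shape) - 1:
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    else:
        # large cohorts: Lanczos on the top components only, with a fixed
        # start vector so repeated runs are bit-identical
        from scipy.sparse.linalg import svds

        v0 = np.linspace(1.0, 2.0, min(x.shape))
        u, s, vt = svds(x, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    # reproducible orientation: largest-|loading| entry positive per component
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    ids = [genotypes.variant_ids[i] for i in keep]
    return AncestryPCs(
        samples=list(genotypes.samples),
        scores=u,
        eigenvalues=s**2,
        variant_ids=ids,
        variant_loadings=vt.T,
    )


@dataclass
class ContourGrid:
    """Kernel-smoothed prevalence over the (PC1, PC2) plane.

    ``prevalence[i, j]`` corresponds to ``(grid_x[j], grid_y[i])``; cells
    with (numerically) zero total weight are NaN-flagged, not errors.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    prevalence: np.ndarray
    k: float
    d_max: float

    def frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "prevalence": self.prevalence.ravel()}
        )


def max_pairwise_distance(points: np.ndarray, max_points: int = 5000) -> float:
    """Diameter of a 2-D point cloud.

    Uses the convex hull when possible (exact); degenerate clouds fall back
    to pairwise distances on at most ``max_points`` points.
    """
    pts = np.unique(points, axis=0)
    if len(pts) < 2:
        return 0.0
    if len(pts) > max_points and len(pts) >= 4:
        try:
            hull = ConvexHull(points)
            pts = points[hull.vertices]
        except Exception:  # collinear clouds
            step = int(np.ceil(len(pts) / max_points))
            pts = pts[::step]
    return float(pdist(pts).max())


def prevalence_contour(
    pcs: AncestryPCs | np.ndarray,
    outcome: np.ndarray,
    k: float = DEFAULT_SMOOTHING_K,
    grid_size: int = 100,
) -> ContourGrid:
    """Smoothed prevalence surface over the first two PCs.

    ``pcs`` may be an :class:`AncestryPCs` or a raw ``(n, >=2)`` coordinate
    array; ``outcome`` is the binary case indicator.
    """
    if k <= 0:
        raise InvalidArgumentError("smoothing value k must be > 0")
    coords = pcs.scores[:, :2] if isinstance(pcs, AncestryPCs) else np.asarray(pcs)[:, :2]
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(coords):
        raise InvalidArgumentError("outcome length must match number of individuals")
    d_max = max_pairwise_distance(coords)
    if d_max == 0.0:
        raise DegenerateInputError("all individuals share one PC coordinate")
    gx = np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid_size)
    gy = np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid_size)
    prev = np.empty((grid_size, grid_size))
    # row-wise evaluation keeps memory at O(grid_size * n)
    for i, yv in enumerate(gy):
        dx = gx[:, None] - coords[:, 0][None, :]
        dy = yv - coords[:, 1][None, :]
        w = norm.pdf(k * np.sqrt(dx**2 + dy**2) / d_max)
        tot = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            prev[i] = np.where(tot > 0, (w * y).sum(axis=1) / tot, np.nan)
    return ContourGrid(grid_x=gx, grid_y=gy, prevalence=prev, k=float(k), d_max=d_max)


def plot_contour(grid: ContourGrid, path=None, ax=None):  # pragma: no cover
    """Optional raster export of the prevalence surface (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(grid.grid_x, grid.grid_y, grid.prevalence, cmap="RdYlBu_r")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    plt.colorbar(mesh, ax=ax, label="smoothed prevalence")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
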