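"""Voxel-wise group inference with Monte-Carlo cluster-extent correction.

Subject-level maps (wGBC or seed-FC z) are compared voxel by voxel: a
one-sample t-test for the within-group distribution, and an ordinary
least-squares GLM with a group contrast and age/sex/education covariates for
the between-group comparison.  Multiple comparisons are handled with an
AlphaSim-style cluster-extent correction: smooth Gaussian null fields are
simulated at the smoothness estimated from the GLM residuals, thresholded at
the voxel-level p, and the (1 - alpha) quantile of the null distribution of
maximum cluster extents becomes the minimum cluster size.

The voxel threshold is two-sided and positive/negative clusters are labeled
separately.  Cluster connectivity defaults to 18 (edge adjacency) and can be
6 or 26.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .image import ScalarMap, voxel_sizes
from .preprocess import FWHM_TO_SIGMA

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "StatMap",
    "McThreshold",
    "make_design_matrix",
    "one_sample_tmap",
    "fit_voxelwise_glm",
    "estimate_smoothness",
    "monte_carlo_cluster_threshold",
    "extract_clusters",
    "connectivity_structure",
    "cluster_label_map",
]

CLUSTER_COLUMNS = [
    "label", "sign", "extent_vox", "peak_t",
    "peak_i", "peak_j", "peak_k",
    "peak_x_mm", "peak_y_mm", "peak_z_mm", "corrected",
]


@dataclass
class DesignMatrix:
    """Subject-level design: intercept, group indicator and covariates, plus
    the contrast vector selecting the group effect."""

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.contrast = np.asarray(self.contrast, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("design shape does not match column names")
        if len(self.contrast) != self.X.shape[1]:
            raise ValueError("contrast length does not match design columns")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


@dataclass
class StatMap:
    """A t-statistic map with its degrees of freedom and the per-subject
    residual maps needed for smoothness estimation."""

    t: ScalarMap
    df: int
    residual_maps: np.ndarray | None = None  # subjects x voxels-in-mask
    mask: np.ndarray | None = None


@dataclass
class McThreshold:
    """Cluster-defining settings plus the simulated minimum cluster extent."""

    voxel_p: float
    cluster_alpha: float
    n_iter: int
    estimated_fwhm_mm: np.ndarray
    extent_threshold: int
    connectivity: int = 18
    null_max_extents: np.ndarray | None = field(default=None, repr=False)
    null_supra_counts: np.ndarray | None = field(default=None, repr=False)


def make_design_matrix(
    subjects: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "education"),
    group_col: str = "group",
) -> DesignMatrix:
    """Build [intercept | group | covariates] from a subject table.

    Row order follows the table; the contrast selects the group column, so the
    reported t is group 1 minus group 0 (adjusted for covariates).
    """
    cols = [np.ones(len(subjects)), subjects[group_col].to_numpy(float)]
    names = ["intercept", group_col]
    for c in covariates:
        cols.append(subjects[c].to_numpy(float))
        names.append(c)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X=X, columns=names, contrast=contrast)


def _stack_maps(maps: list[ScalarMap], mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    grid = maps[0].grid_shape
    for m in maps:
        if m.grid_shape != grid:
            raise ValueError("maps are not on a common grid")
    mask = np.asarray(mask, bool)
    data = np.stack([m.data[mask] for m in maps])
    if not np.isfinite(data).all():
        raise ValueError("non-finite map values inside the mask")
    return data, mask


def one_sample_tmap(maps: list[ScalarMap], mask: np.ndarray) -> StatMap:
    """Voxel-wise one-sample t-test (mean against zero), df = n - 1.

    Zero-variance voxels get t = 0 (counted in the log).
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 maps")
    Y, mask = _stack_maps(maps, mask)
    n = Y.shape[0]
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    t = np.zeros_like(mu)
    ok = sd > 0
    t[ok] = mu[ok] / (sd[ok] / math.sqrt(n))
    if (~ok).any():
        logger.warning("%d zero-variance voxels set to t = 0", int((~ok).sum()))
    tmap = np.full(mask.shape, np.nan)
    tmap[mask] = t
    resid = Y - mu
    return StatMap(
        t=ScalarMap(tmap, maps[0].affine), df=n - 1, residual_maps=resid, mask=mask
    )


def fit_voxelwise_glm(
    maps: list[ScalarMap], design: DesignMatrix, mask: np.ndarray
) -> StatMap:
    """Ordinary least squares per voxel; t for the group contrast.

    ``t = c' beta / sqrt(sigma^2 c' (X'X)^-1 c)`` with
    ``df = n - rank(X)``.  With an intercept+group design this reduces exactly
    to the pooled two-sample t-test.  Residual maps are retained for
    smoothness estimation.
    """
    X = design.X
    if len(maps) != X.shape[0]:
        raise ValueError("number of maps does not match design rows")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
                bad.append(design.columns[j])
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")
    Y, mask = _stack_maps(maps, mask)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    c = design.contrast
    denom2 = sigma2 * float(c @ xtx_inv @ c)
    effect = c @ beta
    t = np.zeros_like(effect)
    ok = denom2 > 0
    t[ok] = effect[ok] / np.sqrt(denom2[ok])
    if (~ok).any():
        logger.warning("%d zero-variance voxels set to t = 0", int((~ok).sum()))
    tmap = np.full(mask.shape, np.nan)
    tmap[mask] = t
    return StatMap(
        t=ScalarMap(tmap, maps[0].affine), df=df, residual_maps=resid, mask=mask
    )


def estimate_smoothness(
    residual_maps: np.ndarray,
    mask: np.ndarray,
    voxel_sizes_mm: np.ndarray,
    fallback_fwhm_mm: float | None = None,
) -> np.ndarray:
    """Per-axis Gaussian-equivalent smoothness (FWHM, mm) of residual fields.

    For a Gaussian autocorrelation, the lag-1 correlation rho along an axis
    gives ``FWHM = sqrt(2 ln 2 / (-ln rho))`` voxels; rho is estimated from
    the variance of first differences of the standardized residuals, pooled
    over subjects.  Estimates are floored at one voxel size, since smoothness
    below the sampling grid is unresolvable — white noise therefore reports
    approximately the voxel size.
    """
    mask = np.asarray(mask, bool)
    vs = np.asarray(voxel_sizes_mm, dtype=float)
    if residual_maps.shape[0] < 2:
        raise ValueError("need at least 2 residual maps")
    if mask.sum() < 100:
        logger.warning("mask below 100 voxels: falling back to nominal FWHM")
        if fallback_fwhm_mm is None:
            raise ValueError("degenerate mask and no fallback FWHM provided")
        return np.full(3, float(fallback_fwhm_mm))

    sd = residual_maps.std(axis=1, keepdims=True)
    if np.any(sd <= 0):
        logger.warning("constant residual map: falling back to nominal FWHM")
        if fallback_fwhm_mm is None:
            raise ValueError("constant residuals and no fallback FWHM provided")
        return np.full(3, float(fallback_fwhm_mm))
    Z = (residual_maps - residual_maps.mean(axis=1, keepdims=True)) / sd

    fwhm = np.empty(3)
    grid = np.full(mask.shape, np.nan)
    for axis in range(3):
        num = 0.0
        den = 0.0
        for s in range(Z.shape[0]):
            grid[mask] = Z[s]
            a = np.moveaxis(grid, axis, 0)
            d = a[1:] - a[:-1]
            valid = np.isfinite(d)
            if valid.sum() < 10:
                continue
            num += np.nansum(d[valid] ** 2)
            den += valid.sum()
        if den == 0:
            fwhm[axis] = fallback_fwhm_mm if fallback_fwhm_mm else vs[axis]
            continue
        rho = 1.0 - (num / den) / 2.0
        rho = min(max(rho, 1e-6), 1.0 - 1e-6)
        fwhm_vox = math.sqrt(2.0 * math.log(2.0) / (-math.log(rho)))
        fwhm[axis] = max(fwhm_vox, 1.0) * vs[axis]
    return fwhm


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D adjacency footprint: 6 (faces), 18 (faces+edges) or 26 (full cube)."""
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank[connectivity])


def _max_cluster_extent(supra: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    fwhm_mm: np.ndarray | float,
    voxel_sizes_mm: np.ndarray | float = 3.0,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_iter: int = 5000,
    connectivity: int = 18,
    rng: np.random.Generator | int | None = None,
    tails: int = 2,
) -> McThreshold:
    """Simulate the null distribution of maximum cluster extents.

    Each iteration fills the grid with unit Gaussian noise, smooths it to the
    requested FWHM, re-standardizes within the mask, applies the (by default
    two-sided) voxel threshold, and records the largest connected suprathreshold
    cluster over both signs.  The minimum significant extent is the smallest
    integer k for which the null probability of a maximum extent of at least k
    does not exceed ``cluster_alpha`` — the AlphaSim-table convention, which
    guarantees familywise error at or below the nominal level up to simulation
    noise (extents are integers, so the attainable levels are discrete).
    """
    if not (0 < voxel_p < 1 and 0 < cluster_alpha <= 1):
        raise ValueError("voxel_p and cluster_alpha must lie in (0, 1)")
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    mask = np.asarray(mask, bool)
    rng = np.random.default_rng(rng)
    vs = np.broadcast_to(np.asarray(voxel_sizes_mm, float), (3,))
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, float), (3,))
    sigma_vox = fwhm * FWHM_TO_SIGMA / vs
    zcut = stats.norm.ppf(1.0 - voxel_p / tails)
    structure = connectivity_structure(connectivity)

    max_extents = np.empty(n_iter, dtype=np.int64)
    supra_counts = np.empty(n_iter, dtype=np.int64)
    field3d = np.empty(mask.shape)
    for i in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if sigma_vox.max() > 1e-9:
            ndimage.gaussian_filter(noise, sigma=sigma_vox, output=field3d, mode="constant")
        else:
            field3d[...] = noise
        vals = field3d[mask]
        vals = (vals - vals.mean()) / vals.std()
        z = np.zeros(mask.shape)
        z[mask] = vals
        pos = (z > zcut) & mask
        ext = _max_cluster_extent(pos, structure)
        n_supra = int(pos.sum())
        if tails == 2:
            neg = (z < -zcut) & mask
            ext = max(ext, _max_cluster_extent(neg, structure))
            n_supra += int(neg.sum())
        max_extents[i] = ext
        supra_counts[i] = n_supra
    # smallest k with P_null(max extent >= k) <= alpha; FWER <= alpha by design
    exceed = np.bincount(max_extents, minlength=max_extents.max() + 2)[::-1].cumsum()[::-1]
    attained = exceed / n_iter
    extent_threshold = max(1, int(np.argmax(attained <= cluster_alpha)))
    return McThreshold(
        voxel_p=voxel_p,
        cluster_alpha=cluster_alpha,
        n_iter=n_iter,
        estimated_fwhm_mm=np.asarray(fwhm, float),
        extent_threshold=extent_threshold,
        connectivity=connectivity,
        null_max_extents=max_extents,
        null_supra_counts=supra_counts,
    )


def extract_clusters(
    stat: StatMap,
    voxel_p: float = 0.001,
    extent_threshold: int = 1,
    connectivity: int = 18,
) -> pd.DataFrame:
    """Connected components of suprathreshold |t| voxels, by sign.

    The voxel-level p is converted to a two-sided Student-t cutoff at the
    map's df.  All suprathreshold components are listed; ``corrected`` marks
    those meeting the minimum extent.  Peak world coordinates come from the
    affine.  Labels are unique across signs and ordered by descending extent.
    """
    tcut = stats.t.ppf(1.0 - voxel_p / 2.0, stat.df)
    structure = connectivity_structure(connectivity)
    tmap = stat.t.data
    affine = stat.t.affine
    rows = []
    for sign, supra in ((1, tmap > tcut), (-1, tmap < -tcut)):
        supra = supra & np.isfinite(tmap)
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            idx = np.argwhere(labels == lab)
            vals = tmap[tuple(idx.T)]
            peak = idx[np.argmax(np.abs(vals))]
            world = affine @ np.array([*peak, 1.0])
            rows.append(
                dict(
                    sign=sign,
                    extent_vox=len(idx),
                    peak_t=float(tmap[tuple(peak)]),
                    peak_i=int(peak[0]), peak_j=int(peak[1]), peak_k=int(peak[2]),
                    peak_x_mm=float(world[0]), peak_y_mm=float(world[1]),
                    peak_z_mm=float(world[2]),
                    corrected=len(idx) >= extent_threshold,
                    voxels=[tuple(v) for v in idx],
                )
            )
    rows.sort(key=lambda r: -r["extent_vox"])
    for i, r in enumerate(rows, start=1):
        r["label"] = i
    df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS + ["voxels"])
    return df


def cluster_label_map(clusters: pd.DataFrame, grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Integer label volume matching a cluster table (0 = background)."""
    out = np.zeros(grid_shape, dtype=np.int32)
    for _, row in clusters.iterrows():
        for v in row["voxels"]:
            out[v] = int(row["label"])
    return out
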