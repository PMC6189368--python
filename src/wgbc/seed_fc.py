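"""Seed-based resting-state functional connectivity.

Seeds are the significant clusters from the wGBC group comparison (or any
binary mask).  For each subject the seed's mean time series is correlated
with every gray-matter voxel and Fisher z-transformed; group differences in
the z maps are then tested with the same covariate-adjusted GLM and
Monte-Carlo cluster correction as the wGBC maps.  Runs must come from the
FC preprocessing variant (smoothed time series, no global-signal regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gbc import R_CLIP, GrayMask
from .image import BoldRun, ScalarMap
from .inference import (
    DesignMatrix,
    McThreshold,
    StatMap,
    cluster_label_map,
    estimate_smoothness,
    extract_clusters,
    fit_voxelwise_glm,
    monte_carlo_cluster_threshold,
)
from .image import voxel_sizes

__all__ = [
    "SeedMask",
    "FcMap",
    "make_seed_mask",
    "seed_timeseries",
    "compute_fc_map",
    "compare_fc_groups",
]


@dataclass
class SeedMask:
    """Binary seed region with a provenance note (cluster label or file)."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if not self.mask.any():
            raise ValueError("seed mask is empty")


@dataclass
class FcMap:
    """Fisher-z seed-correlation map for one subject; NaN outside the mask."""

    z: ScalarMap


def make_seed_mask(
    clusters: pd.DataFrame, label: int, grid_shape: tuple[int, int, int]
) -> SeedMask:
    """Seed from one corrected-significant cluster-table entry."""
    row = clusters[clusters["label"] == label]
    if row.empty:
        raise KeyError(f"no cluster with label {label}")
    if not bool(row.iloc[0]["corrected"]):
        raise ValueError(f"cluster {label} is not corrected-significant")
    lab_map = cluster_label_map(row, grid_shape)
    return SeedMask(mask=lab_map == label, provenance=f"cluster {label}")


def seed_timeseries(run: BoldRun, seed: SeedMask) -> np.ndarray:
    """Unweighted mean time series over the seed voxels."""
    if seed.mask.shape != run.grid_shape:
        raise ValueError("seed and run grids differ")
    return run.data[seed.mask].mean(axis=0)


def compute_fc_map(run: BoldRun, seed: SeedMask, gray: GrayMask) -> FcMap:
    """Fisher-z correlation between the seed mean series and every masked voxel."""
    s = seed_timeseries(run, seed)
    if s.std() == 0:
        raise ValueError("zero-variance seed time series")
    s = (s - s.mean()) / s.std()
    ts = run.data[gray.mask]  # voxels x time
    mu = ts.mean(axis=1, keepdims=True)
    sd = ts.std(axis=1)
    z_vox = np.zeros_like(ts)
    ok = sd > 0
    z_vox[ok] = (ts[ok] - mu[ok]) / sd[ok, None]
    r = (z_vox @ s) / run.n_volumes
    np.clip(r, -R_CLIP, R_CLIP, out=r)
    out = np.full(run.grid_shape, np.nan)
    out[gray.mask] = np.arctanh(r)
    return FcMap(z=ScalarMap(out, run.affine))


def compare_fc_groups(
    fc_maps: list[FcMap],
    design: DesignMatrix,
    mask: np.ndarray,
    voxel_p: float = 0.001,
    cluster_alpha: float = 0.05,
    n_iter: int = 5000,
    connectivity: int = 18,
    rng: np.random.Generator | int | None = None,
) -> tuple[StatMap, pd.DataFrame, McThreshold]:
    """Covariate-adjusted group comparison of seed-FC z maps.

    Delegates to the voxelwise GLM and Monte-Carlo cluster-extent machinery
    at identical thresholds to the wGBC comparison.
    """
    maps = [m.z for m in fc_maps]
    stat = fit_voxelwise_glm(maps, design, mask)
    vs = voxel_sizes(maps[0].affine)
    fwhm = estimate_smoothness(stat.residual_maps, stat.mask, vs, fallback_fwhm_mm=6.0)
    mc = monte_carlo_cluster_threshold(
        stat.mask, fwhm, vs, voxel_p=voxel_p, cluster_alpha=cluster_alpha,
        n_iter=n_iter, connectivity=connectivity, rng=rng,
    )
    clusters = extract_clusters(stat, voxel_p, mc.extent_threshold, connectivity)
    return stat, clusters, mc
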