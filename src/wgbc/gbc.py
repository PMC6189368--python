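"""Voxel-wise weighted global brain connectivity (wGBC).

For every seed voxel inside a gray-matter mask, the Pearson correlation with
every other masked voxel is computed, Fisher z-transformed
(``z = atanh(r)``), averaged with sign, and transformed back to an r value.
The result is a weighted, unthresholded degree-centrality-like map: voxels
that correlate — positively or negatively — with much of the brain get large
|wGBC|.  No correlation threshold is applied, so many weak connections
contribute, unlike unweighted (thresholded) GBC.

The correlation matrix is never materialized in full: seeds are processed in
blocks against the standardized data matrix, keeping memory at
O(voxels * timepoints + block * voxels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image import BoldRun, ScalarMap
from .preprocess import _smooth3d

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7  # keeps atanh finite at |r| = 1

__all__ = ["GrayMask", "WgbcMap", "make_gray_mask", "compute_wgbc_map", "smooth_wgbc"]


@dataclass
class GrayMask:
    """Boolean gray-matter mask derived from a tissue-probability map by a
    strict ``prob > threshold`` rule."""

    prob: np.ndarray
    threshold: float
    mask: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class WgbcMap:
    """Per-voxel average-connectivity map; NaN outside the gray mask."""

    values: ScalarMap
    n_targets: int


def make_gray_mask(prob: np.ndarray, threshold: float = 0.2) -> GrayMask:
    """Threshold a gray-matter probability map (strictly greater-than)."""
    prob = np.asarray(prob, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = prob > threshold
    if not mask.any():
        raise ValueError(f"gray mask empty at threshold {threshold}")
    logger.info("gray mask: %d voxels at prob > %g", int(mask.sum()), threshold)
    return GrayMask(prob=prob, threshold=float(threshold), mask=mask)


def _standardize_columns(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each column; returns (zscored, nonzero-variance flags)."""
    mu = ts.mean(axis=0)
    sd = ts.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(ts)
    z[:, ok] = (ts[:, ok] - mu[ok]) / sd[ok]
    return z, ok


def compute_wgbc_map(
    run: BoldRun,
    gray: GrayMask,
    targets: str = "gray",
    block_size: int = 512,
) -> WgbcMap:
    """Compute the weighted global brain connectivity map.

    Parameters
    ----------
    run:
        Preprocessed BOLD run (connectivity-mapping variant).
    gray:
        Gray-matter mask; seeds are its voxels.
    targets:
        ``"gray"`` (default) correlates each seed against the other masked
        voxels; ``"wholebrain"`` against every finite-variance voxel in the
        grid.  Self-correlations are always excluded.

    Values are ``tanh(mean_j atanh(clip(r_ij)))`` and lie strictly in (-1, 1).
    """
    if run.grid_shape != gray.mask.shape:
        raise ValueError("run and mask grids differ")
    if run.n_volumes < 3:
        raise ValueError("need at least 3 time points")
    if targets not in ("gray", "wholebrain"):
        raise ValueError("targets must be 'gray' or 'wholebrain'")

    T = run.n_volumes
    ts_all = run.data.reshape(-1, T).T  # time x allvoxels
    seed_flat = np.flatnonzero(gray.mask.ravel())
    if targets == "gray":
        target_flat = seed_flat
    else:
        target_flat = np.arange(ts_all.shape[1])

    z_t, ok_t = _standardize_columns(ts_all[:, target_flat])
    n_dropped = int((~ok_t).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance voxels from targets", n_dropped)
    target_flat = target_flat[ok_t]
    z_t = z_t[:, ok_t]

    seed_keep = np.isin(seed_flat, target_flat) if targets == "gray" else None
    if targets == "gray":
        seed_flat = seed_flat[seed_keep]
        z_s = z_t  # identical voxel set and ordering
    else:
        z_s, ok_s = _standardize_columns(ts_all[:, seed_flat])
        seed_flat = seed_flat[ok_s]
        z_s = z_s[:, ok_s]

    n_seeds, n_targets_tot = len(seed_flat), z_t.shape[1]
    if n_seeds < 2 or n_targets_tot < 2:
        raise ValueError("fewer than 2 usable voxels")

    # Map each seed to its own column in the target set (to exclude self).
    self_col = np.searchsorted(target_flat, seed_flat)
    is_self = target_flat[np.clip(self_col, 0, n_targets_tot - 1)] == seed_flat

    out = np.full(run.grid_shape, np.nan).ravel()
    z_self = np.arctanh(R_CLIP)
    for start in range(0, n_seeds, block_size):
        blk = slice(start, min(start + block_size, n_seeds))
        r = (z_s[:, blk].T @ z_t) / T
        np.clip(r, -R_CLIP, R_CLIP, out=r)
        zsum = np.arctanh(r).sum(axis=1)
        n_tgt = np.full(blk.stop - blk.start, n_targets_tot, dtype=float)
        sc = self_col[blk]
        has_self = is_self[blk]
        zsum[has_self] -= z_self
        n_tgt[has_self] -= 1
        out[seed_flat[blk]] = np.tanh(zsum / n_tgt)
    return WgbcMap(
        values=ScalarMap(out.reshape(run.grid_shape), run.affine),
        n_targets=n_targets_tot - 1,
    )


def smooth_wgbc(wmap: WgbcMap, fwhm_mm: float = 6.0) -> WgbcMap:
    """Mask-normalized Gaussian smoothing of a wGBC map.

    Values outside the mask (NaN) carry no weight, so the missing region does
    not bleed into the masked interior; the output support equals the input's.
    """
    if fwhm_mm <= 0:
        return wmap
    smap = wmap.values
    defined = smap.defined_mask()
    filled = np.where(defined, smap.data, 0.0)
    num = _smooth3d(filled, smap.affine, fwhm_mm)
    den = _smooth3d(defined.astype(float), smap.affine, fwhm_mm)
    out = np.full(smap.data.shape, np.nan)
    inside = den > 1e-12
    np.divide(num, den, out=out, where=inside & defined)
    out[~defined] = np.nan
    return WgbcMap(values=ScalarMap(out, smap.affine), n_targets=wmap.n_targets)
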