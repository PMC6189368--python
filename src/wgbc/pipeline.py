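"""End-to-end study orchestration.

:func:`run_study` executes the full replica on a configured cohort:
demographics table -> motion screening -> both preprocessing variants ->
wGBC maps -> one-sample distribution maps -> covariate-adjusted group
comparison with Monte-Carlo cluster correction -> seed FC from each
significant cluster -> FC group comparison -> symptom correlations.  Every
numeric constant comes from :class:`StudyConfig`; the merged config, the
seed, package versions and per-stage output checksums are written to a
manifest so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import correlate_with_symptoms, summarize_cohort
from .gbc import compute_wgbc_map, make_gray_mask, smooth_wgbc
from .image import (
    BoldRun,
    MotionTrace,
    ScalarMap,
    load_map,
    load_motion_trace,
    save_map,
    voxel_sizes,
)
from .inference import (
    cluster_label_map,
    estimate_smoothness,
    extract_clusters,
    fit_voxelwise_glm,
    make_design_matrix,
    monte_carlo_cluster_threshold,
    one_sample_tmap,
)
from .preprocess import exceeds_motion_limits, preprocess_for_fc, preprocess_for_wgbc
from .seed_fc import SeedMask, compare_fc_groups, compute_fc_map
from .synthetic import CohortSpec, EffectRegion, HubRegion, SyntheticCohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study", "load_cohort_from_paths"]


@dataclass
class StudyConfig:
    """All analysis parameters with the study's defaults, plus the input
    source (a synthetic cohort spec, or paths to runs/motion/masks/table)."""

    synthetic: CohortSpec | None = None
    paths: dict | None = None
    n_discard: int = 10
    fd_threshold_mm: float = 0.5
    motion_limit_trans_mm: float = 1.5
    motion_limit_rot_deg: float = 1.5
    band_hz: tuple[float, float] = (0.01, 0.1)
    gm_threshold: float = 0.2
    smoothing_fwhm_mm: float = 6.0
    voxel_p: float = 0.001
    cluster_alpha: float = 0.05
    mc_iters: int = 5000
    connectivity: int = 18
    min_volumes: int = 50
    wgbc_targets: str = "gray"
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        syn = d.get("synthetic")
        if syn is not None:
            syn = dict(syn)
            syn["grid_shape"] = tuple(syn["grid_shape"])
            syn["hub_regions"] = [
                HubRegion(tuple(h["center"]), h["radius"], h["coupling"])
                for h in syn.get("hub_regions", [])
            ]
            syn["group_effect_regions"] = [
                EffectRegion(tuple(e["center"]), e["radius"], e["delta"], e.get("sign", 1))
                for e in syn.get("group_effect_regions", [])
            ]
            d["synthetic"] = CohortSpec(**syn)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_cohort_from_paths(paths: dict, tr: float) -> SyntheticCohort:
    """Assemble a cohort container from on-disk inputs (NIfTI runs, SPM
    rp-dialect motion text, tissue maps, subject TSV)."""
    subjects = pd.read_csv(paths["subjects"], sep="\t")
    runs = [
        BoldRun.load(p, subject_id=str(sid), tr=tr)
        for p, sid in zip(paths["runs"], subjects["subject_id"])
    ]
    motion = [load_motion_trace(p) for p in paths["motion"]]
    gray = load_map(paths["gray"])
    wm = load_map(paths["wm"]).data > 0.5
    csf = load_map(paths["csf"]).data > 0.5
    return SyntheticCohort(
        runs=runs, motion=motion, gray_prob=gray, wm_mask=wm, csf_mask=csf,
        subjects=subjects, truth={}, spec=None,
    )


def _sha(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _cluster_table_for_disk(clusters: pd.DataFrame) -> pd.DataFrame:
    return clusters.drop(columns=["voxels"])


def run_study(config: StudyConfig, out_dir) -> dict:
    """Run the full pipeline; returns a results dictionary and writes the
    standard artifact set (maps, tables, manifest) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    checksums: dict[str, str] = {}
    stage = "load-inputs"
    try:
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
        elif config.paths is not None:
            cohort = load_cohort_from_paths(config.paths, tr=2.0)
        else:
            raise ValueError("config needs either a synthetic spec or input paths")

        stage = "demographics"
        table1 = summarize_cohort(cohort.subjects)
        table1.to_csv(out / "table1.tsv", sep="\t", index=False)

        stage = "motion-screening"
        keep_rows = []
        for i, (run, trace) in enumerate(zip(cohort.runs, cohort.motion)):
            if exceeds_motion_limits(
                trace, config.motion_limit_trans_mm, config.motion_limit_rot_deg
            ):
                logger.warning("excluding %s: motion limits exceeded", run.subject_id)
            else:
                keep_rows.append(i)
        subjects = cohort.subjects.iloc[keep_rows].reset_index(drop=True)

        stage = "gray-mask"
        gray = make_gray_mask(cohort.gray_prob.data, config.gm_threshold)
        vs = voxel_sizes(cohort.affine)

        wgbc_maps, fc_runs = [], []
        for i in keep_rows:
            run, trace = cohort.runs[i], cohort.motion[i]
            stage = f"preprocess[{run.subject_id}]"
            clean, _ = preprocess_for_wgbc(
                run, trace, cohort.wm_mask, cohort.csf_mask,
                n_discard=config.n_discard, fd_threshold=config.fd_threshold_mm,
                band=config.band_hz, min_volumes=config.min_volumes,
            )
            stage = f"wgbc[{run.subject_id}]"
            wmap = compute_wgbc_map(clean, gray, targets=config.wgbc_targets)
            wgbc_maps.append(smooth_wgbc(wmap, config.smoothing_fwhm_mm).values)
            stage = f"preprocess-fc[{run.subject_id}]"
            fc_clean, _ = preprocess_for_fc(
                run, trace, cohort.wm_mask, cohort.csf_mask,
                n_discard=config.n_discard, fd_threshold=config.fd_threshold_mm,
                band=config.band_hz, smooth_fwhm_mm=config.smoothing_fwhm_mm,
                min_volumes=config.min_volumes,
            )
            fc_runs.append(fc_clean)

        stage = "one-sample-maps"
        for g, tag in ((0, "group_a"), (1, "group_b")):
            sel = [m for m, grp in zip(wgbc_maps, subjects["group"]) if grp == g]
            if len(sel) >= 3:
                stat_g = one_sample_tmap(sel, gray.mask)
                save_map(stat_g.t, out / f"wgbc_onesample_{tag}_t.nii.gz")
                checksums[f"onesample_{tag}"] = _sha(stat_g.t.data)

        stage = "wgbc-group-glm"
        design = make_design_matrix(subjects)
        stat = fit_voxelwise_glm(wgbc_maps, design, gray.mask)
        fwhm = estimate_smoothness(
            stat.residual_maps, stat.mask, vs, fallback_fwhm_mm=config.smoothing_fwhm_mm
        )
        stage = "monte-carlo"
        mc = monte_carlo_cluster_threshold(
            gray.mask, fwhm, vs, voxel_p=config.voxel_p,
            cluster_alpha=config.cluster_alpha, n_iter=config.mc_iters,
            connectivity=config.connectivity, rng=config.rng_seed,
        )
        stage = "wgbc-clusters"
        clusters = extract_clusters(stat, config.voxel_p, mc.extent_threshold, config.connectivity)
        save_map(stat.t, out / "wgbc_group_t.nii.gz")
        _cluster_table_for_disk(clusters).to_csv(out / "wgbc_clusters.tsv", sep="\t", index=False)
        label_map = cluster_label_map(clusters[clusters["corrected"]], gray.mask.shape)
        save_map(ScalarMap(label_map.astype(float), cohort.affine), out / "wgbc_cluster_labels.nii.gz")
        checksums["wgbc_group_t"] = _sha(stat.t.data)

        significant = clusters[clusters["corrected"]]
        fc_results = {}
        symptom_rows = []
        scores = subjects.loc[subjects["group"] == 0, "symptom_score"].to_numpy(float)
        for _, row in significant.iterrows():
            label = int(row["label"])
            stage = f"seed-fc[cluster {label}]"
            seed = SeedMask(label_map == label, provenance=f"cluster {label}")
            fc_maps = [compute_fc_map(r, seed, gray) for r in fc_runs]
            fc_stat, fc_clusters, _ = compare_fc_groups(
                fc_maps, design, gray.mask, voxel_p=config.voxel_p,
                cluster_alpha=config.cluster_alpha, n_iter=config.mc_iters,
                connectivity=config.connectivity, rng=config.rng_seed + label,
            )
            save_map(fc_stat.t, out / f"fc_cluster{label}_group_t.nii.gz")
            _cluster_table_for_disk(fc_clusters).to_csv(
                out / f"fc_cluster{label}_clusters.tsv", sep="\t", index=False
            )
            fc_results[label] = fc_clusters
            stage = f"symptom-correlation[cluster {label}]"
            means_a = [
                float(np.nanmean(m.data[seed.mask]))
                for m, grp in zip(wgbc_maps, subjects["group"]) if grp == 0
            ]
            if np.isfinite(scores).sum() >= 4:
                res = correlate_with_symptoms(means_a, scores)
                symptom_rows.append(
                    dict(cluster=label, r=res.statistic, df=res.df, p=res.p_value)
                )
        if symptom_rows:
            pd.DataFrame(symptom_rows).to_csv(out / "symptom_correlations.tsv", sep="\t", index=False)

        stage = "manifest"
        config.to_yaml(out / "config.yaml")
        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "seed": config.rng_seed,
            "n_subjects_analyzed": len(subjects),
            "n_excluded_motion": len(cohort.runs) - len(keep_rows),
            "estimated_fwhm_mm": [float(f) for f in fwhm],
            "extent_threshold_vox": int(mc.extent_threshold),
            "n_significant_clusters": int(significant.shape[0]),
            "checksums": checksums,
            "elapsed_s": round(time.time() - t0, 2),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err

    return {
        "subjects": subjects,
        "table1": table1,
        "gray": gray,
        "wgbc_maps": wgbc_maps,
        "stat": stat,
        "mc": mc,
        "clusters": clusters,
        "fc_results": fc_results,
        "symptom_correlations": pd.DataFrame(symptom_rows) if symptom_rows else None,
        "manifest": manifest,
    }
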