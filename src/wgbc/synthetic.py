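"""Synthetic two-group resting-state fMRI cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage is testable without real scans:

* each *hub region* (a sphere of voxels) shares one latent band-limited
  (0.01-0.08 Hz) signal; a voxel with coupling ``c`` has series
  ``sqrt(c) * latent + sqrt(1 - c) * AR(1) noise``, all unit variance;
* the hub latents are also mixed, at a lower total coupling, into a fixed
  fraction of non-hub gray-matter voxels ("carriers"), so hub voxels have
  elevated expected mean correlation with the rest of the brain — the
  property the wGBC statistic measures;
* *group effect regions* add a coupling delta for group-B subjects only,
  planting a known between-group difference for recovery tests;
* head motion is a scaled random walk on the six rigid-body parameters with
  optional injected spike frames at known indices;
* demographics are drawn to match a depressed-vs-control cohort: group sizes
  23/34, ages ~30 +/- 7 years, education 13-14 years, symptom scores
  (group A only) ~34 +/- 8, and the 9/14 and 15/19 male/female splits.

The anatomy is a radial gray-matter probability gradient (1 at the grid
center falling to 0 at the edge) with white-matter and CSF shells outside the
gray core; the gray mask rule ``prob > 0.2`` is therefore exercised
nontrivially.  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .image import BoldRun, MotionTrace, ScalarMap, save_map, save_motion_trace

__all__ = [
    "HubRegion",
    "EffectRegion",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_motion_trace",
    "generate_subject_table",
    "write_cohort",
    "demo_spec",
]

# Table-1-style demographic parameters (mean, sd) used for the two groups.
DEMOGRAPHICS = {
    "age": {"a": (30.48, 7.13), "b": (29.71, 7.09)},
    "education": {"a": (13.35, 3.89), "b": (14.18, 2.17)},
    "symptom": {"a": (34.30, 7.58)},
}
# male counts for the canonical 23/34 cohort (sex encoded 0 = female, 1 = male)
SEX_SPLITS = {23: 9, 34: 15}
N_NUISANCE_REGRESSORS = 9  # 6 motion + WM + CSF + global


@dataclass(frozen=True)
class HubRegion:
    """A sphere of voxels sharing one latent signal at the given coupling
    (the fraction of each member voxel's variance carried by the latent)."""

    center: tuple[int, int, int]
    radius: float
    coupling: float


@dataclass(frozen=True)
class EffectRegion:
    """A sphere where group-B subjects get ``sign * delta`` added to the
    voxel coupling, planting a between-group connectivity difference."""

    center: tuple[int, int, int]
    radius: float
    delta: float
    sign: int = 1


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the defaults are the desk-scale
    study conditions (20-voxel cube, 160 volumes at TR 2 s, one strong hub)."""

    n_group_a: int = 23
    n_group_b: int = 34
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    n_volumes: int = 160
    tr_seconds: float = 2.0
    hub_regions: list[HubRegion] = field(
        default_factory=lambda: [HubRegion((7, 9, 10), 3.0, 0.6)]
    )
    group_effect_regions: list[EffectRegion] = field(default_factory=list)
    noise_ar1: float = 0.3
    motion_magnitude_mm: float = 0.08
    carrier_fraction: float = 0.30
    carrier_coupling: float = 0.15
    global_signal_strength: float = 0.1
    voxel_size_mm: float = 3.0
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.n_group_a, self.n_group_b) < 0 or self.n_group_a + self.n_group_b == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_volumes <= N_NUISANCE_REGRESSORS + 10:
            raise ValueError(
                f"n_volumes must exceed {N_NUISANCE_REGRESSORS + 10}"
            )
        if not (0 <= self.noise_ar1 < 1):
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if self.motion_magnitude_mm < 0:
            raise ValueError("motion magnitude must be non-negative")
        if not (0 <= self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must lie in [0, 1]")
        if not (0 <= self.global_signal_strength < 1):
            raise ValueError("global_signal_strength must lie in [0, 1)")
        ext = np.asarray(self.grid_shape)
        for region in [*self.hub_regions, *self.group_effect_regions]:
            c = np.asarray(region.center, float)
            if ((c - region.radius) < 0).any() or ((c + region.radius) > ext - 1).any():
                raise ValueError(f"region {region} does not fit inside the grid")
        for hub in self.hub_regions:
            if not (0 <= hub.coupling < 1):
                raise ValueError("hub couplings must lie in [0, 1)")
        for eff in self.group_effect_regions:
            if eff.sign not in (-1, 1):
                raise ValueError("effect sign must be +1 or -1")


@dataclass
class SyntheticCohort:
    """One generated cohort: runs, motion, anatomy, demographics and the
    planted ground truth (hub / effect / carrier masks)."""

    runs: list[BoldRun]
    motion: list[MotionTrace]
    gray_prob: ScalarMap
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    subjects: pd.DataFrame
    truth: dict
    spec: CohortSpec

    @property
    def affine(self) -> np.ndarray:
        return self.gray_prob.affine


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _anatomy(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Radial gray-probability gradient plus WM and CSF shells."""
    shape = spec.grid_shape
    center = (np.asarray(shape) - 1) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    r0 = 0.5 * min(shape)
    prob = np.clip(1.0 - r / r0, 0.0, 1.0)
    wm = (r >= 0.8 * r0) & (r < 0.9 * r0)
    csf = (r >= 0.9 * r0) & (r < r0)
    return prob, wm, csf


def _affine(spec: CohortSpec) -> np.ndarray:
    aff = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -spec.voxel_size_mm * (np.asarray(spec.grid_shape) - 1) / 2.0
    return aff


def _bandlimited_latent(
    rng: np.random.Generator, n: int, tr: float, low: float = 0.01, high: float = 0.08
) -> np.ndarray:
    """Unit-variance signal with flat spectral power confined to [low, high] Hz."""
    freqs = np.fft.rfftfreq(n, d=tr)
    band = (freqs >= low) & (freqs <= high)
    spectrum = np.zeros(len(freqs), dtype=complex)
    k = int(band.sum())
    if k == 0:
        raise ValueError("no Fourier bins in the requested band; increase n_volumes")
    spectrum[band] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) noise, time on axis 0; white when phi=0."""
    e = rng.standard_normal(shape)
    if phi == 0:
        return e
    e = e * np.sqrt(1.0 - phi**2)
    e[0] /= np.sqrt(1.0 - phi**2)  # exact stationary start
    return signal.lfilter([1.0], [1.0, -phi], e, axis=0)


def _coupling_matrix(
    spec: CohortSpec, gray_mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Variance-coupling weights (voxels x hubs) for group A, plus truth masks."""
    shape = spec.grid_shape
    n_vox = int(np.prod(shape))
    k = len(spec.hub_regions)
    C = np.zeros((n_vox, max(k, 1)))
    hub_masks = []
    hub_union = np.zeros(shape, bool)
    for j, hub in enumerate(spec.hub_regions):
        m = _sphere_mask(shape, hub.center, hub.radius) & gray_mask
        hub_masks.append(m)
        hub_union |= m
        C[m.ravel(), j] = hub.coupling
    candidates = np.flatnonzero((gray_mask & ~hub_union).ravel())
    n_carriers = int(round(spec.carrier_fraction * len(candidates)))
    carrier_idx = rng.choice(candidates, size=n_carriers, replace=False) if n_carriers else np.array([], int)
    carrier_mask = np.zeros(shape, bool)
    carrier_mask.ravel()[carrier_idx] = True
    if k > 0 and n_carriers:
        C[carrier_idx, :k] = spec.carrier_coupling / k
    truth = {
        "hub_masks": hub_masks,
        "hub_mask": hub_union,
        "carrier_mask": carrier_mask,
        "effect_masks": [],
        "effect_signs": [],
    }
    return C, truth


def _apply_effects(
    spec: CohortSpec, C: np.ndarray, gray_mask: np.ndarray, truth: dict
) -> np.ndarray:
    """Group-B coupling matrix: effect deltas added to each voxel's dominant
    latent (its own hub if it has one, else the nearest hub's latent)."""
    Cb = C.copy()
    shape = spec.grid_shape
    centers = np.array([h.center for h in spec.hub_regions], float)
    for eff in spec.group_effect_regions:
        m = _sphere_mask(shape, eff.center, eff.radius) & gray_mask
        truth["effect_masks"].append(m)
        truth["effect_signs"].append(eff.sign)
        idx = np.flatnonzero(m.ravel())
        for v in idx:
            row = Cb[v]
            if row.max() > 0:
                j = int(np.argmax(row))
            else:
                vox = np.unravel_index(v, shape)
                j = int(np.argmin(((centers - np.asarray(vox)) ** 2).sum(axis=1)))
            row[j] = row[j] + eff.sign * eff.delta
    if Cb.min() < 0 or (Cb.sum(axis=1) >= 1).any() or (C.sum(axis=1) >= 1).any():
        raise ValueError("couplings (including group deltas) must stay within [0, 1)")
    return Cb


def generate_motion_trace(
    n_volumes: int,
    magnitude_mm: float,
    rng_seed: int | np.random.Generator,
    spike_indices: list[int] | None = None,
    spike_mm: float = 1.2,
) -> MotionTrace:
    """Random-walk six-parameter motion trace with median FD ~ ``magnitude_mm``.

    Spikes are persistent position steps of total translation ``spike_mm``,
    so FD exceeds the scrubbing threshold at exactly the requested indices
    (a one-frame offset would also trip the following frame).
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = np.random.default_rng(rng_seed)
    params = np.zeros((n_volumes, 6))
    if magnitude_mm > 0:
        steps = rng.standard_normal((n_volumes - 1, 6))
        steps[:, 3:] /= 50.0  # rotations contribute via the 50 mm lever arm
        walk = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
        fd = np.abs(np.diff(walk[:, :3], axis=0)).sum(axis=1) + 50.0 * np.abs(
            np.diff(walk[:, 3:], axis=0)
        ).sum(axis=1)
        med = np.median(fd)
        if med > 0:
            params = walk * (magnitude_mm / med)
    for idx in spike_indices or []:
        if not 1 <= idx < n_volumes:
            raise ValueError("spike indices must lie in [1, n_volumes)")
        params[idx:, :3] += spike_mm / 3.0
    return MotionTrace(params)


def generate_subject_table(spec: CohortSpec, rng_seed: int | None = None) -> pd.DataFrame:
    """Cohort demographics table.

    Ages and education are normal draws per group with the group means/SDs
    above; symptom scores exist for group A only.  For group sizes 23/34 the
    male counts are exactly 9 and 15; otherwise proportional.  Sex is encoded
    0 = female, 1 = male; group 0 = A (patients), 1 = B (controls).
    """
    rng = np.random.default_rng(spec.rng_seed if rng_seed is None else rng_seed)
    rows = []
    for group_label, letter, n in ((0, "a", spec.n_group_a), (1, "b", spec.n_group_b)):
        if n == 0:
            continue
        n_male = SEX_SPLITS.get(n) if n in SEX_SPLITS and spec.n_group_a + spec.n_group_b == 57 else None
        if n_male is None:
            frac = SEX_SPLITS[23] / 23 if letter == "a" else SEX_SPLITS[34] / 34
            n_male = int(round(n * frac))
        sexes = np.zeros(n, int)
        sexes[:n_male] = 1
        sexes = rng.permutation(sexes)
        age_m, age_s = DEMOGRAPHICS["age"][letter]
        edu_m, edu_s = DEMOGRAPHICS["education"][letter]
        ages = rng.normal(age_m, age_s, n)
        edus = rng.normal(edu_m, edu_s, n)
        if letter == "a":
            sym_m, sym_s = DEMOGRAPHICS["symptom"]["a"]
            symptoms = rng.normal(sym_m, sym_s, n)
        else:
            symptoms = np.full(n, np.nan)
        for i in range(n):
            rows.append(
                dict(
                    subject_id=f"sub-{letter}{i + 1:02d}",
                    group=group_label,
                    age=round(float(ages[i]), 2),
                    sex=int(sexes[i]),
                    education=round(float(edus[i]), 2),
                    symptom_score=round(float(symptoms[i]), 2) if letter == "a" else np.nan,
                )
            )
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "age", "sex", "education", "symptom_score"]
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full synthetic cohort described by ``spec``.

    Deterministic: the same spec (including its seed) yields bit-identical
    output, including NIfTI bytes after writing.
    """
    spec.validate()
    seeds = np.random.SeedSequence(spec.rng_seed).spawn(4)
    structure_rng = np.random.default_rng(seeds[0])
    gray_prob, wm, csf = _anatomy(spec)
    gray_mask = gray_prob > 0.2
    C_a, truth = _coupling_matrix(spec, gray_mask, structure_rng)
    C_b = _apply_effects(spec, C_a, gray_mask, truth)
    amp = {0: np.sqrt(C_a), 1: np.sqrt(C_b)}
    noise_w = {g: np.sqrt(1.0 - (amp[g] ** 2).sum(axis=1)) for g in (0, 1)}

    table_seed = int(np.random.default_rng(seeds[1]).integers(2**31))
    subjects = generate_subject_table(spec, rng_seed=table_seed)

    affine = _affine(spec)
    k = max(len(spec.hub_regions), 1)
    run_seed_root, motion_seed_root = seeds[2], seeds[3]
    run_seeds = run_seed_root.spawn(len(subjects))
    motion_seeds = motion_seed_root.spawn(len(subjects))
    runs, motion = [], []
    t, n_vox = spec.n_volumes, int(np.prod(spec.grid_shape))
    for i, row in subjects.iterrows():
        rng = np.random.default_rng(run_seeds[i])
        latents = np.column_stack(
            [_bandlimited_latent(rng, t, spec.tr_seconds) for _ in range(k)]
        )
        noise = _ar1_noise(rng, (t, n_vox), spec.noise_ar1)
        g = int(row["group"])
        data = latents @ amp[g].T + noise * noise_w[g]
        gs = spec.global_signal_strength
        if gs > 0:
            # brain-wide physiological/scanner component shared by every
            # voxel — the signal global-signal regression exists to remove
            global_sig = _bandlimited_latent(rng, t, spec.tr_seconds, low=0.005, high=0.1)
            data = np.sqrt(gs) * global_sig[:, None] + np.sqrt(1.0 - gs) * data
        data = 10.0 * data + 1000.0  # arbitrary BOLD-like scale and offset
        runs.append(
            BoldRun(
                data=np.ascontiguousarray(data.T.reshape(*spec.grid_shape, t)),
                affine=affine,
                tr=spec.tr_seconds,
                subject_id=str(row["subject_id"]),
            )
        )
        motion.append(
            generate_motion_trace(
                t, spec.motion_magnitude_mm, np.random.default_rng(motion_seeds[i])
            )
        )
    return SyntheticCohort(
        runs=runs,
        motion=motion,
        gray_prob=ScalarMap(gray_prob, affine),
        wm_mask=wm,
        csf_mask=csf,
        subjects=subjects,
        truth=truth,
        spec=spec,
    )


def demo_spec(
    effect: bool = False,
    n_per_group: int = 12,
    grid: int = 16,
    n_volumes: int = 160,
    seed: int = 0,
    delta: float = 0.4,
) -> CohortSpec:
    """Desk-scale two-hub cohort used by the examples and recovery studies.

    One strong hub (coupling 0.6) and one weak hub (0.2); with ``effect=True``
    the weak hub gains ``delta`` coupling in group B, the planted group
    difference the pipeline should recover.
    """
    c = grid // 2
    hub = HubRegion((c - 3, c, c + 1), 2.5, 0.6)
    weak = HubRegion((c + 2, c + 1, c - 1), 2.5, 0.2)
    effects = [EffectRegion(weak.center, weak.radius, delta, +1)] if effect else []
    return CohortSpec(
        n_group_a=n_per_group,
        n_group_b=n_per_group,
        grid_shape=(grid, grid, grid),
        n_volumes=n_volumes,
        hub_regions=[hub, weak],
        group_effect_regions=effects,
        rng_seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write the cohort to disk in its interchange formats.

    Runs as NIfTI-1, motion as 6-column SPM ``rp_*.txt`` text, anatomy as
    NIfTI, demographics as TSV, truth masks as NIfTI.  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"runs": [], "motion": []}
    for run, trace in zip(cohort.runs, cohort.motion):
        rp = out / f"rp_{run.subject_id}.txt"
        np.savetxt(rp, trace.params, fmt="%.10e")
        nii = out / f"{run.subject_id}_bold.nii.gz"
        run.save(nii)
        paths["runs"].append(nii)
        paths["motion"].append(rp)
    save_map(cohort.gray_prob, out / "gray_prob.nii.gz")
    aff = cohort.affine
    save_map(ScalarMap(cohort.wm_mask.astype(float), aff), out / "wm_mask.nii.gz")
    save_map(ScalarMap(cohort.csf_mask.astype(float), aff), out / "csf_mask.nii.gz")
    save_map(ScalarMap(cohort.truth["hub_mask"].astype(float), aff), out / "truth_hubs.nii.gz")
    for i, m in enumerate(cohort.truth["effect_masks"]):
        save_map(ScalarMap(m.astype(float), aff), out / f"truth_effect_{i}.nii.gz")
    cohort.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    paths.update(
        gray=out / "gray_prob.nii.gz", wm=out / "wm_mask.nii.gz",
        csf=out / "csf_mask.nii.gz", subjects=out / "subjects.tsv",
    )
    return paths


def save_motion(trace: MotionTrace, path) -> None:  # pragma: no cover - thin alias
    save_motion_trace(trace, path)
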