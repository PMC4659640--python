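"""Seeded synthetic study generator.

Builds a complete toy study — occipital parcellation, unilateral
lesions, paired perimetry exams, clinical covariates and improvement
outcomes — with the statistical structure the analysis assumes, so the
full pipeline runs without any external data.

What is emulated
----------------
* A nine-region occipital/medial-temporal parcellation per hemisphere
  (block-shaped stand-ins for the atlas gyri).
* Unilateral posterior-territory lesions concentrated in the lingual,
  calcarine and cuneus regions, with regionally correlated extent
  driven by a per-patient severity factor.
* Baseline visual-field severity that worsens with calcarine/lingual
  (upper quadrant) and calcarine/cuneus (lower quadrant) involvement.
* Relative improvement (%VFS) generated by a linear-Gaussian model
  whose signs match the observed associations: improvement decreases
  with calcarine/lingual/cuneus rEIL and with a longer onset-to-MR
  interval, and increases with left-sided lesions.
* Covariate prevalences near the study cohort (80 % male, ~51 % left
  PCA, mean onset-to-MR time ~37 h with a right-skewed distribution).

The linear-Gaussian outcome model is a deliberately simple stand-in,
not an estimate of the true data-generating process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import perimetry
from .exceptions import ConfigurationError, SchemaError
from .lesion_quant import (
    HEMISPHERES,
    LesionMask,
    Parcellation,
    REGION_NAMES,
    compute_reil,
    lesion_volume_ml,
)

#: Atlas-space voxel size of the toy grid (mm).
ATLAS_VOXEL_DIMS = (2.0, 2.0, 2.0)

#: Native DWI voxel size: in-plane resolution with a 5 mm slice plus
#: 2 mm inter-slice gap folded into dz.
NATIVE_VOXEL_DIMS = (0.651, 0.651, 7.0)

#: Covariate prevalences / moments the generator targets (study cohort).
PREVALENCES = {
    "male": 0.80,
    "left_pca": 18 / 35,
    "hypertension": 24 / 35,
    "diabetes": 13 / 35,
    "hyperlipidemia": 15 / 35,
    "smoking": 16 / 35,
    "atrial_fibrillation": 8 / 35,
}
AGE_MEAN, AGE_SD = 61.6, 11.0
MR_TIME_SHAPE, MR_TIME_SCALE = 1.4, 26.6  # gamma, mean ~37 h, right-skewed

#: Mean fraction of each region a median-severity lesion covers, derived
#: from the cohort-level mean rEILs (lingual 33 %, calcarine 25 %,
#: fusiform 21 %, cuneus 15 %, tapering through the remaining regions).
REGION_BASE_FRACTION = {
    "lingual": 0.48,
    "calcarine": 0.36,
    "fusiform": 0.30,
    "cuneus": 0.22,
    "inferior_occipital": 0.20,
    "parahippocampal": 0.15,
    "hippocampus": 0.12,
    "superior_occipital": 0.10,
    "middle_occipital": 0.085,
}

#: Spread of the shared severity factor (beta) and of the per-region
#: multipliers (log-normal sigma).  Between-region variation dominates
#: the shared factor, mirroring the observed dispersion of regional
#: involvement and the comparatively weak association of total lesion
#: volume with outcome.
SEVERITY_BETA = (4.0, 4.0)
REGION_LOGNORMAL_SIGMA = 0.8


@dataclass(frozen=True)
class EffectModel:
    """Linear-Gaussian model for quadrant %VFS.

    %VFS = intercept + b_calcarine*rEIL_cal + b_lingual*rEIL_ling
           + b_cuneus*rEIL_cun + c_left*1[left PCA] + c_mrtime*MR_time_h
           + N(0, noise_sd),

    applied to both affected quadrants with independent noise.  The
    default coefficient signs match the observed directions: regional
    involvement and a longer onset-to-imaging interval reduce
    improvement; left-sided lesions improve more.  Baseline quadrant
    VFS (dB) is -(baseline_intercept + baseline_coef * driving rEILs)
    plus Gaussian noise, clipped to the measurable range.
    """

    intercept: float = 47.0
    b_calcarine: float = -0.55
    b_lingual: float = -0.30
    b_cuneus: float = -0.25
    c_left: float = 15.0
    c_mrtime: float = -0.20
    noise_sd: float = 18.0
    baseline_intercept: float = 8.0
    baseline_coef: float = 0.25
    baseline_noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.baseline_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if not (
            self.b_calcarine <= 0 and self.b_lingual <= 0 and self.b_cuneus <= 0
        ):
            raise ConfigurationError("regional rEIL coefficients must be <= 0")
        if self.c_left < 0 or self.c_mrtime > 0:
            raise ConfigurationError(
                "c_left must be >= 0 and c_mrtime <= 0 (planted signs)"
            )


def make_toy_atlas(shape: tuple[int, int, int] = (32, 32, 32), seed: int = 0):
    """Toy parcellation: nine contiguous blocks per hemisphere.

    The first axis splits hemispheres (low indices = left).  Within
    each hemisphere the nine regions tile a 3x3 grid of (y, z) bands;
    the seed jitters band boundaries by up to one voxel.  Left regions
    carry labels 1-9, right regions 101-109, paired by name.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 12:
        raise SchemaError(
            f"atlas shape {shape} too small to fit 9 regions per hemisphere"
        )
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    half = nx // 2
    labels = np.zeros(shape, dtype=np.int16)

    def bands(n: int) -> list[tuple[int, int]]:
        # three bands with 2-voxel outer margin and seeded +/-1 jitter;
        # the margins leave unlabelled "white matter" around the gyri
        lo, hi = 2, n - 2
        cut1 = lo + (hi - lo) // 3 + int(rng.integers(-1, 2))
        cut2 = lo + 2 * (hi - lo) // 3 + int(rng.integers(-1, 2))
        return [(lo, cut1), (cut1, cut2), (cut2, hi)]

    rows = []
    for hemi, (x0, x1) in zip(HEMISPHERES, ((2, half - 2), (half + 2, nx - 2))):
        ybands, zbands = bands(ny), bands(nz)
        for i, name in enumerate(REGION_NAMES):
            (y0, y1), (z0, z1) = ybands[i // 3], zbands[i % 3]
            rid = (i + 1) if hemi == "left" else (100 + i + 1)
            labels[x0:x1, y0:y1, z0:z1] = rid
            rows.append({"region_id": rid, "region_name": name, "hemisphere": hemi})
    parc = Parcellation(labels=labels, regions=pd.DataFrame(rows))
    if (parc.regions["voxel_count"] <= 0).any():
        raise SchemaError(f"atlas shape {shape} produced an empty region")
    return parc


def make_lesion(
    atlas: Parcellation,
    target_reils: Mapping[str, float],
    side: str,
    rng=None,
    background_fraction: float = 0.0,
) -> LesionMask:
    """Grow a lesion hitting per-region involvement targets.

    Within each targeted region, voxels are accreted outward from a
    random seed voxel (distance-ordered growth with slight jitter)
    until the requested fraction is covered; the achieved rEIL is
    within +/-2 percentage points of the target, granularity
    permitting.  ``background_fraction`` additionally involves that
    fraction of the hemisphere's *unlabelled* voxels (white matter and
    unlisted cortex), contributing to lesion volume but to no region's
    rEIL.
    """
    if side not in HEMISPHERES:
        raise ConfigurationError(f"side must be 'left' or 'right', got {side!r}")
    if not 0.0 <= background_fraction <= 1.0:
        raise ConfigurationError("background_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng)
    mask = np.zeros(atlas.labels.shape, dtype=bool)
    for name, target in target_reils.items():
        if not 0.0 <= target <= 100.0:
            raise ConfigurationError(
                f"target rEIL for {name!r} must be in [0, 100], got {target}"
            )
        if target == 0.0:
            continue
        region = atlas.region_mask(name, side)
        voxels = np.argwhere(region)
        n_take = int(round(target / 100.0 * voxels.shape[0]))
        if n_take == 0:
            continue
        seed_voxel = voxels[rng.integers(voxels.shape[0])]
        dist = np.linalg.norm(voxels - seed_voxel, axis=1)
        dist = dist + rng.uniform(0.0, 0.25, size=dist.size)
        chosen = voxels[np.argsort(dist, kind="stable")[:n_take]]
        mask[tuple(chosen.T)] = True
    if background_fraction > 0.0:
        half = atlas.labels.shape[0] // 2
        background = np.zeros_like(mask)
        if side == "left":
            background[:half] = True
        else:
            background[half:] = True
        background &= atlas.labels == 0
        bg_vox = np.argwhere(background)
        n_bg = int(round(background_fraction * bg_vox.shape[0]))
        if n_bg > 0:
            lesioned = np.argwhere(mask)
            seed_voxel = (
                lesioned[rng.integers(lesioned.shape[0])]
                if lesioned.size
                else bg_vox[rng.integers(bg_vox.shape[0])]
            )
            dist = np.linalg.norm(bg_vox - seed_voxel, axis=1)
            dist = dist + rng.uniform(0.0, 0.25, size=dist.size)
            chosen = bg_vox[np.argsort(dist, kind="stable")[:n_bg]]
            mask[tuple(chosen.T)] = True
    return LesionMask(data=mask, voxel_dims_mm=ATLAS_VOXEL_DIMS, space="atlas")


def make_exam_pair(
    baseline_vfs_targets: tuple[float, float],
    pct_vfs: float | tuple[float, float],
    rng=None,
    patient_id: str = "synthetic",
    affected_side: str = "right",
    jitter_db: float = 1.0,
    two_eyes: bool = True,
):
    """Baseline/follow-up exam pair hitting exact quadrant scores.

    ``baseline_vfs_targets`` are the (upper, lower) affected-quadrant
    mean deviations (dB, negative); ``pct_vfs`` is the planted relative
    change, a scalar applied to both quadrants or an (upper, lower)
    pair.  Point-level values are the quadrant mean plus zero-sum
    jitter, so quadrant means reproduce the targets to machine
    precision through the scoring pipeline.  Unaffected-side points sit
    near 0 dB.
    """
    rng = np.random.default_rng(rng)
    bu, bl = (float(v) for v in baseline_vfs_targets)
    if bu >= 0 or bl >= 0:
        raise SchemaError("baseline quadrant targets must be negative (dB)")
    if np.isscalar(pct_vfs):
        pu = pl = float(pct_vfs)
    else:
        pu, pl = (float(v) for v in pct_vfs)
    followups = {}
    for quad, b, p in (("upper", bu, pu), ("lower", bl, pl)):
        f = b * (1.0 - p / 100.0)
        if not -40.0 < f < 10.0 or not -40.0 < b < 10.0:
            raise SchemaError(
                f"{quad} quadrant: baseline {b} dB with %VFS {p} leaves the "
                "measurable [-40, +10] dB range"
            )
        followups[quad] = f

    coords = perimetry.GRID_30_2
    masks = perimetry._quadrant_masks(coords)
    unaffected = "left" if affected_side == "right" else "right"

    def build(values_by_quadrant: Mapping[tuple[str, str], float]) -> np.ndarray:
        grid = np.zeros(perimetry.N_POINTS)
        for key, m in values_by_quadrant.items():
            sel = masks[key]
            n = sel.sum()
            margin = 0.9 * min(10.0 - m, m + 40.0)
            amp = max(0.0, min(jitter_db, margin))
            u = rng.uniform(-amp, amp, size=n)
            d = u - u.mean()  # zero-sum -> quadrant mean is exactly m
            peak = np.max(np.abs(d))
            if peak > amp > 0:
                d *= amp / peak
            grid[sel] = m + d
        return grid

    def eyes(grid: np.ndarray) -> dict[str, np.ndarray]:
        if not two_eyes:
            return {"right": grid}
        margin = np.minimum(10.0 - grid, grid + 40.0)
        e = rng.uniform(-1.0, 1.0, size=grid.size) * np.minimum(jitter_db, margin)
        return {"left": grid + e, "right": grid - e}

    exams = []
    for timepoint, (mu, ml) in (
        ("baseline", (bu, bl)),
        ("followup", (followups["upper"], followups["lower"])),
    ):
        grid = build(
            {
                (affected_side, "upper"): mu,
                (affected_side, "lower"): ml,
                (unaffected, "upper"): -1.0,
                (unaffected, "lower"): -1.0,
            }
        )
        exams.append(
            perimetry.PerimetryExam(
                patient_id=patient_id,
                timepoint=timepoint,
                eye_values=eyes(grid),
                coords=coords,
            )
        )
    return exams[0], exams[1]


@dataclass
class Cohort:
    """A full synthetic study: atlas, per-patient masks, exams, records."""

    atlas: Parcellation
    records: pd.DataFrame
    masks: list[LesionMask]  # atlas space, aligned with records rows
    exams: dict[tuple[str, str], perimetry.PerimetryExam]
    effect: EffectModel
    seed: int
    native_voxel_dims: tuple[float, float, float] = NATIVE_VOXEL_DIMS

    def native_mask(self, row: int) -> LesionMask:
        return LesionMask(
            data=self.masks[row].data,
            voxel_dims_mm=self.native_voxel_dims,
            space="native",
        )


def make_cohort(
    n: int = 35,
    effect: EffectModel | None = None,
    seed: int = 0,
    atlas: Parcellation | None = None,
) -> Cohort:
    """Generate a seeded synthetic cohort of ``n`` patients.

    A single cohort seed derives all sub-generators deterministically.
    Each patient gets covariates, a unilateral lesion with severity-
    correlated regional extents, paired exams whose quadrant scores
    follow the baseline and improvement models, and per-field outcome
    labels computed through the perimetry module itself.
    """
    if n < 10:
        raise ConfigurationError("cohort size must be at least 10")
    effect = effect if effect is not None else EffectModel()
    ss = np.random.SeedSequence(seed)
    atlas_seed, cov_seed, lesion_seed, exam_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    if atlas is None:
        atlas = make_toy_atlas(seed=atlas_seed)
    rng = np.random.default_rng(cov_seed)
    lesion_rng = np.random.default_rng(lesion_seed)
    exam_rng = np.random.default_rng(exam_seed)

    rows, masks = [], []
    exams: dict[tuple[str, str], perimetry.PerimetryExam] = {}
    for i in range(n):
        pid = f"synth{i:03d}"
        cov = {k: int(rng.random() < p) for k, p in PREVALENCES.items()}
        age = float(np.clip(rng.normal(AGE_MEAN, AGE_SD), 35.0, 90.0))
        mr_time = float(
            np.clip(rng.gamma(MR_TIME_SHAPE, MR_TIME_SCALE), 1.0, 168.0)
        )
        lesion_side = "left" if cov["left_pca"] else "right"
        affected_side = "right" if lesion_side == "left" else "left"

        severity = rng.beta(*SEVERITY_BETA)
        targets = {
            name: float(
                np.clip(
                    100.0
                    * base
                    * severity
                    * rng.lognormal(0.0, REGION_LOGNORMAL_SIGMA),
                    0.0,
                    95.0,
                )
            )
            for name, base in REGION_BASE_FRACTION.items()
        }
        background_fraction = float(rng.beta(1.2, 2.5))
        mask = make_lesion(
            atlas,
            targets,
            lesion_side,
            lesion_rng,
            background_fraction=background_fraction,
        )
        reil = compute_reil(mask, atlas, lesion_side)
        volume = lesion_volume_ml(
            LesionMask(mask.data, NATIVE_VOXEL_DIMS, "native")
        )

        cal, ling, cun = (
            reil["calcarine"],
            reil["lingual"],
            reil["cuneus"],
        )
        b_upper = -np.clip(
            effect.baseline_intercept
            + effect.baseline_coef * (cal + ling)
            + rng.normal(0.0, effect.baseline_noise_sd),
            3.0,
            38.0,
        )
        b_lower = -np.clip(
            effect.baseline_intercept
            + effect.baseline_coef * (cal + cun)
            + rng.normal(0.0, effect.baseline_noise_sd),
            3.0,
            38.0,
        )
        drift = (
            effect.intercept
            + effect.b_calcarine * cal
            + effect.b_lingual * ling
            + effect.b_cuneus * cun
            + effect.c_left * cov["left_pca"]
            + effect.c_mrtime * mr_time
        )
        pcts = []
        for b in (b_upper, b_lower):
            p = drift + rng.normal(0.0, effect.noise_sd)
            # keep the follow-up quadrant mean inside the measurable range
            p_lo = (1.0 - 39.0 / abs(b)) * 100.0
            p_hi = (1.0 + 9.0 / abs(b)) * 100.0
            pcts.append(float(np.clip(p, p_lo, p_hi)))
        baseline, followup = make_exam_pair(
            (b_upper, b_lower),
            (pcts[0], pcts[1]),
            exam_rng,
            patient_id=pid,
            affected_side=affected_side,
        )
        exams[(pid, "baseline")] = baseline
        exams[(pid, "followup")] = followup
        scored = perimetry.score_patient(baseline, followup, affected_side)
        scored = scored.set_index("field")

        row = {
            "patient_id": pid,
            "age": age,
            "mr_time_h": mr_time,
            **cov,
            "lesion_side": lesion_side,
            "affected_side": affected_side,
            "lesion_volume_ml": volume,
        }
        row.update({f"reil_{name}": float(reil[name]) for name in REGION_NAMES})
        for fld in ("hemi", "upper", "lower"):
            row[f"baseline_vfs_{fld}"] = float(scored.loc[fld, "baseline_vfs"])
            row[f"followup_vfs_{fld}"] = float(scored.loc[fld, "followup_vfs"])
            row[f"pct_vfs_{fld}"] = float(scored.loc[fld, "pct_vfs"])
            row[f"label_{fld}"] = scored.loc[fld, "label"]
            row[f"defect_{fld}"] = bool(scored.loc[fld, "defect"])
        rows.append(row)
        masks.append(mask)

    records = pd.DataFrame(rows)
    return Cohort(
        atlas=atlas,
        records=records,
        masks=masks,
        exams=exams,
        effect=effect,
        seed=seed,
    )


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write a cohort to disk (NIfTI masks + atlas, CSV tables, manifest)."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.atlas.to_files(outdir / "atlas_labels.nii.gz", outdir / "atlas_regions.csv")
    mask_paths = []
    for row, mask in zip(cohort.records.itertuples(), cohort.masks):
        path = outdir / f"lesion_{row.patient_id}.nii.gz"
        mask.to_nifti(path)
        mask_paths.append(path.name)
    perimetry.write_perimetry_csv(cohort.exams.values(), outdir / "perimetry.csv")
    cohort.records.to_csv(outdir / "covariates.csv", index=False)
    manifest = {
        "n_patients": int(len(cohort.records)),
        "seed": cohort.seed,
        "native_voxel_dims_mm": list(cohort.native_voxel_dims),
        "atlas_labels": "atlas_labels.nii.gz",
        "atlas_regions": "atlas_regions.csv",
        "perimetry": "perimetry.csv",
        "covariates": "covariates.csv",
        "lesion_masks": mask_paths,
        "effect_model": {
            k: getattr(cohort.effect, k)
            for k in (
                "intercept",
                "b_calcarine",
                "b_lingual",
                "b_cuneus",
                "c_left",
                "c_mrtime",
                "noise_sd",
            )
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
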