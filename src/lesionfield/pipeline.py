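"""Study orchestration: simulate -> score -> quantify -> test -> classify.

``run_study`` consumes a study directory (as written by
``synthetic_data.write_cohort`` or assembled from real exports in the
same layout) and emits the full report bundle: per-field visual-field
scores, the rEIL table, group-comparison and correlation tables,
voxel-wise statistics, and per-outcome classification reports.  Every
output embeds a hash of the configuration, and re-running with the same
config and inputs reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from contextlib import contextmanager
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, classifier, group_stats, lesion_quant, perimetry, voxel_stats
from .exceptions import ConfigurationError, LesionfieldError, SchemaError

log = logging.getLogger("lesionfield")

OUTCOME_FIELDS = ("hemi", "upper", "lower")


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of one analysis run.

    Defaults follow the study protocol: 20 % improvement cut-off,
    FDR level q = 0.05, 100 stratified 70/30 splits, linear SVM with
    C = 1.  The defect threshold (baseline quadrant VFS at or below
    which a defect is scored present) is this package's own default.
    """

    improvement_threshold_pct: float = perimetry.IMPROVEMENT_THRESHOLD_PCT
    defect_threshold_db: float = perimetry.DEFECT_THRESHOLD_DB
    fdr_q: float = 0.05
    n_repeats: int = 100
    train_frac: float = 0.7
    svm_c: float = 1.0
    seed: int = 42
    score: str = "mean"
    subgroups: tuple[str, ...] = ("clinical", "baseline", "volume", "reil")

    def __post_init__(self) -> None:
        if self.improvement_threshold_pct <= 0:
            raise ConfigurationError("improvement threshold must be positive")
        if not 0.0 < self.train_frac < 1.0:
            raise ConfigurationError("train_frac must lie in (0, 1)")
        if not 0.0 < self.fdr_q < 1.0:
            raise ConfigurationError("fdr_q must lie in (0, 1)")
        if self.n_repeats < 2:
            raise ConfigurationError("need at least 2 split repeats")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@contextmanager
def _stage(name: str):
    """Label any failure with the pipeline stage that raised it."""
    log.info("stage %s: start", name)
    try:
        yield
    except LesionfieldError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc
    log.info("stage %s: done", name)


def load_study_dir(datadir):
    """Load a study directory (manifest layout of ``write_cohort``)."""
    datadir = Path(datadir)
    manifest_path = datadir / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"missing manifest.json in {datadir}")
    manifest = json.loads(manifest_path.read_text())
    atlas = lesion_quant.Parcellation.from_files(
        datadir / manifest["atlas_labels"], datadir / manifest["atlas_regions"]
    )
    covariates = pd.read_csv(datadir / manifest["covariates"])
    exams = perimetry.read_perimetry_csv(datadir / manifest["perimetry"])
    masks = [
        lesion_quant.LesionMask.from_nifti(datadir / p, space="atlas")
        for p in manifest["lesion_masks"]
    ]
    if len(masks) != len(covariates):
        raise SchemaError(
            f"{len(masks)} lesion masks for {len(covariates)} covariate rows"
        )
    return manifest, atlas, covariates, exams, masks


def score_visual_fields(covariates, exams, config: StudyConfig) -> pd.DataFrame:
    """Per-patient, per-field VFS/%VFS/label/defect rows."""
    frames = []
    for row in covariates.itertuples():
        pid = str(row.patient_id)
        try:
            baseline = exams[(pid, "baseline")]
            followup = exams[(pid, "followup")]
        except KeyError as exc:
            raise SchemaError(f"patient {pid}: missing exam {exc}") from exc
        frames.append(
            perimetry.score_patient(
                baseline,
                followup,
                affected_side=row.affected_side,
                improvement_threshold=config.improvement_threshold_pct,
                defect_threshold=config.defect_threshold_db,
                score=config.score,
            )
        )
    return pd.concat(frames, ignore_index=True)


def build_feature_table(
    covariates: pd.DataFrame,
    scores: pd.DataFrame,
    masks,
    atlas,
    native_voxel_dims,
) -> pd.DataFrame:
    """Assemble the classification feature table from pipeline outputs."""
    reil = lesion_quant.reil_table(
        masks,
        atlas,
        sides=covariates["lesion_side"].tolist(),
        patient_ids=covariates["patient_id"].tolist(),
    ).reset_index()
    volumes = [
        lesion_quant.lesion_volume_ml(
            lesion_quant.LesionMask(m.data, native_voxel_dims, "native")
        )
        for m in masks
    ]
    cols = ["patient_id", "lesion_side", "affected_side"] + [
        c for c in classifier.CLINICAL_COLUMNS if c in covariates.columns
    ]
    base = covariates.loc[:, list(dict.fromkeys(cols))].copy()
    base["lesion_volume_ml"] = volumes
    wide = scores.pivot(index="patient_id", columns="field")
    for fld in OUTCOME_FIELDS:
        base[f"baseline_vfs_{fld}"] = base["patient_id"].map(
            wide[("baseline_vfs", fld)]
        )
        base[f"pct_vfs_{fld}"] = base["patient_id"].map(wide[("pct_vfs", fld)])
        base[f"label_{fld}"] = base["patient_id"].map(wide[("label", fld)])
        base[f"defect_{fld}"] = base["patient_id"].map(wide[("defect", fld)])
    return base.merge(reil, on="patient_id")


def outcome_cohort(features: pd.DataFrame, field: str) -> pd.DataFrame:
    """Patients entering the analysis of one outcome field.

    Quadrant cohorts require a baseline defect of that quadrant; the
    hemifield cohort includes every patient with a defect in any field.
    """
    if field == "hemi":
        keep = features["defect_hemi"] | features["defect_upper"] | features[
            "defect_lower"
        ]
    else:
        keep = features[f"defect_{field}"]
    return features.loc[keep].reset_index(drop=True)


def run_study(datadir, outdir, config: StudyConfig | None = None) -> dict:
    """Run the full analysis and write the report bundle to ``outdir``.

    Returns the report manifest (also written as ``report.json``).
    """
    config = config if config is not None else StudyConfig()
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.digest()

    def save_csv(df: pd.DataFrame, name: str) -> str:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash={cfg_hash}\n")
            df.to_csv(fh, index=False)
        return name

    def save_json(obj, name: str) -> str:
        obj = {"config_hash": cfg_hash, **obj}
        (outdir / name).write_text(json.dumps(obj, indent=2, default=str))
        return name

    with _stage("load"):
        manifest, atlas, covariates, exams, masks = load_study_dir(datadir)
    outputs = {}

    with _stage("score-vf"):
        scores = score_visual_fields(covariates, exams, config)
        outputs["field_scores"] = save_csv(scores, "field_scores.csv")

    with _stage("reil"):
        features = build_feature_table(
            covariates,
            scores,
            masks,
            atlas,
            tuple(manifest.get("native_voxel_dims_mm", (1.0, 1.0, 1.0))),
        )
        reil_cols = ["patient_id"] + [
            c for c in features.columns if c.startswith("reil_")
        ]
        outputs["reil"] = save_csv(features[reil_cols], "reil.csv")
        outputs["features"] = save_csv(features, "features.csv")

    per_outcome = {}
    for fld in OUTCOME_FIELDS:
        cohort = outcome_cohort(features, fld)
        labels = cohort[f"label_{fld}"]
        entry = {"n": int(len(cohort))}
        if labels.nunique() < 2:
            entry["skipped"] = "single improvement class"
            per_outcome[fld] = entry
            continue

        with _stage(f"group-stats[{fld}]"):
            table1 = group_stats.comparison_table(
                cohort,
                labels,
                variables={
                    **{v: "binary" for v in group_stats.BINARY_VARIABLES},
                    "age": "continuous",
                    "mr_time_h": "continuous",
                    f"baseline_vfs_{fld}": "continuous",
                    "lesion_volume_ml": "continuous",
                    **{
                        f"reil_{r}": "continuous"
                        for r in lesion_quant.REGION_NAMES
                    },
                },
            )
            entry["comparisons"] = save_csv(table1, f"table1_{fld}.csv")
            table2 = group_stats.correlation_table(
                cohort, cohort[f"pct_vfs_{fld}"]
            )
            entry["correlations"] = save_csv(table2, f"table2_{fld}.csv")

        with _stage(f"voxel-stats[{fld}]"):
            id_to_mask = dict(zip(features["patient_id"], masks))
            sides = dict(zip(features["patient_id"], features["lesion_side"]))
            sig_ids = cohort.loc[labels == "significant", "patient_id"]
            poor_ids = cohort.loc[labels == "poor", "patient_id"]

            def flipped(ids):
                return [
                    lesion_quant.LesionMask(
                        np.flip(id_to_mask[i].data, axis=0)
                        if sides[i] == "right"
                        else id_to_mask[i].data,
                        id_to_mask[i].voxel_dims_mm,
                        "atlas",
                    )
                    for i in ids
                ]

            result = voxel_stats.voxelwise_test(
                flipped(sig_ids), flipped(poor_ids), q=config.fdr_q
            )
            result.write(
                outdir / f"zmap_{fld}.nii.gz",
                outdir / f"sigmask_{fld}.nii.gz",
                outdir / f"voxel_{fld}.json",
            )
            entry["voxel"] = result.summary()

        with _stage(f"classify[{fld}]"):
            groups = classifier.subgroup_columns(cohort, fld)
            splits = classifier.make_splits(
                labels, config.n_repeats, config.train_frac, config.seed
            )
            runs = {}
            report = {"chance": classifier.random_chance(labels), "subgroups": {}}
            for name in config.subgroups:
                res = classifier.subset_search(
                    cohort,
                    labels,
                    columns=groups[name],
                    splits=splits,
                    C=config.svm_c,
                    seed=config.seed,
                )
                runs[name] = res.best_run
                report["subgroups"][name] = {
                    "best_subset": list(res.best_subset),
                    **res.best_run.as_dict(),
                }
            if "reil" in runs:
                others = [s for s in config.subgroups if s != "reil"]
                comparisons = {}
                for name in others:
                    cmp_ = classifier.compare_runs_paired(
                        runs["reil"], runs[name], n_comparisons=len(others)
                    )
                    comparisons[f"reil_vs_{name}"] = {
                        "t": cmp_.t_statistic,
                        "p": cmp_.p_value,
                        "p_bonferroni": cmp_.p_bonferroni,
                        "mean_difference": cmp_.mean_difference,
                    }
                report["paired_comparisons"] = comparisons
            entry["classification"] = save_json(report, f"classification_{fld}.json")
        per_outcome[fld] = entry

    report = {
        "config": asdict(config),
        "config_hash": cfg_hash,
        "software": {
            "lesionfield": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {"datadir": str(datadir), "n_patients": int(len(covariates))},
        "outputs": outputs,
        "outcomes": per_outcome,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
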