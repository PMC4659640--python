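"""Humphrey 30-2 perimetry scoring.

Converts per-eye 76-point total-deviation grids into hemifield and
quadrant visual-field scores (VFS), the relative change from baseline to
follow-up (%VFS), and the significant/poor improvement label.

Conventions
-----------
* Total deviation is in dB, negative = worse than the age-matched norm.
* The grid has 76 points, 19 per quadrant; no point lies on an axis.
* ``affected_side`` names the affected visual hemifield (``"left"`` or
  ``"right"``), i.e. the side contralateral to the lesioned hemisphere.
  A point belongs to the left hemifield when its x coordinate is
  negative, and to the upper field when its y coordinate is positive.
* VFS is the per-point *mean* deviation over a field: quadrant scores
  average 19 points, the hemifield score averages all 38 affected-side
  points, so the hemifield VFS is the unweighted mean of the two
  quadrant VFS.  A ``score="sum"`` switch is kept for sensitivity
  checks.
* %VFS = (follow-up VFS - baseline VFS) / |baseline VFS| * 100.
  Improvement is *significant* when %VFS is strictly greater than the
  threshold (default 20 %), otherwise *poor*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    CoordinateError,
    NumericalError,
    SchemaError,
    UndefinedChangeError,
)

N_POINTS = 76
N_PER_QUADRANT = 19

#: Default %VFS cut-off separating significant from poor improvement.
IMPROVEMENT_THRESHOLD_PCT = 20.0

#: Default baseline quadrant VFS (dB) at or below which a visual field
#: defect is considered present (inclusive).
DEFECT_THRESHOLD_DB = -10.0


def _build_grid() -> np.ndarray:
    """Canonical 30-2 point coordinates in degrees, (76, 2) array.

    Idealised pattern: per quadrant, all (x, y) with |x|, |y| in
    {3, 9, 15, 21, 27} degrees lying within the 30-degree circle, minus
    the outermost horizontal point (|x| = 27, |y| = 3), giving exactly
    19 points per quadrant and none on an axis.
    """
    offs = [3.0, 9.0, 15.0, 21.0, 27.0]
    quad = [
        (x, y)
        for x, y in itertools.product(offs, offs)
        if x * x + y * y <= 30.0**2 and not (x == 27.0 and y == 3.0)
    ]
    pts = [
        (sx * x, sy * y)
        for sx in (-1.0, 1.0)
        for sy in (-1.0, 1.0)
        for x, y in quad
    ]
    arr = np.array(sorted(pts), dtype=float)
    assert arr.shape == (N_POINTS, 2)
    return arr


#: Shared (76, 2) coordinate grid used by the synthetic generator and
#: by exams constructed without explicit coordinates.
GRID_30_2: np.ndarray = _build_grid()
GRID_30_2.setflags(write=False)


@dataclass
class PerimetryExam:
    """One visual-field test: per-eye total-deviation values on a grid.

    Parameters
    ----------
    patient_id:
        Identifier shared with the covariate table.
    timepoint:
        ``"baseline"`` or ``"followup"``.
    eye_values:
        Mapping eye name (``"left"``/``"right"``/``"od"``/``"os"`` — any
        label) to a length-76 array of total-deviation values in dB.
    coords:
        (76, 2) array of (x_deg, y_deg); defaults to the canonical grid.
    """

    patient_id: str
    timepoint: str
    eye_values: Mapping[str, np.ndarray]
    coords: np.ndarray = field(default_factory=lambda: GRID_30_2)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_POINTS, 2):
            raise SchemaError(
                f"exam {self.patient_id}: grid must have {N_POINTS} points, "
                f"got shape {self.coords.shape}"
            )
        if np.any(self.coords == 0.0):
            raise SchemaError(
                f"exam {self.patient_id}: grid points must not lie on an axis"
            )
        for quad_mask in _quadrant_masks(self.coords).values():
            if quad_mask.sum() != N_PER_QUADRANT:
                raise SchemaError(
                    f"exam {self.patient_id}: each quadrant must hold "
                    f"{N_PER_QUADRANT} points"
                )
        if not self.eye_values:
            raise SchemaError(f"exam {self.patient_id}: no eye grids present")
        clean = {}
        for eye, vals in self.eye_values.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (N_POINTS,):
                raise SchemaError(
                    f"exam {self.patient_id}, eye {eye}: expected "
                    f"{N_POINTS} values, got {vals.shape}"
                )
            if not np.all(np.isfinite(vals)):
                raise SchemaError(
                    f"exam {self.patient_id}, eye {eye}: non-finite deviation"
                )
            if vals.min() < -40.0 or vals.max() > 10.0:
                raise SchemaError(
                    f"exam {self.patient_id}, eye {eye}: total deviation "
                    "outside [-40, +10] dB"
                )
            clean[eye] = vals
        self.eye_values = clean


@dataclass(frozen=True)
class FieldScores:
    """Hemifield and quadrant VFS (dB) on the affected side."""

    hemi_vfs: float
    upper_vfs: float
    lower_vfs: float
    affected_side: str


@dataclass(frozen=True)
class ImprovementOutcome:
    """Change of a field score between baseline and follow-up."""

    pct_vfs: float
    delta_vfs: float
    label: str  # "significant" | "poor"


def _quadrant_masks(coords: np.ndarray) -> dict[tuple[str, str], np.ndarray]:
    """Boolean masks keyed by (hemifield side, vertical half)."""
    x, y = coords[:, 0], coords[:, 1]
    return {
        ("left", "upper"): (x < 0) & (y > 0),
        ("left", "lower"): (x < 0) & (y < 0),
        ("right", "upper"): (x > 0) & (y > 0),
        ("right", "lower"): (x > 0) & (y < 0),
    }


def average_eyes(exam: PerimetryExam) -> np.ndarray:
    """Per-point mean total deviation across the available eyes.

    With a single eye the values are returned unchanged.  Eyes within
    one exam share the exam's coordinate grid by construction; use
    :func:`check_matching_coords` when pairing two exams.
    """
    stacked = np.stack(list(exam.eye_values.values()))
    return stacked.mean(axis=0)


def check_matching_coords(a: PerimetryExam, b: PerimetryExam) -> None:
    """Raise :class:`CoordinateError` unless both exams share a grid."""
    if not np.array_equal(a.coords, b.coords):
        raise CoordinateError(
            f"exams {a.patient_id}/{a.timepoint} and {b.patient_id}/"
            f"{b.timepoint} use different point coordinates"
        )


def field_scores(
    mean_grid: np.ndarray,
    affected_side: str,
    coords: np.ndarray | None = None,
    score: str = "mean",
) -> FieldScores:
    """Quadrant and hemifield VFS over the affected-side points.

    ``score="mean"`` (default) averages the points of each field;
    ``score="sum"`` totals them instead (sensitivity switch — with it
    the hemifield score is the sum, not the mean, of the quadrants).
    """
    if affected_side not in ("left", "right"):
        raise ConfigurationError(
            f"affected_side must be 'left' or 'right', got {affected_side!r}"
        )
    if score not in ("mean", "sum"):
        raise ConfigurationError(f"score must be 'mean' or 'sum', got {score!r}")
    coords = GRID_30_2 if coords is None else np.asarray(coords, dtype=float)
    mean_grid = np.asarray(mean_grid, dtype=float)
    if mean_grid.shape != (N_POINTS,):
        raise SchemaError(f"expected {N_POINTS} point values, got {mean_grid.shape}")
    masks = _quadrant_masks(coords)
    agg = np.mean if score == "mean" else np.sum
    upper = float(agg(mean_grid[masks[(affected_side, "upper")]]))
    lower = float(agg(mean_grid[masks[(affected_side, "lower")]]))
    hemi_mask = masks[(affected_side, "upper")] | masks[(affected_side, "lower")]
    hemi = float(agg(mean_grid[hemi_mask]))
    return FieldScores(
        hemi_vfs=hemi, upper_vfs=upper, lower_vfs=lower, affected_side=affected_side
    )


def percent_change(baseline_vfs: float, followup_vfs: float) -> float:
    """%VFS = (follow-up - baseline) / |baseline| * 100."""
    if baseline_vfs == 0:
        raise UndefinedChangeError(
            "relative VFS change is undefined for a zero baseline score"
        )
    return (followup_vfs - baseline_vfs) / abs(baseline_vfs) * 100.0


def classify_improvement(
    pct_vfs: float, threshold: float = IMPROVEMENT_THRESHOLD_PCT
) -> str:
    """``"significant"`` iff %VFS is strictly greater than the threshold."""
    if not np.isfinite(pct_vfs):
        raise NumericalError(f"%VFS must be finite, got {pct_vfs}")
    return "significant" if pct_vfs > threshold else "poor"


def detect_defect(
    baseline_field_vfs: float, threshold: float = DEFECT_THRESHOLD_DB
) -> bool:
    """Whether a baseline field score indicates a defect (inclusive cut)."""
    return baseline_field_vfs <= threshold


def score_patient(
    baseline: PerimetryExam,
    followup: PerimetryExam,
    affected_side: str,
    improvement_threshold: float = IMPROVEMENT_THRESHOLD_PCT,
    defect_threshold: float = DEFECT_THRESHOLD_DB,
    score: str = "mean",
) -> pd.DataFrame:
    """Full per-patient scoring: one row per field (hemi/upper/lower).

    Columns: patient_id, field, baseline_vfs, followup_vfs, delta_vfs,
    pct_vfs, label, defect.  The ``defect`` flag marks fields whose
    baseline score meets the defect criterion and therefore enter that
    field's analysis cohort.
    """
    check_matching_coords(baseline, followup)
    b = field_scores(average_eyes(baseline), affected_side, baseline.coords, score)
    f = field_scores(average_eyes(followup), affected_side, followup.coords, score)
    rows = []
    for name, bv, fv in (
        ("hemi", b.hemi_vfs, f.hemi_vfs),
        ("upper", b.upper_vfs, f.upper_vfs),
        ("lower", b.lower_vfs, f.lower_vfs),
    ):
        pct = percent_change(bv, fv)
        rows.append(
            {
                "patient_id": baseline.patient_id,
                "field": name,
                "baseline_vfs": bv,
                "followup_vfs": fv,
                "delta_vfs": fv - bv,
                "pct_vfs": pct,
                "label": classify_improvement(pct, improvement_threshold),
                "defect": detect_defect(bv, defect_threshold),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interchange

_CSV_COLS = ["patient_id", "timepoint", "eye", "x_deg", "y_deg", "total_deviation_db"]


def read_perimetry_csv(path) -> dict[tuple[str, str], PerimetryExam]:
    """Read a long-format perimetry CSV into exams keyed (patient, timepoint).

    Expected columns: patient_id, timepoint, eye, x_deg, y_deg,
    total_deviation_db; one row per tested point per eye.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"perimetry CSV missing columns: {missing}")
    exams: dict[tuple[str, str], PerimetryExam] = {}
    for (pid, tp), grp in df.groupby(["patient_id", "timepoint"], sort=True):
        coords = None
        eye_values = {}
        for eye, eg in grp.groupby("eye", sort=True):
            eg = eg.sort_values(["y_deg", "x_deg"], kind="mergesort")
            c = eg[["x_deg", "y_deg"]].to_numpy(dtype=float)
            if coords is None:
                coords = c
            elif not np.array_equal(coords, c):
                raise CoordinateError(
                    f"exam {pid}/{tp}: eyes disagree on point coordinates"
                )
            eye_values[str(eye)] = eg["total_deviation_db"].to_numpy(dtype=float)
        exams[(str(pid), str(tp))] = PerimetryExam(
            patient_id=str(pid), timepoint=str(tp), eye_values=eye_values, coords=coords
        )
    return exams


def write_perimetry_csv(exams: Iterable[PerimetryExam], path) -> None:
    rows = []
    for exam in exams:
        for eye, vals in exam.eye_values.items():
            for (x, y), v in zip(exam.coords, vals):
                rows.append((exam.patient_id, exam.timepoint, eye, x, y, v))
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(path, index=False)


def write_field_scores_csv(scores: pd.DataFrame, path) -> None:
    """Write the output of :func:`score_patient` rows (concatenated)."""
    cols = [
        "patient_id",
        "field",
        "baseline_vfs",
        "followup_vfs",
        "pct_vfs",
        "label",
        "defect",
    ]
    scores.loc[:, cols].to_csv(path, index=False)
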