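"""Univariate group comparisons and correlations with %VFS.

Continuous variables are compared between the significant- and
poor-improvement groups with Student's (pooled-variance) t-test — Welch
behind a flag; binary variables with the Pearson chi-square test,
switching to Fisher's exact test when any expected cell count falls
below 5.  Associations with the relative change of visual field score
use the Pearson product-moment correlation; binary predictors coded 0/1
(point-biserial).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import NumericalError, SchemaError
from .classifier import _as_binary

#: Expected-count rule that switches a 2x2 comparison to Fisher's exact.
FISHER_EXPECTED_MIN = 5.0


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    summary_group1: str  # significant improvement
    summary_group2: str  # poor improvement
    test: str  # "t" | "chi-square" | "fisher"
    statistic: float
    p_value: float


def _split(values, labels):
    y = _as_binary(labels)
    v = np.asarray(values, dtype=float)
    if v.shape[0] != y.shape[0]:
        raise SchemaError("values and labels differ in length")
    if not np.all(np.isfinite(v)):
        raise SchemaError("values contain missing/non-finite entries")
    g1, g2 = v[y == 1], v[y == 0]
    if g1.size == 0 or g2.size == 0:
        raise NumericalError("both groups must be non-empty")
    return g1, g2


def compare_groups(
    values,
    labels,
    variable: str = "",
    var_type: str = "continuous",
    welch: bool = False,
) -> GroupComparison:
    """Compare one variable between improvement groups.

    ``var_type="continuous"``: two-sample t-test (pooled variance unless
    ``welch``).  ``var_type="binary"``: Pearson chi-square on the 2x2
    table, Fisher's exact test when any expected count < 5.
    """
    g1, g2 = _split(values, labels)
    if var_type == "continuous":
        if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
            if g1.mean() == g2.mean():
                # no variance, no difference: the comparison is vacuous
                return GroupComparison(
                    variable,
                    _cont_summary(g1),
                    _cont_summary(g2),
                    "t",
                    0.0,
                    1.0,
                )
            raise NumericalError(
                f"{variable or 'variable'}: zero variance in both groups"
            )
        t, p = stats.ttest_ind(g1, g2, equal_var=not welch)
        return GroupComparison(
            variable, _cont_summary(g1), _cont_summary(g2), "t", float(t), float(p)
        )
    if var_type == "binary":
        table = np.array(
            [
                [np.sum(g1 == 1), np.sum(g1 == 0)],
                [np.sum(g2 == 1), np.sum(g2 == 0)],
            ],
            dtype=float,
        )
        expected = stats.contingency.expected_freq(table)
        if np.any(expected < FISHER_EXPECTED_MIN):
            odds, p = stats.fisher_exact(table)
            return GroupComparison(
                variable,
                _bin_summary(g1),
                _bin_summary(g2),
                "fisher",
                float(odds),
                float(p),
            )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return GroupComparison(
            variable,
            _bin_summary(g1),
            _bin_summary(g2),
            "chi-square",
            float(chi2),
            float(p),
        )
    raise SchemaError(f"var_type must be 'continuous' or 'binary', got {var_type!r}")


def _cont_summary(g: np.ndarray) -> str:
    return f"{g.mean():.1f} [{g.std(ddof=1):.1f}]"


def _bin_summary(g: np.ndarray) -> str:
    return f"{int(np.sum(g == 1))} ({100.0 * np.mean(g == 1):.1f})"


def correlate(feature_values, pct_vfs_values):
    """Pearson r (and two-sided p) between a predictor and %VFS."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(pct_vfs_values, dtype=float)
    if x.size != y.size:
        raise SchemaError("inputs differ in length")
    if x.size < 3:
        raise NumericalError("correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise SchemaError("inputs contain missing/non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise NumericalError("correlation undefined for a zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pooled_mean(group_means, group_ns) -> float:
    """Overall mean reconstructed from per-group means and sizes."""
    m = np.asarray(group_means, dtype=float)
    n = np.asarray(group_ns, dtype=float)
    if m.size == 0 or m.size != n.size:
        raise SchemaError("need equal-length, non-empty mean and count vectors")
    if np.any(n <= 0):
        raise SchemaError("group sizes must be positive")
    return float(np.sum(m * n) / np.sum(n))


BINARY_VARIABLES = (
    "male",
    "left_pca",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "smoking",
    "atrial_fibrillation",
)


def comparison_table(
    records: pd.DataFrame, labels, variables: dict[str, str] | None = None
) -> pd.DataFrame:
    """Group-comparison table (one row per variable) for one outcome.

    ``variables`` maps column name -> 'continuous'|'binary'; defaults to
    the study's covariates plus every baseline VFS / volume / rEIL
    column present.
    """
    if variables is None:
        variables = {}
        for c in records.columns:
            if c in BINARY_VARIABLES:
                variables[c] = "binary"
            elif (
                c in ("age", "mr_time_h", "lesion_volume_ml")
                or c.startswith("baseline_vfs")
                or c.startswith("reil_")
            ):
                variables[c] = "continuous"
    rows = []
    for var, kind in variables.items():
        cmp_ = compare_groups(records[var], labels, variable=var, var_type=kind)
        rows.append(
            {
                "variable": var,
                "significant": cmp_.summary_group1,
                "poor": cmp_.summary_group2,
                "test": cmp_.test,
                "statistic": cmp_.statistic,
                "p": cmp_.p_value,
            }
        )
    return pd.DataFrame(rows)


def correlation_table(
    records: pd.DataFrame, pct_vfs, variables: list[str] | None = None
) -> pd.DataFrame:
    """Correlations of predictors with %VFS (one row per variable)."""
    if variables is None:
        variables = [
            c
            for c in records.columns
            if c in BINARY_VARIABLES
            or c in ("age", "mr_time_h", "lesion_volume_ml")
            or c.startswith("baseline_vfs")
            or c.startswith("reil_")
        ]
    rows = []
    for var in variables:
        r, p = correlate(records[var], pct_vfs)
        rows.append({"variable": var, "r": r, "p": p})
    return pd.DataFrame(rows)
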