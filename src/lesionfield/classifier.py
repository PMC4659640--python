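"""Repeated-split linear-SVM prognosis classification.

Protocol: patients are dichotomised into significant vs poor
improvement; for a chosen set of predictor columns, a linear-kernel
soft-margin SVM (C = 1) is trained on a stratified random 70 % of each
class and tested on the remainder; this is repeated ``n_repeats`` times
(default 100) and the accuracy distribution is summarised by its mean,
SD and the one-sample t-score against *random chance*, defined as the
majority-class fraction of the full cohort.  An exhaustive search over
all 2^M - 1 non-empty column subsets, evaluated on the *same* sequence
of splits (common random numbers), ranks predictor subsets by t-score.
Paired t-tests over the per-split accuracy differences compare two runs
that share splits.

Features are z-scored using training-fold mean and SD before fitting;
training-fold zero-variance features are dropped with a warning.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import config_context
from sklearn.svm import SVC

try:  # low-level libsvm binding: identical solver, far less call overhead
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - fall back to the public estimator
    _libsvm = None

from .exceptions import ConfigurationError, NumericalError, PairingError, SchemaError

POSITIVE_LABEL = "significant"
NEGATIVE_LABEL = "poor"

#: Guard on exhaustive enumeration: 2^M subsets become impractical past this.
MAX_SUBSET_FEATURES = 20

#: Named predictor subgroups; rEIL columns are ``reil_<region>``.
CLINICAL_COLUMNS = (
    "age",
    "male",
    "left_pca",
    "mr_time_h",
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "smoking",
    "atrial_fibrillation",
)


def subgroup_columns(df: pd.DataFrame, outcome_field: str) -> dict[str, list[str]]:
    """Map subgroup name -> feature columns for one outcome field.

    Subgroups follow the study design: clinical (9 variables), baseline
    VFS of the outcome field (1), initial lesion volume (1), and the
    nine regional rEIL values.
    """
    reil = [c for c in df.columns if c.startswith("reil_")]
    groups = {
        "clinical": [c for c in CLINICAL_COLUMNS if c in df.columns],
        "baseline": [f"baseline_vfs_{outcome_field}"],
        "volume": ["lesion_volume_ml"],
        "reil": reil,
    }
    for name, cols in groups.items():
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"subgroup {name!r}: missing columns {missing}")
    return groups


def _as_binary(labels) -> np.ndarray:
    """Coerce labels to an int array with 1 = significant improvement."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        bad = set(np.unique(arr)) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise SchemaError(f"unknown labels {sorted(bad)}")
        return (arr == POSITIVE_LABEL).astype(int)
    return arr.astype(int)


def random_chance(labels) -> float:
    """Majority-class fraction: max(n_sig, n_poor) / n."""
    y = _as_binary(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise NumericalError("random chance needs both improvement classes present")
    return max(n_pos, n_neg) / (n_pos + n_neg)


def stratified_split(labels, train_frac: float = 0.7, rng=None):
    """One stratified train/test split.

    Per class, the training count is round-half-up(train_frac * n),
    clamped so both folds keep at least one member of each class; the
    class members are sampled uniformly without replacement.
    Returns sorted (train_idx, test_idx) integer arrays.
    """
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(rng)
    y = _as_binary(labels)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n = idx.size
        if n < 2:
            raise SchemaError(
                f"class {cls} has {n} member(s); need >= 2 for a stratified split"
            )
        n_train = int(np.floor(train_frac * n + 0.5))  # round half up
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def make_splits(labels, n_repeats: int, train_frac: float = 0.7, seed=None):
    """A reproducible sequence of stratified splits (the common random
    numbers shared by every subset in a search)."""
    rng = np.random.default_rng(seed)
    return [stratified_split(labels, train_frac, rng) for _ in range(n_repeats)]


def splits_digest(splits) -> str:
    """Order-sensitive fingerprint of a split sequence, used to verify
    that two runs are pairable split-by-split."""
    h = hashlib.sha256()
    for tr, te in splits:
        h.update(np.asarray(tr, dtype=np.int64).tobytes())
        h.update(b"|")
        h.update(np.asarray(te, dtype=np.int64).tobytes())
        h.update(b";")
    return h.hexdigest()


def _fit_score(X, y, train_idx, test_idx, C: float, svc: SVC | None = None) -> float:
    Xtr, Xte = X[train_idx], X[test_idx]
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(
            "dropping training-fold zero-variance feature(s)", stacklevel=3
        )
        if not keep.any():
            # degenerate classifier: no usable feature, predict the
            # training-fold majority class
            ytr = y[train_idx]
            counts = np.bincount(ytr, minlength=2)
            pred = np.full(test_idx.size, int(np.argmax(counts)))
            return float(np.mean(pred == y[test_idx]))
        Xtr, Xte, mu, sd = Xtr[:, keep], Xte[:, keep], mu[keep], sd[keep]
    Xtr = (Xtr - mu) / sd
    Xte = (Xte - mu) / sd
    ytr = y[train_idx]
    if np.unique(ytr).size < 2:  # degenerate fold: predict the only class seen
        pred = np.full(test_idx.size, ytr[0])
    elif _libsvm is not None:
        model = _libsvm.fit(
            np.ascontiguousarray(Xtr, dtype=np.float64),
            ytr.astype(np.float64),
            svm_type=0,
            kernel="linear",
            C=C,
        )
        pred = _libsvm.predict(
            np.ascontiguousarray(Xte, dtype=np.float64),
            *model[:7],
            svm_type=0,
            kernel="linear",
        )
    else:
        svc = svc if svc is not None else SVC(kernel="linear", C=C)
        svc.set_params(C=C)
        svc.fit(Xtr, ytr)
        pred = svc.predict(Xte)
    return float(np.mean(pred == y[test_idx]))


def evaluate_once(features, labels, split, C: float = 1.0) -> float:
    """Accuracy of one train/test evaluation of the linear SVM."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 0:
        raise SchemaError("need at least one feature column")
    y = _as_binary(labels)
    train_idx, test_idx = split
    with config_context(assume_finite=True):
        return _fit_score(X, y, np.asarray(train_idx), np.asarray(test_idx), C)


@dataclass
class ClassificationRun:
    """Accuracy distribution of one feature set over repeated splits."""

    accuracies: np.ndarray
    chance: float
    split_digest: str
    columns: tuple[str, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.accuracies.min() < 0 or self.accuracies.max() > 1:
            raise SchemaError("accuracies must lie in [0, 1]")

    @property
    def n_repeats(self) -> int:
        return self.accuracies.size

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def t_score(self) -> float:
        """One-sample t versus random chance; +/-inf sentinel at sd = 0."""
        diff = self.mean - self.chance
        if self.sd == 0:
            return 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
        return diff / (self.sd / np.sqrt(self.n_repeats))

    @property
    def p_value(self) -> float:
        t = self.t_score
        if not np.isfinite(t):
            return 0.0
        return float(2.0 * stats.t.sf(abs(t), df=self.n_repeats - 1))

    def as_dict(self) -> dict:
        return {
            "columns": list(self.columns),
            "n_repeats": self.n_repeats,
            "mean_accuracy": self.mean,
            "sd_accuracy": self.sd,
            "chance": self.chance,
            "t_score": self.t_score if np.isfinite(self.t_score) else None,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def repeat_performance(
    features,
    labels,
    n_repeats: int = 100,
    train_frac: float = 0.7,
    seed=None,
    C: float = 1.0,
    columns: Sequence[str] = (),
    splits=None,
) -> ClassificationRun:
    """Evaluate one feature set over ``n_repeats`` stratified splits.

    Pass precomputed ``splits`` to share common random numbers with
    other runs; otherwise they are derived from ``seed``.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _as_binary(labels)
    if splits is None:
        splits = make_splits(y, n_repeats, train_frac, seed)
    chance = random_chance(y)
    svc = SVC(kernel="linear", C=C)
    with config_context(assume_finite=True):
        acc = np.array(
            [_fit_score(X, y, tr, te, C, svc) for tr, te in splits], dtype=float
        )
    return ClassificationRun(
        accuracies=acc,
        chance=chance,
        split_digest=splits_digest(splits),
        columns=tuple(columns),
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass
class SubsetSearchResult:
    """Outcome of an exhaustive feature-subset search."""

    best_subset: tuple[str, ...]
    best_run: ClassificationRun
    all_results: pd.DataFrame = field(repr=False)


def subset_search(
    features: pd.DataFrame,
    labels,
    columns: Sequence[str] | None = None,
    n_repeats: int = 100,
    train_frac: float = 0.7,
    seed=None,
    C: float = 1.0,
    splits=None,
) -> SubsetSearchResult:
    """Exhaustively evaluate every non-empty subset of ``columns``.

    All subsets see the identical sequence of stratified splits, so
    their accuracy vectors are pairable.  The best subset maximises the
    t-score against chance; ties break toward smaller subsets, then
    lexicographic column order.
    """
    cols = list(columns) if columns is not None else list(features.columns)
    if len(cols) == 0:
        raise SchemaError("need at least one candidate column")
    if len(cols) > MAX_SUBSET_FEATURES:
        raise ConfigurationError(
            f"{len(cols)} features means 2^{len(cols)} subsets; pre-filter to at "
            f"most {MAX_SUBSET_FEATURES}"
        )
    X_full = features.loc[:, cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(X_full)):
        raise SchemaError("feature table contains missing/non-finite values")
    y = _as_binary(labels)
    if splits is None:
        splits = make_splits(y, n_repeats, train_frac, seed)
    digest = splits_digest(splits)
    chance = random_chance(y)
    svc = SVC(kernel="linear", C=C)

    records = []
    best_key, best = None, None
    with config_context(assume_finite=True):
        for k in range(1, len(cols) + 1):
            for combo in itertools.combinations(range(len(cols)), k):
                X = X_full[:, combo]
                acc = np.array(
                    [_fit_score(X, y, tr, te, C, svc) for tr, te in splits]
                )
                names = tuple(cols[i] for i in combo)
                run = ClassificationRun(
                    accuracies=acc,
                    chance=chance,
                    split_digest=digest,
                    columns=names,
                    seed=seed if isinstance(seed, int) else None,
                )
                records.append(
                    {
                        "subset": names,
                        "n_features": k,
                        "mean_accuracy": run.mean,
                        "sd_accuracy": run.sd,
                        "t_score": run.t_score,
                    }
                )
                key = (-run.t_score, k, names)
                if best_key is None or key < best_key:
                    best_key, best = key, run
    table = pd.DataFrame.from_records(records)
    return SubsetSearchResult(
        best_subset=best.columns, best_run=best, all_results=table
    )


@dataclass(frozen=True)
class PairedComparison:
    t_statistic: float
    p_value: float
    p_bonferroni: float
    mean_difference: float


def compare_runs_paired(
    run_a: ClassificationRun,
    run_b: ClassificationRun,
    n_comparisons: int = 1,
) -> PairedComparison:
    """Paired t-test over per-split accuracy differences (A - B).

    Runs must share the identical split sequence; the Bonferroni-adjusted
    p multiplies by the number of comparisons in the report family.
    """
    if run_a.split_digest != run_b.split_digest:
        raise PairingError("runs were evaluated on different split sequences")
    if run_a.n_repeats != run_b.n_repeats:
        raise PairingError("runs differ in number of repeats")
    d = run_a.accuracies - run_b.accuracies
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1)) if d.size > 1 else 0.0
    # constant shifts leave rounding-level spread; treat as zero
    if sd_d <= 1e-12:
        t = 0.0 if mean_d == 0 else float(np.sign(mean_d)) * float("inf")
        p = 1.0 if mean_d == 0 else 0.0
    else:
        t = mean_d / (sd_d / np.sqrt(d.size))
        p = float(2.0 * stats.t.sf(abs(t), df=d.size - 1))
    return PairedComparison(
        t_statistic=t,
        p_value=p,
        p_bonferroni=min(1.0, p * n_comparisons),
        mean_difference=mean_d,
    )


def read_feature_table(path, subgroup_map_path=None):
    """Read a feature table from CSV/XLSX; optional sidecar JSON maps
    column names to subgroup names (returned as a second value)."""
    path = str(path)
    if path.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, comment="#")  # tolerate config-hash header
    mapping: Mapping[str, str] | None = None
    if subgroup_map_path is not None:
        import json

        with open(subgroup_map_path) as fh:
            mapping = json.load(fh)
    return df, mapping
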