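"""Cross-validation plans, the binary-classifier metric panel, cohort
statistics, and the ROI x modality-combination model grid.

The study design evaluates one model per (ROI in {WT, TC}) x (non-empty
subset of the four modalities) — 2 x 15 = 30 models — each with
stratified five-fold cross-validation (80%/20% folds) and a metric panel
of AUC, average accuracy, F1, sensitivity, specificity, PPV, NPV and
Matthews correlation.  AUC uses the Mann-Whitney rank formulation (ties
counted 1/2), which equals the trapezoidal area under the empirical ROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

ROIS = ("WT", "TC")

#: Modality combinations in report order (single, double, triple, all).
MODALITY_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("T1CE",),
    ("ADC",),
    ("T1WI",),
    ("T2WI",),
    ("ADC", "T1CE"),
    ("T1WI", "ADC"),
    ("T1WI", "T1CE"),
    ("T1WI", "T2WI"),
    ("T2WI", "ADC"),
    ("T2WI", "T1CE"),
    ("T1CE", "ADC", "T1WI"),
    ("T1WI", "T2WI", "ADC"),
    ("T1WI", "T2WI", "T1CE"),
    ("T2WI", "ADC", "T1CE"),
    ("T1WI", "T2WI", "T1CE", "ADC"),
)

GROUP_BY_SIZE = {1: "single", 2: "double", 3: "triple", 4: "all"}


def combination_label(modalities: tuple[str, ...]) -> str:
    return " + ".join(modalities)


# ---------------------------------------------------------------------------
# Fold plans


@dataclass
class FoldPlan:
    """A stratified k-fold partition: each patient validates exactly once."""

    folds: list[tuple[np.ndarray, np.ndarray]]
    k: int
    seed: int

    def __iter__(self):
        return iter(self.folds)


def make_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan, deterministic given the seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        (train.copy(), val.copy())
        for train, val in skf.split(np.zeros(len(labels)), labels)
    ]
    return FoldPlan(folds=folds, k=k, seed=seed)


def split_cohort(
    labels: np.ndarray, train_frac: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/validation split.

    Per-class training counts are rounded so the total equals
    ``round(train_frac * n)`` — for 111 patients at 80% that is the 89/22
    split of the study.
    """
    labels = np.asarray(labels)
    n = len(labels)
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    base, frac = {}, {}
    for c in classes:
        exact = train_frac * (labels == c).sum()
        base[c] = int(np.floor(exact))
        frac[c] = exact - base[c]
    short = n_train - sum(base.values())
    for c in sorted(classes, key=lambda c: -frac[c])[:short]:
        base[c] += 1
    train_idx = []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        train_idx.extend(idx[: base[c]])
    train_idx = np.sort(np.asarray(train_idx))
    val_idx = np.setdiff1d(np.arange(n), train_idx)
    return train_idx, val_idx


# ---------------------------------------------------------------------------
# Metrics


def auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Area under the ROC via the Mann-Whitney statistic (ties count 1/2)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=np.float64)
    n1 = int((y_true == 1).sum())
    n0 = int((y_true == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auc undefined: only one class present")
    ranks = stats.rankdata(y_score)
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(y_true: np.ndarray, y_score: np.ndarray) -> np.ndarray:
    """Empirical ROC as (FPR, TPR) points from (0,0) to (1,1)."""
    from sklearn.metrics import roc_curve

    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("roc undefined: only one class present")
    fpr, tpr, _ = roc_curve(y_true, y_score, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def confusion_metrics(
    y_true: np.ndarray, y_score: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """ACC/F1/SENS/SPEC/PPV/NPV/MCC at a score threshold.

    Undefined ratios (zero denominators) are reported as 0 with a logged
    warning rather than NaN.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    y_true = np.asarray(y_true).astype(int)
    pred = (np.asarray(y_score, dtype=np.float64) >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())

    def ratio(num, den, name):
        if den == 0:
            log.warning("confusion_metrics: %s undefined (0 denominator); using 0",
                        name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    ppv = ratio(tp, tp + fp, "PPV")
    npv = ratio(tn, tn + fn, "NPV")
    acc = (tp + tn) / len(y_true)
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "F1")
    mcc_den = np.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = ratio(tp * tn - fp * fn, mcc_den, "MCC")
    return {
        "acc": acc, "f1": f1, "sens": sens, "spec": spec,
        "ppv": ppv, "npv": npv, "mcc": mcc,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


@dataclass
class MetricsRow:
    """The metric panel for one (ROI, modality-combination) model."""

    roi: str
    modalities: tuple[str, ...]
    auc: float
    acc: float
    f1: float
    sens: float
    spec: float
    ppv: float
    npv: float
    mcc: float
    fold_metrics: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def group(self) -> str:
        return GROUP_BY_SIZE[len(self.modalities)]

    @property
    def label(self) -> str:
        return combination_label(self.modalities)

    def as_dict(self) -> dict:
        return {
            "ROI": self.roi, "Modality": self.group, "Model": self.label,
            "AUC": self.auc, "ACC": self.acc, "F1": self.f1, "SENS": self.sens,
            "SPEC": self.spec, "PPV": self.ppv, "NPV": self.npv, "MCC": self.mcc,
        }


# ---------------------------------------------------------------------------
# Cohort statistics


def chi_squared_test(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared on a contingency table (no continuity correction
    by default, matching common statistical-package practice)."""
    counts = np.asarray(counts, dtype=np.float64)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        log.warning("chi_squared_test: a margin is zero; expected counts of 0")
    res = stats.chi2_contingency(counts, correction=correction)
    return float(res.statistic), float(res.pvalue)


def t_test_from_summary(
    mean1, sd1, n1, mean2, sd2, n2, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample Student's t-test from summary statistics."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def cohort_stats(
    characteristics: pd.DataFrame,
    group_col: str = "label",
    categorical: tuple[str, ...] = ("sex", "tumor_type"),
    continuous: tuple[str, ...] = ("age",),
    correction: bool = False,
) -> pd.DataFrame:
    """Group-comparison table: chi-squared for categorical rows, Student's
    t (equal variances) for continuous rows."""
    rows = []
    g = characteristics[group_col]
    for col in categorical:
        table = pd.crosstab(characteristics[col], g)
        stat, p = chi_squared_test(table.to_numpy(), correction=correction)
        rows.append({"parameter": col, "test": "chi-squared",
                     "statistic": stat, "p_value": p})
    for col in continuous:
        a = characteristics.loc[g == g.unique()[0], col]
        b = characteristics.loc[g == g.unique()[1], col]
        res = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"parameter": col, "test": "t-test",
                     "statistic": float(res.statistic),
                     "p_value": float(res.pvalue)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The model grid


@dataclass
class GridResult:
    rows: list[MetricsRow]
    errors: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.rows])

    @property
    def best(self) -> MetricsRow:
        """Highest average accuracy; ties broken by AUC."""
        return max(self.rows, key=lambda r: (r.acc, r.auc))


def run_model_grid(
    table,
    labels: np.ndarray,
    train_config=None,
    n_folds: int = 5,
    seed: int = 0,
    rois: tuple[str, ...] = ROIS,
    combinations: tuple[tuple[str, ...], ...] = MODALITY_COMBINATIONS,
) -> GridResult:
    """Train and evaluate one model per (ROI, modality combination).

    ``table`` is a *raw* feature table containing all 8 region-modality
    column groups; Z-scoring is refit on the training rows of each fold.
    Failures in a single row are recorded and do not abort the grid.
    """
    from .model import CamNet  # local import: model builds on this module

    rows: list[MetricsRow] = []
    errors: dict[str, str] = {}
    for roi in rois:
        for combo in combinations:
            name = f"{roi}:{combination_label(combo)}"
            try:
                res = CamNet(
                    table, labels, rois=(roi,), modalities=combo,
                    train_config=train_config,
                ).fit(n_folds=n_folds, seed=seed)
                rows.append(res.metrics_row)
            except Exception as err:  # noqa: BLE001 - row-level isolation
                log.warning("model %s failed: %s", name, err)
                errors[name] = str(err)
    return GridResult(rows=rows, errors=errors)
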