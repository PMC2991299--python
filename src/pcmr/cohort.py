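"""Evaluation statistics: overlap, inter-operator variability, group
comparison, correlation and ROC characterisation.

These are the tools used to judge the pipeline: Dice overlap between repeated
segmentations, the paired-measurement variability (absolute difference in
percent of the mean), Mann-Whitney group comparison, Pearson correlation
against echocardiographic values, and a full ROC sweep with a Youden-optimal
operating point (sensitivity, specificity, NPV, PPV, accuracy).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PcmrError, ValidationError

EXACT_MW_MAX_N = 12


def overlap_percentage(mask_a: np.ndarray, mask_b: np.ndarray,
                       method: str = "dice") -> float:
    """Percentage of overlap between two binary masks.

    Default is the Dice coefficient x100, ``200 |A^B| / (|A|+|B|)``;
    ``method='iou'`` gives intersection-over-union x100 instead.  Two empty
    masks are identical and score 100.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 100.0
    inter = int((a & b).sum())
    if method == "dice":
        return 200.0 * inter / (na + nb)
    if method == "iou":
        return 100.0 * inter / (na + nb - inter)
    raise ValidationError(f"unknown overlap method {method!r}")


def variability_pct(x1: float, x2: float) -> float:
    """Absolute difference of a repeated measurement in percent of the mean."""
    if x1 == 0 and x2 == 0:
        return 0.0
    mean = (x1 + x2) / 2.0
    if mean == 0:
        raise PcmrError("variability undefined: repeated values average to 0")
    return 100.0 * abs(x1 - x2) / abs(mean)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group a (midranks for ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (for group A) and two-sided p value.

    For ``nA + nB <= 12`` the p value is exact, by enumerating every
    assignment of the pooled values to the two groups (midranks make this
    valid with ties as well); larger samples use the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    u = _u_statistic(a, b)
    n = a.size + b.size
    if n <= EXACT_MW_MAX_N:
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        offset = a.size * (a.size + 1) / 2.0
        u_obs_low = min(u, a.size * b.size - u)
        count = 0
        total = 0
        for comb in itertools.combinations(range(n), a.size):
            u_perm = ranks[list(comb)].sum() - offset
            total += 1
            if min(u_perm, a.size * b.size - u_perm) <= u_obs_low + 1e-9:
                count += 1
        return u, count / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return u, float(res.pvalue)


def pearson(x, y) -> tuple[float, float, float]:
    """Sample Pearson r and the ordinary least-squares line y = slope*x + b."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("zero variance in x or y")
    lr = stats.linregress(x, y)
    return float(lr.rvalue), float(lr.slope), float(lr.intercept)


@dataclass
class RocResult:
    """ROC sweep with the Youden-optimal operating point.

    ``orientation`` is +1 when higher values predict the positive class, -1
    otherwise (the reported orientation always has AUC >= 0.5).  The threshold
    sweep arrays cover all midpoints between consecutive sorted unique values.
    """

    auc: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    npv: float
    ppv: float
    accuracy: float
    orientation: int
    thresholds: np.ndarray = field(repr=False)
    sensitivities: np.ndarray = field(repr=False)
    specificities: np.ndarray = field(repr=False)

    def to_row(self) -> dict:
        return {"Sensitivity": self.sensitivity, "Specificity": self.specificity,
                "NPV": self.npv, "PPV": self.ppv, "Accuracy": self.accuracy,
                "ROC threshold": self.optimal_threshold, "AUC": self.auc}


def _sweep(values: np.ndarray, positive: np.ndarray, orientation: int):
    """Confusion counts at each midpoint threshold for one orientation.

    With orientation +1 a sample is called positive when value > threshold;
    with -1 when value < threshold.
    """
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    rows = []
    for thr in mids:
        pred = values > thr if orientation == 1 else values < thr
        tp = int((pred & positive).sum())
        fp = int((pred & ~positive).sum())
        rows.append((thr, tp / n_pos, 1.0 - fp / n_neg, tp, fp))
    return mids, rows, n_pos, n_neg


def _auc(values: np.ndarray, positive: np.ndarray, orientation: int) -> float:
    """Trapezoidal area under the ROC path over all thresholds."""
    uniq = np.unique(values)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    # threshold path from "call nothing positive" to "call everything positive"
    pts = [(0.0, 0.0)]
    cuts = uniq if orientation == 1 else uniq[::-1]
    for c in cuts:
        pred = values >= c if orientation == 1 else values <= c
        tp = int((pred & positive).sum())
        fp = int((pred & ~positive).sum())
        pts.append((fp / n_neg, tp / n_pos))
    pts.append((1.0, 1.0))
    pts = np.array(sorted(set(pts)))
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc(values, labels, positive_group) -> RocResult:
    """ROC analysis of one parameter against a binary group label.

    Both orientations are tried and the one with AUC >= 0.5 is reported.  The
    optimal threshold maximises Youden's J (sensitivity + specificity - 1);
    ties are broken by higher accuracy, then lower threshold.
    """
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    positive = labels == positive_group
    if not positive.any() or positive.all():
        raise ValidationError("both classes must be present")
    if np.unique(values).size < 2:
        raise ValidationError("all values identical; ROC undefined")

    auc_hi = _auc(values, positive, +1)
    orientation = 1 if auc_hi >= 0.5 else -1
    auc = auc_hi if orientation == 1 else _auc(values, positive, -1)

    mids, rows, n_pos, n_neg = _sweep(values, positive, orientation)
    n = n_pos + n_neg
    best = None
    sens_arr, spec_arr = [], []
    for thr, sens, spec, tp, fp in rows:
        sens_arr.append(sens)
        spec_arr.append(spec)
        acc = (tp + (n_neg - fp)) / n
        key = (-(sens + spec - 1.0), -acc, thr)
        if best is None or key < best[0]:
            best = (key, (thr, sens, spec, tp, fp, acc))
    thr, sens, spec, tp, fp = best[1][:5]
    acc = best[1][5]
    fn = n_pos - tp
    tn = n_neg - fp
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return RocResult(auc=auc, optimal_threshold=float(thr), sensitivity=sens,
                     specificity=spec, npv=npv, ppv=ppv, accuracy=acc,
                     orientation=orientation, thresholds=mids,
                     sensitivities=np.array(sens_arr),
                     specificities=np.array(spec_arr))


def cohort_analysis(table: pd.DataFrame, group_col: str,
                    positive_group: str = "patient",
                    parameters: list[str] | None = None) -> pd.DataFrame:
    """Per-parameter cohort summary: group means +/- SD, Mann-Whitney p and
    the ROC operating point, one row per parameter column.

    Missing values are dropped per parameter.  Columns mirror the standard
    report: mean/SD per group, p value, Sensitivity, Specificity, NPV, PPV,
    Accuracy, ROC threshold, AUC.
    """
    if group_col not in table.columns:
        raise ValidationError(f"group column {group_col!r} not in table")
    groups = table[group_col].dropna().unique()
    if len(groups) != 2:
        raise ValidationError(f"group labels must be binary, got {list(groups)}")
    if positive_group not in groups:
        raise ValidationError(f"positive group {positive_group!r} not among {list(groups)}")
    negative_group = [g for g in groups if g != positive_group][0]
    if parameters is None:
        parameters = [c for c in table.columns
                      if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for param in parameters:
        sub = table[[param, group_col]].dropna()
        a = sub.loc[sub[group_col] == negative_group, param].to_numpy()
        b = sub.loc[sub[group_col] == positive_group, param].to_numpy()
        row = {"parameter": param,
               f"{negative_group}_mean": a.mean() if a.size else np.nan,
               f"{negative_group}_sd": a.std(ddof=1) if a.size > 1 else np.nan,
               f"{positive_group}_mean": b.mean() if b.size else np.nan,
               f"{positive_group}_sd": b.std(ddof=1) if b.size > 1 else np.nan}
        try:
            _, p = mann_whitney(a, b)
            row["p_value"] = p
        except PcmrError:
            row["p_value"] = np.nan
        try:
            r = roc(sub[param].to_numpy(),
                    sub[group_col].to_numpy(), positive_group)
            row.update(r.to_row())
        except PcmrError:
            row.update({k: np.nan for k in ("Sensitivity", "Specificity", "NPV",
                                            "PPV", "Accuracy", "ROC threshold",
                                            "AUC")})
        rows.append(row)
    return pd.DataFrame(rows)
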