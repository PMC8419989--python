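"""Clinical summary statistics: group tests from printed summaries,
reviewer confusion-matrix metrics, and feature-clinical correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lesionrad.tables import CLINICAL_COLUMNS, FeatureTable


@dataclass
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def welch_t_from_summary(a: SummaryStats, b: SummaryStats,
                         equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test from (mean, sd, n) summaries; Welch by default.

    Returns (t, df, two-sided p).  The Welch statistic is
    ``t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with the
    Welch-Satterthwaite degrees of freedom; ``equal_var=True`` gives the
    pooled-variance Student variant.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if equal_var:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = float(a.n + b.n - 2)
    else:
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    if se == 0:
        return 0.0, float(df), 1.0
    t = (a.mean - b.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def yates_chi2(table) -> tuple[float, float]:
    """Continuity-corrected chi-squared test of a 2x2 table.

    ``chi2 = sum(max(0, |O - E| - 0.5)^2 / E)`` with df = 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin")
    expected = row @ col / total
    chi2 = float(np.sum(np.maximum(0.0, np.abs(obs - expected) - 0.5) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int
    positive_class: str = "NMO"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and the hard-classifier AUC.

    For a binary (hard) predictor the rank-based AUC equals
    ``(sensitivity + specificity) / 2`` — balanced accuracy.
    """
    npos = cm.tp + cm.fn
    nneg = cm.tn + cm.fp
    if npos == 0 or nneg == 0:
        raise ValueError("a class margin is empty; metrics undefined")
    sens = cm.tp / npos
    spec = cm.tn / nneg
    return {"accuracy": (cm.tp + cm.tn) / cm.total, "sensitivity": sens,
            "specificity": spec, "hard_auc": (sens + spec) / 2.0}


@dataclass
class InferredSplit:
    matrix: ConfusionMatrix
    orientation: str            # which class is "positive"
    candidates: list            # every (n_pos, orientation) consistent split
    ambiguous: bool


def infer_class_totals(total: int, correct: int, mis_pos_as_neg: int,
                       mis_neg_as_pos: int, printed_sens: float,
                       printed_spec: float, positive: str = "NMO",
                       negative: str = "MS", tol: float = 5e-4) -> InferredSplit:
    """Reconstruct class totals from misdiagnosis counts + printed metrics.

    Enumerates every integer positive-class total (in both orientations of
    which misdiagnosis count belongs to the positive class) and keeps the
    splits whose sensitivity and specificity round to the printed values.
    Raises when no split is consistent; flags when several are.
    """
    if correct + mis_pos_as_neg + mis_neg_as_pos != total:
        raise ValueError("correct + misdiagnosed must equal total")
    candidates = []
    for orientation, (fn, fp) in ((positive, (mis_pos_as_neg, mis_neg_as_pos)),
                                  (negative, (mis_neg_as_pos, mis_pos_as_neg))):
        for n_pos in range(1, total):
            tp = n_pos - fn
            tn = total - n_pos - fp
            if tp < 0 or tn < 0:
                continue
            sens = tp / n_pos
            spec = tn / (total - n_pos)
            if abs(sens - printed_sens) < tol and abs(spec - printed_spec) < tol:
                candidates.append((n_pos, orientation,
                                   ConfusionMatrix(tp, fn, tn, fp, orientation)))
    if not candidates:
        raise ValueError("no integer class split is consistent with the printed metrics")
    unique = {(c[0], c[2].tp, c[2].tn) for c in candidates}
    ambiguous = len(unique) > 1
    n_pos, orientation, cm = candidates[0]
    return InferredSplit(matrix=cm, orientation=orientation,
                         candidates=[(c[0], c[1]) for c in candidates],
                         ambiguous=ambiguous)


def feature_clinical_correlation(table: FeatureTable, phenotype,
                                 covariates=CLINICAL_COLUMNS,
                                 method: str = "pearson", alpha: float = 0.05):
    """Pairwise correlation (+p, +significance) of phenotype features and covariates.

    Sex must be 0/1-coded.  Returns (r, p, significant) DataFrames; the r
    matrix is symmetric with a unit diagonal.
    """
    feats = list(phenotype.features) if hasattr(phenotype, "features") else list(phenotype)
    cols = feats + [c for c in covariates if c not in feats]
    frame = table.frame[cols]
    if table.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = frame.iloc[:, i], frame.iloc[:, j]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                raise ValueError(f"constant column among {cols[i]}, {cols[j]}")
            res = corr_fn(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = (p_df < alpha) & ~np.eye(k, dtype=bool)
    return r_df, p_df, sig
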