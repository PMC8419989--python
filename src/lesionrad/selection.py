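"""Multi-level feature selection.

The univariate level screens features with two Wilcoxon rank-sum filters:
a scanner-robustness filter (keep features *not* significantly different
between 1.5 T and 3 T, compared within each diagnostic class so that class
imbalance across scanners cannot confound the comparison) and a
class-relevance filter (keep features significantly different between MS and
NMO).  The multivariate level runs random-forest sequential forward selection
(RF-SFS) inside each modality (T2, MPR, clinical), then fuses the three
preliminary phenotypes with a final RF-SFS pass — the pyramid search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from lesionrad.forest import BalancedRandomForestClassifier
from lesionrad.tables import CLINICAL_COLUMNS, FeatureTable

DEFAULT_POSITIVE = "NMO"


# ---------------------------------------------------------------------------
# univariate level


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    Exact enumeration when the pooled sample has <= 12 observations and no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.  When every pooled value is identical the variance
    degenerates and p is defined as 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    w = float(stats.rankdata(pooled)[: x.size].sum())
    if np.ptp(pooled) == 0:
        return w, 1.0
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return w, float(res.pvalue)


def univariate_auc(values, labels, positive=DEFAULT_POSITIVE, orient: bool = True) -> float:
    """Univariate AUC via the Mann-Whitney identity (ties count 1/2).

    With ``orient=True`` the reported value is ``max(AUC, 1 - AUC)`` so that a
    feature's discriminability does not depend on its sign.
    """
    y = np.asarray(labels) == positive
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(y, np.asarray(values, dtype=float)))
    return max(auc, 1.0 - auc) if orient else auc


@dataclass
class UnivariateRecord:
    feature: str
    W: float
    p_robust: float
    p_class: float
    auc_uni: float


def robustness_filter(table: FeatureTable, alpha: float = 0.05,
                      candidates=None, within_class: bool = True):
    """Keep features with no significant scanner (1.5 T vs 3 T) difference.

    A feature is removed when the rank-sum comparison between scanner strata
    is significant (p < alpha) in either diagnostic class (``within_class``),
    or pooled over classes otherwise.  Returns (kept names, {name: p_robust}),
    where p_robust is the smaller of the per-class p-values.
    """
    cols = list(candidates) if candidates is not None else table.feature_names
    scanners = table.scanner
    strata = sorted(scanners.unique())
    if len(strata) < 2:
        raise ValueError("robustness filter needs both scanner strata")
    groups = [table.labels.unique()] if not within_class else [[c] for c in sorted(table.labels.unique())]
    kept, pvals = [], {}
    for col in cols:
        p_min = 1.0
        for grp in groups:
            sel = table.labels.isin(grp)
            a = table.frame.loc[sel & (scanners == strata[0]), col]
            b = table.frame.loc[sel & (scanners == strata[1]), col]
            if len(a) == 0 or len(b) == 0:
                continue
            _, p = rank_sum_test(a, b)
            p_min = min(p_min, p)
        pvals[col] = p_min
        if p_min >= alpha:
            kept.append(col)
    return kept, pvals


def relevance_filter(table: FeatureTable, alpha: float = 0.05, candidates=None):
    """Keep features whose MS-vs-NMO rank-sum comparison is significant (p < alpha)."""
    cols = list(candidates) if candidates is not None else table.feature_names
    labels = table.labels
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("relevance filter needs both classes")
    kept, pvals = [], {}
    for col in cols:
        a = table.frame.loc[labels == classes[0], col]
        b = table.frame.loc[labels == classes[1], col]
        _, p = rank_sum_test(a, b)
        pvals[col] = p
        if p < alpha:
            kept.append(col)
    return kept, pvals


def univariate_records(table: FeatureTable, candidates=None,
                       positive=DEFAULT_POSITIVE) -> list[UnivariateRecord]:
    """Full univariate screening record per feature (W, p_robust, p_class, AUC)."""
    cols = list(candidates) if candidates is not None else table.feature_names
    _, p_rob = robustness_filter(table, alpha=0.0, candidates=cols)
    records = []
    labels = table.labels
    classes = sorted(labels.unique())
    for col in cols:
        a = table.frame.loc[labels == classes[0], col]
        b = table.frame.loc[labels == classes[1], col]
        w, p_class = rank_sum_test(a, b)
        records.append(UnivariateRecord(
            feature=col, W=w, p_robust=p_rob[col], p_class=p_class,
            auc_uni=univariate_auc(table.frame[col], labels, positive)))
    return records


# ---------------------------------------------------------------------------
# multivariate level (RF-SFS)


@dataclass
class Phenotype:
    """An ordered selected-feature panel with its selection trace.

    ``features``/``trace`` are truncated at the global trace maximum (the
    SFS stopping point); ``full_trace`` keeps the score after every step that
    was actually evaluated.
    """

    features: list[str]
    trace: list[float]
    full_trace: list[float] = field(default_factory=list)
    full_selection: list[str] = field(default_factory=list)
    cap: int = 0

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("phenotype contains duplicate features")
        if len(self.trace) != len(self.features):
            raise ValueError("trace length must equal the number of features")

    @property
    def max_auc(self) -> float:
        return max(self.trace) if self.trace else float("nan")

    def by_modality(self) -> dict[str, list[str]]:
        out = {"T2": [], "MPR": [], "clinical": []}
        for f in self.features:
            if f.startswith("H-T2-"):
                out["T2"].append(f)
            elif f.startswith("H-MPR-"):
                out["MPR"].append(f)
            else:
                out["clinical"].append(f)
        return out

    def to_dict(self) -> dict:
        return {"features": self.features, "trace": self.trace,
                "full_trace": self.full_trace, "full_selection": self.full_selection,
                "cap": self.cap, "by_modality": self.by_modality()}

    @classmethod
    def from_dict(cls, d: dict) -> "Phenotype":
        return cls(features=list(d["features"]), trace=list(d["trace"]),
                   full_trace=list(d.get("full_trace", d["trace"])),
                   full_selection=list(d.get("full_selection", d["features"])),
                   cap=int(d.get("cap", 0)))


def _cv_auc(X: np.ndarray, y: np.ndarray, seed: int, n_estimators: int, k: int) -> float:
    """Mean stratified k-fold CV AUC of a balanced RF on the candidate set."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        clf = BalancedRandomForestClassifier(n_estimators=n_estimators,
                                             random_state=seed).fit(X[tr], y[tr])
        pos = int(np.flatnonzero(clf.classes_ == 1)[0])
        aucs.append(roc_auc_score(y[te], clf.predict_proba(X[te])[:, pos]))
    return float(np.mean(aucs))


def rf_sfs(table: FeatureTable, candidates, cap: int = 10, seed: int = 0,
           positive=DEFAULT_POSITIVE, n_estimators: int = 50, cv: int = 5,
           patience: int | None = 3) -> Phenotype:
    """Greedy sequential forward selection scored by balanced-RF CV AUC.

    At each step the candidate maximising the internal cross-validated AUC of
    the current set + candidate is added (ties broken toward the earlier
    candidate, i.e. the lower feature id).  Selection stops at ``cap`` features
    or after ``patience`` consecutive steps without improving the global trace
    maximum; the returned phenotype is the prefix achieving that maximum.
    Deterministic for a fixed seed.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate features")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    y = (np.asarray(table.labels) == positive).astype(int)
    data = table.frame[candidates].to_numpy(dtype=float)
    col_of = {c: i for i, c in enumerate(candidates)}

    selected: list[str] = []
    trace: list[float] = []
    best_global = -np.inf
    stalled = 0
    remaining = list(candidates)
    step = 0
    while remaining and len(selected) < cap:
        step_seed = (seed * 1000003 + step) % (2**31)
        best_score, best_col = -np.inf, None
        for c in remaining:
            cols = [col_of[f] for f in selected] + [col_of[c]]
            score = _cv_auc(data[:, cols], y, step_seed, n_estimators, cv)
            if score > best_score + 1e-12:
                best_score, best_col = score, c
        selected.append(best_col)
        remaining.remove(best_col)
        trace.append(best_score)
        if best_score > best_global + 1e-12:
            best_global = best_score
            stalled = 0
        else:
            stalled += 1
        if patience is not None and stalled >= patience:
            break
        step += 1
    stop = int(np.argmax(trace))
    return Phenotype(features=selected[: stop + 1], trace=trace[: stop + 1],
                     full_trace=trace, full_selection=selected, cap=cap)


# ---------------------------------------------------------------------------
# pyramid


@dataclass
class PyramidResult:
    phenotype: Phenotype
    preliminary: dict[str, Phenotype]
    robust_survivors: list[str]
    relevant_survivors: list[str]
    p_robust: dict[str, float]
    p_class: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype.to_dict(),
            "preliminary": {k: v.to_dict() for k, v in self.preliminary.items()},
            "robust_survivors": self.robust_survivors,
            "relevant_survivors": self.relevant_survivors,
            "p_robust": self.p_robust,
            "p_class": self.p_class,
        }


def pyramid_select(table: FeatureTable, alpha: float = 0.05,
                   caps: dict[str, int] | int = 10, fusion_cap: int = 8,
                   seed: int = 0, positive=DEFAULT_POSITIVE,
                   n_estimators: int = 50, cv: int = 5,
                   patience: int | None = 3) -> PyramidResult:
    """The full multi-level pipeline: filters, per-modality RF-SFS, fusion RF-SFS.

    Radiomic features pass the scanner-robustness and class-relevance filters;
    the four clinical covariates enter the clinical SFS directly (they are not
    scanner-dependent by design and the published panel retains EDSS despite
    its univariate strength, so the radiomic filters are not applied to them).
    """
    modmap = table.modality_map()
    robust, p_rob = robustness_filter(table, alpha=alpha)
    relevant, p_cls = relevance_filter(table, alpha=alpha, candidates=robust)
    if isinstance(caps, int):
        caps = {m: caps for m in modmap}

    preliminary: dict[str, Phenotype] = {}
    for mod, cols in modmap.items():
        if mod == "clinical":
            cands = [c for c in cols]
        else:
            cands = [c for c in cols if c in set(relevant)]
        if not cands:
            preliminary[mod] = Phenotype(features=[], trace=[], cap=caps.get(mod, 0))
            continue
        preliminary[mod] = rf_sfs(table, cands, cap=caps.get(mod, 10),
                                  seed=seed, positive=positive,
                                  n_estimators=n_estimators, cv=cv, patience=patience)

    fused = [f for mod in ("T2", "MPR", "clinical") for f in preliminary[mod].features]
    phenotype = rf_sfs(table, fused, cap=fusion_cap, seed=seed + 1,
                       positive=positive, n_estimators=n_estimators,
                       cv=cv, patience=patience)
    return PyramidResult(phenotype=phenotype, preliminary=preliminary,
                         robust_survivors=robust, relevant_survivors=relevant,
                         p_robust=p_rob, p_class=p_cls)
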