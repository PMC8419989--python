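"""Balanced random-forest diagnosis: training, CV, bootstrap evaluation.

The modelling surface follows the statsmodels convention: build an
:class:`MMRFModel` from a feature table and a phenotype, call :meth:`fit` and
receive :class:`MMRFResults` carrying the trained ensemble, cross-validated
metrics (mean, dispersion, CI and the AUC relative standard deviation
``AUC_RSD = AUC_STD / AUC_MEAN``), a ``summary()`` table, and methods for
independent-test bootstrap evaluation and Shapley explanation.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from lesionrad.forest import BalancedRandomForestClassifier
from lesionrad.tables import FeatureTable

DEFAULT_POSITIVE = "NMO"


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(scores, labels, positive=DEFAULT_POSITIVE,
                    threshold: float = 0.5) -> dict[str, float]:
    """AUC (Mann-Whitney identity), accuracy, sensitivity, specificity.

    ``scores`` are positive-class probabilities; sensitivity/specificity are
    taken w.r.t. the declared positive class at the given threshold.
    """
    y = np.asarray(labels) == positive
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    scores = np.asarray(scores, dtype=float)
    pred = scores >= threshold
    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    return {
        "auc": float(roc_auc_score(y, scores)),
        "accuracy": (tp + tn) / y.size,
        "sensitivity": tp / int(y.sum()),
        "specificity": tn / int((~y).sum()),
    }


def auc_rsd(aucs) -> float:
    """Relative standard deviation of a set of AUCs: sample SD / mean."""
    aucs = np.asarray(aucs, dtype=float)
    mean = aucs.mean()
    if mean <= 0:
        raise ValueError("mean AUC must be > 0")
    sd = aucs.std(ddof=1) if aucs.size > 1 else 0.0
    return float(sd / mean)


@dataclass
class MetricSummary:
    mean: float
    std: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:
        return f"{self.mean:.3f} ± {self.std:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f})"


@dataclass
class EvalReport:
    """Per-metric mean/dispersion/CI over CV folds or bootstrap resamples."""

    auc: MetricSummary
    accuracy: MetricSummary
    sensitivity: MetricSummary
    specificity: MetricSummary
    auc_rsd: float
    n_resamples: int
    positive_class: str
    kind: str = "cv"
    flags: list[str] = field(default_factory=list)

    @property
    def auc_mean(self) -> float:
        return self.auc.mean

    @property
    def auc_std(self) -> float:
        return self.auc.std

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        d = dict(d)
        for m in ("auc", "accuracy", "sensitivity", "specificity"):
            d[m] = MetricSummary(**d[m])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __str__(self) -> str:
        lines = [f"EvalReport ({self.kind}, n_resamples={self.n_resamples}, "
                 f"positive={self.positive_class})"]
        for name in ("auc", "accuracy", "sensitivity", "specificity"):
            lines.append(f"  {name:<12} {getattr(self, name)}")
        lines.append(f"  {'auc_rsd':<12} {self.auc_rsd:.4f}")
        return "\n".join(lines)


def _summarize(values: list[dict[str, float]], kind: str, positive: str,
               flags: list[str] | None = None) -> EvalReport:
    frame = pd.DataFrame(values)
    n = len(frame)
    sums = {}
    for m in ("auc", "accuracy", "sensitivity", "specificity"):
        v = frame[m].to_numpy()
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if n > 1 else 0.0
        if kind == "bootstrap" and n > 1:
            lo, hi = (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        else:
            half = 1.959963984540054 * sd / np.sqrt(n) if n > 1 else 0.0
            lo, hi = max(0.0, mean - half), min(1.0, mean + half)
        sums[m] = MetricSummary(mean=mean, std=sd,
                                ci_low=min(lo, mean), ci_high=max(hi, mean))
    return EvalReport(auc=sums["auc"], accuracy=sums["accuracy"],
                      sensitivity=sums["sensitivity"], specificity=sums["specificity"],
                      auc_rsd=auc_rsd(frame["auc"].to_numpy()),
                      n_resamples=n, positive_class=positive, kind=kind,
                      flags=list(flags or []))


# ---------------------------------------------------------------------------
# model bundle


@dataclass
class ModelBundle:
    """A trained ensemble restricted to a phenotype's columns."""

    clf: BalancedRandomForestClassifier
    phenotype: list[str]
    positive_class: str
    class_prior: dict[str, float]
    seed: int
    reference_stats: pd.DataFrame | None = None

    def predict_scores(self, table) -> np.ndarray:
        """Positive-class probability for each subject."""
        frame = table.frame if isinstance(table, FeatureTable) else table
        X = frame[self.phenotype].to_numpy(dtype=float)
        pos = int(np.flatnonzero(self.clf.classes_ == self.positive_class)[0])
        return self.clf.predict_proba(X)[:, pos]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "bundle": self}, fh)
        sidecar = {"version": 1, "phenotype": self.phenotype, "seed": self.seed,
                   "positive_class": self.positive_class, "class_prior": self.class_prior}
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != 1:
            raise ValueError("unsupported model container version")
        return payload["bundle"]


def train_balanced_rf(table: FeatureTable, phenotype, seed: int = 0,
                      n_trees: int = 500, positive=DEFAULT_POSITIVE,
                      max_depth=None) -> ModelBundle:
    """Train the balanced-bootstrap, balanced-weight RF on phenotype columns."""
    phenotype = list(phenotype.features) if hasattr(phenotype, "features") else list(phenotype)
    if not phenotype:
        raise ValueError("empty phenotype")
    missing = [c for c in phenotype if c not in table.frame.columns]
    if missing:
        raise ValueError(f"phenotype columns absent from table: {missing}")
    y = np.asarray(table.labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    clf = BalancedRandomForestClassifier(n_estimators=n_trees, max_depth=max_depth,
                                         random_state=seed)
    clf.fit(table.frame[phenotype].to_numpy(dtype=float), y)
    prior = table.labels.value_counts(normalize=True).to_dict()
    return ModelBundle(clf=clf, phenotype=phenotype, positive_class=positive,
                       class_prior=prior, seed=seed,
                       reference_stats=table.reference_stats)


# ---------------------------------------------------------------------------
# validation


def cross_validate(table: FeatureTable, phenotype, k: int = 10, seed: int = 0,
                   n_trees: int = 500, positive=DEFAULT_POSITIVE) -> EvalReport:
    """Stratified k-fold CV; per-fold metrics summarised as mean/SD/RSD."""
    phenotype = list(phenotype.features) if hasattr(phenotype, "features") else list(phenotype)
    y = np.asarray(table.labels)
    counts = pd.Series(y).value_counts()
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the minority-class count ({counts.min()})")
    X = table.frame[phenotype].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for i, (tr, te) in enumerate(skf.split(X, y)):
        clf = BalancedRandomForestClassifier(n_estimators=n_trees,
                                             random_state=seed + i).fit(X[tr], y[tr])
        pos = int(np.flatnonzero(clf.classes_ == positive)[0])
        scores = clf.predict_proba(X[te])[:, pos]
        per_fold.append(compute_metrics(scores, y[te], positive))
    return _summarize(per_fold, "cv", positive)


def bootstrap_evaluate(bundle: ModelBundle, test: FeatureTable, B: int = 1000,
                       seed: int = 0, stratified: bool = True) -> EvalReport:
    """B bootstrap resamples of the test set; mean +/- sample SD + percentile CI.

    Stratified resampling redraws within each class (class counts preserved);
    with ``stratified=False`` plain resamples lacking a class are redrawn.
    """
    y = np.asarray(test.labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("test set must contain both classes")
    scores = bundle.predict_scores(test)
    rng = np.random.default_rng(seed)
    n = y.size
    reps = []
    flags = []
    if B < 2:
        flags.append("dispersion undefined for B < 2; reported as 0")
    for _ in range(max(B, 1)):
        if stratified:
            idx = np.concatenate([rng.choice(np.flatnonzero(y == c),
                                             size=int(np.sum(y == c)), replace=True)
                                  for c in classes])
        else:
            while True:
                idx = rng.integers(0, n, size=n)
                if np.unique(y[idx]).size == classes.size:
                    break
        reps.append(compute_metrics(scores[idx], y[idx], bundle.positive_class))
    return _summarize(reps, "bootstrap", bundle.positive_class, flags)


# ---------------------------------------------------------------------------
# statsmodels-style surface


class MMRFModel:
    """Multi-parametric multivariate random forest diagnosis model.

    Parameters
    ----------
    table : FeatureTable
        Training cohort (standardised or raw; trees are scale-invariant).
    phenotype : Phenotype or list of str
        The selected feature panel the model is restricted to.
    positive_class : str
        Label treated as "positive" for sensitivity/specificity (default NMO).
    """

    def __init__(self, table: FeatureTable, phenotype, positive_class=DEFAULT_POSITIVE,
                 n_trees: int = 500, seed: int = 0):
        self.table = table
        self.phenotype = (list(phenotype.features) if hasattr(phenotype, "features")
                          else list(phenotype))
        self.positive_class = positive_class
        self.n_trees = n_trees
        self.seed = seed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, phenotype, **kwargs) -> "MMRFModel":
        return cls(FeatureTable.from_dataframe(frame), phenotype, **kwargs)

    @classmethod
    def from_csv(cls, path, phenotype, **kwargs) -> "MMRFModel":
        return cls(FeatureTable.from_csv(path), phenotype, **kwargs)

    def fit(self, cv_folds: int = 10) -> "MMRFResults":
        bundle = train_balanced_rf(self.table, self.phenotype, seed=self.seed,
                                   n_trees=self.n_trees, positive=self.positive_class)
        cv_report = cross_validate(self.table, self.phenotype, k=cv_folds,
                                   seed=self.seed, n_trees=self.n_trees,
                                   positive=self.positive_class)
        return MMRFResults(model=self, bundle=bundle, cv_report=cv_report)


class MMRFResults:
    """Fit results: trained ensemble + cross-validated performance."""

    def __init__(self, model: MMRFModel, bundle: ModelBundle, cv_report: EvalReport):
        self.model = model
        self.bundle = bundle
        self.cv_report = cv_report

    def evaluate(self, test: FeatureTable, B: int = 1000, seed: int | None = None,
                 stratified: bool = True) -> EvalReport:
        return bootstrap_evaluate(self.bundle, test, B=B,
                                  seed=self.model.seed if seed is None else seed,
                                  stratified=stratified)

    def explain(self, rows: FeatureTable | None = None, background: FeatureTable | None = None):
        from lesionrad.explain import explain_table

        rows = rows if rows is not None else self.model.table
        background = background if background is not None else self.model.table
        return explain_table(self.bundle, rows, background)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Multi-parametric Multivariate Random Forest",
            "=" * 60,
            f"subjects: {m.table.n_subjects}   trees: {m.n_trees}   seed: {m.seed}",
            f"positive class: {m.positive_class}   "
            f"class balance: {m.table.class_balance()}",
            "phenotype:",
            *[f"  {f}" for f in m.phenotype],
            str(self.cv_report),
        ]
        return "\n".join(lines)
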