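"""Exact Shapley-value interpretation of the diagnostic model.

Contributions are computed on the positive-class probability scale with the
interventional (marginal) value function: for a coalition S the value is the
mean model output after fixing the features in S to the explained subject's
values and drawing the remaining features from the background table.  With
|phenotype| <= 16 the 2^M coalition lattice is enumerated exhaustively, so the
values are exact up to the background sample (the full training table by
default), and local accuracy (base value + sum of contributions = prediction)
holds to machine precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lesionrad.tables import FeatureTable

MAX_FEATURES = 16


@dataclass
class Explanation:
    """Per-feature Shapley contributions for one subject's prediction."""

    subject_id: str
    base_value: float
    phi: pd.Series           # signed, probability units
    percent: pd.Series       # 100 * |phi| / sum|phi|
    predicted: float
    label: str | None = None

    def to_dict(self) -> dict:
        return {"subject_id": self.subject_id, "base_value": self.base_value,
                "phi": self.phi.to_dict(), "percent": self.percent.to_dict(),
                "predicted": self.predicted, "label": self.label}


def contribution_percent(phi) -> np.ndarray:
    """Normalised absolute contributions: ``100 * |phi_i| / sum|phi|``."""
    phi = np.asarray(phi, dtype=float)
    total = np.abs(phi).sum()
    if total <= 0:
        raise ValueError("all contributions are zero")
    return 100.0 * np.abs(phi) / total


def exact_shapley(predict_fn, x: pd.Series, background: pd.DataFrame,
                  features=None) -> tuple[float, pd.Series, float]:
    """Exhaustive interventional Shapley values.

    Parameters
    ----------
    predict_fn : callable
        Maps an (n, M) array of feature rows to n scalar outputs.
    x : Series
        The record to explain (indexed by feature name).
    background : DataFrame
        Reference sample used to marginalise absent features.

    Returns ``(base_value, phi, predicted)``.
    """
    features = list(features) if features is not None else list(background.columns)
    m = len(features)
    if m > MAX_FEATURES:
        raise ValueError(f"exact enumeration limited to {MAX_FEATURES} features; got {m}")
    bg = background[features].to_numpy(dtype=float)
    if bg.shape[0] == 0:
        raise ValueError("background must be non-empty")
    xv = np.asarray([x[f] for f in features], dtype=float)
    n_bg = bg.shape[0]
    n_coal = 1 << m

    stacked = np.tile(bg, (n_coal, 1))
    for s in range(n_coal):
        block = slice(s * n_bg, (s + 1) * n_bg)
        for i in range(m):
            if s >> i & 1:
                stacked[block, i] = xv[i]
    v = np.asarray(predict_fn(stacked), dtype=float).reshape(n_coal, n_bg).mean(axis=1)

    fact = [math.factorial(k) for k in range(m + 1)]
    phi = np.zeros(m)
    for s in range(n_coal):
        size = bin(s).count("1")
        w = fact[size] * fact[m - size - 1] / fact[m]
        for i in range(m):
            if not s >> i & 1:
                phi[i] += w * (v[s | (1 << i)] - v[s])
    base = float(v[0])
    predicted = float(v[n_coal - 1])
    return base, pd.Series(phi, index=features), predicted


def explain_record(bundle, row: pd.Series, background: FeatureTable | pd.DataFrame,
                   subject_id: str | None = None, label: str | None = None) -> Explanation:
    """Explain one subject's positive-class probability under a trained bundle."""
    bg = background.frame if isinstance(background, FeatureTable) else background
    feats = bundle.phenotype
    pos = int(np.flatnonzero(bundle.clf.classes_ == bundle.positive_class)[0])

    def predict(arr):
        return bundle.clf.predict_proba(arr)[:, pos]

    base, phi, predicted = exact_shapley(predict, row, bg, features=feats)
    return Explanation(
        subject_id=str(subject_id if subject_id is not None else row.name),
        base_value=base, phi=phi,
        percent=pd.Series(contribution_percent(phi), index=feats),
        predicted=predicted, label=label)


def explain_table(bundle, rows: FeatureTable, background: FeatureTable) -> list[Explanation]:
    labels = rows.labels
    return [explain_record(bundle, rows.frame.loc[sid], background,
                           subject_id=sid, label=labels.loc[sid])
            for sid in rows.frame.index]


def global_importance(explanations) -> pd.DataFrame:
    """Mean |phi| per feature, descending; plus the per-subject phi matrix.

    Returns a DataFrame indexed by feature with columns ``importance`` (mean
    absolute contribution) and ``rank``; the raw contribution matrix is
    available via :func:`contribution_matrix` for beeswarm-style reporting.
    """
    if not explanations:
        raise ValueError("no explanations given")
    mat = contribution_matrix(explanations)
    imp = mat.abs().mean(axis=0).sort_values(ascending=False)
    out = pd.DataFrame({"importance": imp})
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def contribution_matrix(explanations) -> pd.DataFrame:
    """Subjects x features matrix of signed Shapley contributions."""
    return pd.DataFrame({e.subject_id: e.phi for e in explanations}).T


def value_contribution_trend(values, phi) -> tuple[float, str]:
    """OLS slope of contribution against feature value and its sign label."""
    values = np.asarray(values, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(values) == 0:
        raise ValueError("feature values are constant")
    slope = float(np.polyfit(values, phi, 1)[0])
    return slope, ("positive" if slope > 0 else "negative" if slope < 0 else "flat")


def explanations_to_json(explanations, path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in explanations], fh, indent=1)


# ---------------------------------------------------------------------------
# plots (waterfall / beeswarm / dependence)


def plot_waterfall(explanation: Explanation, path=None):
    """Per-subject contribution bar chart ordered by |phi|."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = explanation.phi.abs().sort_values().index
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(order) + 1.5))
    vals = explanation.phi[order]
    ax.barh(range(len(order)), vals, color=["#d62728" if v > 0 else "#1f77b4" for v in vals])
    ax.set_yticks(range(len(order)), order)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("contribution to P(positive)")
    ax.set_title(f"{explanation.subject_id}: base {explanation.base_value:.3f} "
                 f"-> predicted {explanation.predicted:.3f}")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_beeswarm(explanations, path=None):
    """Model-level contribution spread per feature (strip plot)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mat = contribution_matrix(explanations)
    order = mat.abs().mean(axis=0).sort_values().index
    rng = np.random.default_rng(0)
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(order) + 1.5))
    for i, feat in enumerate(order):
        y = i + rng.uniform(-0.25, 0.25, size=len(mat))
        ax.scatter(mat[feat], y, s=8, alpha=0.6)
    ax.set_yticks(range(len(order)), order)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("contribution to P(positive)")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_dependence(explanations, feature: str, values: pd.Series, path=None):
    """Contribution vs feature value with the fitted linear trend."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mat = contribution_matrix(explanations)
    phi = mat[feature]
    vals = values.loc[phi.index]
    slope, sign = value_contribution_trend(vals, phi)
    coeffs = np.polyfit(vals, phi, 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(vals, phi, s=12)
    xs = np.linspace(float(vals.min()), float(vals.max()), 50)
    ax.plot(xs, np.polyval(coeffs, xs), color="k", lw=1)
    ax.set_xlabel(feature)
    ax.set_ylabel("contribution")
    ax.set_title(f"{sign} linear relationship (slope {slope:.3g})")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
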