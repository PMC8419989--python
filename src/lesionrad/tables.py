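"""Subjects-by-features tables shared by every pipeline stage.

A :class:`FeatureTable` wraps a pandas DataFrame indexed by ``subject_id``
whose leading columns are the metadata (``diagnosis``, ``scanner``) and the
four clinical covariates (``age``, ``sex``, ``edss``, ``duration``; ``sex``
encoded 0 = female, 1 = male), followed by the radiomic feature columns named
by the extraction registry (``H-<seq>-<filter>-<family>-<stat>``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLINICAL_COLUMNS = ("age", "sex", "edss", "duration")
META_COLUMNS = ("diagnosis", "scanner")


@dataclass
class FeatureTable:
    frame: pd.DataFrame
    standardized: bool = False
    #: per-column (mean, sd) of the reference table used for standardisation
    reference_stats: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS + CLINICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing required columns: {missing}")
        if self.frame.columns.duplicated().any():
            dupes = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise ValueError(f"duplicate columns: {dupes}")

    # -- accessors -----------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def feature_names(self) -> list[str]:
        """Radiomic feature columns (everything beyond metadata + clinical)."""
        reserved = set(META_COLUMNS) | set(CLINICAL_COLUMNS)
        return [c for c in self.frame.columns if c not in reserved]

    @property
    def labels(self) -> pd.Series:
        return self.frame["diagnosis"]

    @property
    def scanner(self) -> pd.Series:
        return self.frame["scanner"]

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[self.feature_names]

    @property
    def clinical(self) -> pd.DataFrame:
        return self.frame[list(CLINICAL_COLUMNS)]

    @property
    def data(self) -> pd.DataFrame:
        """Model-ready columns: clinical covariates + radiomic features."""
        return self.frame[list(CLINICAL_COLUMNS) + self.feature_names]

    def modality_map(self) -> dict[str, list[str]]:
        """Partition of candidate columns into T2 / MPR / clinical."""
        return {
            "T2": [c for c in self.feature_names if c.startswith("H-T2-")],
            "MPR": [c for c in self.feature_names if c.startswith("H-MPR-")],
            "clinical": list(CLINICAL_COLUMNS),
        }

    def subset(self, index) -> "FeatureTable":
        return FeatureTable(self.frame.loc[index].copy(), self.standardized, self.reference_stats)

    def class_balance(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    # -- standardisation -----------------------------------------------------

    def standardize(self, reference: "FeatureTable | None" = None,
                    include_clinical: bool = False) -> "FeatureTable":
        """Z-score feature columns using the reference table's mean/SD.

        Zero-SD columns are mapped to 0 and recorded in the returned table's
        ``reference_stats`` with sd = 0 (the degenerate-column flag).
        """
        ref = self if reference is None else reference
        cols = self.feature_names + (list(CLINICAL_COLUMNS) if include_clinical else [])
        if any(c not in ref.frame.columns for c in cols):
            raise ValueError("reference table does not carry the same columns")
        mean = ref.frame[cols].mean()
        sd = ref.frame[cols].std(ddof=0)
        # an effectively-constant column has sd at rounding-noise level
        degenerate = sd <= 1e-12 * np.maximum(1.0, mean.abs())
        out = self.frame.copy()
        safe = sd.mask(degenerate, np.nan)
        out[cols] = ((self.frame[cols] - mean) / safe).fillna(0.0)
        stats = pd.DataFrame({"mean": mean, "sd": sd.mask(degenerate, 0.0)})
        return FeatureTable(out, standardized=True, reference_stats=stats)

    def destandardize(self) -> "FeatureTable":
        """Invert :meth:`standardize` using the stored reference statistics."""
        if not self.standardized or self.reference_stats is None:
            raise ValueError("table is not standardized")
        out = self.frame.copy()
        stats = self.reference_stats
        cols = stats.index
        out[cols] = out[cols] * stats["sd"].values + stats["mean"].values
        return FeatureTable(out, standardized=False)

    # -- IO ------------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, index_col="subject_id")
        return cls(frame)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "FeatureTable":
        return cls(frame.copy())
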