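"""Whole-signature extraction: 1118 radiomic features per MRI sequence.

For each sequence the 86-feature panel (first-order + four texture families)
is computed on the original image, on each LoG-filtered image and on each of
the 8 wavelet subbands; filters are applied to the whole volume before the
lesion mask selects the VOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lesionrad.features import registry
from lesionrad.features.filters import log_filter, wavelet_subbands
from lesionrad.features.firstorder import first_order_features
from lesionrad.features.texture import glcm_features, gldm_features, glrlm_features, glszm_features
from lesionrad.tables import CLINICAL_COLUMNS, FeatureTable


@dataclass
class ExtractionConfig:
    """Tunable extraction parameters (all exposed; defaults documented)."""

    bin_width: float = 25.0
    log_sigmas: tuple[float, ...] = registry.DEFAULT_LOG_SIGMAS
    wavelet: str = "haar"
    glcm_distance: int = 1
    gldm_alpha: int = 0
    gldm_distance: int = 1

    def filter_labels(self) -> tuple[str, ...]:
        return registry.filter_labels(self.log_sigmas)


def extract_image_features(volume: np.ndarray, mask: np.ndarray,
                           config: ExtractionConfig | None = None) -> dict[str, dict[str, float]]:
    """The 86-feature panel of one (possibly filtered) image, keyed by family."""
    cfg = config or ExtractionConfig()
    values = np.asarray(volume, dtype=float)[np.asarray(mask, dtype=bool)]
    return {
        "firstorder": first_order_features(values, cfg.bin_width),
        "glcm": glcm_features(volume, mask, cfg.bin_width, cfg.glcm_distance),
        "glrlm": glrlm_features(volume, mask, cfg.bin_width),
        "glszm": glszm_features(volume, mask, cfg.bin_width),
        "gldm": gldm_features(volume, mask, cfg.bin_width, cfg.gldm_alpha, cfg.gldm_distance),
    }


def _filtered_images(volume: np.ndarray, spacing, cfg: ExtractionConfig) -> dict[str, np.ndarray]:
    images = {"original": np.asarray(volume, dtype=float)}
    for s in cfg.log_sigmas:
        images[f"log{s:g}"] = log_filter(volume, s, spacing)
    for band, img in wavelet_subbands(volume, cfg.wavelet).items():
        images[f"wavelet{band}"] = img
    return images


def extract_sequence(volume: np.ndarray, mask: np.ndarray, sequence: str,
                     spacing=(1.0, 1.0, 1.0),
                     config: ExtractionConfig | None = None) -> dict[str, float]:
    """All 1118 named features of one sequence, in registry order."""
    cfg = config or ExtractionConfig()
    images = _filtered_images(volume, spacing, cfg)
    record: dict[str, float] = {}
    for filt in cfg.filter_labels():
        panel = extract_image_features(images[filt], mask, cfg)
        for family, stats in registry.FAMILIES.items():
            for stat in stats:
                record[f"H-{sequence}-{filt}-{family}-{stat}"] = panel[family][stat]
    return record


def extract_all(pair, config: ExtractionConfig | None = None) -> dict[str, float]:
    """Full dual-sequence record: 2 x 1118 radiomic values + clinical covariates."""
    record: dict[str, float] = {}
    subj = pair.subject
    record.update({
        "age": subj.age, "sex": subj.sex, "edss": subj.edss, "duration": subj.duration,
    })
    record.update(extract_sequence(pair.t2, pair.mask, "T2", pair.spacing, config))
    record.update(extract_sequence(pair.mpr, pair.mask, "MPR", pair.spacing, config))
    return record


def extract_cohort(pairs, config: ExtractionConfig | None = None) -> FeatureTable:
    """Run :func:`extract_all` over a cohort of volume pairs into a FeatureTable."""
    rows, meta = [], []
    for pair in pairs:
        rows.append(extract_all(pair, config))
        meta.append({"diagnosis": pair.subject.diagnosis, "scanner": pair.subject.scanner,
                     "subject_id": pair.subject.id})
    frame = pd.DataFrame(rows, index=[m["subject_id"] for m in meta])
    frame.index.name = "subject_id"
    frame.insert(0, "scanner", [m["scanner"] for m in meta])
    frame.insert(0, "diagnosis", [m["diagnosis"] for m in meta])
    # clinical columns directly after metadata, features after
    features = [c for c in frame.columns
                if c not in ("diagnosis", "scanner") and c not in CLINICAL_COLUMNS]
    frame = frame[["diagnosis", "scanner", *CLINICAL_COLUMNS, *features]]
    return FeatureTable(frame)
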