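"""Deterministic enumeration of the radiomic feature namespace.

Each MRI sequence yields 1118 named features: an 86-feature panel
(18 first-order + 22 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM) computed on the
original image, on 4 Laplacian-of-Gaussian filtered images and on 8 wavelet
subbands, i.e. ``86 * (1 + 4 + 8) = 1118``.

Names render as ``H-<sequence>-<filter>-<family>-<stat>``, e.g.
``H-T2-waveletHHL-glcm-Idn`` or ``H-MPR-log3-firstorder-Median``.  Integer ids
are assigned by deterministic enumeration (sequence -> filter -> family ->
stat); they are stable for a given configuration but carry no meaning beyond
ordering.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

SEQUENCES = ("T2", "MPR")

FIRSTORDER_STATS = (
    "Energy", "Entropy", "Minimum", "P10", "P90", "Maximum", "Mean", "Median",
    "IQR", "Range", "MAD", "rMAD", "RMS", "SD", "Variance", "Skewness",
    "Kurtosis", "Uniformity",
)

GLCM_STATS = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DA", "DE", "DV", "JointEnergy", "JE",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "IV", "MaxProb",
    "SumAverage", "SumEntropy", "SumSquares",
)

GLRLM_STATS = (
    "SRE", "LRE", "GLNU", "GLNUN", "RLNU", "RLNUN", "RP", "GLV", "RV", "RE",
    "LGLRE", "HGLRE", "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
)

GLSZM_STATS = (
    "SAE", "LAE", "GLNU", "GLNUN", "SZNU", "SZNUN", "ZP", "GLV", "ZV", "ZE",
    "LGLZE", "HGLZE", "SALGLE", "SAHGLE", "LALGLE", "LAHGLE",
)

GLDM_STATS = (
    "SDE", "LDE", "GLNU", "DNU", "DNUN", "GLV", "DV", "DE",
    "LGLE", "HGLE", "SDLGLE", "SDHGLE", "LDLGLE", "LDHGLE",
)

FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_STATS,
    "glcm": GLCM_STATS,
    "glrlm": GLRLM_STATS,
    "glszm": GLSZM_STATS,
    "gldm": GLDM_STATS,
}

#: Wavelet subband labels; letter i is the low/high-pass choice along axis i
#: of the volume array (L = low-pass, H = high-pass).
SUBBANDS = tuple("".join(c) for c in itertools.product("LH", repeat=3))

DEFAULT_LOG_SIGMAS = (2.0, 3.0, 4.0, 5.0)

FEATURES_PER_IMAGE = sum(len(v) for v in FAMILIES.values())  # 86


@dataclass(frozen=True)
class FeatureName:
    """One fully-qualified radiomic feature identifier."""

    sequence: str
    filter: str
    family: str
    stat: str
    id: int

    def render(self) -> str:
        return f"H-{self.sequence}-{self.filter}-{self.family}-{self.stat}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def filter_labels(log_sigmas=DEFAULT_LOG_SIGMAS) -> tuple[str, ...]:
    """Image-filter labels in enumeration order: original, LoG scales, wavelet subbands."""
    logs = tuple(f"log{s:g}" for s in log_sigmas)
    wavelets = tuple(f"wavelet{b}" for b in SUBBANDS)
    return ("original",) + logs + wavelets


def build_registry(sequence: str, log_sigmas=DEFAULT_LOG_SIGMAS, start_id: int = 0) -> list[FeatureName]:
    """Enumerate every feature name for one sequence, assigning dense ids."""
    if sequence not in SEQUENCES:
        raise ValueError(f"unknown sequence {sequence!r}; expected one of {SEQUENCES}")
    names: list[FeatureName] = []
    fid = start_id
    for filt in filter_labels(log_sigmas):
        for family, stats in FAMILIES.items():
            for stat in stats:
                names.append(FeatureName(sequence, filt, family, stat, fid))
                fid += 1
    expected = FEATURES_PER_IMAGE * len(filter_labels(log_sigmas))
    assert len(names) == expected
    return names


def registry_names(sequences=SEQUENCES, log_sigmas=DEFAULT_LOG_SIGMAS) -> list[str]:
    """Rendered feature names for the given sequences, in enumeration order."""
    out: list[str] = []
    for seq in sequences:
        out.extend(n.render() for n in build_registry(seq, log_sigmas, start_id=len(out)))
    return out


def family_subtotals(log_sigmas=DEFAULT_LOG_SIGMAS) -> dict[str, int]:
    """Per-sequence feature counts grouped the way the taxonomy is usually quoted.

    ``intensity`` is the first-order panel on the original image, ``texture``
    the four matrix families on the original image, ``log`` and ``wavelet``
    everything computed on the respective filtered images.
    """
    n_texture = FEATURES_PER_IMAGE - len(FIRSTORDER_STATS)
    return {
        "intensity": len(FIRSTORDER_STATS),
        "texture": n_texture,
        "log": FEATURES_PER_IMAGE * len(log_sigmas),
        "wavelet": FEATURES_PER_IMAGE * len(SUBBANDS),
    }


def dump_registry(path, sequences=SEQUENCES, log_sigmas=DEFAULT_LOG_SIGMAS) -> None:
    """Write the registry (name -> id -> parts) as JSON."""
    entries = []
    for seq in sequences:
        for n in build_registry(seq, log_sigmas, start_id=len(entries)):
            entries.append({"name": n.render(), **asdict(n)})
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)
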