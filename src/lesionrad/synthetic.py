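"""Synthetic two-class, two-scanner cohorts for pipeline validation.

The study design being emulated: 116 patients (78 MS, 38 NMO) imaged on two
scanners (1.5 T and 3 T) with dual MRI sequences (T2, T1-MPRAGE).  The
generator plants

* class-informative features with a configurable standardised mean difference
  (Cohen's d) between MS and NMO,
* scanner-shifted features with an additive batch effect between field
  strengths, and
* clinical covariates drawn from the published cohort moments
  (age, sex, EDSS, disease duration),

either directly at the feature-table level (fast, the default test path) or
at the image level, where class is encoded as a within-lesion texture
difference and scanner as a global gain + noise change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from lesionrad.features.registry import build_registry
from lesionrad.tables import CLINICAL_COLUMNS, FeatureTable

DIAGNOSES = ("MS", "NMO")
SCANNERS = ("3T", "1.5T")

#: Published cohort cell sizes {(diagnosis, scanner): n}
DEFAULT_CELLS = {("MS", "3T"): 38, ("NMO", "3T"): 30, ("MS", "1.5T"): 40, ("NMO", "1.5T"): 8}

#: Clinical covariate moments per diagnosis (mean, sd); male counts as rates.
CLINICAL_MOMENTS = {
    "MS": {"age": (36.5, 10.0), "edss": (2.9, 1.5), "duration": (56.8, 54.1), "male_rate": 27 / 78},
    "NMO": {"age": (40.9, 11.7), "edss": (3.8, 1.6), "duration": (66.4, 58.4), "male_rate": 7 / 38},
}


@dataclass
class SynthConfig:
    """Cohort generation parameters; identical configs (incl. seed) reproduce bit-identically."""

    n_per_class_per_scanner: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    n_features: int = 60            # radiomic features per sequence (table mode)
    n_discriminative: int = 4       # planted class-informative features, split across sequences
    effect_size: float = 1.2        # Cohen's d of planted features
    n_scanner_shifted: int = 4      # features with an additive batch shift, split across sequences
    shift_size: float = 1.0         # batch shift in SD units
    block_correlation: float = 0.0  # within-block equicorrelation of noise features
    block_size: int = 10
    clinical_effect_size: float = 0.0  # optional planted standardized EDSS class difference
    # image mode
    shape: tuple = (32, 32, 32)
    spacing: tuple = (1.0, 1.0, 1.0)
    lesion_count_range: tuple = (1, 3)
    lesion_radius_range_mm: tuple = (3.0, 6.0)
    noise_sd: float = 0.05
    texture_amplitude: float = 0.5  # within-lesion texture contrast carrying the class signal
    seed: int = 0

    def __post_init__(self) -> None:
        cells = {(d, s): int(self.n_per_class_per_scanner.get((d, s),
                 self.n_per_class_per_scanner.get(f"{d}/{s}", 0)))
                 for d in DIAGNOSES for s in SCANNERS}
        self.n_per_class_per_scanner = cells
        if any(v < 0 for v in cells.values()):
            raise ValueError("cohort cell sizes must be >= 0")
        for d in DIAGNOSES:
            if sum(cells[(d, s)] for s in SCANNERS) == 0:
                raise ValueError(f"zero subjects in class {d}")
        if self.n_features < 0 or self.n_discriminative < 0 or self.n_scanner_shifted < 0:
            raise ValueError("counts must be >= 0")
        if self.n_discriminative > 2 * self.n_features:
            raise ValueError("n_discriminative exceeds the number of radiomic features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        lo, hi = self.lesion_radius_range_mm
        extent = min(n * sp for n, sp in zip(self.shape, self.spacing))
        if hi * 2 >= extent:
            raise ValueError("lesion radius range exceeds the volume extent")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_class_per_scanner"] = {f"{k[0]}/{k[1]}": v
                                        for k, v in self.n_per_class_per_scanner.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        cells = d.get("n_per_class_per_scanner")
        if cells:
            d["n_per_class_per_scanner"] = {
                (k.split("/")[0], k.split("/")[1]) if isinstance(k, str) else tuple(k): v
                for k, v in cells.items()}
        for key in ("shape", "spacing", "lesion_count_range", "lesion_radius_range_mm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Subject:
    id: str
    diagnosis: str
    scanner: str
    age: float
    sex: int        # 0 = female, 1 = male
    edss: float     # 0-10 in 0.5 steps
    duration: float  # months

    def __post_init__(self) -> None:
        if not (0.0 <= self.edss <= 10.0) or (self.edss * 2) % 1 != 0:
            raise ValueError("edss must lie in [0, 10] on a half-point grid")
        if self.age <= 0 or self.duration < 0:
            raise ValueError("age must be > 0 and duration >= 0")


@dataclass
class VolumePair:
    """Co-registered dual-sequence volumes + lesion mask on a shared grid."""

    t2: np.ndarray
    mpr: np.ndarray
    mask: np.ndarray
    spacing: tuple
    subject: Subject

    def __post_init__(self) -> None:
        if not (self.t2.shape == self.mpr.shape == self.mask.shape):
            raise ValueError("t2, mpr and mask must share one grid")
        if not self.mask.any():
            raise ValueError("mask must contain at least one foreground voxel")


# ---------------------------------------------------------------------------
# subjects & covariates


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _draw_subjects(config: SynthConfig, rng: np.random.Generator) -> list[Subject]:
    subjects = []
    idx = 0
    for diag in DIAGNOSES:
        mom = CLINICAL_MOMENTS[diag]
        edss_mean, edss_sd = mom["edss"]
        if config.clinical_effect_size > 0:
            # symmetric planted separation on a common scale (pooled sd 1.55)
            pooled = 1.55
            centre = 3.35
            offset = config.clinical_effect_size * pooled / 2.0
            edss_mean = centre + (offset if diag == "NMO" else -offset)
        mu_d, sd_d = _lognormal_params(*mom["duration"])
        for scanner in SCANNERS:
            for _ in range(config.n_per_class_per_scanner[(diag, scanner)]):
                age = 0.0
                while age <= 18.0:
                    age = rng.normal(*mom["age"])
                edss = np.clip(rng.normal(edss_mean, edss_sd), 0.0, 10.0)
                edss = np.round(edss * 2.0) / 2.0
                subjects.append(Subject(
                    id=f"S{idx:04d}",
                    diagnosis=diag,
                    scanner=scanner,
                    age=float(np.round(age, 1)),
                    sex=int(rng.random() < mom["male_rate"]),
                    edss=float(edss),
                    duration=float(np.round(rng.lognormal(mu_d, sd_d), 1)),
                ))
                idx += 1
    return subjects


# ---------------------------------------------------------------------------
# table mode


def generate_feature_cohort(config: SynthConfig) -> FeatureTable:
    """Feature-matrix cohort with planted class effects and scanner batch shifts.

    Radiomic features are standard-normal noise (optionally block-correlated);
    the first ``n_discriminative`` registry names, alternating between the T2
    and MPR sequences, receive a +/- d/2 class-mean offset; the next
    ``n_scanner_shifted`` names receive a ``shift_size`` offset on the 3 T
    stratum.  Feature names follow the extraction registry convention.
    """
    rng = np.random.default_rng(config.seed)
    subjects = _draw_subjects(config, rng)
    n = len(subjects)
    names_t2 = [f.render() for f in build_registry("T2")][: config.n_features]
    names_mpr = [f.render() for f in build_registry("MPR")][: config.n_features]
    if config.n_features > len(build_registry("T2")):
        raise ValueError("n_features exceeds the registry size for one sequence")
    names = names_t2 + names_mpr
    p = len(names)

    if config.block_correlation > 0:
        rho = config.block_correlation
        n_blocks = int(np.ceil(p / config.block_size))
        z = rng.standard_normal((n, n_blocks))
        eps = rng.standard_normal((n, p))
        shared = np.repeat(z, config.block_size, axis=1)[:, :p]
        x = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
    else:
        x = rng.standard_normal((n, p))

    # planted class-informative features: alternate T2 / MPR registry heads
    disc_idx = []
    for k in range(config.n_discriminative):
        seq_block = 0 if k % 2 == 0 else 1
        disc_idx.append(seq_block * config.n_features + k // 2)
    shift_idx = []
    for k in range(config.n_scanner_shifted):
        seq_block = 0 if k % 2 == 0 else 1
        base = config.n_discriminative // 2 + config.n_discriminative % 2
        shift_idx.append(seq_block * config.n_features + base + k // 2)
    if disc_idx and max(disc_idx) >= p or shift_idx and max(shift_idx) >= p:
        raise ValueError("n_features too small for the requested planted/shifted counts")

    is_nmo = np.array([s.diagnosis == "NMO" for s in subjects])
    is_3t = np.array([s.scanner == "3T" for s in subjects])
    for j in disc_idx:
        x[:, j] += np.where(is_nmo, config.effect_size / 2.0, -config.effect_size / 2.0)
    for j in shift_idx:
        x[:, j] += np.where(is_3t, config.shift_size, 0.0)

    frame = pd.DataFrame(x, columns=names, index=[s.id for s in subjects])
    frame.index.name = "subject_id"
    frame.insert(0, "duration", [s.duration for s in subjects])
    frame.insert(0, "edss", [s.edss for s in subjects])
    frame.insert(0, "sex", [s.sex for s in subjects])
    frame.insert(0, "age", [s.age for s in subjects])
    frame.insert(0, "scanner", [s.scanner for s in subjects])
    frame.insert(0, "diagnosis", [s.diagnosis for s in subjects])
    return FeatureTable(frame)


def planted_feature_names(config: SynthConfig) -> list[str]:
    """Registry names of the class-informative features a config plants."""
    names_t2 = [f.render() for f in build_registry("T2")][: config.n_features]
    names_mpr = [f.render() for f in build_registry("MPR")][: config.n_features]
    out = []
    for k in range(config.n_discriminative):
        pool = names_t2 if k % 2 == 0 else names_mpr
        out.append(pool[k // 2])
    if config.clinical_effect_size > 0:
        out.append("edss")
    return out


# ---------------------------------------------------------------------------
# image mode


def _smooth_noise(rng, shape, corr_len):
    from scipy.ndimage import gaussian_filter

    raw = rng.standard_normal(shape)
    if corr_len <= 0:
        return raw
    sm = gaussian_filter(raw, corr_len, mode="wrap")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_volume_cohort(config: SynthConfig) -> list[VolumePair]:
    """Image-level cohort: ellipsoidal lesions inside a brain-like envelope.

    Class is encoded as the spatial autocorrelation length of the within-lesion
    texture (MS short, NMO long); scanner as a global intensity gain and a
    noise-SD change.  Masks mark lesion voxels exactly.
    """
    rng = np.random.default_rng(config.seed)
    subjects = _draw_subjects(config, rng)
    shape = tuple(int(v) for v in config.shape)
    spacing = tuple(float(v) for v in config.spacing)
    grid = np.stack(np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                                indexing="ij"))
    centre = np.array([(s - 1) * sp / 2.0 for s, sp in zip(shape, spacing)])
    semi = np.array([(s - 1) * sp / 2.0 * 0.9 for s, sp in zip(shape, spacing)])
    envelope = (((grid[0] - centre[0]) / semi[0]) ** 2
                + ((grid[1] - centre[1]) / semi[1]) ** 2
                + ((grid[2] - centre[2]) / semi[2]) ** 2) <= 1.0

    pairs = []
    for subj in subjects:
        corr_len = 0.6 if subj.diagnosis == "MS" else 1.6  # voxels
        gain = 1.0 if subj.scanner == "3T" else 0.8
        noise_sd = config.noise_sd * (1.0 if subj.scanner == "3T" else 1.5)
        mask = np.zeros(shape, dtype=bool)
        n_lesions = int(rng.integers(config.lesion_count_range[0],
                                     config.lesion_count_range[1] + 1))
        for _ in range(n_lesions):
            radius = rng.uniform(*config.lesion_radius_range_mm)
            # centre the lesion well inside the envelope
            c = centre + (rng.random(3) - 0.5) * (semi - radius) * 1.2
            dist2 = sum(((grid[a] - c[a]) / radius) ** 2 for a in range(3))
            mask |= (dist2 <= 1.0) & envelope
        if not mask.any():  # guarantee >= 1 foreground voxel
            mask[tuple(np.array(shape) // 2)] = True

        texture = _smooth_noise(rng, shape, corr_len) * config.texture_amplitude
        t2 = np.where(envelope, 80.0, 0.0) + np.where(mask, 40.0 + 20.0 * texture, 0.0)
        mpr = np.where(envelope, 120.0, 0.0) + np.where(mask, -30.0 + 15.0 * texture, 0.0)
        t2 = gain * t2 + rng.normal(0.0, noise_sd, shape) if noise_sd > 0 else gain * t2
        mpr = gain * mpr + rng.normal(0.0, noise_sd, shape) if noise_sd > 0 else gain * mpr
        pairs.append(VolumePair(t2=t2, mpr=mpr, mask=mask, spacing=spacing, subject=subj))
    return pairs


# ---------------------------------------------------------------------------
# splitting


def split_train_test(table: FeatureTable, n_train: int, seed: int = 0,
                     stratify: bool = False) -> tuple[FeatureTable, FeatureTable]:
    """Disjoint, exhaustive random train/test partition (seed-deterministic)."""
    n = table.n_subjects
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}); got {n_train}")
    rng = np.random.default_rng(seed)
    if stratify:
        train_idx: list = []
        labels = table.labels
        for cls in sorted(labels.unique()):
            members = np.array(labels.index[labels == cls])
            k = int(round(n_train * len(members) / n))
            train_idx.extend(rng.choice(members, size=k, replace=False))
        # adjust to exactly n_train
        train_set = set(train_idx)
        rest = [i for i in table.frame.index if i not in train_set]
        while len(train_set) > n_train:
            train_set.remove(sorted(train_set)[-1])
        fill = iter(rng.permutation(rest))
        while len(train_set) < n_train:
            train_set.add(next(fill))
        order = [i for i in table.frame.index if i in train_set]
    else:
        perm = rng.permutation(np.array(table.frame.index))
        order = sorted(perm[:n_train], key=list(table.frame.index).index)
    train = table.subset(order)
    test = table.subset([i for i in table.frame.index if i not in set(order)])
    return train, test
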