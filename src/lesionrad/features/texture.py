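"""Gray-level matrix texture features (GLCM, GLRLM, GLSZM, GLDM).

All families share the same fixed-bin-width, minimum-referenced intensity
discretisation and operate on the 3-D lesion VOI.  Feature values are averaged
over the 13 unique 3-D directions where a family is directional (GLCM, GLRLM).
Undefined features (empty matrices, zero-variance denominators) are imputed as
0 so downstream selection never sees missing values; GLCM ``Correlation``
degenerates to 1 for a single-level VOI.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from lesionrad.features.registry import GLCM_STATS, GLDM_STATS, GLRLM_STATS, GLSZM_STATS

__all__ = [
    "discretize",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
]


def discretize(values, bin_width: float) -> np.ndarray:
    """Map intensities to integer gray levels: ``floor((v - min) / w) + 1``.

    The minimum-referenced origin makes the levels (and hence every texture
    feature) invariant to adding a constant to the intensities.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty value set")
    return (np.floor((values - values.min()) / bin_width) + 1).astype(np.int64)


def direction_offsets(distance: int = 1) -> list[tuple[int, int, int]]:
    """The 13 unique 3-D direction offsets (half of the 26-neighbourhood)."""
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                o = (dx, dy, dz)
                if o == (0, 0, 0):
                    continue
                # keep one representative of each +/- pair
                if o > (0, 0, 0):
                    offs.append((dx * distance, dy * distance, dz * distance))
    assert len(offs) == 13
    return offs


def _level_volume(volume, mask, bin_width):
    """Cropped integer level volume with 0 outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        raise ValueError("mask has no foreground voxels")
    vol = np.asarray(volume, dtype=float)
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    mask_c = mask[sl]
    vol_c = vol[sl]
    levels = np.zeros(mask_c.shape, dtype=np.int64)
    levels[mask_c] = discretize(vol_c[mask_c], bin_width)
    return levels, mask_c


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# GLCM


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    lv = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float(np.sum(lv * px))
    sigma = float(np.sqrt(np.sum((lv - mu) ** 2 * px)))

    psum = np.bincount((ii + jj).astype(int).ravel(), weights=p.ravel())
    pdiff = np.bincount(np.abs(ii - jj).astype(int).ravel(), weights=p.ravel())
    ks = np.arange(psum.size, dtype=float)
    kd = np.arange(pdiff.size, dtype=float)

    da = float(np.sum(kd * pdiff))
    hxy = _entropy(p)
    hx = _entropy(px)  # == hy by symmetry
    nz = p > 0
    outer = np.outer(px, px)
    hxy1 = float(-np.sum(p[nz] * np.log2(outer[nz]))) if nz.any() else 0.0
    hxy2 = _entropy(outer.ravel())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    iv = float(np.sum(p[off] / (ii[off] - jj[off]) ** 2)) if off.any() else 0.0
    corr = float((np.sum(ii * jj * p) - mu * mu) / (sigma * sigma)) if sigma > 0 else 1.0

    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "DA": da,
        "DE": _entropy(pdiff),
        "DV": float(np.sum((kd - da) ** 2 * pdiff)),
        "JointEnergy": float(np.sum(p**2)),
        "JE": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng**2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "IV": iv,
        "MaxProb": float(p.max()),
        "SumAverage": float(np.sum(ks * psum)),
        "SumEntropy": _entropy(psum),
        "SumSquares": float(np.sum((ii - mu) ** 2 * p)),
    }


def glcm_features(volume, mask, bin_width: float = 25.0, distance: int = 1) -> dict[str, float]:
    """Gray-level co-occurrence features, symmetric, averaged over 13 directions.

    Directions with no valid voxel pair at the given distance are skipped; if
    every direction is empty all features are imputed as 0.
    """
    levels, mask_c = _level_volume(volume, mask, bin_width)
    ng = int(levels.max())
    per_dir: list[dict[str, float]] = []
    shape = levels.shape
    for off in direction_offsets(distance):
        src = tuple(slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape))
        dst = tuple(slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape))
        a = levels[src].ravel()
        b = levels[dst].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        a, b = a[valid] - 1, b[valid] - 1
        counts = np.zeros((ng, ng), dtype=float)
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)  # symmetric
        per_dir.append(_glcm_stats(counts / counts.sum()))
    if not per_dir:
        return {s: 0.0 for s in GLCM_STATS}
    return {s: float(np.mean([d[s] for d in per_dir])) for s in GLCM_STATS}


# ---------------------------------------------------------------------------
# GLRLM


def _runs_along(levels: np.ndarray, off) -> list[tuple[int, int]]:
    """(gray level, run length) of maximal constant-level in-mask runs along ``off``."""
    pad = np.pad(levels, 1)
    runs = []
    for x, y, z in np.argwhere(levels > 0):
        lev = levels[x, y, z]
        # run start: predecessor along -off differs (0-padding covers bounds)
        if pad[x + 1 - off[0], y + 1 - off[1], z + 1 - off[2]] == lev:
            continue
        length = 1
        cx, cy, cz = x + off[0], y + off[1], z + off[2]
        while pad[cx + 1, cy + 1, cz + 1] == lev:
            length += 1
            cx, cy, cz = cx + off[0], cy + off[1], cz + off[2]
        runs.append((int(lev), length))
    return runs


def _sparse_panel(entries: dict[tuple[int, int], float], n_total: float, np_voxels: int, kind: str) -> dict[str, float]:
    """Shared feature arithmetic for run/zone/dependence matrices.

    ``entries`` maps (gray level i, second index j) to counts; ``n_total`` is
    the matrix sum (number of runs / zones / voxels).
    """
    if not entries or n_total <= 0:
        names = {"glrlm": GLRLM_STATS, "glszm": GLSZM_STATS, "gldm": GLDM_STATS}[kind]
        return {s: 0.0 for s in names}
    i = np.array([k[0] for k in entries], dtype=float)
    j = np.array([k[1] for k in entries], dtype=float)
    s = np.array(list(entries.values()), dtype=float)
    n = float(n_total)
    p = s / n
    gl_marg: dict[int, float] = {}
    j_marg: dict[int, float] = {}
    for (gi, gj), c in entries.items():
        gl_marg[gi] = gl_marg.get(gi, 0.0) + c
        j_marg[gj] = j_marg.get(gj, 0.0) + c
    glnu = sum(v**2 for v in gl_marg.values()) / n
    jnu = sum(v**2 for v in j_marg.values()) / n
    mu_i = float(np.sum(p * i))
    mu_j = float(np.sum(p * j))
    base = {
        "small": float(np.sum(s / j**2) / n),
        "large": float(np.sum(s * j**2) / n),
        "glnu": glnu,
        "glnun": glnu / n,
        "jnu": jnu,
        "jnun": jnu / n,
        "pct": n / np_voxels,
        "glv": float(np.sum(p * (i - mu_i) ** 2)),
        "jv": float(np.sum(p * (j - mu_j) ** 2)),
        "ent": _entropy(p),
        "lgl": float(np.sum(s / i**2) / n),
        "hgl": float(np.sum(s * i**2) / n),
        "slgl": float(np.sum(s / (i**2 * j**2)) / n),
        "shgl": float(np.sum(s * i**2 / j**2) / n),
        "llgl": float(np.sum(s * j**2 / i**2) / n),
        "lhgl": float(np.sum(s * i**2 * j**2) / n),
    }
    if kind == "glrlm":
        keys = ("small", "large", "glnu", "glnun", "jnu", "jnun", "pct", "glv",
                "jv", "ent", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl")
        return dict(zip(GLRLM_STATS, (base[k] for k in keys)))
    if kind == "glszm":
        keys = ("small", "large", "glnu", "glnun", "jnu", "jnun", "pct", "glv",
                "jv", "ent", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl")
        return dict(zip(GLSZM_STATS, (base[k] for k in keys)))
    if kind == "gldm":
        keys = ("small", "large", "glnu", "jnu", "jnun", "glv", "jv", "ent",
                "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl")
        return dict(zip(GLDM_STATS, (base[k] for k in keys)))
    raise ValueError(kind)


def glrlm_features(volume, mask, bin_width: float = 25.0) -> dict[str, float]:
    """Gray-level run-length features averaged over the 13 directions."""
    levels, mask_c = _level_volume(volume, mask, bin_width)
    np_voxels = int(mask_c.sum())
    per_dir = []
    for off in direction_offsets(1):
        entries: dict[tuple[int, int], float] = {}
        n_runs = 0
        for lev, length in _runs_along(levels, off):
            entries[(lev, length)] = entries.get((lev, length), 0.0) + 1.0
            n_runs += 1
        per_dir.append(_sparse_panel(entries, n_runs, np_voxels, "glrlm"))
    return {s: float(np.mean([d[s] for d in per_dir])) for s in GLRLM_STATS}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features(volume, mask, bin_width: float = 25.0) -> dict[str, float]:
    """Gray-level size-zone features with 26-connected zones."""
    levels, mask_c = _level_volume(volume, mask, bin_width)
    np_voxels = int(mask_c.sum())
    structure = np.ones((3, 3, 3), dtype=int)
    entries: dict[tuple[int, int], float] = {}
    n_zones = 0
    for lev in np.unique(levels[levels > 0]):
        labelled, n = ndimage.label(levels == lev, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        for size in sizes:
            key = (int(lev), int(size))
            entries[key] = entries.get(key, 0.0) + 1.0
        n_zones += n
    return _sparse_panel(entries, n_zones, np_voxels, "glszm")


# ---------------------------------------------------------------------------
# GLDM


def gldm_features(volume, mask, bin_width: float = 25.0, alpha: int = 0, distance: int = 1) -> dict[str, float]:
    """Gray-level dependence features.

    A neighbour within Chebyshev ``distance`` is dependent on the centre voxel
    when the absolute level difference is <= ``alpha``.  The dependence index
    is 1 + (number of dependent neighbours), so isolated voxels land in column
    1 and the matrix never has a zero column index.
    """
    levels, mask_c = _level_volume(volume, mask, bin_width)
    np_voxels = int(mask_c.sum())
    pad = np.pad(levels, distance)
    core = tuple(slice(distance, distance + s) for s in levels.shape)
    dep = np.zeros(levels.shape, dtype=np.int64)
    rng = range(-distance, distance + 1)
    for dx in rng:
        for dy in rng:
            for dz in rng:
                if dx == dy == dz == 0:
                    continue
                shifted = pad[core[0].start + dx: core[0].stop + dx,
                              core[1].start + dy: core[1].stop + dy,
                              core[2].start + dz: core[2].stop + dz]
                dep += ((shifted > 0) & (levels > 0)
                        & (np.abs(shifted - levels) <= alpha)).astype(np.int64)
    entries: dict[tuple[int, int], float] = {}
    for lev, d in zip(levels[levels > 0].ravel(), dep[levels > 0].ravel()):
        key = (int(lev), int(d) + 1)
        entries[key] = entries.get(key, 0.0) + 1.0
    return _sparse_panel(entries, np_voxels, np_voxels, "gldm")
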