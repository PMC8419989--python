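"""Naive, loop-based reference implementations of the texture features.

Everything here is deliberately brute force (explicit voxel loops, flood
fill, direct formula evaluation on dense dictionaries) and shares no code
with the package implementation, so agreement between the two is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def oracle_discretize(values, bin_width):
    vmin = min(values)
    return [int(math.floor((v - vmin) / bin_width)) + 1 for v in values]


def _levels_array(volume, mask, bin_width):
    vox = [(x, y, z) for x in range(mask.shape[0])
           for y in range(mask.shape[1]) for z in range(mask.shape[2]) if mask[x, y, z]]
    vals = [float(volume[p]) for p in vox]
    levs = oracle_discretize(vals, bin_width)
    lv = {p: l for p, l in zip(vox, levs)}
    ng = max(levs)
    return lv, vox, ng


def _directions():
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) > (0, 0, 0):
                    dirs.append((dx, dy, dz))
    return dirs


def _entropy(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


# ---------------------------------------------------------------------------


def oracle_glcm(volume, mask, bin_width=25.0, distance=1):
    lv, vox, ng = _levels_array(volume, mask, bin_width)
    feats_per_dir = []
    for d in _directions():
        off = tuple(c * distance for c in d)
        counts = {}
        for p in vox:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q in lv:
                for a, b in ((lv[p], lv[q]), (lv[q], lv[p])):
                    counts[(a, b)] = counts.get((a, b), 0) + 1
        if not counts:
            continue
        total = sum(counts.values())
        p2 = {k: v / total for k, v in counts.items()}
        feats_per_dir.append(_glcm_formulas(p2, ng))
    if not feats_per_dir:
        return {k: 0.0 for k in _glcm_formulas({(1, 1): 1.0}, 1)}
    keys = feats_per_dir[0].keys()
    return {k: sum(f[k] for f in feats_per_dir) / len(feats_per_dir) for k in keys}


def _glcm_formulas(p, ng):
    px = {}
    for (i, j), v in p.items():
        px[i] = px.get(i, 0.0) + v
    mu = sum(i * v for i, v in px.items())
    sigma = math.sqrt(sum((i - mu) ** 2 * v for i, v in px.items()))
    psum, pdiff = {}, {}
    for (i, j), v in p.items():
        psum[i + j] = psum.get(i + j, 0.0) + v
        pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + v
    da = sum(k * v for k, v in pdiff.items())
    hxy = _entropy(p.values())
    hx = _entropy(px.values())
    hxy1 = -sum(v * math.log2(px[i] * px[j]) for (i, j), v in p.items() if v > 0)
    hxy2 = _entropy([px[i] * px[j] for i in px for j in px])
    out = {
        "Autocorrelation": sum(i * j * v for (i, j), v in p.items()),
        "ClusterProminence": sum((i + j - 2 * mu) ** 4 * v for (i, j), v in p.items()),
        "ClusterShade": sum((i + j - 2 * mu) ** 3 * v for (i, j), v in p.items()),
        "ClusterTendency": sum((i + j - 2 * mu) ** 2 * v for (i, j), v in p.items()),
        "Contrast": sum((i - j) ** 2 * v for (i, j), v in p.items()),
        "Correlation": (sum(i * j * v for (i, j), v in p.items()) - mu * mu) / sigma**2
        if sigma > 0 else 1.0,
        "DA": da,
        "DE": _entropy(pdiff.values()),
        "DV": sum((k - da) ** 2 * v for k, v in pdiff.items()),
        "JointEnergy": sum(v * v for v in p.values()),
        "JE": hxy,
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items()),
        "Idmn": sum(v / (1 + (i - j) ** 2 / ng**2) for (i, j), v in p.items()),
        "Id": sum(v / (1 + abs(i - j)) for (i, j), v in p.items()),
        "Idn": sum(v / (1 + abs(i - j) / ng) for (i, j), v in p.items()),
        "IV": sum(v / (i - j) ** 2 for (i, j), v in p.items() if i != j),
        "MaxProb": max(p.values()),
        "SumAverage": sum(k * v for k, v in psum.items()),
        "SumEntropy": _entropy(psum.values()),
        "SumSquares": sum((i - mu) ** 2 * v for (i, j), v in p.items()),
    }
    return out


# ---------------------------------------------------------------------------


def _sparse_formulas(entries, n, np_voxels, names, normalized_jnu):
    """Direct evaluation of the shared run/zone/dependence panels."""
    p = {k: v / n for k, v in entries.items()}
    gi = {}
    gj = {}
    for (i, j), v in entries.items():
        gi[i] = gi.get(i, 0.0) + v
        gj[j] = gj.get(j, 0.0) + v
    mu_i = sum(i * v for (i, j), v in p.items())
    mu_j = sum(j * v for (i, j), v in p.items())
    vals = {
        "small": sum(v / j**2 for (i, j), v in entries.items()) / n,
        "large": sum(v * j**2 for (i, j), v in entries.items()) / n,
        "glnu": sum(v**2 for v in gi.values()) / n,
        "glnun": sum(v**2 for v in gi.values()) / n**2,
        "jnu": sum(v**2 for v in gj.values()) / n,
        "jnun": sum(v**2 for v in gj.values()) / n**2,
        "pct": n / np_voxels,
        "glv": sum(v * (i - mu_i) ** 2 for (i, j), v in p.items()),
        "jv": sum(v * (j - mu_j) ** 2 for (i, j), v in p.items()),
        "ent": _entropy(p.values()),
        "lgl": sum(v / i**2 for (i, j), v in entries.items()) / n,
        "hgl": sum(v * i**2 for (i, j), v in entries.items()) / n,
        "slgl": sum(v / (i**2 * j**2) for (i, j), v in entries.items()) / n,
        "shgl": sum(v * i**2 / j**2 for (i, j), v in entries.items()) / n,
        "llgl": sum(v * j**2 / i**2 for (i, j), v in entries.items()) / n,
        "lhgl": sum(v * i**2 * j**2 for (i, j), v in entries.items()) / n,
    }
    order = (("small", "large", "glnu", "glnun", "jnu", "jnun", "pct", "glv",
              "jv", "ent", "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl")
             if normalized_jnu else
             ("small", "large", "glnu", "jnu", "jnun", "glv", "jv", "ent",
              "lgl", "hgl", "slgl", "shgl", "llgl", "lhgl"))
    return dict(zip(names, (vals[k] for k in order)))


def oracle_glrlm(volume, mask, bin_width=25.0):
    from lesionrad.features.registry import GLRLM_STATS

    lv, vox, ng = _levels_array(volume, mask, bin_width)
    feats = []
    for d in _directions():
        entries = {}
        n_runs = 0
        seen = set()
        for p in sorted(vox):
            if p in seen:
                continue
            prev = (p[0] - d[0], p[1] - d[1], p[2] - d[2])
            if prev in lv and lv[prev] == lv[p]:
                continue  # not a run start
            length = 0
            q = p
            while q in lv and lv[q] == lv[p]:
                seen.add(q)
                length += 1
                q = (q[0] + d[0], q[1] + d[1], q[2] + d[2])
            entries[(lv[p], length)] = entries.get((lv[p], length), 0) + 1
            n_runs += 1
        seen.clear()
        feats.append(_sparse_formulas(entries, n_runs, len(vox), GLRLM_STATS, True))
    return {k: sum(f[k] for f in feats) / len(feats) for k in feats[0]}


def oracle_glszm(volume, mask, bin_width=25.0):
    from lesionrad.features.registry import GLSZM_STATS

    lv, vox, ng = _levels_array(volume, mask, bin_width)
    visited = set()
    entries = {}
    n_zones = 0
    for p in vox:
        if p in visited:
            continue
        # BFS flood fill over the 26-neighbourhood within the same level
        queue = deque([p])
        visited.add(p)
        size = 0
        while queue:
            q = queue.popleft()
            size += 1
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        r = (q[0] + dx, q[1] + dy, q[2] + dz)
                        if r != q and r in lv and r not in visited and lv[r] == lv[p]:
                            visited.add(r)
                            queue.append(r)
        entries[(lv[p], size)] = entries.get((lv[p], size), 0) + 1
        n_zones += 1
    return _sparse_formulas(entries, n_zones, len(vox), GLSZM_STATS, True)


def oracle_gldm(volume, mask, bin_width=25.0, alpha=0, distance=1):
    from lesionrad.features.registry import GLDM_STATS

    lv, vox, ng = _levels_array(volume, mask, bin_width)
    entries = {}
    for p in vox:
        dep = 0
        for dx in range(-distance, distance + 1):
            for dy in range(-distance, distance + 1):
                for dz in range(-distance, distance + 1):
                    if dx == dy == dz == 0:
                        continue
                    q = (p[0] + dx, p[1] + dy, p[2] + dz)
                    if q in lv and abs(lv[q] - lv[p]) <= alpha:
                        dep += 1
        key = (lv[p], dep + 1)
        entries[key] = entries.get(key, 0) + 1
    return _sparse_formulas(entries, len(vox), len(vox), GLDM_STATS, False)


# ---------------------------------------------------------------------------


def oracle_first_order(values, bin_width=25.0):
    """Direct-formula first-order panel (independent arithmetic)."""
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p75, p90 = (float(np.percentile(np.array(x), q)) for q in (10, 25, 75, 90))
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    levels = oracle_discretize(x, bin_width)
    probs = {}
    for l in levels:
        probs[l] = probs.get(l, 0) + 1 / n
    return {
        "Energy": sum(v * v for v in x),
        "Entropy": _entropy(probs.values()),
        "Minimum": x[0],
        "P10": p10,
        "P90": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": float(np.median(np.array(x))),
        "IQR": p75 - p25,
        "Range": x[-1] - x[0],
        "MAD": sum(abs(v - mean) for v in x) / n,
        "rMAD": sum(abs(v - rmean) for v in robust) / len(robust),
        "RMS": math.sqrt(sum(v * v for v in x) / n),
        "SD": math.sqrt(m2),
        "Variance": m2,
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Uniformity": sum(p * p for p in probs.values()),
    }


def random_voi(rng, max_shape=(4, 4, 2)):
    """A random small volume + non-empty mask for oracle comparisons."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    volume = rng.uniform(0, 100, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[0, 0, 0] = True
    return volume, mask
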