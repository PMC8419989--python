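"""Image filters applied before texture extraction: LoG and wavelet subbands."""

from __future__ import annotations

import numpy as np
import pywt
from scipy.ndimage import correlate1d


def _gauss(t: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (t / sigma) ** 2) / (np.sqrt(2.0 * np.pi) * sigma)


def _gauss_d2(t: np.ndarray, sigma: float) -> np.ndarray:
    return _gauss(t, sigma) * (t**2 - sigma**2) / sigma**4


def log_filter(volume: np.ndarray, sigma: float, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Scale-normalised Laplacian-of-Gaussian response at scale ``sigma`` (mm).

    The filter is the analytic 3-D LoG kernel ``sigma^2 * laplacian(G_sigma)``
    sampled at voxel-centre offsets (physical coordinates via ``spacing``) and
    truncated at a 4-sigma radius; sampled values are multiplied by the voxel
    volume so the discrete sum approximates the continuous convolution.  The
    second-derivative taps are DC-corrected to sum exactly to zero, so a
    constant image (and, by tap symmetry, a linear ramp away from the
    boundary) maps exactly to zero despite the truncation.
    Applied separably with nearest-edge padding; output is on the input grid.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D volume")
    spacing = np.asarray(spacing, dtype=float)
    taps_g, taps_d2 = [], []
    for ax in range(3):
        h = spacing[ax]
        radius = max(1, int(np.ceil(4.0 * sigma / h)))
        t = np.arange(-radius, radius + 1) * h
        taps_g.append(_gauss(t, sigma) * h)
        d2 = _gauss_d2(t, sigma) * h
        taps_d2.append(d2 - d2.mean())
    out = np.zeros_like(vol)
    for ax in range(3):
        part = vol
        for other in range(3):
            w = taps_d2[other] if other == ax else taps_g[other]
            part = correlate1d(part, w, axis=other, mode="nearest")
        out += part
    return sigma**2 * out


def wavelet_subbands(volume: np.ndarray, wavelet: str = "haar") -> dict[str, np.ndarray]:
    """Single-level, undecimated 3-axis wavelet decomposition into 8 subbands.

    Subband label letter ``i`` gives the filter applied along array axis ``i``
    (L = low-pass, H = high-pass).  Filtering is circular (periodic boundary)
    and each 1-D filter is the orthonormal decomposition filter scaled by
    1/sqrt(2), so that for an orthonormal kernel the total energy over the 8
    subbands equals the energy of the input (a Parseval identity that the
    decimated transform would satisfy).  Subbands stay on the input grid, so
    the lesion mask applies unchanged.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if min(vol.shape) < 2:
        raise ValueError("each axis must have length >= 2")
    wav = pywt.Wavelet(wavelet)
    lo = np.asarray(wav.dec_lo, dtype=float) / np.sqrt(2.0)
    hi = np.asarray(wav.dec_hi, dtype=float) / np.sqrt(2.0)
    out: dict[str, np.ndarray] = {}
    from lesionrad.features.registry import SUBBANDS

    for label in SUBBANDS:
        sub = vol
        for ax, letter in enumerate(label):
            w = lo if letter == "L" else hi
            sub = correlate1d(sub, w, axis=ax, mode="wrap")
        out[label] = sub
    return out
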