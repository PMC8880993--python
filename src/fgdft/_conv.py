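"""Discrete planar convolutions on the z-grid.

Kernels are tabulated on symmetric integer offsets m = -K..K at the grid
spacing dz, value[m+K] = k(m*dz).  A convolution result is

    r[j] = dz * sum_k  f(z_k) * kernel(z_j - z_k)

with f extended beyond the box: zero below the wall, and a constant
(reservoir) value above the top of the box.  Correlations (needed for
functional derivatives, where the kernel argument is z_k - z_j) use the
reversed kernel; for even kernels the two coincide, for odd (vector)
kernels they differ by a sign.
"""

from __future__ import annotations

import numpy as np


def convolve(profile: np.ndarray, kernel: np.ndarray, dz: float,
             pad_hi: float = 0.0) -> np.ndarray:
    """r[j] = dz * sum_k ext[k] kernel[(j-k)+K] with bottom pad 0, top pad ``pad_hi``."""
    nk = len(kernel)
    if nk % 2 != 1:
        raise ValueError("kernel must have odd length (symmetric offsets)")
    K = nk // 2
    L = len(profile)
    ext = np.empty(L + 2 * K)
    ext[:K] = 0.0
    ext[K:K + L] = profile
    ext[K + L:] = pad_hi
    full = np.convolve(ext, kernel)
    return full[2 * K:2 * K + L] * dz


def correlate(profile: np.ndarray, kernel: np.ndarray, dz: float,
              pad_hi: float = 0.0) -> np.ndarray:
    """r[j] = dz * sum_k ext[k] kernel[(k-j)+K]  (kernel argument reversed)."""
    return convolve(profile, kernel[::-1], dz, pad_hi=pad_hi)


def kernel_offsets(K: int, dz: float) -> np.ndarray:
    """Offsets m*dz for m = -K..K."""
    return np.arange(-K, K + 1) * dz
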