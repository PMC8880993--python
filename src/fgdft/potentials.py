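"""Pair and wall potentials.

Cohesion between beads/spheres is a 3D Morse potential

    u3D(r) = eps * (exp(-2 a (r - d_ij)) - 2 exp(-a (r - d_ij)))

with well depth ``eps`` (kT) at contact distance d_ij and inverse decay
length ``a``.  In the planar geometry only the lateral integral matters:

    U(z) = 2 pi \\int_{|z|}^{inf} r u3D(r) dr ,

which has the closed form used below.  The stored kernel is shifted by
-U(z_cut) and truncated to zero beyond the cutoff z_cut = 2 d_ij, keeping
the cohesive interactions short ranged and continuous at the cutoff.

Because excluded volume is treated separately (and essentially exactly) by
the hard-sphere functional, the cohesion kernel integrates the *cohesive
part* of the Morse potential: u(r) where the Morse is negative, i.e. for
r >= r0 = d_ij - ln(2)/a, and zero below r0 where the Morse turns
repulsive.  Folding the Morse's soft e^{+2 a d_ij} core into a mean-field
kernel would double-count the repulsion FMT already provides and make
every kernel's net integral strongly positive, i.e. not a cohesion at
all; keeping the negative part only makes every kernel net-attractive
and, at the calibrated strengths, reproduces the measured film thickness
and inert-particle exclusion barriers of the reference system.

U(z) carries units of energy * nm^2 and is contracted with 3D densities
(nm^-3); the combination is invariant under the equivalent 1D-density
(rho = A rho_hat) formulation, where the kernel would carry a 1/A.

The grafting surface is a purely repulsive Weeks-Chandler-Andersen wall
of height ``eps_ext`` (20 kT by default), cut off at z = d_i so that it is
zero where a sphere of diameter d_i no longer overlaps the wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._conv import kernel_offsets
from .system import Grid


def morse_3d(r, eps: float, alpha: float, d_ij: float):
    """3D Morse pair potential; minimum -eps at r = d_ij."""
    x = np.exp(-alpha * (np.asarray(r, dtype=float) - d_ij))
    return eps * (x * x - 2.0 * x)


def morse_attractive(r, eps: float, alpha: float, d_ij: float):
    """Cohesive part of the Morse: u(r) where negative, zero where repulsive.

    The Morse crosses zero at r0 = d_ij - ln(2)/alpha; below r0 (inside the
    soft core, a region the hard spheres exclude anyway) the cohesion is
    set to zero.
    """
    r = np.asarray(r, dtype=float)
    r0 = d_ij - np.log(2.0) / alpha
    return np.where(r < r0, 0.0, morse_3d(r, eps, alpha, d_ij))


def lateral_integral(z, eps: float, alpha: float, d_ij: float):
    """Unshifted planar integral U(z) = 2 pi int_|z|^inf r u3D(r) dr of the
    full Morse potential.

    Closed form: int_z^inf r e^{-b r} dr = e^{-b z} (z/b + 1/b^2).
    """
    az = np.abs(np.asarray(z, dtype=float))
    b2 = 2.0 * alpha
    t_rep = np.exp(b2 * d_ij - b2 * az) * (az / b2 + 1.0 / (b2 * b2))
    t_att = np.exp(alpha * d_ij - alpha * az) * (az / alpha + 1.0 / (alpha * alpha))
    return 2.0 * np.pi * eps * (t_rep - 2.0 * t_att)


def lateral_integral_attractive(z, eps: float, alpha: float, d_ij: float):
    """Planar integral of the cohesive (negative) part of the Morse.

    Since u_att vanishes for r < r0 = d_ij - ln(2)/alpha, the radial
    integral simply starts at max(|z|, r0), where the closed form of the
    full Morse integral applies.
    """
    az = np.abs(np.asarray(z, dtype=float))
    r0 = d_ij - np.log(2.0) / alpha
    return lateral_integral(np.maximum(az, r0), eps, alpha, d_ij)


@dataclass(frozen=True)
class PairKernel:
    """Truncated-and-shifted planar cohesion kernel on grid offsets.

    ``values[m + K]`` = U_shifted(m * dz) for m = -K..K; identically zero
    for |z| >= cutoff = cutoff_multiplier * d_ij.
    """

    pair: tuple
    values: np.ndarray
    dz: float
    cutoff: float

    @property
    def half_width(self) -> int:
        return len(self.values) // 2

    def integral(self) -> float:
        """Trapezoid-consistent integral of the kernel (energy nm^3)."""
        return float(self.values.sum() * self.dz)


def integrate_planar(eps: float, alpha: float, d_ij: float, grid: Grid,
                     cutoff_multiplier: float = 2.0,
                     pair: tuple = ("", "")) -> PairKernel:
    """Tabulate the shifted planar Morse kernel for one species pair."""
    if grid.dz > d_ij:
        raise ValueError(f"dz={grid.dz} cannot resolve a kernel with d_ij={d_ij}")
    cutoff = cutoff_multiplier * d_ij
    K = int(np.ceil(cutoff / grid.dz))
    z = kernel_offsets(K, grid.dz)
    vals = (lateral_integral_attractive(z, eps, alpha, d_ij)
            - lateral_integral_attractive(cutoff, eps, alpha, d_ij))
    vals[np.abs(z) >= cutoff] = 0.0
    return PairKernel(pair=pair, values=vals, dz=grid.dz, cutoff=cutoff)


def wca_wall(z, d_i: float, eps_ext: float):
    """WCA wall potential: 4 e [(s/z)^12 - (s/z)^6] + e for 0 < z < d_i, else 0.

    s = 2^(-1/6) d_i, so the potential crosses eps_ext at z = s and reaches
    zero smoothly at its minimum z = d_i.  Non-positive z is treated as an
    impenetrable region (infinite energy).
    """
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    sigma = 2.0 ** (-1.0 / 6.0) * d_i
    inside = (z > 0) & (z < d_i)
    x6 = (sigma / z[inside]) ** 6
    out[inside] = 4.0 * eps_ext * (x6 * x6 - x6) + eps_ext
    out[z <= 0] = np.inf
    return out


def wall_on_grid(grid: Grid, d_i: float, eps_ext: float,
                 cap: float = 500.0) -> np.ndarray:
    """WCA wall sampled on the grid midpoints, capped for safe exponentials.

    The cap (default 500 kT) only affects slices whose Boltzmann factor is
    numerically zero either way.
    """
    v = wca_wall(grid.midpoints, d_i, eps_ext)
    return np.minimum(v, cap)
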