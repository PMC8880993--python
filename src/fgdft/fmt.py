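"""Fundamental measure theory in planar geometry.

The hard-sphere excess free energy is the White Bear functional of the
scalar and vector weighted densities n0..n3, nv1, nv2; chain connectivity
of the tangent-bead polymer is restored by a Yu-Wu-type correction built
on the contact value of the hard-sphere pair correlation function.

Planar reduction: for a sphere of radius R the 3D weight functions reduce
to z-kernels supported on |z| <= R,

    w3(z) = pi (R^2 - z^2)        (volume)
    w2(z) = 2 pi R                (surface)
    wv2(z) = 2 pi z               (z-component of the surface vector weight)

with w1 = w2/(4 pi R), w0 = w2/(4 pi R^2), wv1 = wv2/(4 pi R).  Kernels are
tabulated by exact integration over each dz bin, so the discrete quadrature
of each kernel equals its analytic integral (e.g. sum(w3) dz = 4/3 pi R^3)
to machine precision, edge bins included.

Conventions: weighted densities are convolutions n_a(z) = sum_i
(rho_i (*) w_a^i)(z) of 3D densities (nm^-3); the one-body direct
correlation function follows the standard liquid-state sign,
c_i(z) = -beta dF_hs/drho_i(z), so that in a uniform bulk c_i equals minus
the hard-sphere excess chemical potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._conv import convolve, correlate
from .system import Grid

_N3_SERIES_CUT = 1e-3   # below this, evaluate the third WB term by series
_TINY = 1e-30


class OverpackingError(RuntimeError):
    """Raised when a local packing fraction n3 reaches 1 (unphysical state)."""


@dataclass(frozen=True)
class SpeciesWeights:
    """Discretised planar FMT weight kernels for one sphere radius."""

    R: float
    w0: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray
    wv1: np.ndarray
    wv2: np.ndarray


def planar_weights(R: float, grid: Grid) -> SpeciesWeights:
    """Exact bin-integrated planar weight kernels for radius R."""
    dz = grid.dz
    if R <= dz / 2:
        raise ValueError(f"radius {R} unresolvable at dz={dz}")
    K = int(np.ceil((R + dz / 2) / dz))
    m = np.arange(-K, K + 1)
    lo = np.clip((m - 0.5) * dz, -R, R)
    hi = np.clip((m + 0.5) * dz, -R, R)

    # antiderivatives: W3 = pi (R^2 z - z^3/3);  W2 = 2 pi R z;  Wv2 = pi z^2
    w3 = (np.pi * (R * R * hi - hi ** 3 / 3) - np.pi * (R * R * lo - lo ** 3 / 3)) / dz
    w2 = 2 * np.pi * R * (hi - lo) / dz
    wv2 = np.pi * (hi * hi - lo * lo) / dz
    return SpeciesWeights(
        R=R, w0=w2 / (4 * np.pi * R * R), w1=w2 / (4 * np.pi * R),
        w2=w2, w3=w3, wv1=wv2 / (4 * np.pi * R), wv2=wv2,
    )


@dataclass
class WeightedDensities:
    """Species-summed weighted densities plus the polymer-only n0."""

    n0: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n3: np.ndarray
    nv1: np.ndarray
    nv2: np.ndarray
    n0_poly: np.ndarray


def weighted_densities(profiles: dict, weights: dict, dz: float,
                       polymer_id: str, pads: dict | None = None) -> WeightedDensities:
    """Convolve density profiles with the weight kernels and sum over species.

    ``pads[sid]`` is the constant density assumed above the top of the box
    (the particle reservoir); below the wall the density is zero.
    """
    pads = pads or {}
    L = len(next(iter(profiles.values())))
    tot = {a: np.zeros(L) for a in ("0", "1", "2", "3", "v1", "v2")}
    n0_poly = np.zeros(L)
    for sid, rho in profiles.items():
        w = weights[sid]
        pad = pads.get(sid, 0.0)
        for a, kern in (("0", w.w0), ("1", w.w1), ("2", w.w2), ("3", w.w3),
                        ("v1", w.wv1), ("v2", w.wv2)):
            tot[a] += convolve(rho, kern, dz, pad_hi=pad)
        if sid == polymer_id:
            n0_poly = convolve(rho, w.w0, dz, pad_hi=pad)
    n = WeightedDensities(n0=tot["0"], n1=tot["1"], n2=tot["2"], n3=tot["3"],
                          nv1=tot["v1"], nv2=tot["v2"], n0_poly=n0_poly)
    if np.max(n.n3) >= 1.0:
        raise OverpackingError(f"n3 reached {np.max(n.n3):.4f} >= 1")
    return n


def _f3_and_deriv(n3: np.ndarray):
    """f3 = [n3 + (1-n3)^2 ln(1-n3)] / [36 pi n3^2 (1-n3)^2] and d f3/d n3.

    The numerator vanishes as 1.5 n3^2 for small n3; below the series cut
    g = num/n3^2 and its derivative are evaluated by Taylor expansion to
    avoid catastrophic cancellation (the n3 -> 0 limit of f3 is 1/(24 pi)).
    """
    n3 = np.asarray(n3)
    omn = 1.0 - n3
    small = n3 < _N3_SERIES_CUT
    n3s = np.where(small, 0.5, n3)            # safe placeholder for exact branch
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.log(1.0 - n3s)
        num = n3s + (1.0 - n3s) ** 2 * L
        nump = n3s - 2.0 * (1.0 - n3s) * L
        g_exact = num / n3s ** 2
        gp_exact = nump / n3s ** 2 - 2.0 * num / n3s ** 3
    g_ser = 1.5 - n3 / 3 - n3 ** 2 / 12 - n3 ** 3 / 30
    gp_ser = -1.0 / 3 - n3 / 6 - n3 ** 2 / 10
    g = np.where(small, g_ser, g_exact)
    gp = np.where(small, gp_ser, gp_exact)
    den = 36 * np.pi * omn ** 2
    f3 = g / den
    df3 = (gp * omn + 2.0 * g) / (36 * np.pi * omn ** 3)
    return f3, df3


def whitebear_phi(n: WeightedDensities) -> np.ndarray:
    """White Bear excess free energy density (kT / nm^3)."""
    omn = 1.0 - n.n3
    f3, _ = _f3_and_deriv(n.n3)
    return (-n.n0 * np.log(omn)
            + (n.n1 * n.n2 - n.nv1 * n.nv2) / omn
            + f3 * (n.n2 ** 3 - 3.0 * n.n2 * n.nv2 ** 2))


def _zeta_and_y(n: WeightedDensities, R: float):
    """Inhomogeneity factor zeta and hard-sphere contact value y for radius R."""
    n2safe = np.where(np.abs(n.n2) > 1e-14, n.n2, 1.0)
    has_n2 = np.abs(n.n2) > 1e-14
    zeta = np.where(has_n2, 1.0 - (n.nv2 / n2safe) ** 2, 1.0)
    t = 1.0 / (1.0 - n.n3)
    y = t + 0.5 * R * n.n2 * zeta * t ** 2 + (R * n.n2) ** 2 * zeta * t ** 3 / 18.0
    return zeta, y, t, n2safe, has_n2


def chain_phi(n: WeightedDensities, M: int, R: float) -> np.ndarray:
    """Yu-Wu chain-connectivity free energy density for M-bead tangent chains.

    Evaluated with the total-mixture weighted densities inside the contact
    value y and the polymer-only n0 as prefactor; identically zero for
    monomers (M = 1).
    """
    if M == 1:
        return np.zeros_like(n.n3)
    zeta, y, _, _, _ = _zeta_and_y(n, R)
    return (1.0 - M) / M * n.n0_poly * zeta * np.log(y)


def phi_derivatives(n: WeightedDensities, M: int, R_poly: float) -> dict:
    """Partial derivatives of phi_WB + phi_CH w.r.t. each weighted density.

    Returns arrays keyed '0', '1', '2', '3', 'v1', 'v2' (total-mixture
    densities) and '0p' (the polymer-only n0 entering the chain term).
    """
    omn = 1.0 - n.n3
    f3, df3 = _f3_and_deriv(n.n3)
    d = {
        "0": -np.log(omn),
        "1": n.n2 / omn,
        "2": n.n1 / omn + f3 * (3.0 * n.n2 ** 2 - 3.0 * n.nv2 ** 2),
        "3": (n.n0 / omn + (n.n1 * n.n2 - n.nv1 * n.nv2) / omn ** 2
              + df3 * (n.n2 ** 3 - 3.0 * n.n2 * n.nv2 ** 2)),
        "v1": -n.nv2 / omn,
        "v2": -n.nv1 / omn - 6.0 * f3 * n.n2 * n.nv2,
        "0p": np.zeros_like(n.n3),
    }
    if M > 1:
        R = R_poly
        cM = (1.0 - M) / M
        zeta, y, t, n2safe, has_n2 = _zeta_and_y(n, R)
        lny = np.log(y)
        P = cM * n.n0_poly
        dy_dn3 = t ** 2 + R * n.n2 * zeta * t ** 3 + (R * n.n2) ** 2 * zeta * t ** 4 / 6.0
        dy_dn2 = 0.5 * R * zeta * t ** 2 + R * R * n.n2 * zeta * t ** 3 / 9.0
        dy_dzeta = 0.5 * R * n.n2 * t ** 2 + (R * n.n2) ** 2 * t ** 3 / 18.0
        dzeta_dn2 = np.where(has_n2, 2.0 * n.nv2 ** 2 / n2safe ** 3, 0.0)
        dzeta_dnv2 = np.where(has_n2, -2.0 * n.nv2 / n2safe ** 2, 0.0)
        d["0p"] = cM * zeta * lny
        d["3"] = d["3"] + P * zeta / y * dy_dn3
        d["2"] = d["2"] + P * (dzeta_dn2 * lny
                               + zeta / y * (dy_dn2 + dy_dzeta * dzeta_dn2))
        d["v2"] = d["v2"] + P * (dzeta_dnv2 * lny
                                 + zeta / y * dy_dzeta * dzeta_dnv2)
    return d


def direct_correlations(profiles: dict, weights: dict, dz: float,
                        polymer_id: str, M: int,
                        pads: dict | None = None,
                        n: WeightedDensities | None = None) -> dict:
    """One-body direct correlation c_i(z) = -beta dF_hs/drho_i(z) per species.

    The functional derivative back-propagates dphi/dn_a through each
    species' weight kernels; vector weights are odd, which the correlation
    (reversed-kernel convolution) handles by construction.  The polymer
    species picks up the extra chain term through its n0 kernel.
    """
    if n is None:
        n = weighted_densities(profiles, weights, dz, polymer_id, pads)
    if polymer_id not in weights:
        M = 1                       # no polymer species: chain term inactive
    R_poly = weights[polymer_id].R if polymer_id in weights else 1.0
    d = phi_derivatives(n, M, R_poly)
    out = {}
    for sid in profiles:
        w = weights[sid]
        acc = np.zeros_like(n.n3)
        for a, kern in (("0", w.w0), ("1", w.w1), ("2", w.w2), ("3", w.w3),
                        ("v1", w.wv1), ("v2", w.wv2)):
            acc += correlate(d[a], kern, dz, pad_hi=d[a][-1])
        if sid == polymer_id and M > 1:
            acc += correlate(d["0p"], w.w0, dz, pad_hi=d["0p"][-1])
        out[sid] = -acc
    return out
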