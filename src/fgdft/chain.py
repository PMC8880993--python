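"""Ideal grafted freely jointed chain in an external field.

A chain of M tangent beads with rigid bond length l, bead 1 anchored at the
grafting surface, every bead feeling the self-consistent field
U(z) = w(z) (the mean field already contains the wall).  The z-marginal of
an isotropically oriented rigid bond of length l is uniform on [-l, l] with
density 1/(2l); chain statistics on the grid therefore reduce to a transfer
kernel applied M-1 times (forward and backward propagators), exactly as in
lattice self-consistent-field theory of polymer brushes.

Propagators are renormalised every step to avoid under/overflow at M=300;
the accumulated log-scales are folded into ln Zc.  The polymer is canonical
(fixed number of chains), so the density is normalised to M*N_chains beads
regardless of Zc's absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._conv import convolve
from .system import Grid


@dataclass(frozen=True)
class TransferKernel:
    """Discretised z-marginal of a rigid bond: uniform 1/(2l) on |z| <= l.

    Edge bins are weighted by their overlap with [-l, l]; the kernel is
    renormalised so that its discrete integral is exactly 1.
    """

    bond_length: float
    values: np.ndarray
    dz: float


def transfer_kernel(bond_length: float, grid: Grid) -> TransferKernel:
    dz = grid.dz
    if bond_length < dz:
        raise ValueError(f"bond length {bond_length} below grid resolution {dz}")
    K = int(np.ceil((bond_length + dz / 2) / dz))
    m = np.arange(-K, K + 1)
    lo = np.clip((m - 0.5) * dz, -bond_length, bond_length)
    hi = np.clip((m + 0.5) * dz, -bond_length, bond_length)
    vals = (hi - lo) / (2.0 * bond_length * dz)
    vals /= vals.sum() * dz
    return TransferKernel(bond_length=bond_length, values=vals, dz=dz)


@dataclass
class Propagators:
    """Forward/backward chain propagators and the log partition function.

    ``forward[s]`` is G_{s+1}(z) (bead s+1 reached from the graft),
    ``backward[s]`` is the complementary propagator from the free end; both
    include the bead's own Boltzmann factor.  ``log_zc`` is ln Zc up to the
    additive constant from the combinatorial/thermal prefactors, which
    cancels in all density observables.
    """

    forward: np.ndarray      # (M, L)
    backward: np.ndarray     # (M, L)
    log_zc: float
    boltzmann: np.ndarray    # exp(-U) per slice
    graft_index: int


try:
    from numba import njit as _njit

    @_njit(cache=False, fastmath=True)
    def _propagate_loop(boltz, kvals, K, M, graft, dz):   # pragma: no cover
        L = boltz.size
        fwd = np.zeros((M, L))
        bwd = np.zeros((M, L))
        g = np.zeros(L)
        g[graft] = boltz[graft] / dz
        fwd[0] = g
        log_scale_f = 0.0
        for s in range(1, M):
            nxt = np.zeros(L)
            for j in range(L):
                acc = 0.0
                lo = j - K if j - K > 0 else 0
                hi = j + K if j + K < L - 1 else L - 1
                for k in range(lo, hi + 1):
                    acc += g[k] * kvals[j - k + K]
                nxt[j] = boltz[j] * acc * dz
            peak = nxt.max()
            if peak <= 0.0:
                return fwd, bwd, np.nan
            g = nxt / peak
            log_scale_f += np.log(peak)
            fwd[s] = g
        b = boltz.copy()
        bwd[M - 1] = b
        for s in range(M - 2, -1, -1):
            nxt = np.zeros(L)
            for j in range(L):
                acc = 0.0
                lo = j - K if j - K > 0 else 0
                hi = j + K if j + K < L - 1 else L - 1
                for k in range(lo, hi + 1):
                    acc += b[k] * kvals[j - k + K]
                nxt[j] = boltz[j] * acc * dz
            peak = nxt.max()
            if peak <= 0.0:
                return fwd, bwd, np.nan
            b = nxt / peak
            bwd[s] = b
        zc = 0.0
        for j in range(L):
            zc += fwd[M - 1, j]
        return fwd, bwd, np.log(zc * dz) + log_scale_f

    _HAVE_NUMBA = True
except ImportError:                                        # pragma: no cover
    _HAVE_NUMBA = False


class _FastBondConvolver:
    """O(L) bond convolution exploiting the kernel's near-uniform shape.

    The rigid-bond z-marginal is a constant plateau with at most a few
    distinct edge bins, so  (h * g)[j] = c * sum_{|m|<=Kb} g[j-m]  plus a
    handful of sparse corrections; the plateau sum is a sliding window
    evaluated with one cumulative sum.  Exactly equals the direct
    convolution (zero-padded) to rounding.
    """

    def __init__(self, kernel: TransferKernel):
        vals = kernel.values
        K = len(vals) // 2
        self.dz = kernel.dz
        c = vals[K]
        box = np.zeros_like(vals)
        box[np.abs(np.arange(-K, K + 1)) <= K] = c
        corr = vals - box
        nz = np.nonzero(np.abs(corr) > 1e-15 * max(abs(c), 1.0))[0]
        self.c = c
        self.K = K
        self.offsets = nz - K
        self.corrections = corr[nz]

    def __call__(self, g: np.ndarray) -> np.ndarray:
        L = len(g)
        K = self.K
        cs = np.zeros(L + 2 * K + 1)
        np.cumsum(g, out=cs[K + 1:K + 1 + L])
        cs[K + 1 + L:] = cs[K + L]
        # window sum_{k=j-K}^{j+K} g[k] = cs[j+K+1] - cs[j-K]
        out = (cs[2 * K + 1:2 * K + 1 + L] - cs[:L]) * self.c
        for m, corr in zip(self.offsets, self.corrections):
            lo_src = max(0, -m)
            hi_src = min(L, L - m)
            if hi_src > lo_src:
                out[lo_src + m:hi_src + m] += corr * g[lo_src:hi_src]
        return out * self.dz


def propagate(field: np.ndarray, M: int, kernel: TransferKernel,
              graft_index: int) -> Propagators:
    """Compute chain propagators for M beads in field U(z) (kT).

    Bead 1 is confined to the graft slice.  G_1 = delta_graft/dz * e^{-U};
    G_{s+1} = e^{-U} (h * G_s).  The backward recursion starts from the
    free end with unit weight.  Each step is renormalised by its maximum;
    the accumulated logs give ln Zc = ln int G_M dz.
    """
    L = len(field)
    U = np.minimum(field, 500.0)
    boltz = np.exp(-U)
    if boltz[graft_index] <= 0:
        raise RuntimeError("graft slice is forbidden by the field")
    if _HAVE_NUMBA and M > 1:
        K = len(kernel.values) // 2
        fwd, bwd, log_zc = _propagate_loop(boltz, kernel.values, K, M,
                                           graft_index, kernel.dz)
        if not np.isfinite(log_zc):
            raise RuntimeError("chain propagator vanished (field prohibitive)")
        return Propagators(forward=fwd, backward=bwd, log_zc=log_zc,
                           boltzmann=boltz, graft_index=graft_index)
    fwd = np.zeros((M, L))
    bwd = np.zeros((M, L))
    conv = _FastBondConvolver(kernel)
    log_scale_f = 0.0

    g = np.zeros(L)
    g[graft_index] = 1.0 / kernel.dz
    g = g * boltz
    if g[graft_index] <= 0:
        raise RuntimeError("graft slice is forbidden by the field")
    fwd[0] = g
    for s in range(1, M):
        g = boltz * conv(g)
        peak = g.max()
        if peak <= 0:
            raise RuntimeError("chain propagator vanished (field prohibitive)")
        g /= peak
        log_scale_f += np.log(peak)
        fwd[s] = g

    b = boltz.copy()
    bwd[M - 1] = b
    for s in range(M - 2, -1, -1):
        b = boltz * conv(b)
        peak = b.max()
        b /= peak
        bwd[s] = b

    log_zc = np.log(fwd[M - 1].sum() * kernel.dz) + log_scale_f
    return Propagators(forward=fwd, backward=bwd, log_zc=log_zc,
                       boltzmann=boltz, graft_index=graft_index)


def polymer_density(props: Propagators, num_chains: int, area: float,
                    dz: float) -> np.ndarray:
    """3D bead density rho_hat(z) (nm^-3), normalised to M*N beads total.

    rho(z) is proportional to sum_s G_s(z) Gbar_s(z) e^{+U(z)}; dividing by
    the bead's doubly counted Boltzmann factor.  Canonical normalisation
    (A * int rho_hat dz = M * N) makes the per-step renormalisation
    constants irrelevant.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_b = np.where(props.boltzmann > 0, 1.0 / props.boltzmann, 0.0)
    pair = props.forward * props.backward * inv_b[None, :]
    tot = pair.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise RuntimeError("zero propagator weight for at least one bead")
    # per-bead normalisation: each bead marginal integrates to 1 exactly
    q = (pair / tot).sum(axis=0)
    rho_1d = q / dz                        # beads per slice -> per nm, per chain
    return rho_1d * num_chains / area


def bead_marginals(props: Propagators, dz: float) -> np.ndarray:
    """Normalised per-bead position distributions p_s(z), shape (M, L)."""
    M = props.forward.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_b = np.where(props.boltzmann > 0, 1.0 / props.boltzmann, 0.0)
    out = np.empty_like(props.forward)
    for s in range(M):
        pair = props.forward[s] * props.backward[s] * inv_b
        out[s] = pair / (pair.sum() * dz)
    return out
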