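"""Measurable quantities derived from converged density profiles.

* film thickness tau: height containing a given fraction (default 95%) of
  the polymer density;
* NTR areal density Gamma = int_0^tau rho_hat dz, reported in pmol/cm^2;
* potential of mean force W(z) = -kT ln(rho/rho_bulk), with the explicit
  Euler-Lagrange form available as a consistency cross-check;
* packing fraction eta(z) = rho_hat(z) pi d^3 / 6 (sphere-volume form; the
  dimensionless alternative rho_hat * d is provided as a separate column);
* PMF well depth/location, and the overlap-based mixed/demixed classifier
  for two-particle-species systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import Grid, areal_to_pmolcm2
from .solver import SolverResult

#: PMF cap (kT) for output in wall-excluded regions where rho = 0
PMF_CAP = 50.0

#: extension (nm) above tau included in the "film interior" windows
FILM_MARGIN = 5.0


def film_thickness(rho_poly: np.ndarray, grid: Grid, fraction: float = 0.95) -> float:
    """Smallest z containing ``fraction`` of the polymer, linearly interpolated.

    The cumulative density is accumulated slice by slice (midpoint rule) and
    interpolated within the slice where the threshold is crossed.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    total = float(rho_poly.sum() * grid.dz)
    if total <= 0:
        raise ValueError("empty polymer profile")
    cum = np.cumsum(rho_poly) * grid.dz
    target = fraction * total
    k = int(np.searchsorted(cum, target))
    if k >= len(cum):
        return grid.height
    prev = cum[k - 1] if k > 0 else 0.0
    frac_in_slice = (target - prev) / (cum[k] - prev) if cum[k] > prev else 1.0
    return (k + frac_in_slice) * grid.dz


def areal_density(rho_i: np.ndarray, tau: float, grid: Grid) -> float:
    """Gamma = int_0^tau rho_hat dz in pmol/cm^2 (partial top slice included)."""
    edges = np.minimum(np.maximum(tau - np.arange(len(rho_i)) * grid.dz, 0.0), grid.dz)
    return areal_to_pmolcm2(float(np.sum(rho_i * edges)))


def pmf(rho_i: np.ndarray, rho_bulk_i: float, cap: float = PMF_CAP) -> np.ndarray:
    """W(z) = -ln(rho/rho_bulk) in kT, capped where the density vanishes."""
    if rho_bulk_i <= 0:
        raise ValueError("rho_bulk must be positive for a PMF")
    with np.errstate(divide="ignore"):
        W = -np.log(rho_i / rho_bulk_i)
    return np.minimum(W, cap)


def pmf_explicit(result: SolverResult, sid: str) -> np.ndarray:
    """Euler-Lagrange form of the PMF: -c_i + att_i + Vext_i - mu_exc.

    At a converged fixed point this equals -ln(rho/rho_bulk) pointwise to
    solver tolerance; the discrepancy bounds the solution's physical error.
    """
    from .potentials import wall_on_grid
    spec = result.spec
    p = spec.particle(sid)
    vext = wall_on_grid(spec.grid, p.diameter, spec.wall_strength)
    W = -result.c[sid] + result.attraction[sid] + vext - p.excess_chem_potential
    return np.minimum(W, PMF_CAP)


def packing_fraction(rho_i: np.ndarray, d_i: float) -> np.ndarray:
    """eta(z) = rho_hat(z) * pi d^3/6 (local volume fraction)."""
    return rho_i * np.pi * d_i ** 3 / 6.0


def reduced_density(rho_i: np.ndarray, d_i: float, area: float) -> np.ndarray:
    """Dimensionless 1D density rho(z)*d = rho_hat*A*d (figure convention)."""
    return rho_i * area * d_i


def well_depth(W: np.ndarray, grid: Grid, d_i: float, tau: float,
               margin: float = FILM_MARGIN) -> tuple[float, float]:
    """(depth, location) of the PMF minimum in the film interior.

    The window runs from the wall contact z = d_i to tau + margin; depth is
    -min W (positive for an attractive well, clipped at 0 for a purely
    repulsive landscape), location is the argmin.
    """
    z = grid.midpoints
    mask = (z >= d_i) & (z <= tau + margin)
    if not np.any(mask):
        raise ValueError("empty film-interior window")
    Wm = W[mask]
    k = int(np.argmin(Wm))
    return max(-float(Wm[k]), 0.0), float(z[mask][k])


def barrier_height(W: np.ndarray, grid: Grid, d_i: float, tau: float,
                   margin: float = FILM_MARGIN) -> float:
    """Maximum PMF in the film interior (entry barrier for an excluded probe)."""
    z = grid.midpoints
    mask = (z >= d_i) & (z <= tau + margin)
    return float(np.max(W[mask]))


def arrhenius_ratio(delta_w: float) -> float:
    """exp(|dW|/kT): the implied fold-change in an Arrhenius unbinding rate.

    Illustrative arithmetic only -- the theory is an equilibrium one and
    carries no kinetics.
    """
    return float(np.exp(abs(delta_w)))


def overlap_coefficient(rho_1: np.ndarray, rho_2: np.ndarray, grid: Grid,
                        tau: float, margin: float = FILM_MARGIN) -> float:
    """int min(p1, p2) dz of the film-restricted normalised profiles.

    1 for identical shapes, 0 for disjoint supports.  The film region
    [0, tau + margin] includes the film-surface layer where an expelled
    larger species accumulates.
    """
    z = grid.midpoints
    mask = z <= tau + margin
    p = []
    for rho in (rho_1, rho_2):
        r = rho[mask]
        tot = r.sum() * grid.dz
        if tot <= 0:
            return 0.0
        p.append(r / tot)
    return float(np.sum(np.minimum(p[0], p[1])) * grid.dz)


@dataclass(frozen=True)
class PhasePoint:
    """Classification of one two-species state."""

    overlap: float
    label: str                    # mixed | size-driven | cohesion-driven | both
    d_ratio: float
    eps_ratio: float
    expelled: bool = False


def overlap_and_classify(rho_1: np.ndarray, rho_2: np.ndarray, grid: Grid,
                         tau: float, d_ratio: float, eps_ratio: float,
                         threshold: float = 0.5, ratio_band: float = 0.2,
                         gamma_floor_pmolcm2: float = 1e-3,
                         gammas: tuple | None = None) -> PhasePoint:
    """Label a two-species state as mixed or demixed.

    Demixed states are attributed to the size disparity when the cohesion
    ratio is within ``ratio_band`` of unity but the size ratio is not, to
    the cohesion disparity in the converse case, and to both otherwise.
    A species essentially absent from the film (Gamma below the floor)
    counts as separated by expulsion.
    """
    if gammas is not None and min(gammas) < gamma_floor_pmolcm2:
        dr, er = _ratio_flags(d_ratio, eps_ratio, ratio_band)
        return PhasePoint(overlap=0.0, label=_demixed_label(dr, er),
                          d_ratio=d_ratio, eps_ratio=eps_ratio, expelled=True)
    ov = overlap_coefficient(rho_1, rho_2, grid, tau)
    if ov >= threshold:
        return PhasePoint(overlap=ov, label="mixed",
                          d_ratio=d_ratio, eps_ratio=eps_ratio)
    dr, er = _ratio_flags(d_ratio, eps_ratio, ratio_band)
    return PhasePoint(overlap=ov, label=_demixed_label(dr, er),
                      d_ratio=d_ratio, eps_ratio=eps_ratio)


def _ratio_flags(d_ratio: float, eps_ratio: float, band: float):
    return abs(d_ratio - 1.0) > band, abs(eps_ratio - 1.0) > band


def _demixed_label(d_far: bool, eps_far: bool) -> str:
    if d_far and not eps_far:
        return "size-driven"
    if eps_far and not d_far:
        return "cohesion-driven"
    return "both"


@dataclass(frozen=True)
class ObservableSet:
    """One row of the standard observables table."""

    tau: float
    gamma: dict                   # sid -> pmol/cm^2
    well: dict                    # sid -> (depth kT, location nm)
    eta_max: dict                 # sid -> max packing fraction
    overlap: float | None = None
    phase_label: str | None = None


def summarise(result: SolverResult, fraction: float = 0.95) -> ObservableSet:
    """Standard per-run observables from a converged result."""
    spec = result.spec
    tau = film_thickness(result.rho_poly, spec.grid, fraction)
    gamma, well, eta_max = {}, {}, {}
    for p in spec.particles:
        rho = result.profiles[p.id]
        gamma[p.id] = areal_density(rho, tau, spec.grid)
        if p.bulk_density > 0:
            W = pmf(rho, p.bulk_density)
            well[p.id] = well_depth(W, spec.grid, p.diameter, tau)
        eta_max[p.id] = float(np.max(packing_fraction(rho, p.diameter)))
    return ObservableSet(tau=tau, gamma=gamma, well=well, eta_max=eta_max)
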