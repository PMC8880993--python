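"""System description, units, and constants.

All energies are expressed in units of the thermal energy kT (beta = 1
internally); every cohesion strength in the parametrised Nsp1/NTF2/Imp-beta
system is quoted in kT, so no absolute temperature enters the computation.
Lengths are in nanometres.  Densities come in two equivalent conventions:

* 3D number densities ``rho_hat(z)`` in nm^-3 (used internally everywhere:
  FMT weighted densities and laterally integrated pair kernels require 3D
  densities), and
* 1D densities ``rho(z) = A * rho_hat(z)`` in nm^-1 (the number of particles
  per unit height over the whole grafting area A).

Thermal de Broglie wavelengths are set to one length unit: they shift each
chemical potential by a constant that cancels identically once particle
densities are referenced to their reservoir values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Avogadro's number (mol^-1)
N_AVOGADRO = 6.02214076e23

#: nm^-3 per micromolar: 1 uM = 1e-6 mol/L * N_A / (1e24 nm^3/L)
_NM3_PER_UM = N_AVOGADRO * 1e-6 / 1e24

#: pmol/cm^2 per nm^-2: 1 nm^-2 * 1e14 nm^2/cm^2 / N_A * 1e12 pmol/mol
_PMOLCM2_PER_NM2 = 1e14 / N_AVOGADRO * 1e12


def concentration_to_density(c_uM: float) -> float:
    """Convert a molar concentration (uM) to a 3D number density (nm^-3)."""
    if np.any(np.asarray(c_uM) < 0):
        raise ValueError(f"negative concentration: {c_uM}")
    return c_uM * _NM3_PER_UM


def density_to_concentration(rho_nm3: float) -> float:
    """Inverse of :func:`concentration_to_density`."""
    if np.any(np.asarray(rho_nm3) < 0):
        raise ValueError(f"negative density: {rho_nm3}")
    return rho_nm3 / _NM3_PER_UM


def areal_to_pmolcm2(sigma_nm2: float) -> float:
    """Convert an areal number density (nm^-2) to pmol/cm^2."""
    if np.any(np.asarray(sigma_nm2) < 0):
        raise ValueError(f"negative areal density: {sigma_nm2}")
    return sigma_nm2 * _PMOLCM2_PER_NM2


@dataclass(frozen=True)
class Grid:
    """Uniform planar grid of slice midpoints z_k = (k + 1/2) dz."""

    num_slices: int
    dz: float

    def __post_init__(self):
        if self.num_slices < 2:
            raise ValueError("grid needs at least two slices")
        if self.dz <= 0:
            raise ValueError("dz must be positive")

    @property
    def height(self) -> float:
        return self.num_slices * self.dz

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.num_slices) + 0.5) * self.dz


@dataclass(frozen=True)
class ParticleSpecies:
    """A free, grand-canonical hard sphere (an NTR-like or inert particle).

    ``bulk_concentration`` is the reservoir concentration in uM;
    ``excess_chem_potential`` (kT) shifts the effective reservoir activity:
    exp(+2) raises the dilute-limit adsorption roughly an order of magnitude.
    """

    id: str
    diameter: float                      # nm
    bulk_concentration: float            # uM
    excess_chem_potential: float = 0.0   # kT

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError(f"species {self.id!r}: diameter must be > 0")
        if self.bulk_concentration < 0:
            raise ValueError(f"species {self.id!r}: negative concentration")

    @property
    def bulk_density(self) -> float:
        """Reservoir 3D number density (nm^-3)."""
        return concentration_to_density(self.bulk_concentration)


@dataclass(frozen=True)
class PolymerSpecies:
    """Grafted freely jointed tangent-bead homopolymer (the FG Nup)."""

    id: str
    bead_diameter: float     # nm
    beads_per_chain: int     # M
    num_chains: int          # N
    bond_length: float       # nm, rigid bond; tangent beads: l = bead diameter

    def __post_init__(self):
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be > 0")
        if self.beads_per_chain < 1:
            raise ValueError("beads_per_chain must be >= 1")
        if self.num_chains < 1:
            raise ValueError("num_chains must be >= 1")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be > 0")


@dataclass(frozen=True)
class InteractionTable:
    """Morse cohesion strengths between species, keyed by species id.

    ``epsilon[(i, j)]`` is the well depth in kT; missing pairs are athermal
    (hard-sphere only).  ``alpha`` is the inverse decay length (nm^-1) and
    ``cutoff_multiplier`` the truncation range in units of the contact
    distance d_ij = (d_i + d_j)/2.
    """

    epsilon: dict = field(default_factory=dict)
    alpha: float = 6.0
    cutoff_multiplier: float = 2.0

    def __post_init__(self):
        for (i, j), e in self.epsilon.items():
            if e < 0:
                raise ValueError(f"epsilon[{i},{j}] must be >= 0")
            rev = self.epsilon.get((j, i))
            if rev is not None and not np.isclose(rev, e):
                raise ValueError(f"epsilon not symmetric for pair ({i},{j})")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.cutoff_multiplier <= 1:
            raise ValueError("cutoff_multiplier must exceed 1")

    def get(self, i: str, j: str) -> float:
        return self.epsilon.get((i, j), self.epsilon.get((j, i), 0.0))


@dataclass(frozen=True)
class SystemSpec:
    """Complete declarative description of one planar film computation."""

    grid: Grid
    area: float                       # nm^2 grafting area
    polymer: PolymerSpecies
    particles: tuple = ()             # ParticleSpecies
    interactions: InteractionTable = field(default_factory=InteractionTable)
    wall_strength: float = 20.0       # kT, WCA barrier height
    timestep: float = 0.002           # Picard fictitious-time step
    tolerance: float = 1e-8           # sup-norm residual
    max_iterations: int = 200_000

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("area must be > 0")
        if not (0 < self.timestep <= 1):
            raise ValueError("timestep must be in (0, 1]")
        if self.wall_strength <= 0:
            raise ValueError("wall_strength must be > 0")
        ids = [p.id for p in self.particles] + [self.polymer.id]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")

    @property
    def species_ids(self) -> list:
        """Particle ids followed by the polymer id."""
        return [p.id for p in self.particles] + [self.polymer.id]

    def diameter(self, sid: str) -> float:
        if sid == self.polymer.id:
            return self.polymer.bead_diameter
        for p in self.particles:
            if p.id == sid:
                return p.diameter
        raise KeyError(sid)

    def contact_distance(self, i: str, j: str) -> float:
        """d_ij = (d_i + d_j)/2, symmetric with d_ii = d_i."""
        return 0.5 * (self.diameter(i) + self.diameter(j))

    @property
    def grafting_density(self) -> float:
        """Chains per nm^2."""
        return self.polymer.num_chains / self.area

    def particle(self, sid: str) -> ParticleSpecies:
        for p in self.particles:
            if p.id == sid:
                return p
        raise KeyError(sid)

    def with_particles(self, particles) -> "SystemSpec":
        return replace(self, particles=tuple(particles))

    def with_epsilon(self, i: str, j: str, value: float) -> "SystemSpec":
        eps = dict(self.interactions.epsilon)
        eps.pop((j, i), None)
        eps[(i, j)] = value
        return replace(self, interactions=replace(self.interactions, epsilon=eps))


def validate_spec(spec: SystemSpec) -> SystemSpec:
    """Validate cross-field consistency and return the spec unchanged.

    Checks beyond dataclass invariants: the box must accommodate at least
    twice the longest pair-interaction range (cohesion kernels would
    otherwise wrap out of the reservoir region), and every cohesion pair
    must refer to declared species.
    """
    known = set(spec.species_ids)
    for (i, j) in spec.interactions.epsilon:
        if i not in known or j not in known:
            raise ValueError(f"epsilon refers to unknown species pair ({i},{j})")
    max_range = 0.0
    for i in known:
        for j in known:
            if spec.interactions.get(i, j) > 0:
                rng = spec.interactions.cutoff_multiplier * spec.contact_distance(i, j)
                max_range = max(max_range, rng)
    if spec.grid.height < 2 * max_range:
        raise ValueError(
            f"box height {spec.grid.height:.3f} nm is shorter than twice the "
            f"longest interaction range ({max_range:.3f} nm)"
        )
    for p in spec.particles:
        if spec.grid.dz > p.diameter:
            raise ValueError(f"grid too coarse to resolve species {p.id!r}")
    return spec
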