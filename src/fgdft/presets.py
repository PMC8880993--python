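"""Bundled parameter sets for the Nsp1/NTF2/Imp-beta film system.

The reference film is 260 Nsp1-like chains of 300 beads (bead diameter
0.76 nm, two residues per bead, tangent bonds) grafted on 88.62 x 88.62 nm^2
(about 3.3 chains per 100 nm^2), behind a 20 kT WCA wall, with an FG-FG
Morse cohesion of 0.275 kT (inverse range 6 nm^-1) calibrated against the
measured 26 +/- 2 nm film thickness.  NTF2 is a 4 nm sphere with 2.4 kT
cohesion to the polymer; Imp-beta a 6 nm sphere with 2.3 kT.  NTR-NTR
cohesion is always zero.
"""

from __future__ import annotations

from dataclasses import replace

from .system import (Grid, InteractionTable, ParticleSpecies, PolymerSpecies,
                     SystemSpec)

POLYMER_ID = "nsp1"
EPS_FF = 0.275
EPS_NTF2 = 2.4
EPS_IMPB = 2.3
D_NTF2 = 4.0
D_IMPB = 6.0


def nsp1_film(eps_ff: float = EPS_FF, tolerance: float = 1e-8,
              max_iterations: int = 200_000) -> SystemSpec:
    """The bare reference film: grid, polymer, wall and FG-FG cohesion."""
    return SystemSpec(
        grid=Grid(num_slices=1024, dz=0.117),
        area=88.62 * 88.62,
        polymer=PolymerSpecies(id=POLYMER_ID, bead_diameter=0.76,
                               beads_per_chain=300, num_chains=260,
                               bond_length=0.76),
        interactions=InteractionTable(
            epsilon={(POLYMER_ID, POLYMER_ID): eps_ff}, alpha=6.0),
        wall_strength=20.0,
        timestep=0.002,
        tolerance=tolerance,
        max_iterations=max_iterations,
    )


def ntf2(concentration_uM: float, sid: str = "ntf2") -> ParticleSpecies:
    return ParticleSpecies(id=sid, diameter=D_NTF2,
                           bulk_concentration=concentration_uM)


def impbeta(concentration_uM: float, sid: str = "impb") -> ParticleSpecies:
    return ParticleSpecies(id=sid, diameter=D_IMPB,
                           bulk_concentration=concentration_uM)


def inert(diameter: float, concentration_uM: float = 0.01,
          sid: str | None = None) -> ParticleSpecies:
    """A non-cohesive probe sphere (dilute by default)."""
    return ParticleSpecies(id=sid or f"inert{diameter:g}", diameter=diameter,
                           bulk_concentration=concentration_uM)


def with_particle(spec: SystemSpec, particle: ParticleSpecies,
                  eps_to_polymer: float = 0.0) -> SystemSpec:
    """Add one particle species (and its polymer cohesion) to a spec."""
    out = spec.with_particles(list(spec.particles) + [particle])
    if eps_to_polymer > 0:
        out = out.with_epsilon(particle.id, spec.polymer.id, eps_to_polymer)
    return out


def film_with_ntrs(ntf2_uM: float | None = None, impb_uM: float | None = None,
                   eps_ff: float = EPS_FF, eps_ntf2: float = EPS_NTF2,
                   eps_impb: float = EPS_IMPB, **kwargs) -> SystemSpec:
    """Reference film plus optional NTF2 and/or Imp-beta species."""
    spec = nsp1_film(eps_ff=eps_ff, **kwargs)
    if ntf2_uM is not None:
        spec = with_particle(spec, ntf2(ntf2_uM), eps_ntf2)
    if impb_uM is not None:
        spec = with_particle(spec, impbeta(impb_uM), eps_impb)
    return spec


def set_concentration(spec: SystemSpec, sid: str, c_uM: float) -> SystemSpec:
    """Copy of spec with one particle's reservoir concentration replaced."""
    parts = [replace(p, bulk_concentration=c_uM) if p.id == sid else p
             for p in spec.particles]
    return spec.with_particles(parts)
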