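"""Shared fixtures.

Small systems ("mini") exercise the full physics at a fraction of the
reference problem size and are used for solver/property tests; the
session-scoped "reference" fixtures solve the full parametrised
Nsp1/NTF2/Imp-beta systems once and are shared by every acceptance test
that needs them.
"""

from __future__ import annotations

import numpy as np
import pytest

from fgdft import presets
from fgdft.solver import solve, warm_start
from fgdft.system import (Grid, InteractionTable, ParticleSpecies,
                          PolymerSpecies, SystemSpec)

REFERENCE_TOL = 1e-8


def mini_spec(particles=(), epsilon=None, num_slices=256, tolerance=1e-8,
              beads=30, chains=30, timestep=0.002):
    """A reduced film: 30 chains of 30 beads on (30 nm)^2, same physics."""
    eps = {("fg", "fg"): 0.275}
    if epsilon:
        eps.update(epsilon)
    return SystemSpec(
        grid=Grid(num_slices=num_slices, dz=0.117),
        area=30.0 * 30.0,
        polymer=PolymerSpecies(id="fg", bead_diameter=0.76,
                               beads_per_chain=beads, num_chains=chains,
                               bond_length=0.76),
        particles=tuple(particles),
        interactions=InteractionTable(epsilon=eps, alpha=6.0),
        tolerance=tolerance,
        timestep=timestep,
        max_iterations=100_000,
    )


@pytest.fixture(scope="session")
def mini_bare():
    res = solve(mini_spec())
    assert res.converged
    return res


@pytest.fixture(scope="session")
def mini_with_ntr():
    """Mini film plus a cohesive 4 nm sphere at 1 uM."""
    spec = mini_spec(
        particles=[ParticleSpecies(id="ntr", diameter=4.0, bulk_concentration=1.0)],
        epsilon={("ntr", "fg"): 2.4})
    res = solve(spec)
    assert res.converged
    return res


# ---------------------------------------------------------------------------
# Full-scale reference solutions (computed once per session, lazily)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def reference_cache():
    """Dict of lazily computed full-size solutions keyed by scenario name."""
    cache = {}

    def get(name):
        if name in cache:
            return cache[name]
        if name == "bare":
            res = solve(presets.nsp1_film(tolerance=REFERENCE_TOL))
        elif name == "probes":
            spec = presets.nsp1_film(tolerance=REFERENCE_TOL)
            for d in (1.0, 2.0, 4.0, 6.0):
                spec = presets.with_particle(spec, presets.inert(d, 0.01))
            res = solve(spec, init=warm_start(get("bare").state, spec))
        elif name.startswith("ntf2_"):
            c = float(name.split("_")[1])
            spec = presets.film_with_ntrs(ntf2_uM=c, tolerance=REFERENCE_TOL)
            base = get("bare") if c <= 0.011 else get("ntf2_0.01")
            res = solve(spec, init=warm_start(base.state, spec))
        elif name.startswith("impb_"):
            c = float(name.split("_")[1])
            spec = presets.film_with_ntrs(impb_uM=c, tolerance=REFERENCE_TOL)
            res = solve(spec, init=warm_start(get("bare").state, spec))
        elif name.startswith("tern_"):
            # tern_<ntf2 uM>_<impb uM>, warm-started along the NTF2 axis
            _, cn, ci = name.split("_")
            cn, ci = float(cn), float(ci)
            spec = presets.film_with_ntrs(ntf2_uM=cn, impb_uM=ci,
                                          tolerance=REFERENCE_TOL)
            prev = {0.01: "bare", 0.1: "tern_0.01_1.0", 1.0: "tern_0.1_1.0",
                    10.0: "tern_1.0_1.0"}.get(cn, "bare")
            res = solve(spec, init=warm_start(get(prev).state, spec))
        elif name.startswith("rev_"):
            # NTF2 fixed at 1 uM, Imp-beta varied: rev_<impb uM>
            ci = float(name.split("_")[1])
            spec = presets.film_with_ntrs(ntf2_uM=1.0, impb_uM=ci,
                                          tolerance=REFERENCE_TOL)
            res = solve(spec, init=warm_start(get("ntf2_1.0").state, spec))
        elif name == "identity":
            # two literally identical NTF2-like species, 1 uM each
            spec = presets.nsp1_film(tolerance=REFERENCE_TOL)
            spec = presets.with_particle(
                spec, presets.inert(4.0, 1.0, sid="a"), presets.EPS_NTF2)
            spec = presets.with_particle(
                spec, presets.inert(4.0, 1.0, sid="b"), presets.EPS_NTF2)
            res = solve(spec, init=warm_start(get("bare").state, spec))
        else:
            raise KeyError(name)
        assert res.converged, f"reference solve {name!r} did not converge"
        cache[name] = res
        return res

    return get
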