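"""Figure-level experiment drivers built on the solver and observables.

Each driver runs a sweep of full DFT solutions, warm-starting every point
from the previous one (the converged field and particle profiles of a
neighbouring state are an excellent initial guess, and the final answer is
checked to be initialisation-independent by the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import observables as obs
from . import presets
from .solver import SolverResult, SolverState, solve
from .system import SystemSpec


@dataclass
class SweepPoint:
    """One solved point of a scenario sweep."""

    value: float | tuple
    result: SolverResult
    summary: obs.ObservableSet


def _run(spec: SystemSpec, warm: SolverState | None, dt_max: float = 0.01) -> SolverResult:
    res = solve(spec, init=warm, dt_max=dt_max)
    if not res.converged:
        # one retry from scratch with a gentler step before giving up
        res = solve(spec, init=None, dt_max=dt_max / 2)
    return res


def calibrate_ff(eps_values, target_thickness: float | None = None,
                 base: SystemSpec | None = None) -> dict:
    """tau(eps_FF) over a cohesion scan of the bare film.

    Returns the thickness table and, when a target is given, the pair of
    scan values bracketing it.  The film contracts monotonically with
    cohesion, so the bracket is well defined whenever the target lies in
    the scanned range.
    """
    eps_values = sorted(eps_values)
    if target_thickness is not None and target_thickness <= 0:
        raise ValueError("target thickness must be positive")
    rows, warm = [], None
    base_spec = base or presets.nsp1_film()
    pid = base_spec.polymer.id
    for eps in eps_values:
        spec = base_spec.with_epsilon(pid, pid, eps)
        res = _run(spec, warm)
        warm = res.state
        rows.append((eps, obs.film_thickness(res.rho_poly, spec.grid), res))
    out = {"eps": [r[0] for r in rows], "tau": [r[1] for r in rows],
           "results": [r[2] for r in rows], "bracket": None}
    if target_thickness is not None:
        taus = np.array(out["tau"])
        hits = np.nonzero((taus[:-1] - target_thickness)
                          * (taus[1:] - target_thickness) <= 0)[0]
        if len(hits) == 0:
            raise ValueError(
                f"target thickness {target_thickness} nm outside scanned "
                f"range [{taus.min():.1f}, {taus.max():.1f}] nm")
        k = int(hits[0])
        out["bracket"] = (out["eps"][k], out["eps"][k + 1])
    return out


def inert_exclusion(diameters, base: SystemSpec | None = None,
                    concentration_uM: float = 0.01,
                    film_state: SolverState | None = None) -> dict:
    """Entry barrier of dilute non-cohesive probes of increasing size.

    All probes are solved together in one system: at probe concentrations
    of order 0.01 uM their feedback on the film (and on each other) is far
    below solver tolerance, so this is the dilute (Henry) limit.  Warm
    started from the bare film when a converged state is supplied.
    """
    spec = base or presets.nsp1_film()
    for d in diameters:
        spec = presets.with_particle(spec, presets.inert(d, concentration_uM))
    warm = None
    if film_state is not None:
        warm = SolverState(
            profiles={p.id: p.bulk_density * np.ones(spec.grid.num_slices)
                      for p in spec.particles},
            w=film_state.w.copy(), dt=spec.timestep)
    res = _run(spec, warm)
    tau = obs.film_thickness(res.rho_poly, spec.grid)
    table = {}
    for d in diameters:
        sid = f"inert{d:g}"
        W = obs.pmf(res.profiles[sid], spec.particle(sid).bulk_density)
        table[d] = {
            "max_pmf": obs.barrier_height(W, spec.grid, d, tau),
            "pmf": W,
            "relative_density": res.profiles[sid] / spec.particle(sid).bulk_density,
        }
    return {"result": res, "tau": tau, "probes": table}


def single_ntr_series(species: str, concentrations,
                      base: SystemSpec | None = None) -> list[SweepPoint]:
    """Adsorption isotherm of one NTR species: Gamma, tau, eta, W per point.

    ``species`` is "ntf2" or "impb"; concentrations in uM, solved in
    ascending order with warm starts.
    """
    points, warm = [], None
    for c in sorted(concentrations):
        if species == "ntf2":
            spec = presets.film_with_ntrs(ntf2_uM=c)
        elif species == "impb":
            spec = presets.film_with_ntrs(impb_uM=c)
        else:
            raise ValueError(f"unknown NTR species {species!r}")
        if base is not None:
            spec = presets.set_concentration(base, species, c)
        res = _run(spec, warm)
        warm = res.state
        points.append(SweepPoint(value=c, result=res, summary=obs.summarise(res)))
    return points


def crowding_vs_inert(ntf2_concentrations, inert_diameters,
                      probe_uM: float = 0.01) -> dict:
    """Inert-probe PMF increase caused by raising the NTF2 concentration.

    Returns max-PMF per probe diameter at each NTF2 concentration and the
    shift relative to the lowest-concentration point.
    """
    rows, warm = {}, None
    for c in sorted(ntf2_concentrations):
        spec = presets.film_with_ntrs(ntf2_uM=c)
        for d in inert_diameters:
            spec = presets.with_particle(spec, presets.inert(d, probe_uM))
        res = _run(spec, warm)
        warm = res.state
        tau = obs.film_thickness(res.rho_poly, spec.grid)
        rows[c] = {d: obs.barrier_height(
            obs.pmf(res.profiles[f"inert{d:g}"], presets.inert(d, probe_uM).bulk_density),
            spec.grid, d, tau) for d in inert_diameters}
    base_c = min(rows)
    shifts = {c: {d: rows[c][d] - rows[base_c][d] for d in inert_diameters}
              for c in rows}
    return {"max_pmf": rows, "delta_pmf": shifts}


def ternary_competition(fixed_species: str, fixed_uM: float,
                        varied_species: str, concentrations,
                        dt_max: float = 0.01) -> list[SweepPoint]:
    """Two-NTR competition sweep: one concentration fixed, the other varied.

    Emits per-point profiles, observables, and the overlap classification.
    Points above 1 uM of the larger species are solved with a halved step
    cap (strong layering makes them stiffer).
    """
    points, warm = [], None
    for c in sorted(concentrations):
        conc = {fixed_species: fixed_uM, varied_species: c}
        spec = presets.film_with_ntrs(ntf2_uM=conc["ntf2"], impb_uM=conc["impb"])
        cap = dt_max / 2 if (conc["impb"] > 1.0) else dt_max
        res = _run(spec, warm, dt_max=cap)
        warm = res.state
        summary = obs.summarise(res)
        phase = obs.overlap_and_classify(
            res.profiles["ntf2"], res.profiles["impb"], spec.grid, summary.tau,
            d_ratio=presets.D_IMPB / presets.D_NTF2,
            eps_ratio=presets.EPS_IMPB / presets.EPS_NTF2,
            gammas=(summary.gamma["ntf2"], summary.gamma["impb"]))
        summary = obs.ObservableSet(tau=summary.tau, gamma=summary.gamma,
                                    well=summary.well, eta_max=summary.eta_max,
                                    overlap=phase.overlap, phase_label=phase.label)
        points.append(SweepPoint(value=c, result=res, summary=summary))
    return points


@dataclass
class PhaseDiagram:
    """Lattice of (d2/d1, eps23/eps13) points with overlap and label."""

    d_ratios: list
    eps_ratios: list
    points: dict = field(default_factory=dict)   # (d_ratio, eps_ratio) -> PhasePoint
    gaps: list = field(default_factory=list)     # unconverged lattice points


def phase_diagram(d_pairs, eps_pairs, concentration_uM: float = 1.0,
                  threshold: float = 0.5) -> PhaseDiagram:
    """Mixed/demixed classification over a lattice of size and cohesion pairs.

    ``d_pairs`` is a list of (d1, d2) in nm, ``eps_pairs`` of (eps13, eps23)
    in kT; both particles are held at the same reservoir concentration.
    Unconverged points are recorded as gaps, never interpolated.
    """
    diag = PhaseDiagram(
        d_ratios=sorted({d2 / d1 for d1, d2 in d_pairs}),
        eps_ratios=sorted({e2 / e1 for e1, e2 in eps_pairs}))
    for d1, d2 in d_pairs:
        warm = None
        for e1, e2 in eps_pairs:
            spec = presets.nsp1_film()
            spec = presets.with_particle(
                spec, presets.inert(d1, concentration_uM, sid="a"), e1)
            spec = presets.with_particle(
                spec, presets.inert(d2, concentration_uM, sid="b"), e2)
            res = _run(spec, warm)
            key = (d2 / d1, e2 / e1)
            if not res.converged:
                diag.gaps.append(key)
                warm = None
                continue
            warm = res.state
            tau = obs.film_thickness(res.rho_poly, spec.grid)
            summary = obs.summarise(res)
            point = obs.overlap_and_classify(
                res.profiles["a"], res.profiles["b"], spec.grid, tau,
                d_ratio=d2 / d1, eps_ratio=e2 / e1, threshold=threshold,
                gammas=(summary.gamma["a"], summary.gamma["b"]))
            if key == (1.0, 1.0) and point.label != "mixed":
                raise AssertionError(
                    "identical species classified as demixed -- solver or "
                    "classifier defect")
            diag.points[key] = point
    return diag
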