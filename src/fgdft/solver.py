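"""Self-consistent solution of the Euler-Lagrange equations.

The equilibrium profiles minimise the grand potential: for each free
particle species

    rho_i(z) = rho_bulk_i * exp( mu_exc_i + c_i(z)
                                 - sum_j (U_ij (*) rho_j)(z) - Vext_i(z) ),

and the polymer mean field obeys

    w(z) = -c_p(z) + sum_j (U_pj (*) rho_j)(z) + Vext_p(z),

with c_i = -beta dF_hs/drho_i the one-body direct correlation function and
the polymer density generated from w by the chain propagators.  (With this
standard sign convention the hard-sphere term enters the particle exponent
with a plus sign and the field with a minus sign; in the non-interacting
limit the barometric profile rho_bulk e^{-Vext} is recovered.)

The fixed point is reached by damped Picard iteration in a fictitious time
t: x <- x + dt (target(x) - x) for the field and each particle profile,
with the polymer density recomputed from the current field every step.
dt grows gently toward dt_max while the iteration is stable and is halved
on overpacking or residual blow-up (rolling back the state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._conv import convolve
from . import fmt
from .chain import TransferKernel, Propagators, transfer_kernel, propagate, polymer_density
from .potentials import PairKernel, integrate_planar, wall_on_grid
from .system import SystemSpec, validate_spec

#: particle-exponent clip (kT); transients only, converged exponents are O(10)
_EXP_CLIP = 30.0


@dataclass
class Workspace:
    """Precomputed kernels and wall potentials for one SystemSpec."""

    spec: SystemSpec
    weights: dict                 # sid -> fmt.SpeciesWeights
    pair_kernels: dict            # (i, j) -> PairKernel, both orderings, eps > 0 only
    walls: dict                   # sid -> Vext on grid (capped)
    kernel: TransferKernel
    graft_index: int
    pads: dict                    # sid -> reservoir density above the box

    @property
    def dz(self) -> float:
        return self.spec.grid.dz


def build_workspace(spec: SystemSpec, graft_index: int | None = None) -> Workspace:
    spec = validate_spec(spec)
    grid = spec.grid
    weights, walls, pads = {}, {}, {}
    for sid in spec.species_ids:
        weights[sid] = fmt.planar_weights(spec.diameter(sid) / 2.0, grid)
        walls[sid] = wall_on_grid(grid, spec.diameter(sid), spec.wall_strength)
        pads[sid] = 0.0
    for p in spec.particles:
        pads[p.id] = p.bulk_density

    kernels = {}
    for i in spec.species_ids:
        for j in spec.species_ids:
            eps = spec.interactions.get(i, j)
            if eps > 0:
                kernels[(i, j)] = integrate_planar(
                    eps, spec.interactions.alpha, spec.contact_distance(i, j),
                    grid, spec.interactions.cutoff_multiplier, pair=(i, j))

    if graft_index is None:
        pid = spec.polymer.id
        below = np.nonzero(walls[pid] < spec.wall_strength)[0]
        if len(below) == 0:
            raise ValueError("no admissible graft slice (wall too steep for grid)")
        graft_index = int(below[0])
    tk = transfer_kernel(spec.polymer.bond_length, grid)
    return Workspace(spec=spec, weights=weights, pair_kernels=kernels,
                     walls=walls, kernel=tk, graft_index=graft_index, pads=pads)


@dataclass
class SolverState:
    """Current iterate: particle profiles (3D, nm^-3) and the mean field w."""

    profiles: dict                # sid -> rho_hat for particle species
    w: np.ndarray
    iteration: int = 0
    dt: float = 0.002
    residual_history: list = field(default_factory=list)

    def copy(self) -> "SolverState":
        return SolverState(profiles={k: v.copy() for k, v in self.profiles.items()},
                           w=self.w.copy(), iteration=self.iteration, dt=self.dt,
                           residual_history=list(self.residual_history))


@dataclass
class RhsBundle:
    """Everything evaluated at one state: polymer density, correlations,
    cohesion fields, and the Picard targets."""

    rho_poly: np.ndarray
    props: Propagators
    c: dict                       # sid -> c_i(z)
    attraction: dict              # sid -> sum_j (U_ij (*) rho_j)(z)
    w_target: np.ndarray
    rho_targets: dict             # particle sid -> target profile
    n: fmt.WeightedDensities


def initial_state(ws: Workspace) -> SolverState:
    """Barometric particles, wall-only field."""
    profiles = {p.id: p.bulk_density * np.exp(-ws.walls[p.id])
                for p in ws.spec.particles}
    return SolverState(profiles=profiles, w=ws.walls[ws.spec.polymer.id].copy(),
                       dt=ws.spec.timestep)


def warm_start(state: SolverState | None, spec: SystemSpec) -> SolverState | None:
    """Adapt a converged state of a related system as an initial guess.

    The mean field carries over; particle species present in the old state
    keep their profiles, new ones start barometrically.  Returns None for a
    None input (cold start).
    """
    if state is None:
        return None
    profiles = {}
    for p in spec.particles:
        if p.id in state.profiles:
            profiles[p.id] = state.profiles[p.id].copy()
        else:
            v = wall_on_grid(spec.grid, p.diameter, spec.wall_strength)
            profiles[p.id] = p.bulk_density * np.exp(-v)
    return SolverState(profiles=profiles, w=state.w.copy(), dt=spec.timestep)


def _all_profiles(ws: Workspace, state: SolverState, rho_poly: np.ndarray) -> dict:
    out = dict(state.profiles)
    out[ws.spec.polymer.id] = rho_poly
    return out


def attraction_field(ws: Workspace, profiles: dict, sid: str) -> np.ndarray:
    """sum_j (U_sid,j (*) rho_j)(z) in kT (beta = 1)."""
    acc = np.zeros(ws.spec.grid.num_slices)
    for j, rho in profiles.items():
        kern = ws.pair_kernels.get((sid, j))
        if kern is not None:
            acc += convolve(rho, kern.values, ws.dz, pad_hi=ws.pads.get(j, 0.0))
    return acc


def evaluate_rhs(ws: Workspace, state: SolverState) -> RhsBundle:
    """Evaluate the polymer density, correlations and both Picard targets."""
    spec = ws.spec
    pid = spec.polymer.id
    props = propagate(state.w, spec.polymer.beads_per_chain, ws.kernel, ws.graft_index)
    rho_poly = polymer_density(props, spec.polymer.num_chains, spec.area, ws.dz)
    profiles = _all_profiles(ws, state, rho_poly)

    n = fmt.weighted_densities(profiles, ws.weights, ws.dz, pid, ws.pads)
    c = fmt.direct_correlations(profiles, ws.weights, ws.dz, pid,
                                spec.polymer.beads_per_chain, ws.pads, n=n)
    att = {sid: attraction_field(ws, profiles, sid) for sid in spec.species_ids}

    w_target = -c[pid] + att[pid] + ws.walls[pid]
    rho_targets = {}
    for p in spec.particles:
        expo = (p.excess_chem_potential + c[p.id] - att[p.id] - ws.walls[p.id])
        rho_targets[p.id] = p.bulk_density * np.exp(np.minimum(expo, _EXP_CLIP))
    return RhsBundle(rho_poly=rho_poly, props=props, c=c, attraction=att,
                     w_target=w_target, rho_targets=rho_targets, n=n)


def particle_rhs(ws: Workspace, state: SolverState, sid: str) -> np.ndarray:
    """Picard target profile for one particle species."""
    return evaluate_rhs(ws, state).rho_targets[sid]


def field_rhs(ws: Workspace, state: SolverState) -> np.ndarray:
    """Picard target for the polymer mean field."""
    return evaluate_rhs(ws, state).w_target


def residual_of(ws: Workspace, state: SolverState,
                rhs: RhsBundle | None = None) -> float:
    """Sup-norm Euler-Lagrange violation.

    max over z of |w - w_target| plus, per particle species, the sup of
    |ln(rho / rho_target)| outside the wall region (z >= d_i, where the
    wall potential vanishes and both densities are strictly positive).
    """
    if rhs is None:
        rhs = evaluate_rhs(ws, state)
    res = float(np.max(np.abs(state.w - rhs.w_target)))
    for p in ws.spec.particles:
        mask = ws.walls[p.id] == 0.0
        rho = state.profiles[p.id][mask]
        tgt = rhs.rho_targets[p.id][mask]
        ok = (rho > 0) & (tgt > 0)
        if np.any(ok):
            res = max(res, float(np.max(np.abs(np.log(rho[ok]) - np.log(tgt[ok])))))
        if np.any(~ok):
            res = max(res, 1.0)   # a pinned-to-zero slice is maximally wrong
    return res


#: trust-region growth bound for particle updates (e^2 per target
#: evaluation); the fixed point is unchanged, but transients with huge
#: Boltzmann factors cannot overshoot into overpacked states
_GROWTH_CAP = np.exp(2.0)


def picard_step(ws: Workspace, state: SolverState, dt: float,
                rhs: RhsBundle | None = None) -> SolverState:
    """x <- x + dt (target - x) for w and every particle profile.

    Particle targets are capped at _GROWTH_CAP times the current profile
    (plus a small absolute floor so empty regions can refill), which keeps
    early iterations from overshooting into n3 >= 1 while leaving the
    converged solution untouched.
    """
    if rhs is None:
        rhs = evaluate_rhs(ws, state)
    new = state.copy()
    new.w = state.w + dt * (rhs.w_target - state.w)
    for sid in state.profiles:
        rho = state.profiles[sid]
        floor = 1e-6 * ws.spec.particle(sid).bulk_density
        capped = np.minimum(rhs.rho_targets[sid], _GROWTH_CAP * rho + floor)
        new.profiles[sid] = np.maximum(rho + dt * (capped - rho), 0.0)
    new.iteration = state.iteration + 1
    return new


@dataclass
class SolverResult:
    """Converged (or flagged) solution plus diagnostics."""

    state: SolverState
    rho_poly: np.ndarray
    profiles: dict                # all species incl. polymer
    c: dict
    attraction: dict
    grand_potential: float
    residual: float
    iterations: int
    converged: bool
    spec: SystemSpec

    @property
    def w(self) -> np.ndarray:
        return self.state.w


class _Anderson:
    """Type-II Anderson mixing over the damped Picard map.

    Accelerates the linear tail of the fixed-point iteration; engaged only
    once the residual is below ``start`` and flushed whenever the solver
    rolls back.  Falls back to the plain Picard step when the least-squares
    combination is ill-conditioned or suggests a wild extrapolation.
    """

    def __init__(self, depth: int = 4, start: float = 1.0):
        self.depth = depth
        self.start = start
        self.xs: list = []
        self.gs: list = []

    def reset(self):
        self.xs.clear()
        self.gs.clear()

    def push(self, x: np.ndarray, g: np.ndarray):
        self.xs.append(x)
        self.gs.append(g)
        if len(self.xs) > self.depth + 1:
            self.xs.pop(0)
            self.gs.pop(0)

    def extrapolate(self) -> np.ndarray | None:
        if len(self.xs) < 2:
            return None
        F = [g - x for g, x in zip(self.gs, self.xs)]
        dF = np.stack([F[i + 1] - F[i] for i in range(len(F) - 1)], axis=1)
        try:
            gamma, *_ = np.linalg.lstsq(dF, F[-1], rcond=1e-12)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(gamma)) or np.linalg.norm(gamma) > 1e5:
            return None
        dG = np.stack([self.gs[i + 1] - self.gs[i] for i in range(len(F) - 1)],
                      axis=1)
        return self.gs[-1] - dG @ gamma


def _pack(state: SolverState, order: list) -> np.ndarray:
    return np.concatenate([state.w] + [state.profiles[s] for s in order])


def _unpack(x: np.ndarray, template: SolverState, order: list) -> SolverState:
    L = len(template.w)
    new = template.copy()
    new.w = x[:L].copy()
    for i, sid in enumerate(order):
        new.profiles[sid] = np.maximum(x[(i + 1) * L:(i + 2) * L], 0.0)
    return new


def solve(spec: SystemSpec, init: SolverState | None = None,
          graft_index: int | None = None, dt_max: float = 0.01,
          log_every: int = 0, anderson_depth: int = 4) -> SolverResult:
    """Iterate to the self-consistent fixed point.

    ``init`` warm-starts from a previous state (e.g. the preceding point of
    a concentration sweep).  The step size starts at spec.timestep, grows
    by 2% per stable iteration up to ``dt_max`` and is halved (with state
    rollback) when the packing diverges or the residual jumps.  Once the
    damped iteration enters its linear regime, Anderson mixing over the
    Picard map accelerates convergence; any misstep flushes the mixing
    history and resumes plain relaxation from the best state seen.
    """
    ws = build_workspace(spec, graft_index=graft_index)
    state = init.copy() if init is not None else initial_state(ws)
    state.dt = min(max(state.dt, spec.timestep), dt_max)
    order = [p.id for p in spec.particles]
    accel = _Anderson(depth=anderson_depth) if anderson_depth else None
    best = None
    prev_res = np.inf
    cooldown = 0
    cooldown_span = 50
    last_was_accel = False

    while state.iteration < spec.max_iterations:
        try:
            rhs = evaluate_rhs(ws, state)
            res = residual_of(ws, state, rhs)
            bad = not np.isfinite(res)
        except (fmt.OverpackingError, RuntimeError, FloatingPointError):
            res = np.nan
            bad = True
        accel_misstep = last_was_accel and (bad or res > 3 * prev_res)
        picard_misstep = (not last_was_accel) and \
            (bad or (res > 10 * prev_res and res > 1.0))
        if accel_misstep or picard_misstep:
            if best is None:
                if bad:
                    raise RuntimeError(
                        "diverged on the first iteration (bad initial state)")
            else:
                state = best.copy()
                if picard_misstep:
                    state.dt = max(state.dt / 2, 1e-5)
                prev_res = np.inf
                if accel:
                    accel.reset()
                # Picard-only recovery window, growing on repeated missteps
                cooldown = state.iteration + cooldown_span
                cooldown_span = min(cooldown_span * 2, 5000)
                last_was_accel = False
                continue
        state.residual_history.append(res)
        if log_every and state.iteration % log_every == 0:
            print(f"  iter {state.iteration:6d}  dt={state.dt:.5f}  "
                  f"residual={res:.3e}")
        if res <= spec.tolerance:
            return _finalise(ws, state, rhs, res, converged=True)
        if res < prev_res:
            best = state.copy()
            prev_res = res

        picard = picard_step(ws, state, state.dt, rhs)
        candidate = None
        if accel is not None and res < accel.start and state.iteration >= cooldown:
            accel.push(_pack(state, order), _pack(picard, order))
            x_acc = accel.extrapolate()
            if x_acc is not None and np.all(np.isfinite(x_acc)):
                candidate = _unpack(x_acc, state, order)
        last_was_accel = candidate is not None
        new = candidate if candidate is not None else picard
        new.iteration = state.iteration + 1
        new.dt = min(state.dt * 1.02, dt_max)
        new.residual_history = state.residual_history
        state = new

    rhs = evaluate_rhs(ws, state)
    res = residual_of(ws, state, rhs)
    return _finalise(ws, state, rhs, res, converged=res <= spec.tolerance)


def _finalise(ws: Workspace, state: SolverState, rhs: RhsBundle,
              res: float, converged: bool) -> SolverResult:
    omega = grand_potential(ws, state, rhs)
    return SolverResult(state=state, rho_poly=rhs.rho_poly,
                        profiles=_all_profiles(ws, state, rhs.rho_poly),
                        c=rhs.c, attraction=rhs.attraction,
                        grand_potential=omega, residual=res,
                        iterations=state.iteration, converged=converged,
                        spec=ws.spec)


def grand_potential(ws: Workspace, state: SolverState,
                    rhs: RhsBundle | None = None) -> float:
    """beta * Omega evaluated on the current profiles (kT).

    Sum of ideal-gas, ideal-polymer (-N ln Zc), mean-field compensation,
    external, reservoir-exchange, cohesion, and hard-sphere terms.
    Thermal-wavelength constants are set to one length unit; the ideal-gas
    x ln x integrand is continued by 0 at zero density.
    """
    if rhs is None:
        rhs = evaluate_rhs(ws, state)
    spec = ws.spec
    A, dz = spec.area, ws.dz
    pid = spec.polymer.id
    profiles = _all_profiles(ws, state, rhs.rho_poly)

    total = 0.0
    for p in spec.particles:
        rho = profiles[p.id]
        mu = (np.log(p.bulk_density) if p.bulk_density > 0 else 0.0) \
            + p.excess_chem_potential
        xlnx = np.where(rho > 0, rho * (np.log(np.where(rho > 0, rho, 1.0)) - 1.0), 0.0)
        total += A * dz * float(np.sum(
            xlnx + rho * (ws.walls[p.id] - mu)))

    total += -spec.polymer.num_chains * rhs.props.log_zc
    total += -A * dz * float(np.sum(state.w * rhs.rho_poly))
    total += A * dz * float(np.sum(rhs.rho_poly * ws.walls[pid]))

    for i in spec.species_ids:
        # attraction[i] = sum_j U_ij (*) rho_j; the double sum over ordered
        # pairs double-counts, hence the 1/2
        total += 0.5 * A * dz * float(np.sum(profiles[i] * rhs.attraction[i]))

    phi = fmt.whitebear_phi(rhs.n) + fmt.chain_phi(
        rhs.n, spec.polymer.beads_per_chain, ws.weights[pid].R)
    total += A * dz * float(np.sum(phi))
    return total
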