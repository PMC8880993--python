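"""Configuration parsing and results serialisation.

Configs are YAML with sections ``grid``, ``polymer``, ``particles``,
``interactions`` and ``solver``; unknown keys are rejected (fail-closed)
so a typo cannot silently fall back to a default.  Profiles are written as
TSV with repr-exact floats, so a write/read round trip is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import presets
from .observables import pmf
from .potentials import wall_on_grid
from .solver import SolverResult
from .system import (Grid, InteractionTable, ParticleSpecies, PolymerSpecies,
                     SystemSpec, validate_spec)

_GRID_KEYS = {"num_slices", "dz"}
_POLYMER_KEYS = {"id", "bead_diameter", "beads_per_chain", "num_chains", "bond_length"}
_PARTICLE_KEYS = {"diameter", "bulk_concentration", "excess_chem_potential"}
_INTERACTION_KEYS = {"epsilon", "alpha", "cutoff_multiplier"}
_SOLVER_KEYS = {"timestep", "tolerance", "max_iterations", "wall_strength"}
_TOP_KEYS = {"preset", "grid", "area", "polymer", "particles", "interactions", "solver"}


class ConfigError(ValueError):
    """A malformed or inconsistent configuration file."""


def _check_keys(section: dict, allowed: set, where: str):
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in [{where}]")


def load_config(path) -> SystemSpec:
    """Parse and validate a YAML system description.

    ``preset: nsp1_film`` loads the bundled reference film, after which any
    explicit section overrides the preset values.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")

    base = presets.nsp1_film() if raw.get("preset") == "nsp1_film" else None
    if raw.get("preset") not in (None, "nsp1_film"):
        raise ConfigError(f"unknown preset {raw['preset']!r}")
    if base is None and not {"grid", "area", "polymer"} <= set(raw):
        raise ConfigError("grid, area and polymer are required without a preset")

    try:
        if "grid" in raw:
            _check_keys(raw["grid"], _GRID_KEYS, "grid")
            grid = Grid(**raw["grid"])
        else:
            grid = base.grid
        if "polymer" in raw:
            _check_keys(raw["polymer"], _POLYMER_KEYS, "polymer")
            polymer = PolymerSpecies(**raw["polymer"])
        else:
            polymer = base.polymer
        area = float(raw.get("area", base.area if base else 0))

        particles = []
        for sid, body in (raw.get("particles") or {}).items():
            _check_keys(body, _PARTICLE_KEYS, f"particles.{sid}")
            particles.append(ParticleSpecies(id=str(sid), **body))

        if "interactions" in raw:
            body = dict(raw["interactions"])
            _check_keys(body, _INTERACTION_KEYS, "interactions")
            eps = {}
            for pair, val in (body.pop("epsilon", {}) or {}).items():
                i, j = (s.strip() for s in str(pair).split(","))
                eps[(i, j)] = float(val)
            inter = InteractionTable(epsilon=eps, **body)
        else:
            inter = base.interactions if base else InteractionTable()

        solver_kw = dict(raw.get("solver") or {})
        _check_keys(solver_kw, _SOLVER_KEYS, "solver")
        defaults = base or presets.nsp1_film()
        spec = SystemSpec(
            grid=grid, area=area, polymer=polymer, particles=tuple(particles),
            interactions=inter,
            wall_strength=solver_kw.get("wall_strength", defaults.wall_strength),
            timestep=solver_kw.get("timestep", defaults.timestep),
            tolerance=solver_kw.get("tolerance", defaults.tolerance),
            max_iterations=solver_kw.get("max_iterations", defaults.max_iterations),
        )
        return validate_spec(spec)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"{path}: {exc}") from exc


def profiles_frame(result: SolverResult) -> pd.DataFrame:
    """Tabular profiles: z, per-species densities (3D and 1D), PMFs, field."""
    spec = result.spec
    z = spec.grid.midpoints
    cols = {"z_nm": z}
    pid = spec.polymer.id
    cols[f"rho3d_{pid}"] = result.rho_poly
    cols[f"rho1d_{pid}"] = result.rho_poly * spec.area
    for p in spec.particles:
        rho = result.profiles[p.id]
        cols[f"rho3d_{p.id}"] = rho
        cols[f"rho1d_{p.id}"] = rho * spec.area
        if p.bulk_density > 0:
            cols[f"pmf_{p.id}"] = pmf(rho, p.bulk_density)
        else:
            cols[f"pmf_{p.id}"] = np.zeros_like(rho)
    cols["w"] = result.w
    for sid in spec.species_ids:
        cols[f"vext_{sid}"] = wall_on_grid(spec.grid, spec.diameter(sid),
                                           spec.wall_strength)
    return pd.DataFrame(cols)


def write_profiles(result: SolverResult, path) -> None:
    """Write the profiles table as TSV with repr-exact floats."""
    df = profiles_frame(result)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def save_state(state, path) -> None:
    """Checkpoint a solver state as TSV (repr-exact floats).

    First line is a comment carrying the scalar fields; columns are the
    mean field and one density column per particle species.
    """
    cols = {"w": state.w}
    for sid, rho in state.profiles.items():
        cols[f"rho_{sid}"] = rho
    with open(path, "w") as fh:
        fh.write(f"# fgdft-checkpoint\titeration={state.iteration}"
                 f"\tdt={float(state.dt)!r}\n")
        fh.write("\t".join(cols) + "\n")
        for row in zip(*cols.values()):
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def load_state(path):
    """Inverse of :func:`save_state`."""
    from .solver import SolverState
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# fgdft-checkpoint"):
            raise ConfigError(f"{path}: not a checkpoint file")
        meta = dict(item.split("=") for item in header.split("\t")[1:])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    profiles = {c[len("rho_"):]: df[c].to_numpy() for c in df.columns
                if c.startswith("rho_")}
    return SolverState(profiles=profiles, w=df["w"].to_numpy(),
                       iteration=int(meta["iteration"]),
                       dt=float(meta["dt"]))


def kernel_table(kernel) -> pd.DataFrame:
    """TSV-ready dump of a pair kernel for inspection."""
    K = kernel.half_width
    return pd.DataFrame({
        "offset_nm": np.arange(-K, K + 1) * kernel.dz,
        "energy": kernel.values,
    })


def run_manifest(result: SolverResult, outputs: list, config_path=None) -> dict:
    """JSON-able record of one run: config hash, convergence, output index."""
    from . import __version__
    h = None
    if config_path is not None:
        h = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    return {
        "code_version": __version__,
        "config_sha256": h,
        "converged": bool(result.converged),
        "iterations": int(result.iterations),
        "residual": float(result.residual),
        "grand_potential_kT": float(result.grand_potential),
        "outputs": [str(o) for o in outputs],
    }


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
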