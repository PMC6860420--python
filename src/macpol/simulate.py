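"""Stiff ODE integration, steady-state pre-equilibration and event scheduling.

Scenarios are simulated from the equilibrated unstimulated state.  Ligand
stimuli are converted from mass doses (ng/ml) to molecules per cell using the
plating density and added (+=) to the extracellular pool at the event time;
oxygen conditions reset the buffered oxygen species.  Integration restarts at
each event so trajectories are continuous except at event discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelDefinition, ParameterSet, assemble_rhs

__all__ = [
    "AVOGADRO",
    "DEFAULT_CELL_DENSITY",
    "NORMOXIA_PERCENT",
    "StimulusEvent",
    "OxygenCondition",
    "SimulationResult",
    "SimulationError",
    "EquilibrationError",
    "dose_to_copies",
    "equilibrate",
    "run_scenario",
]

AVOGADRO = 6.02214076e23
#: macrophages plated at one million cells per ml of culture medium
DEFAULT_CELL_DENSITY = 1.0e6
NORMOXIA_PERCENT = 21.0

#: id of the species that carries the oxygen condition in models that have one
OXYGEN_SPECIES = "O2"


class SimulationError(RuntimeError):
    """Integration failure; carries the last good time and state."""

    def __init__(self, message: str, t_last: float | None = None,
                 state_last: np.ndarray | None = None):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


class EquilibrationError(RuntimeError):
    """Steady-state search did not converge; carries the residual report."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class StimulusEvent:
    """Addition of a ligand dose at a given time.

    ``dose`` is in ng/ml for mass-based doses (requires ``mol_weight`` in
    g/mol) or directly in molecules per cell when ``in_copies`` is true
    (miR mimics, copy-number stimuli).
    """

    ligand: str  # species id of the extracellular/cellular pool to increment
    dose: float
    mol_weight: float | None = None
    time_added: float = 0.0
    in_copies: bool = False

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.time_added < 0:
            raise ValueError("time_added must be >= 0")
        if not self.in_copies and (self.mol_weight is None or self.mol_weight <= 0):
            raise ValueError("mass-based doses need mol_weight > 0")

    def copies(self, cell_density: float = DEFAULT_CELL_DENSITY) -> float:
        if self.in_copies:
            return self.dose
        return dose_to_copies(self.dose, self.mol_weight, cell_density)


@dataclass(frozen=True)
class OxygenCondition:
    """Oxygen level in percent O2 (21 = normoxia), applied at a given time."""

    percent_O2: float = NORMOXIA_PERCENT
    time_applied: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.percent_O2 <= NORMOXIA_PERCENT):
            raise ValueError("percent_O2 must be in (0, 21]")
        if self.time_applied < 0:
            raise ValueError("time_applied must be >= 0")


@dataclass
class SimulationResult:
    """Time grid (hours), per-species trajectories and an event log."""

    time: np.ndarray
    trajectories: np.ndarray  # shape (n_species, n_times)
    species_ids: list[str]
    events_applied: list[dict] = field(default_factory=list)
    solver_stats: dict = field(default_factory=dict)

    def __getitem__(self, species_id: str) -> np.ndarray:
        return self.trajectories[self.species_ids.index(species_id)]

    def at_time(self, t: float) -> np.ndarray:
        """State vector at time ``t``, linearly interpolated on the grid."""
        return np.array([np.interp(t, self.time, row) for row in self.trajectories])

    def value(self, species_id: str, t: float) -> float:
        return float(np.interp(t, self.time, self[species_id]))

    def to_frame(self):
        """Tidy (time, species, value) DataFrame."""
        import pandas as pd

        n_t = len(self.time)
        return pd.DataFrame({
            "time": np.tile(self.time, len(self.species_ids)),
            "species": np.repeat(self.species_ids, n_t),
            "value": self.trajectories.reshape(-1),
        })


def dose_to_copies(dose: float, mol_weight: float,
                   cell_density: float = DEFAULT_CELL_DENSITY) -> float:
    """Convert a mass dose (ng/ml) to average molecules per cell.

    copies = dose[g/ml] / MW[g/mol] * N_A / density[cells/ml].
    """
    if mol_weight is None or mol_weight <= 0:
        raise ValueError("mol_weight must be > 0")
    if cell_density <= 0:
        raise ValueError("cell_density must be > 0")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return dose * 1e-9 / mol_weight * AVOGADRO / cell_density


def _clamp_small_negatives(y: np.ndarray, t: float) -> np.ndarray:
    """Nonnegativity guard: clamp tiny transient undershoots, fail on large ones."""
    scale = max(float(np.max(y)), 1.0)
    tol = 1e-9 * scale
    bad = y < -tol
    if np.any(bad):
        raise SimulationError(
            f"state went negative beyond tolerance at t={t:.3g} "
            f"(min {float(np.min(y)):.3g})", t_last=t, state_last=y)
    return np.maximum(y, 0.0)


def _integrate(rhs, t0, t1, y0, rtol, atol, t_eval=None, method="LSODA"):
    sol = solve_ivp(rhs, (t0, t1), y0, method=method, rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise SimulationError(
            f"integration failed on [{t0}, {t1}]: {sol.message}",
            t_last=float(sol.t[-1]) if sol.t.size else t0,
            state_last=sol.y[:, -1] if sol.t.size else y0)
    return sol


def equilibrate(
    model: ModelDefinition,
    parameters: ParameterSet | None = None,
    state0: np.ndarray | None = None,
    residual_tol: float = 1e-8,
    chunk: float = 2000.0,
    max_time: float = 2.0e5,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> np.ndarray:
    """Steady state of the unstimulated model by long-horizon integration.

    Integrates in chunks until max |dX/dt| / max(X, eps) < ``residual_tol``
    per hour, mirroring the control-condition pre-equilibration used to set
    the physiological baseline of unpolarized cells.
    """
    rhs = assemble_rhs(model, parameters)
    y = model.initial_state() if state0 is None else np.asarray(state0, float).copy()
    t = 0.0
    eps = 1e-6
    residual = np.inf
    while t < max_time:
        sol = _integrate(rhs, t, t + chunk, y, rtol, atol)
        y = np.maximum(sol.y[:, -1], 0.0)
        t += chunk
        dy = rhs(t, y)
        residual = float(np.max(np.abs(dy) / np.maximum(np.max(y), eps)))
        if residual < residual_tol:
            return y
    raise EquilibrationError(
        f"no steady state within {max_time} h (residual {residual:.3g}/h, "
        f"tol {residual_tol:.3g}/h)", residual=residual)


def run_scenario(
    model: ModelDefinition,
    events: list[StimulusEvent] | None = None,
    oxygen: OxygenCondition | None = None,
    horizon: float = 48.0,
    state0: np.ndarray | None = None,
    parameters: ParameterSet | None = None,
    cell_density: float = DEFAULT_CELL_DENSITY,
    n_grid: int = 241,
    rtol: float = 1e-6,
    atol: float = 1e-3,
    method: str = "LSODA",
) -> SimulationResult:
    """Simulate a stimulation scenario from a baseline state.

    ``state0`` defaults to the model's stored initial state (normally the
    equilibrated baseline).  Ligand doses are *added* to the current pool at
    their event time; oxygen conditions *set* the buffered oxygen species.
    The output grid contains every event time.
    """
    events = sorted(events or [], key=lambda e: e.time_added)
    edits: list[tuple[float, str, float, str]] = []  # (time, species, value, mode)
    for ev in events:
        edits.append((ev.time_added, ev.ligand, ev.copies(cell_density), "add"))
    if oxygen is not None and OXYGEN_SPECIES in model.species_index:
        edits.append((oxygen.time_applied, OXYGEN_SPECIES,
                      float(oxygen.percent_O2), "set"))
    edits.sort(key=lambda e: e[0])
    if edits and edits[-1][0] > horizon:
        raise ValueError("horizon must cover every event time")

    rhs = assemble_rhs(model, parameters)
    index = model.species_index
    y = model.initial_state() if state0 is None else np.asarray(state0, float).copy()

    grid = np.linspace(0.0, horizon, n_grid)
    event_times = sorted({t for t, *_ in edits})
    grid = np.unique(np.concatenate([grid, np.array(event_times)]))

    times: list[np.ndarray] = []
    trajs: list[np.ndarray] = []
    log: list[dict] = []
    nsteps = 0

    segment_bounds = [0.0] + [t for t in event_times if t > 0] + [horizon]
    segment_bounds = sorted(set(segment_bounds))

    # apply t=0 edits before the first segment
    for t_e, sp, val, mode in edits:
        if t_e == 0.0:
            i = index[sp]
            y[i] = y[i] + val if mode == "add" else val
            log.append({"time": 0.0, "species": sp, "value": val, "mode": mode})

    for a, b in zip(segment_bounds[:-1], segment_bounds[1:]):
        t_eval = grid[(grid >= a) & (grid <= b)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        sol = _integrate(rhs, a, b, y, rtol, atol, t_eval=t_eval, method=method)
        nsteps += sol.t.size
        keep = slice(0, None) if not times else slice(1, None)
        times.append(sol.t[keep])
        trajs.append(sol.y[:, keep])
        y = _clamp_small_negatives(sol.y[:, -1].copy(), b)
        for t_e, sp, val, mode in edits:
            if t_e == b and b < horizon:
                i = index[sp]
                y[i] = y[i] + val if mode == "add" else val
                log.append({"time": b, "species": sp, "value": val, "mode": mode})
        # overwrite segment-end column with post-event state so the next
        # segment starts from it; the stored trajectory keeps pre-event values
    time = np.concatenate(times)
    traj = np.concatenate(trajs, axis=1)
    traj = np.maximum(traj, 0.0)
    return SimulationResult(
        time=time, trajectories=traj, species_ids=model.species_ids,
        events_applied=log,
        solver_stats={"n_points": int(nsteps), "rtol": rtol, "atol": atol,
                      "method": method},
    )
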