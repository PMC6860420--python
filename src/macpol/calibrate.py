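"""Calibration against normalized literature-style datasets.

The objective is a weighted sum of squared errors between each dataset's
normalized measurement series and the matching normalized simulation, plus a
smooth admissibility penalty keeping steady-state copy numbers of the
"unique" species groups within a 0.5x-2x band of literature priors.
Optimization is a deterministic, bound-respecting compass/pattern search
(derivative-free direct search over a shrinking/expanding mesh on log-scale
parameters); bootstrap uncertainty resamples datasets with replacement and
refits a small free-parameter subset per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelDefinition, ParameterSet
from .scenarios import (NormalizationMode, Scenario, apply_perturbations,
                        normalize_series)
from .simulate import EquilibrationError, SimulationError, equilibrate, run_scenario

__all__ = [
    "CalibDataset",
    "CopyNumberPrior",
    "FitResult",
    "CalibrationError",
    "objective",
    "check_initial_conditions",
    "pattern_search",
    "fit",
    "bootstrap_fit",
]

#: finite penalty charged when a candidate parameter set cannot be simulated;
#: keeps derivative-free search alive at pathological mesh points
FAILURE_PENALTY = 1.0e9


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibDataset:
    """One normalized measurement series tied to a stimulation scenario.

    ``points`` is a tuple of (time h, normalized value) pairs; ``observable``
    is the species id read out of the simulation.  ``weight`` defaults to
    1/n_points so every dataset carries equal influence.
    """

    id: str
    scenario: Scenario
    observable: str
    points: tuple[tuple[float, float], ...]
    normalization: NormalizationMode
    weight: float | None = None
    level: str = "protein"  # or "mRNA"
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "points",
                           tuple((float(t), float(v)) for t, v in self.points))
        if not self.points:
            raise CalibrationError(f"dataset {self.id!r} has no points")
        horizon = self.scenario.horizon
        for t, _ in self.points:
            if t < 0 or t > horizon:
                raise CalibrationError(
                    f"dataset {self.id!r}: time {t} outside scenario horizon")
        w = self.weight
        if w is not None and w <= 0:
            raise CalibrationError(f"dataset {self.id!r}: weight must be > 0")

    @property
    def effective_weight(self) -> float:
        return self.weight if self.weight is not None else 1.0 / len(self.points)


@dataclass(frozen=True)
class CopyNumberPrior:
    """Literature copy numbers per species group with an admissible band."""

    copies: dict[str, float]
    band: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise CalibrationError("admissibility band must satisfy 0 < lo < hi")
        for group, c in self.copies.items():
            if c <= 0:
                raise CalibrationError(f"prior for {group!r} must be > 0")


@dataclass
class FitResult:
    parameters: ParameterSet
    objective_value: float
    per_dataset_residuals: dict[str, float]
    admissibility: dict[str, bool] = field(default_factory=dict)
    trace: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def _simulate_dataset(model: ModelDefinition, params: ParameterSet,
                      dataset: CalibDataset,
                      baseline: np.ndarray) -> np.ndarray:
    """Normalized simulated values at the dataset's time points."""
    scen = dataset.scenario
    sim_model, state = model, baseline
    if scen.perturbations:
        base = model.copy()
        base.parameters.update(params)
        sim_model, state = apply_perturbations(base, baseline,
                                               scen.perturbations)
        params = sim_model.parameters
    result = run_scenario(sim_model, events=scen.stimuli, oxygen=scen.oxygen,
                          horizon=scen.horizon, state0=state, parameters=params)
    times = np.array([t for t, _ in dataset.points])
    utr = None
    if dataset.normalization.mode == "to_untreated":
        utr = float(baseline[model.species_index[dataset.observable]])
    series = normalize_series(result[dataset.observable], result.time,
                              dataset.normalization, untreated=utr,
                              species=dataset.observable)
    return np.interp(times, result.time, series)


def objective(
    model: ModelDefinition,
    params: ParameterSet,
    datasets: list[CalibDataset],
    prior: CopyNumberPrior | None = None,
    penalty_weight: float = 1.0,
    baseline: np.ndarray | None = None,
    equilibrate_kwargs: dict | None = None,
) -> float:
    """Weighted SSE of normalized simulation vs data, plus admissibility penalty.

    Simulation failures contribute a large finite penalty instead of raising,
    which keeps pattern search informative near infeasible mesh points.
    """
    total = 0.0
    eq_kw = {"residual_tol": 1e-6, **(equilibrate_kwargs or {})}
    try:
        y0 = baseline if baseline is not None else \
            equilibrate(model, parameters=params, **eq_kw)
    except (EquilibrationError, SimulationError):
        return FAILURE_PENALTY * (len(datasets) or 1)
    for ds in datasets:
        try:
            sim = _simulate_dataset(model, params, ds, y0)
            obs = np.array([v for _, v in ds.points])
            total += ds.effective_weight * float(np.sum((sim - obs) ** 2))
        except (SimulationError, RuntimeError, ValueError):
            total += FAILURE_PENALTY * ds.effective_weight
    if prior is not None:
        total += penalty_weight * _admissibility_penalty(model, y0, prior)
    return total


def _group_totals(model: ModelDefinition, state: np.ndarray) -> dict[str, float]:
    idx = model.species_index
    return {g: float(sum(state[idx[s]] for s in members))
            for g, members in model.groups.items()}


def _admissibility_penalty(model: ModelDefinition, state: np.ndarray,
                           prior: CopyNumberPrior) -> float:
    """Quadratic in log-distance outside the [lo, hi] x prior band."""
    lo, hi = prior.band
    totals = _group_totals(model, state)
    pen = 0.0
    for group, target in prior.copies.items():
        total = totals.get(group, 0.0)
        ratio = total / target if target > 0 else np.inf
        if ratio <= 0:
            pen += 25.0  # (log 0.5/75)^2-scale cap for extinct groups
            continue
        if ratio < lo:
            pen += np.log(ratio / lo) ** 2
        elif ratio > hi:
            pen += np.log(ratio / hi) ** 2
    return pen


def check_initial_conditions(
    model: ModelDefinition,
    params: ParameterSet | None = None,
    prior: CopyNumberPrior | None = None,
    state: np.ndarray | None = None,
    **equilibrate_kwargs,
) -> dict[str, dict]:
    """Steady-state copy-number admissibility per species group.

    Returns {group: {"total", "prior", "margin", "pass"}} where margin is
    steady total / prior and pass means margin lies within the band.
    """
    if prior is None:
        raise CalibrationError("a CopyNumberPrior is required")
    if state is None:
        state = equilibrate(model, parameters=params, **equilibrate_kwargs)
    lo, hi = prior.band
    totals = _group_totals(model, state)
    out = {}
    for group, target in prior.copies.items():
        total = totals.get(group, 0.0)
        margin = total / target
        out[group] = {"total": total, "prior": target, "margin": margin,
                      "pass": bool(lo <= margin <= hi)}
    return out


# ---------------------------------------------------------------------------
# Derivative-free direct search
# ---------------------------------------------------------------------------

def pattern_search(
    func,
    x0: np.ndarray,
    bounds: list[tuple[float, float]],
    mesh0: float = 0.25,
    mesh_min: float = 1e-4,
    expand: float = 2.0,
    contract: float = 0.5,
    max_iter: int = 200,
    log_scale: bool = True,
):
    """Compass/pattern search: poll +/- each coordinate on a mesh, expand on
    success, contract on failure, stop when the mesh underflows.

    Deterministic given the start point; bound-respecting by clipping polls.
    Returns (x_best, f_best, trace, n_eval) with a non-increasing trace over
    accepted iterations.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if log_scale:
        if np.any(lo <= 0):
            raise CalibrationError("log-scale search needs positive bounds")
        tlo, thi = np.log(lo), np.log(hi)
        to_x = np.exp
        from_x = np.log
    else:
        tlo, thi = lo, hi
        to_x = from_x = lambda v: v

    z = np.clip(from_x(np.asarray(x0, dtype=float)), tlo, thi)
    span = thi - tlo
    f_best = func(to_x(z))
    n_eval = 1
    trace = [f_best]
    mesh = mesh0
    n = len(z)
    for _ in range(max_iter):
        improved = False
        for j in range(n):
            for sign in (+1.0, -1.0):
                cand = z.copy()
                cand[j] = np.clip(cand[j] + sign * mesh * span[j], tlo[j], thi[j])
                if cand[j] == z[j]:
                    continue
                f = func(to_x(cand))
                n_eval += 1
                if f < f_best:
                    z, f_best, improved = cand, f, True
        trace.append(f_best)
        mesh = mesh * expand if improved else mesh * contract
        mesh = min(mesh, 1.0)
        if mesh < mesh_min:
            break
    return to_x(z), f_best, trace, n_eval


def fit(
    model: ModelDefinition,
    datasets: list[CalibDataset],
    free_params: list[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    prior: CopyNumberPrior | None = None,
    n_starts: int = 3,
    bound_fold: float = 10.0,
    **search_kwargs,
) -> FitResult:
    """Calibrate ``free_params`` by seeded multistart pattern search.

    Start 0 is the nominal point; further starts are log-uniform draws inside
    the bounds from a generator seeded by ``seed``.  Bounds default to
    x/÷``bound_fold`` around nominal.
    """
    for label in free_params:
        if label not in model.parameters:
            raise CalibrationError(f"unknown free parameter {label!r}")
    nominal = np.array([model.parameters[l] for l in free_params])
    if not free_params:
        val = objective(model, model.parameters, datasets, prior=prior)
        return FitResult(model.parameters.copy(), val,
                         _per_dataset(model, model.parameters, datasets),
                         trace=[val], n_evaluations=1)
    if bounds is None:
        bounds = {l: (v / bound_fold, v * bound_fold)
                  for l, v in zip(free_params, nominal)}
    blist = [bounds[l] for l in free_params]
    for l, (lo_b, hi_b) in bounds.items():
        if not (0 < lo_b < hi_b):
            raise CalibrationError(f"bounds for {l!r} must be positive, lo < hi")

    def wrapped(x: np.ndarray) -> float:
        params = model.parameters.copy()
        for label, value in zip(free_params, x):
            params[label] = float(value)
        return objective(model, params, datasets, prior=prior)

    rng = np.random.default_rng(seed)
    starts = [nominal]
    for _ in range(max(0, n_starts - 1)):
        draw = np.array([np.exp(rng.uniform(np.log(lo_b), np.log(hi_b)))
                         for lo_b, hi_b in blist])
        starts.append(draw)

    best = None
    for x0 in starts:
        x, fval, trace, n_eval = pattern_search(wrapped, x0, blist,
                                                **search_kwargs)
        if best is None or fval < best[1]:
            best = (x, fval, trace, n_eval)
    x, fval, trace, n_eval = best
    params = model.parameters.copy()
    for label, value in zip(free_params, x):
        params[label] = float(value)
        params.provenance[label] = "optimized"
    admiss = {}
    if prior is not None:
        try:
            report = check_initial_conditions(model, params=params, prior=prior,
                                              residual_tol=1e-6)
            admiss = {g: r["pass"] for g, r in report.items()}
        except (EquilibrationError, SimulationError):
            admiss = {}
    return FitResult(params, fval, _per_dataset(model, params, datasets),
                     admissibility=admiss, trace=trace, n_evaluations=n_eval)


def _per_dataset(model, params, datasets) -> dict[str, float]:
    out = {}
    try:
        y0 = equilibrate(model, parameters=params, residual_tol=1e-6)
    except (EquilibrationError, SimulationError):
        return {ds.id: float("nan") for ds in datasets}
    for ds in datasets:
        try:
            sim = _simulate_dataset(model, params, ds, y0)
            obs = np.array([v for _, v in ds.points])
            out[ds.id] = float(np.sum((sim - obs) ** 2))
        except (SimulationError, RuntimeError, ValueError):
            out[ds.id] = float("nan")
    return out


def bootstrap_fit(
    model: ModelDefinition,
    datasets: list[CalibDataset],
    free_params: list[str],
    n_boot: int = 50,
    seed: int = 0,
    start_jitter: float = 0.0,
    **fit_kwargs,
) -> list[ParameterSet]:
    """Dataset-level bootstrap: resample datasets with replacement, refit the
    free subset per replicate (default 50 replicates; the full-model workflow
    frees an 11-parameter high-sensitivity subset), collect the estimates.

    ``start_jitter`` > 0 displaces each replicate's free-parameter start by
    a seeded multiplicative lognormal factor (sigma = start_jitter in log
    space); parameters the data do not constrain then keep their displaced
    values, so the replicate spread exposes practical non-identifiability.

    Failed replicate fits are dropped and their count recorded under the
    ``_bootstrap_dropped`` provenance key of the surviving estimates.
    """
    if n_boot < 2:
        raise CalibrationError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    estimates: list[ParameterSet] = []
    dropped = 0
    for b in range(n_boot):
        idx = rng.integers(0, len(datasets), size=len(datasets))
        resampled = [datasets[i] for i in idx]
        start = model
        if start_jitter > 0:
            start = model.copy()
            for label in free_params:
                start.parameters[label] *= float(
                    rng.lognormal(0.0, start_jitter))
        try:
            result = fit(start, resampled, free_params,
                         seed=seed + 1 + b, **fit_kwargs)
            estimates.append(result.parameters)
        except (CalibrationError, SimulationError, EquilibrationError):
            dropped += 1
    if dropped:
        for est in estimates:
            est.provenance["_bootstrap_dropped"] = str(dropped)
    return estimates
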