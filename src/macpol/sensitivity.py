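"""Global sensitivity of the M1/M2 score: Latin-hypercube sampling + PRCC.

Parameters are sampled log-uniformly on per-parameter ranges (default x/÷10
around nominal), the scenario is re-simulated per sample, and the partial
rank correlation coefficient of each parameter with the score is computed
with a t-test p-value.  Significance follows the raw p < 0.05 convention;
an optional Benjamini-Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .model import ModelDefinition
from .scenarios import Scenario, apply_perturbations, m1m2_score
from .simulate import SimulationError, equilibrate, run_scenario

__all__ = [
    "SamplingPlan",
    "PRCCResult",
    "SensitivityError",
    "lhs_sample",
    "prcc",
    "score_sensitivity",
]


class SensitivityError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplingPlan:
    """Log-uniform Latin-hypercube plan over a set of parameter labels."""

    labels: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    n_samples: int
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.n_samples < len(self.labels) + 2:
            raise SensitivityError(
                "n_samples must be >= number of parameters + 2")
        for label in self.labels:
            lo, hi = self.ranges[label]
            if not (0 < lo < hi):
                raise SensitivityError(
                    f"degenerate range for {label!r}: ({lo}, {hi})")

    @classmethod
    def around_nominal(cls, parameters, labels, fold: float = 10.0,
                       n_samples: int = 5000, seed: int = 0) -> "SamplingPlan":
        """Default plan: x/÷``fold`` log-uniform band around nominal values."""
        ranges = {}
        for label in labels:
            nominal = parameters[label]
            if nominal <= 0:
                raise SensitivityError(
                    f"cannot build a log range around non-positive {label!r}")
            ranges[label] = (nominal / fold, nominal * fold)
        return cls(tuple(labels), ranges, n_samples, seed)


@dataclass
class PRCCResult:
    """Per-parameter partial rank correlation with significance."""

    table: pd.DataFrame  # columns: label, prcc, p_value, rank

    def __getitem__(self, label: str) -> float:
        row = self.table.loc[self.table["label"] == label, "prcc"]
        return float(row.iloc[0])

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_value"] < alpha]

    def top(self, k: int = 25) -> dict[str, pd.DataFrame]:
        sig = self.significant().sort_values("prcc")
        return {"positive": sig[sig["prcc"] > 0].tail(k).iloc[::-1],
                "negative": sig[sig["prcc"] < 0].head(k)}


def lhs_sample(plan: SamplingPlan) -> np.ndarray:
    """Latin-hypercube draw: one sample per equal-probability stratum and
    dimension, mapped through the log-uniform range. Shape (n_samples, p)."""
    p = len(plan.labels)
    sampler = qmc.LatinHypercube(d=p, seed=plan.seed)
    unit = sampler.random(n=plan.n_samples)
    out = np.empty_like(unit)
    for j, label in enumerate(plan.labels):
        lo, hi = plan.ranges[label]
        out[:, j] = np.exp(np.log(lo) + unit[:, j] * (np.log(hi) - np.log(lo)))
    return out


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, method="average")


def _residuals(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of y after least-squares regression on [1, Z]."""
    X = np.column_stack([np.ones(len(y)), Z]) if Z.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta

def prcc(X: np.ndarray, y: np.ndarray,
         labels: tuple[str, ...] | None = None) -> PRCCResult:
    """Partial rank correlation of each column of X with y.

    Ranks (average ties) are taken column-wise; the coefficient for
    parameter j is the Pearson correlation of the residuals of rank(x_j) and
    rank(y) after regressing both on the ranks of all other parameters.
    The p-value uses the t statistic with n - 2 - (p - 1) degrees of
    freedom.  Constant columns have no defined PRCC and are reported as NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise SensitivityError("rows of X must align with y")
    if labels is None:
        labels = tuple(f"x{j}" for j in range(p))

    Xr = np.column_stack([_rank(X[:, j]) for j in range(p)])
    yr = _rank(y)
    dof = n - 2 - (p - 1)
    rows = []
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            rows.append((labels[j], np.nan, np.nan))
            continue
        others = np.delete(Xr, j, axis=1)
        rx = _residuals(Xr[:, j], others)
        ry = _residuals(yr, others)
        denom = np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2))
        if denom == 0:
            rows.append((labels[j], np.nan, np.nan))
            continue
        r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
        if dof <= 0 or abs(r) >= 1.0:
            pval = 0.0 if abs(r) >= 1.0 else np.nan
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            pval = float(2 * stats.t.sf(abs(t), dof))
        rows.append((labels[j], r, pval))
    table = pd.DataFrame(rows, columns=["label", "prcc", "p_value"])
    table["rank"] = table["prcc"].abs().rank(ascending=False, method="min")
    return PRCCResult(table=table)


def score_sensitivity(
    model: ModelDefinition,
    scenario: Scenario,
    plan: SamplingPlan,
    t_eval: float = 24.0,
    m1_panel: dict[str, str] | None = None,
    m2_panel: dict[str, str] | None = None,
    baseline_state: np.ndarray | None = None,
    max_failure_fraction: float = 0.05,
    bh_adjust: bool = False,
) -> PRCCResult:
    """PRCC of the sampled parameters against the M1/M2 score at ``t_eval``.

    Each sampled parameter set re-equilibrates the baseline and re-simulates
    the scenario; failed simulations are dropped and counted, and the
    analysis aborts if more than ``max_failure_fraction`` of runs fail.
    """
    m1 = m1_panel or model.marker_panels.get("M1")
    m2 = m2_panel or model.marker_panels.get("M2")
    if not m1 or not m2:
        raise SensitivityError("model carries no M1/M2 marker panels")

    samples = lhs_sample(plan)
    scores = np.empty(len(samples))
    ok = np.zeros(len(samples), dtype=bool)
    for i, row in enumerate(samples):
        params = model.parameters.copy()
        for label, value in zip(plan.labels, row):
            params[label] = value
        try:
            y0 = baseline_state
            if y0 is None:
                y0 = equilibrate(model, parameters=params, residual_tol=1e-6)
            sim_model, state = model, y0
            if scenario.perturbations:
                sim_model, state = apply_perturbations(model, y0,
                                                       scenario.perturbations)
                params2 = sim_model.parameters
                for label, value in zip(plan.labels, row):
                    params2[label] = value
                params = params2
            result = run_scenario(sim_model, events=scenario.stimuli,
                                  oxygen=scenario.oxygen,
                                  horizon=max(scenario.horizon, t_eval),
                                  state0=state, parameters=params)
            scores[i] = m1m2_score(result, m1, m2, t_eval=t_eval)
            ok[i] = True
        except (SimulationError, RuntimeError, ValueError):
            # stiff blow-ups at extreme samples: drop and report
            ok[i] = False
    n_failed = int((~ok).sum())
    if n_failed > max_failure_fraction * len(samples):
        raise SensitivityError(
            f"{n_failed}/{len(samples)} sampled simulations failed "
            "(above the failure budget); check sampling ranges")
    result = prcc(samples[ok], scores[ok], labels=plan.labels)
    result.table.attrs["n_failed"] = n_failed
    result.table.attrs["n_used"] = int(ok.sum())
    if bh_adjust:
        pv = result.table["p_value"].to_numpy()
        order = np.argsort(pv)
        m = len(pv)
        adj = np.empty(m)
        prev = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            i = m - rank_i
            prev = min(prev, pv[idx] * m / i)
            adj[idx] = prev
        result.table["p_adjusted"] = adj
    return result
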