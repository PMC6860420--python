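"""Objective construction, admissibility check, pattern search, bootstrap."""

import numpy as np
import pytest

from macpol import (CalibDataset, CopyNumberPrior, NormalizationMode,
                    Scenario, StimulusEvent, ToySpec, bootstrap_fit,
                    check_initial_conditions, equilibrate, fit,
                    make_synthetic_datasets, make_toy, objective,
                    pattern_search)
from macpol.calibrate import CalibrationError


@pytest.fixture(scope="module")
def toy():
    model, ref = make_toy(ToySpec("ligand_receptor_stat"))
    baseline = equilibrate(model, residual_tol=1e-8)
    return model.with_initial_state(baseline), ref


def step_scenario(name="step", dose=1e4, horizon=24.0):
    return Scenario(name=name, stimuli=[
        StimulusEvent("L", dose, time_added=0.0, in_copies=True)],
        horizon=horizon)


@pytest.fixture(scope="module")
def toy_datasets(toy):
    model, _ = toy
    grids = [np.array([0.5, 1, 2, 4, 8, 16]), np.array([1, 4, 12, 24])]
    scens = [(step_scenario("hi", 1e4), "pS", grids[0]),
             (step_scenario("lo", 2e3), "pS", grids[1]),
             (step_scenario("hi2", 1e4), "I", grids[0])]
    return make_synthetic_datasets(model, scens, noise_cv=0.05, seed=5)


class TestObjective:
    def test_self_consistency_is_zero_without_noise(self, toy):
        model, _ = toy
        scens = [(step_scenario(), "pS", np.array([1.0, 4.0, 12.0]))]
        datasets = make_synthetic_datasets(model, scens, noise_cv=0.0, seed=0)
        assert objective(model, model.parameters, datasets) < 1e-10

    def test_single_point_arithmetic(self, toy):
        model, _ = toy
        # simulated normalized value vs observation 1.0 with weight 2:
        # craft the dataset so sim(t)=0.8 via to_max on a known series
        scen = step_scenario(horizon=24.0)
        ds = CalibDataset(
            id="one", scenario=scen, observable="pS",
            points=((24.0, 1.0),), normalization=NormalizationMode("to_max"),
            weight=2.0)
        from macpol import run_scenario
        from macpol.scenarios import normalize_series

        res = run_scenario(model, events=scen.stimuli, horizon=24.0)
        sim = normalize_series(res["pS"], res.time,
                               NormalizationMode("to_max"))[-1]
        expected = 2.0 * (sim - 1.0) ** 2
        got = objective(model, model.parameters, [ds],
                        baseline=model.initial_state())
        assert got == pytest.approx(expected, rel=1e-6)

    def test_invariant_to_dataset_ordering(self, toy, toy_datasets):
        model, _ = toy
        a = objective(model, model.parameters, toy_datasets)
        b = objective(model, model.parameters, toy_datasets[::-1])
        assert a == pytest.approx(b, rel=1e-12)

    def test_weight_rescaling_rescales_objective(self, toy, toy_datasets):
        model, _ = toy
        scaled = [CalibDataset(
            id=d.id, scenario=d.scenario, observable=d.observable,
            points=d.points, normalization=d.normalization,
            weight=3.0 * d.effective_weight, level=d.level, source=d.source)
            for d in toy_datasets]
        a = objective(model, model.parameters, toy_datasets)
        b = objective(model, model.parameters, scaled)
        assert b == pytest.approx(3.0 * a, rel=1e-9)

    def test_true_parameters_beat_perturbed_ones(self, toy):
        """Monte-Carlo check: objective at truth < objective at 2x-perturbed
        parameters in at least 95% of seeded replicates."""
        model, _ = toy
        scens = [(step_scenario(), "pS", np.array([0.5, 1, 2, 4, 8, 16.0])),
                 (step_scenario("i"), "I", np.array([1, 4, 12, 24.0]))]
        wins = 0
        n_rep = 40
        for seed in range(n_rep):
            datasets = make_synthetic_datasets(model, scens, noise_cv=0.05,
                                               seed=seed)
            at_truth = objective(model, model.parameters, datasets,
                                 baseline=model.initial_state())
            perturbed = model.parameters.copy()
            perturbed["k_phos"] *= 2.0
            perturbed["k_fb"] *= 2.0
            at_wrong = objective(model, perturbed, datasets,
                                 baseline=model.initial_state())
            wins += at_truth < at_wrong
        assert wins >= 0.95 * n_rep


class TestInitialConditionCheck:
    def test_margins_and_band_edges(self, toy):
        model, _ = toy
        state = model.initial_state()
        totals = {}
        idx = model.species_index
        for g, members in model.groups.items():
            totals[g] = sum(state[idx[s]] for s in members)
        prior = CopyNumberPrior({
            "stat": totals["stat"],          # exactly at prior -> margin 1
            "receptor": totals["receptor"] / 0.4,  # at 0.4x -> fail
            "inhibitor": max(totals["inhibitor"], 1e-12) / 1.9,  # 1.9x -> pass
        })
        report = check_initial_conditions(model, prior=prior, state=state)
        assert report["stat"]["pass"] and \
            report["stat"]["margin"] == pytest.approx(1.0)
        assert not report["receptor"]["pass"]
        assert report["receptor"]["margin"] == pytest.approx(0.4)

    def test_closed_form_steady_state_band(self):
        s, d = 100.0, 0.1  # steady state 1000
        model, _ = make_toy(ToySpec("production_degradation",
                                    rates={"s": s, "d": d}))
        for prior_value, should_pass in ((1000.0, True), (400.0, False),
                                         (2200.0, False), (600.0, True)):
            prior = CopyNumberPrior({"X": prior_value})
            report = check_initial_conditions(model, prior=prior,
                                              residual_tol=1e-10)
            assert report["X"]["pass"] is should_pass, prior_value


class TestPatternSearch:
    def test_minimizes_smooth_bowl(self):
        target = np.array([2.0, 0.5])

        def f(x):
            return float(np.sum((np.log(x) - np.log(target)) ** 2))

        x, fval, trace, n_eval = pattern_search(
            f, np.array([0.3, 3.0]), [(0.01, 10.0), (0.01, 10.0)])
        np.testing.assert_allclose(x, target, rtol=1e-3)
        assert fval < 1e-6

    def test_trace_non_increasing(self):
        def f(x):
            return float((x[0] - 1.3) ** 2 + 0.5 * abs(x[1] - 0.7))

        _, _, trace, _ = pattern_search(f, np.array([5.0, 5.0]),
                                        [(0.01, 10.0)] * 2)
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_respects_bounds(self):
        def f(x):
            return -x[0]  # pushes to the upper bound

        x, *_ = pattern_search(f, np.array([1.0]), [(0.5, 4.0)], max_iter=60)
        assert x[0] <= 4.0 + 1e-12
        assert x[0] == pytest.approx(4.0, rel=1e-6)


class TestFit:
    def test_zero_free_parameters_is_identity(self, toy, toy_datasets):
        model, _ = toy
        result = fit(model, toy_datasets, [])
        assert dict(result.parameters) == dict(model.parameters)
        assert result.objective_value == pytest.approx(
            objective(model, model.parameters, toy_datasets), rel=1e-9)

    def test_two_parameter_recovery_from_displaced_start(self, toy):
        """Fit from a 3x displaced start recovers the truth within 10%."""
        model, _ = toy
        truth = {k: model.parameters[k] for k in ("k_phos", "k_fb")}
        scens = [(step_scenario(), "pS", np.array([0.5, 1, 2, 4, 8, 16.0])),
                 (step_scenario("lo", 2e3), "pS",
                  np.array([0.5, 1, 2, 4, 8, 16.0])),
                 (step_scenario("i"), "I", np.array([1, 2, 4, 8, 16.0]))]
        datasets = make_synthetic_datasets(model, scens, noise_cv=0.05, seed=1)
        start = model.copy()
        start.parameters["k_phos"] = truth["k_phos"] * 3.0
        start.parameters["k_fb"] = truth["k_fb"] / 3.0
        bounds = {k: (v / 10, v * 10) for k, v in truth.items()}
        result = fit(start, datasets, ["k_phos", "k_fb"], bounds=bounds,
                     seed=0, n_starts=1, max_iter=60)
        for k, v in truth.items():
            assert result.parameters[k] == pytest.approx(v, rel=0.10)

    def test_unknown_free_parameter_rejected(self, toy, toy_datasets):
        model, _ = toy
        with pytest.raises(CalibrationError, match="unknown"):
            fit(model, toy_datasets, ["nosuch"])


class TestBootstrap:
    def test_returns_requested_number_of_estimates(self, toy, toy_datasets):
        model, _ = toy
        estimates = bootstrap_fit(model, toy_datasets, ["k_phos"], n_boot=3,
                                  seed=1, n_starts=1, max_iter=8)
        assert len(estimates) == 3

    def test_deterministic_given_seed(self, toy, toy_datasets):
        model, _ = toy
        a = bootstrap_fit(model, toy_datasets, ["k_phos"], n_boot=2, seed=9,
                          n_starts=1, max_iter=5)
        b = bootstrap_fit(model, toy_datasets, ["k_phos"], n_boot=2, seed=9,
                          n_starts=1, max_iter=5)
        assert [dict(e) for e in a] == [dict(e) for e in b]

    def test_rejects_too_few_replicates(self, toy, toy_datasets):
        model, _ = toy
        with pytest.raises(CalibrationError, match="n_boot"):
            bootstrap_fit(model, toy_datasets, ["k_phos"], n_boot=1)
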