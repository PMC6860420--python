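"""Latin-hypercube sampling and partial rank correlation coefficients."""

import numpy as np
import pytest
from scipy import stats

from macpol import SamplingPlan, ToySpec, lhs_sample, make_toy, prcc
from macpol.scenarios import Scenario
from macpol.sensitivity import SensitivityError, score_sensitivity
from macpol.simulate import StimulusEvent


def plan_for(labels_ranges, n, seed=0):
    return SamplingPlan(tuple(labels_ranges), dict(labels_ranges), n, seed)


class TestLHS:
    def test_one_draw_per_logarithmic_stratum(self):
        plan = plan_for({"p": (1.0, 16.0)}, 4, seed=3)
        x = lhs_sample(plan)[:, 0]
        strata = [(1, 2), (2, 4), (4, 8), (8, 16)]
        counts = [np.sum((x >= lo) & (x < hi)) for lo, hi in strata]
        assert counts == [1, 1, 1, 1]

    def test_seed_reproducibility(self):
        plan = plan_for({"a": (0.1, 10.0), "b": (1.0, 100.0)}, 50, seed=11)
        np.testing.assert_array_equal(lhs_sample(plan), lhs_sample(plan))

    def test_marginals_are_loguniform(self):
        """KS distance of 5000 draws against the log-uniform CDF < 0.05."""
        lo, hi = 0.5, 50.0
        plan = plan_for({"p": (lo, hi)}, 5000, seed=7)
        x = lhs_sample(plan)[:, 0]
        u = (np.log(x) - np.log(lo)) / (np.log(hi) - np.log(lo))
        d = stats.kstest(u, "uniform").statistic
        assert d < 0.05

    def test_degenerate_range_rejected(self):
        with pytest.raises(SensitivityError, match="range"):
            plan_for({"p": (2.0, 2.0)}, 10)

    def test_minimum_sample_size_enforced(self):
        with pytest.raises(SensitivityError, match="n_samples"):
            plan_for({"a": (1, 2), "b": (1, 2), "c": (1, 2)}, 4)


def brute_force_prcc(X, y, j):
    """Independent oracle: explicit rank residualization via lstsq."""
    Xr = np.column_stack([stats.rankdata(X[:, k]) for k in range(X.shape[1])])
    yr = stats.rankdata(y)
    others = np.delete(Xr, j, axis=1)
    A = np.column_stack([np.ones(len(yr)), others])
    rx = Xr[:, j] - A @ np.linalg.lstsq(A, Xr[:, j], rcond=None)[0]
    ry = yr - A @ np.linalg.lstsq(A, yr, rcond=None)[0]
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


class TestPRCC:
    def test_null_parameter_has_negligible_coefficient(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, size=(1000, 3))
        y = rng.normal(size=1000)  # independent of every column
        res = prcc(X, y)
        assert np.all(np.abs(res.table["prcc"]) < 0.05)
        assert np.all(res.table["p_value"] > 0.05)

    def test_monotone_function_signs(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, size=(1000, 2))
        y = X[:, 0] - X[:, 1] + rng.normal(scale=0.01, size=1000)
        res = prcc(X, y, labels=("up", "down"))
        assert res["up"] > 0.95
        assert res["down"] < -0.95

    @pytest.mark.parametrize("seed", range(5))
    def test_three_parameter_brute_force_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 10, size=(200, 3))
        y = 2 * X[:, 0] - X[:, 1] ** 2 + rng.normal(size=200)
        res = prcc(X, y)
        for j in range(3):
            assert res.table["prcc"].iloc[j] == pytest.approx(
                brute_force_prcc(X, y, j), abs=1e-10)

    def test_invariance_to_monotone_transform_of_output(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, size=(300, 3))
        y = X[:, 0] + 0.5 * X[:, 2] + rng.normal(scale=0.1, size=300)
        a = prcc(X, y).table["prcc"].to_numpy()
        b = prcc(X, np.exp(y)).table["prcc"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_invariance_to_joint_row_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(100, 2))
        y = X[:, 0] + rng.normal(scale=0.1, size=100)
        perm = rng.permutation(100)
        a = prcc(X, y).table["prcc"].to_numpy()
        b = prcc(X[perm], y[perm]).table["prcc"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_coefficients_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            X = rng.uniform(0, 1, size=(50, 4))
            y = rng.normal(size=50)
            coeffs = prcc(X, y).table["prcc"].dropna()
            assert np.all(np.abs(coeffs) <= 1.0)

    def test_constant_column_reported_undefined(self):
        X = np.column_stack([np.full(50, 3.0),
                             np.random.default_rng(5).uniform(size=50)])
        y = X[:, 1] * 2
        res = prcc(X, y)
        assert np.isnan(res.table["prcc"].iloc[0])

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(SensitivityError, match="align"):
            prcc(np.ones((10, 2)), np.ones(5))


@pytest.fixture(scope="module")
def toy_setup():
    """Cascade whose terminal species is the M1 score numerator, padded with
    dummy markers and a disconnected Z subnetwork."""
    from macpol import (ModelDefinition, ParameterSet, RateLaw,
                        ReactionDef, SpeciesDef)

    model, _ = make_toy(ToySpec("linear_cascade", size=3))
    species = list(model.species)
    reactions = list(model.reactions)
    params = dict(model.parameters)
    for i in range(8):
        sid = f"D{i}"
        species.append(SpeciesDef(sid, group_id=sid, initial_copies=10.0))
        params[f"sd{i}"] = 1.0
        params[f"dd{i}"] = 0.1
        reactions.append(ReactionDef(
            f"syn{sid}", (), ((sid, 1),),
            RateLaw("mass_action_irreversible", (f"sd{i}",))))
        reactions.append(ReactionDef(
            f"deg{sid}", ((sid, 1),), (),
            RateLaw("mass_action_irreversible", (f"dd{i}",))))
    species.append(SpeciesDef("Z", group_id="Z", initial_copies=5.0))
    params["sz"] = 1.0
    params["dz"] = 0.2
    reactions.append(ReactionDef(
        "synZ", (), (("Z", 1),),
        RateLaw("mass_action_irreversible", ("sz",))))
    reactions.append(ReactionDef(
        "degZ", (("Z", 1),), (),
        RateLaw("mass_action_irreversible", ("dz",))))
    return ModelDefinition(
        species, reactions, ParameterSet(params),
        marker_panels={
            "M1": {"A2": "A2", **{f"D{i}": f"D{i}" for i in range(5)}},
            "M2": {f"D{i}": f"D{i}" for i in range(5, 8)}})


class TestScoreSensitivity:
    def test_directly_producing_rate_has_largest_positive_prcc(self, toy_setup):
        scenario = Scenario(name="step", stimuli=[
            StimulusEvent("A0", 100.0, time_added=0.0, in_copies=True)],
            horizon=30.0)
        labels = ("k1", "k_deg", "sz")  # k1 makes the scored species A2
        plan = SamplingPlan.around_nominal(toy_setup.parameters, labels,
                                           fold=5.0, n_samples=60, seed=21)
        res = score_sensitivity(toy_setup, scenario, plan, t_eval=24.0)
        assert res["k1"] > 0.9  # directly produces the scored species
        assert res["k_deg"] < 0  # clears it
        table = res.table.set_index("label")
        assert table.loc["k1", "prcc"] == table["prcc"].max()

    def test_disconnected_parameter_not_significant(self, toy_setup):
        """Sampling a rate of an unreachable subnetwork gives p >= 0.05."""
        scenario = Scenario(name="step", stimuli=[
            StimulusEvent("A0", 100.0, time_added=0.0, in_copies=True)],
            horizon=30.0)
        plan = SamplingPlan.around_nominal(
            toy_setup.parameters, ("k1", "sz", "dz"), fold=5.0,
            n_samples=60, seed=22)
        res = score_sensitivity(toy_setup, scenario, plan, t_eval=24.0)
        table = res.table.set_index("label")
        assert table.loc["k1", "p_value"] < 0.05
        assert table.loc["sz", "p_value"] >= 0.05
        assert table.loc["dz", "p_value"] >= 0.05
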