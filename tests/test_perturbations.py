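"""Perturbation semantics, normalization modes and the M1/M2 score."""

import itertools

import numpy as np
import pytest

from macpol import (NormalizationMode, PerturbationSpec, StimulusEvent,
                    apply_perturbations, m1m2_score, run_scenario)
from macpol.fullmodel import MW_IFNG
from macpol.scenarios import (NormalizationError, PerturbationError,
                              ScoreError, normalize_series,
                              production_reactions)
from macpol.simulate import SimulationResult


class TestApplyPerturbations:
    def test_overexpress_scales_initials_fifty_fold_only(self, full_model,
                                                         full_baseline):
        edited, state = apply_perturbations(
            full_model, full_baseline, [PerturbationSpec("overexpress", "SOCS1")])
        idx = full_model.species_index
        for sp in full_model.groups["SOCS1"]:
            assert state[idx[sp]] == pytest.approx(50 * full_baseline[idx[sp]])
        # production rates untouched (1x), every other parameter untouched
        assert dict(edited.parameters) == dict(full_model.parameters)
        untouched = [i for s, i in idx.items()
                     if s not in full_model.groups["SOCS1"]]
        np.testing.assert_array_equal(state[untouched],
                                      full_baseline[untouched])

    def test_silence_zeroes_initials_and_production(self, full_model,
                                                    full_baseline):
        edited, state = apply_perturbations(
            full_model, full_baseline, [PerturbationSpec("silence", "SOCS3")])
        idx = full_model.species_index
        assert state[idx["SOCS3"]] == 0.0
        prod = production_reactions(full_model, "SOCS3")
        labels = {r.rate_law.param_labels[0]
                  for r in full_model.reactions if r.id in prod}
        assert labels  # SOCS3 has production channels to zero
        for label in labels:
            assert edited.parameters[label] == 0.0

    def test_silencing_dominance_trajectory_identically_zero(
            self, full_model, full_baseline):
        """A silenced species stays at zero under any stimulation."""
        edited, state = apply_perturbations(
            full_model, full_baseline, [PerturbationSpec("silence", "SOCS3")])
        ev = [StimulusEvent("IFNg_ext", 10.0, MW_IFNG, 0.0)]
        res = run_scenario(edited, events=ev, horizon=24.0, state0=state)
        np.testing.assert_array_equal(res["SOCS3"], 0.0)

    def test_production_scale_touches_exactly_the_production_labels(
            self, full_model, full_baseline):
        edited, _ = apply_perturbations(
            full_model, full_baseline,
            [PerturbationSpec("production_scale", "IFNg", 0.1)])
        prod = production_reactions(full_model, "IFNg")
        labels = {r.rate_law.param_labels[0]
                  for r in full_model.reactions if r.id in prod}
        assert "k127" in labels  # the translation/production step
        diff = {k for k in full_model.parameters
                if edited.parameters[k] != full_model.parameters[k]}
        assert diff == labels
        for label in labels:
            assert edited.parameters[label] == pytest.approx(
                0.1 * full_model.parameters[label])

    def test_rate_scale_touches_exactly_one_label(self, full_model,
                                                  full_baseline):
        edited, _ = apply_perturbations(
            full_model, full_baseline,
            [PerturbationSpec("rate_scale", "kf63", 0.1)])
        diff = {k for k in full_model.parameters
                if edited.parameters[k] != full_model.parameters[k]}
        assert diff == {"kf63"}
        assert edited.parameters["kf63"] == pytest.approx(
            0.1 * full_model.parameters["kf63"])

    def test_disjoint_edits_commute(self, full_model, full_baseline):
        specs = [PerturbationSpec("production_scale", "IFNg", 0.1),
                 PerturbationSpec("production_scale", "HIF1a", 0.1),
                 PerturbationSpec("overexpress", "SOCS1")]
        results = []
        for perm in itertools.permutations(specs):
            edited, state = apply_perturbations(full_model, full_baseline,
                                                list(perm))
            results.append((dict(edited.parameters), state.copy()))
        ref_params, ref_state = results[0]
        for params, state in results[1:]:
            assert params == ref_params
            np.testing.assert_array_equal(state, ref_state)

    def test_conflicting_edits_raise(self, full_model, full_baseline):
        with pytest.raises(PerturbationError, match="conflicting"):
            apply_perturbations(full_model, full_baseline, [
                PerturbationSpec("rate_scale", "kf63", 0.1),
                PerturbationSpec("rate_scale", "kf63", 0.5)])

    def test_unresolvable_target_raises(self, full_model, full_baseline):
        with pytest.raises(PerturbationError, match="unknown"):
            apply_perturbations(full_model, full_baseline,
                                [PerturbationSpec("silence", "NOSUCH")])

    def test_silence_admits_no_factor(self):
        with pytest.raises(PerturbationError, match="no factor"):
            PerturbationSpec("silence", "SOCS1", 0.5)


def _result(time, values, species="X"):
    arr = np.asarray(values, float)[None, :]
    return SimulationResult(time=np.asarray(time, float), trajectories=arr,
                            species_ids=[species])


class TestNormalization:
    def test_constant_trajectory_to_t0_is_one(self):
        t = np.linspace(0, 10, 11)
        out = normalize_series(np.full(11, 7.0), t, NormalizationMode("to_t0"))
        np.testing.assert_allclose(out, 1.0)

    def test_log2_fold_eightfold_is_three(self):
        t = np.array([0.0, 1.0])
        out = normalize_series(np.array([2.0, 16.0]), t,
                               NormalizationMode("log2_fold"))
        np.testing.assert_allclose(out, [0.0, 3.0])

    def test_to_max_peaks_at_exactly_one(self):
        t = np.linspace(0, 5, 6)
        v = np.array([1.0, 4.0, 9.0, 5.0, 2.0, 1.0])
        out = normalize_series(v, t, NormalizationMode("to_max"))
        assert out.max() == 1.0

    def test_to_reference_time(self):
        t = np.array([0.0, 6.0, 18.0])
        v = np.array([1.0, 3.0, 4.0])
        out = normalize_series(v, t, NormalizationMode("to_reference_time",
                                                       reference=18.0))
        np.testing.assert_allclose(out, v / 4.0)

    def test_zero_denominator_names_the_species(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(NormalizationError, match="iNOS"):
            normalize_series(np.array([0.0, 5.0]), t,
                             NormalizationMode("to_t0"), species="iNOS")


class TestM1M2Score:
    M1 = {f"m{i}": f"m{i}" for i in range(6)}
    M2 = {f"n{i}": f"n{i}" for i in range(3)}

    def _res(self, m1_vals, m2_vals):
        ids = list(self.M1) + list(self.M2)
        vals = np.array(list(m1_vals) + list(m2_vals), float)
        return SimulationResult(time=np.array([0.0, 48.0]),
                                trajectories=np.tile(vals[:, None], (1, 2)),
                                species_ids=ids)

    def test_all_ones_scores_one(self):
        res = self._res([1] * 6, [1] * 3)
        assert m1m2_score(res, self.M1, self.M2) == pytest.approx(1.0)

    def test_homogeneity(self):
        base = m1m2_score(self._res([2, 1, 1, 1, 1, 1], [1, 1, 1]),
                          self.M1, self.M2)
        assert base == pytest.approx(2.0)
        doubled_m1 = m1m2_score(self._res([4, 1, 1, 1, 1, 1], [1, 1, 1]),
                                self.M1, self.M2)
        assert doubled_m1 == pytest.approx(2 * base)
        doubled_m2 = m1m2_score(self._res([2, 1, 1, 1, 1, 1], [2, 1, 1]),
                                self.M1, self.M2)
        assert doubled_m2 == pytest.approx(base / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_product_ratio(self, seed):
        rng = np.random.default_rng(seed)
        m1 = rng.uniform(0.1, 100, 6)
        m2 = rng.uniform(0.1, 100, 3)
        expected = np.prod(m1) / np.prod(m2)
        got = m1m2_score(self._res(m1, m2), self.M1, self.M2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_panel_sizes_enforced(self):
        res = self._res([1] * 6, [1] * 3)
        with pytest.raises(ScoreError):
            m1m2_score(res, dict(list(self.M1.items())[:5]), self.M2)

    def test_nonpositive_marker_rejected(self):
        res = self._res([0.0, 1, 1, 1, 1, 1], [1, 1, 1])
        with pytest.raises(ScoreError, match="non-positive"):
            m1m2_score(res, self.M1, self.M2)
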