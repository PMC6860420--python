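"""Structure, baseline physiology and qualitative dynamics of the full
polarization network, plus the calibration registry scale."""

import numpy as np
import pytest

from macpol import (CopyNumberPrior, OxygenCondition, PerturbationSpec,
                    StimulusEvent, apply_perturbations,
                    check_initial_conditions, default_copy_number_priors,
                    m1m2_score, run_scenario, structural_report)
from macpol.fullmodel import (BOOTSTRAP_SUBSET_11, M1_PANEL, M2_PANEL,
                              MW_IFNG, MW_IL4, SENSITIVITY_LABELS_NEGATIVE,
                              SENSITIVITY_LABELS_POSITIVE)
from macpol.model import assemble_rhs


class TestStructure:
    def test_structural_counts(self, full_model):
        rep = structural_report(full_model)
        assert rep["n_nodes"] == 80
        assert rep["n_reactions"] == 130
        assert rep["n_groups"] == 34

    def test_sensitivity_figure_labels_all_resolve(self, full_model):
        for label in (SENSITIVITY_LABELS_POSITIVE
                      + SENSITIVITY_LABELS_NEGATIVE):
            assert label in full_model.parameters, label

    def test_bootstrap_subset_has_eleven_resolvable_labels(self, full_model):
        assert len(BOOTSTRAP_SUBSET_11) == 11
        assert all(l in full_model.parameters for l in BOOTSTRAP_SUBSET_11)

    def test_no_orphan_parameters_or_dead_species(self, full_model):
        rep = structural_report(full_model)
        assert rep["parameter_labels_unused"] == []
        assert rep["species_without_production"] == []

    def test_marker_panels_have_paper_sizes(self, full_model):
        assert len(full_model.marker_panels["M1"]) == 6
        assert len(full_model.marker_panels["M2"]) == 3


class TestBaseline:
    def test_equilibrium_residual_is_small(self, full_model, full_baseline):
        rhs = assemble_rhs(full_model)
        dy = rhs(0.0, full_baseline)
        assert np.max(np.abs(dy)) / np.max(full_baseline) < 1e-8

    def test_baseline_strictly_positive(self, full_baseline):
        assert np.all(full_baseline > 0)

    def test_group_totals_within_copy_number_band(self, full_model,
                                                  full_baseline):
        """Every unique-species group sits within 0.5x-2x of its prior."""
        prior = CopyNumberPrior(default_copy_number_priors())
        report = check_initial_conditions(full_model, prior=prior,
                                          state=full_baseline)
        assert len(report) == 34
        failures = {g: r for g, r in report.items() if not r["pass"]}
        assert not failures, failures

    def test_conserved_pools_constant_under_stimulation(self, full_model,
                                                        full_at_baseline):
        """STAT1, STAT6 and JAK totals are conserved cycles: their totals
        stay constant along stimulated trajectories to solver tolerance."""
        ev = [StimulusEvent("IFNg_ext", 10.0, MW_IFNG, 0.0),
              StimulusEvent("IL4", 10.0, MW_IL4, 0.0)]
        res = run_scenario(full_at_baseline, events=ev, horizon=24.0,
                           rtol=1e-8, atol=1e-6)
        stat1 = (res["STAT1"] + res["pSTAT1"] + 2 * res["pSTAT1_dim"]
                 + 2 * res["pSTAT1_n"])
        np.testing.assert_allclose(stat1, stat1[0], rtol=1e-6)
        stat6 = (res["STAT6"] + res["pSTAT6"] + 2 * res["pSTAT6_dim"]
                 + 2 * res["pSTAT6_n"])
        np.testing.assert_allclose(stat6, stat6[0], rtol=1e-6)
        jak = (res["JAK"] + res["IFNg_RCp"] + res["S1_IgRC"] + res["S3_IgRC"]
               + res["IL4_RCp"] + res["IL4_RCi"] + res["S1_I4RC"]
               + res["S1_I4RCi"] + res["S3_I4RC"])
        np.testing.assert_allclose(jak, jak[0], rtol=1e-6)


@pytest.fixture(scope="module")
def ifng_run(full_at_baseline):
    ev = [StimulusEvent("IFNg_ext", 10.0, MW_IFNG, 0.0)]
    return run_scenario(full_at_baseline, events=ev, horizon=48.0)


def total_pstat1(res):
    return res["pSTAT1"] + 2 * res["pSTAT1_dim"] + 2 * res["pSTAT1_n"]


class TestQualitativeDynamics:
    def test_ifng_drives_pstat1_peak_then_decay(self, ifng_run):
        ps = total_pstat1(ifng_run)
        i_peak = np.argmax(ps)
        t_peak = ifng_run.time[i_peak]
        assert 0.25 < t_peak < 12.0
        assert ps[-1] < 0.5 * ps.max()

    def test_socs1_overexpression_lowers_peak_pstat1(self, full_model,
                                                     full_baseline, ifng_run):
        edited, state = apply_perturbations(
            full_model, full_baseline,
            [PerturbationSpec("overexpress", "SOCS1")])
        ev = [StimulusEvent("IFNg_ext", 10.0, MW_IFNG, 0.0)]
        res = run_scenario(edited, events=ev, horizon=48.0, state0=state)
        assert total_pstat1(res).max() < total_pstat1(ifng_run).max()

    def test_delayed_il4_lowers_irf1_under_ifng(self, full_at_baseline,
                                                ifng_run):
        ev = [StimulusEvent("IFNg_ext", 10.0, MW_IFNG, 0.0),
              StimulusEvent("IL4", 20.0, MW_IL4, 4.0)]
        seq = run_scenario(full_at_baseline, events=ev, horizon=48.0)
        assert seq.value("IRF1", 24.0) < ifng_run.value("IRF1", 24.0)

    def test_delayed_ifng_lowers_active_akt_under_il4(self, full_at_baseline):
        il4_only = run_scenario(full_at_baseline,
                                events=[StimulusEvent("IL4", 20.0, MW_IL4,
                                                      0.0)],
                                horizon=48.0)
        seq = run_scenario(full_at_baseline,
                           events=[StimulusEvent("IL4", 20.0, MW_IL4, 0.0),
                                   StimulusEvent("IFNg_ext", 10.0, MW_IFNG,
                                                 1.0)],
                           horizon=48.0)
        assert seq.value("pAKT", 24.0) < il4_only.value("pAKT", 24.0)

    def test_hypoxia_raises_both_inos_and_arg1(self, full_at_baseline,
                                               full_baseline, full_model):
        res = run_scenario(full_at_baseline, oxygen=OxygenCondition(2.0, 0.0),
                           horizon=48.0)
        idx = full_model.species_index
        assert res.value("iNOS", 24.0) > 1.5 * full_baseline[idx["iNOS"]]
        assert res.value("Arg1", 24.0) > 1.5 * full_baseline[idx["Arg1"]]

    def test_hypoxia_stabilizes_hifs_and_induces_vegf(self, full_at_baseline,
                                                      full_baseline,
                                                      full_model):
        res = run_scenario(full_at_baseline, oxygen=OxygenCondition(2.0, 0.0),
                           horizon=24.0)
        idx = full_model.species_index
        assert res.value("HIF1a", 12.0) > 2 * full_baseline[idx["HIF1a"]]
        assert res.value("HIF2a", 12.0) > 2 * full_baseline[idx["HIF2a"]]
        assert res.value("VEGF_sec", 24.0) > full_baseline[idx["VEGF_sec"]]

    def test_m1m2_score_shifts_with_polarization(self, full_at_baseline,
                                                 full_model):
        m1, m2 = full_model.marker_panels["M1"], full_model.marker_panels["M2"]
        ifng = run_scenario(full_at_baseline,
                            events=[StimulusEvent("IFNg_ext", 10.0, MW_IFNG,
                                                  0.0)], horizon=30.0)
        il4 = run_scenario(full_at_baseline,
                           events=[StimulusEvent("IL4", 20.0, MW_IL4, 0.0)],
                           horizon=30.0)
        utr = run_scenario(full_at_baseline, horizon=30.0)
        s_ifng = m1m2_score(ifng, m1, m2)
        s_il4 = m1m2_score(il4, m1, m2)
        s_utr = m1m2_score(utr, m1, m2)
        assert s_ifng > s_utr > s_il4


@pytest.fixture(scope="module")
def registry(full_model, full_baseline):
    from macpol import build_calibration_registry

    return build_calibration_registry(full_model, baseline=full_baseline)


class TestRegistryScale:
    def test_corpus_scale(self, registry):
        from macpol import registry_summary

        summary = registry_summary(registry)
        assert summary["n_datasets"] >= 70
        assert summary["n_points"] >= 300

    def test_registry_tsv_round_trip(self, registry, tmp_path):
        from macpol.registry import load_registry_tsv, write_registry_tsv

        path = write_registry_tsv(registry, tmp_path / "registry.tsv")
        back = load_registry_tsv(path)
        assert len(back) == len(registry)
        for a, b in zip(registry, back):
            assert a.id == b.id and a.observable == b.observable
            np.testing.assert_allclose([v for _, v in a.points],
                                       [v for _, v in b.points], rtol=1e-9)
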