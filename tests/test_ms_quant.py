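"""The quantification chain: elementary steps, peak assignment, full pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ippdyn import ms_quant, synthetic
from ippdyn.ms_quant import (
    SPECIES_1IP7,
    SPECIES_5IP7,
    SPECIES_IP6,
    SPECIES_IP8,
    AmbiguousAssignmentError,
    QuantConfig,
    RecoveryTable,
    TransitionTable,
    VolumeModel,
    assign_peaks,
    correct_recovery,
    cytosolic_concentration,
    fold_change,
    per_cell_amount,
    percent_change,
    percent_remaining,
    quantify_isotope_dilution,
    recovery_from_spike,
    scale_to_extract,
    summarize_replicates,
)

finite_pos = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestTransitionTable:
    def test_default_transition_set(self):
        """The monitored m/z pairs, as printed on the instrument method."""
        tt = TransitionTable()
        expected = {
            ("IP8", "13C"): (411.9, 362.9),
            ("IP8", "12C"): (408.9, 359.9),
            ("IP7", "13C"): (371.9, 322.9),
            ("IP7", "12C"): (368.9, 319.9),
            ("IP6", "13C"): (331.9, 486.9),
            ("IP6", "12C"): (328.9, 480.9),
        }
        observed = {
            (tr.compound, tr.label): (tr.precursor_mz, tr.product_mz)
            for tr in tt.transitions
        }
        assert observed == expected

    def test_heavy_precursor_offset_is_three_mz(self):
        """Six 13C on a doubly charged ion shift the precursor by +3.0 m/z."""
        tt = TransitionTable()
        by = {(tr.compound, tr.label): tr.precursor_mz for tr in tt.transitions}
        for compound in ("IP8", "IP7", "IP6"):
            assert by[(compound, "13C")] - by[(compound, "12C")] == pytest.approx(3.0)

    def test_classify_and_species_mapping(self):
        tt = TransitionTable()
        assert tt.classify(368.9, 319.9, "12C") == "IP7"
        assert tt.classify(368.9, 319.9, "13C") is None
        assert tt.classify(500.0, 400.0, "12C") is None
        assert tt.class_of(SPECIES_5IP7) == "IP7"
        assert tt.class_of(SPECIES_IP8) == "IP8"
        with pytest.raises(KeyError):
            tt.class_of("IP9")


class TestVolumeModel:
    def test_accessible_volume_excludes_organelles_only(self):
        vm = VolumeModel()
        assert vm.v_cell_fl == 42.0
        assert vm.v_accessible_fl == pytest.approx(42.0 * 0.82)  # 34.44 fL

    def test_optional_nuclear_exclusion(self):
        vm = VolumeModel(exclude_nucleus=True)
        assert vm.v_accessible_fl == pytest.approx(42.0 * 0.74)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            VolumeModel(f_nucleus=0.5, f_organelles=0.6)
        with pytest.raises(ValueError):
            VolumeModel(v_cell_fl=0)


def _peak(sample, pre, prod, mt, area, label):
    return {
        "sample_id": sample, "precursor_mz": pre, "product_mz": prod,
        "migration_time_min": mt, "peak_area": area, "label": label,
    }


def _standard_rows(sample="s1"):
    return [
        _peak(sample, 411.9, 362.9, 18.0, 1000.0, "13C"),
        _peak(sample, 371.9, 322.9, 19.5, 1000.0, "13C"),
        _peak(sample, 371.9, 322.9, 20.1, 1000.0, "13C"),
        _peak(sample, 331.9, 486.9, 21.5, 1000.0, "13C"),
    ]


class TestAssignPeaks:
    def test_exact_match_resolves_ip7_isomers(self):
        peaks = pd.DataFrame(_standard_rows() + [
            _peak("s1", 368.9, 319.9, 19.5, 500.0, "12C"),
            _peak("s1", 368.9, 319.9, 20.1, 300.0, "12C"),
        ])
        out = assign_peaks(peaks)
        by_mt = out[out["label"] == "12C"].set_index("migration_time_min")["species"]
        assert by_mt[19.5] == SPECIES_5IP7
        assert by_mt[20.1] == SPECIES_1IP7

    def test_global_shift_beyond_tolerance_is_aligned_out(self):
        """A +0.30 min electrophoretic shift of all analytes changes nothing."""
        base = pd.DataFrame(_standard_rows() + [
            _peak("s1", 408.9, 359.9, 18.02, 80.0, "12C"),
            _peak("s1", 368.9, 319.9, 19.48, 500.0, "12C"),
            _peak("s1", 368.9, 319.9, 20.13, 300.0, "12C"),
        ])
        shifted = base.copy()
        is12 = shifted["label"] == "12C"
        shifted.loc[is12, "migration_time_min"] += 0.30

        # independent oracle: brute-force all-pairs matching on the unshifted table
        expected = assign_peaks(base)
        observed = assign_peaks(shifted)
        assert list(observed["species"]) == list(expected["species"])
        assert observed["assigned"].all()

    def test_two_analytes_claiming_one_reference_is_ambiguous(self):
        peaks = pd.DataFrame([
            _peak("s1", 371.9, 322.9, 19.5, 1000.0, "13C"),
            _peak("s1", 368.9, 319.9, 19.48, 500.0, "12C"),
            _peak("s1", 368.9, 319.9, 19.52, 400.0, "12C"),
        ])
        with pytest.raises(AmbiguousAssignmentError, match="claim"):
            assign_peaks(peaks, mt_tolerance=0.2)

    def test_no_reference_within_tolerance_flags_unassigned(self):
        peaks = pd.DataFrame(_standard_rows() + [
            _peak("s1", 368.9, 319.9, 25.0, 500.0, "12C"),
        ])
        out = assign_peaks(peaks)
        stray = out[(out["label"] == "12C")].iloc[0]
        assert not stray["assigned"] and stray["species"] is None


class TestElementarySteps:
    def test_isotope_dilution_examples(self):
        assert quantify_isotope_dilution(2000, 4000, 7.5) == pytest.approx(3.75)
        assert quantify_isotope_dilution(0, 4000, 7.5) == 0.0
        # wt replete 1-IP7: 17.22 zmol/cell through loss 0.89 and 15/20 aliquot
        area_ratio = 17.22e-6 * 1e7 * 0.89 * (15 / 20) / 7500
        assert area_ratio == pytest.approx(0.015326, rel=1e-4)
        assert quantify_isotope_dilution(area_ratio * 4000, 4000, 7500) == pytest.approx(
            114.94, rel=1e-3
        )
        with pytest.raises(ValueError, match="standard"):
            quantify_isotope_dilution(100, 0, 7.5)

    def test_scale_to_extract(self):
        assert scale_to_extract(114.94, 15, 20) == pytest.approx(153.26, rel=1e-3)
        assert scale_to_extract(42.0, 20, 20) == 42.0
        assert scale_to_extract(0.0, 15, 20) == 0.0
        with pytest.raises(ValueError):
            scale_to_extract(1.0, 0, 20)
        with pytest.raises(ValueError):
            scale_to_extract(1.0, 25, 20)

    def test_correct_recovery(self):
        assert correct_recovery(153.26, 0.89) == pytest.approx(172.2, rel=1e-3)
        assert correct_recovery(5.0, 1.0) == 5.0
        for bad in (0.0, -0.1, 1.2):
            with pytest.raises(ValueError):
                correct_recovery(1.0, bad)

    def test_recovery_from_spike(self):
        assert recovery_from_spike(200, 178) == pytest.approx(0.89)
        assert recovery_from_spike(200, 200) == 1.0
        assert recovery_from_spike(200, 150) == pytest.approx(0.75)
        with pytest.raises(ValueError):
            recovery_from_spike(0, 10)

    def test_per_cell_amount(self):
        assert per_cell_amount(172.2, 1e7) == pytest.approx(17.22)
        assert per_cell_amount(1.0, 1e6) == pytest.approx(1.0)
        assert per_cell_amount(0.0, 1e7) == 0.0
        with pytest.raises(ValueError):
            per_cell_amount(1.0, 0)

    def test_cytosolic_concentration(self):
        vm = VolumeModel()
        assert cytosolic_concentration(17.22, vm) == pytest.approx(0.50)
        assert cytosolic_concentration(24.108, vm) == pytest.approx(0.70)
        assert cytosolic_concentration(0.0, vm) == 0.0

    def test_fold_change(self):
        assert fold_change(14.0, 0.70) == pytest.approx(20.0)
        assert fold_change(3.3, 3.3) == 1.0
        assert fold_change(5.0, 0.50) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    def test_percent_change_and_remaining(self):
        assert percent_change(0.30, 0.075) == pytest.approx(75.0)
        assert percent_change(1.7, 1.7) == 0.0
        assert percent_remaining(0.70, 0.021) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    def test_summarize_replicates(self):
        assert summarize_replicates([1, 1, 1]) == (1.0, 0.0, 3)
        mean, sd, n = summarize_replicates([0.4, 0.5, 0.6])
        assert (mean, n) == (pytest.approx(0.5), 3)
        assert sd == pytest.approx(0.1)
        assert summarize_replicates([2.5]) == (2.5, 0.0, 1)
        with pytest.raises(ValueError):
            summarize_replicates([])


@settings(derandomize=True, max_examples=50)
@given(a=finite_pos, std=finite_pos, moles=finite_pos, k=st.floats(0.1, 10))
def test_chain_is_linear_in_analyte_area(a, std, moles, k):
    one = quantify_isotope_dilution(a, std, moles)
    scaled = quantify_isotope_dilution(k * a, std, moles)
    assert scaled == pytest.approx(k * one, rel=1e-9)


@settings(derandomize=True, max_examples=50)
@given(c0=finite_pos, frac=st.floats(0.0, 1.0))
def test_decline_plus_remaining_is_total(c0, frac):
    ct = c0 * frac
    assert percent_change(c0, ct) + percent_remaining(c0, ct) == pytest.approx(100.0)


class TestPipeline:
    def test_wt_replete_reproduces_printed_concentrations(self):
        peaks, _ = synthetic.generate_ms_fixture(synthetic.wt_replete_scenario())
        _, summary = ms_quant.run_quant_pipeline(peaks)
        conc = summary.set_index("species")["mean_conc_uM"]
        assert conc[SPECIES_1IP7] == pytest.approx(0.5, rel=1e-9)
        assert conc[SPECIES_5IP7] == pytest.approx(0.7, rel=1e-9)
        assert conc[SPECIES_IP8] == pytest.approx(0.3, rel=1e-9)

    def test_pipeline_matches_closed_form_oracle(self):
        """Pipeline output equals the direct formula on every fixture row."""
        sc = synthetic.mutants_replete_scenario()
        peaks, _ = synthetic.generate_ms_fixture(sc)
        results, _ = ms_quant.run_quant_pipeline(peaks)
        cfg = QuantConfig()
        tt = TransitionTable()
        for _, row in results.iterrows():
            sp = row["species"]
            pre12, _ = tt.mz_pair(sp, "12C")
            pre13, _ = tt.mz_pair(sp, "13C")
            grp = peaks[peaks["sample_id"] == row["sample_id"]]
            mt = synthetic.DEFAULT_MIGRATION_TIMES[sp]
            near = (grp["migration_time_min"] - mt).abs() < 0.3
            a12 = grp.loc[(grp["precursor_mz"] == pre12) & near, "peak_area"].sum()
            a13 = grp.loc[(grp["precursor_mz"] == pre13) & near, "peak_area"].sum()
            oracle = (
                (a12 / a13) * cfg.spike.moles_fmol(sp) * (20 / 15)
                / cfg.recovery[sp] / 1e7 * 1e6 / cfg.volume_model.v_accessible_fl
            )
            assert row["conc_uM"] == pytest.approx(oracle, rel=1e-9, abs=1e-15)

    def test_doubling_truth_doubles_concentrations(self):
        sc = synthetic.wt_replete_scenario()
        doubled = synthetic.FixtureScenario(
            name="wt_doubled", strains=sc.strains, timepoints=sc.timepoints,
            truth_amounts={k: 2 * v for k, v in sc.truth_amounts.items()},
        )
        _, s1 = ms_quant.run_quant_pipeline(synthetic.generate_ms_fixture(sc)[0])
        _, s2 = ms_quant.run_quant_pipeline(synthetic.generate_ms_fixture(doubled)[0])
        merged = s1.merge(s2, on="species")
        np.testing.assert_allclose(
            merged["mean_conc_uM_y"], 2 * merged["mean_conc_uM_x"], rtol=1e-9
        )

    def test_disabling_recovery_scales_by_the_loss_factor(self):
        peaks, _ = synthetic.generate_ms_fixture(synthetic.wt_replete_scenario())
        cfg = QuantConfig(apply_recovery=False)
        _, summary = ms_quant.run_quant_pipeline(peaks, cfg)
        conc = summary.set_index("species")["mean_conc_uM"]
        assert conc[SPECIES_1IP7] == pytest.approx(0.5 * 0.89, rel=1e-9)
        assert conc[SPECIES_5IP7] == pytest.approx(0.7 * 0.90, rel=1e-9)
        assert conc[SPECIES_IP8] == pytest.approx(0.3 * 0.75, rel=1e-9)

    def test_time_course_concentrations_are_non_increasing(self):
        peaks, _ = synthetic.generate_ms_fixture(synthetic.wt_starvation_scenario())
        _, summary = ms_quant.run_quant_pipeline(peaks)
        for sp, grp in summary.groupby("species"):
            ordered = grp.sort_values("time_min")["mean_conc_uM"].to_numpy()
            assert np.all(np.diff(ordered) <= 1e-12)

    def test_estimator_recovers_truth_under_replicate_noise(self):
        """CV 0.15, n=4, averaged over seeds: mean within 10% of truth."""
        concs = []
        for seed in range(8):
            sc = synthetic.wt_replete_scenario(replicate_cv=0.15, n_replicates=4, seed=seed)
            peaks, _ = synthetic.generate_ms_fixture(sc)
            _, summary = ms_quant.run_quant_pipeline(peaks)
            concs.append(summary.set_index("species")["mean_conc_uM"])
        mean = pd.concat(concs, axis=1).mean(axis=1)
        for sp, truth in [(SPECIES_1IP7, 0.5), (SPECIES_5IP7, 0.7), (SPECIES_IP8, 0.3)]:
            assert mean[sp] == pytest.approx(truth, rel=0.10)

    def test_doubling_cell_volume_halves_concentrations(self):
        peaks, _ = synthetic.generate_ms_fixture(synthetic.wt_replete_scenario())
        cfg = QuantConfig(volume_model=VolumeModel(v_cell_fl=84.0))
        _, summary = ms_quant.run_quant_pipeline(peaks, cfg)
        conc = summary.set_index("species")["mean_conc_uM"]
        assert conc[SPECIES_5IP7] == pytest.approx(0.35, rel=1e-9)

    def test_ip6_excluded_from_reporting_by_default(self):
        peaks, _ = synthetic.generate_ms_fixture(synthetic.wt_replete_scenario())
        results, _ = ms_quant.run_quant_pipeline(peaks)
        assert SPECIES_IP6 not in set(results["species"])
        results_ip6, _ = ms_quant.run_quant_pipeline(peaks, QuantConfig(report_ip6=True))
        assert SPECIES_IP6 in set(results_ip6["species"])

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = QuantConfig(
            recovery=RecoveryTable({**RecoveryTable().fractions, SPECIES_IP8: 0.8}),
            n_cells=5e6,
            apply_recovery=False,
        )
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        loaded = QuantConfig.from_yaml(path)
        assert loaded.recovery[SPECIES_IP8] == 0.8
        assert loaded.n_cells == 5e6
        assert loaded.apply_recovery is False
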