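"""Screening overlay: schedules, test positivity, rounds, surveillance."""

from dataclasses import replace

import numpy as np
import pytest

from crcscreen.screening import (
    TEST_PRESETS,
    ComplicationRisks,
    OverlayCohort,
    Reach,
    StrategyConfig,
    SurveillanceRule,
    TestPerformance as TP,
    apply_screening_round,
    apply_surveillance,
    round_schedule,
    simulate_strategy,
    test_positivity as positivity,
    J_NORMAL,
    N_PD,
    OFF_CLIN,
    OFF_NEVER,
    OFF_POOL,
    OFF_SURV,
    _surv_cell,
)
from crcscreen.states import Compartment, HealthState, Location, idx_preclin
from crcscreen.natural_history import run_natural_history
from crcscreen.uncertainty import simulate_with_inputs


NO_COMPLICATIONS = ComplicationRisks(0, 0, 0, 0, 0, 0, 0)


class TestRoundSchedule:
    def test_biennial_55_74_has_ten_rounds(self, presets):
        ages = round_schedule(presets["FIT_55_74"])
        assert ages == [55, 57, 59, 61, 63, 65, 67, 69, 71, 73]

    def test_once_only_fsig(self, presets):
        assert round_schedule(presets["FSIG_60"]) == [60]

    def test_biennial_55_64_has_five_rounds(self, presets):
        assert len(round_schedule(presets["FIT_55_64"])) == 5

    def test_no_screening_has_empty_schedule(self, presets):
        assert round_schedule(presets["no_screening"]) == []


class TestPositivity:
    def test_fit_detects_preclinical_cancer_at_crc_sensitivity(self):
        state = HealthState(Compartment.CRC_PRECLIN_II, Location.PROXIMAL,
                            provenance=None)
        assert positivity(TEST_PRESETS["FIT"], state) == pytest.approx(0.71)

    def test_fsig_out_of_reach_lesion_uses_one_minus_specificity(self):
        state = HealthState(Compartment.ADENOMA_HIGH, Location.PROXIMAL)
        assert positivity(TEST_PRESETS["FSIG"], state) == pytest.approx(0.08)

    def test_clinical_state_rejected(self):
        with pytest.raises(ValueError):
            positivity(TEST_PRESETS["FIT"], HealthState(Compartment.CRC_CLINICAL_I))

    def test_reflex_product_matches_two_test_enumeration(self):
        """gFOBT followed by reflex FIT on a preclinical cancer: the referral
        probability equals the product of sensitivities, verified against an
        exhaustive enumeration of the four independent two-test outcomes."""
        s_g, s_f = 0.36, 0.71
        outcomes = {}
        for g in (True, False):
            for f in (True, False):
                pr = (s_g if g else 1 - s_g) * (s_f if f else 1 - s_f)
                # referral requires a positive primary test AND positive reflex
                outcomes[(g, f)] = pr
        referral = outcomes[(True, True)]
        assert referral == pytest.approx(0.36 * 0.71)
        assert referral == pytest.approx(0.2556)
        assert sum(outcomes.values()) == pytest.approx(1.0)


class TestScreeningRound:
    def test_zero_uptake_leaves_cohort_unchanged(self, presets):
        strat = replace(presets["FIT_55_74"], uptake=0.0)
        coh = OverlayCohort.initial(strat.never_attender_fraction, age=55)
        coh2, tally = apply_screening_round(coh, strat)
        assert np.array_equal(coh2.occupancy, coh.occupancy)
        assert all(
            v == 0.0 for k, v in tally.counts.items() if not k.startswith("kits")
        )

    def test_unscheduled_age_rejected(self, presets):
        coh = OverlayCohort.initial(0.13, age=56)
        with pytest.raises(ValueError):
            apply_screening_round(coh, presets["FIT_55_74"])

    def test_perfect_test_detects_all_prevalent_preclinical(self, presets):
        """sens = spec = uptake = compliance = 1 with no complications moves
        every eligible preclinical cancer to a screen-detected clinical state."""
        perfect = TP("FIT", 1.0, 1.0, 1.0, 1.0)
        col = TP("COL", 1.0, 1.0, 1.0, 1.0)
        tests = dict(TEST_PRESETS, FIT=perfect, COL=col)
        strat = replace(
            presets["FIT_55_74"],
            uptake=1.0,
            never_attender_fraction=0.0,
            colonoscopy_compliance=1.0,
            ctc_fraction=0.0,
        )
        occ = np.zeros(196)
        occ[OFF_POOL + idx_preclin(2, True, False)] = 0.6
        occ[OFF_POOL + J_NORMAL] = 0.4
        coh = OverlayCohort(55, occ)
        coh2, tally = apply_screening_round(
            coh, strat, tests, risks=NO_COMPLICATIONS
        )
        assert coh2.occupancy[OFF_CLIN + 1] == pytest.approx(0.6, abs=1e-12)
        assert tally.counts["crc_screen_detected_II"] == pytest.approx(0.6)
        assert coh2.total == pytest.approx(1.0, abs=1e-12)

    def test_false_positive_colonoscopy_volume_closed_form(self, presets):
        """All-normal cohort, specificity 0.95, uptake 0.53, compliance 0.86:
        diagnostic colonoscopies = 100000 x 0.53 x 0.05 x 0.86 = 2279 per 100k."""
        strat = replace(presets["FIT_55_74"], ctc_fraction=0.0)
        coh = OverlayCohort.initial(strat.never_attender_fraction, age=55)
        _, tally = apply_screening_round(coh, strat)
        assert tally.per_100k()["colonoscopies_diagnostic"] == pytest.approx(2279, rel=1e-9)

    def test_mass_conserved_through_round(self, presets):
        coh = OverlayCohort.initial(0.13, age=55)
        occ = coh.occupancy
        occ[OFF_POOL + J_NORMAL] = 0.5
        occ[OFF_POOL + 3] = 0.2
        occ[OFF_POOL + idx_preclin(1, True, False)] = 0.17
        coh2, _ = apply_screening_round(coh, presets["gFOBT_55_74"])
        assert coh2.total == pytest.approx(coh.total, abs=1e-12)

    def test_fsig_round_counts_fsig_not_kits(self, presets):
        coh = OverlayCohort.initial(0.0, age=60)
        _, tally = apply_screening_round(coh, presets["FSIG_60"])
        assert tally.counts["fsig_screens"] > 0
        assert tally.counts["tests_fit"] == 0
        assert tally.counts["tests_gfobt"] == 0


class TestSurveillance:
    def test_zero_compliance_leaves_surveillance_progressing_naturally(self):
        rule = SurveillanceRule(compliance=0.0)
        occ = np.zeros(196)
        occ[OFF_SURV + 0 * N_PD + J_NORMAL] = 1.0  # high-risk tier
        coh = OverlayCohort(58, occ)
        coh2, tally = apply_surveillance(coh, rule, risks=NO_COMPLICATIONS)
        assert tally.counts["colonoscopies_surveillance"] == 0.0
        assert coh2.occupancy[OFF_SURV + 0 * N_PD + J_NORMAL] == pytest.approx(1.0)

    def test_two_clear_exams_three_years_apart_exit_surveillance(self):
        """A disease-free intermediate-tier member exits to the routine pool
        after the second clear exam."""
        rule = SurveillanceRule(compliance=1.0)
        col = TP("COL", 1.0, 1.0, 1.0, 1.0)
        occ = np.zeros(196)
        occ[OFF_SURV + 1 * N_PD + J_NORMAL] = 1.0  # intermediate, no clears, clock 0
        coh = OverlayCohort(58, occ)
        exams = 0
        for _ in range(6):  # two 3-year intervals
            coh, tally = apply_surveillance(coh, rule, col, risks=NO_COMPLICATIONS)
            exams += tally.counts["colonoscopies_surveillance"]
        assert exams == pytest.approx(2.0)
        assert coh.occupancy[OFF_POOL + J_NORMAL] == pytest.approx(1.0, abs=1e-12)
        assert coh.occupancy[OFF_SURV:OFF_CLIN].sum() == pytest.approx(0.0, abs=1e-12)

    def test_high_risk_fraction_of_entrants(self, presets):
        """29% of detected intermediate/high-risk adenomas enter the annual
        (high-risk) tier."""
        col = TP("COL", 1.0, 1.0, 1.0, 1.0)
        tests = dict(TEST_PRESETS, COL=col, FIT=TP("FIT", 1.0, 1.0, 1.0, 1.0))
        strat = replace(
            presets["FIT_55_74"], uptake=1.0, never_attender_fraction=0.0,
            colonoscopy_compliance=1.0, ctc_fraction=0.0,
        )
        occ = np.zeros(196)
        occ[OFF_POOL + 3] = 1.0  # high-risk adenoma, distal
        coh = OverlayCohort(55, occ)
        coh2, _ = apply_screening_round(coh, strat, tests, risks=NO_COMPLICATIONS)
        high = coh2.occupancy[_surv_cell(0)].sum()
        inter = coh2.occupancy[_surv_cell(1)].sum()
        assert high == pytest.approx(0.29)
        assert inter == pytest.approx(0.71)


class TestSimulateStrategy:
    def test_no_screening_overlay_matches_natural_history(
        self, presets, ref_params, life_table, base_inputs
    ):
        res = simulate_with_inputs(presets["no_screening"], ref_params, life_table, base_inputs)
        nh = run_natural_history(ref_params, life_table)
        assert res.lifetime_incidence == pytest.approx(nh.lifetime_incidence, abs=1e-9)
        assert res.lifetime_mortality == pytest.approx(nh.lifetime_mortality, abs=1e-9)

    def test_fsig_strategy_tallies_fsig_only(self, presets, ref_params, life_table, base_inputs):
        res = simulate_with_inputs(presets["FSIG_60"], ref_params, life_table, base_inputs)
        assert res.tally["fsig_screens"] > 0
        assert res.tally["tests_fit"] == 0
        assert res.tally["tests_gfobt"] == 0

    def test_tally_flow_consistency(self, presets, ref_params, life_table, base_inputs):
        """Screen- + surveillance-detected + symptomatic cancers equal total
        lifetime incidence."""
        res = simulate_with_inputs(presets["FIT_55_74"], ref_params, life_table, base_inputs)
        routes = sum(
            res.tally[f"crc_{route}_{s}"]
            for route in ("screen_detected", "surveillance_detected", "symptomatic")
            for s in ("I", "II", "III", "IV")
        )
        assert routes == pytest.approx(res.lifetime_incidence, abs=1e-9)

    def test_blind_screening_reproduces_no_screening_outcomes(
        self, presets, ref_params, life_table, base_inputs
    ):
        """Zero sensitivity, perfect specificity, no complications: identical
        incidence and mortality to no screening, test counts aside."""
        blind = TP("FIT", 0.0, 0.0, 0.0, 1.0)
        tests = dict(TEST_PRESETS, FIT=blind)
        strat = presets["FIT_55_74"]
        res = simulate_strategy(
            strat,
            ref_params,
            tests=tests,
            life_table=life_table,
            risks=NO_COMPLICATIONS,
        )
        nh = run_natural_history(ref_params, life_table)
        assert res.tally["tests_fit"] > 0
        assert res.lifetime_incidence == pytest.approx(nh.lifetime_incidence, abs=1e-9)
        assert res.lifetime_mortality == pytest.approx(nh.lifetime_mortality, abs=1e-9)

    def test_mortality_non_increasing_in_sensitivity_and_uptake(
        self, presets, ref_params, life_table
    ):
        """Across a grid of FIT cancer sensitivities and uptakes, lifetime CRC
        mortality never increases when either rises."""
        def mort(sens, uptake):
            tests = dict(
                TEST_PRESETS, FIT=TP("FIT", 0.21, 0.21, sens, 0.95)
            )
            strat = replace(presets["FIT_55_74"], uptake=uptake)
            res = simulate_strategy(
                strat, ref_params, tests=tests, life_table=life_table
            )
            return res.lifetime_mortality

        grid = {}
        for sens in (0.5, 0.71, 0.9):
            for up in (0.3, 0.53, 0.7):
                grid[(sens, up)] = mort(sens, up)
        for up in (0.3, 0.53, 0.7):
            assert grid[(0.5, up)] >= grid[(0.71, up)] >= grid[(0.9, up)]
        for sens in (0.5, 0.71, 0.9):
            assert grid[(sens, 0.3)] >= grid[(sens, 0.53)] >= grid[(sens, 0.7)]

    def test_never_attender_accounting(self, presets, ref_params, life_table, base_inputs):
        """Per-round attendance among potential attenders is 0.53/0.87 and the
        never-attender block is never tested."""
        strat = presets["FIT_55_74"]
        assert strat.uptake / (1 - strat.never_attender_fraction) == pytest.approx(
            0.609, abs=5e-4
        )
        coh = OverlayCohort.initial(strat.never_attender_fraction, age=55)
        coh2, tally = apply_screening_round(coh, strat)
        assert tally.counts["tests_fit"] == pytest.approx(0.53)
        # never-attenders untouched
        assert coh2.occupancy[OFF_NEVER + J_NORMAL] == pytest.approx(0.13)

    def test_complications_scale_linearly_with_procedures(
        self, presets, ref_params, life_table
    ):
        """Doubling per-procedure complication probabilities doubles complication
        counts at (almost) fixed procedure volumes."""
        r1 = ComplicationRisks()
        r2 = ComplicationRisks(
            fsig_perforation=2 * r1.fsig_perforation,
            fsig_perforation_death=r1.fsig_perforation_death,
            fsig_bleed=2 * r1.fsig_bleed,
            col_perforation_polypectomy=2 * r1.col_perforation_polypectomy,
            col_perforation_no_polypectomy=2 * r1.col_perforation_no_polypectomy,
            col_perforation_death=r1.col_perforation_death,
            col_bleed=2 * r1.col_bleed,
        )
        res1 = simulate_strategy(
            presets["FIT_55_74"], ref_params, life_table=life_table, risks=r1
        )
        res2 = simulate_strategy(
            presets["FIT_55_74"], ref_params, life_table=life_table, risks=r2
        )
        ratio_proc = res2.tally["colonoscopies_diagnostic"] / res1.tally["colonoscopies_diagnostic"]
        assert ratio_proc == pytest.approx(1.0, abs=2e-3)
        assert res2.tally["bleeds"] / res1.tally["bleeds"] == pytest.approx(2.0, abs=5e-3)
        assert res2.tally["perforations"] / res1.tally["perforations"] == pytest.approx(
            2.0, abs=5e-3
        )
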