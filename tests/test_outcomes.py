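import dataclasses

import numpy as np
import pytest

from apbi_cea.conventions import (
    END_OF_CYCLE,
    FIRST_CYCLE_UNDISCOUNTED,
    HealthState,
    ModelConventions,
)
from apbi_cea.engine import run_cohort
from apbi_cea.outcomes import (
    DOMINANT,
    DOMINATED,
    MEASURES,
    TRADE_OFF,
    UndefinedICERError,
    benefits,
    classify_dominance,
    compare,
    discounted_state_time,
    icer,
    outcome_set,
    per_patient_cost,
)
from apbi_cea.params import ArmParameters, ModelConfig, MortalityTable, UtilitySet
from apbi_cea.synthetic import generate_random_model_spec

DF = HealthState.DISEASE_FREE


@pytest.fixture(scope="module")
def immortal_trace():
    """A cohort that never leaves the disease-free state."""
    arm = ArmParameters(
        arm_label="immortal",
        p_local_recurrence=(0.0,) * 10,
        p_bc_death=(0.0,) * 10,
        p_metastasis_from_disease_free=0.0,
        p_metastasis_from_local_recurrence=0.0,
        cost_treatment=0.0,
        cost_other_direct=0.0,
    )
    mort = MortalityTable(bands=((0, 120, 0.0),))
    return run_cohort(arm, mort, ModelConfig())


class TestDiscountedStateTime:
    def test_zero_rate_full_horizon(self, immortal_trace):
        time = discounted_state_time(immortal_trace, 0.0, ModelConventions())
        assert time[DF] == pytest.approx(10.0, abs=1e-12)

    def test_first_cycle_undiscounted_geometric_sum(self, immortal_trace):
        conv = ModelConventions(discount_timing=FIRST_CYCLE_UNDISCOUNTED)
        time = discounted_state_time(immortal_trace, 0.03, conv)
        assert time[DF] == pytest.approx(sum(1.03 ** -k for k in range(10)))
        assert time[DF] == pytest.approx(8.7861, abs=5e-5)

    def test_end_of_cycle_geometric_sum(self, immortal_trace):
        conv = ModelConventions(discount_timing=END_OF_CYCLE)
        time = discounted_state_time(immortal_trace, 0.03, conv)
        assert time[DF] == pytest.approx(sum(1.03 ** -k for k in range(1, 11)))
        assert time[DF] == pytest.approx(8.5302, abs=5e-5)

    def test_half_cycle_correction_no_op_for_constant_occupancy(self, immortal_trace):
        plain = discounted_state_time(immortal_trace, 0.03, ModelConventions())
        hcc = discounted_state_time(
            immortal_trace, 0.03,
            ModelConventions(half_cycle_correction=True),
        )
        np.testing.assert_allclose(plain, hcc, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_discounted_never_exceeds_undiscounted(self, seed):
        spec = generate_random_model_spec(seed)
        trace = run_cohort(spec.iort, spec.mortality, spec.config)
        conv = spec.config.conventions
        discounted = discounted_state_time(trace, 0.05, conv)
        undiscounted = discounted_state_time(trace, 0.0, conv)
        assert np.all(discounted <= undiscounted + 1e-12)


class TestBenefits:
    def test_unit_utilities_make_qaly_equal_ly(self, bundle):
        trace = run_cohort(bundle.iort, bundle.mortality, bundle.config)
        ones = UtilitySet(1.0, 1.0, 1.0)
        b = benefits(trace, ones, bundle.config)
        assert b["qaly"] == pytest.approx(b["ly"], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_benefit_identities_and_bounds(self, seed):
        spec = generate_random_model_spec(seed)
        trace = run_cohort(spec.iort, spec.mortality, spec.config)
        b = benefits(trace, spec.utilities, spec.config)
        assert b["rfly"] <= b["ly"] + 1e-12
        assert b["qaly"] <= b["ly"] + 1e-12
        # quality-adjusted recurrence-free time is exactly utility-weighted
        assert b["qarfly"] == pytest.approx(
            b["rfly"] * spec.utilities.u_disease_free, abs=1e-12
        )
        # mean utility per life-year is bracketed by the state utilities
        ratio = b["qaly"] / b["ly"]
        assert (spec.utilities.u_metastasis - 1e-12
                <= ratio
                <= spec.utilities.u_disease_free + 1e-12)


class TestCosts:
    def test_published_per_patient_costs(self, bundle):
        assert per_patient_cost(bundle.iort, bundle.config) == pytest.approx(
            418 + 359 + 55344 / 100
        )
        assert per_patient_cost(bundle.imrt, bundle.config) == pytest.approx(323.0)

    def test_maintenance_exclusion(self, bundle):
        cfg = dataclasses.replace(bundle.config, include_maintenance=False)
        assert per_patient_cost(bundle.iort, cfg) == pytest.approx(777.0)
        assert per_patient_cost(bundle.imrt, cfg) == pytest.approx(323.0)

    def test_maintenance_allocated_over_cohort(self, bundle):
        cfg = dataclasses.replace(bundle.config, cohort_size=1000)
        assert per_patient_cost(bundle.iort, cfg) == pytest.approx(
            418 + 359 + 55344 / 1000
        )


class TestICER:
    @pytest.mark.parametrize(
        "dc, db, expected", [(100, 2, 50), (0, 1, 0), (1006, -0.269, 1006 / -0.269)]
    )
    def test_signed_ratio(self, dc, db, expected):
        assert icer(dc, db) == pytest.approx(expected)

    def test_antisymmetry(self):
        assert icer(-1006.44, 0.266) == icer(1006.44, -0.266)

    def test_zero_benefit_is_undefined(self):
        with pytest.raises(UndefinedICERError):
            icer(100.0, 0.0)

    @pytest.mark.parametrize(
        "dc, db, label",
        [
            (1006, -0.27, DOMINATED),
            (-5, 1, DOMINANT),
            (5, 1, TRADE_OFF),
            (-5, -1, TRADE_OFF),
            (0, 1, TRADE_OFF),
        ],
    )
    def test_dominance_classification(self, dc, db, label):
        assert classify_dominance(dc, db) == label


class TestCompare:
    def test_identical_arms_zero_incrementals(self, bundle):
        trace = run_cohort(bundle.imrt, bundle.mortality, bundle.config)
        out = outcome_set(trace, bundle.imrt, bundle.utilities, bundle.config)
        result = compare(out, out)
        assert result.delta_cost == 0.0
        for m in MEASURES:
            assert result.delta_benefit[m] == 0.0
            assert result.icers[m] is None
            assert result.dominance[m] == TRADE_OFF

    def test_result_frame_layout(self, bundle):
        iort = outcome_set(
            run_cohort(bundle.iort, bundle.mortality, bundle.config),
            bundle.iort, bundle.utilities, bundle.config,
        )
        imrt = outcome_set(
            run_cohort(bundle.imrt, bundle.mortality, bundle.config),
            bundle.imrt, bundle.utilities, bundle.config,
        )
        frame = compare(iort, imrt).to_frame()
        assert list(frame["measure"]) == ["LY", "RFLY", "QALY", "QARFLY", "COST"]
        assert {"IORT", "IMRT", "incremental", "icer"} <= set(frame.columns)
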