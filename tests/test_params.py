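import dataclasses

import pytest

from apbi_cea.params import (
    ArmParameters,
    ModelConfig,
    MortalityTable,
    SchemaError,
    UtilitySet,
    builtin_table1,
    load_parameters,
    serialize_parameters,
    validate_parameters,
)


class TestBuiltinTable:
    def test_published_spot_values(self, bundle):
        assert bundle.iort.p_local_recurrence[2] == 0.018  # year 3
        assert bundle.imrt.p_metastasis_from_disease_free == 0.0029
        assert bundle.iort.cost_annual_maintenance == 55344
        assert bundle.imrt.cost_treatment == 29
        assert bundle.iort.p_bc_death[9] == 0.018  # year 10
        assert bundle.utilities.u_disease_free == 0.920
        assert bundle.utilities.u_metastasis == 0.685

    def test_sensitivity_variants_replace_only_stated_block(self, bundle):
        lower_rec = bundle.iort_lower_recurrence
        assert lower_rec.p_local_recurrence[2] == 0.010
        assert lower_rec.p_bc_death == bundle.iort.p_bc_death
        assert (lower_rec.p_metastasis_from_disease_free
                == bundle.iort.p_metastasis_from_disease_free)
        assert lower_rec.cost_treatment == bundle.iort.cost_treatment

        lower_met = bundle.iort_lower_metastasis
        assert lower_met.p_metastasis_from_disease_free == 0.004
        assert lower_met.p_local_recurrence == bundle.iort.p_local_recurrence

    def test_config_defaults(self, bundle):
        cfg = bundle.config
        assert (cfg.cohort_size, cfg.start_age, cfg.horizon) == (100, 60, 10)
        assert cfg.discount_rate_benefits == cfg.discount_rate_costs == 0.03
        assert cfg.include_maintenance

    def test_utility_ordering(self, bundle):
        u = bundle.utilities
        assert u.u_metastasis <= u.u_local_recurrence <= u.u_disease_free

    def test_serialize_load_round_trip(self, bundle):
        reloaded = load_parameters(serialize_parameters(bundle))
        assert reloaded.iort == bundle.iort
        assert reloaded.imrt == bundle.imrt
        assert reloaded.mortality == bundle.mortality
        assert reloaded.utilities == bundle.utilities
        assert reloaded.config == bundle.config


class TestSchemaValidation:
    def _doc(self, bundle, mutate):
        doc = serialize_parameters(bundle)
        mutate(doc)
        return doc

    def test_probability_out_of_bounds_rejected(self, bundle):
        doc = self._doc(
            bundle, lambda d: d["arms"]["IORT"].update(
                p_metastasis_from_disease_free=1.2)
        )
        with pytest.raises(SchemaError, match="p_metastasis_from_disease_free"):
            load_parameters(doc)

    def test_vector_length_mismatch_rejected(self, bundle):
        doc = self._doc(
            bundle,
            lambda d: d["arms"]["IORT"].update(
                p_local_recurrence=d["arms"]["IORT"]["p_local_recurrence"][:9]),
        )
        with pytest.raises(SchemaError, match="same years"):
            load_parameters(doc)

    def test_vector_shorter_than_horizon_rejected(self, bundle):
        doc = self._doc(
            bundle,
            lambda d: d["arms"]["IORT"].update(
                p_local_recurrence=d["arms"]["IORT"]["p_local_recurrence"][:9],
                p_bc_death=d["arms"]["IORT"]["p_bc_death"][:9]),
        )
        with pytest.raises(SchemaError, match="horizon"):
            load_parameters(doc)

    def test_unknown_key_rejected(self, bundle):
        doc = self._doc(bundle, lambda d: d["arms"]["IORT"].update(typo_key=1))
        with pytest.raises(SchemaError, match="typo_key"):
            load_parameters(doc)

    def test_missing_section_rejected(self, bundle):
        doc = serialize_parameters(bundle)
        del doc["utilities"]
        with pytest.raises(SchemaError, match="utilities"):
            load_parameters(doc)

    def test_negative_cost_rejected(self):
        with pytest.raises(SchemaError, match="cost_treatment"):
            ArmParameters(
                arm_label="X",
                p_local_recurrence=(0.0,) * 10,
                p_bc_death=(0.0,) * 10,
                p_metastasis_from_disease_free=0.0,
                p_metastasis_from_local_recurrence=0.0,
                cost_treatment=-1.0,
                cost_other_direct=0.0,
            )


class TestMortalityTable:
    def test_lookup_covers_modelled_ages(self, bundle):
        for age in range(50, 70):
            assert 0.0 <= bundle.mortality.annual_probability(age) <= 1.0
        assert bundle.mortality.annual_probability(60) == 0.006
        assert bundle.mortality.annual_probability(65) == 0.009

    def test_age_outside_bands_raises(self, bundle):
        with pytest.raises(KeyError):
            bundle.mortality.annual_probability(120)

    def test_non_contiguous_bands_rejected(self):
        with pytest.raises(SchemaError, match="contiguous"):
            MortalityTable(bands=((50, 54, 0.002), (56, 60, 0.004)))


class TestValidateParameters:
    def test_bundled_sets_valid(self, bundle):
        report = validate_parameters(bundle)
        assert report.ok and len(report) == 0

    def test_row_sum_above_one_flagged_only_under_applicable_conventions(
        self, bundle
    ):
        """An LR->M probability of 0.99 plus the applicable death
        probabilities breaks feasibility only when disease-specific
        mortality acts from the local-recurrence state (0.99 + 0.018 +
        0.009 > 1); with background mortality alone the row still sums
        below 1."""
        from apbi_cea.conventions import HealthState, ModelConventions

        bad = bundle.iort.with_variant(
            "bad", p_metastasis_from_local_recurrence=0.99
        )
        lr_conv = ModelConventions(
            bc_death_source_states=frozenset(
                {HealthState.LOCAL_RECURRENCE, HealthState.METASTASIS}
            )
        )
        cfg = dataclasses.replace(bundle.config, conventions=lr_conv)
        report = validate_parameters(bad, cfg, bundle.mortality)
        assert not report.ok
        assert any("LOCAL_RECURRENCE" in v for v in report)
        # under the calibrated conventions the same arm remains feasible
        assert validate_parameters(bad, bundle.config, bundle.mortality).ok

    def test_zero_parameter_set_valid(self):
        zero = ArmParameters(
            arm_label="zero",
            p_local_recurrence=(0.0,) * 10,
            p_bc_death=(0.0,) * 10,
            p_metastasis_from_disease_free=0.0,
            p_metastasis_from_local_recurrence=0.0,
            cost_treatment=0.0,
            cost_other_direct=0.0,
        )
        mort = MortalityTable(bands=((0, 120, 0.0),))
        assert validate_parameters(zero, ModelConfig(), mort).ok

    def test_horizon_mismatch_flagged(self, bundle):
        cfg = dataclasses.replace(bundle.config, horizon=5)
        report = validate_parameters(bundle.iort, cfg, bundle.mortality)
        assert any("horizon" in v for v in report)
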