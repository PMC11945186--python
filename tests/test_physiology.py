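import numpy as np
import pytest

from tofasim.physiology import (
    CHILD_PUGH_SCALERS,
    DEFAULT_VARIABILITY,
    HepaticStatus,
    Individual,
    PopulationSpec,
    RenalStatus,
    TISSUES,
    apply_hepatic_impairment,
    apply_pediatric_scaling,
    apply_renal_impairment,
    build_reference_adult,
    sample_population,
)


class TestReferenceAdult:
    def test_reference_is_thirty_years_old(self):
        assert build_reference_adult().age == 30.0

    def test_deterministic_construction(self):
        a, b = build_reference_adult(), build_reference_adult()
        assert a == b

    def test_venous_return_equals_cardiac_output(self):
        ind = build_reference_adult()
        total = sum(ind.blood_flows[t] for t in TISSUES)
        assert total == pytest.approx(ind.cardiac_output, rel=1e-6)


class TestPopulationSampling:
    def test_size_age_range_and_determinism(self):
        spec = PopulationSpec(n=200, age_range=(18.0, 60.0), female_fraction=0.5, seed=1)
        pop = sample_population(spec)
        assert len(pop) == 200
        assert all(18.0 <= i.age <= 60.0 for i in pop)
        pop2 = sample_population(spec)
        for a, b in zip(pop, pop2):  # bitwise-identical draws
            assert a.organ_volumes == b.organ_volumes
            assert a.blood_flows == b.blood_flows
            assert a.gfr == b.gfr

    def test_sex_assignment_matches_female_fraction(self):
        pop = sample_population(PopulationSpec(n=400, female_fraction=0.7, seed=5))
        frac = np.mean([i.sex == "female" for i in pop])
        assert frac == pytest.approx(0.7, abs=0.08)

    def test_zero_variance_reproduces_reference(self):
        cv0 = {k: 0.0 for k in DEFAULT_VARIABILITY}
        pop = sample_population(
            PopulationSpec(n=5, age_range=(30.0, 30.0), female_fraction=0.0,
                           seed=9, variability=cv0)
        )
        ref = build_reference_adult()
        for ind in pop:
            assert ind.organ_volumes == pytest.approx(ref.organ_volumes)
            assert ind.gfr == ref.gfr
            assert ind.enzyme_abundance == {"CYP3A4": 1.0, "CYP2C19": 1.0}

    def test_conservation_holds_for_every_sample(self):
        for ind in sample_population(PopulationSpec(n=50, seed=3)):
            assert sum(ind.blood_flows[t] for t in TISSUES) == pytest.approx(
                ind.cardiac_output, rel=1e-6
            )

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(n=0)
        with pytest.raises(ValueError):
            PopulationSpec(n=10, age_range=(60.0, 18.0))
        with pytest.raises(ValueError):
            PopulationSpec(n=10, female_fraction=1.5)


class TestPediatricScaling:
    def test_growth_is_monotone(self):
        young = apply_pediatric_scaling(4.0)
        teen = apply_pediatric_scaling(14.0)
        adult = build_reference_adult()
        assert young.body_weight < teen.body_weight
        assert teen.organ_volumes["liver"] <= adult.organ_volumes["liver"]
        adolescent = apply_pediatric_scaling(17.99)
        assert adolescent.organ_volumes["liver"] <= adult.organ_volumes["liver"]

    @pytest.mark.parametrize("age_pair", [(5.99, 6.01), (11.99, 12.01)])
    def test_no_discontinuity_across_ages(self, age_pair):
        lo, hi = (apply_pediatric_scaling(a) for a in age_pair)
        assert hi.body_weight == pytest.approx(lo.body_weight, rel=0.005)
        assert hi.gfr == pytest.approx(lo.gfr, rel=0.005)
        assert hi.organ_volumes["liver"] == pytest.approx(
            lo.organ_volumes["liver"], rel=0.005
        )

    def test_females_are_smaller_in_adolescence(self):
        girl = apply_pediatric_scaling(15.0, sex="female")
        boy = apply_pediatric_scaling(15.0, sex="male")
        assert girl.body_weight < boy.body_weight
        assert girl.organ_volumes["liver"] < boy.organ_volumes["liver"]

    def test_size_percentile_shifts_weight(self):
        small = apply_pediatric_scaling(9.0, size_percentile=0.1)
        big = apply_pediatric_scaling(9.0, size_percentile=0.9)
        assert small.body_weight < big.body_weight

    def test_age_below_two_unsupported(self):
        with pytest.raises(ValueError):
            apply_pediatric_scaling(1.5)
        with pytest.raises(ValueError):
            apply_pediatric_scaling(18.0)


class TestHepaticImpairment:
    def test_healthy_class_is_identity(self, ref_adult):
        out = apply_hepatic_impairment(ref_adult, HepaticStatus("healthy"))
        assert out.enzyme_abundance == ref_adult.enzyme_abundance
        assert out.blood_flows == ref_adult.blood_flows
        assert out.fu_scaler == ref_adult.fu_scaler

    def test_class_b_direction(self, ref_adult):
        out = apply_hepatic_impairment(ref_adult, HepaticStatus("B"))
        assert out.enzyme_abundance["CYP3A4"] < ref_adult.enzyme_abundance["CYP3A4"]
        assert out.fu_scaler > ref_adult.fu_scaler
        assert out.functional_liver_fraction < 1.0
        assert out.blood_flows["liver"] < ref_adult.blood_flows["liver"]
        # untouched fields
        assert out.organ_volumes == ref_adult.organ_volumes
        assert out.enzyme_abundance["CYP2C19"] == 1.0

    def test_input_not_mutated(self, ref_adult):
        before = dict(ref_adult.enzyme_abundance)
        apply_hepatic_impairment(ref_adult, HepaticStatus("B"))
        assert ref_adult.enzyme_abundance == before

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            HepaticStatus("C")

    def test_healthy_scalers_are_unity(self):
        assert all(v == 1.0 for v in CHILD_PUGH_SCALERS["healthy"].values())


class TestRenalImpairment:
    def test_normal_reference_is_identity(self, ref_adult):
        out = apply_renal_impairment(ref_adult, RenalStatus("normal", egfr=100.0))
        assert out.gfr == ref_adult.gfr

    def test_gfr_scales_with_egfr_ratio(self, ref_adult):
        out = apply_renal_impairment(ref_adult, RenalStatus("moderate", egfr=50.0))
        assert out.gfr == pytest.approx(ref_adult.gfr * 0.5)

    def test_hepatic_parameters_untouched(self, ref_adult):
        out = apply_renal_impairment(ref_adult, RenalStatus("severe"))
        assert out.enzyme_abundance == ref_adult.enzyme_abundance
        assert out.functional_liver_fraction == 1.0

    def test_invalid_status_rejected(self):
        with pytest.raises(ValueError):
            RenalStatus("anuric")
        with pytest.raises(ValueError):
            RenalStatus("severe", egfr=-1.0)
        with pytest.raises(ValueError):  # inconsistent with the band
            RenalStatus("severe", egfr=80.0)
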