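"""Dose arithmetic: region DLP apportionment, factor lookup, conservation."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torsodose.dosimetry import (
    REGIONS,
    ConversionFactorTable,
    CtAcquisition,
    PetAcquisition,
    RegionPartition,
    WeightingFactorTable,
    age_to_weighting_factor,
    ct_effective_dose,
    effective_dose,
    irradiated_length,
    pet_effective_dose,
    region_dlp,
    region_ed,
    total_effective_dose,
)
from torsodose.errors import (
    ConfigurationError,
    InconsistencyError,
    InvalidAcquisitionError,
)


class TestIrradiatedLength:
    @pytest.mark.parametrize(
        "dlp,ctdi,expected",
        [
            (300.0, 3.0, 100.0),
            (2.9, 2.9, 1.0),
            # long division cross-checked with exact rational arithmetic
            (308.5, 2.9, float(Fraction(3085, 29))),
        ],
    )
    def test_is_dlp_over_ctdivol(self, dlp, ctdi, expected):
        assert irradiated_length(CtAcquisition(ctdi, dlp)) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("ctdi,dlp", [(0.0, 300.0), (-1.0, 300.0), (3.0, 0.0), (3.0, -5.0)])
    def test_non_positive_dose_metadata_rejected(self, ctdi, dlp):
        with pytest.raises(InvalidAcquisitionError):
            CtAcquisition(ctdi, dlp)


class TestRegionDlp:
    def test_half_the_slices_gets_half_the_dlp(self):
        ct = CtAcquisition(3.0, 300.0, n_slices=100)
        part = RegionPartition.from_counts([50, 10, 10, 10, 10, 10])
        assert region_dlp(ct, part, "head") == pytest.approx(150.0)

    def test_empty_region_gets_zero(self):
        ct = CtAcquisition(3.0, 300.0, n_slices=100)
        part = RegionPartition.from_counts([0, 20, 20, 20, 20, 20])
        assert region_dlp(ct, part, "head") == 0.0

    def test_apportionment_matches_brute_force_and_conserves_dlp(self):
        ct = CtAcquisition(2.0, 200.0, n_slices=100)
        counts = [10, 10, 30, 20, 20, 10]
        part = RegionPartition.from_counts(counts)
        expected = {r: c / 100 * 200.0 for r, c in zip(REGIONS, counts)}
        dlps = {r: region_dlp(ct, part, r) for r in REGIONS}
        assert dlps == pytest.approx(expected)
        assert sum(dlps.values()) == pytest.approx(200.0, rel=1e-12)

    def test_slice_count_mismatch_is_an_error(self):
        ct = CtAcquisition(3.0, 300.0, n_slices=101)
        part = RegionPartition.from_counts([50, 10, 10, 10, 10, 10])
        with pytest.raises(InconsistencyError):
            region_dlp(ct, part, "head")

    def test_missing_slice_count_is_an_error(self):
        ct = CtAcquisition(3.0, 300.0)
        part = RegionPartition.from_counts([50, 10, 10, 10, 10, 10])
        with pytest.raises(InconsistencyError):
            region_dlp(ct, part, "head")


class TestRegionEd:
    @pytest.mark.parametrize(
        "region,dlp,expected",
        [("chest", 100.0, 1.4), ("head", 0.0, 0.0), ("pelvis", 40.0, 0.6)],
    )
    def test_dlp_times_icrp_factor(self, region, dlp, expected):
        assert region_ed(dlp, ConversionFactorTable.icrp102(), region) == pytest.approx(
            expected, rel=1e-12
        )

    def test_unknown_region_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            region_ed(10.0, ConversionFactorTable.icrp102(), "torso")


class TestCtEffectiveDose:
    def test_single_region_degenerate_partition(self):
        ct = CtAcquisition(1.0, 100.0, n_slices=50)
        part = RegionPartition.from_counts([0, 0, 50, 0, 0, 0])
        result = ct_effective_dose(ct, part)
        assert result.ct_ed == pytest.approx(1.4, rel=1e-12)
        assert result.pet_ed == 0.0

    def test_uniform_factor_reduces_to_whole_body_conversion(self):
        # with one factor everywhere, the partition must not matter
        ct = CtAcquisition(2.5, 412.5, n_slices=99)
        uniform = ConversionFactorTable.uniform(0.015)
        for counts in ([99, 0, 0, 0, 0, 0], [17, 16, 30, 12, 14, 10], [1, 1, 1, 1, 1, 94]):
            result = ct_effective_dose(ct, RegionPartition.from_counts(counts), uniform)
            assert result.ct_ed == pytest.approx(0.015 * 412.5, rel=1e-12)

    def test_matches_per_slice_accumulation_oracle(self):
        # brute force: give each slice its share of the irradiated length and
        # its own region's factor, then sum
        counts = [5, 8, 35, 25, 20, 7]
        ct = CtAcquisition(3.0, 300.0, n_slices=100)
        factors = ConversionFactorTable.icrp102()
        length = 300.0 / 3.0
        per_slice = 0.0
        for region, count in zip(REGIONS, counts):
            for _ in range(count):
                per_slice += (length / 100) * 3.0 * factors[region]
        result = ct_effective_dose(ct, RegionPartition.from_counts(counts), factors)
        assert result.ct_ed == pytest.approx(per_slice, rel=1e-12)
        assert result.ct_ed == pytest.approx(sum(result.region_ed.values()), rel=1e-15)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(0, 400), min_size=6, max_size=6).filter(
            lambda c: sum(c) >= 6
        ),
        ctdi=st.floats(0.5, 20.0),
        length=st.floats(10.0, 200.0),
    )
    def test_region_dlps_conserve_torso_dlp(self, counts, ctdi, length):
        dlp = ctdi * length
        ct = CtAcquisition(ctdi, dlp, n_slices=sum(counts))
        part = RegionPartition.from_counts(counts)
        total = sum(region_dlp(ct, part, r) for r in REGIONS)
        assert math.isclose(total, dlp, rel_tol=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(scale=st.floats(1.01, 10.0))
    def test_ct_ed_strictly_increases_with_dlp(self, scale):
        part = RegionPartition.from_counts([10, 10, 30, 20, 20, 10])
        low = ct_effective_dose(CtAcquisition(3.0, 300.0, 100), part)
        high = ct_effective_dose(CtAcquisition(3.0, 300.0 * scale, 100), part)
        assert high.ct_ed > low.ct_ed


class TestPetDosimetry:
    @pytest.mark.parametrize(
        "age,factor",
        [(0, 0.095), (1, 0.095), (2, 0.056), (5, 0.056), (6, 0.037), (8, 0.037),
         (10, 0.037), (11, 0.024), (15, 0.024), (16, 0.019), (60, 0.019)],
    )
    def test_age_band_lookup(self, age, factor):
        assert age_to_weighting_factor(age) == factor

    def test_fractional_ages_floor_to_whole_years(self):
        assert age_to_weighting_factor(15.9) == 0.024
        assert age_to_weighting_factor(16.0) == 0.019

    def test_every_age_maps_to_exactly_one_band(self):
        table = WeightingFactorTable.icrp128_fdg()
        for age in range(121):
            hits = [
                f for lo, hi, f in table.bands
                if age >= lo and (hi is None or age <= hi)
            ]
            assert len(hits) == 1

    def test_negative_age_rejected(self):
        with pytest.raises(InvalidAcquisitionError):
            age_to_weighting_factor(-1)

    @pytest.mark.parametrize(
        "dose,age,expected",
        [(200.0, 40, 3.8), (100.0, 8, 3.7), (318.6, 60, 6.0534)],
    )
    def test_pet_ed_is_dose_times_age_factor(self, dose, age, expected):
        assert pet_effective_dose(PetAcquisition(dose, age)) == pytest.approx(
            expected, rel=1e-12
        )

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(dose=st.floats(1.0, 1000.0), scale=st.floats(1.01, 5.0))
    def test_pet_ed_strictly_increases_with_dose(self, dose, scale):
        age = 50
        assert pet_effective_dose(PetAcquisition(dose * scale, age)) > pet_effective_dose(
            PetAcquisition(dose, age)
        )


class TestTotals:
    @pytest.mark.parametrize(
        "ct,pet,expected", [(4.46, 6.52, 10.98), (1.91, 2.07, 3.98), (0.0, 2.5, 2.5)]
    )
    def test_total_is_ct_plus_pet(self, ct, pet, expected):
        assert total_effective_dose(ct, pet) == pytest.approx(expected, rel=1e-12)

    def test_negative_components_rejected(self):
        with pytest.raises(InvalidAcquisitionError):
            total_effective_dose(-0.1, 1.0)

    def test_combined_result_satisfies_conservation_invariants(self):
        ct = CtAcquisition(2.9, 308.5, n_slices=263)
        part = RegionPartition.from_counts([20, 25, 75, 40, 40, 63])
        pet = PetAcquisition(228.3, 60)
        result = effective_dose(ct, part, pet)
        assert sum(result.region_dlp.values()) == pytest.approx(308.5, rel=1e-9)
        assert result.ct_ed == pytest.approx(sum(result.region_ed.values()), rel=1e-15)
        assert result.total_ed == result.ct_ed + result.pet_ed


class TestFactorTables:
    def test_conversion_table_requires_all_six_regions(self):
        with pytest.raises(ConfigurationError):
            ConversionFactorTable({"head": 0.0021})

    def test_conversion_table_rejects_unknown_region(self):
        factors = dict(ConversionFactorTable.icrp102().factors)
        factors["tail"] = 0.01
        with pytest.raises(ConfigurationError):
            ConversionFactorTable(factors)

    def test_conversion_table_rejects_non_positive_factor(self):
        factors = dict(ConversionFactorTable.icrp102().factors)
        factors["chest"] = 0.0
        with pytest.raises(ConfigurationError):
            ConversionFactorTable(factors)

    @pytest.mark.parametrize(
        "bands",
        [
            (),  # empty
            ((1, 5, 0.1), (6, None, 0.2)),  # does not start at 0
            ((0, 5, 0.1), (7, None, 0.2)),  # gap
            ((0, 5, 0.1), (4, None, 0.2)),  # overlap
            ((0, 5, 0.1), (6, 10, 0.2)),  # not open-ended
            ((0, 5, -0.1), (6, None, 0.2)),  # non-positive factor
        ],
    )
    def test_weighting_table_band_validation(self, bands):
        with pytest.raises(ConfigurationError):
            WeightingFactorTable(bands)
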