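"""DLP-method CT dosimetry and injected-activity PET dosimetry.

The effective dose (ED) of a torso PET/CT examination is estimated as

    ED_total = ED_CT + ED_PET

where the CT part uses the DLP method: the torso is partitioned into six
anatomical regions (head, neck, chest, abdomen, pelvis, femur), the dose
length product (DLP) is apportioned to each region by its share of the
scanned slices, and each regional DLP is converted to an effective dose
with an ICRP 102 region-specific conversion factor (mSv per mGy*cm):

    ED_CT = sum_i DLP_i * k_i
    DLP_i = (n_i / N) * L * CTDIvol,   L = DLP / CTDIvol

with n_i the region's slice count, N the total slice count and L the
irradiated length in cm. Note (n_i / N) * L * CTDIvol == (n_i / N) * DLP
algebraically; the implementation computes ``fraction * DLP`` so the
floating-point evaluation order is fixed and regional DLPs sum exactly
to the torso DLP.

The PET part multiplies the injected activity (MBq) by an age-specific
ICRP 128 dose coefficient for the radiopharmaceutical (mSv/MBq).

Factor tables are data, not constants: the ICRP defaults ship as
classmethods but any institution-specific table can be supplied, either
programmatically or from a YAML/JSON config (see ``torsodose.config``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import (
    ConfigurationError,
    InconsistencyError,
    InvalidAcquisitionError,
)

#: the six torso regions in anatomical order, superior to inferior
REGIONS: tuple[str, ...] = ("head", "neck", "chest", "abdomen", "pelvis", "femur")

#: ICRP 102 DLP-to-ED conversion factors, mSv/(mGy*cm), adult
_ICRP102_FACTORS: dict[str, float] = {
    "head": 0.0021,
    "neck": 0.0059,
    "chest": 0.014,
    "abdomen": 0.015,
    "pelvis": 0.015,
    "femur": 0.015,
}

#: ICRP 128 dose coefficients for 18F-FDG, mSv/MBq, by age band (years)
_ICRP128_FDG_BANDS: tuple[tuple[int, int | None, float], ...] = (
    (0, 1, 0.095),
    (2, 5, 0.056),
    (6, 10, 0.037),
    (11, 15, 0.024),
    (16, None, 0.019),
)


@dataclass(frozen=True)
class ConversionFactorTable:
    """Region -> DLP-to-ED conversion factor, mSv/(mGy*cm)."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [r for r in REGIONS if r not in self.factors]
        extra = [r for r in self.factors if r not in REGIONS]
        if missing or extra:
            raise ConfigurationError(
                f"conversion factor table must cover exactly {REGIONS}; "
                f"missing={missing}, unknown={extra}"
            )
        bad = {r: f for r, f in self.factors.items() if not f > 0}
        if bad:
            raise ConfigurationError(f"conversion factors must be > 0: {bad}")
        object.__setattr__(self, "factors", dict(self.factors))

    def __getitem__(self, region: str) -> float:
        try:
            return self.factors[region]
        except KeyError:
            raise ConfigurationError(f"unknown region {region!r}") from None

    @classmethod
    def icrp102(cls) -> "ConversionFactorTable":
        """The ICRP 102 adult torso factors."""
        return cls(_ICRP102_FACTORS)

    @classmethod
    def uniform(cls, factor: float) -> "ConversionFactorTable":
        """A whole-body conversion-factor table (same factor everywhere)."""
        return cls({r: factor for r in REGIONS})


@dataclass(frozen=True)
class WeightingFactorTable:
    """Ordered closed integer age bands (years) -> dose coefficient, mSv/MBq.

    The last band may be open-ended (upper bound ``None``). Bands must be
    disjoint and jointly cover all non-negative integer ages.
    """

    bands: tuple[tuple[int, int | None, float], ...]

    def __post_init__(self) -> None:
        bands = tuple((int(lo), None if hi is None else int(hi), float(f))
                      for lo, hi, f in self.bands)
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise ConfigurationError("weighting factor table is empty")
        if bands[0][0] != 0:
            raise ConfigurationError("age bands must start at 0")
        for i, (lo, hi, f) in enumerate(bands):
            if not f > 0:
                raise ConfigurationError(f"weighting factor must be > 0, got {f}")
            last = i == len(bands) - 1
            if hi is None and not last:
                raise ConfigurationError("only the last age band may be open-ended")
            if hi is not None and hi < lo:
                raise ConfigurationError(f"band [{lo}, {hi}] is empty")
            if not last and bands[i + 1][0] != (hi if hi is not None else -1) + 1:
                raise ConfigurationError(
                    f"age bands must be contiguous; gap/overlap after [{lo}, {hi}]"
                )
        if bands[-1][1] is not None:
            raise ConfigurationError("last age band must be open-ended to cover all ages")

    def factor_for_age(self, age_years: float) -> float:
        """Factor of the band containing ``age_years`` (floored to whole years)."""
        if age_years < 0 or not math.isfinite(age_years):
            raise InvalidAcquisitionError(f"invalid age {age_years!r}")
        age = math.floor(age_years)
        for lo, hi, f in self.bands:
            if age >= lo and (hi is None or age <= hi):
                return f
        raise ConfigurationError(f"no age band contains {age}")  # pragma: no cover

    @classmethod
    def icrp128_fdg(cls) -> "WeightingFactorTable":
        """The ICRP 128 coefficients for 18F-FDG."""
        return cls(_ICRP128_FDG_BANDS)


@dataclass(frozen=True)
class CtAcquisition:
    """Torso-level CT dose metadata.

    ``n_slices`` is carried by the image/label volume rather than the dose
    report, so it may be None until the pipeline attaches it; all slice-based
    operations require it.
    """

    ctdi_vol: float  # mGy
    dlp: float  # mGy*cm
    n_slices: int | None = None

    def __post_init__(self) -> None:
        if not (self.ctdi_vol > 0 and math.isfinite(self.ctdi_vol)):
            raise InvalidAcquisitionError(f"CTDIvol must be > 0, got {self.ctdi_vol}")
        if not (self.dlp > 0 and math.isfinite(self.dlp)):
            raise InvalidAcquisitionError(f"DLP must be > 0, got {self.dlp}")
        if self.n_slices is not None and self.n_slices < len(REGIONS):
            raise InvalidAcquisitionError(
                f"slice count must be >= {len(REGIONS)}, got {self.n_slices}"
            )


@dataclass(frozen=True)
class PetAcquisition:
    """Injected activity and the demographics that select its dose coefficient."""

    injected_dose_mbq: float
    age_years: int
    radiopharmaceutical: str = "18F-FDG"

    def __post_init__(self) -> None:
        if not (self.injected_dose_mbq > 0 and math.isfinite(self.injected_dose_mbq)):
            raise InvalidAcquisitionError(
                f"injected dose must be > 0 MBq, got {self.injected_dose_mbq}"
            )
        if self.age_years < 0:
            raise InvalidAcquisitionError(f"age must be >= 0, got {self.age_years}")


@dataclass(frozen=True)
class RegionPartition:
    """Per-region slice counts, anatomical order head -> femur.

    Counts derive from contiguous half-open slice ranges, so they are
    non-negative and sum to the slice count of the volume they partition.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [r for r in REGIONS if r not in self.counts]
        extra = [r for r in self.counts if r not in REGIONS]
        if missing or extra:
            raise ConfigurationError(
                f"partition must cover exactly {REGIONS}; missing={missing}, unknown={extra}"
            )
        bad = {r: c for r, c in self.counts.items() if c < 0 or int(c) != c}
        if bad:
            raise ConfigurationError(f"slice counts must be non-negative integers: {bad}")
        object.__setattr__(self, "counts", {r: int(self.counts[r]) for r in REGIONS})

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "RegionPartition":
        if len(counts) != len(REGIONS):
            raise ConfigurationError(f"expected {len(REGIONS)} counts, got {len(counts)}")
        return cls(dict(zip(REGIONS, counts)))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, region: str) -> float:
        if region not in self.counts:
            raise ConfigurationError(f"unknown region {region!r}")
        return self.counts[region] / self.total


@dataclass(frozen=True)
class EffectiveDoseResult:
    """Full dose breakdown for one study."""

    irradiated_length_cm: float
    region_dlp: Mapping[str, float] = field(default_factory=dict)  # mGy*cm
    region_ed: Mapping[str, float] = field(default_factory=dict)  # mSv
    ct_ed: float = 0.0  # mSv
    pet_ed: float = 0.0  # mSv

    @property
    def total_ed(self) -> float:
        return self.ct_ed + self.pet_ed


def irradiated_length(ct: CtAcquisition) -> float:
    """Irradiated length in cm: torso DLP / torso CTDIvol.

    In helical CT this exceeds the nominal scan range (over-ranging), which
    is why it is preferred over the scan-range length for apportioning dose.
    """
    return ct.dlp / ct.ctdi_vol


def _check_partition(ct: CtAcquisition, partition: RegionPartition) -> None:
    if ct.n_slices is None:
        raise InconsistencyError("CtAcquisition has no slice count attached")
    if partition.total != ct.n_slices:
        raise InconsistencyError(
            f"partition covers {partition.total} slices but acquisition has {ct.n_slices}"
        )


def region_dlp(ct: CtAcquisition, partition: RegionPartition, region: str) -> float:
    """DLP apportioned to one region, mGy*cm.

    Defined as (region slices / total slices) * irradiated length * CTDIvol;
    computed as fraction * DLP, which is the same product with a fixed
    evaluation order (DLP = irradiated length * CTDIvol by construction).
    """
    _check_partition(ct, partition)
    return partition.fraction(region) * ct.dlp


def region_ed(dlp: float, factors: ConversionFactorTable, region: str) -> float:
    """Effective dose of one region: its DLP times its conversion factor."""
    if dlp < 0:
        raise InvalidAcquisitionError(f"region DLP must be >= 0, got {dlp}")
    return dlp * factors[region]


def ct_effective_dose(
    ct: CtAcquisition,
    partition: RegionPartition,
    factors: ConversionFactorTable | None = None,
) -> EffectiveDoseResult:
    """CT effective dose: sum of the six regional effective doses.

    Returns a result whose PET component is zero; combine with
    :func:`pet_effective_dose` via :func:`effective_dose` for the full study.
    """
    factors = factors or ConversionFactorTable.icrp102()
    _check_partition(ct, partition)
    dlps = {r: region_dlp(ct, partition, r) for r in REGIONS}
    eds = {r: region_ed(dlps[r], factors, r) for r in REGIONS}
    return EffectiveDoseResult(
        irradiated_length_cm=irradiated_length(ct),
        region_dlp=dlps,
        region_ed=eds,
        ct_ed=sum(eds[r] for r in REGIONS),
    )


def age_to_weighting_factor(
    age_years: float, table: WeightingFactorTable | None = None
) -> float:
    """Dose coefficient (mSv/MBq) for a patient age in years."""
    table = table or WeightingFactorTable.icrp128_fdg()
    return table.factor_for_age(age_years)


def pet_effective_dose(
    pet: PetAcquisition, table: WeightingFactorTable | None = None
) -> float:
    """PET effective dose: injected activity times the age-specific coefficient."""
    return pet.injected_dose_mbq * age_to_weighting_factor(pet.age_years, table)


def total_effective_dose(ct_ed: float, pet_ed: float) -> float:
    """Study effective dose: CT plus PET components."""
    if ct_ed < 0 or pet_ed < 0:
        raise InvalidAcquisitionError("effective doses must be >= 0")
    return ct_ed + pet_ed


def effective_dose(
    ct: CtAcquisition,
    partition: RegionPartition,
    pet: PetAcquisition,
    factors: ConversionFactorTable | None = None,
    weights: WeightingFactorTable | None = None,
) -> EffectiveDoseResult:
    """Full CT + PET effective-dose breakdown for one study."""
    ct_part = ct_effective_dose(ct, partition, factors)
    pet_ed = pet_effective_dose(pet, weights)
    return EffectiveDoseResult(
        irradiated_length_cm=ct_part.irradiated_length_cm,
        region_dlp=ct_part.region_dlp,
        region_ed=ct_part.region_ed,
        ct_ed=ct_part.ct_ed,
        pet_ed=pet_ed,
    )
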