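"""Synthetic study-folder generator with analytic ground truth.

A phantom is a small label volume whose six structures (brain, C1, T1,
liver, left/right hip) are simple boxes placed in correct anatomical order
along the superior-inferior axis, plus matching dose metadata (a CT dose
report and a PET header). The generator records the ground-truth landmark
slices, region partition and effective doses, computed here by straight-line
arithmetic that deliberately shares no code with ``torsodose.dosimetry`` —
so the full pipeline can be verified end to end against an independent
oracle without any external data.

Geometry contract: the brain's most superior voxel sits exactly 4 slices
below the intended top-of-skull boundary, so the skull-top rule recovers it;
vertebrae, liver and hips are placed so each landmark equals the intended
region boundary. Realistic shapes are a non-goal: landmark logic only reads
per-slice voxel extents.

The module also ships the 30-patient method-comparison table (per-patient
PET ED plus CT/total ED for five CT-dosimetry methods) used to validate the
automated calculator against a physician's manual calculation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .dicom_io import CODE_CT_ACQUISITION, CODE_DLP, CODE_MEAN_CTDIVOL, RDSR_SOP_CLASS_UID
from .errors import PhantomSpecError

_REGIONS = ("head", "neck", "chest", "abdomen", "pelvis", "femur")

#: default structure-name -> label-id map written to labels.json
DEFAULT_LABEL_IDS: dict[str, int] = {
    "brain": 1,
    "vertebrae_C1": 2,
    "vertebrae_T1": 3,
    "liver": 4,
    "hip_left": 5,
    "hip_right": 6,
}

#: intended top-of-skull boundary slice; the brain starts 4 slices below it
TOP_OF_SKULL_SLICE = 2

#: methods of the shipped comparison table, as column prefixes
COMPARISON_METHODS = ("automated", "physician", "ct_expo", "wbcf_0.0082", "wbcf_0.015")

PET_IMAGE_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.128"
COMPREHENSIVE_SR_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.88.33"
_FIXTURE_DATE = "20240301"


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to render one synthetic study.

    Defaults emulate a torso scan on the newer-generation scanner of the
    validation cohort: 263 slices split as in a spec'd example partition,
    CTDIvol 2.9 mGy with DLP 308.5 mGy*cm (irradiated length ~106 cm),
    228.3 MBq injected activity, 60-year-old patient.
    """

    region_counts: tuple[int, int, int, int, int, int] = (20, 25, 75, 40, 40, 63)
    plane_shape: tuple[int, int] = (24, 24)
    label_ids: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_IDS))
    ctdi_vol: float = 2.9  # mGy
    dlp: float = 308.5  # mGy*cm
    injected_dose_mbq: float = 228.3
    age_years: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.region_counts)
        object.__setattr__(self, "region_counts", counts)
        if len(counts) != 6:
            raise PhantomSpecError(f"need 6 region counts, got {len(counts)}")
        head, neck, chest, abdomen, pelvis, femur = counts
        if head < TOP_OF_SKULL_SLICE + 5:
            raise PhantomSpecError(
                f"head region needs >= {TOP_OF_SKULL_SLICE + 5} slices to hold a brain "
                f"4 slices below the skull top, got {head}"
            )
        if min(neck, chest, abdomen, pelvis, femur) < 1:
            raise PhantomSpecError(f"every region needs >= 1 slice, got {counts}")
        if min(self.plane_shape) < 8:
            raise PhantomSpecError("in-plane size must be >= 8 voxels")
        missing = [s for s in DEFAULT_LABEL_IDS if s not in self.label_ids]
        if missing:
            raise PhantomSpecError(f"label_ids lacks {missing}")
        if not (self.ctdi_vol > 0 and self.dlp > 0 and self.injected_dose_mbq > 0):
            raise PhantomSpecError("CTDIvol, DLP and injected dose must be > 0")
        if self.age_years < 0:
            raise PhantomSpecError("age must be >= 0")

    @property
    def total_slices(self) -> int:
        return sum(self.region_counts)


@dataclass(frozen=True)
class GroundTruth:
    """Independent analytic truth for one phantom."""

    landmarks: Mapping[str, int]
    region_counts: Mapping[str, int]
    irradiated_length_cm: float
    region_dlp: Mapping[str, float]
    region_ed: Mapping[str, float]
    ct_ed: float
    pet_ed: float
    total_ed: float


def _ground_truth(spec: PhantomSpec, boundaries: Mapping[str, int]) -> GroundTruth:
    # straight-line re-derivation of the dose equations; numbers written out
    # literally so this stays an oracle independent of the dosimetry module
    total = sum(spec.region_counts)
    length = spec.dlp / spec.ctdi_vol
    factors = {
        "head": 0.0021,
        "neck": 0.0059,
        "chest": 0.014,
        "abdomen": 0.015,
        "pelvis": 0.015,
        "femur": 0.015,
    }
    counts = dict(zip(_REGIONS, spec.region_counts))
    dlps = {}
    eds = {}
    ct_ed = 0.0
    for region in _REGIONS:
        part_dlp = (counts[region] / total) * length * spec.ctdi_vol
        dlps[region] = part_dlp
        eds[region] = part_dlp * factors[region]
        ct_ed += eds[region]
    age = spec.age_years
    if age <= 1:
        wf = 0.095
    elif age <= 5:
        wf = 0.056
    elif age <= 10:
        wf = 0.037
    elif age <= 15:
        wf = 0.024
    else:
        wf = 0.019
    pet_ed = spec.injected_dose_mbq * wf
    return GroundTruth(
        landmarks=dict(boundaries),
        region_counts=counts,
        irradiated_length_cm=length,
        region_dlp=dlps,
        region_ed=eds,
        ct_ed=ct_ed,
        pet_ed=pet_ed,
        total_ed=ct_ed + pet_ed,
    )


def _render_labels(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, dict[str, int]]:
    """Canonical (slice, y, x) label array plus the intended boundary slices."""
    head, neck, chest, abdomen, pelvis, femur = spec.region_counts
    total = spec.total_slices
    c1 = head
    t1 = c1 + neck
    hepatic = t1 + chest
    iliac = hepatic + abdomen
    pelvis_bottom = iliac + pelvis  # most inferior hip slice; femur starts here
    boundaries = {
        "top_of_skull": TOP_OF_SKULL_SLICE,
        "c1_boundary": c1,
        "t1_boundary": t1,
        "hepatic_dome": hepatic,
        "iliac_crest": iliac,
        "pelvis_bottom": pelvis_bottom,
        "last_slice": total - 1,
    }
    ny, nx = spec.plane_shape
    labels = np.zeros((total, ny, nx), dtype=np.int16)

    def box(z0: int, z1: int, structure: str, x_range: tuple[int, int] | None = None) -> None:
        # inclusive slice range; jittered in-plane placement
        y0 = int(rng.integers(1, max(2, ny // 3)))
        y1 = int(rng.integers(2 * ny // 3, ny - 1))
        if x_range is None:
            x0 = int(rng.integers(1, max(2, nx // 3)))
            x1 = int(rng.integers(2 * nx // 3, nx - 1))
        else:
            x0, x1 = x_range
        labels[z0 : z1 + 1, y0:y1, x0:x1] = spec.label_ids[structure]

    brain_top = TOP_OF_SKULL_SLICE + 4
    box(brain_top, c1 - 1, "brain")
    box(c1, min(c1 + 1, t1 - 1), "vertebrae_C1")
    box(t1, min(t1 + 1, hepatic - 1), "vertebrae_T1")
    box(hepatic, min(hepatic + max(abdomen // 2, 1), iliac - 1), "liver")
    # hips: left spans the full pelvis, right starts one slice lower so the
    # landmark truly requires the union of both sides
    box(iliac, pelvis_bottom, "hip_left", x_range=(1, nx // 2 - 1))
    box(min(iliac + 1, pelvis_bottom), pelvis_bottom, "hip_right", x_range=(nx // 2 + 1, nx - 1))
    return labels, boundaries


def _write_nifti(labels: np.ndarray, path: Path) -> None:
    # store as (x, y, z) with z inferior -> superior (RAS affine); loaders
    # must reorient to canonical order from the affine. Uncompressed so a
    # fixed seed regenerates byte-identical output.
    arr = np.transpose(labels, (2, 1, 0))[:, :, ::-1]
    affine = np.diag([1.0, 1.0, 3.0, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(arr), affine)
    nib.save(img, str(path))


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(path: Path, sop_class: str, entropy: str) -> FileDataset:
    sop_instance = generate_uid(entropy_srcs=[entropy])
    ds = FileDataset(str(path), {}, file_meta=_file_meta(sop_class, sop_instance),
                     preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    ds.StudyInstanceUID = generate_uid(entropy_srcs=[entropy + "/study"])
    ds.SeriesInstanceUID = generate_uid(entropy_srcs=[entropy + "/series"])
    ds.PatientID = "PHANTOM"
    ds.PatientName = "Phantom^Torso"
    ds.StudyDate = _FIXTURE_DATE
    ds.SeriesDate = _FIXTURE_DATE
    ds.AcquisitionDate = _FIXTURE_DATE
    ds.ContentDate = _FIXTURE_DATE
    return ds


def _num_item(code: str, meaning: str, value: float, units: str) -> Dataset:
    item = Dataset()
    item.ValueType = "NUM"
    item.RelationshipType = "CONTAINS"
    name = Dataset()
    name.CodeValue = code
    name.CodingSchemeDesignator = "DCM"
    name.CodeMeaning = meaning
    item.ConceptNameCodeSequence = [name]
    mv = Dataset()
    mv.NumericValue = str(value)
    unit = Dataset()
    unit.CodeValue = units
    unit.CodingSchemeDesignator = "UCUM"
    unit.CodeMeaning = units
    mv.MeasurementUnitsCodeSequence = [unit]
    item.MeasuredValueSequence = [mv]
    return item


def write_rdsr(
    path: str | Path,
    events: Sequence[Mapping[str, float]],
    seed: int = 0,
) -> Path:
    """Write a minimal radiation-dose SR with one container per event.

    Each event mapping may carry ``ctdi_vol`` (mGy) and/or ``dlp`` (mGy*cm);
    an event without ``dlp`` emulates a localizer. Built directly from coded
    concepts (CT Acquisition / Mean CTDIvol / DLP) of the dose-SR standard.
    """
    path = Path(path)
    ds = _base_dataset(path, RDSR_SOP_CLASS_UID, f"torsodose/rdsr/{seed}")
    ds.Modality = "SR"
    containers = []
    for i, event in enumerate(events):
        container = Dataset()
        container.ValueType = "CONTAINER"
        container.RelationshipType = "CONTAINS"
        name = Dataset()
        name.CodeValue = CODE_CT_ACQUISITION
        name.CodingSchemeDesignator = "DCM"
        name.CodeMeaning = "CT Acquisition"
        container.ConceptNameCodeSequence = [name]
        items = []
        if "ctdi_vol" in event:
            items.append(_num_item(CODE_MEAN_CTDIVOL, "Mean CTDIvol", event["ctdi_vol"], "mGy"))
        if "dlp" in event:
            items.append(_num_item(CODE_DLP, "DLP", event["dlp"], "mGy.cm"))
        container.ContentSequence = items
        containers.append(container)
    ds.ContentSequence = containers
    ds.save_as(str(path), enforce_file_format=True)
    return path


def write_pet_header(
    path: str | Path,
    injected_dose_mbq: float | None,
    age_years: int | None,
    seed: int = 0,
    dose_units: str = "Bq",
) -> Path:
    """Write a minimal PET DICOM header fixture.

    ``injected_dose_mbq=None`` omits the radionuclide-total-dose element and
    ``age_years=None`` omits both the age string and the dates that could
    substitute for it — the two sabotage modes seen in transferred studies.
    """
    path = Path(path)
    ds = _base_dataset(path, PET_IMAGE_SOP_CLASS_UID, f"torsodose/pet/{seed}")
    ds.Modality = "PT"
    info = Dataset()
    info.Radiopharmaceutical = "18F-FDG"
    if injected_dose_mbq is not None:
        if dose_units == "Bq":
            info.RadionuclideTotalDose = injected_dose_mbq * 1e6
        else:
            info.RadionuclideTotalDose = injected_dose_mbq
    ds.RadiopharmaceuticalInformationSequence = [info]
    if age_years is not None:
        ds.PatientAge = f"{min(age_years, 999):03d}Y"
    else:
        del ds.StudyDate, ds.SeriesDate, ds.AcquisitionDate
    ds.save_as(str(path), enforce_file_format=True)
    return path


def generate_phantom(
    spec: PhantomSpec,
    out_dir: str | Path,
    dose_report_format: str = "sidecar",
    drop: Iterable[str] = (),
) -> GroundTruth:
    """Render one study folder and return its analytic ground truth.

    ``dose_report_format`` is ``"sidecar"`` (JSON, default) or ``"sr"``
    (DICOM RDSR). ``drop`` lists sabotage modes: ``"dose_report"`` omits the
    dose report, ``"radionuclide_dose"`` strips the injected activity from
    the PET header, ``"age"`` strips the demographics, and
    ``"structure:<name>"`` erases one structure from the label volume.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    drop = set(drop)
    unknown = {
        d for d in drop
        if d not in {"dose_report", "radionuclide_dose", "age"} and not d.startswith("structure:")
    }
    if unknown:
        raise PhantomSpecError(f"unknown drop option(s): {sorted(unknown)}")

    rng = np.random.default_rng(spec.seed)
    labels, boundaries = _render_labels(spec, rng)
    for d in drop:
        if d.startswith("structure:"):
            name = d.split(":", 1)[1]
            if name not in spec.label_ids:
                raise PhantomSpecError(f"cannot drop unknown structure {name!r}")
            labels[labels == spec.label_ids[name]] = 0

    _write_nifti(labels, out_dir / "segmentation.nii")
    with open(out_dir / "labels.json", "w") as fh:
        json.dump({k: int(v) for k, v in spec.label_ids.items()}, fh, indent=0, sort_keys=True)

    if "dose_report" not in drop:
        if dose_report_format == "sidecar":
            with open(out_dir / "dose_report.json", "w") as fh:
                json.dump(
                    {"schema": "torsodose-ct-dose-sidecar-v1",
                     "ctdi_vol": spec.ctdi_vol, "dlp": spec.dlp},
                    fh, indent=0, sort_keys=True,
                )
        elif dose_report_format == "sr":
            write_rdsr(out_dir / "dose_report.dcm",
                       [{"ctdi_vol": spec.ctdi_vol, "dlp": spec.dlp}], seed=spec.seed)
        else:
            raise PhantomSpecError(f"unknown dose report format {dose_report_format!r}")

    write_pet_header(
        out_dir / "pet_header.dcm",
        None if "radionuclide_dose" in drop else spec.injected_dose_mbq,
        None if "age" in drop else spec.age_years,
        seed=spec.seed,
    )
    return _ground_truth(spec, boundaries)


def random_phantom_spec(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """A realistic randomized phantom: torso scans of 200-450 slices,
    CTDIvol 2-8 mGy, irradiated length 95-115 cm, 150-400 MBq, adult ages."""
    counts = (
        int(rng.integers(15, 31)),
        int(rng.integers(10, 26)),
        int(rng.integers(60, 111)),
        int(rng.integers(30, 61)),
        int(rng.integers(30, 61)),
        int(rng.integers(20, 81)),
    )
    ctdi = float(np.round(rng.uniform(2.0, 8.0), 2))
    length = float(rng.uniform(95.0, 115.0))
    params = dict(
        region_counts=counts,
        ctdi_vol=ctdi,
        dlp=float(np.round(ctdi * length, 1)),
        injected_dose_mbq=float(np.round(rng.uniform(150.0, 400.0), 1)),
        age_years=int(rng.integers(18, 86)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return PhantomSpec(**params)


def load_method_comparison_table() -> pd.DataFrame:
    """The shipped 30-patient method-comparison table.

    Columns: ``patient``, ``pet_ed`` and, for each method in
    :data:`COMPARISON_METHODS`, ``<method>_ct`` and ``<method>_total``
    (all mSv, printed at 2 decimals).
    """
    with resources.files("torsodose.data").joinpath(
        "method_comparison_group1.csv"
    ).open() as fh:
        return pd.read_csv(fh)
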