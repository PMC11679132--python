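"""Dose-report and PET-header parsing plus per-study input discovery.

CT dose metadata is accepted in two dialects:

* a DICOM X-Ray Radiation Dose SR (RDSR), from which per-irradiation-event
  Mean CTDIvol (DCM 113830) and DLP (DCM 113838) are read. Events without a
  DLP (localizers) are ignored; remaining DLPs are summed and CTDIvol is
  their DLP-weighted mean, yielding the single torso-level pair the DLP
  method needs;
* a JSON sidecar ``{"ctdi_vol": <mGy>, "dlp": <mGy*cm>}`` for sites whose
  dose pages exist only as secondary-capture screenshots and must be
  transcribed by hand (sidecar schema v1; extra keys are ignored).

PET metadata comes from any PET DICOM header: injected activity from the
radiopharmaceutical information sequence (values > 1e4 are taken to be Bq
and converted to MBq — the standard stores Bq but vendors vary) and patient
age from the DICOM age string, falling back to birth date vs. acquisition
date.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pydicom
from pydicom.dataset import Dataset

from .dosimetry import CtAcquisition, PetAcquisition
from .errors import (
    MissingAgeError,
    MissingDoseReportError,
    MissingRadionuclideDoseError,
    UnreadableFileError,
)

logger = logging.getLogger(__name__)

#: SOP class of the DICOM X-Ray Radiation Dose SR
RDSR_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.88.67"

#: DCM coded concepts read from the RDSR content tree
CODE_CT_ACQUISITION = "113819"
CODE_MEAN_CTDIVOL = "113830"
CODE_DLP = "113838"

#: parsed injected doses outside this MBq range trigger a unit-suspicion warning
PLAUSIBLE_MBQ = (1.0, 1e4)

#: sidecar files are recognised by carrying both of these keys
SIDECAR_KEYS = ("ctdi_vol", "dlp")


@dataclass
class StudyFolder:
    """Resolved input roles for one study folder."""

    path: Path
    ct_labels: Path | None = None  # multi-label NIfTI or per-structure mask dir
    label_map: Path | None = None  # JSON name->id map (multi-label dialect)
    dose_report: Path | None = None  # RDSR DICOM or JSON sidecar
    pet_header: Path | None = None  # any PET DICOM
    warnings: list[str] = field(default_factory=list)


def _read_dicom(path: Path) -> Dataset:
    try:
        return pydicom.dcmread(str(path), stop_before_pixels=True)
    except Exception as exc:
        raise UnreadableFileError(f"cannot read DICOM {path}: {exc}") from exc


def _iter_content(ds: Dataset):
    """Depth-first walk of an SR content tree."""
    for item in getattr(ds, "ContentSequence", []):
        yield item
        yield from _iter_content(item)


def _concept_code(item: Dataset) -> str | None:
    seq = getattr(item, "ConceptNameCodeSequence", None)
    if seq:
        return str(seq[0].CodeValue)
    return None


def _numeric_value(item: Dataset) -> float | None:
    seq = getattr(item, "MeasuredValueSequence", None)
    if seq:
        try:
            return float(seq[0].NumericValue)
        except (AttributeError, TypeError, ValueError):
            return None
    return None


def _parse_rdsr(ds: Dataset, path: Path) -> CtAcquisition:
    # group measurements by CT-acquisition event container; fall back to one
    # implicit event when the tree is flat
    events: list[dict[str, float]] = []
    containers = [
        item for item in _iter_content(ds) if _concept_code(item) == CODE_CT_ACQUISITION
    ]
    if not containers:
        containers = [ds]
    for container in containers:
        event: dict[str, float] = {}
        for item in _iter_content(container):
            code = _concept_code(item)
            value = _numeric_value(item)
            if value is None:
                continue
            if code == CODE_MEAN_CTDIVOL:
                event["ctdi_vol"] = value
            elif code == CODE_DLP:
                event["dlp"] = value
        if event:
            events.append(event)

    dosed = [e for e in events if e.get("dlp", 0) > 0]
    skipped = len(events) - len(dosed)
    if skipped:
        logger.info("%s: ignored %d irradiation event(s) without DLP", path, skipped)
    if not dosed:
        raise MissingDoseReportError(
            f"dose report {path} carries no irradiation event with a DLP"
        )
    total_dlp = sum(e["dlp"] for e in dosed)
    weighted = [e for e in dosed if e.get("ctdi_vol", 0) > 0]
    if not weighted:
        raise MissingDoseReportError(f"dose report {path} carries no CTDIvol")
    ctdi = sum(e["ctdi_vol"] * e["dlp"] for e in weighted) / sum(
        e["dlp"] for e in weighted
    )
    return CtAcquisition(ctdi_vol=ctdi, dlp=total_dlp)


def _parse_sidecar(path: Path) -> CtAcquisition:
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except Exception as exc:
        raise UnreadableFileError(f"cannot read sidecar {path}: {exc}") from exc
    missing = [k for k in SIDECAR_KEYS if k not in raw]
    if missing:
        raise MissingDoseReportError(f"sidecar {path} lacks {missing}")
    return CtAcquisition(ctdi_vol=float(raw["ctdi_vol"]), dlp=float(raw["dlp"]))


def parse_dose_report(path: str | Path) -> CtAcquisition:
    """Torso-level (CTDIvol, DLP) from an RDSR DICOM or JSON sidecar.

    The returned acquisition has no slice count attached; the pipeline fills
    it in from the label volume.
    """
    path = Path(path)
    if not path.exists():
        raise MissingDoseReportError(f"no dose report at {path}")
    if path.suffix.lower() == ".json":
        return _parse_sidecar(path)
    return _parse_rdsr(_read_dicom(path), path)


def _dose_to_mbq(raw: float, path: Path) -> float:
    """Injected-activity unit heuristic: large values are Bq, else MBq."""
    mbq = raw / 1e6 if raw > 1e4 else raw
    if raw > 1e4:
        logger.info("%s: radionuclide dose %g interpreted as Bq -> %g MBq", path, raw, mbq)
    if not (PLAUSIBLE_MBQ[0] < mbq < PLAUSIBLE_MBQ[1]):
        warnings.warn(
            f"injected dose {mbq:g} MBq from {path} is outside the plausible "
            f"range {PLAUSIBLE_MBQ}; check the stored units",
            stacklevel=3,
        )
    return mbq


def _parse_age_string(value: str) -> int | None:
    value = value.strip().upper()
    if len(value) < 2 or value[-1] not in "DWMY" or not value[:-1].isdigit():
        return None
    n = int(value[:-1])
    per_year = {"D": 365.25, "W": 52.18, "M": 12.0, "Y": 1.0}[value[-1]]
    return int(n / per_year)


def _parse_dicom_date(value: str) -> _dt.date | None:
    try:
        return _dt.datetime.strptime(value.strip()[:8], "%Y%m%d").date()
    except (ValueError, AttributeError):
        return None


def _age_from_dates(ds: Dataset) -> int | None:
    born = _parse_dicom_date(getattr(ds, "PatientBirthDate", "") or "")
    if born is None:
        return None
    for tag in ("AcquisitionDate", "SeriesDate", "StudyDate"):
        scanned = _parse_dicom_date(getattr(ds, tag, "") or "")
        if scanned is not None:
            years = scanned.year - born.year
            if (scanned.month, scanned.day) < (born.month, born.day):
                years -= 1
            return max(years, 0)
    return None


def parse_pet_header(path: str | Path) -> PetAcquisition:
    """Injected activity (MBq) and patient age (whole years) from a PET header."""
    path = Path(path)
    if not path.exists():
        raise MissingRadionuclideDoseError(f"no PET header at {path}")
    ds = _read_dicom(path)

    seq = getattr(ds, "RadiopharmaceuticalInformationSequence", None)
    if not seq:
        raise MissingRadionuclideDoseError(
            f"{path} lacks the radiopharmaceutical information sequence"
        )
    info = seq[0]
    raw = getattr(info, "RadionuclideTotalDose", None)
    if raw in (None, "") or float(raw) <= 0:
        raise MissingRadionuclideDoseError(f"{path} carries no radionuclide total dose")
    dose_mbq = _dose_to_mbq(float(raw), path)
    label = str(getattr(info, "Radiopharmaceutical", "") or "18F-FDG")

    age = None
    age_str = getattr(ds, "PatientAge", None)
    if age_str:
        age = _parse_age_string(str(age_str))
    if age is None:
        age = _age_from_dates(ds)
    if age is None:
        raise MissingAgeError(f"{path} provides neither an age string nor usable dates")
    return PetAcquisition(injected_dose_mbq=dose_mbq, age_years=age, radiopharmaceutical=label)


def _json_role(path: Path) -> str:
    """Classify a JSON file as dose sidecar or label map by its keys."""
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except Exception:
        return "unknown"
    if isinstance(raw, dict) and all(k in raw for k in SIDECAR_KEYS):
        return "sidecar"
    if isinstance(raw, dict) and raw and all(
        isinstance(v, int) and not isinstance(v, bool) for v in raw.values()
    ):
        return "label_map"
    return "unknown"


def _dicom_role(path: Path) -> str:
    try:
        ds = pydicom.dcmread(str(path), stop_before_pixels=True,
                             specific_tags=["Modality", "SOPClassUID"])
    except Exception:
        return "unknown"
    sop = str(getattr(ds, "SOPClassUID", ""))
    modality = str(getattr(ds, "Modality", ""))
    if sop == RDSR_SOP_CLASS_UID or modality == "SR":
        return "dose_report"
    if modality == "PT":
        return "pet_header"
    return "unknown"


def _assign(folder: StudyFolder, role: str, candidates: list[Path]) -> None:
    if not candidates:
        return
    candidates = sorted(candidates)
    if len(candidates) > 1:
        msg = (
            f"{len(candidates)} candidates for role {role!r}; "
            f"using {candidates[0].name} (lexicographic tie-break)"
        )
        folder.warnings.append(msg)
        logger.warning("%s: %s", folder.path, msg)
    setattr(folder, role, candidates[0])


def discover_inputs(folder: str | Path) -> StudyFolder:
    """Deterministically assign the files in a study folder to input roles.

    Roles: ``ct_labels`` (multi-label NIfTI, or a subdirectory of
    per-structure masks), ``label_map`` (JSON name->id map), ``dose_report``
    (RDSR or sidecar), ``pet_header`` (PET DICOM). Ties break
    lexicographically with a logged warning; absent roles stay ``None`` so
    the pipeline can map each to its failure code without aborting a batch.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise UnreadableFileError(f"{folder} is not a readable folder")
    study = StudyFolder(path=folder)
    by_role: dict[str, list[Path]] = {
        "ct_labels": [], "label_map": [], "dose_report": [], "pet_header": []
    }
    for entry in sorted(folder.iterdir()):
        if entry.is_dir():
            if any(p.name.endswith((".nii", ".nii.gz")) for p in entry.iterdir()):
                by_role["ct_labels"].append(entry)
        elif entry.name.endswith((".nii", ".nii.gz")):
            by_role["ct_labels"].append(entry)
        elif entry.suffix.lower() == ".json":
            role = _json_role(entry)
            if role == "sidecar":
                by_role["dose_report"].append(entry)
            elif role == "label_map":
                by_role["label_map"].append(entry)
        else:
            role = _dicom_role(entry)
            if role in by_role:
                by_role[role].append(entry)
    for role, candidates in by_role.items():
        _assign(study, role, candidates)
    return study
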