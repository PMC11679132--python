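"""Batch orchestration: discover -> parse -> landmarks -> partition -> doses.

Each study folder is processed independently and deterministically; any
failure is mapped to exactly one reason code in its report row, so a batch
never aborts on a single bad study and the summary can report a failure
histogram alongside the success rate.
"""

from __future__ import annotations

import dataclasses
import json
import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .dicom_io import discover_inputs, parse_dose_report, parse_pet_header
from .dosimetry import REGIONS, effective_dose
from .errors import (
    MissingDoseReportError,
    MissingRadionuclideDoseError,
    MissingStructureError,
    TorsodoseError,
    UnreadableFileError,
)
from .landmarks import (
    StructureLabelVolume,
    extract_landmarks,
    load_label_map,
    partition_torso,
)

#: the closed set of per-study failure reason codes
REASON_CODES = (
    "missing_dose_report",
    "missing_radionuclide_dose",
    "missing_age",
    "missing_structure",
    "anatomy_inconsistency",
    "unreadable_file",
)


@dataclass
class StudyRow:
    """One line of a batch report."""

    study_id: str
    status: str  # "ok" | "failed"
    reason: str | None = None
    detail: str | None = None
    irradiated_length_cm: float | None = None
    region_ed: dict[str, float] = field(default_factory=dict)  # mSv
    ct_ed: float | None = None
    pet_ed: float | None = None
    total_ed: float | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class BatchReport:
    rows: list[StudyRow]

    @property
    def n_ok(self) -> int:
        return sum(r.status == "ok" for r in self.rows)

    @property
    def n_failed(self) -> int:
        return sum(r.status == "failed" for r in self.rows)

    @property
    def success_percent(self) -> float:
        return 100.0 * self.n_ok / len(self.rows) if self.rows else 0.0

    @property
    def reason_histogram(self) -> dict[str, int]:
        hist: dict[str, int] = {}
        for r in self.rows:
            if r.status == "failed" and r.reason:
                hist[r.reason] = hist.get(r.reason, 0) + 1
        return hist

    def summary(self) -> dict:
        return {
            "n_studies": len(self.rows),
            "n_ok": self.n_ok,
            "n_failed": self.n_failed,
            "success_percent": self.success_percent,
            "failure_reasons": self.reason_histogram,
        }

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            rec: dict = {
                "study_id": r.study_id,
                "status": r.status,
                "reason": r.reason or "",
                "irradiated_length_cm": r.irradiated_length_cm,
            }
            for region in REGIONS:
                rec[f"{region}_ed"] = r.region_ed.get(region)
            rec["ct_ed"] = r.ct_ed
            rec["pet_ed"] = r.pet_ed
            rec["total_ed"] = r.total_ed
            rec["warnings"] = "; ".join(r.warnings)
            rec["detail"] = r.detail or ""
            records.append(rec)
        return pd.DataFrame(records)

    def to_csv(self, path: str | Path | None = None) -> str:
        """CSV body with doses rounded to 2 decimals (presentation precision)."""
        text = self.to_dataframe().to_csv(index=False, float_format="%.2f")
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_json(self, path: str | Path | None = None) -> str:
        """Full-precision JSON: summary plus one object per study."""
        payload = {
            "summary": self.summary(),
            "studies": [dataclasses.asdict(r) for r in self.rows],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_volume(study, config: PipelineConfig, label_map_path) -> StructureLabelVolume:
    if study.ct_labels is None:
        raise MissingStructureError("label_volume", "no segmentation found in folder")
    if study.ct_labels.is_dir():
        return StructureLabelVolume.from_mask_directory(study.ct_labels)
    lm_path = label_map_path or study.label_map
    if lm_path is None:
        raise UnreadableFileError(
            f"{study.ct_labels.name} is a multi-label volume but no label map "
            "(JSON name->id) was found"
        )
    return StructureLabelVolume.from_nifti(study.ct_labels, load_label_map(lm_path))


def _maybe_segment(study, config: PipelineConfig, segment: bool) -> None:
    """Optional hook: shell out to an external segmentation tool.

    Disabled unless both the flag and ``config.segment_command`` are set;
    the command template receives ``{folder}`` and ``{out}``.
    """
    if not segment or study.ct_labels is not None or not config.segment_command:
        return
    out = study.path / "segmentation"
    cmd = config.segment_command.format(folder=study.path, out=out)
    subprocess.run(cmd, shell=True, check=True)
    refreshed = discover_inputs(study.path)
    study.ct_labels = refreshed.ct_labels
    study.label_map = refreshed.label_map


def run_study(
    folder: str | Path,
    config: PipelineConfig | None = None,
    label_map_path: str | Path | None = None,
    segment: bool = False,
) -> StudyRow:
    """Process one study folder into a report row; never raises per-study errors."""
    config = config or PipelineConfig()
    folder = Path(folder)
    row = StudyRow(study_id=folder.name, status="failed")
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            study = discover_inputs(folder)
            row.warnings.extend(study.warnings)
            _maybe_segment(study, config, segment)
            vol = _load_volume(study, config, label_map_path)

            if study.dose_report is None:
                raise MissingDoseReportError(f"no dose report in {folder}")
            ct = parse_dose_report(study.dose_report)
            ct = dataclasses.replace(ct, n_slices=vol.n_slices)

            if study.pet_header is None:
                raise MissingRadionuclideDoseError(f"no PET header in {folder}")
            pet = parse_pet_header(study.pet_header)

            landmarks = extract_landmarks(vol, boundary_rule=config.boundary_rule)
            partition = partition_torso(
                landmarks, vol.n_slices, head_margin_warning=config.head_margin_warning
            )
            result = effective_dose(
                ct, partition, pet,
                factors=config.conversion_factors,
                weights=config.weighting_factors,
            )
        row.warnings.extend(str(w.message) for w in caught)
        row.status = "ok"
        row.irradiated_length_cm = result.irradiated_length_cm
        row.region_ed = dict(result.region_ed)
        row.ct_ed = result.ct_ed
        row.pet_ed = result.pet_ed
        row.total_ed = result.total_ed
    except TorsodoseError as exc:
        row.status = "failed"
        row.reason = exc.reason or "unreadable_file"
        row.detail = str(exc)
    return row


def run_batch(
    root: str | Path,
    config: PipelineConfig | None = None,
    label_map_path: str | Path | None = None,
    segment: bool = False,
) -> BatchReport:
    """Process every immediate subfolder of ``root`` (sorted by name)."""
    root = Path(root)
    if not root.is_dir():
        raise UnreadableFileError(f"{root} is not a readable folder")
    folders = sorted(p for p in root.iterdir() if p.is_dir())
    if not folders:
        warnings.warn(f"no study folders under {root}", stacklevel=2)
    rows = [run_study(f, config, label_map_path=label_map_path, segment=segment)
            for f in folders]
    return BatchReport(rows=rows)
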