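"""Anatomical landmark extraction from a multi-structure segmentation volume.

A torso CT's companion segmentation (TotalSegmentator structure names) is
reduced to six boundary landmarks along the superior-inferior axis, which in
turn define the six-region partition consumed by the DLP dosimetry:

======== ==========================================================
region   canonical slice range (half-open, index 0 = most superior)
======== ==========================================================
head     [0, c1_boundary)
neck     [c1_boundary, t1_boundary)
chest    [t1_boundary, hepatic_dome)
abdomen  [hepatic_dome, iliac_crest)
pelvis   [iliac_crest, pelvis_bottom)
femur    [pelvis_bottom, n_slices)
======== ==========================================================

Boundary definitions: the C1/T1 boundaries default to the most superior
slice of the vertebra (configurable), the hepatic dome is the most superior
liver slice, the iliac crest is the most superior slice of the merged
left+right hip, and the pelvis bottom is the most inferior merged-hip slice.
The top of the skull is taken as 4 slices above the most superior brain
slice — the skull label itself is never used, because arm-raised
acquisitions can mislabel the radius as skull. Each landmark slice opens
the region inferior to it, so the ranges tile the scan exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import nibabel as nib
import numpy as np

from .dosimetry import REGIONS, RegionPartition
from .errors import (
    AnatomyInconsistencyError,
    ConfigurationError,
    MissingStructureError,
    UnreadableFileError,
)

#: structures every study must resolve
REQUIRED_STRUCTURES = (
    "brain",
    "vertebrae_C1",
    "vertebrae_T1",
    "liver",
    "hip_left",
    "hip_right",
)

#: slices added above the first brain slice to reach the top of the skull
SKULL_OFFSET_SLICES = 4

BoundaryRule = Literal["superior", "inferior", "centroid"]


class StructureLabelVolume:
    """A 3D label image in canonical orientation plus its name -> id map.

    Canonical orientation: axis 0 indexes axial slices with index 0 the most
    superior slice. Constructors accept any axis order/direction and reorient
    on load, so all landmark logic can speak anatomically.
    """

    def __init__(self, labels: np.ndarray, label_map: Mapping[str, int]):
        labels = np.asarray(labels)
        if labels.ndim != 3:
            raise ConfigurationError(f"label volume must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ConfigurationError(f"label volume must be integer-typed, got {labels.dtype}")
        if labels.size and labels.min() < 0:
            raise ConfigurationError("label ids must be non-negative")
        bad = {k: v for k, v in label_map.items() if int(v) <= 0}
        if bad:
            raise ConfigurationError(f"label ids must be positive integers: {bad}")
        self.labels = labels
        self.label_map = {str(k): int(v) for k, v in label_map.items()}

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    @classmethod
    def from_array(
        cls,
        labels: np.ndarray,
        label_map: Mapping[str, int],
        superior_axis: int = 0,
        superior_is_first: bool = True,
    ) -> "StructureLabelVolume":
        """Build from an arbitrarily oriented array.

        ``superior_axis`` is the array axis running superior-inferior;
        ``superior_is_first`` says whether index 0 on that axis is the most
        superior slice (if False the axis is flipped on load).
        """
        arr = np.moveaxis(np.asarray(labels), superior_axis, 0)
        if not superior_is_first:
            arr = arr[::-1]
        return cls(np.ascontiguousarray(arr), label_map)

    @classmethod
    def from_nifti(
        cls, path: str | Path, label_map: Mapping[str, int]
    ) -> "StructureLabelVolume":
        """Load a multi-label NIfTI volume, reorienting via its affine.

        The affine's axis codes identify which array axis runs
        superior-inferior and in which direction; the volume is reoriented to
        canonical order regardless of how it was stored.
        """
        try:
            img = nib.load(str(path))
            axcodes = nib.aff2axcodes(img.affine)
            data = np.asanyarray(img.dataobj)
        except Exception as exc:
            raise UnreadableFileError(f"cannot read NIfTI {path}: {exc}") from exc
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise ConfigurationError(f"{path} does not hold integer labels")
            data = rounded.astype(np.int32)
        for axis, code in enumerate(axcodes):
            if code in ("S", "I"):
                return cls.from_array(
                    data, label_map, superior_axis=axis, superior_is_first=(code == "I")
                )
        raise ConfigurationError(
            f"cannot identify the superior-inferior axis of {path} (axcodes {axcodes})"
        )

    @classmethod
    def from_mask_directory(cls, path: str | Path) -> "StructureLabelVolume":
        """Compose per-structure binary NIfTI masks (one file per structure).

        Files are named ``<structure>.nii[.gz]``; ids are assigned in sorted
        filename order. Overlapping masks resolve to the later id.
        """
        path = Path(path)
        files = sorted(
            p for p in path.iterdir() if p.name.endswith((".nii", ".nii.gz"))
        )
        if not files:
            raise UnreadableFileError(f"no NIfTI masks in {path}")
        labels = None
        label_map: dict[str, int] = {}
        for i, f in enumerate(files, start=1):
            name = f.name[: -len(".nii.gz")] if f.name.endswith(".nii.gz") else f.stem
            vol = cls.from_nifti(f, {name: 1})
            mask = vol.labels > 0
            if labels is None:
                labels = np.zeros(mask.shape, dtype=np.int32)
            elif mask.shape != labels.shape:
                raise ConfigurationError(
                    f"mask {f.name} shape {mask.shape} differs from {labels.shape}"
                )
            labels[mask] = i
            label_map[name] = i
        return cls(labels, label_map)

    def slice_presence(self, name: str) -> np.ndarray:
        """Boolean per canonical slice: does the slice contain the structure?"""
        if name not in self.label_map:
            raise MissingStructureError(name, "not in label map")
        return (self.labels == self.label_map[name]).any(axis=(1, 2))


@dataclass(frozen=True)
class LandmarkSet:
    """The six boundary slice indices, canonical order (0 = most superior)."""

    top_of_skull: int
    c1_boundary: int
    t1_boundary: int
    hepatic_dome: int
    iliac_crest: int
    pelvis_bottom: int
    last_slice: int

    def __post_init__(self) -> None:
        ordered = (
            ("top_of_skull", self.top_of_skull),
            ("c1_boundary", self.c1_boundary),
            ("t1_boundary", self.t1_boundary),
            ("hepatic_dome", self.hepatic_dome),
            ("iliac_crest", self.iliac_crest),
            ("pelvis_bottom", self.pelvis_bottom),
            ("last_slice", self.last_slice),
        )
        if self.top_of_skull < 0:
            raise AnatomyInconsistencyError("top_of_skull below 0")
        for (na, va), (nb, vb) in zip(ordered, ordered[1:]):
            if va > vb:
                raise AnatomyInconsistencyError(
                    f"landmark order violated: {na} (slice {va}) is inferior to {nb} (slice {vb})"
                )


def structure_extent(vol: StructureLabelVolume, name: str) -> tuple[int, int]:
    """(most superior, most inferior) canonical slice indices of a structure."""
    present = vol.slice_presence(name)
    idx = np.flatnonzero(present)
    if idx.size == 0:
        raise MissingStructureError(name)
    return int(idx[0]), int(idx[-1])


def merge_hips(vol: StructureLabelVolume) -> tuple[int, int]:
    """Extent of the left+right hip union (the single "hip" entity).

    Degrades to the present side with a warning if one hip is missing;
    raises if both are absent.
    """
    extents = []
    missing = []
    for side in ("hip_left", "hip_right"):
        try:
            extents.append(structure_extent(vol, side))
        except MissingStructureError:
            missing.append(side)
    if not extents:
        raise MissingStructureError("hip", "both hip_left and hip_right absent")
    if missing:
        warnings.warn(
            f"{missing[0]} absent; hip extent taken from the remaining side only",
            stacklevel=2,
        )
    return min(e[0] for e in extents), max(e[1] for e in extents)


def top_of_skull(vol: StructureLabelVolume) -> int:
    """Top of the skull: 4 slices above the most superior brain slice.

    Clamped to slice 0 (with a warning) when the scan starts fewer than 4
    slices above the brain.
    """
    brain_top, _ = structure_extent(vol, "brain")
    if brain_top < SKULL_OFFSET_SLICES:
        if brain_top > 0:
            warnings.warn(
                f"only {brain_top} slices above the brain; top of skull clamped to slice 0",
                stacklevel=2,
            )
        return 0
    return brain_top - SKULL_OFFSET_SLICES


def _vertebra_boundary(
    vol: StructureLabelVolume, name: str, rule: BoundaryRule
) -> int:
    sup, inf = structure_extent(vol, name)
    if rule == "superior":
        return sup
    if rule == "inferior":
        return inf
    if rule == "centroid":
        return (sup + inf) // 2
    raise ConfigurationError(f"unknown boundary rule {rule!r}")


def extract_landmarks(
    vol: StructureLabelVolume, boundary_rule: BoundaryRule = "superior"
) -> LandmarkSet:
    """All six region boundaries from the label volume.

    ``boundary_rule`` selects which slice of the C1/T1 vertebrae acts as the
    boundary (superior is the default; institutions may prefer inferior or
    centroid). Raises :class:`MissingStructureError` naming the first absent
    structure and :class:`AnatomyInconsistencyError` if the landmarks are out
    of superior-to-inferior order.
    """
    skull = top_of_skull(vol)
    c1 = _vertebra_boundary(vol, "vertebrae_C1", boundary_rule)
    t1 = _vertebra_boundary(vol, "vertebrae_T1", boundary_rule)
    liver_top, _ = structure_extent(vol, "liver")
    hip_top, hip_bottom = merge_hips(vol)
    return LandmarkSet(
        top_of_skull=skull,
        c1_boundary=c1,
        t1_boundary=t1,
        hepatic_dome=liver_top,
        iliac_crest=hip_top,
        pelvis_bottom=hip_bottom,
        last_slice=vol.n_slices - 1,
    )


def partition_torso(
    landmarks: LandmarkSet,
    total_slices: int,
    head_margin_warning: int = 10,
) -> RegionPartition:
    """Six contiguous half-open slice ranges covering the whole scan.

    Each landmark slice begins the region inferior to it, so counts always
    sum to ``total_slices``. Slices superior to the computed top of the skull
    stay in the head region; if more than ``head_margin_warning`` such slices
    exist a QC warning is emitted (the scan may start well above the head).
    """
    if total_slices < 1:
        raise ConfigurationError(f"total_slices must be >= 1, got {total_slices}")
    if landmarks.last_slice != total_slices - 1:
        raise ConfigurationError(
            f"landmarks were extracted from a {landmarks.last_slice + 1}-slice volume, "
            f"not {total_slices}"
        )
    if landmarks.top_of_skull > head_margin_warning:
        warnings.warn(
            f"{landmarks.top_of_skull} slices above the computed top of the skull "
            "are included in the head region; check the scan range",
            stacklevel=2,
        )
    bounds = [
        0,
        landmarks.c1_boundary,
        landmarks.t1_boundary,
        landmarks.hepatic_dome,
        landmarks.iliac_crest,
        landmarks.pelvis_bottom,
        total_slices,
    ]
    counts = {r: bounds[i + 1] - bounds[i] for i, r in enumerate(REGIONS)}
    return RegionPartition(counts)


def load_label_map(path: str | Path) -> dict[str, int]:
    """Read a JSON structure-name -> label-id map."""
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except Exception as exc:
        raise UnreadableFileError(f"cannot read label map {path}: {exc}") from exc
    if not isinstance(raw, dict) or not all(
        isinstance(v, int) and not isinstance(v, bool) for v in raw.values()
    ):
        raise ConfigurationError(f"{path} is not a name->integer label map")
    return {str(k): int(v) for k, v in raw.items()}
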