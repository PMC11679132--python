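"""Landmark extraction and the six-region torso partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torsodose.dosimetry import REGIONS
from torsodose.errors import (
    AnatomyInconsistencyError,
    ConfigurationError,
    MissingStructureError,
)
from torsodose.landmarks import (
    LandmarkSet,
    StructureLabelVolume,
    extract_landmarks,
    merge_hips,
    partition_torso,
    structure_extent,
    top_of_skull,
)

LABELS = {
    "brain": 1,
    "vertebrae_C1": 2,
    "vertebrae_T1": 3,
    "liver": 4,
    "hip_left": 5,
    "hip_right": 6,
}


def make_volume(n_slices: int, placements: dict[str, tuple[int, int]]) -> StructureLabelVolume:
    """Canonical volume with each structure filling its inclusive slice range."""
    arr = np.zeros((n_slices, 8, 8), dtype=np.int16)
    for name, (lo, hi) in placements.items():
        arr[lo : hi + 1, 2:6, 2:6] = LABELS[name]
    return StructureLabelVolume(arr, LABELS)


class TestStructureExtent:
    def test_extent_of_a_slab(self):
        vol = make_volume(64, {"brain": (4, 40)})
        assert structure_extent(vol, "brain") == (4, 40)

    def test_single_slice_structure(self):
        vol = make_volume(64, {"liver": (17, 17)})
        assert structure_extent(vol, "liver") == (17, 17)

    def test_matches_exhaustive_voxel_scan_on_random_sparse_volumes(self):
        rng = np.random.default_rng(1234)
        for _ in range(10):
            shape = tuple(rng.integers(8, 33, size=3))
            arr = np.zeros(shape, dtype=np.int16)
            voxels = rng.integers(0, shape, size=(30, 3))
            arr[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = LABELS["brain"]
            vol = StructureLabelVolume(arr, LABELS)
            # brute force over every voxel
            hits = [
                z
                for z in range(shape[0])
                for y in range(shape[1])
                for x in range(shape[2])
                if arr[z, y, x] == LABELS["brain"]
            ]
            assert structure_extent(vol, "brain") == (min(hits), max(hits))

    def test_absent_structure_error_names_it(self):
        vol = make_volume(16, {"brain": (0, 3)})
        with pytest.raises(MissingStructureError, match="liver"):
            structure_extent(vol, "liver")


class TestMergeHips:
    def test_union_of_overlapping_ranges(self):
        vol = make_volume(160, {"hip_left": (100, 140), "hip_right": (102, 143)})
        assert merge_hips(vol) == (100, 143)

    def test_identical_ranges(self):
        vol = make_volume(160, {"hip_left": (100, 140), "hip_right": (100, 140)})
        assert merge_hips(vol) == (100, 140)

    def test_single_side_degrades_with_warning(self):
        vol = make_volume(160, {"hip_left": (100, 140)})
        with pytest.warns(UserWarning, match="hip_right absent"):
            assert merge_hips(vol) == (100, 140)

    def test_both_sides_absent_is_fatal(self):
        vol = make_volume(160, {"brain": (0, 5)})
        with pytest.raises(MissingStructureError, match="hip"):
            merge_hips(vol)


class TestTopOfSkull:
    def test_four_slices_above_the_brain(self):
        vol = make_volume(64, {"brain": (10, 20)})
        assert top_of_skull(vol) == 6

    def test_clamped_to_first_slice_with_warning(self):
        vol = make_volume(64, {"brain": (2, 20)})
        with pytest.warns(UserWarning, match="clamped"):
            assert top_of_skull(vol) == 0

    def test_exactly_four_slices_above_needs_no_clamp(self):
        vol = make_volume(64, {"brain": (4, 20)})
        assert top_of_skull(vol) == 0


FULL_PLACEMENTS = {
    "brain": (6, 18),
    "vertebrae_C1": (20, 22),
    "vertebrae_T1": (45, 47),
    "liver": (120, 140),
    "hip_left": (160, 200),
    "hip_right": (161, 199),
}


class TestExtractLandmarks:
    def test_boundaries_from_structure_extents(self):
        vol = make_volume(263, FULL_PLACEMENTS)
        lm = extract_landmarks(vol)
        assert lm == LandmarkSet(
            top_of_skull=2,
            c1_boundary=20,
            t1_boundary=45,
            hepatic_dome=120,
            iliac_crest=160,
            pelvis_bottom=200,
            last_slice=262,
        )

    def test_boundary_rule_selects_vertebra_slice(self):
        vol = make_volume(263, FULL_PLACEMENTS)
        assert extract_landmarks(vol, "inferior").c1_boundary == 22
        assert extract_landmarks(vol, "centroid").c1_boundary == 21
        with pytest.raises(ConfigurationError):
            extract_landmarks(vol, "sagittal")

    def test_liver_above_t1_is_an_anatomy_inconsistency(self):
        placements = dict(FULL_PLACEMENTS, liver=(30, 40))
        vol = make_volume(263, placements)
        with pytest.raises(AnatomyInconsistencyError, match="hepatic_dome"):
            extract_landmarks(vol)

    def test_missing_vertebra_names_the_structure(self):
        placements = {k: v for k, v in FULL_PLACEMENTS.items() if k != "vertebrae_T1"}
        vol = make_volume(263, placements)
        with pytest.raises(MissingStructureError, match="vertebrae_T1"):
            extract_landmarks(vol)

    def test_recovers_generator_ground_truth(self, phantom_study):
        from torsodose.landmarks import load_label_map

        folder, _, gt = phantom_study
        vol = StructureLabelVolume.from_nifti(
            folder / "segmentation.nii", load_label_map(folder / "labels.json")
        )
        lm = extract_landmarks(vol)
        assert {
            "top_of_skull": lm.top_of_skull,
            "c1_boundary": lm.c1_boundary,
            "t1_boundary": lm.t1_boundary,
            "hepatic_dome": lm.hepatic_dome,
            "iliac_crest": lm.iliac_crest,
            "pelvis_bottom": lm.pelvis_bottom,
            "last_slice": lm.last_slice,
        } == dict(gt.landmarks)


class TestPartitionTorso:
    def test_half_open_ranges_count_correctly(self):
        lm = LandmarkSet(6, 20, 45, 120, 160, 200, 262)
        part = partition_torso(lm, 263)
        assert [part.counts[r] for r in REGIONS] == [20, 25, 75, 40, 40, 63]
        assert part.total == 263

    def test_degenerate_landmarks_put_everything_in_the_femur(self):
        lm = LandmarkSet(0, 0, 0, 0, 0, 0, 99)
        part = partition_torso(lm, 100)
        assert part.counts["femur"] == 100
        assert part.total == 100

    def test_large_head_margin_triggers_qc_warning(self):
        lm = LandmarkSet(15, 30, 45, 120, 160, 200, 262)
        with pytest.warns(UserWarning, match="above the computed top of the skull"):
            partition_torso(lm, 263)

    def test_landmarks_from_a_different_volume_rejected(self):
        lm = LandmarkSet(6, 20, 45, 120, 160, 200, 262)
        with pytest.raises(ConfigurationError):
            partition_torso(lm, 300)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(data=st.data())
    def test_counts_always_sum_to_total(self, data):
        total = data.draw(st.integers(10, 400))
        cuts = sorted(data.draw(
            st.lists(st.integers(0, total - 1), min_size=5, max_size=5)
        ))
        lm = LandmarkSet(0, *cuts, total - 1)
        part = partition_torso(lm, total, head_margin_warning=total)
        assert part.total == total
        assert all(c >= 0 for c in part.counts.values())


class TestOrientationHandling:
    def test_partition_invariant_under_axis_flip_and_permutation(self):
        canonical = make_volume(263, FULL_PLACEMENTS).labels
        reference = partition_torso(
            extract_landmarks(StructureLabelVolume(canonical, LABELS)), 263
        )
        flipped = StructureLabelVolume.from_array(
            canonical[::-1], LABELS, superior_axis=0, superior_is_first=False
        )
        moved = StructureLabelVolume.from_array(
            np.moveaxis(canonical, 0, 2), LABELS, superior_axis=2, superior_is_first=True
        )
        moved_flipped = StructureLabelVolume.from_array(
            np.moveaxis(canonical[::-1], 0, 1), LABELS, superior_axis=1, superior_is_first=False
        )
        for vol in (flipped, moved, moved_flipped):
            assert partition_torso(extract_landmarks(vol), 263).counts == reference.counts

    def test_nifti_round_trip_preserves_canonical_order(self, tmp_path):
        import nibabel as nib

        canonical = make_volume(64, {"brain": (6, 12)}).labels
        # store inferior-first along z (RAS affine): loader must flip
        arr = np.transpose(canonical, (2, 1, 0))[:, :, ::-1]
        path = tmp_path / "vol.nii"
        nib.save(nib.Nifti1Image(arr, np.diag([1.0, 1.0, 3.0, 1.0])), str(path))
        vol = StructureLabelVolume.from_nifti(path, LABELS)
        assert structure_extent(vol, "brain") == (6, 12)
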