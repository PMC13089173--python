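import numpy as np
import pytest

from beamsel import (
    StructureMask,
    VoxelVolume,
    average_intensity_projection,
    expand_margin,
    read_mask,
    read_volume,
    union_masks,
    write_mask,
    write_volume,
)
from beamsel.volumes import itv_from_gtvs


def brute_force_expand(mask: StructureMask, margin_mm: float) -> np.ndarray:
    """Oracle: voxel centers within margin (Euclidean, physical mm) of an input center."""
    sp = mask.spacing_mm
    src = np.argwhere(mask.data) * sp
    out = np.zeros(mask.shape, dtype=bool)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * sp
        if np.any(np.sum((src - p) ** 2, axis=1) <= margin_mm**2 + 1e-9):
            out[idx] = True
    return out


class TestNiftiIO:
    def test_volume_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = VoxelVolume(rng.normal(size=(7, 8, 9)) * 500, (1.0, 1.5, 2.5), (-3.0, 4.0, 10.0))
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        assert np.array_equal(back.data, vol.data)
        assert np.allclose(back.spacing_mm, vol.spacing_mm)
        assert np.allclose(back.origin_mm, vol.origin_mm)

    def test_mask_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        mask = StructureMask(rng.random((6, 6, 6)) > 0.5, (2, 2, 2), (0, 0, 0), role="heart")
        path = tmp_path / "mask.nii.gz"
        write_mask(mask, path)
        back = read_mask(path, role="heart")
        assert np.array_equal(back.data, mask.data)

    def test_non_axis_aligned_orientation_rejected(self, tmp_path):
        import nibabel as nib

        theta = np.radians(10)
        aff = np.eye(4)
        aff[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        path = tmp_path / "oblique.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4)), aff), path)
        with pytest.raises(ValueError, match="non-axis-aligned"):
            read_volume(path)

    def test_unreadable_file_rejected(self, tmp_path):
        path = tmp_path / "junk.nii"
        path.write_bytes(b"not an image")
        with pytest.raises(ValueError, match="unreadable"):
            read_volume(path)


class TestDicomSeries:
    @staticmethod
    def _write_slice(path, z, arr, spacing=(1.0, 1.0)):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.Rows, ds.Columns = arr.shape
        ds.PixelSpacing = [spacing[0], spacing[1]]  # [row=y, col=x]
        ds.ImagePositionPatient = [0.0, 0.0, float(z)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = arr.astype(np.int16).tobytes()
        ds.save_as(str(path), enforce_file_format=True)

    def test_series_read(self, tmp_path):
        rng = np.random.default_rng(2)
        raw = rng.integers(0, 3000, size=(5, 6, 4))  # [row=y, col=x, z]
        for k in range(raw.shape[2]):
            self._write_slice(tmp_path / f"ct_{k:03d}.dcm", 2.0 * k, raw[:, :, k])
        vol = read_volume(tmp_path)
        assert vol.shape == (6, 5, 4)  # (x, y, z)
        assert np.allclose(vol.spacing_mm, (1.0, 1.0, 2.0))
        expected = raw.transpose(1, 0, 2).astype(float) - 1024.0
        assert np.array_equal(vol.data, expected)

    def test_missing_slice_names_the_gap(self, tmp_path):
        arr = np.zeros((4, 4), dtype=np.int16)
        for z in (0.0, 2.0, 6.0, 8.0):  # slice at z=4 missing
            self._write_slice(tmp_path / f"ct_{z:.0f}.dcm", z, arr)
        with pytest.raises(ValueError, match=r"z = 2.0+ and z = 6.0+"):
            read_volume(tmp_path)


class TestAverageIntensityProjection:
    def test_mean_of_identical_phases_is_the_phase(self):
        vol = VoxelVolume(np.full((4, 4, 4), -300.0), (1, 1, 1))
        aip = average_intensity_projection([vol.copy() for _ in range(10)])
        assert np.array_equal(aip.data, vol.data)

    def test_two_phase_arithmetic(self):
        a = VoxelVolume(np.full((2, 2, 2), -800.0), (1, 1, 1))
        b = VoxelVolume(np.full((2, 2, 2), -700.0), (1, 1, 1))
        assert np.all(average_intensity_projection([a, b]).data == -750.0)

    def test_grid_mismatch_rejected(self):
        a = VoxelVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        b = VoxelVolume(np.zeros((2, 2, 2)), (2, 2, 2))
        with pytest.raises(ValueError, match="grid mismatch"):
            average_intensity_projection([a, b])

    def test_moving_tumour_blurs_into_intermediate_hu(self, moving_case):
        ph, _ = moving_case
        aip = average_intensity_projection(ph.phases)
        gtv_union = union_masks(ph.gtv_masks)
        swept_only = gtv_union.data & ~ph.gtv_masks[0].data  # visited by the tumour sometimes
        vals = aip.data[swept_only]
        assert np.all(vals > -750.0) and np.all(vals < 30.0)


class TestExpandMargin:
    def test_zero_margin_is_identity(self):
        mask = StructureMask(np.eye(5, dtype=bool)[:, :, None] * np.ones((5, 5, 3), bool), (1, 1, 1), (0, 0, 0), role="GTV")
        out = expand_margin(mask, 0.0)
        assert np.array_equal(out.data, mask.data)

    def test_single_voxel_5mm_margin_matches_brute_force(self):
        data = np.zeros((13, 13, 13), dtype=bool)
        data[6, 6, 6] = True
        mask = StructureMask(data, (1, 1, 1), (0, 0, 0), role="GTV")
        out = expand_margin(mask, 5.0)
        oracle = brute_force_expand(mask, 5.0)
        assert np.array_equal(out.data, oracle)
        assert out.voxel_count() == 515  # lattice points with x^2+y^2+z^2 <= 25

    def test_anisotropic_spacing_matches_brute_force(self):
        rng = np.random.default_rng(3)
        data = rng.random((10, 10, 8)) > 0.93
        mask = StructureMask(data, (2.0, 2.0, 3.0), (0, 0, 0), role="heart")
        out = expand_margin(mask, 5.0)
        assert np.array_equal(out.data, brute_force_expand(mask, 5.0))

    def test_monotone_in_margin(self):
        data = np.zeros((11, 11, 11), dtype=bool)
        data[5, 5, 5] = True
        mask = StructureMask(data, (1, 2, 1), (0, 0, 0), role="GTV")
        small = expand_margin(mask, 3.0)
        large = expand_margin(mask, 5.0)
        assert np.all(large.data[small.data])

    def test_clipping_warns(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[0, 2, 2] = True
        mask = StructureMask(data, (1, 1, 1), (0, 0, 0), role="GTV")
        with pytest.warns(UserWarning, match="clipped"):
            expand_margin(mask, 3.0)

    def test_negative_margin_rejected(self):
        mask = StructureMask(np.ones((2, 2, 2), bool), (1, 1, 1), (0, 0, 0), role="GTV")
        with pytest.raises(ValueError):
            expand_margin(mask, -1.0)


class TestUnionMasks:
    def _mask(self, data):
        return StructureMask(data, (1, 1, 1), (0, 0, 0), role="lungs")

    def test_identity_and_disjoint_or(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b = np.zeros((4, 4, 4), dtype=bool)
        b[3, 3, 3] = True
        assert np.array_equal(union_masks([self._mask(a)]).data, a)
        assert union_masks([self._mask(a), self._mask(b)]).voxel_count() == 2

    def test_commutative_associative_idempotent(self):
        rng = np.random.default_rng(4)
        m = [self._mask(rng.random((5, 5, 5)) > 0.6) for _ in range(3)]
        ab = union_masks([m[0], m[1]])
        ba = union_masks([m[1], m[0]])
        assert np.array_equal(ab.data, ba.data)
        left = union_masks([union_masks([m[0], m[1]]), m[2]])
        right = union_masks([m[0], union_masks([m[1], m[2]])])
        assert np.array_equal(left.data, right.data)
        assert np.array_equal(union_masks([m[0], m[0]]).data, m[0].data)

    def test_itv_strictly_larger_than_any_ctv_under_motion(self, moving_case):
        ph, case = moving_case
        ctvs, itv = itv_from_gtvs(ph.gtv_masks, margin_mm=5.0)
        for ctv in ctvs:
            assert itv.voxel_count() > ctv.voxel_count()
            assert np.all(itv.data[ctv.data])
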