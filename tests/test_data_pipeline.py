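"""I/O, normalization, padding, patching and reassembly tests."""

import nibabel as nib
import numpy as np
import pytest

from maunet.data_pipeline import (LabelVolume, MultimodalVolume, Patch,
                                  PatchSpec, assemble_prediction, crop_depth,
                                  extract_patches, inference_patches,
                                  load_case, manifest_row_paths, normalize,
                                  pad_depth, random_flip, read_manifest)
from maunet.losses_metrics import combined_loss, encode_regions
from maunet.network import NetworkConfig, build_maunet


def small_spec(**kw):
    kw.setdefault("depth_chunk", 32)
    kw.setdefault("inplane", 8)
    kw.setdefault("depth_target", 160)
    kw.setdefault("stride", 8)
    return PatchSpec(**kw)


class TestLoadCase:
    def test_round_trip_preserves_values(self, tiny_cohort):
        row = read_manifest(tiny_cohort).iloc[0]
        volume, label = load_case(manifest_row_paths(row))
        assert volume.shape == (4, 32, 64, 64)
        direct = np.asarray(nib.load(row["path_t1ce"]).dataobj, dtype=np.float32)
        np.testing.assert_array_equal(volume.intensities[1], direct)
        assert label is not None and label.labels.shape == (32, 64, 64)

    def test_missing_modality_named_in_error(self, tiny_cohort):
        row = manifest_row_paths(read_manifest(tiny_cohort).iloc[0])
        row.pop("t2")
        with pytest.raises(FileNotFoundError, match="t2"):
            load_case(row)

    def test_grid_mismatch_names_offending_file(self, tiny_cohort, tmp_path):
        row = manifest_row_paths(read_manifest(tiny_cohort).iloc[0])
        odd = tmp_path / "odd.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((3, 3, 3), dtype=np.float32), np.eye(4)), odd)
        row["t2"] = str(odd)
        with pytest.raises(ValueError, match="mismatch"):
            load_case(row)


class TestNormalize:
    def test_brain_moments_and_untouched_background(self, rng):
        arr = np.zeros((4, 6, 6, 6), dtype=np.float32)
        mask = rng.random((6, 6, 6)) > 0.4
        for m in range(4):
            arr[m][mask] = rng.normal(5.0, 2.0, mask.sum())
        v = normalize(MultimodalVolume(arr))
        for m in range(4):
            vals = v.intensities[m][mask]
            assert abs(vals.mean()) < 1e-6 and abs(vals.std() - 1) < 1e-5
            assert np.all(v.intensities[m][~mask] == 0)

    def test_constant_brain_maps_to_zero(self):
        arr = np.zeros((4, 4, 4, 4), dtype=np.float32)
        arr[:, 1:3] = 7.0
        v = normalize(MultimodalVolume(arr))
        assert np.all(v.intensities == 0)


class TestPadDepth:
    def test_scanner_geometry_padded_and_recovered(self, rng):
        arr = rng.standard_normal((4, 155, 8, 8)).astype(np.float32)
        labels = np.zeros((155, 8, 8), dtype=np.int16)
        v, l = pad_depth(MultimodalVolume(arr), LabelVolume(labels))
        assert v.shape == (4, 160, 8, 8) and l.labels.shape == (160, 8, 8)
        assert np.all(v.intensities[:, :2] == 0) and np.all(v.intensities[:, 157:] == 0)
        assert np.all(l.labels[:2] == 0) and np.all(l.labels[157:] == 0)
        np.testing.assert_array_equal(crop_depth(v.intensities), arr)

    def test_unexpected_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            pad_depth(MultimodalVolume(np.zeros((4, 100, 8, 8))))


class TestExtractPatches:
    def test_grid_sampling_yields_five_depth_segments(self, rng):
        arr = rng.standard_normal((4, 160, 16, 16)).astype(np.float32)
        spec = small_spec(sampling="grid", inplane=8)
        patches = extract_patches(MultimodalVolume(arr), None, spec)
        assert len(patches) == 5
        assert all(p.image.shape == (4, 32, 8, 8) for p in patches)
        assert [p.offset[0] for p in patches] == [0, 32, 64, 96, 128]

    def test_random_crops_reproducible_from_seed(self, rng):
        arr = rng.standard_normal((4, 160, 16, 16)).astype(np.float32)
        spec = small_spec(sampling="random-crop")
        v = MultimodalVolume(arr)
        off1 = [p.offset for p in extract_patches(v, None, spec, np.random.default_rng(9))]
        off2 = [p.offset for p in extract_patches(v, None, spec, np.random.default_rng(9))]
        assert off1 == off2

    def test_grid_patches_reassemble_exactly(self, rng):
        arr = rng.standard_normal((4, 160, 8, 8)).astype(np.float32)
        spec = small_spec(sampling="grid")
        patches = extract_patches(MultimodalVolume(arr), None, spec)
        rebuilt = assemble_prediction([p.image for p in patches],
                                      [p.offset for p in patches], (160, 8, 8))
        np.testing.assert_allclose(rebuilt, arr, atol=1e-6)

    def test_too_small_plane_rejected(self):
        with pytest.raises(ValueError, match="smaller than window"):
            extract_patches(MultimodalVolume(np.zeros((4, 32, 4, 4))), None,
                            small_spec())


class TestRandomFlip:
    def test_involution_with_replayed_axes(self, rng):
        patch = Patch(rng.standard_normal((4, 4, 4, 4)),
                      (rng.random((4, 4, 4)) > 0.5).astype(np.int16) * 2, (0, 0, 0))
        flipped, axes = random_flip(patch, rng)
        restored, _ = random_flip(flipped, rng, axes=axes)
        np.testing.assert_array_equal(restored.image, patch.image)
        np.testing.assert_array_equal(restored.label, patch.label)

    def test_label_foreground_preserved(self, rng):
        patch = Patch(rng.standard_normal((4, 4, 4, 4)),
                      (rng.random((4, 4, 4)) > 0.5).astype(np.int16) * 4, (0, 0, 0))
        flipped, _ = random_flip(patch, rng)
        assert (flipped.label > 0).sum() == (patch.label > 0).sum()

    def test_flip_sequence_reproducible(self):
        draws = []
        for _ in range(2):
            rng = np.random.default_rng(17)
            patch = Patch(np.zeros((4, 2, 2, 2)), None, (0, 0, 0))
            draws.append([random_flip(patch, rng)[1] for _ in range(100)])
        assert draws[0] == draws[1]


class TestAssemble:
    def test_two_identical_overlapping_patches_average_to_same(self, rng):
        pred = rng.random((3, 4, 4, 4))
        out = assemble_prediction([pred, pred], [(0, 0, 0), (0, 0, 0)], (4, 4, 4))
        np.testing.assert_allclose(out, pred, atol=1e-12)

    def test_checkerboard_scatter_matches_loop_oracle(self, rng):
        preds = [rng.random((1, 2, 2, 2)) for _ in range(8)]
        offsets = [(z, y, x) for z in (0, 2) for y in (0, 2) for x in (0, 2)]
        got = assemble_prediction(preds, offsets, (4, 4, 4))
        want = np.zeros((1, 4, 4, 4))
        for pred, (z, y, x) in zip(preds, offsets):
            for dz in range(2):
                for dy in range(2):
                    for dx in range(2):
                        want[0, z + dz, y + dy, x + dx] = pred[0, dz, dy, dx]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_coverage_gap_detected(self, rng):
        with pytest.raises(RuntimeError, match="gap"):
            assemble_prediction([np.zeros((1, 2, 2, 2))], [(0, 0, 0)], (4, 4, 4))

    def test_sliding_window_covers_whole_plane(self, rng):
        arr = rng.standard_normal((4, 32, 20, 20)).astype(np.float32)
        spec = small_spec(depth_target=32, inplane=8, stride=6)
        patches = inference_patches(MultimodalVolume(arr), spec)
        cnt = np.zeros((32, 20, 20), dtype=int)
        for p in patches:
            z, y, x = p.offset
            cnt[z:z + 32, y:y + 8, x:x + 8] += 1
        assert (cnt > 0).all()


def test_augmentation_consistency_for_symmetric_baseline(rng):
    """Loss is invariant when input and target receive the same flip."""
    cfg = NetworkConfig(base_width=8, enable_gate=False, enable_smwa=False,
                        enable_cfc=False, dtype="float64")
    net = build_maunet(cfg, seed=4)
    for p in net.parameters():
        if p.data.ndim == 5:                      # palindromic kernels along W
            p.data = 0.5 * (p.data + p.data[..., ::-1])
    x = rng.standard_normal((4, 8, 16, 16))
    labels = np.zeros((8, 16, 16), dtype=np.int16)
    labels[3:5, 6:10, 6:10] = 2
    y = encode_regions(labels).stack()
    base = combined_loss(net.predict(x), y).item()
    flipped = combined_loss(net.predict(x[..., ::-1].copy()),
                            y[..., ::-1].copy()).item()
    assert flipped == pytest.approx(base, abs=1e-4)
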