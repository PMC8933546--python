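"""Cine loop and ROI I/O: containers, calibration, round-trips, rasterization."""

import json

import numpy as np
import pytest

import imageio.v3 as iio

from fluctmap import InputError, RoiMask, load_cine, load_roi
from fluctmap.cine_io import (load_score_map, rasterize_polygon, save_level_png,
                              save_score_map)

SPACING = (0.2, 0.2)


def _write_dicom_cine(path, frames_u8, frame_time_ms=50.0, spacing=(0.2, 0.2)):
    import pydicom
    from pydicom.dataset import Dataset, FileDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = Dataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    T, R, C = frames_u8.shape
    ds.NumberOfFrames = T
    ds.Rows, ds.Columns = R, C
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 8
    ds.HighBit = 7
    ds.PixelRepresentation = 0
    ds.FrameTime = frame_time_ms
    ds.PixelSpacing = [spacing[0], spacing[1]]
    ds.PixelData = frames_u8.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


class TestLoadCine:
    def test_png_dir_identity_stack(self, tmp_path):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        d = tmp_path / "frames"
        d.mkdir()
        for i in range(70):
            iio.imwrite(d / f"f{i:03d}.png", frame)
        cine = load_cine(d, pixel_spacing_override=SPACING, frame_rate_override=20)
        assert cine.frames.shape == (70, 64, 64)
        assert cine.frame_rate_hz == 20
        assert np.array_equal(cine.frames[0], cine.frames[42])

    def test_png_dir_8bit_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        stack = rng.random((3, 32, 32))
        stack[0, 0, 0], stack[0, 0, 1] = 0.0, 1.0  # pin the dynamic range
        d = tmp_path / "frames"
        d.mkdir()
        for i, fr in enumerate(stack):
            iio.imwrite(d / f"f{i}.png", np.floor(fr * 255 + 0.5).astype(np.uint8))
        cine = load_cine(d, pixel_spacing_override=SPACING, frame_rate_override=20)
        assert np.abs(cine.frames - stack).max() <= 1.0 / 255.0 + 1e-12

    def test_npy_roundtrip_lossless(self, tmp_path):
        rng = np.random.default_rng(2)
        stack = rng.random((5, 16, 16))
        stack[0, 0, 0], stack[0, 0, 1] = 0.0, 1.0
        p = tmp_path / "clip.npy"
        np.save(p, stack)
        cine = load_cine(p, pixel_spacing_override=SPACING, frame_rate_override=20)
        assert np.array_equal(cine.frames, stack)

    def test_normalization_idempotent(self, tmp_path):
        rng = np.random.default_rng(3)
        stack = 500.0 + 80.0 * rng.random((4, 16, 16))  # arbitrary intensity scale
        p1, p2 = tmp_path / "a.npy", tmp_path / "b.npy"
        np.save(p1, stack)
        first = load_cine(p1, pixel_spacing_override=SPACING, frame_rate_override=20)
        np.save(p2, first.frames)
        second = load_cine(p2, pixel_spacing_override=SPACING, frame_rate_override=20)
        assert np.array_equal(first.frames, second.frames)

    def test_dicom_multiframe_calibration(self, tmp_path):
        rng = np.random.default_rng(4)
        frames = rng.integers(0, 256, (70, 32, 32), dtype=np.uint8)
        p = tmp_path / "cine.dcm"
        _write_dicom_cine(p, frames, frame_time_ms=50.0, spacing=(0.2, 0.3))
        cine = load_cine(p)
        assert cine.n_frames == 70
        assert cine.frame_rate_hz == pytest.approx(20.0)
        assert cine.pixel_spacing_mm == (0.2, 0.3)

    def test_overrides_take_precedence_over_dicom_tags(self, tmp_path):
        frames = np.zeros((3, 8, 8), dtype=np.uint8)
        frames[1, 2, 2] = 200
        p = tmp_path / "cine.dcm"
        _write_dicom_cine(p, frames)
        cine = load_cine(p, pixel_spacing_override=(0.5, 0.5), frame_rate_override=15)
        assert cine.frame_rate_hz == 15
        assert cine.pixel_spacing_mm == (0.5, 0.5)

    def test_missing_calibration_is_an_error(self, tmp_path):
        p = tmp_path / "clip.npy"
        np.save(p, np.random.default_rng(0).random((3, 8, 8)))
        with pytest.raises(InputError, match="spacing"):
            load_cine(p, frame_rate_override=20)
        with pytest.raises(InputError, match="frame rate"):
            load_cine(p, pixel_spacing_override=SPACING)

    def test_too_few_frames(self, tmp_path):
        p = tmp_path / "clip.npy"
        np.save(p, np.random.default_rng(0).random((1, 8, 8)))
        with pytest.raises(InputError, match="frames"):
            load_cine(p, pixel_spacing_override=SPACING, frame_rate_override=20)

    def test_inconsistent_frame_shapes(self, tmp_path):
        d = tmp_path / "frames"
        d.mkdir()
        iio.imwrite(d / "a.png", np.zeros((8, 8), dtype=np.uint8))
        iio.imwrite(d / "b.png", np.zeros((9, 8), dtype=np.uint8))
        with pytest.raises(InputError, match="inconsistent"):
            load_cine(d, pixel_spacing_override=SPACING, frame_rate_override=20)

    def test_missing_file(self, tmp_path):
        with pytest.raises(InputError, match="no such"):
            load_cine(tmp_path / "nope.npy")


def _brute_force_even_odd(verts, shape):
    """Independent per-pixel even-odd ray-cast scan."""
    out = np.zeros(shape, dtype=bool)
    n = len(verts)
    for r in range(shape[0]):
        for c in range(shape[1]):
            inside = False
            for k in range(n):
                r1, c1 = verts[k]
                r2, c2 = verts[(k + 1) % n]
                if (r1 > r) != (r2 > r):
                    if c < c1 + (r - r1) * (c2 - c1) / (r2 - r1):
                        inside = not inside
            out[r, c] = inside
    return out


class TestRoi:
    def test_rect_halfopen_area(self, tmp_path):
        p = tmp_path / "roi.json"
        p.write_text(json.dumps({"type": "rect", "row0": 10, "col0": 10,
                                 "row1": 20, "col1": 20}))
        roi = load_roi(p, (64, 64))
        assert roi.n_pixels == 100
        assert roi.bounding_box == (10, 10, 20, 20)

    def test_rect_whole_frame(self, tmp_path):
        p = tmp_path / "roi.json"
        p.write_text(json.dumps({"type": "rect", "row0": 0, "col0": 0,
                                 "row1": 64, "col1": 64}))
        roi = load_roi(p, (64, 64))
        assert roi.mask.all()
        assert roi.bounding_box == (0, 0, 64, 64)

    @pytest.mark.parametrize("verts", [
        [(0, 0), (0, 10), (10, 0)],
        [(2.5, 3.5), (2.5, 25.0), (20.0, 14.0), (12.0, 4.0)],
        [(1, 1), (1, 20), (20, 20), (20, 1)],
    ])
    def test_polygon_matches_even_odd_scan(self, tmp_path, verts):
        p = tmp_path / "roi.json"
        p.write_text(json.dumps({"type": "polygon", "vertices": [list(v) for v in verts]}))
        roi = load_roi(p, (28, 28))
        expected = _brute_force_even_odd([tuple(v) for v in verts], (28, 28))
        assert np.array_equal(roi.mask, expected)

    def test_polygon_outside_frame(self, tmp_path):
        p = tmp_path / "roi.json"
        p.write_text(json.dumps({"type": "polygon",
                                 "vertices": [[0, 0], [0, 99], [99, 0]]}))
        with pytest.raises(InputError, match="outside"):
            load_roi(p, (28, 28))

    def test_degenerate_polygon_empty_mask(self, tmp_path):
        p = tmp_path / "roi.json"
        # zero-area sliver between pixel centers
        p.write_text(json.dumps({"type": "polygon",
                                 "vertices": [[0.1, 0.1], [0.1, 0.2], [0.2, 0.1]]}))
        with pytest.raises(InputError, match="empty"):
            load_roi(p, (8, 8))

    def test_rect_mask_bbox_is_tight(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[3:5, 7:12] = True
        roi = RoiMask(mask)
        assert roi.bounding_box == (3, 7, 5, 12)

    def test_rasterize_polygon_needs_three_vertices(self):
        with pytest.raises(InputError):
            rasterize_polygon([(0, 0), (1, 1)], (8, 8))


class TestMapIO:
    @pytest.mark.parametrize("ext", [".npy", ".tif"])
    def test_score_map_lossless_roundtrip(self, tmp_path, ext):
        rng = np.random.default_rng(5)
        score = rng.random((32, 32))
        p = save_score_map(score, tmp_path / f"s{ext}")
        assert np.array_equal(load_score_map(p), score)

    @pytest.mark.parametrize("value", [0, 255])
    def test_level_png_preserves_extremes(self, tmp_path, value):
        level = np.full((8, 8), value, dtype=np.int64)
        p = save_level_png(level, tmp_path / "level.png")
        assert np.array_equal(iio.imread(p), np.full((8, 8), value, dtype=np.uint8))
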