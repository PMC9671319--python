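"""I/O: cine loading round trips, annotation validation, signal tables."""

import json

import numpy as np
import pytest

import respitune as rt
from respitune import cine_io


def _annotation_doc(tiny_phantom):
    """Serialize the phantom annotation to the JSON schema as a dict."""
    ann = tiny_phantom.annotation

    def pts(arr):
        return [[i + 1, float(x), float(y)] for i, (x, y) in enumerate(arr)]

    return {
        "left": {"ip": pts(ann.left.ip), "ep": pts(ann.left.ep)},
        "right": {"ip": pts(ann.right.ip), "ep": pts(ann.right.ep)},
        "diaphragm_point_index": 5,
        "diaphragm_trace": [[t, float(y)] for t, y in enumerate(ann.diaphragm_trace)],
    }


class TestCineSequence:
    def test_rejects_single_frame(self):
        with pytest.raises(ValueError, match="2 frames"):
            rt.CineSequence(frames=np.zeros((1, 8, 8)), frame_rate=12.5)

    def test_rejects_out_of_range_pixels(self):
        with pytest.raises(ValueError, match="outside"):
            rt.CineSequence(
                frames=np.full((2, 4, 4), 5000.0), frame_rate=12.5, bit_depth=4096
            )

    def test_times_axis(self):
        cine = rt.CineSequence(frames=np.zeros((5, 4, 4)), frame_rate=12.5)
        assert cine.times[-1] == pytest.approx(4 / 12.5)


class TestImageStack:
    def test_png_round_trip_is_bit_identical(self, tiny_phantom, tmp_path):
        """Phantom written as a PNG stack reloads with identical pixels."""
        quantized = rt.CineSequence(
            frames=np.rint(tiny_phantom.cine.frames),
            frame_rate=tiny_phantom.cine.frame_rate,
            bit_depth=tiny_phantom.cine.bit_depth,
        )
        rt.write_cine(quantized, tmp_path / "cine")
        loaded = rt.load_cine(tmp_path / "cine", frame_rate=12.5, bit_depth=4096)
        assert loaded.n_frames == quantized.n_frames
        assert np.array_equal(loaded.frames, quantized.frames)
        # loader never rescales: histograms match
        assert np.array_equal(
            np.bincount(loaded.frames.ravel().astype(int)),
            np.bincount(quantized.frames.ravel().astype(int)),
        )

    def test_requires_frame_rate(self, tiny_phantom, tmp_path):
        rt.write_cine(tiny_phantom.cine, tmp_path / "cine")
        with pytest.raises(ValueError, match="frame.rate|frame_rate"):
            rt.load_cine(tmp_path / "cine")

    def test_rejects_single_file(self, tmp_path):
        import imageio.v3 as iio

        d = tmp_path / "one"
        d.mkdir()
        iio.imwrite(d / "frame_0.png", np.zeros((4, 4), dtype=np.uint16))
        with pytest.raises(ValueError, match="2 frames"):
            rt.load_cine(d, frame_rate=12.5)


class TestDicom:
    def _multiframe(self, frames, rate=12.5):
        import pydicom
        from pydicom.dataset import FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = generate_uid()
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.Rows, ds.Columns = frames.shape[1:]
        ds.NumberOfFrames = frames.shape[0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.FrameTime = f"{1000.0 / rate:.6g}"  # ms per frame, VR DS
        ds.PixelData = frames.astype(np.uint16).tobytes()
        return ds

    def test_multiframe_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 4096, size=(6, 8, 8), dtype=np.uint16)
        ds = self._multiframe(frames)
        path = tmp_path / "cine.dcm"
        ds.save_as(path, enforce_file_format=True)
        cine = rt.load_cine(path)
        assert cine.frame_rate == 12.5  # from CineRate metadata
        assert cine.bit_depth == 4096  # 2**BitsStored
        assert np.array_equal(cine.frames, frames)

    def test_explicit_rate_overrides_metadata(self, tmp_path):
        frames = np.zeros((3, 4, 4), dtype=np.uint16)
        ds = self._multiframe(frames, rate=30)
        path = tmp_path / "cine.dcm"
        ds.save_as(path, enforce_file_format=True)
        assert rt.load_cine(path, frame_rate=12.5).frame_rate == 12.5


class TestAnnotation:
    def test_valid_round_trip(self, tiny_phantom, tmp_path):
        p = tmp_path / "ann.json"
        p.write_text(json.dumps(_annotation_doc(tiny_phantom)))
        ann = rt.load_annotation(p)
        assert ann.left.ip.shape == (12, 2)
        assert ann.right.ep.shape == (10, 2)
        np.testing.assert_allclose(ann.left.ip, tiny_phantom.annotation.left.ip)
        np.testing.assert_allclose(
            ann.diaphragm_trace, tiny_phantom.annotation.diaphragm_trace
        )

    def test_writer_reader_agree(self, tiny_phantom, tmp_path):
        p = tmp_path / "ann.json"
        rt.write_annotation(tiny_phantom.annotation, p)
        ann = rt.load_annotation(p)
        np.testing.assert_allclose(ann.right.ip, tiny_phantom.annotation.right.ip)

    @pytest.mark.parametrize(
        "mutate, msg",
        [
            (lambda d: d["left"]["ip"].pop(), "left lung requires 12"),
            (lambda d: d["right"]["ep"].pop(), "right lung requires 10"),
            (
                lambda d: d["left"]["ip"].__setitem__(0, [2, 1.0, 1.0]),
                "duplicate",
            ),
        ],
    )
    def test_invalid_annotations_rejected(self, tiny_phantom, tmp_path, mutate, msg):
        doc = _annotation_doc(tiny_phantom)
        mutate(doc)
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match=msg):
            rt.load_annotation(p)


class TestBlockSignals:
    def test_shape_and_round_trip(self, tmp_path):
        values = np.arange(12.0).reshape(3, 4) / 7.0
        ids = [("left", 1, 1), ("left", 1, 2), ("right", 2, 1)]
        p = tmp_path / "sig.csv"
        rt.write_block_signals(values, ids, p)
        header = p.read_text().splitlines()[0]
        assert header == "block_id,frame_0,frame_1,frame_2,frame_3"
        back, back_ids = cine_io.read_block_signals(p)
        assert back_ids == ids
        np.testing.assert_allclose(back, values, atol=1e-9)

    def test_empty_table_is_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        rt.write_block_signals([], [], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1

    def test_ragged_table_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="ragged"):
            rt.write_block_signals(
                [np.zeros(3), np.zeros(4)], [("left", 1, 1), ("left", 1, 2)],
                tmp_path / "x.csv",
            )
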