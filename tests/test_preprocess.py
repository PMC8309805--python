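"""DICOM ingestion, bilinear resizing, and channel conversions."""

import csv

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from PIL import Image

from mammocad import (
    GrayWeights,
    MammogramImage,
    dicom_to_png,
    gray_to_rgb,
    resize_image,
    rgb_to_gray_average,
    rgb_to_gray_weighted,
)
from .conftest import make_dicom


class TestDicomToPng:
    def test_pixel_lossless_round_trip(self, tmp_path):
        pixels = np.arange(16, dtype=np.uint16).reshape(4, 4) * 1000
        make_dicom(tmp_path / "a.dcm", pixels)
        img, record = dicom_to_png(tmp_path / "a.dcm", tmp_path / "out")
        decoded = np.asarray(Image.open(tmp_path / "out" / "a.png"))
        np.testing.assert_array_equal(decoded, pixels)
        assert record.patient_id == "P001"
        assert record.age == 48
        np.testing.assert_allclose(img.pixels, pixels / 65535.0)

    def test_patient_id_logged_to_csv(self, tmp_path):
        make_dicom(tmp_path / "a.dcm", np.zeros((4, 4)), patient_id="P001")
        dicom_to_png(tmp_path / "a.dcm", tmp_path / "out")
        text = (tmp_path / "out" / "metadata.csv").read_text()
        assert "P001" in text

    def test_batch_accumulates_rows_and_pngs(self, tmp_path):
        for i in range(3):
            make_dicom(tmp_path / f"img{i}.dcm", np.full((4, 4), i),
                       patient_id=f"P{i:03d}")
            dicom_to_png(tmp_path / f"img{i}.dcm", tmp_path / "out")
        with open(tmp_path / "out" / "metadata.csv") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 4  # header + 3 records
        assert len(list((tmp_path / "out").glob("*.png"))) == 3

    def test_missing_pixel_data_names_the_file(self, tmp_path):
        make_dicom(tmp_path / "broken.dcm", np.zeros((4, 4)), with_pixels=False)
        with pytest.raises(ValueError, match="broken.dcm"):
            dicom_to_png(tmp_path / "broken.dcm", tmp_path / "out")

    def test_non_monochrome_rejected(self, tmp_path):
        make_dicom(tmp_path / "rgb.dcm", np.zeros((4, 4)), photometric="RGB")
        with pytest.raises(ValueError, match="photometric"):
            dicom_to_png(tmp_path / "rgb.dcm", tmp_path / "out")


class TestResize:
    def test_output_dimensions(self, rng):
        img = MammogramImage(rng.random((2047, 4096)))
        out = resize_image(img, 320, 240)
        assert (out.height_px, out.width_px) == (240, 320)

    def test_identity_when_dims_match(self, gray_image):
        out = resize_image(gray_image, gray_image.width_px, gray_image.height_px)
        np.testing.assert_array_equal(out.pixels, gray_image.pixels)

    def test_downsize_matches_per_pixel_bilinear_oracle(self, rng):
        a = rng.random((4, 4))
        out = resize_image(MammogramImage(a), 2, 2).pixels

        # half-pixel-center bilinear oracle, written out longhand
        expected = np.empty((2, 2))
        for i in range(2):
            for j in range(2):
                y = (i + 0.5) * 2 - 0.5
                x = (j + 0.5) * 2 - 0.5
                y0, x0 = int(np.floor(y)), int(np.floor(x))
                fy, fx = y - y0, x - x0
                expected[i, j] = (
                    a[y0, x0] * (1 - fy) * (1 - fx)
                    + a[y0, x0 + 1] * (1 - fy) * fx
                    + a[y0 + 1, x0] * fy * (1 - fx)
                    + a[y0 + 1, x0 + 1] * fy * fx
                )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_invalid_target_rejected(self, gray_image):
        with pytest.raises(ValueError):
            resize_image(gray_image, 0, 10)


class TestChannelConversions:
    def test_average_of_equal_channels(self):
        img = MammogramImage(np.full((2, 2, 3), 0.5))
        np.testing.assert_allclose(rgb_to_gray_average(img).pixels, 0.5)

    def test_average_is_arithmetic_mean(self):
        img = MammogramImage(np.array([[[0.3, 0.6, 0.9]]]))
        assert rgb_to_gray_average(img).pixels[0, 0] == pytest.approx(0.6)

    def test_average_of_black_is_black(self):
        img = MammogramImage(np.zeros((3, 3, 3)))
        np.testing.assert_array_equal(rgb_to_gray_average(img).pixels, 0.0)

    def test_average_rejects_grayscale(self, gray_image):
        with pytest.raises(ValueError):
            rgb_to_gray_average(gray_image)

    def test_uniform_weights_reduce_to_average(self, rgb_image):
        w = GrayWeights(1 / 3, 1 / 3, 1 / 3)
        np.testing.assert_allclose(
            rgb_to_gray_weighted(rgb_image, w).pixels,
            rgb_to_gray_average(rgb_image).pixels,
            atol=1e-12,
        )

    def test_weighted_selects_single_channel(self):
        img = MammogramImage(np.array([[[1.0, 0.0, 0.0]]]))
        out = rgb_to_gray_weighted(img, GrayWeights(0.299, 0.587, 0.114))
        assert out.pixels[0, 0] == pytest.approx(0.299)

    def test_weighted_matches_scalar_loop_oracle(self, rng):
        a = rng.random((8, 8, 3))
        w = GrayWeights(0.299, 0.587, 0.114)
        out = rgb_to_gray_weighted(MammogramImage(a), w).pixels
        expected = np.empty((8, 8))
        for i in range(8):
            for j in range(8):
                expected[i, j] = (
                    a[i, j, 0] * 0.299 + a[i, j, 1] * 0.587 + a[i, j, 2] * 0.114
                )
        assert np.abs(out - expected).max() == 0.0

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            GrayWeights(0.5, 0.5, 0.5)

    def test_gray_to_rgb_replicates_planes(self):
        img = MammogramImage(np.full((2, 2), 0.7))
        out = gray_to_rgb(img)
        assert out.pixels.shape == (2, 2, 3)
        for ch in range(3):
            np.testing.assert_array_equal(out.pixels[:, :, ch], 0.7)

    def test_gray_to_rgb_of_zero(self):
        out = gray_to_rgb(MammogramImage(np.zeros((1, 1))))
        np.testing.assert_array_equal(out.pixels, np.zeros((1, 1, 3)))

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(
            np.float64,
            (4, 5),
            elements=st.floats(0, 1, allow_nan=False, width=32),
        )
    )
    def test_gray_rgb_gray_round_trip(self, a):
        img = MammogramImage(a)
        back = rgb_to_gray_average(gray_to_rgb(img))
        np.testing.assert_allclose(back.pixels, a, atol=1e-15)
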