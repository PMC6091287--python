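"""Domain types, invariants and file round-trips."""

import numpy as np
import pytest

from vpmmi import io
from vpmmi.types import (
    Affine2D,
    FormatError,
    GeometryError,
    Image2D,
    InputError,
    LandmarkTriplet,
    Mask2D,
    RegistrationConfig,
)


class TestImage2D:
    def test_rejects_nonfinite_and_bad_spacing(self):
        with pytest.raises(InputError):
            Image2D(np.full((16, 16), np.nan))
        with pytest.raises(InputError):
            Image2D(np.zeros((16, 16)), pixel_size=(0.0, 1.0))

    def test_shape_properties(self):
        img = Image2D(np.zeros((10, 20)))
        assert (img.height, img.width) == (10, 20)

    def test_enhanced_values_above_255_are_allowed(self):
        Image2D(np.full((16, 16), 355.0))  # enhanced domain, no clipping


class TestLandmarkTriplet:
    def test_collinear_rejected(self):
        with pytest.raises(GeometryError):
            LandmarkTriplet([(0, 0), (1, 1), (2, 2)])

    def test_repeated_point_rejected(self):
        with pytest.raises(GeometryError):
            LandmarkTriplet([(5, 5), (5, 5), (9, 2)])

    def test_bounds_check(self):
        lm = LandmarkTriplet([(10, 10), (50, 20), (30, 60)])
        lm.require_within((100, 100))
        with pytest.raises(InputError):
            lm.require_within((40, 40))


class TestAffine2D:
    def test_singular_rejected(self):
        m = np.eye(3)
        m[0, 0] = m[1, 1] = 0.0
        m[0, 1] = m[1, 0] = 0.0
        with pytest.raises(GeometryError):
            Affine2D(m)

    def test_bad_last_row_rejected(self):
        m = np.eye(3)
        m[2] = (0.1, 0.0, 1.0)
        with pytest.raises(GeometryError):
            Affine2D(m)

    def test_apply_and_inverse_roundtrip(self, rng):
        m = np.eye(3)
        m[:2, :2] = [[1.1, 0.2], [-0.1, 0.95]]
        m[:2, 2] = [5.0, -3.0]
        t = Affine2D(m)
        pts = rng.uniform(-50, 50, size=(20, 2))
        back = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(back, pts, atol=1e-10)


class TestRegistrationConfig:
    @pytest.mark.parametrize("bad", [
        {"N": -1}, {"nmi_bins": 4}, {"powell_xtol": 0.0},
        {"powell_max_iter": 0}, {"transform_model": "projective"},
    ])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(InputError):
            RegistrationConfig(**bad)

    def test_defaults_match_method_constants(self):
        cfg = RegistrationConfig()
        assert cfg.N == 80 and cfg.M == 100


class TestImageIO:
    def test_uint8_roundtrip_exact(self, tmp_path, rng):
        arr = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        p = tmp_path / "img.png"
        io.write_image(Image2D(arr.astype(float)), p)
        back = io.read_image(p)
        np.testing.assert_array_equal(back.pixels, arr.astype(float))

    def test_all_zero_image_reads(self, tmp_path):
        p = tmp_path / "z.png"
        io.write_image(Image2D(np.zeros((16, 16))), p)
        img = io.read_image(p)
        assert img.pixels.sum() == 0 and img.shape == (16, 16)

    @pytest.mark.parametrize("modality,expected", [
        ("CT", (0.32, 0.32)), ("TEE", (0.224, 0.224)), (None, (1.0, 1.0)),
    ])
    def test_modality_pixel_size_defaults(self, tmp_path, modality, expected):
        p = tmp_path / "img.png"
        io.write_image(Image2D(np.full((16, 16), 7.0)), p)
        assert io.read_image(p, modality=modality).pixel_size == expected

    def test_16bit_tiff_rescaled_to_8bit_range(self, tmp_path):
        import tifffile

        p = tmp_path / "img.tif"
        tifffile.imwrite(p, np.full((16, 16), 65535, dtype=np.uint16))
        img = io.read_image(p)
        assert img.pixels.max() == pytest.approx(255.0)

    def test_true_color_image_rejected(self, tmp_path):
        import imageio.v3 as iio

        p = tmp_path / "rgb.png"
        arr = np.zeros((16, 16, 3), dtype=np.uint8)
        arr[..., 0] = 200  # genuinely different channels
        iio.imwrite(p, arr)
        with pytest.raises(FormatError):
            io.read_image(p)

    def test_tiny_image_rejected(self, tmp_path):
        import imageio.v3 as iio

        p = tmp_path / "tiny.png"
        iio.imwrite(p, np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(FormatError):
            io.read_image(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FormatError):
            io.read_image(tmp_path / "absent.png")


class TestMaskIO:
    def test_roundtrip_lossless(self, tmp_path, rng):
        bits = rng.uniform(size=(16, 16)) > 0.5
        p = tmp_path / "mask.png"
        io.write_mask(Mask2D(bits), p)
        np.testing.assert_array_equal(io.read_mask(p).bits, bits)


class TestLandmarkIO:
    def _write(self, tmp_path, rows, header="x,y"):
        p = tmp_path / "lm.csv"
        p.write_text(header + "\n" + "\n".join(f"{x},{y}" for x, y in rows))
        return p

    def test_valid_triplet(self, tmp_path):
        p = self._write(tmp_path, [(10, 10), (50, 20), (30, 60)])
        img = Image2D(np.zeros((100, 100)))
        lm = io.read_landmarks(p, img)
        np.testing.assert_array_equal(lm.points, [(10, 10), (50, 20), (30, 60)])

    def test_collinear_rows_rejected(self, tmp_path):
        p = self._write(tmp_path, [(0, 0), (1, 1), (2, 2)])
        with pytest.raises(GeometryError):
            io.read_landmarks(p)

    def test_wrong_row_count_rejected(self, tmp_path):
        p = self._write(tmp_path, [(10, 10), (50, 20)])
        with pytest.raises(InputError):
            io.read_landmarks(p)

    def test_out_of_bounds_rejected(self, tmp_path):
        p = self._write(tmp_path, [(10, 10), (50, 20), (30, 600)])
        with pytest.raises(InputError):
            io.read_landmarks(p, Image2D(np.zeros((100, 100))))

    def test_roundtrip(self, tmp_path):
        lm = LandmarkTriplet([(10.5, 10.25), (50, 20), (30, 60)])
        p = tmp_path / "lm.csv"
        io.write_landmarks(lm, p)
        np.testing.assert_allclose(io.read_landmarks(p).points, lm.points)


class TestTransformIO:
    @pytest.mark.parametrize("matrix", [
        np.eye(3),
        [[1, 0, 5], [0, 1, -3], [0, 0, 1]],
        [[1.1, 0.2, 5.123456789012345], [-0.1, 0.95, -3], [0, 0, 1]],
    ])
    def test_roundtrip_to_1e12(self, tmp_path, matrix):
        t = Affine2D(np.asarray(matrix, dtype=float))
        p = tmp_path / "t.txt"
        io.write_transform(t, p)
        np.testing.assert_allclose(io.read_transform(p).matrix, t.matrix,
                                   atol=1e-12)

    def test_singular_matrix_rejected_on_read(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("1 1 0\n1 1 0\n0 0 1\n")
        with pytest.raises(GeometryError):
            io.read_transform(p)

    def test_malformed_file_rejected(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("not a matrix\n")
        with pytest.raises(FormatError):
            io.read_transform(p)
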