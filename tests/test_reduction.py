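"""Geometry, masking, radial integration, normalization expressions, config."""

import numpy as np
import pytest

from saxskit import synthetic
from saxskit.reduction import (
    ConfigError,
    DetectorGeometry,
    ExpressionError,
    ReductionConfig,
    evaluate_normalization,
    load_config,
    make_mask,
    q_of_pixel,
    radial_average,
    reduce_image,
    save_config,
)

GEOM = DetectorGeometry(beam_center_x=100.0, beam_center_y=100.0,
                        distance=1000.0, wavelength=1.0, pixel_size=0.172)


class TestQOfPixel:
    def test_beam_center_is_zero(self):
        assert q_of_pixel(GEOM, 100.0, 100.0) == 0.0

    def test_hand_computed_value(self):
        # d = 0.172*100 mm; 2theta = arctan(17.2/1000); q = 4*pi*sin(theta)/1
        d = 0.172 * 100
        two_theta = np.arctan(d / 1000.0)
        expected = 4 * np.pi * np.sin(two_theta / 2) / 1.0
        assert q_of_pixel(GEOM, 200.0, 100.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_distance(self):
        far = DetectorGeometry(100, 100, 2000.0, 1.0, 0.172)
        assert q_of_pixel(far, 200, 100) < q_of_pixel(GEOM, 200, 100)

    def test_radially_symmetric(self):
        qs = [q_of_pixel(GEOM, 100 + dx, 100 + dy)
              for dx, dy in [(30, 0), (0, 30), (-30, 0), (0, -30)]]
        assert np.ptp(qs) < 1e-15


class TestRadialAverage:
    def test_uniform_image_every_bin_constant(self):
        img = np.full((64, 64), 3.5)
        geom = DetectorGeometry(32, 32, 500.0, 1.0, 0.1)
        p = radial_average(img, geom, n_bins=20)
        np.testing.assert_allclose(p.intensity, 3.5)

    def test_mask_does_not_bias_constant(self):
        img = np.full((64, 64), 3.5)
        geom = DetectorGeometry(32, 32, 500.0, 1.0, 0.1)
        mask = np.zeros((64, 64), bool)
        mask[:, :32] = True
        p = radial_average(img, geom, mask, n_bins=20)
        np.testing.assert_allclose(p.intensity, 3.5)

    def test_all_masked_errors(self):
        img = np.ones((8, 8))
        with pytest.raises(ValueError, match="masked"):
            radial_average(img, GEOM, np.ones((8, 8), bool))

    def test_recovers_generating_profile(self):
        """Expectation-mode synthetic image -> radial average reproduces the
        input curve in every bin with >= 50 pixels (detector q range kept
        below the sphere form factor's first zero)."""
        q = np.linspace(1e-4, 0.2, 500)
        prof = synthetic.sphere_profile(20.0, 1000.0, q)
        img = synthetic.simulate_image(prof, GEOM, (200, 200), mode="expectation")
        p = radial_average(img, GEOM, n_bins=100)
        from saxskit.reduction import _pixel_q_map

        qmap, _ = _pixel_q_map(GEOM, img.shape)
        idx = np.minimum((qmap / qmap.max() * 100).astype(int), 99)
        npix = np.bincount(idx.ravel(), minlength=100)
        big = npix[npix > 0] >= 50
        ref = np.interp(p.q, q, prof.intensity)
        rel = np.abs(p.intensity - ref) / np.abs(ref)
        assert rel[big].max() < 0.01


class TestNormalizationExpression:
    @pytest.mark.parametrize("expr,header,expected", [
        ("mon", {"mon": 2}, 2.0),
        ("i0/(t*1e6)", {"i0": 3e6, "t": 1.5}, 2.0),
        ("1 + 2*3", {}, 7.0),
        ("-(2+3)", {}, -5.0),
        ("max(a, b)", {"a": 1, "b": 4}, 4.0),
        ("sqrt(exp(log(16)))", {}, 4.0),
        ("min(2, 3)/2", {}, 1.0),
    ])
    def test_arithmetic(self, expr, header, expected):
        assert evaluate_normalization(expr, header) == pytest.approx(expected)

    def test_unknown_name_lists_available(self):
        with pytest.raises(ExpressionError, match="mon"):
            evaluate_normalization("flux", {"mon": 1.0})

    def test_division_by_zero(self):
        with pytest.raises(ExpressionError, match="zero"):
            evaluate_normalization("1/(2-2)", {})

    def test_disallowed_token(self):
        with pytest.raises(ExpressionError):
            evaluate_normalization("__import__('os')", {})

    def test_unknown_function_rejected(self):
        with pytest.raises(ExpressionError):
            evaluate_normalization("sin(1)", {})


class TestMakeMask:
    def test_empty_region_list(self):
        assert not make_mask((8, 8), []).any()

    def test_full_rectangle_masks_all(self):
        m = make_mask((8, 8), [{"type": "rectangle", "xmin": 0, "xmax": 7,
                                "ymin": 0, "ymax": 7}])
        assert m.all()

    def test_zero_radius_circle(self):
        m = make_mask((8, 8), [{"type": "circle", "center": [3, 3], "radius": 0}])
        assert m.sum() <= 1

    def test_invert(self):
        spec = [{"type": "circle", "center": [4, 4], "radius": 2}]
        assert (make_mask((8, 8), spec) == ~make_mask((8, 8), spec, invert=True)).all()

    def test_polygon_triangle(self):
        m = make_mask((10, 10), [{"type": "polygon",
                                  "vertices": [[0, 0], [9.5, 0], [0, 9.5]]}])
        assert m[0, 1] and not m[9, 9]


class TestReduceImage:
    def test_unit_normalization_matches_radial_average(self):
        img = np.full((64, 64), 2.0)
        geom = DetectorGeometry(32, 32, 500.0, 1.0, 0.1)
        cfg = ReductionConfig(geometry=geom, n_bins=20)
        direct = radial_average(img, geom, n_bins=20)
        reduced = reduce_image(img, cfg)
        np.testing.assert_allclose(reduced.intensity, direct.intensity)

    def test_normalization_divides(self):
        img = np.full((64, 64), 2.0)
        geom = DetectorGeometry(32, 32, 500.0, 1.0, 0.1)
        cfg = ReductionConfig(geometry=geom, n_bins=20, normalization="2")
        reduced = reduce_image(img, cfg)
        np.testing.assert_allclose(reduced.intensity, 1.0)

    def test_header_expression_and_history(self):
        img = np.full((64, 64), 8.0)
        geom = DetectorGeometry(32, 32, 500.0, 1.0, 0.1)
        cfg = ReductionConfig(geometry=geom, n_bins=20, normalization="mon/2")
        reduced = reduce_image(img, cfg, header={"mon": 8.0})
        np.testing.assert_allclose(reduced.intensity, 2.0)
        assert reduced.history.parameters["normalization_value"] == 4.0

    def test_text_and_tiff_inputs(self, tmp_path):
        img = np.full((32, 32), 5.0)
        geom = DetectorGeometry(16, 16, 500.0, 1.0, 0.1)
        cfg = ReductionConfig(geometry=geom, n_bins=10)
        txt = tmp_path / "img.txt"
        np.savetxt(txt, img)
        import tifffile

        tif = tmp_path / "img.tif"
        tifffile.imwrite(tif, img.astype(np.float32))
        p_txt = reduce_image(txt, cfg)
        p_tif = reduce_image(tif, cfg)
        np.testing.assert_allclose(p_txt.intensity, p_tif.intensity)


class TestConfigIO:
    def _config(self):
        return ReductionConfig(
            geometry=GEOM,
            mask_regions=[{"type": "circle", "center": [10, 10], "radius": 5}],
            normalization="mon",
            n_bins=150,
            absolute_scale=2.5,
        )

    def test_roundtrip(self, tmp_path):
        path = tmp_path / "cfg.json"
        cfg = self._config()
        save_config(cfg, path)
        back = load_config(path)
        assert back.to_dict() == cfg.to_dict()

    def test_missing_n_bins_defaults(self, tmp_path):
        import json

        path = tmp_path / "cfg.json"
        d = self._config().to_dict()
        del d["n_bins"]
        path.write_text(json.dumps(d))
        assert load_config(path).n_bins == 200

    def test_negative_distance_rejected(self, tmp_path):
        import json

        path = tmp_path / "cfg.json"
        d = self._config().to_dict()
        d["geometry"]["distance"] = -1.0
        path.write_text(json.dumps(d))
        with pytest.raises(ConfigError, match="distance"):
            load_config(path)
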