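"""Image I/O round trips, pipeline determinism, CLI surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import adaptpsf as ap
from adaptpsf.cli import main as cli_main
from conftest import replicate_blur


class TestImageIO:
    def test_uint16_tiff_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 65535, (64, 128)).astype(np.float64)
        path = tmp_path / "img.tif"
        ap.write_image(img, path)
        back = ap.read_image(path)
        np.testing.assert_array_equal(back, img)

    def test_float32_map_roundtrip(self, tmp_path):
        img = np.random.default_rng(1).uniform(-1, 1, (32, 32))
        path = tmp_path / "map.tif"
        ap.write_image(img, path, dtype="float32")
        back = ap.read_image(path)
        np.testing.assert_allclose(back, img.astype(np.float32))

    def test_png_8bit_promotion_records_scale(self, tmp_path):
        img = np.arange(64, dtype=np.float64).reshape(8, 8)
        path = tmp_path / "img.png"
        ap.write_image(img, path)  # written as 16-bit png
        # write an 8-bit png through imageio to exercise promotion
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "img8.png", img.astype(np.uint8))
        arr, meta = ap.read_image(tmp_path / "img8.png", with_meta=True)
        assert meta["promoted_from"] == "8-bit"
        np.testing.assert_array_equal(arr, img)

    def test_raw_sidecar_roundtrip_and_integrity(self, tmp_path):
        img = np.random.default_rng(2).integers(0, 4095, (16, 24)).astype(np.uint16)
        raw = tmp_path / "img.raw"
        img.tofile(raw)
        (tmp_path / "img.json").write_text(
            json.dumps({"shape": [16, 24], "dtype": "uint16"})
        )
        back = ap.read_image(raw)
        np.testing.assert_array_equal(back, img)
        # corrupt the sidecar shape
        (tmp_path / "img.json").write_text(
            json.dumps({"shape": [16, 25], "dtype": "uint16"})
        )
        with pytest.raises(ap.InputError):
            ap.read_image(raw)

    def test_unsupported_container_rejected(self, tmp_path):
        with pytest.raises(ap.InputError):
            ap.write_image(np.zeros((4, 4)), tmp_path / "img.bmp")


@pytest.fixture(scope="module")
def image_pair_dir(tmp_path_factory, line_pattern_adu):
    d = tmp_path_factory.mktemp("pair")
    thin = replicate_blur(line_pattern_adu, 1.0)
    thick = replicate_blur(line_pattern_adu, 2.0)
    ap.write_image(thin, d / "thin.tif")
    ap.write_image(thick, d / "thick.tif")
    return d


class TestPipeline:
    def test_run_pipeline_report_and_determinism(self, image_pair_dir, tmp_path):
        cfg = ap.PipelineConfig(
            thin_path=str(image_pair_dir / "thin.tif"),
            thick_path=str(image_pair_dir / "thick.tif"),
            output_dir=str(tmp_path / "out"),
            grid=ap.SigmaGrid(0.25, 3.0, 0.25),
            tv_cfg=ap.TVRestorationConfig(lam=0.01, max_iterations=60),
        )
        report = ap.run_pipeline(cfg)
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "restored.tif").exists()
        # defaults echoed in the self-describing report
        assert report["config"]["tv_cfg"]["lam"] == 0.01
        assert report["config"]["tv_cfg"]["tolerance"] == 1e-4
        target = np.sqrt(2.0**2 - 1.0**2)
        assert abs(report["sigma_final"] - target) <= 0.5
        # rerun reproduces every numeric field
        cfg2 = ap.PipelineConfig(**{**cfg.__dict__, "output_dir": str(tmp_path / "out2")})
        report2 = ap.run_pipeline(cfg2)
        assert report2["sigma_final"] == report["sigma_final"]
        np.testing.assert_array_equal(report2["ssim_curve"], report["ssim_curve"])
        assert report2["metrics"] == report["metrics"]

    def test_identical_pair_degenerates_gracefully(self, image_pair_dir, tmp_path):
        cfg = ap.PipelineConfig(
            thin_path=str(image_pair_dir / "thin.tif"),
            thick_path=str(image_pair_dir / "thin.tif"),
            output_dir=str(tmp_path / "same"),
            grid=ap.SigmaGrid(0.25, 1.5, 0.25),
            tv_cfg=ap.TVRestorationConfig(lam=0.01, max_iterations=40),
        )
        report = ap.run_pipeline(cfg)
        assert report["sigma_final"] == pytest.approx(0.25)

    def test_yaml_config_roundtrip(self, image_pair_dir, tmp_path):
        yaml_path = tmp_path / "cfg.yaml"
        yaml_path.write_text(
            "thin_path: {t}\nthick_path: {k}\noutput_dir: {o}\n"
            "grid: {{start: 0.5, stop: 1.5, step: 0.5}}\nmethod: wiener\n".format(
                t=image_pair_dir / "thin.tif",
                k=image_pair_dir / "thick.tif",
                o=tmp_path / "yout",
            )
        )
        cfg = ap.PipelineConfig.from_yaml(yaml_path)
        assert cfg.method == "wiener"
        assert cfg.grid.values.tolist() == [0.5, 1.0, 1.5]


class TestCLI:
    def test_estimate_sigma_command(self, image_pair_dir, tmp_path):
        out = tmp_path / "sigma.json"
        result = CliRunner().invoke(
            cli_main,
            ["estimate-sigma", "--thin", str(image_pair_dir / "thin.tif"),
             "--thick", str(image_pair_dir / "thick.tif"),
             "--grid", "0.25:3.0:0.25", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert abs(payload["sigma_final"] - np.sqrt(3.0)) <= 0.5

    def test_deconvolve_command(self, image_pair_dir, tmp_path):
        out = tmp_path / "restored.tif"
        result = CliRunner().invoke(
            cli_main,
            ["deconvolve", "--in", str(image_pair_dir / "thick.tif"),
             "--sigma", "1.7", "--method", "wiener", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert ap.read_image(out).shape == (160, 160)

    def test_mtf_inverse_command(self, tmp_path):
        curve = ap.mtf_from_sigma(2.61, np.linspace(0, 0.5, 51))
        path = tmp_path / "mtf.csv"
        from adaptpsf.io import write_curve_csv

        write_curve_csv(path, curve.frequencies, curve.values, "frequency,value")
        result = CliRunner().invoke(cli_main, ["mtf", "--curve", str(path)])
        assert result.exit_code == 0
        assert "2.61" in result.output

    def test_simulate_command(self, tmp_path, monkeypatch):
        # shrink the desk preset for test speed
        import adaptpsf.cli as cli_mod

        monkeypatch.setattr(
            cli_mod, "DESK_SCALE_GEOMETRY",
            ap.ProjectionGeometry(pixel_pitch=0.15, detector_shape=(64, 96), i0=2000.0),
        )
        monkeypatch.setattr(
            cli_mod, "build_dice_phantom",
            lambda n_voxels=150, **kw: ap.build_dice_phantom(n_voxels=60, **kw),
        )
        out = tmp_path / "sim"
        result = CliRunner().invoke(
            cli_main,
            ["simulate", "--profile", "detector1", "--profile", "detector2",
             "--seed", "3", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        manifest = json.loads((out / "manifest.json").read_text())
        assert set(manifest["outputs"]) == {"clean", "detector1", "detector2"}
        assert ap.read_image(out / "detector1.tif").shape == (64, 96)

    def test_missing_file_exit_code(self, tmp_path):
        result = CliRunner().invoke(
            cli_main,
            ["estimate-sigma", "--thin", str(tmp_path / "none.tif"),
             "--thick", str(tmp_path / "none.tif"), "--out", str(tmp_path / "o.json")],
        )
        assert result.exit_code == 2
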