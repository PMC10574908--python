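"""End-to-end: simulate a dual-detector acquisition, estimate, restore, report.

Projects a PMMA die phantom through a cone-beam geometry, degrades the clean
projection with the thin (detector1) and medium (detector2) profiles, runs the
full pipeline (sigma sweep -> averaging -> TV deconvolution of the thick
image) and prints the report's headline numbers.
"""

import tempfile
from pathlib import Path

import numpy as np

from adaptpsf import (
    PipelineConfig,
    ProjectionGeometry,
    SigmaGrid,
    TVRestorationConfig,
    build_dice_phantom,
    degrade_image,
    load_detector_profiles,
    project_phantom,
    run_pipeline,
    write_image,
)

phantom = build_dice_phantom(n_voxels=100)
geometry = ProjectionGeometry(pixel_pitch=0.1, detector_shape=(128, 160), i0=3000.0)
clean = project_phantom(phantom, geometry)

profiles = load_detector_profiles()
thin = degrade_image(clean, profiles["detector1"], seed=1)
thick = degrade_image(clean, profiles["detector2"], seed=2)

workdir = Path(tempfile.mkdtemp(prefix="adaptpsf_demo_"))
write_image(thin, workdir / "thin.tif")
write_image(thick, workdir / "thick.tif")

report = run_pipeline(
    PipelineConfig(
        thin_path=str(workdir / "thin.tif"),
        thick_path=str(workdir / "thick.tif"),
        output_dir=str(workdir / "out"),
        grid=SigmaGrid(start=0.1, stop=3.0, step=0.1),
        tv_cfg=TVRestorationConfig(lam=0.01),
    )
)

print(f"estimated sigma (SSIM/FSIM/final): {report['sigma_ssim']:.2f} / "
      f"{report['sigma_fsim']:.2f} / {report['sigma_final']:.2f} px")
m = report["metrics"]
print(f"mean gradient magnitude thin / thick / restored: "
      f"{m['gm_thin']:.1f} / {m['gm_thick_before']:.1f} / {m['gm_restored']:.1f}")
print(f"restored-vs-thin SSIM {m['ssim_restored_vs_thin']:.3f}, "
      f"FSIM {m['fsim_restored_vs_thin']:.3f}")

from adaptpsf import read_image  # noqa: E402

restored = read_image(workdir / "out" / "restored.tif")
rmse_thick = np.sqrt(((thick - clean) ** 2).mean())
rmse_rest = np.sqrt(((restored - clean) ** 2).mean())
print(f"RMSE to the clean projection: thick {rmse_thick:.1f} ADU -> restored {rmse_rest:.1f} ADU")
print(f"artifacts in {workdir}/out (report.json, restored.tif, score curves)")
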