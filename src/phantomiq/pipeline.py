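"""Full factorial experiment: simulate -> correct -> VOI -> metrics -> stats.

One experiment sweeps every (TBR, amplitude) combination of the design — by
default TBR in {2, 5, 10.5} and amplitude in {0, 7, 10, 20, 30} mm, one
acquisition each — measures all six spheres on the uncorrected and
surrogate-corrected images, and produces the paired record table (90 rows
per corrected flag by default), the ratio tables, the background-noise
summary, and the statistical report.

Every stochastic stage draws its seed deterministically from the master seed
and the cell's position in the design, so a re-run with the same
configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correction import CorrectionConfig, correct_motion
from .io import save_image
from .metrics import (MeasurementRecord, aggregate_ratios, noise_change,
                      records_to_frame)
from .phantom import (GridSpec, PhantomSpec, VoxelImage, rasterize_phantom,
                      sphere_volume_ml)
from .simulate import (DEFAULT_AMPLITUDES_MM, MotionSpec, motion_kernel,
                       simulate_acquisition)
from .stats import format_report, run_statistical_report
from .voi import background_stats, background_voi, refine_midpoint

logger = logging.getLogger("phantomiq")

DEFAULT_TBRS = (2.0, 5.0, 10.5)


@dataclass
class ExperimentConfig:
    """Everything needed to run one factorial experiment.

    The default phantom/grid pair is the "desk-scale" setup: real sphere and
    body dimensions with the scanner's voxel sizes, but a grid cropped to the
    phantom bounding box plus a 3 cm margin rather than the full 440 x 440
    matrix.  ``grid=None`` requests that cropped default.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    grid: GridSpec | None = None
    tbrs: tuple[float, ...] = DEFAULT_TBRS
    amplitudes: tuple[float, ...] = DEFAULT_AMPLITUDES_MM
    motion_axis: int = 2
    motion_speed_cm_s: float = 0.75
    psf_fwhm_mm: float = 5.0
    noise_model: str = "gaussian"
    noise_level: float = 0.15
    master_seed: int = 0
    correction_method: str = "richardson_lucy_like"
    correction_iterations: int = 25
    correction_regularization: float = 0.0
    supersample: int = 4
    background_voi_center_mm: tuple[float, float, float] = (-80.0, -52.0, 0.0)
    save_images: bool = False

    def resolved_grid(self) -> GridSpec:
        if self.grid is not None:
            return self.grid
        body = self.phantom.body
        margin = 30.0
        extent = (2 * body.semi_axis_x + 2 * margin,
                  2 * body.semi_axis_y + 2 * margin,
                  body.length + 2 * margin)
        return GridSpec.centered(extent)

    def cell_seed(self, tbr_index: int, amp_index: int) -> int:
        """Deterministic per-cell noise seed below 2**31."""
        ss = np.random.SeedSequence(entropy=self.master_seed,
                                    spawn_key=(tbr_index, amp_index))
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))

    def to_manifest(self) -> dict:
        payload = {
            "version": __version__,
            "tbrs": list(self.tbrs),
            "amplitudes": list(self.amplitudes),
            "sphere_diameters_mm": [d for d, _ in self.phantom.spheres],
            "background_activity_kbq_ml": self.phantom.background_activity,
            "calibration_to_scan_minutes": self.phantom.calibration_to_scan_minutes,
            "grid_shape": list(self.resolved_grid().shape),
            "voxel_size_mm": list(self.resolved_grid().voxel_size),
            "psf_fwhm_mm": self.psf_fwhm_mm,
            "noise_model": self.noise_model,
            "noise_level": self.noise_level,
            "master_seed": self.master_seed,
            "correction_method": self.correction_method,
            "correction_iterations": self.correction_iterations,
            "supersample": self.supersample,
            "background_voi_center_mm": list(self.background_voi_center_mm),
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()
        payload["config_sha256"] = digest
        return payload


def config_from_dict(cfg: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a (YAML-loaded) nested mapping."""
    phantom_cfg = cfg.get("phantom", {})
    phantom = PhantomSpec(
        background_activity=phantom_cfg.get("background_activity", 2.0),
        tbr=phantom_cfg.get("tbr", 5.0),
        calibration_to_scan_minutes=phantom_cfg.get("calibration_to_scan_minutes", 0.0),
    )
    grid = None
    if "grid" in cfg:
        g = cfg["grid"]
        grid = GridSpec(shape=tuple(g["shape"]),
                        voxel_size=tuple(g.get("voxel_size", (500 / 440, 500 / 440, 2.0))),
                        origin=tuple(g.get("origin", (0.0, 0.0, 0.0))))
    noise = cfg.get("noise", {})
    corr = cfg.get("correction", {})
    voi_cfg = cfg.get("voi", {})
    return ExperimentConfig(
        phantom=phantom,
        grid=grid,
        tbrs=tuple(cfg.get("tbrs", DEFAULT_TBRS)),
        amplitudes=tuple(cfg.get("amplitudes", DEFAULT_AMPLITUDES_MM)),
        psf_fwhm_mm=cfg.get("psf_fwhm_mm", 5.0),
        noise_model=noise.get("model", "gaussian"),
        noise_level=noise.get("level", 0.15),
        master_seed=cfg.get("seed", 0),
        correction_method=corr.get("method", "richardson_lucy_like"),
        correction_iterations=corr.get("iterations", 25),
        supersample=cfg.get("supersample", 4),
        background_voi_center_mm=tuple(
            voi_cfg.get("background_center_mm", (-80.0, -52.0, 0.0))),
        save_images=cfg.get("save_images", False),
    )


def measure_image(image: VoxelImage, phantom: PhantomSpec, amplitude: float,
                  corrected: bool,
                  background_center_mm: tuple[float, float, float],
                  ) -> list[MeasurementRecord]:
    """VOI search and metric extraction for all spheres of one image.

    The initial midpoint guess for each sphere is the voxel nearest its true
    center (the batch equivalent of the interactive click), then refined by
    the local search.  The background VOI reuses the largest sphere's
    half-width at the fixed configured position.
    """
    grid = image.grid
    r_largest = max(d for d, _ in phantom.spheres) / 2.0
    bg_voi = background_voi(grid, r_largest, center_mm=background_center_mm,
                            phantom=phantom)
    b_mean, sigma_b = background_stats(image, bg_voi)
    records = []
    for k, (d, center) in enumerate(phantom.spheres):
        initial = grid.nearest_voxel(center)
        _, stats = refine_midpoint(image, initial, r_s=d / 2.0)
        records.append(MeasurementRecord(
            sphere_id=k,
            sphere_diameter_mm=d,
            sphere_volume_ml=round(sphere_volume_ml(d), 1),
            amplitude=amplitude,
            tbr=phantom.tbr,
            corrected=corrected,
            t_max=stats.t_max,
            t_mean=stats.t_mean,
            b_mean=b_mean,
            sigma_b=sigma_b,
            t_in=phantom.sphere_activity,
            b_in=phantom.background_activity,
        ))
    return records


def run_experiment(config: ExperimentConfig,
                   output_dir: str | Path | None = None) -> dict:
    """Run the full factorial design and return every result table.

    Returns a dict with ``records`` (one row per sphere x amplitude x TBR x
    corrected flag), ``ratios_over_tbr``, ``ratios_over_sphere``,
    ``noise_change``, ``stat_results``, ``stat_report`` (text) and
    ``manifest``.  When ``output_dir`` is given, everything is also written
    there as CSV/JSON/text (and NIfTI images if ``save_images``).
    """
    grid = config.resolved_grid()
    all_records: list[MeasurementRecord] = []
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for it, tbr in enumerate(config.tbrs):
        phantom = PhantomSpec(
            spheres=config.phantom.spheres,
            background_activity=config.phantom.background_activity,
            tbr=tbr,
            body=config.phantom.body,
            background_volume_l=config.phantom.background_volume_l,
            calibration_to_scan_minutes=config.phantom.calibration_to_scan_minutes,
        )
        if phantom.calibration_to_scan_minutes > 0:
            phantom = phantom.decayed(phantom.calibration_to_scan_minutes)
        logger.info("rasterizing phantom, TBR %s", tbr)
        truth = rasterize_phantom(phantom, grid, supersample=config.supersample)
        for ia, amp in enumerate(config.amplitudes):
            label = f"tbr{tbr:g}_amp{amp:g}"
            logger.info("simulating cell %s", label)
            try:
                motion = MotionSpec(amplitude=amp, speed=config.motion_speed_cm_s,
                                    axis=config.motion_axis)
                seed = config.cell_seed(it, ia)
                acquired, kernel = simulate_acquisition(
                    truth, motion, psf_fwhm=config.psf_fwhm_mm,
                    noise_model=config.noise_model,
                    noise_level=config.noise_level, seed=seed)
                corr = CorrectionConfig(
                    kernel=kernel, method=config.correction_method,
                    iterations=config.correction_iterations,
                    regularization=config.correction_regularization,
                    axis=config.motion_axis)
                corrected = correct_motion(acquired, corr)
                all_records += measure_image(
                    acquired, phantom, amp, corrected=False,
                    background_center_mm=config.background_voi_center_mm)
                all_records += measure_image(
                    corrected, phantom, amp, corrected=True,
                    background_center_mm=config.background_voi_center_mm)
                if out is not None and config.save_images:
                    save_image(acquired, out / f"{label}_uncorrected.nii.gz")
                    save_image(corrected, out / f"{label}_corrected.nii.gz")
            except Exception as exc:
                raise RuntimeError(f"experiment cell {label} failed: {exc}") from exc

    records = records_to_frame(all_records)
    ratios_tbr = aggregate_ratios(records, "over_tbr")
    ratios_sphere = aggregate_ratios(records, "over_sphere")
    noise = noise_change(records)
    stat_results, qq = run_statistical_report(records)
    report = format_report(stat_results)
    manifest = config.to_manifest()
    manifest["n_records"] = int(len(records))
    manifest["n_pairs"] = int(len(records)) // 2

    results = {
        "records": records,
        "ratios_over_tbr": ratios_tbr,
        "ratios_over_sphere": ratios_sphere,
        "noise_change": noise,
        "stat_results": stat_results,
        "qq_tables": qq,
        "stat_report": report,
        "manifest": manifest,
    }
    if out is not None:
        _write_outputs(results, out)
    return results


def _float_fmt(x):
    return f"{x:.12g}"


def _write_outputs(results: dict, out: Path) -> None:
    results["records"].to_csv(out / "records.csv", index=False,
                              float_format="%.12g")
    results["ratios_over_tbr"].to_csv(out / "ratios_over_tbr.csv", index=False,
                                      float_format="%.12g")
    results["ratios_over_sphere"].to_csv(out / "ratios_over_sphere.csv",
                                         index=False, float_format="%.12g")
    results["noise_change"]["per_cell"].to_csv(out / "noise_change.csv",
                                               index=False, float_format="%.12g")
    results["stat_results"].to_csv(out / "stat_results.csv", index=False,
                                   float_format="%.12g")
    (out / "stat_report.txt").write_text(results["stat_report"] + "\n")
    noise_summary = {k: v for k, v in results["noise_change"].items()
                     if k != "per_cell"}
    (out / "manifest.json").write_text(
        json.dumps({**results["manifest"], "noise_change": noise_summary},
                   indent=2, sort_keys=True) + "\n")


def plot_ratio_figure(ratios: pd.DataFrame, parameter: str, path: str | Path,
                      ) -> None:
    """Ratio vs sphere volume, one line per amplitude (from the CSV table)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = ratios[ratios["parameter"] == parameter]
    fig, ax = plt.subplots(figsize=(6, 4))
    for amp, grp in sub.groupby("amplitude"):
        grp = grp.sort_values("sphere_volume_ml", ascending=False)
        ax.plot(grp["sphere_volume_ml"], grp["ratio"], marker="o",
                label=f"{amp:g} mm")
    ax.invert_xaxis()
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("sphere volume (mL), large to small")
    ax.set_ylabel(f"{parameter} ratio (with / without correction)")
    ax.legend(title="amplitude")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
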