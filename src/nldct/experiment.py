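"""Experiment orchestration: the full pipeline x CNR x N grid.

``run_experiment`` reproduces the study grid at a selectable scale: for
each noise level it calibrates the incident intensity to the target CNR
(cached per CNR, since CNR is defined on FBP images only), simulates the
acquisition stack, and for each pipeline computes the NLDobject,
NLDobject' and NLDnoise images, the percentile maps, muscle-ROI noise
table and horizontal profiles.  Every artifact is written as float TIFF /
CSV with a JSON manifest tying it to its parameters and seeds; the whole
run is reproducible from (config, master_seed).

At a given CNR the acquisition stack is simulated once at the largest
requested N and prefixes are used for smaller N, so all N share the same
noise level and seed family.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nio
from .acquisition import (
    AcquisitionStack,
    calibrate_incident_intensity,
    simulate_low_noise,
    simulate_stack,
    tune_tv_lambda,
)
from .nld import extract_profile, nld_noise, nld_object, nld_object_approx, roi_stats
from .phantom import build_phantom, cnr_rois, default_rois
from .projection import FanBeamGeometry, desk_geometry, paper_geometry
from .reconstruct import ReconConfig, reconstruct_stack

logger = logging.getLogger("nldct")

__all__ = ["ExperimentConfig", "run_experiment", "make_report", "geometry_for_scale"]

#: display windows (HU) for the rendered previews
DISPLAY_WINDOWS = {"image": (-150.0, 250.0), "nld_object": (-10.0, 10.0), "nld_noise": (-50.0, 50.0), "percentile": (-50.0, 50.0)}


def geometry_for_scale(scale: str) -> FanBeamGeometry:
    if scale == "desk":
        return desk_geometry()
    if scale == "paper":
        return paper_geometry()
    raise ValueError(f"unknown scale preset {scale!r}")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment grid."""

    scale: str = "desk"
    pipelines: tuple[str, ...] = ("fbp", "sirtmed", "cglstv")
    cnr_targets: tuple[float, ...] = (0.4, 0.7, 1.4, 2.4)
    n_repeats: tuple[int, ...] | None = None  # default depends on scale
    master_seed: int = 1
    out_dir: str = "nldct-run"
    calibration_realizations: int = 48
    display_windows: dict = field(default_factory=lambda: dict(DISPLAY_WINDOWS))

    def __post_init__(self):
        if self.n_repeats is None:
            self.n_repeats = (16, 32, 64, 128, 256) if self.scale == "paper" else (8, 16, 32)
        self.pipelines = tuple(self.pipelines)
        self.cnr_targets = tuple(float(c) for c in self.cnr_targets)
        self.n_repeats = tuple(int(n) for n in self.n_repeats)
        if any(c <= 0 for c in self.cnr_targets):
            raise ValueError("cnr_targets must be positive")
        if any(n < 2 for n in self.n_repeats):
            raise ValueError("n_repeats entries must be >= 2")
        unknown = set(self.pipelines) - {"fbp", "sirtmed", "cglstv"}
        if unknown:
            raise ValueError(f"unknown pipelines: {sorted(unknown)}")

    def geometry(self) -> FanBeamGeometry:
        return geometry_for_scale(self.scale)


def _pipeline_config(name: str, tv_lambda: float | None) -> ReconConfig:
    if name == "fbp":
        return ReconConfig.fbp_preset()
    if name == "sirtmed":
        return ReconConfig.sirtmed_preset()
    if name == "cglstv":
        return ReconConfig.cglstv_preset(tv_lambda=tv_lambda if tv_lambda else 1.9)
    raise ValueError(f"unknown pipeline {name!r}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full grid; returns (and writes) the manifest."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = config.geometry()
    grid = geom.image_rows
    phantom = build_phantom(grid, geom.pixel_size)
    rois = {r.role: r for r in default_rois(grid)}
    liver_cal, muscle_cal = cnr_rois(grid)

    nio.save_image(out / "phantom.tiff", phantom, rois={r: dataclasses.asdict(v) for r, v in rois.items()})

    manifest: dict = {
        "scale": config.scale,
        "master_seed": config.master_seed,
        "geometry": nio.geometry_to_dict(geom),
        "geometry_hash": nio.geometry_hash(geom),
        "pipelines": list(config.pipelines),
        "cnr_targets": list(config.cnr_targets),
        "n_repeats": list(config.n_repeats),
        "display_windows": {k: list(v) for k, v in config.display_windows.items()},
        "calibration": {},
        "tv_lambda": {},
        "entries": [],
        "noise_table": [],
    }

    n_max = max(config.n_repeats)
    for cnr_t in config.cnr_targets:
        t0 = time.time()
        i0 = calibrate_incident_intensity(
            phantom,
            geom,
            cnr_t,
            liver_cal,
            muscle_cal,
            config.master_seed,
            n_realizations=config.calibration_realizations,
        )
        manifest["calibration"][str(cnr_t)] = i0
        logger.info("calibrated CNR %.2f -> I0 %.1f (%.1fs)", cnr_t, i0, time.time() - t0)

        tv_lambda = None
        if "cglstv" in config.pipelines:
            t0 = time.time()
            tv_lambda = tune_tv_lambda(phantom, geom, i0, muscle_cal, config.master_seed)
            manifest["tv_lambda"][str(cnr_t)] = tv_lambda
            logger.info("tuned TV lambda %.3f at CNR %.2f (%.1fs)", tv_lambda, cnr_t, time.time() - t0)

        stack_full = simulate_stack(phantom, geom, i0, n_max, config.master_seed, cnr_target=cnr_t)
        nio.save_stack(out / f"stack_cnr{cnr_t}.tiff", stack_full)

        for pipeline in config.pipelines:
            pcfg = _pipeline_config(pipeline, tv_lambda)
            for n in config.n_repeats:
                t0 = time.time()
                stack = AcquisitionStack(
                    sinograms=stack_full.sinograms[:n],
                    geometry=geom,
                    incident_intensity=i0,
                    master_seed=config.master_seed,
                    seeds=stack_full.seeds[:n],
                    cnr_target=cnr_t,
                    noise_free=stack_full.noise_free,
                )
                tag = f"{pipeline}_cnr{cnr_t}_n{n}"
                obj = nld_object(stack, pcfg, geom)
                low_sino = simulate_low_noise(phantom, geom, i0, n, config.master_seed)
                low_img = reconstruct_stack(low_sino.values, pcfg, geom)
                approx = nld_object_approx(stack, pcfg, low_img, geom)
                noise = nld_noise(stack, pcfg, geom)

                entry = {
                    "pipeline": pipeline,
                    "cnr": cnr_t,
                    "n": n,
                    "i0": i0,
                    "tv_lambda": tv_lambda,
                    "seeds": list(stack.seeds),
                    "files": {},
                }
                images = {
                    "nld_object": obj.nld_image,
                    "nld_object_approx": approx.nld_image,
                    "sb_bar": obj.sb_bar,
                    "sb_tilde": obj.sb_tilde,
                    "nld_noise_first": noise.series[0],
                }
                for level, img in obj.percentiles.items():
                    images[f"percentile_{int(level)}"] = img
                for name, img in images.items():
                    fname = f"{tag}_{name}.tiff"
                    nio._write(out / fname, img, {"kind": name, "pipeline": pipeline, "cnr": cnr_t, "n": n, "units": "HU"})
                    entry["files"][name] = fname

                prow = rois["profile_row"]
                profile = extract_profile(obj.nld_image, prow.row, 0, grid)
                pfile = f"{tag}_profile.csv"
                np.savetxt(
                    out / pfile,
                    np.column_stack([np.arange(grid), profile]),
                    delimiter=",",
                    header="pixel,nld_hu",
                    comments="",
                )
                entry["files"]["profile"] = pfile

                sigmas = [roi_stats(r, rois["muscle"])[1] for r in (obj.per_acquisition + obj.sb_tilde)]
                manifest["noise_table"].append(
                    {"pipeline": pipeline, "cnr": cnr_t, "n": n, "muscle_sigma": float(np.mean(sigmas))}
                )
                manifest["entries"].append(entry)
                logger.info("%s done (%.1fs)", tag, time.time() - t0)

    manifest["runtime_s"] = time.time() - t_start
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _window(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def make_report(manifest_path) -> Path:
    """Render image panels (study display windows) with profile plots.

    Regeneration is idempotent: the report depends only on the manifest and
    the artifacts it lists.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import tifffile

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())

    missing = [
        f
        for e in manifest["entries"]
        for f in e["files"].values()
        if not (root / f).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing artifacts: {missing}")

    windows = manifest["display_windows"]
    entries = manifest["entries"]
    ncols = max(1, len(entries))
    fig, axes = plt.subplots(3, ncols, figsize=(3 * ncols, 9), squeeze=False)
    for j, e in enumerate(entries):
        tag = f"{e['pipeline']} CNR {e['cnr']} N {e['n']}"
        obj = tifffile.imread(root / e["files"]["nld_object"])
        noi = tifffile.imread(root / e["files"]["nld_noise_first"])
        lo, hi = windows["nld_object"]
        axes[0][j].imshow(_window(obj, lo, hi), cmap="gray", vmin=0, vmax=1)
        axes[0][j].set_title(f"NLDobject\n{tag}", fontsize=7)
        lo, hi = windows["nld_noise"]
        axes[1][j].imshow(_window(noi, lo, hi), cmap="gray", vmin=0, vmax=1)
        axes[1][j].set_title("NLDnoise (first)", fontsize=7)
        prof = np.loadtxt(root / e["files"]["profile"], delimiter=",", skiprows=1)
        axes[2][j].plot(prof[:, 0], prof[:, 1], lw=0.8)
        axes[2][j].set_ylim(-70, 70)
        axes[2][j].set_title("NLDobject profile", fontsize=7)
        for row in axes[:2]:
            row[j].set_axis_off()
    fig.tight_layout()
    out = root / "report.png"
    fig.savefig(out, dpi=110)
    plt.close(fig)
    return out
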