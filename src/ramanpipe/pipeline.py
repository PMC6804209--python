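"""End-to-end orchestration: simulate -> preprocess -> classify ->
band-image -> texture -> report, fully seed-deterministic."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import chemometrics, cube as cube_mod, io as rio, preprocess, synth, texture

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "generate_fixture"]

FIXTURE_PRESETS = {
    "small": {"n_spectra_per_class": 20, "cube_shape": (20, 50)},
    "tiny": {"n_spectra_per_class": 5, "cube_shape": (8, 12)},
}


@dataclass
class RunConfig:
    """Everything a run needs; serialized verbatim into the output dir."""

    outdir: str = "ramanpipe_run"
    seed: int = 0
    # inputs: synthetic by default, or a CSV of labeled spectra
    spectra_csv: str | None = None
    n_spectra_per_class: int = 100
    noise_sd: float = 0.02
    baseline_magnitude: float = 0.5
    # preprocessing
    baseline_degree: int = 9
    sg_window: int = 21
    sg_order: int = 3
    crop_silent_region: bool = True
    # chemometrics
    classify: bool = True
    variance_threshold: float = 0.95
    holdout_fraction: float = 0.25
    split_level: str = "spectrum"
    k_neighbors: int = 1
    # imaging / texture
    imaging: bool = True
    run_texture: bool = True
    bands: tuple = synth.BAND_CENTERS
    half_window: float = 5.0
    n_levels: int = 8
    cube_shape: tuple = (20, 50)
    overlay_bands: tuple = (1331.0, 1445.0)
    reference_class: str = "gland"

    def validate(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if self.sg_window % 2 == 0 or self.sg_order >= self.sg_window:
            raise ValueError("bad Savitzky-Golay parameters")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def preprocess_config(self) -> preprocess.PreprocessConfig:
        regions = preprocess.DEFAULT_REGIONS if self.crop_silent_region else None
        return preprocess.PreprocessConfig(
            baseline=preprocess.BaselineFitConfig(degree=self.baseline_degree),
            sg_window=self.sg_window,
            sg_order=self.sg_order,
            regions=regions,
            on_constant="zeros",
        )

    def synthetic_config(self, n: int | None = None) -> synth.SyntheticConfig:
        return synth.SyntheticConfig(
            n_spectra_per_class=n or self.n_spectra_per_class,
            noise_sd=self.noise_sd,
            baseline=("polynomial", self.baseline_magnitude),
            seed=self.seed,
        )


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all requested stages in order; return a run report dict.

    Every artifact in the output directory is reproducible from the
    serialized config + seed alone.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(asdict(config), sort_keys=True)
    )
    report: dict = {"seed": config.seed, "stages": []}
    pp = config.preprocess_config()

    # --- spectra: load or simulate -------------------------------------
    t0 = _stage("spectra")
    if config.spectra_csv:
        dataset = rio.read_labeled_csv(config.spectra_csv)
    else:
        dataset = synth.simulate_labeled_dataset(config.synthetic_config())
        rio.write_labeled_csv(dataset, outdir / "spectra_raw.csv")
    report["n_spectra"] = dataset.n_spectra
    report["stages"].append(("spectra", time.perf_counter() - t0))

    # --- classification -------------------------------------------------
    if config.classify:
        t0 = _stage("classify")
        wn, Y, info = preprocess.preprocess_matrix(
            dataset.wavenumbers, dataset.intensities, pp
        )
        if info["baseline_not_converged"] or info["constant_fallbacks"]:
            logger.warning("preprocess warnings: %s", info)
        pre = type(dataset)(
            wavenumbers=wn, intensities=Y, labels=dataset.labels,
            biopsy_ids=dataset.biopsy_ids,
        )
        cls_report = chemometrics.holdout_classification(
            pre,
            variance_threshold=config.variance_threshold,
            fraction=config.holdout_fraction,
            level=config.split_level,
            k=config.k_neighbors,
            seed=config.seed,
        )
        (outdir / "classification.json").write_text(
            json.dumps(cls_report.to_dict(), indent=2)
        )
        np.savetxt(
            outdir / "confusion_matrix.csv", cls_report.confusion,
            fmt="%d", delimiter=",",
            header=",".join(str(c) for c in cls_report.classes),
        )
        report["classification"] = cls_report.to_dict()
        report["preprocess_warnings"] = info
        report["stages"].append(("classify", time.perf_counter() - t0))

    # --- imaging + texture ---------------------------------------------
    if config.imaging:
        t0 = _stage("imaging")
        band_images: dict = {}
        rng = np.random.default_rng(config.seed)
        for cls in synth.IMAGING_CLASSES:
            profile = synth.make_class_profile(cls, rng_seed=int(rng.integers(2**31)))
            pattern = synth.smooth_random_pattern(
                config.cube_shape, synth.BAND_CENTERS,
                seed=int(rng.integers(2**31)),
            )
            cube = synth.simulate_cube(
                profile, pattern, config.synthetic_config(),
                seed=int(rng.integers(2**31)),
            )
            rio.write_cube_h5(cube, outdir / f"cube_{cls}.h5")
            band_images[cls] = {
                band: cube_mod.extract_band_image(cube, band, config.half_window)
                for band in config.bands
            }
        a_band, b_band = config.overlay_bands
        overlay = cube_mod.two_band_overlay(
            band_images[config.reference_class][a_band],
            band_images[config.reference_class][b_band],
        )
        plt.imsave(outdir / "overlay.png", np.clip(overlay, 0, 1))
        report["imaging_classes"] = list(synth.IMAGING_CLASSES)
        report["stages"].append(("imaging", time.perf_counter() - t0))

        if config.run_texture:
            t0 = _stage("texture")
            grouped = {
                (cls, band): [band_images[cls][band]]
                for cls in band_images for band in config.bands
            }
            summary = texture.class_texture_summary(grouped, n_levels=config.n_levels)
            summary.to_csv(outdir / "texture_features.csv", index=False)
            corr = texture.class_band_correlation_matrix(
                band_images, reference=config.reference_class
            )
            corr.to_csv(outdir / "correlation_matrix.csv")
            _heatmap(corr, outdir / "correlation_matrix.png")
            report["texture_rows"] = int(len(summary))
            report["stages"].append(("texture", time.perf_counter() - t0))

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _heatmap(frame, path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(frame.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(frame.columns)), [f"{c:g}" for c in frame.columns],
                  rotation=90)
    ax.set_yticks(range(len(frame.index)), list(frame.index))
    fig.colorbar(im, ax=ax, label="corr2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def generate_fixture(kind: str, preset: str, seed: int, outdir) -> Path:
    """Write a small deterministic fixture (spectra CSV or cube HDF5)."""
    if kind not in ("spectra", "cube"):
        raise ValueError("kind must be 'spectra' or 'cube'")
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"preset must be one of {sorted(FIXTURE_PRESETS)}")
    params = FIXTURE_PRESETS[preset]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "spectra":
        cfg = synth.SyntheticConfig(
            n_spectra_per_class=params["n_spectra_per_class"], seed=seed
        )
        path = outdir / f"spectra_{preset}_{seed}.csv"
        rio.write_labeled_csv(synth.simulate_labeled_dataset(cfg), path)
    else:
        cfg = synth.SyntheticConfig(seed=seed)
        profile = synth.make_class_profile("gland", rng_seed=seed)
        pattern = synth.smooth_random_pattern(
            params["cube_shape"], synth.BAND_CENTERS, seed=seed
        )
        path = outdir / f"cube_{preset}_{seed}.h5"
        rio.write_cube_h5(synth.simulate_cube(profile, pattern, cfg, seed=seed), path)
    return path
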