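"""End-to-end experiment pipelines with seeded determinism and reports.

Two experiments are provided:

* ``noise_correlation`` — the three-rod phantom is scanned, decomposed
  (2/3/4 materials), and reconstructed twice (noisy and matched
  noiseless); per-rod, per-pair Pearson noise correlations are measured
  and compared with analytic covariance propagation at each rod's
  central-ray operating point.
* ``head_vmi`` — the head phantom is decomposed into one of four basis
  material sets (BM-1..BM-4), basis images and a 45-keV VMI are formed,
  and background noise plus lesion CNR are reported.

A single seed fixes every stochastic stage; identical configurations
produce identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .decomposition import ForwardModel, calibrate, decompose_sinogram
from .materials import get_material
from .metrics import cnr, noise_correlation_report, synthesize_vmi
from .noise import effective_mu, operating_point, propagate_covariance
from .phantoms import (BASIS_NAMES, ROD_FRACTIONS, PhantomImage,
                       build_head_phantom, build_noise_phantom, roi_pixels)
from .projection import Geometry, expected_counts, line_integrals, sample_counts
from .reconstruction import reconstruct_all
from .spectrum import CHANNEL_PRESETS, DetectorResponse, source_spectrum

#: head-experiment basis material sets
BASIS_SETS: dict[str, tuple[str, ...]] = {
    "BM-1": ("adipose", "pmma", "teflon"),
    "BM-2": ("adipose", "pmma", "iodine_20mgml"),
    "BM-3": ("soft_tissue", "iodine_20mgml", "cortical_bone"),
    "BM-4": ("adipose", "iodine_20mgml", "teflon"),
}

VMI_ENERGY_KEV = 45.0


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    experiment: str = "noise_correlation"  # or "head_vmi"
    mode: str = "2md"  # 2md | 3md | 4md (noise_correlation)
    basis_set: str = "BM-3"  # BM-1..BM-4 (head_vmi)
    response: str = "ideal"  # ideal | realistic
    fluence_scale: float = 1e7
    n_pixels: int = 256
    pixel_mm: float = 1.0
    n_cells: int = 432
    cell_pitch_mm: float = 2.048
    n_views: int = 360
    seed: int = 0
    fbp_window: str = "hann"
    out_dir: str | None = None

    def __post_init__(self):
        if self.experiment not in ("noise_correlation", "head_vmi"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.mode not in ROD_FRACTIONS:
            raise ValueError(f"mode must be one of {sorted(ROD_FRACTIONS)}")
        if self.basis_set not in BASIS_SETS:
            raise ValueError(f"basis_set must be one of {sorted(BASIS_SETS)}")
        if self.response not in ("ideal", "realistic"):
            raise ValueError("response must be 'ideal' or 'realistic'")
        if self.fluence_scale <= 0:
            raise ValueError("fluence_scale must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def geometry(self) -> Geometry:
        return Geometry(n_cells=self.n_cells, cell_pitch=self.cell_pitch_mm,
                        n_views=self.n_views)


@dataclass
class Report:
    """Everything a run measured, plus provenance."""

    config: dict
    version: str
    basis_names: tuple[str, ...]
    roi_noise: dict  # roi -> material -> std of noise image
    roi_means: dict | None = None  # roi -> material -> mean of noisy image
    pearson: object | None = None  # DataFrame for noise_correlation runs
    analytic: dict | None = None  # roi -> CovarianceEstimate summary
    vmi_noise: dict | None = None  # head runs
    vmi_cnr: dict | None = None
    artifacts: dict = field(default_factory=dict)


def _forward_model(cfg: RunConfig, basis_names) -> ForwardModel:
    spectrum = source_spectrum(fluence_scale=cfg.fluence_scale)
    channels = CHANNEL_PRESETS[len(basis_names)]
    response = DetectorResponse(cfg.response)
    basis = tuple(get_material(n) for n in basis_names)
    return ForwardModel(spectrum, channels, response, basis)


def _scan_decompose_reconstruct(cfg: RunConfig, phantom: PhantomImage,
                                fm: ForwardModel, a_max: np.ndarray,
                                ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run the full chain twice (noisy, matched noiseless); returns the
    two basis-image stacks and solver diagnostics."""
    geom = cfg.geometry()
    a_true = line_integrals(phantom, geom)
    calib = calibrate(fm, a_max=a_max)
    counts = sample_counts(a_true, fm.spectrum, fm.channels, fm.response,
                           phantom.materials, seed=cfg.seed)
    dec_noisy = decompose_sinogram(counts, fm, calib)
    ibar = expected_counts(a_true, fm.spectrum, fm.channels, fm.response,
                           phantom.materials)
    dec_clean = decompose_sinogram(ibar, fm, calib)
    img_noisy = reconstruct_all(dec_noisy.a_est, geom, cfg.n_pixels,
                                cfg.pixel_mm, window=cfg.fbp_window)
    img_clean = reconstruct_all(dec_clean.a_est, geom, cfg.n_pixels,
                                cfg.pixel_mm, window=cfg.fbp_window)
    diag = {
        "nonconverged_noisy": float(1 - dec_noisy.converged.mean()),
        "nonconverged_clean": float(1 - dec_clean.converged.mean()),
        "calibration_residual_cm": calib.max_residual,
    }
    return img_noisy, img_clean, diag


def _central_ray_a(mode: str, rod_index: int) -> np.ndarray:
    """Basis line integrals of a representative ray through one rod:
    a diameter path through the water cylinder plus the rod composition
    along the rod chord through its center.  The water part maps onto the
    basis as soft-tissue path (first basis material), which is the
    dominant term of its decomposition."""
    water_path_cm = 20.0 - 7.0
    a = 7.0 * np.asarray(ROD_FRACTIONS[mode][rod_index], dtype=float)
    a[0] += water_path_cm
    return a


def run_noise_correlation(cfg: RunConfig) -> Report:
    """Noise-correlation experiment on the three-rod phantom."""
    if cfg.experiment != "noise_correlation":
        raise ValueError("config experiment must be 'noise_correlation'")
    basis_names = BASIS_NAMES[cfg.mode]
    fm = _forward_model(cfg, basis_names)
    phantom = build_noise_phantom(cfg.mode, cfg.n_pixels, cfg.pixel_mm)
    max_frac = np.max(np.asarray(ROD_FRACTIONS[cfg.mode]), axis=0)
    a_max = 1.2 * 20.0 * np.maximum(max_frac, 0.2)
    a_max[0] = 1.2 * 24.0  # water background decomposes mostly into tissue
    img_noisy, img_clean, diag = _scan_decompose_reconstruct(
        cfg, phantom, fm, a_max)
    noise = img_noisy - img_clean

    table = noise_correlation_report(noise, cfg.pixel_mm, phantom.rois,
                                     list(basis_names))
    roi_noise = {
        roi.name: {
            name: float(np.std(roi_pixels(noise[:, :, i], cfg.pixel_mm, roi)))
            for i, name in enumerate(basis_names)
        }
        for roi in phantom.rois
    }
    roi_means = {
        roi.name: {
            name: float(np.mean(roi_pixels(img_noisy[:, :, i], cfg.pixel_mm, roi)))
            for i, name in enumerate(basis_names)
        }
        for roi in phantom.rois
    }
    analytic = {}
    for idx, roi in enumerate(phantom.rois):
        a_op = _central_ray_a(cfg.mode, idx)
        cov = propagate_covariance(effective_mu(fm, a_op),
                                   operating_point(fm, a_op))
        analytic[roi.name] = {
            "rho_a": cov.rho_a.tolist(),
            "sigma_a": cov.sigma.tolist(),
            "delta": cov.delta,
        }
    report = Report(config=asdict(cfg), version=__version__,
                    basis_names=basis_names, roi_noise=roi_noise,
                    roi_means=roi_means, pearson=table, analytic=analytic,
                    artifacts=diag)
    if cfg.out_dir:
        _save_artifacts(report, cfg, img_noisy, img_clean)
    return report


def run_head_vmi(cfg: RunConfig) -> Report:
    """Head-phantom 3-MD run with one basis set; basis images + 45 keV VMI."""
    if cfg.experiment != "head_vmi":
        raise ValueError("config experiment must be 'head_vmi'")
    basis_names = BASIS_SETS[cfg.basis_set]
    fm = _forward_model(cfg, basis_names)
    phantom = build_head_phantom(cfg.n_pixels, cfg.pixel_mm)
    a_max = np.full(len(basis_names), 30.0)
    img_noisy, img_clean, diag = _scan_decompose_reconstruct(
        cfg, phantom, fm, a_max)
    noise = img_noisy - img_clean
    basis = fm.basis
    vmi_noisy = synthesize_vmi(img_noisy, basis, VMI_ENERGY_KEV)
    vmi_clean = synthesize_vmi(img_clean, basis, VMI_ENERGY_KEV)
    signal_roi, background_roi = phantom.rois

    roi_noise = {
        background_roi.name: {
            name: float(np.std(roi_pixels(noise[:, :, i], cfg.pixel_mm,
                                          background_roi)))
            for i, name in enumerate(basis_names)
        }
    }
    vmi_noise = {
        "background": float(np.std(roi_pixels(vmi_noisy - vmi_clean,
                                              cfg.pixel_mm, background_roi))),
    }
    res = cnr(roi_pixels(vmi_noisy, cfg.pixel_mm, signal_roi),
              roi_pixels(vmi_noisy, cfg.pixel_mm, background_roi))
    vmi_cnr = {"cnr": res.cnr, "contrast": res.contrast,
               "m_sig": res.m_sig, "m_bkg": res.m_bkg,
               "sigma_sig": res.sigma_sig, "sigma_bkg": res.sigma_bkg}
    # noiseless VMI background mean, for basis-set-invariance checks
    vmi_clean_bkg = float(np.mean(roi_pixels(vmi_clean, cfg.pixel_mm,
                                             background_roi)))
    report = Report(config=asdict(cfg), version=__version__,
                    basis_names=basis_names, roi_noise=roi_noise,
                    vmi_noise=vmi_noise, vmi_cnr=vmi_cnr,
                    artifacts={**diag, "vmi_clean_background": vmi_clean_bkg})
    if cfg.out_dir:
        _save_artifacts(report, cfg, img_noisy, img_clean,
                        vmi=(vmi_noisy, vmi_clean))
    return report


def sweep_head_vmi(base: RunConfig, basis_sets=None) -> dict[str, Report]:
    """Run the head experiment over several basis sets at matched dose."""
    from dataclasses import replace

    basis_sets = tuple(basis_sets or BASIS_SETS)
    return {bs: run_head_vmi(replace(base, basis_set=bs)) for bs in basis_sets}


def _save_artifacts(report: Report, cfg: RunConfig, img_noisy, img_clean,
                    vmi=None) -> None:
    import tifffile

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "basis_noisy.tif",
                     np.moveaxis(img_noisy, 2, 0).astype(np.float32))
    tifffile.imwrite(out / "basis_noiseless.tif",
                     np.moveaxis(img_clean, 2, 0).astype(np.float32))
    if vmi is not None:
        tifffile.imwrite(out / "vmi_45kev.tif",
                         np.stack(vmi).astype(np.float32))
    cfg.to_yaml(out / "config.yaml")
    payload = {
        "version": report.version,
        "basis_names": list(report.basis_names),
        "roi_noise": report.roi_noise,
        "analytic": report.analytic,
        "vmi_noise": report.vmi_noise,
        "vmi_cnr": report.vmi_cnr,
        "artifacts": report.artifacts,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    if report.pearson is not None:
        report.pearson.to_csv(out / "pearson.csv", index=False)
    report.artifacts["out_dir"] = str(out)


def make_figures(report_dir: str | Path) -> list[Path]:
    """Scatterplots, noise bars and image montages from saved artifacts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd
    import tifffile

    out = Path(report_dir)
    report_path = out / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"no report.json under {out}")
    with open(report_path) as fh:
        report = json.load(fh)
    noisy = np.moveaxis(tifffile.imread(out / "basis_noisy.tif"), 0, 2)
    clean = np.moveaxis(tifffile.imread(out / "basis_noiseless.tif"), 0, 2)
    noise = noisy - clean
    names = report["basis_names"]
    written = []

    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 4))
    for ax, i in zip(np.atleast_1d(axes), range(len(names))):
        ax.imshow(noisy[:, :, i], cmap="gray")
        ax.set_title(names[i])
        ax.axis("off")
    path = out / "basis_images.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)

    pearson_csv = out / "pearson.csv"
    if pearson_csv.exists():
        table = pd.read_csv(pearson_csv)
        pairs = table[["material_1", "material_2"]].drop_duplicates()
        fig, axes = plt.subplots(1, len(pairs),
                                 figsize=(4 * len(pairs), 4), squeeze=False)
        center = noise.shape[0] // 2
        sl = slice(center - 20, center + 20)
        for ax, (_, row) in zip(axes[0], pairs.iterrows()):
            i, j = names.index(row.material_1), names.index(row.material_2)
            ax.plot(noise[sl, sl, i].ravel(), noise[sl, sl, j].ravel(),
                    ".", ms=2)
            ax.set_xlabel(row.material_1)
            ax.set_ylabel(row.material_2)
        path = out / "noise_scatter.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(5, 4))
    roi_noise = report["roi_noise"]
    rois = list(roi_noise)
    x = np.arange(len(names))
    width = 0.8 / len(rois)
    for r, roi in enumerate(rois):
        ax.bar(x + r * width, [roi_noise[roi][n] for n in names],
               width, label=roi)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(names, rotation=20)
    ax.set_ylabel("noise (std of coefficient)")
    ax.legend()
    path = out / "roi_noise.png"
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
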