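"""VMI synthesis, Pearson noise correlation, ROI statistics, and CNR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .materials import Material, attenuation
from .phantoms import ROI, roi_pixels


def synthesize_vmi(basis_images: np.ndarray, basis: list[Material] | tuple[Material, ...],
                   e_mono_kev: float) -> np.ndarray:
    """Virtual monochromatic image mu(x; E) = sum_p a_p(x) mu_p(E) [1/cm]."""
    if basis_images.shape[-1] != len(basis):
        raise ValueError("one basis image per basis material is required")
    mus = np.array([attenuation(m, e_mono_kev) for m in basis])
    return basis_images @ mus


def hounsfield(vmi: np.ndarray, e_mono_kev: float) -> np.ndarray:
    """HU map relative to water at the VMI energy."""
    from .materials import get_material

    mu_w = attenuation(get_material("water"), e_mono_kev)
    return 1000.0 * (vmi - mu_w) / mu_w


@dataclass
class PearsonResult:
    r: float
    n: int
    pair: tuple[str, str] = ("", "")
    roi_name: str = ""


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation coefficient of paired pixel values."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 2:
        raise ValueError("need at least two samples")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        raise ValueError("zero variance in one of the inputs")
    return float((dx * dy).sum() / denom)


@dataclass
class CNRResult:
    m_sig: float
    sigma_sig: float
    m_bkg: float
    sigma_bkg: float

    @property
    def contrast(self) -> float:
        return self.m_sig - self.m_bkg

    @property
    def cnr(self) -> float:
        return self.contrast / (0.5 * (self.sigma_sig + self.sigma_bkg))


def cnr(signal_pixels: np.ndarray, background_pixels: np.ndarray) -> CNRResult:
    """Contrast-to-noise ratio with the average-standard-deviation denominator."""
    s = np.asarray(signal_pixels, dtype=float)
    b = np.asarray(background_pixels, dtype=float)
    if s.size == 0 or b.size == 0:
        raise ValueError("empty ROI")
    res = CNRResult(float(s.mean()), float(s.std(ddof=1)),
                    float(b.mean()), float(b.std(ddof=1)))
    if res.sigma_sig + res.sigma_bkg == 0:
        raise ZeroDivisionError("zero noise in both ROIs")
    return res


def noise_images(noisy: np.ndarray, noiseless: np.ndarray) -> np.ndarray:
    """Noise-only maps: noisy reconstruction minus the matched noiseless one.

    Subtracting the matched noiseless run (rather than mean-subtracting
    within the ROI) removes deterministic reconstruction texture so it
    does not bias the correlation estimate.
    """
    if noisy.shape != noiseless.shape:
        raise ValueError("noisy and noiseless image stacks must match")
    return noisy - noiseless


def noise_correlation_report(noise_stack: np.ndarray, pixel_mm: float,
                             rois: list[ROI] | tuple[ROI, ...],
                             material_names: list[str]) -> pd.DataFrame:
    """Pearson R of every unordered material pair within every ROI."""
    p = noise_stack.shape[-1]
    if p < 2:
        raise ValueError("need at least two basis images")
    rows = []
    for roi in rois:
        pix = [roi_pixels(noise_stack[:, :, i], pixel_mm, roi) for i in range(p)]
        for i in range(p):
            for j in range(i + 1, p):
                rows.append({
                    "roi": roi.name,
                    "material_1": material_names[i],
                    "material_2": material_names[j],
                    "r": pearson_r(pix[i], pix[j]),
                    "n_pixels": pix[i].size,
                })
    return pd.DataFrame(rows)
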