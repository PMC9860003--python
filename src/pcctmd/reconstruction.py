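"""Equiangular fan-beam filtered backprojection.

Standard full-scan FBP for a curved equiangular detector: cosine
weighting of the projections, convolution with the modified ramp kernel
(gamma / sin gamma)^2 * h(gamma) apodized by a Hann window, and
distance-weighted backprojection with linear interpolation in fan angle.
The operator is linear in the sinogram.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .projection import Geometry, MM_PER_CM


def _ramp_kernel(n_cells: int, dgamma: float, window: str = "hann") -> np.ndarray:
    """Modified equiangular ramp kernel g(n*dgamma), length 2n-1."""
    n = np.arange(-(n_cells - 1), n_cells)
    h = np.zeros_like(n, dtype=float)
    h[n == 0] = 1.0 / (8 * dgamma**2)
    odd = n % 2 == 1
    h[odd] = -0.5 / (np.pi * n[odd] * dgamma) ** 2
    gamma = n * dgamma
    corr = np.ones_like(gamma)
    nz = n != 0
    corr[nz] = (gamma[nz] / np.sin(gamma[nz])) ** 2
    g = corr * h
    if window == "hann":
        # apodize in the frequency domain
        m = len(g)
        nfft = 1 << int(np.ceil(np.log2(2 * m)))
        spec = np.fft.rfft(g, nfft)
        f = np.arange(spec.size) / spec.size
        spec *= 0.5 * (1 + np.cos(np.pi * f))
        g = np.fft.irfft(spec, nfft)[:m]
        # re-center: irfft of the shifted kernel keeps alignment because the
        # window is zero-phase (real, even in frequency)
    elif window not in (None, "ramp"):
        raise ValueError(f"unknown window {window!r}")
    return g


def fbp_fanbeam(sino: np.ndarray, geom: Geometry, n_pixels: int,
                pixel_mm: float, window: str = "hann") -> np.ndarray:
    """Reconstruct one sinogram (n_views, n_cells), values in cm, onto an
    n_pixels^2 grid with the phantom pixel convention; output per pixel is
    the local coefficient (dimensionless for basis sinograms)."""
    sino = np.asarray(sino, dtype=float)
    if sino.shape != (geom.n_views, geom.n_cells):
        raise ValueError("sinogram shape does not match geometry")
    gamma = geom.fan_angles()
    dgamma = geom.dgamma
    d_mm = geom.source_to_iso

    # cosine weighting; sinogram values are in cm so convert to mm for a
    # reconstruction in 1/mm, then back to 1/cm at the end
    weighted = sino * MM_PER_CM * (d_mm * np.cos(gamma))[None, :]
    kernel = _ramp_kernel(geom.n_cells, dgamma, window=window)
    filtered = fftconvolve(weighted, kernel[None, :], mode="same", axes=1) * dgamma

    c = (np.arange(n_pixels) + 0.5 - n_pixels / 2) * pixel_mm
    xx, yy = np.meshgrid(c, c, indexing="xy")
    out = np.zeros((n_pixels, n_pixels))
    dbeta = 2 * np.pi / geom.n_views
    for v, beta in enumerate(geom.view_angles()):
        sx, sy = d_mm * np.cos(beta), d_mm * np.sin(beta)
        vx, vy = xx - sx, yy - sy
        # central ray direction is -(cos beta, sin beta); signed fan angle
        d0x, d0y = -np.cos(beta), -np.sin(beta)
        dot = vx * d0x + vy * d0y
        cross = d0x * vy - d0y * vx
        gamma_p = np.arctan2(cross, dot)
        l2 = vx * vx + vy * vy
        q = np.interp(gamma_p, gamma, filtered[v], left=0.0, right=0.0)
        out += q / l2
    # units: sinogram [mm] x D [mm] x kernel [1/angle^2] x dgamma / L^2 [mm^2]
    # -> dimensionless coefficient
    out *= dbeta
    return out


def reconstruct_all(a_sino: np.ndarray, geom: Geometry, n_pixels: int,
                    pixel_mm: float, window: str = "hann") -> np.ndarray:
    """FBP every material channel of an (V, cells, P) sinogram -> (N, N, P)."""
    a_sino = np.asarray(a_sino, dtype=float)
    out = np.stack(
        [fbp_fanbeam(a_sino[:, :, p], geom, n_pixels, pixel_mm, window=window)
         for p in range(a_sino.shape[2])],
        axis=2,
    )
    return out
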