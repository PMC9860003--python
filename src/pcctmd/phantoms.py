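"""Digital phantoms as basis-coefficient maps with analytic region lists.

Two phantoms are provided:

* the **noise-correlation phantom** — a 20-cm water cylinder holding three
  7-cm rods (120 degrees apart on a 5.5-cm radius) whose compositions are
  fixed fraction-weighted mixtures of the decomposition basis materials,
  with a 6-cm measurement ROI concentric with each rod;
* the **head phantom** — the standard Shepp–Logan ellipse geometry with
  materials reassigned (outer shell cortical bone, interior soft tissue,
  the two large lateral ellipses adipose, the small lesions 20 mg/ml
  iodine solution) plus a signal ROI inside one lesion and a background
  ROI in adjacent soft tissue.

Each phantom carries both a rasterized per-pixel coefficient map (pixel
centers at (i + 0.5 - N/2) * pitch, isocenter origin, mm units) and the
analytic circle/ellipse regions it was built from, so line integrals can
be computed exactly by chord lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import Material, get_material

# Table-governed rod compositions: per mode, per rod, the basis-material
# coefficient fractions in basis order.
ROD_FRACTIONS: dict[str, list[tuple[float, ...]]] = {
    "2md": [(1 / 3, 2 / 3), (1 / 2, 1 / 2), (2 / 3, 1 / 3)],
    "3md": [
        (2 / 7, 4 / 7, 1 / 7),
        (3 / 7, 3 / 7, 1 / 7),
        (4 / 7, 2 / 7, 1 / 7),
    ],
    "4md": [
        (2 / 7, 2.5 / 7, 2 / 7, 0.5 / 7),
        (3 / 7, 2 / 7, 1.5 / 7, 0.5 / 7),
        (3 / 7, 2.5 / 7, 1 / 7, 0.5 / 7),
    ],
}

BASIS_NAMES: dict[str, tuple[str, ...]] = {
    "2md": ("soft_tissue", "cortical_bone"),
    "3md": ("soft_tissue", "iodine_10mgml", "cortical_bone"),
    "4md": ("soft_tissue", "iodine_10mgml", "gadolinium_10mgml", "cortical_bone"),
}

CYLINDER_DIAMETER_MM = 200.0
ROD_DIAMETER_MM = 70.0
ROD_RING_RADIUS_MM = 55.0
ROI_DIAMETER_MM = 60.0


@dataclass(frozen=True)
class Region:
    """Analytic region contributing an additive coefficient delta.

    ``kind`` is 'circle' (a = b = radius) or 'ellipse'; angles in radians;
    lengths in mm; ``delta`` has one entry per phantom component.
    """

    kind: str
    center: tuple[float, float]
    a: float
    b: float
    theta: float
    delta: tuple[float, ...]


@dataclass(frozen=True)
class ROI:
    """Circular region of interest in isocenter mm coordinates."""

    center: tuple[float, float]
    diameter_mm: float
    name: str = ""


@dataclass
class PhantomImage:
    """Rasterized coefficient maps plus the analytic regions behind them."""

    materials: tuple[Material, ...]
    coeffs: np.ndarray  # (N, N, C)
    pixel_mm: float
    regions: tuple[Region, ...]
    rois: tuple[ROI, ...] = field(default_factory=tuple)

    @property
    def n_pixels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def fov_mm(self) -> float:
        return self.n_pixels * self.pixel_mm

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n_pixels
        c = (np.arange(n) + 0.5 - n / 2) * self.pixel_mm
        return np.meshgrid(c, c, indexing="xy")

    def monochromatic_image(self, energy_kev: float) -> np.ndarray:
        """Noiseless mu(x; E) [1/cm] image at a single energy."""
        from .materials import attenuation

        mus = np.array([attenuation(m, energy_kev) for m in self.materials])
        return self.coeffs @ mus


def _rasterize(regions, materials, n_pixels, pixel_mm) -> np.ndarray:
    n_comp = len(materials)
    coeffs = np.zeros((n_pixels, n_pixels, n_comp))
    c = (np.arange(n_pixels) + 0.5 - n_pixels / 2) * pixel_mm
    xx, yy = np.meshgrid(c, c, indexing="xy")
    for reg in regions:
        dx, dy = xx - reg.center[0], yy - reg.center[1]
        ct, st = np.cos(reg.theta), np.sin(reg.theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        inside = (u / reg.a) ** 2 + (v / reg.b) ** 2 <= 1.0
        coeffs[inside] += np.asarray(reg.delta)
    return coeffs


def build_noise_phantom(mode: str, n_pixels: int = 256,
                        pixel_mm: float = 1.0) -> PhantomImage:
    """Three-rod noise-correlation phantom for a given decomposition mode.

    Components are the decomposition basis materials plus water (the
    background cylinder); rod compositions follow the fixed fraction
    table for the mode.  Returns the phantom with one 6-cm ROI per rod.
    """
    if mode not in ROD_FRACTIONS:
        raise ValueError(f"mode must be one of {sorted(ROD_FRACTIONS)}, got {mode!r}")
    if n_pixels * pixel_mm < CYLINDER_DIAMETER_MM:
        raise ValueError("field of view smaller than the 20-cm cylinder")
    basis = [get_material(n) for n in BASIS_NAMES[mode]]
    water = get_material("water")
    materials = tuple(basis) + (water,)
    p = len(basis)
    water_vec = np.zeros(p + 1)
    water_vec[-1] = 1.0

    regions = [
        Region("circle", (0.0, 0.0), CYLINDER_DIAMETER_MM / 2,
               CYLINDER_DIAMETER_MM / 2, 0.0, tuple(water_vec)),
    ]
    rois = []
    for i, fr in enumerate(ROD_FRACTIONS[mode]):
        ang = np.pi / 2 + i * 2 * np.pi / 3  # rod 1 at top, 120 deg apart
        cx = ROD_RING_RADIUS_MM * np.cos(ang)
        cy = ROD_RING_RADIUS_MM * np.sin(ang)
        delta = np.array(list(fr) + [0.0]) - water_vec  # replaces water
        regions.append(
            Region("circle", (cx, cy), ROD_DIAMETER_MM / 2,
                   ROD_DIAMETER_MM / 2, 0.0, tuple(delta))
        )
        rois.append(ROI((cx, cy), ROI_DIAMETER_MM, name=f"rod{i + 1}"))

    coeffs = _rasterize(regions, materials, n_pixels, pixel_mm)
    return PhantomImage(materials, coeffs, pixel_mm, tuple(regions), tuple(rois))


# Standard Shepp-Logan ellipses in unit coordinates: (x0, y0, a, b, phi_deg)
_SHEPP_LOGAN = [
    (0.0, 0.0, 0.69, 0.92, 0.0),        # skull shell
    (0.0, -0.0184, 0.6624, 0.874, 0.0), # brain
    (0.22, 0.0, 0.11, 0.31, -18.0),     # right ventricle
    (-0.22, 0.0, 0.16, 0.41, 18.0),     # left ventricle
    (0.0, 0.35, 0.21, 0.25, 0.0),       # large top ellipse
    (0.0, 0.1, 0.046, 0.046, 0.0),      # lesions...
    (0.0, -0.1, 0.046, 0.046, 0.0),
    (-0.08, -0.605, 0.046, 0.023, 0.0),
    (0.0, -0.605, 0.023, 0.023, 0.0),
    (0.06, -0.605, 0.023, 0.046, 0.0),
]

HEAD_SCALE_MM = 100.0  # unit coordinate -> mm
LESION_CONC_MG_ML = 20.0


def build_head_phantom(n_pixels: int = 256, pixel_mm: float = 1.0,
                       signal_roi: ROI | None = None,
                       background_roi: ROI | None = None) -> PhantomImage:
    """Humanoid head phantom: Shepp-Logan geometry with materials reassigned.

    Components: (cortical_bone, soft_tissue, adipose, iodine 20 mg/ml).
    The default signal ROI sits inside the central 9-mm iodine lesion and
    the background ROI in homogeneous soft tissue beside it.
    """
    if n_pixels * pixel_mm < 2 * 0.92 * HEAD_SCALE_MM:
        raise ValueError("field of view smaller than the head phantom")
    materials = tuple(
        [get_material("cortical_bone"), get_material("soft_tissue"),
         get_material("adipose"),
         get_material(f"iodine_{LESION_CONC_MG_ML:g}mgml")]
    )
    e = lambda *v: tuple(float(x) for x in v)
    assignment = [e(1, 0, 0, 0), e(0, 1, 0, 0), e(0, 0, 1, 0), e(0, 0, 1, 0),
                  e(0, 1, 0, 0), e(0, 0, 0, 1), e(0, 0, 0, 1), e(0, 0, 0, 1),
                  e(0, 0, 0, 1), e(0, 0, 0, 1)]

    # each listed ellipse is fully inside its predecessor's material, so
    # replacement semantics convert to additive deltas against the parent
    parent = [None, 0, 1, 1, 1, 1, 1, 1, 1, 1]
    regions = []
    for (x0, y0, a, b, phi), comp, par in zip(_SHEPP_LOGAN, assignment, parent):
        vec = np.asarray(comp, dtype=float)
        if par is not None:
            vec = vec - np.asarray(assignment[par], dtype=float)
        regions.append(
            Region("ellipse", (x0 * HEAD_SCALE_MM, y0 * HEAD_SCALE_MM),
                   a * HEAD_SCALE_MM, b * HEAD_SCALE_MM,
                   np.deg2rad(phi), tuple(vec))
        )

    if signal_roi is None:
        signal_roi = ROI((0.0, 10.0), 6.0, name="signal")
    if background_roi is None:
        background_roi = ROI((45.0, 40.0), 14.0, name="background")
    coeffs = _rasterize(regions, materials, n_pixels, pixel_mm)
    return PhantomImage(materials, coeffs, pixel_mm, tuple(regions),
                        (signal_roi, background_roi))


def roi_mask(shape: tuple[int, int], pixel_mm: float, roi: ROI) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the circular ROI."""
    n = shape[0]
    c = (np.arange(n) + 0.5 - n / 2) * pixel_mm
    xx, yy = np.meshgrid(c, c, indexing="xy")
    r2 = (xx - roi.center[0]) ** 2 + (yy - roi.center[1]) ** 2
    return r2 <= (roi.diameter_mm / 2) ** 2


def roi_pixels(image: np.ndarray, pixel_mm: float, roi: ROI) -> np.ndarray:
    """Values of all pixels inside the ROI (raises if the ROI is empty)."""
    mask = roi_mask(image.shape, pixel_mm, roi)
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("ROI contains no pixel centers")
    return vals
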