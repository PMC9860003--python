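# Methods

`pcctmd` simulates the imaging chain of a photon-counting spectral CT
scanner at desk scale and analyses how count noise propagates into
material-specific (basis) images under projection-domain multi-material
decomposition (MD), and what that means for virtual monochromatic
imaging (VMI). This note records the model, its assumptions, the
parameters that matter, and the numerical choices.

## Signal model

The expected counts in spectral channel *k* for a ray *L* are

    Ibar_k(L) = ∫ D_k(E) N0(E) exp(-Σ_p A_p(L) μ_p(E)) dE,

with `N0(E)` the air-scan fluence per 1-keV bin, `D_k(E)` the channel
detection weight, `μ_p(E)` the linear attenuation of basis material *p*
and `A_p(L) = ∫_L a_p dl` the basis line integrals. Measured counts are
Poisson around `Ibar_k`. Energy integration is a left-Riemann sum on the
1-keV grid [1, 140] keV, matching the resolution of the packaged
attenuation tables.

### Attenuation tables

Per-element mass attenuation is a three-term parameterization —
photoelectric `∝ Z^4/E^3` (with K-edge jump factors for iodine at
33.2 keV and gadolinium at 50.2 keV), coherent scattering `∝ Z^2.5/E^2`,
and the exact Klein–Nishina incoherent cross section. The two free
constants are calibrated once against the standard water mass
attenuation at 30/60/100 keV; water at 60 keV reproduces 0.2059 cm²/g to
0.1%, and the high-Z extrapolation lands elemental iodine and gadolinium
within ~15% of standard tables. The photoelectric Z-exponent is 4.0
rather than the steeper textbook 4.5: calibrated at water (Z_eff ≈ 7.5),
the 4.5 exponent over-predicts iodine/gadolinium attenuation by roughly
4×. Three *independent* smooth energy shapes matter: with only two,
every edge-free material would lie in a two-dimensional function space
and the adipose/PMMA/Teflon basis set would be exactly singular instead
of merely ill-conditioned.

Tables are shipped as CSV fixtures on the 1-keV grid and regenerated
bit-identically by `materials.generate_tables`; lookup is nearest-bin so
K-edges stay sharp. Absolute values are a plausible parameterization,
not a copy of a published library — only structure (edge locations,
jumps, material ordering, conditioning relations) should be trusted.

### Source and channels

The 140 kVp source is a Kramers bremsstrahlung shape multiplied by
aluminum filtration, normalized to `fluence_scale` photons per detector
cell per view. The filtration thickness (7.2 mm Al-equivalent) is chosen
so that the two-channel preset boundary 58/59 keV bisects the detected
air counts — the equal-count channelization principle that also defined
the shipped presets ([1–58, 59–140], [1–51, 52–68, 69–140],
[1–43, 44–58, 59–72, 73–140] keV). A deterministic cumulative-sum
splitter (`channelize_equal_counts`) is provided for other spectra.

`fluence_scale` defaults to 1e7 photons/cell/view, which is the
tube-output estimate for the simulated technique: a 140 kVp source with
~6 mm Al filtration emits on the order of 1.4e6 photons/mm²/mAs at 1 m,
a 1000 mA tube at 1 rot/s delivers 2.78 mAs per view (360 views), and a
desk-profile detector cell (2.048 × 1.092 mm at 949 mm) subtends
2.24 mm² — together ≈1e7 photons per cell per view. Much lower
settings starve the three- and four-channel modes behind the contrast
rods (at 1e5, tens of counts per channel and >10% decomposition
failures).

### Detector response

*Ideal*: each photon is recorded at its true energy (identity kernel,
no sharing). *Realistic*: a parameterized CZT-like kernel — Gaussian
photopeak with `σ(E) = 1.5 + 0.3·√E` keV, a K-escape satellite at
`E − 27` keV with weight 0.08, a flat low-energy tail with weight 0.12 —
plus charge sharing: with probability 0.1 a photon yields *two* recorded
counts at `u·E` and `(1−u)·E`, `u ~ U(0.1, 0.5)`. Charge sharing is the
mechanism that correlates channels: sampling treats it as a compound
Poisson process (independent single-count rates plus pair rates that
increment two channels at once), which makes the channel covariance
available in closed form — `V_kk = r_ind,k + Σ_ab r_ab·m_ab,k²`,
`V_k1k2 = Σ_ab r_ab·m_ab,k1·m_ab,k2` with `m_ab,k` the channel increment
of an (a, b) pair. There is no pile-up, count-rate dependence, or
neighbor-cell transport.

## Phantoms

The noise phantom is a 20-cm water cylinder with three 7-cm rods on a
5.5-cm ring, 120° apart, each a fixed fraction-weighted mixture of the
decomposition basis (soft tissue, cortical bone, and 10 mg/ml iodine /
gadolinium solutions in the 3/4-material modes); a 6-cm ROI sits
concentric with each rod. The head phantom reuses the standard
Shepp–Logan ellipse geometry with materials reassigned: shell = cortical
bone, interior = soft tissue, the two large lateral ellipses = adipose,
small lesions = 20 mg/ml iodine; the signal ROI (6 mm) sits in the
central lesion and the background ROI (14 mm) in homogeneous tissue at
(45, 40) mm. Phantoms carry analytic region lists, so line integrals
are exact chord lengths — no ray-tracing discretization error — while a
bilinear grid integrator over the rasterized maps serves as an
independent cross-check in the tests.

Rod placement and the head-phantom material/ROI assignments are
package choices (the source geometry pictures them but does not print
coordinates); both are config-exposed.

## Geometry and reconstruction

Equiangular fan beam, source-to-iso 541.0 mm, source-to-detector
949.0 mm, full 360° scan. The full-resolution detector is a single row
of 864 cells at 1.024 mm pitch; the default desk profile halves that to
432 cells at 2.048 mm (coverage is preserved — halving cells without
doubling pitch would shrink the fan below the field of view) with 360
views and a 256² image at 1.0 mm pixels.

Reconstruction is standard equiangular fan-beam FBP: cosine weighting,
convolution with the `(γ/sin γ)²`-modified ramp kernel apodized by a
Hann window at the Nyquist cutoff, and distance-weighted backprojection
with linear interpolation in fan angle. The window scales absolute
noise but not correlation structure, so correlation-based results are
kernel-robust; a noiseless unit disc reconstructs to 1 within 0.1% at
the desk profile. The operator is linear, which the VMI analysis relies
on.

## Decomposition

Square systems only (K channels = P materials). Per ray, the solver
minimizes the log-count residual `r_k = ln Ibar_k(A) − ln c_k` by
Levenberg–Marquardt-damped Newton iteration; the Jacobian
`∂ln Ibar_k/∂A_p = −μ_kp` is analytic (the effective attenuation). Two
accepted outcomes: an exact root (`max|r| < 1e-8`) or a first-order
stationary point of `½‖r‖²` (projected gradient `< 1e-9`). The second
state matters: a noisy count vector can fall outside the attainable set
of the forward map — especially for near-collinear bases — and the
least-squares fit is then the natural estimate (verified against an
independent optimizer). Iterates are clamped to [−10, 100] cm; the
lower clamp admits the genuinely negative component coefficients that
appear when the head phantom is decomposed into mismatched bases
(BM-1/BM-2). Zero counts are clamped to 0.5 and flagged. Initialization
comes from an order-3 polynomial (with cross terms) fitted to noiseless
forward counts on a 6-point tensor grid per material spanning 1.2× the
longest plausible path.

## Noise analytics

At an operating point, first-order propagation gives
`V[A] = F⁻¹·V[I]·F⁻ᵀ` with `F_kp = −Ibar_k·μ_kp`. `V[I]` is diagonal
Poisson for the ideal response and the exact compound-Poisson form
above for the realistic one. The two-material closed forms (including
the interchannel-correlation terms and their classical uncorrelated
degeneration) are implemented literally and agree with the matrix route
to 1e-10; `Δ` is defined as `det(μ_kp)` of the effective-attenuation
matrix. Three-plus-material covariances use the matrix route
exclusively and are validated against a single-ray Monte Carlo
(repeated sampling + decomposition), which doubles as the oracle for
the realistic response. The analytic operating point for each rod uses
a representative central ray (13 cm water mapped onto the tissue axis
plus the 7-cm rod chord); propagation is first-order, so agreement with
Monte Carlo degrades at very low counts.

## Measured quantities

Noise images are *matched differences*: the noisy reconstruction minus
a noiseless reconstruction of the same configuration, so deterministic
FBP texture and beam-hardening bias cancel and do not bias the Pearson
correlation (computed literally from the paired-pixel formula within
each ROI). VMIs are `Σ_p a_p(x)·μ_p(45 keV)`; CNR uses the
average-of-standard-deviations denominator. Scatterplot data, per-pair
correlation tables, ROI noise, and CNR are emitted as CSV/JSON, images
as 32-bit float TIFF.

## What the synthetic study does and does not show

The generator reproduces the study conditions: polychromatic Poisson
counting, equal-count channelization, spectral distortion with charge
sharing, fraction-weighted rods with exact ground truth. It omits
scatter, bowtie filtration, focal-spot blur, pile-up, detector gain
drift and anatomical texture, so passing tests demonstrate the internal
consistency of the noise-propagation theory and the pipeline — not
absolute noise levels of any physical scanner. Correlation
coefficients, sign patterns, conditioning orderings and scaling laws
are the transferable results; absolute σ values depend on the FBP
kernel and fluence calibration.

## Problem sizes

Unit tests run a quarter-scale profile (64² image, 4-mm pixels, 216
cells, 180 views); the acceptance checks and the acceptance script use
a half-scale desk profile (128², 2-mm pixels, 432 cells, 360 views,
1e7 photons/cell/view), where a full 2-material pipeline takes ~10 s
and the four-set head sweep ~80 s on one CPU. The full 256² desk
profile is the library default for interactive use.

## Known limitations

- Attenuation values are parameterized, not library-copied; quantities
  that depend on absolute μ (e.g. exact CNR values) are
  model-specific.
- First-order covariance propagation assumes small relative count
  noise; below ~50 counts/channel the Monte Carlo and analytic routes
  visibly diverge.
- On ill-conditioned basis axes (soft tissue vs dilute iodine), noisy
  count vectors that leave the attainable set of the forward map give
  one-sidedly displaced constrained least-squares estimates; the
  resulting ROI-mean bias on the tissue/iodine axes of the 3/4-material
  modes is a few percent even at the default fluence and does not
  vanish with Poisson-weighted refitting. Well-conditioned axes
  (gadolinium, bone, all two-material entries) recover to well within
  2%.
- The analytic rod operating point maps the water background onto the
  soft-tissue axis; for bases without a tissue-like first material the
  reported operating point would need reinterpretation.
- Charge sharing deposits both counts in the same detector cell;
  spatial cross-talk between neighboring cells is not modeled.
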