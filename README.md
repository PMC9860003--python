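# pcctmd — noise correlation in photon-counting CT material decomposition

`pcctmd` is a desk-scale simulator and analysis toolkit for spectral
imaging in photon-counting CT. It models the full imaging chain —
polychromatic 140 kVp source, spectral channelization, ideal or
distorted (CZT-like) detector response, Poisson counting, fan-beam
acquisition — then performs projection-domain multi-material
decomposition (2, 3, or 4 basis materials), reconstructs each
material-specific (basis) image by filtered backprojection, and
quantifies the **noise and noise correlation** in those images and
their impact on **virtual monochromatic imaging (VMI)**.

It is aimed at medical-physics researchers studying why basis images
are so noisy, why their noise is so strongly correlated, and why VMIs
are surprisingly robust to poor basis-material conditioning.

## The model

Counts in spectral channel *k* along ray *L* follow

```
I_k(L) = Poisson( ∫ D_k(E) N0(E) exp(−Σ_p A_p(L) μ_p(E)) dE ),
```

where `A_p(L) = ∫_L a_p dl` are the line integrals of the basis
coefficients. With K channels and P = K materials, each ray is
inverted for `A` by damped Newton–Raphson iteration (polynomial
calibration provides the start), and each `a_p(x)` map is recovered by
fan-beam FBP.

Treating counts and line integrals as random vectors linked by
`F_kp = ∂I_k/∂A_p = −Ī_k μ_kp` (with `μ_kp` the effective attenuation
of material *p* in channel *k*), first-order propagation gives the
A-space covariance

```
V[A] = F⁻¹ · V[I] · F⁻ᵀ,
```

whose off-diagonal signs — the noise correlations `ρ_A` between basis
images — are set by the cofactor signs of the inverse. For two
materials `ρ_A` is always negative (approaching −1); for three and
four materials the pairwise correlations alternate between ±1. The
package implements both the literal two-material closed forms
(including the interchannel-correlation terms and their classical
uncorrelated degeneration) and the generic matrix route, validates them
against single-ray Monte Carlo, and measures the image-domain
counterpart as the Pearson R of matched noise images inside rod ROIs.

## Worked example

```python
from pcctmd.pipeline import RunConfig, run_noise_correlation

cfg = RunConfig(experiment="noise_correlation", mode="2md",
                response="ideal", n_pixels=128, pixel_mm=2.0, seed=11)
report = run_noise_correlation(cfg)
print(report.pearson)
print(report.analytic["rod3"]["rho_a"][0][1])
```

prints

```
    roi   material_1     material_2         r  n_pixels
0  rod1  soft_tissue  cortical_bone -0.993790       698
1  rod2  soft_tissue  cortical_bone -0.993204       709
2  rod3  soft_tissue  cortical_bone -0.993507       709
-0.9885839427826101
```

Each row is the Pearson correlation between the soft-tissue and
cortical-bone noise images (noisy minus matched noiseless
reconstruction) inside one rod's 6-cm ROI: two-material decomposition
noise is almost perfectly anti-correlated (R ≈ −0.99), and the analytic
single-ray propagation predicts the same behaviour (ρ_A ≈ −0.99).
Running `mode="3md"` or `"4md"` shows the pairwise correlations
alternating between ≈+1 and ≈−1.

The same pipelines are scriptable from the shell:

```
pcctmd run --config run.yaml --seed 3 --out results/run1
pcctmd sweep --experiment head_vmi --basis-sets BM-1,BM-2,BM-3,BM-4 --out results/sweep
pcctmd report results/run1
```

`BM-1`..`BM-4` are the head-phantom basis sets (adipose/PMMA/Teflon,
adipose/PMMA/iodine, tissue/iodine/bone, adipose/iodine/Teflon); the
sweep shows basis-image noise varying drastically with basis-set
conditioning while the 45-keV VMI noise and lesion CNR stay nearly
constant.

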