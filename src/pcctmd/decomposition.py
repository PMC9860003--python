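"""Projection-domain material decomposition.

For K spectral channels and P = K basis materials, each ray's channel
counts are inverted for the basis line integrals A_p by a damped
Newton-Raphson iteration on the log-count residual

    r_k(A) = ln Ibar_k(A) - ln c_k,

whose Jacobian is minus the effective attenuation matrix
mu_kp = -(1/Ibar_k) dIbar_k/dA_p, available in closed form from the
spectral integral.  Starting values come from a polynomial calibration
fitted to noiseless forward counts on a tensor grid in A-space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .materials import Material
from .projection import CountsSinogram
from .spectrum import ChannelSet, DetectorResponse, Spectrum

MAX_ITER = 200
TOL = 1e-8
GRAD_TOL = 1e-9
DEFAULT_CLAMP_CM = -10.0


class ForwardModel:
    """Polychromatic counts model Ibar_k(A) for a fixed basis.

    Bundles spectrum, channel set, detector response and basis materials;
    precomputes the spectral weights so repeated evaluations are cheap.
    """

    def __init__(self, spectrum: Spectrum, channels: ChannelSet,
                 response: DetectorResponse, basis: list[Material] | tuple[Material, ...]):
        if channels.n_channels != len(basis):
            raise ValueError(
                f"square systems only: {channels.n_channels} channels vs "
                f"{len(basis)} basis materials"
            )
        self.spectrum = spectrum
        self.channels = channels
        self.response = response
        self.basis = tuple(basis)
        weights = spectrum.fluence[:, None] * response.channel_mass(channels)
        # drop energy bins carrying no measurable fluence: they contribute
        # nothing to the counts but their huge low-energy mu would overflow
        # exp() whenever an iterate goes slightly negative
        self.support = spectrum.fluence >= 1e-9 * spectrum.fluence.max()
        self.weights = weights[self.support]
        self.mu = np.stack([m.mu for m in basis], axis=1)[self.support]  # (nE', P)
        self.air = self.weights.sum(axis=0)  # (K,)

    @property
    def n_channels(self) -> int:
        return self.channels.n_channels

    @property
    def n_basis(self) -> int:
        return len(self.basis)

    def _attenuation(self, a: np.ndarray) -> np.ndarray:
        z = a @ self.mu.T
        return np.exp(-np.clip(z, -600.0, None))

    def expected(self, a: np.ndarray) -> np.ndarray:
        """Ibar for A of shape (..., P) -> (..., K)."""
        a = np.atleast_2d(np.asarray(a, dtype=float))
        return self._attenuation(a) @ self.weights

    def expected_and_mu_eff(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ibar (n, K) and effective attenuation mu_kp (n, K, P)."""
        a = np.atleast_2d(np.asarray(a, dtype=float))
        atten = self._attenuation(a)  # (n, nE)
        ibar = atten @ self.weights  # (n, K)
        # numerator N_kp = sum_E W_kE mu_Ep atten_E
        num = np.einsum("ne,ek,ep->nkp", atten, self.weights, self.mu, optimize=True)
        return ibar, num / np.maximum(ibar, 1e-300)[:, :, None]


@dataclass
class CalibrationModel:
    """Polynomial map from log-attenuation vector y_k = -ln(I_k/air_k) to A."""

    powers: np.ndarray  # (n_feat, K) exponent tuples
    coef: np.ndarray  # (n_feat, P)
    y_scale: np.ndarray  # per-channel feature scaling
    max_residual: float = 0.0
    a_max: np.ndarray = field(default_factory=lambda: np.array([]))

    def predict(self, y: np.ndarray) -> np.ndarray:
        y = np.atleast_2d(y) / self.y_scale
        feats = np.prod(y[:, None, :] ** self.powers[None, :, :], axis=2)
        return feats @ self.coef


def _poly_powers(n_vars: int, order: int) -> np.ndarray:
    powers = [p for p in itertools.product(range(order + 1), repeat=n_vars)
              if sum(p) <= order]
    return np.array(sorted(powers, key=sum))


def calibrate(fm: ForwardModel, a_max: np.ndarray | None = None,
              order: int = 3, n_points: int = 6,
              cond_limit: float = 1e12) -> CalibrationModel:
    """Fit the initialization polynomial on a noiseless tensor grid.

    The grid spans [0, a_max] per material with ``n_points`` samples; the
    default a_max is 1.2 x the longest plausible path (20 cm times the
    largest rod coefficient, ~24 cm of unit coefficient).
    """
    p = fm.n_basis
    if a_max is None:
        a_max = np.full(p, 24.0)
    a_max = np.asarray(a_max, dtype=float)
    axes = [np.linspace(0, m, n_points) for m in a_max]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, p)
    counts = fm.expected(grid)
    y = -np.log(counts / fm.air)
    y_scale = np.maximum(np.abs(y).max(axis=0), 1e-12)
    powers = _poly_powers(fm.n_channels, order)
    feats = np.prod((y / y_scale)[:, None, :] ** powers[None, :, :], axis=2)
    sv = np.linalg.svd(feats, compute_uv=False)
    if sv[-1] / sv[0] < 1.0 / cond_limit:
        raise np.linalg.LinAlgError(
            "calibration design is rank deficient; basis attenuation "
            "curves are too close to proportional"
        )
    coef, res, *_ = np.linalg.lstsq(feats, grid, rcond=None)
    resid = np.max(np.abs(feats @ coef - grid))
    return CalibrationModel(powers=powers, coef=coef, y_scale=y_scale,
                            max_residual=float(resid), a_max=a_max)


def newton_raphson_md(counts: np.ndarray, fm: ForwardModel,
                      init: np.ndarray | CalibrationModel | None = None,
                      clamp_cm: float = DEFAULT_CLAMP_CM,
                      clamp_hi_cm: float = 100.0,
                      max_iter: int = MAX_ITER, tol: float = TOL,
                      grad_tol: float = GRAD_TOL,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert channel counts to basis line integrals for a batch of rays.

    Damped (Levenberg-Marquardt) Newton iteration on the log-count
    residual.  A ray converges when either the residual vanishes
    (max |r| < tol — counts matched exactly) or a first-order stationary
    point of the least-squares objective is reached (max |J^T r| <
    grad_tol) — noisy count vectors can fall outside the attainable set
    of the forward map, in which case the least-squares fit is the
    natural estimate.  Iterates are confined to the physical box
    [clamp_cm, clamp_hi_cm].

    Returns (A, converged, clamped_counts_flag); counts of zero are
    clamped to 0.5 and flagged.
    """
    c = np.atleast_2d(np.asarray(counts, dtype=float))
    zero_flag = np.any(c <= 0, axis=1)
    c = np.clip(c, 0.5, None)
    log_c = np.log(c)
    n, p = c.shape[0], fm.n_basis

    if init is None:
        a = np.zeros((n, p))
    elif isinstance(init, CalibrationModel):
        y = np.log(fm.air) - log_c
        a = np.clip(init.predict(y), clamp_cm, clamp_hi_cm)
    else:
        a = np.array(np.atleast_2d(init), dtype=float).copy()
        if a.shape[0] == 1:
            a = np.repeat(a, n, axis=0)

    def residual(a_batch, logc_batch):
        ib, mu = fm.expected_and_mu_eff(a_batch)
        res = np.log(np.maximum(ib, 1e-300)) - logc_batch
        return res, mu

    r, mu_eff = residual(a, log_c)
    rnorm2 = np.linalg.norm(r, axis=1)
    lam = np.full(n, 1e-10)
    eye = np.eye(p)

    def bound_active(a_batch, grad):
        """Coordinates pinned at a clamp with the gradient pushing outward
        (KKT-active constraints of the box)."""
        at_lo = a_batch <= clamp_cm + 1e-12
        at_hi = a_batch >= clamp_hi_cm - 1e-12
        return (at_lo & (grad > 0)) | (at_hi & (grad < 0))

    def flags(a_batch, res, mu):
        grad = np.einsum("nkp,nk->np", -mu, res)
        proj = np.where(bound_active(a_batch, grad), 0.0, grad)
        exact = np.max(np.abs(res), axis=1) <= tol
        stationary = np.max(np.abs(proj), axis=1) <= grad_tol
        return exact | stationary

    done = flags(a, r, mu_eff)
    for _ in range(max_iter):
        if np.all(done):
            break
        idx = np.flatnonzero(~done)
        jac = -mu_eff[idx]
        grad = np.einsum("nkp,nk->np", jac, r[idx])
        act = bound_active(a[idx], grad)
        jtj = np.einsum("nkp,nkq->npq", jac, jac)
        diag = np.einsum("npp->np", jtj)
        lhs = jtj + lam[idx, None, None] * (diag[:, :, None] * eye)
        # active-set reduction: freeze KKT-active coordinates this iteration
        free = ~act
        lhs = lhs * (free[:, :, None] & free[:, None, :])
        lhs += act[:, :, None] * eye
        rhs = np.where(act, 0.0, -grad)
        try:
            step = np.linalg.solve(lhs, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("nij,nj->ni", np.linalg.pinv(lhs), rhs)
        a_try = np.clip(a[idx] + step, clamp_cm, clamp_hi_cm)
        r_try, mu_try = residual(a_try, log_c[idx])
        rn_try = np.linalg.norm(r_try, axis=1)
        improved = rn_try < rnorm2[idx]
        acc = idx[improved]
        a[acc] = a_try[improved]
        r[acc] = r_try[improved]
        mu_eff[acc] = mu_try[improved]
        rnorm2[acc] = rn_try[improved]
        lam[acc] = np.maximum(lam[acc] / 3.0, 1e-12)
        rej = idx[~improved]
        lam[rej] = np.minimum(lam[rej] * 8.0, 1e10)
        done[idx] = flags(a[idx], r[idx], mu_eff[idx])

    converged = flags(a, r, mu_eff)
    return a, converged, zero_flag


@dataclass
class DecomposedSinogram:
    """Estimated basis line-integral sinogram with solver diagnostics."""

    a_est: np.ndarray  # (V, cells, P) [cm]
    converged: np.ndarray  # (V, cells) bool
    clamped: np.ndarray  # (V, cells) bool


def decompose_sinogram(counts: CountsSinogram | np.ndarray, fm: ForwardModel,
                       calib: CalibrationModel | None = None,
                       clamp_cm: float = DEFAULT_CLAMP_CM) -> DecomposedSinogram:
    """Run the per-ray Newton inversion over a whole sinogram."""
    arr = counts.counts if isinstance(counts, CountsSinogram) else np.asarray(counts)
    if arr.shape[-1] != fm.n_channels:
        raise ValueError("channel count of sinogram does not match the model")
    if calib is None:
        calib = calibrate(fm)
    flat = arr.reshape(-1, arr.shape[-1])
    a, conv, clamped = newton_raphson_md(flat, fm, init=calib, clamp_cm=clamp_cm)
    shape = arr.shape[:-1]
    return DecomposedSinogram(
        a_est=a.reshape(shape + (fm.n_basis,)),
        converged=conv.reshape(shape),
        clamped=clamped.reshape(shape),
    )
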