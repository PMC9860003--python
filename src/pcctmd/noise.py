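"""Analytic propagation of count noise into A-space, with a Monte Carlo oracle.

At an operating point A the counts model gives expected channel counts
Ibar_k and the effective attenuation matrix

    mu_kp = -(1/Ibar_k) dIbar_k/dA_p,

so the count->A mapping matrix is F_kp = dIbar_k/dA_p = -Ibar_k mu_kp and
first-order error propagation yields

    V[A] = F^-1 V[I] F^-T.

For two materials the covariance entries reduce to closed forms in the
effective attenuations, channel SNRs and the interchannel count
correlation rho_I12; with rho_I12 = 0 they degenerate to the classical
uncorrelated-channel (Alvarez-Macovski) expressions.  Both closed forms
are implemented literally and cross-checked against the matrix route.

V[I] is diagonal Poisson (V_kk = Ibar_k) under the ideal response.  Under
the realistic response the charge-sharing process is a compound Poisson
whose covariance is available exactly: independent single counts keep
Poisson variance, while each shared pair adds simultaneous counts to two
channels, contributing rate * m_a m_b to the covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import ForwardModel, newton_raphson_md
from .materials import N_BINS


@dataclass
class OperatingPoint:
    """Counts statistics at a fixed A: means, covariance, SNRs, correlations."""

    a: np.ndarray  # (P,)
    ibar: np.ndarray  # (K,)
    v_i: np.ndarray  # (K, K)

    @property
    def snr(self) -> np.ndarray:
        return self.ibar / np.sqrt(np.diag(self.v_i))

    @property
    def rho_i(self) -> np.ndarray:
        s = np.sqrt(np.diag(self.v_i))
        return self.v_i / np.outer(s, s)


@dataclass
class CovarianceEstimate:
    """A-space covariance: full matrix, correlations, and the Jacobian
    determinant Delta of the effective-mu matrix."""

    v_a: np.ndarray  # (P, P)
    rho_a: np.ndarray  # (P, P)
    delta: float
    n_samples: int | None = None  # set for Monte Carlo estimates

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(np.diag(self.v_a))


def effective_mu(fm: ForwardModel, a: np.ndarray) -> np.ndarray:
    """Effective attenuation matrix mu_kp [1/cm] at operating point A."""
    ibar, mu_eff = fm.expected_and_mu_eff(np.atleast_2d(a))
    if np.any(ibar <= 0):
        raise ValueError("zero expected count at the operating point")
    return mu_eff[0]


def count_covariance(fm: ForwardModel, a: np.ndarray) -> np.ndarray:
    """Exact channel-count covariance V[I] at A.

    Poisson-diagonal for the ideal response; for the realistic response
    the charge-sharing pair events add cross-channel covariance.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    resp = fm.response
    k = fm.n_channels
    atten_full = np.exp(-np.clip(
        a @ np.stack([m.mu for m in fm.basis], axis=1).T, -600, None))[0]
    lam = fm.spectrum.fluence * resp.efficiency * atten_full  # (nE,)
    p = resp.sharing_fraction
    if p == 0:
        return np.diag(fm.expected(a)[0])
    kern = resp.kernel()
    chan = fm.channels.channel_of_bins()
    single = np.zeros((N_BINS, k))
    for c in range(k):
        single[:, c] = kern[chan == c, :].sum(axis=0)
    ind_rate = (1 - p) * lam @ single  # (K,)
    q = resp.split_pair_probs(fm.channels)  # (nE, K, K)
    pair_rate = p * np.einsum("e,eab->ab", lam, q)  # (K, K)
    v = np.diag(ind_rate)
    eye = np.eye(k)
    for aa in range(k):
        for bb in range(k):
            m = eye[aa] + eye[bb]  # channel increment vector of an (a,b) pair
            v += pair_rate[aa, bb] * np.outer(m, m)
    return v


def operating_point(fm: ForwardModel, a: np.ndarray) -> OperatingPoint:
    a = np.asarray(a, dtype=float)
    return OperatingPoint(a=a, ibar=fm.expected(a)[0], v_i=count_covariance(fm, a))


def propagate_covariance(mu_eff: np.ndarray, op: OperatingPoint) -> CovarianceEstimate:
    """First-order A-space covariance V[A] = F^-1 V[I] F^-T."""
    k, p = mu_eff.shape
    if k != p:
        raise ValueError("square systems only (K = P)")
    f = -op.ibar[:, None] * mu_eff
    cond = np.linalg.cond(f)
    if cond > 1e12:
        cols = mu_eff / np.linalg.norm(mu_eff, axis=0)
        gram = np.abs(cols.T @ cols) - np.eye(p)
        i, j = np.unravel_index(np.argmax(gram), gram.shape)
        raise np.linalg.LinAlgError(
            f"mapping matrix is singular; basis materials {i} and {j} have "
            f"near-proportional effective attenuation"
        )
    finv = np.linalg.inv(f)
    v_a = finv @ op.v_i @ finv.T
    s = np.sqrt(np.diag(v_a))
    rho = v_a / np.outer(s, s)
    return CovarianceEstimate(v_a=v_a, rho_a=rho, delta=float(np.linalg.det(mu_eff)))


def closed_form_2md(mu11, mu12, mu21, mu22, snr1, snr2, rho_i12) -> dict:
    """Literal two-material closed forms (correlated channels).

    mu_kp indexes channel k, material p; SNR_k = Ibar_k / sigma_Ik;
    rho_i12 the interchannel count correlation.
    """
    delta = mu11 * mu22 - mu21 * mu12
    if delta == 0:
        raise ZeroDivisionError("proportional basis attenuations (Delta = 0)")
    if abs(rho_i12) > 1:
        raise ValueError("|rho_I12| must be <= 1")
    d2 = delta**2
    var1 = (mu22**2 / snr1**2 + mu12**2 / snr2**2
            - 2 * rho_i12 * (mu22 / snr1) * (mu12 / snr2)) / d2
    var2 = (mu21**2 / snr1**2 + mu11**2 / snr2**2
            - 2 * rho_i12 * (mu11 / snr2) * (mu21 / snr1)) / d2
    cov = -(mu21 * mu22 / snr1**2 + mu12 * mu11 / snr2**2
            - rho_i12 * ((mu11 / snr2) * (mu22 / snr1)
                         + (mu12 / snr2) * (mu21 / snr1))) / d2
    rho = cov / np.sqrt(var1 * var2)
    return {"var_a1": var1, "var_a2": var2, "cov_a1a2": cov,
            "rho_a1a2": rho, "delta": delta}


def closed_form_2md_uncorrelated(mu11, mu12, mu21, mu22, snr1, snr2) -> dict:
    """Degenerate (rho_I12 = 0) closed forms — the classical
    uncorrelated-channel expressions, implemented independently."""
    delta = mu11 * mu22 - mu21 * mu12
    if delta == 0:
        raise ZeroDivisionError("proportional basis attenuations (Delta = 0)")
    d2 = delta**2
    var1 = (mu22**2 / snr1**2 + mu12**2 / snr2**2) / d2
    var2 = (mu21**2 / snr1**2 + mu11**2 / snr2**2) / d2
    cov = -(mu21 * mu22 / snr1**2 + mu12 * mu11 / snr2**2) / d2
    num = mu21 * mu22 / snr1**2 + mu12 * mu11 / snr2**2
    den = np.sqrt(mu22**2 / snr1**2 + mu12**2 / snr2**2) \
        * np.sqrt(mu21**2 / snr1**2 + mu11**2 / snr2**2)
    return {"var_a1": var1, "var_a2": var2, "cov_a1a2": cov,
            "rho_a1a2": -num / den, "delta": delta}


def jacobian_3md(mu: np.ndarray) -> float:
    """Explicit 3x3 determinant expansion of the effective-mu matrix."""
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (3, 3):
        raise ValueError("jacobian_3md needs a 3x3 matrix")
    return float(
        mu[0, 0] * mu[1, 1] * mu[2, 2]
        + mu[0, 1] * mu[1, 2] * mu[2, 0]
        + mu[0, 2] * mu[1, 0] * mu[2, 1]
        - mu[0, 2] * mu[1, 1] * mu[2, 0]
        - mu[0, 0] * mu[1, 2] * mu[2, 1]
        - mu[0, 1] * mu[1, 0] * mu[2, 2]
    )


def monte_carlo_covariance(fm: ForwardModel, a_truth: np.ndarray, n_reps: int,
                           seed: int, max_nonconverged: float = 0.05,
                           ) -> CovarianceEstimate:
    """Sample covariance of repeated single-ray decompositions.

    Draws counts at the operating point ``n_reps`` times, inverts every
    repetition with the Newton solver, and returns the sample covariance
    and correlation of the A estimates.
    """
    if n_reps < 100:
        raise ValueError("need at least 100 repetitions")
    from .projection import sample_counts

    a_truth = np.asarray(a_truth, dtype=float)
    a_batch = np.broadcast_to(a_truth, (n_reps, 1, a_truth.size))
    cs = sample_counts(a_batch, fm.spectrum, fm.channels, fm.response,
                       fm.basis, seed=seed)
    counts = cs.counts.reshape(n_reps, fm.n_channels)
    a_est, conv, _ = newton_raphson_md(counts, fm, init=np.tile(a_truth, (n_reps, 1)))
    frac_bad = 1.0 - conv.mean()
    if frac_bad > max_nonconverged:
        raise RuntimeError(f"{frac_bad:.1%} of repetitions failed to converge")
    a_ok = a_est[conv]
    v_a = np.cov(a_ok.T)
    s = np.sqrt(np.diag(v_a))
    rho = v_a / np.outer(s, s)
    delta = float(np.linalg.det(effective_mu(fm, a_truth)))
    return CovarianceEstimate(v_a=v_a, rho_a=rho, delta=delta, n_samples=int(conv.sum()))
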