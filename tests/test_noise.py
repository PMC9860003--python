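"""Noise propagation: effective attenuation, covariance forms, Monte Carlo."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pcctmd import decomposition as D
from pcctmd import noise as NZ
from pcctmd import spectrum as S
from pcctmd.materials import attenuation, get_material


@pytest.fixture(scope="module")
def fm_2md(spectrum_1e6, channels_2md, ideal_response, basis_2md):
    return D.ForwardModel(spectrum_1e6, channels_2md, ideal_response, basis_2md)


@pytest.fixture(scope="module")
def fm_3md(spectrum_1e6, ideal_response):
    basis = (get_material("soft_tissue"), get_material("iodine_10mgml"),
             get_material("cortical_bone"))
    return D.ForwardModel(spectrum_1e6, S.CHANNEL_PRESETS[3], ideal_response,
                          basis)


def _rand_closed_form_inputs(rng):
    """Admissible random inputs: positive effective attenuations with a
    nonzero determinant and positive SNRs."""
    while True:
        mu = rng.uniform(0.05, 1.5, size=4)
        if abs(mu[0] * mu[3] - mu[1] * mu[2]) > 1e-3:
            break
    snr = rng.uniform(3.0, 300.0, size=2)
    return mu, snr


def test_effective_mu_monochromatic():
    fl = np.zeros(140)
    fl[59] = 1e5
    sp = S.Spectrum(fl)
    fm = D.ForwardModel(sp, S.ChannelSet(((1, 140),)),
                        S.DetectorResponse("ideal"), (get_material("water"),))
    mu = NZ.effective_mu(fm, np.array([2.0]))
    assert mu[0, 0] == pytest.approx(attenuation(get_material("water"), 60.0),
                                     rel=1e-12)


def test_effective_mu_matches_finite_difference(fm_2md):
    a0 = np.array([12.0, 2.5])
    mu = NZ.effective_mu(fm_2md, a0)
    h = 1e-5
    for p in range(2):
        dp = np.zeros(2)
        dp[p] = h
        fd = -(np.log(fm_2md.expected(a0 + dp)) -
               np.log(fm_2md.expected(a0 - dp))) / (2 * h)
        assert np.allclose(mu[:, p], fd[0], rtol=1e-6)


def test_beam_hardening_reduces_effective_mu(fm_2md):
    """More tissue path hardens the channel spectrum, lowering mu_eff."""
    mu_thin = NZ.effective_mu(fm_2md, np.array([2.0, 0.5]))
    mu_thick = NZ.effective_mu(fm_2md, np.array([16.0, 0.5]))
    assert np.all(mu_thick[:, 0] < mu_thin[:, 0])


def test_propagate_identity_case():
    op = NZ.OperatingPoint(a=np.zeros(2), ibar=np.ones(2), v_i=np.eye(2))
    cov = NZ.propagate_covariance(-np.eye(2), op)  # F = identity
    assert np.allclose(cov.v_a, np.eye(2))


def test_closed_form_matches_matrix_route():
    """The literal two-material expressions equal the generic
    F^-1 V F^-T propagation term by term."""
    rng = np.random.default_rng(2)
    for _ in range(200):
        (m11, m12, m21, m22), (s1, s2) = _rand_closed_form_inputs(rng)
        rho = rng.uniform(-0.9, 0.9)
        ibar = rng.uniform(1e2, 1e5, size=2)
        sig = ibar / np.array([s1, s2])
        v_i = np.array([[sig[0]**2, rho * sig[0] * sig[1]],
                        [rho * sig[0] * sig[1], sig[1]**2]])
        op = NZ.OperatingPoint(a=np.zeros(2), ibar=ibar, v_i=v_i)
        mu = np.array([[m11, m12], [m21, m22]])
        mat = NZ.propagate_covariance(mu, op)
        cf = NZ.closed_form_2md(m11, m12, m21, m22, s1, s2, rho)
        assert cf["var_a1"] == pytest.approx(mat.v_a[0, 0], rel=1e-10)
        assert cf["var_a2"] == pytest.approx(mat.v_a[1, 1], rel=1e-10)
        assert cf["cov_a1a2"] == pytest.approx(mat.v_a[0, 1], rel=1e-10)
        assert cf["rho_a1a2"] == pytest.approx(mat.rho_a[0, 1], rel=1e-10)
        assert cf["delta"] == pytest.approx(mat.delta, rel=1e-10)


def test_uncorrelated_degenerate_identity():
    """With rho_I12 = 0 the correlated forms reduce exactly to the
    classical uncorrelated-channel expressions."""
    rng = np.random.default_rng(3)
    for _ in range(1000):
        (m11, m12, m21, m22), (s1, s2) = _rand_closed_form_inputs(rng)
        full = NZ.closed_form_2md(m11, m12, m21, m22, s1, s2, 0.0)
        degen = NZ.closed_form_2md_uncorrelated(m11, m12, m21, m22, s1, s2)
        for key in ("var_a1", "var_a2", "cov_a1a2", "rho_a1a2", "delta"):
            assert full[key] == pytest.approx(degen[key], rel=1e-10)


def test_uncorrelated_case_always_negative_correlation():
    rng = np.random.default_rng(4)
    for _ in range(200):
        (m11, m12, m21, m22), (s1, s2) = _rand_closed_form_inputs(rng)
        out = NZ.closed_form_2md_uncorrelated(m11, m12, m21, m22, s1, s2)
        assert out["rho_a1a2"] < 0
        assert -1 <= out["rho_a1a2"]


def test_symmetric_inputs_give_equal_variances():
    out = NZ.closed_form_2md(0.5, 0.2, 0.2, 0.5, 40.0, 40.0, 0.0)
    assert out["var_a1"] == pytest.approx(out["var_a2"], rel=1e-12)


def test_closed_form_rejects_singular_and_bad_rho():
    with pytest.raises(ZeroDivisionError):
        NZ.closed_form_2md(0.4, 0.2, 0.4, 0.2, 10.0, 10.0, 0.0)
    with pytest.raises(ValueError):
        NZ.closed_form_2md(0.5, 0.2, 0.2, 0.5, 10.0, 10.0, 1.5)


def test_jacobian_3md_determinant():
    assert NZ.jacobian_3md(np.eye(3)) == 1.0
    degenerate = np.array([[0.3, 0.2, 0.1], [0.3, 0.2, 0.1], [0.5, 0.1, 0.9]])
    assert NZ.jacobian_3md(degenerate) == pytest.approx(0.0, abs=1e-15)
    rng = np.random.default_rng(5)
    for _ in range(50):
        m = rng.uniform(0.05, 2.0, size=(3, 3))
        assert NZ.jacobian_3md(m) == pytest.approx(np.linalg.det(m), rel=1e-12)
    with pytest.raises(ValueError):
        NZ.jacobian_3md(np.eye(2))


@given(seed=st.integers(0, 10_000))
def test_propagated_covariance_is_psd(seed):
    rng = np.random.default_rng(seed)
    p = rng.integers(2, 5)
    mu = rng.uniform(0.05, 1.5, size=(p, p)) + np.eye(p)
    root = rng.normal(size=(p, p))
    v_i = root @ root.T + 1e-6 * np.eye(p)
    op = NZ.OperatingPoint(a=np.zeros(p), ibar=rng.uniform(10, 1e4, p), v_i=v_i)
    cov = NZ.propagate_covariance(mu, op)
    assert np.allclose(cov.v_a, cov.v_a.T)
    assert np.all(np.linalg.eigvalsh(cov.v_a) > -1e-12)
    assert np.all(np.abs(cov.rho_a) <= 1 + 1e-12)


def test_singular_mapping_names_the_basis_pair():
    op = NZ.OperatingPoint(a=np.zeros(2), ibar=np.ones(2), v_i=np.eye(2))
    mu = np.array([[0.4, 0.8], [0.2, 0.4]])  # proportional columns
    with pytest.raises(np.linalg.LinAlgError, match="near-proportional"):
        NZ.propagate_covariance(mu, op)


def test_monte_carlo_matches_analytic_2md(fm_2md):
    """Sample covariance of repeated single-ray decompositions agrees
    with first-order propagation."""
    a0 = np.array([14.0, 2.0])
    analytic = NZ.propagate_covariance(NZ.effective_mu(fm_2md, a0),
                                       NZ.operating_point(fm_2md, a0))
    mc = NZ.monte_carlo_covariance(fm_2md, a0, n_reps=2000, seed=17)
    assert mc.rho_a[0, 1] == pytest.approx(analytic.rho_a[0, 1], abs=0.05)
    for i in range(2):
        assert mc.v_a[i, i] == pytest.approx(analytic.v_a[i, i], rel=0.1)


def test_fluence_scaling_halves_variance_leaves_rho(channels_2md,
                                                    ideal_response, basis_2md):
    a0 = np.array([10.0, 2.0])
    out = {}
    for scale in (1e6, 2e6):
        sp = S.source_spectrum(fluence_scale=scale)
        fm = D.ForwardModel(sp, channels_2md, ideal_response, basis_2md)
        out[scale] = NZ.monte_carlo_covariance(fm, a0, n_reps=3000, seed=19)
    ratio = np.diag(out[1e6].v_a) / np.diag(out[2e6].v_a)
    assert np.allclose(ratio, 2.0, rtol=0.15)
    assert out[1e6].rho_a[0, 1] == pytest.approx(out[2e6].rho_a[0, 1], abs=0.05)


def test_realistic_response_raises_noise_and_correlation(spectrum_1e6,
                                                         channels_2md,
                                                         basis_2md,
                                                         ideal_response,
                                                         realistic_response):
    a0 = np.array([14.0, 2.0])
    fm_i = D.ForwardModel(spectrum_1e6, channels_2md, ideal_response, basis_2md)
    fm_r = D.ForwardModel(spectrum_1e6, channels_2md, realistic_response, basis_2md)
    op_r = NZ.operating_point(fm_r, a0)
    assert op_r.rho_i[0, 1] > 0  # charge sharing couples the channels
    cov_i = NZ.propagate_covariance(NZ.effective_mu(fm_i, a0),
                                    NZ.operating_point(fm_i, a0))
    cov_r = NZ.propagate_covariance(NZ.effective_mu(fm_r, a0), op_r)
    assert np.all(np.diag(cov_r.v_a) > np.diag(cov_i.v_a))
    assert abs(cov_r.rho_a[0, 1]) >= abs(cov_i.rho_a[0, 1]) - 0.05
    mc_r = NZ.monte_carlo_covariance(fm_r, a0, n_reps=2000, seed=23)
    assert mc_r.rho_a[0, 1] == pytest.approx(cov_r.rho_a[0, 1], abs=0.05)


def test_monte_carlo_requires_enough_reps(fm_2md):
    with pytest.raises(ValueError):
        NZ.monte_carlo_covariance(fm_2md, np.array([1.0, 1.0]), n_reps=10, seed=0)
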