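import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import specgc as sg
from specgc.specfac import FactorizationError

from conftest import model_spectrum, random_stationary_models


def identity_spectrum(N=64, n=2):
    return sg.SpectralDensityMatrix(
        values=np.tile(np.eye(n, dtype=complex), (N, 1, 1)),
        fs=1.0,
        labels=tuple("XY"[:n]),
    )


def random_unitary(n, seed):
    rng = np.random.default_rng(seed)
    Q, R = np.linalg.qr(rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)))
    return Q * (np.diagonal(R) / np.abs(np.diagonal(R)))


class TestScalarFactor:
    def test_constant_spectrum(self):
        c = sg.scalar_factor(np.full(64, 4.0))
        assert c[0] == pytest.approx(2.0)
        np.testing.assert_allclose(c[1:], 0.0, atol=1e-12)

    def test_ma1_minimum_phase_closed_form(self):
        f = np.arange(1024) / 1024
        psd = np.abs(1 - 0.6 * np.exp(-2j * np.pi * f)) ** 2
        c = sg.scalar_factor(psd)
        assert c[0] == pytest.approx(1.0, abs=1e-10)
        assert c[1] == pytest.approx(-0.6, abs=1e-10)
        np.testing.assert_allclose(c[2:], 0.0, atol=1e-10)

    def test_rejects_nonpositive(self):
        psd = np.ones(32)
        psd[3] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            sg.scalar_factor(psd)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reconstruction_and_geometric_mean(self, seed):
        """|s+(f)|^2 = psd on the grid; c0^2 is the spectrum's geometric mean."""
        rng = np.random.default_rng(seed)
        N = 256
        # log-smooth positive spectrum: few low-order cepstral components
        k = np.arange(N)
        logpsd = np.zeros(N)
        for order in range(1, 4):
            logpsd += rng.uniform(-0.5, 0.5) * np.cos(2 * np.pi * order * k / N)
        psd = np.exp(logpsd + rng.uniform(-1, 1))
        c = sg.scalar_factor(psd)
        rec = np.abs(np.fft.fft(c.astype(complex))) ** 2
        np.testing.assert_allclose(rec, psd, rtol=1e-8)
        geo = np.exp(np.mean(np.log(psd)))
        assert c[0] ** 2 == pytest.approx(geo, rel=1e-8)


class TestWilson:
    def test_identity_spectrum_immediate(self):
        F = sg.factorize_wilson(identity_spectrum())
        np.testing.assert_allclose(F.A0, np.eye(2), atol=1e-12)
        assert F.info["iterations"] <= 2
        np.testing.assert_allclose(
            F.grid_values, np.tile(np.eye(2), (64, 1, 1)), atol=1e-10
        )

    def test_diagonal_spectrum_decouples(self):
        N = 256
        f = np.arange(N) / N
        V = np.zeros((N, 2, 2), dtype=complex)
        V[:, 0, 0] = np.abs(1 - 0.6 * np.exp(-2j * np.pi * f)) ** 2
        V[:, 1, 1] = 2.25
        S = sg.SpectralDensityMatrix(V, fs=1.0, labels=("X", "Y"))
        F = sg.canonicalize(sg.factorize_wilson(S))
        np.testing.assert_allclose(F.coeffs[0], np.diag([1.0, 1.5]), atol=1e-7)
        np.testing.assert_allclose(F.coeffs[1], np.diag([-0.6, 0.0]), atol=1e-7)

    def test_recovers_generative_noise_covariance(self, coupled_factor_wilson):
        Sigma = coupled_factor_wilson.A0 @ np.conj(coupled_factor_wilson.A0.T)
        np.testing.assert_allclose(Sigma.real, np.eye(2), atol=1e-4)

    def test_residual_trajectory_decreases(self, coupled_factor_wilson):
        r = coupled_factor_wilson.info["residuals"]
        assert r[-1] <= r[0]
        assert r[-1] < 1e-9

    def test_rejects_singular_bin(self):
        V = np.tile(np.eye(2, dtype=complex), (64, 1, 1))
        V[10] = 0.0
        S = sg.SpectralDensityMatrix(V, fs=1.0, labels=("X", "Y"))
        with pytest.raises(FactorizationError, match="singular"):
            sg.factorize_wilson(S)


class TestJLA:
    def test_identity_spectrum(self):
        F = sg.factorize_jla(identity_spectrum())
        np.testing.assert_allclose(
            np.abs(F.grid_values @ np.conj(np.swapaxes(F.grid_values, 1, 2))),
            np.tile(np.eye(2), (64, 1, 1)),
            atol=1e-10,
        )
        assert F.analyticity_defect() < 1e-12

    def test_bivariate_ma1_finite_impulse_response(self):
        """The factor of an MA(1) spectrum has exactly two nonzero coefficients."""
        B1 = np.array([[0.4, 0.3], [0.0, 0.2]])
        S = model_spectrum("ma", B1, np.eye(2), 256)
        F = sg.canonicalize(sg.factorize_jla(S))
        np.testing.assert_allclose(F.coeffs[0], np.eye(2), atol=1e-6)
        np.testing.assert_allclose(F.coeffs[1], B1, atol=1e-6)
        assert np.max(np.abs(F.coeffs[2:])) < 1e-6

    def test_agrees_with_wilson_after_canonicalization(
        self, coupled_spectrum, coupled_factor_wilson
    ):
        FJ = sg.canonicalize(sg.factorize_jla(coupled_spectrum))
        FW = sg.canonicalize(coupled_factor_wilson)
        assert np.max(np.abs(FJ.coeffs[:100] - FW.coeffs[:100])) < 1e-4

    def test_scalar_input_uses_cepstral_route(self):
        f = np.arange(128) / 128
        psd = np.abs(1 - 0.5 * np.exp(-2j * np.pi * f)) ** 2
        S = sg.SpectralDensityMatrix(psd[:, None, None].astype(complex), fs=1.0, labels=("X",))
        F = sg.factorize_jla(S)
        assert F.coeffs[0, 0, 0].real == pytest.approx(1.0, abs=1e-9)
        assert F.coeffs[1, 0, 0].real == pytest.approx(-0.5, abs=1e-9)


@pytest.mark.parametrize("idx", range(4))
def test_backend_equivalence_on_low_order_polynomial_spectra(idx):
    """Both backends reproduce the generative minimum-phase factor of MA
    spectra of order <= 3 on a 256 grid, after canonicalization."""
    rng = np.random.default_rng(1234 + idx)
    order = idx % 3 + 1
    N = 256
    f = np.arange(N) / N
    H = np.tile(np.eye(2, dtype=complex), (N, 1, 1))
    true_coeffs = [np.eye(2)]
    for k in range(1, order + 1):
        Bk = rng.uniform(-0.3, 0.3, (2, 2)) / k
        true_coeffs.append(Bk)
        H += Bk[None] * np.exp(-2j * np.pi * f * k)[:, None, None]
    V = H @ np.conj(np.swapaxes(H, 1, 2))
    S = sg.SpectralDensityMatrix(0.5 * (V + np.conj(np.swapaxes(V, 1, 2))), fs=1.0,
                                 labels=("X", "Y"))
    ev = np.linalg.eigvalsh(S.values)
    if ev.min() < 1e-3:  # keep the draw comfortably minimum-phase
        pytest.skip("draw too close to singular")
    FW = sg.canonicalize(sg.factorize_wilson(S))
    FJ = sg.canonicalize(sg.factorize_jla(S))
    for k, Bk in enumerate(true_coeffs):
        np.testing.assert_allclose(FW.coeffs[k], Bk, atol=1e-5)
        np.testing.assert_allclose(FJ.coeffs[k], Bk, atol=1e-5)


class TestCanonicalize:
    def test_idempotent(self, coupled_factor_wilson):
        c1 = sg.canonicalize(coupled_factor_wilson)
        c2 = sg.canonicalize(c1)
        np.testing.assert_allclose(c1.coeffs, c2.coeffs, atol=1e-12)
        assert c1.canonical and c2.canonical

    @pytest.mark.parametrize("seed", [0, 1])
    def test_invariant_under_constant_unitary(self, coupled_factor_wilson, seed):
        Q = random_unitary(2, seed)
        rotated = dataclasses.replace(
            coupled_factor_wilson,
            coeffs=coupled_factor_wilson.coeffs @ Q,
            grid_values=coupled_factor_wilson.grid_values @ Q,
        )
        c0 = sg.canonicalize(coupled_factor_wilson)
        c1 = sg.canonicalize(rotated)
        assert np.max(np.abs(c0.coeffs - c1.coeffs)) < 1e-10

    def test_a0_lower_triangular_positive_diagonal(self, coupled_spectrum):
        F = sg.canonicalize(sg.factorize_jla(coupled_spectrum))
        A0 = F.A0
        assert abs(A0[0, 1]) < 1e-10
        assert A0[0, 0].real > 0 and A0[1, 1].real > 0
        assert abs(A0[0, 0].imag) < 1e-10 and abs(A0[1, 1].imag) < 1e-10

    def test_sigma_preserved(self, coupled_factor_wilson):
        before = coupled_factor_wilson.A0 @ np.conj(coupled_factor_wilson.A0.T)
        c = sg.canonicalize(coupled_factor_wilson)
        after = c.A0 @ np.conj(c.A0.T)
        np.testing.assert_allclose(before, after, atol=1e-12)


@pytest.mark.parametrize("backend", [sg.factorize_wilson, sg.factorize_jla])
def test_factor_contract_on_random_models(backend):
    """Reconstruction, analyticity and the Szego outerness identity hold on
    random stationary spectra for both backends."""
    for kind, A, cov in random_stationary_models(4, seed=99):
        S = model_spectrum(kind, A, cov, 256)
        F = backend(S)
        assert F.reconstruction_residual(S) < 1e-6
        assert F.analyticity_defect() < 1e-8
        assert F.szego_defect(S) < 1e-6


def test_factor_npz_round_trip(tmp_path, coupled_factor_wilson):
    p = tmp_path / "factor.npz"
    sg.save_factor(p, coupled_factor_wilson)
    F2 = sg.load_factor(p)
    np.testing.assert_array_equal(F2.coeffs, coupled_factor_wilson.coeffs)
    assert F2.backend == "wilson"
    assert F2.labels == coupled_factor_wilson.labels
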